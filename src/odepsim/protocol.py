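"""Discrete-event simulation of the light-pattern sorting protocol.

One sorting cycle (the chip's operating scheme): cells flow into the
junction isolation zone; when fluorescence detection sees a gated cancer
cell the flow is suspended (stop-flow batch); each gated cancer cell is
enclosed by a hollow-circle light image; a long light bar sweeps every
unenclosed cell to the channel side at 100 um/s; the circles then carry
their cargo into the side channel at 50 um/s; a relay bar repositions
collected cells toward the harvesting port.  A cell follows a moving
pattern iff the pattern speed does not exceed the cell's calibrated
maximum manipulation velocity (live cells are pulled at the attracting
edge, dead cells pushed ahead of it - both obey the same threshold);
otherwise the pattern passes over it and the escape is logged.

Purity = collected true-cancer / collected total; recovery = collected
true-cancer / spiked cancer.  With perfect gating and the default
speeds, every staged leukocyte stays in the main channel and purity is
100% by construction of the physics - which is the claim the simulation
reproduces as a property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .physics import (ForceModel, LightPattern, ODEPConfig,
                      class_max_velocity)
from .sample import CellRecord, SamplePopulation, stage_batch

__all__ = ["GatingRule", "ProtocolConfig", "SortRunResult", "gate_cells",
           "simulate_batch", "run_protocol", "compute_metrics"]


@dataclass(frozen=True)
class GatingRule:
    """Three-channel immunofluorescence gate.

    cancer:    EpCAM >= t_E  and  CD45 < t_C  and  Hoechst >= t_H
    leukocyte: CD45 >= t_C  and  EpCAM < t_E  and  Hoechst >= t_H
    anything else is unclassified and conservatively treated as a
    leukocyte for sweeping (never enclosed, never collected).
    """

    epcam_threshold: float = 100.0
    cd45_threshold: float = 100.0
    hoechst_threshold: float = 100.0

    def __post_init__(self):
        if min(self.epcam_threshold, self.cd45_threshold,
               self.hoechst_threshold) <= 0:
            raise ValidationError("gating thresholds must be positive")


@dataclass(frozen=True)
class ProtocolConfig:
    """Operating parameters of one sorting cycle."""

    sweep_speed: float = 100.0    # um/s, leukocyte-clearing bar
    circle_speed: float = 50.0    # um/s, cancer-cell transport circles
    relay_speed: float = 100.0    # um/s, in-side-channel relay bar
    voltage: float = 8.0
    bar: LightPattern = LightPattern(kind="bar", bandwidth=150.0)
    circle: LightPattern = LightPattern(kind="hollow_circle", bandwidth=40.0)
    batch_size: int = 30
    max_batches: int | None = None
    detection_miss_probability: float = 0.0
    collection_loss_probability: float = 0.0
    use_cell_radius: bool = False

    def __post_init__(self):
        if self.sweep_speed <= 0 or self.circle_speed <= 0 \
                or self.relay_speed <= 0:
            raise ValidationError("pattern speeds must be positive")
        if self.batch_size <= 0:
            raise ValidationError("batch_size must be positive")
        for p in (self.detection_miss_probability,
                  self.collection_loss_probability):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class SortRunResult:
    """Outcome of a full protocol run (the acceptance surface)."""

    collected_ids: list
    swept_ids: list
    escaped_events: list          # (cell id, pattern kind, phase)
    purity: float                 # fraction in [0, 1]; nan if undefined
    recovery: float
    n_batches: int
    event_log: list
    seed: int
    purity_defined: bool = True
    n_spiked_cancer: int = 0

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["purity"] = None if not self.purity_defined else self.purity
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def collected_frame(self, population: SamplePopulation) -> pd.DataFrame:
        by_id = {c.id: c for c in population.cells}
        rows = [by_id[i] for i in self.collected_ids]
        return pd.DataFrame(
            [{"id": c.id, "cell_type": c.cell_type,
              "viability": c.viability, "radius_um": c.radius}
             for c in rows])


def gate_cells(batch: list[CellRecord], rule: GatingRule) -> list[str]:
    """Label each cell 'cancer' / 'leukocyte' / 'unclassified'."""
    labels = []
    for c in batch:
        for name in ("epcam", "cd45", "hoechst"):
            val = getattr(c, name)
            if val is None or not np.isfinite(val):
                raise ValidationError(f"cell {c.id} missing {name} intensity")
        nucleated = c.hoechst >= rule.hoechst_threshold
        ep = c.epcam >= rule.epcam_threshold
        cd = c.cd45 >= rule.cd45_threshold
        if nucleated and ep and not cd:
            labels.append("cancer")
        elif nucleated and cd and not ep:
            labels.append("leukocyte")
        else:
            labels.append("unclassified")
    return labels


def _escape_speed(cell: CellRecord, pattern: LightPattern,
                  config: ODEPConfig, model: ForceModel,
                  use_cell_radius: bool) -> float:
    return class_max_velocity(cell.cell_type, cell.viability, cell.radius,
                              pattern, config, model,
                              use_cell_radius=use_cell_radius)


def simulate_batch(batch: list[CellRecord], labels: list[str],
                   protocol: ProtocolConfig, force_model: ForceModel,
                   flow=None, rng=None):
    """Run the stop-flow manipulation phases on one staged batch.

    Returns (dispositions, events): ``dispositions`` maps cell id to one
    of 'collected', 'swept', 'escaped'; ``events`` is the ordered phase
    log.  ``flow`` is accepted for interface symmetry: manipulation is a
    stop-flow phase, the carrier flow is suspended (zero field).
    """
    if force_model is None:
        raise ValidationError("calibrated force model required")
    odep = ODEPConfig(voltage=protocol.voltage)
    events = []
    disposition = {}
    enclosed = [c for c, lab in zip(batch, labels) if lab == "cancer"]
    others = [c for c, lab in zip(batch, labels) if lab != "cancer"]

    for c in enclosed:
        events.append((c.id, "hollow_circle", "enclose"))

    # phase VII: bar sweep of everything not enclosed
    for c in others:
        vmax = _escape_speed(c, protocol.bar, odep, force_model,
                             protocol.use_cell_radius)
        if protocol.sweep_speed <= vmax:
            disposition[c.id] = "swept"
            events.append((c.id, "bar", "sweep"))
        else:
            disposition[c.id] = "escaped"
            events.append((c.id, "bar", "escape_sweep"))

    # phase VIII: circle transport into the side channel
    for c in enclosed:
        vmax = _escape_speed(c, protocol.circle, odep, force_model,
                             protocol.use_cell_radius)
        if protocol.circle_speed <= vmax:
            if rng is not None and protocol.collection_loss_probability > 0 \
                    and rng.random() < protocol.collection_loss_probability:
                disposition[c.id] = "escaped"
                events.append((c.id, "hollow_circle", "lost_in_transfer"))
                continue
            disposition[c.id] = "collected"
            events.append((c.id, "hollow_circle", "collect"))
            # phase IX-X: relay repositioning inside the side channel;
            # lagging the relay does not revoke collection
            relay_vmax = _escape_speed(c, protocol.bar, odep, force_model,
                                       protocol.use_cell_radius)
            events.append((c.id, "bar",
                           "relay" if protocol.relay_speed <= relay_vmax
                           else "relay_lag"))
        else:
            disposition[c.id] = "escaped"
            events.append((c.id, "hollow_circle", "escape_circle"))
    return disposition, events


def run_protocol(population: SamplePopulation, protocol: ProtocolConfig,
                 rule: GatingRule, force_model: ForceModel, flow=None,
                 seed: int = 0,
                 zone: tuple[float, float] = (1000.0, 1000.0)
                 ) -> SortRunResult:
    """Iterate stage -> detect -> gate -> manipulate over the population.

    Batches without any detected cancer cell flow through to waste
    (recorded as swept); a batch with at least one gated cancer cell
    triggers stop-flow and the manipulation phases.
    """
    if force_model is None:
        raise ValidationError("calibrated force model required")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(population.cells))
    queue = [population.cells[i] for i in order]

    collected, swept, escaped = [], [], []
    event_log = []
    n_batches = 0
    while queue:
        if protocol.max_batches is not None \
                and n_batches >= protocol.max_batches:
            break
        batch_cells = queue[:protocol.batch_size]
        queue = queue[protocol.batch_size:]
        batch = stage_batch(batch_cells, zone,
                            seed=int(rng.integers(2 ** 31)))
        labels = gate_cells(batch, rule)
        if protocol.detection_miss_probability > 0:
            labels = ["unclassified" if lab == "cancer"
                      and rng.random() < protocol.detection_miss_probability
                      else lab for lab in labels]
        n_batches += 1
        if "cancer" not in labels:
            # no detection: flow is never suspended, batch passes to waste
            for c in batch:
                swept.append(c.id)
                event_log.append((c.id, "flow", "pass_through"))
            continue
        event_log.append((None, "flow", f"stop_flow_batch_{n_batches}"))
        disposition, events = simulate_batch(batch, labels, protocol,
                                             force_model, flow=flow, rng=rng)
        event_log.extend(events)
        for cid, d in disposition.items():
            {"collected": collected, "swept": swept,
             "escaped": escaped}[d].append(cid)

    by_id = {c.id: c for c in population.cells}
    n_true = sum(1 for i in collected if by_id[i].cell_type == "cancer")
    n_spiked = sum(1 for c in population.cells if c.cell_type == "cancer")
    purity_defined = len(collected) > 0
    purity = n_true / len(collected) if purity_defined else float("nan")
    recovery = n_true / n_spiked if n_spiked else 0.0
    esc_events = [e for e in event_log if str(e[2]).startswith("escape")]
    return SortRunResult(collected_ids=sorted(collected),
                         swept_ids=sorted(swept),
                         escaped_events=esc_events,
                         purity=purity, recovery=recovery,
                         n_batches=n_batches, event_log=event_log,
                         seed=seed, purity_defined=purity_defined,
                         n_spiked_cancer=n_spiked)


def compute_metrics(result: SortRunResult,
                    spiked_cancer: int | None = None) -> dict:
    """Purity and recovery on the 0-100% scale.

    Recovery uses the spiked (not staged) cancer count as denominator;
    purity is flagged undefined when nothing was collected.
    """
    spiked = result.n_spiked_cancer if spiked_cancer is None else spiked_cancer
    n_collected = len(result.collected_ids)
    if n_collected == 0:
        return {"purity_pct": float("nan"), "purity_defined": False,
                "recovery_pct": 0.0}
    n_true = round(result.purity * n_collected)
    recovery = 100.0 * n_true / spiked if spiked else 0.0
    return {"purity_pct": 100.0 * result.purity, "purity_defined": True,
            "recovery_pct": recovery}
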
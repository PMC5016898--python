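"""Synthetic cell populations for the spiking experiments.

Emulates the bench scenario: 500 PC-3 prostate-cancer cells spiked into
8 ml of blood (62.5 cells/ml) and carried through negative selection,
leaving ~1e4 background leukocytes.  Each cell carries a radius (cancer:
diameter 23 +/- 2.1 um; leukocyte: diameter ~10 um), a live/dead state,
and three fluorescence marker intensities - EpCAM (epithelial, cancer
positive), CD45 (pan-leukocyte) and Hoechst (nuclear, positive for every
nucleated cell).  Positive channels are log-normal with a 100:1 median
separation over background at default noise; a single ``overlap``
parameter widens the log-spread to stress the gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PlacementError, ValidationError

__all__ = ["CellRecord", "SamplePopulation", "IntensityParams",
           "generate_population", "stage_batch", "bayes_error",
           "DEFAULT_SPIKED_CANCER", "DEFAULT_LEUKOCYTES",
           "BLOOD_VOLUME_ML"]

DEFAULT_SPIKED_CANCER = 500
DEFAULT_LEUKOCYTES = 10_000
BLOOD_VOLUME_ML = 8.0

CANCER_RADIUS_MEAN = 11.5    # um (diameter 23)
CANCER_RADIUS_SD = 1.05      # um (diameter SD 2.1)
LEUKO_RADIUS_MEAN = 5.0
LEUKO_RADIUS_SD = 0.75
RADIUS_FLOOR = 2.5           # truncation: no cell below 5 um diameter


@dataclass(frozen=True)
class IntensityParams:
    """Log-normal marker intensity model (arbitrary units).

    ``positive_median``/``background_median`` set the 100:1 separation;
    ``sigma_log`` is the log-space spread; ``overlap`` >= 0 inflates the
    spread (0 = default noise, larger values push the channels together
    for stress tests).
    """

    positive_median: float = 1000.0
    background_median: float = 10.0
    sigma_log: float = 0.25
    overlap: float = 0.0

    def __post_init__(self):
        if self.positive_median <= self.background_median:
            raise ValidationError("positive median must exceed background")
        if self.sigma_log <= 0 or self.overlap < 0:
            raise ValidationError("sigma_log must be > 0 and overlap >= 0")

    @property
    def effective_sigma(self) -> float:
        return self.sigma_log * (1.0 + self.overlap)


@dataclass(frozen=True)
class CellRecord:
    """One cell staged for sorting."""

    id: int
    cell_type: str            # 'cancer' | 'leukocyte'
    viability: str            # 'live' | 'dead'
    radius: float             # um
    epcam: float
    cd45: float
    hoechst: float
    x: float = np.nan         # um, set when staged in the isolation zone
    y: float = np.nan

    @property
    def markers(self) -> tuple[float, float, float]:
        return (self.epcam, self.cd45, self.hoechst)


@dataclass
class SamplePopulation:
    cells: list[CellRecord]
    seed: int
    provenance: dict = dfield(default_factory=dict)

    def __len__(self):
        return len(self.cells)

    def counts(self) -> dict:
        out: dict = {}
        for c in self.cells:
            out[(c.cell_type, c.viability)] = out.get(
                (c.cell_type, c.viability), 0) + 1
        return out

    @property
    def cancer_per_ml(self) -> float:
        """Spiked cancer density in the blood-equivalent sample."""
        n = sum(1 for c in self.cells if c.cell_type == "cancer")
        return n / self.provenance.get("blood_volume_ml", BLOOD_VOLUME_ML)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.cells])


def _truncated_normal(rng, mean, sd, floor, size):
    """Normal(mean, sd) resampled until all draws exceed ``floor``."""
    out = rng.normal(mean, sd, size)
    bad = out <= floor
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= floor
    return out


def generate_population(n_cancer: int = DEFAULT_SPIKED_CANCER,
                        n_leukocyte: int = DEFAULT_LEUKOCYTES,
                        live_fraction_cancer: float = 0.9,
                        live_fraction_leuko: float = 0.9,
                        intensity_params: IntensityParams | None = None,
                        seed: int = 0,
                        blood_volume_ml: float = BLOOD_VOLUME_ML,
                        ) -> SamplePopulation:
    """Draw a seeded synthetic population.

    Radii: truncated normals matching the printed cancer-cell size
    distribution; markers: log-normal positive/background channels;
    Hoechst positive for every cell (all are nucleated).  Regeneration
    with identical arguments is bit-identical.
    """
    if n_cancer < 0 or n_leukocyte < 0:
        raise ValidationError("cell counts must be non-negative")
    for f in (live_fraction_cancer, live_fraction_leuko):
        if not (0.0 <= f <= 1.0):
            raise ValidationError("live fractions must lie in [0, 1]")
    ip = intensity_params or IntensityParams()
    rng = np.random.default_rng(seed)
    sig = ip.effective_sigma
    mu_pos, mu_bg = np.log(ip.positive_median), np.log(ip.background_median)

    cells = []
    cid = 0
    for ctype, n, live_frac, r_mean, r_sd in (
            ("cancer", n_cancer, live_fraction_cancer,
             CANCER_RADIUS_MEAN, CANCER_RADIUS_SD),
            ("leukocyte", n_leukocyte, live_fraction_leuko,
             LEUKO_RADIUS_MEAN, LEUKO_RADIUS_SD)):
        if n == 0:
            continue
        radii = _truncated_normal(rng, r_mean, r_sd, RADIUS_FLOOR, n)
        live = rng.random(n) < live_frac
        ep_mu = mu_pos if ctype == "cancer" else mu_bg
        cd_mu = mu_bg if ctype == "cancer" else mu_pos
        epcam = rng.lognormal(ep_mu, sig, n)
        cd45 = rng.lognormal(cd_mu, sig, n)
        hoechst = rng.lognormal(mu_pos, sig, n)
        for k in range(n):
            cells.append(CellRecord(
                id=cid, cell_type=ctype,
                viability="live" if live[k] else "dead",
                radius=float(radii[k]), epcam=float(epcam[k]),
                cd45=float(cd45[k]), hoechst=float(hoechst[k])))
            cid += 1

    prov = dict(n_cancer=n_cancer, n_leukocyte=n_leukocyte,
                live_fraction_cancer=live_fraction_cancer,
                live_fraction_leuko=live_fraction_leuko,
                intensity_params=asdict(ip), seed=seed,
                blood_volume_ml=blood_volume_ml)
    return SamplePopulation(cells=cells, seed=seed, provenance=prov)


def bayes_error(params: IntensityParams) -> float:
    """Bayes error of the one-channel positive-vs-background decision at
    the optimal (geometric-midpoint) threshold, under the log-normal
    model.  At default noise this is ~1e-19, so perfect gating of the
    synthetic sample is expected; it grows with ``overlap``."""
    sig = params.effective_sigma
    d = (np.log(params.positive_median)
         - np.log(params.background_median)) / 2.0
    return float(stats.norm.sf(d / sig))


def stage_batch(cells: list[CellRecord], zone: tuple[float, float],
                seed: int, max_retries: int = 200) -> list[CellRecord]:
    """Place a batch of cells uniformly in the isolation zone with
    non-overlapping positions (centre gap of at least one cell radius
    beyond contact).  Raises :class:`PlacementError` when the zone is
    too crowded to place a cell within ``max_retries`` draws.
    """
    Lx, Ly = zone
    if Lx <= 0 or Ly <= 0:
        raise ValidationError("zone dimensions must be positive")
    # close-packing guard: padded disc area vs zone area
    padded = sum(np.pi * (1.5 * c.radius) ** 2 for c in cells)
    if padded > 0.55 * Lx * Ly:
        raise PlacementError(
            f"batch of {len(cells)} cells exceeds the packing capacity of "
            f"the {Lx} x {Ly} um zone")
    rng = np.random.default_rng(seed)
    placed: list[CellRecord] = []
    px = np.empty(len(cells))
    py = np.empty(len(cells))
    pr = np.empty(len(cells))
    for k, c in enumerate(cells):
        r = c.radius
        for attempt in range(max_retries):
            x = rng.uniform(r, Lx - r) - Lx / 2.0
            y = rng.uniform(r, Ly - r) - Ly
            if k == 0:
                break
            d2 = (px[:k] - x) ** 2 + (py[:k] - y) ** 2
            gap = pr[:k] + r + np.maximum(pr[:k], r)
            if np.all(d2 >= gap ** 2):
                break
        else:
            raise PlacementError(
                f"could not place cell {c.id} after {max_retries} retries")
        px[k], py[k], pr[k] = x, y, r
        placed.append(CellRecord(**{**asdict(c), "x": x, "y": y}))
    return placed
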
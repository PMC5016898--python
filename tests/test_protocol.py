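import numpy as np
import pytest

import odepsim as o
from odepsim.errors import ValidationError
from odepsim.sample import CellRecord


def make_cell(cid=0, epcam=10.0, cd45=10.0, hoechst=1000.0,
              cell_type="leukocyte", viability="live", radius=5.0):
    return CellRecord(id=cid, cell_type=cell_type, viability=viability,
                      radius=radius, epcam=epcam, cd45=cd45, hoechst=hoechst)


class TestGating:
    rule = o.GatingRule()

    def test_three_channel_contradistinction(self):
        cancer = make_cell(epcam=1000, cd45=10, hoechst=1000)
        leuko = make_cell(epcam=10, cd45=1000, hoechst=1000)
        ambiguous = make_cell(epcam=10, cd45=10, hoechst=10)
        double = make_cell(epcam=1000, cd45=1000, hoechst=1000)
        anucleate = make_cell(epcam=1000, cd45=10, hoechst=10)
        labels = o.gate_cells([cancer, leuko, ambiguous, double, anucleate],
                              self.rule)
        assert labels == ["cancer", "leukocyte", "unclassified",
                          "unclassified", "unclassified"]

    def test_missing_channel_rejected(self):
        bad = make_cell(epcam=float("nan"))
        with pytest.raises(ValidationError):
            o.gate_cells([bad], self.rule)

    def test_synthetic_population_gates_perfectly(self, default_population):
        """At default noise, 10500 synthetic cells are all classified
        to their true type (exhaustive check)."""
        labels = o.gate_cells(default_population.cells, self.rule)
        truth = [c.cell_type for c in default_population.cells]
        assert labels == truth


class TestEscapeRule:
    def test_default_sweep_carries_all_leukocytes(self, force_model):
        bar = o.LightPattern(kind="bar", bandwidth=150.0)
        cfg = o.ODEPConfig(voltage=8.0)
        for viability in ("live", "dead"):
            v = o.class_max_velocity("leukocyte", viability, 5.0, bar, cfg,
                                     force_model)
            assert v >= 100.0

    def test_fast_sweep_loses_exactly_dead_leukocytes(self, force_model,
                                                      small_population):
        """At 150 um/s the bar outruns the dead leukocytes (max 115.57)
        but not the live ones (max 250.49)."""
        proto = o.ProtocolConfig(sweep_speed=150.0)
        res = o.run_protocol(small_population, proto, o.GatingRule(),
                             force_model, seed=3)
        by_id = {c.id: c for c in small_population.cells}
        escaped = {e[0] for e in res.escaped_events}
        dead_leukos = {c.id for c in small_population.cells
                       if c.cell_type == "leukocyte"
                       and c.viability == "dead"}
        # escapes only happen in batches that triggered stop-flow, so
        # every escape is a dead leukocyte and no live cell ever escapes
        assert escaped <= dead_leukos
        assert escaped, "some dead leukocytes must have been staged"
        swept_types = {(by_id[i].cell_type, by_id[i].viability)
                       for i in res.swept_ids}
        assert ("leukocyte", "dead") in swept_types  # pass-through batches

    def test_circle_carries_both_viabilities(self, force_model):
        circ = o.LightPattern(kind="hollow_circle", bandwidth=40.0)
        cfg = o.ODEPConfig(voltage=8.0)
        for viability in ("live", "dead"):
            v = o.class_max_velocity("cancer", viability, 11.5, circ, cfg,
                                     force_model)
            assert v >= 50.0


class TestRunProtocol:
    def test_default_run_reaches_full_purity(self, small_population,
                                             force_model):
        res = o.run_protocol(small_population, o.ProtocolConfig(),
                             o.GatingRule(), force_model, seed=1)
        m = o.compute_metrics(res)
        assert m["purity_pct"] == 100.0
        assert m["recovery_pct"] == 100.0

    def test_conservation_partition(self, small_population, force_model):
        """Every staged cell ends in exactly one of collected / swept /
        escaped-in-place."""
        res = o.run_protocol(small_population,
                             o.ProtocolConfig(sweep_speed=150.0),
                             o.GatingRule(), force_model, seed=5)
        collected = set(res.collected_ids)
        swept = set(res.swept_ids)
        escaped = {e[0] for e in res.escaped_events}
        assert collected & swept == set()
        assert collected & escaped == set()
        assert swept & escaped == set()
        assert collected | swept | escaped \
            == {c.id for c in small_population.cells}

    def test_zero_cancer_population_flags_undefined_purity(self,
                                                           force_model):
        pop = o.generate_population(n_cancer=0, n_leukocyte=300, seed=2)
        res = o.run_protocol(pop, o.ProtocolConfig(), o.GatingRule(),
                             force_model, seed=2)
        assert res.collected_ids == []
        assert not res.purity_defined
        m = o.compute_metrics(res)
        assert np.isnan(m["purity_pct"])
        assert m["recovery_pct"] == 0.0
        # no batch ever triggered stop-flow
        assert not any("stop_flow" in str(e[2]) for e in res.event_log)

    def test_forced_misclassification_purity_identity(self, force_model):
        """Thresholds forced to misclassify k leukocytes as cancer give
        purity C/(C+k) - the accounting identity checked by count."""
        pop = o.generate_population(n_cancer=40, n_leukocyte=400, seed=13)
        # disable the CD45 veto and set the EpCAM cut inside the
        # leukocyte background distribution
        rule = o.GatingRule(epcam_threshold=12.0, cd45_threshold=1e12)
        labels = o.gate_cells(pop.cells, rule)
        k = sum(1 for lab, c in zip(labels, pop.cells)
                if lab == "cancer" and c.cell_type == "leukocyte")
        assert k > 0
        res = o.run_protocol(pop, o.ProtocolConfig(), rule, force_model,
                             seed=4)
        C = sum(1 for i in res.collected_ids
                if next(c for c in pop.cells if c.id == i).cell_type
                == "cancer")
        assert res.purity == pytest.approx(C / (C + k))

    def test_determinism_of_serialised_result(self, small_population,
                                              force_model):
        r1 = o.run_protocol(small_population, o.ProtocolConfig(),
                            o.GatingRule(), force_model, seed=17)
        r2 = o.run_protocol(small_population, o.ProtocolConfig(),
                            o.GatingRule(), force_model, seed=17)
        assert r1.to_json() == r2.to_json()

    def test_overlap_noise_never_improves_purity(self, force_model):
        """Expected purity is non-increasing along a marker-overlap
        ladder (two seeds per rung, lenient gating so contamination can
        actually happen)."""
        rule = o.GatingRule(epcam_threshold=50.0, cd45_threshold=1e12)
        mean_purity = []
        for overlap in (0.0, 4.0, 9.0):
            ps = []
            for seed in (0, 1):
                pop = o.generate_population(
                    n_cancer=40, n_leukocyte=400,
                    intensity_params=o.IntensityParams(overlap=overlap),
                    seed=seed)
                res = o.run_protocol(pop, o.ProtocolConfig(), rule,
                                     force_model, seed=seed)
                if res.purity_defined:
                    ps.append(res.purity)
            mean_purity.append(np.mean(ps))
        assert mean_purity[0] >= mean_purity[1] >= mean_purity[2]

    def test_uncalibrated_model_rejected(self, small_population):
        with pytest.raises(ValidationError):
            o.run_protocol(small_population, o.ProtocolConfig(),
                           o.GatingRule(), None, seed=0)


class TestMetrics:
    def test_formulas_on_known_counts(self, force_model):
        pop = o.generate_population(n_cancer=10, n_leukocyte=100, seed=21)
        res = o.run_protocol(pop, o.ProtocolConfig(), o.GatingRule(),
                             force_model, seed=21)
        m = o.compute_metrics(res, spiked_cancer=500)
        assert m["purity_pct"] == 100.0
        assert m["recovery_pct"] == pytest.approx(100.0 * 10 / 500)

    def test_collection_loss_reduces_recovery_not_purity(self, force_model):
        pop = o.generate_population(n_cancer=200, n_leukocyte=200, seed=8)
        proto = o.ProtocolConfig(collection_loss_probability=0.5)
        res = o.run_protocol(pop, proto, o.GatingRule(), force_model,
                             seed=8)
        m = o.compute_metrics(res)
        assert m["purity_pct"] == 100.0
        assert 20.0 < m["recovery_pct"] < 80.0
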
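"""Path-model components: outcome models, stepwise selection, diagrams."""

import numpy as np
import pandas as pd
import pytest

from qmpipe import profiling
from qmpipe.benchmarks import _mediation_config
from qmpipe.mediation import (
    outcome_exposure_model,
    run_mediation,
    select_mediator_taxa,
    standardized_log_abundance,
    variance_explained,
)
from qmpipe.simulate import simulate_cohort


def _noise_taxa(rng, n, k):
    return pd.DataFrame(rng.normal(0, 1, (n, k)),
                        columns=[f"Tax{j:02d}" for j in range(k)],
                        index=[f"s{i}" for i in range(n)])


class TestVarianceExplained:
    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        n = 80
        Z = _noise_taxa(rng, n, 10)
        y = pd.Series(5 + 2 * Z["Tax00"] + rng.normal(0, 1, n), index=Z.index)
        m1 = select_mediator_taxa(y, Z, family="gaussian")
        m2 = select_mediator_taxa(3.0 * y + 7.0, Z, family="gaussian")
        assert m1.selected == m2.selected
        assert m1.variance_explained == pytest.approx(m2.variance_explained,
                                                      abs=1e-10)

    def test_exact_linear_outcome_explained_fully(self):
        rng = np.random.default_rng(1)
        Z = _noise_taxa(rng, 50, 8)
        y = pd.Series(10 + 4 * Z["Tax03"], index=Z.index)
        m = select_mediator_taxa(y, Z, family="gaussian")
        assert "Tax03" in m.selected
        assert m.variance_explained == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_zero(self):
        assert variance_explained(np.ones(5), np.arange(5.0)) == 0.0


class TestStepwise:
    def test_planted_mediator_selected(self):
        rng = np.random.default_rng(2)
        n = 60
        Z = _noise_taxa(rng, n, 20)
        mu = 4 * np.exp(-0.4 * Z["Tax05"].to_numpy())
        y = pd.Series(rng.poisson(rng.gamma(8, mu / 8)), index=Z.index)
        m = select_mediator_taxa(y, Z)
        assert "Tax05" in m.selected

    def test_pure_noise_keeps_model_small(self):
        rng = np.random.default_rng(3)
        ves = []
        for _ in range(10):
            Z = _noise_taxa(rng, 60, 50)
            y = pd.Series(rng.poisson(rng.gamma(8, 4 / 8, 60)), index=Z.index)
            ves.append(select_mediator_taxa(y, Z).variance_explained)
        assert np.median(ves) <= 0.15

    def test_no_improvement_gives_empty_set(self):
        rng = np.random.default_rng(4)
        Z = _noise_taxa(rng, 40, 3)
        y = pd.Series(rng.poisson(4.0, 40), index=Z.index)
        m = select_mediator_taxa(y, Z)
        if not m.selected:
            assert m.variance_explained == 0.0

    def test_model_size_cap_respected(self):
        rng = np.random.default_rng(5)
        n = 60
        Z = _noise_taxa(rng, n, 30)
        eta = 0.3 * Z.iloc[:, :10].sum(axis=1)
        y = pd.Series(rng.poisson(np.exp(1.2 + eta.to_numpy())), index=Z.index)
        m = select_mediator_taxa(y, Z)
        assert len(m.selected) <= n // 10

    def test_selection_deterministic(self):
        rng = np.random.default_rng(6)
        Z = _noise_taxa(rng, 60, 15)
        mu = 4 * np.exp(0.5 * Z["Tax01"].to_numpy())
        y = pd.Series(rng.poisson(mu), index=Z.index)
        assert (select_mediator_taxa(y, Z).selected
                == select_mediator_taxa(y, Z).selected)


class TestOutcomeModels:
    def test_constant_outcome_rejected(self, small_sim):
        wb = small_sim.wellbeing.copy()
        wb["defecation_rate"] = 4
        with pytest.raises(ValueError, match="constant"):
            outcome_exposure_model(wb, small_sim.metadata,
                                   "defecation_rate", 4.0)

    def test_exposure_terms_reported(self, small_sim):
        m = outcome_exposure_model(small_sim.wellbeing, small_sim.metadata,
                                   "defecation_rate", 4.0)
        assert {"CS", "cephalosporin", "penicillin"} <= set(m.terms)
        for term in m.terms.values():
            assert 0 <= term["p"] <= 1


class TestPathAssembly:
    def test_planted_chain_recovered_and_mediated(self):
        sim = simulate_cohort(_mediation_config(21, beta_taxon=-0.5,
                                                beta_direct=0.05,
                                                exposure_log_fc=-2.0))
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                          sim.copy_numbers, sim.taxonomy)
        res = run_mediation(prof.cells, sim.metadata, sim.wellbeing,
                            "defecation_rate", 4.0)
        names = [m["taxon"] for m in res.mediators]
        assert "Bacteroides" in names
        assert any(e["taxon"] == "Bacteroides" for e in res.exposure_edges)
        assert 0 <= res.variance_explained <= 1

    def test_direct_only_effect_not_mediated(self):
        # outcome responds to exposure but no taxon carries the signal
        sim = simulate_cohort(_mediation_config(22, beta_taxon=0.0,
                                                beta_direct=0.6,
                                                exposure_log_fc=0.0))
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                          sim.copy_numbers, sim.taxonomy)
        res = run_mediation(prof.cells, sim.metadata, sim.wellbeing,
                            "defecation_rate", 4.0)
        assert res.mediation.get("CS") in ("direct", "none")
        assert res.mediation.get("CS") != "mediated" or res.mediators

    def test_empty_mediator_set_empty_edges(self):
        sim = simulate_cohort(_mediation_config(23, beta_taxon=0.0,
                                                beta_direct=0.0,
                                                exposure_log_fc=0.0))
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                          sim.copy_numbers, sim.taxonomy)
        res = run_mediation(prof.cells, sim.metadata, sim.wellbeing,
                            "defecation_rate", 4.0)
        if not res.mediators:
            assert res.exposure_edges == []
            assert res.variance_explained == 0.0

    def test_json_serializable(self):
        sim = simulate_cohort(_mediation_config(24, beta_taxon=-0.4,
                                                beta_direct=0.05,
                                                exposure_log_fc=-1.5))
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                          sim.copy_numbers, sim.taxonomy)
        res = run_mediation(prof.cells, sim.metadata, sim.wellbeing,
                            "defecation_rate", 4.0)
        import json

        parsed = json.loads(res.to_json())
        assert parsed["outcome"] == "defecation_rate"


def test_standardized_log_abundance_unit_scale(small_sim):
    prof = profiling.relative_abundance(small_sim.counts) * 1e4
    Z = standardized_log_abundance(prof)
    np.testing.assert_allclose(Z.mean(), 0, atol=1e-9)
    keep = Z.std(ddof=0) > 0
    np.testing.assert_allclose(Z.std(ddof=0)[keep], 1, atol=1e-9)
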
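"""Validation experiments on synthetic cohorts with planted ground truth.

Each function runs the real pipeline modules on generated data and returns
plain numbers: recovery power, empirical false-discovery proportions, oracle
agreement errors, masking fractions.  They are shared between the test suite
and the reproduction script so both report the same computations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from qmpipe import datasets, ordination, profiling
from qmpipe.cohort import assign_study_groups
from qmpipe.da import fdr_adjust, run_differential_abundance
from qmpipe.mediation import run_mediation
from qmpipe.simulate import (
    GroupEffect,
    MediationEffect,
    SimConfig,
    simulate_cohort,
    simulate_discordant_taxon,
)

EXPOSURE_GROUPS = ("VD-cep", "VD-pen", "CS-cep", "CS-other")


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# cohort construction from the printed intake table


def group_sizes_from_records(subset: str = "full") -> dict[str, int]:
    """Apply the study-group rule to the bundled delivery records."""
    rec = datasets.exposure_records(subset=subset)
    groups = assign_study_groups(rec)
    return groups.value_counts().to_dict()


# ---------------------------------------------------------------------------
# QMP conservation


def conservation_error(seed: int = 0) -> float:
    """Max relative error of per-sample copy sums vs the qPCR load."""
    sim = simulate_cohort(SimConfig(seed=seed))
    prof = profiling.absolute_profile(sim.counts, sim.qpcr, sim.copy_numbers,
                                      sim.taxonomy)
    load = sim.qpcr.loc[prof.copies.index, "copies_per_g"]
    return float((prof.copies.sum(axis=1) / load - 1.0).abs().max())


def profile_recovery_error(seed: int = 0) -> float:
    """Median relative error of estimated cells/g vs true cells/g.

    Restricted to taxa contributing at least 1% of reads in a sample so the
    comparison reflects quantification error, not multinomial sampling of
    rare taxa.
    """
    sim = simulate_cohort(SimConfig(seed=seed))
    rel = profiling.relative_abundance(sim.counts)
    prof = profiling.absolute_profile(sim.counts, sim.qpcr, sim.copy_numbers,
                                      sim.taxonomy)
    truth = sim.truth.cells
    common = [t for t in truth.columns if t in prof.cells.columns]
    est = prof.cells[common]
    tru = truth.loc[est.index, common]
    mask = rel.loc[est.index, common] >= 0.01
    err = ((est - tru).abs() / tru)[mask]
    return float(np.nanmedian(err.to_numpy()))


# ---------------------------------------------------------------------------
# relative-vs-absolute discordance


def discordance_slopes(seed: int = 0, taxon: str = "Escherichia") -> dict[str, float]:
    """Fitted age slopes of one taxon on the relative and absolute scales.

    The taxon is pinned to a flat absolute trajectory while the total load
    rises, so the estimated relative slope should be negative and the
    absolute slope non-negative (opposite or null trend).
    """
    sim = simulate_discordant_taxon(SimConfig(seed=seed), taxon)
    rel = profiling.relative_abundance(sim.counts)
    prof = profiling.absolute_profile(sim.counts, sim.qpcr, sim.copy_numbers,
                                      sim.taxonomy)
    # scale proportions so the log-slope comparison is unit-free
    meta = sim.metadata
    return {
        "relative_slope": ordination.age_slope(rel * 1e4, meta, taxon),
        "absolute_slope": ordination.age_slope(prof.cells, meta, taxon),
    }


# ---------------------------------------------------------------------------
# differential-abundance power and error control


def _power_config(seed: int, n_per_group: int, log_fc: float,
                  taxon: str = "Bacteroides") -> SimConfig:
    return SimConfig(
        n_infants_per_group={g: n_per_group for g in
                             ("VD", "VD-cep", "VD-pen", "CS-cep", "CS-other")},
        timepoints=(4,),
        group_effects=(GroupEffect(taxon, "CS-cep", (4, 4), log_fc),),
        mediation_spec=(),
        seed=seed,
    )


def da_power(seed: int = 0, n_reps: int = 50, n_per_group: int = 25,
             log_fc: float = 1.5, taxon: str = "Bacteroides") -> float:
    """Fraction of replicates flagging the planted taxon at FDR < 0.1."""
    hits = 0
    for r in range(n_reps):
        sim = simulate_cohort(_power_config(_child_seed(seed, r), n_per_group, log_fc))
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                         sim.copy_numbers, sim.taxonomy)
        res = run_differential_abundance(
            prof.cells, sim.metadata, timepoints=[4.0],
            covariates=("breastfeeding", "probiotics"))
        row = res[(res["taxon"] == taxon) & (res["contrast"] == "CS-cep")]
        if len(row) and bool(row["significant"].iloc[0]):
            hits += 1
    return hits / n_reps


def da_null_fdr(seed: int = 0, n_reps: int = 200, n_taxa: int = 500,
                n_per_group: int = 10) -> float:
    """Empirical FDR (mean V / max(R, 1)) under a global null.

    All group effects and mediation effects are zero, so every discovery at
    the FDR < 0.1 gate is false.  The false-discovery proportion is measured
    per correction family (one timepoint x contrast, the unit at which
    Benjamini-Hochberg operates) and averaged over families and replicates.
    """
    fdp = []
    for r in range(n_reps):
        cfg = SimConfig(
            n_infants_per_group={g: n_per_group for g in
                                 ("VD", "VD-cep", "VD-pen", "CS-cep", "CS-other")},
            timepoints=(4,), n_taxa=n_taxa, group_effects=(),
            mediation_spec=(), seed=_child_seed(seed, 1000 + r),
        )
        sim = simulate_cohort(cfg)
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                         sim.copy_numbers, sim.taxonomy)
        res = run_differential_abundance(prof.cells, sim.metadata,
                                         timepoints=[4.0], covariates=())
        for _, fam in res.groupby(["timepoint", "contrast"]):
            n_disc = int(fam["significant"].sum())
            fdp.append(1.0 if n_disc else 0.0)
    return float(np.mean(fdp))


def fold_change_recovery(seed: int = 0, n_reps: int = 50, n_per_group: int = 30,
                         fold: float = 18.0, taxon: str = "Bifidobacterium"
                         ) -> float:
    """Fraction of replicates whose estimated fold change is within [fold/2, 2*fold]."""
    ok = 0
    for r in range(n_reps):
        sim = simulate_cohort(_power_config(_child_seed(seed, 2000 + r),
                                            n_per_group, float(np.log(fold)),
                                            taxon=taxon))
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                         sim.copy_numbers, sim.taxonomy)
        res = run_differential_abundance(prof.cells, sim.metadata,
                                         timepoints=[4.0], covariates=())
        row = res[(res["taxon"] == taxon) & (res["contrast"] == "CS-cep")]
        if len(row) and fold / 2 <= float(row["fold_change"].iloc[0]) <= fold * 2:
            ok += 1
    return ok / n_reps


def bh_agreement(seed: int = 0, n_vectors: int = 1000, size: int = 50) -> float:
    """Max |q - brute-force BH q| over random P-value vectors (0 = exact)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(size)
        df = pd.DataFrame({"p": p, "timepoint": 4.0, "contrast": "g"})
        q = fdr_adjust(df)["q"].to_numpy()
        # brute-force step-up: q_(i) = min over j >= i of p_(j) * m / j
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_bf = np.minimum.accumulate(q_sorted[::-1])[::-1].clip(max=1.0)
        q_ref = np.empty(m)
        q_ref[order] = q_bf
        worst = max(worst, float(np.abs(q - q_ref).max()))
    return worst


# ---------------------------------------------------------------------------
# compositional masking


_MASKING_TAXA = ("Bacteroides", "Escherichia", "Veillonella", "Streptococcus",
                 "Klebsiella", "Staphylococcus", "Enterococcus", "Lactobacillus",
                 "Blautia", "Parabacteroides")


def masking_fractions(seed: int = 0, n_per_group: int = 25,
                      log_fc: float = 1.5) -> dict[str, float]:
    """Discovery counts for 10 absolutely-increased taxa: absolute vs proportions.

    The ten planted taxa jointly dominate the community, so the exposed
    group's total load rises and proportion-scale fold changes shrink toward
    one: the compositional masking effect.
    """
    effects = tuple(GroupEffect(t, "CS-cep", (4, 4), log_fc) for t in _MASKING_TAXA)
    cfg = SimConfig(
        n_infants_per_group={g: n_per_group for g in
                             ("VD", "VD-cep", "VD-pen", "CS-cep", "CS-other")},
        timepoints=(4,), group_effects=effects, mediation_spec=(), seed=seed,
    )
    sim = simulate_cohort(cfg)
    prof = profiling.absolute_profile(sim.counts, sim.qpcr, sim.copy_numbers,
                                      sim.taxonomy)
    rel = profiling.relative_abundance(sim.counts)

    def hits(matrix: pd.DataFrame) -> int:
        res = run_differential_abundance(matrix, sim.metadata, timepoints=[4.0],
                                         covariates=())
        sub = res[(res["contrast"] == "CS-cep") & res["taxon"].isin(_MASKING_TAXA)]
        up = sub[(sub["fold_change"] > 1)]
        return int(up["significant"].sum())

    n_abs = hits(prof.cells)
    n_rel = hits(rel * 25000)  # proportions on a common read scale
    return {"absolute_hits": n_abs, "relative_hits": n_rel,
            "lost_fraction": (n_abs - n_rel) / n_abs if n_abs else np.nan}


# ---------------------------------------------------------------------------
# ordination oracles


def pcoa_distance_error(seed: int = 0, n_samples: int = 5, n_taxa: int = 8) -> float:
    """Max |distance - brute-force (1 - Pearson r)| on a random matrix."""
    rng = np.random.default_rng(seed)
    prof = pd.DataFrame(rng.gamma(2, 100, size=(n_samples, n_taxa)),
                        index=[f"s{i}" for i in range(n_samples)],
                        columns=[f"t{j}" for j in range(n_taxa)])
    dm, _ = ordination.pearson_log_distance(prof)
    logx = np.log10(prof.to_numpy() + 1.0)
    worst = 0.0
    for i in range(n_samples):
        for j in range(n_samples):
            r = stats.pearsonr(logx[i], logx[j]).statistic if i != j else 1.0
            worst = max(worst, abs(dm[prof.index[i], prof.index[j]] - (1 - r)))
    return float(worst)


def separation_pvalue(seed: int = 0, n_per_group: int = 25,
                      log_fc: float = 2.5) -> float:
    """ANOVA P on PC1 for a strong planted group separation at week 4."""
    effects = tuple(GroupEffect(t, g, (4, 4), s * log_fc)
                    for g in ("CS-cep", "CS-other")
                    for t, s in (("Bacteroides", -1), ("Bifidobacterium", -1),
                                 ("Staphylococcus", 1), ("Streptococcus", 1),
                                 ("Enterococcus", 1)))
    cfg = SimConfig(
        n_infants_per_group={"VD": n_per_group, "VD-cep": 3, "VD-pen": 3,
                             "CS-cep": n_per_group, "CS-other": n_per_group},
        timepoints=(4,), group_effects=effects, mediation_spec=(), seed=seed,
    )
    sim = simulate_cohort(cfg)
    prof = profiling.absolute_profile(sim.counts, sim.qpcr, sim.copy_numbers,
                                      sim.taxonomy)
    ordn = ordination.pcoa_pearson(prof.cells)
    p = ordination.test_group_separation(ordn, sim.metadata, 4.0)
    return float(p["PC1"])


def shuffle_uniformity(seed: int = 0, n_shuffles: int = 200) -> float:
    """KS-test P of per-shuffle ANOVA P values against Uniform(0, 1)."""
    cfg = SimConfig(
        n_infants_per_group={g: 12 for g in
                             ("VD", "VD-cep", "VD-pen", "CS-cep", "CS-other")},
        timepoints=(4,), group_effects=(), mediation_spec=(), seed=seed,
    )
    sim = simulate_cohort(cfg)
    prof = profiling.absolute_profile(sim.counts, sim.qpcr, sim.copy_numbers,
                                      sim.taxonomy)
    ordn = ordination.pcoa_pearson(prof.cells)
    rng = np.random.default_rng(seed + 1)
    meta = sim.metadata.copy()
    pvals = []
    for _ in range(n_shuffles):
        meta["group"] = rng.permutation(meta["group"].to_numpy())
        pvals.append(ordination.test_group_separation(ordn, meta, 4.0)["PC1"])
    return float(stats.kstest(pvals, "uniform").pvalue)


# ---------------------------------------------------------------------------
# mediation recovery


def _mediation_config(seed: int, beta_taxon: float, beta_direct: float,
                      exposure_log_fc: float,
                      mediator: str = "Bacteroides") -> SimConfig:
    spec = ()
    if beta_taxon or beta_direct:
        spec = (MediationEffect("defecation_rate", "birth_mode", "CS", mediator,
                                beta_taxon, beta_direct, 8.0),)
    effects = ()
    if exposure_log_fc:
        effects = (GroupEffect(mediator, "CS-cep", (4, 4), exposure_log_fc),
                   GroupEffect(mediator, "CS-other", (4, 4), exposure_log_fc))
    return SimConfig(
        n_infants_per_group={"VD": 20, "VD-cep": 10, "VD-pen": 10,
                             "CS-cep": 10, "CS-other": 10},
        timepoints=(4,), group_effects=effects, mediation_spec=spec, seed=seed,
    )


def mediation_recovery(seed: int = 0, n_reps: int = 50,
                       beta_taxon: float = -0.40,
                       exposure_log_fc: float = -1.5) -> dict[str, float]:
    """Planted exposure -> taxon -> outcome chain at n = 60.

    Reports the mediator-selection rate, the mean |variance-explained error|
    against the per-replicate planted truth, and the rate at which the full
    two-edge path is recovered.
    """
    selected, ve_err, full_path = 0, [], 0
    for r in range(n_reps):
        cfg = _mediation_config(_child_seed(seed, 3000 + r), beta_taxon, 0.05,
                                exposure_log_fc)
        sim = simulate_cohort(cfg)
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                         sim.copy_numbers, sim.taxonomy)
        res = run_mediation(prof.cells, sim.metadata, sim.wellbeing,
                            "defecation_rate", 4.0)
        names = [m["taxon"] for m in res.mediators]
        if "Bacteroides" in names:
            selected += 1
            if any(e["taxon"] == "Bacteroides" for e in res.exposure_edges):
                full_path += 1
        truth_mu = sim.truth.outcome_mean.loc[sim.metadata.index, "defecation_rate"]
        obs = sim.wellbeing.loc[sim.metadata.index, "defecation_rate"]
        ok = truth_mu.notna() & obs.notna()
        r2_true = float(np.corrcoef(truth_mu[ok], obs[ok])[0, 1] ** 2)
        ve_err.append(abs(res.variance_explained - r2_true))
    return {"selection_rate": selected / n_reps,
            "full_path_rate": full_path / n_reps,
            "mean_ve_error": float(np.mean(ve_err))}


def mediation_null(seed: int = 0, n_reps: int = 50, n_taxa: int = 50
                   ) -> dict[str, float]:
    """Pure-noise mediation scenario: no exposure or taxon effects anywhere.

    A spurious full-path discovery is a replicate where some exposure term is
    labeled mediated and the mediator carries an exposure edge.
    """
    ves, spurious = [], 0
    for r in range(n_reps):
        cfg = _mediation_config(_child_seed(seed, 4000 + r), 0.0, 0.0, 0.0)
        cfg = SimConfig(**{**cfg.__dict__, "n_taxa": n_taxa})
        sim = simulate_cohort(cfg)
        prof = profiling.absolute_profile(sim.counts, sim.qpcr,
                                         sim.copy_numbers, sim.taxonomy)
        res = run_mediation(prof.cells, sim.metadata, sim.wellbeing,
                            "defecation_rate", 4.0)
        ves.append(res.variance_explained)
        mediated_levels = {k for k, v in res.mediation.items() if v == "mediated"}
        edge_levels = {e["exposure"] for e in res.exposure_edges}
        if mediated_levels & edge_levels:
            spurious += 1
    return {"median_ve": float(np.median(ves)),
            "spurious_full_path_rate": spurious / n_reps}
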
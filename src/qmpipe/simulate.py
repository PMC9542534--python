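"""Synthetic longitudinal infant-cohort generator with ground-truth bookkeeping.

The generator emulates the data a quantitative microbiota profiling study of
birth interventions collects: genus-level amplicon count tables with
sequencing-depth variation and reagent contaminants, per-sample qPCR total
16S loads, taxon copy numbers, per-sample metadata (study group, feeding,
probiotics, run), and parent-reported well-being outcomes partially mediated
by planted taxa.

Model
-----
True cell abundances are log-normal per taxon with infant-level random
intercepts (repeated-measures structure).  Expected abundance of taxon *t*
at age *a* is ``load(a) * w_t * a^s_t`` (power-law age trend, copy-weighted
normalised so the expected total 16S copy load tracks the configured
age-increasing load curve).  Exposure effects are natural-log fold changes on
the absolute scale applied inside (group, week-window) cells.  Reads are
amplicon copies: cell abundances are inflated by 16S copy numbers *before*
multinomial read sampling at a negative-binomially distributed depth.
Blank controls carry only contaminant taxa; the same contaminant means are
added to biological samples of the run, so blank subtraction is exact in
expectation.  Well-being outcomes follow log-link linear predictors that
combine standardized mediator log-abundances with a direct exposure term;
crying is a bounded 0-100 visual-analog score (scaled beta-binomial), the
remaining symptoms are negative-binomial counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from qmpipe import datasets

STUDY_GROUPS = ("VD", "VD-cep", "VD-pen", "CS-cep", "CS-other")

#: outcomes and their sampling horizon in weeks
OUTCOME_HORIZON = {
    "crying": 26,
    "defecation_rate": 39,
    "stomach_pain": 39,
    "flatulence": 39,
}


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class GroupEffect:
    """Planted natural-log fold change on absolute abundance.

    Applies to ``taxon`` in ``group`` for ages within ``weeks`` (inclusive
    window, in weeks).
    """

    taxon: str
    group: str
    weeks: tuple[float, float]
    log_fc: float


@dataclass(frozen=True)
class MediationEffect:
    """One planted exposure -> taxon -> outcome pathway.

    ``beta_taxon`` multiplies the within-timepoint z-score of the mediator's
    log abundance on the outcome's log-link scale; ``beta_direct`` is the
    direct exposure term remaining after the mediator.  ``residual_noise`` is
    the overdispersion parameter of the outcome family (beta-binomial
    concentration for the VAS, negative-binomial size otherwise).
    """

    outcome: str
    exposure_factor: str  # "birth_mode" or "antibiotic_class"
    exposure_level: str  # e.g. "CS", "cephalosporin", "penicillin"
    mediator: str
    beta_taxon: float
    beta_direct: float = 0.0
    residual_noise: float = 8.0


def _default_group_sizes() -> dict[str, int]:
    # qPCR-quantified subset of the reference cohort: 92 infants
    return {"VD": 26, "VD-cep": 7, "VD-pen": 13, "CS-cep": 33, "CS-other": 13}


def _default_load_curve() -> dict[float, float]:
    # geometric-mean total 16S copies / g feces, rising steeply early
    return {1: 3e9, 4: 1e10, 6: 2e10, 12: 4e10, 26: 8e10, 39: 1e11, 52: 1.2e11}


def _default_group_effects() -> tuple[GroupEffect, ...]:
    eff: list[GroupEffect] = []
    for g in ("CS-cep", "CS-other"):
        eff.append(GroupEffect("Bacteroides", g, (1, 12), -2.5))
        eff.append(GroupEffect("Collinsella", g, (1, 12), -1.5))
    for g in ("VD-cep", "VD-pen", "CS-cep", "CS-other"):
        eff.append(GroupEffect("Bifidobacterium", g, (1, 6), -2.0))
        for bac in ("Staphylococcus", "Streptococcus", "Enterococcus"):
            eff.append(GroupEffect(bac, g, (1, 12), 1.5))
    eff.append(GroupEffect("Escherichia", "CS-cep", (4, 12), 1.0))
    return tuple(eff)


def _default_mediation_spec() -> tuple[MediationEffect, ...]:
    return (
        MediationEffect("crying", "antibiotic_class", "cephalosporin",
                        "Bacteroides", -0.30, 0.05, 30.0),
        MediationEffect("defecation_rate", "birth_mode", "CS",
                        "Bacteroides", -0.20, 0.10, 8.0),
        MediationEffect("defecation_rate", "antibiotic_class", "cephalosporin",
                        "Veillonella", -0.15, 0.05, 8.0),
        MediationEffect("stomach_pain", "antibiotic_class", "cephalosporin",
                        "Collinsella", -0.20, 0.05, 6.0),
        MediationEffect("stomach_pain", "antibiotic_class", "cephalosporin",
                        "Escherichia", 0.20, 0.0, 6.0),
        MediationEffect("flatulence", "birth_mode", "CS",
                        "Alistipes", -0.15, 0.05, 6.0),
    )


# (week-1 relative weight, power-law age slope) of the bundled genus panel;
# zero weight marks contaminant-only lineages.
_PANEL_DYNAMICS: dict[str, tuple[float, float]] = {
    "Bifidobacterium": (0.30, 0.30),
    "Bacteroides": (0.15, 0.20),
    "Escherichia": (0.20, 0.25),
    "Klebsiella": (0.04, 0.00),
    "Streptococcus": (0.04, 0.00),
    "Staphylococcus": (0.03, -0.40),
    "Veillonella": (0.05, 0.10),
    "Collinsella": (0.010, 0.40),
    "Blautia": (0.020, 0.60),
    "Roseburia": (0.005, 0.80),
    "Faecalibacterium": (0.004, 0.90),
    "Clostridium": (0.010, 0.50),
    "Haemophilus": (0.010, 0.00),
    "Enterococcus": (0.020, -0.10),
    "Lactobacillus": (0.020, 0.00),
    "Parabacteroides": (0.020, 0.30),
    "Alistipes": (0.005, 0.60),
    "Paludibacter": (0.002, 0.50),
    "Actinomyces": (0.005, 0.00),
    "Rothia": (0.005, -0.20),
    "Finegoldia": (0.003, 0.20),
    "Christensenella": (0.001, 0.70),
    "Phascolarctobacterium": (0.004, 0.40),
    "Akkermansia": (0.002, 0.90),
    "Achromobacter": (0.0, 0.0),
}


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the study conditions the generator emulates: five
    exposure groups with the qPCR-subset sizes, seven sampling ages over the
    first year, an age-increasing total load, and planted exposure effects
    and mediation pathways of realistic magnitude.
    """

    n_infants_per_group: Mapping[str, int] = field(default_factory=_default_group_sizes)
    timepoints: tuple[float, ...] = (1, 4, 6, 12, 26, 39, 52)
    n_taxa: int = 25
    seed: int = 0
    depth_mean: float = 25000.0
    depth_dispersion: float = 3.0  # NB size parameter of sequencing depth
    load_curve: Mapping[float, float] = field(default_factory=_default_load_curve)
    group_effects: tuple[GroupEffect, ...] = field(default_factory=_default_group_effects)
    contaminant_taxa: Mapping[str, float] = field(
        default_factory=lambda: {"Achromobacter": 25.0}
    )
    copy_numbers: pd.DataFrame = field(default_factory=datasets.default_copy_numbers)
    mediation_spec: tuple[MediationEffect, ...] = field(
        default_factory=_default_mediation_spec
    )
    infant_intercept_sd: float = 0.8  # natural-log scale, per infant x taxon
    residual_sd: float = 0.7  # natural-log scale, per sample x taxon
    qpcr_cv: float = 0.15  # multiplicative log-normal measurement noise
    discordant_taxa: tuple[str, ...] = ()
    discordant_growth: float = 0.3  # power-law exponent of a discordant taxon's
    # absolute trajectory; must stay below the load curve's growth at every step
    jorvi_fraction_vd: float = 0.4  # share of unexposed-VD infants in the Jorvi arm

    def validate(self, taxonomy: pd.DataFrame) -> None:
        if set(self.n_infants_per_group) != set(STUDY_GROUPS):
            raise ConfigError(
                f"group labels must be exactly {set(STUDY_GROUPS)}, "
                f"got {set(self.n_infants_per_group)}"
            )
        if any(n <= 0 for n in self.n_infants_per_group.values()):
            raise ConfigError("group sizes must be positive")
        if self.depth_mean < 1 or self.depth_dispersion <= 0:
            raise ConfigError("sequencing depth parameters must be >= 1 / > 0")
        if (self.copy_numbers["mean16S"] < 1).any():
            raise ConfigError("copy numbers must be >= 1")
        taxa = set(taxonomy.index)
        for e in self.group_effects:
            if not np.isfinite(e.log_fc):
                raise ConfigError(f"non-finite effect size for {e.taxon}")
            if e.taxon not in taxa:
                raise ConfigError(f"group_effects references unknown taxon {e.taxon!r}")
            if e.group not in STUDY_GROUPS:
                raise ConfigError(f"group_effects references unknown group {e.group!r}")
        for m in self.mediation_spec:
            if m.mediator not in taxa:
                raise ConfigError(f"mediation_spec references unknown taxon {m.mediator!r}")
            if not np.isfinite(m.beta_taxon) or not np.isfinite(m.beta_direct):
                raise ConfigError("mediation effect sizes must be finite")
        for t in self.contaminant_taxa:
            if t not in taxa:
                raise ConfigError(f"contaminant_taxa references unknown taxon {t!r}")


@dataclass
class GroundTruth:
    """Planted truth for every simulated quantity."""

    cells: pd.DataFrame  # sample x taxon true cells/g
    copies: pd.DataFrame  # sample x taxon true 16S copies/g
    total_copies: pd.Series  # per sample, the noise-free qPCR value
    effect_matrix: pd.DataFrame  # sample x taxon applied ln fold change
    group_effects: tuple[GroupEffect, ...]
    mediators: dict[str, list[MediationEffect]]
    outcome_mean: pd.DataFrame  # (infant, age) x outcome true mean


@dataclass
class SimulatedCohort:
    counts: pd.DataFrame  # sample x taxon reads
    blanks: pd.DataFrame  # blank x taxon reads
    blank_runs: pd.Series  # blank id -> run id
    qpcr: pd.DataFrame  # sample -> copies_per_g
    copy_numbers: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    wellbeing: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


def _resolve_taxonomy(config: SimConfig, rng: np.random.Generator):
    """Taxon panel of size n_taxa with per-taxon (weight, slope) dynamics."""
    panel = datasets.default_taxonomy()
    names = list(panel.index)
    weights = {t: _PANEL_DYNAMICS[t][0] for t in names}
    slopes = {t: _PANEL_DYNAMICS[t][1] for t in names}
    if config.n_taxa < len(names):
        # keep every taxon an effect or pathway references, then the most abundant
        keep = {e.taxon for e in config.group_effects}
        keep |= {m.mediator for m in config.mediation_spec}
        keep |= set(config.contaminant_taxa)
        rest = sorted(set(names) - keep, key=lambda t: -weights[t])
        names = [t for t in names if t in keep] + rest
        names = names[: config.n_taxa]
        panel = panel.loc[names]
    elif config.n_taxa > len(names):
        fillers = config.n_taxa - len(names)
        host = [("Lachnospiraceae", "Clostridiales", "Clostridia"),
                ("Ruminococcaceae", "Clostridiales", "Clostridia"),
                ("Enterobacteriaceae", "Enterobacteriales", "Gammaproteobacteria")]
        extra_w = np.exp(rng.normal(np.log(0.002), 1.0, size=fillers))
        extra_s = rng.normal(0.3, 0.3, size=fillers)
        rows = []
        for i in range(fillers):
            fam, ordr, cls = host[i % len(host)]
            g = f"Genus{i + 1:03d}"
            rows.append((g, fam, ordr, cls))
            weights[g] = float(extra_w[i])
            slopes[g] = float(extra_s[i])
        extra = pd.DataFrame(rows, columns=["genus", "family", "order", "class"]
                             ).set_index("genus")
        panel = pd.concat([panel, extra])
    return panel, weights, slopes


def resolve_copy_number(taxon: str, taxonomy: pd.DataFrame,
                        copy_numbers: pd.DataFrame) -> tuple[float, str]:
    """Copy number for a taxon: exact match, then ancestor ranks, then global mean.

    Returns (value, source) where source names the matched entry.
    """
    table = copy_numbers.set_index("name")["mean16S"]
    if taxon in table.index:
        return float(table[taxon]), taxon
    if taxon in taxonomy.index:
        for rank in ("family", "order", "class"):
            anc = taxonomy.loc[taxon, rank]
            if anc in table.index:
                return float(table[anc]), str(anc)
    return float(table.mean()), "global-mean"


def _copy_number_vector(taxonomy: pd.DataFrame, copy_numbers: pd.DataFrame) -> pd.Series:
    vals = {t: resolve_copy_number(t, taxonomy, copy_numbers)[0] for t in taxonomy.index}
    return pd.Series(vals, name="copy_number")


def _assign_exposures(group: str, i: int) -> tuple[str, str]:
    """(birth_mode, antibiotic) consistent with a study group."""
    if group == "VD":
        return "VD", "none"
    if group == "VD-cep":
        return "VD", "cefuroxime"
    if group == "VD-pen":
        return "VD", "penicillin"
    if group == "CS-cep":
        mode = "elective CS" if i % 2 == 0 else "emergency CS"
        abx = "cefuroxime" if i % 3 else "cephalexin"
        return mode, abx
    mode = "elective CS" if i % 2 == 0 else "emergency CS"
    abx = ("clindamycin", "combination", "metronidazole", "penicillin")[i % 4]
    return mode, abx


def _exposure_indicator(factor: str, level: str, group: str) -> float:
    if factor == "birth_mode":
        is_cs = group.startswith("CS")
        return float((level == "CS") == is_cs) if level in ("CS", "VD") else 0.0
    if factor == "antibiotic_class":
        cls = {"VD": "none", "VD-cep": "cephalosporin", "VD-pen": "penicillin",
               "CS-cep": "cephalosporin", "CS-other": "other"}[group]
        return float(cls == level)
    raise ConfigError(f"unknown exposure factor {factor!r}")


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate one synthetic cohort; bit-identical for identical config+seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    taxonomy, weights, slopes = _resolve_taxonomy(config, rng)
    config.validate(taxonomy)
    taxa = list(taxonomy.index)
    cn = _copy_number_vector(taxonomy, config.copy_numbers)

    contaminant_only = [t for t in config.contaminant_taxa if weights.get(t, 0.0) == 0.0]
    bio_taxa = [t for t in taxa if weights.get(t, 0.0) > 0.0]
    for t in config.discordant_taxa:
        if t not in taxa:
            raise ConfigError(f"discordant taxon {t!r} not in the panel")
        if t not in bio_taxa:
            raise ConfigError(f"discordant taxon {t!r} is contaminant-only")

    tps = list(config.timepoints)
    loads = {tp: config.load_curve[tp] for tp in tps}

    # expected cells/g per (taxon, timepoint), copy-weighted normalised to the
    # load curve; discordant taxa pinned to their first-timepoint expectation
    mean_cells = pd.DataFrame(index=bio_taxa, columns=tps, dtype=float)
    for tp in tps:
        w = np.array([weights[t] * tp ** slopes[t] for t in bio_taxa])
        w_copy = w * cn[bio_taxa].to_numpy()
        mean_cells[tp] = loads[tp] * w / w_copy.sum()
    for t in config.discordant_taxa:
        base = mean_cells.loc[t, tps[0]]
        for tp in tps:
            mean_cells.loc[t, tp] = base * (tp / tps[0]) ** config.discordant_growth

    # infants
    rows = []
    for g in STUDY_GROUPS:
        for i in range(config.n_infants_per_group[g]):
            infant = f"{g}_{i + 1:03d}"
            mode, abx = _assign_exposures(g, i)
            rows.append((infant, g, mode, abx))
    infants = pd.DataFrame(rows, columns=["infant_id", "group", "birth_mode", "antibiotic"])

    # per-infant covariates
    n_inf = len(infants)
    bf_stop = rng.normal(17, 5, n_inf).clip(6, 40)
    bf_wean = bf_stop + rng.gamma(4, 4, n_inf)
    solids = rng.normal(18, 3, n_inf).clip(12, 30)
    prob_cat = rng.choice(
        ["none", "Lactobacillus", "Bifidobacterium", "both", "Saccharomyces"],
        size=n_inf, p=[0.60, 0.15, 0.15, 0.05, 0.05])
    is_vd_ref = (infants["group"] == "VD").to_numpy()
    jorvi = np.zeros(n_inf, dtype=bool)
    jorvi[is_vd_ref] = rng.random(is_vd_ref.sum()) < config.jorvi_fraction_vd
    run_ids = rng.choice(["run1", "run2", "run3"], size=n_inf)
    protocol_mod = rng.random(n_inf) < 0.10

    # infant-level random intercepts, per taxon
    u = rng.normal(0.0, config.infant_intercept_sd, size=(n_inf, len(bio_taxa)))

    sample_ids, meta_rows = [], []
    cells_rows, copies_rows, eff_rows = [], [], []
    for j, inf in infants.iterrows():
        for tp in tps:
            sid = f"{inf.infant_id}_w{tp:g}"
            sample_ids.append(sid)
            eps = rng.normal(0.0, config.residual_sd, len(bio_taxa))
            lnfc = np.zeros(len(bio_taxa))
            for e in config.group_effects:
                if e.group == inf.group and e.weeks[0] <= tp <= e.weeks[1] and e.taxon in bio_taxa:
                    lnfc[bio_taxa.index(e.taxon)] += e.log_fc
            mu = mean_cells[tp].to_numpy()
            shrink = 0.5 * (config.infant_intercept_sd ** 2 + config.residual_sd ** 2)
            cells = mu * np.exp(lnfc + u[j] + eps - shrink)
            copies = cells * cn[bio_taxa].to_numpy()
            cells_rows.append(cells)
            copies_rows.append(copies)
            eff_rows.append(lnfc)
            age = float(tp)
            if age <= bf_stop[j]:
                bf = "exclusive"
            elif age <= bf_wean[j]:
                bf = "partial"
            else:
                bf = "none"
            meta_rows.append({
                "sample_id": sid,
                "infant_id": inf.infant_id,
                "age_weeks": age,
                "group": inf.group,
                "birth_mode": inf.birth_mode,
                "antibiotic": inf.antibiotic,
                "cohort": "Jorvi" if jorvi[j] else "HELMi",
                "run_id": run_ids[j],
                "protocol_modified": bool(protocol_mod[j]),
                "breastfeeding": bf,
                "weeks_since_solids": max(0.0, age - solids[j]),
                "probiotics": prob_cat[j],
            })

    cells_df = pd.DataFrame(cells_rows, index=sample_ids, columns=bio_taxa)
    copies_df = pd.DataFrame(copies_rows, index=sample_ids, columns=bio_taxa)
    eff_df = pd.DataFrame(eff_rows, index=sample_ids, columns=bio_taxa)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    total_copies = copies_df.sum(axis=1)
    sigma_q = float(np.sqrt(np.log1p(config.qpcr_cv ** 2)))
    qpcr_val = total_copies * np.exp(rng.normal(0, sigma_q, len(total_copies)))
    qpcr = pd.DataFrame({"copies_per_g": qpcr_val})

    # read sampling: NB depth, multinomial over copy proportions, contaminants on top
    n_s = len(sample_ids)
    lam = rng.gamma(config.depth_dispersion, config.depth_mean / config.depth_dispersion, n_s)
    depth = np.maximum(rng.poisson(lam), 50)
    props = copies_df.to_numpy() / total_copies.to_numpy()[:, None]
    counts = np.vstack([rng.multinomial(depth[i], props[i]) for i in range(n_s)])
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=bio_taxa)
    for t in taxa:
        if t not in counts_df.columns:
            counts_df[t] = 0
    counts_df = counts_df[taxa]
    for t, m in config.contaminant_taxa.items():
        counts_df[t] = counts_df[t] + rng.poisson(m, n_s)

    # blanks: contaminant taxa only, two per run
    blank_rows, blank_ids, blank_run = [], [], []
    for run in ("run1", "run2", "run3"):
        for b in (1, 2):
            bid = f"BLK_{run}_{b}"
            row = {t: 0 for t in taxa}
            for t, m in config.contaminant_taxa.items():
                row[t] = int(rng.poisson(m))
            blank_rows.append(row)
            blank_ids.append(bid)
            blank_run.append(run)
    blanks = pd.DataFrame(blank_rows, index=blank_ids)[taxa]
    blank_runs = pd.Series(blank_run, index=blank_ids, name="run_id")

    # well-being outcomes with planted mediation
    mediators: dict[str, list[MediationEffect]] = {}
    for m in config.mediation_spec:
        mediators.setdefault(m.outcome, []).append(m)
    base_mean = {"crying": 30.0, "defecation_rate": 4.0,
                 "stomach_pain": 2.0, "flatulence": 3.0}
    log_cells = np.log(cells_df.clip(lower=1.0))
    zscores = log_cells.groupby(metadata["age_weeks"]).transform(
        lambda x: (x - x.mean()) / (x.std(ddof=0) + 1e-12))
    wb_rows, mean_rows = [], []
    for sid in sample_ids:
        age = metadata.loc[sid, "age_weeks"]
        grp = metadata.loc[sid, "group"]
        rec = {"infant_id": metadata.loc[sid, "infant_id"], "age_weeks": age,
               "sample_id": sid}
        true_mu = {}
        for outcome, horizon in OUTCOME_HORIZON.items():
            if age > horizon:
                rec[outcome] = np.nan
                true_mu[outcome] = np.nan
                continue
            eta = np.log(base_mean[outcome])
            noise = 8.0
            for m in mediators.get(outcome, []):
                eta += m.beta_taxon * zscores.loc[sid, m.mediator]
                eta += m.beta_direct * _exposure_indicator(
                    m.exposure_factor, m.exposure_level, grp)
                noise = m.residual_noise
            mu = float(np.exp(eta))
            true_mu[outcome] = mu
            if outcome == "crying":
                p = min(max(mu / 100.0, 0.01), 0.95)
                kappa = noise
                q = rng.beta(p * kappa, (1 - p) * kappa)
                rec[outcome] = int(rng.binomial(100, q))
            else:
                size = noise
                lam_o = rng.gamma(size, mu / size)
                rec[outcome] = int(rng.poisson(lam_o))
        rec["overall_health"] = int(5 - rng.binomial(2, 0.15))
        rec["postnatal_abx_courses"] = 0
        wb_rows.append(rec)
        mean_rows.append(true_mu)
    wellbeing = pd.DataFrame(wb_rows).set_index("sample_id")
    outcome_mean = pd.DataFrame(mean_rows, index=sample_ids)

    truth = GroundTruth(
        cells=cells_df, copies=copies_df, total_copies=total_copies,
        effect_matrix=eff_df, group_effects=config.group_effects,
        mediators=mediators, outcome_mean=outcome_mean,
    )
    return SimulatedCohort(
        counts=counts_df, blanks=blanks, blank_runs=blank_runs, qpcr=qpcr,
        copy_numbers=config.copy_numbers, taxonomy=taxonomy, metadata=metadata,
        wellbeing=wellbeing, truth=truth, config=config,
    )


def simulate_discordant_taxon(config: SimConfig, taxon: str) -> SimulatedCohort:
    """Re-simulate with ``taxon`` pinned to a flat absolute trajectory.

    The taxon's expected cells/g stay at their first-timepoint value while the
    total load keeps rising, so its true relative abundance strictly
    decreases: the classic artifact where relative profiling shows a decline
    for a taxon whose absolute abundance does not fall.

    Raises
    ------
    ConfigError
        If the taxon is absent from the panel or is contaminant-only.
    """
    amended = dataclasses.replace(
        config, discordant_taxa=tuple(config.discordant_taxa) + (taxon,))
    return simulate_cohort(amended)
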
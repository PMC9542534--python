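"""Exposure -> taxa -> symptom path models.

Per outcome and timepoint: (1) regress the outcome on the two exposure
factors (birth mode, antibiotic class) with feeding and probiotic adjustment
using a negative-binomial model; (2) select taxa predicting the outcome by
forward-backward stepwise AIC over standardized log abundances, reporting the
variance explained as the squared correlation between fitted and observed
outcome; (3) test each selected taxon against the exposure factors with the
differential-abundance cascade; (4) assemble the three edge sets into one
path diagram, calling an exposure effect "mediated" when its direct term
loses significance once the mediator taxa enter the outcome model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from qmpipe.cohort import build_design
from qmpipe.da import (ALPHA, fit_cascade, prevalence_filter, _mom_alpha,
                       _overdispersion_z)

logger = logging.getLogger(__name__)

MAX_MODEL_FRACTION = 10  # stepwise size cap: n / 10 predictors


def _count_fit(y: np.ndarray, X: pd.DataFrame, family: str = "negbin"):
    """NB (Poisson-seeded, MoM dispersion) with Poisson/Gaussian alternatives.

    Returns (results, family_label, extra_params) where extra_params counts
    the dispersion parameter in AIC comparisons.
    """
    if family == "gaussian":
        return sm.OLS(y, X).fit(), "gaussian", 0
    yi = np.round(np.asarray(y, dtype=float)).clip(min=0)
    pois = sm.GLM(yi, X, family=sm.families.Poisson()).fit(maxiter=50, tol=1e-6)
    mu = np.asarray(pois.fittedvalues)
    alpha = _mom_alpha(yi, mu)
    if family == "poisson" or alpha <= 1e-3 or _overdispersion_z(yi, mu) <= 1.645:
        return pois, "poisson", 0
    a = float(np.clip(alpha, 1e-3, 1e4))
    nb = sm.GLM(yi, X, family=sm.families.NegativeBinomial(alpha=a)).fit(
        maxiter=50, tol=1e-6, start_params=np.asarray(pois.params))
    if not nb.converged:
        logger.info("NB outcome model did not converge; Poisson fallback")
        return pois, "poisson", 0
    return nb, "negbin", 1


def _aic(res, extra_params: int) -> float:
    return float(res.aic) + 2.0 * extra_params


def variance_explained(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation of fitted vs observed outcome."""
    if np.std(fitted) == 0 or np.std(observed) == 0:
        return 0.0
    return float(np.corrcoef(fitted, observed)[0, 1] ** 2)


@dataclass
class ExposureModel:
    outcome: str
    timepoint: float
    family: str
    terms: dict[str, dict]  # exposure level -> {coef, p}
    n: int
    results: object = None


def outcome_exposure_model(
    wellbeing: pd.DataFrame,
    metadata: pd.DataFrame,
    outcome: str,
    timepoint: float,
    family: str = "negbin",
    covariates: tuple[str, ...] = ("breastfeeding", "probiotics"),
) -> ExposureModel:
    """Outcome vs birth mode + antibiotic class, feeding/probiotic adjusted."""
    design = build_design(metadata, timepoint,
                          exposure="birth_mode+antibiotic_class",
                          covariates=covariates)
    X = design.matrix
    y = wellbeing.loc[X.index.intersection(wellbeing.index), outcome].dropna()
    X = X.loc[y.index]
    if y.nunique() <= 1:
        raise ValueError(f"outcome {outcome!r} constant at week {timepoint}")
    res, fam, _ = _count_fit(y.to_numpy(), X, family=family)
    terms = {}
    for level, col in design.exposure_columns.items():
        if col in res.params:
            terms[level] = {"coef": float(res.params[col]),
                            "p": float(res.pvalues[col])}
    return ExposureModel(outcome=outcome, timepoint=timepoint, family=fam,
                         terms=terms, n=len(y), results=res)


@dataclass
class MediatorModel:
    selected: list[str]
    coefficients: dict[str, float]
    variance_explained: float
    pseudo_r2: float
    aic: float
    family: str
    fitted: pd.Series | None = None


def select_mediator_taxa(
    outcome_values: pd.Series,
    taxa_log: pd.DataFrame,
    family: str = "negbin",
    max_model_size: int | None = None,
) -> MediatorModel:
    """Forward-backward stepwise AIC over standardized log taxon abundances.

    Two overfitting guards: the model size is capped at n / 10 predictors,
    and the per-parameter penalty is inflated from AIC's 2 to
    ``max(2, 2 ln m)`` where m is the number of candidate taxa (the risk
    inflation criterion), so the best-of-m selection bias of greedy stepwise
    search does not manufacture spurious mediators.  Deterministic: candidate
    sweeps are in sorted taxon order and ties break lexicographically, so
    identical inputs select identical sets.
    """
    y = outcome_values.dropna()
    Z = taxa_log.loc[y.index]
    n = len(y)
    cap = max_model_size if max_model_size is not None else max(1, n // MAX_MODEL_FRACTION)
    candidates = sorted(Z.columns)
    selected: list[str] = []
    penalty = max(2.0, 2.0 * np.log(max(len(candidates), 1)))

    def fit_set(cols: list[str]):
        X = pd.DataFrame({"Intercept": 1.0}, index=y.index)
        for c in cols:
            X[c] = Z[c]
        res, fam, extra = _count_fit(y.to_numpy(), X, family=family)
        score = -2.0 * float(res.llf) + penalty * (len(cols) + 1 + extra)
        return res, fam, score

    res0, fam0, best_aic = fit_set([])
    best = (res0, fam0)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, str]] = []
        if len(selected) < cap:
            for c in candidates:
                if c in selected:
                    continue
                try:
                    r, f, a = fit_set(selected + [c])
                except Exception:  # noqa: BLE001 - skip non-fitting candidates
                    continue
                moves.append((a, "add", c))
        for c in selected:
            r, f, a = fit_set([t for t in selected if t != c])
            moves.append((a, "drop", c))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        a, action, c = moves[0]
        if a < best_aic - 1e-9:
            if action == "add":
                selected.append(c)
            else:
                selected.remove(c)
            selected.sort()
            res, fam, best_aic = fit_set(selected)
            best = (res, fam)
            improved = True

    res, fam = best
    fitted = np.asarray(res.fittedvalues)
    ve = variance_explained(fitted, y.to_numpy()) if selected else 0.0
    if fam == "gaussian":
        pseudo = float(getattr(res, "rsquared", 0.0)) if selected else 0.0
    else:
        null_dev = float(res.null_deviance) if hasattr(res, "null_deviance") else np.nan
        pseudo = float(1 - res.deviance / null_dev) if selected and null_dev else 0.0
    coefs = {c: float(res.params[c]) for c in selected if c in res.params}
    aic_final = _aic(res, 1 if fam == "negbin" else 0)
    return MediatorModel(selected=selected, coefficients=coefs,
                         variance_explained=ve, pseudo_r2=pseudo,
                         aic=aic_final, family=fam,
                         fitted=pd.Series(fitted, index=y.index))


def exposure_taxon_links(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    selected: list[str],
    timepoint: float,
    covariates: tuple[str, ...] = ("breastfeeding", "probiotics"),
) -> list[dict]:
    """Exposure -> taxon edges: cascade tests of each mediator's abundance.

    Edges are kept at P < .05; each records the exposure level, the sign of
    the association and the model family used.
    """
    if not selected:
        return []
    design = build_design(metadata, timepoint,
                          exposure="birth_mode+antibiotic_class",
                          covariates=covariates)
    X = design.matrix
    groups = metadata.loc[X.index, "group"] if "group" in metadata else None
    edges = []
    for taxon in selected:
        if taxon not in profile.columns:
            continue
        fit = fit_cascade(profile.loc[X.index, taxon], X, groups=groups)
        if fit.params is None:
            continue
        for level, col in design.exposure_columns.items():
            if col not in fit.params:
                continue
            p = float(fit.pvalues[col])
            if p < ALPHA:
                edges.append({"exposure": level, "taxon": taxon,
                              "sign": int(np.sign(fit.params[col])),
                              "p": p, "family": fit.family})
    return edges


@dataclass
class PathModelResult:
    outcome: str
    timepoint: float
    exposure_terms: dict[str, dict]
    mediators: list[dict]
    exposure_edges: list[dict]
    variance_explained: float
    pseudo_r2: float
    aic: float
    mediation: dict[str, str]  # exposure level -> mediated / direct / none
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        return json.dumps(payload, indent=2, default=str)


def assemble_path_diagram(
    exposure_model: ExposureModel,
    mediator_model: MediatorModel,
    edges: list[dict],
    wellbeing: pd.DataFrame,
    metadata: pd.DataFrame,
    taxa_log: pd.DataFrame,
    family: str = "negbin",
) -> PathModelResult:
    """Merge the three edge sets; classify each exposure effect.

    An exposure term significant on its own (P < .05) that loses significance
    once the selected mediator taxa are added to the outcome model is labeled
    ``"mediated"``; one that stays significant is ``"direct"``; a term never
    significant is ``"none"``.
    """
    outcome, tp = exposure_model.outcome, exposure_model.timepoint
    design = build_design(metadata, tp, exposure="birth_mode+antibiotic_class",
                          covariates=("breastfeeding", "probiotics"))
    X = design.matrix
    y = wellbeing.loc[X.index.intersection(wellbeing.index), outcome].dropna()
    X = X.loc[y.index]
    Xm = X.copy()
    for taxon in mediator_model.selected:
        if taxon in taxa_log.columns:
            Xm[taxon] = taxa_log.loc[y.index, taxon]
    mediation: dict[str, str] = {}
    notes: list[str] = []
    if mediator_model.selected:
        res_m, _, _ = _count_fit(y.to_numpy(), Xm, family=family)
    else:
        res_m = None
    for level, term in exposure_model.terms.items():
        p0 = term["p"]
        if p0 >= ALPHA:
            mediation[level] = "none"
            continue
        col = design.exposure_columns.get(level)
        p1 = float(res_m.pvalues[col]) if res_m is not None and col in res_m.params else p0
        mediation[level] = "mediated" if p1 >= ALPHA else "direct"
        if mediation[level] == "mediated":
            notes.append(f"{level}: direct P {p0:.3g} -> {p1:.3g} with mediators")
    mediators = [
        {"taxon": t, "coef": mediator_model.coefficients.get(t, np.nan),
         "sign": int(np.sign(mediator_model.coefficients.get(t, 0.0))),
         "exposure_edges": [e for e in edges if e["taxon"] == t]}
        for t in mediator_model.selected
    ]
    return PathModelResult(
        outcome=outcome, timepoint=tp, exposure_terms=exposure_model.terms,
        mediators=mediators, exposure_edges=edges,
        variance_explained=mediator_model.variance_explained,
        pseudo_r2=mediator_model.pseudo_r2, aic=mediator_model.aic,
        mediation=mediation, notes=notes,
    )


def standardized_log_abundance(profile: pd.DataFrame,
                               log_pseudocount: float = 1.0) -> pd.DataFrame:
    """Column-wise z-scores of log10 abundance; the stepwise predictor scale."""
    logx = np.log10(profile + log_pseudocount)
    return (logx - logx.mean()) / logx.std(ddof=0).replace(0, 1.0)


def run_mediation(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    wellbeing: pd.DataFrame,
    outcome: str,
    timepoint: float,
    family: str = "negbin",
    prevalence: float = 0.30,
    max_model_size: int | None = None,
) -> PathModelResult:
    """Full path analysis for one outcome at one timepoint."""
    exp_model = outcome_exposure_model(wellbeing, metadata, outcome, timepoint,
                                       family=family)
    at_tp = metadata[metadata["age_weeks"] == timepoint]
    if "censored" in at_tp.columns:
        at_tp = at_tp[~at_tp["censored"]]
    samples = profile.index.intersection(at_tp.index)
    prof_tp = profile.loc[samples]
    taxa = prevalence_filter(prof_tp, prevalence)
    taxa_log = standardized_log_abundance(prof_tp[taxa])
    y = wellbeing.loc[samples.intersection(wellbeing.index), outcome]
    med_model = select_mediator_taxa(y, taxa_log, family=family,
                                     max_model_size=max_model_size)
    edges = exposure_taxon_links(profile, metadata, med_model.selected, timepoint)
    return assemble_path_diagram(exp_model, med_model, edges, wellbeing,
                                 metadata, taxa_log, family=family)
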
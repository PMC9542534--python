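"""Exposure-group construction, post-natal antibiotic censoring, model designs.

Infants are grouped by birth mode crossed with intrapartum antibiotic class:
a vaginally delivered reference without antibiotics (VD), cephalosporin or
penicillin exposure in vaginal delivery (VD-cep, VD-pen), and cesarean birth
with cephalosporin or with any other antibiotic (CS-cep, CS-other; elective
and emergency sections are pooled and all involve antibiotics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STUDY_GROUPS = ("VD", "VD-cep", "VD-pen", "CS-cep", "CS-other")
UNCLASSIFIABLE = "unclassifiable"

CEPHALOSPORINS = frozenset({"cefuroxime", "cephalexin"})
ANTIBIOTIC_VOCAB = frozenset({
    "none", "penicillin", "cefuroxime", "cephalexin", "clindamycin",
    "metronidazole", "combination", "not_reported", "other",
})

#: reference levels used in every adjusted design
REFERENCE_LEVELS = {
    "group": "VD",
    "birth_mode": "VD",
    "antibiotic_class": "none",
    "breastfeeding": "exclusive",
    "probiotics": "none",
}


def antibiotic_class(antibiotic: str) -> str:
    """Collapse individual agents to {none, penicillin, cephalosporin, other}."""
    if antibiotic == "none":
        return "none"
    if antibiotic == "penicillin":
        return "penicillin"
    if antibiotic in CEPHALOSPORINS:
        return "cephalosporin"
    return "other"


def assign_study_group(birth_mode: str, antibiotic: str) -> str:
    """Map one (birth mode, intrapartum antibiotic) record to a study group.

    Cesarean modes (elective or emergency) are pooled.  A cesarean record
    without antibiotic violates the cohort invariant that every CS involved
    intrapartum antibiotics and raises.  A vaginal delivery with an agent
    outside the penicillin/cephalosporin classes is returned as
    ``"unclassifiable"`` rather than silently dropped or forced into a group.
    """
    if antibiotic not in ANTIBIOTIC_VOCAB:
        raise ValueError(f"unknown antibiotic {antibiotic!r}")
    is_cs = "CS" in birth_mode.upper()
    if not is_cs and birth_mode.upper() != "VD":
        raise ValueError(f"unknown birth mode {birth_mode!r}")
    if is_cs:
        if antibiotic == "none":
            raise ValueError("cesarean record without intrapartum antibiotic")
        return "CS-cep" if antibiotic in CEPHALOSPORINS else "CS-other"
    if antibiotic == "none":
        return "VD"
    if antibiotic in CEPHALOSPORINS:
        return "VD-cep"
    if antibiotic == "penicillin":
        return "VD-pen"
    return UNCLASSIFIABLE


def assign_study_groups(records: pd.DataFrame) -> pd.Series:
    """Vectorised `assign_study_group` over a records frame."""
    return records.apply(
        lambda r: assign_study_group(r["birth_mode"], r["antibiotic"]), axis=1
    )


def censor_postnatal_antibiotics(
    metadata: pd.DataFrame, treatments: pd.DataFrame
) -> pd.DataFrame:
    """Flag samples taken after an infant's first post-natal antibiotic course.

    ``treatments`` has columns ``infant_id`` and ``week`` (age at course
    start).  Samples strictly after the first course are flagged
    ``censored=True``; infants whose first course precedes their first sample
    are dropped entirely.
    """
    out = metadata.copy()
    out["censored"] = False
    if treatments is None or treatments.empty:
        return out
    first = treatments.groupby("infant_id")["week"].min()
    drop_infants = []
    for infant, week in first.items():
        mask = out["infant_id"] == infant
        if not mask.any():
            continue
        first_sample = out.loc[mask, "age_weeks"].min()
        if week <= first_sample:
            drop_infants.append(infant)
            continue
        out.loc[mask & (out["age_weeks"] > week), "censored"] = True
    if drop_infants:
        logger.info("dropping %d infants treated before first sample: %s",
                    len(drop_infants), drop_infants)
        out = out[~out["infant_id"].isin(drop_infants)]
    return out


@dataclass
class Design:
    """A dummy-coded, covariate-adjusted model design for one timepoint."""

    matrix: pd.DataFrame  # includes an Intercept column
    exposure_columns: dict[str, str]  # contrast label -> column name
    dropped: list[str] = field(default_factory=list)
    timepoint: float | None = None


def _dummies(col: pd.Series, name: str, reference: str) -> pd.DataFrame:
    levels = [l for l in pd.unique(col) if l != reference]
    out = pd.DataFrame(index=col.index)
    for lev in sorted(map(str, levels)):
        out[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return out


def build_design(
    metadata: pd.DataFrame,
    timepoint: float,
    exposure: str = "group",
    covariates: tuple[str, ...] = (
        "breastfeeding", "weeks_since_solids", "probiotics", "run_id",
        "protocol_modified",
    ),
) -> Design:
    """Exposure factor + adjustment covariates, dummy-coded with fixed references.

    ``exposure`` may be ``"group"`` (five-level study group), or
    ``"birth_mode+antibiotic_class"`` for the two separate factors used in
    the health-outcome models.  Censored samples are excluded.  Constant
    covariates at the timepoint are dropped with a logged note.
    """
    sub = metadata[metadata["age_weeks"] == timepoint]
    if "censored" in sub.columns:
        sub = sub[~sub["censored"]]
    if sub.empty:
        raise ValueError(f"no samples at timepoint {timepoint}")
    X = pd.DataFrame({"Intercept": 1.0}, index=sub.index)
    exposure_columns: dict[str, str] = {}

    def add_factor(col_name: str) -> None:
        ref = REFERENCE_LEVELS.get(col_name)
        dm = _dummies(sub[col_name], col_name, ref)
        for c in dm.columns:
            X[c] = dm[c]
            exposure_columns[c.split("[", 1)[1].rstrip("]")] = c

    if exposure == "group":
        add_factor("group")
    elif exposure == "birth_mode+antibiotic_class":
        mode = sub["birth_mode"].map(lambda m: "CS" if "CS" in m.upper() else "VD")
        tmp = sub.assign(birth_mode=mode)
        dm = _dummies(tmp["birth_mode"], "birth_mode", "VD")
        for c in dm.columns:
            X[c] = dm[c]
            exposure_columns[c.split("[", 1)[1].rstrip("]")] = c
        if "antibiotic_class" not in sub.columns:
            tmp["antibiotic_class"] = sub["antibiotic"].map(antibiotic_class)
        else:
            tmp["antibiotic_class"] = sub["antibiotic_class"]
        dm = _dummies(tmp["antibiotic_class"], "antibiotic_class", "none")
        for c in dm.columns:
            X[c] = dm[c]
            exposure_columns[c.split("[", 1)[1].rstrip("]")] = c
    else:
        raise ValueError(f"unknown exposure specification {exposure!r}")

    dropped: list[str] = []
    for cov in covariates:
        if cov not in sub.columns:
            dropped.append(cov)
            continue
        col = sub[cov]
        if col.nunique(dropna=False) <= 1:
            dropped.append(cov)
            logger.info("covariate %r constant at week %s; dropped", cov, timepoint)
            continue
        if col.dtype == bool or col.dtype == object:
            ref = REFERENCE_LEVELS.get(cov)
            if ref is None:
                ref = str(sorted(map(str, pd.unique(col)))[0])
            dm = _dummies(col, cov, ref)
            dm = dm.loc[:, dm.nunique() > 1]
            X = pd.concat([X, dm], axis=1)
        else:
            x = col.astype(float)
            X[cov] = (x - x.mean()) / (x.std(ddof=0) or 1.0)
    # prune linearly dependent adjustment columns (small-cohort aliasing);
    # exposure dummies are kept and pruning only touches covariates
    protected = {"Intercept", *exposure_columns.values()}
    keep: list[str] = [c for c in X.columns if c in protected]
    A = X[keep].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    for c in X.columns:
        if c in protected:
            continue
        cand = np.column_stack([A, X[c].to_numpy(dtype=float)])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(c)
            A, rank = cand, r
        else:
            dropped.append(c)
            logger.info("covariate column %r aliased at week %s; dropped",
                        c, timepoint)
    X = X[[c for c in X.columns if c in keep]]
    return Design(matrix=X, exposure_columns=exposure_columns,
                  dropped=dropped, timepoint=timepoint)
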
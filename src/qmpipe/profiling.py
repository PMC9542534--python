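"""From raw counts + qPCR + copy numbers to QC-filtered relative and absolute profiles.

Count tables are pandas DataFrames with samples as rows and taxa as columns.
Per-sample run / cohort labels are passed as aligned Series (typically columns
of the metadata table).  Provenance of irreversible steps is tracked in
``DataFrame.attrs`` so that e.g. blank subtraction refuses re-application.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qmpipe.simulate import resolve_copy_number

logger = logging.getLogger(__name__)

RANKS = ("class", "order", "family", "genus")


@dataclass
class AbsoluteProfile:
    """Sample x taxon abundances on the absolute scale.

    ``copies`` is the qPCR-anchored profile in 16S copies per g feces
    (relative abundance times total load, uncorrected); ``cells`` divides each
    taxon by its mean 16S copy number to approximate cells per g.
    """

    copies: pd.DataFrame
    cells: pd.DataFrame
    copy_number: pd.Series  # per-taxon copy number used
    copy_source: pd.Series  # which table entry resolved it
    excluded_samples: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _require_not(counts: pd.DataFrame, flag: str, step: str) -> None:
    if counts.attrs.get(flag):
        raise ValueError(
            f"{step} was already applied to this table; re-application would "
            "repeat the subtraction and corrupt the counts"
        )


def subtract_blank_contaminants(
    counts: pd.DataFrame,
    blanks: pd.DataFrame,
    runs: pd.Series,
    blank_runs: pd.Series,
    mode: str = "mean",
) -> pd.DataFrame:
    """Remove contaminant reads seen in negative controls, run by run.

    For each taxon present in a run's blanks, its blank summary (per-run mean
    by default, ``mode="max"`` for the conservative variant) is subtracted
    from every sample of that run and floored at zero.  Taxa reduced to zero
    everywhere are dropped.  Runs without any blank are passed through with a
    warning.
    """
    _require_not(counts, "blanks_subtracted", "blank subtraction")
    if mode not in ("mean", "max"):
        raise ValueError(f"unknown blank summary mode {mode!r}")
    out = counts.astype(float).copy()
    for run in runs.loc[out.index].unique():
        brows = blanks.loc[blank_runs[blank_runs == run].index.intersection(blanks.index)]
        if brows.empty:
            logger.warning("no blank control for run %s; counts passed through", run)
            continue
        summary = brows.mean(axis=0) if mode == "mean" else brows.max(axis=0)
        members = runs.loc[out.index][runs.loc[out.index] == run].index
        common = out.columns.intersection(summary.index)
        out.loc[members, common] = (
            out.loc[members, common] - summary[common]
        ).clip(lower=0)
    out = out.loc[:, (out > 0).any(axis=0)]
    out = out.round().astype(int)
    out.attrs = dict(counts.attrs)
    out.attrs["blanks_subtracted"] = True
    return out


def filter_rare_reads(
    counts: pd.DataFrame, min_count: int, runs: pd.Series | None = None
) -> pd.DataFrame:
    """Zero out taxa whose within-run read total is below ``min_count``.

    Mimics the removal of probable sequencing-error reads; the threshold is
    typically in the 10-50 range depending on run size.  Without ``runs`` the
    whole table is one run.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    out = counts.copy()
    if runs is None:
        groups = [("all", out.index)]
    else:
        groups = [(r, idx) for r, idx in out.groupby(runs.loc[out.index]).groups.items()]
    for _, idx in groups:
        totals = out.loc[idx].sum(axis=0)
        out.loc[idx, totals[totals < min_count].index] = 0
    out.attrs = dict(counts.attrs)
    return out


def apply_coverage_cutoff(
    counts: pd.DataFrame,
    cutoff_per_cohort: dict[str, int],
    cohorts: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples whose total reads fall below their cohort's cutoff.

    The cutoff is inclusive: a sample with exactly the cutoff is retained.
    Returns the retained table and a removal log (sample, cohort, total,
    cutoff).
    """
    missing = set(cohorts.loc[counts.index].unique()) - set(cutoff_per_cohort)
    if missing:
        raise KeyError(f"no coverage cutoff for cohort(s): {sorted(missing)}")
    totals = counts.sum(axis=1)
    cut = cohorts.loc[counts.index].map(cutoff_per_cohort)
    keep = totals >= cut
    removed = pd.DataFrame({
        "cohort": cohorts.loc[counts.index][~keep],
        "total_reads": totals[~keep],
        "cutoff": cut[~keep],
    })
    if len(removed):
        logger.info("coverage cutoff removed %d samples", len(removed))
    out = counts.loc[keep]
    out.attrs = dict(counts.attrs)
    return out, removed


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions (rows sum to one); no copy-number correction."""
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    out = counts.div(totals, axis=0)
    out.attrs = dict(counts.attrs)
    return out


def absolute_profile(
    counts: pd.DataFrame,
    qpcr: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    taxonomy: pd.DataFrame,
) -> AbsoluteProfile:
    """qPCR-anchored absolute profile with 16S copy-number correction.

    ``copies[t, s] = relative[t, s] * load(s)`` and
    ``cells[t, s] = copies[t, s] / copy_number(t)``.  Copy numbers resolve by
    exact taxon match, then nearest ancestor rank (family, order, class),
    then the global mean of the table.  Samples without a qPCR value are
    excluded with a logged reason; a non-positive load is an error.
    """
    load = qpcr["copies_per_g"] if "copies_per_g" in qpcr else qpcr.iloc[:, 0]
    have = counts.index.intersection(load.index)
    excluded = [s for s in counts.index if s not in have]
    if excluded:
        logger.warning("%d samples lack qPCR values and were excluded: %s",
                       len(excluded), excluded[:5])
    if (load.loc[have] < 0).any():
        bad = load.loc[have][load.loc[have] < 0].index.tolist()
        raise ValueError(f"negative qPCR load for sample(s): {bad}")
    rel = relative_abundance(counts.loc[have])
    copies = rel.mul(load.loc[have], axis=0)
    res = {t: resolve_copy_number(t, taxonomy, copy_numbers) for t in counts.columns}
    cn = pd.Series({t: v for t, (v, _) in res.items()}, name="copy_number")
    src = pd.Series({t: s for t, (_, s) in res.items()}, name="copy_source")
    cells = copies.div(cn, axis=1)
    return AbsoluteProfile(
        copies=copies, cells=cells, copy_number=cn, copy_source=src,
        excluded_samples=excluded,
        provenance={"n_samples": len(have), "copy_corrected": True},
    )


def aggregate_rank(
    matrix: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum abundances within a taxonomic rank (class/order/family/genus).

    Taxa without an assignment at the requested rank pool into
    ``unclassified-<rank>``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if rank == "genus":
        labels = pd.Series(matrix.columns, index=matrix.columns)
    else:
        labels = taxonomy[rank].reindex(matrix.columns)
    labels = labels.fillna(f"unclassified-{rank}")
    labels = labels.replace("", f"unclassified-{rank}")
    out = matrix.T.groupby(labels).sum().T
    out.attrs = dict(matrix.attrs)
    return out
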
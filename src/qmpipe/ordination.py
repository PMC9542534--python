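"""PCoA on Pearson-correlation distances and smoothed abundance trajectories.

Profiles are log-transformed (log10 with a configurable pseudo-count), the
distance between two samples is one minus the Pearson correlation of their
transformed abundance vectors, and classical scaling (principal coordinates
analysis) embeds the samples.  Group differences on the first two coordinates
are tested per timepoint with one-way ANOVA.  Class-level developmental
trajectories are local-linear smooths of log abundance against age with a
pointwise confidence band of the mean (default 30%, matching the narrow
display band used for developmental curves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x PC1..PCk
    eigenvalues: pd.Series
    proportion_explained: pd.Series
    negative_eigenvalue_mass: float  # summed magnitude of zeroed negatives
    excluded_samples: list[str] = field(default_factory=list)


@dataclass
class TrajectoryCurve:
    taxon: str
    scale: str  # "absolute" or "relative"
    age_weeks: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


def pearson_log_distance(
    profile: pd.DataFrame, log_pseudocount: float = 1.0
) -> tuple[DistanceMatrix, list[str]]:
    """Distance matrix d(i,j) = 1 - Pearson r of log10-transformed profiles.

    Samples with a constant transformed vector (correlation undefined) are
    excluded with a note and returned separately.
    """
    logx = np.log10(profile + log_pseudocount)
    sd = logx.std(axis=1, ddof=0)
    excluded = list(logx.index[sd == 0])
    if excluded:
        logger.warning("excluding %d constant sample vector(s): %s",
                       len(excluded), excluded)
        logx = logx.drop(index=excluded)
    r = np.corrcoef(logx.to_numpy())
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(d, ids=list(logx.index)), excluded


def pcoa_pearson(
    profile: pd.DataFrame, log_pseudocount: float = 1.0, n_axes: int | None = None
) -> OrdinationResult:
    """Classical scaling of the Pearson-correlation distance matrix.

    Negative eigenvalues (correlation distances are not generally Euclidean)
    are zeroed and their summed magnitude recorded.
    """
    if len(profile) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    dm, excluded = pearson_log_distance(profile, log_pseudocount)
    import warnings

    with warnings.catch_warnings():
        # skbio warns about full-dimension eigh and negative eigenvalues;
        # negatives are expected for correlation distances and handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh")
    # negative part of the Gram spectrum (skbio zeroes it in the output)
    n = dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    gram_eig = np.linalg.eigvalsh(-0.5 * J @ (dm.data ** 2) @ J)
    neg_mass = float(-gram_eig[gram_eig < -1e-12].sum())
    eig = res.eigvals.clip(lower=0.0)
    prop = eig / eig.sum() if eig.sum() > 0 else eig
    coords = res.samples
    coords.index = dm.ids
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    if n_axes:
        coords = coords.iloc[:, :n_axes]
    eig.index = [f"PC{i + 1}" for i in range(len(eig))]
    prop.index = eig.index
    return OrdinationResult(
        coordinates=coords, eigenvalues=eig, proportion_explained=prop,
        negative_eigenvalue_mass=neg_mass, excluded_samples=excluded,
    )


def test_group_separation(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    timepoint: float,
    axes: tuple[str, ...] = ("PC1", "PC2"),
    group_col: str = "group",
) -> dict[str, float]:
    """One-way ANOVA of group on each principal coordinate at one timepoint.

    Groups with fewer than 2 samples are excluded with a note.  Returns a
    per-axis P value plus a pooled two-axis test (``"pooled"``: smallest
    per-axis P, Bonferroni-doubled).
    """
    samples = ordination.coordinates.index.intersection(metadata.index)
    meta = metadata.loc[samples]
    at_tp = meta[meta["age_weeks"] == timepoint]
    sizes = at_tp[group_col].value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.info("excluding group(s) with <2 samples at week %s: %s",
                    timepoint, small)
        at_tp = at_tp[~at_tp[group_col].isin(small)]
    if at_tp[group_col].nunique() < 2:
        raise ValueError(f"fewer than 2 groups at timepoint {timepoint}")
    out: dict[str, float] = {}
    for axis in axes:
        scores = ordination.coordinates.loc[at_tp.index, axis]
        arrays = [scores[at_tp[group_col] == g].to_numpy()
                  for g in at_tp[group_col].unique()]
        out[axis] = float(stats.f_oneway(*arrays).pvalue)
    out["pooled"] = float(min(1.0, min(out[a] for a in axes) * len(axes)))
    return out


def group_median_trajectories(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    axes: tuple[str, ...] = ("PC1", "PC2"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Median coordinates per (group, timepoint): the trajectory anchors."""
    samples = ordination.coordinates.index.intersection(metadata.index)
    df = ordination.coordinates.loc[samples, list(axes)].join(
        metadata.loc[samples, [group_col, "age_weeks"]])
    return df.groupby([group_col, "age_weeks"])[list(axes)].median()


def _local_linear(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                  bandwidth: float) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-kernel local linear regression with pointwise SE of the mean."""
    est = np.full(len(grid), np.nan)
    se = np.full(len(grid), np.nan)
    for k, g in enumerate(grid):
        u = (x - g) / bandwidth
        w = np.where(np.abs(u) < 1, (1 - np.abs(u) ** 3) ** 3, 0.0)
        use = w > 0
        if use.sum() < 3:
            continue
        Xl = np.column_stack([np.ones(use.sum()), x[use] - g])
        W = w[use]
        XtW = Xl.T * W
        A = XtW @ Xl
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        beta = Ainv @ (XtW @ y[use])
        resid = y[use] - Xl @ beta
        m = int(use.sum())
        sigma2 = float((W * resid ** 2).sum() / W.sum()) * m / max(m - 2, 1)
        B = (Xl.T * W ** 2) @ Xl
        V = sigma2 * (Ainv @ B @ Ainv)
        est[k] = beta[0]
        se[k] = float(np.sqrt(max(V[0, 0], 0.0)))
    return est, se


def smooth_class_trajectories(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    taxa: list[str],
    scale: str = "absolute",
    level: float = 0.30,
    age_range: tuple[float, float] = (4.0, 39.0),
    bandwidth_frac: float = 0.5,
    n_grid: int = 25,
    log_pseudocount: float = 1.0,
) -> list[TrajectoryCurve]:
    """Smoothed mean log-abundance curves with a pointwise confidence band.

    One curve per requested taxon/class column of ``profile``; taxa absent
    from the table are skipped with a note.  The band is
    ``mean +/- z_{(1+level)/2} * SE`` of the local-linear smooth, evaluated on
    a fixed age grid inside ``age_range``.
    """
    ages_all = metadata.loc[profile.index.intersection(metadata.index), "age_weeks"]
    in_range = ages_all[(ages_all >= age_range[0]) & (ages_all <= age_range[1])]
    if in_range.nunique() < 2:
        raise ValueError("need at least 2 distinct ages inside the range")
    grid = np.linspace(age_range[0], age_range[1], n_grid)
    bw = bandwidth_frac * (age_range[1] - age_range[0])
    z = stats.norm.ppf(0.5 + level / 2.0)
    curves = []
    for taxon in taxa:
        if taxon not in profile.columns:
            logger.info("taxon %r absent from profile; skipped", taxon)
            continue
        y = np.log10(profile.loc[in_range.index, taxon].to_numpy(dtype=float)
                     + log_pseudocount)
        est, se = _local_linear(in_range.to_numpy(dtype=float), y, grid, bw)
        curves.append(TrajectoryCurve(
            taxon=taxon, scale=scale, age_weeks=grid, mean=est,
            lower=est - z * se, upper=est + z * se, level=level,
        ))
    return curves


def age_slope(profile: pd.DataFrame, metadata: pd.DataFrame, taxon: str,
              log_pseudocount: float = 1.0) -> float:
    """Least-squares slope of log10 abundance vs age; the trend-sign summary."""
    samples = profile.index.intersection(metadata.index)
    x = metadata.loc[samples, "age_weeks"].to_numpy(dtype=float)
    y = np.log10(profile.loc[samples, taxon].to_numpy(dtype=float) + log_pseudocount)
    return float(stats.linregress(x, y).slope)
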
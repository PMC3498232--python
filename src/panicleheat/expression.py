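"""Normalization, QC, detection-flag filtering and fold-change calling.

The processing order mirrors standard single-channel array practice:
quantile normalization across arrays, baseline-to-median per probe, log2
values throughout, then a present-call filter (at least half the samples
flagged P) and pure fold-change rules for differential and heat-responsive
calls (no variance-based test — the design has only two replicates per
time point).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .datatypes import (
    TREATMENT_TIME_POINTS,
    DifferentialCalls,
    ExpressionDataset,
    FoldChangeTable,
    HRSet,
    QcReport,
    map_probes_to_genes,
)

__all__ = [
    "quantile_normalize",
    "baseline_to_median",
    "replicate_correlation",
    "flag_filter",
    "fold_changes",
    "differential_probes",
    "intersect_all_timepoints",
    "heat_responsive",
]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Each rank is replaced by the cross-sample mean of the values at that
    rank; ties within a column receive the mean of their tied rank-means.
    Row and column labels are preserved.
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization needs >=2 columns; returning input unchanged")
        return values.copy()
    if values.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix")

    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    rank_means = np.take_along_axis(arr, order, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = np.empty(arr.shape[0])
        col[order[:, j]] = rank_means
        # ties: every cell with the same input value gets the mean of the
        # rank-means its tied group spans
        col = pd.Series(col).groupby(arr[:, j]).transform("mean").to_numpy()
        out[:, j] = col
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def baseline_to_median(values: pd.DataFrame) -> pd.DataFrame:
    """Center each probe row on its across-sample median (log2 scale).

    Idempotent: the median of a centered row is zero.
    """
    med = values.median(axis=1)
    return values.sub(med, axis=0)


def replicate_correlation(
    values: pd.DataFrame, design: pd.DataFrame, threshold: float = 0.99
) -> QcReport:
    """Pairwise sample Pearson correlations plus a complete-linkage tree.

    The tree is built on 1 - r distances, as used for replicate QC of array
    data.  Replicate pairs (same time point) falling below ``threshold`` are
    flagged; a zero-variance sample yields an undefined correlation, which is
    reported as a failure for the pairs involving it.
    """
    corr = values.corr(method="pearson")

    dist = 1.0 - corr.to_numpy(dtype=float)
    dist = np.where(np.isfinite(dist), dist, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="complete")
    leaf_order = [values.columns[i] for i in leaves_list(z)]

    rows = []
    for tp, sub in design.loc[design.index.intersection(values.columns)].groupby(
        "time_point", sort=False
    ):
        samples = list(sub.sort_values("replicate").index)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                r = corr.loc[samples[i], samples[j]]
                passed = bool(np.isfinite(r) and r >= threshold)
                rows.append((tp, samples[i], samples[j], r, passed))
    pairs = pd.DataFrame(
        rows, columns=["time_point", "sample_a", "sample_b", "r", "passed"]
    )
    return QcReport(
        correlations=corr,
        linkage=z,
        leaf_order=leaf_order,
        replicate_pairs=pairs,
        threshold=threshold,
    )


def flag_filter(dataset: ExpressionDataset, min_present: int | None = None) -> pd.Index:
    """Probes detected (P flag) in at least half of the samples.

    With the canonical 12-sample design the cutoff is >=6 P flags.  For other
    sample counts the threshold rescales to ceil(n_samples / 2) with a
    warning (unless ``min_present`` is given explicitly).
    """
    n_samples = dataset.values.shape[1]
    if min_present is None:
        if n_samples == 12:
            min_present = 6
        else:
            min_present = math.ceil(n_samples / 2)
            warnings.warn(
                f"{n_samples} samples (expected 12); present-call threshold "
                f"rescaled to {min_present}"
            )
    n_present = (dataset.flags == "P").sum(axis=1)
    kept = dataset.probes[n_present >= min_present]
    return kept


def fold_changes(dataset: ExpressionDataset) -> FoldChangeTable:
    """Log2 fold change per treatment time point vs the untreated control.

    log2fc(probe, t) = mean(log2 values of t's replicates)
                     - mean(log2 values of CK's replicates).
    A time point with a single available replicate uses that value, with a
    warning.
    """
    ck_samples = dataset.samples_for("CK")
    if not ck_samples:
        raise ValueError("no control (CK) samples in design")
    ck_mean = dataset.values[ck_samples].mean(axis=1)

    cols = {}
    for tp in TREATMENT_TIME_POINTS:
        samples = dataset.samples_for(tp)
        if not samples:
            raise ValueError(f"no samples for time point {tp}")
        if len(samples) < 2:
            warnings.warn(f"time point {tp} has a single replicate; using it as the mean")
        cols[tp] = dataset.values[samples].mean(axis=1) - ck_mean
    return FoldChangeTable(pd.DataFrame(cols)[list(TREATMENT_TIME_POINTS)])


def differential_probes(fct: FoldChangeTable, fold: float = 3.0) -> DifferentialCalls:
    """Per-time-point up/down calls at a strict |fold change| > ``fold``.

    "More than ``fold``-fold" is read strictly: |log2fc| must exceed
    log2(fold); a probe sitting exactly on the boundary is not called.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    cut = math.log2(fold)
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for tp in TREATMENT_TIME_POINTS:
        col = fct.log2fc[tp]
        up[tp] = set(col.index[col > cut])
        down[tp] = set(col.index[col < -cut])
    return DifferentialCalls(up=up, down=down, fold=fold)


def intersect_all_timepoints(
    calls: DifferentialCalls, probe_gene: pd.Series | None = None
) -> tuple[set[str], set[str]]:
    """Probes differential (either direction) at every treatment time point.

    Direction need not be consistent across time points.  Returns the probe
    set and, when annotation is supplied, the mapped gene set (any-probe
    rule); otherwise an empty gene set.
    """
    probe_sets = [calls.differential(tp) for tp in TREATMENT_TIME_POINTS]
    probes = set.intersection(*probe_sets) if probe_sets else set()
    genes = map_probes_to_genes(probes, probe_gene) if probe_gene is not None else set()
    return probes, genes


def heat_responsive(
    calls: DifferentialCalls,
    probe_gene: pd.Series | None = None,
    min_timepoints: int = 2,
) -> HRSet:
    """Heat-responsive set: differential in >= ``min_timepoints`` time points.

    Membership is direction-agnostic across time points — a probe strongly
    induced early and repressed late qualifies just as a monotone one does.
    """
    if min_timepoints > len(TREATMENT_TIME_POINTS):
        raise ValueError(
            f"min_timepoints must be <= {len(TREATMENT_TIME_POINTS)}"
        )
    counts = calls.n_qualifying()
    probes = set(counts.index[counts >= min_timepoints])
    genes = map_probes_to_genes(probes, probe_gene) if probe_gene is not None else set()
    return HRSet(probes=probes, genes=genes, min_timepoints=min_timepoints)
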
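"""Core containers for the time-course heat-stress expression pipeline.

The experimental design is fixed by the study layout this package models:
a single-channel microarray time course on rice panicle sampled at 0 min
(untreated control, ``CK``), 20 min, 60 min, 2 h, 4 h and 8 h after transfer
to 40 °C, with two independent biological replicates per time point
(12 arrays in total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: All time points in sampling order.  ``CK`` is the untreated calibrator.
TIME_POINTS: tuple[str, ...] = ("CK", "20min", "60min", "2h", "4h", "8h")

#: Heat-treatment time points (everything except the control).
TREATMENT_TIME_POINTS: tuple[str, ...] = TIME_POINTS[1:]

#: Replicates per time point in the canonical design.
N_REPLICATES = 2


def default_design() -> pd.DataFrame:
    """The canonical 12-sample design table.

    Returns a frame indexed by sample id (``CK-1`` ... ``8h-2``) with columns
    ``time_point`` and ``replicate``, ordered CK-1, CK-2, 20min-1, ... 8h-2.
    """
    rows = []
    for tp in TIME_POINTS:
        for rep in range(1, N_REPLICATES + 1):
            rows.append((f"{tp}-{rep}", tp, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "time_point", "replicate"])
    return df.set_index("sample_id")


@dataclass
class ExpressionDataset:
    """A probe x sample log2-intensity matrix with detection flags.

    Attributes
    ----------
    values : DataFrame
        Probe x sample log2 intensities.
    flags : DataFrame
        Same shape as ``values``; cells in {P, A, M} (present / absent /
        marginal detection calls from feature extraction).  Missing flags are
        treated as A (conservative).
    design : DataFrame
        Indexed by sample id with columns ``time_point`` and ``replicate``.
    probe_gene : Series
        Probe id -> gene id.  Probes without annotation may be absent or NaN.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    design: pd.DataFrame
    probe_gene: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape != self.flags.shape:
            raise ValueError("values and flags must have identical shape")
        if not self.values.columns.equals(self.flags.columns):
            raise ValueError("values and flags must share sample columns")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        bad = set(self.flags.to_numpy().ravel()) - {"P", "A", "M"}
        if bad:
            raise ValueError(f"invalid detection flags: {sorted(bad)}")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, time_point: str) -> list[str]:
        """Sample ids belonging to one time point, in replicate order."""
        sub = self.design.loc[self.design["time_point"] == time_point]
        sub = sub.loc[sub.index.intersection(self.samples)]
        return list(sub.sort_values("replicate").index)

    def subset(self, probes) -> "ExpressionDataset":
        """Restrict to a probe subset, preserving order of ``probes``."""
        idx = pd.Index(probes)
        return ExpressionDataset(
            values=self.values.loc[idx],
            flags=self.flags.loc[idx],
            design=self.design,
            probe_gene=self.probe_gene,
        )


@dataclass
class FoldChangeTable:
    """Per-probe log2 fold change vs the untreated control at each treatment
    time point.  Columns are fixed to ``TREATMENT_TIME_POINTS`` order."""

    log2fc: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.log2fc.columns)
        if cols != list(TREATMENT_TIME_POINTS):
            raise ValueError(
                f"fold-change columns must be {TREATMENT_TIME_POINTS}, got {cols}"
            )

    @property
    def probes(self) -> pd.Index:
        return self.log2fc.index


@dataclass
class DifferentialCalls:
    """Per-time-point up/down probe sets from a fold-change cutoff."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]
    fold: float = 3.0

    def __post_init__(self) -> None:
        for tp in self.up:
            overlap = self.up[tp] & self.down.get(tp, set())
            if overlap:
                raise ValueError(f"probe(s) both up and down at {tp}: {sorted(overlap)[:3]}")

    def differential(self, time_point: str) -> set[str]:
        """Probes differential (either direction) at one time point."""
        return self.up.get(time_point, set()) | self.down.get(time_point, set())

    def n_qualifying(self) -> pd.Series:
        """Per probe, the number of time points at which it is differential."""
        counts: dict[str, int] = {}
        for tp in self.up:
            for p in self.differential(tp):
                counts[p] = counts.get(p, 0) + 1
        return pd.Series(counts, dtype=int)


@dataclass
class HRSet:
    """Heat-responsive probes/genes: differential (>fold change vs control)
    in at least ``min_timepoints`` of the treatment time points."""

    probes: set[str]
    genes: set[str]
    min_timepoints: int = 2


@dataclass
class QcReport:
    """Replicate-quality report: all pairwise Pearson correlations, the
    complete-linkage sample tree on 1 - r, and per-replicate-pair QC flags."""

    correlations: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    replicate_pairs: pd.DataFrame  # columns: time_point, sample_a, sample_b, r, passed
    threshold: float = 0.99

    @property
    def all_passed(self) -> bool:
        return bool(self.replicate_pairs["passed"].all())


def map_probes_to_genes(probes, probe_gene: pd.Series) -> set[str]:
    """Collapse a probe set to the gene level (any-probe rule).

    A gene is included iff at least one of its probes is in ``probes``.
    Probes lacking annotation are dropped; a warning reports how many.
    """
    probes = set(probes)
    annotated = probe_gene.dropna()
    hit = annotated.loc[annotated.index.intersection(probes)]
    n_unmapped = len(probes) - len(hit)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} probe(s) lack gene annotation and were dropped")
    return set(hit.values)
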
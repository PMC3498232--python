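"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is exercised against data produced
here: a 12-sample log2 expression matrix with planted temporal fold-change
profiles and P/A/M detection flags, promoter databases with motifs planted
at controlled per-cluster frequencies (including co-occurring pairs at a
fixed start-to-start distance), and qPCR plates whose CT values encode a
known log2 fold change.

All generators are deterministic given (config, seed).  Intensities are
generated directly on the log2 scale (baseline + planted profile +
Gaussian noise); the linear scale is never materialized, since the
pipeline consumes log2 values throughout.  Promoter background sequence is
i.i.d. with configurable GC content — adequate for testing enrichment
statistics, though real promoters have dinucleotide and positional
structure this does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    N_REPLICATES,
    TIME_POINTS,
    TREATMENT_TIME_POINTS,
    ExpressionDataset,
    default_design,
)
from .motifs import IUPAC, validate_motif
from .qpcr import QpcrPlate

__all__ = [
    "DEFAULT_CLUSTER_PROFILES",
    "DEFAULT_MOTIF_LIBRARY",
    "ExpressionSimConfig",
    "PromoterSimConfig",
    "GroundTruth",
    "generate_expression_dataset",
    "generate_promoter_set",
    "generate_qpcr_plate",
    "default_expression_config",
    "default_promoter_config",
    "null_promoter_config",
]

#: Twelve temporal log2FC archetypes (20 min, 60 min, 2 h, 4 h, 8 h vs CK),
#: one per co-expression cluster resolved by the panicle heat time course:
#: early/late/continuous regulation in both directions, including the
#: early-down-late-up reversal, with several magnitude variants of the
#: abundant early-up and late-up classes.
DEFAULT_CLUSTER_PROFILES: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("early-down", (-2.0, -2.0, -1.5, 0.0, 0.0)),
    ("early-down-late-up", (-2.0, -1.5, -1.2, 1.5, 2.0)),
    ("late-down", (0.0, 0.0, -0.5, -2.0, -2.0)),
    ("continuous-down", (-2.0, -2.0, -2.0, -2.0, -2.0)),
    ("early-up", (2.0, 2.0, 1.5, 0.0, 0.0)),
    ("early-up", (3.0, 2.5, 2.0, 0.5, 0.0)),
    ("late-up", (0.0, 0.0, 0.5, 2.0, 2.0)),
    ("early-up", (2.5, 3.0, 1.8, 0.3, 0.3)),
    ("early-up", (1.5, 1.5, 1.2, 0.0, 0.0)),
    ("late-up", (0.3, 0.3, 0.5, 2.5, 3.0)),
    ("late-up", (0.0, 0.2, 1.0, 1.8, 1.5)),
    ("continuous-up", (2.5, 3.0, 3.0, 2.5, 2.0)),
)

#: Synthetic cis-element library.  Names evoke the stress-responsive
#: PlantCARE elements central to the heat-response promoter analysis (HSE,
#: ABRE, CE3, GCC box, GC repeat, Box I, W box, MYB site), but the consensi
#: are synthetic, lengthened stand-ins (10-14 bp around the natural cores)
#: so that chance matches in i.i.d. promoter sequence are rare enough for
#: planted-signal recovery experiments.
DEFAULT_MOTIF_LIBRARY: dict[str, str] = {
    "HSE_like": "TTCTAGAAGCTTCT",
    "ABRE_like": "TACGTGTCGCAC",
    "CE3_like": "GACGCGTGKCCTC",
    "GCC_box_like": "TAAGAGCCGCCA",
    "GC_repeat_like": "GCCGGCGGCGCA",
    "Box_I_like": "TTTCAAACCTGCAC",
    "W_box_like": "GTTGACCACGTA",
    "MYB_like": "CAACTGGTCGTA",
}


@dataclass
class ExpressionSimConfig:
    """Design of a synthetic 12-sample expression experiment.

    ``cluster_profiles`` are 5-vectors of log2FC per treatment time point;
    ``n_planted_per_cluster`` is one count or a per-cluster list.  Noise is
    i.i.d. Gaussian on the log2 scale; each cell is flagged A independently
    with ``flag_absent_rate`` (M with ``flag_marginal_rate``), else P.
    """

    n_probes: int = 5000
    n_planted_per_cluster: int | Sequence[int] = 60
    cluster_profiles: Sequence[Sequence[float]] = field(
        default_factory=lambda: [p for _, p in DEFAULT_CLUSTER_PROFILES]
    )
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.5
    flag_absent_rate: float = 0.3
    flag_marginal_rate: float = 0.0
    frac_unannotated: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.flag_absent_rate < 1:
            raise ValueError("flag_absent_rate must be in [0, 1)")
        for prof in self.cluster_profiles:
            if len(prof) != len(TREATMENT_TIME_POINTS):
                raise ValueError(
                    f"each profile needs {len(TREATMENT_TIME_POINTS)} entries, got {len(prof)}"
                )

    def planted_counts(self) -> list[int]:
        k = len(self.cluster_profiles)
        if isinstance(self.n_planted_per_cluster, int):
            return [self.n_planted_per_cluster] * k
        counts = list(self.n_planted_per_cluster)
        if len(counts) != k:
            raise ValueError("n_planted_per_cluster list must match cluster_profiles")
        return counts


@dataclass
class PromoterSimConfig:
    """Design of a synthetic promoter database with planted cis-elements.

    Background genes carry each motif independently at ``background_freqs``;
    genes of cluster ``c`` carry motif ``m`` at ``motif_plant_freqs[(c, m)]``
    when given, else at the background frequency (so an unplanted cluster is
    exchangeable with the background).  ``pair_plants`` entries
    ``(target, motif_a, motif_b, distance, probability)`` plant motif_a at a
    uniform legal start with motif_b exactly ``distance`` bp downstream
    (start-to-start); ``target`` is a cluster index or ``"background"``.
    """

    n_background_genes: int = 200
    cluster_sizes: Sequence[int] = (40,)
    promoter_length: int = 3000
    gc_content: float = 0.45
    motif_library: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_LIBRARY)
    )
    background_freqs: Mapping[str, float] = field(default_factory=dict)
    motif_plant_freqs: Mapping[tuple[int, str], float] = field(default_factory=dict)
    pair_plants: Sequence[tuple] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        probs = list(self.background_freqs.values()) + list(
            self.motif_plant_freqs.values()
        ) + [p for *_, p in self.pair_plants]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all planting probabilities must be in [0, 1]")
        longest = max((len(c) for c in self.motif_library.values()), default=0)
        if self.promoter_length < longest:
            raise ValueError("promoter_length shorter than the longest motif")
        for target, a, b, dist, _p in self.pair_plants:
            if dist < 0:
                raise ValueError("planted pair distance must be >= 0")
            if dist < len(self.motif_library[a]):
                raise ValueError(
                    f"pair distance {dist} < len({a}); planted sites would overlap"
                )
            if dist + len(self.motif_library[b]) > self.promoter_length:
                raise ValueError("pair distance + motif length exceeds promoter_length")


@dataclass
class GroundTruth:
    """What the generators planted, keyed the way the pipeline reports.

    ``planted_de``: probe -> {time point -> +1/-1} for nonzero planted
    log2FC entries; ``planted_cluster``: probe or gene -> 1-based cluster
    index; ``planted_profiles``: cluster -> log2FC 5-vector;
    ``planted_motif_sites``: gene -> [(motif, 1-based start)];
    ``planted_pairs``: [(gene, motif_a, motif_b, start distance)].
    """

    planted_de: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_cluster: dict[str, int] = field(default_factory=dict)
    planted_profiles: dict[int, tuple[float, ...]] = field(default_factory=dict)
    planted_motif_sites: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str, str, int]] = field(default_factory=list)

    def de_sets(self, fold: float = 3.0) -> tuple[dict[str, set], dict[str, set]]:
        """Planted up/down probe sets per time point at a strict
        |log2FC| > log2(fold) rule — the sets a perfect caller recovers."""
        cut = np.log2(fold)
        up: dict[str, set] = {tp: set() for tp in TREATMENT_TIME_POINTS}
        down: dict[str, set] = {tp: set() for tp in TREATMENT_TIME_POINTS}
        for probe, cluster in self.planted_cluster.items():
            profile = self.planted_profiles[cluster]
            for tp, value in zip(TREATMENT_TIME_POINTS, profile):
                if value > cut:
                    up[tp].add(probe)
                elif value < -cut:
                    down[tp].add(probe)
        return up, down

    def planted_hr(self, fold: float = 3.0, min_timepoints: int = 2) -> set[str]:
        """Probes planted differential in >= ``min_timepoints`` time points."""
        up, down = self.de_sets(fold)
        counts: dict[str, int] = {}
        for tp in TREATMENT_TIME_POINTS:
            for probe in up[tp] | down[tp]:
                counts[probe] = counts.get(probe, 0) + 1
        return {p for p, c in counts.items() if c >= min_timepoints}

    def planted_all_timepoints(self, fold: float = 3.0) -> set[str]:
        return self.planted_hr(fold, min_timepoints=len(TREATMENT_TIME_POINTS))

    def to_json(self, path) -> None:
        payload = {
            "planted_de": self.planted_de,
            "planted_cluster": self.planted_cluster,
            "planted_profiles": {str(k): list(v) for k, v in self.planted_profiles.items()},
            "planted_motif_sites": {
                g: [[m, s] for m, s in sites]
                for g, sites in self.planted_motif_sites.items()
            },
            "planted_pairs": [list(p) for p in self.planted_pairs],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def default_expression_config(seed: int = 0, **overrides) -> ExpressionSimConfig:
    """The standard simulated experiment: 5,000 probes, 12 planted temporal
    archetypes x 60 probes, log2 noise SD 0.25, 30% absent calls."""
    return ExpressionSimConfig(seed=seed, **overrides)


def generate_expression_dataset(
    config: ExpressionSimConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the 12-array experiment (6 time points x 2 replicates).

    Column order is CK-1, CK-2, 20min-1, ..., 8h-2.  Planted probes' expected
    log2FC at each time point equals their assigned profile; non-planted
    probes have expectation zero at every time point.  Flags are drawn
    independently per cell.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.planted_counts()
    n_planted = sum(counts)
    if n_planted > config.n_probes:
        raise ValueError("more planted probes than probes")

    width = max(5, len(str(config.n_probes)))
    probes = [f"P{i:0{width}d}" for i in range(1, config.n_probes + 1)]
    design = default_design()
    samples = list(design.index)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_probes)
    effects = np.zeros((config.n_probes, len(samples)))

    planted_idx = rng.choice(config.n_probes, size=n_planted, replace=False)
    truth = GroundTruth()
    pos = 0
    tp_of_sample = design["time_point"].to_numpy()
    for cluster_ix, (profile, count) in enumerate(
        zip(config.cluster_profiles, counts), start=1
    ):
        profile = tuple(float(x) for x in profile)
        truth.planted_profiles[cluster_ix] = profile
        lfc_by_tp = dict(zip(TREATMENT_TIME_POINTS, profile))
        for idx in planted_idx[pos : pos + count]:
            probe = probes[idx]
            truth.planted_cluster[probe] = cluster_ix
            truth.planted_de[probe] = {
                tp: (1 if v > 0 else -1) for tp, v in lfc_by_tp.items() if v != 0
            }
            for j, tp in enumerate(tp_of_sample):
                effects[idx, j] = lfc_by_tp.get(tp, 0.0)
        pos += count

    noise = rng.normal(0.0, config.noise_sd, effects.shape) if config.noise_sd > 0 else 0.0
    values = pd.DataFrame(
        baseline[:, None] + effects + noise, index=probes, columns=samples
    )

    u = rng.random(effects.shape)
    flags_arr = np.where(
        u < config.flag_absent_rate,
        "A",
        np.where(u < config.flag_absent_rate + config.flag_marginal_rate, "M", "P"),
    )
    flags = pd.DataFrame(flags_arr, index=probes, columns=samples)

    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.n_probes + 1)]
    probe_gene = pd.Series(gene_ids, index=probes, dtype=object)
    if config.frac_unannotated > 0:
        drop = rng.random(config.n_probes) < config.frac_unannotated
        probe_gene[drop] = np.nan

    dataset = ExpressionDataset(
        values=values, flags=flags, design=design, probe_gene=probe_gene
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# promoter simulation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _realize_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else rng.choice(list(IUPAC[c])) for c in consensus)


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    length: int,
    promoter_length: int,
    max_tries: int = 200,
) -> int | None:
    """Uniform random 0-based start for a site that avoids existing sites."""
    for _ in range(max_tries):
        start = int(rng.integers(0, promoter_length - length + 1))
        if all(start + length <= s or start >= e for s, e in occupied):
            return start
    return None


def default_promoter_config(seed: int = 0) -> PromoterSimConfig:
    """The standard planted-promoter experiment: 200 background genes and
    one 40-gene cluster over 3,000-bp promoters; every motif at 10%
    background frequency; one motif planted in 80% of cluster promoters; one
    motif pair planted at start-to-start distance 100 in 60% of cluster
    promoters vs 2% of background."""
    lib = dict(DEFAULT_MOTIF_LIBRARY)
    return PromoterSimConfig(
        n_background_genes=200,
        cluster_sizes=(40,),
        promoter_length=3000,
        gc_content=0.45,
        motif_library=lib,
        background_freqs={m: 0.10 for m in lib},
        motif_plant_freqs={(1, "HSE_like"): 0.80},
        pair_plants=(
            (1, "GCC_box_like", "CE3_like", 100, 0.60),
            ("background", "GCC_box_like", "CE3_like", 100, 0.02),
        ),
        seed=seed,
    )


def null_promoter_config(seed: int = 0) -> PromoterSimConfig:
    """A no-planting configuration for type-I-error calibration: the
    "cluster" receives every motif at exactly its background frequency, so
    enrichment tests see pure exchangeable noise.  Background frequencies
    span 0.15-0.50 so the discrete hypergeometric tail has fine granularity
    near the nominal level; 1,000-bp promoters keep the study fast without
    affecting gene-level carrier frequencies."""
    lib = dict(DEFAULT_MOTIF_LIBRARY)
    freqs = dict(zip(sorted(lib), (0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)))
    return PromoterSimConfig(
        n_background_genes=500,
        cluster_sizes=(100,),
        promoter_length=1000,
        gc_content=0.45,
        motif_library=lib,
        background_freqs=freqs,
        motif_plant_freqs={(1, m): f for m, f in freqs.items()},
        pair_plants=(),
        seed=seed,
    )


def generate_promoter_set(
    config: PromoterSimConfig,
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Simulate a promoter database with planted motifs and motif pairs.

    Returns (promoters, motif library, ground truth).  Gene ids are unique:
    background genes ``BGxxxx`` and cluster genes ``C<cluster>Gxxx``.
    Planted sites never overlap one another (positions are redrawn on
    collision); ground truth lists planted sites only — the scanner may
    additionally find chance matches in the random background.
    """
    rng = np.random.default_rng(config.seed)
    library = {name: validate_motif(c) for name, c in config.motif_library.items()}

    genes: list[tuple[str, int | None]] = [
        (f"BG{i:04d}", None) for i in range(1, config.n_background_genes + 1)
    ]
    for c, size in enumerate(config.cluster_sizes, start=1):
        genes += [(f"C{c}G{i:03d}", c) for i in range(1, size + 1)]

    truth = GroundTruth()
    promoters: dict[str, str] = {}
    for gene, cluster in genes:
        seq = _random_sequence(rng, config.promoter_length, config.gc_content)
        occupied: list[tuple[int, int]] = []
        sites: list[tuple[str, int]] = []
        if cluster is not None:
            truth.planted_cluster[gene] = cluster

        # pairs first: they are the most position-constrained plantings
        for target, name_a, name_b, dist, prob in config.pair_plants:
            applies = (target == "background" and cluster is None) or (target == cluster)
            if not applies or rng.random() >= prob:
                continue
            len_a, len_b = len(library[name_a]), len(library[name_b])
            spans = None
            for _ in range(200):
                start_a = int(rng.integers(0, config.promoter_length - dist - len_b + 1))
                cand = [(start_a, start_a + len_a), (start_a + dist, start_a + dist + len_b)]
                # dist >= len_a (validated), so the two sites cannot collide
                if all(
                    e2 <= s or s2 >= e for s, e in occupied for s2, e2 in cand
                ):
                    spans = cand
                    break
            if spans is None:
                raise RuntimeError(f"could not place pair {name_a}/{name_b} in {gene}")
            for (start, end), name in zip(spans, (name_a, name_b)):
                seq[start:end] = list(_realize_consensus(rng, library[name]))
                occupied.append((start, end))
                sites.append((name, start + 1))
            truth.planted_pairs.append((gene, name_a, name_b, dist))

        # independent single-motif plantings
        for name in sorted(library):
            if cluster is not None:
                prob = config.motif_plant_freqs.get(
                    (cluster, name), config.background_freqs.get(name, 0.0)
                )
            else:
                prob = config.background_freqs.get(name, 0.0)
            if rng.random() >= prob:
                continue
            length = len(library[name])
            start = _place(rng, occupied, length, config.promoter_length)
            if start is None:
                raise RuntimeError(f"could not place {name} in {gene}")
            seq[start : start + length] = list(_realize_consensus(rng, library[name]))
            occupied.append((start, start + length))
            sites.append((name, start + 1))

        if sites:
            truth.planted_motif_sites[gene] = sorted(sites, key=lambda x: x[1])
        promoters[gene] = "".join(seq)

    return promoters, library, truth


# ---------------------------------------------------------------------------
# qPCR simulation


def generate_qpcr_plate(
    genes: Sequence[str],
    true_log2fc: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    ref_ct: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_ct: float = 24.0,
    n_bio: int = 2,
    n_tech: int = 3,
    reference_gene: str = "actin1",
) -> QpcrPlate:
    """Simulate a qPCR plate whose noiseless 2^(-ddCT) equals 2^(true log2FC).

    Target CT in a condition is ``base_ct`` minus the gene's true log2FC
    there (CK has log2FC 0 by definition); the reference gene sits at
    ``ref_ct`` in every condition.  Gaussian CT noise with SD ``noise_sd``
    is added independently to every well; each biological replicate carries
    ``n_tech`` technical replicates.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(true_log2fc, pd.DataFrame):
        true_log2fc = {
            g: true_log2fc.loc[g].to_dict() for g in true_log2fc.index
        }
    rng = np.random.default_rng(seed)

    def well_noise() -> float:
        return float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0

    rows = []
    for condition in TIME_POINTS:
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                rows.append(
                    (reference_gene, condition, bio, tech, ref_ct + well_noise())
                )
            for gene in genes:
                lfc = 0.0 if condition == "CK" else float(
                    true_log2fc[gene].get(condition, 0.0)
                )
                for tech in range(1, n_tech + 1):
                    rows.append(
                        (gene, condition, bio, tech, base_ct - lfc + well_noise())
                    )
    records = pd.DataFrame(
        rows, columns=["gene", "condition", "bio_rep", "tech_rep", "ct"]
    )
    return QpcrPlate(records=records, reference_gene=reference_gene, calibrator="CK")
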
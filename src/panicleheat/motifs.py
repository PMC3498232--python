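"""Promoter cis-element scanning, enrichment and co-occurrence networks.

Promoters are the -3000..-1 region upstream of the ATG.  Motifs are
PlantCARE-style IUPAC consensus strings (HSE, ABRE, CE3, GCC box, ...),
matched exactly under the degenerate-code table on both strands — a
deterministic alternative to PWM scanning that suits consensus-defined
elements and makes every downstream count reproducible.

Counting is gene-level throughout: a motif "occurs" in a gene if the
promoter carries at least one match, and two distinct motifs "co-occur"
in a gene if any pair of their matches starts within a fixed window
(default 250 bp), counted at most once per promoter however many times the
configuration repeats.  Enrichment of a motif in a co-expression cluster
and significance of a pair's co-occurrence are both scored against the
whole-database background with the hypergeometric upper tail, and the
results export as a Cytoscape-style network: node size = carrier count,
node color = enrichment ratio, node shape = enrichment class (diamond
p < 0.001, triangle 0.001 <= p < 0.05, circle otherwise), edge style =
co-occurrence class (solid p < 0.01, dash 0.01 <= p < 0.05).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .stats import enrichment_ratio, hypergeom_upper_tail

__all__ = [
    "IUPAC",
    "reverse_complement_iupac",
    "validate_motif",
    "scan_motifs",
    "cooccurrences",
    "BackgroundDB",
    "build_background",
    "motif_enrichment",
    "pair_cooccurrence",
    "build_network",
    "classify_node",
    "classify_edge",
]

#: IUPAC nucleotide code -> set of concrete bases matched.  A consensus N
#: matches any base of the sequence, but an N *in the sequence* (masked or
#: unknown base) matches nothing.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_iupac(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus (degeneracy-preserving)."""
    return consensus.translate(_COMPLEMENT)[::-1]


def validate_motif(consensus: str, min_length: int = 4) -> str:
    """Uppercase and validate an IUPAC consensus; rejected codes raise."""
    consensus = consensus.strip().upper()
    bad = set(consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in motif {consensus!r}")
    if len(consensus) < min_length:
        raise ValueError(f"motif {consensus!r} shorter than {min_length} bp")
    return consensus


def _consensus_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported; character classes
    # never include N, so sequence Ns match nothing
    body = "".join(
        IUPAC[c] if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_motifs(promoters: dict[str, str], motifs: dict[str, str]) -> pd.DataFrame:
    """Scan every promoter for every consensus on both strands.

    Returns a frame with columns ``gene, motif, start, end, strand``.
    Coordinates are 1-based within the promoter string; a reverse-strand
    match is reported at the forward-strand coordinate of its leftmost base.
    Overlapping matches are all reported.
    """
    compiled = {}
    for name, consensus in motifs.items():
        consensus = validate_motif(consensus)
        fwd = _consensus_regex(consensus)
        rc = reverse_complement_iupac(consensus)
        rev = None if rc == consensus else _consensus_regex(rc)
        compiled[name] = (len(consensus), fwd, rev)

    rows = []
    for gene, seq in promoters.items():
        seq = seq.upper()
        for name, (length, fwd, rev) in compiled.items():
            for m in fwd.finditer(seq):
                rows.append((gene, name, m.start() + 1, m.start() + length, "+"))
            if rev is not None:
                for m in rev.finditer(seq):
                    rows.append((gene, name, m.start() + 1, m.start() + length, "-"))
    df = pd.DataFrame(rows, columns=["gene", "motif", "start", "end", "strand"])
    return df.sort_values(["gene", "motif", "start", "strand"]).reset_index(drop=True)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def cooccurrences(
    occurrences: pd.DataFrame, window: int = 250, distance_mode: str = "start"
) -> dict[str, set[tuple[str, str]]]:
    """Per-gene sets of unordered distinct-motif pairs found within ``window``.

    Distance between two matches is |start difference| in ``start`` mode
    (default) or the inter-match gap in ``gap`` mode (0 for touching or
    overlapping matches).  Strand is ignored.  A pair is recorded at most
    once per gene regardless of how many match pairs qualify.
    """
    if distance_mode not in ("start", "gap"):
        raise ValueError("distance_mode must be 'start' or 'gap'")
    out: dict[str, set[tuple[str, str]]] = {}
    for gene, sub in occurrences.groupby("gene", sort=False):
        by_motif = {
            motif: list(zip(g["start"], g["end"]))
            for motif, g in sub.groupby("motif", sort=False)
        }
        pairs = set()
        for a, b in combinations(sorted(by_motif), 2):
            hit = False
            for sa, ea in by_motif[a]:
                for sb, eb in by_motif[b]:
                    if distance_mode == "start":
                        d = abs(sa - sb)
                    else:
                        d = max(0, max(sa, sb) - min(ea, eb) - 1)
                    if d <= window:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add(_pair_key(a, b))
        if pairs:
            out[gene] = pairs
    return out


@dataclass
class BackgroundDB:
    """Gene-level motif counts over the whole promoter database.

    ``N`` genes total; ``n[motif]`` genes carrying >=1 match;
    ``pair_n[(a, b)]`` genes where the (sorted) pair co-occurs within the
    window.  ``gene_motifs``/``gene_pairs`` retain the per-gene sets so a
    cluster's counts can be formed by intersection.
    """

    N: int
    n: dict[str, int]
    pair_n: dict[tuple[str, str], int]
    window: int
    gene_motifs: dict[str, set[str]] = field(default_factory=dict)
    gene_pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def pair_count(self, a: str, b: str) -> int:
        return self.pair_n.get(_pair_key(a, b), 0)


def build_background(
    occurrences: pd.DataFrame,
    promoters: dict[str, str],
    window: int = 250,
    distance_mode: str = "start",
) -> BackgroundDB:
    """Summarize a scan of the full promoter database into gene-level counts."""
    gene_motifs = {
        gene: set(sub["motif"]) for gene, sub in occurrences.groupby("gene", sort=False)
    }
    gene_pairs = cooccurrences(occurrences, window=window, distance_mode=distance_mode)

    n: dict[str, int] = {}
    for motifs in gene_motifs.values():
        for m in motifs:
            n[m] = n.get(m, 0) + 1
    pair_n: dict[tuple[str, str], int] = {}
    for pairs in gene_pairs.values():
        for p in pairs:
            pair_n[p] = pair_n.get(p, 0) + 1
    return BackgroundDB(
        N=len(promoters),
        n=n,
        pair_n=pair_n,
        window=window,
        gene_motifs=gene_motifs,
        gene_pairs=gene_pairs,
    )


def classify_node(p: float) -> str:
    """Enrichment significance class: diamond < 0.001 <= triangle < 0.05
    <= circle.  Boundary values fall in the less significant class."""
    if p < 0.001:
        return "diamond"
    if p < 0.05:
        return "triangle"
    return "circle"


def classify_edge(p: float) -> str:
    """Co-occurrence class: solid < 0.01 <= dash < 0.05 <= none."""
    if p < 0.01:
        return "solid"
    if p < 0.05:
        return "dash"
    return "none"


def motif_enrichment(
    cluster_genes, background: BackgroundDB, cluster: int | str = 1
) -> pd.DataFrame:
    """Per-motif enrichment of a cluster against the database background.

    For each motif with a nonzero background count: m cluster genes carrying
    it, M cluster size, n database carriers, N database size, ratio
    (m/M)/(n/N) and hypergeometric upper-tail p.  Motifs never seen in the
    database are skipped (no background frequency to compare against).
    """
    cluster_genes = set(cluster_genes)
    M = len(cluster_genes)
    if M == 0:
        raise ValueError("empty cluster")
    rows = []
    for motif in sorted(background.n):
        n = background.n[motif]
        m = sum(
            1 for g in cluster_genes if motif in background.gene_motifs.get(g, ())
        )
        ratio = enrichment_ratio(m, M, n, background.N)
        p = hypergeom_upper_tail(m, background.N, n, M)
        rows.append((cluster, motif, m, M, n, background.N, ratio, p, classify_node(p)))
    return pd.DataFrame(
        rows,
        columns=["cluster", "motif", "m", "M", "n", "N", "ratio", "p", "node_class"],
    )


def pair_cooccurrence(
    cluster_genes, background: BackgroundDB, cluster: int | str = 1
) -> pd.DataFrame:
    """Per-pair co-occurrence significance of a cluster vs the background.

    For each unordered motif pair with a nonzero background pair count:
    t cluster genes where the pair co-occurs within the window, T cluster
    size, k background carriers of the pair, K database size, upper-tail p.
    Symmetric in pair order by construction.
    """
    cluster_genes = set(cluster_genes)
    T = len(cluster_genes)
    if T == 0:
        raise ValueError("empty cluster")
    rows = []
    for pair in sorted(background.pair_n):
        k = background.pair_n[pair]
        t = sum(
            1 for g in cluster_genes if pair in background.gene_pairs.get(g, ())
        )
        p = hypergeom_upper_tail(t, background.N, k, T)
        rows.append(
            (cluster, pair[0], pair[1], t, T, k, background.N, p, classify_edge(p))
        )
    return pd.DataFrame(
        rows,
        columns=["cluster", "motif_a", "motif_b", "t", "T", "k", "K", "p", "edge_class"],
    )


def build_network(
    enrich: pd.DataFrame, cooc: pd.DataFrame, prune_isolated: bool = False
) -> nx.Graph:
    """Assemble the Cytoscape-style motif network for one cluster.

    Node attributes: ``size`` (cluster genes carrying the motif, m),
    ``color`` (enrichment ratio), ``shape`` (significance class), ``p``.
    Edges are kept only for pairs with co-occurrence p < 0.05, styled
    ``solid`` (p < 0.01) or ``dash``.  With ``prune_isolated`` set,
    non-significant motifs without any retained edge are dropped.
    """
    g = nx.Graph()
    for row in enrich.itertuples():
        g.add_node(
            row.motif,
            size=int(row.m),
            color=float(row.ratio),
            shape=row.node_class,
            p=float(row.p),
        )
    for row in cooc.itertuples():
        if row.p < 0.05:
            if row.motif_a not in g or row.motif_b not in g:
                continue  # endpoints must be scored nodes
            g.add_edge(
                row.motif_a,
                row.motif_b,
                p=float(row.p),
                style=classify_edge(row.p),
            )
    if prune_isolated:
        drop = [
            n
            for n, d in g.nodes(data=True)
            if d["shape"] == "circle" and g.degree(n) == 0
        ]
        g.remove_nodes_from(drop)
    return g
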
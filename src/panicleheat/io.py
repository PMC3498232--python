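"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices and flags travel as TSV (probes x samples), the sample
design as CSV, promoters as FASTA (one record per gene, sequence =
-3000..-1 upstream of ATG), motif libraries as two-column TSV
(name<TAB>IUPAC consensus), and networks as Cytoscape SIF plus node/edge
attribute tables or GraphML.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import ExpressionDataset


def write_matrix(df: pd.DataFrame, path, index_label: str = "probe") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index_label="sample_id")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_probe_gene(probe_gene: pd.Series, path) -> None:
    probe_gene.rename("gene").to_csv(path, sep="\t", index_label="probe")


def read_probe_gene(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="probe")
    return df["gene"]


def read_dataset(
    values_path, flags_path, design_path, probe_gene_path=None
) -> ExpressionDataset:
    values = read_matrix(values_path)
    flags = read_matrix(flags_path)
    design = read_design(design_path)
    if probe_gene_path is not None:
        probe_gene = read_probe_gene(probe_gene_path)
    else:
        probe_gene = pd.Series(dtype=object)
    return ExpressionDataset(
        values=values, flags=flags, design=design, probe_gene=probe_gene
    )


def write_dataset(dataset: ExpressionDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.values, outdir / "expression.tsv")
    write_matrix(dataset.flags, outdir / "flags.tsv")
    write_design(dataset.design, outdir / "design.csv")
    write_probe_gene(dataset.probe_gene, outdir / "probe_gene.tsv")


def write_promoters(promoters: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path) -> dict[str, str]:
    promoters: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in promoters:
            raise ValueError(f"duplicate gene id in FASTA: {rec.id}")
        promoters[rec.id] = str(rec.seq).upper()
    return promoters


def write_motif_library(motifs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, consensus in motifs.items():
            fh.write(f"{name}\t{consensus}\n")


def read_motif_library(path) -> dict[str, str]:
    motifs: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, consensus = line.split("\t")
            motifs[name] = consensus
    return motifs


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_network_sif(graph: nx.Graph, path) -> None:
    """SIF: one `motifA  cooccur  motifB` line per edge; isolated nodes are
    emitted as bare node lines so Cytoscape keeps them."""
    with open(path, "w") as fh:
        for a, b in graph.edges():
            fh.write(f"{a}\tcooccur\t{b}\n")
        for node in graph.nodes():
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def write_network_attributes(graph: nx.Graph, node_path, edge_path) -> None:
    nodes = pd.DataFrame(
        [
            (n, d["size"], d["color"], d["shape"], d["p"])
            for n, d in graph.nodes(data=True)
        ],
        columns=["motif", "size", "color", "shape", "p"],
    )
    edges = pd.DataFrame(
        [(a, b, d["p"], d["style"]) for a, b, d in graph.edges(data=True)],
        columns=["motif_a", "motif_b", "p", "style"],
    )
    write_table(nodes, node_path)
    write_table(edges, edge_path)


def write_network_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))
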
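"""Plain-text readers and writers for the pipeline's tabular formats.

All formats are TSV (or GMT for gene sets): DEG tables, expression
matrices, GRN edge lists, ontologies with annotations, behavior tables,
gRNA counts, fingerprints and network edge lists.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from pertconv.meta import DEG_COLUMNS, DEGTable
from pertconv.network import GeneNetwork
from pertconv.semsim import Ontology

import networkx as nx


# -- DEG tables -------------------------------------------------------------

def write_deg_table(table: DEGTable, path) -> None:
    df = table.data.copy()
    df.insert(0, "cell_type", table.cell_type)
    df.insert(0, "ko_id", table.ko_id)
    df.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> DEGTable:
    df = pd.read_csv(path, sep="\t")
    ko = df["ko_id"].iloc[0]
    ct = df["cell_type"].iloc[0]
    return DEGTable(ko_id=ko, cell_type=ct, data=df[DEG_COLUMNS].copy())


def write_deg_tables(tables: list[DEGTable], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tables:
        p = directory / f"deg_{t.cell_type}_{t.ko_id}.tsv"
        write_deg_table(t, p)
        paths.append(p)
    return paths


# -- expression -------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path) -> None:
    """Matrix TSV; MultiIndex columns are flattened as context|gene."""
    out = expr.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [f"{a}|{b}" for a, b in out.columns]
    out.to_csv(path, sep="\t")


def read_expression(path, multiindex: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if multiindex:
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split("|", 1)) for c in df.columns], names=["context", "gene"]
        )
    return df


# -- GRN edges --------------------------------------------------------------

def write_grn_edges(grn: dict, path) -> None:
    rows = [
        {"context": ctx, "gene_a": a, "gene_b": b, "weight": w}
        for ctx, edges in grn.items()
        for a, b, w in edges
    ]
    pd.DataFrame(rows, columns=["context", "gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_grn_edges(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    grn: dict = {}
    for row in df.itertuples(index=False):
        grn.setdefault(row.context, []).append((row.gene_a, row.gene_b, row.weight))
    return grn


# -- ontology + annotations -------------------------------------------------

def write_ontology(ont: Ontology, terms_path, gmt_path) -> None:
    rows = [
        {"term_id": t, "parent_id": p}
        for t in ont.terms
        for p in sorted(ont.parents[t])
    ]
    pd.DataFrame(rows, columns=["term_id", "parent_id"]).to_csv(
        terms_path, sep="\t", index=False
    )
    term_genes: dict = {}
    for g, ts in ont.annotations.items():
        for t in ts:
            term_genes.setdefault(t, []).append(g)
    with open(gmt_path, "w") as fh:
        for t in sorted(term_genes):
            genes = "\t".join(sorted(term_genes[t]))
            fh.write(f"{t}\t{ont.namespace}\t{genes}\n")


def read_ontology(terms_path, gmt_path, namespace: str = "synthetic") -> Ontology:
    df = pd.read_csv(terms_path, sep="\t")
    parents: dict = {}
    for row in df.itertuples(index=False):
        parents.setdefault(row.term_id, set()).add(row.parent_id)
        parents.setdefault(row.parent_id, set())
    annotations: dict = {}
    for term, _, genes in read_gmt(gmt_path):
        for g in genes:
            annotations.setdefault(g, set()).add(term)
    return Ontology(parents=parents, annotations=annotations, namespace=namespace)


# -- GMT gene sets ----------------------------------------------------------

def read_gmt(path) -> list[tuple[str, str, list]]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append((parts[0], parts[1], [g for g in parts[2:] if g]))
    return out


def write_gmt(gene_sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# -- behavior / counts / fingerprints --------------------------------------

def write_behavior_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_behavior_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- networks ---------------------------------------------------------------

def write_network(net: GeneNetwork, path) -> None:
    net.edge_frame().to_csv(path, sep="\t", index=False)


def read_network(path) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("network edge list is empty")
    n_runs = int(df["n_runs"].iloc[0])
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, duplication_count=int(row.duplication_count))
    return GeneNetwork(graph=g, n_runs=n_runs)
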
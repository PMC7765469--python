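"""Readers and writers for the pipeline's plain-text formats.

Universal dialect: tab-separated UTF-8 with '#' comment lines; gene sets in
GMT. Readers validate rather than coerce: ragged rows, duplicate gene ids
and non-integer counts are errors.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .diffexpr import CountMatrix, DEGProfile
from .enrich import TermCatalog
from .integrate import OrthologMap
from .simulate import GroundTruth

__all__ = [
    "read_counts", "write_counts", "read_design", "write_design",
    "read_gmt", "write_gmt", "read_annotation", "write_annotation",
    "read_orthologs", "write_orthologs", "read_network", "write_network",
    "read_disease", "write_disease", "read_gene_list", "write_gene_list",
    "read_de_table", "write_de_table", "read_truth", "write_truth",
    "read_series", "write_series",
]


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((i, line))
    return out


def read_counts(path: str | Path) -> CountMatrix:
    """Counts TSV: first column gene id, header row of sample ids."""
    lines = _data_lines(path)
    if not lines:
        warnings.warn(f"{path}: empty counts file")
        return CountMatrix(pd.DataFrame())
    header = lines[0][1].split("\t")
    samples = header[1:]
    genes, rows = [], []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: ragged row "
                             f"({len(parts)} fields, expected {len(header)})")
        gene = parts[0]
        if gene in set(genes):
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        try:
            vals = [int(v) for v in parts[1:]]
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-integer count") from e
        genes.append(gene)
        rows.append(vals)
    df = pd.DataFrame(rows, index=genes, columns=samples, dtype=int)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(map(str, cm.samples)) + "\n")
        for gene, row in cm.counts.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(str(int(v)) for v in row)
                     + "\n")


_DESIGN_COLS = ["sample", "experiment", "condition", "replicate"]


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_DESIGN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design missing columns {sorted(missing)}")
    bad = set(df["condition"]) - {"treatment", "control"}
    if bad:
        raise ValueError(f"{path}: unknown conditions {sorted(bad)}")
    return df[_DESIGN_COLS]


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design[_DESIGN_COLS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, namespace: str = "pathway-like") -> TermCatalog:
    """GMT: term id, description, then member genes, tab-separated."""
    members, names, ns = {}, {}, {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs id, "
                             "description and at least one gene")
        tid, desc = parts[0], parts[1]
        if tid in members:
            raise ValueError(f"{path}:{lineno}: duplicate term {tid!r}")
        members[tid] = frozenset(parts[2:])
        names[tid] = desc if desc else tid
        ns[tid] = namespace
    return TermCatalog(members, names, ns)


def write_gmt(catalog: TermCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in catalog.terms():
            genes = sorted(catalog.members[term])
            fh.write("\t".join([term, catalog.names[term]] + genes) + "\n")


def read_annotation(path: str | Path) -> TermCatalog:
    """Annotation TSV: gene, term_id, term_name[, namespace] per row."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"gene", "term_id", "term_name"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(need)}")
    members: dict[str, set] = {}
    names, ns = {}, {}
    for _, r in df.iterrows():
        members.setdefault(r["term_id"], set()).add(r["gene"])
        names[r["term_id"]] = r["term_name"]
        ns[r["term_id"]] = r.get("namespace", "GO-like") or "GO-like"
    return TermCatalog({t: frozenset(g) for t, g in members.items()},
                       names, ns)


def write_annotation(catalog: TermCatalog, path: str | Path) -> None:
    rows = []
    for term in catalog.terms():
        for gene in sorted(catalog.members[term]):
            rows.append({"gene": gene, "term_id": term,
                         "term_name": catalog.names[term],
                         "namespace": catalog.namespace[term]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_orthologs(path: str | Path) -> OrthologMap:
    """Ortholog TSV: human_id, yeast_id[, best]; missing flag -> best."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"human", "yeast"} <= set(df.columns):
        raise ValueError(f"{path}: ortholog table needs human and yeast "
                         "columns")
    if "best" not in df.columns:
        warnings.warn(f"{path}: no best-hit flag; assuming all rows best")
        df["best"] = "true"
    df["best"] = df["best"].fillna("true").str.lower().isin(
        ["true", "1", "yes"])
    return OrthologMap(df[["human", "yeast", "best"]])


def write_orthologs(omap: OrthologMap, path: str | Path) -> None:
    df = omap.pairs.copy()
    df["best"] = df["best"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> nx.Graph:
    """Weighted edge list TSV: gene_a, gene_b, weight; self-loops dropped."""
    g = nx.Graph()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] == "gene_a":
            continue
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: edge needs two genes")
        a, b = parts[0], parts[1]
        w = float(parts[2]) if len(parts) > 2 else 1.0
        if a == b:
            warnings.warn(f"{path}:{lineno}: self-loop on {a!r} dropped")
            continue
        g.add_edge(a, b, weight=w)
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d.get('weight', 1.0)}\n")


def read_disease(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene", "disease"} <= set(df.columns):
        raise ValueError(f"{path}: disease table needs gene and disease "
                         "columns")
    return df[["gene", "disease"]]


def write_disease(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene", "disease"]].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    return [line for _, line in _data_lines(path)]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    need = {"log2fc", "p", "fdr", "direction"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(need)}")
    return df


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


def de_profile_from_table(table: pd.DataFrame, experiment: str) -> DEGProfile:
    return DEGProfile(experiment=experiment,
                      direction=table["direction"].astype(object))


def read_series(path: str | Path, value: str = "value") -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df[value]


def write_series(s: pd.Series, path: str | Path, value: str = "value",
                 index_label: str = "gene") -> None:
    s.rename(value).to_csv(path, sep="\t", index_label=index_label)


def read_truth(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_mapping(json.load(fh))


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_mapping(), fh, indent=1)
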
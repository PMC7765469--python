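"""Candidate-selection cascade and network-based disease prediction.

The cascade nominates conserved programmed-cell-death candidates: genes
that are direction-concordant DEGs across cell-death experiments, sit in a
death-enriched co-expression module, are not already annotated to apoptosis
or autophagy, are not cancer-census genes, respond exclusively (or with
opposite sign) relative to stress experiments, and have a best yeast
ortholog that is a sign-concordant DEG during yeast cell death. Surviving
genes are finally screened against a functional network by neighbor voting.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpnet import ModuleAssignment, UNASSIGNED
from .diffexpr import DEGProfile, bh_fdr
from .enrich import TermCatalog

__all__ = [
    "OrthologMap", "concordance", "classify_annotation", "select_candidates",
    "stress_filter", "ortholog_concordance", "occurrence_report",
    "predict_disease", "candidate_cascade",
]

DEATH_KEYWORDS = ("apopto", "autophag")


@dataclasses.dataclass
class OrthologMap:
    """Human gene -> (yeast gene, best-hit flag); only the best hit is used."""

    pairs: pd.DataFrame  # columns: human, yeast, best (bool)

    def best(self) -> pd.Series:
        b = self.pairs[self.pairs["best"]]
        if b["human"].duplicated().any():
            dup = b.loc[b["human"].duplicated(), "human"].iloc[0]
            raise ValueError(f"multiple best orthologs for {dup!r}")
        return b.set_index("human")["yeast"]


def concordance(profiles: Sequence[DEGProfile]) -> pd.DataFrame:
    """Occurrence counts and cross-experiment direction concordance.

    Returns a per-gene DataFrame with columns ``occurrence`` (number of
    experiments with a non-none call), ``direction`` ('up'/'down'/'none')
    and ``concordant`` (True iff all non-none calls agree; genes never
    called are not concordant and have direction 'none').
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    ids = [p.experiment for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate experiment ids")
    mat = pd.DataFrame({p.experiment: p.direction for p in profiles})
    mat = mat.fillna("none")
    up = (mat == "up").sum(axis=1)
    down = (mat == "down").sum(axis=1)
    occ = up + down
    concordant = (occ > 0) & ((up == 0) | (down == 0))
    direction = pd.Series("none", index=mat.index, dtype=object)
    direction[concordant & (up > 0)] = "up"
    direction[concordant & (down > 0)] = "down"
    return pd.DataFrame({"occurrence": occ.astype(int),
                         "direction": direction,
                         "concordant": concordant})


def classify_annotation(catalog: TermCatalog, genes: Iterable[str],
                        keywords: Sequence[str] = DEATH_KEYWORDS) -> pd.Series:
    """Annotation class per gene from keyword matches on its term names.

    Case-insensitive substring matching of ``keywords`` (default apoptosis
    and autophagy stems) against the names of the terms each gene belongs
    to; classes are apoptosis-only / autophagy-only / both / neither.
    """
    if len(keywords) == 0:
        raise ValueError("empty keyword set")
    kw = [k.lower() for k in keywords]
    apo_terms, auto_terms = set(), set()
    for t, name in catalog.names.items():
        low = name.lower()
        if kw[0] in low:
            apo_terms.add(t)
        if len(kw) > 1 and kw[1] in low:
            auto_terms.add(t)
    apo_genes = frozenset().union(*[catalog.members[t] for t in apo_terms]) \
        if apo_terms else frozenset()
    auto_genes = frozenset().union(*[catalog.members[t] for t in auto_terms]) \
        if auto_terms else frozenset()
    out = {}
    for g in genes:
        a, b = g in apo_genes, g in auto_genes
        out[g] = ("both" if a and b else "apoptosis-only" if a
                  else "autophagy-only" if b else "neither")
    return pd.Series(out, dtype=object)


def select_candidates(modules: ModuleAssignment,
                      death_enriched_modules: Iterable[str],
                      classes: pd.Series, census: Iterable[str],
                      occurrence: pd.Series) -> pd.Index:
    """Module-and-annotation filter of the cascade.

    Keeps genes that (i) belong to a death-enriched module, (ii) carry no
    apoptosis/autophagy annotation, (iii) are not cancer-census genes and
    (iv) are DEGs in at least one death experiment.
    """
    enriched = set(death_enriched_modules)
    unknown = enriched - set(modules.labels.unique())
    if unknown:
        raise ValueError(f"unknown module labels: {sorted(unknown)}")
    census = frozenset(census)
    in_mod = modules.labels.isin(enriched)
    genes = modules.labels.index[in_mod]
    keep = []
    for g in genes:
        if classes.get(g, "neither") != "neither":
            continue
        if g in census:
            continue
        if occurrence.get(g, 0) < 1:
            continue
        keep.append(g)
    return pd.Index(keep)


def stress_filter(candidates: pd.DataFrame,
                  stress_profiles: Sequence[DEGProfile]) -> pd.Series:
    """Stress status per candidate: exclusive / opposite / dropped.

    ``candidates`` is a concordance-style frame (direction column) for the
    candidate genes. exclusive: never a DEG in any stress experiment;
    opposite: a DEG in at least one stress experiment, always with the
    opposite direction; dropped: any same-direction stress call.
    """
    if len(candidates) == 0:
        return pd.Series(dtype=object)
    mat = pd.DataFrame({p.experiment: p.direction.reindex(candidates.index)
                        for p in stress_profiles}).fillna("none")
    out = {}
    for g in candidates.index:
        d = candidates.loc[g, "direction"]
        calls = [c for c in mat.loc[g]] if len(stress_profiles) else []
        called = [c for c in calls if c != "none"]
        if not called:
            out[g] = "exclusive"
        elif all(c != d for c in called):
            out[g] = "opposite"
        else:
            out[g] = "dropped"
    return pd.Series(out, dtype=object)


def ortholog_concordance(candidates: pd.DataFrame, orthologs: OrthologMap,
                         yeast_profiles: Sequence[DEGProfile],
                         strict: bool = True) -> pd.DataFrame:
    """Cross-species conservation of candidate DEG direction.

    A candidate is conserved when its best yeast ortholog is a DEG in at
    least one yeast condition with the same direction as the human call and
    (``strict``) never with the opposite direction.

    Returns a frame indexed like ``candidates`` with columns ``ortholog``
    (yeast id or None), ``yeast_direction`` and ``conserved``.
    """
    if len(yeast_profiles) == 0:
        raise ValueError("need at least one yeast profile")
    best = orthologs.best()
    yeast_genes = set()
    for p in yeast_profiles:
        yeast_genes |= set(p.direction.index)
    unknown = set(best.values) - yeast_genes
    if unknown:
        raise ValueError(
            f"ortholog map references unknown yeast ids: {sorted(unknown)[:5]}")
    ymat = pd.DataFrame({p.experiment: p.direction for p in yeast_profiles})
    ymat = ymat.fillna("none")
    rows = {}
    for g in candidates.index:
        d = candidates.loc[g, "direction"]
        y = best.get(g)
        if y is None or y not in ymat.index:
            rows[g] = {"ortholog": None, "yeast_direction": "none",
                       "conserved": False}
            continue
        calls = [c for c in ymat.loc[y] if c != "none"]
        same = sum(c == d for c in calls)
        opposite = len(calls) - same
        conserved = same >= 1 and (opposite == 0 if strict else True)
        ydir = ("none" if not calls else
                d if same >= 1 else calls[0])
        rows[g] = {"ortholog": y, "yeast_direction": ydir,
                   "conserved": bool(conserved and d != "none")}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(candidates.index)


def occurrence_report(table: pd.DataFrame,
                      multi_threshold: int = 1) -> pd.DataFrame:
    """Stratified counts by occurrence (Table-style summary).

    ``table`` is a candidate table with at least ``occurrence`` plus the
    boolean columns ``concordant``, ``specific``, ``has_ortholog`` and
    ``conserved`` (missing boolean columns are treated as absent columns).
    Rows: stratum '1', '>1' and 'Total'; additivity of the Total row is
    asserted.
    """
    cols = [c for c in ("concordant", "specific", "has_ortholog", "conserved")
            if c in table.columns]
    strata = {"1": table["occurrence"] == multi_threshold if multi_threshold == 1
              else table["occurrence"] <= multi_threshold,
              ">1": table["occurrence"] > multi_threshold}
    rows = {}
    for name, mask in strata.items():
        sub = table[mask & (table["occurrence"] >= 1)]
        row = {"degs": int(len(sub))}
        for c in cols:
            row[c] = int(sub[c].sum())
        rows[name] = row
    total = {k: rows["1"][k] + rows[">1"][k] for k in rows["1"]}
    rows["Total"] = total
    out = pd.DataFrame.from_dict(rows, orient="index")
    assert (out.loc["Total"] == out.loc["1"] + out.loc[">1"]).all(), \
        "occurrence strata must partition the table"
    return out


def predict_disease(genes: Iterable[str], network: nx.Graph,
                    annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
                    fdr_cut: float = 0.05,
                    min_weight: float = 0.0) -> pd.DataFrame:
    """Guilt-by-association disease prediction by neighbor voting.

    For each (gene, disease) pair the disease-annotated fraction of the
    gene's direct neighbors (edges with weight >= ``min_weight``) is tested
    against the network-wide annotation rate with a hypergeometric tail; BH
    across all pairs. ``status`` is 'known' when the gene itself carries the
    annotation, 'predicted' when significant but unannotated.
    """
    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, set] = {}
        for _, r in annotation.iterrows():
            ann.setdefault(str(r["gene"]), set()).add(str(r["disease"]))
    else:
        ann = {g: set(ds) for g, ds in annotation.items()}
    diseases = sorted(set().union(*ann.values())) if ann else []
    if not diseases:
        return pd.DataFrame(columns=["gene", "disease", "neighbors",
                                     "annotated_neighbors", "p", "fdr",
                                     "status", "evaluable"])
    nodes = set(network.nodes)
    rows = []
    for g in genes:
        if g not in nodes:
            for d in diseases:
                rows.append({"gene": g, "disease": d, "neighbors": 0,
                             "annotated_neighbors": 0, "p": 1.0,
                             "status": "unannotated", "evaluable": False})
            continue
        nbrs = [v for v in network.neighbors(g)
                if network[g][v].get("weight", 1.0) >= min_weight]
        pool = nodes - {g}
        for d in diseases:
            annotated_pool = sum(1 for v in pool if d in ann.get(v, ()))
            k = sum(1 for v in nbrs if d in ann.get(v, ()))
            if len(nbrs) == 0 or k == 0:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(k - 1, len(pool),
                                             annotated_pool, len(nbrs)))
            rows.append({"gene": g, "disease": d, "neighbors": len(nbrs),
                         "annotated_neighbors": k, "p": min(p, 1.0),
                         "status": "known" if d in ann.get(g, ()) else
                         "unannotated", "evaluable": True})
    cols = ["gene", "disease", "neighbors", "annotated_neighbors", "p",
            "status", "evaluable"]
    if not rows:
        return pd.DataFrame(columns=cols + ["fdr"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].values)
    significant = out["fdr"] < fdr_cut
    out.loc[significant & (out["status"] == "unannotated"),
            "status"] = "predicted"
    return out


def candidate_cascade(death_profiles: Sequence[DEGProfile],
                      stress_profiles: Sequence[DEGProfile],
                      modules: ModuleAssignment,
                      death_enriched_modules: Iterable[str],
                      catalog: TermCatalog, census: Iterable[str],
                      orthologs: OrthologMap,
                      yeast_profiles: Sequence[DEGProfile],
                      strict_orthologs: bool = True) -> pd.DataFrame:
    """Run the full selection cascade; returns the candidate table.

    One row per gene that is a DEG in at least one death experiment, with
    the cascade columns (occurrence, concordant, in_death_module,
    annotation_class, in_cancer_census, stress_status, ortholog,
    yeast_direction, specific, conserved). Subset monotonicity of the
    cascade (conserved ⊆ specific ⊆ candidates ⊆ module-selected ⊆ DEGs)
    is asserted on every run.
    """
    conc = concordance(death_profiles)
    deg_universe = conc.index[conc["occurrence"] >= 1]
    table = conc.loc[deg_universe].copy()
    enriched = set(death_enriched_modules)
    table["in_death_module"] = [modules.labels.get(g, UNASSIGNED) in enriched
                                for g in table.index]
    classes = classify_annotation(catalog, table.index)
    table["annotation_class"] = classes.reindex(table.index)
    census = frozenset(census)
    table["in_cancer_census"] = [g in census for g in table.index]

    selected = select_candidates(modules, enriched, classes, census,
                                 table["occurrence"])
    selected = pd.Index([g for g in selected if g in table.index])
    candidate_mask = table.index.isin(selected) & table["concordant"]
    candidates = table[candidate_mask]

    table["stress_status"] = "n/a"
    stress = stress_filter(candidates, stress_profiles)
    table.loc[stress.index, "stress_status"] = stress
    table["specific"] = table["stress_status"].isin(["exclusive", "opposite"])

    table["ortholog"] = None
    table["yeast_direction"] = "none"
    table["conserved"] = False
    specific = table[table["specific"]]
    if len(specific) > 0:
        orth = ortholog_concordance(specific, orthologs, yeast_profiles,
                                    strict=strict_orthologs)
        table.loc[orth.index, "ortholog"] = orth["ortholog"]
        table.loc[orth.index, "yeast_direction"] = orth["yeast_direction"]
        table.loc[orth.index, "conserved"] = orth["conserved"]
    table["has_ortholog"] = table["ortholog"].notna()

    # cascade monotonicity
    conserved_set = set(table.index[table["conserved"]])
    specific_set = set(table.index[table["specific"]])
    candidate_set = set(candidates.index)
    module_set = set(table.index[table["in_death_module"]])
    assert conserved_set <= specific_set <= candidate_set <= module_set \
        <= set(table.index), "cascade must be monotone"
    return table
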
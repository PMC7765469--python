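"""Over-representation analysis and cross-experiment pathway dysregulation.

ORA is a one-sided hypergeometric test of a query gene set against a term
catalog. Pathway dysregulation across experiments ranks each experiment's
genes by log2 fold-change, scores every pathway with an unweighted
Kolmogorov–Smirnov running-sum enrichment score (ES), and aggregates per
pathway into a signed experiment-fraction ES with a Fisher-combined p-value.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

__all__ = [
    "TermCatalog", "ora", "rank_genes", "ks_enrichment", "ks_pvalue",
    "aggregate_pep", "pep_analysis",
]


@dataclasses.dataclass
class TermCatalog:
    """Term id -> (name, member gene set), with a namespace tag per term.

    ``namespace`` distinguishes GO-like from pathway-like collections; it is
    carried through to enrichment records but does not change the test.
    """

    members: dict[str, frozenset]
    names: dict[str, str] = dataclasses.field(default_factory=dict)
    namespace: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = {t: frozenset(g) for t, g in self.members.items()}
        for t in self.members:
            self.names.setdefault(t, t)
            self.namespace.setdefault(t, "pathway-like")

    def terms(self) -> list[str]:
        return sorted(self.members)

    def genes_of(self, gene: str) -> list[str]:
        return [t for t, g in self.members.items() if gene in g]

    def subset(self, namespace: str) -> "TermCatalog":
        keep = [t for t in self.members if self.namespace[t] == namespace]
        return TermCatalog({t: self.members[t] for t in keep},
                           {t: self.names[t] for t in keep},
                           {t: namespace for t in keep})


def ora(query: Iterable[str], background: Iterable[str], catalog: TermCatalog,
        fdr_cut: float = 0.01) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each catalog term.

    p = P(X >= overlap) drawing |query| genes from the background; BH across
    terms. Returns a DataFrame with term, name, overlap, term_size, p, fdr,
    significant — sorted by p.
    """
    bg = frozenset(background)
    if len(bg) == 0:
        raise ValueError("empty background")
    q = frozenset(query)
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    rows = []
    for term in catalog.terms():
        memb = catalog.members[term] & bg
        if len(memb) == 0:
            continue
        k = len(q & memb)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(memb), len(q)))
        rows.append({"term": term, "name": catalog.names[term],
                     "namespace": catalog.namespace[term],
                     "overlap": k, "term_size": len(memb), "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["term", "name", "namespace", "overlap",
                                     "term_size", "p", "fdr", "significant"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].values)
    out["significant"] = out["fdr"] < fdr_cut
    return out.sort_values(["p", "term"]).reset_index(drop=True)


def rank_genes(de_table: pd.DataFrame) -> list[str]:
    """Ranking for enrichment scoring: by log2FC descending, ties broken by
    ascending p then gene id."""
    df = de_table.copy()
    df["_gene"] = df.index.astype(str)
    df = df.sort_values(["log2fc", "p", "_gene"],
                        ascending=[False, True, True], kind="mergesort")
    return df["_gene"].tolist()


def ks_enrichment(ranked: Sequence[str], term: Iterable[str]) -> float:
    """Unweighted KS running-sum enrichment score in [-1, 1].

    Walking the ranking, the sum gains 1/|hits| at term members and loses
    1/(N - |hits|) elsewhere; ES is the extremum of largest magnitude
    (positive on ties).
    """
    memb = frozenset(term)
    hits = np.fromiter((g in memb for g in ranked), dtype=bool,
                       count=len(ranked))
    nh = int(hits.sum())
    n = len(ranked)
    if nh == 0 or nh == n:
        raise ValueError("term must overlap the ranking partially")
    steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    run = np.cumsum(steps)
    hi, lo = run.max(), run.min()
    return float(hi if hi >= -lo else lo)


def ks_pvalue(ranked: Sequence[str], term: Iterable[str],
              n_perm: int = 1000, seed: int = 0) -> float:
    """Two-sided permutation p for the KS enrichment score.

    Gene labels are permuted (equivalently: member positions redrawn);
    p = (1 + #{|ES_perm| >= |ES_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    es_obs = ks_enrichment(ranked, term)
    memb = frozenset(term)
    nh = sum(g in memb for g in ranked)
    n = len(ranked)
    rng = np.random.default_rng(seed)
    # vectorized: each row is a random placement of the nh member positions
    step_hit, step_miss = 1.0 / nh, -1.0 / (n - nh)
    count = 0
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        mat = np.full((b, n), step_miss)
        cols = np.argsort(rng.random((b, n)), axis=1)[:, :nh]
        rows = np.repeat(np.arange(b), nh)
        mat[rows, cols.ravel()] = step_hit
        run = np.cumsum(mat, axis=1)
        es_perm = np.where(run.max(axis=1) >= -run.min(axis=1),
                           run.max(axis=1), run.min(axis=1))
        count += int((np.abs(es_perm) >= abs(es_obs) - 1e-12).sum())
        done += b
    return (1 + count) / (n_perm + 1)


def aggregate_pep(per_experiment: pd.DataFrame, fdr_cut: float = 0.01,
                  n_experiments: int | None = None) -> pd.DataFrame:
    """Aggregate per-experiment pathway scores across experiments.

    ``per_experiment`` has columns term, experiment, es, p (one row per
    evaluable term/experiment pair). Per term the aggregate ES is the
    signed fraction of experiments sharing the majority ES sign (ties
    broken toward the direction with the smaller Fisher-combined
    evidence); the aggregate p is Fisher's combination of the
    per-experiment p-values, BH-adjusted across terms. The fraction's
    denominator is ``n_experiments`` when given (so non-evaluable
    experiments dilute the score), else the number of evaluable ones.
    """
    rows = []
    for term, grp in per_experiment.groupby("term", sort=True):
        es = grp["es"].values.astype(float)
        ps = np.clip(grp["p"].values.astype(float), 1e-300, 1.0)
        n_eval = max(len(es), n_experiments or 0)
        f_up = float((es > 0).sum()) / n_eval
        f_down = float((es < 0).sum()) / n_eval
        if f_up > f_down:
            es_agg = f_up
        elif f_down > f_up:
            es_agg = -f_down
        elif f_up == 0.0:
            es_agg = 0.0
        else:
            up_p = _fisher(ps[es > 0])
            down_p = _fisher(ps[es < 0])
            es_agg = f_up if up_p <= down_p else -f_down
        rows.append({"term": term, "es": es_agg, "p": _fisher(ps),
                     "n_experiments": n_eval,
                     "per_experiment_es": list(es)})
    if not rows:
        return pd.DataFrame(columns=["term", "es", "p", "fdr", "significant",
                                     "n_experiments", "per_experiment_es"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].values)
    out["significant"] = out["fdr"] < fdr_cut
    return out.sort_values(["p", "term"]).reset_index(drop=True)


def _fisher(ps: np.ndarray) -> float:
    if len(ps) == 0:
        return 1.0
    return float(stats.combine_pvalues(ps, method="fisher")[1])


def pep_analysis(de_tables: Mapping[str, pd.DataFrame], catalog: TermCatalog,
                 n_perm: int = 1000, seed: int = 0,
                 fdr_cut: float = 0.01) -> pd.DataFrame:
    """Pathway dysregulation across experiments (ranked-list KS + aggregation).

    ``de_tables`` maps experiment id -> per-gene DE table with log2fc and p.
    Terms with no partial overlap in an experiment are skipped there (and a
    term missing everywhere is absent from the output).
    """
    records = []
    for i, (exp, table) in enumerate(sorted(de_tables.items())):
        ranked = rank_genes(table)
        in_rank = frozenset(ranked)
        for term in catalog.terms():
            memb = catalog.members[term] & in_rank
            if len(memb) == 0 or len(memb) == len(ranked):
                continue
            es = ks_enrichment(ranked, memb)
            p = ks_pvalue(ranked, memb, n_perm=n_perm,
                          seed=seed * 100003 + i)
            records.append({"term": term, "experiment": exp, "es": es, "p": p})
    if not records:
        return aggregate_pep(pd.DataFrame(columns=["term", "experiment",
                                                   "es", "p"]), fdr_cut)
    return aggregate_pep(pd.DataFrame(records), fdr_cut=fdr_cut,
                         n_experiments=len(de_tables))
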
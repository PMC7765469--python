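"""Weighted co-expression networks, module detection and preservation.

Implements the signed-network workflow: soft-thresholded correlation
adjacency, topological overlap, average-linkage module detection with
eigengene merging, and a permutation Zsummary statistic quantifying whether
a module's density and connectivity replicate in an independent dataset.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .config import Thresholds

__all__ = [
    "ModuleAssignment", "PreservationReport",
    "log_expression", "wgcna_input_filter", "center_within_groups",
    "pick_soft_threshold", "adjacency", "tom", "detect_modules",
    "module_eigengene", "module_preservation",
]

UNASSIGNED = "unassigned"


@dataclasses.dataclass
class ModuleAssignment:
    """Gene -> module label map plus per-module eigengenes.

    ``labels`` maps every clustered gene to a module label, with the
    reserved label ``"unassigned"`` for genes outside any module.
    ``eigengenes`` is samples x modules, each column unit-norm and
    sign-oriented to correlate positively with the module mean expression.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame | None = None

    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclasses.dataclass
class PreservationReport:
    """Per-module permutation Z statistics; ``table`` has one row per module
    with columns zsummary, zdensity, zconnectivity, observed stats, and an
    ``infinite`` flag set when a permutation sd was zero."""

    table: pd.DataFrame
    n_perm: int


def log_expression(counts: pd.DataFrame, library_sizes: pd.Series | None = None,
                   gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """log2(RPKM + 1) when gene lengths are given, else log2(CPM + 1)."""
    lib = (library_sizes if library_sizes is not None
           else counts.sum(axis=0)).astype(float)
    x = counts.divide(lib, axis=1) * 1e6
    if gene_lengths is not None:
        kb = gene_lengths.reindex(counts.index).astype(float) / 1e3
        if kb.isna().any() or (kb <= 0).any():
            raise ValueError("gene lengths must be positive and complete")
        x = x.divide(kb, axis=0)
    else:
        warnings.warn("no gene lengths supplied; using log2(CPM + 1)")
    return np.log2(x + 1.0)


def wgcna_input_filter(counts: pd.DataFrame, thr: Thresholds = Thresholds()) -> pd.Index:
    """Genes with >= wgcna_min_reads raw reads in >= wgcna_min_rep_frac of samples."""
    frac = (counts >= thr.wgcna_min_reads).mean(axis=1)
    return counts.index[frac >= thr.wgcna_min_rep_frac]


def center_within_groups(expr: pd.DataFrame,
                         groups: Sequence[str]) -> pd.DataFrame:
    """Subtract each gene's per-group mean (samples grouped by experiment).

    Standard batch adjustment before pooling samples from several
    experiments into one co-expression network: between-experiment mean
    differences (including differential expression) are removed so that
    correlation reflects within-experiment covariation only.
    """
    groups = np.asarray(groups)
    if len(groups) != expr.shape[1]:
        raise ValueError("groups must match sample count")
    out = expr.copy()
    for g in pd.unique(groups):
        cols = expr.columns[groups == g]
        out[cols] = expr[cols].sub(expr[cols].mean(axis=1), axis=0)
    return out


def _check_expr(expr: pd.DataFrame) -> np.ndarray:
    vals = expr.values.astype(float)
    if not np.isfinite(vals).all():
        raise ValueError("expression must be finite")
    if (vals.std(axis=1) == 0).any():
        bad = expr.index[vals.std(axis=1) == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}; filter before networking")
    return vals


def adjacency(expr: pd.DataFrame, beta: float, mode: str = "signed") -> pd.DataFrame:
    """Soft-thresholded correlation adjacency in [0, 1], unit diagonal.

    signed: ((1 + cor)/2)^beta;  unsigned: |cor|^beta. Pearson correlation
    is taken across samples (expr is genes x samples).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    vals = _check_expr(expr)
    cor = np.corrcoef(vals)
    cor = np.clip(cor, -1.0, 1.0)
    if mode == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    elif mode == "unsigned":
        a = np.abs(cor) ** beta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    shared-neighbor sum excluding u in {i, j} and k the connectivity
    excluding the diagonal; TOM_ii = 1.
    """
    a = adj.values.astype(float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    n = a.shape[0]
    shared = a @ a - 2.0 * a  # removes u=i and u=j terms (diag is 1)
    k = a.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (shared + a) / np.where(denom > 0, denom, 1.0),
                     0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def pick_soft_threshold(expr: pd.DataFrame, powers: Iterable[int] = range(1, 21),
                        r2_target: float = 0.8, mode: str = "signed",
                        n_bins: int = 10) -> int:
    """Smallest power giving approximate scale-free topology.

    For each power the connectivity distribution is binned and
    log10 p(k) regressed on log10 k; the fit R^2 counts only when the slope
    is negative. Returns the smallest power with R^2 >= target, else 12
    with a warning.
    """
    if expr.shape[0] < 10 or expr.shape[1] < 4:
        raise ValueError("need >= 10 genes and >= 4 samples")
    vals = _check_expr(expr)
    powers = list(powers)
    if r2_target <= 0:
        return int(min(powers))
    cor = np.clip(np.corrcoef(vals), -1.0, 1.0)
    base = (1.0 + cor) / 2.0 if mode == "signed" else np.abs(cor)
    np.fill_diagonal(base, 0.0)
    for beta in powers:
        k = (base ** beta).sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins)
        if slope < 0 and r2 >= r2_target:
            return int(beta)
    warnings.warn("no power reached the scale-free target; falling back to 12")
    return 12


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def module_eigengene(expr: pd.DataFrame, members: Sequence[str]) -> pd.Series:
    """First principal component of the standardized member submatrix.

    Samples are observations; the returned per-sample vector has unit norm
    and is oriented to correlate positively with mean member expression.
    """
    members = list(members)
    if len(members) == 0:
        raise ValueError("empty module")
    sub = expr.loc[members].values.astype(float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    # right singular vector over samples = PC scores of samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def detect_modules(tom_dissim: pd.DataFrame, expr: pd.DataFrame | None = None,
                   min_size: int = 30, cut_height: float = 0.995,
                   merge_height: float = 0.25,
                   kme_rescue: float | None = None) -> ModuleAssignment:
    """Average-linkage tree cut on TOM dissimilarity with eigengene merging.

    Clusters smaller than ``min_size`` become unassigned. When ``expr`` is
    given, modules whose eigengene dissimilarity (1 - correlation) is below
    ``merge_height`` are merged iteratively until stable, and unassigned
    genes correlating at least ``kme_rescue`` with some module eigengene
    (when set) are assigned to their best-correlated module. Labels are
    M1, M2, ... ordered by decreasing size (ties: lowest gene index).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    d = tom_dissim.values.astype(float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    genes = tom_dissim.index
    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    link = average(squareform(dsym, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    groups = {c: list(genes[labels == c]) for c in np.unique(raw)}
    groups = {c: g for c, g in groups.items() if len(g) >= min_size}

    if expr is not None and len(groups) > 1:
        groups = _merge_by_eigengene(expr, groups, merge_height)
    if expr is not None and kme_rescue is not None and groups:
        assigned = set().union(*groups.values())
        keys = sorted(groups)
        eigs = {k: module_eigengene(expr, groups[k]).values for k in keys}
        for g in genes:
            if g in assigned:
                continue
            prof = expr.loc[g].values
            kme = {k: _safe_cor(prof, eigs[k]) for k in keys}
            best = max(keys, key=lambda k: kme[k])
            if kme[best] >= kme_rescue:
                groups[best].append(g)

    out = pd.Series(UNASSIGNED, index=genes, dtype=object)
    ordered = sorted(groups.values(),
                     key=lambda g: (-len(g), min(genes.get_loc(x) for x in g)))
    eig = {}
    for i, g in enumerate(ordered, start=1):
        out[g] = f"M{i}"
        if expr is not None:
            eig[f"M{i}"] = module_eigengene(expr, g)
    eigdf = pd.DataFrame(eig) if eig else None
    return ModuleAssignment(labels=out, eigengenes=eigdf)


def _merge_by_eigengene(expr: pd.DataFrame, groups: dict, merge_height: float) -> dict:
    groups = {k: list(v) for k, v in groups.items()}
    while len(groups) > 1:
        keys = sorted(groups)
        eigs = np.array([module_eigengene(expr, groups[k]).values for k in keys])
        cor = np.corrcoef(eigs)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_height:
            break
        a, b = keys[i], keys[j]
        groups[a] = groups[a] + groups[b]
        del groups[b]
    return groups


def _preservation_stats(ref: np.ndarray, test: np.ndarray, idx: np.ndarray,
                        beta: float) -> tuple[float, float, float]:
    """(density_test, cor_kIM, cor_kME) for the gene subset ``idx``.

    ref/test are genes x samples value arrays over the shared universe.
    """
    def net(v):
        c = np.clip(np.corrcoef(v[idx]), -1.0, 1.0)
        a = ((1.0 + c) / 2.0) ** beta
        np.fill_diagonal(a, 0.0)
        return a

    a_ref, a_test = net(ref), net(test)
    m = len(idx)
    density = a_test.sum() / (m * (m - 1))
    kim_ref, kim_test = a_ref.sum(axis=1), a_test.sum(axis=1)
    cor_kim = _safe_cor(kim_ref, kim_test)

    def kme(v):
        sub = v[idx]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        if np.dot(e, z.mean(axis=0)) < 0:
            e = -e
        return z @ e / (np.linalg.norm(e) * np.sqrt((z ** 2).sum(axis=1)))

    cor_kme = _safe_cor(kme(ref), kme(test))
    return float(density), float(cor_kim), float(cor_kme)


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def module_preservation(ref_expr: pd.DataFrame, test_expr: pd.DataFrame,
                        modules: ModuleAssignment, n_perm: int = 200,
                        seed: int = 0, beta: float = 6.0) -> PreservationReport:
    """Permutation Zsummary preservation of reference modules in test data.

    Observed statistics per module: mean within-module adjacency in the
    test network (density), correlation of intramodular connectivities
    between datasets, and correlation of gene-eigengene correlations (kME)
    between datasets. The null resamples ``n_perm`` random gene sets of the
    same size. Zsummary = (Zdensity + Zconnectivity)/2 with Zconnectivity
    the median of the two connectivity Z scores.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    common = ref_expr.index.intersection(test_expr.index)
    if not ref_expr.index.equals(test_expr.index):
        if len(common) == 0:
            raise ValueError("no shared genes between datasets")
        ref_expr = ref_expr.loc[common]
        test_expr = test_expr.loc[common]
    universe = ref_expr.index
    ref = ref_expr.values.astype(float)
    test = test_expr.values.astype(float)
    rng = np.random.default_rng(seed)
    rows = []
    for mod in modules.modules():
        members = modules.members(mod)
        if len(members) > len(universe):
            raise ValueError("module larger than gene universe")
        members = members.intersection(universe)
        m = len(members)
        if m < 3:
            continue
        idx = universe.get_indexer(members)
        obs = _preservation_stats(ref, test, idx, beta)
        null = np.empty((n_perm, 3))
        for p in range(n_perm):
            ridx = rng.choice(len(universe), size=m, replace=False)
            null[p] = _preservation_stats(ref, test, ridx, beta)
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        infinite = bool((sd == 0).any())
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (np.asarray(obs) - mu) / sd,
                         np.sign(np.asarray(obs) - mu) * np.inf)
        zdensity = z[0]
        zconnectivity = float(np.median(z[1:]))
        rows.append({"module": mod, "size": m,
                     "zsummary": (zdensity + zconnectivity) / 2.0,
                     "zdensity": zdensity, "zconnectivity": zconnectivity,
                     "density": obs[0], "cor_kim": obs[1], "cor_kme": obs[2],
                     "infinite": infinite})
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
        columns=["size", "zsummary", "zdensity", "zconnectivity",
                 "density", "cor_kim", "cor_kme", "infinite"])
    return PreservationReport(table=table, n_perm=n_perm)
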
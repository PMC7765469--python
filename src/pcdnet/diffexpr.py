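"""Per-experiment differential expression on count data.

Counts are TMM/CPM-normalized and tested with a conditional negative-binomial
exact test (the classic two-group RNA-seq test): replicate counts are rescaled
to a common effective library size, summed per arm, and the arm split is
tested conditionally on the total. Genes are called differentially expressed
when |log2FC| >= 1 and BH FDR < 0.05.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .config import Thresholds

__all__ = [
    "CountMatrix", "DEGProfile",
    "cpm_normalize", "tmm_factors", "filter_expressed",
    "estimate_dispersion", "nb_exact_test", "bh_fdr", "call_degs", "run_de",
]


@dataclasses.dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample library sizes.

    ``library_sizes`` defaults to column sums. Negative entries and
    non-positive library sizes are rejected.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ValueError("library sizes missing for some samples")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0][0]
            raise ValueError(f"non-positive library size for sample {bad!r}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclasses.dataclass
class DEGProfile:
    """Per-gene DEG direction calls ('up'/'down'/'none') for one experiment."""

    experiment: str
    direction: pd.Series  # gene -> {'up','down','none'}

    def degs(self) -> pd.Index:
        return self.direction.index[self.direction != "none"]


def cpm_normalize(counts: CountMatrix | pd.DataFrame,
                  factors: pd.Series | Mapping[str, float] | None = None,
                  library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count / (library_size * factor) * 1e6."""
    if isinstance(counts, CountMatrix):
        mat, lib = counts.counts, counts.library_sizes
    else:
        mat = counts
        lib = library_sizes if library_sizes is not None else mat.sum(axis=0).astype(float)
    lib = lib.reindex(mat.columns).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")
    eff = lib.copy()
    if factors is not None:
        f = pd.Series(factors, dtype=float).reindex(mat.columns)
        if f.isna().any():
            raise ValueError("normalization factor missing for some samples")
        eff = eff * f
    return mat.divide(eff, axis=1) * 1e6


def tmm_factors(counts: CountMatrix | pd.DataFrame,
                trim_lfc: float = 0.3, trim_abund: float = 0.05,
                ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values composition factors, geometric mean 1.

    For each sample a trimmed, precision-weighted mean of per-gene log2
    ratios against a reference column is taken over genes expressed in both;
    the most extreme ``trim_lfc`` fraction of log-ratios (each side) and
    ``trim_abund`` fraction of abundances are discarded first.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = (counts.library_sizes if isinstance(counts, CountMatrix)
           else mat.sum(axis=0).astype(float))
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (mat.sum(axis=0) == 0).any():
        bad = mat.columns[mat.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    p = mat.divide(lib, axis=1)  # proportions
    if ref_sample is None:
        # reference = sample whose upper-quartile proportion is most typical
        uq = p.apply(lambda c: np.quantile(c[c > 0], 0.75), axis=0)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    pr = p[ref_sample].values
    nr = float(lib[ref_sample])
    logf = {}
    for s in mat.columns:
        if s == ref_sample:
            logf[s] = 0.0
            continue
        ps = p[s].values
        ns = float(lib[s])
        ok = (ps > 0) & (pr > 0)
        m = np.log2(ps[ok] / pr[ok])
        a = 0.5 * np.log2(ps[ok] * pr[ok])
        # asymptotic (delta-method) inverse variances of M
        x, r = mat[s].values[ok].astype(float), mat[ref_sample].values[ok].astype(float)
        w = 1.0 / ((ns - x) / (ns * x) + (nr - r) / (nr * r))
        keep = _doubletrim_mask(m, trim_lfc) & _doubletrim_mask(a, trim_abund)
        if keep.sum() == 0:
            logf[s] = 0.0
        else:
            logf[s] = float(np.average(m[keep], weights=w[keep]))
    f = pd.Series({s: 2.0 ** v for s, v in logf.items()}).reindex(mat.columns)
    return f / np.exp(np.log(f).mean())


def _doubletrim_mask(v: np.ndarray, frac: float) -> np.ndarray:
    """Keep values strictly inside the [frac, 1-frac] quantile band (ties kept)."""
    if frac <= 0:
        return np.ones(v.shape, dtype=bool)
    lo, hi = np.quantile(v, [frac, 1.0 - frac])
    return (v >= lo) & (v <= hi)


def filter_expressed(cpm: pd.DataFrame, design: pd.DataFrame,
                     thr: Thresholds = Thresholds()) -> pd.Index:
    """Genes with CPM >= cpm_min in every replicate of both arms."""
    samples = design["sample"].tolist()
    missing = set(samples) - set(cpm.columns)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
    if len(cpm) == 0:
        return cpm.index
    keep = (cpm[samples] >= thr.cpm_min).all(axis=1)
    return cpm.index[keep]


def estimate_dispersion(counts: CountMatrix, groups: Sequence[str],
                        shrink_weight: float = 0.7,
                        trim: float = 0.1) -> tuple[float, pd.Series]:
    """Method-of-moments NB dispersion with shrinkage to a common value.

    Per gene and arm, phi_hat = max(0, (s^2 - m) / m^2) on library-size
    normalized counts, pooled across arms by residual degrees of freedom.
    The common dispersion is a trimmed mean over genes; per-gene estimates
    are shrunk toward it with fixed weight ``shrink_weight`` on the common
    value.

    Returns ``(common_phi, shrunken_per_gene_phi)``.
    """
    groups = np.asarray(groups)
    if len(groups) != counts.counts.shape[1]:
        raise ValueError("groups must match sample count")
    arms = pd.unique(groups)
    sizes = np.array([(groups == a).sum() for a in arms])
    if (sizes < 2).all():
        raise ValueError(
            "no arm has replication; supply a dispersion explicitly")
    # normalize to the mean library size so MoM moments are comparable
    lib = counts.library_sizes.values.astype(float)
    norm = counts.counts.values * (lib.mean() / lib)
    num = np.zeros(norm.shape[0])
    den = 0.0
    for a in arms:
        cols = groups == a
        if cols.sum() < 2:
            continue
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        phi_g = np.clip(phi_g, 0.0, None)
        df = cols.sum() - 1
        num += phi_g * df
        den += df
    phi_gene = num / den
    expressed = norm.mean(axis=1) > 0
    vals = np.sort(phi_gene[expressed])
    if len(vals) == 0:
        common = 0.0
    else:
        k = int(len(vals) * trim)
        trimmed = vals[k:len(vals) - k] if len(vals) > 2 * k else vals
        common = float(trimmed.mean())
    shrunk = (1.0 - shrink_weight) * phi_gene + shrink_weight * common
    return common, pd.Series(shrunk, index=counts.genes)


def common_dispersion_cml(counts: CountMatrix, groups: Sequence[str],
                          factors: pd.Series | None = None) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    The classical estimator paired with the conditional exact test: counts
    are rescaled to a common library size, and within each arm the
    likelihood of the replicate counts conditional on their sum (negative
    multinomial) depends only on the dispersion. The summed conditional
    log-likelihood is maximized over phi by golden-section search, with the
    Poisson boundary (phi = 0) checked explicitly.
    """
    groups = np.asarray(groups)
    lib = counts.library_sizes.values.astype(float)
    eff = lib * (factors.reindex(counts.samples).values
                 if factors is not None else 1.0)
    common = float(np.exp(np.log(eff).mean()))
    pseudo = np.rint(counts.counts.values * (common / eff)).astype(np.int64)

    arms = [pseudo[:, groups == a] for a in pd.unique(groups)
            if (groups == a).sum() >= 2]
    if not arms:
        raise ValueError("no arm has replication")

    def loglik(phi: float) -> float:
        if phi <= 0:
            phi = 1e-8
        r = 1.0 / phi
        total = 0.0
        for y in arms:
            n = y.shape[1]
            t = y.sum(axis=1)
            total += float(
                (gammaln(y + r).sum(axis=1) - gammaln(y + 1).sum(axis=1)
                 - n * gammaln(r) - gammaln(t + n * r) + gammaln(t + 1)
                 + gammaln(n * r)).sum())
        return total

    # golden-section on log phi
    lo, hi = np.log(1e-4), np.log(5.0)
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = loglik(np.exp(c)), loglik(np.exp(d))
    for _ in range(60):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = loglik(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = loglik(np.exp(d))
    phi_hat = float(np.exp((a + b) / 2.0))
    if loglik(1e-8) >= loglik(phi_hat):
        return 0.0
    return phi_hat


def _exact_pvalue(s1: int, total: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p-value for an arm split of ``total``.

    Under a shared NB mean and dispersion ``phi``, the arm-1 sum conditioned
    on the total follows a beta-binomial-type law with shape parameters
    n1/phi and n2/phi (binomial(total, n1/(n1+n2)) in the Poisson limit).
    Two-sided by summing the probability of every split whose point
    probability does not exceed the observed one.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    if total == 0:
        return 1.0
    x = np.arange(total + 1)
    if phi < 1e-12:
        q = n1 / (n1 + n2)
        logpmf = (gammaln(total + 1) - gammaln(x + 1) - gammaln(total - x + 1)
                  + x * np.log(q) + (total - x) * np.log1p(-q))
    else:
        r1, r2 = n1 / phi, n2 / phi
        logpmf = (gammaln(x + r1) - gammaln(x + 1)
                  + gammaln(total - x + r2) - gammaln(total - x + 1))
        logpmf -= logsumexp(logpmf)
    obs = logpmf[s1]
    p = float(np.exp(logsumexp(logpmf[logpmf <= obs + 1e-10])))
    return min(p, 1.0)


def _exact_pvalue_batch(s1: np.ndarray, total: np.ndarray, n1: int, n2: int,
                        phi: np.ndarray, chunk_cells: int = 4_000_000,
                        mid_p: bool = False) -> np.ndarray:
    """Vectorized conditional exact p-values over many genes.

    Same definition as :func:`_exact_pvalue`; genes are processed in chunks
    of bounded split-table size so memory stays flat. ``mid_p`` returns the
    mid-p variant (half weight on equally-extreme outcomes), the standard
    choice when assessing the calibration of a discrete test.
    """
    n_genes = len(total)
    pvals = np.ones(n_genes)
    order = np.argsort(total)
    pos = 0
    while pos < n_genes:
        tmax = int(total[order[min(n_genes - 1, pos)]])
        # grow the chunk while the padded table stays within budget
        end = pos
        while end < n_genes:
            tmax = int(total[order[end]])
            if (end - pos + 1) * (tmax + 1) > chunk_cells and end > pos:
                break
            end += 1
        idx = order[pos:end]
        pos = end
        t = total[idx]
        tm = int(t.max())
        x = np.arange(tm + 1)[None, :]
        valid = x <= t[:, None]
        ph = phi[idx][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            poisson = ph[:, 0] < 1e-12
            r1 = np.where(poisson, 1.0, n1 / np.maximum(ph[:, 0], 1e-300))
            r2 = np.where(poisson, 1.0, n2 / np.maximum(ph[:, 0], 1e-300))
            lp = np.where(
                poisson[:, None],
                (gammaln(t[:, None] + 1) - gammaln(x + 1)
                 - gammaln(np.maximum(t[:, None] - x, 0) + 1)
                 + x * np.log(n1 / (n1 + n2))
                 + (t[:, None] - x) * np.log(n2 / (n1 + n2))),
                (gammaln(x + r1[:, None]) - gammaln(x + 1)
                 + gammaln(np.maximum(t[:, None] - x, 0) + r2[:, None])
                 - gammaln(np.maximum(t[:, None] - x, 0) + 1)))
        lp[~valid] = -np.inf
        lp -= lp.max(axis=1, keepdims=True)
        pmf = np.exp(lp)
        pmf /= pmf.sum(axis=1, keepdims=True)
        obs = pmf[np.arange(len(idx)), s1[idx]]
        take = pmf <= (obs[:, None] * (1 + 1e-10) + 1e-300)
        if mid_p:
            ties = np.abs(pmf - obs[:, None]) <= (obs[:, None] * 1e-10 + 1e-300)
            pvals[idx] = np.minimum(
                (pmf * (take & ~ties)).sum(axis=1)
                + 0.5 * (pmf * ties).sum(axis=1), 1.0)
        else:
            pvals[idx] = np.minimum((pmf * take).sum(axis=1), 1.0)
        zero = t == 0
        pvals[idx[zero]] = 1.0 if not mid_p else 0.5
    return pvals


def nb_exact_test(counts: CountMatrix, groups: Sequence[str],
                  phi: pd.Series | float, *,
                  treatment: str = "treatment", control: str = "control",
                  factors: pd.Series | None = None,
                  prior_cpm: float = 0.5, mid_p: bool = False) -> pd.DataFrame:
    """Conditional NB exact test of treatment vs control, per gene.

    Counts are rescaled to a common effective library size (geometric mean
    of effective sizes), summed per arm and rounded; the split of the total
    between arms is then tested exactly. log2FC uses arm-mean CPM with a
    pseudo-count of ``prior_cpm`` so it is always finite.

    Returns a DataFrame indexed by gene with columns
    ``log2fc, p, cpm_treatment, cpm_control``.
    """
    groups = np.asarray(groups)
    t_cols = groups == treatment
    c_cols = groups == control
    if t_cols.sum() == 0 or c_cols.sum() == 0:
        raise ValueError("both arms must contain samples")
    if np.isscalar(phi):
        phi_arr = np.full(len(counts.genes), float(phi))
    else:
        phi_arr = phi.reindex(counts.genes).values.astype(float)
    if (phi_arr < 0).any():
        raise ValueError("dispersion must be non-negative")

    lib = counts.library_sizes.values.astype(float)
    eff = lib * (factors.reindex(counts.samples).values if factors is not None
                 else 1.0)
    common = float(np.exp(np.log(eff).mean()))
    pseudo = counts.counts.values * (common / eff)

    n1, n2 = int(t_cols.sum()), int(c_cols.sum())
    s1 = np.rint(pseudo[:, t_cols].sum(axis=1)).astype(np.int64)
    s2 = np.rint(pseudo[:, c_cols].sum(axis=1)).astype(np.int64)
    total = s1 + s2

    pvals = _exact_pvalue_batch(s1, total, n1, n2, phi_arr, mid_p=mid_p)

    cpm = cpm_normalize(counts, factors=factors)
    cpm_t = cpm.values[:, t_cols].mean(axis=1)
    cpm_c = cpm.values[:, c_cols].mean(axis=1)
    log2fc = np.log2((cpm_t + prior_cpm) / (cpm_c + prior_cpm))
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals,
         "cpm_treatment": cpm_t, "cpm_control": cpm_c},
        index=counts.genes)


def bh_fdr(pvals: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr if not isinstance(pvals, pd.Series) else pd.Series(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN p-value")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(adj, index=pvals.index)
    return adj


def call_degs(results: pd.DataFrame, thr: Thresholds = Thresholds(),
              experiment: str = "experiment") -> DEGProfile:
    """Direction calls from a DE table with ``log2fc`` and ``fdr`` columns.

    up if log2FC >= lfc_min and FDR < fdr_deg; down if log2FC <= -lfc_min
    and FDR < fdr_deg; none otherwise. The fold-change bound is inclusive,
    the FDR bound strict.
    """
    up = (results["log2fc"] >= thr.lfc_min) & (results["fdr"] < thr.fdr_deg)
    down = (results["log2fc"] <= -thr.lfc_min) & (results["fdr"] < thr.fdr_deg)
    direction = pd.Series("none", index=results.index, dtype=object)
    direction[up] = "up"
    direction[down] = "down"
    return DEGProfile(experiment=experiment, direction=direction)


def run_de(counts: CountMatrix, design: pd.DataFrame, experiment: str,
           thr: Thresholds = Thresholds(),
           use_tmm: bool = True) -> tuple[pd.DataFrame, DEGProfile]:
    """Full single-experiment DE: filter, normalize, test, adjust, call.

    ``design`` needs columns sample/experiment/condition; only rows of the
    named experiment are used. Returns the per-gene DE table (log2fc, p,
    fdr, direction, arm CPMs) and the DEGProfile. Genes failing the
    expression filter are absent from the table and implicitly 'none'.
    """
    sub = design[design["experiment"] == experiment]
    if len(sub) == 0:
        raise ValueError(f"experiment {experiment!r} not in design")
    samples = sub["sample"].tolist()
    cm = CountMatrix(counts.counts[samples],
                     counts.library_sizes[samples])
    factors = tmm_factors(cm) if use_tmm else None
    cpm = cpm_normalize(cm, factors=factors)
    keep = filter_expressed(cpm, sub, thr)
    cm_f = CountMatrix(cm.counts.loc[keep], cm.library_sizes)
    groups = sub.set_index("sample").loc[cm_f.samples, "condition"].values
    # common dispersion by conditional ML (well calibrated in the far tail),
    # per-gene spread from the moment estimator, shrunk and floored: with a
    # handful of residual df, below-common per-gene estimates are noise and
    # only inflate false positives
    common = common_dispersion_cml(cm_f, groups, factors=factors)
    _, phi = estimate_dispersion(
        cm_f, groups, shrink_weight=thr.dispersion_shrink_weight)
    phi = phi.clip(lower=common)
    table = nb_exact_test(cm_f, groups, phi, factors=factors,
                          prior_cpm=thr.lfc_prior_cpm)
    table["fdr"] = bh_fdr(table["p"])
    profile = call_degs(table, thr, experiment=experiment)
    table["direction"] = profile.direction
    # genes filtered out are reported as 'none' in the profile
    full_dir = pd.Series("none", index=counts.genes, dtype=object)
    full_dir[profile.direction.index] = profile.direction
    return table, DEGProfile(experiment=experiment, direction=full_dir)
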
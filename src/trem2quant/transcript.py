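"""Post-count RNA-seq analysis.

Everything downstream of a gene x sample count matrix: sample QC exclusion,
expression filtering (at least 4 samples with 10 counts), trimmed-mean-of-
M-values (TMM) between-sample normalization, gene-wise negative-binomial
differential-expression testing with Benjamini-Hochberg FDR and the study's
threshold classification (FDR < 0.05, |log2FC| > 0.25), hierarchical
clustering on standardized Euclidean distances, signed-hybrid weighted
co-expression modules (soft power 12, minimum size 40, eigengene-merge at
correlation > 0.6) with module eigengenes, memberships, hubs and trait
correlation, and a permutation Zsummary statistic for module preservation
across datasets (> 2 moderate, > 10 strong preservation).

The differential-expression test is a gene-wise negative-binomial Wald test
with trend-shrunk moment dispersion estimates: per-gene moment dispersions
are shrunk toward a running-median mean-dispersion trend and the group
log-abundance contrast is referred to a t distribution whose degrees of
freedom add the shrinkage prior weight to the residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from . import groupstats

__all__ = [
    "CountMatrix",
    "CoexpressionParams",
    "ModuleSet",
    "sample_qc",
    "filter_genes",
    "tmm_factors",
    "genewise_de_test",
    "bh_adjust",
    "classify_deg",
    "hier_cluster",
    "residualize",
    "log_cpm",
    "build_modules",
    "module_trait_correlation",
    "preservation_zsummary",
]


@dataclass
class CountMatrix:
    """Gene x sample nonnegative integer counts plus per-sample metadata.

    ``meta`` is indexed by sample (matching the count columns) and carries
    at least ``genotype``; QC covariates (``gene_count_pct``,
    ``strandness``, ``exonic_rate``) and ``sex`` are optional.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("metadata must be keyed to the count columns, in order")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[samples], self.meta.loc[samples])


def sample_qc(
    cm: CountMatrix,
    min_gene_count_pct: float = 50.0,
    strandness_band: tuple = (0.70, 1.0),
) -> tuple:
    """Drop samples failing library-level QC, with a per-sample reason.

    A sample is excluded when its mapped gene-count percentage falls below
    ``min_gene_count_pct`` or its strandness score falls outside
    ``strandness_band`` (a score near 0.5 indicates an ambiguous library).
    Returns ``(retained CountMatrix, exclusion report DataFrame)``.
    """
    reasons = {}
    for s in cm.counts.columns:
        row = cm.meta.loc[s]
        why = []
        if "gene_count_pct" in cm.meta.columns and row["gene_count_pct"] < min_gene_count_pct:
            why.append(f"gene count percentage {row['gene_count_pct']:g}% "
                       f"< {min_gene_count_pct:g}%")
        if "strandness" in cm.meta.columns and not (
            strandness_band[0] <= row["strandness"] <= strandness_band[1]
        ):
            why.append(f"strandness {row['strandness']:g} outside "
                       f"[{strandness_band[0]:g}, {strandness_band[1]:g}]")
        if why:
            reasons[s] = "; ".join(why)
    keep = [s for s in cm.counts.columns if s not in reasons]
    if not keep:
        raise ValueError("sample QC excluded every sample")
    report = pd.DataFrame(
        {"sample": list(reasons), "reason": list(reasons.values())}
    )
    return cm.subset_samples(keep), report


def filter_genes(cm: CountMatrix, min_count: int = 10, min_samples: int = 4) -> CountMatrix:
    """Keep genes with at least ``min_samples`` samples at >= ``min_count`` counts."""
    ok = (cm.counts >= min_count).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[ok], cm.meta)


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    lib_sizes=None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample against a reference column (the one whose upper-
    quartile count fraction is closest to the mean), gene-wise log2 ratios
    (M) and average log2 abundances (A) over genes expressed in both are
    doubly trimmed (``trim_M`` on each M tail, ``trim_A`` on each A tail)
    and combined by an inverse-asymptotic-variance weighted mean.
    """
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = (np.asarray(lib_sizes, float) if lib_sizes is not None
           else y.sum(axis=0))
    if np.any(lib <= 0):
        raise ValueError("every library must have nonzero total count")
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref], trim_M, trim_A)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_M, trim_A) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no expressed genes with the reference")
    o, r = obs[pos], ref[pos]
    M = np.log2((o / n_obs) / (r / n_ref))
    A = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[fin], A[fin], w[fin]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    loM = np.floor(n * trim_M) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_A) + 1
    hiA = n + 1 - loA
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    return float(2.0**f) if np.isfinite(f) else 1.0


def genewise_de_test(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    group_col: str = "genotype",
    groups: tuple = ("WT", "Hom"),
    prior_count: float = 0.5,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Gene-wise negative-binomial Wald test between two sample groups.

    Returns a DataFrame (index = genes) with ``log2FC`` (second group over
    first, with a library-scaled prior count), ``p_value``, and the
    shrunken dispersion used. ``factors`` default to TMM on the matrix.
    """
    if factors is None:
        factors = tmm_factors(cm.counts)
    labels = cm.meta[group_col]
    m1 = (labels == groups[0]).to_numpy()
    m2 = (labels == groups[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    y = cm.counts.to_numpy(dtype=float)
    L = cm.lib_sizes.to_numpy(dtype=float) * factors.reindex(cm.counts.columns).to_numpy()
    n_used = int(m1.sum() + m2.sum())

    lam1 = y[:, m1].sum(axis=1) / L[m1].sum()
    lam2 = y[:, m2].sum(axis=1) / L[m2].sum()
    mu = np.where(np.repeat(m1[None, :], y.shape[0], axis=0),
                  np.outer(lam1, L), 0.0)
    mu[:, m2] = np.outer(lam2, L[m2])
    use = m1 | m2
    mu_u, y_u = mu[:, use], y[:, use]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = ((y_u - mu_u) ** 2 - mu_u) / mu_u**2
    contrib = np.where(mu_u > 0, contrib, 0.0)
    df_resid = max(n_used - 2, 1)
    phi_raw = np.clip(contrib.sum(axis=1) / df_resid, 0.0, None)

    # running-median mean-dispersion trend, then shrink toward it
    mean_expr = y_u.sum(axis=1) / L[use].sum()
    trend = _running_median_trend(np.log(mean_expr + 1e-300), phi_raw)
    phi = (prior_df * trend + df_resid * phi_raw) / (prior_df + df_resid)
    phi = np.clip(phi, 1e-6, None)

    # Wald contrast of log abundances; delta-method variance with NB counts
    var1 = (mu[:, m1] + phi[:, None] * mu[:, m1] ** 2).sum(axis=1) / L[m1].sum() ** 2
    var2 = (mu[:, m2] + phi[:, None] * mu[:, m2] ** 2).sum(axis=1) / L[m2].sum() ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var1 / np.maximum(lam1, 1e-300) ** 2
                     + var2 / np.maximum(lam2, 1e-300) ** 2)
        zstat = (np.log(np.maximum(lam2, 1e-300))
                 - np.log(np.maximum(lam1, 1e-300))) / se
    df_t = df_resid + prior_df
    p = 2.0 * stats.t.sf(np.abs(zstat), df_t)
    p = np.where(np.isfinite(p), p, 1.0)

    p1 = prior_count * L[m1].sum() / L[use].sum()
    p2 = prior_count * L[m2].sum() / L[use].sum()
    lfc = np.log2((y[:, m2].sum(axis=1) + p2) / L[m2].sum()) - np.log2(
        (y[:, m1].sum(axis=1) + p1) / L[m1].sum()
    )
    return pd.DataFrame(
        {"log2FC": lfc, "p_value": p, "dispersion": phi},
        index=cm.counts.index,
    )


def _running_median_trend(x: np.ndarray, y: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Median of y in quantile bins of x, interpolated back to every point."""
    order = np.argsort(x, kind="stable")
    n = x.size
    if n < 2 * n_bins:
        return np.full(n, np.median(y))
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    centers, meds = [], []
    for b in range(n_bins):
        sel = order[edges[b]:edges[b + 1]]
        centers.append(np.median(x[sel]))
        meds.append(np.median(y[sel]))
    return np.interp(x, centers, meds)


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_deg(de: pd.DataFrame, fdr_cut: float = 0.05, lfc_cut: float = 0.25) -> pd.DataFrame:
    """Attach FDR, up/down/ns status and volcano coordinates to a DE table.

    ``up`` when fdr < ``fdr_cut`` and log2FC > ``lfc_cut``; ``down`` when
    fdr < ``fdr_cut`` and log2FC < -``lfc_cut``; otherwise ``ns`` (strict
    inequalities on both axes).
    """
    out = de.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["fdr"] < fdr_cut
    out["status"] = np.where(sig & (out["log2FC"] > lfc_cut), "up",
                             np.where(sig & (out["log2FC"] < -lfc_cut), "down", "ns"))
    out["volcano_x"] = out["log2FC"]
    with np.errstate(divide="ignore"):
        out["volcano_y"] = -np.log10(out["fdr"])
    return out


def hier_cluster(X: pd.DataFrame) -> dict:
    """Average-linkage hierarchical clustering on standardized Euclidean
    distances between rows (features = columns, each scaled to unit variance).

    Zero-variance features are standardized to zeros with a warning.
    Returns ``{"linkage", "order", "labels"}`` with a deterministic leaf
    order (scipy's index-based tie-breaking).
    """
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    V = X.to_numpy(dtype=float)
    sd = V.std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance feature standardized to zeros", stacklevel=2)
    Z = np.where(sd > 0, (V - V.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    from scipy.spatial.distance import pdist

    dists = pdist(Z, metric="euclidean")
    link = hierarchy.linkage(dists, method="average")
    order = hierarchy.leaves_list(link)
    return {"linkage": link, "order": order, "labels": list(X.index[order]),
            "distances": dists}


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
            prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes."""
    if factors is None:
        factors = tmm_factors(counts)
    L = counts.sum(axis=0) * factors.reindex(counts.columns)
    return np.log2((counts + prior_count).div(L, axis=1) * 1e6)


def residualize(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-gene least-squares residuals against [intercept | covariates].

    ``expr`` is genes x samples; ``covariates`` is samples x k (numeric or
    convertible, e.g. sex coded 0/1). Raises on a rank-deficient design.
    """
    if list(expr.columns) != list(covariates.index):
        raise ValueError("covariates must be indexed by the expression columns, in order")
    C = covariates.apply(lambda c: pd.factorize(c)[0] if c.dtype == object else c)
    X = np.column_stack([np.ones(len(C)), C.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"collinear covariate design: {list(covariates.columns)} "
            "(with intercept) is rank deficient"
        )
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return pd.DataFrame(R.T, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# co-expression modules


@dataclass
class CoexpressionParams:
    """Parameters of the signed-hybrid co-expression network.

    ``beta`` is the soft-threshold power (adjacency = cor^beta for positive
    correlations, 0 otherwise); ``merge_cut`` merges modules whose
    eigengenes correlate above ``1 - merge_cut``.
    """

    beta: float = 12.0
    min_module_size: int = 40
    merge_cut: float = 0.4
    n_permutations: int = 100
    seed: int = 0
    density_z_min: float = 5.0
    n_null_networks: int = 10

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleSet:
    """Module assignment with eigengenes, memberships, hubs and trait stats."""

    labels: pd.Series  # gene -> module name or "unassigned"
    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns
    membership: pd.DataFrame  # genes x modules (correlation with ME)
    membership_p: pd.DataFrame
    hubs: dict  # module -> list of top genes by MM p-value
    params: CoexpressionParams
    trait_cor: pd.DataFrame | None = None
    zsummary: pd.Series | None = None

    @property
    def modules(self) -> list:
        return list(self.eigengenes.columns)

    def members(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])


def signed_hybrid_adjacency(residuals, beta: float) -> np.ndarray:
    """Signed-hybrid soft adjacency: cor^beta where cor > 0, else 0; zero diag."""
    X = residuals.to_numpy(dtype=float) if hasattr(residuals, "to_numpy") else np.asarray(residuals, float)
    R = np.corrcoef(X)
    A = np.where(R > 0, R, 0.0) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def _tom_dissimilarity(A: np.ndarray) -> np.ndarray:
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def _weighted_modularity(A: np.ndarray, labels: np.ndarray) -> float:
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        if lab < 0:
            continue  # unassigned genes act as singletons
        idx = labels == lab
        q += A[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return q


def _eigengene(resid_block: np.ndarray) -> np.ndarray:
    """First principal component of the scaled member profiles (unit norm)."""
    Zs = resid_block - resid_block.mean(axis=1, keepdims=True)
    sd = Zs.std(axis=1, keepdims=True)
    Zs = np.where(sd > 0, Zs / np.where(sd > 0, sd, 1.0), 0.0)
    _, _, vt = np.linalg.svd(Zs, full_matrices=False)
    me = vt[0]
    # sign: average member correlation with the eigengene must be positive
    cors = _safe_corr_rows(Zs, me)
    if np.nanmean(cors) < 0:
        me = -me
    return me


def _safe_corr_rows(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    vc = v - v.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Mc, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (Mc @ vc) / denom
    return np.where(denom > 0, c, 0.0)


def build_modules(residuals: pd.DataFrame, params: CoexpressionParams | None = None) -> ModuleSet:
    """Detect co-expression modules in a genes x samples residual matrix.

    Signed-hybrid adjacency at ``params.beta`` -> topological-overlap
    dissimilarity -> average-linkage tree cut at the static height that
    maximizes weighted modularity subject to ``min_module_size`` -> a
    permutation screen keeping only candidate modules whose intramodule
    density exceeds that of random same-size gene sets by
    ``density_z_min`` standard deviations (so pure-noise data yields no
    modules) -> modules whose eigengenes correlate above ``1 - merge_cut``
    merged -> eigengenes, memberships and hubs. Genes in no surviving
    module are "unassigned".
    """
    params = params or CoexpressionParams()
    resid = residuals
    const = resid.std(axis=1) == 0
    if const.any():
        warnings.warn(f"excluding {int(const.sum())} constant gene(s) from the network",
                      stacklevel=2)
        resid = resid.loc[~const]
    n_genes = resid.shape[0]
    if n_genes < params.min_module_size:
        raise ValueError("fewer genes than min_module_size")
    X = resid.to_numpy(dtype=float)
    A = signed_hybrid_adjacency(X, params.beta)
    candidates = _candidate_modules(A, params.min_module_size, X)

    # selection-aware null: rerun the identical clustering on data whose
    # gene profiles are independently sample-permuted (correlation
    # destroyed), and record the densest candidate module each time; an
    # observed module survives only if its density clears that null by
    # density_z_min standard deviations
    rng = np.random.default_rng(params.seed)
    null_max = np.zeros(params.n_null_networks)
    for b in range(params.n_null_networks):
        Xp = np.array([row[rng.permutation(row.size)] for row in X])
        Ap = signed_hybrid_adjacency(Xp, params.beta)
        # retain half-size clusters in the null: purified noise clusters
        # rarely reach full module size, and the relevant null quantity is
        # the density the selection process achieves on noise
        null_max[b] = max((_density(Ap, g) for g in
                           _candidate_modules(Ap, max(5, params.min_module_size // 2), Xp)),
                          default=0.0)
    thr = null_max.mean() + params.density_z_min * max(
        null_max.std(ddof=1), 0.05 * null_max.mean())
    survivors = [g for g in candidates if _density(A, g) > thr]

    groups = _merge_by_eigengene(X, survivors, 1.0 - params.merge_cut)

    # name modules by size, largest first
    sizes = sorted(((len(g), i) for i, g in enumerate(groups)), reverse=True)
    names = {}
    for rank, (_, gi) in enumerate(sizes, start=1):
        names[gi] = f"M{rank}"
    labels = pd.Series("unassigned", index=resid.index, dtype=object)
    me_cols = {}
    for gi, idx in enumerate(groups):
        labels.iloc[idx] = names[gi]
        me_cols[names[gi]] = _eigengene(X[idx])
    me = pd.DataFrame(me_cols, index=resid.columns)
    me = me[[f"M{r}" for r in range(1, len(groups) + 1)]] if groups else me

    n_samp = resid.shape[1]
    mm = pd.DataFrame(
        {m: _safe_corr_rows(X, me[m].to_numpy()) for m in me.columns},
        index=resid.index,
    )
    mm_p = mm.apply(lambda c: _corr_pvalue(c.to_numpy(), n_samp))
    hubs = {}
    for m in me.columns:
        members = labels.index[labels == m]
        order = mm_p.loc[members, m].sort_values(kind="stable")
        hubs[m] = list(order.index[:10])
    full_labels = labels.reindex(residuals.index, fill_value="unassigned")
    mm = mm.reindex(residuals.index)
    mm_p = mm_p.reindex(residuals.index)
    return ModuleSet(full_labels, me, mm, mm_p, hubs, params)


def _drop_small(cl: np.ndarray, min_size: int) -> np.ndarray:
    labels = np.full(cl.size, -1)
    nxt = 0
    for lab in np.unique(cl):
        idx = cl == lab
        if idx.sum() >= min_size:
            labels[idx] = nxt
            nxt += 1
    return labels


def _candidate_modules(A: np.ndarray, min_size: int, X: np.ndarray,
                       mm_cut: float = 0.3, n_purify: int = 2) -> list:
    """Average-linkage tree on TOM dissimilarity, cut at the static height
    maximizing weighted modularity, then eigengene-purified: members whose
    module membership falls below ``mm_cut`` are released (repeated
    ``n_purify`` times). Returns index arrays of size >= min_size."""
    diss = _tom_dissimilarity(A)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    heights = np.unique(link[:, 2])
    best_labels, best_q = None, -np.inf
    for h in np.quantile(heights, np.linspace(0.05, 0.999, 40)):
        cl = hierarchy.fcluster(link, t=h, criterion="distance")
        labels = _drop_small(cl, min_size)
        if (labels >= 0).sum() == 0:
            continue
        q = _weighted_modularity(A, labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    if best_labels is None:
        return []
    out = []
    for lab in np.unique(best_labels):
        if lab < 0:
            continue
        idx = np.nonzero(best_labels == lab)[0]
        for _ in range(n_purify):
            if idx.size < min_size:
                break
            me = _eigengene(X[idx])
            mm = _safe_corr_rows(X[idx], me)
            kept = idx[mm > mm_cut]
            if kept.size == idx.size:
                break
            idx = kept
        if idx.size >= min_size:
            out.append(idx)
    return out


def _density(A: np.ndarray, idx: np.ndarray) -> float:
    """Mean off-diagonal intramodule adjacency."""
    if idx.size < 2:
        return 0.0
    return A[np.ix_(idx, idx)].sum() / (idx.size * (idx.size - 1))


def _merge_by_eigengene(X: np.ndarray, groups: list, cor_cut: float) -> list:
    """Iteratively merge module index-groups whose eigengenes correlate > cor_cut."""
    groups = [np.asarray(g) for g in groups]
    changed = True
    while changed and len(groups) > 1:
        changed = False
        mes = [_eigengene(X[g]) for g in groups]
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                c = np.corrcoef(mes[i], mes[j])[0, 1]
                if c > cor_cut and (best is None or c > best[0]):
                    best = (c, i, j)
        if best is not None:
            _, i, j = best
            groups[i] = np.concatenate([groups[i], groups[j]])
            del groups[j]
            changed = True
    return groups


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -0.9999999, 0.9999999)
    if n <= 2:
        return np.ones_like(r)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def module_trait_correlation(ms: ModuleSet, trait, trait_name: str = "genotype") -> pd.DataFrame:
    """Correlate each module eigengene with a sample trait (e.g. WT=0/Hom=1).

    For binary traits the two-group eigengene comparison by Wilcoxon
    rank-sum is reported alongside the Pearson correlation.
    """
    t = np.asarray(trait, dtype=float)
    if t.size != ms.eigengenes.shape[0]:
        raise ValueError("trait must have one value per sample")
    if np.ptp(t) == 0:
        raise ValueError("trait is constant; correlation undefined")
    rows = []
    binary = np.unique(t).size == 2
    for m in ms.modules:
        me = ms.eigengenes[m].to_numpy()
        r, p = stats.pearsonr(me, t)
        row = {"module": m, "trait": trait_name, "cor": r, "p": p}
        if binary:
            lo, hi = np.unique(t)
            row["ranksum_p"] = groupstats.ranksum(me[t == lo], me[t == hi]).p_value
        rows.append(row)
    out = pd.DataFrame(rows).set_index("module")
    ms.trait_cor = out
    return out


def preservation_zsummary(
    reference: ModuleSet,
    ref_residuals: pd.DataFrame,
    test_residuals: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Permutation Zsummary of reference modules in an independent dataset.

    For each reference module, two preservation statistics are computed in
    the test data: density (mean intramodule signed-hybrid adjacency) and
    connectivity (Pearson correlation between reference and test
    intramodule connectivity of the member genes). Each is standardized
    against ``n_permutations`` random gene sets of the same size drawn from
    the shared gene universe; Zsummary is the mean of the two Z scores.
    Modules with fewer than 3 genes in the shared universe get NaN.
    """
    if n_permutations < 50:
        raise ValueError("n_permutations must be >= 50")
    rng = np.random.default_rng(seed)
    universe = ref_residuals.index.intersection(test_residuals.index)
    beta = reference.params.beta
    A_ref = signed_hybrid_adjacency(ref_residuals.loc[universe], beta)
    A_test = signed_hybrid_adjacency(test_residuals.loc[universe], beta)
    pos = pd.Series(np.arange(len(universe)), index=universe)

    out = {}
    for m in reference.modules:
        genes = [g for g in reference.members(m) if g in pos.index]
        if len(genes) < 3:
            warnings.warn(f"module {m}: fewer than 3 genes in the shared universe",
                          stacklevel=2)
            out[m] = np.nan
            continue
        idx = pos[genes].to_numpy()
        obs_d, obs_c = _preservation_stats(A_ref, A_test, idx)
        null_d = np.empty(n_permutations)
        null_c = np.empty(n_permutations)
        for b in range(n_permutations):
            ridx = rng.choice(len(universe), size=len(idx), replace=False)
            null_d[b], null_c[b] = _preservation_stats(A_ref, A_test, ridx)
        zd = _zscore(obs_d, null_d)
        zc = _zscore(obs_c, null_c)
        out[m] = 0.5 * (zd + zc)
    z = pd.Series(out, name="zsummary")
    reference.zsummary = z
    return z


def _preservation_stats(A_ref, A_test, idx):
    sub_t = A_test[np.ix_(idx, idx)]
    n = idx.size
    density = sub_t.sum() / (n * (n - 1))
    k_ref = A_ref[np.ix_(idx, idx)].sum(axis=1)
    k_test = sub_t.sum(axis=1)
    if np.ptp(k_ref) == 0 or np.ptp(k_test) == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(k_ref, k_test)[0, 1])
    return density, conn


def _zscore(obs: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((obs - null.mean()) / sd)
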
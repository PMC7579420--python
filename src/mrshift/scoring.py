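"""Gene-set scoring, cell-cycle phases, stemness index, SNN clustering, and
the subpopulation labeling rules.

The labels follow the printed cascade: per-cell arrest module scores are
binarized by the top one-fifth rule into Arr/NArr; a cluster is Arr when its
Arr:NArr ratio exceeds 0.8 and NArr when it falls below 0.2; a cluster is
low-APC when its mean APC expression is below the first tertile of the
cluster-mean APC distribution; low-APC+NArr clusters are LFG (fast growth),
low-APC+Arr are LSG (slow growth), high-APC+NArr are HFG, anything else None.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

SUBPOP_LABELS = ("HFG", "LFG", "LSG", "None")


def _resolve_set(gene_ids: list[str], gene_set: list[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = np.array([pos[g] for g in gene_set if g in pos], dtype=int)
    return idx


def module_score(
    values: np.ndarray,
    gene_ids: list[str],
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expression-matched gene-set score per cell.

    Genes are binned into ``n_bins`` equal-size groups by their across-cell
    average expression; each set gene contributes ``n_ctrl`` control genes
    sampled from its bin (with replacement when the bin is smaller than
    ``n_ctrl``). The score is the mean expression of the set genes minus the
    mean over the pooled control draws, so a score of zero means "no more
    expressed than expression-matched background".
    """
    values = np.asarray(values, dtype=float)
    idx = _resolve_set(gene_ids, gene_set)
    if idx.size == 0:
        raise ValueError("gene set has empty intersection with the universe")
    avg = values.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(gene_ids), dtype=int)
    bins[order] = np.arange(len(gene_ids)) * n_bins // len(gene_ids)
    rng = np.random.default_rng(seed)
    ctrl_idx = []
    for g in idx:
        pool = np.flatnonzero(bins == bins[g])
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_idx)
    return values[:, idx].mean(axis=1) - values[:, ctrl_idx].mean(axis=1)


def cell_cycle_assign(
    values: np.ndarray,
    gene_ids: list[str],
    s_set: list[str],
    g2m_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """S/G2M module scores and the phase call per cell.

    Phase is G2M when the G2M score is the larger and positive, S when the S
    score is the larger and positive, otherwise G1.
    """
    s_score = module_score(values, gene_ids, s_set, n_bins, n_ctrl, seed)
    g2m_score = module_score(values, gene_ids, g2m_set, n_bins, n_ctrl, seed + 1)
    phase = np.where(
        (g2m_score >= s_score) & (g2m_score > 0),
        "G2M",
        np.where((s_score > g2m_score) & (s_score > 0), "S", "G1"),
    )
    return pd.DataFrame({"s_score": s_score, "g2m_score": g2m_score, "phase": phase})


def stemness_index(
    values: np.ndarray, gene_ids: list[str], weights: pd.Series
) -> np.ndarray:
    """mRNAsi-style stemness index in [0, 1].

    Per cell, the Spearman correlation between expression and the stemness
    weight vector over shared genes, linearly rescaled across cells to [0, 1].
    Cells constant over the shared genes get 0.5 with a warning.
    """
    idx = _resolve_set(gene_ids, list(weights.index))
    if idx.size < 2:
        raise ValueError("need at least two genes shared with the weight vector")
    shared = [gene_ids[i] for i in idx]
    w = weights.loc[shared].values.astype(float)
    sub = np.asarray(values, dtype=float)[:, idx]
    w_rank = stats.rankdata(w)
    w_rank = w_rank - w_rank.mean()
    w_norm = np.sqrt((w_rank**2).sum())
    ranks = stats.rankdata(sub, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    const = norms < 1e-12
    corr = np.zeros(sub.shape[0])
    ok = ~const
    corr[ok] = (ranks[ok] @ w_rank) / (norms[ok] * w_norm)
    span = corr[ok].max() - corr[ok].min() if ok.any() else 0.0
    if span > 0:
        out = (corr - corr[ok].min()) / span
    else:
        out = np.full_like(corr, 0.5)
    if const.any():
        warnings.warn(f"{int(const.sum())} cell(s) constant over stemness genes; index 0.5")
        out[const] = 0.5
    return np.clip(out, 0.0, 1.0)


def snn_cluster(
    values: np.ndarray,
    k: int = 20,
    resolution: float = 1.0,
    n_pcs: int = 20,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Shared-nearest-neighbor modularity clustering (Seurat-style).

    The scaled matrix is reduced to its top principal components, a kNN graph
    is built (each cell's neighborhood includes itself), SNN edge weights are
    the Jaccard overlap of neighbor sets with weights below ``prune`` removed,
    and communities are found by Leiden modularity optimization (RB
    configuration model) at the given resolution. Deterministic for a fixed
    seed.
    """
    import igraph as ig
    import leidenalg
    import scipy.sparse as sp
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    n_pcs = min(n_pcs, min(values.shape) - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed).fit_transform(values)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, nbrs = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    member = sp.csr_matrix(
        (np.ones(n * k), (rows, nbrs.ravel())), shape=(n, n)
    )
    inter = member @ member.T
    inter = inter.tocoo()
    jac = inter.data / (2 * k - inter.data)
    keep = (jac >= prune) & (inter.row != inter.col)
    g = ig.Graph(
        n=n,
        edges=list(zip(inter.row[keep].tolist(), inter.col[keep].tolist())),
        edge_attrs={"weight": jac[keep].tolist()},
    )
    g.simplify(combine_edges="max")
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.array(part.membership)


def binarize_by_quantile(
    scores: np.ndarray, top_fraction: float = 0.2
) -> np.ndarray:
    """Label the top fraction of cells by score as arrested.

    Exactly ``ceil(top_fraction * n)`` cells get ``Arr``; ties are broken by
    the stable input order, so the earliest cells win among equal scores.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_top = min(n, math.ceil(top_fraction * n))
    order = np.argsort(-scores, kind="stable")
    flags = np.full(n, "NArr", dtype=object)
    flags[order[:n_top]] = "Arr"
    return flags.astype(str)


def label_clusters(
    clusters: np.ndarray,
    arr_flags: np.ndarray,
    apc_expr: np.ndarray,
    ratio_hi: float = 0.8,
    ratio_lo: float = 0.2,
    tertile_ref: str = "cluster",
    ratio_semantics: str = "odds",
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the printed cluster-label rules; returns per-cluster table and
    per-cell subpopulation labels.

    ``ratio_semantics='odds'`` reads "ratio of Arr cells to NArr cells"
    literally as #Arr/#NArr (a cluster with no NArr cell has infinite ratio
    and is Arr); ``'fraction'`` uses #Arr/total instead. ``tertile_ref``
    chooses the reference distribution for the first-tertile APC rule:
    ``'cluster'`` (default) uses the cluster means, ``'cell'`` the per-cell
    values.
    """
    clusters = np.asarray(clusters)
    arr = np.asarray(arr_flags) == "Arr"
    apc = np.asarray(apc_expr, dtype=float)
    uniq = np.unique(clusters)
    rows = []
    for c in uniq:
        sel = clusters == c
        n_arr = int(arr[sel].sum())
        n_narr = int((~arr[sel]).sum())
        if ratio_semantics == "odds":
            ratio = math.inf if n_narr == 0 else n_arr / n_narr
        elif ratio_semantics == "fraction":
            ratio = n_arr / (n_arr + n_narr)
        else:
            raise ValueError("ratio_semantics must be 'odds' or 'fraction'")
        if ratio > ratio_hi:
            growth = "Arr"
        elif ratio < ratio_lo:
            growth = "NArr"
        else:
            growth = "unlabeled"
        rows.append((c, n_arr + n_narr, n_arr, n_narr, ratio, growth, apc[sel].mean()))
    table = pd.DataFrame(
        rows,
        columns=["cluster", "n_cells", "n_arr", "n_narr", "arr_ratio", "growth", "apc_mean"],
    )
    ref = table["apc_mean"].values if tertile_ref == "cluster" else apc
    tertile = float(np.quantile(ref, 1.0 / 3.0))
    table["apc_level"] = np.where(table["apc_mean"] < tertile, "lowAPC", "highAPC")
    table["apc_tertile"] = tertile

    def _subpop(row):
        if row.apc_level == "lowAPC" and row.growth == "NArr":
            return "LFG"
        if row.apc_level == "lowAPC" and row.growth == "Arr":
            return "LSG"
        if row.apc_level == "highAPC" and row.growth == "NArr":
            return "HFG"
        return "None"

    table["subpop"] = [_subpop(r) for r in table.itertuples()]
    per_cluster = dict(zip(table["cluster"], table["subpop"]))
    per_cell = pd.Series([per_cluster[c] for c in clusters], dtype=str)
    return table, per_cell


def find_markers(
    values: np.ndarray,
    gene_ids: list[str],
    group_a: np.ndarray,
    group_b: np.ndarray,
    logfc_min: float = 0.25,
    test: str = "wilcox",
    base: float = math.e,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential markers between two cell groups.

    ``values`` is a log-scale layer; fold changes are computed on the
    natural-scale group means (``expm1`` of the layer, pseudocount added)
    in the requested log base. ``wilcox`` uses the rank-sum test (the default
    marker test), ``t`` Welch's t-test (the bulk-style DEG variant, typically
    with ``logfc_min=1`` and ``base=2`` for the two-fold-change rule).
    Genes with |logFC| below ``logfc_min`` are dropped; q-values are BH.
    """
    values = np.asarray(values, dtype=float)
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.flatnonzero(group_a)
    if group_b.dtype == bool:
        group_b = np.flatnonzero(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be nonempty")
    xa, xb = values[group_a], values[group_b]
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    logfc = (np.log(mean_a + pseudocount) - np.log(mean_b + pseudocount)) / np.log(base)
    if test == "wilcox":
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(xa, xb, axis=0)
        pvals = np.asarray(res.pvalue, dtype=float)
    elif test == "t":
        res = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError("test must be 'wilcox' or 't'")
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    out = pd.DataFrame(
        {
            "gene": gene_ids,
            "logfc": logfc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "p": pvals,
        }
    )
    out = out[np.abs(out["logfc"]) >= logfc_min].copy()
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"].values, method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
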
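"""Target-selection cascade.

From the differential-activity table the cascade keeps significant regulators,
selects the group downregulated in the slow-growing state by hierarchical
clustering, intersects rank-fraction cuts on activity and expression
differences, collects interaction-graph evidence (shortest path to APC through
the candidate's own regulon plus the Wnt anchors, and the fraction of regulon
targets shared with APC), probes pairwise modulation between candidates with a
conditional mutual-information (MINDy-style) statistic, and finally picks the
most densely connected TF of the modulator network as the master regulator.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .regulons import Regulon


def filter_by_da(da_table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Keep regulators with differential-activity p below ``alpha``."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    kept = da_table[da_table["p"] < alpha]
    if kept.empty:
        raise ValueError(
            f"no regulator passed the differential-activity filter at alpha={alpha}"
        )
    return kept.copy()


def split_by_direction(candidates: pd.DataFrame) -> pd.DataFrame:
    """Return the candidate group downregulated in SG.

    Average-linkage Euclidean hierarchical clustering of the per-candidate
    (mean_a, mean_b) = (mean SG, mean FG) activity vectors, cut into two
    groups; the group with the lower mean (mean_a - mean_b) is returned. A
    single candidate is returned iff its SG mean is below its FG mean.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates to split")
    if len(candidates) == 1:
        row = candidates.iloc[0]
        return candidates.copy() if row["mean_a"] < row["mean_b"] else candidates.iloc[0:0].copy()
    from scipy.cluster.hierarchy import fcluster, linkage

    X = candidates[["mean_a", "mean_b"]].values
    groups = fcluster(linkage(X, method="average", metric="euclidean"), t=2, criterion="maxclust")
    delta = candidates["mean_a"].values - candidates["mean_b"].values
    means = {g: delta[groups == g].mean() for g in np.unique(groups)}
    low = min(means, key=lambda g: (means[g], g))
    return candidates[groups == low].copy()


def direction_filter(candidates: pd.DataFrame) -> pd.DataFrame:
    """Robust variant of :func:`split_by_direction` used by the pipeline.

    Runs the same two-way average-linkage split but keeps every cluster whose
    mean (SG minus FG) is negative, instead of only the lowest one: with a
    single extreme SG-down candidate, the two-way cut isolates that outlier
    and the lowest-group rule would silently discard the other genuinely
    down-regulated candidates. Clusters with non-negative mean (the SG-up
    group) are dropped.
    """
    if len(candidates) <= 1:
        return split_by_direction(candidates)
    delta = candidates["mean_a"].values - candidates["mean_b"].values
    if (delta < 0).all():
        return candidates.copy()
    from scipy.cluster.hierarchy import fcluster, linkage

    X = candidates[["mean_a", "mean_b"]].values
    groups = fcluster(
        linkage(X, method="average", metric="euclidean"), t=2, criterion="maxclust"
    )
    keep = np.zeros(len(candidates), dtype=bool)
    for g in np.unique(groups):
        if delta[groups == g].mean() < 0:
            keep |= groups == g
    if not keep.any():
        return split_by_direction(candidates)
    return candidates[keep].copy()


def rank_shortlist(
    candidates: pd.DataFrame,
    act_fraction: float = 1.0 / 6.0,
    expr_fraction: float = 1.0 / 3.0,
    act_col: str = "delta_activity",
    expr_col: str = "delta_expression",
) -> pd.DataFrame:
    """Intersect rank-fraction cuts on activity and expression differences.

    Candidates must carry FG-minus-SG activity and expression differences;
    the shortlist keeps those ranked in the top ``ceil(N * act_fraction)`` by
    activity difference AND the top ``ceil(N * expr_fraction)`` by expression
    difference. An empty intersection falls back to the activity-only top set
    with a warning.
    """
    n = len(candidates)
    if n == 0:
        raise ValueError("no candidates to shortlist")
    k_act = min(n, math.ceil(n * act_fraction))
    k_expr = min(n, math.ceil(n * expr_fraction))
    by_act = candidates.sort_values(act_col, ascending=False, kind="stable").head(k_act)
    by_expr = candidates.sort_values(expr_col, ascending=False, kind="stable").head(k_expr)
    keep = by_act.index.intersection(by_expr.index)
    if keep.empty:
        warnings.warn("empty shortlist intersection; falling back to activity-only cut")
        keep = by_act.index
    return candidates.loc[keep].sort_values(act_col, ascending=False, kind="stable")


def shortest_path_to_anchor(
    edges: pd.DataFrame | list[tuple[str, str]],
    candidate: str,
    regulon: Regulon | None,
    anchors: dict[str, str] | None = None,
) -> float:
    """Hop count of the shortest path from a candidate to APC.

    The search runs on the subgraph induced by the anchor nodes (APC, CTNNB1,
    and the caller-mapped WNT alias), the candidate itself, and the
    candidate's own regulon targets - the same gene list a curator would paste
    into an interaction database. Returns inf when disconnected.
    """
    if anchors is None:
        anchors = {"APC": "APC", "CTNNB1": "CTNNB1", "WNT": "WNT3A"}
    g = nx.Graph()
    if isinstance(edges, pd.DataFrame):
        pairs = edges[["source", "target"]].itertuples(index=False)
    else:
        pairs = edges
    for a, b in pairs:
        if a != b:
            g.add_edge(str(a), str(b))
    apc = anchors.get("APC", "APC")
    if apc not in g:
        raise ValueError("APC is absent from the interaction graph")
    allowed = set(anchors.values()) | {candidate}
    if regulon is not None:
        allowed |= set(regulon.target_genes)
    sub = g.subgraph(n for n in g.nodes if n in allowed)
    if candidate not in sub or not nx.has_path(sub, candidate, apc):
        return math.inf
    return float(nx.shortest_path_length(sub, candidate, apc))


def shared_regulon_ratio(candidate_regulon: Regulon, apc_regulon: Regulon | None) -> float:
    """|targets(candidate) ∩ targets(APC)| / |targets(candidate)|."""
    if len(candidate_regulon) == 0:
        raise ValueError("candidate regulon is empty")
    if apc_regulon is None or len(apc_regulon) == 0:
        warnings.warn("APC regulon empty; shared-regulon ratio set to 0")
        return 0.0
    cand = set(candidate_regulon.target_genes)
    return len(cand & set(apc_regulon.target_genes)) / len(cand)


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    bx = _equal_freq_bins(x, n_bins)
    by = _equal_freq_bins(y, n_bins)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint /= joint.sum()
    px = joint.reshape(n_bins, n_bins).sum(axis=1)
    py = joint.reshape(n_bins, n_bins).sum(axis=0)
    outer = np.outer(px, py).ravel()
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mindy_modulation(
    values: np.ndarray,
    gene_ids: list[str],
    modulator: str,
    tf: str,
    targets: list[str],
    split_fraction: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Conditional mutual-information test for modulation of a TF's program.

    Cells are split into the top and bottom ``split_fraction`` by modulator
    expression; for each target the TF-target mutual information is estimated
    on each split with equal-frequency binning (bins = clamp(floor(sqrt(n)),
    2, 8)); the statistic is the mean over targets of I(high) - I(low). Its
    p-value comes from permuting the high/low assignment within the pooled
    extreme cells. Returns (delta_I, p); a constant modulator gives (nan, nan).
    """
    values = np.asarray(values, dtype=float)
    n_cells = values.shape[0]
    if n_cells < 40:
        raise ValueError("mindy_modulation needs at least 40 cells")
    if not targets:
        raise ValueError("empty target list")
    pos = {g: i for i, g in enumerate(gene_ids)}
    mod = values[:, pos[modulator]]
    if np.all(mod == mod[0]):
        return float("nan"), float("nan")
    n_split = int(split_fraction * n_cells)
    order = np.argsort(mod, kind="stable")
    low_idx = order[:n_split]
    high_idx = order[-n_split:]
    n_bins = int(np.clip(int(np.sqrt(n_split)), 2, 8))
    tf_vec = values[:, pos[tf]]
    tgt_idx = [pos[g] for g in targets if g in pos]

    def delta(hi: np.ndarray, lo: np.ndarray) -> float:
        ds = []
        for j in tgt_idx:
            ih = _mutual_information(tf_vec[hi], values[hi, j], n_bins)
            il = _mutual_information(tf_vec[lo], values[lo, j], n_bins)
            ds.append(ih - il)
        return float(np.mean(ds))

    observed = delta(high_idx, low_idx)
    pool = np.concatenate([high_idx, low_idx])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        d = delta(perm[:n_split], perm[n_split:])
        if abs(d) >= abs(observed):
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return observed, p


def select_master(
    modulation: pd.DataFrame,
    delta_activity: pd.Series | dict | None = None,
    q_max: float = 0.05,
) -> dict:
    """Pick the master regulator from the pairwise modulator network.

    ``modulation`` has one row per ordered candidate pair (modulator, tf,
    delta_i, p). Edges with BH-FDR q <= ``q_max`` form a directed network;
    the master regulator is the node of maximal total degree (in + out), ties
    broken by larger |delta activity|. Pairs with edges in both directions are
    reported as cross-modulating. An empty network yields no selection.
    """
    from statsmodels.stats.multitest import multipletests

    mod = modulation.copy()
    if len(mod):
        mod["q"] = multipletests(mod["p"].values, method="fdr_bh")[1]
    else:
        mod["q"] = pd.Series(dtype=float)
    edges = mod[mod["q"] <= q_max]
    degree: dict[str, int] = {}
    for row in edges.itertuples():
        degree[row.modulator] = degree.get(row.modulator, 0) + 1
        degree[row.tf] = degree.get(row.tf, 0) + 1
    pair_set = {(r.modulator, r.tf) for r in edges.itertuples()}
    cross = sorted(
        {tuple(sorted(p)) for p in pair_set if (p[1], p[0]) in pair_set}
    )
    if not degree:
        return {
            "master": None,
            "ranking": [],
            "cross_modulating": [],
            "edges": edges,
            "note": "no modulation edge at the requested FDR",
        }

    def da(node: str) -> float:
        if delta_activity is None:
            return 0.0
        try:
            return abs(float(delta_activity[node]))
        except (KeyError, TypeError):
            return 0.0

    ranking = sorted(degree, key=lambda n: (-degree[n], -da(n), n))
    return {
        "master": ranking[0],
        "ranking": [(n, degree[n]) for n in ranking],
        "cross_modulating": cross,
        "edges": edges,
        "note": "",
    }
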
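"""Protein-activity inference from rank-based regulon enrichment.

A gene-expression signature (per cell, or for a group contrast) is mapped to
standard-normal quantile scores; the activity of a regulator on a signature is
the analytic normalized enrichment score (NES) of its regulon,

    ES  = sum_t w_t * m_t * q_t
    NES = ES / sqrt(sum_t (w_t * m_t)^2)

with target likelihoods w, modes m in {-1,+1}, and quantile scores q. Under a
random signature the NES is standard normal, so p = 2*Phi(-|NES|). When
several candidate networks exist (here: the SG-derived and FG-derived
regulons, optionally an external network), per-network NES values are
integrated with NES^2 weights, which favors whichever network shows the
regulon most strongly - the rationale behind multi-network (metaVIPER-style)
integration when no tissue-matched network is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regulons import Regulon


def _quantile_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    return stats.norm.ppf(ranks / (n + 1.0))


def group_signature(
    values: np.ndarray,
    gene_ids: list[str],
    group_a: np.ndarray,
    group_b: np.ndarray,
    genes: list[str] | None = None,
) -> pd.Series:
    """Signature of a two-group contrast as normal quantile scores.

    Per gene a Welch t-statistic (a minus b) is computed, ranked ascending
    (average ties), and mapped through the standard-normal inverse CDF:
    q_g = Phi^-1(rank_g / (G + 1)). ``genes`` optionally restricts the
    signature to a caller-supplied gene list (e.g. a DEG list) first.
    """
    values = np.asarray(values, dtype=float)
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.flatnonzero(group_a)
    if group_b.dtype == bool:
        group_b = np.flatnonzero(group_b)
    if group_a.size < 3 or group_b.size < 3:
        raise ValueError("both groups need at least three cells")
    if genes is not None:
        keep = [i for i, g in enumerate(gene_ids) if g in set(genes)]
        values = values[:, keep]
        gene_ids = [gene_ids[i] for i in keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = stats.ttest_ind(
            values[group_a], values[group_b], axis=0, equal_var=False
        )
    t = np.where(np.isfinite(t), t, 0.0)
    ranks = stats.rankdata(t)
    return pd.Series(_quantile_scores(ranks, t.size), index=gene_ids)


def cell_signatures(values: np.ndarray, gene_ids: list[str]) -> pd.DataFrame:
    """Per-cell signatures: genes rank-transformed to normal quantiles within
    each cell's (scaled) expression profile. Returns cells x genes."""
    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values, axis=1)
    q = _quantile_scores(ranks, values.shape[1])
    return pd.DataFrame(q, columns=gene_ids)


def area_nes(signature: pd.Series, regulon: Regulon) -> float:
    """Analytic rank-enrichment NES of one regulon on one signature.

    Targets absent from the signature universe are dropped with a warning;
    with no usable target the NES is NaN.
    """
    genes = [g for g in regulon.target_genes if g in signature.index]
    if len(genes) < len(regulon):
        import warnings

        warnings.warn(
            f"{len(regulon) - len(genes)} target(s) of {regulon.tf} missing from signature"
        )
    if not genes:
        return float("nan")
    w = regulon.likelihoods(genes) * regulon.modes(genes)
    q = signature.loc[genes].values
    return float(np.dot(w, q) / np.sqrt(np.sum(w**2)))


def nes_matrix(
    signatures: pd.DataFrame, regulons: dict[str, Regulon]
) -> pd.DataFrame:
    """NES of every regulon (columns) on every signature row (cells/groups).

    Vectorized version of :func:`area_nes` over a signature matrix whose
    columns are the gene universe.
    """
    genes = list(signatures.columns)
    pos = {g: i for i, g in enumerate(genes)}
    out = {}
    sig = signatures.values
    for tf, reg in regulons.items():
        tgt = [g for g in reg.target_genes if g in pos]
        if not tgt:
            out[tf] = np.full(sig.shape[0], np.nan)
            continue
        w = reg.likelihoods(tgt) * reg.modes(tgt)
        idx = [pos[g] for g in tgt]
        out[tf] = sig[:, idx] @ w / np.sqrt(np.sum(w**2))
    return pd.DataFrame(out, index=signatures.index)


def nes_pvalues(nes: float | np.ndarray | pd.DataFrame):
    """Two-sided normal p-value(s) for NES: p = 2*Phi(-|NES|)."""
    arr = nes.values if isinstance(nes, pd.DataFrame) else np.asarray(nes, dtype=float)
    p = 2.0 * stats.norm.cdf(-np.abs(arr))
    if isinstance(nes, pd.DataFrame):
        return pd.DataFrame(p, index=nes.index, columns=nes.columns)
    return p


def meta_integrate(nes_per_network: np.ndarray | list[float]) -> float:
    """Integrate one regulator's NES across K networks with NES^2 weights:
    iNES = sum_k NES_k^3 / sum_k NES_k^2. Missing (NaN) networks are skipped;
    all-missing gives NaN. Bounded between the min and max finite NES."""
    arr = np.asarray(nes_per_network, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return float("nan")
    denom = np.sum(arr**2)
    if denom == 0.0:
        return 0.0
    return float(np.sum(arr**3) / denom)


def meta_integrate_frames(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Integrate NES matrices (cells x regulators) from several networks."""
    regs = sorted(set().union(*[set(f.columns) for f in frames]))
    index = frames[0].index
    stack = np.full((len(frames), len(index), len(regs)), np.nan)
    for k, f in enumerate(frames):
        for j, r in enumerate(regs):
            if r in f.columns:
                stack[k, :, j] = f[r].values
    valid = np.isfinite(stack)
    sq = np.where(valid, stack**2, 0.0)
    cub = np.where(valid, stack**3, 0.0)
    denom = sq.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cub.sum(axis=0) / denom
    out[denom == 0.0] = np.where(valid.any(axis=0)[denom == 0.0], 0.0, np.nan)
    return pd.DataFrame(out, index=index, columns=regs)


def differential_activity(
    activity: pd.DataFrame, labels: np.ndarray, group_a: str = "SG", group_b: str = "FG"
) -> pd.DataFrame:
    """Welch t-test of per-cell activity between two labeled groups.

    Returns per regulator: mean_a, mean_b, delta (a minus b), t, p (two-sided).
    Zero variance in both groups with equal means gives t=0, p=1.
    """
    labels = np.asarray(labels)
    a = activity.loc[labels == group_a]
    b = activity.loc[labels == group_b]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least three cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a.values, b.values, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {
            "regulator": activity.columns,
            "mean_a": a.mean(axis=0).values,
            "mean_b": b.mean(axis=0).values,
            "delta": a.mean(axis=0).values - b.mean(axis=0).values,
            "t": t,
            "p": p,
        }
    ).set_index("regulator")
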
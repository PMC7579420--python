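"""Co-expression regulon inference (SCENIC-like, without motif pruning).

A regulon is a transcription factor together with its inferred targets, each
carrying a regulation mode (sign) and a likelihood (confidence weight). Edges
are scored from expression alone: by default the absolute Spearman correlation
between a TF and every other gene, optionally by gradient-boosted-tree feature
importance. Motif-based pruning is out of scope; an optional annotation table
(TF -> permitted targets) can emulate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class Regulon:
    """A TF with a signed, likelihood-weighted target set.

    ``targets`` maps gene id -> (mode, likelihood) with mode in {-1, +1} and
    likelihood in (0, 1]. The TF never appears among its own targets.
    """

    tf: str
    targets: dict[str, tuple[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"regulon for {self.tf} contains the TF itself")
        for gene, (mode, lik) in self.targets.items():
            if mode not in (-1, 1):
                raise ValueError(f"mode of {self.tf}->{gene} must be -1 or +1")
            if not (0.0 < lik <= 1.0):
                raise ValueError(f"likelihood of {self.tf}->{gene} outside (0, 1]")

    @property
    def target_genes(self) -> list[str]:
        return list(self.targets)

    def modes(self, genes: list[str] | None = None) -> np.ndarray:
        genes = self.target_genes if genes is None else genes
        return np.array([self.targets[g][0] for g in genes], dtype=float)

    def likelihoods(self, genes: list[str] | None = None) -> np.ndarray:
        genes = self.target_genes if genes is None else genes
        return np.array([self.targets[g][1] for g in genes], dtype=float)

    def __len__(self) -> int:
        return len(self.targets)


def regulons_to_frame(regulons: dict[str, Regulon]) -> pd.DataFrame:
    """Serialize a regulon collection to a long table (tf, target, mode, likelihood)."""
    rows = [
        (reg.tf, g, mode, lik)
        for reg in regulons.values()
        for g, (mode, lik) in reg.targets.items()
    ]
    return pd.DataFrame(rows, columns=["tf", "target", "mode", "likelihood"])


def frame_to_regulons(frame: pd.DataFrame) -> dict[str, Regulon]:
    out: dict[str, Regulon] = {}
    for tf, sub in frame.groupby("tf", sort=True):
        targets = {
            row.target: (int(row.mode), float(row.likelihood))
            for row in sub.itertuples()
        }
        out[str(tf)] = Regulon(tf=str(tf), targets=targets)
    return out


def _spearman_tf_vs_all(values: np.ndarray, tf_idx: np.ndarray) -> np.ndarray:
    """Spearman correlation of each TF column against every gene column.

    ``values`` is cells x genes. Returns len(tf_idx) x genes. Constant columns
    get correlation 0.
    """
    ranks = rankdata(values, axis=0).astype(float)
    ranks -= ranks.mean(axis=0, keepdims=True)
    sd = ranks.std(axis=0)
    ok = sd > 0
    denom = np.where(ok, sd, 1.0)
    z = ranks / denom
    n = values.shape[0]
    rho = (z[:, tf_idx].T @ z) / n
    rho[~ok[tf_idx], :] = 0.0
    rho[:, ~ok] = 0.0
    return np.clip(rho, -1.0, 1.0)


def score_tf_target_edges(
    values: np.ndarray,
    gene_ids: list[str],
    tf_list: list[str],
    method: str = "corr",
    seed: int = 0,
) -> pd.DataFrame:
    """Score TF -> target edge importances from expression.

    Parameters
    ----------
    values
        cells x genes expression (a normalized or batch-adjusted layer).
    method
        ``corr``: |Spearman| (deterministic, the default). ``tree``:
        gradient-boosted-tree feature importances per target gene,
        max-normalized per target so weights land in [0, 1].

    Returns a long DataFrame (tf, target, weight, rho) where ``rho`` is the
    signed Spearman correlation used later for the regulation mode.
    """
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    tfs = [t for t in tf_list if t in gene_pos]
    if not tfs:
        raise ValueError("no TF from tf_list is present in the gene universe")
    tf_idx = np.array([gene_pos[t] for t in tfs])
    rho = _spearman_tf_vs_all(np.asarray(values, dtype=float), tf_idx)

    if method == "corr":
        weight = np.abs(rho)
    elif method == "tree":
        weight = _tree_importances(values, gene_ids, tfs, tf_idx, seed)
    else:
        raise ValueError(f"unknown method {method!r}")

    tf_set = set(tfs)
    records = []
    for i, tf in enumerate(tfs):
        for j, gene in enumerate(gene_ids):
            if gene in tf_set:
                continue
            records.append((tf, gene, float(weight[i, j]), float(rho[i, j])))
    return pd.DataFrame(records, columns=["tf", "target", "weight", "rho"])


def _tree_importances(values, gene_ids, tfs, tf_idx, seed) -> np.ndarray:
    from sklearn.ensemble import GradientBoostingRegressor

    values = np.asarray(values, dtype=float)
    n_genes = len(gene_ids)
    tf_mat = values[:, tf_idx]
    imp = np.zeros((len(tfs), n_genes))
    tf_set = set(tfs)
    for j, gene in enumerate(gene_ids):
        if gene in tf_set:
            continue
        y = values[:, j]
        if np.std(y) == 0:
            continue
        model = GradientBoostingRegressor(
            n_estimators=50, max_depth=3, random_state=seed, subsample=0.9
        )
        model.fit(tf_mat, y)
        imp[:, j] = model.feature_importances_
        m = imp[:, j].max()
        if m > 0:  # per-target max-normalization to [0, 1]
            imp[:, j] /= m
    return imp


def assemble_regulons(
    edges: pd.DataFrame,
    weight_min: float = 0.5,
    min_targets: int = 5,
    annotation: dict[str, set[str]] | None = None,
) -> dict[str, Regulon]:
    """Threshold scored edges into a regulon collection.

    Keeps edges with ``weight >= weight_min``; the regulation mode is the sign
    of the Spearman correlation and the likelihood is the edge weight. Regulons
    with fewer than ``min_targets`` surviving targets are dropped. ``annotation``
    optionally restricts each TF to a permitted target set (motif-pruning
    stand-in).
    """
    kept = edges[edges["weight"] >= weight_min]
    out: dict[str, Regulon] = {}
    for tf, sub in kept.groupby("tf", sort=True):
        targets = {}
        allowed = annotation.get(str(tf)) if annotation is not None else None
        for row in sub.itertuples():
            if row.target == tf:
                continue
            if allowed is not None and row.target not in allowed:
                continue
            mode = 1 if row.rho >= 0 else -1
            lik = float(min(max(row.weight, np.nextafter(0, 1)), 1.0))
            targets[row.target] = (mode, lik)
        if len(targets) >= min_targets:
            out[str(tf)] = Regulon(tf=str(tf), targets=targets)
    if not out:
        raise ValueError(
            "no regulon survived assembly; lower weight_min or min_targets"
        )
    return out
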
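"""Preprocessing: QC filtering, TMM normalization, empirical-Bayes batch
adjustment, optional low-rank imputation, and scaling with covariate
(cell-cycle score) regression.

All operations work on an AnnData (cells x genes) and read/write named layers:
``counts`` -> ``tmm`` (library-composition normalized, linear scale) ->
``corrected`` (batch-adjusted log1p of tmm) -> optional ``imputed`` ->
``scaled`` (per-gene mean 0 / variance 1 residuals).
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import scipy.sparse as sp


def _dense(layer) -> np.ndarray:
    if sp.issparse(layer):
        return np.asarray(layer.todense(), dtype=float)
    return np.asarray(layer, dtype=float)


def qc_filter(
    adata: ad.AnnData, min_genes: int = 200, min_counts: int = 500
) -> tuple[ad.AnnData, dict]:
    """Remove low-quality cells.

    A cell is dropped when it has fewer than ``min_genes`` detected genes or a
    total count below ``min_counts`` (dying cells and debris tend to show very
    few genes or very low unique counts). Genes are untouched. Returns the
    filtered view (copied) and a removal report. Idempotent.
    """
    counts = adata.layers.get("counts", adata.X)
    if sp.issparse(counts):
        detected = np.asarray((counts > 0).sum(axis=1)).ravel()
        total = np.asarray(counts.sum(axis=1)).ravel()
    else:
        counts = np.asarray(counts)
        detected = (counts > 0).sum(axis=1)
        total = counts.sum(axis=1)
    keep = (detected >= min_genes) & (total >= min_counts)
    if not keep.any():
        raise ValueError("qc_filter removed every cell; thresholds too strict")
    report = {
        "n_input": int(adata.n_obs),
        "n_removed": int((~keep).sum()),
        "removed_few_genes": int((detected < min_genes).sum()),
        "removed_low_counts": int((total < min_counts).sum()),
        "removed_cells": list(adata.obs_names[~keep]),
    }
    return adata[keep].copy(), report


def tmm_factors(
    counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factor per cell.

    The reference cell is the one whose 75th percentile of nonzero counts is
    closest to the across-cell mean of that statistic. For each cell, M- and
    A-values against the reference are computed over genes nonzero in both
    (log2, no pseudocount needed since zeros are excluded); the top and bottom
    ``trim_m`` of M and ``trim_a`` of A are trimmed, and the factor is
    2**(precision-weighted mean M), precision weights from the usual binomial
    variance approximation. Factors are rescaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    n_cells = counts.shape[0]
    if n_cells < 2:
        raise ValueError("TMM needs at least two cells")
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("TMM cannot handle all-zero cells")
    q75 = np.array(
        [np.percentile(row[row > 0], 75) if (row > 0).any() else 0.0 for row in counts]
    )
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts[ref_idx]
    log_fac = np.zeros(n_cells)
    for i in range(n_cells):
        if i == ref_idx:
            continue
        both = (counts[i] > 0) & (ref > 0)
        if not both.any():
            warnings.warn(
                f"cell {i} shares no expressed gene with the reference; factor 1"
            )
            continue
        x, r = counts[i, both], ref[both]
        m = np.log2(x) - np.log2(r)
        a = 0.5 * (np.log2(x) + np.log2(r))
        keep = np.ones(m.size, dtype=bool)
        if m.size > 4:
            lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
            lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
            keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
            if not keep.any():
                keep[:] = True
        # asymptotic variance of M for count data (delta method)
        var = (lib[i] - x) / (lib[i] * x) + (lib[ref_idx] - r) / (lib[ref_idx] * r)
        var = np.maximum(var, 1e-12)
        w = 1.0 / var
        log_fac[i] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    log_fac -= log_fac.mean()  # geometric mean 1
    return np.power(2.0, log_fac)


def tmm_normalize(
    adata: ad.AnnData, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Write the ``tmm`` layer and return the per-cell factors.

    Normalized value = count / factor. The factors are computed from raw-count
    M-values, so they absorb both sequencing depth and library composition;
    dividing by the factor alone maps exactly proportional cells onto
    identical normalized profiles (dividing additionally by library size
    would correct depth twice and re-introduce composition artifacts).
    """
    counts = _dense(adata.layers.get("counts", adata.X))
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    adata.layers["tmm"] = counts / factors[:, None]
    adata.obs["tmm_factor"] = factors
    return factors


def combat_adjust(
    adata: ad.AnnData,
    batch_key: str = "batch",
    layer: str = "tmm",
    out_layer: str = "corrected",
    log_input: bool = True,
    eb: bool = True,
) -> np.ndarray:
    """Location/scale batch adjustment with optional empirical-Bayes shrinkage.

    Per gene the data are standardized, per-batch location and scale are
    estimated, optionally shrunk across genes (normal prior on locations,
    inverse-gamma on scales, moment-matched hyperparameters, one-step
    posterior), then removed and the gene-level location/scale restored. With
    ``eb=False`` the per-gene per-batch means are exactly equalized to the
    overall gene mean.

    ``log_input`` applies log1p first (batch adjustment assumes roughly
    Gaussian data); the adjusted layer then lives on log scale.
    """
    batches = adata.obs[batch_key].astype(str).values
    uniq = np.unique(batches)
    if len(uniq) < 2:
        raise ValueError("combat_adjust needs at least two batches")
    for b in uniq:
        if (batches == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than two cells")
    x = _dense(adata.layers[layer])
    if log_input:
        x = np.log1p(x)
    grand = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    z = (x - grand) / sd_safe

    adj = np.array(z)
    for b in uniq:
        sel = batches == b
        nb = int(sel.sum())
        gamma = z[sel].mean(axis=0)
        delta2 = z[sel].var(axis=0, ddof=0)
        zero_var = delta2 <= 1e-12  # standardized scale; treat fp dust as zero
        if zero_var.any():
            warnings.warn(
                f"{int(zero_var.sum())} gene(s) with zero variance in batch {b!r}; "
                "scale adjustment skipped for those"
            )
        if eb:
            g_bar = gamma.mean()
            t2 = gamma.var(ddof=1)
            d_ok = delta2[~zero_var]
            m = d_ok.mean() if d_ok.size else 1.0
            s2 = d_ok.var(ddof=1) if d_ok.size > 1 else 0.0
            if s2 > 0:
                a_prior = (2 * s2 + m**2) / s2
                b_prior = (m * s2 + m**3) / s2
            else:
                a_prior, b_prior = 2.0, m
            if t2 > 0:
                gamma_star = (nb * t2 * gamma + delta2 * g_bar) / (nb * t2 + delta2)
                gamma_star = np.where(zero_var, gamma, gamma_star)
            else:
                gamma_star = np.full_like(gamma, g_bar)
            ss = ((z[sel] - gamma_star) ** 2).sum(axis=0)
            delta2_star = (b_prior + 0.5 * ss) / (nb / 2.0 + a_prior - 1.0)
            delta2_star = np.where(zero_var, 1.0, delta2_star)
        else:
            gamma_star = gamma
            delta2_star = np.where(zero_var, 1.0, delta2)
        adj[sel] = (z[sel] - gamma_star) / np.sqrt(np.maximum(delta2_star, 1e-12))

    out = adj * sd_safe + grand
    out[:, const] = x[:, const]
    adata.layers[out_layer] = out
    return out


def alra_impute(
    adata: ad.AnnData, rank: int = 20, layer: str = "corrected", out_layer: str = "imputed"
) -> np.ndarray:
    """Adaptively thresholded low-rank imputation.

    Reconstructs the layer at the given SVD rank; per gene, reconstructed
    entries smaller in magnitude than that gene's most negative reconstructed
    value are zeroed (the symmetry of the reconstruction error around zero
    makes this an adaptive noise floor); surviving values of genes observed
    nonzero are affinely rescaled to restore the observed nonzero mean and
    variance.
    """
    x = _dense(adata.layers[layer])
    n, g = x.shape
    if rank <= 0:
        raise ValueError("rank must be positive")
    if rank >= min(n, g):
        recon = x.copy()
    else:
        from scipy.sparse.linalg import svds

        u, s, vt = svds(x, k=rank, random_state=0)
        order = np.argsort(s)[::-1]
        recon = (u[:, order] * s[order]) @ vt[order]

    thresh = np.abs(np.minimum(recon.min(axis=0), 0.0))
    out = np.where(np.abs(recon) <= thresh[None, :], 0.0, recon)
    out[out < 0] = 0.0

    observed = x > 0
    for j in range(g):
        obs = observed[:, j]
        kept = obs & (out[:, j] > 0)
        if kept.sum() < 2:
            continue
        mu_o, sd_o = x[obs, j].mean(), x[obs, j].std()
        mu_r, sd_r = out[kept, j].mean(), out[kept, j].std()
        if sd_r > 1e-12 and sd_o > 0:
            col = out[:, j]
            nz = col > 0
            col[nz] = (col[nz] - mu_r) / sd_r * sd_o + mu_o
            col[col < 0] = 0.0
            out[:, j] = col
    adata.layers[out_layer] = out
    return out


def scale_regress(
    adata: ad.AnnData,
    covariates: np.ndarray | None = None,
    layer: str = "corrected",
    out_layer: str = "scaled",
) -> np.ndarray:
    """Regress per-cell covariates out of each gene, then standardize.

    Each gene is replaced by the residual of an ordinary least-squares fit on
    the covariates plus intercept (used to rule out cell-cycle heterogeneity by
    regressing the S and G2M scores), then scaled to mean 0 / variance 1.
    Residuals are exactly orthogonal to every covariate. Genes with constant
    residuals are set to all-zero with a warning.
    """
    x = _dense(adata.layers[layer])
    n = x.shape[0]
    if covariates is None or np.size(covariates) == 0:
        design = np.ones((n, 1))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariates must be finite")
        design = np.column_stack([np.ones(n), cov])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    sd = resid.std(axis=0, ddof=0)
    const = sd < 1e-12
    if const.any():
        warnings.warn(
            f"{int(const.sum())} gene(s) constant after regression; scaled row set to 0"
        )
    out = np.zeros_like(resid)
    ok = ~const
    out[:, ok] = (resid[:, ok] - resid[:, ok].mean(axis=0)) / sd[ok]
    adata.layers[out_layer] = out
    return out
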
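"""End-to-end orchestration: simulate/load -> preprocess -> classify ->
regulons -> activity -> prioritize -> report.

Each stage is a plain function over an AnnData plus a context dict, so the
numbered analysis drivers and the tests can run any stage in isolation. A
stage failure raises :class:`StageError` naming the stage; outputs produced
up to that point stay in the context.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import activity as act
from . import io as mio
from . import preprocess as pp
from . import prioritize as pri
from . import regulons as regmod
from . import scoring as sco
from . import synthetic as syn
from .config import PipelineConfig

SCHEMA_VERSION = 1


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage:{stage}] {message}")
        self.stage = stage


def stage_data(cfg: PipelineConfig) -> dict:
    """Simulate the planted study or load the fixture files."""
    ctx: dict = {"config": cfg}
    if cfg.simulate:
        design_kwargs = dict(cfg.sim_design)
        if "n_cells" in design_kwargs:
            # YAML spells the (condition, batch) keys as "condition:batch"
            design_kwargs["n_cells"] = {
                (tuple(k.split(":")) if isinstance(k, str) else tuple(k)): int(v)
                for k, v in design_kwargs["n_cells"].items()
            }
        design = syn.SimDesign(seed=cfg.seed, **design_kwargs)
        network, design, adata, truth = syn.make_study(
            seed=cfg.seed,
            design=design,
            n_tfs=cfg.sim_n_tfs,
            targets_per_tf=cfg.sim_targets_per_tf,
            n_mrs=cfg.sim_n_mrs,
        )
        ctx.update(
            adata=adata,
            truth=truth,
            network=network,
            signatures=adata.uns["signatures"],
            stem_weights=pd.Series(adata.uns["stem_weights"]),
            tf_list=list(network.tf_ids) + [syn.APC],
            graph_edges=pd.DataFrame(
                adata.uns["interaction_edges"], columns=["source", "target"]
            ),
            # the planted network stands in for the externally supplied
            # patient-derived regulatory network (shared-regulon evidence)
            external_network=dict(network.regulons),
        )
        return ctx
    for name in ("data_dir", "gene_sets_gmt", "stem_weights_tsv", "tf_list_tsv", "graph_tsv"):
        path = getattr(cfg, name)
        if path is None or not Path(path).exists():
            raise StageError("data", f"missing required input: {name}={path}")
    adata = mio.read_10x_dir(cfg.data_dir)
    external = None
    if cfg.external_network_tsv and Path(cfg.external_network_tsv).exists():
        external = regmod.frame_to_regulons(
            pd.read_csv(cfg.external_network_tsv, sep="\t")
        )
    ctx.update(
        adata=adata,
        truth=None,
        network=None,
        signatures=mio.read_gmt(cfg.gene_sets_gmt),
        stem_weights=mio.read_weights(cfg.stem_weights_tsv),
        tf_list=mio.read_tf_list(cfg.tf_list_tsv) + [cfg.apc_gene],
        graph_edges=mio.read_edge_list(cfg.graph_tsv),
        external_network=external,
    )
    return ctx


def stage_preprocess(ctx: dict) -> dict:
    cfg: PipelineConfig = ctx["config"]
    try:
        adata, qc_report = pp.qc_filter(ctx["adata"], cfg.min_genes, cfg.min_counts)
        pp.tmm_normalize(adata, trim_m=cfg.trim_m, trim_a=cfg.trim_a)
        pp.combat_adjust(adata, batch_key="batch", eb=cfg.eb)
        if cfg.impute:
            pp.alra_impute(adata, rank=cfg.impute_rank)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", str(exc)) from exc
    ctx["adata"] = adata
    ctx["qc_report"] = {k: v for k, v in qc_report.items() if k != "removed_cells"}
    return ctx


def stage_classify(ctx: dict) -> dict:
    """Module scores, cell-cycle regression, clustering, subpopulation labels."""
    cfg: PipelineConfig = ctx["config"]
    adata: ad.AnnData = ctx["adata"]
    sigs = ctx["signatures"]
    try:
        layer = adata.layers["imputed" if cfg.impute and "imputed" in adata.layers else "corrected"]
        genes = list(adata.var_names)
        adata.obs["arrest_score"] = sco.module_score(
            layer, genes, sigs["arrest"], cfg.n_bins, cfg.n_ctrl, cfg.seed
        )
        adata.obs["apoptosis_score"] = sco.module_score(
            layer, genes, sigs["apoptosis"], cfg.n_bins, cfg.n_ctrl, cfg.seed + 2
        )
        adata.obs["stemness"] = sco.stemness_index(layer, genes, ctx["stem_weights"])
        cc = sco.cell_cycle_assign(
            layer, genes, sigs["s_phase"], sigs["g2m_phase"],
            cfg.n_bins, cfg.n_ctrl, cfg.seed + 10,
        )
        adata.obs[["s_score", "g2m_score"]] = cc[["s_score", "g2m_score"]].values
        adata.obs["phase"] = cc["phase"].values
        pp.scale_regress(
            adata, covariates=cc[["s_score", "g2m_score"]].values, layer="corrected"
        )
        adata.obs["cluster"] = sco.snn_cluster(
            adata.layers["scaled"], k=cfg.knn, resolution=cfg.resolution,
            n_pcs=cfg.n_pcs, seed=cfg.seed,
        )
        adata.obs["arr_flag"] = sco.binarize_by_quantile(
            adata.obs["arrest_score"].values, cfg.top_fraction
        )
        apc_expr = np.asarray(layer)[:, genes.index(cfg.apc_gene)]
        cluster_table, subpop = sco.label_clusters(
            adata.obs["cluster"].values,
            adata.obs["arr_flag"].values,
            apc_expr,
            ratio_hi=cfg.ratio_hi,
            ratio_lo=cfg.ratio_lo,
            tertile_ref=cfg.tertile_ref,
            ratio_semantics=cfg.ratio_semantics,
        )
        adata.obs["subpop"] = subpop.values
        ctx["cluster_table"] = cluster_table
        is_sg = (adata.obs["subpop"] == "LSG").values
        is_fg = (adata.obs["subpop"] == "LFG").values
        if is_sg.sum() < 3 or is_fg.sum() < 3:
            raise ValueError(
                f"labeling found {int(is_sg.sum())} LSG / {int(is_fg.sum())} LFG cells; "
                "cannot contrast the subpopulations"
            )
        ctx["markers"] = sco.find_markers(
            layer, genes, is_sg, is_fg, logfc_min=cfg.logfc_min
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", str(exc)) from exc
    return ctx


def _subset_values(adata: ad.AnnData, mask: np.ndarray, layer: str) -> np.ndarray:
    vals = adata.layers[layer]
    return np.asarray(vals[mask], dtype=float)


def stage_regulons(ctx: dict) -> dict:
    """Infer SG- and FG-specific regulons plus a pooled reference network."""
    cfg: PipelineConfig = ctx["config"]
    adata: ad.AnnData = ctx["adata"]
    genes = list(adata.var_names)
    subpop = adata.obs["subpop"].values
    networks: dict[str, dict[str, regmod.Regulon]] = {}
    try:
        for name, mask in (
            ("SG", subpop == "LSG"),
            ("FG", subpop == "LFG"),
            ("pooled", np.ones(adata.n_obs, dtype=bool)),
        ):
            if mask.sum() < cfg.min_subset_cells and name != "pooled":
                warnings.warn(f"{name} subset has {int(mask.sum())} cells; skipping network")
                continue
            edges = regmod.score_tf_target_edges(
                _subset_values(adata, mask, "corrected"),
                genes,
                ctx["tf_list"],
                method=cfg.edge_method,
                seed=cfg.seed,
            )
            networks[name] = regmod.assemble_regulons(
                edges, weight_min=cfg.weight_min, min_targets=cfg.min_targets
            )
        if not ({"SG", "FG"} & set(networks)):
            raise ValueError("no subpopulation network could be inferred")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("regulons", str(exc)) from exc
    ctx["networks"] = networks
    return ctx


def stage_activity(ctx: dict) -> dict:
    """Per-cell NES, multi-network integration, SG-vs-FG differential activity."""
    cfg: PipelineConfig = ctx["config"]
    adata: ad.AnnData = ctx["adata"]
    genes = list(adata.var_names)
    subpop = adata.obs["subpop"].values
    mask = (subpop == "LSG") | (subpop == "LFG")
    try:
        values = _subset_values(adata, mask, "scaled")
        if cfg.signature_genes == "markers":
            marker_genes = set(ctx["markers"]["gene"])
            keep = [i for i, g in enumerate(genes) if g in marker_genes]
            if len(keep) < 50:
                warnings.warn("fewer than 50 marker genes; using the full universe")
            else:
                values = values[:, keep]
                genes = [genes[i] for i in keep]
        signatures = act.cell_signatures(values, genes)
        frames = []
        for name in ("SG", "FG"):
            if name in ctx["networks"]:
                frames.append(act.nes_matrix(signatures, ctx["networks"][name]))
        integrated = act.meta_integrate_frames(frames)
        labels = np.where(subpop[mask] == "LSG", "SG", "FG")
        da = act.differential_activity(integrated, labels)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("activity", str(exc)) from exc
    ctx["activity"] = integrated
    ctx["activity_labels"] = labels
    ctx["da_table"] = da
    return ctx


def stage_prioritize(ctx: dict) -> dict:
    cfg: PipelineConfig = ctx["config"]
    adata: ad.AnnData = ctx["adata"]
    genes = list(adata.var_names)
    subpop = adata.obs["subpop"].values
    try:
        da = ctx["da_table"].drop(index=cfg.apc_gene, errors="ignore")
        cands = pri.filter_by_da(da, alpha=cfg.alpha)
        # keep the SG-downregulated side of the candidate clustering (every
        # cluster with negative mean difference, so a single extreme
        # candidate cannot absorb the whole "down" group)
        cands = pri.direction_filter(cands)
        if cands.empty:
            raise ValueError("no SG-downregulated candidate group")
        # FG-minus-SG differences on activity and expression
        cands["delta_activity"] = cands["mean_b"] - cands["mean_a"]
        layer = np.asarray(adata.layers["corrected"], dtype=float)
        sg_cells = subpop == "LSG"
        fg_cells = subpop == "LFG"
        dexpr = []
        for g in cands.index:
            j = genes.index(g)
            dexpr.append(layer[fg_cells, j].mean() - layer[sg_cells, j].mean())
        cands["delta_expression"] = dexpr
        if cfg.exclusion_tsv and Path(cfg.exclusion_tsv).exists():
            excluded = set(mio.read_tf_list(cfg.exclusion_tsv))
            cands = cands.drop(index=[g for g in cands.index if g in excluded])
        shortlist = pri.rank_shortlist(
            cands, act_fraction=cfg.act_fraction, expr_fraction=cfg.expr_fraction
        )
        # graph evidence uses the candidate's inferred downstream targets;
        # shared-regulon evidence uses the external (patient-derived) network
        # when available, the pooled inferred network otherwise
        reference = (
            ctx["networks"].get("pooled")
            or ctx["networks"].get("FG")
            or ctx["networks"].get("SG")
        )
        external = ctx.get("external_network") or reference
        apc_reg = external.get(cfg.apc_gene) or reference.get(cfg.apc_gene)
        paths, shared = [], []
        for g in shortlist.index:
            reg = reference.get(g) or ctx["networks"].get("FG", {}).get(g) or ctx[
                "networks"
            ].get("SG", {}).get(g)
            paths.append(
                pri.shortest_path_to_anchor(ctx["graph_edges"], g, reg)
                if reg is not None
                else float("inf")
            )
            ext_reg = external.get(g) or reg
            shared.append(
                pri.shared_regulon_ratio(ext_reg, apc_reg) if ext_reg is not None else 0.0
            )
        shortlist["path_to_apc"] = paths
        shortlist["shared_with_apc"] = shared
        # pairwise MINDy modulation among shortlisted candidates
        mask = sg_cells | fg_cells
        values = np.asarray(adata.layers["corrected"], dtype=float)[mask]
        rows = []
        cand_list = list(shortlist.index)
        for m in cand_list:
            for t in cand_list:
                if m == t:
                    continue
                reg = reference.get(t) or ctx["networks"].get("FG", {}).get(t)
                if reg is None:
                    continue
                targets = sorted(
                    reg.targets, key=lambda g: -reg.targets[g][1]
                )[: cfg.mindy_max_targets]
                di, p = pri.mindy_modulation(
                    values, genes, m, t, targets,
                    split_fraction=cfg.mindy_split,
                    n_perm=cfg.mindy_perm,
                    seed=cfg.seed + 7,
                )
                rows.append((m, t, di, p))
        modulation = pd.DataFrame(rows, columns=["modulator", "tf", "delta_i", "p"])
        modulation = modulation.dropna(subset=["p"])
        selection = pri.select_master(
            modulation, delta_activity=shortlist["delta_activity"], q_max=cfg.q_max
        )
        degree_rank = [n for n, _ in selection["ranking"]]
        if selection["master"] is None:
            # no modulation edge survived: fall back to the activity ranking
            ranked = shortlist.sort_values(
                "delta_activity", ascending=False, kind="stable"
            ).index.tolist()
            selection["master"] = ranked[0] if ranked else None
            selection["note"] = (
                selection["note"] + "; master from activity ranking fallback"
            ).strip("; ")
            degree_rank = ranked
        shortlist["modulation_degree"] = [
            dict(selection["ranking"]).get(g, 0) for g in shortlist.index
        ]
        # primary target: among a cross-modulating pair the member sharing the
        # most regulon targets with APC wins (the evidence that broke the
        # CCDC85B-vs-PTTG1 tie); otherwise the master itself
        primary = selection["master"]
        cross_nodes = {n for pair in selection["cross_modulating"] for n in pair}
        cross_nodes &= set(shortlist.index)
        if cross_nodes:
            ratios = shortlist.loc[sorted(cross_nodes), "shared_with_apc"]
            if ratios.max() > ratios.min():
                primary = ratios.idxmax()
        shortlist["selected"] = [g == primary for g in shortlist.index]
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("prioritize", str(exc)) from exc
    ctx["candidates"] = cands
    ctx["shortlist"] = shortlist
    ctx["modulation"] = modulation
    ctx["selection"] = {
        "master": selection["master"],
        "primary_target": primary,
        "ranking": degree_rank,
        "cross_modulating": [list(p) for p in selection["cross_modulating"]],
        "note": selection["note"],
    }
    return ctx


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the full context."""
    ctx = stage_data(cfg)
    ctx = stage_preprocess(ctx)
    ctx = stage_classify(ctx)
    ctx = stage_regulons(ctx)
    ctx = stage_activity(ctx)
    ctx = stage_prioritize(ctx)
    return ctx


def build_report(ctx: dict) -> dict:
    """Assemble the machine-readable run report (JSON-serializable)."""
    cfg: PipelineConfig = ctx["config"]
    adata: ad.AnnData = ctx["adata"]
    counts = adata.obs["subpop"].value_counts().to_dict()
    config_echo = cfg.to_dict()
    if "n_cells" in config_echo.get("sim_design", {}):
        config_echo["sim_design"] = dict(config_echo["sim_design"])
        config_echo["sim_design"]["n_cells"] = {
            (k if isinstance(k, str) else ":".join(k)): int(v)
            for k, v in config_echo["sim_design"]["n_cells"].items()
        }
    report = {
        "schema_version": SCHEMA_VERSION,
        "config": config_echo,
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
        "qc": ctx.get("qc_report", {}),
        "n_clusters": int(adata.obs["cluster"].nunique()),
        "subpop_counts": {str(k): int(v) for k, v in counts.items()},
        "n_markers": int(len(ctx.get("markers", []))),
        "networks": {
            name: {tf: len(reg) for tf, reg in net.items()}
            for name, net in ctx.get("networks", {}).items()
        },
        "n_candidates": int(len(ctx.get("candidates", []))),
        "shortlist": list(ctx.get("shortlist", pd.DataFrame()).index),
        "selection": ctx.get("selection", {"master": None}),
        "empty_selection": ctx.get("selection", {}).get("master") is None,
    }
    if ctx.get("truth") is not None:
        truth = ctx["truth"]
        common = adata.obs_names.intersection(truth.index)
        true_sg = truth.loc[common, "subpop"] == "SG"
        called_sg = adata.obs.loc[common, "subpop"] == "LSG"
        n_true = int(true_sg.sum())
        report["truth"] = {
            "planted_mrs": ctx["network"].mr_ids if ctx.get("network") else [],
            "dominant_mr": ctx["network"].mr_ids[0] if ctx.get("network") else None,
            "sg_recall": float((true_sg & called_sg).sum() / n_true) if n_true else None,
            "primary_is_dominant_mr": (
                ctx.get("selection", {}).get("primary_target")
                == (ctx["network"].mr_ids[0] if ctx.get("network") else None)
            ),
        }
    return report


def write_report(ctx: dict, outdir: str | Path) -> Path:
    """Write the JSON report plus CSV evidence tables; returns the JSON path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = build_report(ctx)
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    for key, name in (
        ("cluster_table", "clusters.csv"),
        ("markers", "markers.csv"),
        ("da_table", "differential_activity.csv"),
        ("candidates", "candidates.csv"),
        ("shortlist", "shortlist.csv"),
        ("modulation", "modulation.csv"),
    ):
        obj = ctx.get(key)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / name)
    ctx["adata"].obs.to_csv(outdir / "cell_table.tsv", sep="\t")
    return path


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
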
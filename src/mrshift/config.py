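"""Pipeline configuration: every threshold of the cascade in one place.

Defaults mirror the printed analysis rules: QC at <200 detected genes /
<500 total counts, the top one-fifth arrest binarization, Arr:NArr cluster
ratio cuts at 0.8/0.2, the first-tertile APC rule, a 0.25 log-fold-change
marker threshold, the p<0.01 differential-activity filter, one-sixth /
one-third shortlist fractions, and a 0.05 FDR for the modulator network.
Unknown keys are rejected so config typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    # run control
    simulate: bool = True
    seed: int = 0
    outdir: str = "results/run"
    # file inputs (used when simulate is False; fixture dir with MTX triple etc.)
    data_dir: str | None = None
    gene_sets_gmt: str | None = None
    stem_weights_tsv: str | None = None
    tf_list_tsv: str | None = None
    graph_tsv: str | None = None
    exclusion_tsv: str | None = None
    external_network_tsv: str | None = None
    # synthetic design (used when simulate is True)
    sim_n_tfs: int = 20
    sim_targets_per_tf: int = 20
    sim_n_mrs: int = 10
    sim_design: dict[str, Any] = field(default_factory=dict)
    # preprocessing
    min_genes: int = 200
    min_counts: int = 500
    trim_m: float = 0.30
    trim_a: float = 0.05
    eb: bool = True
    impute: bool = False
    impute_rank: int = 20
    expr_layer: str = "corrected"
    # scoring / classification
    n_bins: int = 24
    n_ctrl: int = 100
    knn: int = 20
    resolution: float = 1.0
    n_pcs: int = 20
    top_fraction: float = 0.2
    ratio_hi: float = 0.8
    ratio_lo: float = 0.2
    ratio_semantics: str = "odds"
    tertile_ref: str = "cell"
    apc_gene: str = "APC"
    logfc_min: float = 0.25
    # regulon inference
    edge_method: str = "corr"
    weight_min: float = 0.5
    min_targets: int = 5
    min_subset_cells: int = 50
    # activity
    signature_genes: str = "all"  # 'all' or 'markers' (restrict to SG/FG DEGs)
    # prioritization
    alpha: float = 0.01
    act_fraction: float = 1.0 / 6.0
    expr_fraction: float = 1.0 / 3.0
    mindy_split: float = 0.25
    mindy_perm: int = 200
    mindy_max_targets: int = 20
    q_max: float = 0.05

    def __post_init__(self) -> None:
        checks = [
            (0 < self.top_fraction <= 1, "top_fraction in (0, 1]"),
            (self.ratio_lo < self.ratio_hi, "ratio_lo < ratio_hi"),
            (0 < self.alpha <= 1, "alpha in (0, 1]"),
            (0 < self.act_fraction <= 1, "act_fraction in (0, 1]"),
            (0 < self.expr_fraction <= 1, "expr_fraction in (0, 1]"),
            (0 < self.q_max <= 1, "q_max in (0, 1]"),
            (0 < self.mindy_split <= 0.5, "mindy_split in (0, 0.5]"),
            (self.min_genes >= 0 and self.min_counts >= 0, "QC thresholds >= 0"),
            (self.ratio_semantics in ("odds", "fraction"), "ratio_semantics"),
            (self.tertile_ref in ("cluster", "cell"), "tertile_ref"),
            (self.signature_genes in ("all", "markers"), "signature_genes"),
            (self.edge_method in ("corr", "tree"), "edge_method"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"config constraint violated: {what}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
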
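"""Synthetic scRNA-seq generator with a planted regulatory network.

Emulates the shAPC/shScr two-condition, two-time-point design in which a
minority arrested (slow-growing, SG) subpopulation hides inside the
APC-knockdown cells. The generator plants, with full ground truth:

* a gene regulatory network (TFs with signed, likelihood-weighted regulons),
  a subset of which are differential master regulators (MRs) whose activity
  is shifted in SG cells;
* an APC gene whose mean drops by a configurable knockdown factor in shAPC
  cells (with a slightly deeper drop in SG cells, modeling heterogeneous
  shRNA efficacy: the cells that arrest are the ones that responded most);
* signature programs (cell-cycle arrest, apoptosis execution, stemness,
  S-phase and G2M-phase marker blocks) whose means move in SG cells or with
  the planted cell-cycle phase;
* a knockdown-response program shared by all shAPC cells, so conditions are
  separable by unsupervised clustering;
* cross-modulation between designated MR pairs: the coupling of one MR to its
  targets is strong only in cells where the partner MR's latent activity is
  high, which is exactly the conditional-dependence pattern a MINDy-style
  analysis should detect.

Counts are negative binomial around cell-specific log-means, with optional
independent Bernoulli dropout. A single RNG stream seeded once determines the
whole output; the draw order is documented in :func:`simulate_cells`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import write_10x_dir, write_edge_list, write_gmt, write_weights
from .regulons import Regulon

APC = "APC"
ANCHOR_ALIASES = {"APC": "APC", "CTNNB1": "CTNNB1", "WNT": "WNT3A"}

#: signature block sizes carved from the tail of the gene universe
_BLOCKS = (
    ("arrest", 80),
    ("apoptosis", 60),
    ("stemness", 60),
    ("s_phase", 40),
    ("g2m_phase", 40),
    ("response", 100),
)
RESERVED_TAIL = sum(n for _, n in _BLOCKS)  # 380 genes


def gene_universe(n_genes: int, n_tfs: int) -> list[str]:
    """Gene id layout: APC, then TFs, then generic genes.

    index 0 is always ``APC``; indices 1..n_tfs are ``TF01``..; the rest are
    ``G####``. The last :data:`RESERVED_TAIL` generic genes are reserved for
    the signature blocks and are never drawn as regulon targets.
    """
    if n_genes < n_tfs + 1 + RESERVED_TAIL + 10:
        raise ValueError("gene universe too small for TFs plus signature blocks")
    ids = [APC]
    ids += [f"TF{i:02d}" for i in range(1, n_tfs + 1)]
    ids += [f"G{i:04d}" for i in range(n_tfs + 1, n_genes)]
    return ids


def signature_blocks(gene_ids: list[str]) -> dict[str, list[str]]:
    """Positional assignment of the signature blocks to the universe tail."""
    out: dict[str, list[str]] = {}
    stop = len(gene_ids)
    for name, size in reversed(_BLOCKS):
        out[name] = gene_ids[stop - size : stop]
        stop -= size
    return out


@dataclass
class PlantedNetwork:
    """Ground-truth regulatory network.

    ``effects`` maps each master regulator to its activity shift (log scale)
    between subpopulations: SG cells carry latent activity lowered by the
    effect, so MRs (and their activated targets) are down in SG.
    """

    tf_ids: list[str]
    regulons: dict[str, Regulon]
    mr_ids: list[str]
    effects: dict[str, float]

    def __post_init__(self) -> None:
        if not set(self.mr_ids) <= set(self.tf_ids):
            raise ValueError("mr_ids must be a subset of tf_ids")
        for tf, reg in self.regulons.items():
            if len(reg) < 5:
                raise ValueError(f"regulon {tf} has fewer than 5 targets")
        missing = set(self.mr_ids) - set(self.effects)
        if missing:
            raise ValueError(f"missing effect for MRs: {sorted(missing)}")


def generate_grn(
    n_tfs: int,
    targets_per_tf: int,
    n_mrs: int,
    seed: int,
    n_genes: int = 2000,
    activator_fraction: float = 0.7,
    mr_effects: np.ndarray | list[float] | None = None,
) -> PlantedNetwork:
    """Draw a planted regulatory network.

    Targets are drawn without replacement per TF from the generic gene pool
    (signature-block genes excluded), modes are +/-1 with
    ``activator_fraction`` activators, likelihoods uniform in (0.5, 1]
    (the dominant MR pair draws from (0.75, 1], see below). The first
    ``n_mrs`` TFs are the designated master regulators with the effect
    profile of :func:`default_mr_effects`. Deterministic for a fixed seed.
    """
    if n_tfs <= 0 or n_mrs <= 0 or targets_per_tf <= 0:
        raise ValueError("n_tfs, targets_per_tf and n_mrs must be positive")
    if targets_per_tf < 5:
        raise ValueError("targets_per_tf must be at least 5")
    if n_mrs > n_tfs:
        raise ValueError("n_mrs cannot exceed n_tfs")
    ids = gene_universe(n_genes, n_tfs)
    tf_ids = ids[1 : n_tfs + 1]
    pool = np.array(ids[n_tfs + 1 : len(ids) - RESERVED_TAIL])
    rng = np.random.default_rng(seed)
    regulons: dict[str, Regulon] = {}
    mr_head = set(tf_ids[: min(2, n_mrs)])
    for tf in tf_ids:
        genes = rng.choice(pool, size=targets_per_tf, replace=False)
        modes = np.where(rng.random(targets_per_tf) < activator_fraction, 1, -1)
        # the dominant MR pair gets high-confidence targets: strong MRs have
        # tight programs, and their coupling is later diluted by the
        # cross-modulation gate, so the floor is raised to keep the planted
        # regulons recoverable
        lik_lo = 0.75 if tf in mr_head else 0.5
        liks = rng.uniform(lik_lo, 1.0, targets_per_tf)
        regulons[tf] = Regulon(
            tf=tf,
            targets={
                g: (int(m), float(lk)) for g, m, lk in zip(genes, modes, liks)
            },
        )
    mr_ids = tf_ids[:n_mrs]
    if mr_effects is None:
        mr_effects = default_mr_effects(n_mrs)
    effects = {mr: float(e) for mr, e in zip(mr_ids, mr_effects)}
    return PlantedNetwork(tf_ids=tf_ids, regulons=regulons, mr_ids=mr_ids, effects=effects)


def default_mr_effects(n_mrs: int) -> list[float]:
    """Default MR activity-shift profile: a clearly dominant cross-modulating
    pair (1.8, 1.5) followed by a graded tail (0.5 down to 0.3).

    The head is larger than the tail by design for two reasons: the coupling
    of the two modulated MRs to their targets is diluted by the
    cross-modulation gate (mean coupling (1 + low)/2), and the rank-based NES
    saturates for large target shifts, so the tail must stay in the linear
    response regime for the activity ranking to separate the pair from it.
    """
    if n_mrs == 1:
        return [1.2]
    if n_mrs == 2:
        return [1.8, 1.5]
    return [1.8, 1.5] + list(np.linspace(0.5, 0.3, n_mrs - 2))


def _default_cells() -> dict[tuple[str, str], int]:
    return {
        ("shAPC", "d3"): 750,
        ("shAPC", "d7"): 750,
        ("shScr", "d3"): 750,
        ("shScr", "d7"): 750,
    }


def _default_batch_shift() -> dict[str, float]:
    return {"d3": 0.0, "d7": 0.1}


@dataclass
class SimDesign:
    """Study design and noise model for :func:`simulate_cells`.

    The defaults are the conditions the analysis is validated under:
    two shRNA conditions x two time points (750 cells each, ~3,000 total),
    an SG fraction of 1/7 among shAPC cells (SG:FG about 1:6), a 50% APC
    knockdown, negative-binomial counts with shared dispersion, and mild
    multiplicative batch effects. Effect sizes are log-scale shifts applied to
    the corresponding signature blocks in SG cells; ``sigma_activity`` is the
    sd of the per-cell latent TF activities that make TF-target co-expression
    observable.
    """

    n_cells: dict[tuple[str, str], int] = field(default_factory=_default_cells)
    sg_fraction: float = 1.0 / 7.0
    apc_knockdown_factor: float = 0.5
    sg_apc_factor: float = 0.8
    # APC is modeled as a well-expressed, low-variance gene so that its
    # per-cell level is informative for the low/high-APC rule
    apc_sigma: float = 0.3
    apc_base_mean: float = 30.0
    dropout: float = 0.05
    nb_dispersion: float = 10.0
    batch_shift: dict[str, float] = field(default_factory=_default_batch_shift)
    batch_gene_sd: float = 0.1
    seed: int = 0
    n_genes: int = 2000
    # log-scale effect sizes of the SG / condition / phase programs
    arrest_effect: float = 1.2
    apoptosis_effect: float = 0.8
    stem_effect: float = 1.0
    phase_effect: float = 1.0
    response_effect: float = 0.8
    sigma_activity: float = 1.25
    phase_probs: tuple[float, float, float] = (0.55, 0.20, 0.25)  # G1, S, G2M
    modulation_low_coupling: float = 0.35
    # fraction of a modulated TF's targets whose coupling is gated by the
    # partner (1.0 = the whole program is conditioned)
    modulated_fraction: float = 1.0
    cross_modulation: list[tuple[str, str]] = field(default_factory=list)
    # baseline expression (log-normal). Network genes (TFs and their
    # targets) and signature-block genes live in separate mean ranges so the
    # expression-matched control pools of the module scores are not dominated
    # by TF targets, whose latent fluctuations would otherwise leak into
    # every gene-set score as structured noise.
    background_mean: float = 0.5
    background_sdlog: float = 1.0
    program_mean: float = 15.0
    program_sdlog: float = 0.3
    signature_mean: float = 3.0
    signature_sdlog: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.sg_fraction < 1.0):
            raise ValueError("sg_fraction must lie in (0, 1)")
        if not (0.0 < self.apc_knockdown_factor <= 1.0):
            raise ValueError("apc_knockdown_factor must lie in (0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if any(n <= 0 for n in self.n_cells.values()):
            raise ValueError("cell counts must be positive")
        if abs(sum(self.phase_probs) - 1.0) > 1e-9:
            raise ValueError("phase_probs must sum to 1")


def default_cross_modulation(network: PlantedNetwork) -> list[tuple[str, str]]:
    """Mutual modulation between the two strongest planted MRs."""
    if len(network.mr_ids) < 2:
        return []
    a, b = network.mr_ids[0], network.mr_ids[1]
    return [(a, b), (b, a)]


def simulate_cells(
    network: PlantedNetwork, design: SimDesign
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate counts under the planted design.

    Draw order (fixed so determinism survives refactors): (1) baseline gene
    means and stemness weights, (2) per-batch per-gene loadings, (3) cell
    table with subpopulation and phase labels, (4) latent TF activities,
    (5) negative-binomial counts, (6) dropout mask.

    Returns the AnnData (cells x genes, integer counts in ``layers['counts']``)
    and the per-cell ground-truth table. Signature gene sets, stemness weights,
    the synthetic interaction graph, and the planted network are carried in
    ``adata.uns``.
    """
    rng = np.random.default_rng(design.seed)
    n_tfs = len(network.tf_ids)
    ids = gene_universe(design.n_genes, n_tfs)
    if list(network.tf_ids) != ids[1 : n_tfs + 1]:
        raise ValueError("network TF ids do not match the gene universe layout")
    blocks = signature_blocks(ids)
    for name, members in blocks.items():
        if not members:
            raise ValueError(f"empty gene set {name!r} in design")
    gene_pos = {g: i for i, g in enumerate(ids)}
    n_genes = len(ids)

    # --- (1) baseline means -------------------------------------------------
    network_genes = set([APC] + network.tf_ids)
    for reg in network.regulons.values():
        network_genes.update(reg.target_genes)
    # the knockdown-response program is not a module-score input, so it can
    # live in the well-expressed range where it separates the conditions
    network_genes.update(blocks["response"])
    signature_genes = {
        g
        for name, members in blocks.items()
        if name != "response"
        for g in members
    }
    is_network = np.array([g in network_genes for g in ids])
    is_signature = np.array([g in signature_genes for g in ids]) & ~is_network
    base = rng.lognormal(
        np.log(design.background_mean), design.background_sdlog, n_genes
    )
    base = np.where(
        is_network,
        rng.lognormal(np.log(design.program_mean), design.program_sdlog, n_genes),
        base,
    )
    base = np.where(
        is_signature,
        rng.lognormal(np.log(design.signature_mean), design.signature_sdlog, n_genes),
        base,
    )
    base[0] = design.apc_base_mean  # index 0 is always APC
    log_base = np.log(base)
    stem_w = pd.Series(
        rng.uniform(0.3, 1.0, len(blocks["stemness"])), index=blocks["stemness"]
    )
    # gene-specific response to APC knockdown, shared by all shAPC cells;
    # modeled as induced genes only (up-shifts), which keeps the response
    # program's pooled averages above the signature-gene expression range:
    # down-shifted well-expressed genes would drift into the signature bins
    # and contaminate the module scores' expression-matched control pools
    # with condition-dependent genes. The jitter scales with the effect so a
    # zero effect is a true null.
    n_resp = len(blocks["response"])
    resp_shift = np.abs(
        rng.normal(design.response_effect, 0.25 * design.response_effect, n_resp)
    )

    # --- (2) batch loadings -------------------------------------------------
    batches = sorted({b for _, b in design.n_cells})
    batch_load = {
        b: design.batch_shift.get(b, 0.0)
        + rng.normal(0.0, design.batch_gene_sd, n_genes)
        for b in batches
    }

    # --- (3) cell table -----------------------------------------------------
    rows = []
    for (cond, batch), n in sorted(design.n_cells.items()):
        for i in range(n):
            rows.append((f"{cond}_{batch}_{i:05d}", cond, batch))
    cells = pd.DataFrame(rows, columns=["cell_id", "condition", "batch"])
    n_cells = len(cells)
    is_shapc = (cells["condition"] == "shAPC").values
    subpop = np.where(is_shapc, "FG", "control").astype(object)
    sg_draw = rng.random(n_cells) < design.sg_fraction
    subpop[is_shapc & sg_draw] = "SG"
    cells["subpop"] = subpop
    is_sg = subpop == "SG"
    phases = np.array(["G1", "S", "G2M"])
    cells["phase"] = phases[
        rng.choice(3, size=n_cells, p=np.asarray(design.phase_probs))
    ]

    # --- (4) latent TF activities ------------------------------------------
    # ``noise`` keeps each regulator's intrinsic fluctuation around its
    # state-dependent mean; the cross-modulation gate conditions on it so the
    # planted modulation does not cancel the modulated MR's subpopulation
    # shift (a gate on total activity would: the partner MR is itself down in
    # SG, which would switch the coupling off exactly where the shift acts).
    activity: dict[str, np.ndarray] = {}
    noise: dict[str, np.ndarray] = {}
    regulators = list(network.regulons)
    for tf in regulators:
        sigma = design.apc_sigma if tf == APC else design.sigma_activity
        eps = rng.normal(0.0, sigma, n_cells)
        noise[tf] = eps
        a = eps.copy()
        if tf in network.effects:
            a = a - network.effects[tf] * is_sg
        if tf == APC:
            a = a + np.log(design.apc_knockdown_factor) * is_shapc
            a = a + np.log(design.sg_apc_factor) * is_sg
        activity[tf] = a
    if APC not in activity:
        eps = rng.normal(0.0, design.apc_sigma, n_cells)
        noise[APC] = eps
        a = eps + np.log(design.apc_knockdown_factor) * is_shapc
        a = a + np.log(design.sg_apc_factor) * is_sg
        activity[APC] = a

    # assemble per-cell log-means
    logmu = np.tile(log_base, (n_cells, 1))
    for b in batches:
        logmu[(cells["batch"] == b).values] += batch_load[b]

    def _add(genes, shift):
        idx = [gene_pos[g] for g in genes]
        logmu[np.ix_(np.flatnonzero(is_sg), idx)] += np.atleast_1d(shift)

    _add(blocks["arrest"], design.arrest_effect)
    _add(blocks["apoptosis"], design.apoptosis_effect)
    _add(blocks["stemness"], -design.stem_effect * stem_w.values)
    resp_idx = [gene_pos[g] for g in blocks["response"]]
    logmu[np.ix_(np.flatnonzero(is_shapc), resp_idx)] += resp_shift
    for ph, block in (("S", "s_phase"), ("G2M", "g2m_phase")):
        sel = (cells["phase"] == ph).values
        idx = [gene_pos[g] for g in blocks[block]]
        logmu[np.ix_(np.flatnonzero(sel), idx)] += design.phase_effect

    # TF own expression follows its latent activity
    for tf, a in activity.items():
        logmu[:, gene_pos[tf]] += a
    # targets follow mode x likelihood x activity, scaled by the modulation
    # coupling when a cross-modulating partner is planted
    modulators: dict[str, list[str]] = {}
    for modulator, tf in design.cross_modulation:
        modulators.setdefault(tf, []).append(modulator)
    for tf, reg in network.regulons.items():
        a = activity[tf]
        coupling = np.ones(n_cells)
        for modulator in modulators.get(tf, []):
            hi = noise[modulator] > 0
            coupling = coupling * np.where(hi, 1.0, design.modulation_low_coupling)
        genes = reg.target_genes
        idx = [gene_pos[g] for g in genes]
        w = reg.modes(genes) * reg.likelihoods(genes)
        # only the first `modulated_fraction` of targets (in regulon order)
        # are gated by the modulators; the rest couple plainly
        n_mod = int(np.ceil(design.modulated_fraction * len(genes)))
        gated = np.zeros(len(genes), dtype=bool)
        gated[:n_mod] = True
        input_mat = np.where(
            gated[None, :], (a * coupling)[:, None], a[:, None]
        )
        logmu[:, idx] += input_mat * w[None, :]

    # --- (5) counts ---------------------------------------------------------
    mu = np.exp(logmu)
    theta = design.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)

    # --- (6) dropout --------------------------------------------------------
    if design.dropout > 0:
        counts[rng.random(counts.shape) < design.dropout] = 0

    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=cells.set_index("cell_id")[["condition", "batch"]].copy(),
        var=pd.DataFrame(index=pd.Index(ids, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.var["is_tf"] = [g in set(network.tf_ids) for g in ids]
    truth = cells.set_index("cell_id")[["condition", "batch", "subpop", "phase"]]
    adata.uns["signatures"] = {k: list(v) for k, v in blocks.items()}
    adata.uns["stem_weights"] = {g: float(w) for g, w in stem_w.items()}
    adata.uns["planted"] = {
        "tf_ids": list(network.tf_ids),
        "mr_ids": list(network.mr_ids),
        "effects": dict(network.effects),
        "cross_modulation": [list(p) for p in design.cross_modulation],
    }
    adata.uns["interaction_edges"] = build_interaction_graph(
        network, seed=design.seed
    )
    return adata, truth


def build_interaction_graph(
    network: PlantedNetwork, seed: int = 0, n_random_edges: int = 100
) -> list[list[str]]:
    """Synthetic stand-in for a STRING-like interaction graph.

    Plants the canonical Wnt spine (APC -- CTNNB1 -- WNT3A) and, for every TF,
    edges to its regulon targets plus one target wired to CTNNB1, so each TF
    reaches APC through a shortest path of three hops (TF - target - CTNNB1 -
    APC), mirroring the evidence pattern used to screen candidates. Random
    target-target edges add clutter without shortening the planted paths.
    """
    rng = np.random.default_rng(seed + 977)
    edges: list[list[str]] = [
        [APC, ANCHOR_ALIASES["CTNNB1"]],
        [ANCHOR_ALIASES["CTNNB1"], ANCHOR_ALIASES["WNT"]],
    ]
    all_targets: list[str] = []
    for tf in network.tf_ids:
        reg = network.regulons[tf]
        genes = reg.target_genes
        all_targets.extend(genes)
        for g in genes:
            edges.append([tf, g])
        bridge = genes[int(rng.integers(len(genes)))]
        edges.append([bridge, ANCHOR_ALIASES["CTNNB1"]])
    if APC in network.regulons:
        for g in network.regulons[APC].target_genes:
            edges.append([APC, g])
    pool = sorted(set(all_targets))
    for _ in range(n_random_edges):
        a, b = rng.choice(pool, 2, replace=False)
        edges.append([str(a), str(b)])
    seen = set()
    out = []
    for a, b in edges:
        key = (a, b) if a <= b else (b, a)
        if a != b and key not in seen:
            seen.add(key)
            out.append([a, b])
    return out


def attach_apc_regulon(
    network: PlantedNetwork,
    seed: int,
    targets_per_tf: int = 20,
    n_genes: int = 2000,
    activator_fraction: float = 0.7,
    overlap_fraction: float = 0.5,
) -> PlantedNetwork:
    """Give APC its own planted regulon.

    A fraction of APC's targets is shared with the dominant MR's regulon
    (mirroring the observation that the top candidate is among the densest
    APC-regulon sharers); the rest comes from genes not already targeted.
    """
    rng = np.random.default_rng(seed + 131)
    ids = gene_universe(n_genes, len(network.tf_ids))
    taken = set()
    for reg in network.regulons.values():
        taken.update(reg.target_genes)
    pool = np.array(
        [g for g in ids[len(network.tf_ids) + 1 : len(ids) - RESERVED_TAIL] if g not in taken]
    )
    n_shared = int(round(overlap_fraction * targets_per_tf)) if network.mr_ids else 0
    shared = []
    if n_shared:
        mr_targets = np.array(network.regulons[network.mr_ids[0]].target_genes)
        n_shared = min(n_shared, len(mr_targets))
        shared = list(rng.choice(mr_targets, size=n_shared, replace=False))
    fresh = list(rng.choice(pool, size=targets_per_tf - len(shared), replace=False))
    genes = shared + fresh
    modes = np.where(rng.random(targets_per_tf) < activator_fraction, 1, -1)
    liks = rng.uniform(0.5, 1.0, targets_per_tf)
    regulons = dict(network.regulons)
    regulons[APC] = Regulon(
        tf=APC,
        targets={g: (int(m), float(lk)) for g, m, lk in zip(genes, modes, liks)},
    )
    return PlantedNetwork(
        tf_ids=list(network.tf_ids),
        regulons=regulons,
        mr_ids=list(network.mr_ids),
        effects=dict(network.effects),
    )


def make_study(
    seed: int,
    design: SimDesign | None = None,
    n_tfs: int = 20,
    targets_per_tf: int = 20,
    n_mrs: int = 10,
) -> tuple[PlantedNetwork, SimDesign, ad.AnnData, pd.DataFrame]:
    """Convenience bundle: planted network + APC regulon + default design.

    Cross-modulation is planted between the two strongest MRs unless the
    design already specifies pairs.
    """
    if design is None:
        design = SimDesign(seed=seed)
    else:
        design.seed = seed
    network = generate_grn(
        n_tfs, targets_per_tf, n_mrs, seed, n_genes=design.n_genes
    )
    network = attach_apc_regulon(
        network, seed, targets_per_tf=targets_per_tf, n_genes=design.n_genes
    )
    if not design.cross_modulation:
        design.cross_modulation = default_cross_modulation(network)
    adata, truth = simulate_cells(network, design)
    return network, design, adata, truth


def export_fixture(adata: ad.AnnData, truth: pd.DataFrame, path) -> None:
    """Write the simulated study as plain-text files.

    Produces the 10x MTX triple, the truth table, the signature GMT, the
    stemness weights, the TF list, and the interaction graph, so every
    pipeline stage can also be exercised from files.
    """
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_10x_dir(adata, path)
    truth.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        path / "truth.tsv", sep="\t", index=False
    )
    if "signatures" in adata.uns:
        write_gmt(adata.uns["signatures"], path / "gene_sets.gmt")
    if "stem_weights" in adata.uns:
        write_weights(pd.Series(adata.uns["stem_weights"]), path / "stem_weights.tsv")
    if "planted" in adata.uns:
        pd.Series(adata.uns["planted"]["tf_ids"]).to_csv(
            path / "tf_list.tsv", sep="\t", header=False, index=False
        )
    if "interaction_edges" in adata.uns:
        write_edge_list(
            [tuple(e) for e in adata.uns["interaction_edges"]], path / "graph.tsv"
        )


def export_network(network: PlantedNetwork, path) -> None:
    """Write the planted regulons as the external-network TSV stand-in."""
    from .regulons import regulons_to_frame

    regulons_to_frame(network.regulons).to_csv(path, sep="\t", index=False)
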
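"""End-to-end orchestration: simulate (or load) inputs, normalize tracks,
profile genes and enhancers, cluster, and run the functional, TFBS and
network analyses, writing every output with a content hash so reruns are
verifiably deterministic."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, enhancers, enrichment, functional, io as eio
from . import network, profiles, synthetic_data, tfbs
from .enrichment import CONDITIONS
from .synthetic_data import CONTROL_MARK, PROMOTER_MARK, SimConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage parameter in one validated place.

    The defaults are the analysis constants: 200-bp bins, 600-bp island
    merge gap, island FDR 0.01, 95th-percentile column scaling, KDE
    bandwidth 0.025, enhancer alpha 0.05, FSS gate q < 0.01, PPI confidence
    cutoff 400, Louvain resolution 1.66 and PageRank damping 0.85.
    """

    out_dir: str = "epicoord_out"
    seed: int = 0
    bin_width: int = 200
    island_gap: int = 600
    island_fdr: float = 0.01
    scaling_pct: float = 95.0
    kde_bandwidth: float = 0.025
    enhancer_alpha: float = 0.05
    fss_q: float = 0.01
    ppi_cutoff: int = 400
    resolution: float = 1.66
    damping: float = 0.85
    down_seed_log2fc: float = -2.0
    cluster_engine: str = "som"
    sim: SimConfig | None = None

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a plain mapping, rejecting unknown keys; the global
        seed propagates into the simulator unless the ``sim`` section sets
        its own."""
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        known = {f.name for f in fields(cls)} - {"sim"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_unknown = set(sim) - {f.name for f in fields(SimConfig)}
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        if "seed" in d and "seed" not in sim:
            sim["seed"] = d["seed"]
        return cls(**d, sim=SimConfig(**sim))


def validate_config(config: PipelineConfig) -> list[str]:
    """Range and consistency checks; returns problems (empty = valid)."""
    problems = []
    pos = ["bin_width", "island_gap", "kde_bandwidth", "resolution"]
    for name in pos:
        if getattr(config, name) <= 0:
            problems.append(f"{name} must be positive")
    for name, lo, hi in [("island_fdr", 0, 1), ("enhancer_alpha", 0, 1),
                         ("fss_q", 0, 1), ("damping", 0, 1),
                         ("scaling_pct", 0, 100)]:
        v = getattr(config, name)
        if not (lo < v < hi):
            problems.append(f"{name} must be in ({lo}, {hi})")
    if config.ppi_cutoff < 0:
        problems.append("ppi_cutoff must be nonnegative")
    if config.cluster_engine not in ("som", "kmedoids", "file"):
        problems.append(f"unknown cluster engine {config.cluster_engine!r}")
    try:
        missing = set(config.sim.enhancer_marks) - set(config.sim.marks)
        if missing:
            problems.append(
                f"enhancer marks without a track: {sorted(missing)}")
    except Exception as exc:  # invalid sim config
        problems.append(str(exc))
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def enhancer_layouts(loci):
    return [profiles.SegmentLayout(
        locus_id=l.locus_id, chrom=l.chrom,
        segments={"ENH": l.bin_range}) for l in loci]


def compute_sde_tracks(tracks, marks):
    """Pair-normalize every mark and return its SDE track plus size factors."""
    sde, factors = {}, {}
    for m in marks:
        _, _, sde_m, pair = enrichment.normalize_pair(
            tracks[(m, "epithelial")], tracks[(m, "mesenchymal")])
        sde[m] = sde_m
        factors[m] = pair
    return sde, factors


def discover_putative_enhancers(tracks, chrom_sizes, island_gap: int = 600,
                                island_fdr: float = 0.01):
    """Island calling, anchoring, promoter filtering and collapsing.

    Returns the 2,200-bp putative loci from H3K4me1/H3K27ac islands in both
    conditions, cleaned of anchors overlapping H3K4me3 islands.
    """
    anchors = {m: [] for m in enhancers.CORE_ENHANCER_MARKS}
    k4me3_islands = []
    for cond in CONDITIONS:
        ctrl = tracks[(CONTROL_MARK, cond)]
        for m in enhancers.CORE_ENHANCER_MARKS:
            isl = enhancers.call_islands(tracks[(m, cond)], ctrl,
                                         gap=island_gap, fdr=island_fdr)
            anchors[m] += [enhancers.select_anchor(i, tracks[(m, cond)])
                           for i in isl]
        k4me3_islands += enhancers.call_islands(
            tracks[(PROMOTER_MARK, cond)], ctrl,
            gap=island_gap, fdr=island_fdr)
    for m in anchors:
        seen, dedup = set(), []
        for a in anchors[m]:
            if (a.chrom, a.bin) not in seen:
                seen.add((a.chrom, a.bin))
                dedup.append(a)
        anchors[m] = enhancers.filter_h3k4me3(dedup, k4me3_islands)
    return enhancers.collapse_anchors(anchors["H3K4me1"], anchors["H3K27ac"],
                                      chrom_sizes=chrom_sizes)


def filter_enhancers(loci, sde, scaling_pct: float = 95.0,
                     kde_bandwidth: float = 0.025, alpha: float = 0.05,
                     enh_marks=None):
    """Enhancer DEP matrix, extreme-value null fit and differential filter.

    Returns (differential loci, scaled enhancer DEP matrix, null model).
    """
    enh_marks = enh_marks or enhancers.identify_enhancer_marks(loci, sde)
    raw = profiles.build_dep_matrix(enhancer_layouts(loci), sde, enh_marks)
    enh_dep = profiles.scale_columns(raw, pct=scaling_pct)
    mags = enhancers.compute_max_magnitudes(enh_dep)
    for loc in loci:
        loc.max_magnitude = float(mags.loc[loc.locus_id])
    null = enhancers.fit_extreme_null(mags, bandwidth=kde_bandwidth)
    diff = enhancers.filter_differential(loci, null, alpha=alpha)
    return diff, enh_dep, null


def run_pipeline(config: PipelineConfig, simulate: bool = True) -> dict:
    """Run all stages in dependency order; returns the output manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = eio.ensure_dir(config.out_dir)
    t0 = time.time()
    manifest: dict = {"config": {**asdict(config)}, "stages": {}, "files": {}}

    def record(stage, name, path):
        manifest["files"][name] = _sha256(Path(path))
        manifest["stages"].setdefault(stage, []).append(str(name))

    # ---- stage: simulate -------------------------------------------------
    if not simulate:
        raise NotImplementedError(
            "external-input runs use the stage functions directly; the "
            "orchestrated pipeline runs from simulated inputs")
    sim_dir = eio.ensure_dir(out / "inputs")
    sim = synthetic_data.write_all(config.sim, sim_dir)
    for f in sorted(sim_dir.iterdir()):
        record("simulate", f"inputs/{f.name}", f)
    genes, chrom_sizes = sim["genes"], sim["chrom_sizes"]
    tracks, truth = sim["tracks"], sim["manifest"]
    logger.info("simulate: %d genes, %d planted enhancers",
                len(genes), len(truth.enhancers))

    # ---- stage: enrich ---------------------------------------------------
    marks = list(config.sim.marks)
    sde, factors = compute_sde_tracks(tracks, marks)
    pd.DataFrame(
        [(m, p.factor_E, p.factor_M) for m, p in factors.items()],
        columns=["mark", "factor_E", "factor_M"],
    ).to_csv(out / "scale_factors.tsv", sep="\t", index=False)
    record("enrich", "scale_factors.tsv", out / "scale_factors.tsv")

    # ---- stage: profiles ---------------------------------------------------
    layouts = profiles.segment_genes(genes, chrom_sizes)
    gene_dep_raw = profiles.build_dep_matrix(layouts, sde, marks)
    gene_dep = profiles.scale_columns(gene_dep_raw, pct=config.scaling_pct)
    profiles.write_dep_matrix(gene_dep, out / "gene_dep.tsv",
                              out / "gene_dep_u.json")
    record("profiles", "gene_dep.tsv", out / "gene_dep.tsv")
    record("profiles", "gene_dep_u.json", out / "gene_dep_u.json")

    # ---- stage: enhancers --------------------------------------------------
    loci = discover_putative_enhancers(tracks, chrom_sizes,
                                       island_gap=config.island_gap,
                                       island_fdr=config.island_fdr)
    logger.info("enhancers: %d putative loci", len(loci))
    enh_marks = enhancers.identify_enhancer_marks(loci, sde)
    diff_loci, enh_dep, null = filter_enhancers(
        loci, sde, scaling_pct=config.scaling_pct,
        kde_bandwidth=config.kde_bandwidth, alpha=config.enhancer_alpha,
        enh_marks=enh_marks)
    diff_loci = enhancers.assign_to_genes(diff_loci, genes)
    eio.write_bed(enhancers.loci_to_bed(diff_loci), out / "enhancers.bed")
    record("enhancers", "enhancers.bed", out / "enhancers.bed")
    pd.DataFrame(
        [(l.locus_id, g) for l in diff_loci for g in l.genes],
        columns=["locus_id", "gene_id"],
    ).to_csv(out / "enhancer_genes.tsv", sep="\t", index=False)
    record("enhancers", "enhancer_genes.tsv", out / "enhancer_genes.tsv")
    logger.info("enhancers: %d differential (null mu=%.3f sigma=%.3f)",
                len(diff_loci), null.mu_hat, null.sigma_hat)

    # ---- stage: cluster ------------------------------------------------------
    gene_assign = clustering.cluster_profiles(
        gene_dep, engine=config.cluster_engine, seed=config.seed)
    diff_dep = profiles.DEPMatrix(
        values=enh_dep.values.loc[[l.locus_id for l in diff_loci]],
        scaled=True, u=enh_dep.u)
    enh_assign = clustering.cluster_profiles(
        diff_dep, engine=config.cluster_engine, seed=config.seed + 17)
    gene_assign.labels.rename("cluster").to_csv(out / "gene_clusters.tsv", sep="\t")
    enh_assign.labels.rename("cluster").to_csv(out / "enhancer_clusters.tsv", sep="\t")
    record("cluster", "gene_clusters.tsv", out / "gene_clusters.tsv")
    record("cluster", "enhancer_clusters.tsv", out / "enhancer_clusters.tsv")
    scores = clustering.score_clusters(enh_assign, diff_dep, enh_marks)
    gene_log2fc = clustering.probe_to_gene(sim["probes"])
    try:
        r = clustering.correlate_score_expression(
            scores, enh_assign, diff_loci, gene_log2fc)
    except ValueError as exc:
        logger.warning("score/expression correlation unavailable: %s", exc)
        r = np.nan
    pd.DataFrame(
        [(s.cluster, s.n_members, s.gain_loss, s.direction, s.mean_log2fc)
         for s in scores],
        columns=["cluster", "n", "gain_loss", "direction", "mean_log2fc"],
    ).to_csv(out / "enhancer_cluster_scores.tsv", sep="\t", index=False)
    record("cluster", "enhancer_cluster_scores.tsv",
           out / "enhancer_cluster_scores.tsv")
    logger.info("cluster: %d gene / %d enhancer clusters, score-expression r=%.3f",
                gene_assign.n_clusters, enh_assign.n_clusters, r)

    # ---- stage: functional ---------------------------------------------------
    background = genes["gene_id"].tolist()
    enrich_by_cluster = {
        c: functional.enrich_terms(gene_assign.members(c), background,
                                   sim["terms"])
        for c in sorted(gene_assign.labels.unique())}
    pd.concat([df.assign(cluster=c) for c, df in enrich_by_cluster.items()],
              ignore_index=True).to_csv(out / "term_enrichment.tsv",
                                        sep="\t", index=False)
    record("functional", "term_enrichment.tsv", out / "term_enrichment.tsv")
    fcm_matrix = fcm_order = None
    if len(enrich_by_cluster) >= 2:
        fcm_matrix, fcm_order = functional.fcm(enrich_by_cluster,
                                               q_threshold=config.fss_q)
        fcm_matrix.to_csv(out / "fcm.tsv", sep="\t")
        (out / "fcm_row_order.json").write_text(
            json.dumps([int(i) for i in fcm_order]))
        record("functional", "fcm.tsv", out / "fcm.tsv")
        record("functional", "fcm_row_order.json", out / "fcm_row_order.json")

    # ---- stage: tfbs -----------------------------------------------------------
    loci_df = pd.DataFrame({
        "locus_id": [l.locus_id for l in diff_loci],
        "chrom": [l.chrom for l in diff_loci],
        "start": [l.start for l in diff_loci],
        "end": [l.end for l in diff_loci]})
    tf_enrich = tfbs.tf_enrichment(loci_df, enh_assign.labels, sim["tfbs"])
    tf_enrich.to_csv(out / "tf_enrichment.tsv", sep="\t", index=False)
    record("tfbs", "tf_enrichment.tsv", out / "tf_enrichment.tsv")
    heat = tfbs.heatmap_matrix(tf_enrich, scores)
    heat.to_csv(out / "tf_heatmap.tsv", sep="\t")
    record("tfbs", "tf_heatmap.tsv", out / "tf_heatmap.tsv")

    # ---- stage: network ---------------------------------------------------------
    graph = network.load_interactions(sim["ppi"], cutoff=config.ppi_cutoff)
    seed_genes = network.seed_from_expression(
        gene_log2fc, threshold=config.down_seed_log2fc)
    summary_net = {}
    if seed_genes and any(graph.has_node(s) for s in seed_genes):
        sub = network.expand_seed(graph, seed_genes)
        hubs = network.pagerank_hubs(sub, damping=config.damping)
        modules = network.detect_modules(sub, resolution=config.resolution,
                                         seed=config.seed)
        network.write_graphml(sub, out / "network.graphml")
        network.hub_table(sub, modules, gene_assign.labels).to_csv(
            out / "hubs.tsv", sep="\t", index=False)
        record("network", "network.graphml", out / "network.graphml")
        record("network", "hubs.tsv", out / "hubs.tsv")
        summary_net = {"nodes": sub.number_of_nodes(),
                       "edges": sub.number_of_edges(),
                       "modules": len(set(modules.values())),
                       "top_hub": hubs.iloc[0]["gene"] if len(hubs) else None}
    else:
        logger.warning("network stage skipped: empty effective seed")

    manifest["summary"] = {
        "n_genes": int(len(genes)),
        "n_putative_enhancers": int(len(loci)),
        "n_differential_enhancers": int(len(diff_loci)),
        "n_gene_clusters": gene_assign.n_clusters,
        "n_enhancer_clusters": enh_assign.n_clusters,
        "score_expression_r": None if np.isnan(r) else float(r),
        "null_mu": null.mu_hat, "null_sigma": null.sigma_hat,
        "network": summary_net,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
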
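"""Synthetic two-condition ChIP-seq study generator.

Emulates the statistical structure the analysis assumes: 200-bp binned
negative-binomial tag counts for an 18-mark histone panel (plus a pan-H3
control) in an epithelial and a mesenchymal condition, with planted
segment-specific gain/loss archetypes at gene loci, planted triangular
enhancer peaks of the enhancer-associated marks, promoter-restricted
H3K4me3, cluster-concordant expression effects, term sets enriched in the
planted clusters, transcription-factor sites co-located with activated or
repressed enhancers, and a protein-interaction graph with planted dense
modules. A truth manifest records every planted entity for recovery tests.

Every artifact draws from its own RNG stream seeded as ``seed + stream
index`` so each file can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import BIN_WIDTH, BinnedTrack
from . import io as eio

# Panel: the 17 profiled marks plus H4K12ac to complete an 18-mark panel;
# the enhancer-associated and promoter marks come first so truncated panels
# keep the marks the enhancer analysis needs.
DEFAULT_MARKS = (
    "H3K4me1", "H3K27ac", "H3K4me2", "H3K9ac", "H4K8ac", "H3R17me2asym",
    "H3K4me3", "H2A.Z", "H3K27me2", "H3K27me3", "H3K14ac", "H3K36me3",
    "H3K79me3", "H3K9me1", "H3K9me3", "H4R3me2asym", "H4K20me1", "H4K12ac",
)
CONTROL_MARK = "panH3"
PROMOTER_MARK = "H3K4me3"
DEFAULT_ENHANCER_MARKS = (
    "H3K4me1", "H3K4me2", "H3K27ac", "H3K9ac", "H4K8ac", "H3R17me2asym",
)

CONDITIONS = ("epithelial", "mesenchymal")

# genomic layout constants (bp)
_SLOT_MIN = 40_000          # minimum per-gene slot
_GENE_OFFSET = (20_000, 36_000)   # gene left edge within its slot
_GENE_LENGTH = (2_000, 10_000)
_ENH_OFFSET = 12_000        # differential-enhancer anchor upstream of the gene
_ENH_NULL_OFFSET = 20_000   # second, farther intergenic site for null enhancers

# triangular enhancer peak: apex at the anchor bin, support +/- 5 bins
_PEAK_WEIGHTS = 1.0 - np.abs(np.arange(-5, 6)) / 6.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 50_000_000
    n_genes: int = 2000
    n_marks: int = 18
    enhancer_marks: tuple = DEFAULT_ENHANCER_MARKS
    n_enhancers: int = 300
    n_gene_clusters: int = 4
    effect_size: float = 25.0
    dispersion: float = 0.05
    locus_noise_sd: float = 0.0
    background_rate: float = 10.0
    frac_null: float = 0.6
    library_factor: float = 1.3
    probes_per_gene: int = 3
    probe_noise_sd: float = 0.25
    expression_effect: float = 3.0
    n_terms: int = 24
    term_size: int = 25
    term_preference: float = 0.9
    tf_inside_prob: float = 0.9
    n_background_tfs: int = 3
    n_tf_background_sites: int = 60
    n_ppi_modules: int = 3
    ppi_module_size: int = 20
    ppi_p_in: float = 0.6
    n_ppi_background_edges: int = 250

    def __post_init__(self):
        if self.chrom_length % BIN_WIDTH:
            raise ValueError("chrom_length must be a multiple of 200")
        for name in ("n_chroms", "chrom_length", "n_marks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_enhancers", "n_gene_clusters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0 <= self.frac_null <= 1:
            raise ValueError("frac_null must be in [0, 1]")
        if self.n_marks > len(DEFAULT_MARKS):
            raise ValueError(f"at most {len(DEFAULT_MARKS)} marks available")
        unknown = set(self.enhancer_marks) - set(self.marks)
        if unknown:
            raise ValueError(f"enhancer marks not in the panel: {unknown}")

    @property
    def marks(self) -> tuple:
        return DEFAULT_MARKS[: self.n_marks]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class TruthManifest:
    """Ground truth of every planted entity."""

    gene_clusters: dict = field(default_factory=dict)   # gene -> cluster (0 = null)
    cluster_directions: dict = field(default_factory=dict)  # cluster -> +1/-1
    gene_log2fc: dict = field(default_factory=dict)
    enhancers: list = field(default_factory=list)       # dicts, see plant_enhancers
    term_clusters: dict = field(default_factory=dict)   # term -> cluster
    tf_directions: dict = field(default_factory=dict)   # factor -> 'gain'/'loss'
    ppi_modules: dict = field(default_factory=dict)     # gene -> module id

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class GeneArchetype:
    cluster: int
    sign: int                  # +1 mesenchymal gain, -1 loss
    segments: tuple
    marks: tuple
    log2fc: float


def gene_archetypes(config: SimConfig) -> list[GeneArchetype]:
    """Planted per-cluster profile archetypes with disjoint mark blocks.

    Even-indexed clusters gain three marks in the mesenchymal condition,
    odd ones lose them; mark blocks rotate through the non-enhancer part of
    the panel (so gene-body effects never masquerade as enhancer islands)
    and segment support alternates between promoter-proximal and gene-body.
    """
    pool = [m for m in config.marks if m not in config.enhancer_marks]
    if not pool:
        pool = list(config.marks)
    seg_options = (("PR", "TSS", "GS"), ("WG",), ("PR", "TSS"), ("GS", "WG"))
    archs = []
    for j in range(config.n_gene_clusters):
        sign = 1 if j % 2 == 0 else -1
        segs = seg_options[(j // 2) % len(seg_options)]
        marks = tuple(pool[(3 * j + k) % len(pool)] for k in range(3))
        archs.append(GeneArchetype(cluster=j + 1, sign=sign, segments=segs,
                                   marks=marks,
                                   log2fc=sign * config.expression_effect))
    return archs


# enhancer subtypes: (direction, weights over the 6 enhancer marks); core
# marks keep full weight so island discovery is never pattern-dependent
def enhancer_patterns(config: SimConfig) -> list[dict]:
    marks = list(config.enhancer_marks)
    core = {"H3K4me1", "H3K27ac"}
    group1 = {"H3K4me2", "H3R17me2asym"}
    pats = []
    for direction in ("gain", "loss"):
        for p in range(3):
            w = {}
            for m in marks:
                if m in core or p == 0:
                    w[m] = 1.0
                elif (m in group1) == (p == 1):
                    w[m] = 1.0
                else:
                    w[m] = 0.0
            pats.append({"direction": direction, "pattern": p, "weights": w})
    return pats


def simulate_genome(config: SimConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene models on evenly spaced slots plus chromosome sizes.

    Each gene gets its own slot so promoters, gene bodies and the
    intergenic enhancer sites planted upstream never collide.
    """
    rng = np.random.default_rng(config.seed + 0)
    chrom_sizes = config.chrom_sizes
    if config.n_genes == 0:
        return (pd.DataFrame(columns=["gene_id", "chrom", "strand",
                                      "txStart", "txEnd"]), chrom_sizes)
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    rows = []
    gid = 0
    for ci, chrom in enumerate(chrom_sizes):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        slot = config.chrom_length // n
        if slot < _SLOT_MIN:
            raise ValueError(
                f"chromosome {chrom} too short for {n} genes: slot {slot} bp "
                f"< {_SLOT_MIN} bp minimum")
        for k in range(n):
            off = int(rng.integers(*_GENE_OFFSET))
            length = int(rng.integers(*_GENE_LENGTH))
            start = k * slot + off
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{gid:04d}", chrom, strand, start, start + length))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                        "txStart", "txEnd"])
    return genes, chrom_sizes


def _enhancer_site(gene, null: bool = False) -> int:
    """Deterministic intergenic anchor position upstream of a gene's slot.

    Null enhancers use a second, farther site so a gene can host one
    differential and one non-differential enhancer without overlap.
    """
    off = _ENH_NULL_OFFSET if null else _ENH_OFFSET
    return int(gene.txStart) - off


def _nb_draw(rng: np.random.Generator, lam: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(lam)
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + lam))


def simulate_tracks(genes: pd.DataFrame, config: SimConfig
                    ) -> tuple[dict, TruthManifest]:
    """Binned RE tracks for every (mark, condition) plus the truth manifest.

    Background bins are negative binomial; planted gene-cluster loci add
    ``effect_size`` to their archetype's segments in the gaining condition;
    planted enhancers add a triangular peak of the enhancer-associated
    marks around the anchor (asymmetric between conditions for gain/loss,
    symmetric for null); H3K4me3 is elevated at promoters only. The whole
    mesenchymal expectation is multiplied by ``library_factor`` so pair
    normalization is exercised.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom_sizes = config.chrom_sizes
    n_bins = {c: s // BIN_WIDTH for c, s in chrom_sizes.items()}
    marks = list(config.marks) + [CONTROL_MARK]
    manifest = TruthManifest()

    # --- assign genes to planted clusters -------------------------------
    archs = gene_archetypes(config)
    manifest.cluster_directions = {a.cluster: a.sign for a in archs}
    gene_ids = genes["gene_id"].tolist()
    perm = rng.permutation(len(gene_ids))
    n_planted = int(round((1 - config.frac_null) * len(gene_ids)))
    labels = {g: 0 for g in gene_ids}
    for i, pi in enumerate(perm[:n_planted]):
        labels[gene_ids[pi]] = archs[i % len(archs)].cluster if archs else 0
    manifest.gene_clusters = labels
    arch_of = {a.cluster: a for a in archs}
    for g in gene_ids:
        cl = labels[g]
        base = arch_of[cl].log2fc if cl else 0.0
        noise_sd = 0.25 if cl else 0.15
        manifest.gene_log2fc[g] = float(base + rng.normal(0, noise_sd))

    # --- plan enhancers --------------------------------------------------
    pats = enhancer_patterns(config)
    n_null_e = int(round(config.frac_null * config.n_enhancers))
    n_diff = config.n_enhancers - n_null_e
    n_gain = n_diff // 2 + n_diff % 2
    n_loss = n_diff // 2
    # gain/loss enhancers are hosted near expression-concordant genes (the
    # planted coupling); null enhancers may sit at any gene's second site
    by_dir = {"gain": [], "loss": [], "null": list(gene_ids)}
    for g in gene_ids:
        cl = labels[g]
        if cl == 0:
            continue
        elif manifest.cluster_directions[cl] > 0:
            by_dir["gain"].append(g)
        else:
            by_dir["loss"].append(g)
    need = {"gain": n_gain, "loss": n_loss, "null": n_null_e}
    for d, n in need.items():
        if n > len(by_dir[d]):
            raise ValueError(
                f"cannot host {n} {d} enhancers on {len(by_dir[d])} "
                f"{d}-direction genes; lower n_enhancers or frac_null")
    genes_ix = genes.set_index("gene_id")
    eid = 0
    gain_pats = [p for p in pats if p["direction"] == "gain"]
    loss_pats = [p for p in pats if p["direction"] == "loss"]
    for direction, n in need.items():
        hosts = [by_dir[direction][i] for i in
                 rng.choice(len(by_dir[direction]), size=n, replace=False)]
        for host in hosts:
            gene = genes_ix.loc[host]
            pos = _enhancer_site(gene, null=direction == "null")
            if direction == "gain":
                pat = gain_pats[eid % len(gain_pats)]
            elif direction == "loss":
                pat = loss_pats[eid % len(loss_pats)]
            else:
                pat = {"pattern": -1,
                       "weights": {m: 1.0 for m in config.enhancer_marks}}
            manifest.enhancers.append({
                "id": f"true_enh_{eid:04d}", "chrom": str(gene["chrom"]),
                "position": pos, "anchor_bin": pos // BIN_WIDTH,
                "direction": direction, "pattern": int(pat["pattern"]),
                "host_gene": host,
            })
            eid += 1

    # --- build per-(mark, condition) expectation maps --------------------
    lam = {(m, c): {ch: np.full(n_bins[ch], config.background_rate)
                    for ch in chrom_sizes}
           for m in marks for c in CONDITIONS}

    # planted gene-cluster effects
    from .profiles import segment_gene
    for gene in genes.itertuples(index=False):
        cl = labels[gene.gene_id]
        # promoter-restricted H3K4me3 in both conditions, every gene
        ref_layout = segment_gene(gene, n_bins=n_bins[gene.chrom])
        ts, te = ref_layout.segments["TSS"]
        if PROMOTER_MARK in config.marks:
            for c in CONDITIONS:
                lam[(PROMOTER_MARK, c)][gene.chrom][ts:te] += 1.5 * config.effect_size
        if cl == 0:
            continue
        arch = arch_of[cl]
        cond = "mesenchymal" if arch.sign > 0 else "epithelial"
        for seg in arch.segments:
            s, e = ref_layout.segments[seg]
            for m in arch.marks:
                lam[(m, cond)][gene.chrom][s:e] += config.effect_size

    # planted enhancer peaks
    level = {"gain": {"epithelial": 0.15, "mesenchymal": 1.0},
             "loss": {"epithelial": 1.0, "mesenchymal": 0.15}}
    for e in manifest.enhancers:
        if e["direction"] == "null":
            # null loci carry no planted effect: background positions the
            # manifest records for false-call measurement
            continue
        else:
            pool = gain_pats if e["direction"] == "gain" else loss_pats
            weights = next(p["weights"] for p in pool
                           if p["pattern"] == e["pattern"])
            lev = level[e["direction"]]
        # marks at one enhancer co-fluctuate with local accessibility: a
        # shared per-locus, per-condition lognormal factor (mean 1)
        s = config.locus_noise_sd
        shared = {c: float(rng.lognormal(-s * s / 2, s)) if s > 0 else 1.0
                  for c in CONDITIONS}
        b = e["anchor_bin"]
        lo, hi = b - 5, b + 6
        for m in config.enhancer_marks:
            for c in CONDITIONS:
                amp = config.effect_size * weights[m] * lev[c] * shared[c]
                vec = lam[(m, c)][e["chrom"]]
                vec[max(lo, 0):hi] += amp * _PEAK_WEIGHTS[max(lo, 0) - lo:]

    # --- sample counts ----------------------------------------------------
    tracks = {}
    for m in marks:
        for c in CONDITIONS:
            factor = config.library_factor if c == "mesenchymal" else 1.0
            data = {ch: _nb_draw(rng, factor * lam[(m, c)][ch],
                                 config.dispersion).astype(np.int64)
                    for ch in chrom_sizes}
            tracks[(m, c)] = BinnedTrack(data=data, mark=m, condition=c,
                                         kind="RE")
    return tracks, manifest


def simulate_expression(genes: pd.DataFrame, manifest: TruthManifest,
                        config: SimConfig) -> pd.DataFrame:
    """Probe-level log2 fold-changes: gene truth plus Gaussian probe noise.

    Returns a table with columns probe_id, gene_id, log2fc (the probe->gene
    map is the (probe_id, gene_id) projection).
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for g in genes["gene_id"]:
        true_fc = manifest.gene_log2fc[g]
        for k in range(config.probes_per_gene):
            fc = true_fc + rng.normal(0, config.probe_noise_sd)
            rows.append((f"{g}_p{k}", g, float(fc)))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "log2fc"])


def simulate_annotations(genes: pd.DataFrame, manifest: TruthManifest,
                         config: SimConfig
                         ) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """GMT term sets, TFBS intervals and the PPI edge list.

    Each planted cluster gets terms drawing members preferentially from it;
    an activated TF gets sites inside gain-planted enhancers and a repressed
    TF inside loss-planted ones; the PPI graph is planted dense blocks over
    sparse background with confidences straddling the 400 cutoff.
    """
    rng = np.random.default_rng(config.seed + 3)
    gene_ids = genes["gene_id"].tolist()
    clusters = sorted({c for c in manifest.gene_clusters.values() if c})
    members = {c: [g for g, cl in manifest.gene_clusters.items() if cl == c]
               for c in clusters}

    # --- terms ----------------------------------------------------------
    terms: dict[str, list[str]] = {}
    terms_per_cluster = 2
    ti = 0
    for c in clusters:
        for _ in range(terms_per_cluster):
            name = f"TERM{ti:03d}_cluster{c}"
            chosen: set = set()
            while len(chosen) < min(config.term_size, len(gene_ids)):
                if members[c] and rng.random() < config.term_preference:
                    chosen.add(members[c][int(rng.integers(len(members[c])))])
                else:
                    chosen.add(gene_ids[int(rng.integers(len(gene_ids)))])
            terms[name] = sorted(chosen)
            manifest.term_clusters[name] = c
            ti += 1
    while ti < config.n_terms:
        name = f"TERM{ti:03d}_bg"
        size = min(config.term_size, len(gene_ids))
        idx = rng.choice(len(gene_ids), size=size, replace=False)
        terms[name] = sorted(gene_ids[i] for i in idx)
        ti += 1

    # --- TFBS ------------------------------------------------------------
    chrom_sizes = config.chrom_sizes
    site_w = 15
    rows = []

    def _random_site(factor):
        ch = list(chrom_sizes)[int(rng.integers(config.n_chroms))]
        s = int(rng.integers(0, chrom_sizes[ch] - site_w))
        rows.append((ch, s, s + site_w, factor))

    for factor, direction in (("TF_ACT", "gain"), ("TF_REP", "loss")):
        manifest.tf_directions[factor] = direction
        for e in manifest.enhancers:
            if e["direction"] == direction and rng.random() < config.tf_inside_prob:
                center = e["position"] + BIN_WIDTH // 2 + int(rng.integers(-400, 400))
                rows.append((e["chrom"], center, center + site_w, factor))
        for _ in range(10):  # sparse off-target background
            _random_site(factor)
    for b in range(config.n_background_tfs):
        for _ in range(config.n_tf_background_sites):
            _random_site(f"TF_BG{b}")
    tfbs = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    tfbs["score"] = 0
    tfbs["strand"] = "."

    # --- PPI --------------------------------------------------------------
    n_block_genes = config.n_ppi_modules * config.ppi_module_size
    if n_block_genes > len(gene_ids):
        raise ValueError("not enough genes for the requested PPI modules")
    # dense blocks live among the planted-cluster genes when possible, so
    # seeded subnetworks (cluster or expression seeds) reach them
    planted = [i for i, g in enumerate(gene_ids) if manifest.gene_clusters.get(g)]
    pool_ix = planted if len(planted) >= n_block_genes else range(len(gene_ids))
    block_pool = rng.choice(np.fromiter(pool_ix, dtype=int),
                            size=n_block_genes, replace=False)
    edges = {}
    for m in range(config.n_ppi_modules):
        blk = [gene_ids[i] for i in
               block_pool[m * config.ppi_module_size:(m + 1) * config.ppi_module_size]]
        for g in blk:
            manifest.ppi_modules[g] = m + 1
        for i in range(len(blk)):
            for j in range(i + 1, len(blk)):
                if rng.random() < config.ppi_p_in:
                    conf = int(rng.integers(500, 1000))
                    edges[(blk[i], blk[j])] = conf
    for _ in range(config.n_ppi_background_edges):
        i, j = rng.choice(len(gene_ids), size=2, replace=False)
        a, b = sorted((gene_ids[i], gene_ids[j]))
        conf = int(rng.integers(100, 1000))  # some fall below the 400 cutoff
        edges.setdefault((a, b), conf)
    ppi = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(edges.items())],
        columns=["geneA", "geneB", "confidence"])
    return terms, tfbs, ppi


def write_all(config: SimConfig, out_dir) -> dict:
    """Generate every artifact and write the standard file set.

    Writes genes.tsv, chrom.sizes, re_<mark>_<condition>.bedgraph,
    probes.tsv, terms.gmt, tfbs.bed, ppi.tsv and truth.json; returns the
    in-memory objects for callers that continue in-process.
    """
    out = eio.ensure_dir(out_dir)
    genes, chrom_sizes = simulate_genome(config)
    tracks, manifest = simulate_tracks(genes, config)
    probes = simulate_expression(genes, manifest, config)
    terms, tfbs, ppi = simulate_annotations(genes, manifest, config)

    eio.write_genes(genes, out / "genes.tsv")
    eio.write_chrom_sizes(chrom_sizes, out / "chrom.sizes")
    cond_tag = {"epithelial": "E", "mesenchymal": "M"}
    for (mark, cond), track in tracks.items():
        eio.write_bedgraph(track, out / f"re_{mark}_{cond_tag[cond]}.bedgraph")
    probes.to_csv(out / "probes.tsv", sep="\t", index=False)
    eio.write_gmt(terms, out / "terms.gmt")
    eio.write_bed(tfbs, out / "tfbs.bed")
    eio.write_ppi(ppi, out / "ppi.tsv")
    manifest.to_json(out / "truth.json")
    return {"genes": genes, "chrom_sizes": chrom_sizes, "tracks": tracks,
            "manifest": manifest, "probes": probes, "terms": terms,
            "tfbs": tfbs, "ppi": ppi}
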
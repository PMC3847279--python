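"""Putative-enhancer discovery and differential filtering.

Candidate enhancers are broad islands of H3K4me1 or H3K27ac raw enrichment
called against a pan-H3 control, anchored on the maximally enriched 200-bp
bin, cleaned of promoter-like anchors (H3K4me3 overlap), collapsed between
the two core marks, and extended to fixed 2,200-bp loci. A locus is kept as
*differential* when its single largest scaled gain-or-loss feature across
the enhancer-associated marks is improbable under a Gaussian noise model
whose location is the mode of a kernel density estimate of all maxima and
whose spread is estimated from the left (sub-modal) tail only — the side
of the distribution uncontaminated by genuine epigenetic change.
Differential loci are finally assigned to the genes in whose cis-regions
(TSS to neighboring TSS, capped at 1 Mb per side) they fall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import BIN_WIDTH, BinnedTrack
from .profiles import DEPMatrix

logger = logging.getLogger(__name__)

CORE_ENHANCER_MARKS = ("H3K4me1", "H3K27ac")

# the six marks whose differential signal tracks the two core marks
ENHANCER_ASSOCIATED_MARKS = (
    "H3K4me1", "H3K4me2", "H3K27ac", "H3K9ac", "H4K8ac", "H3R17me2asym",
)

FLANK_BP = 1000          # extension on each side of the 200-bp anchor
LOCUS_BINS = 11          # resulting locus size: 2,200 bp


@dataclass
class Island:
    chrom: str
    start_bin: int  # half-open bin range
    end_bin: int
    p: float = 1.0

    def overlaps_bin(self, b: int) -> bool:
        return self.start_bin <= b < self.end_bin


@dataclass
class Anchor:
    chrom: str
    bin: int
    source_mark: str

    @property
    def center(self) -> int:
        return self.bin * BIN_WIDTH + BIN_WIDTH // 2


@dataclass
class EnhancerLocus:
    """A 2,200-bp putative enhancer centered on its anchor bin."""

    locus_id: str
    chrom: str
    anchor_bin: int
    source_mark: str
    start: int
    end: int
    max_magnitude: float | None = None
    p_null: float | None = None
    status: str = "putative"
    genes: list[str] = field(default_factory=list)

    @property
    def bin_range(self) -> tuple[int, int]:
        return self.anchor_bin - 5, self.anchor_bin + 6


@dataclass
class NullModel:
    """Gaussian noise model for per-locus maximal feature magnitudes."""

    mu_hat: float
    sigma_hat: float
    bandwidth: float
    n_tail: int


def _moment_dispersion(counts: np.ndarray) -> float:
    """Method-of-moments NB dispersion from the bulk of a count track.

    Estimated on bins at or below the 99th percentile so genuine peaks do
    not inflate it; 0 means the data are at most Poisson-dispersed.
    """
    bulk = counts[counts <= np.percentile(counts, 99)]
    m = bulk.mean()
    if m <= 0:
        return 0.0
    v = bulk.var()
    return max(float((v - m) / (m * m)), 0.0)


def _count_tail_sf(total: np.ndarray, lam: np.ndarray, disp: float,
                   n_bins: float = 1.0):
    """Upper-tail P(X >= total) for a (sum of) NB/Poisson bin count(s)."""
    if disp <= 1e-9:
        return stats.poisson.sf(total - 1, lam)
    r = n_bins / disp
    return stats.nbinom.sf(total - 1, r, r / (r + lam))


def call_islands(re_mark: BinnedTrack, re_control: BinnedTrack,
                 gap: int = 600, fdr: float = 0.01,
                 bin_p: float = 0.05, min_bins: int = 2) -> list[Island]:
    """Enrichment island caller against a library-scaled control track.

    Bins whose count beats a negative-binomial tail test at ``bin_p``
    (dispersion moment-estimated from the mark track's bulk; Poisson when
    not over-dispersed) given the control-derived local expectation are
    candidates; candidate runs separated by at most ``gap`` bp are merged;
    islands must span at least ``min_bins`` candidate bins (sustained
    enrichment, so isolated outlier bins never seed an island) and are kept
    at a BH-adjusted island-level tail p <= ``fdr``.
    """
    if not re_mark.same_grid(re_control):
        raise ValueError("mark and control tracks are on different grids")
    total_mark = re_mark.total()
    total_ctrl = re_control.total()
    gap_bins = gap // re_mark.bin_width
    all_counts = np.concatenate([re_mark.data[c] for c in re_mark.chroms])
    disp = _moment_dispersion(all_counts.astype(float))
    islands: list[Island] = []
    for chrom in re_mark.chroms:
        counts = re_mark.data[chrom].astype(float)
        if total_ctrl > 0:
            lam = re_control.data[chrom].astype(float) * (total_mark / total_ctrl)
            floor = max(total_mark / max(sum(len(v) for v in re_mark.data.values()), 1), 0.1)
            lam = np.maximum(lam, floor)
        else:
            logger.warning("control track empty; falling back to global-mean "
                           "background for %s", re_mark.mark)
            lam = np.full_like(counts, max(counts.mean(), 0.1))
        cand = _count_tail_sf(counts, lam, disp) <= bin_p
        if not cand.any():
            continue
        idx = np.flatnonzero(cand)
        breaks = np.flatnonzero(np.diff(idx) > gap_bins + 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(idx) - 1]])
        for rs, re_ in zip(run_starts, run_ends):
            if re_ - rs + 1 < min_bins:
                continue
            s, e = int(idx[rs]), int(idx[re_]) + 1
            p = float(_count_tail_sf(counts[s:e].sum(), lam[s:e].sum(),
                                     disp, n_bins=e - s))
            islands.append(Island(chrom=chrom, start_bin=s, end_bin=e, p=p))
    if not islands:
        return []
    reject, _, _, _ = multipletests([i.p for i in islands], alpha=fdr,
                                    method="fdr_bh")
    return [i for i, keep in zip(islands, reject) if keep]


def select_anchor(island: Island, re_mark: BinnedTrack) -> Anchor:
    """The island bin with maximal raw enrichment; ties go leftmost."""
    vec = re_mark.data[island.chrom][island.start_bin:island.end_bin]
    if len(vec) == 0:
        raise ValueError("empty island")
    b = island.start_bin + int(np.argmax(vec))
    return Anchor(chrom=island.chrom, bin=b, source_mark=re_mark.mark)


def filter_h3k4me3(anchors: list[Anchor],
                   k4me3_islands: list[Island]) -> list[Anchor]:
    """Drop anchors whose bin overlaps any H3K4me3 island (promoter-like)."""
    by_chrom: dict[str, list[Island]] = {}
    for isl in k4me3_islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    kept = []
    for a in anchors:
        if any(isl.overlaps_bin(a.bin) for isl in by_chrom.get(a.chrom, [])):
            continue
        kept.append(a)
    return kept


def collapse_anchors(k4me1_anchors: list[Anchor], k27ac_anchors: list[Anchor],
                     radius: int = 1000,
                     chrom_sizes=None) -> list[EnhancerLocus]:
    """Collapse H3K4me1 anchors onto nearby H3K27ac anchors and emit loci.

    A K4me1 anchor within ``radius`` bp (bin-center distance) of any K27ac
    anchor is dropped in favor of the K27ac site; every surviving anchor is
    extended by 1,000 bp on each side into a 2,200-bp locus. Anchors whose
    locus would run past a chromosome edge are dropped (with ``chrom_sizes``
    given) so every emitted locus is exactly 11 bins.
    """
    k27_by_chrom: dict[str, np.ndarray] = {}
    for a in k27ac_anchors:
        k27_by_chrom.setdefault(a.chrom, [])
    for a in k27ac_anchors:
        k27_by_chrom[a.chrom].append(a.center)
    k27_by_chrom = {c: np.sort(np.asarray(v)) for c, v in k27_by_chrom.items()}
    survivors: list[Anchor] = list(k27ac_anchors)
    for a in k4me1_anchors:
        centers = k27_by_chrom.get(a.chrom)
        if centers is not None and len(centers):
            i = np.searchsorted(centers, a.center)
            near = min(
                abs(a.center - centers[j])
                for j in (max(i - 1, 0), min(i, len(centers) - 1)))
            if near <= radius:
                continue
        survivors.append(a)
    survivors.sort(key=lambda a: (a.chrom, a.bin, a.source_mark))
    loci = []
    for i, a in enumerate(survivors):
        start = a.bin * BIN_WIDTH - FLANK_BP
        if start < 0:
            continue
        if chrom_sizes is not None and start + 2200 > chrom_sizes[a.chrom]:
            continue
        loci.append(EnhancerLocus(
            locus_id=f"enh_{i:05d}", chrom=a.chrom, anchor_bin=a.bin,
            source_mark=a.source_mark, start=start, end=start + 2200))
    return loci


def locus_mark_signal(loci: list[EnhancerLocus],
                      sde: BinnedTrack) -> np.ndarray:
    """Summed SDE of one mark over each locus's 11 bins."""
    out = np.zeros(len(loci))
    for i, loc in enumerate(loci):
        vec = sde.data[loc.chrom]
        s, e = loc.bin_range
        out[i] = vec[max(s, 0):min(e, len(vec))].sum()
    return out


def identify_enhancer_marks(loci, sde_tracks, core=CORE_ENHANCER_MARKS,
                            r_min: float = 0.5,
                            fixed_set: bool = True) -> list[str]:
    """Marks whose per-locus differential signal tracks a core enhancer mark.

    With ``fixed_set`` (the default configuration) the six canonical
    enhancer-associated marks are returned outright; otherwise every
    available mark whose Pearson correlation with either core mark's
    per-locus signal reaches ``r_min`` is added to the core set.
    """
    if fixed_set:
        return [m for m in ENHANCER_ASSOCIATED_MARKS]
    if len(loci) < 3:
        raise ValueError("need at least 3 loci to estimate correlations")
    core_sig = {m: locus_mark_signal(loci, sde_tracks[m]) for m in core}
    selected = list(core)
    for mark, track in sde_tracks.items():
        if mark in core:
            continue
        sig = locus_mark_signal(loci, track)
        if sig.std() == 0:
            continue
        r = max(abs(stats.pearsonr(sig, cs)[0]) for cs in core_sig.values()
                if cs.std() > 0)
        if r >= r_min:
            selected.append(mark)
    return selected


def compute_max_magnitudes(dep_scaled: DEPMatrix) -> pd.Series:
    """Per-locus extreme value: the largest single scaled gain/loss feature."""
    if not dep_scaled.scaled:
        raise ValueError("extreme values are defined on the scaled matrix")
    return dep_scaled.values.max(axis=1)


def fit_extreme_null(max_magnitudes, bandwidth: float = 0.025,
                     grid_points: int = 2001,
                     sigma_denominator: str = "tail") -> NullModel:
    """Fit the Gaussian extreme-value null from a KDE mode and the left tail.

    The kernel density estimate (Gaussian kernel, fixed bandwidth) is
    evaluated on an even grid over [0, max]; mu_hat is the grid argmax.
    sigma_hat = sqrt( sum_{x_i <= mu_hat} (x_i - mu_hat)^2 / (n - 1) ) where
    n counts the tail points (``sigma_denominator='tail'``) or the whole
    sample (``'full'``).
    """
    x = np.asarray(max_magnitudes, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate sample: cannot fit the null model")
    grid = np.linspace(0.0, float(x.max()), grid_points)
    dens = np.zeros_like(grid)
    # chunk over data to bound memory on large locus sets
    for chunk in np.array_split(x, max(len(x) // 4096, 1)):
        dens += stats.norm.pdf((grid[:, None] - chunk[None, :]) / bandwidth).sum(axis=1)
    mu_hat = float(grid[int(np.argmax(dens))])
    tail = x[x <= mu_hat]
    n_tail = int(len(tail))
    if n_tail < 2:
        raise ValueError("fewer than 2 points at or below the mode")
    denom = (n_tail if sigma_denominator == "tail" else len(x)) - 1
    sigma_hat = float(np.sqrt(((tail - mu_hat) ** 2).sum() / denom))
    if sigma_hat <= 0:
        raise ValueError("left tail has zero spread; cannot fit the null model")
    return NullModel(mu_hat=mu_hat, sigma_hat=sigma_hat, bandwidth=bandwidth,
                     n_tail=n_tail)


def filter_differential(loci: list[EnhancerLocus], null: NullModel,
                        alpha: float = 0.05) -> list[EnhancerLocus]:
    """Keep loci whose extreme value is significant under the null.

    p_null is the upper-tail Gaussian probability of the locus's maximal
    magnitude; loci with p_null > alpha are dropped (the boundary p = alpha
    is retained). The per-mark requirement of a significant change in at
    least one enhancer-associated mark is equivalent to this test because
    the extreme value is the maximum over those marks' features.
    """
    if null is None or null.sigma_hat <= 0:
        raise ValueError("null model not fitted")
    kept = []
    for loc in loci:
        if loc.max_magnitude is None:
            raise ValueError(f"locus {loc.locus_id} has no extreme value")
        loc.p_null = float(stats.norm.sf(loc.max_magnitude, loc=null.mu_hat,
                                         scale=null.sigma_hat))
        if loc.p_null <= alpha:
            loc.status = "differential"
            kept.append(loc)
    return kept


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """Strand-appropriate TSS coordinate (base of the 5' cap)."""
    return pd.Series(
        np.where(genes["strand"] == "+", genes["txStart"], genes["txEnd"] - 1),
        index=genes["gene_id"])


def cis_regions(genes: pd.DataFrame, cap: int = 1_000_000) -> pd.DataFrame:
    """Half-open cis-region per gene: TSS to neighboring TSS each side,
    capped at ``cap`` bp per side."""
    tss = gene_tss(genes)
    rows = []
    for chrom, sub in genes.groupby("chrom"):
        ids = sub["gene_id"].to_numpy()
        pos = tss[ids].to_numpy()
        order = np.argsort(pos, kind="stable")
        ids, pos = ids[order], pos[order]
        for i, (gid, p) in enumerate(zip(ids, pos)):
            left = max(p - cap, pos[i - 1] if i > 0 else p - cap, 0)
            right = min(p + cap, pos[i + 1] if i + 1 < len(pos) else p + cap)
            rows.append((gid, chrom, int(left), int(right)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def assign_to_genes(loci: list[EnhancerLocus], genes: pd.DataFrame,
                    cap: int = 1_000_000) -> list[EnhancerLocus]:
    """Assign each locus to every gene whose cis-region it overlaps
    (half-open intervals; multiple assignment permitted)."""
    regions = cis_regions(genes, cap=cap)
    by_chrom = {c: sub for c, sub in regions.groupby("chrom")}
    for loc in loci:
        sub = by_chrom.get(loc.chrom)
        loc.genes = []
        if sub is None:
            continue
        hit = (sub["start"] < loc.end) & (loc.start < sub["end"])
        loc.genes = sub.loc[hit, "gene_id"].tolist()
    return loci


def loci_to_bed(loci: list[EnhancerLocus]) -> pd.DataFrame:
    score = [
        0.0 if loc.p_null is None
        else float(-np.log10(max(loc.p_null, 1e-300))) for loc in loci]
    return pd.DataFrame({
        "chrom": [l.chrom for l in loci],
        "start": [l.start for l in loci],
        "end": [l.end for l in loci],
        "name": [l.source_mark for l in loci],
        "score": score,
        "strand": ".",
    })
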
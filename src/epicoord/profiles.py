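"""Differential epigenetic profiles (DEPs) of gene and enhancer loci.

Each gene is divided into four segments laid out on the fixed 200-bp bin
grid: a 25-bin promoter (PR), a 3-bin transcription-start segment (TSS,
the bin containing the start coordinate plus one bin on each side), a
25-bin gene start (GS), and a variable whole-gene segment (WG) running
from the TSS reference bin to 5 bins past the bin holding the termination
site. Within every segment the scaled differential enrichment of each mark
is reduced to a gain (sum of positive bins) and a loss (absolute sum of
negative bins). The resulting loci x (segment, mark, direction) matrix is
column-scaled with a saturating sigmoid anchored at an upper percentile so
all features live on a common [0, 1) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import BIN_WIDTH, BinnedTrack

logger = logging.getLogger(__name__)

GENE_SEGMENTS = ("PR", "TSS", "GS", "WG")
ENHANCER_SEGMENT = "ENH"
DIRECTIONS = ("gain", "loss")

MIN_GENE_LENGTH = 1200  # bp; shorter genes cannot host the minimal WG segment
FLANK_BINS = 25         # PR and GS size in bins (5 kb)
WG_TAIL_BINS = 5        # WG extension past the termination-site bin (1 kb)


@dataclass
class SegmentLayout:
    """Bin-index ranges (half-open) of one locus's segments on one chromosome."""

    locus_id: str
    chrom: str
    segments: dict[str, tuple[int, int]]
    clipped: bool = False


def segment_gene(gene, n_bins: int | None = None,
                 bin_width: int = BIN_WIDTH) -> SegmentLayout:
    """Lay out PR/TSS/GS/WG segments for one gene record.

    ``gene`` needs fields gene_id, chrom, strand, txStart, txEnd (0-based
    half-open). The bin grid is fixed; bins are never shifted to the TSS.
    For minus-strand genes the layout is mirrored so PR stays
    transcriptionally upstream. Ranges running off the chromosome are
    clipped and flagged.
    """
    tx_start, tx_end = int(gene.txStart), int(gene.txEnd)
    if tx_end - tx_start < MIN_GENE_LENGTH:
        raise ValueError(
            f"gene {gene.gene_id} is {tx_end - tx_start} bp, "
            f"shorter than the {MIN_GENE_LENGTH} bp minimum")
    if gene.strand == "+":
        ref = tx_start // bin_width
        tts_bin = (tx_end - 1) // bin_width
        segs = {
            "PR": (ref - 1 - FLANK_BINS, ref - 1),
            "TSS": (ref - 1, ref + 2),
            "GS": (ref + 2, ref + 2 + FLANK_BINS),
            "WG": (ref, tts_bin + WG_TAIL_BINS + 1),
        }
    else:
        ref = (tx_end - 1) // bin_width  # bin holding the 5' cap base
        tts_bin = tx_start // bin_width
        segs = {
            "PR": (ref + 2, ref + 2 + FLANK_BINS),
            "TSS": (ref - 1, ref + 2),
            "GS": (ref - 1 - FLANK_BINS, ref - 1),
            "WG": (tts_bin - WG_TAIL_BINS, ref + 1),
        }
    clipped = False
    if n_bins is not None:
        for name, (s, e) in segs.items():
            cs, ce = max(s, 0), min(e, n_bins)
            if (cs, ce) != (s, e):
                clipped = True
                segs[name] = (cs, ce)
    elif any(s < 0 for s, _ in segs.values()):
        clipped = True
        segs = {k: (max(s, 0), max(e, 0)) for k, (s, e) in segs.items()}
    if clipped:
        logger.debug("segments of %s clipped at chromosome edge", gene.gene_id)
    return SegmentLayout(locus_id=str(gene.gene_id), chrom=gene.chrom,
                         segments=segs, clipped=clipped)


def segment_genes(genes: pd.DataFrame,
                  chrom_sizes: Mapping[str, int] | None = None,
                  bin_width: int = BIN_WIDTH) -> list[SegmentLayout]:
    """Segment a gene table, skipping (with a warning) genes below 1.2 kb."""
    layouts = []
    for gene in genes.itertuples(index=False):
        n_bins = None
        if chrom_sizes is not None:
            n_bins = -(-int(chrom_sizes[gene.chrom]) // bin_width)
        try:
            layouts.append(segment_gene(gene, n_bins=n_bins, bin_width=bin_width))
        except ValueError as exc:
            logger.warning("skipping gene: %s", exc)
    return layouts


def quantify_segment(sde: BinnedTrack, chrom: str,
                     bins: tuple[int, int]) -> tuple[float, float]:
    """Gain and loss of one mark over one segment.

    gain = sum of positive SDE bins, loss = |sum of negative SDE bins|;
    gain - loss equals the plain SDE sum over the segment.
    """
    start, stop = bins
    if stop <= start:
        raise ValueError("empty segment range")
    vec = sde.data[chrom]
    if start < 0 or stop > len(vec):
        raise ValueError(f"segment bins [{start}, {stop}) outside track")
    window = vec[start:stop]
    gain = float(window[window > 0].sum())
    loss = float(abs(window[window < 0].sum()))
    return gain, loss


@dataclass
class DEPMatrix:
    """Loci x (segment, mark, direction) gain/loss feature matrix.

    ``values`` holds raw (nonnegative) or scaled ([0, 1)) features; the
    per-column scale constants ``u`` (the upper percentile of the raw
    values) are kept so gene and enhancer matrices are reproducibly
    rescalable.
    """

    values: pd.DataFrame
    scaled: bool = False
    u: pd.Series | None = None

    @property
    def columns(self) -> pd.Index:
        return self.values.columns


def feature_columns(segments: Sequence[str], marks: Sequence[str]) -> list[str]:
    """Deterministic column order: segment-major, then mark, gain before loss."""
    return [f"{seg}|{mark}|{d}"
            for seg in segments for mark in marks for d in DIRECTIONS]


def build_dep_matrix(layouts: Iterable[SegmentLayout],
                     sde_tracks: Mapping[str, BinnedTrack],
                     marks: Sequence[str]) -> DEPMatrix:
    """Raw DEP matrix: one row per locus, 2 features per (segment, mark)."""
    layouts = list(layouts)
    missing = [m for m in marks if m not in sde_tracks]
    if missing:
        raise KeyError(f"missing SDE track(s) for mark(s): {', '.join(missing)}")
    if not layouts:
        raise ValueError("no loci to profile")
    segments = list(layouts[0].segments)
    cols = feature_columns(segments, marks)
    rows = np.zeros((len(layouts), len(cols)))
    col_of = {c: i for i, c in enumerate(cols)}
    for i, lay in enumerate(layouts):
        for seg, rng in lay.segments.items():
            if rng[1] <= rng[0]:  # fully clipped segment stays all-zero
                continue
            for mark in marks:
                g, l = quantify_segment(sde_tracks[mark], lay.chrom, rng)
                rows[i, col_of[f"{seg}|{mark}|gain"]] = g
                rows[i, col_of[f"{seg}|{mark}|loss"]] = l
    df = pd.DataFrame(rows, index=[lay.locus_id for lay in layouts], columns=cols)
    return DEPMatrix(values=df, scaled=False)


def scale_value(x, u):
    """Saturating sigmoid z = 2 / (1 + exp(-2x/u)) - 1.

    Maps 0 to 0, is approximately linear below the anchor u (z(u) = tanh 1
    ~ 0.762) and approaches 1 from below for large x.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return 2.0 / (1.0 + np.exp(-2.0 * x / u)) - 1.0


def scale_columns(m: DEPMatrix, pct: float = 95.0) -> DEPMatrix:
    """Scale each raw column by its ``pct``-th percentile (linear-interpolation
    percentile). A column whose percentile is 0 maps entirely to 0."""
    if m.scaled:
        raise ValueError("matrix already scaled")
    vals = m.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("raw DEP values must be nonnegative")
    u = np.percentile(vals, pct, axis=0)
    out = np.zeros_like(vals)
    nz = u > 0
    out[:, nz] = scale_value(vals[:, nz], u[nz])
    scaled = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return DEPMatrix(values=scaled, scaled=True,
                     u=pd.Series(u, index=m.values.columns))


def write_dep_matrix(m: DEPMatrix, path, u_path=None) -> None:
    m.values.to_csv(path, sep="\t", index_label="locus_id")
    if u_path is not None and m.u is not None:
        import json
        with open(u_path, "w") as fh:
            json.dump({str(k): float(v) for k, v in m.u.items()}, fh, indent=1)


def read_dep_matrix(path, scaled: bool = False) -> DEPMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus_id")
    return DEPMatrix(values=df, scaled=scaled)
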
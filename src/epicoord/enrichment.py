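"""Binned ChIP-seq enrichments and scaled differential enrichments.

Tags mapped in an epithelial (E) and a mesenchymal (M) sample are extended
to the expected nucleosomal fragment length, counted into fixed 200-bp
genomic bins (raw enrichment, RE), pair-normalized per mark with
median-of-ratios size factors (scaled enrichment, SE), and differenced
bin-wise into the scaled differential enrichment (SDE = MSE - ESE), whose
positive values are mesenchymal gains and negative values mesenchymal
losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

BIN_WIDTH = 200

CONDITIONS = ("epithelial", "mesenchymal")


@dataclass(frozen=True)
class TagRecord:
    """A single mapped sequencing tag, identified by its 5' end."""

    chrom: str
    pos5: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos5 < 0:
            raise ValueError("tag 5' position must be nonnegative")


@dataclass
class BinnedTrack:
    """Per-chromosome vectors of per-bin signal for one mark.

    ``kind`` is one of ``RE`` (raw integer counts), ``SE`` (size-factor
    scaled counts) or ``SDE`` (mesenchymal-minus-epithelial difference of
    SEs). Bin k covers the half-open interval [k*bin_width, (k+1)*bin_width).
    """

    data: dict[str, np.ndarray]
    mark: str
    condition: str
    kind: str = "RE"
    bin_width: int = BIN_WIDTH

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int], mark: str, condition: str,
              kind: str = "RE", bin_width: int = BIN_WIDTH,
              dtype=np.int64) -> "BinnedTrack":
        data = {
            c: np.zeros(-(-int(size) // bin_width), dtype=dtype)
            for c, size in chrom_sizes.items()
        }
        return cls(data=data, mark=mark, condition=condition, kind=kind,
                   bin_width=bin_width)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (self.bin_width == other.bin_width
                and set(self.data) == set(other.data)
                and all(len(self.data[c]) == len(other.data[c])
                        for c in self.data))

    def copy(self, **overrides) -> "BinnedTrack":
        kw = dict(data={c: v.copy() for c, v in self.data.items()},
                  mark=self.mark, condition=self.condition, kind=self.kind,
                  bin_width=self.bin_width)
        kw.update(overrides)
        return BinnedTrack(**kw)


@dataclass(frozen=True)
class ScalePair:
    """Reciprocal median-of-ratios size factors for one E/M track pair.

    The factors are multipliers: SE = factor * RE bin-wise.
    """

    factor_E: float
    factor_M: float
    mark: str

    def __post_init__(self):
        for f in (self.factor_E, self.factor_M):
            if not np.isfinite(f) or f <= 0:
                raise ValueError(f"scale factors must be finite positive, got {f}")


def extend_tags(tags: Iterable[TagRecord], chrom_sizes: Mapping[str, int],
                length: int = 200) -> dict[str, np.ndarray]:
    """Extend each tag to ``length`` bp in its 3' direction.

    A plus-strand tag at p becomes [p, p+length); a minus-strand tag whose
    5' end is p becomes [p-length+1, p+1). Intervals are clipped to the
    chromosome. Returns per-chromosome (n, 2) arrays of half-open intervals.
    """
    if length <= 0:
        raise ValueError("extension length must be positive")
    out: dict[str, list[tuple[int, int]]] = {}
    for t in tags:
        size = chrom_sizes[t.chrom]
        if not (0 <= t.pos5 < size):
            raise ValueError(f"tag at {t.chrom}:{t.pos5} outside chromosome")
        if t.strand == "+":
            start, end = t.pos5, t.pos5 + length
        else:
            start, end = t.pos5 - length + 1, t.pos5 + 1
        start = max(start, 0)
        end = min(end, size)
        out.setdefault(t.chrom, []).append((start, end))
    return {c: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for c, v in out.items()}


def bin_counts(intervals: Mapping[str, np.ndarray],
               chrom_sizes: Mapping[str, int],
               mark: str = "", condition: str = "",
               bin_width: int = BIN_WIDTH) -> BinnedTrack:
    """Count extended tags into fixed bins; a tag increments *every* bin
    its interval overlaps, so an off-grid 200-bp tag counts in two bins."""
    track = BinnedTrack.zeros(chrom_sizes, mark, condition, kind="RE",
                              bin_width=bin_width)
    for chrom, ivs in intervals.items():
        if chrom not in track.data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        vec = track.data[chrom]
        size = chrom_sizes[chrom]
        if len(ivs) == 0:
            continue
        starts = ivs[:, 0]
        ends = ivs[:, 1]
        if starts.min() < 0 or ends.max() > size:
            raise ValueError(f"interval outside chromosome {chrom}")
        first = starts // bin_width
        last = (ends - 1) // bin_width  # inclusive
        # difference-array trick: +1 at first bin, -1 past last bin
        np.add.at(vec, first, 1)
        past = last + 1
        inb = past < len(vec)
        np.add.at(vec, past[inb], -1)
        np.cumsum(vec, out=vec)
    return track


def compute_scale_pair(re_E: BinnedTrack, re_M: BinnedTrack) -> ScalePair:
    """Median-of-ratios size factors (DESeq-style) for an E/M pair.

    Over bins where both conditions have nonzero counts, each condition's
    size factor is the median ratio of its count to the bin geometric mean;
    the returned multipliers are the reciprocals, so SE = factor * RE.
    """
    if not re_E.same_grid(re_M):
        raise ValueError("tracks are not on the same bin grid")
    e = np.concatenate([re_E.data[c] for c in sorted(re_E.data)]).astype(float)
    m = np.concatenate([re_M.data[c] for c in sorted(re_M.data)]).astype(float)
    both = (e > 0) & (m > 0)
    if not both.any():
        raise ValueError("no bin with nonzero counts in both conditions; "
                         "cannot normalize")
    ref = np.sqrt(e[both] * m[both])
    s_e = float(np.median(e[both] / ref))
    s_m = float(np.median(m[both] / ref))
    return ScalePair(factor_E=1.0 / s_e, factor_M=1.0 / s_m, mark=re_E.mark)


def apply_scale(track: BinnedTrack, factor: float) -> BinnedTrack:
    """Multiply a raw track bin-wise by its size factor, yielding an SE track."""
    out = track.copy(kind="SE")
    out.data = {c: v.astype(float) * factor for c, v in track.data.items()}
    return out


def compute_sde(se_E: BinnedTrack, se_M: BinnedTrack) -> BinnedTrack:
    """Scaled differential enrichment: SDE = MSE - ESE per bin.

    Positive bins are mesenchymal gains, negative ones losses.
    """
    if not se_E.same_grid(se_M):
        raise ValueError("tracks are not on the same bin grid")
    data = {c: se_M.data[c].astype(float) - se_E.data[c].astype(float)
            for c in se_E.data}
    return BinnedTrack(data=data, mark=se_E.mark, condition="differential",
                       kind="SDE", bin_width=se_E.bin_width)


def normalize_pair(re_E: BinnedTrack, re_M: BinnedTrack
                   ) -> tuple[BinnedTrack, BinnedTrack, BinnedTrack, ScalePair]:
    """Convenience: size factors, SE tracks and the SDE for one mark."""
    pair = compute_scale_pair(re_E, re_M)
    se_E = apply_scale(re_E, pair.factor_E)
    se_M = apply_scale(re_M, pair.factor_M)
    return se_E, se_M, compute_sde(se_E, se_M), pair
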
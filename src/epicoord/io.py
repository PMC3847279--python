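"""Readers and writers for the plain-text genomic formats used throughout.

Everything is 0-based half-open. bedGraph tracks are written one line per
run of equal-valued bins; on read they are rasterized back onto the fixed
bin grid, so write->read round-trips exactly for bin-aligned data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import BIN_WIDTH, BinnedTrack


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{int(size)}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Run-length-compressed 4-column bedGraph; zero runs are skipped."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                val = vec[s]
                if val == 0:
                    continue
                v = int(val) if float(val).is_integer() else float(val)
                fh.write(f"{chrom}\t{s * w}\t{e * w}\t{v}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int], mark: str = "",
                  condition: str = "", kind: str = "RE",
                  bin_width: int = BIN_WIDTH) -> BinnedTrack:
    dtype = np.int64 if kind == "RE" else float
    track = BinnedTrack.zeros(chrom_sizes, mark, condition, kind=kind,
                              bin_width=bin_width, dtype=dtype)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            s, e = int(start), int(end)
            if s % bin_width or e % bin_width:
                raise ValueError(f"bedGraph interval {chrom}:{s}-{e} not "
                                 f"aligned to {bin_width}-bp bins")
            val = float(value)
            if kind == "RE":
                if not val.is_integer():
                    raise ValueError("raw enrichment values must be integers")
                val = int(val)
            track.data[chrom][s // bin_width:e // bin_width] = val
    return track


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6 file from columns chrom/start/end/name/score/strand
    (missing optional columns are filled with '.' / 0 / '.')."""
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df["name"] if "name" in df else ".",
        "score": df["score"] if "score" in df else 0,
        "strand": df["strand"] if "strand" in df else ".",
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(cols)]
    df.columns = cols[: df.shape[1]]
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False,
                 columns=["gene_id", "chrom", "strand", "txStart", "txEnd"])


def read_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(terms: Mapping[str, list[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_ppi(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False,
                 columns=["geneA", "geneB", "confidence"])


def read_ppi(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
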
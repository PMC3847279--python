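"""Transcription-factor binding-site enrichment in locus clusters.

A locus (differential enhancer, or a 5,400-bp promoter window centered on
the TSS-containing bin) "hits" a factor when it has at least 1 bp of
overlap with any of the factor's sites (half-open arithmetic). Per factor
and cluster, a one-tailed (greater) Fisher exact test contrasts cluster
membership with hit status over all loci of the same kind; the heat-map
statistic is -log10 p, z-score standardized within each row (cluster)
using the population standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import BIN_WIDTH

logger = logging.getLogger(__name__)

PROMOTER_FLANK_BINS = 13   # 27 bins = 5,400 bp per promoter window


def promoter_windows(genes: pd.DataFrame,
                     chrom_sizes=None) -> pd.DataFrame:
    """5,400-bp promoter window per gene: the TSS-containing 200-bp bin
    extended by 13 bins on each side; clipped windows are flagged."""
    tss = np.where(genes["strand"] == "+", genes["txStart"],
                   genes["txEnd"] - 1)
    k = tss // BIN_WIDTH
    start = (k - PROMOTER_FLANK_BINS) * BIN_WIDTH
    end = (k + PROMOTER_FLANK_BINS + 1) * BIN_WIDTH
    clipped = start < 0
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        lim = genes["chrom"].map(chrom_sizes).to_numpy()
        clipped |= end > lim
        end = np.minimum(end, lim)
    return pd.DataFrame({
        "locus_id": genes["gene_id"], "chrom": genes["chrom"],
        "start": start.astype(int), "end": end.astype(int),
        "clipped": clipped,
    })


def _hit_vector(loci: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    """Boolean per-locus indicator of >= 1 bp overlap with any site.

    Idempotent under site duplication by construction.
    """
    hits = np.zeros(len(loci), dtype=bool)
    for chrom, sub in sites.groupby("chrom"):
        sel = loci["chrom"] == chrom
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        ends = sub["end"].to_numpy()[order]
        # prefix max of ends over sites sorted by start
        emax = np.maximum.accumulate(ends)
        ls = loci.loc[sel, "start"].to_numpy()
        le = loci.loc[sel, "end"].to_numpy()
        idx = np.searchsorted(starts, le)  # sites with start < locus end
        got = np.zeros(sel.sum(), dtype=bool)
        nz = idx > 0
        got[nz] = emax[idx[nz] - 1] > ls[nz]
        hits[np.flatnonzero(sel)] = got
    return hits


def tf_enrichment(loci: pd.DataFrame, labels: pd.Series,
                  tfbs: pd.DataFrame) -> pd.DataFrame:
    """One-tailed Fisher enrichment of each factor in each cluster.

    ``loci`` needs columns locus_id/chrom/start/end; ``labels`` maps
    locus_id to cluster id; ``tfbs`` is BED-like with the factor in
    ``name``. The universe of every test is all loci in the table.
    """
    labels = labels.reindex(loci["locus_id"]).to_numpy()
    rows = []
    clusters = sorted(pd.unique(labels[~pd.isna(labels)]))
    for factor, sites in tfbs.groupby("name"):
        if len(sites) == 0:
            continue
        hit = _hit_vector(loci, sites)
        for cl in clusters:
            inc = labels == cl
            a = int((hit & inc).sum())          # hits in cluster
            b = int((~hit & inc).sum())
            c = int((hit & ~inc).sum())
            d = int((~hit & ~inc).sum())
            p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            rows.append((factor, cl, a, a + b, c, c + d, p))
    df = pd.DataFrame(rows, columns=["factor", "cluster", "hits_in", "n_in",
                                     "hits_out", "n_out", "p"])
    for factor in set(tfbs["name"]) - set(df["factor"]):
        logger.warning("factor %s has zero sites; p set to 1", factor)
    return df


def heatmap_matrix(enrichment: pd.DataFrame, scores=None,
                   top_k: int = 10) -> pd.DataFrame:
    """Row-standardized -log10 p matrix (clusters x factors).

    With ``scores`` (ClusterScore list) rows are restricted to the
    ``top_k`` strongest gain and ``top_k`` strongest loss clusters by
    gain-loss score. Rows use the population standard deviation; a
    zero-variance row is flagged and left all-zero.
    """
    mat = enrichment.pivot(index="cluster", columns="factor", values="p")
    mat = -np.log10(mat.clip(lower=1e-300))
    if scores is not None:
        by_score = sorted(scores, key=lambda s: s.gain_loss)
        losses = [s.cluster for s in by_score if s.gain_loss <= 0][:top_k]
        gains = [s.cluster for s in by_score[::-1] if s.gain_loss > 0][:top_k]
        keep = [c for c in mat.index if c in set(gains) | set(losses)]
        mat = mat.loc[keep]
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 factors per row to standardize")
    vals = mat.to_numpy()
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population sd
    out = np.zeros_like(vals)
    nz = sd[:, 0] > 0
    out[nz] = (vals[nz] - mean[nz]) / sd[nz]
    for cl in mat.index[~nz]:
        logger.warning("cluster %s has zero variance across factors", cl)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)
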
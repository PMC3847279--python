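"""Directional term enrichment, functional similarity scores (FSS), and
the all-pairs functional correlation matrix (FCM).

Enrichment of annotation terms in a gene set is a two-sided Fisher exact
test with a fold (observed/expected) that classifies each significant term
as enriched or depleted. The FSS between two gene sets sums, over terms
significant in both and concordant in direction, -log(p_A * p_B); the E
component collects enriched-in-both terms, D depleted-in-both, FSS = E + D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

FSS_Q_THRESHOLD = 0.01


@dataclass
class FSSResult:
    pair: tuple
    E: float
    D: float
    fss: float
    enriched_terms: list = field(default_factory=list)
    depleted_terms: list = field(default_factory=list)


def enrich_terms(gene_set: Sequence[str], background: Sequence[str],
                 annotation: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-term Fisher exact enrichment of ``gene_set`` against ``background``.

    Returns a frame with columns term, hits, term_size, fold, p, q,
    direction, BH-corrected across the tested terms. Terms with no gene in
    the background are skipped.
    """
    bg = set(background)
    gs = set(gene_set)
    if not gs or not bg:
        raise ValueError("gene set and background must be non-empty")
    if not gs <= bg:
        raise ValueError("gene set must be a subset of the background")
    rows = []
    for term, genes in annotation.items():
        tset = set(genes) & bg
        if not tset:
            continue
        a = len(gs & tset)
        b = len(gs) - a
        c = len(tset) - a
        d = len(bg) - a - b - c
        p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        expected = len(tset) / len(bg)
        fold = (a / len(gs)) / expected
        rows.append((term, a, len(tset), fold, p))
    df = pd.DataFrame(rows, columns=["term", "hits", "term_size", "fold", "p"])
    if df.empty:
        df["q"] = []
        df["direction"] = []
        return df
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["direction"] = np.where(df["fold"] > 1, "enriched", "depleted")
    return df


def significant(records: pd.DataFrame,
                q_threshold: float = FSS_Q_THRESHOLD) -> pd.DataFrame:
    return records[records["q"] < q_threshold].reset_index(drop=True)


def fss(listA: pd.DataFrame, listB: pd.DataFrame,
        q_threshold: float = FSS_Q_THRESHOLD, pair=("A", "B"),
        literal_sign: bool = False) -> FSSResult:
    """Functional similarity of two thresholded enrichment lists.

    Both inputs must already be restricted to q < ``q_threshold``
    (a contract check rejects unthresholded lists). Concordant terms
    contribute -log(p_A * p_B) (natural log); with ``literal_sign`` the sum
    is left signed as +log, under which more similar pairs are more
    negative.
    """
    for df in (listA, listB):
        if len(df) and (df["q"] >= q_threshold).any():
            raise ValueError("input lists must be thresholded at "
                             f"q < {q_threshold}")
    sign = 1.0 if literal_sign else -1.0
    a = listA.set_index("term") if len(listA) else pd.DataFrame()
    b = listB.set_index("term") if len(listB) else pd.DataFrame()
    shared = (set(a.index) & set(b.index)) if len(a) and len(b) else set()
    E = D = 0.0
    c_terms, d_terms = [], []
    for t in sorted(shared):
        da, db = a.loc[t, "direction"], b.loc[t, "direction"]
        if da != db:
            continue  # discordant terms are excluded
        contrib = sign * float(np.log(a.loc[t, "p"] * b.loc[t, "p"]))
        if da == "enriched":
            E += contrib
            c_terms.append(t)
        else:
            D += contrib
            d_terms.append(t)
    return FSSResult(pair=tuple(pair), E=E, D=D, fss=E + D,
                     enriched_terms=c_terms, depleted_terms=d_terms)


def fcm(cluster_enrichments: Mapping[int, pd.DataFrame],
        q_threshold: float = FSS_Q_THRESHOLD
        ) -> tuple[pd.DataFrame, list]:
    """Functional correlation matrix over clusters.

    One row per source cluster; two columns (E, D) per target cluster in
    numeric order. Rows are ordered by Ward hierarchical clustering of the
    row vectors under the cosine metric; the ordered id list is returned
    alongside the matrix (whose rows stay in numeric order).
    """
    ids = sorted(cluster_enrichments)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    thresholded = {i: significant(cluster_enrichments[i], q_threshold)
                   for i in ids}
    cols = pd.MultiIndex.from_tuples(
        [(j, comp) for j in ids for comp in ("E", "D")],
        names=["target", "component"])
    mat = pd.DataFrame(0.0, index=pd.Index(ids, name="source"), columns=cols)
    for i in ids:
        for j in ids:
            r = fss(thresholded[i], thresholded[j], q_threshold, pair=(i, j))
            mat.loc[i, (j, "E")] = r.E
            mat.loc[i, (j, "D")] = r.D
    X = mat.to_numpy()
    if len(ids) > 2:
        d = np.nan_to_num(pdist(X, metric="cosine"), nan=1.0)
        order = [ids[k] for k in leaves_list(linkage(d, method="ward"))]
    else:
        order = list(ids)
    return mat, order
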
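"""Crisp clustering of DEP matrices and cluster-level scores.

The default engine is a batch self-organizing map on a rectangular grid
(cosine best-matching units, Gaussian neighborhood annealed over the
epochs) whose occupied map nodes are then agglomerated by single linkage
at an automatically chosen gap in the merge heights, yielding a crisp
assignment. A k-medoids engine (cosine distance, silhouette-selected k)
and direct import of an external assignment are available alternatives,
so cluster files produced by other tools can be analyzed unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .profiles import DEPMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Crisp locus -> cluster mapping; cluster ids are dense from 1."""

    labels: pd.Series
    engine: str
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster: int) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()


@dataclass
class ClusterScore:
    cluster: int
    gain_loss: float
    direction: str          # 'gain' iff gain_loss > 0, ties -> 'loss'
    n_members: int
    mean_log2fc: float | None = None


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    out = np.zeros_like(X)
    nz = norms[:, 0] > 0
    out[nz] = X[nz] / norms[nz]
    return out


def _dense_labels(raw: np.ndarray, index) -> pd.Series:
    """Relabel clusters 1..K in decreasing size (ties by first appearance)."""
    ser = pd.Series(raw, index=index)
    order = ser.value_counts(sort=True).index
    remap = {old: i + 1 for i, old in enumerate(order)}
    return ser.map(remap)


def _som_labels(X: np.ndarray, seed: int, grid=(10, 10), epochs: int = 200,
                sigma_end: float = 0.5) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n, d = X.shape
    Xu = _unit_rows(X)
    gx, gy = grid
    nodes = np.array([(i, j) for i in range(gx) for j in range(gy)], float)
    node_d2 = ((nodes[:, None, :] - nodes[None, :, :]) ** 2).sum(-1)
    code = X[rng.integers(0, n, size=gx * gy)] + rng.normal(0, 1e-3, (gx * gy, d))
    sigma0 = max(gx, gy) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 * (sigma_end / sigma0) ** frac
        cu = _unit_rows(code)
        bmu = np.argmax(Xu @ cu.T, axis=1)
        H = np.exp(-node_d2[:, bmu] / (2 * sigma * sigma))  # nodes x rows
        wsum = H.sum(axis=1, keepdims=True)
        upd = wsum[:, 0] > 1e-12
        code[upd] = (H[upd] @ X) / wsum[upd]
    cu = _unit_rows(code)
    bmu = np.argmax(Xu @ cu.T, axis=1)
    occupied = np.unique(bmu)
    if len(occupied) == 1:
        return np.zeros(n, dtype=int)
    # agglomerate occupied node codebooks by single linkage; the cut height
    # is chosen automatically as the candidate maximizing the row-level
    # mean silhouette (cosine), evaluated on a capped subsample
    occ_code = code[occupied]
    dist = np.nan_to_num(pdist(_unit_rows(occ_code), metric="cosine"), nan=1.0)
    Z = linkage(dist, method="single")
    heights = np.unique(Z[:, 2])
    if heights.max() < 1e-3:        # map collapsed to one archetype
        return np.zeros(n, dtype=int)
    cands = (heights[:-1] + heights[1:]) / 2 if len(heights) > 1 else []
    sample = np.arange(n)
    if n > 4000:
        sample = np.sort(rng.choice(n, size=4000, replace=False))
    from scipy.spatial.distance import squareform
    Ds = squareform(np.nan_to_num(pdist(Xu[sample], "cosine"), nan=1.0))
    results = []  # (silhouette, k, node_cluster)
    for thr in cands:
        node_cluster = fcluster(Z, t=thr, criterion="distance")
        node_map = dict(zip(occupied, node_cluster))
        lab = np.array([node_map[b] for b in bmu[sample]])
        k = len(np.unique(lab))
        if k < 2:
            continue
        sil = silhouette_score(Ds, lab, metric="precomputed")
        results.append((sil, k, node_cluster))
    if not results:
        return np.zeros(n, dtype=int)
    # near-ties in silhouette resolve toward the finer partition, so
    # sub-archetypes sharing support with a dominant one are not absorbed
    best_sil = max(r[0] for r in results)
    best_cluster = max((r for r in results if r[0] >= best_sil - 0.05),
                       key=lambda r: r[1])[2]
    node_map = dict(zip(occupied, best_cluster))
    return np.array([node_map[b] for b in bmu])


def _kmedoids_labels(X: np.ndarray, seed: int, k_max: int = 10,
                     n_iter: int = 50) -> np.ndarray:
    from scipy.spatial.distance import squareform
    D = squareform(np.nan_to_num(pdist(_unit_rows(X), "cosine"), nan=1.0))
    n = len(X)
    best, best_sil = None, -np.inf
    rng = np.random.default_rng(seed)
    for k in range(2, min(k_max, n - 1) + 1):
        med = rng.choice(n, size=k, replace=False)
        for _ in range(n_iter):
            lab = np.argmin(D[:, med], axis=1)
            new = np.array([
                np.flatnonzero(lab == j)[np.argmin(
                    D[np.ix_(lab == j, lab == j)].sum(axis=1))]
                if (lab == j).any() else med[j]
                for j in range(k)])
            if np.array_equal(np.sort(new), np.sort(med)):
                break
            med = new
        lab = np.argmin(D[:, med], axis=1)
        if len(np.unique(lab)) < 2:
            continue
        sil = silhouette_score(D, lab, metric="precomputed")
        if sil > best_sil:
            best, best_sil = lab, sil
    return best if best is not None else np.zeros(n, dtype=int)


def cluster_profiles(m: DEPMatrix, engine: str = "som", seed: int = 0,
                     **params) -> ClusterAssignment:
    """Cluster a scaled DEP matrix into crisp clusters.

    Engines: ``som`` (default), ``kmedoids``, or ``file`` (pass
    ``assignment=`` a Series/TSV path of external labels, e.g. real
    AutoSOME output).
    """
    if engine == "file":
        a = params["assignment"]
        if not isinstance(a, pd.Series):
            a = pd.read_csv(a, sep="\t", index_col=0).iloc[:, 0]
        a = a.reindex(m.values.index)
        if a.isna().any():
            raise ValueError("external assignment misses some loci")
        return ClusterAssignment(labels=_dense_labels(a.to_numpy(), a.index),
                                 engine="file", seed=None, params={})
    if not m.scaled:
        raise ValueError("cluster the scaled DEP matrix")
    X = m.values.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 loci to cluster")
    if engine == "som":
        raw = _som_labels(X, seed=seed, **params)
    elif engine == "kmedoids":
        raw = _kmedoids_labels(X, seed=seed, **params)
    else:
        raise ValueError(f"unknown clustering engine {engine!r}")
    return ClusterAssignment(labels=_dense_labels(raw, m.values.index),
                             engine=engine, seed=seed, params=dict(params))


def gain_loss_score(members: list[str], dep: DEPMatrix,
                    enhancer_marks, cluster: int = 0) -> ClusterScore:
    """Mean over members and enhancer-associated marks of (gain - loss)."""
    if not members:
        raise ValueError("empty cluster")
    gains = [c for c in dep.columns if c.split("|")[1] in enhancer_marks
             and c.endswith("|gain")]
    losses = [g.replace("|gain", "|loss") for g in gains]
    sub = dep.values.loc[members]
    diff = sub[gains].to_numpy() - sub[losses].to_numpy()
    score = float(diff.mean())
    return ClusterScore(cluster=cluster, gain_loss=score,
                        direction="gain" if score > 0 else "loss",
                        n_members=len(members))


def score_clusters(assignment: ClusterAssignment, dep: DEPMatrix,
                   enhancer_marks) -> list[ClusterScore]:
    return [gain_loss_score(assignment.members(c), dep, enhancer_marks,
                            cluster=c)
            for c in sorted(assignment.labels.unique())]


def probe_to_gene(probes: pd.DataFrame) -> pd.Series:
    """Representative per-gene log2fc: the probe with maximal |log2fc|.

    A tie between +x and -x resolves to the positive value. Genes without
    probes are simply absent. ``probes`` needs columns gene_id, log2fc.
    """
    df = probes[["gene_id", "log2fc"]].copy()
    # sort so the winner (largest |fc|, positive first on ties) comes first
    df["absfc"] = df["log2fc"].abs()
    df = df.sort_values(["absfc", "log2fc"], ascending=[False, False],
                        kind="stable")
    rep = df.drop_duplicates("gene_id").set_index("gene_id")["log2fc"]
    return rep.sort_index()


def genes_of_cluster(assignment: ClusterAssignment, cluster: int,
                     loci) -> list[str]:
    """Union of genes assigned (via cis-regions) to a cluster's enhancers."""
    member_ids = set(assignment.members(cluster))
    out: set = set()
    for loc in loci:
        if loc.locus_id in member_ids:
            out.update(loc.genes)
    return sorted(out)


def correlate_score_expression(scores: list[ClusterScore],
                               assignment: ClusterAssignment,
                               loci, gene_log2fc: pd.Series) -> float:
    """Pearson r between cluster gain-loss scores and the mean log2fc of
    genes linked to each cluster through its enhancers."""
    xs, ys = [], []
    for sc in scores:
        genes = [g for g in genes_of_cluster(assignment, sc.cluster, loci)
                 if g in gene_log2fc.index]
        if not genes:
            logger.info("cluster %d has no assigned genes; excluded", sc.cluster)
            continue
        sc.mean_log2fc = float(gene_log2fc.loc[genes].mean())
        xs.append(sc.gain_loss)
        ys.append(sc.mean_log2fc)
    if len(xs) < 3:
        raise ValueError("need at least 3 clusters with assigned genes")
    return float(stats.pearsonr(xs, ys)[0])


def expression_percentiles(cluster_genes: list[str],
                           gene_log2fc: pd.Series) -> dict[str, float]:
    """Quartiles of the cluster genes' percentile ranks of log2fc within
    the full gene universe (a 1-gene universe ranks 100 by convention)."""
    if gene_log2fc.empty:
        raise ValueError("empty gene universe")
    ranks = pd.Series(stats.rankdata(gene_log2fc.to_numpy()),
                      index=gene_log2fc.index) / len(gene_log2fc) * 100.0
    member = ranks.loc[[g for g in cluster_genes if g in ranks.index]]
    if member.empty:
        return {"q25": np.nan, "median": np.nan, "q75": np.nan, "n": 0}
    return {"q25": float(member.quantile(0.25)),
            "median": float(member.quantile(0.5)),
            "q75": float(member.quantile(0.75)),
            "n": int(len(member))}
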
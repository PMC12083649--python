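"""Perturbation-signature analysis of spot-resolved CRISPR screens.

The downstream model follows the Mixscape idea adapted to spatial spots:

1. every spot's expression is compared to the mean of its *k* nearest
   non-perturbed (NP) neighbours in PC space, giving a perturbation
   signature that cancels local, perturbation-independent variation
   (tissue region, cell-type composition);
2. for each target gene ``t`` a differential vector ``v_t`` (mean signature
   of t-spots minus mean NP signature, restricted to the strongest genes)
   defines a perturbation score: the projection of a spot's signature onto
   ``v_t``;
3. scores are scaled so that the fixed +-0.2 classification thresholds are
   meaningful: raw projections are divided by the 95th percentile of their
   absolute value over the t-spots and NP spots.  A spot is *perturbed*
   when its own-target score exceeds 0.2 and *NP-like* below -0.2,
   otherwise unresolved (possible escapee).  The scaling convention is this
   package's own reconstruction (the thresholds are fixed upstream, the
   scaling is not published) and is configurable.
4. the spot x target score matrix is embedded and clustered like gene
   expression ("pUMAP"); a cluster is labelled by every perturbation
   exceeding 20% of its spots, or "NP + n" when none does (n = number of
   distinct perturbations detected in the cluster).

Clustering everywhere is Seurat-style: PCA, shared-nearest-neighbour (SNN)
graph with Jaccard weights, Leiden modularity optimisation over a grid of
resolutions, and data-driven resolution selection using average silhouette
width (partitions with more than 3 clusters preferred) with total
within-cluster sum of squares breaking ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from anndata import AnnData
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "normalize_expression",
    "ReductionResult",
    "reduce_and_cluster",
    "calc_signature",
    "PerturbationScoreAssay",
    "calc_scores",
    "PerturbClusterLabels",
    "pumap_cluster",
    "spot_status",
]

NP_LABEL = "NP"
EXCLUDE_LABEL = "exclude"


def normalize_expression(adata: AnnData, target_sum: float = 1e4,
                         clip: float = 10.0) -> AnnData:
    """Library-size normalisation and per-gene scaling.

    Adds two layers to (a copy of) ``adata``:

    * ``lognorm`` = ln(1 + target_sum * c / libsize)  (log-CPM at 1e4);
    * ``scaled``  = per-gene z-score of lognorm, clipped at +-clip.

    Spots with zero total counts are dropped with a warning.  Raw counts
    stay in ``X``.
    """
    X = np.asarray(
        adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X, dtype=float
    )
    lib = X.sum(axis=1)
    keep = lib > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} spots with zero total counts")
        adata = adata[keep].copy()
        X = X[keep]
        lib = lib[keep]
    else:
        adata = adata.copy()
    lognorm = np.log1p(target_sum * X / lib[:, None])
    mu = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = np.clip((lognorm - mu) / sd, -clip, clip)
    adata.layers["lognorm"] = lognorm
    adata.layers["scaled"] = scaled
    return adata


# ---------------------------------------------------------------------------
# clustering


def _snn_graph(pcs: np.ndarray, k: int, prune: float = 1 / 15) -> ig.Graph:
    """Seurat-style SNN graph: Jaccard overlap of k-NN sets, pruned."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(pcs)
    idx = nn.kneighbors(return_distance=False)
    sets = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(n):
        cand = set()
        for j in sets[i]:
            cand.update(sets[j])
        for j in cand:
            if j <= i:
                continue
            inter = len(sets[i] & sets[j])
            if inter == 0:
                continue
            w = inter / len(sets[i] | sets[j])
            if w >= prune:
                edges.append((i, j))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def _wss(pcs: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for c in np.unique(labels):
        sub = pcs[labels == c]
        tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot


@dataclass
class ReductionResult:
    pcs: np.ndarray
    n_pcs: int
    umap: np.ndarray | None
    labels: np.ndarray  # cluster id per row at the chosen resolution
    resolution: float
    diagnostics: pd.DataFrame  # per resolution: n_clusters, wss, silhouette
    all_labels: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def reduce_and_cluster(
    X: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 20,
    resolutions=tuple(np.round(np.arange(0.2, 1.61, 0.2), 2)),
    min_dist: float = 0.01,
    n_pcs: int | None = None,
    var_frac: float = 0.80,
    compute_umap: bool = True,
) -> ReductionResult:
    """PCA -> SNN graph -> Leiden over a resolution grid -> selection.

    The number of PCs defaults to the smallest count explaining
    ``var_frac`` of the variance captured by the top 50 components (a
    formalised elbow).  The resolution is chosen by maximal average
    silhouette width among partitions with more than 3 clusters (falling
    back to all multi-cluster partitions when none qualifies); total
    within-cluster sum of squares breaks silhouette ties.  Deterministic
    for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} rows, got {n}")
    n_comp = min(50, n - 1, p)
    pca = PCA(n_components=n_comp, random_state=seed)
    pcs_full = pca.fit_transform(X)
    if n_pcs is None:
        frac = np.cumsum(pca.explained_variance_ratio_)
        frac = frac / frac[-1]
        n_pcs = int(np.searchsorted(frac, var_frac) + 1)
    n_pcs = min(n_pcs, n_comp)
    pcs = pcs_full[:, :n_pcs]

    graph = _snn_graph(pcs, n_neighbors)
    rows = []
    all_labels: dict[float, np.ndarray] = {}
    for res in resolutions:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=float(res),
            seed=int(seed),
        )
        labels = np.asarray(part.membership)
        k = len(np.unique(labels))
        sil = (
            silhouette_score(pcs, labels) if 1 < k < n else np.nan
        )
        rows.append(
            {"resolution": float(res), "n_clusters": k,
             "wss": _wss(pcs, labels), "silhouette": sil}
        )
        all_labels[float(res)] = labels
    diag = pd.DataFrame(rows)

    cand = diag[diag["n_clusters"] > 3]
    if cand.empty:
        cand = diag[diag["n_clusters"] > 1]
    if cand.empty:
        cand = diag
    cand = cand.sort_values(
        ["silhouette", "wss", "resolution"], ascending=[False, True, True]
    )
    best = cand.iloc[0]
    chosen = float(best["resolution"])

    umap_xy = None
    if compute_umap:
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            umap_xy = umap.UMAP(
                n_neighbors=min(n_neighbors, n - 1),
                min_dist=min_dist,
                random_state=seed,
            ).fit_transform(pcs)
    return ReductionResult(
        pcs=pcs, n_pcs=n_pcs, umap=umap_xy, labels=all_labels[chosen],
        resolution=chosen, diagnostics=diag, all_labels=all_labels,
    )


# ---------------------------------------------------------------------------
# perturbation status, signatures, scores


def spot_status(assignment: pd.DataFrame, lib, areas: pd.Series,
                area_min: int = 4) -> pd.Series:
    """Map spot assignment labels to a perturbation status per spot.

    Returns a Series aligned with ``assignment`` whose values are a target
    gene symbol (candidate perturbed spot), ``"NP"`` (non-perturbed pool:
    spots with no sgRNA, or assigned to a non-targeting control), or
    ``"exclude"`` (ambiguous / assigned to an sgRNA below the area filter /
    non-tissue).  Only sgRNAs detected with area >= ``area_min`` spots count
    as perturbations.
    """
    target = dict(zip(lib.names, lib.targets))
    ntc = dict(zip(lib.names, lib.is_ntc))
    eligible = {g for g, a in areas.items() if a >= area_min}
    out = []
    for _, row in assignment.iterrows():
        lab, sg = row["label"], row["sgrna"]
        if lab == "non_perturbed":
            out.append(NP_LABEL)
        elif sg is not None and ntc.get(sg, False):
            out.append(NP_LABEL)
        elif sg is not None and sg in eligible:
            out.append(target[sg])
        else:
            out.append(EXCLUDE_LABEL)
    return pd.Series(out, index=assignment.index, name="status")


def calc_signature(
    adata: AnnData,
    status: pd.Series | np.ndarray,
    k: int = 20,
    pcs: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
    layer: str = "lognorm",
) -> np.ndarray:
    """Local-neighbour perturbation signature for every spot.

    signature(spot) = lognorm(spot) - mean lognorm of its ``k`` nearest
    NP spots in PC space.  When expression ``clusters`` are given the
    neighbour search is restricted to the spot's own cluster whenever that
    cluster holds at least ``k`` NP spots (otherwise the global NP pool is
    used) -- perturbation effects are then measured against transcriptomic
    context rather than the whole section.  The spot itself is excluded
    from its neighbour set.
    """
    status = np.asarray(status)
    expr = np.asarray(adata.layers[layer], dtype=float)
    n = expr.shape[0]
    if len(status) != n:
        raise ValueError("status length != number of spots")
    np_mask = status == NP_LABEL
    if not np_mask.any():
        raise ValueError("no non-perturbed spots")
    if pcs is None:
        n_comp = min(30, n - 1, expr.shape[1])
        pcs = PCA(n_components=n_comp, random_state=0).fit_transform(
            np.asarray(adata.layers["scaled"], dtype=float)
            if "scaled" in adata.layers else expr
        )

    sig = np.empty_like(expr)

    def fill(rows: np.ndarray, pool: np.ndarray) -> None:
        kk = min(k, len(pool) - 1) if np.isin(rows, pool).any() else min(k, len(pool))
        kk = max(kk, 1)
        nn = NearestNeighbors(n_neighbors=min(kk + 1, len(pool))).fit(pcs[pool])
        _, nbr = nn.kneighbors(pcs[rows])
        pool_set = {int(p): j for j, p in enumerate(pool)}
        for r, nb in zip(rows, nbr):
            cand = [int(pool[j]) for j in nb if int(pool[j]) != int(r)]
            cand = cand[:kk]
            sig[r] = expr[r] - expr[cand].mean(axis=0)

    all_rows = np.arange(n)
    np_rows = all_rows[np_mask]
    if clusters is not None:
        clusters = np.asarray(clusters)
        done = np.zeros(n, dtype=bool)
        for c in np.unique(clusters):
            rows = all_rows[clusters == c]
            pool = rows[np_mask[rows]]
            if len(pool) >= k:
                fill(rows, pool)
                done[rows] = True
        rest = all_rows[~done]
        if len(rest):
            fill(rest, np_rows)
    else:
        fill(all_rows, np_rows)
    return sig


@dataclass
class PerturbationScoreAssay:
    """Spot x target matrix of scaled perturbation scores plus classes."""

    scores: pd.DataFrame  # rows = spots (aligned with status), cols = targets
    classes: pd.Series  # "perturbed" | "NP" | "unresolved" | "excluded"
    status: pd.Series
    score_hi: float = 0.2
    score_lo: float = -0.2

    @property
    def targets(self) -> list[str]:
        return list(self.scores.columns)

    def classified_mask(self) -> np.ndarray:
        return np.isin(self.classes.to_numpy(), ("perturbed", "NP"))


def calc_scores(
    signature: np.ndarray,
    status: pd.Series,
    top_m: int = 100,
    scale_percentile: float = 95.0,
    score_hi: float = 0.2,
    score_lo: float = -0.2,
    min_spots: int = 3,
) -> PerturbationScoreAssay:
    """Per-target perturbation scores and the +-0.2 classification.

    For target ``t``: v_t = mean signature of t-spots - mean signature of
    NP spots, restricted to the ``top_m`` genes by |v_t|; the raw score of
    spot i is <sig_i, v_t> / ||v_t||; scaled scores divide by the
    ``scale_percentile`` percentile of |raw| over t-spots and NP spots.
    Targets with fewer than ``min_spots`` spots get NaN scores and a warning.
    """
    status = pd.Series(np.asarray(status), index=getattr(status, "index", None))
    st = status.to_numpy()
    np_mask = st == NP_LABEL
    target_names = sorted(
        t for t in pd.unique(st) if t not in (NP_LABEL, EXCLUDE_LABEL)
    )
    n = signature.shape[0]
    cols = {}
    for t in target_names:
        t_mask = st == t
        if t_mask.sum() < min_spots:
            warnings.warn(f"target {t!r} has <{min_spots} spots; scores set to NaN")
            cols[t] = np.full(n, np.nan)
            continue
        v = signature[t_mask].mean(axis=0) - signature[np_mask].mean(axis=0)
        idx = np.argsort(-np.abs(v))[: min(top_m, len(v))]
        vs = v[idx]
        norm = np.linalg.norm(vs)
        if norm == 0:
            cols[t] = np.zeros(n)
            continue
        raw = signature[:, idx] @ (vs / norm)
        # centre between the two populations (perturbed end up positive,
        # NP negative, as the two-sided +-0.2 filter presumes), then scale
        # so typical magnitudes lie in ~[-1, 1]
        raw = raw - 0.5 * (raw[t_mask].mean() + raw[np_mask].mean())
        ref = np.abs(raw[t_mask | np_mask])
        scale = np.percentile(ref, scale_percentile)
        cols[t] = raw / scale if scale > 0 else raw
    scores = pd.DataFrame(cols, index=status.index, columns=target_names)

    classes = []
    for i, s in enumerate(st):
        if s == NP_LABEL:
            classes.append("NP")
        elif s == EXCLUDE_LABEL:
            classes.append("excluded")
        elif s in scores.columns and not np.isnan(scores.iloc[i][s]):
            val = scores.iloc[i][s]
            classes.append(
                "perturbed" if val > score_hi
                else ("NP" if val < score_lo else "unresolved")
            )
        else:
            classes.append("excluded")
    return PerturbationScoreAssay(
        scores=scores,
        classes=pd.Series(classes, index=status.index, name="class"),
        status=status, score_hi=score_hi, score_lo=score_lo,
    )


def label_clusters(cluster_ids: np.ndarray, classes: np.ndarray,
                   status: np.ndarray, targets, major_frac: float = 0.2
                   ) -> tuple[dict[int, str], dict[int, list[str]]]:
    """Label perturbation clusters by their major perturbations.

    A target is *major* in a cluster iff its perturbed spots are strictly
    more than ``major_frac`` of the cluster's spots.  Clusters without a
    major perturbation are labelled ``"NP + n"``, n = number of distinct
    perturbations detected (perturbed spots) in the cluster.
    """
    labels: dict[int, str] = {}
    majors: dict[int, list[str]] = {}
    for c in np.unique(cluster_ids):
        member = cluster_ids == c
        size = int(member.sum())
        perturbed = member & (classes == "perturbed")
        major = sorted(
            t for t in targets
            if int((perturbed & (status == t)).sum()) / size > major_frac
        )
        majors[int(c)] = major
        if major:
            labels[int(c)] = ", ".join(major)
        else:
            labels[int(c)] = f"NP + {len(set(status[perturbed]))}"
    return labels, majors


@dataclass
class PerturbClusterLabels:
    """Clusters of the perturbation-score embedding with their labels."""

    spot_rows: np.ndarray  # row indices (into the assay) that were clustered
    clusters: np.ndarray  # cluster id per clustered spot
    labels: dict[int, str]  # cluster id -> "tA, tB" or "NP + n"
    majors: dict[int, list[str]]
    reduction: ReductionResult


def pumap_cluster(
    assay: PerturbationScoreAssay,
    seed: int = 0,
    major_frac: float = 0.2,
    n_neighbors: int = 20,
    compute_umap: bool = True,
    **cluster_kw,
) -> PerturbClusterLabels:
    """Cluster classified spots by their perturbation-score profiles.

    Restricted to perturbed and NP spots; the score matrix is column
    z-scored, then embedded and clustered exactly like gene expression.
    Each cluster is labelled with every perturbation whose perturbed spots
    are strictly more than ``major_frac`` of the cluster; clusters without
    a major perturbation get "NP + n", n = number of distinct perturbations
    detected in the cluster.
    """
    if len(assay.targets) < 2:
        raise ValueError("pUMAP needs at least 2 perturbation targets")
    mask = assay.classified_mask()
    rows = np.flatnonzero(mask)
    X = assay.scores.to_numpy()[rows]
    X = np.nan_to_num(X, nan=0.0)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    rr = reduce_and_cluster(
        (X - mu) / sd, seed=seed, n_neighbors=n_neighbors,
        compute_umap=compute_umap, **cluster_kw,
    )
    classes = assay.classes.to_numpy()[rows]
    status = assay.status.to_numpy()[rows]
    labels, majors = label_clusters(rr.labels, classes, status, assay.targets,
                                    major_frac)
    return PerturbClusterLabels(
        spot_rows=rows, clusters=rr.labels, labels=labels, majors=majors,
        reduction=rr,
    )
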
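"""Differential expression and enrichment statistics for spot clusters.

Implements the screen's downstream statistics: per-gene Wilcoxon rank-sum
tests between spot groups (with a pseudobulk "pseudo-replicate" variant),
the published filter presets, preranked gene-set enrichment with a weighted
Kolmogorov-Smirnov running sum (weight exponent 0.1, set sizes 2..500,
ambiguous pathway names removed), tRNA isotype aggregation, and
miRNA-target rank correlation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_de",
    "pseudo_replicate_de",
    "de_filter",
    "gsea_preranked",
    "GeneSetResult",
    "trna_isotype_aggregate",
    "mirna_target_correlation",
    "AMBIGUOUS_PATHWAYS",
]

#: Pathway names removed from enrichment output as too generic to interpret.
AMBIGUOUS_PATHWAYS = ("Translation", "Transcription", "Gene Expression")

_EXACT_MAX_N = 12  # total group size up to which the exact permutation p is used


def _lognorm_matrix(adata, layer: str = "lognorm") -> np.ndarray:
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run normalize_expression first")
    return np.asarray(adata.layers[layer], dtype=float)


def _mwu_asymptotic(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided tie-corrected Mann-Whitney per column; constant columns p=1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided",
                                 method="asymptotic")
    U, p = np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    const = np.array([
        len(np.unique(np.concatenate([A[:, j], B[:, j]]))) == 1
        for j in range(A.shape[1])
    ])
    p = np.where(const | np.isnan(p), 1.0, p)
    return U, p


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact permutation two-sided p of the U statistic (ties allowed)."""
    def stat(x, y):
        return stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").statistic

    if len(np.unique(np.concatenate([a, b]))) == 1:
        return len(a) * len(b) / 2, 1.0
    res = stats.permutation_test(
        (a, b), stat, permutation_type="independent",
        alternative="two-sided", n_resamples=np.inf,
    )
    return float(stat(a, b)), float(res.pvalue)


def _de_frame(adata, A: np.ndarray, B: np.ndarray, rowsA, rowsB,
              eps: float = 1e-9) -> pd.DataFrame:
    ln = _lognorm_matrix(adata)
    raw = np.asarray(
        adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X
    )
    meanA = np.expm1(ln[rowsA]).mean(axis=0)
    meanB = np.expm1(ln[rowsB]).mean(axis=0)
    lfc = np.log2((meanA + eps) / (meanB + eps))
    detA = (raw[rowsA] >= 1).mean(axis=0)
    detB = (raw[rowsB] >= 1).mean(axis=0)
    return pd.DataFrame(
        {"log2fc": lfc, "det_a": detA, "det_b": detB},
        index=list(adata.var_names),
    )


def wilcoxon_de(adata, group_a, group_b, layer: str = "lognorm") -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two spot groups.

    ``group_a`` / ``group_b`` are row indices into ``adata``.  Returns a
    DataFrame indexed by gene with ``log2fc`` (on expm1 of lognorm means,
    pseudocount 1e-9), ``u``, ``p``, ``padj`` (Benjamini-Hochberg across
    all genes), and detection fractions (share of spots with raw count
    >= 1) per group.  Groups small enough for complete enumeration (total
    <= 12 spots) get the exact permutation p; larger groups use the
    tie-corrected normal approximation.
    """
    rowsA = np.asarray(group_a, dtype=int)
    rowsB = np.asarray(group_b, dtype=int)
    if len(rowsA) == 0 or len(rowsB) == 0:
        raise ValueError("empty group")
    ln = _lognorm_matrix(adata, layer)
    A, B = ln[rowsA], ln[rowsB]
    if len(rowsA) + len(rowsB) <= _EXACT_MAX_N:
        out = [_mwu_exact(A[:, j], B[:, j]) for j in range(A.shape[1])]
        U = np.array([u for u, _ in out])
        p = np.array([q for _, q in out])
    else:
        U, p = _mwu_asymptotic(A, B)
    df = _de_frame(adata, A, B, rowsA, rowsB)
    df["u"] = U
    df["p"] = p
    df["padj"] = multipletests(p, method="fdr_bh")[1]
    return df[["log2fc", "u", "p", "padj", "det_a", "det_b"]]


def pseudo_replicate_de(adata, group_a, group_b, r: int = 3, seed: int = 0,
                        min_spots_per_rep: int = 5,
                        layer: str = "lognorm") -> pd.DataFrame:
    """Pseudobulk DE: random spot partitions stand in for replicates.

    Each group is split (seeded, uniformly) into ``r`` pseudo-replicates;
    per-gene means of the lognorm layer per replicate are compared by the
    exact Wilcoxon rank-sum (r vs r).  When either group cannot supply
    ``r`` replicates of at least ``min_spots_per_rep`` spots the function
    falls back to spot-level :func:`wilcoxon_de` and flags it in
    ``df.attrs["fallback"]``.
    """
    rowsA = np.asarray(group_a, dtype=int)
    rowsB = np.asarray(group_b, dtype=int)
    if r < 3:
        raise ValueError("need r >= 3 pseudo-replicates")
    if len(rowsA) < r * min_spots_per_rep or len(rowsB) < r * min_spots_per_rep:
        warnings.warn("groups too small for pseudo-replicates; "
                      "falling back to spot-level Wilcoxon")
        out = wilcoxon_de(adata, rowsA, rowsB, layer=layer)
        out.attrs["fallback"] = True
        return out
    rng = np.random.default_rng(seed)
    ln = _lognorm_matrix(adata, layer)

    def pseudobulk(rows: np.ndarray) -> np.ndarray:
        perm = rng.permutation(rows)
        return np.stack([chunk.mean(axis=0)
                         for chunk in np.array_split(ln[perm], r)])

    A, B = pseudobulk(rowsA), pseudobulk(rowsB)
    out = [_mwu_exact(A[:, j], B[:, j]) for j in range(A.shape[1])]
    df = _de_frame(adata, A, B, rowsA, rowsB)
    df["u"] = np.array([u for u, _ in out])
    df["p"] = np.array([q for _, q in out])
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df[["log2fc", "u", "p", "padj", "det_a", "det_b"]]
    df.attrs["fallback"] = False
    return df


def de_filter(res: pd.DataFrame, mode: str, padj_max: float = 0.05,
              det_min: float = 0.20, lfc_min: float = 1.0,
              det_diff_min: float = 0.25, signed_det_diff: bool = False
              ) -> list[str]:
    """Published DE gene filters.

    ``cluster_markers``: padj < 0.05 and detected in > 20% of the cluster
    (group A).  ``heatmap``: padj < 0.05, |log2FC| > 1, and detection
    difference between groups > 25% (absolute by default; set
    ``signed_det_diff`` for the one-directional reading).
    """
    if mode == "cluster_markers":
        keep = (res["padj"] < padj_max) & (res["det_a"] > det_min)
    elif mode == "heatmap":
        diff = res["det_a"] - res["det_b"]
        if not signed_det_diff:
            diff = diff.abs()
        keep = (
            (res["padj"] < padj_max)
            & (res["log2fc"].abs() > lfc_min)
            & (diff > det_diff_min)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return list(res.index[keep])


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class GeneSetResult:
    name: str
    es: float
    nes: float
    p: float
    size: int
    leading_edge: list[str]


def _running_es(order: np.ndarray, weights: np.ndarray,
                member: np.ndarray) -> tuple[float, int]:
    """Weighted KS enrichment score and the position of its extremum.

    ``order``: gene indices sorted by decreasing rank metric; ``weights``:
    |metric|^gseaParam per gene; ``member``: boolean set membership per gene.
    """
    m = member[order]
    w = weights[order]
    nr = w[m].sum()
    n_miss = (~m).sum()
    hit = np.where(m, w, 0.0)
    hit = np.cumsum(hit) / (nr if nr > 0 else 1.0)
    miss = np.cumsum(np.where(m, 0.0, 1.0)) / (n_miss if n_miss > 0 else 1.0)
    dev = hit - miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), i


def gsea_preranked(
    ranks: pd.Series,
    sets: dict[str, list[str]],
    gsea_param: float = 0.1,
    min_size: int = 2,
    max_size: int = 500,
    n_perm: int = 10_000,
    seed: int = 0,
    exclude: tuple[str, ...] = AMBIGUOUS_PATHWAYS,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with a weighted running sum.

    ``ranks`` maps gene -> rank metric (the pipeline feeds log2 fold-changes
    of genes at adjusted p < 0.2).  Per set the enrichment score is the
    signed extremum of the weighted Kolmogorov-Smirnov running sum with
    hit weight |metric|^``gsea_param``; p-values come from ``n_perm``
    seeded gene-label permutations (random same-size sets), compared to
    null scores of the same sign; NES divides ES by the mean |null ES| of
    that sign.  Sets are filtered to [min_size, max_size] genes present in
    the ranking; names in ``exclude`` are removed (exact, case-sensitive).
    """
    ranks = ranks.astype(float).dropna()
    genes = np.asarray(ranks.index)
    metric = ranks.to_numpy()
    order = np.argsort(-metric, kind="stable")
    weights = np.abs(metric) ** gsea_param
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets.items():
        if name in exclude:
            continue
        idx = np.array([gene_pos[g] for g in set(members) if g in gene_pos],
                       dtype=int)
        if not (min_size <= len(idx) <= max_size):
            continue
        member = np.zeros(len(genes), dtype=bool)
        member[idx] = True
        es, peak = _running_es(order, weights, member)
        ordered_member = member[order]
        if es >= 0:
            le = [genes[order[i]] for i in range(peak + 1) if ordered_member[i]]
        else:
            le = [genes[order[i]] for i in range(peak, len(genes))
                  if ordered_member[i]]
        null = np.empty(n_perm)
        for b in range(n_perm):
            rand = np.zeros(len(genes), dtype=bool)
            rand[rng.choice(len(genes), size=len(idx), replace=False)] = True
            null[b], _ = _running_es(order, weights, rand)
        same = null[null >= 0] if es >= 0 else null[null <= 0]
        if es >= 0:
            p = (1 + (same >= es).sum()) / (1 + len(same))
        else:
            p = (1 + (same <= es).sum()) / (1 + len(same))
        denom = np.abs(same).mean() if len(same) else np.nan
        rows.append(
            {"pathway": name, "es": es, "nes": es / denom if denom else np.nan,
             "p": p, "size": int(len(idx)), "leading_edge": le}
        )
    if not rows:
        warnings.warn("no gene sets survive the size filter")
        return pd.DataFrame(
            columns=["pathway", "es", "nes", "p", "padj", "size", "leading_edge"]
        )
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df[["pathway", "es", "nes", "p", "padj", "size", "leading_edge"]]


# ---------------------------------------------------------------------------
# tRNA isotypes and miRNA-target correlation

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val"
).split()
#: 20 canonical amino acids plus initiator Met and selenocysteine bucket.
ISOTYPES = tuple(_AA3) + ("iMet", "SeC")

_ISO_RE = re.compile(
    r"(?:^|[-_])(" + "|".join(list(_AA3) + ["iMet", "SeC", "Sec"]) + r")(?:[-_]|$)"
)


def trna_isotype_aggregate(adata, feature_class: str = "tRNA",
                           class_key: str = "feature_class") -> pd.DataFrame:
    """Sum tRNA gene counts per amino-acid isotype, per spot.

    tRNA features are recognised by ``adata.var[class_key] == feature_class``
    and parsed for an isotype token (e.g. ``tRNA-His-GTG-1`` -> His).
    Unparseable features are collected under ``unknown`` with a warning.
    Column sums conserve total tRNA counts per spot.
    """
    raw = np.asarray(
        adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X
    )
    is_trna = np.asarray(adata.var[class_key] == feature_class)
    out = pd.DataFrame(
        0.0, index=list(adata.obs_names), columns=list(ISOTYPES) + ["unknown"]
    )
    unknown = []
    for j in np.flatnonzero(is_trna):
        name = str(adata.var_names[j])
        m = _ISO_RE.search(name)
        iso = m.group(1) if m else None
        if iso == "Sec":
            iso = "SeC"
        if iso is None:
            unknown.append(name)
            iso = "unknown"
        out[iso] += raw[:, j]
    if unknown:
        warnings.warn(f"{len(unknown)} tRNA features without an isotype token: "
                      f"{unknown[:5]}...")
    return out


def mirna_target_correlation(adata, mirna: str, targets,
                             layer: str = "lognorm",
                             min_nonzero: int = 10) -> pd.DataFrame:
    """Spearman correlation between one miRNA and candidate target mRNAs.

    Computed across spots on the lognorm layer; negative rho flags
    candidate repression.  Constant vectors yield NA.  Target lists come
    from the user (prediction databases are out of scope here).
    """
    ln = _lognorm_matrix(adata, layer)
    var_idx = {g: j for j, g in enumerate(adata.var_names)}
    if mirna not in var_idx:
        raise KeyError(f"miRNA {mirna!r} not in the matrix")
    mi = ln[:, var_idx[mirna]]
    if (mi > 0).sum() < min_nonzero:
        raise ValueError(
            f"miRNA {mirna!r} detected in fewer than {min_nonzero} spots"
        )
    rows = []
    for g in targets:
        if g not in var_idx:
            rows.append({"target": g, "rho": np.nan, "p": np.nan})
            continue
        tv = ln[:, var_idx[g]]
        if np.all(tv == tv[0]) or np.all(mi == mi[0]):
            rows.append({"target": g, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(mi, tv)
        rows.append({"target": g, "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows).set_index("target")
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df
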
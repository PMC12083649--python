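"""Spot-level sgRNA quantification and spatial statistics.

Builds the sparse spot x sgRNA UMI-count matrix on the deterministic
(A-index, B-index) grid, labels each spot by the screen's assignment rule,
and derives sgRNA area, regional perturbation burden, and sgRNA-pair
colocalization.

Assignment rule (verbatim from the screen analysis): a spot with no
detected sgRNA is non-perturbed; with exactly one it is uniquely assigned;
with several it is *resolved* to the top sgRNA iff that sgRNA has >= 10
UMIs and every other detected sgRNA has exactly 1, otherwise *ambiguous*.
A tie for the top count is ambiguous (the rule names a single top sgRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SpotSgrnaMatrix",
    "RegionMask",
    "build_matrix",
    "assign_spots",
    "sgrna_area",
    "perturbation_burden",
    "colocalization",
]


@dataclass
class RegionMask:
    """A named set of 1-based (x, y) spot coordinates (e.g. one tumor region)."""

    name: str
    spots: frozenset
    pitch_um: float | None = None

    def __post_init__(self) -> None:
        self.spots = frozenset(tuple(map(int, s)) for s in self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def physical_area_um2(self) -> float | None:
        return None if self.pitch_um is None else len(self.spots) * self.pitch_um ** 2


@dataclass
class SpotSgrnaMatrix:
    """Sparse spot x sgRNA UMI-count matrix.

    Spots are ordered row-major by (x, y), both 1-based: the flat index of
    spot (x, y) is ``(x - 1) * n_b + (y - 1)``.  ``tissue`` optionally marks
    spots under tissue; None means unknown (all spots considered).
    """

    grid_dims: tuple[int, int]  # (n_a, n_b)
    counts: sparse.csr_matrix  # (n_a * n_b) x n_sgrna
    sgrnas: tuple[str, ...]
    tissue: frozenset | None = None
    pitch_um: float = 50.0

    def __post_init__(self) -> None:
        na, nb = self.grid_dims
        if self.counts.shape != (na * nb, len(self.sgrnas)):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({na * nb}, {len(self.sgrnas)})"
            )

    def spot_index(self, x: int, y: int) -> int:
        na, nb = self.grid_dims
        if not (1 <= x <= na and 1 <= y <= nb):
            raise ValueError(f"spot ({x}, {y}) outside {na}x{nb} grid")
        return (x - 1) * nb + (y - 1)

    def spot_coord(self, idx: int) -> tuple[int, int]:
        nb = self.grid_dims[1]
        return idx // nb + 1, idx % nb + 1

    def sgrna_index(self, name: str) -> int:
        try:
            return self.sgrnas.index(name)
        except ValueError:
            raise KeyError(f"unknown sgRNA {name!r}") from None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def spot_coords(self) -> pd.DataFrame:
        na, nb = self.grid_dims
        xs, ys = np.divmod(np.arange(na * nb), nb)
        return pd.DataFrame({"x": xs + 1, "y": ys + 1})


def build_matrix(triples, grid_dims: tuple[int, int],
                 sgrnas, tissue=None, pitch_um: float = 50.0) -> SpotSgrnaMatrix:
    """Collapse deduplicated ((x, y), sgRNA, UMI) triples to UMI counts.

    The matrix total equals the number of input triples exactly; spots with
    no counts are retained implicitly as zero rows.
    """
    sgrnas = tuple(sgrnas)
    na, nb = grid_dims
    col = {g: j for j, g in enumerate(sgrnas)}
    rows, cols = [], []
    for (x, y), sg, _umi in triples:
        if sg not in col:
            raise ValueError(f"triple references unknown sgRNA {sg!r}")
        if not (1 <= x <= na and 1 <= y <= nb):
            raise ValueError(f"triple spot ({x}, {y}) outside {na}x{nb} grid")
        rows.append((x - 1) * nb + (y - 1))
        cols.append(col[sg])
    counts = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(na * nb, len(sgrnas)),
    ).tocsr()
    return SpotSgrnaMatrix(
        grid_dims=grid_dims, counts=counts, sgrnas=sgrnas,
        tissue=None if tissue is None else frozenset(tissue), pitch_um=pitch_um,
    )


def assign_spots(M: SpotSgrnaMatrix, resolve_top_min: int = 10,
                 resolve_other_max: int = 1) -> pd.DataFrame:
    """Label every spot by the assignment rule.

    Returns a DataFrame indexed like the matrix rows with columns ``x``,
    ``y``, ``label`` (non_perturbed | unique:<sg> | resolved:<sg> |
    ambiguous) and ``sgrna`` (the assigned sgRNA or None).  When a tissue
    mask is present only tissue spots are labeled.
    """
    csr = M.counts.tocsr()
    coords = M.spot_coords()
    labels: list[str] = []
    assigned: list[str | None] = []
    tissue_rows = (
        None if M.tissue is None
        else {M.spot_index(x, y) for x, y in M.tissue}
    )
    for i in range(csr.shape[0]):
        if tissue_rows is not None and i not in tissue_rows:
            labels.append("non_tissue")
            assigned.append(None)
            continue
        row = csr.getrow(i)
        vals = row.data[row.data > 0]
        idxs = row.indices[row.data > 0]
        if len(vals) == 0:
            labels.append("non_perturbed")
            assigned.append(None)
        elif len(vals) == 1:
            labels.append(f"unique:{M.sgrnas[idxs[0]]}")
            assigned.append(M.sgrnas[idxs[0]])
        else:
            top = int(vals.max())
            top_hits = np.flatnonzero(vals == top)
            others = vals[vals != top]
            if (
                len(top_hits) == 1
                and top >= resolve_top_min
                and np.all(others <= resolve_other_max)
            ):
                g = M.sgrnas[idxs[top_hits[0]]]
                labels.append(f"resolved:{g}")
                assigned.append(g)
            else:
                labels.append("ambiguous")
                assigned.append(None)
    out = coords.copy()
    out["label"] = labels
    out["sgrna"] = assigned
    return out


def sgrna_area(M: SpotSgrnaMatrix, sgrna: str) -> int:
    """Number of spots in which the sgRNA is detected (>= 1 UMI)."""
    j = M.sgrna_index(sgrna)
    return int((M.counts.getcol(j) > 0).sum())


def sgrna_areas(M: SpotSgrnaMatrix) -> pd.Series:
    """Detection area of every sgRNA, in spots."""
    nnz = np.asarray((M.counts > 0).sum(axis=0)).ravel()
    return pd.Series(nnz, index=list(M.sgrnas), name="area")


def perturbation_burden(M: SpotSgrnaMatrix, region: RegionMask) -> dict:
    """Perturbation burden: spots within the region carrying any sgRNA.

    Returns ``{"spots_with_sgrna", "region_spots", "fraction",
    "physical_area_um2"}``; physical area uses the matrix pitch.
    """
    if len(region) == 0:
        raise ValueError("empty region")
    rows = [M.spot_index(x, y) for x, y in region.spots]  # validates coords
    per_spot = np.asarray(M.counts.sum(axis=1)).ravel()
    n = int((per_spot[rows] >= 1).sum())
    pitch = region.pitch_um or M.pitch_um
    return {
        "spots_with_sgrna": n,
        "region_spots": len(region),
        "fraction": n / len(region),
        "physical_area_um2": n * pitch ** 2,
    }


def _detection_set(M: SpotSgrnaMatrix, sgrna: str) -> set[tuple[int, int]]:
    j = M.sgrna_index(sgrna)
    rows = M.counts.getcol(j).tocoo().row
    return {M.spot_coord(int(r)) for r in rows}


def colocalization(M: SpotSgrnaMatrix, g1: str, g2: str, mode: str = "jaccard",
                   n_perm: int = 999, seed: int = 0, radius: int = 1) -> dict:
    """Spatial colocalization of an sgRNA pair with a permutation null.

    ``jaccard``: |S1 n S2| / |S1 u S2| over the two detection spot sets.
    ``neighborhood``: fraction of S1 spots with an S2 spot within Chebyshev
    radius ``radius``.  The null shuffles each detection set uniformly over
    the tissue spots (sizes preserved); p = (1 + #{perm >= obs}) / (1 + n_perm).

    The colocalization statistic is a reconstruction -- the screen reports
    colocalized pairs without defining a score -- hence both variants.
    """
    if mode not in ("jaccard", "neighborhood"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    s1, s2 = _detection_set(M, g1), _detection_set(M, g2)
    if not s1 or not s2:
        raise ValueError("both sgRNAs must be detected somewhere")

    def score(a: set, b: set) -> float:
        if mode == "jaccard":
            return len(a & b) / len(a | b)
        hits = sum(
            1 for (x, y) in a
            if any(max(abs(x - u), abs(y - v)) <= radius for (u, v) in b)
        )
        return hits / len(a)

    obs = score(s1, s2)
    if M.tissue is not None:
        universe = sorted(M.tissue)
    else:
        na, nb = M.grid_dims
        universe = [(x, y) for x in range(1, na + 1) for y in range(1, nb + 1)]
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        i1 = rng.choice(len(universe), size=len(s1), replace=False)
        i2 = rng.choice(len(universe), size=len(s2), replace=False)
        a = {universe[i] for i in i1}
        b = {universe[i] for i in i2}
        if score(a, b) >= obs:
            ge += 1
    return {"score": obs, "p": (1 + ge) / (1 + n_perm), "mode": mode, "n_perm": n_perm}
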
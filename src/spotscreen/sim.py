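"""Ground-truth simulator for spatially barcoded CRISPR screens.

Generates every input the pipeline consumes, with the truth recorded so
downstream modules can be tested against exact bookkeeping:

* a spot grid with a grown tissue blob and labelled tumor/parenchyma
  regions;
* contiguous sgRNA clones (clonal geography: each clone carries one sgRNA)
  plus sparse background molecules;
* negative-binomial gene expression with per-target knockout effect
  vectors applied multiplicatively in clone spots;
* chemistry-faithful paired reads (barcodes + linkers + UMI on mate 2,
  spacer + scaffold on mate 1) with i.i.d. substitution errors;
* a pooled-screen detection table in which per-lobe detection probability
  rises logistically with clone size.

Everything is driven by one :class:`numpy.random.Generator` seed;
identical (params, seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from anndata import AnnData

from .chemistry import (
    BarcodeSet,
    ChemistryProfile,
    SgRNALibrary,
    default_pac_profile,
)
from .quant import RegionMask, build_matrix

__all__ = [
    "random_barcode_set",
    "generate_tissue",
    "Clone",
    "seed_clones",
    "default_gene_panel",
    "make_effect_vectors",
    "sample_expression",
    "emit_reads",
    "emit_pooled_table",
    "SceneParams",
    "Scene",
    "simulate_scene",
    "knockout_scene",
    "default_library",
]

_BASES = np.array(list("ACGT"))


def random_barcode_set(n: int, role: str, length: int = 8, min_dist: int = 4,
                       rng: np.random.Generator | None = None,
                       seed: int = 0) -> BarcodeSet:
    """Rejection-sample ``n`` barcodes with pairwise Hamming distance >= min_dist.

    Distance 3 (2m+1) already makes single-substitution correction
    unambiguous; the default of 4 (2m+2) additionally guarantees that a
    double substitution can never be miscorrected into a wrong channel --
    it is rejected instead -- which is the property a barcode designer
    wants when spot identity is at stake.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    chosen: list[str] = []
    arrs: list[np.ndarray] = []
    guard = 0
    while len(chosen) < n:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("cannot satisfy min_dist; too many barcodes requested")
        cand = rng.integers(0, 4, size=length)
        if all((cand != a).sum() >= min_dist for a in arrs):
            arrs.append(cand)
            chosen.append("".join(_BASES[cand]))
    return BarcodeSet(role=role, entries=tuple(chosen))


def _neighbors4(x: int, y: int, dims: tuple[int, int]):
    na, nb = dims
    if x > 1:
        yield x - 1, y
    if x < na:
        yield x + 1, y
    if y > 1:
        yield x, y - 1
    if y < nb:
        yield x, y + 1


def _grow_blob(rng: np.random.Generator, dims: tuple[int, int],
               start: tuple[int, int], size: int,
               within: set | None = None) -> set:
    """Random-frontier growth of a 4-connected blob from ``start``."""
    def ok(c):
        return within is None or c in within

    blob = {start}
    frontier = [c for c in _neighbors4(*start, dims) if ok(c)]
    while len(blob) < size and frontier:
        i = rng.integers(0, len(frontier))
        cell = frontier.pop(i)
        if cell in blob:
            continue
        blob.add(cell)
        for nb in _neighbors4(*cell, dims):
            if nb not in blob and ok(nb):
                frontier.append(nb)
    return blob


def generate_tissue(dims: tuple[int, int], n_regions: int = 3, seed: int = 0,
                    tissue_frac: float = 0.6,
                    rng: np.random.Generator | None = None
                    ) -> tuple[frozenset, list[RegionMask]]:
    """Grow a tissue blob and label tumor sub-regions plus parenchyma.

    Returns (tissue spots, region masks).  Tumor regions are disjoint blobs
    inside the tissue, each ~tissue/(2*n_regions) spots; the remainder is
    the ``parenchyma`` region.  Deterministic per seed.
    """
    na, nb = dims
    if na < 10 or nb < 10:
        raise ValueError("grid must be at least 10x10")
    rng = rng if rng is not None else np.random.default_rng(seed)
    target = int(round(tissue_frac * na * nb))
    center = (na // 2, nb // 2)
    tissue = _grow_blob(rng, dims, center, target)
    if n_regions >= len(tissue):
        raise ValueError("more regions requested than tissue spots")

    regions: list[RegionMask] = []
    free = set(tissue)
    per = max(4, len(tissue) // (2 * max(n_regions, 1)))
    for i in range(n_regions):
        if not free:
            raise ValueError("tissue exhausted while placing regions")
        start = sorted(free)[rng.integers(0, len(free))]
        blob = _grow_blob(rng, dims, start, per, within=free)
        regions.append(RegionMask(name=f"tumor{i + 1}", spots=frozenset(blob)))
        free -= blob
    regions.append(RegionMask(name="parenchyma", spots=frozenset(free)))
    return frozenset(tissue), regions


@dataclass(frozen=True)
class Clone:
    clone_id: int
    sgrna: str
    spots: frozenset


def seed_clones(tissue: frozenset, sgrnas, n_clones: int = 12,
                mean_size: float = 30.0, seed: int = 0,
                rng: np.random.Generator | None = None,
                regions: list[RegionMask] | None = None,
                tumor_bias: float = 0.8) -> list[Clone]:
    """Place contiguous single-sgRNA clones on the tissue.

    Clone sizes are Poisson(mean_size) truncated at 1; clones may overlap
    each other and may share sgRNAs (independent transduction events).
    With ``regions`` given, a clone seeds inside a tumor region with
    probability ``tumor_bias``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    sgrnas = list(sgrnas)
    tissue_sorted = sorted(tissue)
    tumor_spots = (
        sorted(set().union(*[r.spots for r in regions if r.name.startswith("tumor")]))
        if regions else []
    )
    clones = []
    for i in range(n_clones):
        size = max(1, int(rng.poisson(mean_size)))
        if size > len(tissue):
            raise ValueError("requested clone larger than tissue")
        pool = tumor_spots if (tumor_spots and rng.random() < tumor_bias) \
            else tissue_sorted
        start = pool[rng.integers(0, len(pool))]
        spots = _grow_blob(rng, _bounds(tissue), start, size, within=set(tissue))
        sg = sgrnas[rng.integers(0, len(sgrnas))]
        clones.append(Clone(clone_id=i, sgrna=sg, spots=frozenset(spots)))
    return clones


def _bounds(spots) -> tuple[int, int]:
    xs = [x for x, _ in spots]
    ys = [y for _, y in spots]
    return max(xs), max(ys)


# ---------------------------------------------------------------------------
# expression


def default_gene_panel(n_coding: int = 500, n_trna: int = 40, n_mirna: int = 30,
                       n_lnc: int = 30, seed: int = 0,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gene panel with feature classes, baseline NB means and dispersions.

    Baseline means are log-normal (median 1 count/spot) -- a handful of
    high expressors and a long tail, as in real spot data; dispersions
    (NB alpha, var = mu + alpha mu^2) are gamma-distributed around 0.3.
    tRNA names carry isotype tokens cycling through the 20 amino acids.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    from .de import ISOTYPES

    names, classes = [], []
    for i in range(n_coding):
        names.append(f"GENE{i + 1:04d}")
        classes.append("protein_coding")
    iso_cycle = [iso for iso in ISOTYPES if iso not in ("iMet", "SeC")]
    for i in range(n_trna):
        iso = iso_cycle[i % len(iso_cycle)]
        names.append(f"tRNA-{iso}-{i + 1}")
        classes.append("tRNA")
    for i in range(n_mirna):
        names.append(f"miR-{i + 1}")
        classes.append("miRNA")
    for i in range(n_lnc):
        names.append(f"LINC{i + 1:04d}")
        classes.append("lncRNA")
    n = len(names)
    return pd.DataFrame(
        {
            "name": names,
            "feature_class": classes,
            "base_mean": rng.lognormal(mean=0.0, sigma=1.0, size=n),
            "dispersion": rng.gamma(shape=2.0, scale=0.15, size=n),
        }
    )


def make_effect_vectors(panel: pd.DataFrame, targets, n_genes: int = 50,
                        magnitude: float = 2.0, seed: int = 0,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, np.ndarray]:
    """Multiplicative knockout effect vectors, one per target gene.

    Each target perturbs ``n_genes`` genes drawn from the upper half of
    baseline expression (effects on near-silent genes are unobservable),
    half up by ``magnitude`` and half down by 1/magnitude.  Returns
    target -> per-gene factor vector (1.0 elsewhere).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(panel)
    expressed = np.flatnonzero(
        panel["base_mean"].to_numpy() >= np.median(panel["base_mean"])
    )
    out = {}
    for t in targets:
        idx = rng.choice(expressed, size=min(n_genes, len(expressed)),
                         replace=False)
        vec = np.ones(n)
        half = len(idx) // 2
        vec[idx[:half]] = magnitude
        vec[idx[half:]] = 1.0 / magnitude
        out[t] = vec
    return out


def sample_expression(spots, spot_targets, panel: pd.DataFrame,
                      effects: dict[str, np.ndarray], seed: int = 0,
                      rng: np.random.Generator | None = None) -> AnnData:
    """Negative-binomial counts per spot and gene, with effects applied.

    ``spots`` is the ordered list of (x, y); ``spot_targets`` maps each
    spot to a (possibly empty) tuple of perturbed target genes whose effect
    vectors multiply that spot's baseline means.  Counts are sampled via
    the gamma-Poisson mixture NB(mu, alpha) with var = mu + alpha mu^2.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    mu0 = panel["base_mean"].to_numpy(dtype=float)
    if (mu0 < 0).any():
        raise ValueError("non-positive baseline means")
    alpha = panel["dispersion"].to_numpy(dtype=float)
    n_spots, n_genes = len(spots), len(panel)
    mu = np.tile(mu0, (n_spots, 1))
    truth_target = []
    for i, s in enumerate(spots):
        tgts = tuple(spot_targets.get(s, ()))
        truth_target.append(";".join(tgts))
        for t in tgts:
            mu[i] *= effects[t]
    shape = np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), np.inf)
    lam = np.where(
        np.isfinite(shape) & (mu > 0),
        rng.gamma(np.broadcast_to(shape, mu.shape),
                  np.where(mu > 0, mu, 1.0) / np.broadcast_to(
                      np.where(np.isfinite(shape), shape, 1.0), mu.shape)),
        mu,
    )
    counts = rng.poisson(lam).astype(np.int64)
    obs = pd.DataFrame(
        {
            "x": [x for x, _ in spots],
            "y": [y for _, y in spots],
            "true_targets": truth_target,
        },
        index=[f"spot_{x}_{y}" for x, y in spots],
    )
    var = panel.set_index("name")[["feature_class", "base_mean", "dispersion"]]
    ad = AnnData(X=counts, obs=obs, var=var.copy())
    ad.uns["effect_targets"] = sorted(effects)
    return ad


# ---------------------------------------------------------------------------
# reads


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _corrupt(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    s = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(0, 3)]
    return "".join(s)


def emit_reads(pair_umis: dict, profile: ChemistryProfile, lib: SgRNALibrary,
               reads_per_umi: int = 3, error_rate: float = 0.0, seed: int = 0,
               rng: np.random.Generator | None = None, read_len: int = 50
               ) -> tuple[list, list, set]:
    """Assemble paired reads for given molecules and corrupt them.

    ``pair_umis`` maps ((x, y), sgrna_name) -> number of UMIs to create for
    that molecule group.  Mate 2 follows the profile's sgRNA layout (spot
    barcodes + linkers + fresh random UMI, padded with T); mate 1 is the
    spacer + scaffold flank + random filler.  Truth triples are recorded
    *before* corruption.  Returns (mate1, mate2, truth_triples) where the
    mates are lists of (read_id, sequence).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    layout = profile.sgrna_layout
    xr, yr = profile.sgrna_roles
    set_x, set_y = profile.barcode_sets[xr], profile.barcode_sets[yr]
    spacer_of = dict(zip(lib.names, lib.spacers))
    umi_len = profile.umi_length

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    truth: set = set()
    rid = 0
    for ((x, y), sg), n_umis in sorted(pair_umis.items()):
        if sg not in spacer_of:
            raise ValueError(f"unknown sgRNA {sg!r}")
        prefix_parts = []
        for seg in layout.segments:
            if seg.kind == "anchor":
                prefix_parts.append((None, seg.sequence))
            elif seg.kind == "barcode":
                bset = set_x if seg.role == xr else set_y
                idx = x if seg.role == xr else y
                prefix_parts.append((None, bset.entries[idx - 1]))
            elif seg.kind == "umi":
                prefix_parts.append(("umi", None))
        spacer = spacer_of[sg]
        for _ in range(int(n_umis)):
            umi = _random_dna(rng, umi_len)
            truth.add(((x, y), sg, umi))
            mate2 = "".join(
                umi if tag == "umi" else const for tag, const in prefix_parts
            )
            if len(mate2) < read_len:
                mate2 = mate2 + "T" * (read_len - len(mate2))
            filler = read_len - len(spacer) - len(profile.scaffold_flank)
            mate1 = spacer + profile.scaffold_flank + (
                _random_dna(rng, filler) if filler > 0 else ""
            )
            for _ in range(int(reads_per_umi)):
                name = f"read{rid:08d}"
                rid += 1
                reads1.append((name, _corrupt(rng, mate1, error_rate)))
                reads2.append((name, _corrupt(rng, mate2, error_rate)))
    return reads1, reads2, truth


def emit_pooled_table(areas: pd.Series, n_lobes: int = 10, slope: float = 0.15,
                      midpoint: float = 10.0, floor: float = 0.05,
                      seed: int = 0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Pooled-screen detection table paired with spatial areas.

    Per sgRNA the per-lobe detection probability follows a logistic curve
    in clone size (spots): p = floor + (1 - floor) / (1 + exp(-slope *
    (area - midpoint))); an sgRNA entirely absent from the tissue (area 0)
    is only detectable at the noise ``floor``.  The pooled fraction is
    Binomial(n_lobes, p) / n_lobes, so larger clones are more reliably
    detected by the pooled assay, as in a real screen.
    """
    if n_lobes < 1:
        raise ValueError("n_lobes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for sg, area in areas.items():
        if area == 0:
            p = floor
        else:
            p = floor + (1.0 - floor) / (1.0 + math.exp(-slope * (area - midpoint)))
        frac = rng.binomial(n_lobes, p) / n_lobes
        rows.append({"sgrna": sg, "pooled_fraction": frac,
                     "spatial_area": int(area)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole scenes


def default_library(n_targets: int = 18, n_ntc: int = 2, spacer_len: int = 20,
                    seed: int = 0,
                    rng: np.random.Generator | None = None) -> SgRNALibrary:
    """Small screen library: one sgRNA per target gene plus NTCs.

    Spacers are random with pairwise Hamming distance >= 6 so the default
    2-mismatch spacer tolerance stays unambiguous.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    spacers: list[np.ndarray] = []
    while len(spacers) < n_targets + n_ntc:
        cand = rng.integers(0, 4, size=spacer_len)
        if all((cand != s).sum() >= 6 for s in spacers):
            spacers.append(cand)
    names, targets, ntc = [], [], []
    for i in range(n_targets):
        names.append(f"sgT{i + 1:02d}")
        targets.append(f"T{i + 1:02d}")
        ntc.append(False)
    for i in range(n_ntc):
        names.append(f"sgNTC{i + 1}")
        targets.append("")
        ntc.append(True)
    return SgRNALibrary(
        names=tuple(names),
        spacers=tuple("".join(_BASES[s]) for s in spacers),
        targets=tuple(targets),
        is_ntc=tuple(ntc),
    )


@dataclass
class SceneParams:
    """Study conditions of the default synthetic scene.

    Sized as a desk-scale version of a 50-micron screen section: 50x50
    grid, ~60% tissue, a 20-guide library (2 NTC), two dozen clones, a
    600-gene panel, and roughly 2e5 sgRNA reads at 3 reads per UMI.
    """

    grid: tuple[int, int] = (50, 50)
    tissue_frac: float = 0.6
    n_regions: int = 3
    n_targets: int = 18
    n_ntc: int = 2
    n_clones: int = 24
    clone_mean_size: float = 55.0
    enriched_frac: float = 0.6  # fraction of the library ever forming clones
    umi_mean: float = 40.0
    background_rate: float = 0.3
    reads_per_umi: int = 3
    error_rate: float = 0.0
    n_effect_genes: int = 50
    effect_magnitude: float = 2.0
    panel: tuple[int, int, int, int] = (500, 40, 30, 30)
    n_lobes: int = 10
    read_len: int = 50


@dataclass
class Scene:
    """A fully simulated experiment plus its ground truth."""

    params: SceneParams
    seed: int
    profile: ChemistryProfile
    lib: SgRNALibrary
    tissue: frozenset
    regions: list[RegionMask]
    clones: list[Clone]
    pair_umis: dict
    reads1: list
    reads2: list
    truth_triples: set
    adata: AnnData
    effects: dict[str, np.ndarray]
    pooled: pd.DataFrame

    def truth_matrix(self):
        """Spot x sgRNA matrix implied by the truth triples."""
        return build_matrix(
            self.truth_triples, self.profile.grid_dims, self.lib.names,
            tissue=self.tissue, pitch_um=self.profile.spot_pitch_um,
        )

    def truth_areas(self) -> pd.Series:
        per = {sg: set() for sg in self.lib.names}
        for (spot, sg, _umi) in self.truth_triples:
            per[sg].add(spot)
        return pd.Series({sg: len(s) for sg, s in per.items()}, name="area")


def simulate_scene(params: SceneParams | None = None, seed: int = 0) -> Scene:
    """Generate the full default scene from a single seed."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    na, nb = params.grid
    set_a = random_barcode_set(na, "A", rng=rng)
    set_b = random_barcode_set(nb, "B", rng=rng)
    profile = default_pac_profile(set_a, set_b)
    lib = default_library(params.n_targets, params.n_ntc, rng=rng)

    tissue, regions = generate_tissue(
        params.grid, params.n_regions, tissue_frac=params.tissue_frac, rng=rng
    )
    # only a subset of the library expands into clones (selection leaves
    # most guides depleted), so the rest stays spatially undetected
    n_enriched = max(2, int(round(params.enriched_frac * len(lib.names))))
    enriched = [lib.names[i] for i in sorted(
        rng.choice(len(lib.names), size=n_enriched, replace=False)
    )]
    clones = seed_clones(
        tissue, enriched, n_clones=params.n_clones,
        mean_size=params.clone_mean_size, rng=rng, regions=regions,
    )

    # molecules: clone spots get Poisson(umi_mean) UMIs (min 1); a fraction
    # of tissue spots additionally carries 1-2 stray background molecules
    # ambient from the clones present in the section.
    clone_sgrnas = sorted({c.sgrna for c in clones})
    pair_umis: dict = {}
    for clone in clones:
        for spot in sorted(clone.spots):
            key = (spot, clone.sgrna)
            n = max(1, int(rng.poisson(params.umi_mean)))
            pair_umis[key] = pair_umis.get(key, 0) + n
    for spot in sorted(tissue):
        if rng.random() < params.background_rate:
            sg = clone_sgrnas[rng.integers(0, len(clone_sgrnas))]
            key = (spot, sg)
            extra = 1 if rng.random() < 0.8 else 2
            pair_umis[key] = pair_umis.get(key, 0) + extra

    reads1, reads2, truth = emit_reads(
        pair_umis, profile, lib, reads_per_umi=params.reads_per_umi,
        error_rate=params.error_rate, rng=rng, read_len=params.read_len,
    )

    # expression: perturbation applies where a clone's (non-NTC) target sits
    panel = default_gene_panel(*params.panel, rng=rng)
    target_of = dict(zip(lib.names, lib.targets))
    ntc = dict(zip(lib.names, lib.is_ntc))
    targets = sorted({t for t in lib.targets if t})
    effects = make_effect_vectors(
        panel, targets, n_genes=params.n_effect_genes,
        magnitude=params.effect_magnitude, rng=rng,
    )
    spot_targets: dict = {}
    for clone in clones:
        if ntc[clone.sgrna]:
            continue
        for spot in clone.spots:
            cur = set(spot_targets.get(spot, ()))
            cur.add(target_of[clone.sgrna])
            spot_targets[spot] = tuple(sorted(cur))
    spots = sorted(tissue)
    adata = sample_expression(spots, spot_targets, panel, effects, rng=rng)

    areas = pd.Series(
        {sg: len({s for (s, g, _u) in truth if g == sg}) for sg in lib.names}
    )
    pooled = emit_pooled_table(areas, n_lobes=params.n_lobes, rng=rng)

    return Scene(
        params=params, seed=seed, profile=profile, lib=lib, tissue=tissue,
        regions=regions, clones=clones, pair_umis=pair_umis, reads1=reads1,
        reads2=reads2, truth_triples=truth, adata=adata, effects=effects,
        pooled=pooled,
    )


def knockout_scene(n_target: int = 200, n_np: int = 500, n_genes: int = 600,
                   n_effect_genes: int = 50, magnitude: float = 2.0,
                   seed: int = 0) -> tuple[AnnData, pd.Series]:
    """Expression-level knockout benchmark: one target vs an NP pool.

    Returns (AnnData, status Series) where status holds the target gene
    name for perturbed spots and "NP" otherwise -- ready for
    :func:`spotscreen.perturb.calc_signature` / ``calc_scores``.
    """
    rng = np.random.default_rng(seed)
    side = int(math.ceil(math.sqrt(n_target + n_np)))
    spots = [(x + 1, y + 1) for x in range(side) for y in range(side)]
    spots = spots[: n_target + n_np]
    panel = default_gene_panel(
        n_coding=n_genes - 100, n_trna=40, n_mirna=30, n_lnc=30, rng=rng
    )
    effects = make_effect_vectors(
        panel, ["KO1"], n_genes=n_effect_genes, magnitude=magnitude, rng=rng
    )
    perturbed = set(spots[:n_target])
    spot_targets = {s: ("KO1",) for s in perturbed}
    adata = sample_expression(spots, spot_targets, panel, effects, rng=rng)
    status = pd.Series(
        ["KO1" if s in perturbed else "NP" for s in spots],
        index=adata.obs_names, name="status",
    )
    return adata, status
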
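"""Declarative read chemistry for deterministic-barcoding spatial screens.

Two microfluidic barcoding passes lay down orthogonal 8-mer barcode sets
(A across channels x, B across channels y), separated by fixed ligation
linkers, so that every sequencing read of the barcode-bearing mate encodes
its spot of origin as an (A-index, B-index) pair.  Two chemistry variants
are modelled:

* PAC (polyadenylated capture): in-situ poly(A) tailing makes every RNA --
  including the sgRNA of a CRISPR screen -- capturable by a poly-dT primer,
  so transcriptome and sgRNA reads share one A/B barcode layout.
* DC (direct capture): a scaffold-complementary primer captures sgRNAs with
  a dedicated C/D barcode pair while mRNA uses A/B.

The classes here only *describe* the chemistry; parsing happens in
:mod:`spotscreen.demux`, simulation in :mod:`spotscreen.sim`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "BarcodeSet",
    "Segment",
    "ReadLayout",
    "SgRNALibrary",
    "ChemistryProfile",
    "load_whitelist",
    "write_whitelist",
    "load_library",
    "write_library",
    "min_pairwise_distance",
    "validate_profile",
    "hamming",
    "default_pac_profile",
    "default_dc_profile",
    "DEFAULT_LINKERS",
    "DEFAULT_SCAFFOLD_FLANK",
]

_DNA = frozenset("ACGT")

#: Default 10-mer ligation linkers (anchor sequences between barcode blocks).
#: The physical oligos are chemistry-specific reagents; these defaults are
#: placeholders used by the simulator and overridable in any profile config.
DEFAULT_LINKERS = {
    "linker1": "GTGGCCGATG",
    "linker2": "CCCATGATCG",
    "linker3": "ATCCACGTGC",
    "linker4": "GGTAGCCTAA",
}

#: First 10 nt of the SpCas9 tracrRNA scaffold, used as the 3' flank that
#: delimits the sgRNA spacer on the payload mate.
DEFAULT_SCAFFOLD_FLANK = "GTTTAAGAGC"


class DuplicateBarcodeError(ValueError):
    """Two whitelist rows carry the same sequence."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeSet:
    """An ordered whitelist of equal-length DNA barcodes.

    The 1-based position of an entry is its microchannel index: entry ``i``
    of the A set is ligated in channel ``i`` of the first device, so spot
    coordinates are recovered directly from whitelist indices.
    """

    role: str  # "A", "B", "C" or "D"
    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty barcode set")
        L = len(self.entries[0])
        seen: set[str] = set()
        for e in self.entries:
            if len(e) != L:
                raise ValueError(f"ragged barcode lengths in set {self.role!r}")
            if not _DNA.issuperset(e):
                raise ValueError(f"non-ACGT barcode {e!r}")
            if e in seen:
                raise DuplicateBarcodeError(f"duplicate barcode {e!r}")
            seen.add(e)

    @property
    def length(self) -> int:
        return len(self.entries[0])

    def __len__(self) -> int:
        return len(self.entries)

    def index_of(self, seq: str) -> int | None:
        """1-based index of an exact match, or None."""
        return self._lookup().get(seq)

    def _lookup(self) -> dict[str, int]:
        # cached on the instance despite frozen=True (object.__setattr__)
        lut = getattr(self, "_lut", None)
        if lut is None:
            lut = {e: i + 1 for i, e in enumerate(self.entries)}
            object.__setattr__(self, "_lut", lut)
        return lut

    def min_pairwise_distance(self) -> int:
        return min_pairwise_distance(self)


def min_pairwise_distance(bset: BarcodeSet) -> int:
    """Exact minimum Hamming distance over all entry pairs (brute force).

    Governs how much mismatch tolerance is safe: correcting up to ``m``
    substitutions is unambiguous iff the minimum distance is >= 2m + 1.
    """
    if len(bset) < 2:
        raise ValueError("need >= 2 entries for a pairwise distance")
    return min(hamming(a, b) for a, b in itertools.combinations(bset.entries, 2))


@dataclass(frozen=True)
class Segment:
    """One 5'->3' block of a read layout.

    kind:
      anchor  -- fixed sequence (ligation linker / flank), located with up
                 to ``max_mismatches`` substitutions;
      barcode -- fixed-length slice matched against a BarcodeSet role;
      umi     -- unique molecular identifier slice;
      payload -- free sequence (sgRNA spacer + downstream scaffold).
    """

    name: str
    kind: str
    length: int = 0
    sequence: str | None = None  # anchors only
    max_mismatches: int = 1  # anchors only
    role: str | None = None  # barcodes only
    min_length: int = 0  # payload only

    def __post_init__(self) -> None:
        if self.kind not in ("anchor", "barcode", "umi", "payload"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "anchor":
            if not self.sequence:
                raise ValueError(f"anchor {self.name!r} needs a sequence")
            object.__setattr__(self, "length", len(self.sequence))
        if self.kind == "barcode" and self.role is None:
            raise ValueError(f"barcode segment {self.name!r} needs a role")


@dataclass(frozen=True)
class ReadLayout:
    """Ordered segments of one mate, 5' to 3'."""

    segments: tuple[Segment, ...]
    mate: int = 2

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError("mate must be 1 or 2")

    @property
    def fixed_length(self) -> int:
        """Total length of the fixed-length prefix (everything but payload)."""
        return sum(s.length for s in self.segments if s.kind != "payload")

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def umi_segment(self) -> Segment:
        umis = [s for s in self.segments if s.kind == "umi"]
        if len(umis) != 1:
            raise ValueError(f"layout has {len(umis)} UMI segments, expected 1")
        return umis[0]

    @property
    def barcode_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "barcode")


@dataclass(frozen=True)
class SgRNALibrary:
    """sgRNA library table: name, spacer, target gene, NTC flag."""

    names: tuple[str, ...]
    spacers: tuple[str, ...]
    targets: tuple[str, ...]
    is_ntc: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.spacers) == len(self.targets) == len(self.is_ntc) == n):
            raise ValueError("library columns have unequal lengths")
        spacers = tuple(s.upper() for s in self.spacers)
        object.__setattr__(self, "spacers", spacers)
        if len(set(self.names)) != n:
            raise ValueError("sgRNA names not unique")
        if len(set(spacers)) != n:
            raise ValueError("spacer sequences not unique (after uppercasing)")
        for s in spacers:
            if not 18 <= len(s) <= 21:
                raise ValueError(f"spacer length {len(s)} outside 18..21: {s!r}")
            if not _DNA.issuperset(s):
                raise ValueError(f"non-ACGT spacer {s!r}")
        for name, tgt, ntc in zip(self.names, self.targets, self.is_ntc):
            if not ntc and not tgt:
                raise ValueError(f"{name!r} has no target gene and is not NTC")

    def __len__(self) -> int:
        return len(self.names)

    def target_of(self, name: str) -> str:
        return self.targets[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgrna_name": self.names,
                "spacer": self.spacers,
                "gene": self.targets,
                "is_ntc": [int(x) for x in self.is_ntc],
            }
        )


@dataclass(frozen=True)
class ChemistryProfile:
    """Everything the demultiplexer needs to know about one experiment.

    ``barcode_sets`` maps role ("A".."D") to its whitelist.  PAC uses A/B
    for both read classes; DC additionally needs C/D for the sgRNA mate.
    Spot coordinates are 1-based: x = A (or C) index, y = B (or D) index.
    """

    variant: str  # "PAC" | "DC"
    sgrna_layout: ReadLayout
    transcriptome_layout: ReadLayout | None = None
    barcode_sets: dict[str, BarcodeSet] = field(default_factory=dict)
    spot_pitch_um: float = 50.0
    grid_dims: tuple[int, int] = (50, 50)  # (N_A, N_B)
    umi_length: int = 10
    scaffold_flank: str = DEFAULT_SCAFFOLD_FLANK

    def __post_init__(self) -> None:
        if self.variant not in ("PAC", "DC"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def sgrna_roles(self) -> tuple[str, str]:
        """(x-axis role, y-axis role) of the sgRNA read."""
        return ("C", "D") if self.variant == "DC" else ("A", "B")


def validate_profile(profile: ChemistryProfile) -> list[str]:
    """Pure consistency check; returns a list of violations (empty = valid)."""
    v: list[str] = []
    required = ("A", "B", "C", "D") if profile.variant == "DC" else ("A", "B")
    for role in required:
        if role not in profile.barcode_sets:
            v.append(f"missing {role} barcode set")
    layouts = [("sgrna", profile.sgrna_layout)]
    if profile.transcriptome_layout is not None:
        layouts.append(("transcriptome", profile.transcriptome_layout))
    for lname, layout in layouts:
        try:
            layout.umi_segment
        except ValueError as e:
            v.append(f"{lname} layout: {e}")
        else:
            if layout.umi_segment.length != profile.umi_length:
                v.append(
                    f"{lname} layout: UMI length {layout.umi_segment.length} "
                    f"!= profile umi_length {profile.umi_length}"
                )
        if not layout.barcode_segments:
            v.append(f"{lname} layout: no barcode segments")
        for seg in layout.barcode_segments:
            bset = profile.barcode_sets.get(seg.role or "")
            if bset is None:
                v.append(f"{lname} layout: barcode role {seg.role!r} has no whitelist")
            elif seg.length != bset.length:
                v.append(
                    f"{lname} layout: segment {seg.name!r} length {seg.length} "
                    f"!= whitelist length {bset.length}"
                )
    na, nb = profile.grid_dims
    xr, yr = profile.sgrna_roles
    if xr in profile.barcode_sets and len(profile.barcode_sets[xr]) != na:
        v.append(f"grid N_A={na} != |{xr} whitelist|={len(profile.barcode_sets[xr])}")
    if yr in profile.barcode_sets and len(profile.barcode_sets[yr]) != nb:
        v.append(f"grid N_B={nb} != |{yr} whitelist|={len(profile.barcode_sets[yr])}")
    return v


def _sgrna_mate2_layout(roles: tuple[str, str], bc_len: int, umi_len: int,
                        linkers: tuple[str, str]) -> ReadLayout:
    xr, yr = roles
    return ReadLayout(
        mate=2,
        segments=(
            Segment(f"barcode_{yr}", "barcode", length=bc_len, role=yr),
            Segment("linker_a", "anchor", sequence=linkers[0]),
            Segment(f"barcode_{xr}", "barcode", length=bc_len, role=xr),
            Segment("linker_b", "anchor", sequence=linkers[1]),
            Segment("umi", "umi", length=umi_len),
        ),
    )


def default_pac_profile(
    set_a: BarcodeSet,
    set_b: BarcodeSet,
    spot_pitch_um: float = 50.0,
    umi_length: int = 10,
) -> ChemistryProfile:
    """PAC chemistry: one A/B layout shared by sgRNA and transcriptome reads."""
    layout = _sgrna_mate2_layout(
        ("A", "B"), set_a.length, umi_length,
        (DEFAULT_LINKERS["linker2"], DEFAULT_LINKERS["linker1"]),
    )
    return ChemistryProfile(
        variant="PAC",
        sgrna_layout=layout,
        transcriptome_layout=layout,
        barcode_sets={"A": set_a, "B": set_b},
        spot_pitch_um=spot_pitch_um,
        grid_dims=(len(set_a), len(set_b)),
        umi_length=umi_length,
    )


def default_dc_profile(
    set_a: BarcodeSet,
    set_b: BarcodeSet,
    set_c: BarcodeSet,
    set_d: BarcodeSet,
    spot_pitch_um: float = 50.0,
    umi_length: int = 10,
) -> ChemistryProfile:
    """DC chemistry: A/B for mRNA, dedicated C/D + linkers 3/4 for sgRNA.

    Read class is decided by which whitelist pair matches; anchor (linker)
    identity breaks ties since linkers 1/2 and 3/4 differ.
    """
    mrna = _sgrna_mate2_layout(
        ("A", "B"), set_a.length, umi_length,
        (DEFAULT_LINKERS["linker2"], DEFAULT_LINKERS["linker1"]),
    )
    sg = _sgrna_mate2_layout(
        ("C", "D"), set_c.length, umi_length,
        (DEFAULT_LINKERS["linker4"], DEFAULT_LINKERS["linker3"]),
    )
    return ChemistryProfile(
        variant="DC",
        sgrna_layout=sg,
        transcriptome_layout=mrna,
        barcode_sets={"A": set_a, "B": set_b, "C": set_c, "D": set_d},
        spot_pitch_um=spot_pitch_um,
        grid_dims=(len(set_c), len(set_d)),
        umi_length=umi_length,
    )


# ---------------------------------------------------------------------------
# on-disk formats


def load_whitelist(path, role: str) -> BarcodeSet:
    """Read a barcode whitelist TSV (columns ``index``, ``sequence``).

    Indices must be contiguous from 1; order on disk is canonical.
    """
    df = pd.read_csv(path, sep="\t", dtype={"index": int, "sequence": str})
    if list(df.columns) != ["index", "sequence"]:
        raise ValueError(f"{path}: expected columns index, sequence")
    df = df.sort_values("index")
    if list(df["index"]) != list(range(1, len(df) + 1)):
        raise ValueError(f"{path}: indices not contiguous from 1")
    return BarcodeSet(role=role, entries=tuple(df["sequence"]))


def write_whitelist(bset: BarcodeSet, path) -> None:
    pd.DataFrame(
        {"index": range(1, len(bset) + 1), "sequence": bset.entries}
    ).to_csv(path, sep="\t", index=False)


def load_library(path) -> SgRNALibrary:
    """Read an sgRNA library TSV: sgrna_name, spacer, gene, is_ntc."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    need = ["sgrna_name", "spacer", "gene", "is_ntc"]
    if list(df.columns) != need:
        raise ValueError(f"{path}: expected columns {need}")
    return SgRNALibrary(
        names=tuple(df["sgrna_name"]),
        spacers=tuple(df["spacer"]),
        targets=tuple(df["gene"]),
        is_ntc=tuple(bool(int(x)) for x in df["is_ntc"]),
    )


def write_library(lib: SgRNALibrary, path) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False)
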
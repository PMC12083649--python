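"""Parse raw spatially barcoded screen reads into (spot, sgRNA, UMI) records.

Stages, applied in fixed order so that every dropped read carries exactly
one canonical reason (the first failing stage):

1. ``extract``   -- anchor-guided slicing of the barcode-bearing mate;
2. ``umi``       -- membership of the 10-mer UMI in a data-derived whitelist;
3. ``barcode_x`` -- A (or C) barcode, mismatch-tolerant unique-best match;
4. ``barcode_y`` -- B (or D) barcode, same semantics;
5. ``spacer``    -- sgRNA spacer on the payload mate, delimited by the
                    scaffold flank.

Matching is native Hamming matching with unique-best-hit rejection: a query
is assigned to the single whitelist entry within ``max_mm`` substitutions,
and rejected when two entries tie at the minimal distance.  This reproduces
short-read aligner ``-v``/``-m 1`` semantics deterministically.  One-mismatch
barcode correction is only safe when the whitelist's minimum pairwise
Hamming distance is >= 3 (see :func:`spotscreen.chemistry.min_pairwise_distance`).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .chemistry import BarcodeSet, ChemistryProfile, ReadLayout, SgRNALibrary

__all__ = [
    "DemuxRecord",
    "DemuxOptions",
    "UmiWhitelist",
    "extract_segments",
    "build_umi_whitelist",
    "match_barcode",
    "match_spacer",
    "demux_reads",
    "dedup_umis",
    "open_fastq",
]

DROP_STAGES = ("extract", "umi", "barcode_x", "barcode_y", "spacer")


@dataclass(frozen=True)
class DemuxRecord:
    read_id: str
    x: int | None  # A/C whitelist index, 1-based
    y: int | None  # B/D whitelist index, 1-based
    sgrna: str | None
    umi: str | None
    status: str  # "assigned" | "dropped:<stage>[:detail]"

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


@dataclass
class DemuxOptions:
    """Knobs of the demultiplexer; defaults follow the pipeline settings.

    ``umi_filter``: drop reads whose UMI is absent from the whitelist
    (mirrors aligning UMIs against a whitelist reference); set False to
    pass every UMI through.
    """

    max_mm_barcode: int = 1
    max_mm_spacer: int = 2
    max_mm_umi: int = 0  # whitelist lookup is exact by default
    anchor_jitter: int = 2
    umi_filter: bool = True
    umi_collapse: bool = False


@dataclass
class UmiWhitelist:
    """Distinct truncated 10-mer UMIs observed in the data, with counts."""

    counts: Counter = field(default_factory=Counter)

    def __contains__(self, umi: str) -> bool:
        return umi in self.counts

    def __len__(self) -> int:
        return len(self.counts)


def open_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from FASTQ or FASTQ.gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


def _find_anchor(seq: str, anchor: str, expected: int, max_mm: int,
                 jitter: int) -> int | None:
    """Best anchor start position within +-jitter of ``expected``.

    Exact match at the expected offset is the fast path; otherwise positions
    are scanned by increasing distance from ``expected`` and the first
    position with <= max_mm substitutions wins.
    """
    L = len(anchor)
    if seq[expected:expected + L] == anchor:
        return expected
    best_pos, best_mm = None, max_mm + 1
    for delta in sorted(range(-jitter, jitter + 1), key=lambda d: (abs(d), d)):
        pos = expected + delta
        if pos < 0 or pos + L > len(seq):
            continue
        window = seq[pos:pos + L]
        mm = 0
        for a, b in zip(window, anchor):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        else:
            if mm < best_mm:
                best_pos, best_mm = pos, mm
                if mm == 0:
                    break
    return best_pos


def extract_segments(seq: str, layout: ReadLayout,
                     jitter: int = 2) -> dict[str, str] | str:
    """Slice a read into its layout segments.

    Returns ``{segment name -> subsequence}`` on success, or a failure
    string (``"too_short"`` or ``"anchor_not_found:<name>"``).  Anchors are
    located with up to their ``max_mismatches`` substitutions within a
    positional window of +-``jitter`` nt; downstream offsets shift with the
    found anchor position (robust to small synthesis slippage, though the
    error model proper is substitution-only).
    """
    out: dict[str, str] = {}
    offset = 0
    for seg in layout.segments:
        if seg.kind == "anchor":
            pos = _find_anchor(seq, seg.sequence, offset, seg.max_mismatches, jitter)
            if pos is None:
                return f"anchor_not_found:{seg.name}"
            out[seg.name] = seq[pos:pos + seg.length]
            offset = pos + seg.length
        elif seg.kind == "payload":
            if len(seq) - offset < seg.min_length:
                return "too_short"
            out[seg.name] = seq[offset:]
            offset = len(seq)
        else:  # barcode / umi: fixed-length slice
            end = offset + seg.length
            if end > len(seq):
                return "too_short"
            out[seg.name] = seq[offset:end]
            offset = end
    return out


def build_umi_whitelist(candidates: Iterable[str], min_len: int = 10,
                        max_len: int = 12, trunc_len: int = 10,
                        min_count: int = 1) -> UmiWhitelist:
    """Collect plausible UMIs from the data itself.

    A candidate survives if its length lies in [min_len, max_len] and it
    contains no N; survivors are truncated to ``trunc_len`` and counted.
    Defaults mirror the adapter-trimming settings the whitelist construction
    is modelled on (accept 10-12 nt, truncate to 10, reject any N).
    """
    wl = UmiWhitelist()
    for cand in candidates:
        if not (min_len <= len(cand) <= max_len) or "N" in cand:
            continue
        wl.counts[cand[:trunc_len]] += 1
    if min_count > 1:
        wl.counts = Counter({u: c for u, c in wl.counts.items() if c >= min_count})
    return wl


def _unique_best(seq: str, entries: tuple[str, ...], max_mm: int) -> int | None:
    """0-based index of the unique entry within max_mm; None on miss or tie."""
    best_i, best_mm, tie = None, max_mm + 1, False
    for i, e in enumerate(entries):
        mm = 0
        for a, b in zip(seq, e):
            if a != b:
                mm += 1
                if mm > best_mm:
                    break
        else:
            if mm < best_mm:
                best_i, best_mm, tie = i, mm, False
            elif mm == best_mm:
                tie = True
    return None if tie or best_i is None else best_i


def match_barcode(seq: str, bset: BarcodeSet, max_mm: int = 1) -> int | None:
    """1-based whitelist index of ``seq``, tolerating <= max_mm substitutions.

    Unique-best-hit semantics: None when no entry is close enough or when
    two entries tie at the minimal distance (ambiguity rejection).
    """
    if len(seq) != bset.length:
        raise ValueError(f"query length {len(seq)} != barcode length {bset.length}")
    hit = bset.index_of(seq)
    if hit is not None or max_mm == 0:
        return hit
    i = _unique_best(seq, bset.entries, max_mm)
    return None if i is None else i + 1


class _SpacerMatcher:
    """Locates the scaffold flank on the payload mate and matches the spacer.

    The spacer is whatever precedes the flank; per library entry the last
    ``len(spacer)`` bases before the flank are compared, which supports
    mixed 18-21 nt spacer lengths.
    """

    def __init__(self, lib: SgRNALibrary, flank: str,
                 flank_max_mm: int | None = None):
        self.lib = lib
        self.flank = flank
        # error-rate 0.1 convention: 1 mismatch allowed per 10 nt of flank
        self.flank_max_mm = (len(flank) // 10 if flank_max_mm is None
                             else flank_max_mm)
        self._exact = {s: n for s, n in zip(lib.spacers, lib.names)}
        self._lengths = sorted({len(s) for s in lib.spacers})

    def find_flank(self, payload: str) -> int | None:
        pos = payload.find(self.flank)
        if pos >= 0:
            return pos
        if self.flank_max_mm == 0:
            return None
        L = len(self.flank)
        for pos in range(0, len(payload) - L + 1):
            mm = 0
            for a, b in zip(payload[pos:pos + L], self.flank):
                if a != b:
                    mm += 1
                    if mm > self.flank_max_mm:
                        break
            else:
                return pos
        return None

    def match(self, payload: str, max_mm: int = 2) -> tuple[str | None, str | None]:
        """(sgrna_name, drop_detail)."""
        pos = self.find_flank(payload)
        if pos is None:
            return None, "spacer_flank_missing"
        for L in self._lengths:  # exact fast path
            if pos >= L:
                name = self._exact.get(payload[pos - L:pos])
                if name is not None:
                    return name, None
        if max_mm == 0:
            return None, "spacer_unmatched"
        best, best_mm, tie = None, max_mm + 1, False
        for spacer, name in zip(self.lib.spacers, self.lib.names):
            L = len(spacer)
            if pos < L:
                continue
            q = payload[pos - L:pos]
            mm = 0
            for a, b in zip(q, spacer):
                if a != b:
                    mm += 1
                    if mm > best_mm:
                        break
            else:
                if mm < best_mm:
                    best, best_mm, tie = name, mm, False
                elif mm == best_mm:
                    tie = True
        if best is None or tie:
            return None, "spacer_unmatched"
        return best, None


def match_spacer(payload: str, lib: SgRNALibrary, max_mm: int = 2,
                 flank: str | None = None) -> str | None:
    """Convenience wrapper around :class:`_SpacerMatcher` for one payload."""
    from .chemistry import DEFAULT_SCAFFOLD_FLANK

    matcher = _SpacerMatcher(lib, flank or DEFAULT_SCAFFOLD_FLANK)
    name, _ = matcher.match(payload, max_mm=max_mm)
    return name


def demux_reads(
    payload_reads: Iterable[tuple[str, str]] | str | Path,
    barcode_reads: Iterable[tuple[str, str]] | str | Path,
    profile: ChemistryProfile,
    lib: SgRNALibrary,
    options: DemuxOptions | None = None,
    umi_whitelist: UmiWhitelist | None = None,
) -> tuple[list[DemuxRecord], Counter]:
    """Demultiplex a read pair stream into DemuxRecords plus attrition counts.

    ``payload_reads`` (mate 1: spacer + scaffold) and ``barcode_reads``
    (mate 2: barcodes + UMI) may be FASTQ(.gz) paths or iterables of
    (read_id, sequence).  When no UMI whitelist is supplied one is built
    from the data in a first pass over mate 2 (the production behaviour).

    Every input read yields exactly one record; ``assigned + sum(dropped
    reasons) == total`` always holds.  The function is deterministic.
    """
    options = options or DemuxOptions()
    layout = profile.sgrna_layout
    xr, yr = profile.sgrna_roles
    set_x, set_y = profile.barcode_sets[xr], profile.barcode_sets[yr]

    def as_pairs(src):
        if isinstance(src, (str, Path)):
            return [(rid.split()[0], seq) for rid, seq, _ in open_fastq(src)]
        return [(rid, seq) for rid, seq in src]

    p1 = as_pairs(payload_reads)
    p2 = as_pairs(barcode_reads)
    if len(p1) != len(p2):
        raise ValueError(f"mate files of unequal length: {len(p1)} vs {len(p2)}")

    extracted: list[dict[str, str] | str] = [
        extract_segments(seq, layout, jitter=options.anchor_jitter) for _, seq in p2
    ]
    umi_name = layout.umi_segment.name

    if umi_whitelist is None and options.umi_filter:
        umi_whitelist = build_umi_whitelist(
            e[umi_name] for e in extracted if isinstance(e, dict)
        )

    matcher = _SpacerMatcher(lib, profile.scaffold_flank)
    bx_name = f"barcode_{xr}"
    by_name = f"barcode_{yr}"

    records: list[DemuxRecord] = []
    attrition: Counter = Counter()
    for (rid1, payload), (rid2, _), segs in zip(p1, p2, extracted):
        if rid1 != rid2:
            raise ValueError(f"mate read ids differ: {rid1!r} vs {rid2!r}")
        if not isinstance(segs, dict):
            records.append(DemuxRecord(rid1, None, None, None, None,
                                       f"dropped:extract:{segs}"))
            attrition["extract"] += 1
            continue
        umi = segs[umi_name]
        if options.umi_filter and (umi_whitelist is None or umi not in umi_whitelist):
            records.append(DemuxRecord(rid1, None, None, None, umi, "dropped:umi"))
            attrition["umi"] += 1
            continue
        x = match_barcode(segs[bx_name], set_x, options.max_mm_barcode)
        if x is None:
            records.append(DemuxRecord(rid1, None, None, None, umi,
                                       "dropped:barcode_x"))
            attrition["barcode_x"] += 1
            continue
        y = match_barcode(segs[by_name], set_y, options.max_mm_barcode)
        if y is None:
            records.append(DemuxRecord(rid1, x, None, None, umi,
                                       "dropped:barcode_y"))
            attrition["barcode_y"] += 1
            continue
        sg, detail = matcher.match(payload, max_mm=options.max_mm_spacer)
        if sg is None:
            records.append(DemuxRecord(rid1, x, y, None, umi,
                                       f"dropped:spacer:{detail}"))
            attrition["spacer"] += 1
            continue
        records.append(DemuxRecord(rid1, x, y, sg, umi, "assigned"))
        attrition["assigned"] += 1
    return records, attrition


def dedup_umis(records: Iterable[DemuxRecord],
               collapse: bool = False) -> set[tuple[tuple[int, int], str, str]]:
    """Deduplicate assigned records to distinct ((x, y), sgRNA, UMI) triples.

    With ``collapse=True`` a directional one-mismatch merge is applied
    within each (spot, sgRNA) group: UMI u' folds into UMI u when they are
    at Hamming distance 1 and u has at least twice the read support of u'.
    Off by default.
    """
    by_group: dict[tuple[tuple[int, int], str], Counter] = {}
    for r in records:
        if not r.assigned:
            continue
        key = ((r.x, r.y), r.sgrna)
        by_group.setdefault(key, Counter())[r.umi] += 1

    triples: set[tuple[tuple[int, int], str, str]] = set()
    for (spot, sg), umis in by_group.items():
        kept: list[str]
        if not collapse or len(umis) == 1:
            kept = list(umis)
        else:
            order = sorted(umis, key=lambda u: (-umis[u], u))
            kept = []
            for u in order:
                parent = None
                for k in kept:
                    if umis[k] >= 2 * umis[u] and _ham1(k, u):
                        parent = k
                        break
                if parent is None:
                    kept.append(u)
        triples.update((spot, sg, u) for u in kept)
    return triples


def _ham1(a: str, b: str) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return False
    return mm == 1
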
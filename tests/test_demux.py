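"""Read parsing, mismatch-tolerant matching, and demultiplexing semantics."""

from collections import Counter

import numpy as np
import pytest

from spotscreen.chemistry import BarcodeSet
from spotscreen.demux import (
    DemuxOptions,
    DemuxRecord,
    build_umi_whitelist,
    dedup_umis,
    demux_reads,
    extract_segments,
    match_barcode,
    match_spacer,
)
from spotscreen.sim import SceneParams, random_barcode_set, simulate_scene


def _assemble(profile, x, y, umi):
    """Build a clean mate-2 read straight from the layout (test-local)."""
    parts = []
    for seg in profile.sgrna_layout.segments:
        if seg.kind == "anchor":
            parts.append(seg.sequence)
        elif seg.kind == "barcode":
            bset = profile.barcode_sets[seg.role]
            parts.append(bset.entries[(x if seg.role == "A" else y) - 1])
        else:
            parts.append(umi)
    return "".join(parts)


class TestExtractSegments:
    def test_clean_read_recovered_verbatim(self, small_profile):
        read = _assemble(small_profile, 2, 3, "ACGTACGTAC")
        segs = extract_segments(read, small_profile.sgrna_layout)
        assert segs["umi"] == "ACGTACGTAC"
        assert segs["barcode_A"] == small_profile.barcode_sets["A"].entries[1]
        assert segs["barcode_B"] == small_profile.barcode_sets["B"].entries[2]

    def test_one_substitution_in_linker_tolerated(self, small_profile):
        read = list(_assemble(small_profile, 1, 1, "ACGTACGTAC"))
        # mutate one base inside the first linker (offset 8..17)
        read[10] = "A" if read[10] != "A" else "C"
        segs = extract_segments("".join(read), small_profile.sgrna_layout)
        assert isinstance(segs, dict) and segs["umi"] == "ACGTACGTAC"

    def test_missing_second_linker_fails_with_stage_name(self, small_profile):
        read = _assemble(small_profile, 1, 1, "ACGTACGTAC")
        broken = read[:26] + "ACGTACGTAC" * 2  # clobber linker_b onwards
        assert extract_segments(broken, small_profile.sgrna_layout) == \
            "anchor_not_found:linker_b"

    def test_short_read_fails(self, small_profile):
        read = _assemble(small_profile, 1, 1, "ACGTACGTAC")
        assert extract_segments(read[:40], small_profile.sgrna_layout) == "too_short"


class TestUmiWhitelist:
    def test_truncation_merges_counts(self):
        wl = build_umi_whitelist(
            ["ACGTACGTAC"] * 3 + ["ACGTACGTACGT"]
        )
        assert wl.counts == Counter({"ACGTACGTAC": 4})

    def test_n_containing_candidate_excluded(self):
        assert len(build_umi_whitelist(["ACGTNCGTAC"])) == 0

    def test_short_candidate_excluded(self):
        assert len(build_umi_whitelist(["ACGTACGTA"])) == 0  # length 9 < 10


@pytest.fixture(scope="module")
def bset():
    return random_barcode_set(20, "A", seed=5)  # min distance >= 4


class TestMatchBarcode:

    def test_exact_hit(self, bset):
        assert match_barcode(bset.entries[6], bset) == 7

    def test_single_mismatch_corrected(self, bset):
        q = list(bset.entries[2])
        q[0] = "A" if q[0] != "A" else "C"
        assert match_barcode("".join(q), bset, max_mm=1) == 3

    def test_tie_rejected(self):
        bset = BarcodeSet("A", ("AAAAAAAA", "AAAAAATT"))
        # equidistant (1) from both entries
        assert match_barcode("AAAAAAAT", bset, max_mm=1) is None

    def test_length_mismatch_raises(self, bset):
        with pytest.raises(ValueError):
            match_barcode("ACGT", bset)

    def test_single_error_correction_exhaustive(self):
        """Min pairwise distance >= 3 makes 1-substitution correction sound."""
        bset = random_barcode_set(12, "A", min_dist=3, seed=9)
        for idx, entry in enumerate(bset.entries, start=1):
            for pos in range(bset.length):
                for b in "ACGT":
                    if b == entry[pos]:
                        continue
                    corrupted = entry[:pos] + b + entry[pos + 1:]
                    assert match_barcode(corrupted, bset, max_mm=1) == idx

    def test_distance_2_set_can_misassign_hence_unsafe(self):
        """Below the 2m+1 bound a single error may hit a wrong entry."""
        bset = BarcodeSet("A", ("AAAAAAAA", "AATTAAAA"))  # distance 2
        assert match_barcode("AATAAAAA", bset, max_mm=1) is None  # tie


class TestMatchSpacer:
    def test_exact(self, small_library):
        payload = small_library.spacers[0] + "GTTTAAGAGC" + "T" * 10
        assert match_spacer(payload, small_library) == "sgS100A4"

    def test_two_mismatches_tolerated(self, small_library):
        sp = list(small_library.spacers[1])
        sp[0], sp[5] = "A", "A"
        payload = "".join(sp) + "GTTTAAGAGC" + "T" * 10
        assert match_spacer(payload, small_library, max_mm=2) == "sgMT1E"

    def test_equidistant_ambiguity_rejected(self):
        from spotscreen.chemistry import SgRNALibrary

        lib = SgRNALibrary(
            names=("a", "b"),
            spacers=("AAAAAAAAAAAAAAAAAAAA", "AAAAAAAAAAAAAAAAAATT"),
            targets=("X", "Y"),
            is_ntc=(False, False),
        )
        payload = "AAAAAAAAAAAAAAAAAAAT" + "GTTTAAGAGC"
        assert match_spacer(payload, lib, max_mm=2) is None

    def test_missing_flank(self, small_library):
        assert match_spacer("ACGT" * 10, small_library) is None


def _corrupt_barcode_region(seq, rng):
    """Scramble the barcode_B slice (first 8 nt) beyond 1-mm reach."""
    return "".join(rng.permuted(list("ACGT" * 2))) [:8] + seq[8:]


class TestDemuxReads:
    def test_error_free_reads_fully_recovered(self, tiny_scene):
        records, att = demux_reads(
            tiny_scene.reads1, tiny_scene.reads2, tiny_scene.profile,
            tiny_scene.lib,
        )
        assert att["assigned"] == len(tiny_scene.reads1)
        assert dedup_umis(records) == tiny_scene.truth_triples

    def test_constructed_barcode_failures_counted(self, small_profile,
                                                  small_library):
        reads2 = []
        reads1 = []
        umi = "ACGTACGTAC"
        payload = small_library.spacers[0] + "GTTTAAGAGC" + "T" * 20
        for i in range(50):
            seq = _assemble(small_profile, 1 + i % 4, 1 + (i // 4) % 4, umi)
            if i < 10:  # scramble barcode_B slice to distance > 1 from all
                seq = "CGCGCGCG" + seq[8:]
            reads1.append((f"r{i}", payload))
            reads2.append((f"r{i}", seq))
        records, att = demux_reads(
            reads1, reads2, small_profile, small_library
        )
        # barcode_B rides the y axis of the PAC layout's first slice
        assert att["barcode_y"] == 10
        assert att["assigned"] == 40

    def test_conservation_of_reads(self, tiny_scene):
        scene = simulate_scene(
            SceneParams(grid=(20, 20), n_clones=4, clone_mean_size=8,
                        umi_mean=4, error_rate=0.02, panel=(50, 10, 5, 5)),
            seed=3,
        )
        records, att = demux_reads(
            scene.reads1, scene.reads2, scene.profile, scene.lib
        )
        assert sum(att.values()) == len(scene.reads1) == len(records)
        by_status = Counter(
            r.status.split(":")[1] if not r.assigned else "assigned"
            for r in records
        )
        assert by_status["assigned"] == att["assigned"]

    def test_monotone_in_mismatch_budget(self):
        scene = simulate_scene(
            SceneParams(grid=(20, 20), n_clones=4, clone_mean_size=8,
                        umi_mean=4, error_rate=0.02, panel=(50, 10, 5, 5)),
            seed=4,
        )
        assigned = []
        for mm_b, mm_s in [(0, 0), (1, 1), (1, 2), (2, 2)]:
            _, att = demux_reads(
                scene.reads1, scene.reads2, scene.profile, scene.lib,
                DemuxOptions(max_mm_barcode=mm_b, max_mm_spacer=mm_s),
            )
            assigned.append(att["assigned"])
        assert assigned == sorted(assigned)

    def test_deterministic(self, tiny_scene):
        a = demux_reads(tiny_scene.reads1, tiny_scene.reads2,
                        tiny_scene.profile, tiny_scene.lib)
        b = demux_reads(tiny_scene.reads1, tiny_scene.reads2,
                        tiny_scene.profile, tiny_scene.lib)
        assert a[0] == b[0] and a[1] == b[1]

    def test_unequal_mate_files_rejected(self, tiny_scene):
        with pytest.raises(ValueError, match="unequal"):
            demux_reads(tiny_scene.reads1[:-1], tiny_scene.reads2,
                        tiny_scene.profile, tiny_scene.lib)


def _oracle_demux(reads1, reads2, profile, lib, max_mm_barcode=1,
                  max_mm_spacer=2, jitter=2):
    """Independent brute-force re-matcher (loops everywhere, no fast paths)."""
    layout = profile.sgrna_layout

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    def extract(seq):
        out, off = {}, 0
        for seg in layout.segments:
            if seg.kind == "anchor":
                best = None
                for d in sorted(range(-jitter, jitter + 1),
                                key=lambda d: (abs(d), d)):
                    pos = off + d
                    if pos < 0 or pos + seg.length > len(seq):
                        continue
                    mm = ham(seq[pos:pos + seg.length], seg.sequence)
                    if mm <= seg.max_mismatches and (best is None or mm < best[0]):
                        best = (mm, pos)
                if best is None:
                    return None
                off = best[1] + seg.length
            else:
                if off + seg.length > len(seq):
                    return None
                out[seg.name] = seq[off:off + seg.length]
                off += seg.length
        return out

    extracted = [extract(seq) for _, seq in reads2]
    whitelist = Counter(
        e["umi"] for e in extracted if e is not None
    )

    def bc(seq, entries):
        dists = [ham(seq, e) for e in entries]
        best = min(dists)
        if best > max_mm_barcode or dists.count(best) > 1:
            return None
        return dists.index(best) + 1

    xr, yr = profile.sgrna_roles
    out = []
    for (rid, payload), e in zip(reads1, extracted):
        if e is None:
            out.append((rid, None))
            continue
        if e["umi"] not in whitelist:
            out.append((rid, None))
            continue
        x = bc(e[f"barcode_{xr}"], profile.barcode_sets[xr].entries)
        y = bc(e[f"barcode_{yr}"], profile.barcode_sets[yr].entries)
        if x is None or y is None:
            out.append((rid, None))
            continue
        # flank: leftmost exact, else leftmost within tolerance
        flank = profile.scaffold_flank
        fpos = payload.find(flank)
        if fpos < 0:
            fpos = next(
                (p for p in range(len(payload) - len(flank) + 1)
                 if ham(payload[p:p + len(flank)], flank) <= 1),
                None,
            )
        if fpos is None:
            out.append((rid, None))
            continue
        cands = []
        for name, spacer in zip(lib.names, lib.spacers):
            L = len(spacer)
            if fpos >= L:
                cands.append((ham(payload[fpos - L:fpos], spacer), name))
        best = min(c[0] for c in cands)
        hits = [n for d, n in cands if d == best]
        if best > max_mm_spacer or len(hits) > 1:
            out.append((rid, None))
        else:
            out.append((rid, (x, y, hits[0], e["umi"])))
    return out


class TestOracleEquivalence:
    def test_noisy_demux_matches_brute_force_oracle(self):
        scene = simulate_scene(
            SceneParams(grid=(15, 15), n_clones=4, clone_mean_size=8,
                        umi_mean=4, error_rate=0.005, panel=(50, 10, 5, 5)),
            seed=12,
        )
        records, _ = demux_reads(
            scene.reads1, scene.reads2, scene.profile, scene.lib
        )
        oracle = _oracle_demux(scene.reads1, scene.reads2, scene.profile,
                               scene.lib)
        assert len(records) == len(oracle)
        for rec, (rid, exp) in zip(records, oracle):
            assert rec.read_id == rid
            if exp is None:
                assert not rec.assigned
            else:
                assert rec.assigned
                assert (rec.x, rec.y, rec.sgrna, rec.umi) == exp


class TestDedupUmis:
    def _rec(self, umi, n, spot=(1, 1), sg="g1"):
        return [DemuxRecord(f"r{umi}{i}", spot[0], spot[1], sg, umi, "assigned")
                for i in range(n)]

    def test_identical_reads_collapse_to_one_triple(self):
        assert len(dedup_umis(self._rec("ACGTACGTAC", 5))) == 1

    def test_one_mismatch_umis_kept_when_collapse_off(self):
        recs = self._rec("ACGTACGTAC", 1) + self._rec("ACGTACGTAT", 1)
        assert len(dedup_umis(recs, collapse=False)) == 2

    def test_directional_collapse_merges_minor_umi(self):
        recs = self._rec("ACGTACGTAC", 10) + self._rec("ACGTACGTAT", 1)
        triples = dedup_umis(recs, collapse=True)
        assert triples == {((1, 1), "g1", "ACGTACGTAC")}

    def test_collapse_requires_double_abundance(self):
        recs = self._rec("ACGTACGTAC", 3) + self._rec("ACGTACGTAT", 2)
        assert len(dedup_umis(recs, collapse=True)) == 2
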
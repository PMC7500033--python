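"""Split-read alignment, junction calling, left alignment, and the
detection catalog."""

import numpy as np
import pytest

import mitodel as M
from mitodel.refmap import CircularReference, DeletionSpan
from mitodel.splitread import (AlignmentResult, AmbiguousJunctionError, Anchor,
                               ReadAligner, SplitAlignment, UndefinedLoadError,
                               build_catalog, call_junction, deletion_load,
                               left_align, mate_contradicts, mean_quality,
                               quality_filter, revcomp)


def junction_read(ref, span, left_flank, right_flank):
    """Read crossing a deletion junction with the given flank lengths."""
    left = ref.fetch(span.ls5 - left_flank, span.ls5 - 1)
    right = ref.fetch(span.hs5 + 1, span.hs5 + right_flank)
    return left + right


@pytest.fixture(scope="module")
def aligner(ref):
    return ReadAligner(ref)


class TestAlignSplit:
    def test_common_deletion_junction_read(self, ref, aligner):
        read = junction_read(ref, DeletionSpan(8471, 13447), 100, 101)
        res = aligner.align(read)
        assert res is not None and res.kind == "split"
        span = left_align(call_junction(res.split, ref), ref)
        assert (span.ls5, span.hs5) == (8471, 13447)
        assert res.split.gap % ref.length == 4977 or res.split.gap == 4977

    def test_contiguous_read_not_split(self, ref, aligner):
        read = ref.fetch(100, 250)
        res = aligner.align(read)
        assert res is not None and res.kind == "contig"
        a = res.anchors[0]
        assert (a.ref_start, a.ref_end) == (100, 250)

    def test_reverse_complement_read_aligned_on_forward_axis(self, ref, aligner):
        read = revcomp(junction_read(ref, DeletionSpan(8471, 13447), 80, 80))
        res = aligner.align(read)
        assert res is not None and res.kind == "split"
        span = left_align(call_junction(res.split, ref), ref)
        assert (span.ls5, span.hs5) == (8471, 13447)

    def test_random_sequence_unalignable(self, ref, aligner):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=120))
        assert aligner.align(read) is None

    def test_origin_crossing_junction(self, ref, aligner):
        # deletion wrapping position 1: junction between 16400 and 600
        span = DeletionSpan(16401, 599, wraps=True)
        read = junction_read(ref, span, 75, 75)
        res = aligner.align(read)
        assert res is not None and res.kind == "split"
        called = left_align(call_junction(res.split, ref), ref)
        recovered = left_align(span, ref)
        assert (called.ls5, called.hs5) == (recovered.ls5, recovered.hs5)

    def test_tolerates_scattered_mismatches(self, ref, aligner):
        read = list(junction_read(ref, DeletionSpan(8471, 13447), 100, 100))
        read[30] = "A" if read[30] != "A" else "C"
        read[170] = "A" if read[170] != "A" else "C"
        res = aligner.align("".join(read))
        assert res is not None and res.kind == "split"
        span = left_align(call_junction(res.split, ref), ref)
        assert (span.ls5, span.hs5) == (8471, 13447)


class TestCallJunction:
    L = 16571

    def _split(self, left_end, right_start):
        la = Anchor(0, 50, left_end - 49, left_end)
        ra = Anchor(50, 100, right_start, right_start + 49)
        return SplitAlignment(la, ra)

    @pytest.mark.parametrize("left_end,right_start,expected", [
        (8470, 13448, (8471, 13447)),
        (10013, 12406, (10014, 12405)),
    ])
    def test_last_missing_base_convention(self, ref, left_end, right_start, expected):
        span = call_junction(self._split(left_end, right_start), ref)
        assert (span.ls5, span.hs5) == expected

    def test_minimal_wrap(self, ref):
        span = call_junction(self._split(self.L, self.L + 2), ref)
        assert (span.ls5, span.hs5) == (1, 1)

    def test_overlapping_anchors_rejected(self, ref):
        with pytest.raises(AmbiguousJunctionError):
            call_junction(self._split(5000, 5000), ref)


class TestLeftAlign:
    def test_homopolymer_shifts_to_leftmost(self):
        seq = "ACGT" * 25 + "AAAAAA" + "CGTA" * 25
        ref = CircularReference("r", seq)
        run_start = 101  # 1-based start of the A-run
        oracle = min(
            k for k in range(run_start, run_start + 6)
            if seq[:k - 1] + seq[k:] == seq[:run_start - 1] + seq[run_start:]
        )
        got = left_align(DeletionSpan(run_start + 3, run_start + 3), ref)
        assert (got.ls5, got.hs5) == (oracle, oracle)

    def test_no_homology_is_fixpoint(self, ref):
        span = DeletionSpan(7000, 13000)  # tmh 0 on the bundled reference
        assert left_align(span, ref) == span

    def test_idempotent(self, ref):
        span = left_align(DeletionSpan(8484, 13460), ref)
        assert left_align(span, ref) == span

    def test_common_deletion_representations_collapse(self, ref):
        # all 14 equivalent representations across the 13-bp repeat
        for k in range(14):
            span = DeletionSpan(8471 + k, 13447 + k)
            got = left_align(span, ref)
            assert (got.ls5, got.hs5) == (8471, 13447)


class TestQualityFilter:
    def _pair(self, q1, q2, n=60):
        seq = "A" * n
        qual1 = chr(q1 + 33) * n
        qual2 = chr(q2 + 33) * n
        return ("r", (seq, qual1), (seq, qual2))

    def test_threshold_behavior(self):
        pairs = [self._pair(25, 30), self._pair(19, 35), self._pair(20, 20)]
        kept = list(quality_filter(pairs, 20))
        assert len(kept) == 2  # the (19, 35) pair drops as a pair

    def test_empty_stream(self):
        assert list(quality_filter([], 20)) == []

    def test_mean_quality(self):
        assert mean_quality("I" * 10) == pytest.approx(40.0)


class TestReconcile:
    def test_contiguous_mate_over_junction_contradicts(self, ref):
        span = DeletionSpan(8471, 13447)
        covering = AlignmentResult(
            "contig", (Anchor(0, 150, 8400, 8549),))
        assert mate_contradicts(span, covering, ref.length)

    def test_distant_mate_is_compatible(self, ref):
        span = DeletionSpan(8471, 13447)
        away = AlignmentResult("contig", (Anchor(0, 150, 2000, 2149),))
        assert not mate_contradicts(span, away, ref.length)

    def test_homology_extension_does_not_contradict(self, ref):
        # a contiguous alignment ending inside the 13-bp repeat covers ls5
        # but not ls5 + margin; it must not suppress the junction
        span = DeletionSpan(8471, 13447)
        grazing = AlignmentResult("contig", (Anchor(0, 150, 8334, 8483),))
        assert not mate_contradicts(span, grazing, ref.length)


class TestCatalog:
    def test_wildtype_only_sample_has_no_calls(self, ref, tmp_path):
        from mitodel.synth import PopulationSpec

        spec = PopulationSpec(ref=ref, species=[], depth=60, seed=3)
        M.generate_reads(spec, tmp_path / "1.fq", tmp_path / "2.fq")
        cat = build_catalog(tmp_path / "1.fq", tmp_path / "2.fq", ref)
        assert len(cat.calls) == 0
        assert cat.r_t > 0
        covered = cat.depth > 0
        assert covered.mean() > 0.99

    def test_known_deletant_recovered(self, ref, small_catalog, small_sample):
        calls = small_catalog.calls
        keys = set(zip(calls["ls5"], calls["hs5"]))
        for span, _f in small_sample["species"]:
            la = left_align(span, ref)
            assert (la.ls5, la.hs5) in keys

    def test_depth_conservation(self, small_catalog):
        # total depth equals total aligned bases = r_t * L_r
        assert small_catalog.depth.sum() == pytest.approx(
            small_catalog.r_t * small_catalog.L_r)

    def test_deterministic_rerun(self, ref, small_sample):
        c1 = build_catalog(small_sample["fq1"], small_sample["fq2"], ref)
        c2 = build_catalog(small_sample["fq1"], small_sample["fq2"], ref)
        assert c1.calls.equals(c2.calls)
        assert np.array_equal(c1.depth, c2.depth)
        assert (c1.r_t, c1.L_r) == (c2.r_t, c2.L_r)

    def test_catalog_roundtrip_tsv(self, small_catalog, tmp_path):
        from mitodel.splitread import DeletionCatalog

        small_catalog.write(tmp_path)
        back = DeletionCatalog.read(tmp_path)
        assert back.calls.equals(
            small_catalog.calls.astype(back.calls.dtypes.to_dict()))
        assert back.r_t == small_catalog.r_t


class TestDeletionLoad:
    def test_formula(self, small_catalog):
        cat = small_catalog
        load = deletion_load(cat)
        assert load["per_mbp"] == pytest.approx(
            cat.calls["x_i"].sum() / (cat.r_t * cat.L_r) * 1e6)

    def test_fixed_example(self):
        from tests.conftest import make_catalog

        cat = make_catalog([(1000, 2000, 300)], r_t=100_000, L_r=100.0)
        assert deletion_load(cat)["per_mbp"] == pytest.approx(30.0)

    def test_zero_junctions(self):
        from tests.conftest import make_catalog

        cat = make_catalog([], r_t=1000)
        assert deletion_load(cat)["per_mbp"] == 0.0

    def test_no_reads_undefined(self):
        from tests.conftest import make_catalog

        cat = make_catalog([], r_t=0)
        with pytest.raises(UndefinedLoadError):
            deletion_load(cat)


class TestRoundTrip:
    @pytest.mark.parametrize("ls5,hs5", [
        (1000, 3500), (6100, 9100), (9498, 11498), (14197, 15797),
        (12000, 15500),
    ])
    def test_synthesized_junction_recalled_left_aligned(self, ref, aligner,
                                                        ls5, hs5):
        span = DeletionSpan(ls5, hs5)
        expected = left_align(span, ref)
        for lf, rf in ((30, 120), (75, 75), (120, 30)):
            res = aligner.align(junction_read(ref, span, lf, rf))
            assert res is not None and res.kind == "split"
            got = left_align(call_junction(res.split, ref), ref)
            assert (got.ls5, got.hs5) == (expected.ls5, expected.hs5)
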
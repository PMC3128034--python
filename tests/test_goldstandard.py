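"""Gold-standard construction: oracle vs seeded builds, rates, GSI round trips."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import make_instance, rand_seq
from mapbench.alignment import (
    DistanceModel,
    reset_touched,
    touched_positions,
)
from mapbench.goldstandard import (
    GoldStandard,
    GsiFormatError,
    SeedMatch,
    annotate_min_k,
    build_oracle,
    build_seeded,
    extend_interval,
    rate_to_k,
    read_gsi,
    write_gsi,
)
from mapbench.seqs import Sequence, reverse_complement


def complete_seeds(gs: GoldStandard):
    """One seed per gold interval: its first (feasible) end position."""
    return [
        SeedMatch(iv.read_id, iv.contig_id, iv.strand, iv.first) for iv in gs
    ]


def seed_sam(path, gs, reads, refs):
    """Write seeds as a minimal SAM file (end position encoded via POS+CIGAR)."""
    read_map = {r.id: r for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for c in refs:
            fh.write(f"@SQ\tSN:{c.id}\tLN:{len(c)}\n")
        for s in complete_seeds(gs):
            read = read_map[s.read_id]
            m = len(read)
            pos = max(0, s.end - m + 1)
            span = s.end - pos + 1
            cigar = f"{span}M" + (f"{m - span}I" if m > span else "")
            seq = read.bases if s.strand == "+" else reverse_complement(read).bases
            flag = 16 if s.strand == "-" else 0
            fh.write(
                f"{s.read_id}\t{flag}\t{s.contig_id}\t{pos + 1}\t255\t{cigar}"
                f"\t*\t0\t0\t{seq}\t*\n"
            )


class TestRateToK:
    @pytest.mark.parametrize("rate,length,k", [(8, 36, 2), (8, 100, 8), (0, 50, 0)])
    def test_examples(self, rate, length, k):
        assert rate_to_k(rate, length) == k

    def test_floor_never_rounds_up(self):
        for length in range(1, 300):
            assert rate_to_k(8, length) == (8 * length) // 100

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rate_to_k(-1, 36)


class TestBuildOracle:
    def test_verbatim_read_rate_zero(self, rng):
        ref = rand_seq(rng, 150, "c")
        read = Sequence("r0", ref.bases[40:60])
        gs = build_oracle([ref], [read], DistanceModel.EDIT, 0)
        fwd = [iv for iv in gs if iv.strand == "+"]
        assert any(iv.first <= 59 <= iv.last for iv in fwd)
        for iv in gs:
            assert iv.k == 0 and iv.min_k == 0

    def test_read_without_occurrence_has_no_intervals(self, rng):
        ref = Sequence("c", "A" * 100)
        read = Sequence("r0", "CGCGCGCGCG")
        gs = build_oracle([ref], [read], DistanceModel.EDIT, 10)
        assert sum(len(v) for v in gs.intervals.values()) == 0

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            build_oracle([Sequence("c", "ACGT")], [], DistanceModel.EDIT, 0)

    def test_contig_id_collision_rejected(self, rng):
        c = rand_seq(rng, 50, "c")
        with pytest.raises(ValueError):
            build_oracle([c, c], [Sequence("r", "ACGT")], DistanceModel.EDIT, 0)


class TestExtendInterval:
    def test_unique_exact_seed(self, rng):
        ref = rand_seq(rng, 200, "c")
        read = Sequence("r0", ref.bases[100:120])
        seed = SeedMatch("r0", "c", "+", 119)
        iv = extend_interval(seed, read, ref, DistanceModel.EDIT, 0)
        assert (iv.first, iv.last, iv.min_k) == (119, 119, 0)

    def test_short_tandem_repeat_merges_to_one_wide_interval(self):
        # off-phase end positions inside a period-2 repeat cost 2 (an indel
        # shift plus the forced mismatch), so the lakes fuse at k = 2
        ref = Sequence("c", "TTGTTGTTG" + "AC" * 20 + "GTTGTTGTT")
        read = Sequence("r0", "ACACAC")
        k = 2
        gs = build_oracle([ref], [read], DistanceModel.EDIT, k, rate_mode=False)
        oracle_fwd = [iv for iv in gs if iv.strand == "+" and iv.k == k]
        assert len(oracle_fwd) == 1  # one merged class across the repeat
        seed = SeedMatch("r0", "c", "+", oracle_fwd[0].first)
        iv = extend_interval(seed, read, ref, DistanceModel.EDIT, k)
        assert iv == oracle_fwd[0]

    def test_two_seeds_same_class_identical(self, rng):
        read, ref = make_instance(rng, 150, 10, 2)
        gs = build_oracle([ref], [read], DistanceModel.EDIT, 20)
        for iv in gs:
            if iv.first == iv.last:
                continue
            a = extend_interval(
                SeedMatch(iv.read_id, iv.contig_id, iv.strand, iv.first),
                read, ref, DistanceModel.EDIT, iv.k,
            )
            b = extend_interval(
                SeedMatch(iv.read_id, iv.contig_id, iv.strand, iv.last),
                read, ref, DistanceModel.EDIT, iv.k,
            )
            assert a == b == iv

    def test_infeasible_seed_returns_none(self, rng):
        ref = Sequence("c", "A" * 60)
        read = Sequence("r0", "CCCCCC")
        assert (
            extend_interval(SeedMatch("r0", "c", "+", 30), read, ref,
                            DistanceModel.EDIT, 1)
            is None
        )

    def test_window_locality(self, rng):
        """Seeded extension inspects O(interval + read + k) positions."""
        ref = rand_seq(rng, 5000, "c")
        read = Sequence("r0", ref.bases[2500:2530])
        reset_touched()
        iv = extend_interval(
            SeedMatch("r0", "c", "+", 2529), read, ref, DistanceModel.EDIT, 2
        )
        touched = touched_positions()
        budget = 12 * ((iv.last - iv.first + 1) + len(read) + 2)
        assert touched <= budget
        assert touched < len(ref)  # a fraction of the reference only


class TestBuildSeeded:
    @pytest.mark.parametrize("model", [DistanceModel.EDIT, DistanceModel.HAMMING])
    def test_complete_seeds_reproduce_oracle(self, rng, model):
        for _ in range(10):
            reads = []
            ref = None
            read, ref = make_instance(rng, int(rng.integers(60, 200)), 12, 3)
            read = Sequence("r0", read.bases)
            gs = build_oracle([ref], [read], model, 20)
            seeded = build_seeded([ref], [read], complete_seeds(gs), model, 20)
            assert seeded.intervals == gs.intervals

    def test_seeds_via_sam_path(self, rng, tmp_path):
        read, ref = make_instance(rng, 120, 12, 2)
        read = Sequence("r0", read.bases)
        gs = build_oracle([ref], [read], DistanceModel.EDIT, 16)
        sam = tmp_path / "seeds.sam"
        seed_sam(sam, gs, [read], [ref])
        seeded = build_seeded([ref], [read], str(sam), DistanceModel.EDIT, 16)
        assert seeded.intervals == gs.intervals

    def test_missing_seed_leaves_class_out(self, rng):
        ref = Sequence("c", "T" * 30 + "ACGTACGTGG" + "T" * 30 + "ACGTACGTGG" + "T" * 30)
        read = Sequence("r0", "ACGTACGTGG")
        gs = build_oracle([ref], [read], DistanceModel.HAMMING, 0)
        seeds = complete_seeds(gs)
        fwd = [s for s in seeds if s.strand == "+"]
        assert len(fwd) == 2
        partial = build_seeded([ref], [read], [fwd[0]], DistanceModel.HAMMING, 0)
        got = [iv for iv in partial if iv.strand == "+"]
        assert len(got) == 1 and got[0].first == fwd[0].end

    def test_duplicate_seeds_idempotent(self, rng):
        read, ref = make_instance(rng, 100, 10, 2)
        read = Sequence("r0", read.bases)
        gs = build_oracle([ref], [read], DistanceModel.EDIT, 10)
        seeds = complete_seeds(gs)
        doubled = build_seeded([ref], [read], seeds + seeds, DistanceModel.EDIT, 10)
        single = build_seeded([ref], [read], seeds, DistanceModel.EDIT, 10)
        assert doubled.intervals == single.intervals

    def test_over_budget_seed_reported_not_raised(self):
        ref = Sequence("c", "A" * 50)
        read = Sequence("r0", "ACCCCC")
        gs = build_seeded(
            [ref], [read], [SeedMatch("r0", "c", "+", 20)], DistanceModel.EDIT, 0
        )
        assert len(gs.invalid_seeds) == 1
        assert sum(len(v) for v in gs.intervals.values()) == 0


class TestAnnotateMinK:
    def test_min_k_equals_min_delta_oracle(self, rng):
        from mapbench.alignment import landscape

        for _ in range(8):
            read, ref = make_instance(rng, 100, 10, 3)
            read = Sequence("r0", read.bases)
            gs = build_oracle([ref], [read], DistanceModel.EDIT, 30)
            ann = annotate_min_k(gs)
            assert ann.intervals == gs.intervals  # builders already exact
            for iv in ann:
                query = read if iv.strand == "+" else reverse_complement(read)
                land = landscape(query, ref, DistanceModel.EDIT)
                assert iv.min_k == int(land.delta[iv.first : iv.last + 1].min())

    def test_annotation_fills_unset_min_k(self, rng):
        read, ref = make_instance(rng, 80, 10, 2)
        read = Sequence("r0", read.bases)
        gs = build_oracle([ref], [read], DistanceModel.EDIT, 20)
        stripped = replace(gs, intervals={
            key: [replace(iv, min_k=-1) for iv in ivals]
            for key, ivals in gs.intervals.items()
        })
        assert annotate_min_k(stripped).intervals == gs.intervals


class TestGsiRoundTrip:
    def test_round_trip_identity(self, rng, tmp_path):
        read, ref = make_instance(rng, 120, 12, 3)
        read = Sequence("r0", read.bases)
        gs = build_oracle([ref], [read], DistanceModel.EDIT, 25)
        path = tmp_path / "gold.gsi"
        write_gsi(gs, path)
        loaded = read_gsi(path)
        assert loaded.intervals == gs.intervals
        assert loaded.model == gs.model
        assert loaded.max_error_rate == gs.max_error_rate

    def test_empty_standard_is_header_only(self, tmp_path):
        gs = GoldStandard(DistanceModel.HAMMING, 4.0)
        path = tmp_path / "empty.gsi"
        write_gsi(gs, path)
        text = path.read_text()
        assert all(line.startswith("@") for line in text.splitlines())
        assert read_gsi(path).intervals == {}

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.gsi"
        path.write_text("@MAPBENCH-GSI\tVERSION:99\n@MODEL:edit\n@RATE:8\n")
        with pytest.raises(GsiFormatError):
            read_gsi(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gsi"
        path.write_text(
            "@MAPBENCH-GSI\tVERSION:1\n@MODEL:edit\n@RATE:8\nr0\tc\t+\tnope\n"
        )
        with pytest.raises(GsiFormatError, match=":4"):
            read_gsi(path)
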
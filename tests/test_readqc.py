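"""Raw-read filtering criteria, pair-level semantics, duplicate removal."""
from __future__ import annotations

import numpy as np
import pytest

from somaclone._seq import encode
from somaclone.config import QCConfig
from somaclone.genome import build_donor_genome
from somaclone.readqc import (REASONS, assess_read, filter_pairs,
                              remove_duplicates)
from somaclone.simulate import PairAlignments, SampleReads, simulate_reads

from conftest import small_sim_config

CFG = QCConfig()
Q40 = [40] * 100


def mk_reads(pairs):
    """Build a SampleReads batch from [(seq1, qual1, seq2, qual2), ...]."""
    s1 = np.stack([encode(p[0]) for p in pairs])
    q1 = np.stack([np.array(p[1], dtype=np.uint8) for p in pairs])
    s2 = np.stack([encode(p[2]) for p in pairs])
    q2 = np.stack([np.array(p[3], dtype=np.uint8) for p in pairs])
    return SampleReads("t", s1.shape[1], s1, q1, s2, q2,
                       np.zeros(len(pairs), dtype=bool))


class TestAssessRead:
    def test_n_fraction_strictly_exceeding_ten_percent_fails(self):
        seq = "N" * 11 + "A" * 89
        assert "N_FRACTION" in assess_read(seq, Q40, 1, CFG).reasons

    def test_exactly_ten_percent_n_passes(self):
        seq = "N" * 10 + "A" * 90
        assert assess_read(seq, Q40, 1, CFG).passed

    def test_mean_quality_boundary_is_strict(self):
        assert assess_read("A" * 100, [15] * 100, 1, CFG).passed
        v = assess_read("A" * 100, [14] * 100, 1, CFG)
        assert "MEAN_QUALITY" in v.reasons

    def test_low_quality_fraction_boundary(self):
        qual = [14] * 10 + [40] * 90           # exactly 10% under 15
        assert assess_read("A" * 100, qual, 1, CFG).passed
        qual = [14] * 11 + [40] * 89
        assert "LOW_QUAL_FRACTION" in assess_read("A" * 100, qual, 1, CFG).reasons

    def test_adapter_suffix_of_ten_bases_fails_mate1(self):
        seq = "A" * 90 + CFG.index_adapter_seq[:10]
        assert "ADAPTER" in assess_read(seq, Q40, 1, CFG).reasons

    def test_adapter_nine_bases_passes(self):
        seq = "A" * 91 + CFG.index_adapter_seq[:9]
        assert "ADAPTER" not in assess_read(seq, Q40, 1, CFG).reasons

    def test_mate2_checks_reverse_complement_of_universal_adapter(self):
        from somaclone._seq import revcomp_str
        rc = revcomp_str(CFG.universal_adapter_seq)
        seq = "A" * 88 + rc[:12]
        assert "ADAPTER" in assess_read(seq, Q40, 2, CFG).reasons
        assert "ADAPTER" not in assess_read(seq, Q40, 1, CFG).reasons

    def test_strict_adapter_mode_requires_more_than_threshold(self):
        strict = QCConfig(adapter_match_strict=True)
        seq10 = "A" * 90 + CFG.index_adapter_seq[:10]
        seq11 = "A" * 89 + CFG.index_adapter_seq[:11]
        assert "ADAPTER" not in assess_read(seq10, Q40, 1, strict).reasons
        assert "ADAPTER" in assess_read(seq11, Q40, 1, strict).reasons

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assess_read("ACGT", [40] * 3, 1, CFG)

    def test_verdict_consistency(self):
        v = assess_read("A" * 100, Q40, 1, CFG)
        assert v.passed and not v.reasons


class TestFilterPairs:
    def test_clean_pairs_all_pass(self):
        reads = mk_reads([("A" * 100, Q40, "C" * 100, Q40)] * 5)
        keep, report = filter_pairs(reads, CFG)
        assert len(keep) == 5 and report.n_pairs_removed == 0

    def test_pair_removed_when_only_mate2_fails(self):
        reads = mk_reads([("A" * 100, Q40, "C" * 100, [10] * 100),
                          ("A" * 100, Q40, "C" * 100, Q40)])
        keep, report = filter_pairs(reads, CFG)
        assert list(keep) == [1]
        assert report.pairs_failed["MEAN_QUALITY"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(50):
            s = "".join(rng.choice(list("ACGTN"), 100, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
            q = rng.integers(5, 41, 100).tolist()
            pairs.append((s, q, s, q))
        reads = mk_reads(pairs)
        keep1, _ = filter_pairs(reads, CFG)
        keep2, _ = filter_pairs(reads, CFG, idx=keep1)
        assert np.array_equal(keep1, keep2)

    def test_monotone_in_n_fraction_threshold(self):
        rng = np.random.default_rng(4)
        pairs = []
        for _ in range(80):
            s = "".join(rng.choice(list("ACGTN"), 100, p=[0.2, 0.2, 0.2, 0.2, 0.2]))
            pairs.append((s, Q40, s, Q40))
        reads = mk_reads(pairs)
        passes = []
        for thr in (0.05, 0.10, 0.20, 0.40, 1.0):
            keep, _ = filter_pairs(reads, QCConfig(max_n_fraction=thr))
            passes.append(len(keep))
        assert passes == sorted(passes)

    def test_survivors_pass_rescan(self):
        cfg = small_sim_config(n_base_rate=0.02, qual_start=24, qual_end=16,
                               autosome_length=60_000, sex_chrom_length=20_000)
        donor, _ = build_donor_genome(cfg)
        reads, _ = simulate_reads(donor, cfg, "donor")
        keep, _ = filter_pairs(reads, CFG)
        for i in keep[:300]:
            assert assess_read(reads.seq1[i], reads.qual1[i], 1, CFG).passed
            assert assess_read(reads.seq2[i], reads.qual2[i], 2, CFG).passed


def mk_aln(rows, chroms=("chr1",)):
    """rows: (chrom1, pos1, chrom2, pos2); all mapped, FR, aln_len 100."""
    n = len(rows)
    arr = lambda vals, dt: np.array(vals, dtype=dt)
    return PairAlignments(
        chroms=list(chroms),
        chrom1=arr([r[0] for r in rows], np.int32),
        pos1=arr([r[1] for r in rows], np.int64),
        aln_len1=arr([100] * n, np.int32),
        mapped1=np.ones(n, bool),
        chrom2=arr([r[2] for r in rows], np.int32),
        pos2=arr([r[3] for r in rows], np.int64),
        aln_len2=arr([100] * n, np.int32),
        mapped2=np.ones(n, bool),
    )


class TestRemoveDuplicates:
    def test_unique_coordinates_untouched(self):
        aln = mk_aln([(0, 100, 0, 300), (0, 200, 0, 400), (0, 500, 0, 700)])
        reads = mk_reads([("A" * 100, Q40, "C" * 100, Q40)] * 3)
        kept = remove_duplicates(aln, reads)
        assert list(kept) == [0, 1, 2]

    def test_identical_pairs_collapse_to_highest_quality(self):
        aln = mk_aln([(0, 100, 0, 300), (0, 100, 0, 300)])
        reads = mk_reads([("A" * 100, [30] * 100, "C" * 100, [30] * 100),
                          ("A" * 100, [40] * 100, "C" * 100, [40] * 100)])
        kept = remove_duplicates(aln, reads)
        assert list(kept) == [1]

    def test_quality_tie_keeps_lower_index(self):
        aln = mk_aln([(0, 100, 0, 300), (0, 100, 0, 300)])
        reads = mk_reads([("A" * 100, Q40, "C" * 100, Q40)] * 2)
        assert list(remove_duplicates(aln, reads)) == [0]

    def test_unsorted_input_rejected(self):
        aln = mk_aln([(0, 500, 0, 700), (0, 100, 0, 300)])
        reads = mk_reads([("A" * 100, Q40, "C" * 100, Q40)] * 2)
        with pytest.raises(ValueError, match="sorted"):
            remove_duplicates(aln, reads)

    def test_idempotent(self):
        aln = mk_aln([(0, 100, 0, 300), (0, 100, 0, 300), (0, 200, 0, 420)])
        reads = mk_reads([("A" * 100, Q40, "C" * 100, Q40)] * 3)
        k1 = remove_duplicates(aln, reads)
        k2 = remove_duplicates(aln, reads, idx=k1)
        assert np.array_equal(k1, k2)

    def test_simulated_duplicates_removed_at_configured_fraction(self):
        cfg = small_sim_config(duplicate_fraction=0.05, autosome_length=200_000,
                               sex_chrom_length=60_000)
        donor, _ = build_donor_genome(cfg)
        reads, aln = simulate_reads(donor, cfg, "donor")
        order = np.lexsort((aln.pos1, aln.chrom1))
        kept = remove_duplicates(aln, reads, order)
        removed = aln.n_pairs - len(kept)
        n_dup_truth = int(reads.is_duplicate.sum())
        # every truth duplicate shares coordinates with its source
        assert removed >= 0.9 * n_dup_truth
        assert removed <= 1.2 * n_dup_truth + 20


def test_reasons_enumeration_is_stable():
    assert REASONS == ("N_FRACTION", "MEAN_QUALITY", "LOW_QUAL_FRACTION", "ADAPTER")
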
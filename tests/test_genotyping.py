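"""Genotype caller semantics: scalar oracle agreement, boundaries, indels."""
from __future__ import annotations

import math

import numpy as np
import pytest

from somaclone.config import CallerConfig
from somaclone.genotyping import (CallableMask, GENOTYPES, PileupColumn,
                                  SamplePileup, call_genotype, call_indels,
                                  call_variants, callable_region,
                                  genotype_log_posteriors, _posterior_probs,
                                  iter_pileup_columns)

from conftest import small_sim_config


def col(ref, bases, quals, chrom="chr1", pos=100):
    return PileupColumn(chrom=chrom, pos=pos, ref_base=ref,
                        bases=np.array(bases, dtype=np.uint8),
                        quals=np.array(quals, dtype=np.int64))


# independent log-space enumeration oracle (pure python, per observation)
def oracle_call(ref_code, bases, quals, theta=0.001, min_depth=5,
                max_depth=200, min_gq=10.0):
    obs = [(b, q) for b, q in zip(bases, quals) if b < 4]
    depth = len(obs)
    if depth < min_depth or depth > max_depth:
        return None
    counts = [0, 0, 0, 0]
    for b, _ in obs:
        counts[b] += 1
    nonref = [(c if i != ref_code else 0) for i, c in enumerate(counts)]
    if sum(nonref) == 0:
        return None
    alt_code = int(np.argmax(nonref))
    logls = []
    for gt in ((ref_code, ref_code), (ref_code, alt_code), (alt_code, alt_code)):
        ll = 0.0
        for b, q in obs:
            eps = min(max(10 ** (-q / 10), 1e-12), 0.999999)
            p = 0.0
            for allele in gt:
                p += 0.5 * ((1 - eps) if b == allele else eps / 3)
            ll += math.log(p)
        logls.append(ll)
    priors = [math.log(1 - 1.5 * theta), math.log(theta), math.log(theta / 2)]
    post = [l + p for l, p in zip(logls, priors)]
    m = max(post)
    probs = [math.exp(x - m) for x in post]
    z = sum(probs)
    probs = [x / z for x in probs]
    best = int(np.argmax(probs))
    gq = -10 * math.log10(max(1 - probs[best], 1e-300))
    if best == 0 or gq < min_gq:
        return None
    return GENOTYPES[best], gq, alt_code


class TestCallGenotype:
    def test_depth_below_window_is_no_call(self):
        c = col("A", [2, 2, 2, 2], [40] * 4)  # four clear G reads
        assert call_genotype(c) is None

    def test_overwhelming_alt_evidence_is_hom_alt(self):
        c = col("A", [2] * 30, [40] * 30)
        v = call_genotype(c)
        assert v.genotype == "1/1" and v.genotype_quality >= 10
        assert v.allele_depths == (0, 30)

    def test_balanced_alleles_call_het(self):
        c = col("A", [0] * 15 + [2] * 15, [40] * 30)
        v = call_genotype(c)
        assert v.genotype == "0/1"
        o = oracle_call(0, c.bases, c.quals)
        assert o[0] == "0/1"
        assert v.genotype_quality == pytest.approx(o[1], abs=1e-6)

    @pytest.mark.parametrize("depth,callable_", [(4, False), (5, True),
                                                 (200, True), (201, False)])
    def test_depth_window_boundaries(self, depth, callable_):
        c = col("A", [2] * depth, [40] * depth)
        v = call_genotype(c)
        assert (v is not None) == callable_

    def test_non_acgt_reference_is_no_call(self):
        c = col("N", [0] * 20, [40] * 20)
        assert call_genotype(c) is None

    def test_agrees_with_enumeration_oracle_on_random_columns(self, rng):
        for _ in range(1000):
            depth = int(rng.integers(1, 13))
            ref_code = int(rng.integers(0, 4))
            bases = rng.choice([ref_code, (ref_code + 2) % 4, (ref_code + 1) % 4, 4],
                               size=depth, p=[0.55, 0.3, 0.1, 0.05]).astype(np.uint8)
            quals = rng.integers(5, 41, size=depth)
            c = col("ACGT"[ref_code], bases, quals)
            mine = call_genotype(c)
            theirs = oracle_call(ref_code, bases, quals)
            if theirs is None:
                assert mine is None
            else:
                assert mine is not None
                assert mine.genotype == theirs[0]
                assert mine.genotype_quality == pytest.approx(theirs[1], abs=1e-6)

    def test_posterior_sums_to_one(self, rng):
        for _ in range(100):
            depth = int(rng.integers(1, 30))
            bases = rng.integers(0, 4, depth).astype(np.uint8)
            quals = rng.integers(2, 41, depth)
            lp = genotype_log_posteriors(0, 2, bases, quals, 0.001)
            assert _posterior_probs(lp).sum() == pytest.approx(1.0, abs=1e-9)


def uniform_pileup(depth_value, L=1000, chrom="chr1"):
    counts = np.zeros((4, L), dtype=np.uint16)
    counts[0] = depth_value
    return SamplePileup([chrom], {chrom: counts},
                        {chrom: np.full(L, depth_value, dtype=np.int32)}, {})


class TestCallableRegion:
    def test_uniform_depth_inside_window_counts_every_base(self):
        mask = callable_region(uniform_pileup(20))
        assert mask.size == 1000

    def test_depth_below_minimum_gives_empty_mask(self):
        assert callable_region(uniform_pileup(4)).size == 0

    def test_boundaries_inclusive(self):
        assert callable_region(uniform_pileup(5)).size == 1000
        assert callable_region(uniform_pileup(200)).size == 1000
        assert callable_region(uniform_pileup(201)).size == 0

    def test_intersection(self):
        a = callable_region(uniform_pileup(20))
        b_pile = uniform_pileup(20)
        b_pile.depth["chr1"][:500] = 2
        b = callable_region(b_pile)
        assert a.intersect(b).size == 500


class TestCallIndels:
    def test_no_observations_no_calls(self):
        assert call_indels(uniform_pileup(20)).empty

    def test_half_supported_deletion_called_het(self):
        pile = uniform_pileup(10)
        pile.indel_obs[("chr1", 50, "D", 3)] = 10
        calls = call_indels(pile)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row["kind"], row["length"], row["genotype"]) == ("D", 3, "0/1")
        assert row.pos == 51

    def test_full_support_called_hom(self):
        pile = uniform_pileup(20)
        pile.indel_obs[("chr1", 50, "I", "ACG")] = 19
        calls = call_indels(pile)
        assert calls.iloc[0]["genotype"] == "1/1"

    def test_below_support_fraction_dropped(self):
        pile = uniform_pileup(20)
        pile.indel_obs[("chr1", 50, "I", "A")] = 3  # 3/20 < 0.25
        assert call_indels(pile).empty

    def test_conflicting_alleles_keep_majority(self):
        pile = uniform_pileup(20)
        pile.indel_obs[("chr1", 50, "D", 2)] = 8
        pile.indel_obs[("chr1", 50, "D", 3)] = 3
        calls = call_indels(pile)
        assert len(calls) == 1 and calls.iloc[0]["length"] == 2


class TestVectorizedPath:
    def test_vectorized_calls_match_scalar_on_simulated_data(self):
        cfg = small_sim_config(autosome_length=60_000, sex_chrom_length=20_000,
                               somatic_snv_rate=0, somatic_indel_rate=0,
                               telomere_length_donor=0, telomere_length_clone=0)
        from somaclone.genome import build_donor_genome
        from somaclone.simulate import simulate_reads
        donor, _ = build_donor_genome(cfg)
        reads, aln = simulate_reads(donor, cfg, "donor")
        calls, _ = call_variants(reads, aln, donor.reference)
        assert len(calls) > 10  # germline hets are present
        by_site = {(r.chrom, r.pos): r for r in calls.itertuples(index=False)}
        checked = 0
        for column in iter_pileup_columns(reads, aln, donor.reference):
            v = call_genotype(column)
            key = (column.chrom, column.pos)
            if v is None:
                assert key not in by_site
            else:
                assert key in by_site
                row = by_site[key]
                assert row.genotype == v.genotype
                assert row.gq == pytest.approx(v.genotype_quality, rel=1e-6)
                checked += 1
            if checked >= 40:
                break
        assert checked >= 20

    def test_error_free_diploid_reads_recover_truth_exactly(self):
        cfg = small_sim_config(autosome_length=100_000, sex_chrom_length=20_000,
                               base_error_rate=0, n_base_rate=0,
                               somatic_snv_rate=0, somatic_indel_rate=0,
                               telomere_length_donor=0, telomere_length_clone=0,
                               duplicate_fraction=0)
        from somaclone.genome import build_donor_genome
        from somaclone.simulate import simulate_reads
        donor, truth = build_donor_genome(cfg)
        reads, aln = simulate_reads(donor, cfg, "donor")
        calls, pileup = call_variants(reads, aln, donor.reference)
        mask = callable_region(pileup)
        truth_in_mask = truth.germline[
            [mask.contains(c, p) for c, p in zip(truth.germline.chrom,
                                                 truth.germline.pos)]]
        called = set(zip(calls.chrom, calls.pos, calls.alt))
        expected = set(zip(truth_in_mask.chrom, truth_in_mask.pos, truth_in_mask.alt))
        missing = expected - called
        extra = called - expected
        assert not extra
        # allelic sampling can leave a het unbalanced even without errors
        assert len(missing) <= 0.02 * max(len(expected), 1)


def test_pileup_counts_simple_columns():
    cfg = small_sim_config(autosome_length=50_000, sex_chrom_length=20_000,
                           base_error_rate=0, n_base_rate=0, germline_het_rate=0,
                           somatic_snv_rate=0, somatic_indel_rate=0,
                           telomere_length_donor=0, telomere_length_clone=0,
                           duplicate_fraction=0)
    from somaclone.genome import build_donor_genome
    from somaclone.simulate import simulate_reads
    from somaclone.genotyping import build_pileup
    donor, _ = build_donor_genome(cfg)
    reads, aln = simulate_reads(donor, cfg, "donor")
    pile = build_pileup(reads, aln, {c: len(s) for c, s in donor.reference.items()})
    chrom = "chr1"
    counts = pile.counts[chrom]
    ref = donor.reference[chrom]
    # with no noise, every observation matches the reference base
    interior = slice(500, 45_000)
    depth = pile.depth[chrom][interior]
    ref_counts = counts[np.minimum(ref[interior], 3), np.arange(*interior.indices(len(ref))[:2])]
    assert np.array_equal(depth, ref_counts)
    assert abs(depth.mean() - cfg.coverage) / cfg.coverage < 0.05
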
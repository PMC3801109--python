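"""Generator correctness: determinism, planted-event statistics, read truth."""
from __future__ import annotations

import numpy as np
import pytest

from somaclone._seq import COMP, decode, encode
from somaclone.config import ConfigError, SimulationConfig
from somaclone.genome import build_donor_genome, derive_clone_genome
from somaclone.io import write_fastq_pair
from somaclone.simulate import simulate_pair, simulate_reads

from conftest import small_sim_config


def test_same_seed_gives_byte_identical_fastq(tmp_path):
    cfg = small_sim_config(autosome_length=100_000, sex_chrom_length=40_000)
    outputs = []
    for run in ("a", "b"):
        _, _, _, dr, _, cr, _ = simulate_pair(cfg)
        p1, p2 = tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq"
        write_fastq_pair(dr, p1, p2)
        outputs.append((p1.read_bytes(), p2.read_bytes(), cr.seq1.tobytes()))
    assert outputs[0] == outputs[1]


def test_zero_telomere_leaves_termini_random():
    cfg = small_sim_config(telomere_length_donor=0, telomere_length_clone=0)
    donor, _ = build_donor_genome(cfg)
    seq, _ = donor.materialize("chr1", 0)
    for terminus in (decode(seq[:600]), decode(seq[-600:])):
        assert "TTAGGG" * 4 not in terminus
        assert "CCCTAA" * 4 not in terminus


def test_telomere_tracts_present_at_both_termini():
    cfg = small_sim_config(telomere_length_donor=1200)
    donor, _ = build_donor_genome(cfg)
    for chrom in ("chr1", "chrX"):
        seq, _ = donor.materialize(chrom, 0)
        assert "CCCTAA" * 10 in decode(seq[:1200])
        assert "TTAGGG" * 10 in decode(seq[-1200:])
    mito, _ = donor.materialize("chrM", 0)
    assert "TTAGGG" * 4 not in decode(mito)


def test_germline_het_count_within_poisson_bound():
    cfg = SimulationConfig(seed=5, n_autosomes=1, autosome_length=1_000_000,
                           sex_chrom_length=50_000, germline_het_rate=1e-3,
                           telomere_length_donor=0, telomere_length_clone=0)
    _, truth = build_donor_genome(cfg)
    n = (truth.germline["chrom"] == "chr1").sum()
    assert abs(n - 1000) <= 3 * np.sqrt(1000)


def test_somatic_snv_count_within_poisson_bound():
    # 3.77/Mb on a 10 Mb diploid nuclear genome: ~38 planted events
    cfg = SimulationConfig(seed=6, n_autosomes=5, autosome_length=1_960_000,
                           sex_chrom_length=200_000, germline_het_rate=1e-4,
                           telomere_length_donor=0, telomere_length_clone=0)
    donor, _ = build_donor_genome(cfg)
    _, truth = derive_clone_genome(donor, cfg)
    nuclear = truth.somatic_snvs.query("compartment != 'mitochondrial'")
    expected = 3.77 * 10.0
    assert abs(len(nuclear) - expected) <= 4 * np.sqrt(expected)


def test_zero_rates_give_identical_clone():
    cfg = small_sim_config(somatic_snv_rate=0, somatic_indel_rate=0,
                           mito_divergence=0)
    donor, _ = build_donor_genome(cfg)
    clone, truth = derive_clone_genome(donor, cfg)
    assert truth.somatic_snvs.empty and truth.somatic_indels.empty
    for chrom in donor.chroms:
        for hap in range(donor.ploidy[chrom]):
            ds, _ = donor.materialize(chrom, hap)
            cs, _ = clone.materialize(chrom, hap)
            assert np.array_equal(ds, cs)


def test_cnv_deletion_shortens_one_haplotype():
    cfg = small_sim_config(cnv_events=[("chr1", 100_000, 150_000, 1)],
                           somatic_snv_rate=0, somatic_indel_rate=0)
    donor, _ = build_donor_genome(cfg)
    clone, truth = derive_clone_genome(donor, cfg)
    assert clone.haplotype_length("chr1", 0) == cfg.autosome_length
    assert clone.haplotype_length("chr1", 1) == cfg.autosome_length - 50_000
    assert truth.cnv_truth.iloc[0]["copy_number"] == 1


def test_expected_pair_count_matches_coverage():
    cfg = small_sim_config(duplicate_fraction=0.0)
    donor, _ = build_donor_genome(cfg)
    reads, _ = simulate_reads(donor, cfg, "donor")
    genome_bp = sum(len(s) for s in donor.reference.values())
    # haploid chrX/chrM run at half dosage
    diploid_bp = sum(len(donor.reference[c]) * donor.ploidy[c] / 2
                     for c in donor.chroms)
    expected = cfg.coverage * diploid_bp / (2 * cfg.read_length)
    assert abs(reads.n_pairs - expected) / expected < 0.01
    assert genome_bp > 0


def test_fragment_length_mean_close_to_insert_mean():
    cfg = SimulationConfig(seed=8, n_autosomes=1, autosome_length=1_000_000,
                           sex_chrom_length=50_000, telomere_length_donor=0,
                           telomere_length_clone=0, duplicate_fraction=0.0)
    donor, _ = build_donor_genome(cfg)
    reads, aln = simulate_reads(donor, cfg, "donor")
    both = aln.both_mapped & (aln.chrom1 == aln.chrom2)
    span = (aln.pos2[both] + aln.aln_len2[both]) - aln.pos1[both]
    assert len(span) >= 1e5
    assert abs(span.mean() - cfg.insert_mean) <= 1.0


def test_zero_duplicate_fraction_means_no_coordinate_sharing(sim_pair):
    cfg = small_sim_config(duplicate_fraction=0.0)
    donor, _ = build_donor_genome(cfg)
    _, aln = simulate_reads(donor, cfg, "donor")
    both = np.nonzero(aln.both_mapped)[0]
    keys = np.stack([aln.chrom1[both], aln.pos1[both],
                     aln.chrom2[both], aln.pos2[both]], axis=1)
    uniq = np.unique(keys, axis=0)
    collisions = len(both) - len(uniq)
    assert collisions / len(both) < 1e-3  # chance collisions only


def test_short_fragments_produce_adapter_readthrough():
    cfg = small_sim_config(insert_mean=150.0, insert_sd=20.0,
                           autosome_length=200_000, duplicate_fraction=0.0)
    donor, _ = build_donor_genome(cfg)
    reads, _ = simulate_reads(donor, cfg, "donor")
    # any read1 whose suffix of length >= 10 equals the adapter head
    found = 0
    for i in range(reads.n_pairs):
        s = decode(reads.seq1[i])
        if any(s[-k:] == cfg.adapter_seq_index[:k]
               for k in range(10, min(len(s), len(cfg.adapter_seq_index)) + 1)):
            found += 1
    assert found > 0


def test_truth_alignments_reproduce_reference_without_noise():
    cfg = small_sim_config(base_error_rate=0.0, n_base_rate=0.0,
                           germline_het_rate=0.0, somatic_snv_rate=0.0,
                           somatic_indel_rate=0.0, mito_divergence=0.0,
                           telomere_length_donor=0, telomere_length_clone=0,
                           duplicate_fraction=0.0)
    donor, _ = build_donor_genome(cfg)
    reads, aln = simulate_reads(donor, cfg, "donor")
    ref = donor.reference
    rl = cfg.read_length
    check = np.random.default_rng(0).choice(reads.n_pairs, 300, replace=False)
    for i in check:
        if aln.mapped1[i] and aln.aln_len1[i] == rl and i not in aln.cigar1:
            chrom = aln.chroms[aln.chrom1[i]]
            sub = ref[chrom][aln.pos1[i]:aln.pos1[i] + rl]
            assert np.array_equal(sub, reads.seq1[i])
        if aln.mapped2[i] and aln.aln_len2[i] == rl and i not in aln.cigar2:
            chrom = aln.chroms[aln.chrom2[i]]
            sub = ref[chrom][aln.pos2[i]:aln.pos2[i] + rl]
            assert np.array_equal(sub, COMP[reads.seq2[i]][::-1])


def test_config_rejections():
    with pytest.raises(ConfigError):
        SimulationConfig(coverage=0).validate()
    with pytest.raises(ConfigError):
        SimulationConfig(insert_mean=90.0, read_length=100).validate()
    with pytest.raises(ConfigError):
        small_sim_config(telomere_length_donor=200_000).validate()
    with pytest.raises(ConfigError):
        small_sim_config(cnv_events=[("chr1", 100, 50, 1)]).validate()
    with pytest.raises(ConfigError):
        small_sim_config(cnv_events=[("chr1", 1000, 2000, 1),
                                     ("chr1", 1500, 2500, 3)]).validate()
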
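"""Paired-end read simulation with truth alignments.

Fragments are drawn per haplotype at half the configured fold coverage each
(so diploid autosomes reach full coverage and the haploid chrX/chrM half),
with Normal(insert_mean, insert_sd) lengths.  Fragments shorter than the read
length cause adapter read-through: the 3' end of each mate runs into the
library adapter, exercising the adapter QC criterion.  A configurable
fraction of fragments is emitted twice (PCR duplicates), sequencing errors
and ambiguous bases are injected at fixed per-base rates, and per-base Phred
qualities decline linearly along the read.

Because fragments are drawn from haplotypes whose block tables map back to
reference coordinates, every read comes with its true alignment (including
small-indel CIGARs); no external aligner is needed downstream.  Reads whose
alignment would cross a structural-variant junction are emitted unmapped,
as a short-read aligner would clip or discard them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import COMP, encode, revcomp
from .config import ConfigError, SimulationConfig
from .genome import (BLOCK_NOVEL, BLOCK_REF, Genome, TruthSet, _seed_streams,
                     build_donor_genome, derive_clone_genome, merge_truth)

MAX_INDEL_IN_READ = 100  # larger jumps are treated as unmappable junction reads
_CHUNK = 200_000


@dataclass
class SampleReads:
    """Vectorized paired reads for one sample (FASTQ orientation)."""

    sample: str
    read_length: int
    seq1: np.ndarray   # (n, L) uint8 codes
    qual1: np.ndarray  # (n, L) uint8 Phred
    seq2: np.ndarray
    qual2: np.ndarray
    is_duplicate: np.ndarray  # (n,) truth label for re-emitted fragments

    @property
    def n_pairs(self) -> int:
        return len(self.seq1)

    def name(self, i: int) -> str:
        return f"{self.sample}:{i}"

    def subset(self, idx: np.ndarray) -> "SampleReads":
        return SampleReads(self.sample, self.read_length,
                           self.seq1[idx], self.qual1[idx],
                           self.seq2[idx], self.qual2[idx],
                           self.is_duplicate[idx])


@dataclass
class PairAlignments:
    """Per-pair alignments against the reference (truth or parsed from SAM).

    Mate 1 is the forward/leftmost read of the fragment, mate 2 the reverse
    one.  ``pos`` is the 0-based leftmost aligned reference position; reads
    with ``mapped`` False have no reference home (novel insertions, junction
    reads).  Non-trivial CIGARs are kept sparsely in ``cigar1``/``cigar2``
    keyed by pair index as lists of ``(op, length)`` with op in "MID".
    """

    chroms: list[str]
    chrom1: np.ndarray
    pos1: np.ndarray
    aln_len1: np.ndarray   # reference span of mate 1
    mapped1: np.ndarray
    chrom2: np.ndarray
    pos2: np.ndarray
    aln_len2: np.ndarray
    mapped2: np.ndarray
    cigar1: dict[int, list] = field(default_factory=dict)
    cigar2: dict[int, list] = field(default_factory=dict)
    rev1: np.ndarray | None = None  # True where the mate aligns to the reverse strand
    rev2: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.pos1)
        if self.rev1 is None:
            self.rev1 = np.zeros(n, dtype=bool)
        if self.rev2 is None:
            self.rev2 = np.ones(n, dtype=bool)

    @property
    def n_pairs(self) -> int:
        return len(self.pos1)

    @property
    def both_mapped(self) -> np.ndarray:
        return self.mapped1 & self.mapped2


def _ref_span(cigar: list) -> int:
    return sum(ln for op, ln in cigar if op in "MD")


def _map_interval(blocks, a: int, b: int):
    """Map haplotype interval [a, b) to (chrom_idx, ref_pos, cigar) or None."""
    i = int(np.searchsorted(blocks.hap_start, a, side="right")) - 1
    ops: list[tuple[str, int]] = []
    chrom = -1
    prev_ref_end = None
    pos = None
    while i < len(blocks.hap_start) and blocks.hap_start[i] < b:
        ov_start = max(a, int(blocks.hap_start[i]))
        ov_end = min(b, int(blocks.hap_end[i]))
        ln = ov_end - ov_start
        if ln > 0:
            if blocks.kind[i] == BLOCK_NOVEL:
                if not ops or ov_end >= b:
                    return None  # leading/trailing insertion: unalignable
                if ln > MAX_INDEL_IN_READ:
                    return None
                ops.append(("I", ln))
            else:
                rs = int(blocks.map_start[i]) + (ov_start - int(blocks.hap_start[i]))
                if chrom == -1:
                    chrom = int(blocks.map_chrom[i])
                    pos = rs
                else:
                    if int(blocks.map_chrom[i]) != chrom:
                        return None
                    gap = rs - prev_ref_end
                    if gap < 0 or gap > MAX_INDEL_IN_READ:
                        return None
                    if gap > 0:
                        ops.append(("D", gap))
                if ops and ops[-1][0] == "M":
                    ops[-1] = ("M", ops[-1][1] + ln)
                else:
                    ops.append(("M", ln))
                prev_ref_end = rs + ln
        i += 1
    if pos is None or not ops or ops[0][0] != "M" or ops[-1][0] != "M":
        return None
    return chrom, pos, ops


def _decline_profile(config: SimulationConfig) -> np.ndarray:
    return np.linspace(config.qual_start, config.qual_end, config.read_length)


def _inject_artifacts(rng, seq: np.ndarray, qual: np.ndarray, config: SimulationConfig) -> None:
    """In-place sequencing errors and ambiguous bases."""
    total = seq.size
    n_err = rng.binomial(total, config.base_error_rate)
    if n_err:
        idx = rng.integers(0, total, size=n_err)
        cur = seq.reshape(-1)[idx]
        ok = cur < 4
        idx = idx[ok]
        shift = rng.integers(1, 4, size=len(idx)).astype(np.uint8)
        seq.reshape(-1)[idx] = (seq.reshape(-1)[idx] + shift) % 4
    n_amb = rng.binomial(total, config.n_base_rate)
    if n_amb:
        idx = rng.integers(0, total, size=n_amb)
        seq.reshape(-1)[idx] = 4
        qual.reshape(-1)[idx] = 2


def simulate_reads(genome: Genome, config: SimulationConfig, sample_tag: str,
                   rng: np.random.Generator | None = None
                   ) -> tuple[SampleReads, PairAlignments]:
    """Sample paired reads from every haplotype of ``genome`` with truth."""
    config.validate()
    if config.coverage <= 0:
        raise ConfigError("coverage must be > 0")
    if rng is None:
        stream = 2 if sample_tag.startswith("donor") else 3
        rng = _seed_streams(config)[stream]
    rl = config.read_length
    profile = _decline_profile(config)
    adapter1 = encode(config.adapter_seq_index)
    adapter2 = revcomp(encode(config.adapter_seq_universal)).copy()

    seq1_parts, qual1_parts, seq2_parts, qual2_parts = [], [], [], []
    c1_parts, p1_parts, c2_parts, p2_parts = [], [], [], []
    len1_parts, len2_parts, map1_parts, map2_parts, dup_parts = [], [], [], [], []
    cigar1: dict[int, list] = {}
    cigar2: dict[int, list] = {}
    pair_offset = 0

    for chrom in genome.chroms:
        for hap in range(genome.ploidy[chrom]):
            seq, blocks = genome.materialize(chrom, hap)
            hap_len = len(seq)
            if hap_len < rl + 1:
                continue
            n_frag = int(round((config.coverage / 2.0) * hap_len / (2.0 * rl)))
            if n_frag == 0:
                continue
            flen = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_frag))
            flen = np.clip(flen, 20, hap_len).astype(np.int64)
            start = rng.integers(0, hap_len - flen + 1)
            n_dup = rng.binomial(n_frag, config.duplicate_fraction)
            if n_dup:
                dup_src = rng.choice(n_frag, size=n_dup, replace=False)
                flen = np.concatenate([flen, flen[dup_src]])
                start = np.concatenate([start, start[dup_src]])
            is_dup = np.zeros(len(flen), dtype=bool)
            is_dup[n_frag:] = True

            for lo in range(0, len(flen), _CHUNK):
                hi = min(lo + _CHUNK, len(flen))
                s, f = start[lo:hi], flen[lo:hi]
                n = len(s)
                r1 = np.empty((n, rl), dtype=np.uint8)
                r2 = np.empty((n, rl), dtype=np.uint8)
                long_mask = f >= rl
                li = np.nonzero(long_mask)[0]
                if len(li):
                    idx1 = s[li, None] + np.arange(rl)
                    r1[li] = seq[idx1]
                    idx2 = (s[li] + f[li] - rl)[:, None] + np.arange(rl)
                    r2[li] = COMP[seq[idx2]][:, ::-1]
                for j in np.nonzero(~long_mask)[0]:
                    frag = seq[s[j]:s[j] + f[j]]
                    over = rl - int(f[j])
                    r1[j, :f[j]] = frag
                    r1[j, f[j]:] = np.resize(adapter1, over)
                    rc = COMP[frag][::-1]
                    r2[j, :f[j]] = rc
                    r2[j, f[j]:] = np.resize(adapter2, over)

                q1 = np.clip(np.rint(profile + config.qual_sd *
                                     rng.standard_normal((n, rl), dtype=np.float32)),
                             2, 41).astype(np.uint8)
                q2 = np.clip(np.rint(profile + config.qual_sd *
                                     rng.standard_normal((n, rl), dtype=np.float32)),
                             2, 41).astype(np.uint8)
                _inject_artifacts(rng, r1, q1, config)
                _inject_artifacts(rng, r2, q2, config)

                # truth alignments
                a1 = s
                b1 = s + np.minimum(f, rl)
                a2 = np.where(long_mask, s + f - rl, s)
                b2 = s + f
                aln1 = (b1 - a1).astype(np.int32)
                aln2 = (b2 - a2).astype(np.int32)

                c1 = np.full(n, -1, dtype=np.int32)
                p1 = np.full(n, -1, dtype=np.int64)
                c2 = np.full(n, -1, dtype=np.int32)
                p2 = np.full(n, -1, dtype=np.int64)
                m1 = np.zeros(n, dtype=bool)
                m2 = np.zeros(n, dtype=bool)

                def map_simple(a, b, cvec, pvec, mvec):
                    bi = np.searchsorted(blocks.hap_start, a, side="right") - 1
                    be = np.searchsorted(blocks.hap_start, b - 1, side="right") - 1
                    simple = (bi == be) & (blocks.kind[bi] == BLOCK_REF)
                    si = np.nonzero(simple)[0]
                    cvec[si] = blocks.map_chrom[bi[si]]
                    pvec[si] = blocks.map_start[bi[si]] + (a[si] - blocks.hap_start[bi[si]])
                    mvec[si] = True
                    return np.nonzero(~simple)[0]

                hard1 = map_simple(a1, b1, c1, p1, m1)
                hard2 = map_simple(a2, b2, c2, p2, m2)
                for j in hard1:
                    res = _map_interval(blocks, int(a1[j]), int(b1[j]))
                    if res is not None:
                        c1[j], p1[j], ops = res
                        m1[j] = True
                        aln1[j] = _ref_span(ops)
                        if len(ops) > 1:
                            cigar1[pair_offset + lo + j] = ops
                for j in hard2:
                    res = _map_interval(blocks, int(a2[j]), int(b2[j]))
                    if res is not None:
                        c2[j], p2[j], ops = res
                        m2[j] = True
                        aln2[j] = _ref_span(ops)
                        if len(ops) > 1:
                            cigar2[pair_offset + lo + j] = ops

                seq1_parts.append(r1); qual1_parts.append(q1)
                seq2_parts.append(r2); qual2_parts.append(q2)
                c1_parts.append(c1); p1_parts.append(p1); len1_parts.append(aln1)
                c2_parts.append(c2); p2_parts.append(p2); len2_parts.append(aln2)
                map1_parts.append(m1); map2_parts.append(m2)
                dup_parts.append(is_dup[lo:hi])
            pair_offset += len(flen)

    reads = SampleReads(
        sample=sample_tag, read_length=rl,
        seq1=np.concatenate(seq1_parts), qual1=np.concatenate(qual1_parts),
        seq2=np.concatenate(seq2_parts), qual2=np.concatenate(qual2_parts),
        is_duplicate=np.concatenate(dup_parts),
    )
    aln = PairAlignments(
        chroms=genome.chroms,
        chrom1=np.concatenate(c1_parts), pos1=np.concatenate(p1_parts),
        aln_len1=np.concatenate(len1_parts), mapped1=np.concatenate(map1_parts),
        chrom2=np.concatenate(c2_parts), pos2=np.concatenate(p2_parts),
        aln_len2=np.concatenate(len2_parts), mapped2=np.concatenate(map2_parts),
        cigar1=cigar1, cigar2=cigar2,
    )
    return reads, aln


def simulate_pair(config: SimulationConfig):
    """Build donor + clone genomes and a read set for each; return with truth.

    Returns ``(donor_genome, clone_genome, truth, donor_reads, donor_aln,
    clone_reads, clone_aln)`` — everything the pipeline stages consume.
    """
    streams = _seed_streams(config)
    donor, truth_g = build_donor_genome(config, streams[0])
    clone, truth_s = derive_clone_genome(donor, config, streams[1])
    truth = merge_truth(truth_g, truth_s)
    donor_reads, donor_aln = simulate_reads(donor, config, "donor", streams[2])
    clone_reads, clone_aln = simulate_reads(clone, config, "clone", streams[3])
    return donor, clone, truth, donor_reads, donor_aln, clone_reads, clone_aln
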
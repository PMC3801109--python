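"""Raw-read filtering and PCR-duplicate removal.

A read fails QC if any of four criteria hold:

1. ``N_FRACTION``       — ambiguous bases exceed 10% of the read (strict >);
2. ``MEAN_QUALITY``     — arithmetic mean Phred is under 15 (strict <);
3. ``LOW_QUAL_FRACTION``— bases under Phred 15 exceed 10% of the read;
4. ``ADAPTER``          — the read tail matches the head of its library
   adapter over at least ``adapter_min_match`` bases (mate 1 against the
   index adapter, mate 2 against the reverse complement of the universal
   adapter), i.e. the fragment was shorter than the read and sequencing ran
   into the adapter.

Filtering is pair-level: if either mate fails, the whole pair is removed,
because every downstream stage consumes pairs.  Quality encoding is fixed to
Phred+33 (the FASTQ reader rejects apparent Phred+64 input).

PCR-duplicate removal mirrors post-alignment ``rmdup``: among pairs sharing
both outer alignment coordinates and orientation, the pair with the highest
summed base quality survives (ties broken by name order).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .config import QCConfig
from .simulate import PairAlignments, SampleReads

REASONS = ("N_FRACTION", "MEAN_QUALITY", "LOW_QUAL_FRACTION", "ADAPTER")


@dataclass
class QCVerdict:
    passed: bool
    reasons: frozenset[str]

    def __post_init__(self):
        assert self.passed == (not self.reasons)


@dataclass
class QCReport:
    n_pairs_in: int = 0
    n_pairs_pass: int = 0
    reads_failed: dict = field(default_factory=lambda: {r: 0 for r in REASONS})
    pairs_failed: dict = field(default_factory=lambda: {r: 0 for r in REASONS})

    @property
    def n_pairs_removed(self) -> int:
        return self.n_pairs_in - self.n_pairs_pass


def _adapter_for_mate(mate_index: int, config: QCConfig) -> np.ndarray:
    if mate_index == 1:
        return encode(config.index_adapter_seq)
    return revcomp(encode(config.universal_adapter_seq)).copy()


def _adapter_hits(seqs: np.ndarray, adapter: np.ndarray, min_match: int,
                  strict: bool) -> np.ndarray:
    """True where a read suffix of length >= min_match equals an adapter prefix.

    For each candidate suffix start ``p`` only rows whose first two bases
    match the adapter head are verified in full, which keeps the scan linear
    in practice.
    """
    n, L = seqs.shape
    if strict:
        min_match = min_match + 1
    m = min(L, len(adapter))
    hit = np.zeros(n, dtype=bool)
    if min_match > m:
        return hit
    for p in range(L - m, L - min_match + 1):
        k = L - p
        if k >= 2:
            cand = (seqs[:, p] == adapter[0]) & (seqs[:, p + 1] == adapter[1]) & ~hit
        else:
            cand = (seqs[:, p] == adapter[0]) & ~hit
        rows = np.nonzero(cand)[0]
        if rows.size:
            full = (seqs[rows, p:] == adapter[:k]).all(axis=1)
            hit[rows[full]] = True
    return hit


def _mate_failures(seqs: np.ndarray, quals: np.ndarray, mate_index: int,
                   config: QCConfig) -> dict[str, np.ndarray]:
    L = seqs.shape[1]
    return {
        "N_FRACTION": (seqs == 4).sum(axis=1) > config.max_n_fraction * L,
        "MEAN_QUALITY": quals.mean(axis=1) < config.min_mean_quality,
        "LOW_QUAL_FRACTION":
            (quals < config.low_quality_threshold).sum(axis=1)
            > config.max_low_quality_fraction * L,
        "ADAPTER": _adapter_hits(seqs, _adapter_for_mate(mate_index, config),
                                 config.adapter_min_match, config.adapter_match_strict),
    }


def assess_read(seq, qual, mate_index: int, config: QCConfig | None = None) -> QCVerdict:
    """Apply the four criteria to a single read (mate_index 1 or 2)."""
    config = config or QCConfig()
    if isinstance(seq, str):
        seq = encode(seq)
    seq = np.asarray(seq, dtype=np.uint8)
    qual = np.asarray(qual, dtype=np.int32)
    if len(seq) == 0:
        raise ValueError("empty read")
    if len(seq) != len(qual):
        raise ValueError(f"sequence length {len(seq)} != quality length {len(qual)}")
    fails = _mate_failures(seq[None, :], qual[None, :], mate_index, config)
    reasons = frozenset(r for r, v in fails.items() if bool(v[0]))
    return QCVerdict(passed=not reasons, reasons=reasons)


def filter_pairs(reads: SampleReads, config: QCConfig | None = None,
                 idx: np.ndarray | None = None) -> tuple[np.ndarray, QCReport]:
    """Pair-level filtering; returns surviving pair indices (order preserved)."""
    config = config or QCConfig()
    config.validate()
    if idx is None:
        idx = np.arange(reads.n_pairs)
    f1 = _mate_failures(reads.seq1[idx], reads.qual1[idx], 1, config)
    f2 = _mate_failures(reads.seq2[idx], reads.qual2[idx], 2, config)
    report = QCReport(n_pairs_in=len(idx))
    pair_fail = np.zeros(len(idx), dtype=bool)
    for r in REASONS:
        report.reads_failed[r] = int(f1[r].sum() + f2[r].sum())
        both = f1[r] | f2[r]
        report.pairs_failed[r] = int(both.sum())
        pair_fail |= both
    keep = idx[~pair_fail]
    report.n_pairs_pass = len(keep)
    return keep, report


def remove_duplicates(aln: PairAlignments, reads: SampleReads,
                      idx: np.ndarray | None = None,
                      require_sorted: bool = True) -> np.ndarray:
    """Keep one pair per (chrom1, pos1, chrom2, pos2, orientation) group.

    The retained pair is the one with the highest summed base quality over
    both mates; ties fall to the lower pair index (name order).  Pairs with
    an unmapped mate are left untouched.  Input pairs must be sorted by
    mate-1 coordinate, as after alignment; unsorted input raises ValueError.
    """
    if idx is None:
        idx = np.arange(aln.n_pairs)
    both = aln.both_mapped[idx]
    midx = idx[both]
    if require_sorted and len(midx) > 1:
        c, p = aln.chrom1[midx], aln.pos1[midx]
        breaks = np.nonzero(np.diff(c) != 0)[0]
        ok_chrom = np.all(np.diff(c) >= 0)
        within = np.diff(p) >= 0
        within[breaks] = True
        if not (ok_chrom and np.all(within)):
            raise ValueError("alignments are not coordinate-sorted")
    if len(midx) == 0:
        return idx
    qsum = (reads.qual1[midx].sum(axis=1, dtype=np.int64)
            + reads.qual2[midx].sum(axis=1, dtype=np.int64))
    orient = aln.rev1[midx].astype(np.int8) + 2 * aln.rev2[midx].astype(np.int8)
    order = np.lexsort((midx, -qsum, aln.pos2[midx], aln.chrom2[midx],
                        orient, aln.pos1[midx], aln.chrom1[midx]))
    keys = np.stack([aln.chrom1[midx][order], aln.pos1[midx][order],
                     aln.chrom2[midx][order], aln.pos2[midx][order],
                     orient[order]], axis=1)
    first = np.ones(len(order), dtype=bool)
    if len(order) > 1:
        first[1:] = (np.diff(keys, axis=0) != 0).any(axis=1)
    kept_mapped = midx[order][first]
    kept = np.concatenate([idx[~both], kept_mapped])
    kept.sort()
    return kept
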
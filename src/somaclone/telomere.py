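"""Relative telomere length from raw reads.

The estimator counts reads containing the telomeric motif TTAGGG repeated
k times in tandem (k = 1..6, exact substring match, both strands by
default) and divides by the total read count.  Permutations of the motif's
base composition (e.g. GGGATT) serve as controls for sequencing-quality
bias: the telomeric fraction is normalized by the mean control fraction.
Controls carry no tandem tracts in a real (or simulated) genome, so their
counts at high multiplicities vanish; the control denominator is therefore
taken at a low multiplicity (default k=1), where chance hits give a stable
per-sample background.  The headline statistic is the normalized fraction
at k=4 — high enough that chance hits are negligible, low enough that a
100 bp read can hold the 24 bp tandem with margin.

Absolute lengths are not estimable this way; ratios between samples
sequenced comparably are.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import CODE_TO_ASCII, revcomp_str
from .config import TelomereConfig
from .simulate import SampleReads

TELOMERE_MOTIF = "TTAGGG"


@dataclass
class TelomereEstimate:
    sample: str
    total_reads: int
    k_max: int
    k_control: int
    telo_counts: np.ndarray                  # index k-1 -> reads with (motif)x k
    control_counts: dict[str, np.ndarray]    # motif -> same structure

    def raw_fraction(self, k: int) -> float:
        return float(self.telo_counts[k - 1]) / self.total_reads

    def control_fraction(self, k: int | None = None) -> float:
        k = self.k_control if k is None else k
        vals = [c[k - 1] / self.total_reads for c in self.control_counts.values()]
        return float(np.mean(vals))

    def normalized(self, k: int) -> float:
        """Telomeric fraction over mean control fraction (NaN if no background)."""
        denom = self.control_fraction()
        if denom == 0:
            return float("nan")
        return self.raw_fraction(k) / denom

    def per_k_table(self) -> dict:
        rows = {"k": list(range(1, self.k_max + 1)),
                "telomere": [int(c) for c in self.telo_counts]}
        for motif, counts in self.control_counts.items():
            rows[motif] = [int(c) for c in counts]
        return rows


def _reads_as_blob(seqs: np.ndarray) -> tuple[bytes, int]:
    """Rows joined with a newline separator so matches cannot span reads."""
    n, L = seqs.shape
    padded = np.full((n, L + 1), ord("\n"), dtype=np.uint8)
    padded[:, :L] = CODE_TO_ASCII[seqs]
    return padded.tobytes(), L + 1


def _rows_with_pattern(blob: bytes, stride: int, pattern: bytes, hit: np.ndarray) -> None:
    start = blob.find(pattern)
    while start != -1:
        hit[start // stride] = True
        start = blob.find(pattern, start + 1)


def count_repeat_reads(reads, motif: str = TELOMERE_MOTIF, k_max: int = 6,
                       include_revcomp: bool = True) -> tuple[np.ndarray, int]:
    """Reads containing (motif) x k as an exact tandem substring, per k.

    ``reads`` may be a SampleReads batch (both mates pooled), a (n, L) code
    array, or an iterable of strings.  Each read is counted at most once per
    k; containment nests, so counts are non-increasing in k.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if isinstance(reads, SampleReads):
        arrays = [reads.seq1, reads.seq2]
    elif isinstance(reads, np.ndarray):
        arrays = [reads]
    else:
        strs = list(reads)
        if not strs:
            raise ValueError("empty read stream")
        from ._seq import encode
        arrays = [np.stack([encode(s) for s in strs])]
    total = sum(len(a) for a in arrays)
    if total == 0:
        raise ValueError("empty read stream")
    counts = np.zeros(k_max, dtype=np.int64)
    patterns = [motif.encode()]
    if include_revcomp:
        patterns.append(revcomp_str(motif).encode())
    for k in range(1, k_max + 1):
        n_hit = 0
        for arr in arrays:
            blob, stride = _reads_as_blob(arr)
            hit = np.zeros(len(arr), dtype=bool)
            for pat in patterns:
                _rows_with_pattern(blob, stride, pat * k, hit)
            n_hit += int(hit.sum())
        counts[k - 1] = n_hit
    return counts, total


def estimate(reads, config: TelomereConfig | None = None,
             sample: str = "sample") -> TelomereEstimate:
    """Full per-k table for the telomeric motif and every control motif."""
    config = config or TelomereConfig()
    config.validate()
    comp = sorted(TELOMERE_MOTIF)
    for motif in config.control_motifs:
        if sorted(motif) != comp:
            raise ValueError(f"control motif {motif!r} is not a base-composition "
                             f"permutation of {TELOMERE_MOTIF}")
    telo, total = count_repeat_reads(reads, TELOMERE_MOTIF, config.k_max,
                                     config.include_revcomp)
    controls = {}
    for motif in config.control_motifs:
        c, _ = count_repeat_reads(reads, motif, config.k_max, config.include_revcomp)
        controls[motif] = c
    return TelomereEstimate(sample=sample, total_reads=total, k_max=config.k_max,
                            k_control=config.k_control, telo_counts=telo,
                            control_counts=controls)


def compare_samples(est_a: TelomereEstimate, est_b: TelomereEstimate,
                    k: int | None = None) -> dict:
    """Relative telomere length ratio a/b at multiplicity k, with both tables."""
    if est_a.k_max != est_b.k_max:
        raise ValueError("estimates were computed with different k_max")
    k = 4 if k is None else k
    na, nb = est_a.normalized(k), est_b.normalized(k)
    if np.isnan(na) or np.isnan(nb) or nb == 0:
        raise ValueError(f"normalized value unavailable at k={k}; use a lower k")
    return {
        "k": k,
        "ratio": na / nb,
        "normalized_a": na,
        "normalized_b": nb,
        "table_a": est_a.per_k_table(),
        "table_b": est_b.per_k_table(),
    }
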
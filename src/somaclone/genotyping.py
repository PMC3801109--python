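"""Pileup construction and simplified biallelic genotype calling.

The calling contract: sites are callable at read depth 5-200; genotypes come
from per-observation likelihoods with P(base|allele) = 1-eps for a match and
eps/3 otherwise (eps = 10^(-Q/10)); the prior puts theta = 0.001 on the
heterozygote, theta/2 on the homozygous alternate, and the remainder on the
homozygous reference; a call is emitted when the posterior-best genotype is
not 0/0 and its Phred-scaled genotype quality is at least 10.

Indels are called from pileup observations by support fraction (default 1/4
of spanning depth; heterozygous below 3/4), a deliberately simple surrogate
for a realignment-based micro-assembly caller.

Two code paths produce identical results: a scalar `call_genotype` on one
`PileupColumn` (the reference semantics, used by tests) and a vectorized
whole-genome path (`call_variants`) used by the pipeline.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import COMP, decode, encode
from .config import CallerConfig
from .simulate import PairAlignments, SampleReads

logger = logging.getLogger(__name__)

_OBS_CHUNK = 100_000
# log-space weight tables by Phred score: match, mismatch, het-match
_QMAX = 64
_q = np.arange(_QMAX, dtype=np.float64)
_eps = np.power(10.0, -_q / 10.0)
_eps = np.clip(_eps, 1e-12, 0.999999)
W_MATCH = np.log(1.0 - _eps)
W_MISMATCH = np.log(_eps / 3.0)
W_HET = np.log(0.5 * (1.0 - _eps) + 0.5 * _eps / 3.0)

GENOTYPES = ("0/0", "0/1", "1/1")


@dataclass
class PileupColumn:
    """Per-site observations for one sample (1-based position)."""

    chrom: str
    pos: int
    ref_base: str
    bases: np.ndarray            # uint8 codes per observation (N allowed)
    quals: np.ndarray            # Phred per observation
    indel_obs: dict = field(default_factory=dict)  # (kind, payload) -> count

    @property
    def depth(self) -> int:
        """Observations carrying a called base (N excluded)."""
        return int((np.asarray(self.bases) < 4).sum())

    @property
    def base_counts(self) -> dict[str, int]:
        b = np.asarray(self.bases)
        return {base: int((b == i).sum()) for i, base in enumerate("ACGT")}


@dataclass
class VariantCall:
    chrom: str
    pos: int                    # 1-based
    ref: str
    alt: str
    genotype: str               # 0/1 or 1/1
    genotype_quality: float
    depth: int
    allele_depths: tuple[int, int]


class CallableMask:
    """Positions with depth inside the callable window, per chromosome."""

    def __init__(self, masks: dict[str, np.ndarray]):
        self.masks = masks

    @property
    def size(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))

    def contains(self, chrom: str, pos1: int) -> bool:
        m = self.masks.get(chrom)
        return bool(m is not None and 0 <= pos1 - 1 < len(m) and m[pos1 - 1])

    def contains_many(self, chroms: pd.Series, pos1: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos1), dtype=bool)
        for chrom, m in self.masks.items():
            sel = (chroms == chrom).to_numpy()
            if sel.any():
                p = pos1[sel] - 1
                ok = (p >= 0) & (p < len(m))
                vals = np.zeros(sel.sum(), dtype=bool)
                vals[ok] = m[p[ok]]
                out[sel] = vals
        return out

    def intersect(self, other: "CallableMask") -> "CallableMask":
        common = {c: self.masks[c] & other.masks[c]
                  for c in self.masks if c in other.masks}
        return CallableMask(common)


@dataclass
class SamplePileup:
    """Vectorized per-chromosome tallies for one sample."""

    chroms: list[str]
    counts: dict[str, np.ndarray]          # (4, L) uint16 base counts
    depth: dict[str, np.ndarray]           # int32 called-base depth
    indel_obs: dict[tuple, int]            # (chrom, pos0, kind, payload) -> support

    def allele_counts(self, chrom: str, pos1: int, ref: str, alt: str) -> tuple[int, int]:
        col = self.counts[chrom][:, pos1 - 1]
        return int(col[encode(ref)[0]]), int(col[encode(alt)[0]])


# ---------------------------------------------------------------- scalar path
def genotype_log_posteriors(ref_code: int, alt_code: int, bases: np.ndarray,
                            quals: np.ndarray, theta: float) -> np.ndarray:
    """Unnormalized log posteriors over (0/0, 0/1, 1/1)."""
    valid = bases < 4
    b, q = bases[valid], np.clip(quals[valid], 0, _QMAX - 1)
    is_ref = b == ref_code
    is_alt = b == alt_code
    other = ~(is_ref | is_alt)
    l00 = W_MATCH[q[is_ref]].sum() + W_MISMATCH[q[~is_ref]].sum()
    l11 = W_MATCH[q[is_alt]].sum() + W_MISMATCH[q[~is_alt]].sum()
    l01 = W_HET[q[is_ref | is_alt]].sum() + W_MISMATCH[q[other]].sum()
    priors = np.log([1.0 - 1.5 * theta, theta, theta / 2.0])
    return priors + np.array([l00, l01, l11])


def _posterior_probs(logpost: np.ndarray) -> np.ndarray:
    m = logpost.max()
    p = np.exp(logpost - m)
    return p / p.sum()


def call_genotype(column: PileupColumn, theta: float = 0.001, min_depth: int = 5,
                  max_depth: int = 200, min_gq: float = 10.0) -> VariantCall | None:
    """Genotype one pileup column; None when the site is not callable."""
    bases = np.asarray(column.bases, dtype=np.uint8)
    quals = np.asarray(column.quals, dtype=np.int64)
    if len(bases) == 0:
        raise ValueError("pileup column with no observations")
    if column.ref_base not in "ACGT":
        logger.debug("no-call at %s:%d: non-ACGT reference base", column.chrom, column.pos)
        return None
    depth = int((bases < 4).sum())
    if depth < min_depth or depth > max_depth:
        return None
    ref_code = int(encode(column.ref_base)[0])
    counts = np.bincount(bases[bases < 4], minlength=4)
    nonref = counts.copy()
    nonref[ref_code] = 0
    if nonref.sum() == 0:
        return None  # best genotype is necessarily 0/0
    alt_code = int(nonref.argmax())
    if counts.sum() - counts[ref_code] - counts[alt_code] > 0:
        logger.debug("tri-allelic column at %s:%d: using two most frequent alleles",
                     column.chrom, column.pos)
    logpost = genotype_log_posteriors(ref_code, alt_code, bases, quals, theta)
    probs = _posterior_probs(logpost)
    best = int(probs.argmax())
    gq = -10.0 * np.log10(max(1.0 - probs[best], 1e-300))
    if best == 0 or gq < min_gq:
        return None
    return VariantCall(
        chrom=column.chrom, pos=column.pos, ref=column.ref_base,
        alt=decode(np.array([alt_code], dtype=np.uint8)), genotype=GENOTYPES[best],
        genotype_quality=float(gq), depth=depth,
        allele_depths=(int(counts[ref_code]), int(counts[alt_code])),
    )


# ------------------------------------------------------------- vectorized path
def _iter_observations(reads: SampleReads, aln: PairAlignments, idx: np.ndarray,
                       chrom_idx: int):
    """Yield (pos, code, qual) chunks of reference-oriented observations.

    Also yields indel observations as a side channel: chunks are tuples
    (pos, code, qual, indel_list) where indel_list holds
    (pos0, kind, payload) items from reads with non-trivial CIGARs.
    """
    rl = reads.read_length
    for mate in (1, 2):
        chrom = aln.chrom1 if mate == 1 else aln.chrom2
        mapped = aln.mapped1 if mate == 1 else aln.mapped2
        pos = aln.pos1 if mate == 1 else aln.pos2
        alen = aln.aln_len1 if mate == 1 else aln.aln_len2
        rev = aln.rev1 if mate == 1 else aln.rev2
        cigars = aln.cigar1 if mate == 1 else aln.cigar2
        seqs = reads.seq1 if mate == 1 else reads.seq2
        quals = reads.qual1 if mate == 1 else reads.qual2

        on = idx[(chrom[idx] == chrom_idx) & mapped[idx]]
        if cigars:
            ckeys = np.fromiter(cigars.keys(), dtype=np.int64)
            has_cigar = np.isin(on, ckeys)
        else:
            has_cigar = np.zeros(len(on), dtype=bool)
        simple = (alen[on] == rl) & ~has_cigar
        srows = on[simple]
        for lo in range(0, len(srows), _OBS_CHUNK):
            rows = srows[lo:lo + _OBS_CHUNK]
            if not len(rows):
                continue
            s = seqs[rows]
            q = quals[rows]
            flip = rev[rows]
            if flip.any():
                s = s.copy(); q = q.copy()
                s[flip] = COMP[s[flip]][:, ::-1]
                q[flip] = q[flip][:, ::-1]
            p = (pos[rows, None] + np.arange(rl)).ravel()
            yield p, s.ravel(), q.ravel(), []

        # complex reads: soft-clipped short fragments and indel-spanning reads
        crows = on[~simple]
        if len(crows):
            plist, clist, qlist, indels = [], [], [], []
            for i in crows:
                i = int(i)
                s = seqs[i]; q = quals[i]
                if rev[i]:
                    s = COMP[s][::-1]; q = q[::-1]
                ops = cigars.get(i, [("M", int(alen[i]))])
                if rev[i] and int(alen[i]) < rl and i not in cigars:
                    # clipped bases sit left in reference orientation
                    s = s[rl - int(alen[i]):]; q = q[rl - int(alen[i]):]
                r = int(pos[i])
                rc = 0  # read cursor
                for op, ln in ops:
                    if op == "M":
                        plist.append(np.arange(r, r + ln))
                        clist.append(s[rc:rc + ln])
                        qlist.append(q[rc:rc + ln])
                        r += ln; rc += ln
                    elif op == "I":
                        indels.append((r - 1, "I", decode(s[rc:rc + ln])))
                        rc += ln
                    elif op == "D":
                        indels.append((r, "D", ln))
                        r += ln
            if plist:
                yield (np.concatenate(plist), np.concatenate(clist),
                       np.concatenate(qlist), indels)
            elif indels:
                yield (np.empty(0, np.int64), np.empty(0, np.uint8),
                       np.empty(0, np.uint8), indels)


def build_pileup(reads: SampleReads, aln: PairAlignments,
                 ref_lengths: dict[str, int],
                 idx: np.ndarray | None = None) -> SamplePileup:
    """Whole-genome base-count pileup plus indel observations."""
    if idx is None:
        idx = np.arange(reads.n_pairs)
    counts: dict[str, np.ndarray] = {}
    indel_obs: dict[tuple, int] = {}
    for ci, chrom in enumerate(aln.chroms):
        L = ref_lengths[chrom]
        c = np.zeros((4, L), dtype=np.uint32)
        for p, codes, quals, indels in _iter_observations(reads, aln, idx, ci):
            for b in range(4):
                sel = codes == b
                if sel.any():
                    c[b] += np.bincount(p[sel], minlength=L).astype(np.uint32)
            for pos0, kind, payload in indels:
                key = (chrom, int(pos0), kind, payload)
                indel_obs[key] = indel_obs.get(key, 0) + 1
        counts[chrom] = c.astype(np.uint16)
    depth = {c: v.sum(axis=0).astype(np.int32) for c, v in counts.items()}
    return SamplePileup(list(aln.chroms), counts, depth, indel_obs)


def call_variants(reads: SampleReads, aln: PairAlignments,
                  reference: dict[str, np.ndarray],
                  config: CallerConfig | None = None,
                  idx: np.ndarray | None = None,
                  pileup: SamplePileup | None = None
                  ) -> tuple[pd.DataFrame, SamplePileup]:
    """Vectorized SNV genotyping over the whole genome.

    Returns the call table (columns chrom, pos, ref, alt, genotype, gq,
    depth, ref_ad, alt_ad) and the pileup used, for downstream subtraction.
    """
    config = config or CallerConfig()
    config.validate()
    if idx is None:
        idx = np.arange(reads.n_pairs)
    ref_lengths = {c: len(s) for c, s in reference.items()}
    if pileup is None:
        pileup = build_pileup(reads, aln, ref_lengths, idx)

    priors = np.log([1.0 - 1.5 * config.theta, config.theta, config.theta / 2.0])
    frames = []
    for ci, chrom in enumerate(aln.chroms):
        c = pileup.counts[chrom].astype(np.int64)
        depth = pileup.depth[chrom].astype(np.int64)
        refc = reference[chrom]
        nonref = c.sum(axis=0) - c[np.minimum(refc, 3), np.arange(len(refc))]
        cand = ((nonref >= 2) & (depth >= config.min_depth)
                & (depth <= config.max_depth) & (refc < 4))
        cpos = np.nonzero(cand)[0]
        if not len(cpos):
            continue
        cindex = np.full(len(refc), -1, dtype=np.int64)
        cindex[cpos] = np.arange(len(cpos))
        ncand = len(cpos)
        S1 = np.zeros((ncand, 4)); S2 = np.zeros((ncand, 4)); S3 = np.zeros((ncand, 4))
        for p, codes, quals, _ in _iter_observations(reads, aln, idx, ci):
            if not len(p):
                continue
            sel = (codes < 4) & cand[p]
            if not sel.any():
                continue
            key = cindex[p[sel]] * 4 + codes[sel]
            q = np.clip(quals[sel], 0, _QMAX - 1)
            for S, W in ((S1, W_MATCH), (S2, W_MISMATCH), (S3, W_HET)):
                S += np.bincount(key, weights=W[q], minlength=ncand * 4).reshape(ncand, 4)

        refcode = np.minimum(refc[cpos], 3)
        ccand = c[:, cpos].T  # (ncand, 4)
        nr = ccand.copy()
        nr[np.arange(ncand), refcode] = 0
        altcode = nr.argmax(axis=1)
        ar = np.arange(ncand)
        S2tot = S2.sum(axis=1)
        l00 = S1[ar, refcode] + S2tot - S2[ar, refcode]
        l11 = S1[ar, altcode] + S2tot - S2[ar, altcode]
        l01 = (S3[ar, refcode] + S3[ar, altcode]
               + S2tot - S2[ar, refcode] - S2[ar, altcode])
        logpost = np.stack([l00, l01, l11], axis=1) + priors
        m = logpost.max(axis=1, keepdims=True)
        probs = np.exp(logpost - m)
        probs /= probs.sum(axis=1, keepdims=True)
        best = probs.argmax(axis=1)
        gq = -10.0 * np.log10(np.clip(1.0 - probs[ar, best], 1e-300, None))
        emit = (best != 0) & (gq >= config.min_genotype_quality)
        if not emit.any():
            continue
        e = np.nonzero(emit)[0]
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": cpos[e] + 1,
            "ref": [ "ACGT"[b] for b in refcode[e] ],
            "alt": [ "ACGT"[b] for b in altcode[e] ],
            "genotype": [GENOTYPES[b] for b in best[e]],
            "gq": gq[e],
            "depth": depth[cpos[e]],
            "ref_ad": ccand[e, refcode[e]],
            "alt_ad": ccand[e, altcode[e]],
        }))
    cols = ["chrom", "pos", "ref", "alt", "genotype", "gq", "depth", "ref_ad", "alt_ad"]
    calls = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=cols))
    return calls, pileup


def call_indels(pileup: SamplePileup, config: CallerConfig | None = None) -> pd.DataFrame:
    """Indel calls from pileup observations by support fraction.

    Spanning depth at the site is the aligned depth plus deletion-carrying
    reads (which leave no aligned base at the deleted positions).  Positions
    are reported 1-based: first deleted base for deletions, the base
    preceding the insertion for insertions.
    """
    config = config or CallerConfig()
    by_site: dict[tuple, dict] = {}
    for (chrom, pos0, kind, payload), n in pileup.indel_obs.items():
        by_site.setdefault((chrom, pos0), {})[(kind, payload)] = n
    rows = []
    for (chrom, pos0), alleles in sorted(by_site.items()):
        if len(alleles) > 1:
            logger.info("conflicting indel alleles at %s:%d; keeping majority",
                        chrom, pos0 + 1)
        (kind, payload), support = max(alleles.items(), key=lambda kv: (kv[1], kv[0]))
        depth = int(pileup.depth[chrom][pos0]) if pos0 < len(pileup.depth[chrom]) else 0
        if kind == "D":
            depth += support
        if depth < config.min_depth or depth > config.max_depth:
            continue
        frac = support / depth
        if frac < config.indel_min_support_fraction:
            continue
        genotype = "1/1" if frac >= config.indel_hom_fraction else "0/1"
        rows.append((chrom, pos0 + 1, kind,
                     len(payload) if kind == "I" else int(payload),
                     payload if kind == "I" else "", genotype, support, depth))
    return pd.DataFrame(rows, columns=["chrom", "pos", "kind", "length", "seq",
                                       "genotype", "support", "depth"])


def callable_region(pileup: SamplePileup, min_depth: int = 5,
                    max_depth: int = 200) -> CallableMask:
    """Positions whose depth lies in [min_depth, max_depth]."""
    return CallableMask({c: (d >= min_depth) & (d <= max_depth)
                         for c, d in pileup.depth.items()})


def iter_pileup_columns(reads: SampleReads, aln: PairAlignments,
                        reference: dict[str, np.ndarray],
                        idx: np.ndarray | None = None):
    """Yield PileupColumn objects in coordinate order (desk-scale helper)."""
    if idx is None:
        idx = np.arange(reads.n_pairs)
    for ci, chrom in enumerate(aln.chroms):
        refc = reference[chrom]
        obs: dict[int, tuple[list, list]] = {}
        indels: dict[int, dict] = {}
        for p, codes, quals, ind in _iter_observations(reads, aln, idx, ci):
            for pos, b, q in zip(p, codes, quals):
                slot = obs.setdefault(int(pos), ([], []))
                slot[0].append(int(b)); slot[1].append(int(q))
            for pos0, kind, payload in ind:
                d = indels.setdefault(int(pos0), {})
                d[(kind, payload)] = d.get((kind, payload), 0) + 1
        for pos in sorted(obs):
            bases, quals = obs[pos]
            yield PileupColumn(chrom=chrom, pos=pos + 1,
                               ref_base="ACGTN"[min(int(refc[pos]), 4)],
                               bases=np.array(bases, dtype=np.uint8),
                               quals=np.array(quals, dtype=np.int64),
                               indel_obs=indels.get(pos, {}))
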
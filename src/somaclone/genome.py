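"""Donor and clone genome construction with planted truth.

The generator emulates a somatic-cell-nuclear-transfer pair: the clone shares
the donor's nuclear genome up to post-cloning somatic events (SNVs, small
indels, CNVs, SVs) and carries a divergent mitochondrial haplotype from the
oocyte donor.  Autosomes are diploid (two haplotypes), chrX and chrM haploid.

Haplotypes are represented against a shared random reference as a sparse set
of SNVs plus structural ops (insertions/deletions/copied segments); each
haplotype materializes to a code array together with a block table mapping
haplotype coordinates back to reference coordinates, so read simulation can
emit truth alignments without an external aligner.  Terminal telomeric
(TTAGGG)n / (CCCTAA)n tracts of per-sample length overwrite the chromosome
ends at materialization time.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import CODE_TO_ASCII, decode, encode, random_codes, revcomp
from .config import ConfigError, SimulationConfig

logger = logging.getLogger(__name__)

# ref->hap block kinds
BLOCK_REF = 0       # maps to reference coordinates (possibly another chromosome)
BLOCK_NOVEL = 1     # inserted sequence with no reference home

TELOMERE_FWD = encode("TTAGGG")
TELOMERE_REV = encode("CCCTAA")

# keep planted variants clear of telomere overwrites and read-length edges
EDGE_MARGIN = 200


@dataclass
class StructuralOp:
    """A length-changing edit applied to one haplotype, in reference coords.

    Deletes ``[pos, pos + ref_len)`` and inserts either an explicit sequence
    (``ins``) or a copy of reference segment ``src = (chrom, start, end)``.
    """

    pos: int
    ref_len: int = 0
    ins: np.ndarray | None = None
    src: tuple[str, int, int] | None = None

    @property
    def ins_len(self) -> int:
        if self.src is not None:
            return self.src[2] - self.src[1]
        return 0 if self.ins is None else len(self.ins)


@dataclass
class BlockTable:
    """Mapping from haplotype coordinates to reference coordinates."""

    hap_start: np.ndarray   # int64, block start in haplotype coords
    hap_end: np.ndarray
    kind: np.ndarray        # BLOCK_REF / BLOCK_NOVEL
    map_chrom: np.ndarray   # chrom index, -1 for novel blocks
    map_start: np.ndarray   # reference position of hap_start (BLOCK_REF only)


@dataclass
class TruthSet:
    """Planted events and per-sample telomere lengths; the analysis oracle."""

    germline: pd.DataFrame = field(default_factory=pd.DataFrame)
    somatic_snvs: pd.DataFrame = field(default_factory=pd.DataFrame)
    somatic_indels: pd.DataFrame = field(default_factory=pd.DataFrame)
    cnv_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    sv_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    telomere_truth: dict = field(default_factory=dict)


class Genome:
    """A sample genome: shared reference + per-haplotype sparse edits."""

    def __init__(self, name: str, reference: dict[str, np.ndarray],
                 ploidy: dict[str, int], telomere_length: int):
        self.name = name
        self.reference = reference
        self.ploidy = ploidy
        self.telomere_length = telomere_length
        self.chroms = list(reference.keys())
        # (chrom, hap) -> sorted int64 positions / uint8 alt codes
        self.snvs: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
        # (chrom, hap) -> ops sorted by pos
        self.ops: dict[tuple[str, int], list[StructuralOp]] = {}
        self._cache: dict[tuple[str, int], tuple[np.ndarray, BlockTable]] = {}

    # ------------------------------------------------------------------ edits
    def add_snvs(self, chrom: str, hap: int, pos: np.ndarray, alt: np.ndarray) -> None:
        old_pos, old_alt = self.snvs.get((chrom, hap), (np.empty(0, np.int64), np.empty(0, np.uint8)))
        pos = np.concatenate([old_pos, np.asarray(pos, np.int64)])
        alt = np.concatenate([old_alt, np.asarray(alt, np.uint8)])
        order = np.argsort(pos, kind="stable")
        self.snvs[(chrom, hap)] = (pos[order], alt[order])
        self._cache.pop((chrom, hap), None)

    def add_op(self, chrom: str, hap: int, op: StructuralOp) -> None:
        ops = self.ops.setdefault((chrom, hap), [])
        ops.append(op)
        ops.sort(key=lambda o: o.pos)
        for a, b in zip(ops, ops[1:]):
            if a.pos + a.ref_len > b.pos:
                raise ConfigError(
                    f"overlapping structural ops on {chrom} hap{hap}: "
                    f"{a.pos}+{a.ref_len} > {b.pos}"
                )
        self._cache.pop((chrom, hap), None)

    def copy(self, name: str, telomere_length: int | None = None) -> "Genome":
        g = Genome(
            name, self.reference, dict(self.ploidy),
            self.telomere_length if telomere_length is None else telomere_length,
        )
        g.snvs = {k: (p.copy(), a.copy()) for k, (p, a) in self.snvs.items()}
        g.ops = {k: list(v) for k, v in self.ops.items()}
        return g

    # ---------------------------------------------------------- materialize
    def _snv_applied(self, chrom: str, hap: int) -> np.ndarray:
        base = self.reference[chrom].copy()
        pos, alt = self.snvs.get((chrom, hap), (None, None))
        if pos is not None and len(pos):
            base[pos] = alt
        return base

    def materialize(self, chrom: str, hap: int) -> tuple[np.ndarray, BlockTable]:
        """Haplotype sequence plus its block table (cached)."""
        key = (chrom, hap)
        if key in self._cache:
            return self._cache[key]
        base = self._snv_applied(chrom, hap)
        ops = self.ops.get(key, [])
        chrom_idx = {c: i for i, c in enumerate(self.chroms)}

        pieces: list[np.ndarray] = []
        blocks: list[tuple[int, int, int, int, int]] = []  # hs, he, kind, mchrom, mstart
        cursor = 0  # haplotype coordinate
        ref_cursor = 0
        for op in ops:
            if op.pos > ref_cursor:
                seg = base[ref_cursor:op.pos]
                pieces.append(seg)
                blocks.append((cursor, cursor + len(seg), BLOCK_REF,
                               chrom_idx[chrom], ref_cursor))
                cursor += len(seg)
            if op.src is not None:
                sc, ss, se = op.src
                src_base = base if sc == chrom else self._snv_applied(sc, min(hap, self.ploidy[sc] - 1))
                seg = src_base[ss:se]
                pieces.append(seg)
                blocks.append((cursor, cursor + len(seg), BLOCK_REF, chrom_idx[sc], ss))
                cursor += len(seg)
            elif op.ins is not None and len(op.ins):
                pieces.append(op.ins)
                blocks.append((cursor, cursor + len(op.ins), BLOCK_NOVEL, -1, -1))
                cursor += len(op.ins)
            ref_cursor = op.pos + op.ref_len
        tail = base[ref_cursor:]
        pieces.append(tail)
        blocks.append((cursor, cursor + len(tail), BLOCK_REF, chrom_idx[chrom], ref_cursor))
        cursor += len(tail)

        seq = np.concatenate(pieces) if len(pieces) > 1 else pieces[0].copy()
        tel = self.telomere_length
        if tel > 0 and chrom != "chrM":
            if 2 * tel > len(seq):
                raise ConfigError(f"telomere tract {tel} bp does not fit on {chrom}")
            reps = -(-tel // 6)
            seq[:tel] = np.tile(TELOMERE_REV, reps)[:tel]
            seq[-tel:] = np.tile(TELOMERE_FWD, reps)[:tel]

        arr = lambda col, dt: np.array([b[col] for b in blocks], dtype=dt)
        table = BlockTable(arr(0, np.int64), arr(1, np.int64), arr(2, np.int8),
                           arr(3, np.int32), arr(4, np.int64))
        self._cache[key] = (seq, table)
        return self._cache[key]

    def haplotype_length(self, chrom: str, hap: int) -> int:
        length = len(self.reference[chrom])
        for op in self.ops.get((chrom, hap), []):
            length += op.ins_len - op.ref_len
        return length

    def nuclear_span(self) -> int:
        """Reference bp of nuclear chromosomes (autosomes + chrX)."""
        return sum(len(s) for c, s in self.reference.items() if c != "chrM")

    def write_fasta(self, path, line_width: int = 70) -> None:
        """Write materialized haplotypes (hap suffix per diploid chromosome)."""
        with open(path, "wb") as fh:
            for chrom in self.chroms:
                for hap in range(self.ploidy[chrom]):
                    seq, _ = self.materialize(chrom, hap)
                    name = chrom if self.ploidy[chrom] == 1 else f"{chrom}_hap{hap}"
                    fh.write(f">{name}\n".encode())
                    ascii_seq = CODE_TO_ASCII[seq]
                    for i in range(0, len(ascii_seq), line_width):
                        fh.write(ascii_seq[i:i + line_width].tobytes() + b"\n")


def write_reference_fasta(reference: dict[str, np.ndarray], path, line_width: int = 70) -> None:
    with open(path, "wb") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n".encode())
            ascii_seq = CODE_TO_ASCII[seq]
            for i in range(0, len(ascii_seq), line_width):
                fh.write(ascii_seq[i:i + line_width].tobytes() + b"\n")


# --------------------------------------------------------------------- sampling
def _blocked_union(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ivs = sorted(intervals)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, np.int64), np.array(ends, np.int64)


def sample_positions(rng: np.random.Generator, length: int, n: int,
                     blocked: list[tuple[int, int]], label: str = "variant") -> np.ndarray:
    """Draw ``n`` distinct positions in [0, length) outside blocked intervals.

    Collisions with blocked intervals or already-drawn positions are re-drawn
    (and logged), mirroring how planted somatic events avoid germline sites.
    """
    starts, ends = _blocked_union(blocked)
    chosen: set[int] = set()
    redraws = 0
    attempts = 0
    while len(chosen) < n:
        need = n - len(chosen)
        draw = rng.integers(0, length, size=max(need * 2, 16))
        if len(starts):
            idx = np.searchsorted(starts, draw, side="right") - 1
            inside = (idx >= 0) & (draw < ends[np.clip(idx, 0, len(ends) - 1)])
            redraws += int(inside.sum())
            draw = draw[~inside]
        for p in draw:
            if len(chosen) >= n:
                break
            p = int(p)
            if p in chosen:
                redraws += 1
                continue
            chosen.add(p)
        attempts += 1
        if attempts > 1000:
            raise ConfigError(f"cannot place {n} {label}s in {length} bp of open sequence")
    if redraws:
        logger.info("re-drew %d colliding %s position(s)", redraws, label)
    return np.array(sorted(chosen), dtype=np.int64)


def _random_alts(rng: np.random.Generator, ref_codes: np.ndarray,
                 transition_fraction: float = 2.0 / 3.0) -> np.ndarray:
    """Random alternate base, transition-biased (ts:tv defaults to 2:1).

    Code order is A,C,G,T, so the transition partner is A<->G (codes 0,2)
    and C<->T (codes 1,3): an XOR with 2.
    """
    n = len(ref_codes)
    ts_partner = ref_codes ^ 2
    is_ts = rng.random(n) < transition_fraction
    # two transversion partners: the two codes of the other parity
    tv_choice = rng.integers(0, 2, size=n)
    tv_partner = (ref_codes + 1 + 2 * tv_choice) % 4
    return np.where(is_ts, ts_partner, tv_partner).astype(np.uint8)


# ---------------------------------------------------------------- construction
def _seed_streams(config: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def build_donor_genome(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> tuple[Genome, TruthSet]:
    """Random reference + donor germline heterozygous SNVs (Poisson-planted)."""
    config.validate()
    if rng is None:
        rng = _seed_streams(config)[0]
    reference = {c: random_codes(rng, config.chrom_length(c)) for c in config.chrom_names()}
    ploidy = {c: (2 if c not in ("chrX", "chrM") else 1) for c in config.chrom_names()}
    genome = Genome("donor", reference, ploidy, config.telomere_length_donor)

    tel_margin = max(config.telomere_length_donor, config.telomere_length_clone) + EDGE_MARGIN
    rows = []
    for chrom in config.chrom_names():
        if chrom == "chrM":
            continue
        length = len(reference[chrom])
        n = rng.poisson(config.germline_het_rate * length)
        blocked = [(0, tel_margin), (length - tel_margin, length)]
        pos = sample_positions(rng, length, n, blocked, "germline SNV")
        ref_codes = reference[chrom][pos]
        alt_codes = _random_alts(rng, ref_codes, config.transition_fraction)
        if ploidy[chrom] == 2:
            haps = rng.integers(0, 2, size=n)
            gt = "0/1"
        else:
            haps = np.zeros(n, dtype=np.int64)
            gt = "1"
        for hap in np.unique(haps):
            sel = haps == hap
            genome.add_snvs(chrom, int(hap), pos[sel], alt_codes[sel])
        for p, r, a, h in zip(pos, ref_codes, alt_codes, haps):
            rows.append((chrom, int(p) + 1, decode(np.array([r])), decode(np.array([a])), gt, int(h)))
    truth = TruthSet(
        germline=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype", "hap"]),
        telomere_truth={"donor": config.telomere_length_donor},
    )
    return genome, truth


def _occupied_intervals(config: SimulationConfig, chrom: str) -> list[tuple[int, int]]:
    """Reference intervals on ``chrom`` claimed by planted CNV/SV events (padded)."""
    pad = EDGE_MARGIN + 100
    ivs = []
    for c, s, e, _cn in config.cnv_events:
        if c == chrom:
            ivs.append((s - pad, e + pad))
    for svtype, c, s, size in config.sv_events:
        if c == chrom:
            end = s + (size if svtype != "INS" else 1)
            ivs.append((s - pad, end + pad))
    return ivs


def derive_clone_genome(donor: Genome, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> tuple[Genome, TruthSet]:
    """Clone = donor nuclear genome + somatic events + replaced chrM haplotype."""
    if rng is None:
        rng = _seed_streams(config)[1]
    clone = donor.copy("clone", telomere_length=config.telomere_length_clone)
    reference = donor.reference
    tel_margin = max(config.telomere_length_donor, config.telomere_length_clone) + EDGE_MARGIN

    germline_positions = {
        chrom: np.unique(np.concatenate([
            donor.snvs.get((chrom, h), (np.empty(0, np.int64),))[0]
            for h in range(donor.ploidy[chrom])
        ])) if any((chrom, h) in donor.snvs for h in range(donor.ploidy[chrom]))
        else np.empty(0, np.int64)
        for chrom in donor.chroms
    }

    nuclear_mb = donor.nuclear_span() / 1e6
    snv_rows, indel_rows = [], []

    # --- somatic SNVs (heterozygous, one haplotype), allocated by chromosome size
    n_snv = rng.poisson(config.somatic_snv_rate * nuclear_mb)
    n_indel = rng.poisson(config.somatic_indel_rate * nuclear_mb)
    nuclear = [c for c in donor.chroms if c != "chrM"]
    weights = np.array([len(reference[c]) for c in nuclear], dtype=float)
    weights /= weights.sum()

    def blocked_for(chrom: str, extra_pts: np.ndarray) -> list[tuple[int, int]]:
        length = len(reference[chrom])
        blocked = [(0, tel_margin), (length - tel_margin, length)]
        blocked += _occupied_intervals(config, chrom)
        blocked += [(int(p), int(p) + 1) for p in germline_positions[chrom]]
        blocked += [(int(p) - 30, int(p) + 30) for p in extra_pts]
        return blocked

    snv_chroms = rng.choice(len(nuclear), size=n_snv, p=weights)
    indel_chroms = rng.choice(len(nuclear), size=n_indel, p=weights)
    for ci, chrom in enumerate(nuclear):
        placed = np.empty(0, np.int64)
        k = int((snv_chroms == ci).sum())
        if k:
            pos = sample_positions(rng, len(reference[chrom]), k,
                                   blocked_for(chrom, placed), "somatic SNV")
            placed = pos
            ref_codes = reference[chrom][pos]
            alt_codes = _random_alts(rng, ref_codes, config.transition_fraction)
            haps = (rng.integers(0, 2, size=k) if donor.ploidy[chrom] == 2
                    else np.zeros(k, dtype=np.int64))
            for hap in np.unique(haps):
                sel = haps == hap
                clone.add_snvs(chrom, int(hap), pos[sel], alt_codes[sel])
            comp = "sex" if chrom == "chrX" else "autosomal"
            gt = "0/1" if donor.ploidy[chrom] == 2 else "1"
            for p, r, a, h in zip(pos, ref_codes, alt_codes, haps):
                snv_rows.append((chrom, int(p) + 1, decode(np.array([r])),
                                 decode(np.array([a])), gt, int(h), comp))
        k = int((indel_chroms == ci).sum())
        if k:
            pos = sample_positions(rng, len(reference[chrom]), k,
                                   blocked_for(chrom, placed), "somatic indel")
            kinds = rng.random(k) < 0.5
            lengths = rng.integers(1, 11, size=k)
            haps = (rng.integers(0, 2, size=k) if donor.ploidy[chrom] == 2
                    else np.zeros(k, dtype=np.int64))
            comp = "sex" if chrom == "chrX" else "autosomal"
            for p, is_del, ln, h in zip(pos, kinds, lengths, haps):
                p, ln, h = int(p), int(ln), int(h)
                if is_del:
                    clone.add_op(chrom, h, StructuralOp(pos=p, ref_len=ln))
                    indel_rows.append((chrom, p + 1, "D", ln,
                                       decode(reference[chrom][p:p + ln]), h, comp))
                else:
                    ins = random_codes(rng, ln)
                    clone.add_op(chrom, h, StructuralOp(pos=p, ref_len=0, ins=ins))
                    # insertion attributed to the preceding reference base
                    indel_rows.append((chrom, p, "I", ln, decode(ins), h, comp))

    # --- replaced mitochondrial haplotype (oocyte donor)
    m = len(reference["chrM"])
    n_mito = rng.poisson(config.mito_divergence * m)
    pos = sample_positions(rng, m, n_mito, [], "mitochondrial substitution")
    ref_codes = reference["chrM"][pos]
    alt_codes = _random_alts(rng, ref_codes, config.transition_fraction)
    clone.add_snvs("chrM", 0, pos, alt_codes)
    for p, r, a in zip(pos, ref_codes, alt_codes):
        snv_rows.append(("chrM", int(p) + 1, decode(np.array([r])),
                         decode(np.array([a])), "1", 0, "mitochondrial"))

    # --- planted CNVs (copy-number change of the interval)
    cnv_rows = []
    for chrom, start, end, cn in config.cnv_events:
        if cn in (0, 1):
            haps = [0, 1] if cn == 0 else [1]
            for h in haps:
                clone.add_op(chrom, h, StructuralOp(pos=start, ref_len=end - start))
        else:  # 3, 4: tandem duplication of the interval
            haps = [1] if cn == 3 else [0, 1]
            for h in haps:
                clone.add_op(chrom, h, StructuralOp(pos=end, ref_len=0,
                                                    src=(chrom, start, end)))
        cnv_rows.append((chrom, start, end, cn))

    # --- planted SVs (realized on both haplotypes)
    sv_rows = []
    autosomes = [c for c in donor.chroms if c not in ("chrX", "chrM")]
    for svtype, chrom, start, size in config.sv_events:
        if svtype == "DEL":
            for h in range(donor.ploidy[chrom]):
                clone.add_op(chrom, h, StructuralOp(pos=start, ref_len=size))
            sv_rows.append((svtype, chrom, start, size, "", -1))
        elif svtype == "INS":
            ins = random_codes(rng, size)
            for h in range(donor.ploidy[chrom]):
                clone.add_op(chrom, h, StructuralOp(pos=start, ref_len=0, ins=ins.copy()))
            sv_rows.append((svtype, chrom, start, size, "", -1))
        else:  # CTX: copy of the segment inserted on another chromosome
            if len(autosomes) < 2:
                raise ConfigError("CTX events require at least two autosomes")
            target = autosomes[(autosomes.index(chrom) + 1) % len(autosomes)]
            tpos = len(reference[target]) // 2
            for h in range(donor.ploidy[target]):
                clone.add_op(target, h, StructuralOp(pos=tpos, ref_len=0,
                                                     src=(chrom, start, start + size)))
            sv_rows.append((svtype, chrom, start, size, target, tpos))

    truth = TruthSet(
        somatic_snvs=pd.DataFrame(
            snv_rows, columns=["chrom", "pos", "ref", "alt", "genotype", "hap", "compartment"]),
        somatic_indels=pd.DataFrame(
            indel_rows, columns=["chrom", "pos", "kind", "length", "seq", "hap", "compartment"]),
        cnv_truth=pd.DataFrame(cnv_rows, columns=["chrom", "start", "end", "copy_number"]),
        sv_truth=pd.DataFrame(
            sv_rows, columns=["type", "chrom", "start", "size", "target_chrom", "target_pos"]),
        telomere_truth={"clone": config.telomere_length_clone},
    )
    return clone, truth


def merge_truth(germline: TruthSet, somatic: TruthSet) -> TruthSet:
    merged = TruthSet(
        germline=germline.germline,
        somatic_snvs=somatic.somatic_snvs,
        somatic_indels=somatic.somatic_indels,
        cnv_truth=somatic.cnv_truth,
        sv_truth=somatic.sv_truth,
        telomere_truth={**germline.telomere_truth, **somatic.telomere_truth},
    )
    return merged
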
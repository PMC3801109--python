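"""File-format surfaces: FASTQ, SAM, VCF and BED-like TSV.

The analysis stages operate on in-memory vectorized containers; these
functions are the boundary to the standard on-disk formats (Phred+33 FASTQ,
coordinate-sorted SAM, VCF v4.2, tab-separated interval tables).  SAM and VCF
go through pysam; FASTQ parsing goes through pysam.FastxFile.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from ._seq import ASCII_TO_CODE, CODE_TO_ASCII, revcomp
from .simulate import PairAlignments, SampleReads


class FormatError(ValueError):
    """Malformed input file (CLI exit code 3)."""


PHRED_OFFSET = 33


# ------------------------------------------------------------------- FASTQ
def write_fastq_pair(reads: SampleReads, path1, path2,
                     idx: np.ndarray | None = None) -> None:
    if idx is None:
        idx = np.arange(reads.n_pairs)
    for path, seqs, quals in ((path1, reads.seq1, reads.qual1),
                              (path2, reads.seq2, reads.qual2)):
        with open(path, "wb") as fh:
            for i in idx:
                seq = CODE_TO_ASCII[seqs[i]].tobytes()
                qual = (quals[i] + PHRED_OFFSET).astype(np.uint8).tobytes()
                fh.write(b"@" + reads.name(int(i)).encode() + b"\n" + seq +
                         b"\n+\n" + qual + b"\n")


def read_fastq_pair(path1, path2, sample: str = "sample") -> SampleReads:
    """Load a FASTQ pair into a SampleReads batch (uniform read length).

    Phred+64-encoded input (no quality character below ';') is rejected:
    the pipeline is fixed to Phred+33.
    """
    def load(path):
        seqs, quals, names = [], [], []
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                if rec.quality is None or len(rec.sequence) != len(rec.quality):
                    raise FormatError(f"truncated FASTQ record {rec.name!r} in {path}")
                seqs.append(rec.sequence)
                quals.append(rec.quality)
                names.append(rec.name)
        if not seqs:
            raise FormatError(f"empty FASTQ file {path}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise FormatError(f"reads in {path} have mixed lengths {sorted(lengths)}")
        seq_arr = ASCII_TO_CODE[np.frombuffer("".join(seqs).encode(), np.uint8)]
        qual_arr = np.frombuffer("".join(quals).encode(), np.uint8).astype(np.int16)
        qual_arr = qual_arr - PHRED_OFFSET
        if qual_arr.min() < 0:
            raise FormatError(f"negative Phred score in {path}: not Phred+33?")
        if qual_arr.min() > 30:
            raise FormatError(
                f"all quality characters in {path} are above 'N': looks like "
                "Phred+64 input, which is not supported (re-encode to Phred+33)")
        n = len(seqs)
        L = lengths.pop()
        return seq_arr.reshape(n, L), qual_arr.astype(np.uint8).reshape(n, L), names

    s1, q1, n1 = load(path1)
    s2, q2, n2 = load(path2)
    if len(n1) != len(n2):
        raise FormatError("FASTQ mates differ in record count")
    return SampleReads(sample, s1.shape[1], s1, q1, s2, q2,
                       np.zeros(len(n1), dtype=bool))


# --------------------------------------------------------------------- SAM
def _cigar_tuples(ops):
    code = {"M": 0, "I": 1, "D": 2, "S": 4}
    return [(code[op], ln) for op, ln in ops]


def write_sam(reads: SampleReads, aln: PairAlignments, ref_lengths: dict[str, int],
              path, idx: np.ndarray | None = None) -> None:
    """Write pairs as coordinate-ready SAM (sorted by mate-1 position)."""
    if idx is None:
        idx = np.arange(reads.n_pairs)
    order = np.lexsort((aln.pos1[idx], aln.chrom1[idx]))
    idx = idx[order]
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": int(ref_lengths[c])} for c in aln.chroms]}
    rl = reads.read_length
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in idx:
            i = int(i)
            for mate in (1, 2):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = reads.name(i)
                mapped = bool((aln.mapped1 if mate == 1 else aln.mapped2)[i])
                other_mapped = bool((aln.mapped2 if mate == 1 else aln.mapped1)[i])
                rev = bool((aln.rev1 if mate == 1 else aln.rev2)[i])
                other_rev = bool((aln.rev2 if mate == 1 else aln.rev1)[i])
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if rev and mapped:
                    flag |= 0x10
                if other_rev and other_mapped:
                    flag |= 0x20
                if not mapped:
                    flag |= 0x4
                if not other_mapped:
                    flag |= 0x8
                if mapped and other_mapped and aln.chrom1[i] == aln.chrom2[i]:
                    flag |= 0x2
                seg.flag = flag
                seq = reads.seq1[i] if mate == 1 else reads.seq2[i]
                qual = reads.qual1[i] if mate == 1 else reads.qual2[i]
                if rev:  # store in aligned (reference) orientation
                    seq = revcomp(seq)
                    qual = qual[::-1]
                seg.query_sequence = CODE_TO_ASCII[seq].tobytes().decode()
                seg.query_qualities = pysam.qualitystring_to_array(
                    (qual + PHRED_OFFSET).astype(np.uint8).tobytes().decode())
                if mapped:
                    chrom = int((aln.chrom1 if mate == 1 else aln.chrom2)[i])
                    pos = int((aln.pos1 if mate == 1 else aln.pos2)[i])
                    alen = int((aln.aln_len1 if mate == 1 else aln.aln_len2)[i])
                    cig = (aln.cigar1 if mate == 1 else aln.cigar2).get(i)
                    seg.reference_id = chrom
                    seg.reference_start = pos
                    seg.mapping_quality = 60
                    if cig is None:
                        clip = rl - alen
                        ops = [("M", alen)]
                        if clip > 0:
                            # adapter bases soft-clipped on the fragment 3' side
                            ops = ops + [("S", clip)] if not rev else [("S", clip)] + ops
                        seg.cigar = _cigar_tuples(ops)
                    else:
                        seg.cigar = _cigar_tuples(cig)
                if other_mapped:
                    ochrom = int((aln.chrom2 if mate == 1 else aln.chrom1)[i])
                    opos = int((aln.pos2 if mate == 1 else aln.pos1)[i])
                    seg.next_reference_id = ochrom
                    seg.next_reference_start = opos
                if mapped and other_mapped and aln.chrom1[i] == aln.chrom2[i]:
                    outer = (int(aln.pos2[i]) + int(aln.aln_len2[i])) - int(aln.pos1[i])
                    seg.template_length = outer if mate == 1 else -outer
                seg.set_tag("DT", int(reads.is_duplicate[i]))
                out.write(seg)


def read_sam(path, sample: str = "sample") -> tuple[SampleReads, PairAlignments]:
    """Parse a SAM/BAM of uniform-length pairs back into the containers."""
    by_name: dict[str, list] = {}
    chroms: list[str] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        chroms = list(fh.references)
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            by_name.setdefault(seg.query_name, [None, None])[0 if seg.is_read1 else 1] = (
                seg.reference_id if not seg.is_unmapped else -1,
                seg.reference_start if not seg.is_unmapped else -1,
                seg.is_reverse,
                seg.query_sequence,
                seg.query_qualities,
                seg.cigartuples,
                seg.is_unmapped,
            )
    if not by_name:
        raise FormatError(f"no alignments in {path}")
    names = sorted(by_name)
    n = len(names)
    first = next(v for pair in by_name.values() for v in pair if v is not None)
    rl = len(first[3])
    mk = lambda dt, fill=0: np.full(n, fill, dtype=dt)
    s1, q1 = np.zeros((n, rl), np.uint8), np.zeros((n, rl), np.uint8)
    s2, q2 = np.zeros((n, rl), np.uint8), np.zeros((n, rl), np.uint8)
    c1, c2 = mk(np.int32, -1), mk(np.int32, -1)
    p1, p2 = mk(np.int64, -1), mk(np.int64, -1)
    l1, l2 = mk(np.int32), mk(np.int32)
    m1, m2 = mk(bool, False), mk(bool, False)
    r1f, r2f = mk(bool, False), mk(bool, True)
    cig1: dict[int, list] = {}
    cig2: dict[int, list] = {}
    code_to_op = {0: "M", 1: "I", 2: "D"}
    for i, name in enumerate(names):
        for mate, rec in enumerate(by_name[name]):
            if rec is None:
                raise FormatError(f"pair {name!r} is missing a mate in {path}")
            chrom, pos, is_rev, seq, quals, cig, unmapped = rec
            codes = ASCII_TO_CODE[np.frombuffer(seq.encode(), np.uint8)]
            quals = np.asarray(quals, dtype=np.uint8)
            if is_rev:  # back to FASTQ orientation
                codes = revcomp(codes)
                quals = quals[::-1]
            if len(codes) != rl:
                raise FormatError(f"mixed read lengths in {path}")
            (s1 if mate == 0 else s2)[i] = codes
            (q1 if mate == 0 else q2)[i] = quals
            (r1f if mate == 0 else r2f)[i] = is_rev
            if not unmapped:
                (m1 if mate == 0 else m2)[i] = True
                (c1 if mate == 0 else c2)[i] = chrom
                (p1 if mate == 0 else p2)[i] = pos
                ops = [(code_to_op[op], ln) for op, ln in (cig or []) if op in code_to_op]
                span = sum(ln for op, ln in ops if op in "MD")
                (l1 if mate == 0 else l2)[i] = span
                if len(ops) > 1:
                    (cig1 if mate == 0 else cig2)[i] = ops
    reads = SampleReads(sample, rl, s1, q1, s2, q2, np.zeros(n, bool))
    aln = PairAlignments(chroms, c1, p1, l1, m1, c2, p2, l2, m2, cig1, cig2,
                         rev1=r1f, rev2=r2f)
    return reads, aln


# --------------------------------------------------------------------- VCF
def write_vcf(calls: pd.DataFrame, ref_lengths: dict[str, int], path,
              sample: str, info_fields: bool = False) -> None:
    """Write a calls table (chrom,pos,ref,alt,genotype,gq,depth,ref_ad,alt_ad).

    With ``info_fields`` the somatic annotations (SOMATIC, FISHER_P,
    COMPARTMENT, EFFECT) are emitted into INFO.
    """
    header = pysam.VariantHeader()
    for chrom, length in ref_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (Phred)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allele depths")
    if info_fields:
        header.info.add("SOMATIC", 0, "Flag", "Clone-only (post-cloning) variant")
        header.info.add("FISHER_P", 1, "Float", "Two-sided Fisher exact p of allele counts")
        header.info.add("COMPARTMENT", 1, "String", "autosomal/sex/mitochondrial")
        header.info.add("EFFECT", 1, "String", "Coding effect")
        header.info.add("AMINO_CHANGE", 1, "String", "Amino-acid change")
    header.add_sample(sample)
    gt_map = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1), "1": (1,)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in calls.itertuples(index=False):
            rec = out.new_record(contig=row.chrom, start=int(row.pos) - 1,
                                 alleles=(row.ref, row.alt))
            rec.samples[sample]["GT"] = gt_map.get(row.genotype, (None,))
            rec.samples[sample]["GQ"] = int(round(float(row.gq)))
            rec.samples[sample]["DP"] = int(row.depth)
            rec.samples[sample]["AD"] = (int(row.ref_ad), int(row.alt_ad))
            if info_fields:
                rec.info["SOMATIC"] = True
                rec.info["FISHER_P"] = float(row.fisher_p)
                rec.info["COMPARTMENT"] = str(row.compartment)
                if getattr(row, "effect", ""):
                    rec.info["EFFECT"] = str(row.effect)
                if getattr(row, "amino_change", ""):
                    rec.info["AMINO_CHANGE"] = str(row.amino_change)
            out.write(rec)


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as fh:
        sample = list(fh.header.samples)[0]
        for rec in fh:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                genotype = "./."
            else:
                genotype = "/".join(str(a) for a in gt)
            ad = call.get("AD") or (0, 0)
            rows.append((rec.contig, rec.pos, rec.ref, rec.alts[0] if rec.alts else ".",
                         genotype, call.get("GQ") or 0, call.get("DP") or 0,
                         ad[0] or 0, (ad[1] if len(ad) > 1 else 0) or 0))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype",
                                       "gq", "depth", "ref_ad", "alt_ad"])


# --------------------------------------------------------------------- TSV
def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
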
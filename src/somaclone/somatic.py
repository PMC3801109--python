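"""Clone-only (post-cloning de novo) variant identification.

A clone call is a somatic candidate when the nuclear-donor sample shows no
call with the same alternate allele at that position AND the donor site is
callable (depth 5-200) — otherwise the site is counted as unresolvable
rather than somatic.  Candidates are then screened with a two-sided Fisher
exact test on the 2x2 allele-count table [[clone_ref, clone_alt],
[donor_ref, donor_alt]]; candidates with p > alpha (default 0.05) are
filtered out, which removes sites where the two samples' allele counts are
statistically indistinguishable (sequencing noise).

The exact p is computed by full hypergeometric enumeration in integer
arithmetic: the probabilities of all tables with the observed margins that
are at most as likely as the observed table are summed (the standard
two-sided definition, with the 1+1e-7 relative tie tolerance used by R and
SciPy so independent implementations agree to float precision).

The mitochondrial compartment is not diploid: chrM calls are interpreted by
allele fraction (>= 0.9 homoplasmic, else heteroplasmic), since the clone's
mitochondria derive from the oocyte donor.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._seq import decode
from .genotyping import CallableMask, SamplePileup

logger = logging.getLogger(__name__)

COMPARTMENTS = ("autosomal", "sex", "mitochondrial")

_AUTO_RE = re.compile(r"^(chr)?\d+$")
DEFAULT_ALIASES = {"X": "sex", "Y": "sex", "chrX": "sex", "chrY": "sex",
                   "M": "mitochondrial", "MT": "mitochondrial",
                   "chrM": "mitochondrial", "chrMT": "mitochondrial"}


@dataclass
class SomaticEvent:
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str                       # SNV / INS / DEL
    compartment: str
    fisher_p: float
    clone_counts: tuple[int, int]   # (ref, alt)
    donor_counts: tuple[int, int]
    effect: str = "NA"
    amino_change: str = ""


# ------------------------------------------------------------------ Fisher
def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    ``table`` is ((a, b), (c, d)).  All tables with the observed margins
    whose probability is at most that of the observed table (within a
    1 + 1e-7 relative tie tolerance) contribute.  Exact integer arithmetic
    throughout; only the final ratio is floated.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in contingency table")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    w_obs = comb(r1, a) * comb(r2, c)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    scale = 10**7
    threshold = w_obs * (scale + 1)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w * scale <= threshold:
            num += w
    return float(Fraction(num, comb(n, c1)))


def fisher_somatic_filter(event: SomaticEvent, alpha: float = 0.05) -> bool:
    """Keep a candidate iff the allele counts differ (p <= alpha).

    Degenerate tables (an empty sample margin) are dropped: with no coverage
    on one side the test carries no evidence.
    """
    if sum(event.clone_counts) == 0 or sum(event.donor_counts) == 0:
        return False
    return fisher_exact_p((event.clone_counts, event.donor_counts)) <= alpha


# ------------------------------------------------------------- compartments
def classify_compartment(chrom: str, aliases: dict[str, str] | None = None) -> str:
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    if chrom in table:
        return table[chrom]
    if _AUTO_RE.match(chrom):
        return "autosomal"
    raise ValueError(f"cannot classify contig {chrom!r}: add an alias entry for it")


# -------------------------------------------------------------- subtraction
def subtract_paired(clone_calls: pd.DataFrame, donor_calls: pd.DataFrame,
                    clone_pileup: SamplePileup, donor_pileup: SamplePileup,
                    min_depth: int = 5, max_depth: int = 200,
                    max_donor_alt_fraction: float = 0.05
                    ) -> tuple[pd.DataFrame, int]:
    """Candidate somatic SNVs: clone calls absent from the callable donor.

    Besides requiring that no donor call with the same alternate allele
    exists, a candidate must show essentially no donor support for the
    allele (donor allele fraction at most ``max_donor_alt_fraction``): a
    germline heterozygote whose donor allele sampling happens to fall
    between the genotype classes produces no confident donor call, yet its
    pileup still exhibits the allele — paired callers classify sites with
    appreciable normal-sample allele fraction as germline, not somatic.

    Returns the candidate table (with both samples' allele counts attached)
    and the number of unresolvable sites (donor not callable there).
    """
    if clone_calls.empty:
        return clone_calls.assign(donor_ref=[], donor_alt=[]), 0
    donor_keys = (set(zip(donor_calls["chrom"], donor_calls["pos"], donor_calls["alt"]))
                  if not donor_calls.empty else set())
    keep_rows, unresolvable = [], 0
    for row in clone_calls.itertuples(index=False):
        if (row.chrom, row.pos, row.alt) in donor_keys:
            continue
        ddepth = int(donor_pileup.depth[row.chrom][row.pos - 1])
        if ddepth < min_depth or ddepth > max_depth:
            unresolvable += 1
            continue
        dref, dalt = donor_pileup.allele_counts(row.chrom, row.pos, row.ref, row.alt)
        if dalt > max_donor_alt_fraction * ddepth:
            continue
        keep_rows.append(row._asdict() | {"donor_ref": dref, "donor_alt": dalt})
    cand = pd.DataFrame(keep_rows, columns=list(clone_calls.columns) + ["donor_ref", "donor_alt"])
    return cand, unresolvable


def subtract_indels(clone_indels: pd.DataFrame, donor_indels: pd.DataFrame,
                    clone_pileup: SamplePileup, donor_pileup: SamplePileup,
                    min_depth: int = 5, max_depth: int = 200,
                    max_donor_alt_fraction: float = 0.05
                    ) -> tuple[pd.DataFrame, int]:
    """Same contract as subtract_paired, for the indel call tables."""
    if clone_indels.empty:
        return clone_indels.assign(donor_ref=[], donor_alt=[]), 0
    donor_keys = (set(zip(donor_indels["chrom"], donor_indels["pos"],
                          donor_indels["kind"], donor_indels["length"]))
                  if not donor_indels.empty else set())
    donor_support: dict[tuple, int] = {}
    for (chrom, pos0, kind, payload), nsup in donor_pileup.indel_obs.items():
        key = (chrom, pos0 + 1, kind)
        donor_support[key] = donor_support.get(key, 0) + nsup
    keep_rows, unresolvable = [], 0
    for row in clone_indels.itertuples(index=False):
        if (row.chrom, row.pos, row.kind, row.length) in donor_keys:
            continue
        ddepth = int(donor_pileup.depth[row.chrom][row.pos - 1])
        if ddepth < min_depth or ddepth > max_depth:
            unresolvable += 1
            continue
        dalt = donor_support.get((row.chrom, row.pos, row.kind), 0)
        if dalt > max_donor_alt_fraction * ddepth:
            continue
        keep_rows.append(row._asdict() | {"donor_ref": max(ddepth - dalt, 0),
                                          "donor_alt": dalt})
    cand = pd.DataFrame(keep_rows,
                        columns=list(clone_indels.columns) + ["donor_ref", "donor_alt"])
    return cand, unresolvable


def apply_fisher_filter(candidates: pd.DataFrame, alpha: float = 0.05,
                        clone_ref_col: str = "ref_ad", clone_alt_col: str = "alt_ad"
                        ) -> pd.DataFrame:
    """Attach fisher_p and retain candidates with p <= alpha."""
    if candidates.empty:
        out = candidates.copy()
        out["fisher_p"] = pd.Series(dtype=float)
        return out
    ps, keep = [], []
    for row in candidates.itertuples(index=False):
        cr, ca = int(getattr(row, clone_ref_col)), int(getattr(row, clone_alt_col))
        dr, da = int(row.donor_ref), int(row.donor_alt)
        if cr + ca == 0 or dr + da == 0:
            ps.append(np.nan)
            keep.append(False)
            continue
        p = fisher_exact_p(((cr, ca), (dr, da)))
        ps.append(p)
        keep.append(p <= alpha)
    out = candidates.copy()
    out["fisher_p"] = ps
    return out[np.array(keep)].reset_index(drop=True)


def add_compartments(events: pd.DataFrame,
                     aliases: dict[str, str] | None = None) -> pd.DataFrame:
    out = events.copy()
    out["compartment"] = [classify_compartment(c, aliases) for c in out["chrom"]] \
        if len(out) else pd.Series(dtype=object)
    return out


def mito_state(row) -> str:
    """Homoplasmic vs heteroplasmic label for chrM events by allele fraction."""
    depth = row["ref_ad"] + row["alt_ad"]
    if depth == 0:
        return "NA"
    return "homoplasmic" if row["alt_ad"] / depth >= 0.9 else "heteroplasmic"


# ------------------------------------------------------------- gene models
@dataclass
class GeneModel:
    """A protein-coding gene: strand-aware CDS intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str                      # '+' or '-'
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the spliced CDS."""
        off = 0
        if self.strand == "+":
            for s, e in self.cds:
                if pos < s:
                    break
                if pos <= e:
                    return off + (pos - s)
                off += e - s + 1
        else:
            for s, e in reversed(self.cds):
                if pos > e:
                    break
                if pos >= s:
                    return off + (e - pos)
                off += e - s + 1
        raise ValueError(f"position {pos} not inside CDS of {self.gene_id}")

    def cds_sequence(self, reference: dict[str, np.ndarray]) -> str:
        ref = reference[self.chrom]
        parts = [decode(ref[s - 1:e]) for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def load_gene_models_gff3(path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file (grouped by Parent/ID)."""
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", feat.attributes.get("ID", ["?"]))[0]
        if parent not in genes:
            genes[parent] = GeneModel(parent, feat.seqid, feat.strand, [])
        genes[parent].cds.append((feat.start, feat.end))
    out = []
    for g in genes.values():
        out.append(GeneModel(g.gene_id, g.chrom, g.strand, g.cds))  # re-validate
    return out


def write_gene_models_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            start = min(s for s, _ in g.cds)
            end = max(e for _, e in g.cds)
            fh.write(f"{g.chrom}\t.\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\t.\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.cds):
                fh.write(f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n")


# ----------------------------------------------------------------- effects
def annotate_effect(chrom: str, pos: int, ref: str, alt: str, kind: str,
                    gene_models: list[GeneModel],
                    reference: dict[str, np.ndarray]) -> tuple[str, str, bool]:
    """Coding effect of one event: (effect, amino_change, in_cds).

    SNVs inside a CDS are translated strand-aware with the standard code;
    an unchanged amino acid is synonymous, otherwise nonsynonymous with a
    change string like "K811E".  Indels inside a CDS are flagged via
    ``in_cds`` with effect "NA" (frame effects are not modelled).  A
    reference CDS containing an internal stop is warned about and the event
    annotated NA.
    """
    gene = next((g for g in gene_models if g.chrom == chrom and g.contains(pos)), None)
    if gene is None:
        return "noncoding", "", False
    if kind != "SNV":
        return "NA", "", True
    cds_seq = gene.cds_sequence(reference)
    protein = str(Seq(cds_seq).translate())
    if "*" in protein[:-1]:
        logger.warning("reference CDS of %s has an internal stop; annotating NA",
                       gene.gene_id)
        return "NA", "", True
    off = gene.cds_offset(pos)
    base = ref if gene.strand == "+" else str(Seq(ref).complement())
    alt_base = alt if gene.strand == "+" else str(Seq(alt).complement())
    if cds_seq[off] != base:
        logger.warning("reference mismatch at %s:%d inside %s", chrom, pos, gene.gene_id)
    codon_i = off // 3
    codon = cds_seq[3 * codon_i:3 * codon_i + 3]
    mutated = codon[:off % 3] + alt_base + codon[off % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return "synonymous", "", True
    return "nonsynonymous", f"{aa_ref}{codon_i + 1}{aa_alt}", True


def annotate_events(events: pd.DataFrame, gene_models: list[GeneModel],
                    reference: dict[str, np.ndarray]) -> pd.DataFrame:
    """Add effect/amino_change/in_cds columns to an event table."""
    out = events.copy()
    effects, changes, in_cds = [], [], []
    for row in out.itertuples(index=False):
        kind = getattr(row, "kind", "SNV")
        ref = getattr(row, "ref", "")
        alt = getattr(row, "alt", "")
        e, ch, inc = annotate_effect(row.chrom, int(row.pos), ref, alt, kind,
                                     gene_models, reference)
        effects.append(e); changes.append(ch); in_cds.append(inc)
    out["effect"] = effects if len(out) else pd.Series(dtype=object)
    out["amino_change"] = changes if len(out) else pd.Series(dtype=object)
    out["in_cds"] = in_cds if len(out) else pd.Series(dtype=bool)
    return out


def events_from_frame(snvs: pd.DataFrame, indels: pd.DataFrame) -> list[SomaticEvent]:
    """Materialize SomaticEvent objects from the filtered tables."""
    events = []
    for row in snvs.itertuples(index=False):
        events.append(SomaticEvent(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt, kind="SNV",
            compartment=row.compartment, fisher_p=float(row.fisher_p),
            clone_counts=(int(row.ref_ad), int(row.alt_ad)),
            donor_counts=(int(row.donor_ref), int(row.donor_alt)),
            effect=getattr(row, "effect", "NA"),
            amino_change=getattr(row, "amino_change", "")))
    for row in indels.itertuples(index=False):
        events.append(SomaticEvent(
            chrom=row.chrom, pos=int(row.pos), ref="", alt=row.seq,
            kind="INS" if row.kind == "I" else "DEL",
            compartment=row.compartment, fisher_p=float(row.fisher_p),
            clone_counts=(max(int(row.depth) - int(row.support), 0), int(row.support)),
            donor_counts=(int(row.donor_ref), int(row.donor_alt)),
            effect=getattr(row, "effect", "NA"),
            amino_change=getattr(row, "amino_change", "")))
    return events
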
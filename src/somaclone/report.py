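"""Pipeline orchestration and the machine-readable comparison summary.

`run_pipeline` executes the stages in order — simulate, QC, duplicate
removal, pileup/genotyping, paired somatic subtraction with the Fisher
filter, mutation rate and spectrum, CNV segmentation, SV calling and
subtraction, telomere estimation — and `build_summary` condenses the event
streams into one summary object whose totals are computed only from those
streams, so the compartment breakdowns sum to their totals by construction.

The headline somatic mutation rate is nuclear (autosomes + sex chromosome):
the clone's mitochondria descend from the oocyte donor, so clone/donor chrM
differences reflect lineage divergence, not post-cloning mutation; they are
counted in the mitochondrial compartment but excluded from the per-Mb rate.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import io as io_mod
from . import rates as rates_mod
from . import readqc, somatic, sv as sv_mod, telomere as telo_mod
from .config import PipelineConfig
from .genotyping import (CallableMask, call_indels, call_variants,
                         callable_region)
from .genome import Genome
from .simulate import simulate_pair
from .somatic import GeneModel

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 4)."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits),
                                           rounding=ROUND_HALF_UP))


@dataclass
class ComparisonSummary:
    """Table-1-style clone/donor global statistics."""

    sample_case: str = "clone"
    sample_control: str = "donor"
    n_somatic_snv: int = 0
    snv_breakdown: dict = field(default_factory=lambda: dict.fromkeys(
        somatic.COMPARTMENTS, 0))
    n_somatic_indel: int = 0
    indel_breakdown: dict = field(default_factory=lambda: dict.fromkeys(
        somatic.COMPARTMENTS, 0))
    somatic_rate_per_mb: float = 0.0
    n_somatic_nssnv: int = 0
    n_coding_indel: int = 0
    n_somatic_cnv: int = 0
    n_somatic_sv: int = 0
    n_total_sv_clone: int = 0
    n_total_sv_donor: int = 0
    somatic_sv_fraction: float = 0.0      # percent, 1 decimal
    telomere_ratio: float = float("nan")
    transition_fraction: float = float("nan")
    callable_bases: int = 0

    def validate(self) -> None:
        assert sum(self.snv_breakdown.values()) == self.n_somatic_snv
        assert sum(self.indel_breakdown.values()) == self.n_somatic_indel
        if self.n_total_sv_clone:
            expect = round_half_up(100.0 * self.n_somatic_sv / self.n_total_sv_clone)
            assert self.somatic_sv_fraction == expect

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2,
                          allow_nan=True, default=float)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonSummary":
        return cls(**json.loads(text))

    def to_tsv(self) -> str:
        d = asdict(self)
        lines = ["metric\tvalue"]
        for key, value in d.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    lines.append(f"{key}.{sub}\t{v}")
            else:
                lines.append(f"{key}\t{value}")
        return "\n".join(lines) + "\n"


def build_summary(somatic_snvs: pd.DataFrame, somatic_indels: pd.DataFrame,
                  rate: rates_mod.MutationRate | None = None,
                  spectrum: rates_mod.SubstitutionSpectrum | None = None,
                  cnv_calls: pd.DataFrame | None = None,
                  sv_clone: pd.DataFrame | None = None,
                  sv_donor: pd.DataFrame | None = None,
                  sv_somatic: pd.DataFrame | None = None,
                  telomere_comparison: dict | None = None) -> ComparisonSummary:
    """Condense event streams into the summary (totals derived, never entered)."""
    s = ComparisonSummary()
    for comp in somatic.COMPARTMENTS:
        if len(somatic_snvs):
            s.snv_breakdown[comp] = int((somatic_snvs["compartment"] == comp).sum())
        if len(somatic_indels):
            s.indel_breakdown[comp] = int((somatic_indels["compartment"] == comp).sum())
    s.n_somatic_snv = sum(s.snv_breakdown.values())
    s.n_somatic_indel = sum(s.indel_breakdown.values())
    if len(somatic_snvs) and "effect" in somatic_snvs.columns:
        s.n_somatic_nssnv = int(((somatic_snvs["effect"] == "nonsynonymous")
                                 & (somatic_snvs["compartment"] == "autosomal")).sum())
    if len(somatic_indels) and "in_cds" in somatic_indels.columns:
        s.n_coding_indel = int(somatic_indels["in_cds"].sum())
    if rate is not None:
        s.somatic_rate_per_mb = round(rate.rate_per_mb, 2)
        s.callable_bases = rate.callable_bases
    if spectrum is not None:
        s.transition_fraction = spectrum.transition_fraction
    if cnv_calls is not None:
        s.n_somatic_cnv = int(len(cnv_calls))
    if sv_clone is not None:
        s.n_total_sv_clone = int(len(sv_clone))
    if sv_donor is not None:
        s.n_total_sv_donor = int(len(sv_donor))
    if sv_somatic is not None:
        s.n_somatic_sv = int(len(sv_somatic))
    if s.n_total_sv_clone:
        s.somatic_sv_fraction = round_half_up(100.0 * s.n_somatic_sv / s.n_total_sv_clone)
    if telomere_comparison is not None:
        s.telomere_ratio = telomere_comparison["ratio"]
    s.validate()
    return s


def synthetic_gene_models(genome: Genome, genes_per_chrom: int = 2,
                          n_codons: int = 300) -> list[GeneModel]:
    """Deterministic single-CDS gene models tiling the nuclear chromosomes.

    Placed at fixed fractions of each chromosome (alternating strand), clear
    of the telomeric termini, so simulated runs exercise the coding-effect
    annotator without a real annotation.
    """
    models = []
    for chrom in genome.chroms:
        if chrom == "chrM":
            continue
        L = len(genome.reference[chrom])
        for gi in range(genes_per_chrom):
            frac = (gi + 1) / (genes_per_chrom + 1)
            start = int(L * frac)
            end = start + 3 * n_codons - 1
            if end >= L - genome.telomere_length - 200:
                continue
            strand = "+" if gi % 2 == 0 else "-"
            models.append(GeneModel(f"SYNGENE_{chrom}_{gi}", chrom, strand,
                                    [(start + 1, end + 1)]))
    return models


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 gene_models: list[GeneModel] | None = None,
                 write_files: bool = True) -> dict:
    """Run every stage on a simulated donor/clone pair; return all outputs.

    With ``out_dir`` set (and ``write_files``), emits FASTQ/SAM for both
    samples, the somatic VCF, CNV/SV TSVs, the QC report, truth tables and
    the summary JSON/TSV.
    """
    config.validate()
    sim = config.simulation
    out: dict = {"config": config}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(
                f"stage {name!r} failed: {exc}; reproduce with seed={sim.seed}"
            ) from exc

    (donor_g, clone_g, truth, donor_reads, donor_aln,
     clone_reads, clone_aln) = stage("simulate", lambda: simulate_pair(sim))
    reference = donor_g.reference
    ref_lengths = {c: len(s) for c, s in reference.items()}
    out.update(truth=truth, donor_genome=donor_g, clone_genome=clone_g,
               reference=reference)

    samples = {}
    for tag, reads, aln in (("donor", donor_reads, donor_aln),
                            ("clone", clone_reads, clone_aln)):
        qc_idx, qc_report = stage("qc", lambda r=reads: readqc.filter_pairs(r, config.qc))
        order = np.lexsort((aln.pos1[qc_idx], aln.chrom1[qc_idx]))
        sorted_idx = qc_idx[order]
        dedup_idx = stage("dedup", lambda a=aln, r=reads, s=sorted_idx:
                          readqc.remove_duplicates(a, r, s))
        calls, pileup = stage("genotype", lambda r=reads, a=aln, d=dedup_idx:
                              call_variants(r, a, reference, config.caller, d))
        indels = stage("genotype", lambda p=pileup: call_indels(p, config.caller))
        mask = callable_region(pileup, config.caller.min_depth, config.caller.max_depth)
        samples[tag] = dict(reads=reads, aln=aln, qc_idx=qc_idx, qc_report=qc_report,
                            dedup_idx=dedup_idx, calls=calls, indels=indels,
                            pileup=pileup, mask=mask)
    out["samples"] = samples

    # --- somatic subtraction + Fisher filter + annotation
    def somatic_stage():
        cand, unres = somatic.subtract_paired(
            samples["clone"]["calls"], samples["donor"]["calls"],
            samples["clone"]["pileup"], samples["donor"]["pileup"],
            config.caller.min_depth, config.caller.max_depth)
        snvs = somatic.apply_fisher_filter(cand, config.fisher_alpha)
        snvs = somatic.add_compartments(snvs)
        icand, iunres = somatic.subtract_indels(
            samples["clone"]["indels"], samples["donor"]["indels"],
            samples["clone"]["pileup"], samples["donor"]["pileup"],
            config.caller.min_depth, config.caller.max_depth)
        # clone allele counts for the indel table: (spanning - support, support)
        icand = icand.assign(
            ref_ad=(icand["depth"] - icand["support"]).clip(lower=0)
            if len(icand) else pd.Series(dtype=int),
            alt_ad=icand["support"] if len(icand) else pd.Series(dtype=int))
        indels = somatic.apply_fisher_filter(icand, config.fisher_alpha)
        indels = somatic.add_compartments(indels)
        models = gene_models if gene_models is not None \
            else synthetic_gene_models(donor_g)
        snvs = somatic.annotate_events(snvs.assign(kind="SNV"), models, reference)
        if len(indels):
            ind_annot = somatic.annotate_events(
                indels.assign(kind=indels["kind"].map({"I": "INS", "D": "DEL"})),
                models, reference)
        else:
            ind_annot = indels.assign(kind=pd.Series(dtype=object),
                                      effect=pd.Series(dtype=object),
                                      amino_change=pd.Series(dtype=object),
                                      in_cds=pd.Series(dtype=bool))
        return snvs, ind_annot, unres, iunres, models

    snvs, indel_events, n_unres_snv, n_unres_indel, models = stage("somatic", somatic_stage)
    out.update(somatic_snvs=snvs, somatic_indels=indel_events,
               n_unresolvable_snv=n_unres_snv, n_unresolvable_indel=n_unres_indel,
               gene_models=models)

    # --- rates over the intersected nuclear callable region
    def rates_stage():
        inter = samples["clone"]["mask"].intersect(samples["donor"]["mask"])
        nuclear = CallableMask({c: m for c, m in inter.masks.items() if c != "chrM"})
        nuclear_snvs = snvs[snvs["compartment"] != "mitochondrial"] if len(snvs) else snvs
        rate = rates_mod.mutation_rate(nuclear_snvs, nuclear) if nuclear.size else None
        spec = rates_mod.spectrum(snvs[["ref", "alt"]]) if len(snvs) else \
            rates_mod.spectrum(pd.DataFrame(columns=["ref", "alt"]))
        return inter, nuclear, rate, spec

    inter_mask, nuclear_mask, rate, spec = stage("rates", rates_stage)
    out.update(callable_mask=inter_mask, rate=rate, spectrum=spec)

    # --- CNV (clone = case, donor = control)
    def cnv_stage():
        bins = cnv_mod.bin_counts(samples["clone"]["aln"], samples["donor"]["aln"],
                                  ref_lengths, config.cnv.bin_size,
                                  samples["clone"]["dedup_idx"],
                                  samples["donor"]["dedup_idx"])
        segments = cnv_mod.segment(bins, config.cnv.lam, config.cnv.initial_window,
                                   config.cnv.bin_size)
        calls = cnv_mod.call_states(segments, config.cnv.log2_threshold)
        return bins, segments, calls

    bins, segments, cnv_calls = stage("cnv", cnv_stage)
    out.update(cnv_bins=bins, cnv_segments=segments, cnv_calls=cnv_calls)

    # --- SV per sample + somatic subtraction
    def sv_stage():
        res = {}
        for tag in ("clone", "donor"):
            res[tag] = sv_mod.call_svs(
                samples[tag]["aln"], ref_lengths, samples[tag]["dedup_idx"],
                min_support=config.sv.min_support, min_size=config.sv.min_size,
                min_score=config.sv.min_score,
                discordance_multiplier=config.sv.discordance_multiplier)
        som = sv_mod.somatic_svs(res["clone"], res["donor"], config.sv.match_window)
        return res["clone"], res["donor"], som

    sv_clone, sv_donor, sv_som = stage("sv", sv_stage)
    out.update(sv_clone=sv_clone, sv_donor=sv_donor, sv_somatic=sv_som)

    # --- telomeres from QC-passed reads
    def telo_stage():
        ests = {tag: telo_mod.estimate(
            samples[tag]["reads"].subset(samples[tag]["qc_idx"]),
            config.telomere, sample=tag) for tag in ("clone", "donor")}
        comparison = telo_mod.compare_samples(ests["clone"], ests["donor"],
                                              config.telomere.k_report)
        return ests, comparison

    telo_ests, telo_cmp = stage("telomere", telo_stage)
    out.update(telomere_estimates=telo_ests, telomere_comparison=telo_cmp)

    summary = stage("report", lambda: build_summary(
        snvs, indel_events, rate, spec, cnv_calls, sv_clone, sv_donor, sv_som,
        telo_cmp))
    out["summary"] = summary

    if out_dir is not None and write_files:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stage("report", lambda: _write_outputs(out_dir, config, out))
    return out


def _write_outputs(out_dir: Path, config: PipelineConfig, out: dict) -> None:
    ref_lengths = {c: len(s) for c, s in out["reference"].items()}
    from .genome import write_reference_fasta
    write_reference_fasta(out["reference"], out_dir / "reference.fa")
    (out_dir / "config.yaml").write_text(config.to_yaml())
    for tag in ("donor", "clone"):
        s = out["samples"][tag]
        io_mod.write_fastq_pair(s["reads"], out_dir / f"{tag}_R1.fastq",
                                out_dir / f"{tag}_R2.fastq", s["qc_idx"])
        io_mod.write_sam(s["reads"], s["aln"], ref_lengths,
                         out_dir / f"{tag}.sam", s["dedup_idx"])
        (out_dir / f"{tag}_qc.json").write_text(json.dumps(
            {"n_pairs_in": s["qc_report"].n_pairs_in,
             "n_pairs_pass": s["qc_report"].n_pairs_pass,
             "reads_failed": s["qc_report"].reads_failed,
             "pairs_failed": s["qc_report"].pairs_failed}, indent=2, sort_keys=True))
    snvs = out["somatic_snvs"]
    if len(snvs):
        io_mod.write_vcf(snvs, ref_lengths, out_dir / "somatic_snvs.vcf",
                         "clone", info_fields=True)
    io_mod.write_tsv(out["somatic_indels"], out_dir / "somatic_indels.tsv")
    io_mod.write_tsv(out["cnv_calls"], out_dir / "cnv_calls.tsv")
    io_mod.write_tsv(out["sv_clone"], out_dir / "sv_clone.tsv")
    io_mod.write_tsv(out["sv_donor"], out_dir / "sv_donor.tsv")
    io_mod.write_tsv(out["sv_somatic"], out_dir / "sv_somatic.tsv")
    truth = out["truth"]
    io_mod.write_tsv(truth.germline, out_dir / "truth_germline.tsv")
    io_mod.write_tsv(truth.somatic_snvs, out_dir / "truth_somatic_snvs.tsv")
    io_mod.write_tsv(truth.somatic_indels, out_dir / "truth_somatic_indels.tsv")
    (out_dir / "summary.json").write_text(out["summary"].to_json())
    (out_dir / "summary.tsv").write_text(out["summary"].to_tsv())
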
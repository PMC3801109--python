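"""Configuration objects for the simulator and the analysis pipeline.

All tunables live here so a whole run is reproducible from one YAML file plus
a seed.  Defaults mirror the sequencing design the pipeline targets: 2x100 bp
paired-end reads, ~265 bp (sd 20) insert libraries, ~20x depth, a somatic SNV
burden of 3.77/Mb, and the 5-200x callable-depth window used downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants (CLI exit code 2)."""


# Placeholder library adapters (index / universal); real kits vary, so these
# are configurable and only need to be non-genomic fixed strings.
DEFAULT_INDEX_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
DEFAULT_UNIVERSAL_ADAPTER = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic donor/clone read-pair generator.

    Rates are per base pair unless the name says per-Mb.  ``cnv_events`` are
    ``(chrom, start, end, copy_number)`` with 0-based half-open coordinates and
    total diploid copy number in {0, 1, 3, 4}; ``sv_events`` are
    ``(type, chrom, start, size)`` with type in {"DEL", "INS", "CTX"}.
    """

    seed: int = 0
    n_autosomes: int = 2
    autosome_length: int = 1_000_000
    sex_chrom_length: int = 300_000
    mito_length: int = 16_500  # circular; sampled as linear (edge effect ~insert size)
    telomere_length_donor: int = 2_000
    telomere_length_clone: int = 2_000
    germline_het_rate: float = 1e-3
    transition_fraction: float = 2.0 / 3.0  # ts:tv = 2:1 substitution bias
    somatic_snv_rate: float = 3.77   # per Mb of nuclear reference
    somatic_indel_rate: float = 3.04  # per Mb; indel:SNV ratio ~0.8 as in deep WGS pairs
    mito_divergence: float = 0.005   # substitutions/bp between donor and clone chrM
    cnv_events: Sequence[tuple] = field(default_factory=list)
    sv_events: Sequence[tuple] = field(default_factory=list)
    read_length: int = 100
    insert_mean: float = 265.0
    insert_sd: float = 20.0
    coverage: float = 20.0
    base_error_rate: float = 1e-3
    n_base_rate: float = 2e-4
    adapter_seq_index: str = DEFAULT_INDEX_ADAPTER
    adapter_seq_universal: str = DEFAULT_UNIVERSAL_ADAPTER
    duplicate_fraction: float = 0.02
    # per-base mean Phred declines linearly from qual_start to qual_end
    qual_start: float = 38.0
    qual_end: float = 30.0
    qual_sd: float = 3.0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_autosomes)] + ["chrX", "chrM"]

    def chrom_length(self, chrom: str) -> int:
        if chrom == "chrX":
            return self.sex_chrom_length
        if chrom == "chrM":
            return self.mito_length
        return self.autosome_length

    def validate(self) -> None:
        rates = {
            "germline_het_rate": self.germline_het_rate,
            "somatic_snv_rate": self.somatic_snv_rate,
            "somatic_indel_rate": self.somatic_indel_rate,
            "mito_divergence": self.mito_divergence,
            "base_error_rate": self.base_error_rate,
            "n_base_rate": self.n_base_rate,
            "duplicate_fraction": self.duplicate_fraction,
        }
        for name, value in rates.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if not 0 <= self.transition_fraction <= 1:
            raise ConfigError("transition_fraction must be in [0,1]")
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if self.insert_mean <= self.read_length:
            raise ConfigError("insert_mean must exceed read_length")
        if self.read_length < 20:
            raise ConfigError("read_length must be >= 20")
        for tel in (self.telomere_length_donor, self.telomere_length_clone):
            if tel < 0:
                raise ConfigError("telomere lengths must be >= 0")
            for chrom in self.chrom_names():
                if chrom != "chrM" and 2 * tel > self.chrom_length(chrom):
                    raise ConfigError(
                        f"telomere tract {tel} bp does not fit on {chrom} "
                        f"({self.chrom_length(chrom)} bp)"
                    )
        self._validate_intervals()

    def _validate_intervals(self) -> None:
        names = set(self.chrom_names())
        intervals: list[tuple[str, int, int]] = []
        for ev in self.cnv_events:
            chrom, start, end, cn = ev
            if chrom not in names:
                raise ConfigError(f"CNV event on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_length(chrom)):
                raise ConfigError(f"CNV interval out of bounds: {ev}")
            if cn not in (0, 1, 3, 4):
                raise ConfigError(f"copy_number must be in {{0,1,3,4}}: {ev}")
            intervals.append((chrom, start, end))
        for ev in self.sv_events:
            svtype, chrom, start, size = ev
            if svtype not in ("DEL", "INS", "CTX"):
                raise ConfigError(f"SV type must be DEL/INS/CTX: {ev}")
            if chrom not in names:
                raise ConfigError(f"SV event on unknown chromosome {chrom!r}")
            if size <= 0:
                raise ConfigError(f"SV size must be > 0: {ev}")
            end = start + size if svtype != "INS" else start + 1
            if not (0 <= start and end <= self.chrom_length(chrom)):
                raise ConfigError(f"SV interval out of bounds: {ev}")
            if svtype != "INS":
                intervals.append((chrom, start, start + size))
        intervals.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(intervals, intervals[1:]):
            if c1 == c2 and s2 < e1:
                raise ConfigError(
                    f"planted CNV/SV intervals overlap on {c1}: [{s1},{e1}) and [{s2},{e2})"
                )


@dataclass
class QCConfig:
    """Raw-read filtering thresholds (the four criteria plus adapter strings)."""

    max_n_fraction: float = 0.10
    min_mean_quality: float = 15.0
    low_quality_threshold: int = 15
    max_low_quality_fraction: float = 0.10
    adapter_min_match: int = 10
    adapter_match_strict: bool = False  # True: require match length > adapter_min_match
    index_adapter_seq: str = DEFAULT_INDEX_ADAPTER
    universal_adapter_seq: str = DEFAULT_UNIVERSAL_ADAPTER

    def validate(self) -> None:
        for name in ("max_n_fraction", "max_low_quality_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.adapter_min_match < 1:
            raise ConfigError("adapter_min_match must be >= 1")


@dataclass
class CallerConfig:
    """Genotype-calling contract: depth window, quality floor, het prior."""

    min_depth: int = 5
    max_depth: int = 200
    min_genotype_quality: float = 10.0
    theta: float = 0.001           # prior probability of a heterozygous site
    indel_min_support_fraction: float = 0.25
    indel_hom_fraction: float = 0.75

    def validate(self) -> None:
        if not 0 < self.theta < 1:
            raise ConfigError("theta must be in (0,1)")
        if self.min_depth < 1 or self.max_depth < self.min_depth:
            raise ConfigError("require 1 <= min_depth <= max_depth")


@dataclass
class CNVConfig:
    bin_size: int = 100
    lam: float = 2.0               # BIC penalty weight per segment
    initial_window: int = 200      # bins per window-local first merging pass
    log2_threshold: float = 0.2

    def validate(self) -> None:
        if self.bin_size < 1 or self.initial_window < 1:
            raise ConfigError("bin_size and initial_window must be >= 1")
        if self.lam < 0:
            raise ConfigError("lambda must be >= 0")


@dataclass
class SVConfig:
    discordance_multiplier: float = 3.0
    min_support: int = 4           # supporting pairs; set 10 to mirror deep WGS practice
    min_size: int = 1000
    min_score: float = 80.0
    match_window: int = 1000       # somatic subtraction breakpoint tolerance

    def validate(self) -> None:
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")


@dataclass
class TelomereConfig:
    k_max: int = 6
    k_report: int = 4
    k_control: int = 1             # control-motif multiplicity for normalization
    control_motifs: Sequence[str] = ("GGGATT", "GTAGTG")
    include_revcomp: bool = True

    def validate(self) -> None:
        if not 1 <= self.k_report <= self.k_max:
            raise ConfigError("k_report must be in [1, k_max]")
        if not self.control_motifs:
            raise ConfigError("at least one control motif is required")


@dataclass
class PipelineConfig:
    """Everything needed for an end-to-end donor/clone comparison run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    cnv: CNVConfig = field(default_factory=CNVConfig)
    sv: SVConfig = field(default_factory=SVConfig)
    telomere: TelomereConfig = field(default_factory=TelomereConfig)
    fisher_alpha: float = 0.05

    def validate(self) -> None:
        for sub in (self.simulation, self.qc, self.caller, self.cnv, self.sv, self.telomere):
            sub.validate()
        if not 0 < self.fisher_alpha <= 1:
            raise ConfigError("fisher_alpha must be in (0,1]")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["simulation"]["cnv_events"] = [list(e) for e in d["simulation"]["cnv_events"]]
        d["simulation"]["sv_events"] = [list(e) for e in d["simulation"]["sv_events"]]
        d["telomere"]["control_motifs"] = list(d["telomere"]["control_motifs"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:  # pragma: no cover - format error path
            raise ConfigError(f"invalid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = {
            "simulation": SimulationConfig,
            "qc": QCConfig,
            "caller": CallerConfig,
            "cnv": CNVConfig,
            "sv": SVConfig,
            "telomere": TelomereConfig,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in known:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                try:
                    sub = known[key](**value)
                except TypeError as exc:
                    raise ConfigError(f"bad field in section {key!r}: {exc}") from exc
                kwargs[key] = sub
            elif key == "fisher_alpha":
                kwargs[key] = float(value)
            else:
                raise ConfigError(f"unknown config section {key!r}")
        cfg = cls(**kwargs)
        sim = cfg.simulation
        sim.cnv_events = [tuple(e) for e in sim.cnv_events]
        sim.sv_events = [tuple(e) for e in sim.sv_events]
        cfg.validate()
        return cfg
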
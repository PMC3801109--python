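"""Discordant-read-pair structural variant detection.

Each mapped pair is classified against a fitted insert-size model: mates on
different chromosomes signal an inter-chromosomal translocation (CTX),
anomalous orientation (same-strand mates) an intra-chromosomal one (ITX),
an apparent insert more than m standard deviations above the mean a
deletion (DEL), below the mean an insertion (INS); everything else is
concordant.  Signals of one type whose breakpoint intervals fall within an
insert-sized window are clustered; a call is emitted when the cluster
support, predicted size (intra-chromosomal types) and Poisson-surprise
score clear their thresholds (defaults: support 4, size >= 1000 bp,
score >= 80).  Somatic SVs are clone calls with no donor call of the same
type within a breakpoint match window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .simulate import PairAlignments

SV_TYPES = ("DEL", "INS", "ITX", "CTX")
_SCORE_CAP = 10_000.0


@dataclass
class InsertModel:
    mean: float
    sd: float
    discordance_multiplier: float = 3.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    @property
    def window(self) -> float:
        """Breakpoint clustering pad: mean + 3 sd."""
        return self.mean + 3.0 * self.sd


@dataclass
class SVCall:
    type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    size: int
    support: int
    score: float


def _pair_geometry(aln: PairAlignments, idx: np.ndarray):
    """Outer span and left/right ends for both-mapped pairs."""
    start = np.minimum(aln.pos1[idx], aln.pos2[idx])
    end = np.maximum(aln.pos1[idx] + aln.aln_len1[idx],
                     aln.pos2[idx] + aln.aln_len2[idx])
    left_end = np.minimum(aln.pos1[idx] + aln.aln_len1[idx],
                          aln.pos2[idx] + aln.aln_len2[idx])
    right_start = np.maximum(aln.pos1[idx], aln.pos2[idx])
    return start, end, left_end, right_start


def fit_insert_model(aln: PairAlignments, idx: np.ndarray | None = None,
                     sample_n: int = 100_000,
                     discordance_multiplier: float = 3.0) -> InsertModel:
    """Insert mean/sd from properly oriented intra-chromosomal pairs.

    The top and bottom 1% of spans are trimmed before estimating, making
    the fit robust to a small admixture of discordant pairs.
    """
    if idx is None:
        idx = np.arange(aln.n_pairs)
    usable = idx[aln.both_mapped[idx]
                 & (aln.chrom1[idx] == aln.chrom2[idx])
                 & (aln.rev1[idx] != aln.rev2[idx])]
    if len(usable) < 1000:
        raise ValueError(f"only {len(usable)} usable pairs; need >= 1000 to fit "
                         "the insert model")
    usable = usable[:sample_n]
    start, end, _, _ = _pair_geometry(aln, usable)
    spans = (end - start).astype(float)
    lo, hi = np.quantile(spans, [0.01, 0.99])
    core = spans[(spans >= lo) & (spans <= hi)]
    mean = float(core.mean())
    # a 1% two-sided trim of a Normal shrinks the SD by a known factor:
    # sqrt(1 - 2 z phi(z) / 0.98) with z = Phi^-1(0.99); undo it
    trim_correction = 0.93460
    sd = float(max(core.std(ddof=1) / trim_correction, 1.0))
    return InsertModel(mean=mean, sd=sd, discordance_multiplier=discordance_multiplier)


def classify_pairs(aln: PairAlignments, model: InsertModel,
                   idx: np.ndarray | None = None) -> pd.DataFrame:
    """Signal table for discordant pairs; concordant pairs are dropped.

    Unmapped-mate pairs are skipped (and counted in the ``n_skipped``
    attribute of the returned frame).
    """
    if idx is None:
        idx = np.arange(aln.n_pairs)
    both = aln.both_mapped[idx]
    skipped = int((~both).sum())
    idx = idx[both]
    start, end, left_end, right_start = _pair_geometry(aln, idx)
    span = end - start
    m = model.discordance_multiplier
    ctx = aln.chrom1[idx] != aln.chrom2[idx]
    itx = ~ctx & (aln.rev1[idx] == aln.rev2[idx])
    dele = ~ctx & ~itx & (span > model.mean + m * model.sd)
    ins = ~ctx & ~itx & (span < model.mean - m * model.sd)
    svtype = np.full(len(idx), "", dtype=object)
    svtype[ctx] = "CTX"
    svtype[itx] = "ITX"
    svtype[dele] = "DEL"
    svtype[ins] = "INS"
    keep = svtype != ""
    out = pd.DataFrame({
        "type": svtype[keep],
        "chrom1": np.asarray(aln.chroms, dtype=object)[aln.chrom1[idx[keep]]],
        "pos1": aln.pos1[idx[keep]],
        "end1": aln.pos1[idx[keep]] + aln.aln_len1[idx[keep]],
        "chrom2": np.asarray(aln.chroms, dtype=object)[aln.chrom2[idx[keep]]],
        "pos2": aln.pos2[idx[keep]],
        "end2": aln.pos2[idx[keep]] + aln.aln_len2[idx[keep]],
        "span": span[keep],
        "left_end": left_end[keep],
        "right_start": right_start[keep],
    })
    out.attrs["n_skipped"] = skipped
    out.attrs["n_pairs_classified"] = int(len(idx))
    return out


def classify_pair(aln: PairAlignments, i: int, model: InsertModel) -> str:
    """Signal type of a single pair ('' means concordant)."""
    df = classify_pairs(aln, model, np.array([i]))
    if df.attrs["n_skipped"]:
        raise ValueError("pair has an unmapped mate")
    return df["type"].iloc[0] if len(df) else ""


def cluster_signals(signals: pd.DataFrame, model: InsertModel,
                    genome_span: int, min_support: int = 4,
                    min_size: int = 1000, min_score: float = 80.0) -> pd.DataFrame:
    """Cluster same-type signals into SV calls and apply the filters.

    The score is the Poisson tail surprise of seeing >= support signals of
    that type in one clustering window, given the genome-wide background
    rate of that signal type: -10*log10 P(Poisson(mu) >= support).
    """
    pad = model.window
    calls = []
    for svtype, group in signals.groupby("type", sort=True):
        rate = len(group) / max(genome_span, 1)
        mu = rate * 2.0 * pad
        if svtype == "CTX":
            group = group.sort_values(["chrom1", "chrom2", "pos1", "pos2"])
        else:
            group = group.sort_values(["chrom1", "left_end"])
        cluster: list = []

        def flush(cluster):
            if not cluster:
                return
            g = pd.DataFrame(cluster)
            support = len(g)
            if svtype == "CTX":
                pos1 = int(np.median(g["end1"]))
                pos2 = int(np.median(g["pos2"]))
                size = 0
            else:
                # robust inner bracket of the breakpoints (chance signals can
                # contaminate a cluster, so avoid the raw max/min)
                pos1 = int(np.quantile(g["left_end"], 0.9))
                pos2 = int(np.quantile(g["right_start"], 0.1))
                med_span = float(np.median(g["span"]))
                if svtype == "DEL":
                    size = int(round(med_span - model.mean))
                elif svtype == "INS":
                    size = int(round(model.mean - med_span))
                else:
                    size = int(round(abs(med_span - model.mean)))
            score = float(min(-10.0 * poisson.logsf(support - 1, mu) / np.log(10.0),
                              _SCORE_CAP)) if mu > 0 else _SCORE_CAP
            if support >= min_support and score >= min_score \
                    and (svtype == "CTX" or size >= min_size):
                calls.append((svtype, g["chrom1"].iloc[0], pos1,
                              g["chrom2"].iloc[0], pos2, size, support, score))

        prev = None
        for row in group.itertuples(index=False):
            if prev is not None:
                same = row.chrom1 == prev.chrom1 and row.chrom2 == prev.chrom2
                if svtype == "CTX":
                    near = same and abs(row.pos1 - prev.pos1) <= pad \
                        and abs(row.pos2 - prev.pos2) <= pad
                else:
                    near = same and (row.left_end - prev.left_end) <= pad
                if not near:
                    flush(cluster)
                    cluster = []
            cluster.append(row._asdict())
            prev = row
        flush(cluster)
    out = pd.DataFrame(calls, columns=["type", "chrom1", "pos1", "chrom2", "pos2",
                                       "size", "support", "score"])
    return out.sort_values(["chrom1", "pos1"]).reset_index(drop=True)


def call_svs(aln: PairAlignments, ref_lengths: dict[str, int],
             idx: np.ndarray | None = None, model: InsertModel | None = None,
             min_support: int = 4, min_size: int = 1000,
             min_score: float = 80.0,
             discordance_multiplier: float = 3.0) -> pd.DataFrame:
    """End-to-end per-sample SV calling from alignments."""
    if model is None:
        model = fit_insert_model(aln, idx, discordance_multiplier=discordance_multiplier)
    signals = classify_pairs(aln, model, idx)
    genome_span = sum(ref_lengths.values())
    calls = cluster_signals(signals, model, genome_span, min_support,
                            min_size, min_score)
    calls.attrs["n_signals"] = len(signals)
    return calls


def somatic_svs(clone_calls: pd.DataFrame, donor_calls: pd.DataFrame,
                match_window: int = 1000) -> pd.DataFrame:
    """Clone calls with no donor call of the same type within the window."""
    if clone_calls.empty:
        return clone_calls.copy()
    keep = []
    for row in clone_calls.itertuples(index=False):
        matched = False
        for drow in donor_calls.itertuples(index=False):
            if drow.type != row.type or drow.chrom1 != row.chrom1 \
                    or drow.chrom2 != row.chrom2:
                continue
            if abs(drow.pos1 - row.pos1) <= match_window \
                    and abs(drow.pos2 - row.pos2) <= match_window:
                matched = True
                break
        keep.append(not matched)
    return clone_calls[np.array(keep)].reset_index(drop=True)
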
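"""Case/control read-depth CNV detection.

Reads are counted into fixed bins (default 100 bp) by leftmost aligned base;
adjacent bins are merged greedily under a binomial likelihood with a
BIC penalty: within a segment every read is a case read with segment
probability p, so the segment log-likelihood is
k_case*ln(p^) + k_control*ln(1-p^) with p^ = k_case/(k_case+k_control), and
the total criterion is -2*sum(logL) + lambda*n_segments*ln(total reads).
Merging starts from single bins (a window-local pass bounded by
``initial_window`` bins runs first, then a global pass), always taking the
adjacent merge with the largest BIC decrease until no merge decreases BIC;
segments never span chromosome boundaries.

Segment states come from the library-size-normalized log2 depth ratio:
below -0.2 deleted, above +0.2 duplicated, else neutral.  Because the clone
is the case sample and the donor the control, every non-neutral call is
already a clone/donor difference; no further subtraction is needed.
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd

from .simulate import PairAlignments

logger = logging.getLogger(__name__)


@dataclass
class CNVSegment:
    chrom: str
    start: int          # 0-based half-open, bp
    end: int
    case_count: int
    control_count: int
    log2_ratio: float
    state: str          # deleted / neutral / duplicated


def _read_starts(aln: PairAlignments, idx: np.ndarray, chrom_idx: int) -> np.ndarray:
    parts = []
    for chrom, pos, mapped in ((aln.chrom1, aln.pos1, aln.mapped1),
                               (aln.chrom2, aln.pos2, aln.mapped2)):
        sel = idx[(chrom[idx] == chrom_idx) & mapped[idx]]
        parts.append(pos[sel])
    return np.concatenate(parts)


def bin_counts(case_aln: PairAlignments, control_aln: PairAlignments,
               ref_lengths: dict[str, int], bin_size: int = 100,
               case_idx: np.ndarray | None = None,
               control_idx: np.ndarray | None = None
               ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (case, control) read-start counts per bin."""
    if case_aln.chroms != control_aln.chroms:
        raise ValueError("case and control alignments use different references")
    if case_idx is None:
        case_idx = np.arange(case_aln.n_pairs)
    if control_idx is None:
        control_idx = np.arange(control_aln.n_pairs)
    out = {}
    for ci, chrom in enumerate(case_aln.chroms):
        nbins = -(-ref_lengths[chrom] // bin_size)
        case = np.bincount(_read_starts(case_aln, case_idx, ci) // bin_size,
                           minlength=nbins).astype(np.int64)
        ctrl = np.bincount(_read_starts(control_aln, control_idx, ci) // bin_size,
                           minlength=nbins).astype(np.int64)
        out[chrom] = (case[:nbins], ctrl[:nbins])
    return out


def _seg_logl(kc: float, kn: float) -> float:
    t = kc + kn
    if t == 0:
        return 0.0
    l = 0.0
    if kc:
        l += kc * log(kc / t)
    if kn:
        l += kn * log(kn / t)
    return l


def _greedy_merge(kc: np.ndarray, kn: np.ndarray, lam: float, ln_n: float,
                  spans: list[tuple[int, int]]):
    """Greedy adjacent merging; returns merged (kc, kn, spans).

    Every accepted merge strictly decreases the BIC; a lazy heap holds the
    candidate merges keyed by their BIC change.
    """
    n = len(kc)
    kc = [float(x) for x in kc]
    kn = [float(x) for x in kn]
    ll = [_seg_logl(kc[i], kn[i]) for i in range(n)]
    left = list(range(-1, n - 1))
    right = list(range(1, n + 1))
    alive = [True] * n
    stamp = [0] * n
    penalty = lam * ln_n

    def delta(i: int, j: int) -> float:
        merged = _seg_logl(kc[i] + kc[j], kn[i] + kn[j])
        return -2.0 * (merged - ll[i] - ll[j]) - penalty

    heap = []
    for i in range(n - 1):
        heapq.heappush(heap, (delta(i, i + 1), i, i + 1, 0, 0))
    while heap:
        d, i, j, si, sj = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or stamp[i] != si or stamp[j] != sj \
                or right[i] != j:
            continue
        if d >= 0:
            break
        # merge j into i
        kc[i] += kc[j]; kn[i] += kn[j]
        ll[i] = _seg_logl(kc[i], kn[i])
        spans[i] = (spans[i][0], spans[j][1])
        alive[j] = False
        right[i] = right[j]
        if right[i] < n:
            left[right[i]] = i
        stamp[i] += 1
        if left[i] >= 0:
            heapq.heappush(heap, (delta(left[i], i), left[i], i,
                                  stamp[left[i]], stamp[i]))
        if right[i] < n:
            heapq.heappush(heap, (delta(i, right[i]), i, right[i],
                                  stamp[i], stamp[right[i]]))
    keep = [i for i in range(n) if alive[i]]
    return ([kc[i] for i in keep], [kn[i] for i in keep], [spans[i] for i in keep])


def _three_way_pass(kc: list, kn: list, spans: list, lam: float, ln_n: float):
    """Escape pairwise local minima: merge a segment with both neighbors.

    A short noise segment can resist both single merges (each costs one
    penalty term) while the joint merge — which removes two segments and
    two penalty terms — still lowers the BIC.  Alternating this pass with
    pairwise merging optimizes the same objective.
    """
    changed = True
    while changed and len(kc) >= 3:
        changed = False
        best = (0.0, -1)
        for i in range(1, len(kc) - 1):
            la = _seg_logl(kc[i - 1], kn[i - 1])
            lb = _seg_logl(kc[i], kn[i])
            lc = _seg_logl(kc[i + 1], kn[i + 1])
            lm = _seg_logl(kc[i - 1] + kc[i] + kc[i + 1],
                           kn[i - 1] + kn[i] + kn[i + 1])
            d = -2.0 * (lm - la - lb - lc) - 2.0 * lam * ln_n
            if d < best[0]:
                best = (d, i)
        if best[1] >= 0:
            i = best[1]
            kc[i - 1] += kc[i] + kc[i + 1]
            kn[i - 1] += kn[i] + kn[i + 1]
            spans[i - 1] = (spans[i - 1][0], spans[i + 1][1])
            del kc[i:i + 2], kn[i:i + 2], spans[i:i + 2]
            changed = True
    return kc, kn, spans


def segment(bins: dict[str, tuple[np.ndarray, np.ndarray]], lam: float = 2.0,
            initial_window: int = 200, bin_size: int = 100) -> pd.DataFrame:
    """BIC-penalized segmentation of binned counts (per chromosome)."""
    t_case = sum(int(c.sum()) for c, _ in bins.values())
    t_ctrl = sum(int(n.sum()) for _, n in bins.values())
    # penalty scale: total reads in the whole segmentation input
    ln_n = log(max(t_case + t_ctrl, 2))
    rows = []
    for chrom, (case, ctrl) in bins.items():
        total = int(case.sum() + ctrl.sum())
        nbins = len(case)
        if total == 0:
            logger.warning("chromosome %s has zero reads; single neutral segment", chrom)
            rows.append((chrom, 0, nbins * bin_size, 0, 0))
            continue
        spans = [(i, i + 1) for i in range(nbins)]
        kc, kn, sp = list(case), list(ctrl), spans
        # window-local pass, then global merging over the survivors
        wkc, wkn, wsp = [], [], []
        for lo in range(0, nbins, initial_window):
            hi = min(lo + initial_window, nbins)
            a, b, s = _greedy_merge(kc[lo:hi], kn[lo:hi], lam, ln_n, sp[lo:hi])
            wkc += a; wkn += b; wsp += s
        fkc, fkn, fsp = _greedy_merge(wkc, wkn, lam, ln_n, wsp)
        # alternate three-way and pairwise passes until stable
        while True:
            n_before = len(fkc)
            fkc, fkn, fsp = _three_way_pass(fkc, fkn, fsp, lam, ln_n)
            fkc, fkn, fsp = _greedy_merge(fkc, fkn, lam, ln_n, fsp)
            if len(fkc) == n_before:
                break
        for c, n, (b0, b1) in zip(fkc, fkn, fsp):
            rows.append((chrom, b0 * bin_size, b1 * bin_size, int(c), int(n)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "case_count", "control_count"])
    df["log2_ratio"] = log2_ratios(df["case_count"].to_numpy(),
                                   df["control_count"].to_numpy(), t_case, t_ctrl)
    return df


def log2_ratios(case: np.ndarray, ctrl: np.ndarray, t_case: int, t_ctrl: int) -> np.ndarray:
    """Library-size-normalized log2 depth ratios (pseudocount 0.5 on zeros)."""
    case = case.astype(float).copy()
    ctrl = ctrl.astype(float).copy()
    zero = (case == 0) | (ctrl == 0)
    case[zero] += 0.5
    ctrl[zero] += 0.5
    if t_case <= 0 or t_ctrl <= 0:
        return np.zeros(len(case))
    return np.log2(case / ctrl) + np.log2(t_ctrl / max(t_case, 1))


def call_states(segments: pd.DataFrame, log2_threshold: float = 0.2) -> pd.DataFrame:
    """Assign deleted/neutral/duplicated and merge adjacent same-state calls."""
    seg = segments.copy()
    state = np.where(seg["log2_ratio"] < -log2_threshold, "deleted",
                     np.where(seg["log2_ratio"] > log2_threshold, "duplicated", "neutral"))
    seg["state"] = state
    calls = []
    t_case = int(seg["case_count"].sum())
    t_ctrl = int(seg["control_count"].sum())
    for row in seg.itertuples(index=False):
        if row.state == "neutral":
            continue
        if calls and calls[-1][0] == row.chrom and calls[-1][5] == row.state \
                and calls[-1][2] == row.start:
            prev = calls[-1]
            calls[-1] = [row.chrom, prev[1], row.end,
                         prev[3] + row.case_count, prev[4] + row.control_count, row.state]
        else:
            calls.append([row.chrom, row.start, row.end,
                          row.case_count, row.control_count, row.state])
    out = pd.DataFrame(calls, columns=["chrom", "start", "end", "case_count",
                                       "control_count", "state"])
    if len(out):
        out["log2_ratio"] = log2_ratios(out["case_count"].to_numpy(),
                                        out["control_count"].to_numpy(),
                                        t_case, t_ctrl)
    else:
        out["log2_ratio"] = pd.Series(dtype=float)
    return out[["chrom", "start", "end", "case_count", "control_count",
                "log2_ratio", "state"]]
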
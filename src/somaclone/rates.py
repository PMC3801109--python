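"""Somatic mutation rate over the callable region and substitution spectrum.

The rate denominator is the sufficiently covered region — positions with
read depth between 5 and 200 — intersected between clone and donor, since a
somatic call requires adequate coverage in both samples.  Only SNVs enter
the rate (the headline per-Mb figure pairs with the SNV count); indels are
tallied separately.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp_str
from .genotyping import CallableMask

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
SUBSTITUTIONS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


@dataclass
class MutationRate:
    n_variants: int
    callable_bases: int
    rate_per_mb: float

    def summary(self) -> str:
        return f"{self.rate_per_mb:.2f}"


@dataclass
class SubstitutionSpectrum:
    counts12: dict[str, int]        # "A>G" ... directed
    counts6: dict[str, int]         # strand-symmetrized pairs
    transition_fraction: float

    @property
    def total(self) -> int:
        return sum(self.counts12.values())


def mutation_rate(events: pd.DataFrame, mask: CallableMask) -> MutationRate:
    """SNVs per Mb of callable sequence (events outside the mask excluded)."""
    if mask.size == 0:
        raise ValueError("empty callable mask: mutation rate undefined")
    if events.empty:
        n = 0
    else:
        snvs = events[events.get("kind", pd.Series("SNV", index=events.index)) == "SNV"] \
            if "kind" in events.columns else events
        inside = mask.contains_many(snvs["chrom"], snvs["pos"].to_numpy())
        n = int(inside.sum())
    return MutationRate(n_variants=n, callable_bases=mask.size,
                        rate_per_mb=n / (mask.size / 1e6))


def spectrum(events: pd.DataFrame) -> SubstitutionSpectrum:
    """12-type directed tally, 6-type strand-symmetrized collapse, ts fraction."""
    if not events.empty:
        bad = (events["ref"].str.len() != 1) | (events["alt"].str.len() != 1) \
              | (~events["ref"].isin(list("ACGT"))) | (~events["alt"].isin(list("ACGT")))
        if "kind" in events.columns:
            bad |= events["kind"] != "SNV"
        if bad.any():
            raise ValueError("spectrum() accepts SNV events only")
    counts12 = {f"{r}>{a}": 0 for r, a in SUBSTITUTIONS}
    for row in events.itertuples(index=False):
        counts12[f"{row.ref}>{row.alt}"] += 1
    counts6: dict[str, int] = {}
    seen = set()
    for r, a in SUBSTITUTIONS:
        key = f"{r}>{a}"
        rc = f"{revcomp_str(r)}>{revcomp_str(a)}"
        canon = min(key, rc)
        if canon in seen:
            continue
        seen.add(canon)
        counts6[canon] = counts12[key] + (counts12[rc] if rc != key else 0)
    total = sum(counts12.values())
    ts = sum(counts12[f"{r}>{a}"] for r, a in TRANSITIONS)
    return SubstitutionSpectrum(
        counts12=counts12, counts6=counts6,
        transition_fraction=(ts / total) if total else float("nan"))
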
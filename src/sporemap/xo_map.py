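"""Crossover calling and genetic-map construction from random-spore
genotypes.

A crossover event is a switch of parental origin between two consecutive
non-NA calls along the marker order; it is localised to the span between
those two markers.  Events that span an NA gap count toward the spore's
crossover total but not toward any single interval's recombinant tally,
because interval-level sample sizes are computed from spores informative at
both flanking markers.

Genetic distance is the uncorrected two-point recombinant fraction
(cM = 100 x n_recombinant / n_informative); no mapping-function correction
is applied.  Intervals are classified by physical-to-genetic ratio:
hotspot < 15 kb/cM, cold > 75 kb/cM, average in between (boundary values
count as average), and "linked" when no recombinant was observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MarkerTable

__all__ = [
    "CrossoverEvent",
    "CrossoverCallSet",
    "Interval",
    "IntervalMap",
    "call_crossovers",
    "interval_map",
    "map_length",
    "count_multi_co_spores",
    "coefficient_of_coincidence",
    "classify_interval",
    "HOTSPOT_MAX_KB_PER_CM",
    "COLD_MIN_KB_PER_CM",
]

HOTSPOT_MAX_KB_PER_CM = 15.0
COLD_MIN_KB_PER_CM = 75.0


@dataclass(frozen=True)
class CrossoverEvent:
    left_marker: str
    right_marker: str
    left_idx: int
    right_idx: int

    @property
    def spans_gap(self) -> bool:
        return self.right_idx - self.left_idx > 1


@dataclass(frozen=True)
class CrossoverCallSet:
    marker_names: tuple[str, ...]
    events: dict  # spore_id -> tuple[CrossoverEvent, ...]
    all_na_spores: tuple[str, ...]

    def n_events(self, spore_id: str) -> int:
        return len(self.events[spore_id])

    @property
    def total_events(self) -> int:
        return sum(len(v) for v in self.events.values())


@dataclass(frozen=True)
class Interval:
    name: str
    left_marker: str
    right_marker: str
    n_informative: int
    n_recombinant: int
    physical_kb: float

    @property
    def cM(self) -> float:
        if self.n_informative == 0:
            return float("nan")
        return 100.0 * self.n_recombinant / self.n_informative

    @property
    def kb_per_cM(self) -> Optional[float]:
        cm = self.cM
        if np.isnan(cm) or cm == 0:
            return None
        return self.physical_kb / cm

    @property
    def klass(self) -> str:
        if self.n_informative == 0:
            return "no-data"
        if self.n_recombinant == 0:
            return "linked"
        return classify_interval(self.kb_per_cM)


@dataclass(frozen=True)
class IntervalMap:
    chrom_id: str
    intervals: tuple[Interval, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iv in self.intervals:
            ratio = iv.kb_per_cM
            rows.append({
                "interval": iv.name,
                "left_marker": iv.left_marker,
                "right_marker": iv.right_marker,
                "n_informative": iv.n_informative,
                "n_recombinant": iv.n_recombinant,
                "cM": iv.cM,
                "physical_kb": iv.physical_kb,
                "kb_per_cM": np.nan if ratio is None else ratio,
                "class": iv.klass,
            })
        return pd.DataFrame(rows)


def classify_interval(kb_per_cM: Optional[float],
                      hotspot_max: float = HOTSPOT_MAX_KB_PER_CM,
                      cold_min: float = COLD_MIN_KB_PER_CM) -> str:
    """Classify an interval by its kb/cM ratio; ``None`` (no recombinants
    observed) is "linked"."""
    if kb_per_cM is None:
        return "linked"
    if kb_per_cM < hotspot_max:
        return "hotspot"
    if kb_per_cM > cold_min:
        return "cold"
    return "average"


def call_crossovers(gm: GenotypeMatrix, mt: MarkerTable) -> CrossoverCallSet:
    """Scan each spore's non-NA calls in map order; every change of parental
    origin between consecutive informative markers is one event."""
    order = [m for m in mt.marker_names if m in set(gm.marker_names)]
    sub = gm.subset_markers(order)
    calls = sub.calls()
    events: dict[str, tuple] = {}
    all_na = []
    for row, spore_id in zip(calls, sub.spore_ids):
        informative = np.flatnonzero(row >= 0)
        if len(informative) == 0:
            all_na.append(spore_id)
            events[spore_id] = ()
            continue
        evs = []
        for a, b in zip(informative, informative[1:]):
            if row[a] != row[b]:
                evs.append(CrossoverEvent(
                    left_marker=order[a], right_marker=order[b],
                    left_idx=int(a), right_idx=int(b)))
        events[spore_id] = tuple(evs)
    return CrossoverCallSet(marker_names=tuple(order), events=events,
                            all_na_spores=tuple(all_na))


def interval_map(gm: GenotypeMatrix, mt: MarkerTable,
                 physical: Optional[MarkerTable] = None,
                 chrom_id: Optional[str] = None) -> IntervalMap:
    """Per-interval recombinant counts and cM from spores informative at
    both flanking markers."""
    if physical is None:
        physical = mt
    order = [m for m in mt.marker_names if m in set(gm.marker_names)]
    sub = gm.subset_markers(order)
    calls = sub.calls()
    pos = physical.positions(order)
    intervals = []
    for k in range(len(order) - 1):
        left = calls[:, k]
        right = calls[:, k + 1]
        informative = (left >= 0) & (right >= 0)
        n_inf = int(informative.sum())
        n_rec = int((left[informative] != right[informative]).sum())
        name = f"{order[k]}/{order[k + 1]}"
        intervals.append(Interval(
            name=name, left_marker=order[k], right_marker=order[k + 1],
            n_informative=n_inf, n_recombinant=n_rec,
            physical_kb=(pos[k + 1] - pos[k]) / 1000.0))
    if chrom_id is None:
        chroms = set(mt.frame["chrom_id"])
        chrom_id = chroms.pop() if len(chroms) == 1 else "multi"
    return IntervalMap(chrom_id=chrom_id, intervals=tuple(intervals))


def map_length(im: IntervalMap) -> float:
    """Total map length in cM: sum of interval cM over intervals with data
    (linked intervals contribute 0)."""
    total = 0.0
    for iv in im.intervals:
        if iv.n_informative > 0:
            total += iv.cM
    return total


def count_multi_co_spores(ccs: CrossoverCallSet) -> int:
    """Number of spores with two or more crossover events on the
    chromosome."""
    return sum(1 for evs in ccs.events.values() if len(evs) >= 2)


def coefficient_of_coincidence(
    gm: GenotypeMatrix, mt: MarkerTable,
    interval_pair: tuple[str, str],
) -> tuple[Optional[float], int, float]:
    """Coefficient of coincidence for two named intervals ("mA/mB" form).

    coc = observed joint recombinant frequency / product of the single
    frequencies, computed over spores informative at all four flanking
    markers.  Returns (coc, n_double_observed, n_double_expected); coc is
    None when either single-interval frequency is zero.
    """
    order = [m for m in mt.marker_names if m in set(gm.marker_names)]
    sub = gm.subset_markers(order)
    calls = sub.calls()
    idx = {m: i for i, m in enumerate(order)}

    def bounds(name):
        left, right = name.split("/")
        return idx[left], idx[right]

    a1, a2 = bounds(interval_pair[0])
    b1, b2 = bounds(interval_pair[1])
    need = [a1, a2, b1, b2]
    informative = np.all(calls[:, need] >= 0, axis=1)
    if informative.sum() == 0:
        return None, 0, 0.0
    sel = calls[informative]
    rec_a = sel[:, a1] != sel[:, a2]
    rec_b = sel[:, b1] != sel[:, b2]
    n = informative.sum()
    fa = rec_a.mean()
    fb = rec_b.mean()
    n_double = int((rec_a & rec_b).sum())
    expected = fa * fb * n
    if fa == 0 or fb == 0:
        return None, n_double, float(expected)
    coc = (n_double / n) / (fa * fb)
    return float(coc), n_double, float(expected)
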
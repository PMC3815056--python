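"""Marker tables, parental alleles, fragment calls, and genotype matrices.

All tabular formats are plain TSV.  Genotype matrices have a ``spore_id``
first column, marker names as the header in map order, and calls in
{P1, P2, NA}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerTable",
    "ParentalAlleles",
    "GenotypeMatrix",
    "FragmentCall",
    "GenotypeParseError",
    "call_allele",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_marker_table",
    "pool_datasets",
    "PoolingRefusedError",
]

CALL_TOKENS = {"P1", "P2", "NA"}


class GenotypeParseError(ValueError):
    pass


class PoolingRefusedError(RuntimeError):
    """Raised when two datasets fail the homogeneity gate for pooling."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "datasets are not homogeneous; refusing to pool "
            f"(min interval p = {report['min_interval_p']:.4g}, "
            f"combined p = {report['combined_p']:.4g})"
        )


@dataclass(frozen=True)
class MarkerTable:
    """Ordered physical markers: marker_name, chrom_id, position_bp,
    marker_type (SSR | SNP | indel)."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"marker_name", "chrom_id", "position_bp", "marker_type"}
        missing = required - set(self.frame.columns)
        if missing:
            raise GenotypeParseError(f"marker table missing columns {missing}")
        if self.frame["marker_name"].duplicated().any():
            dupes = self.frame.loc[
                self.frame["marker_name"].duplicated(), "marker_name"]
            raise GenotypeParseError(
                f"duplicate marker names: {sorted(set(dupes))}")
        for chrom, grp in self.frame.groupby("chrom_id", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeParseError(
                    f"marker positions not strictly increasing on {chrom}")

    @property
    def marker_names(self) -> list[str]:
        return list(self.frame["marker_name"])

    def positions(self, markers: Sequence[str]) -> np.ndarray:
        lut = dict(zip(self.frame["marker_name"], self.frame["position_bp"]))
        return np.array([lut[m] for m in markers], dtype=float)

    def for_chrom(self, chrom_id: str) -> "MarkerTable":
        sub = self.frame[self.frame["chrom_id"] == chrom_id]
        return MarkerTable(sub.reset_index(drop=True))


@dataclass(frozen=True)
class ParentalAlleles:
    """marker_name -> (p1_allele, p2_allele); fragment sizes or bases."""

    alleles: dict

    def __post_init__(self):
        for marker, (p1, p2) in self.alleles.items():
            if p1 == p2:
                raise GenotypeParseError(
                    f"marker {marker} is uninformative: both parents {p1!r}")

    def __getitem__(self, marker):
        return self.alleles[marker]

    def __contains__(self, marker):
        return marker in self.alleles


@dataclass(frozen=True)
class FragmentCall:
    """One spore x marker fragment-analysis read: peaks of (size_bp,
    height_units)."""

    spore_id: str
    marker_name: str
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(map(tuple, self.peaks)))
        if any(h < 0 for _, h in self.peaks):
            raise GenotypeParseError(
                f"{self.spore_id}/{self.marker_name}: negative peak height")


class GenotypeMatrix:
    """Spores x markers parental-origin calls backed by a pandas frame.

    Values are "P1"/"P2" strings or pd.NA.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise GenotypeParseError(
                f"duplicate spore_id: "
                f"{sorted(set(frame.index[frame.index.duplicated()]))}")
        self.frame = frame.astype(object)
        self.frame.index.name = "spore_id"

    @property
    def marker_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def spore_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def shape(self):
        return self.frame.shape

    def calls(self) -> np.ndarray:
        """Calls as an integer array: 0 = P1, 1 = P2, -1 = NA."""
        mapping = {"P1": 0, "P2": 1}
        arr = np.full(self.frame.shape, -1, dtype=int)
        for tok, code in mapping.items():
            mask = self.frame.eq(tok).fillna(False).to_numpy(dtype=bool)
            arr[mask] = code
        return arr

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.frame[list(markers)])

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.frame.shape != other.frame.shape:
            return False
        if list(self.frame.columns) != list(other.frame.columns):
            return False
        if list(self.frame.index) != list(other.frame.index):
            return False
        a = self.frame.to_numpy(dtype=object)
        b = other.frame.to_numpy(dtype=object)
        return all(
            (x is pd.NA and y is pd.NA) or x == y
            for x, y in zip(a.ravel(), b.ravel())
        )


def call_allele(fc: FragmentCall, pa: ParentalAlleles,
                size_tol_bp: float = 1.0,
                min_height: float = 500.0) -> str:
    """Score a fragment call against the parental alleles.

    A peak is accepted only if its height exceeds ``min_height`` (strictly;
    a peak of exactly 500 units is rejected).  Zero or multiple accepted
    peaks give NA; an accepted peak matching neither parental fragment size
    within ``size_tol_bp`` gives NA with a logged warning.
    """
    if fc.marker_name not in pa:
        raise KeyError(f"marker {fc.marker_name} not in parental alleles")
    accepted = [size for size, height in fc.peaks if height > min_height]
    if len(accepted) != 1:
        return "NA"
    size = accepted[0]
    p1, p2 = pa[fc.marker_name]
    d1, d2 = abs(size - float(p1)), abs(size - float(p2))
    in1, in2 = d1 <= size_tol_bp, d2 <= size_tol_bp
    if in1 and in2:
        # tolerance windows overlap: take the closer parent; exact tie is NA
        if d1 < d2:
            return "P1"
        if d2 < d1:
            return "P2"
        return "NA"
    if in1:
        return "P1"
    if in2:
        return "P2"
    logger.warning(
        "spore %s marker %s: accepted peak %.1f bp matches neither parental "
        "allele (%s / %s) within %.1f bp", fc.spore_id, fc.marker_name, size,
        p1, p2, size_tol_bp)
    return "NA"


def write_genotype_matrix(gm: GenotypeMatrix, path) -> None:
    out = gm.frame.fillna("NA")
    out.to_csv(path, sep="\t", index=True, index_label="spore_id")


def read_genotype_matrix(path) -> GenotypeMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", index_col="spore_id",
                            dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise GenotypeParseError(f"{path}: empty genotype file") from None
    if frame.shape[1] == 0:
        raise GenotypeParseError(f"{path}: no marker columns")
    vals = frame.to_numpy(dtype=object)
    bad = ~np.isin(vals, list(CALL_TOKENS))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: invalid call {vals[i, j]!r} at spore "
            f"{frame.index[i]!r}, marker {frame.columns[j]!r}")
    frame = frame.where(frame != "NA", pd.NA)
    return GenotypeMatrix(frame)


def read_marker_table(path) -> MarkerTable:
    frame = pd.read_csv(path, sep="\t")
    return MarkerTable(frame)


def write_marker_table(mt: MarkerTable, path) -> None:
    mt.frame.to_csv(path, sep="\t", index=False)


def pool_datasets(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix,
                  mt: MarkerTable,
                  interval_p_threshold: float = 0.1,
                  combined_p_threshold: float = 0.05,
                  stats_hook: Optional[Callable] = None) -> GenotypeMatrix:
    """Pool two genotype datasets after a homogeneity gate.

    Per adjacent-marker interval, a Fisher exact test compares recombinant
    vs parental counts between the datasets; a chi-square on the datasets x
    intervals recombinant-count table checks the combined distribution.
    Pools only when every interval p exceeds ``interval_p_threshold`` and
    the combined p exceeds ``combined_p_threshold``; otherwise raises
    :class:`PoolingRefusedError` carrying the per-interval report.
    """
    from . import xo_map, xo_stats

    if gm_a.marker_names != gm_b.marker_names:
        raise GenotypeParseError(
            "cannot pool: datasets have different marker sets")

    im_a = xo_map.interval_map(gm_a, mt)
    im_b = xo_map.interval_map(gm_b, mt)
    interval_ps = {}
    rec_a, rec_b = [], []
    for iv_a, iv_b in zip(im_a.intervals, im_b.intervals):
        table = np.array([
            [iv_a.n_recombinant, iv_a.n_informative - iv_a.n_recombinant],
            [iv_b.n_recombinant, iv_b.n_informative - iv_b.n_recombinant],
        ])
        name = iv_a.name
        if table.sum() == 0:
            interval_ps[name] = 1.0
        else:
            interval_ps[name] = xo_stats.fisher_exact(table)
        rec_a.append(iv_a.n_recombinant)
        rec_b.append(iv_b.n_recombinant)

    combined = np.array([rec_a, rec_b])
    keep = combined.sum(axis=0) > 0
    if keep.sum() >= 2 and combined.sum() > 0:
        _, _, combined_p = xo_stats.chisq(combined[:, keep])
    else:
        combined_p = 1.0

    report = {
        "interval_p": interval_ps,
        "min_interval_p": min(interval_ps.values()) if interval_ps else 1.0,
        "combined_p": combined_p,
    }
    if stats_hook is not None:
        stats_hook(report)
    if report["min_interval_p"] <= interval_p_threshold or \
            combined_p <= combined_p_threshold:
        raise PoolingRefusedError(report)

    frame_a, frame_b = gm_a.frame, gm_b.frame
    if set(frame_a.index) & set(frame_b.index):
        frame_a = frame_a.rename(index=lambda s: f"a:{s}")
        frame_b = frame_b.rename(index=lambda s: f"b:{s}")
    merged = pd.concat([frame_a, frame_b], axis=0)
    return GenotypeMatrix(merged)
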
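"""Meiosis simulator: crossovers with interference, tetrad segregation,
nondisjunction, spore death, and genotyping noise.

The model operates at the bivalent (four-chromatid) stage.  Crossover
positions are drawn either from a stationary gamma renewal process along the
bivalent (shape ``nu`` controls interference; ``nu = 1`` is the no-
interference Poisson case) or as independent Poisson counts per inter-marker
interval (used to emulate subtelomeric hotspots).  Each crossover involves
one chromatid from each homolog, chosen uniformly and independently (no
chromatid interference), so a single spore sees any given crossover with
probability 1/2 and the genetic length of a chromosome is 50·lambda cM.

Meiosis I nondisjunction sends both homolog pairs to one pole, making all
four spores aneuploid; meiosis II nondisjunction in one daughter cell makes
that daughter's two spores aneuploid.  Aneuploid spores are inviable;
euploid spores additionally die independently with a background rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MarkerTable

__all__ = [
    "ChromosomeDef",
    "CrossoverModel",
    "SimConfig",
    "Spore",
    "TetradRecord",
    "simulate_crossovers",
    "segregate_tetrad",
    "simulate_population",
]


@dataclass(frozen=True)
class ChromosomeDef:
    chrom_id: str
    length_bp: int
    centromere_bp: int
    markers: tuple[tuple[str, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(map(tuple, self.markers)))
        pos = [p for _, p in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.chrom_id}: marker positions must increase")
        if not 1 <= self.centromere_bp <= self.length_bp:
            raise ValueError(f"{self.chrom_id}: centromere outside chromosome")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.markers)

    @property
    def marker_positions(self) -> np.ndarray:
        return np.array([p for _, p in self.markers], dtype=float)

    def marker_table(self, marker_type: str = "SSR") -> MarkerTable:
        return MarkerTable(pd.DataFrame({
            "marker_name": self.marker_names,
            "chrom_id": self.chrom_id,
            "position_bp": [p for _, p in self.markers],
            "marker_type": marker_type,
        }))


@dataclass(frozen=True)
class CrossoverModel:
    """Where crossovers fall on the bivalent.

    ``renewal`` mode: ``lam`` expected crossovers per bivalent placed by a
    stationary gamma renewal process of shape ``nu`` (mean spacing
    length/lam).  ``interval_rates`` mode: one Poisson rate (expected
    crossovers per bivalent) per inter-marker interval, positions uniform
    within the interval.
    """

    mode: Literal["renewal", "interval_rates"] = "renewal"
    lam: float = 2.0
    nu: float = 1.0
    interval_rates: Optional[tuple[float, ...]] = None
    obligate_co: bool = False

    def __post_init__(self):
        if self.mode == "renewal":
            if self.lam < 0:
                raise ValueError("lambda must be >= 0")
            if self.nu < 1:
                raise ValueError("gamma shape nu must be >= 1")
            if self.obligate_co and self.lam == 0:
                raise ValueError("obligate crossover with lambda = 0 is "
                                 "unsatisfiable")
        elif self.mode == "interval_rates":
            if self.interval_rates is None:
                raise ValueError("interval_rates mode needs rates")
            rates = tuple(float(r) for r in self.interval_rates)
            if any(r < 0 for r in rates):
                raise ValueError("interval rates must be >= 0")
            object.__setattr__(self, "interval_rates", rates)
            if self.obligate_co and sum(rates) == 0:
                raise ValueError("obligate crossover with all-zero rates is "
                                 "unsatisfiable")
        else:
            raise ValueError(f"unknown crossover mode {self.mode!r}")


@dataclass(frozen=True)
class SimConfig:
    n_meioses: int = 25
    mi_nd_rate: float = 0.0      # d: meiosis I nondisjunction per meiosis
    mii_nd_rate: float = 0.0     # m: meiosis II nondisjunction per division
    spore_death_rate: float = 0.0  # v: background death per euploid spore
    missing_call_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("mi_nd_rate", "mii_nd_rate", "spore_death_rate",
                     "missing_call_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.n_meioses < 0:
            raise ValueError("n_meioses must be >= 0")


@dataclass(frozen=True)
class Spore:
    haplotype: Optional[tuple[str, ...]]  # per-marker P1/P2; None if aneuploid
    euploid: bool
    viable: bool


@dataclass(frozen=True)
class TetradRecord:
    tetrad_id: str
    spores: tuple[Spore, Spore, Spore, Spore]
    nd_event: Literal["none", "MI", "MII_one", "MII_both"]

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)


def _renewal_positions(length: float, lam: float, nu: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Stationary gamma renewal process on [0, length] with mean count lam.

    The first point is U x (size-biased spacing), i.e. U x Gamma(nu+1, theta)
    with theta = length/(lam nu), which is the exact stationary delay
    distribution; subsequent spacings are iid Gamma(nu, theta).
    """
    if lam == 0:
        return np.empty(0)
    theta = length / (lam * nu)
    pos = []
    x = rng.uniform() * rng.gamma(nu + 1.0, theta)
    while x <= length:
        pos.append(x)
        x += rng.gamma(nu, theta)
    return np.asarray(pos)


def simulate_crossovers(chrom: ChromosomeDef, model: CrossoverModel,
                        rng: np.random.Generator
                        ) -> list[tuple[float, tuple[int, int]]]:
    """Draw crossover positions and chromatid pairs for one bivalent.

    Returns a position-sorted list of ``(position_bp, (i, j))`` where ``i``
    in {0,1} is the participating chromatid of homolog 1 and ``j`` in {2,3}
    of homolog 2.
    """
    while True:
        if model.mode == "renewal":
            pos = _renewal_positions(float(chrom.length_bp), model.lam,
                                     model.nu, rng)
        else:
            mpos = chrom.marker_positions
            pieces = []
            for k, rate in enumerate(model.interval_rates):
                count = rng.poisson(rate)
                if count:
                    pieces.append(rng.uniform(mpos[k], mpos[k + 1],
                                              size=count))
            pos = np.sort(np.concatenate(pieces)) if pieces else np.empty(0)
        if not model.obligate_co or len(pos) > 0:
            break
    pos = np.sort(pos)
    chrom_a = rng.integers(0, 2, size=len(pos))
    chrom_b = rng.integers(2, 4, size=len(pos))
    return [(float(p), (int(a), int(b)))
            for p, a, b in zip(pos, chrom_a, chrom_b)]


def _chromatid_origins(crossovers, positions: np.ndarray) -> np.ndarray:
    """Parental origin (0 = P1, 1 = P2) of each of the four chromatids at
    each query position.  Chromatids 0,1 start P1 and 2,3 start P2; a
    chromatid's origin at x flips once per crossover proximal to x in which
    it participates."""
    origins = np.zeros((4, len(positions)), dtype=int)
    origins[2:, :] = 1
    if crossovers:
        co_pos = np.array([p for p, _ in crossovers])
        for g in range(4):
            involved = co_pos[[g in pair for _, pair in crossovers]]
            flips = np.searchsorted(involved, positions, side="left")
            origins[g] = (origins[g] + flips) % 2
    return origins


def segregate_tetrad(crossovers, chrom: ChromosomeDef,
                     nd_draws: tuple[bool, bool, bool],
                     rng: np.random.Generator,
                     spore_death_rate: float = 0.0,
                     tetrad_id: str = "t0") -> TetradRecord:
    """Package four chromatids into a tetrad, applying nondisjunction.

    ``nd_draws`` is (MI fails, MII fails in daughter 1, MII fails in
    daughter 2); when MI fails the MII draws are ignored.
    """
    query = np.append(chrom.marker_positions, float(chrom.centromere_bp))
    origins = _chromatid_origins(crossovers, query)
    marker_origins = origins[:, :-1]
    cen = origins[:, -1]

    mi_fail, mii1, mii2 = nd_draws
    # daughters defined by centromere origin (two chromatids carry each
    # centromere at MI, always)
    daughter1 = [g for g in range(4) if cen[g] == 0]
    daughter2 = [g for g in range(4) if cen[g] == 1]

    if mi_fail:
        nd_event = "MI"
        euploid = [False, False, False, False]
        order = daughter1 + daughter2
    else:
        euploid_map = {}
        for members, fail in ((daughter1, mii1), (daughter2, mii2)):
            for g in members:
                euploid_map[g] = not fail
        nd_event = ("MII_both" if (mii1 and mii2)
                    else "MII_one" if (mii1 or mii2) else "none")
        order = daughter1 + daughter2
        euploid = [euploid_map[g] for g in order]

    spores = []
    for g, eu in zip(order, euploid):
        viable = eu and (rng.uniform() >= spore_death_rate)
        hap = None
        if eu:
            hap = tuple("P1" if o == 0 else "P2" for o in marker_origins[g])
        spores.append(Spore(haplotype=hap, euploid=eu, viable=viable))
    return TetradRecord(tetrad_id=tetrad_id, spores=tuple(spores),
                        nd_event=nd_event)


def simulate_population(
    chroms: Sequence[ChromosomeDef],
    model: CrossoverModel | Mapping[str, CrossoverModel],
    config: SimConfig,
) -> tuple[list[TetradRecord], GenotypeMatrix]:
    """Simulate a cross: tetrads plus the genotype matrix of viable spores.

    With several chromosomes, crossovers are independent across chromosomes
    but nondisjunction/viability are drawn once per tetrad (a spore's
    euploidy flag covers the simulated chromosomes jointly; fine-grained
    per-chromosome aneuploidy is out of scope).  The genotype matrix carries
    viable spores only, emulating a random-spore design, with each call set
    to NA independently at the missing-call rate.
    """
    rng = np.random.default_rng(config.seed)
    if not isinstance(model, Mapping):
        model = {c.chrom_id: model for c in chroms}

    all_marker_names = []
    for c in chroms:
        all_marker_names.extend(c.marker_names)

    tetrads: list[TetradRecord] = []
    rows = []
    row_ids = []
    for i in range(config.n_meioses):
        mi_fail = rng.uniform() < config.mi_nd_rate
        mii = (rng.uniform() < config.mii_nd_rate,
               rng.uniform() < config.mii_nd_rate)
        per_chrom = []
        for c in chroms:
            cos = simulate_crossovers(c, model[c.chrom_id], rng)
            per_chrom.append(segregate_tetrad(
                cos, c, (mi_fail, *mii), rng,
                spore_death_rate=0.0, tetrad_id=f"t{i}"))
        # merge chromosomes: same nd pattern by construction; combine
        # haplotypes and draw viability once per spore
        merged_spores = []
        for s_idx in range(4):
            eu = per_chrom[0].spores[s_idx].euploid
            hap = None
            if eu:
                hap = tuple(h for t in per_chrom
                            for h in t.spores[s_idx].haplotype)
            viable = eu and (rng.uniform() >= config.spore_death_rate)
            merged_spores.append(Spore(haplotype=hap, euploid=eu,
                                       viable=viable))
        tet = TetradRecord(tetrad_id=f"t{i}", spores=tuple(merged_spores),
                           nd_event=per_chrom[0].nd_event)
        tetrads.append(tet)
        for s_idx, spore in enumerate(tet.spores):
            if spore.viable:
                calls = list(spore.haplotype)
                if config.missing_call_rate > 0:
                    mask = rng.uniform(size=len(calls)) < \
                        config.missing_call_rate
                    calls = [pd.NA if m else v for v, m in zip(calls, mask)]
                rows.append(calls)
                row_ids.append(f"t{i}_s{s_idx}")

    frame = pd.DataFrame(rows, index=pd.Index(row_ids, name="spore_id"),
                         columns=all_marker_names, dtype=object)
    return tetrads, GenotypeMatrix(frame)


def tetrads_to_frame(tetrads: Sequence[TetradRecord]) -> pd.DataFrame:
    """Long-format tetrad table (tetrad_id, spore_idx, euploid, viable)."""
    recs = []
    for t in tetrads:
        for idx, s in enumerate(t.spores):
            recs.append((t.tetrad_id, idx, s.euploid, s.viable, t.nd_event))
    return pd.DataFrame(recs, columns=["tetrad_id", "spore_idx", "euploid",
                                       "viable", "nd_event"])
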
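"""Default study design: chromosomes, markers, and strain parameters.

These defaults emulate the mapping study the package was built around: ~100
random spores per cross genotyped at 14 markers along chromosome 3 and 10
markers spanning the chromosome 8 hotspot regions, with crossovers
concentrated in subtelomeric hotspots.

Per-interval genetic lengths for the two strains were derived once from the
published per-interval kb/cM ratios together with the published totals
(95.4 vs 152.6 cM on chromosome 3; 52.7 vs 58.7 cM over the chromosome 8
hotspot panel), solved for a single shared physical marker spacing.
Physical spans with no genetic length on record (the linked interval H/I on
chromosome 3; the unmapped mid-chromosome of chromosome 8) are plausible
cold-region values.  Nondisjunction and death rates are the maximum-
likelihood fits of the tetrad-viability model to the published 100-tetrad
viability tables, rounded.  None of these numbers is asserted as biological
truth; they give simulated data the statistical shape of the study.
"""

from __future__ import annotations

from .meiosis_sim import ChromosomeDef, CrossoverModel, SimConfig

__all__ = [
    "chromosome3",
    "chromosome8",
    "CHR8_HOTSPOT_PANEL",
    "crossover_model",
    "sim_config",
    "STRAIN_PARAMS",
    "CHR3_CM",
    "CHR8_CM",
]

# physical interval spans, kb (shared by both strains)
CHR3_KB = (27.81, 29.09, 117.36, 330.02, 340.01, 349.61, 320.03,
           334.30, 759.60, 777.06, 369.95, 240.36, 262.60)
CHR8_KB = (31.775, 67.6, 26.316, 600.0, 700.0, 700.0, 600.0, 274.1, 92.928)

# per-interval genetic lengths, cM
CHR3_CM = {
    "wildtype": (13.5, 1.7, 12.0, 3.5, 6.1, 2.8, 7.3, 0.0, 2.5, 3.0,
                 5.0, 12.0, 26.0),
    "nbs1-2": (11.17, 19.39, 15.18, 12.90, 9.03, 9.71, 7.30, 0.96, 0.0,
               3.40, 18.01, 21.03, 24.52),
}
CHR8_CM = {
    "wildtype": (7.75, 20.0, 2.15, 2.0, 2.5, 2.5, 2.0, 10.0, 12.8),
    "nbs1-2": (0.0, 19.54, 9.675, 2.0, 2.5, 2.5, 2.0, 19.51, 9.981),
}

# tetrad-model parameters (v: spore death, d: MI ND, m: MII ND per division)
STRAIN_PARAMS = {
    "wildtype": {"spore_death_rate": 0.04, "mi_nd_rate": 0.01,
                 "mii_nd_rate": 0.03},
    "nbs1-2": {"spore_death_rate": 0.05, "mi_nd_rate": 0.15,
               "mii_nd_rate": 0.09},
}

_CHR3_START = 50_000
_CHR8_START = 40_000


def _markers(prefix: str, n: int, start: int, kb_spans) -> tuple:
    letters = [chr(ord("A") + i) for i in range(n)]
    pos = start
    markers = [(f"{prefix}{letters[0]}", pos)]
    for letter, kb in zip(letters[1:], kb_spans):
        pos += int(round(kb * 1000))
        markers.append((f"{prefix}{letter}", pos))
    return tuple(markers)


def chromosome3() -> ChromosomeDef:
    """Chromosome 3: 14 markers, subtelomeric hotspots at both ends,
    centromere inside the linked H/I interval."""
    markers = _markers("c3", 14, _CHR3_START, CHR3_KB)
    return ChromosomeDef(
        chrom_id="chr3",
        length_bp=markers[-1][1] + 120_000,
        centromere_bp=1_700_000,
        markers=markers,
    )


def chromosome8() -> ChromosomeDef:
    """Chromosome 8: 10 markers; the mapped hotspot panel sits at the two
    chromosome ends with a long cold mid-chromosome between D and H."""
    markers = _markers("c8", 10, _CHR8_START, CHR8_KB)
    return ChromosomeDef(
        chrom_id="chr8",
        length_bp=markers[-1][1] + 120_000,
        centromere_bp=1_800_000,
        markers=markers,
    )


CHR8_HOTSPOT_PANEL = ("c8A/c8B", "c8B/c8C", "c8C/c8D", "c8H/c8I", "c8I/c8J")


def crossover_model(chrom_id: str, strain: str) -> CrossoverModel:
    """Interval-rate crossover model for one strain on one chromosome.

    The published interval lengths are observed two-point recombinant
    fractions, which undercount multiple crossovers within an interval; a
    spore's crossover count in an interval is Poisson with mean rate/2, so
    the expected observed fraction is (1 - exp(-rate))/2.  The bivalent
    rate is therefore set to -ln(1 - cM/50), making the simulated data
    reproduce the published per-interval cM in expectation.
    """
    import math

    cm = {"chr3": CHR3_CM, "chr8": CHR8_CM}[chrom_id][strain]
    return CrossoverModel(
        mode="interval_rates",
        interval_rates=tuple(-math.log(1.0 - c / 50.0) for c in cm))


def sim_config(strain: str, n_meioses: int = 25, seed: int = 0,
               missing_call_rate: float = 0.03) -> SimConfig:
    """Study-shaped simulation config: 25 meioses yield ~100 spores; a few
    percent of genotype calls fail, as in the study."""
    params = STRAIN_PARAMS[strain]
    return SimConfig(n_meioses=n_meioses, seed=seed,
                     missing_call_rate=missing_call_rate, **params)
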
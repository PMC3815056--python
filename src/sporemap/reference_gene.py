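"""Synthetic reference gene for the Nbs1-like locus.

The deposited sequence for this gene is not bundled here; instead this module
builds, deterministically, a synthetic gene record with the same documented
structure: a 3528 bp gene with 10 introns, a 3000 bp coding region, a 999
amino-acid product of ~110 kDa, and local sequence context arranged so that
the five characterised alleles produce their documented protein effects:

* ``nbs1-2`` — CC→TT at bp 188–189, serine → phenylalanine at residue 43;
* ``nbs1-3``/``nbs1-4`` — C→T at bp 2126, stop codon at residue 570;
* ``nbs1-5`` — 1 bp substitution at 1072 plus 1 bp deletion at 1074
  (GGCACT → GGTA-T), alanine → valine at 288 with an immediate stop;
* ``nbs1-1`` — A→G in the 3' splice site of intron 5 (bp 1235); retaining the
  intron truncates the protein after residue 328, while re-splicing at the
  next CAG 40 bp downstream puts a stop at residue 400.

Everything not pinned by those constraints is filled from a fixed-seed RNG,
so the record is identical across runs.  It is a synthetic stand-in, fit for
exercising the annotation machinery, not a natural sequence.
"""

from __future__ import annotations

import numpy as np

from .gene_model import (
    Edit,
    GeneModel,
    MutationSpec,
    SpliceMode,
    STOP_CODONS,
    AVERAGE_RESIDUE_MASS,
    translate,
    splice,
)

__all__ = ["build_reference_gene", "allele_specs", "EXONS"]

_SEED = 52801  # fixed; the record must be bit-identical across runs

# Exon intervals in gene-local coordinates (1-based, inclusive).  Intron
# lengths sum to 528 so the 3528 bp gene carries a 3000 bp coding region.
EXONS = (
    (1, 100), (161, 300), (351, 500), (550, 700), (751, 1192),
    (1237, 1400), (1566, 2200), (2228, 2400), (2429, 2600), (2628, 2800),
    (2829, 3528),
)

# CDS positions fixed by the allele table (1-based CDS coordinates).
_FIXED_CDS = {
    1: "A", 2: "T", 3: "G",              # start codon
    127: "T", 128: "C", 129: "C",        # Ser43 (TCC); CC->TT gives Phe
    # GGCACT context at gene bp 1070-1075 (CDS 861-866): Ala288 = GCA at
    # 862-864; deleting CDS 865 brings TAA (866-868) into frame.
    861: "G", 862: "G", 863: "C", 864: "A", 865: "C", 866: "T",
    867: "A", 868: "A",
    # codon 328 spans the exon5/intron5 junction (CDS 982-984); fixing it to
    # GGC keeps both the retained-intron and acceptor-shifted frames stop-free
    # at the junction itself.
    982: "G", 983: "G", 984: "C",
    1021: "C", 1022: "A", 1023: "G",     # cryptic acceptor CAG, 40 bp into exon 6
    1238: "T", 1239: "A", 1240: "A",     # stop in the -40 shifted frame (residue 400)
    1708: "C", 1709: "A", 1710: "A",     # Gln570 (CAA); C->T gives TAA
    2998: "T", 2999: "A", 3000: "A",     # natural stop
}

# CDS window that must stay free of T so that the 40 bp acceptor-shifted
# reading frame cannot hit a premature stop (stops all begin with T), and
# free of cryptic CAG before the one at 1021.
_TFREE_LO, _TFREE_HI = 985, 1237
_CAG_FREE_LO, _CAG_FREE_HI = 984, 1020  # window scanned for spurious CAG starts

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]
_ACG_CODONS = [a + b + c for a in "ACG" for b in "ACG" for c in "ACG"]

_CODON_TABLE = {c: translate("ATG" + c + "TAA")[-1] if len(translate("ATG" + c + "TAA")) == 2 else None
                for c in _SENSE_CODONS}


def _fill_cds(rng: np.random.Generator) -> list[str]:
    cds = [""] * 3000
    for codon_idx in range(1000):
        lo = 3 * codon_idx + 1
        if _TFREE_LO <= lo <= _TFREE_HI or _TFREE_LO <= lo + 2 <= _TFREE_HI:
            codon = _ACG_CODONS[rng.integers(len(_ACG_CODONS))]
        else:
            codon = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
        cds[lo - 1:lo + 2] = list(codon)
    for pos, base in _FIXED_CDS.items():
        cds[pos - 1] = base
    return cds


def _repair(cds: list[str]) -> None:
    fixed = set(_FIXED_CDS)
    # no internal stops in the wild-type frame
    changed = True
    while changed:
        changed = False
        for codon_idx in range(1, 999):
            lo = 3 * codon_idx + 1
            codon = "".join(cds[lo - 1:lo + 2])
            if codon in STOP_CODONS:
                for pos in range(lo, lo + 3):
                    if pos not in fixed:
                        cds[pos - 1] = "C"
                        changed = True
                        break
                else:  # pragma: no cover - construction guarantees a free base
                    raise AssertionError("unrepairable stop codon")
    # the only CAG upstream of the cryptic acceptor must be the acceptor
    while True:
        window = "".join(cds[_CAG_FREE_LO - 1:_CAG_FREE_HI + 2])
        hit = window.find("CAG")
        if hit == -1:
            break
        gpos = _CAG_FREE_LO + hit + 2  # the G of the spurious CAG
        assert gpos not in _FIXED_CDS
        cds[gpos - 1] = "C"


def _tune_mass(cds: list[str], target=110_000.0, tol=450.0) -> None:
    """Nudge free filler codons so the translated product sits at ~110 kDa."""
    fixed = set(_FIXED_CDS)
    free_codons = []
    for codon_idx in range(1, 999):
        lo = 3 * codon_idx + 1
        if any(p in fixed for p in range(lo, lo + 3)):
            continue
        if lo + 2 >= _TFREE_LO - 3 and lo <= _TFREE_HI + 3:
            continue  # leave the splice-sensitive region alone
        free_codons.append(lo)

    def mass() -> float:
        protein = translate("".join(cds))
        return 18.0153 + sum(AVERAGE_RESIDUE_MASS[a] for a in protein)

    m = mass()
    i = 0
    while abs(m - target) > tol and i < len(free_codons):
        lo = free_codons[i]
        i += 1
        codon = "".join(cds[lo - 1:lo + 2])
        res = _CODON_TABLE[codon]
        if m < target and res != "W":
            delta = AVERAGE_RESIDUE_MASS["W"] - AVERAGE_RESIDUE_MASS[res]
            if delta <= 0:
                continue
            cds[lo - 1:lo + 2] = list("TGG")
            m += delta
        elif m > target and res != "G":
            delta = AVERAGE_RESIDUE_MASS["G"] - AVERAGE_RESIDUE_MASS[res]
            if delta >= 0:
                continue
            cds[lo - 1:lo + 2] = list("GGC")
            m += delta


def _intron(rng: np.random.Generator, length: int, head: str = "GT") -> str:
    body_len = length - len(head) - 2
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=body_len))
    return head + body + "AG"


def build_reference_gene() -> GeneModel:
    """Build the deterministic synthetic reference gene model."""
    rng = np.random.default_rng(_SEED)
    cds = _fill_cds(rng)
    _repair(cds)
    _tune_mass(cds)

    introns = []
    intron_spans = []
    for (s1, e1), (s2, e2) in zip(EXONS, EXONS[1:]):
        intron_spans.append((e1 + 1, s2 - 1))
    for k, (lo, hi) in enumerate(intron_spans, start=1):
        length = hi - lo + 1
        head = "GTAA" if k == 5 else "GT"  # intron 5 opens on an in-frame stop
        introns.append(_intron(rng, length, head=head))

    genomic = []
    cds_cursor = 0
    for i, (s, e) in enumerate(EXONS):
        exon_len = e - s + 1
        genomic.append("".join(cds[cds_cursor:cds_cursor + exon_len]))
        cds_cursor += exon_len
        if i < len(introns):
            genomic.append(introns[i])
    gene = GeneModel(gene_id="nbs1_synthetic",
                     genomic_seq="".join(genomic), exons=EXONS)

    # construction-time sanity: structure must match the documented record
    assert len(gene.genomic_seq) == 3528
    spliced = splice(gene)
    assert len(spliced) == 3000
    assert len(translate(spliced)) == 999
    assert gene.genomic_seq[1069:1075] == "GGCACT"
    assert gene.genomic_seq[1234] == "A" and gene.genomic_seq[1235] == "G"
    assert gene.genomic_seq[1273:1276] == "CAG"
    return gene


def allele_specs() -> dict[str, MutationSpec]:
    """The characterised alleles as mutation specs in gene-local coordinates.

    ``nbs1-1`` splicing is ambiguous in vivo (minor product retains intron 5,
    major product re-splices 40 bp downstream), so both outcomes are listed.
    """
    sub = "substitution"
    return {
        "nbs1-1-retained": MutationSpec(
            allele="nbs1-1-retained",
            edits=(Edit(1235, "A", "G", sub),),
            splice_mode=SpliceMode.retain_intron(5),
        ),
        "nbs1-1-resplice": MutationSpec(
            allele="nbs1-1-resplice",
            edits=(Edit(1235, "A", "G", sub),),
            splice_mode=SpliceMode.shift_acceptor(5, 40),
        ),
        "nbs1-2": MutationSpec(
            allele="nbs1-2", edits=(Edit(188, "CC", "TT", sub),),
        ),
        "nbs1-3": MutationSpec(
            allele="nbs1-3", edits=(Edit(2126, "C", "T", sub),),
        ),
        "nbs1-4": MutationSpec(
            allele="nbs1-4", edits=(Edit(2126, "C", "T", sub),),
        ),
        "nbs1-5": MutationSpec(
            allele="nbs1-5",
            edits=(Edit(1072, "C", "T", sub), Edit(1074, "C", "", "deletion")),
        ),
    }
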
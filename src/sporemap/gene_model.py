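"""Gene structure, splicing, translation, and mutation-effect annotation.

Coordinates are 1-based, inclusive, and gene-local: position 1 is the A of
the start codon on the sense strand, and intron positions are counted in the
genomic (unspliced) sequence.  This is the convention used for fungal allele
tables that report mutation positions in base pairs from the ATG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "MutationSpec",
    "Edit",
    "ProteinEffect",
    "GeneStructureError",
    "splice",
    "translate",
    "apply_mutation",
    "annotate_effect",
    "protein_stats",
    "read_gene_record",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Average residue masses (Da), monoisotopic not used: allele tables report
# rounded-kD figures computed from average masses.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153


class GeneStructureError(ValueError):
    """Raised for structurally invalid gene models or mismatching edits."""


@dataclass(frozen=True)
class Edit:
    """A single sequence edit in gene-local 1-based coordinates."""

    position_bp: int
    ref: str
    alt: str
    kind: Literal["substitution", "deletion"]

    def __post_init__(self):
        ref = self.ref.upper()
        alt = self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if self.kind == "substitution":
            if len(ref) != len(alt) or not ref:
                raise GeneStructureError(
                    f"substitution at {self.position_bp}: ref/alt must be "
                    f"non-empty and equal length, got {ref!r}->{alt!r}"
                )
        elif self.kind == "deletion":
            if not ref or alt:
                raise GeneStructureError(
                    f"deletion at {self.position_bp}: ref must be non-empty "
                    f"and alt empty, got {ref!r}->{alt!r}"
                )
        else:
            raise GeneStructureError(f"unknown edit kind {self.kind!r}")

    @property
    def span(self) -> tuple[int, int]:
        return self.position_bp, self.position_bp + len(self.ref) - 1


@dataclass(frozen=True)
class SpliceMode:
    """How a mutant transcript is spliced.

    ``default`` uses the wild-type exon boundaries.  ``retain_intron(k)``
    leaves intron k (1-based) in the mature transcript.  ``shift_acceptor(k,
    offset)`` moves intron k's 3' boundary ``offset`` bases downstream, e.g.
    re-splicing at the next cryptic CAG acceptor.
    """

    mode: Literal["default", "retain_intron", "shift_acceptor"] = "default"
    intron: Optional[int] = None
    offset_bp: int = 0

    @classmethod
    def default(cls) -> "SpliceMode":
        return cls("default")

    @classmethod
    def retain_intron(cls, k: int) -> "SpliceMode":
        return cls("retain_intron", intron=k)

    @classmethod
    def shift_acceptor(cls, k: int, offset_bp: int) -> "SpliceMode":
        return cls("shift_acceptor", intron=k, offset_bp=offset_bp)


@dataclass(frozen=True)
class MutationSpec:
    allele: str
    edits: tuple[Edit, ...] = ()
    splice_mode: SpliceMode = field(default_factory=SpliceMode.default)

    def __post_init__(self):
        edits = tuple(sorted(self.edits, key=lambda e: e.position_bp))
        object.__setattr__(self, "edits", edits)
        for a, b in zip(edits, edits[1:]):
            if a.span[1] >= b.span[0]:
                raise GeneStructureError(
                    f"{self.allele}: overlapping edits at {a.span} and {b.span}"
                )


@dataclass(frozen=True)
class ProteinEffect:
    allele: str
    kind: Literal["missense", "nonsense", "silent", "splice_disruption",
                  "frameshift_truncation"]
    aa_position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    truncated_length: Optional[int] = None


@dataclass(frozen=True)
class GeneModel:
    """A gene as genomic sequence plus ordered exon intervals."""

    gene_id: str
    genomic_seq: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "genomic_seq", self.genomic_seq.upper())
        object.__setattr__(self, "exons", tuple(map(tuple, self.exons)))

    # -- structural validation -------------------------------------------
    def validate(self, strict_cds: bool = True) -> None:
        n = len(self.genomic_seq)
        if not self.exons:
            raise GeneStructureError(f"{self.gene_id}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise GeneStructureError(
                    f"{self.gene_id}: exon ({start},{end}) reversed")
            if start <= prev_end:
                raise GeneStructureError(
                    f"{self.gene_id}: exons overlap or unsorted at {start}")
            if end > n or start < 1:
                raise GeneStructureError(
                    f"{self.gene_id}: exon ({start},{end}) outside [1,{n}]")
            prev_end = end
        if strict_cds:
            cds = splice(self, _validate=False)
            if len(cds) % 3 != 0:
                raise GeneStructureError(
                    f"{self.gene_id}: CDS length {len(cds)} not divisible by 3")
            if not cds.startswith("ATG"):
                raise GeneStructureError(f"{self.gene_id}: CDS lacks ATG start")
            if cds[-3:] not in STOP_CODONS:
                raise GeneStructureError(
                    f"{self.gene_id}: CDS does not end in a stop codon")
        # 3' acceptors should end AG; mutants re-spliced at cryptic sites may
        # not, so this is advisory only.
        for k, (istart, iend) in enumerate(self.introns, start=1):
            if self.genomic_seq[iend - 2:iend] != "AG":
                warnings.warn(
                    f"{self.gene_id}: intron {k} does not end in AG",
                    stacklevel=2,
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)


def splice(gene: GeneModel, _validate: bool = True) -> str:
    """Concatenate exon sequences into the coding sequence."""
    if _validate:
        gene.validate(strict_cds=False)
    return "".join(
        gene.genomic_seq[start - 1:end] for start, end in gene.exons
    )


def translate(cds: str, allow_internal_end: bool = False) -> str:
    """Translate a CDS with the standard nuclear code, stopping at the first
    stop codon; the returned protein excludes the stop symbol."""
    cds = cds.upper()
    if len(cds) < 3:
        raise GeneStructureError(f"CDS too short to translate: {len(cds)} bp")
    if not cds.startswith("ATG"):
        raise GeneStructureError("CDS does not start with ATG")
    usable = cds[: len(cds) - len(cds) % 3]
    protein = str(Seq(usable).translate(table=1))
    stop = protein.find("*")
    if stop == -1:
        if allow_internal_end:
            return protein
        raise GeneStructureError(
            "translation runs off end: no in-frame stop codon")
    return protein[:stop]


def apply_mutation(gene: GeneModel, mut: MutationSpec) -> GeneModel:
    """Apply a mutation spec, shifting exon coordinates across deletions and
    re-splicing per the spec's splice mode."""
    seq = list(gene.genomic_seq)
    exons = [list(ex) for ex in gene.exons]
    boundaries = set()
    for s, e in gene.exons:
        boundaries.update((s, e))

    # check refs before mutating anything
    for edit in mut.edits:
        lo, hi = edit.span
        observed = gene.genomic_seq[lo - 1:hi]
        if observed != edit.ref:
            raise GeneStructureError(
                f"{mut.allele}: ref mismatch at {lo}: expected {edit.ref!r}, "
                f"sequence has {observed!r}"
            )
        if edit.kind == "deletion":
            if any(lo <= b <= hi for b in boundaries) and \
                    mut.splice_mode.mode == "default":
                raise GeneStructureError(
                    f"{mut.allele}: deletion at {lo} removes an exon/intron "
                    "boundary; an explicit splice_mode is required"
                )

    # apply right-to-left so earlier coordinates stay valid
    for edit in sorted(mut.edits, key=lambda e: -e.position_bp):
        lo, hi = edit.span
        if edit.kind == "substitution":
            seq[lo - 1:hi] = list(edit.alt)
        else:
            del seq[lo - 1:hi]
            shift = hi - lo + 1
            for ex in exons:
                if ex[0] > hi:
                    ex[0] -= shift
                if ex[1] >= hi:
                    ex[1] -= shift

    sm = mut.splice_mode
    if sm.mode == "retain_intron":
        k = sm.intron
        if k is None or not (1 <= k <= len(exons) - 1):
            raise GeneStructureError(f"{mut.allele}: no intron {sm.intron}")
        merged = [exons[k - 1][0], exons[k][1]]
        exons = exons[: k - 1] + [merged] + exons[k + 1:]
    elif sm.mode == "shift_acceptor":
        k = sm.intron
        if k is None or not (1 <= k <= len(exons) - 1):
            raise GeneStructureError(f"{mut.allele}: no intron {sm.intron}")
        if exons[k][0] + sm.offset_bp > exons[k][1]:
            raise GeneStructureError(
                f"{mut.allele}: acceptor shift {sm.offset_bp} swallows exon "
                f"{k + 1}")
        exons[k][0] += sm.offset_bp

    return GeneModel(
        gene_id=f"{gene.gene_id}:{mut.allele}",
        genomic_seq="".join(seq),
        exons=tuple((s, e) for s, e in exons),
    )


def annotate_effect(wild: GeneModel, mut: MutationSpec) -> ProteinEffect:
    """Splice and translate wild-type and mutant and classify the change by
    the first differing residue and the mutant protein length."""
    wild.validate(strict_cds=True)
    wild_protein = translate(splice(wild))
    mutant = apply_mutation(wild, mut)
    mutant_protein = translate(splice(mutant, _validate=False),
                               allow_internal_end=True)

    splice_altered = mut.splice_mode.mode != "default"

    if mutant_protein == wild_protein:
        # locate the first codon touched, if any, for reporting
        pos = None
        if mut.edits:
            wild_cds = splice(wild)
            mut_cds = splice(mutant, _validate=False)
            for i, (a, b) in enumerate(zip(wild_cds, mut_cds)):
                if a != b:
                    pos = i // 3 + 1
                    break
        return ProteinEffect(
            allele=mut.allele, kind="silent", aa_position=pos,
            ref_aa=None if pos is None else wild_protein[pos - 1],
            alt_aa=None if pos is None else wild_protein[pos - 1],
        )

    if len(mutant_protein) == len(wild_protein):
        for i, (a, b) in enumerate(zip(wild_protein, mutant_protein)):
            if a != b:
                return ProteinEffect(
                    allele=mut.allele, kind="missense", aa_position=i + 1,
                    ref_aa=a, alt_aa=b,
                )

    # truncation: the stop lands at mutant residue len+1
    stop_at = len(mutant_protein) + 1
    prefix_intact = wild_protein[: len(mutant_protein)] == mutant_protein
    if splice_altered:
        kind = "splice_disruption"
    elif prefix_intact and all(e.kind == "substitution" for e in mut.edits):
        kind = "nonsense"
    else:
        kind = "frameshift_truncation"
    ref_aa = wild_protein[stop_at - 1] if stop_at <= len(wild_protein) else None
    return ProteinEffect(
        allele=mut.allele, kind=kind, aa_position=stop_at,
        ref_aa=ref_aa, alt_aa="*", truncated_length=stop_at - 1,
    )


def protein_stats(protein: str) -> tuple[int, float]:
    """Length in residues and average molecular weight in Da (residue masses
    plus one water).  An empty protein is valid and weighs one water — it is
    the product of an immediate-stop mutant."""
    mass = WATER_MASS
    for aa in protein:
        try:
            mass += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise GeneStructureError(f"unknown residue symbol {aa!r}") from None
    return len(protein), mass


# -- file input ----------------------------------------------------------

def read_gene_record(seq_path, exon_table_path=None, fmt=None) -> GeneModel:
    """Read a gene from a GenBank flat file (exons from CDS/exon features) or
    from FASTA plus a TSV exon table (gene_id, exon_start, exon_end rows)."""
    import os

    if fmt is None:
        ext = os.path.splitext(str(seq_path))[1].lower()
        fmt = "genbank" if ext in {".gb", ".gbk", ".genbank"} else "fasta"
    record = next(SeqIO.parse(str(seq_path), fmt))
    seq = str(record.seq).upper()

    exons: list[tuple[int, int]] = []
    if fmt == "genbank":
        for feat in record.features:
            if feat.type in {"CDS", "exon"}:
                for part in feat.location.parts:
                    exons.append((int(part.start) + 1, int(part.end)))
        exons = sorted(set(exons))
    if exon_table_path is not None:
        exons = []
        with open(exon_table_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "gene_id":  # header
                    continue
                exons.append((int(fields[1]), int(fields[2])))
    if not exons:
        exons = [(1, len(seq))]
    gene = GeneModel(gene_id=record.id, genomic_seq=seq, exons=tuple(exons))
    gene.validate(strict_cds=False)
    return gene
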
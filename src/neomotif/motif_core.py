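"""Peptide windowing, TCEM/GEM motif extraction, and mutant binding registers.

A 9mer bound in an MHC class I groove exposes the side chains of pocket
positions p4-p8 to the T cell receptor (the TCEM I pentamer, ``~~~XXXXX~``)
while p1, p2, p3 and p9 face the groove (the GEM I anchor tetramer).  A 15mer
bound in MHC class II has a fixed central 9mer core starting at 15mer
position 4; the TCEM II is the discontinuous pentamer at core positions
p2, p3, p5, p7, p8 (15mer positions 5, 6, 8, 10, 11; ``XX~X~XX``) and the
GEM II the core anchors p1, p4, p6, p9 (15mer positions 4, 7, 9, 12).

All protein positions, window starts and pocket indices are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters that disqualify a window: ambiguity codes, non-standard residues
#: and the stop symbol.  Conservative superset of X, U, B.
AMBIGUOUS = frozenset("XUBZJO*")

# Pocket positions of the (core) 9mer, 1-based.
TCEM_I_POCKETS = (4, 5, 6, 7, 8)
GEM_I_POCKETS = (1, 2, 3, 9)
TCEM_II_CORE_POCKETS = (2, 3, 5, 7, 8)
GEM_II_CORE_POCKETS = (1, 4, 6, 9)
#: The class II core 9mer begins at 15mer position 4.
CORE_OFFSET_15 = 3

MASK_CODE_I = "~~~XXXXX~"
MASK_CODE_II = "XX~X~XX"

MotifClass = Literal["I", "II"]


class SequenceError(ValueError):
    """Malformed peptide or protein sequence."""


class MutationVerificationError(ValueError):
    """Reference residue in the mutation record does not match the protein."""

    def __init__(self, protein_id: str, position: int, expected: str, found: str):
        self.protein_id = protein_id
        self.position = position
        super().__init__(
            f"{protein_id} position {position}: expected ref residue "
            f"{expected!r}, sequence holds {found!r}"
        )


@dataclass(frozen=True)
class Mutation:
    """A single missense substitution, 1-based position in the protein."""

    case_id: str
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if self.ref_aa not in AA_SET or self.alt_aa not in AA_SET:
            raise SequenceError(
                f"missense mutation must use the 20-letter alphabet, got "
                f"{self.ref_aa!r}->{self.alt_aa!r}"
            )
        if self.ref_aa == self.alt_aa:
            raise SequenceError("ref and alt residue identical; not a missense change")
        if self.position < 1:
            raise SequenceError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    is_mutant: bool = False
    mutation: Optional[Mutation] = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise SequenceError(f"{self.protein_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    protein_id: str
    start: int  # 1-based inclusive
    width: int
    peptide: str

    @property
    def end(self) -> int:
        return self.start + self.width - 1


@dataclass(frozen=True)
class TcemMotif:
    motif_class: MotifClass
    pentamer: str

    @property
    def mask_code(self) -> str:
        return MASK_CODE_I if self.motif_class == "I" else MASK_CODE_II


@dataclass(frozen=True)
class GemMotif:
    motif_class: MotifClass
    tetramer: str


@dataclass(frozen=True)
class PocketAssignment:
    """One mutant-containing window: where the mutant sits and what it exposes."""

    window: PeptideWindow
    motif_class: MotifClass
    mutant_pocket: Optional[int]  # core-9mer pocket p1..p9, None = outside core
    exposed: bool
    tcem: TcemMotif
    gem: GemMotif


def is_clean(peptide: str) -> bool:
    """True if every residue is one of the 20 canonical amino acids."""
    return all(c in AA_SET for c in peptide)


def _check_peptide(peptide: str, width: int) -> None:
    if len(peptide) != width:
        raise SequenceError(f"expected a {width}mer, got length {len(peptide)}")
    if not is_clean(peptide):
        raise SequenceError(f"peptide {peptide!r} contains non-canonical residues")


def window_peptides(protein: ProteinRecord, width: int) -> list[PeptideWindow]:
    """All clean sliding windows of ``width`` (9 or 15), ascending start.

    Windows covering any non-canonical letter are dropped; terminal fragments
    shorter than ``width`` are never emitted.
    """
    if width not in (9, 15):
        raise ValueError(f"width must be 9 or 15, got {width}")
    seq = protein.sequence
    out = []
    for start in range(1, len(seq) - width + 2):
        pep = seq[start - 1 : start - 1 + width]
        if is_clean(pep):
            out.append(PeptideWindow(protein.protein_id, start, width, pep))
    return out


def iter_clean_starts(sequence: str, width: int) -> Iterator[int]:
    """1-based starts of clean windows, without building window objects."""
    for start in range(1, len(sequence) - width + 2):
        if is_clean(sequence[start - 1 : start - 1 + width]):
            yield start


def extract_tcem_i(nine_mer: str) -> TcemMotif:
    """TCEM I pentamer: pocket positions p4-p8 of a 9mer."""
    _check_peptide(nine_mer, 9)
    return TcemMotif("I", nine_mer[3:8])


def extract_tcem_ii(fifteen_mer: str) -> TcemMotif:
    """TCEM II discontinuous pentamer: 15mer positions 5,6,8,10,11."""
    _check_peptide(fifteen_mer, 15)
    p = fifteen_mer
    return TcemMotif("II", p[4] + p[5] + p[7] + p[9] + p[10])


def extract_gem_i(nine_mer: str) -> GemMotif:
    """GEM I anchor tetramer: pocket positions p1,p2,p3,p9 of a 9mer."""
    _check_peptide(nine_mer, 9)
    p = nine_mer
    return GemMotif("I", p[0] + p[1] + p[2] + p[8])


def extract_gem_ii(fifteen_mer: str) -> GemMotif:
    """GEM II anchor tetramer: core p1,p4,p6,p9 = 15mer positions 4,7,9,12."""
    _check_peptide(fifteen_mer, 15)
    p = fifteen_mer
    return GemMotif("II", p[3] + p[6] + p[8] + p[11])


def apply_mutation(protein: ProteinRecord, mutation: Mutation) -> ProteinRecord:
    """Substitute the mutant residue, verifying the recorded reference residue.

    Mirrors the exclusion of mutation records that cannot be resolved in the
    protein isoform: a mismatch raises :class:`MutationVerificationError`
    rather than silently mutating.
    """
    if mutation.protein_id != protein.protein_id:
        raise ValueError(
            f"mutation targets {mutation.protein_id!r}, protein is "
            f"{protein.protein_id!r}"
        )
    if not 1 <= mutation.position <= len(protein):
        raise MutationVerificationError(
            protein.protein_id, mutation.position, mutation.ref_aa, "<out of range>"
        )
    found = protein.sequence[mutation.position - 1]
    if found != mutation.ref_aa:
        raise MutationVerificationError(
            protein.protein_id, mutation.position, mutation.ref_aa, found
        )
    seq = (
        protein.sequence[: mutation.position - 1]
        + mutation.alt_aa
        + protein.sequence[mutation.position :]
    )
    return ProteinRecord(protein.protein_id, seq, is_mutant=True, mutation=mutation)


def core_pocket(width: int, offset_in_window: int) -> Optional[int]:
    """Core-9mer pocket (1..9) of a residue at 1-based ``offset_in_window``.

    For a 9mer the window is its own core.  For a 15mer, positions 1-3 and
    13-15 flank the fixed core and return None ("outside core").
    """
    if width == 9:
        return offset_in_window
    pocket = offset_in_window - CORE_OFFSET_15
    return pocket if 1 <= pocket <= 9 else None


def pocket_exposed(motif_class: MotifClass, pocket: Optional[int]) -> bool:
    """Is the residue in that pocket exposed to the TCR (a TCEM position)?"""
    if pocket is None:
        return False
    exposing = TCEM_I_POCKETS if motif_class == "I" else TCEM_II_CORE_POCKETS
    return pocket in exposing


def enumerate_mutant_registers(
    protein: ProteinRecord, mutation: Mutation, width: int
) -> list[PocketAssignment]:
    """All clean windows containing the mutant residue, with pocket assignment.

    An interior mutation (at least ``width - 1`` residues from both termini)
    yields exactly ``width`` windows; 5 of the 9 class I registers and 5 of
    the 15 class II registers expose the mutant to the TCR.
    """
    if not protein.is_mutant:
        raise ValueError("enumerate_mutant_registers expects the verified mutant")
    if protein.sequence[mutation.position - 1] != mutation.alt_aa:
        raise MutationVerificationError(
            protein.protein_id,
            mutation.position,
            mutation.alt_aa,
            protein.sequence[mutation.position - 1],
        )
    motif_class: MotifClass = "I" if width == 9 else "II"
    out = []
    lo = max(1, mutation.position - width + 1)
    hi = min(mutation.position, len(protein) - width + 1)
    for start in range(lo, hi + 1):
        pep = protein.sequence[start - 1 : start - 1 + width]
        if not is_clean(pep):
            continue
        window = PeptideWindow(protein.protein_id, start, width, pep)
        pocket = core_pocket(width, mutation.position - start + 1)
        if width == 9:
            tcem, gem = extract_tcem_i(pep), extract_gem_i(pep)
        else:
            tcem, gem = extract_tcem_ii(pep), extract_gem_ii(pep)
        out.append(
            PocketAssignment(
                window=window,
                motif_class=motif_class,
                mutant_pocket=pocket,
                exposed=pocket_exposed(motif_class, pocket),
                tcem=tcem,
                gem=gem,
            )
        )
    return out


def mutant_relative_index(window: PeptideWindow, mutation: Mutation) -> int:
    """Window start minus mutant position; 0 when the window starts at the mutant."""
    if window.protein_id != mutation.protein_id:
        raise ValueError(
            f"window is on {window.protein_id!r}, mutation on {mutation.protein_id!r}"
        )
    return window.start - mutation.position


def dedupe_mutations(mutations: list[Mutation]) -> list[Mutation]:
    """Drop duplicate amino-acid changes (same protein, position, alt residue).

    Different codon mutations can encode the same residue change; only the
    first record of each (protein_id, position, alt_aa) triple is kept.
    """
    seen: set[tuple[str, int, str]] = set()
    out = []
    for m in mutations:
        key = (m.protein_id, m.position, m.alt_aa)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out
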
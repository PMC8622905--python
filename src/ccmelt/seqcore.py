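"""Sequence-level design and annotation of coiled-coil peptide fragments.

This module covers the sequence side of the tropomyosin period-3 study:
heptad-register assignment (positions *a*-*g* of the coiled-coil repeat),
construction of expression fragments carrying an N-terminal fusion tag,
application of disease missense mutations, isoform comparison, and
theoretical molecular masses of monomers and disulfide-linked dimers.

Native residue numbering is preserved throughout: a fragment spanning
residues 64-154 keeps those positions, and its fusion-tag residues are
numbered backwards so that the tag ends at ``start - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

from .errors import (
    AlignmentError,
    AlphabetError,
    CoverageError,
    PositionError,
    ValidationError,
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

HEPTAD_LETTERS = "abcdefg"

#: Surface class of each heptad position: a/d pack the hydrophobic core,
#: e/g form the electrostatic inter-helix interface, b/c/f face outward
#: (where the actin-contacting residues of tropomyosin sit).
SURFACE_CLASS = {
    "a": "core",
    "d": "core",
    "e": "interface",
    "g": "interface",
    "b": "outer",
    "c": "outer",
    "f": "outer",
}

#: Mass of two hydrogen atoms lost on disulfide-bond formation (Da).
DISULFIDE_MASS_LOSS = 2 * 1.008


def _check_alphabet(sequence: str, context: str = "") -> None:
    for i, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            where = f" in {context}" if context else ""
            raise AlphabetError(
                f"unknown residue code {aa!r} at position {i + 1}{where}"
            )


@dataclass(frozen=True)
class IsoformSequence:
    """A (sub)sequence of one tropomyosin isoform in native numbering.

    Parameters
    ----------
    isoform_id:
        Label such as ``"Tpm1.1"`` or ``"Tpm3.12"``.
    residues:
        Ordered ``(native_position, amino_acid)`` pairs; positions must be
        contiguous and strictly increasing.
    numbering_offset:
        Offset of this isoform's numbering relative to the reference
        isoform (Tpm3.12 carries an extra N-terminal Met, so its positions
        run one higher than the equivalent Tpm1.1 positions).
    """

    isoform_id: str
    residues: tuple[tuple[int, str], ...]
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"{self.isoform_id}: empty sequence")
        positions = [p for p, _ in self.residues]
        for prev, cur in zip(positions, positions[1:]):
            if cur != prev + 1:
                raise ValidationError(
                    f"{self.isoform_id}: positions must be contiguous and "
                    f"increasing; found {prev} followed by {cur}"
                )
        _check_alphabet("".join(aa for _, aa in self.residues), self.isoform_id)

    @classmethod
    def from_string(
        cls,
        isoform_id: str,
        sequence: str,
        first_position: int,
        numbering_offset: int = 0,
    ) -> "IsoformSequence":
        residues = tuple(
            (first_position + i, aa) for i, aa in enumerate(sequence.upper())
        )
        return cls(isoform_id, residues, numbering_offset)

    @property
    def first_position(self) -> int:
        return self.residues[0][0]

    @property
    def last_position(self) -> int:
        return self.residues[-1][0]

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    def residue_at(self, position: int) -> str:
        if not self.first_position <= position <= self.last_position:
            raise PositionError(
                f"position {position} outside {self.isoform_id} "
                f"[{self.first_position}, {self.last_position}]"
            )
        return self.residues[position - self.first_position][1]

    def subsequence(self, start: int, end: int) -> str:
        if start > end:
            raise PositionError(f"start {start} > end {end}")
        self.residue_at(start)
        self.residue_at(end)
        i = start - self.first_position
        return self.sequence[i : i + (end - start + 1)]


@dataclass(frozen=True)
class FragmentSpec:
    """A designed peptide: an isoform sub-sequence plus N-terminal tag.

    ``peptide_sequence`` is the full chain as expressed
    (``fusion_tag + isoform[start:end]``); ``tag_numbering`` assigns the
    tag residues sequential native-style positions ending at ``start - 1``
    so that every residue of the peptide has a unique position.
    """

    isoform_id: str
    start: int
    end: int
    fusion_tag: str
    peptide_sequence: str
    tag_numbering: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = len(self.fusion_tag) + (self.end - self.start + 1)
        if len(self.peptide_sequence) != expected:
            raise ValidationError(
                f"peptide length {len(self.peptide_sequence)} != tag "
                f"{len(self.fusion_tag)} + range {self.end - self.start + 1}"
            )
        if len(self.tag_numbering) != len(self.fusion_tag):
            raise ValidationError("tag_numbering must cover the fusion tag")
        if self.tag_numbering and self.tag_numbering[-1] != self.start - 1:
            raise ValidationError("tag numbering must end at start - 1")
        _check_alphabet(self.peptide_sequence, self.fragment_id)

    @property
    def fragment_id(self) -> str:
        return f"{self.isoform_id}_{self.start}-{self.end}"

    @property
    def tpm_sequence(self) -> str:
        """The isoform-derived portion of the peptide (tag excluded)."""
        return self.peptide_sequence[len(self.fusion_tag) :]

    @property
    def tpm_length(self) -> int:
        return self.end - self.start + 1

    def peptide_index(self, position: int) -> int:
        """0-based index into ``peptide_sequence`` for a native position."""
        first = self.tag_numbering[0] if self.tag_numbering else self.start
        if not first <= position <= self.end:
            raise PositionError(
                f"position {position} outside {self.fragment_id} "
                f"(peptide spans {first}-{self.end})"
            )
        return position - first

    def residue_at(self, position: int) -> str:
        return self.peptide_sequence[self.peptide_index(position)]


@dataclass(frozen=True)
class Mutation:
    """A missense substitution in native numbering, e.g. I92T."""

    isoform_id: str
    position: int
    wt_aa: str
    mut_aa: str
    disease_label: str = ""
    phenotype_class: str = "NA"  # hypo | hyper | NA

    def __post_init__(self) -> None:
        _check_alphabet(self.wt_aa + self.mut_aa, self.label)
        if self.phenotype_class not in ("hypo", "hyper", "NA"):
            raise ValidationError(
                f"phenotype_class must be hypo/hyper/NA, got "
                f"{self.phenotype_class!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class PeriodMap:
    """User-supplied actin-binding period boundaries for one isoform.

    ``intervals`` holds ``(period_id, start, end)`` triples, ordered and
    non-overlapping, in the isoform's native numbering.
    """

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        last_end = None
        for pid, start, end in self.intervals:
            if start > end:
                raise ValidationError(f"period {pid}: start {start} > end {end}")
            if last_end is not None and start <= last_end:
                raise ValidationError(
                    f"period {pid} overlaps or disorders the previous interval"
                )
            last_end = end

    def period_of(self, position: int) -> str | None:
        for pid, start, end in self.intervals:
            if start <= position <= end:
                return pid
        return None


@dataclass(frozen=True)
class HeptadAnnotation:
    """Per-residue heptad register over a contiguous position range."""

    isoform_id: str
    first_position: int
    letters: str  # one heptad letter per residue, cycling a..g
    period_map: PeriodMap | None = None

    @property
    def last_position(self) -> int:
        return self.first_position + len(self.letters) - 1

    @property
    def positions(self) -> range:
        return range(self.first_position, self.last_position + 1)

    def letter(self, position: int) -> str:
        if not self.first_position <= position <= self.last_position:
            raise CoverageError(
                f"position {position} not covered by annotation "
                f"[{self.first_position}, {self.last_position}]"
            )
        return self.letters[position - self.first_position]

    def surface_class(self, position: int) -> str:
        return SURFACE_CLASS[self.letter(position)]

    def period(self, position: int) -> str | None:
        if self.period_map is None:
            return None
        return self.period_map.period_of(position)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": p,
                "heptad": self.letter(p),
                "surface_class": self.surface_class(p),
                "period": self.period(p),
            }
            for p in self.positions
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def assign_heptad(
    seq: IsoformSequence,
    anchor_position: int,
    anchor_letter: str,
    period_map: PeriodMap | None = None,
) -> HeptadAnnotation:
    """Assign the a-g heptad register to every residue of ``seq``.

    The register advances one letter per residue, cyclically, and is fixed
    by a single anchor: ``letter(anchor_position) = anchor_letter``. For the
    tropomyosin fragments studied here the anchor Tpm1.1 92 = *a*
    (equivalently Tpm3.12 93 = *a*) places I92/V95 in core positions *a*/*d*
    and R91 of Tpm3.12 in the outward-facing *f* position.
    """
    if anchor_letter not in HEPTAD_LETTERS:
        raise ValidationError(f"anchor letter {anchor_letter!r} not in a-g")
    seq.residue_at(anchor_position)  # raises PositionError if absent
    anchor_idx = HEPTAD_LETTERS.index(anchor_letter)
    letters = "".join(
        HEPTAD_LETTERS[(anchor_idx + (p - anchor_position)) % 7]
        for p in range(seq.first_position, seq.last_position + 1)
    )
    return HeptadAnnotation(seq.isoform_id, seq.first_position, letters, period_map)


def count_heptads(fragment: FragmentSpec, annotation: HeptadAnnotation) -> int:
    """Number of complete a->g windows within the fragment's Tpm portion."""
    if (
        annotation.first_position > fragment.start
        or annotation.last_position < fragment.end
    ):
        raise CoverageError(
            f"annotation [{annotation.first_position}, "
            f"{annotation.last_position}] does not cover fragment "
            f"[{fragment.start}, {fragment.end}]"
        )
    return sum(
        1
        for p in range(fragment.start, fragment.end - 5)
        if annotation.letter(p) == "a" and p + 6 <= fragment.end
    )


def design_fragment(
    seq: IsoformSequence, start: int, end: int, fusion_tag: str = "GSHMCGG"
) -> FragmentSpec:
    """Construct the designed peptide ``fusion_tag + seq[start:end]``."""
    tpm_part = seq.subsequence(start, end)
    _check_alphabet(fusion_tag, "fusion tag")
    tag_numbering = tuple(range(start - len(fusion_tag), start))
    return FragmentSpec(
        isoform_id=seq.isoform_id,
        start=start,
        end=end,
        fusion_tag=fusion_tag,
        peptide_sequence=fusion_tag + tpm_part,
        tag_numbering=tag_numbering,
    )


def apply_mutation(fragment: FragmentSpec, mutation: Mutation) -> FragmentSpec:
    """Return a copy of ``fragment`` with the substitution applied.

    The mutation's declared wild-type residue is checked against the
    fragment; a mismatch raises :class:`ValidationError` naming both.
    """
    if not fragment.start <= mutation.position <= fragment.end:
        raise PositionError(
            f"mutation position {mutation.position} outside fragment "
            f"range [{fragment.start}, {fragment.end}]"
        )
    idx = fragment.peptide_index(mutation.position)
    found = fragment.peptide_sequence[idx]
    if found != mutation.wt_aa:
        raise ValidationError(
            f"{fragment.fragment_id} position {mutation.position}: expected "
            f"wild-type {mutation.wt_aa!r}, found {found!r}"
        )
    mutated = (
        fragment.peptide_sequence[:idx]
        + mutation.mut_aa
        + fragment.peptide_sequence[idx + 1 :]
    )
    return replace(fragment, peptide_sequence=mutated)


def diff_fragments(
    a: FragmentSpec, b: FragmentSpec, offset: int = 0
) -> list[tuple[int, str, int, str]]:
    """Aligned residue differences between two fragments' Tpm portions.

    ``offset`` maps positions of ``a`` onto ``b`` (``pos_b = pos_a +
    offset``); for the isoform pair studied here Tpm3.12 numbering runs one
    higher than Tpm1.1, so ``offset = 1``. Fusion tags are excluded.
    Returns ``(pos_a, aa_a, pos_b, aa_b)`` tuples ordered by position.
    """
    if a.tpm_length != b.tpm_length:
        raise AlignmentError(
            f"Tpm portions differ in length: {a.tpm_length} vs {b.tpm_length}"
        )
    if b.start != a.start + offset:
        raise AlignmentError(
            f"offset {offset} does not map {a.fragment_id} start {a.start} "
            f"onto {b.fragment_id} start {b.start}"
        )
    diffs = []
    for pos_a, aa_a, aa_b in zip(
        range(a.start, a.end + 1), a.tpm_sequence, b.tpm_sequence
    ):
        if aa_a != aa_b:
            diffs.append((pos_a, aa_a, pos_a + offset, aa_b))
    return diffs


def molecular_weight(peptide_sequence: str, form: str = "monomer") -> float:
    """Theoretical average molecular mass in Da.

    ``monomer`` sums average residue masses plus one water (the Expasy
    convention). ``disulfide_dimer`` is two monomers minus two hydrogens
    lost on S-S bond formation (2.016 Da).
    """
    if not peptide_sequence:
        raise ValidationError("empty sequence")
    _check_alphabet(peptide_sequence)
    mono = _bio_molecular_weight(
        peptide_sequence, seq_type="protein", monoisotopic=False
    )
    if form == "monomer":
        return mono
    if form == "disulfide_dimer":
        return 2 * mono - DISULFIDE_MASS_LOSS
    raise ValidationError(f"unknown form {form!r}")


def wheel_report(
    annotation: HeptadAnnotation, mutations: Iterable[Mutation]
) -> pd.DataFrame:
    """Helical-wheel placement of mutations: heptad letter and surface class.

    Core positions (*a*/*d*) bury the residue in the dimer interface;
    *b*/*c*/*f* expose it on the outer, actin-facing surface; *e*/*g* sit at
    the electrostatic inter-helix interface.
    """
    rows = []
    for m in mutations:
        letter = annotation.letter(m.position)  # CoverageError if outside
        rows.append(
            {
                "mutation": m.label,
                "isoform": m.isoform_id,
                "position": m.position,
                "heptad": letter,
                "surface_class": SURFACE_CLASS[letter],
                "phenotype_class": m.phenotype_class,
                "disease": m.disease_label,
            }
        )
    return pd.DataFrame(rows)
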
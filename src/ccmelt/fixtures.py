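"""Embedded study fixtures: sequences, mutations, and measured Tm values.

The two 91-residue fragment sequences cover the middle of the tropomyosin
molecule - the conserved actin-binding period 3 flanked by parts of
periods 2 and 4. Tpm1.1 residues 64-154 are embedded verbatim (UniProt
P09493 numbering); Tpm3.12 carries an extra N-terminal Met, so its
equivalent fragment spans 65-155 and differs from Tpm1.1 at exactly four
positions (Thr79/Ala80, Asp84/Glu85, Ser132/Asn133, Gln135/Leu136 in
Tpm1.1/Tpm3.12 numbering).

The designed peptides prepend the fusion tag GSHMCGG: the GSHM tetrapeptide
left after His-tag proteolysis, a cysteine that cross-links the two chains
of the dimer via a disulfide bond, and a flexible Gly-Gly linker.

``TABLE1_TM`` holds the measured melting temperatures (mean of three
replicates, degC) of the wild-type and mutant peptides under non-reducing
(no DTT) and reducing (0.5 mM DTT) conditions; the R91P mutant under
reducing conditions has no determinable Tm (it has already begun unfolding
at 0 degC), recorded here as ``None``.
"""

from __future__ import annotations

from .cdmelt import MeltingResult
from .seqcore import (
    FragmentSpec,
    IsoformSequence,
    Mutation,
    PeriodMap,
    design_fragment,
)

# Tpm1.1 residues 64-154 (91 aa, native numbering 64..154)
TPM1_FRAGMENT_SEQUENCE = (
    "LKDAQEKLELAEKKATDAEADVASLNRRIQLVEEELDRAQERLATALQKL"
    "EEAEKAADESERGMKVIESRAQKDEEKMEIQEIQLKEAKHI"
)

FUSION_TAG = "GSHMCGG"

#: Native-position substitutions turning the Tpm1.1 fragment into Tpm3.12
#: (Tpm1.1 position -> Tpm3.12 residue; Tpm3.12 numbering runs one higher).
ISOFORM_SUBSTITUTIONS = {79: "A", 84: "E", 132: "N", 135: "L"}


def _tpm3_sequence() -> str:
    chars = list(TPM1_FRAGMENT_SEQUENCE)
    for tpm1_pos, aa in ISOFORM_SUBSTITUTIONS.items():
        chars[tpm1_pos - 64] = aa
    return "".join(chars)


TPM3_FRAGMENT_SEQUENCE = _tpm3_sequence()


def tpm1_region() -> IsoformSequence:
    """Tpm1.1 residues 64-154 as an isoform sequence."""
    return IsoformSequence.from_string(
        "Tpm1.1", TPM1_FRAGMENT_SEQUENCE, first_position=64, numbering_offset=0
    )


def tpm3_region() -> IsoformSequence:
    """Tpm3.12 residues 65-155 (numbering offset +1 vs Tpm1.1)."""
    return IsoformSequence.from_string(
        "Tpm3.12", TPM3_FRAGMENT_SEQUENCE, first_position=65, numbering_offset=1
    )


def isoform_region(isoform_id: str) -> IsoformSequence:
    try:
        return {"Tpm1.1": tpm1_region, "Tpm3.12": tpm3_region}[isoform_id]()
    except KeyError:
        raise KeyError(f"unknown isoform {isoform_id!r}") from None


def tpm1_fragment() -> FragmentSpec:
    return design_fragment(tpm1_region(), 64, 154, FUSION_TAG)


def tpm3_fragment() -> FragmentSpec:
    return design_fragment(tpm3_region(), 65, 155, FUSION_TAG)


#: The four disease mutations of the study, keyed by their labels.
MUTATIONS: dict[str, Mutation] = {
    "I92T": Mutation(
        "Tpm1.1", 92, "I", "T",
        disease_label="dilated cardiomyopathy", phenotype_class="hypo",
    ),
    "V95A": Mutation(
        "Tpm1.1", 95, "V", "A",
        disease_label="hypertrophic cardiomyopathy", phenotype_class="hyper",
    ),
    "R91C": Mutation(
        "Tpm3.12", 91, "R", "C",
        disease_label="congenital myopathy", phenotype_class="hypo",
    ),
    "R91P": Mutation(
        "Tpm3.12", 91, "R", "P",
        disease_label="congenital myopathy", phenotype_class="hypo",
    ),
}

#: Default heptad-register anchors: Tpm1.1 92 = a (equivalently Tpm3.12
#: 93 = a), placing I92/V95 in the core (a/d) and Tpm3.12 R91 at f.
DEFAULT_ANCHORS: dict[str, tuple[int, str]] = {
    "Tpm1.1": (92, "a"),
    "Tpm3.12": (93, "a"),
}

#: Default actin-binding period boundaries (native numbering). Period 3 is
#: the 35-residue stretch 85-119 of Tpm1.1 (86-120 of Tpm3.12): it contains
#: the mutation cluster at 91-95 while the isoform differences at 79/84
#: fall in period 2 and those at 132/135 in period 4.
DEFAULT_PERIOD_MAPS: dict[str, PeriodMap] = {
    "Tpm1.1": PeriodMap(
        (("P2", 64, 84), ("P3", 85, 119), ("P4", 120, 154))
    ),
    "Tpm3.12": PeriodMap(
        (("P2", 65, 85), ("P3", 86, 120), ("P4", 121, 155))
    ),
}

#: Measured melting temperatures (degC): sample -> {condition: (mean, se)}.
#: ``None`` marks the single not-determined entry.
TABLE1_TM: dict[str, dict[str, tuple[float, float] | None]] = {
    "Tpm1.1_64-154": {"non_reduced": (46.1, 0.2), "reduced": (23.7, 0.7)},
    "Tpm1.1_64-154_I92T": {"non_reduced": (28.2, 0.1), "reduced": (5.6, 0.5)},
    "Tpm1.1_64-154_V95A": {"non_reduced": (42.2, 0.5), "reduced": (21.7, 0.3)},
    "Tpm3.12_65-155": {"non_reduced": (60.9, 0.2), "reduced": (45.8, 0.9)},
    "Tpm3.12_65-155_R91C": {"non_reduced": (51.5, 0.7), "reduced": (31.3, 0.2)},
    "Tpm3.12_65-155_R91P": {"non_reduced": (28.9, 0.1), "reduced": None},
}

#: Reference (wild-type) sample for each isoform's mutants.
WILD_TYPE_IDS = {"Tpm1.1": "Tpm1.1_64-154", "Tpm3.12": "Tpm3.12_65-155"}


def table1_results() -> list[MeltingResult]:
    """The measured Tm table as melting results (ND entry included)."""
    results = []
    for sample_id, conditions in TABLE1_TM.items():
        for condition, value in conditions.items():
            if value is None:
                results.append(
                    MeltingResult(sample_id, condition, tm=None, truncated_low=True)
                )
            else:
                results.append(MeltingResult(sample_id, condition, tm=value[0]))
    return results
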
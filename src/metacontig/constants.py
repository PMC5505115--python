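"""Monoisotopic mass constants and the residue table.

All masses are in daltons. Cysteine carries the fixed carbamidomethyl
modification (+57.02146) throughout the package: samples are assumed to have
been reduced and alkylated with iodoacetamide before digestion, so the bare
cysteine residue mass never occurs.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

PROTON: float = 1.007276
WATER: float = 18.010565
CARBAMIDOMETHYL: float = 57.02146

#: Residue monoisotopic masses (Da); C is carbamidomethylated.
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}
RESIDUE_MASS["C"] += CARBAMIDOMETHYL

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letters that may appear in public FASTA records but are not part of the
#: 20-letter alphabet this pipeline works with.
ILLEGAL_RESIDUES: frozenset[str] = frozenset("BJOUXZ*")

#: Neutral-fragment offsets (Da) of the ion series used by the three
#: dissociation modes, relative to the summed residue mass of the fragment.
#: A singly protonated fragment ion has m/z = residue sum + offset + PROTON.
ION_OFFSETS: dict[str, float] = {
    "b": 0.0,
    "a": -27.99491,  # b - CO
    "y": WATER,
    "c": 17.02655,   # b + NH3
    "z": 1.99184,    # z-dot (z+1), the radical species observed in ETD
}

#: Which terminus each series fragments from. N-terminal series carry prefix
#: residue masses directly; C-terminal series carry suffix masses.
ION_TERMINUS: dict[str, str] = {"b": "N", "a": "N", "y": "C", "c": "N", "z": "C"}

MODES: tuple[str, ...] = ("CID", "HCD", "ETD")


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic residue-mass sum + water of ``sequence``."""
    try:
        return sum(RESIDUE_MASS[a] for a in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None


def residue_sum(sequence: str) -> float:
    """Summed residue masses of ``sequence`` (no water)."""
    try:
        return sum(RESIDUE_MASS[a] for a in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None
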
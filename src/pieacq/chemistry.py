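"""Mass arithmetic for TMT-labeled tryptic peptides.

Monoisotopic residue masses come from :mod:`pyteomics.mass`; the only
constants added here are the TMT 6-plex label mass and the proton mass used
for m/z conversion.
"""

from __future__ import annotations

from pyteomics import mass as _ptmass

#: Mass of a proton, Da (CODATA).
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of water, Da (added once per peptide).
WATER_MONO = 18.0105646863

#: Monoisotopic mass of one TMT 6-plex label, Da. Labels attach to the
#: peptide N-terminus and to every lysine epsilon-amine.
TMT6_LABEL_MASS = 229.162932

#: Monoisotopic residue (not free amino acid) masses, Da.
STD_AA_MASS: dict[str, float] = dict(_ptmass.std_aa_mass)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for empty sequences or residues outside the 20-letter alphabet."""


def validate_sequence(sequence: str) -> None:
    """Check that *sequence* is non-empty and uses only standard residues.

    Raises :class:`SequenceError` naming the first offending position
    (1-based) otherwise.
    """
    if not sequence:
        raise SequenceError("empty peptide sequence")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in VALID_RESIDUES:
            raise SequenceError(
                f"non-standard residue {aa!r} at position {pos}"
            )


def count_tmt_sites(sequence: str) -> int:
    """Number of TMT label sites: the N-terminus plus every lysine."""
    return 1 + sequence.count("K")


def peptide_mass(sequence: str, n_tmt_labels: int | None = None) -> float:
    """Monoisotopic mass of a peptide in Da.

    Parameters
    ----------
    sequence
        Peptide sequence over the 20 standard residues.
    n_tmt_labels
        Number of TMT 6-plex labels attached. ``None`` (default) counts the
        sites itself (N-terminus + lysines); pass ``0`` for an unlabeled
        peptide.
    """
    validate_sequence(sequence)
    if n_tmt_labels is None:
        n_tmt_labels = count_tmt_sites(sequence)
    if n_tmt_labels < 0:
        raise ValueError("n_tmt_labels must be non-negative")
    residues = sum(STD_AA_MASS[aa] for aa in sequence)
    return residues + WATER_MONO + n_tmt_labels * TMT6_LABEL_MASS


def mz_from_mass(mass: float, charge: int) -> float:
    """m/z of an ion of neutral monoisotopic *mass* at *charge* protons."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from an observed m/z and charge."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return mz * charge - charge * PROTON_MASS


def ppm_diff(mz_a: float, mz_b: float) -> float:
    """Relative difference between two m/z values in ppm of the lower one.

    Computing against the lower member keeps the criterion symmetric in its
    arguments and slightly conservative.
    """
    lo, hi = (mz_a, mz_b) if mz_a <= mz_b else (mz_b, mz_a)
    if lo <= 0:
        raise ValueError("m/z values must be positive")
    return (hi - lo) / lo * 1e6
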
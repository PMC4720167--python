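"""In-silico proteolytic digestion.

The Lys-C + trypsin combination used for sample preparation has the combined
specificity "cleave C-terminal to K or R", so a single rule covers both
enzymes. Fully tryptic peptides with up to a configurable number of internal
missed cleavages are enumerated from the cut-site list.
"""

from __future__ import annotations

from .chemistry import validate_sequence


def cleavage_sites(sequence: str, restrict_proline: bool = False) -> list[int]:
    """Return cut positions (indices into *sequence* after which the chain is
    cleaved), C-terminal to K/R.

    With ``restrict_proline=True`` a K/R immediately followed by proline is
    not cleaved (the classical trypsin "no-P" refinement; off by default).
    """
    sites = []
    last = len(sequence) - 1
    for i, aa in enumerate(sequence):
        if aa in "KR" and i != last:
            if restrict_proline and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest_protein(
    sequence: str,
    max_missed: int = 2,
    min_length: int = 6,
    restrict_proline: bool = False,
) -> list[tuple[str, int]]:
    """Enumerate fully tryptic peptides of a protein.

    Parameters
    ----------
    sequence
        Protein sequence over the 20 standard residues.
    max_missed
        Maximum number of internal missed cleavage sites per peptide.
    min_length
        Minimum peptide length (residues) to report.
    restrict_proline
        Apply the no-cleavage-before-proline refinement.

    Returns
    -------
    list of (peptide sequence, n_missed_cleavages), ordered by position in
    the protein; each (start, end) span appears exactly once.
    """
    validate_sequence(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")

    bounds = [0] + cleavage_sites(sequence, restrict_proline) + [len(sequence)]
    peptides: list[tuple[str, int]] = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for j in range(i, min(i + max_missed + 1, n_seg)):
            start, end = bounds[i], bounds[j + 1]
            if end - start >= min_length:
                peptides.append((sequence[start:end], j - i))
    return peptides
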
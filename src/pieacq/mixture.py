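"""Synthetic two-channel TMT-labeled tryptic peptide mixtures.

This module generates the ground-truth analyte population the acquisition
simulator runs against: proteins with a wide (configurable, several orders
of magnitude) abundance range are digested in silico, each peptide gets a
charge state, a Gaussian elution profile on the gradient, an ionization
efficiency drawn per species, and a two-channel (reporter 126/127) abundance
split derived from the parent protein's true log2 ratio. HILIC and SCX
fraction labels are assigned from two approximately orthogonal
sequence-derived descriptors.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import fasta as _ptfasta

from .chemistry import peptide_mass, mz_from_mass, count_tmt_sites, validate_sequence
from .digest import digest_protein

# Approximate residue frequencies in vertebrate proteomes, used when
# sequences are generated rather than read from FASTA.
AA_FREQUENCIES = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

# Kyte-Doolittle hydropathy; the HILIC descriptor is its negated mean.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class ProteinEntry:
    """One simulated protein: identity, reference-channel abundance and the
    true channel-126/127 log2 ratio."""

    protein_id: str
    sequence: str
    abundance: float
    channel_log2_ratio: float = 0.0

    def __post_init__(self):
        validate_sequence(self.sequence)
        if self.abundance <= 0:
            raise ValueError("protein abundance must be positive")


@dataclass
class PeptideSpecies:
    """One simulated peptide ion species (a sequence at one charge state)."""

    peptide_id: str
    protein_id: str
    sequence: str
    n_missed_cleavages: int
    charge: int
    monoisotopic_mass: float
    mz: float
    rt_apex: float
    rt_sigma: float
    peak_amplitude: float
    channel_fractions: tuple[float, float]
    hilic_fraction: int | None = None
    scx_fraction: int | None = None

    def __post_init__(self):
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if abs(sum(self.channel_fractions) - 1.0) > 1e-9:
            raise ValueError("channel fractions must sum to 1")


@dataclass
class MixtureConfig:
    """Parameters of the synthetic mixture.

    Defaults emulate a medium-complexity two-channel TMT digest: ~55
    proteins yield on the order of 5,000 peptide species, protein abundances
    span four orders of magnitude (log-uniform), elution apexes are uniform
    over a 90-min usable gradient, and 20% of proteins carry a true
    +-1 log2-unit differential between channels.
    """

    n_proteins: int = 55
    dynamic_range_orders: float = 4.0
    abundance_floor: float = 10.0
    abundance_law: str = "log-uniform"  # or "log-normal"
    gradient_length: float = 90.0
    rt_sigma_range: tuple[float, float] = (0.15, 0.45)
    charge_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.55, 3: 0.30, 4: 0.10}
    )
    differential_fraction: float = 0.2
    effect_size_log2: float = 1.0
    protein_length_range: tuple[int, int] = (120, 600)
    ionization_log_sd: float = 1.0
    missed_cleavage_yield: float = 0.3
    max_missed: int = 2
    min_peptide_length: int = 6
    restrict_proline: bool = False
    n_hilic: int = 6
    n_scx: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be non-negative")
        if self.dynamic_range_orders <= 0:
            raise ValueError("dynamic_range_orders must be positive")
        if self.abundance_law not in ("log-uniform", "log-normal"):
            raise ValueError(f"unknown abundance law {self.abundance_law!r}")
        lo, hi = self.rt_sigma_range
        if not (0 < lo < hi):
            raise ValueError("rt_sigma_range must be a non-degenerate positive pair")
        if self.gradient_length <= 0:
            raise ValueError("gradient_length must be positive")
        w = sum(self.charge_distribution.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError("charge_distribution weights must sum to 1")
        if not 0 <= self.differential_fraction <= 1:
            raise ValueError("differential_fraction must be in [0, 1]")
        if not 0 < self.missed_cleavage_yield <= 1:
            raise ValueError("missed_cleavage_yield must be in (0, 1]")
        if self.n_hilic < 1 or self.n_scx < 1:
            raise ValueError("fraction counts must be >= 1")


@dataclass
class Mixture:
    """A generated mixture: proteins, peptide species, and the config used."""

    proteins: list[ProteinEntry]
    peptides: list[PeptideSpecies]
    config: MixtureConfig | None = None

    def protein_map(self) -> dict[str, ProteinEntry]:
        return {p.protein_id: p for p in self.proteins}

    def peptide_map(self) -> dict[str, PeptideSpecies]:
        return {p.peptide_id: p for p in self.peptides}


# ---------------------------------------------------------------------------
# descriptors and fraction assignment


def _sequence_jitter(sequence: str) -> float:
    # Deterministic, sequence-pure tie-breaker so quantile bins of the
    # discrete SCX descriptor stay non-degenerate.
    return zlib.crc32(sequence.encode("ascii")) / 2**32 * 1e-6


def hydrophilicity(sequence: str) -> float:
    """Mean negated Kyte-Doolittle hydropathy (higher = more hydrophilic)."""
    return -float(np.mean([KYTE_DOOLITTLE[a] for a in sequence])) + _sequence_jitter(sequence)


def basicity(sequence: str) -> float:
    """Nominal solution charge proxy: count of K/R/H plus the N-terminus."""
    return sum(sequence.count(a) for a in "KRH") + 1 + _sequence_jitter(sequence)


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, values, side="right") + 1


def assign_fractions(
    peptides: list[PeptideSpecies], n_hilic: int = 6, n_scx: int = 6
) -> list[PeptideSpecies]:
    """Assign each peptide one HILIC and one SCX fraction label in place.

    Bins are quantile bins of a hydrophilicity descriptor (HILIC) and a
    charge/basicity descriptor (SCX), both pure functions of sequence, so the
    two partitions are approximately orthogonal and identical sequences land
    in identical fractions.
    """
    if n_hilic < 1 or n_scx < 1:
        raise ValueError("fraction counts must be >= 1")
    if not peptides:
        return peptides
    hyd = np.array([hydrophilicity(p.sequence) for p in peptides])
    bas = np.array([basicity(p.sequence) for p in peptides])
    hbin = _quantile_bins(hyd, n_hilic)
    sbin = _quantile_bins(bas, n_scx)
    for p, h, s in zip(peptides, hbin, sbin):
        p.hilic_fraction = int(h)
        p.scx_fraction = int(s)
    return peptides


# ---------------------------------------------------------------------------
# generation


def _random_sequences(rng: np.random.Generator, config: MixtureConfig) -> list[str]:
    letters = np.array(list(AA_FREQUENCIES))
    freqs = np.array(list(AA_FREQUENCIES.values()))
    freqs = freqs / freqs.sum()
    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    return [
        "".join(rng.choice(letters, size=n, p=freqs)) for n in lengths
    ]


def _protein_abundances(rng: np.random.Generator, config: MixtureConfig) -> np.ndarray:
    span = config.dynamic_range_orders
    n = config.n_proteins
    if config.abundance_law == "log-uniform":
        exponents = rng.uniform(0.0, span, size=n)
        if n >= 2:
            # pin the extremes so the configured span is realized
            exponents[np.argmin(exponents)] = 0.0
            exponents[np.argmax(exponents)] = span
    else:  # log-normal
        exponents = rng.normal(span / 2, span / 4, size=n)
    return config.abundance_floor * 10.0 ** exponents


def generate_mixture(
    config: MixtureConfig,
    sequences: list[tuple[str, str]] | None = None,
) -> Mixture:
    """Generate a synthetic mixture.

    Parameters
    ----------
    config
        Mixture parameters; ``config.seed`` makes the output deterministic.
    sequences
        Optional list of ``(protein_id, sequence)`` pairs (e.g. from
        :func:`read_fasta`). When given, they replace random sequences and
        ``config.n_proteins`` caps how many are used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if sequences is not None:
        used = sequences[: config.n_proteins] if config.n_proteins else []
        ids = [pid for pid, _ in used]
        seqs = [s for _, s in used]
    else:
        seqs = _random_sequences(rng, config)
        ids = [f"PROT{i:04d}" for i in range(len(seqs))]

    n = len(seqs)
    abundances = _protein_abundances(rng, config)[:n] if n else np.array([])

    log2_ratios = np.zeros(n)
    n_diff = int(round(config.differential_fraction * n))
    if n_diff:
        idx = rng.choice(n, size=n_diff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        log2_ratios[idx] = signs * config.effect_size_log2

    proteins = [
        ProteinEntry(pid, seq, float(ab), float(r))
        for pid, seq, ab, r in zip(ids, seqs, abundances, log2_ratios)
    ]

    charges = np.array(sorted(config.charge_distribution))
    charge_w = np.array([config.charge_distribution[c] for c in charges], dtype=float)
    charge_w = charge_w / charge_w.sum()
    sig_lo, sig_hi = config.rt_sigma_range

    peptides: list[PeptideSpecies] = []
    for prot in proteins:
        frags = digest_protein(
            prot.sequence,
            max_missed=config.max_missed,
            min_length=config.min_peptide_length,
            restrict_proline=config.restrict_proline,
        )
        ratio = 2.0 ** prot.channel_log2_ratio
        ch_frac = (ratio / (1.0 + ratio), 1.0 / (1.0 + ratio))
        for k, (pep_seq, n_missed) in enumerate(frags):
            charge = int(rng.choice(charges, p=charge_w))
            mass = peptide_mass(pep_seq, count_tmt_sites(pep_seq))
            ionization = float(np.exp(rng.normal(0.0, config.ionization_log_sd)))
            amplitude = (
                prot.abundance
                * ionization
                * config.missed_cleavage_yield ** n_missed
            )
            peptides.append(
                PeptideSpecies(
                    peptide_id=f"{prot.protein_id}|p{k:04d}",
                    protein_id=prot.protein_id,
                    sequence=pep_seq,
                    n_missed_cleavages=n_missed,
                    charge=charge,
                    monoisotopic_mass=mass,
                    mz=mz_from_mass(mass, charge),
                    rt_apex=float(rng.uniform(0.02, 0.98) * config.gradient_length),
                    rt_sigma=float(rng.uniform(sig_lo, sig_hi)),
                    peak_amplitude=amplitude,
                    channel_fractions=ch_frac,
                )
            )

    assign_fractions(peptides, config.n_hilic, config.n_scx)
    return Mixture(proteins=proteins, peptides=peptides, config=config)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein sequences from FASTA; the description up to the first
    whitespace becomes the protein_id."""
    out = []
    with _ptfasta.read(str(path)) as reader:
        for description, sequence in reader:
            out.append((description.split()[0], sequence))
    return out


_PEPTIDE_COLUMNS = [
    "peptide_id", "protein_id", "sequence", "n_missed_cleavages", "charge",
    "monoisotopic_mass", "mz", "rt_apex", "rt_sigma", "peak_amplitude",
    "channel126_fraction", "channel127_fraction", "hilic_fraction", "scx_fraction",
]


def peptides_to_frame(mixture: Mixture) -> pd.DataFrame:
    rows = [
        (
            p.peptide_id, p.protein_id, p.sequence, p.n_missed_cleavages,
            p.charge, p.monoisotopic_mass, p.mz, p.rt_apex, p.rt_sigma,
            p.peak_amplitude, p.channel_fractions[0], p.channel_fractions[1],
            p.hilic_fraction, p.scx_fraction,
        )
        for p in mixture.peptides
    ]
    return pd.DataFrame(rows, columns=_PEPTIDE_COLUMNS)


def proteins_to_frame(mixture: Mixture) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.protein_id, p.sequence, p.abundance, p.channel_log2_ratio) for p in mixture.proteins],
        columns=["protein_id", "sequence", "abundance", "channel_log2_ratio"],
    )


def write_mixture_tsv(mixture: Mixture, peptide_path: str | Path, protein_path: str | Path) -> None:
    """Serialize a mixture as two TSV tables (peptides + proteins).

    The peptide table carries a ``#`` header comment documenting columns and
    the generating configuration, so simulator runs are replayable from the
    files alone.
    """
    cfg = json.dumps(asdict(mixture.config), default=str) if mixture.config else "{}"
    header = (
        "# pieacq synthetic mixture; one row per peptide ion species\n"
        "# columns: id, parent protein, sequence, missed cleavages, charge, "
        "monoisotopic mass [Da], m/z [Th], elution apex [min], elution sigma [min], "
        "peak amplitude [arb], channel 126/127 abundance fractions, HILIC/SCX fraction labels\n"
        f"# config: {cfg}\n"
    )
    for path, frame, head in (
        (peptide_path, peptides_to_frame(mixture), header),
        (protein_path, proteins_to_frame(mixture), "# pieacq synthetic mixture proteins\n"),
    ):
        buf = io.StringIO()
        buf.write(head)
        frame.to_csv(buf, sep="\t", index=False)
        Path(path).write_text(buf.getvalue())


def read_mixture_tsv(peptide_path: str | Path, protein_path: str | Path) -> Mixture:
    """Inverse of :func:`write_mixture_tsv` (config is not reconstructed)."""
    pep = pd.read_csv(peptide_path, sep="\t", comment="#")
    prot = pd.read_csv(protein_path, sep="\t", comment="#")
    proteins = [
        ProteinEntry(r.protein_id, r.sequence, float(r.abundance), float(r.channel_log2_ratio))
        for r in prot.itertuples()
    ]
    peptides = [
        PeptideSpecies(
            peptide_id=r.peptide_id,
            protein_id=r.protein_id,
            sequence=r.sequence,
            n_missed_cleavages=int(r.n_missed_cleavages),
            charge=int(r.charge),
            monoisotopic_mass=float(r.monoisotopic_mass),
            mz=float(r.mz),
            rt_apex=float(r.rt_apex),
            rt_sigma=float(r.rt_sigma),
            peak_amplitude=float(r.peak_amplitude),
            channel_fractions=(float(r.channel126_fraction), float(r.channel127_fraction)),
            hilic_fraction=int(r.hilic_fraction),
            scx_fraction=int(r.scx_fraction),
        )
        for r in pep.itertuples()
    ]
    return Mixture(proteins=proteins, peptides=peptides)
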
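"""TMT two-channel reporter quantification and strategy-comparison
statistics.

Accepted PSMs carry their ground-truth peptide, whose parent protein has a
true channel-126/127 log2 ratio. A reporter measurement adds Gaussian noise
in log2 space (multiplicative noise on the ratio scale); peptide ratios are
averaged per distinct peptide and rolled up to the protein as the median.
Two acquisition strategies are compared with Venn counts, percent increase,
an OLS regression of the common proteins' log2 ratios, and the fraction of
common proteins with increased peptide coverage.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .acquisition import PSMRecord, RunResult
from .mixture import Mixture


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass
class ProteinQuantRecord:
    """Quantified protein: median log2 ratio over its accepted peptides."""

    protein_id: str
    n_peptides: int
    log2_ratio: float
    peptide_log2_ratios: list[float] = field(default_factory=list)


class PercentIncrease(NamedTuple):
    raw: float
    rounded: int


class RegressionStats(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def reporter_ratios(
    runs: Iterable[RunResult] | Iterable[PSMRecord],
    mixture: Mixture,
    noise_sd: float = 0.2,
    seed: int | tuple = 0,
) -> list[ProteinQuantRecord]:
    """Reporter-ion quantification over accepted PSMs.

    Each accepted PSM yields one peptide-level measurement: the parent
    protein's true log2(126/127) plus N(0, noise_sd) noise. Measurements are
    averaged per distinct peptide; the protein log2 ratio is the median over
    its peptides. Proteins with no accepted peptide are absent.

    *runs* may be RunResults or a flat PSM list.
    """
    rng = np.random.default_rng(seed)
    psms: list[PSMRecord] = []
    for item in runs:
        if isinstance(item, RunResult):
            psms.extend(item.psms)
        else:
            psms.append(item)
    pep_map = mixture.peptide_map()
    prot_map = mixture.protein_map()

    per_peptide: dict[str, list[float]] = defaultdict(list)
    for p in psms:
        if not p.accepted or p.peptide_id is None:
            continue
        true_log2 = prot_map[pep_map[p.peptide_id].protein_id].channel_log2_ratio
        per_peptide[p.peptide_id].append(true_log2 + float(rng.normal(0.0, noise_sd)))

    per_protein: dict[str, list[float]] = defaultdict(list)
    for pep_id, values in per_peptide.items():
        per_protein[pep_map[pep_id].protein_id].append(float(np.mean(values)))

    return [
        ProteinQuantRecord(
            protein_id=pid,
            n_peptides=len(vals),
            log2_ratio=float(np.median(vals)),
            peptide_log2_ratios=vals,
        )
        for pid, vals in sorted(per_protein.items())
    ]


def regression_stats(x, y) -> RegressionStats:
    """Ordinary least squares of y on x; r_squared is the squared Pearson
    correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; regression undefined")
    fit = _stats.linregress(x, y)
    return RegressionStats(float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2)


def venn_counts(set_a: set, set_b: set) -> tuple[int, int, int]:
    """(only in A, in both, only in B)."""
    set_a, set_b = set(set_a), set(set_b)
    both = set_a & set_b
    return (len(set_a) - len(both), len(both), len(set_b) - len(both))


def percent_increase(n_new: float, n_ref: float) -> PercentIncrease:
    """Percent increase of *n_new* over the reference count, raw and rounded
    to the nearest integer percent."""
    if n_ref == 0:
        raise DegenerateInputError("reference count is zero; percent increase undefined")
    raw = 100.0 * (n_new - n_ref) / n_ref
    return PercentIncrease(raw, int(round(raw)))


def coverage_comparison(
    quant_a: list[ProteinQuantRecord], quant_b: list[ProteinQuantRecord]
) -> tuple[float, pd.DataFrame]:
    """Fraction of proteins common to both strategies with strictly more
    peptides in A than B, plus the full per-protein count table."""
    a = {q.protein_id: q.n_peptides for q in quant_a}
    b = {q.protein_id: q.n_peptides for q in quant_b}
    common = sorted(set(a) & set(b))
    table = pd.DataFrame(
        {
            "protein_id": common,
            "n_peptides_a": [a[p] for p in common],
            "n_peptides_b": [b[p] for p in common],
        }
    )
    if not common:
        raise DegenerateInputError("no proteins common to both strategies")
    frac = float(np.mean(table["n_peptides_a"] > table["n_peptides_b"]))
    return frac, table


@dataclass
class ComparisonReport:
    """Summary of a strategy A vs strategy B comparison (A is typically the
    PIE campaign, B the DDA replicates)."""

    label_a: str
    label_b: str
    n_proteins_a: int
    n_proteins_b: int
    n_peptides_a: int
    n_peptides_b: int
    protein_venn: tuple[int, int, int]
    peptide_venn: tuple[int, int, int]
    protein_percent_increase: PercentIncrease
    peptide_percent_increase: PercentIncrease
    slope: float | None
    intercept: float | None
    r_squared: float | None
    increased_coverage_fraction: float | None
    ratio_table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "labels": [self.label_a, self.label_b],
            "proteins": {self.label_a: self.n_proteins_a, self.label_b: self.n_proteins_b},
            "peptides": {self.label_a: self.n_peptides_a, self.label_b: self.n_peptides_b},
            "protein_venn": {
                f"only_{self.label_a}": self.protein_venn[0],
                "both": self.protein_venn[1],
                f"only_{self.label_b}": self.protein_venn[2],
            },
            "peptide_venn": {
                f"only_{self.label_a}": self.peptide_venn[0],
                "both": self.peptide_venn[1],
                f"only_{self.label_b}": self.peptide_venn[2],
            },
            "protein_percent_increase": {
                "raw": self.protein_percent_increase.raw,
                "rounded": self.protein_percent_increase.rounded,
            },
            "peptide_percent_increase": {
                "raw": self.peptide_percent_increase.raw,
                "rounded": self.peptide_percent_increase.rounded,
            },
            "log2_ratio_regression": {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
            },
            "increased_coverage_fraction": self.increased_coverage_fraction,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_markdown(self, path: str | Path | None = None) -> str:
        a, b = self.label_a, self.label_b
        lines = [
            f"# Acquisition strategy comparison: {a} vs {b}",
            "",
            f"| quantity | {a} | {b} |",
            "|---|---|---|",
            f"| proteins quantified | {self.n_proteins_a} | {self.n_proteins_b} |",
            f"| peptides quantified | {self.n_peptides_a} | {self.n_peptides_b} |",
            "",
            f"Protein Venn (only {a} / both / only {b}): "
            f"{self.protein_venn[0]} / {self.protein_venn[1]} / {self.protein_venn[2]}",
            f"Protein identifications: {self.protein_percent_increase.rounded}% increase "
            f"({self.protein_percent_increase.raw:.1f}% raw) for {a} over {b}",
            f"Peptide identifications: {self.peptide_percent_increase.rounded}% increase "
            f"({self.peptide_percent_increase.raw:.1f}% raw)",
        ]
        if self.slope is not None:
            lines += [
                "",
                f"log2-ratio regression ({a} on {b}): slope {self.slope:.3f}, "
                f"intercept {self.intercept:.3f}, R^2 {self.r_squared:.3f}",
            ]
        if self.increased_coverage_fraction is not None:
            lines.append(
                f"Common proteins with increased coverage in {a}: "
                f"{100 * self.increased_coverage_fraction:.0f}%"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def compare_strategies(
    quant_a: list[ProteinQuantRecord],
    quant_b: list[ProteinQuantRecord],
    peptides_a: set[str],
    peptides_b: set[str],
    label_a: str = "PIE",
    label_b: str = "DDA",
) -> ComparisonReport:
    """Build the full comparison report between two strategies.

    The regression puts strategy B (reference) on x and strategy A on y, so
    a slope below 1 reads as A reporting compressed ratios relative to B.
    """
    prot_a = {q.protein_id for q in quant_a}
    prot_b = {q.protein_id for q in quant_b}
    ra = {q.protein_id: q.log2_ratio for q in quant_a}
    rb = {q.protein_id: q.log2_ratio for q in quant_b}
    common = sorted(prot_a & prot_b)

    slope = intercept = r2 = None
    if len(common) >= 2:
        x = [rb[p] for p in common]
        y = [ra[p] for p in common]
        try:
            slope, intercept, r2 = regression_stats(x, y)
        except DegenerateInputError:
            pass

    coverage = table = None
    if common:
        coverage, table = coverage_comparison(quant_a, quant_b)

    return ComparisonReport(
        label_a=label_a,
        label_b=label_b,
        n_proteins_a=len(prot_a),
        n_proteins_b=len(prot_b),
        n_peptides_a=len(peptides_a),
        n_peptides_b=len(peptides_b),
        protein_venn=venn_counts(prot_a, prot_b),
        peptide_venn=venn_counts(peptides_a, peptides_b),
        protein_percent_increase=percent_increase(len(prot_a), len(prot_b)),
        peptide_percent_increase=percent_increase(len(peptides_a), len(peptides_b)),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        increased_coverage_fraction=coverage,
        ratio_table=table,
    )


def plot_ratio_scatter(report: ComparisonReport, quant_a, quant_b, path: str | Path) -> None:
    """Scatter of common-protein log2 ratios (A vs B) with the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ra = {q.protein_id: q.log2_ratio for q in quant_a}
    rb = {q.protein_id: q.log2_ratio for q in quant_b}
    common = sorted(set(ra) & set(rb))
    x = np.array([rb[p] for p in common])
    y = np.array([ra[p] for p in common])
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
    if report.slope is not None and len(x):
        xs = np.linspace(x.min(), x.max(), 2)
        ax.plot(xs, report.slope * xs + report.intercept, "r-", lw=1,
                label=f"slope={report.slope:.2f}, R$^2$={report.r_squared:.2f}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(f"log2 ratio ({report.label_b})")
    ax.set_ylabel(f"log2 ratio ({report.label_a})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
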
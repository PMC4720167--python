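"""Exclusion-list engine: parse, cluster, merge, cap and export precursor
exclusion lists.

An exclusion list is an instrument-readable table of m/z values with
retention-time windows that must not be selected for MS2. Raw exports
contain many near-duplicate rows (the same precursor sampled across scans),
so the core operation here merges entries that agree within a ppm mass
tolerance and overlap in retention time, transitively, until no further
merge is possible. Merged lists from successive acquisition iterations are
combined the same way, capped to instrument capacity, and written in the
comma-separated ``Mass,Start (min),End (min)`` layout that instrument method
editors import.

Matching is done on m/z (the instrument's dynamic-exclusion criterion is a
ppm window on m/z); clustering on neutral mass instead is available by
converting entries up front.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


class ExclusionFormatError(ValueError):
    """Raised when a delimited exclusion export cannot be interpreted."""


class ConfigError(ValueError):
    """Raised for unknown policy or dialect options."""


@dataclass(frozen=True)
class ExclusionEntry:
    """One excluded precursor window: m/z plus a closed RT interval."""

    mz: float
    rt_start: float
    rt_end: float
    charge: int | None = None
    intensity: float | None = None
    source_run: str | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.rt_start > self.rt_end:
            raise ValueError("rt_start must be <= rt_end")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class ExclusionList:
    """An ordered, canonical collection of exclusion entries.

    ``ppm_tolerance`` and ``rt_pad`` record how the list was built;
    ``provenance`` lists the contributing run identifiers in order.
    """

    entries: list[ExclusionEntry] = field(default_factory=list)
    ppm_tolerance: float = 10.0
    rt_pad: float = 2.0
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def empty(cls, ppm_tolerance: float = 10.0, rt_pad: float = 2.0) -> "ExclusionList":
        return cls([], ppm_tolerance, rt_pad, [])


# ---------------------------------------------------------------------------
# clustering


def _mergeable(mz_a, lo_a, hi_a, mz_b, lo_b, hi_b, ppm, rt_gap) -> bool:
    lo_mz = min(mz_a, mz_b)
    if (abs(mz_a - mz_b) / lo_mz) * 1e6 > ppm:
        return False
    return lo_a <= hi_b + rt_gap and lo_b <= hi_a + rt_gap


class _Cluster:
    """Internal accumulator tracking the ORIGINAL (leaf) members so the
    merged m/z is the arithmetic mean over leaves regardless of the order in
    which intermediate merges happen."""

    __slots__ = ("mz_sum", "n", "rt_start", "rt_end", "charges", "intensity", "sources")

    def __init__(self, entry: ExclusionEntry):
        self.mz_sum = entry.mz
        self.n = 1
        self.rt_start = entry.rt_start
        self.rt_end = entry.rt_end
        self.charges = {entry.charge} if entry.charge is not None else set()
        self.intensity = entry.intensity
        self.sources = [entry.source_run] if entry.source_run is not None else []

    @property
    def mz(self) -> float:
        return self.mz_sum / self.n

    def absorb(self, other: "_Cluster") -> None:
        self.mz_sum += other.mz_sum
        self.n += other.n
        self.rt_start = min(self.rt_start, other.rt_start)
        self.rt_end = max(self.rt_end, other.rt_end)
        self.charges |= other.charges
        if other.intensity is not None:
            self.intensity = other.intensity if self.intensity is None else max(self.intensity, other.intensity)
        for s in other.sources:
            if s not in self.sources:
                self.sources.append(s)

    def to_entry(self) -> ExclusionEntry:
        charge = next(iter(self.charges)) if len(self.charges) == 1 else None
        source = self.sources[0] if len(self.sources) == 1 else None
        return ExclusionEntry(self.mz, self.rt_start, self.rt_end, charge, self.intensity, source)


def cluster_merge(
    entries: list[ExclusionEntry],
    ppm_tolerance: float,
    rt_gap: float = 0.0,
) -> list[ExclusionEntry]:
    """Merge entries that agree within *ppm_tolerance* (ppm of the lower m/z
    of the pair) and whose RT intervals overlap or lie within *rt_gap*.

    The merge is the transitive closure of the pairwise relation, applied in
    whole-closure passes until a fixpoint: each pass groups every currently
    mergeable pair with union-find and collapses groups to a single entry
    with the arithmetic-mean m/z of all original members and the union RT
    interval. The result is canonical: sorted by (mz, rt_start) with no
    remaining mergeable pair, independent of input order.
    """
    if ppm_tolerance <= 0:
        raise ValueError("ppm_tolerance must be positive")
    if rt_gap < 0:
        raise ValueError("rt_gap must be non-negative")

    clusters = [_Cluster(e) for e in entries]
    changed = True
    while changed and len(clusters) > 1:
        changed = False
        clusters.sort(key=lambda c: (c.mz, c.rt_start))
        mzs = [c.mz for c in clusters]
        parent = list(range(len(clusters)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, ci in enumerate(clusters):
            mz_hi = mzs[i] * (1 + ppm_tolerance * 1e-6)
            j = i + 1
            while j < len(clusters) and mzs[j] <= mz_hi:
                cj = clusters[j]
                if _mergeable(ci.mz, ci.rt_start, ci.rt_end,
                              cj.mz, cj.rt_start, cj.rt_end,
                              ppm_tolerance, rt_gap):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
                        changed = True
                j += 1

        if changed:
            groups: dict[int, _Cluster] = {}
            for i, c in enumerate(clusters):
                r = find(i)
                if r in groups:
                    groups[r].absorb(c)
                else:
                    groups[r] = c
            clusters = list(groups.values())

    out = [c.to_entry() for c in clusters]
    out.sort(key=lambda e: (e.mz, e.rt_start))
    return out


def canonicalize(excl: ExclusionList, rt_gap: float = 0.0) -> ExclusionList:
    """Return a copy of *excl* with entries clustered and sorted."""
    return replace(excl, entries=cluster_merge(excl.entries, excl.ppm_tolerance, rt_gap))


def merge_lists(current: ExclusionList, previous: ExclusionList, rt_gap: float = 0.0) -> ExclusionList:
    """Merge the latest exclusion list with the cumulative previous one.

    The union of entries is re-clustered; on a tolerance mismatch the
    stricter (smaller) ppm wins so merging never silently loosens exclusion.
    Provenance is concatenated (current first), deduplicated.
    """
    ppm = min(current.ppm_tolerance, previous.ppm_tolerance)
    entries = cluster_merge(list(current.entries) + list(previous.entries), ppm, rt_gap)
    provenance = list(dict.fromkeys(list(current.provenance) + list(previous.provenance)))
    return ExclusionList(entries, ppm, current.rt_pad, provenance)


def cap_list(excl: ExclusionList, max_entries: int = 2000, policy: str = "intensity") -> ExclusionList:
    """Cap the list to instrument capacity.

    The default ``"intensity"`` policy keeps the highest-intensity entries
    (ties: earlier rt_start, then lower m/z); entries with no intensity rank
    below any entry that has one.
    """
    if max_entries < 0:
        raise ValueError("max_entries must be >= 0")
    if policy != "intensity":
        raise ConfigError(f"unknown cap policy {policy!r}")
    if len(excl.entries) <= max_entries:
        return excl
    ranked = sorted(
        excl.entries,
        key=lambda e: (
            0 if e.intensity is not None else 1,
            -(e.intensity if e.intensity is not None else 0.0),
            e.rt_start,
            e.mz,
        ),
    )
    kept = sorted(ranked[:max_entries], key=lambda e: (e.mz, e.rt_start))
    return replace(excl, entries=kept)


# ---------------------------------------------------------------------------
# parsing and export


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a delimited exclusion export.

    Defaults match a Proteome Discoverer-style export. Either a single RT
    column (point value, padded by ``rt_pad`` into a window) or explicit
    start/end columns may be given.
    """

    sep: str = "\t"
    mz: str = "m/z"
    rt: str | None = "RT [min]"
    rt_start: str | None = None
    rt_end: str | None = None
    charge: str | None = "Charge"
    intensity: str | None = "Intensity"


#: Dialect of the instrument-import CSV written by export_instrument_table.
INSTRUMENT_DIALECT = Dialect(
    sep=",", mz="Mass", rt=None, rt_start="Start (min)", rt_end="End (min)",
    charge=None, intensity=None,
)


def _numeric_column(frame: pd.DataFrame, column: str, required: bool):
    if column not in frame.columns:
        if required:
            raise ExclusionFormatError(f"missing mandatory column {column!r}")
        return None
    raw = frame[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ExclusionFormatError(
            f"non-numeric value {raw.iloc[row]!r} in column {column!r} at data row {row + 1}"
        )
    return values


def parse_exclusion_export(
    source: str | Path | io.TextIOBase,
    dialect: Dialect | None = None,
    rt_pad: float = 2.0,
) -> list[ExclusionEntry]:
    """Parse a delimited exclusion export into entries.

    A point RT value ``t`` becomes the window ``[t - rt_pad, t + rt_pad]``.
    Missing mandatory columns or non-numeric cells raise
    :class:`ExclusionFormatError` naming the column / data row.
    """
    dialect = dialect or Dialect()
    frame = pd.read_csv(source, sep=dialect.sep, dtype=str, comment="#")

    mz = _numeric_column(frame, dialect.mz, required=True)
    if dialect.rt_start and dialect.rt_end:
        rt_lo = _numeric_column(frame, dialect.rt_start, required=True)
        rt_hi = _numeric_column(frame, dialect.rt_end, required=True)
    elif dialect.rt:
        rt = _numeric_column(frame, dialect.rt, required=True)
        rt_lo, rt_hi = rt - rt_pad, rt + rt_pad
    else:
        raise ConfigError("dialect must name either an rt column or rt_start/rt_end")
    charge = _numeric_column(frame, dialect.charge, required=False) if dialect.charge else None
    intensity = _numeric_column(frame, dialect.intensity, required=False) if dialect.intensity else None

    entries = []
    for i in range(len(frame)):
        entries.append(
            ExclusionEntry(
                mz=float(mz.iloc[i]),
                rt_start=float(rt_lo.iloc[i]),
                rt_end=float(rt_hi.iloc[i]),
                charge=int(charge.iloc[i]) if charge is not None and pd.notna(charge.iloc[i]) else None,
                intensity=float(intensity.iloc[i]) if intensity is not None and pd.notna(intensity.iloc[i]) else None,
            )
        )
    return entries


def export_instrument_table(excl: ExclusionList, destination: str | Path | io.TextIOBase) -> None:
    """Write the instrument-import CSV: ``Mass,Start (min),End (min)`` with
    m/z rounded to 4 decimals and RT to 2."""
    lines = ["Mass,Start (min),End (min)"]
    for e in excl.entries:
        lines.append(f"{e.mz:.4f},{e.rt_start:.2f},{e.rt_end:.2f}")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


def parse_instrument_table(source: str | Path | io.TextIOBase, ppm_tolerance: float = 10.0) -> ExclusionList:
    """Read back an instrument-import CSV written by
    :func:`export_instrument_table`."""
    entries = parse_exclusion_export(source, INSTRUMENT_DIALECT)
    return ExclusionList(entries, ppm_tolerance=ppm_tolerance)


# richer round-trip format preserving charge/intensity/provenance ----------

def write_list_tsv(excl: ExclusionList, path: str | Path) -> None:
    """Full-fidelity TSV serialization of an exclusion list."""
    buf = io.StringIO()
    buf.write(f"# pieacq exclusion list; ppm_tolerance={excl.ppm_tolerance}; rt_pad={excl.rt_pad}\n")
    buf.write(f"# provenance={','.join(excl.provenance)}\n")
    buf.write("mz\trt_start\trt_end\tcharge\tintensity\tsource_run\n")
    for e in excl.entries:
        buf.write(
            f"{e.mz!r}\t{e.rt_start!r}\t{e.rt_end!r}\t"
            f"{'' if e.charge is None else e.charge}\t"
            f"{'' if e.intensity is None else repr(e.intensity)}\t"
            f"{'' if e.source_run is None else e.source_run}\n"
        )
    Path(path).write_text(buf.getvalue())


def read_list_tsv(path: str | Path) -> ExclusionList:
    """Inverse of :func:`write_list_tsv`."""
    text = Path(path).read_text().splitlines()
    meta = {}
    provenance: list[str] = []
    body_start = 0
    for i, line in enumerate(text):
        if not line.startswith("#"):
            body_start = i
            break
        if "provenance=" in line:
            payload = line.split("provenance=", 1)[1]
            provenance = [p for p in payload.split(",") if p]
        else:
            for part in line.lstrip("# ").split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k.strip()] = v.strip()
    frame = pd.read_csv(io.StringIO("\n".join(text[body_start:])), sep="\t")
    entries = [
        ExclusionEntry(
            mz=float(r.mz),
            rt_start=float(r.rt_start),
            rt_end=float(r.rt_end),
            charge=int(r.charge) if pd.notna(r.charge) else None,
            intensity=float(r.intensity) if pd.notna(r.intensity) else None,
            source_run=str(r.source_run) if pd.notna(r.source_run) else None,
        )
        for r in frame.itertuples()
    ]
    return ExclusionList(
        entries,
        ppm_tolerance=float(meta.get("ppm_tolerance", 10.0)),
        rt_pad=float(meta.get("rt_pad", 2.0)),
        provenance=provenance,
    )
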
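"""In-silico LC-MS/MS acquisition: top-N selection, dynamic exclusion,
precursor-ion-exclusion (PIE) lists, stochastic identification and
target-decoy FDR filtering.

The simulator is ground-truth-aware by design: no spectra are synthesized.
Each peptide species elutes as a Gaussian profile; at every duty cycle the
instrument surveys the currently detectable precursors in the configured m/z
range, removes those under dynamic exclusion or on the PIE exclusion list,
and fragments the ``top_n`` most intense, each counted as two MS2 events
(an HCD scan for reporter quantification and a CID scan for sequencing).
Identification success is a logistic function of log10 precursor intensity;
scored target PSMs compete with injected decoys in an FDR walk that accepts
score-ranked PSMs until the decoy/target ratio reaches the threshold.

Campaign drivers run either plain DDA replicates or PIE iterations in which
each run's accepted precursors are merged into a cumulative exclusion list
applied to the next run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exclusion import ExclusionEntry, ExclusionList, cluster_merge, merge_lists, cap_list
from .mixture import Mixture, PeptideSpecies

logger = logging.getLogger(__name__)


@dataclass
class AcquisitionConfig:
    """Instrument and identification-model parameters.

    Defaults model an Orbitrap-class top-3x2 method: a 1.0-s high-resolution
    survey scan followed by 3 precursors x (HCD + CID) at 0.4 s per MS2
    event (3.4-s duty cycle), m/z 350-2000, dynamic exclusion of precursors
    selected more than once within 60 s (10 ppm window), and a 1% FDR
    acceptance walk.
    """

    mz_min: float = 350.0
    mz_max: float = 2000.0
    top_n: int = 3
    survey_time: float = 1.0          # seconds
    ms2_event_time: float = 0.4       # seconds per MS2 event (HCD or CID)
    dyn_excl_duration: float = 60.0   # seconds
    dyn_excl_repeat: int = 2          # selections within the window that trigger exclusion
    ppm_window: float = 10.0          # ppm, both dynamic and PIE exclusion
    detection_threshold: float = 30.0  # intensity units
    run_length: float = 90.0          # minutes
    rt_jitter_sd: float = 0.3         # minutes, per-peptide per-run apex shift
    id_midpoint: float = 2.5          # log10 intensity at 50% identification success
    id_steepness: float = 1.0         # logistic slope in log10-intensity units
    score_correct_mean: float = 3.5   # mean score of a correct target PSM
    score_sd: float = 1.0             # score spread (correct and null)
    decoy_rate: float = 0.5           # injected decoy PSMs per target PSM
    fdr_alpha: float = 0.01
    excl_rt_pad: float = 2.0          # minutes, PIE entry half-window around event time
    excl_capacity: int = 2000         # instrument exclusion-table capacity
    seed: int | None = None

    def validate(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        for name in ("survey_time", "ms2_event_time", "dyn_excl_duration", "run_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dyn_excl_repeat < 1:
            raise ValueError("dyn_excl_repeat must be >= 1")
        if self.ppm_window <= 0:
            raise ValueError("ppm_window must be positive")
        if self.detection_threshold <= 0:
            raise ValueError("detection_threshold must be positive")
        if not 0 < self.fdr_alpha <= 1:
            raise ValueError("fdr_alpha must be in (0, 1]")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be non-negative")

    @property
    def cycle_time(self) -> float:
        """Duty-cycle length in minutes: survey + 2 x top_n MS2 events."""
        return (self.survey_time + 2 * self.top_n * self.ms2_event_time) / 60.0


@dataclass(frozen=True)
class SelectionEvent:
    """One precursor picked for fragmentation (= one HCD + one CID scan)."""

    time: float
    mz: float
    intensity: float
    peptide_id: str
    run_id: str
    cycle_index: int


@dataclass
class PSMRecord:
    """A scored identification candidate for one MS2 event (or a decoy)."""

    event: SelectionEvent | None
    peptide_id: str | None
    score: float
    is_decoy: bool
    accepted: bool = False


@dataclass
class RunResult:
    """Everything one simulated LC-MS/MS run produced."""

    run_id: str
    events: list[SelectionEvent]
    psms: list[PSMRecord] = field(default_factory=list)
    accepted_peptides: set[str] = field(default_factory=set)
    accepted_proteins: set[str] = field(default_factory=set)
    n_cycles: int = 0
    exclusion: ExclusionList | None = None

    @property
    def n_ms2_events(self) -> int:
        return 2 * len(self.events)

    def accepted_psms(self) -> list[PSMRecord]:
        return [p for p in self.psms if p.accepted]


# ---------------------------------------------------------------------------
# elementary predicates


def elution_intensity(peptide: PeptideSpecies, t: float) -> float:
    """Gaussian elution profile: amplitude at the apex, sigma in minutes."""
    z = (t - peptide.rt_apex) / peptide.rt_sigma
    return peptide.peak_amplitude * math.exp(-0.5 * z * z)


def is_excluded(mz: float, t: float, excl: ExclusionList, ppm: float) -> bool:
    """True iff some entry matches *mz* within *ppm* (of the entry m/z) with
    ``rt_start <= t <= rt_end``."""
    for e in excl.entries:
        if abs(mz - e.mz) / e.mz * 1e6 <= ppm and e.rt_start <= t <= e.rt_end:
            return True
    return False


def _exclusion_intervals(
    mzs: np.ndarray, excl: ExclusionList | None, ppm: float
) -> dict[int, np.ndarray]:
    """Per-peptide (index) array of (rt_start, rt_end) intervals of matching
    exclusion entries; peptides with no match are absent."""
    if excl is None or not excl.entries:
        return {}
    e_mz = np.array([e.mz for e in excl.entries])
    e_lo = np.array([e.rt_start for e in excl.entries])
    e_hi = np.array([e.rt_end for e in excl.entries])
    order = np.argsort(e_mz)
    e_mz, e_lo, e_hi = e_mz[order], e_lo[order], e_hi[order]
    out: dict[int, np.ndarray] = {}
    # |mz - e| / e <= ppm*1e-6  <=>  e >= mz / (1 + p) and e <= mz / (1 - p)
    p = ppm * 1e-6
    lo_bounds = np.searchsorted(e_mz, mzs / (1 + p), side="left")
    hi_bounds = np.searchsorted(e_mz, mzs / (1 - p), side="right")
    for i, (a, b) in enumerate(zip(lo_bounds, hi_bounds)):
        if b > a:
            sel = np.abs(mzs[i] - e_mz[a:b]) / e_mz[a:b] * 1e6 <= ppm
            if sel.any():
                out[i] = np.column_stack((e_lo[a:b][sel], e_hi[a:b][sel]))
    return out


# ---------------------------------------------------------------------------
# one run


def simulate_run(
    mixture: Mixture,
    config: AcquisitionConfig,
    exclusion: ExclusionList | None = None,
    seed: int | tuple = 0,
    run_id: str = "run",
) -> RunResult:
    """Simulate one LC-MS/MS run and return its selection events.

    Per-run retention-time jitter (Gaussian, sd ``config.rt_jitter_sd``,
    drawn from *seed*) shifts each peptide's apex to model run-to-run
    chromatographic variation. Identification is NOT performed here; see
    :func:`identify_and_filter`.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    peptides = mixture.peptides
    n = len(peptides)

    ct = config.cycle_time
    n_cycles = int(config.run_length // ct)
    result = RunResult(run_id=run_id, events=[], n_cycles=n_cycles,
                       exclusion=exclusion)
    if n == 0 or n_cycles == 0:
        return result

    mzs = np.array([p.mz for p in peptides])
    amps = np.array([p.peak_amplitude for p in peptides])
    sigmas = np.array([p.rt_sigma for p in peptides])
    apex = np.array([p.rt_apex for p in peptides]) + rng.normal(0.0, config.rt_jitter_sd, n)

    thr = config.detection_threshold
    in_range = (mzs >= config.mz_min) & (mzs <= config.mz_max)
    detectable = in_range & (amps >= thr)
    with np.errstate(divide="ignore", invalid="ignore"):
        half = sigmas * np.sqrt(2.0 * np.log(np.maximum(amps / thr, 1.0)))

    t_last = (n_cycles - 1) * ct
    k_lo = np.ceil(np.maximum(apex - half, 0.0) / ct).astype(int)
    k_hi = np.floor(np.minimum(apex + half, t_last) / ct).astype(int)
    valid = detectable & (k_hi >= k_lo)

    pep_idx = np.flatnonzero(valid)
    counts = (k_hi[pep_idx] - k_lo[pep_idx] + 1)
    if counts.sum() == 0:
        return result
    pairs_pep = np.repeat(pep_idx, counts)
    # concatenated aranges k_lo..k_hi per peptide
    offsets = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    pairs_cyc = np.repeat(k_lo[pep_idx], counts) + offsets
    pairs_t = pairs_cyc * ct
    z = (pairs_t - apex[pairs_pep]) / sigmas[pairs_pep]
    pairs_int = amps[pairs_pep] * np.exp(-0.5 * z * z)

    keep = pairs_int >= thr
    # PIE exclusion: drop (peptide, cycle) pairs falling inside a matching entry window
    pie = _exclusion_intervals(mzs, exclusion, config.ppm_window)
    if pie:
        pie_block = np.zeros(len(pairs_pep), dtype=bool)
        # pairs are peptide-major and contiguous per peptide
        starts = np.searchsorted(pairs_pep, pep_idx, side="left")
        ends = np.searchsorted(pairs_pep, pep_idx, side="right")
        for i, a, b in zip(pep_idx, starts, ends):
            ivals = pie.get(i)
            if ivals is None:
                continue
            tt = pairs_t[a:b]
            blocked = np.zeros(b - a, dtype=bool)
            for lo, hi in ivals:
                blocked |= (tt >= lo) & (tt <= hi)
            pie_block[a:b] = blocked
        keep &= ~pie_block
    pairs_pep, pairs_cyc, pairs_t, pairs_int = (
        a[keep] for a in (pairs_pep, pairs_cyc, pairs_t, pairs_int)
    )
    if len(pairs_pep) == 0:
        return result

    order = np.argsort(pairs_cyc, kind="stable")
    pairs_pep, pairs_cyc, pairs_t, pairs_int = (
        a[order] for a in (pairs_pep, pairs_cyc, pairs_t, pairs_int)
    )
    cycles, cyc_starts = np.unique(pairs_cyc, return_index=True)
    cyc_starts = np.append(cyc_starts, len(pairs_cyc))

    dyn_dur = config.dyn_excl_duration / 60.0  # minutes
    excluded_until = np.full(n, -np.inf)
    sel_times: dict[int, list[float]] = {}
    events = result.events

    for c_i, cyc in enumerate(cycles):
        a, b = cyc_starts[c_i], cyc_starts[c_i + 1]
        t = cyc * ct
        cand = pairs_pep[a:b]
        inten = pairs_int[a:b]
        open_mask = excluded_until[cand] <= t
        if not open_mask.any():
            continue
        cand, inten = cand[open_mask], inten[open_mask]
        if len(cand) > 1:
            pick = np.lexsort((mzs[cand], -inten))[: config.top_n]
        else:
            pick = np.array([0])
        for j in pick:
            p = int(cand[j])
            events.append(
                SelectionEvent(
                    time=float(t),
                    mz=float(mzs[p]),
                    intensity=float(inten[j]),
                    peptide_id=peptides[p].peptide_id,
                    run_id=run_id,
                    cycle_index=int(cyc),
                )
            )
            times = sel_times.setdefault(p, [])
            times.append(t)
            recent = [s for s in times if t - s <= dyn_dur + 1e-9]
            sel_times[p] = recent
            if len(recent) >= config.dyn_excl_repeat:
                excluded_until[p] = t + dyn_dur

    logger.info("run %s: %d cycles, %d selection events", run_id, n_cycles, len(events))
    return result


# ---------------------------------------------------------------------------
# identification and FDR


def fdr_filter(psms: list[PSMRecord], alpha: float) -> list[PSMRecord]:
    """Target-decoy FDR walk.

    PSMs are ranked by descending score (score ties: decoys first,
    conservative) and accepted from the top until the running decoy/target
    ratio first exceeds *alpha*; decoys are never marked accepted. Flags are
    set in place and the input list is returned.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    for p in psms:
        p.accepted = False
    ranked = sorted(psms, key=lambda p: (-p.score, 0 if p.is_decoy else 1))
    n_decoy = n_target = 0
    accepted: list[PSMRecord] = []
    for p in ranked:
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        if n_decoy / max(n_target, 1) > alpha:
            break
        if not p.is_decoy:
            accepted.append(p)
    for p in accepted:
        p.accepted = True
    return psms


def identify_and_filter(
    events: list[SelectionEvent],
    config: AcquisitionConfig,
    seed: int | tuple = 0,
) -> list[PSMRecord]:
    """Turn selection events into scored PSMs and apply the 1% FDR walk.

    Each event yields one target PSM: with probability
    ``logistic(id_steepness * (log10 intensity - id_midpoint))`` the match is
    correct and its score is drawn from N(score_correct_mean, score_sd);
    otherwise (and for every injected decoy, ``decoy_rate`` per event) the
    score comes from the null N(0, score_sd).
    """
    rng = np.random.default_rng(seed)
    n = len(events)
    psms: list[PSMRecord] = []
    if n:
        log_i = np.log10([max(e.intensity, 1e-12) for e in events])
        p_correct = expit(config.id_steepness * (log_i - config.id_midpoint))
        correct = rng.random(n) < p_correct
        scores = np.where(
            correct,
            rng.normal(config.score_correct_mean, config.score_sd, n),
            rng.normal(0.0, config.score_sd, n),
        )
        for e, s in zip(events, scores):
            psms.append(PSMRecord(event=e, peptide_id=e.peptide_id, score=float(s), is_decoy=False))
    n_decoys = int(round(config.decoy_rate * n))
    for s in rng.normal(0.0, config.score_sd, n_decoys):
        psms.append(PSMRecord(event=None, peptide_id=None, score=float(s), is_decoy=True))
    return fdr_filter(psms, config.fdr_alpha)


def build_exclusion_from_run(
    result: RunResult, rt_pad: float = 2.0, ppm: float = 10.0
) -> ExclusionList:
    """Exclusion list from a run's accepted PSMs: one entry per accepted
    event (m/z, time +- rt_pad, intensity), then clustered."""
    entries = [
        ExclusionEntry(
            mz=p.event.mz,
            rt_start=p.event.time - rt_pad,
            rt_end=p.event.time + rt_pad,
            intensity=p.event.intensity,
            source_run=result.run_id,
        )
        for p in result.psms
        if p.accepted and p.event is not None
    ]
    merged = cluster_merge(entries, ppm, rt_gap=0.0)
    return ExclusionList(merged, ppm_tolerance=ppm, rt_pad=rt_pad, provenance=[result.run_id])


# ---------------------------------------------------------------------------
# campaigns


def _finalize_run(run: RunResult, mixture: Mixture, config: AcquisitionConfig, id_seed) -> None:
    run.psms = identify_and_filter(run.events, config, id_seed)
    prot_of = {p.peptide_id: p.protein_id for p in mixture.peptides}
    run.accepted_peptides = {p.peptide_id for p in run.psms if p.accepted}
    run.accepted_proteins = {prot_of[pid] for pid in run.accepted_peptides}
    logger.info(
        "run %s: %d accepted PSMs, %d peptides, %d proteins",
        run.run_id, len(run.accepted_psms()), len(run.accepted_peptides),
        len(run.accepted_proteins),
    )


def run_pie_campaign(
    mixture: Mixture,
    config: AcquisitionConfig,
    n_iterations: int,
    seed: int = 0,
    run_prefix: str = "pie",
) -> tuple[list[RunResult], ExclusionList]:
    """Iterative precursor-ion-exclusion campaign.

    Iteration 1 is plain DDA; every subsequent iteration runs with the
    cumulative exclusion list built by merging each finished run's accepted
    precursors into the previous list (capped at ``config.excl_capacity``).
    Per-run random streams are derived from (*seed*, run index) so campaigns
    are reproducible and pairable with DDA replicates of the same seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    cumulative = ExclusionList.empty(config.ppm_window, config.excl_rt_pad)
    runs: list[RunResult] = []
    for k in range(n_iterations):
        in_force = cumulative if k > 0 and len(cumulative) else None
        run = simulate_run(
            mixture, config, exclusion=in_force,
            seed=(seed, k, 0), run_id=f"{run_prefix}{k + 1}",
        )
        _finalize_run(run, mixture, config, (seed, k, 1))
        new_list = build_exclusion_from_run(run, config.excl_rt_pad, config.ppm_window)
        cumulative = cap_list(merge_lists(cumulative, new_list), config.excl_capacity)
        runs.append(run)
        logger.info("cumulative exclusion list: %d entries", len(cumulative))
    return runs, cumulative


def run_dda_replicates(
    mixture: Mixture,
    config: AcquisitionConfig,
    n_reps: int,
    seed: int = 0,
    run_prefix: str = "dda",
) -> list[RunResult]:
    """Independent DDA replicates (no PIE exclusion), seeded like the PIE
    campaign so replicate k pairs with iteration k."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    runs = []
    for k in range(n_reps):
        run = simulate_run(mixture, config, exclusion=None,
                           seed=(seed, k, 0), run_id=f"{run_prefix}{k + 1}")
        _finalize_run(run, mixture, config, (seed, k, 1))
        runs.append(run)
    return runs


def run_fractionated_campaign(
    mixture: Mixture,
    config: AcquisitionConfig,
    mode: str,
    n_runs: int,
    seed: int = 0,
    dimension: str = "hilic",
) -> dict[int, list[RunResult]]:
    """Run a campaign per chromatographic fraction.

    Each fraction's peptides form a sub-mixture analyzed independently with
    its own seed stream; PIE exclusion lists are kept per fraction. Returns
    ``{fraction label: runs}``.
    """
    if dimension not in ("hilic", "scx"):
        raise ValueError("dimension must be 'hilic' or 'scx'")
    if mode not in ("dda", "pie"):
        raise ValueError("mode must be 'dda' or 'pie'")
    attr = f"{dimension}_fraction"
    labels = sorted({getattr(p, attr) for p in mixture.peptides})
    out: dict[int, list[RunResult]] = {}
    for f in labels:
        sub = Mixture(
            proteins=mixture.proteins,
            peptides=[p for p in mixture.peptides if getattr(p, attr) == f],
            config=mixture.config,
        )
        frac_seed = (seed, 1000 + f)
        prefix = f"{dimension}{f}_{mode}"
        if mode == "pie":
            runs, _ = run_pie_campaign(sub, config, n_runs, seed=hash_seed(frac_seed), run_prefix=prefix)
        else:
            runs = run_dda_replicates(sub, config, n_runs, seed=hash_seed(frac_seed), run_prefix=prefix)
        out[f] = runs
    return out


def hash_seed(parts) -> int:
    """Fold a tuple of small ints into one 31-bit seed, deterministically."""
    h = 0
    for p in np.atleast_1d(np.asarray(parts, dtype=np.int64)):
        h = (h * 1_000_003 + int(p)) % (2**31 - 1)
    return h
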
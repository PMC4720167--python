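"""Acquisition simulator: elution, exclusion predicates, selection logic,
dynamic exclusion, FDR filtering and campaign drivers."""

import math

import numpy as np
import pytest

from pieacq import (
    AcquisitionConfig,
    ExclusionEntry,
    ExclusionList,
    Mixture,
    PSMRecord,
    build_exclusion_from_run,
    elution_intensity,
    fdr_filter,
    identify_and_filter,
    is_excluded,
    run_dda_replicates,
    run_pie_campaign,
    run_fractionated_campaign,
    simulate_run,
    SelectionEvent,
)
from pieacq import MixtureConfig, generate_mixture

from conftest import make_peptide
from _oracles import oracle_fdr_walk


def mixture_of(*peptides):
    proteins = []
    return Mixture(proteins=proteins, peptides=list(peptides))


class TestElution:
    def test_apex_value(self):
        p = make_peptide(amplitude=100.0, rt_apex=20.0, rt_sigma=0.5)
        assert elution_intensity(p, 20.0) == 100.0

    def test_one_sigma_value(self):
        p = make_peptide(amplitude=100.0, rt_apex=20.0, rt_sigma=0.5)
        assert elution_intensity(p, 20.5) == pytest.approx(100.0 * math.exp(-0.5))

    def test_six_sigma_is_undetectable(self):
        p = make_peptide(amplitude=100.0, rt_apex=20.0, rt_sigma=0.5)
        assert elution_intensity(p, 23.0) < 100.0 * math.exp(-17.9)


class TestIsExcluded:
    lst = ExclusionList([ExclusionEntry(500.0000, 30, 40)])

    def test_within_ppm_and_rt(self):
        assert is_excluded(500.0040, 35.0, self.lst, 10.0)  # 8 ppm

    def test_outside_rt_window(self):
        assert not is_excluded(500.0040, 45.0, self.lst, 10.0)

    def test_outside_ppm(self):
        assert not is_excluded(500.0100, 35.0, self.lst, 10.0)  # 20 ppm


class TestSimulateRun:
    def test_fully_excluded_peptide_never_selected(self):
        p = make_peptide(mz=500.0, rt_apex=10.0, rt_sigma=0.3, amplitude=1e5)
        excl = ExclusionList([ExclusionEntry(500.0, 0.0, 90.0)])
        cfg = AcquisitionConfig(rt_jitter_sd=0.0)
        run = simulate_run(mixture_of(p), cfg, exclusion=excl, seed=1)
        assert run.events == []

    def test_top_n_selection_single_cycle(self):
        """Five co-eluting peptides, one duty cycle: the 3 most intense are
        picked, counting 6 MS2 events."""
        peps = [
            make_peptide(peptide_id=f"p{i}", mz=400.0 + i, rt_apex=0.0, rt_sigma=1.0,
                         amplitude=100.0 * (i + 1))
            for i in range(5)
        ]
        cfg = AcquisitionConfig(run_length=0.06, rt_jitter_sd=0.0, detection_threshold=10.0)
        assert int(cfg.run_length // cfg.cycle_time) == 1
        run = simulate_run(mixture_of(*peps), cfg, seed=0)
        assert [e.peptide_id for e in run.events] == ["p4", "p3", "p2"]
        assert run.n_ms2_events == 6

    def test_intensity_tie_broken_by_lower_mz(self):
        peps = [
            make_peptide(peptide_id="high_mz", mz=600.0, rt_apex=0.0, amplitude=100.0),
            make_peptide(peptide_id="low_mz", mz=500.0, rt_apex=0.0, amplitude=100.0),
        ]
        cfg = AcquisitionConfig(run_length=0.06, rt_jitter_sd=0.0, top_n=1,
                                detection_threshold=10.0)
        run = simulate_run(mixture_of(*peps), cfg, seed=0)
        assert [e.peptide_id for e in run.events] == ["low_mz"]

    def test_empty_mixture_cycle_count(self):
        cfg = AcquisitionConfig(run_length=10.0)
        run = simulate_run(mixture_of(), cfg, seed=0)
        assert run.events == []
        assert run.n_cycles == int(10.0 // cfg.cycle_time)

    def test_event_invariants(self, small_mixture, fast_config):
        run = simulate_run(small_mixture, fast_config, seed=5)
        cfg = fast_config
        assert run.n_ms2_events == 2 * len(run.events) <= 2 * cfg.top_n * run.n_cycles
        for e in run.events:
            assert cfg.mz_min <= e.mz <= cfg.mz_max
            assert e.intensity >= cfg.detection_threshold

    def test_dynamic_exclusion_limits_reselection(self, small_mixture, fast_config):
        """With repeat=2, no peptide is selected more than twice within any
        single dynamic-exclusion window."""
        run = simulate_run(small_mixture, fast_config, seed=6)
        window = fast_config.dyn_excl_duration / 60.0
        times = {}
        for e in run.events:
            times.setdefault(e.peptide_id, []).append(e.time)
        for ts in times.values():
            for i in range(len(ts) - 2):
                assert ts[i + 2] - ts[i] > window

    def test_same_seed_reproduces_run(self, small_mixture, fast_config):
        a = simulate_run(small_mixture, fast_config, seed=9)
        b = simulate_run(small_mixture, fast_config, seed=9)
        assert a.events == b.events


class TestFdrFilter:
    def make(self, flags, scores=None):
        n = len(flags)
        scores = scores if scores is not None else list(range(n, 0, -1))
        return [
            PSMRecord(event=None, peptide_id=None if d else f"t{i}", score=float(s), is_decoy=d)
            for i, (d, s) in enumerate(zip(flags, scores))
        ]

    def test_no_decoys_accepts_all(self):
        psms = fdr_filter(self.make([False] * 5), 0.01)
        assert all(p.accepted for p in psms)

    def test_walk_stops_at_first_violation(self):
        psms = fdr_filter(self.make([False] * 4 + [True] + [False] * 5), 0.01)
        assert sum(p.accepted for p in psms) == 4

    def test_top_scoring_decoy_empties_acceptance(self):
        psms = fdr_filter(self.make([True] + [False] * 10), 0.01)
        assert not any(p.accepted for p in psms)

    def test_ninety_nine_targets_one_decoy_one_target(self):
        flags = [False] * 99 + [True] + [False]
        psms = fdr_filter(self.make(flags), 0.01)
        assert sum(p.accepted for p in psms) == 99

    def test_decoys_never_accepted(self, rng):
        psms = self.make(rng.random(50) < 0.5, rng.normal(size=50))
        fdr_filter(psms, 0.3)
        assert not any(p.accepted for p in psms if p.is_decoy)

    def test_matches_prefix_scan_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 120))
            scores = rng.normal(size=n)
            flags = rng.random(n) < rng.uniform(0.05, 0.5)
            alpha = float(rng.choice([0.01, 0.05, 0.2]))
            psms = [
                PSMRecord(None, None if d else f"t{i}", float(s), bool(d))
                for i, (s, d) in enumerate(zip(scores, flags))
            ]
            fdr_filter(psms, alpha)
            ours = {i for i, p in enumerate(psms) if p.accepted}
            assert ours == oracle_fdr_walk(scores, flags, alpha)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            fdr_filter([], 0.0)


class TestIdentification:
    def test_no_decoys_all_targets_accepted(self):
        events = [
            SelectionEvent(1.0, 500.0, 1e6, f"p{i}", "r", i) for i in range(10)
        ]
        cfg = AcquisitionConfig(decoy_rate=0.0)
        psms = identify_and_filter(events, cfg, seed=0)
        assert len(psms) == 10 and all(p.accepted for p in psms)

    def test_identification_favors_intense_precursors(self, rng):
        """Acceptance probability rises with precursor intensity under the
        logistic identification model."""
        lo = [SelectionEvent(1.0, 500.0, 40.0, f"lo{i}", "r", i) for i in range(300)]
        hi = [SelectionEvent(1.0, 500.0, 1e5, f"hi{i}", "r", i) for i in range(300)]
        cfg = AcquisitionConfig()
        psms = identify_and_filter(lo + hi, cfg, seed=3)
        acc = {p.peptide_id for p in psms if p.accepted}
        n_lo = sum(1 for i in acc if i and i.startswith("lo"))
        n_hi = sum(1 for i in acc if i and i.startswith("hi"))
        assert n_hi > n_lo


class TestBuildExclusion:
    def run_with_accepted(self, events):
        from pieacq.acquisition import RunResult

        run = RunResult(run_id="r1", events=events)
        run.psms = [PSMRecord(e, e.peptide_id, 5.0, False, accepted=True) for e in events]
        return run

    def test_empty_run_gives_empty_list(self):
        assert len(build_exclusion_from_run(self.run_with_accepted([]))) == 0

    def test_repeat_selections_merge_into_one_window(self):
        events = [
            SelectionEvent(30.0, 500.0, 1e4, "p1", "r1", 0),
            SelectionEvent(30.5, 500.0, 1e4, "p1", "r1", 9),
        ]
        lst = build_exclusion_from_run(self.run_with_accepted(events), rt_pad=2.0)
        (e,) = lst.entries
        assert (e.rt_start, e.rt_end) == (28.0, 32.5)
        assert e.mz == pytest.approx(500.0)

    def test_provenance_carries_run_id(self):
        events = [SelectionEvent(30.0, 500.0, 1e4, "p1", "r1", 0)]
        lst = build_exclusion_from_run(self.run_with_accepted(events))
        assert lst.provenance == ["r1"]
        assert lst.entries[0].source_run == "r1"


class TestCampaigns:
    def test_single_iteration_equals_plain_run(self, small_mixture, fast_config):
        runs, _ = run_pie_campaign(small_mixture, fast_config, 1, seed=11)
        reps = run_dda_replicates(small_mixture, fast_config, 1, seed=11)
        direct = simulate_run(small_mixture, fast_config, None, seed=(11, 0, 0), run_id="pie1")
        assert [e.time for e in runs[0].events] == [e.time for e in direct.events]
        assert runs[0].accepted_peptides == reps[0].accepted_peptides

    def test_iteration_two_accepts_only_new_peptides(self, small_mixture):
        """With no RT jitter, forced identification success and exclusion
        windows wide enough to cover each peptide's detectability span, the
        accepted sets of successive iterations are disjoint by construction."""
        cfg = AcquisitionConfig(
            run_length=15.0, rt_jitter_sd=0.0, decoy_rate=0.0,
            id_midpoint=-1e9, excl_rt_pad=6.0,
        )
        runs, _ = run_pie_campaign(small_mixture, cfg, 2, seed=2)
        assert runs[0].accepted_peptides
        assert not (runs[0].accepted_peptides & runs[1].accepted_peptides)

    def test_exclusion_provenance_lists_prior_runs(self, small_mixture, fast_config):
        runs, final = run_pie_campaign(small_mixture, fast_config, 3, seed=4)
        assert runs[2].exclusion.provenance == ["pie1", "pie2"]
        assert final.provenance == ["pie1", "pie2", "pie3"]

    def test_exclusion_compliance(self, small_mixture, fast_config):
        runs, _ = run_pie_campaign(small_mixture, fast_config, 2, seed=8)
        in_force = runs[1].exclusion
        for e in runs[1].events:
            assert not is_excluded(e.mz, e.time, in_force, fast_config.ppm_window)

    def test_replicates_differ_under_jitter(self, small_mixture, fast_config):
        reps = run_dda_replicates(small_mixture, fast_config, 2, seed=3)
        assert [e.peptide_id for e in reps[0].events] != [e.peptide_id for e in reps[1].events]

    def test_deterministic_replicates_without_jitter(self, small_mixture):
        cfg = AcquisitionConfig(run_length=10.0, rt_jitter_sd=0.0)
        reps = run_dda_replicates(small_mixture, cfg, 2, seed=3)
        assert [e.peptide_id for e in reps[0].events] == [e.peptide_id for e in reps[1].events]

    def test_cumulative_list_grows_until_capped(self, small_mixture, fast_config):
        runs, _ = run_pie_campaign(small_mixture, fast_config, 3, seed=12)
        sizes = [len(r.exclusion) if r.exclusion else 0 for r in runs]
        assert sizes == sorted(sizes)


class TestFractionation:
    def test_per_fraction_runs_partition_the_workload(self, fast_config):
        mix = generate_mixture(MixtureConfig(n_proteins=6, seed=21))
        per_fraction = run_fractionated_campaign(mix, fast_config, "dda", 1, seed=5)
        assert set(per_fraction) == {1, 2, 3, 4, 5, 6}
        frac_of = {p.peptide_id: p.hilic_fraction for p in mix.peptides}
        for f, runs in per_fraction.items():
            for run in runs:
                assert all(frac_of[e.peptide_id] == f for e in run.events)
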
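"""Campaign orchestration: run a configured experiment end to end and write
a deterministic, replayable directory of results."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .acquisition import (
    RunResult,
    hash_seed,
    run_dda_replicates,
    run_fractionated_campaign,
    run_pie_campaign,
)
from .config import ExperimentConfig
from .exclusion import ExclusionList, export_instrument_table, write_list_tsv
from .mixture import generate_mixture, write_mixture_tsv
from .quant import compare_strategies, plot_ratio_scatter, reporter_ratios

logger = logging.getLogger(__name__)


def _events_frame(run: RunResult) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.time, e.mz, e.intensity, e.peptide_id, e.run_id, e.cycle_index) for e in run.events],
        columns=["time", "mz", "intensity", "peptide_id", "run_id", "cycle_index"],
    )


def _psm_frame(run: RunResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.event.time if p.event else "",
                p.event.mz if p.event else "",
                p.peptide_id or "",
                p.score,
                p.is_decoy,
                p.accepted,
            )
            for p in run.psms
        ],
        columns=["time", "mz", "peptide_id", "score", "is_decoy", "accepted"],
    )


def _write_runs(runs: list[RunResult], run_dir: Path) -> dict:
    summary = {}
    for run in runs:
        _events_frame(run).to_csv(run_dir / f"{run.run_id}_events.tsv", sep="\t", index=False)
        _psm_frame(run).to_csv(run_dir / f"{run.run_id}_psms.tsv", sep="\t", index=False)
        summary[run.run_id] = {
            "n_cycles": run.n_cycles,
            "n_events": len(run.events),
            "n_ms2_events": run.n_ms2_events,
            "n_psms": len(run.psms),
            "n_accepted": len(run.accepted_psms()),
            "n_accepted_peptides": len(run.accepted_peptides),
            "n_accepted_proteins": len(run.accepted_proteins),
            "exclusion_in_force": len(run.exclusion) if run.exclusion else 0,
        }
    return summary


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path, force: bool = False
) -> Path:
    """Execute a configured experiment and write its result directory.

    Layout: ``mixture/`` (protein + peptide TSVs), ``runs/`` (per-run event
    and PSM tables + JSON summary), ``exclusion/`` (round-trip TSV and
    instrument CSV of the final PIE list), ``report/`` (JSON + Markdown
    comparison when both strategies ran), and ``manifest.json`` recording
    the config hash and derived seeds. Identical config + seed reproduce
    byte-identical outputs.
    """
    config.validate()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    for sub in ("mixture", "runs", "exclusion", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    master = config.seed
    mixture_seed = hash_seed((master, 1))
    pie_seed = hash_seed((master, 2))
    dda_seed = hash_seed((master, 3))
    quant_seed = hash_seed((master, 4))

    mix_cfg = config.mixture
    mix_cfg.seed = mixture_seed
    mixture = generate_mixture(mix_cfg)
    write_mixture_tsv(mixture, out / "mixture" / "peptides.tsv", out / "mixture" / "proteins.tsv")
    logger.info("mixture: %d proteins, %d peptides", len(mixture.proteins), len(mixture.peptides))

    acq = config.acquisition
    camp = config.campaign
    summary: dict = {}
    pie_runs: list[RunResult] = []
    dda_runs: list[RunResult] = []
    final_list: ExclusionList | None = None

    if camp.fraction_mode:
        modes = {"pie": camp.n_iterations, "dda": camp.n_replicates}
        wanted = ["pie", "dda"] if camp.mode == "compare" else [camp.mode]
        for mode in wanted:
            per_fraction = run_fractionated_campaign(
                mixture, acq, mode, modes[mode],
                seed=pie_seed if mode == "pie" else dda_seed,
                dimension=camp.fraction_dimension,
            )
            runs = [r for rs in per_fraction.values() for r in rs]
            (pie_runs if mode == "pie" else dda_runs).extend(runs)
    else:
        if camp.mode in ("pie", "compare"):
            pie_runs, final_list = run_pie_campaign(mixture, acq, camp.n_iterations, seed=pie_seed)
        if camp.mode in ("dda", "compare"):
            dda_runs = run_dda_replicates(mixture, acq, camp.n_replicates, seed=dda_seed)

    summary.update(_write_runs(pie_runs + dda_runs, out / "runs"))
    if final_list is not None:
        write_list_tsv(final_list, out / "exclusion" / "pie_final.tsv")
        export_instrument_table(final_list, out / "exclusion" / "pie_final_instrument.csv")

    report_paths = {}
    if pie_runs and dda_runs:
        quant_pie = reporter_ratios(pie_runs, mixture, config.report.noise_sd, (quant_seed, 0))
        quant_dda = reporter_ratios(dda_runs, mixture, config.report.noise_sd, (quant_seed, 1))
        pep_pie = set().union(*(r.accepted_peptides for r in pie_runs))
        pep_dda = set().union(*(r.accepted_peptides for r in dda_runs))
        report = compare_strategies(quant_pie, quant_dda, pep_pie, pep_dda)
        report.to_json(out / "report" / "report.json")
        report.to_markdown(out / "report" / "report.md")
        report_paths = {"json": "report/report.json", "markdown": "report/report.md"}
        if config.report.make_plot:
            plot_ratio_scatter(report, quant_pie, quant_dda, out / "report" / "ratio_scatter.png")

    canonical = config.canonical_json()
    manifest = {
        "pieacq_version": __version__,
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seeds": {
            "master": master,
            "mixture": mixture_seed,
            "pie": pie_seed,
            "dda": dda_seed,
            "quant": quant_seed,
        },
        "runs": summary,
        "report": report_paths,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def load_experiment_psms(exp_dir: str | Path):
    """Reload an experiment directory's mixture and per-run PSM records.

    Events are not reconstructed (entries keep only peptide identity, score
    and flags) — enough to recompute quantification and comparison reports.
    Returns ``(mixture, {run_id: [PSMRecord, ...]})``.
    """
    from .acquisition import PSMRecord
    from .mixture import read_mixture_tsv

    exp = Path(exp_dir)
    mixture = read_mixture_tsv(exp / "mixture" / "peptides.tsv", exp / "mixture" / "proteins.tsv")
    runs: dict[str, list] = {}
    for psm_path in sorted((exp / "runs").glob("*_psms.tsv")):
        run_id = psm_path.name[: -len("_psms.tsv")]
        frame = pd.read_csv(psm_path, sep="\t")
        records = []
        for r in frame.itertuples():
            pid = r.peptide_id if isinstance(r.peptide_id, str) and r.peptide_id else None
            records.append(
                PSMRecord(event=None, peptide_id=pid, score=float(r.score),
                          is_decoy=bool(r.is_decoy), accepted=bool(r.accepted))
            )
        runs[run_id] = records
    return mixture, runs
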
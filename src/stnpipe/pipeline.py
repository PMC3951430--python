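"""End-to-end orchestration of the analysis stages.

``run_expression_screen`` wires the microarray and consensus stages into
the study's two contrasts (stimulation effect per group, lesion effect
across groups); ``run_end_to_end`` executes every toggled stage on
synthetic data and writes tables, JSON summaries and a line-delimited
JSON log into a run directory stamped with the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, consensus, locomotion, microarray, spectra, stereology, synthetic

__all__ = ["RunConfig", "ScreenResult", "run_expression_screen", "run_end_to_end"]


@dataclass
class RunConfig:
    """All stage parameters with study defaults, plus stage toggles."""

    seed: int = 0
    simulate: bool = True
    stages: tuple[str, ...] = (
        "microarray",
        "consensus",
        "locomotion",
        "spectra",
        "stereology",
        "qpcr",
    )
    # expression screen
    n_probesets: int = 5000
    probes_per_set: int = 11
    animals_per_group: int = 2
    gamma: float = microarray.DEFAULT_GAMMA
    call_method: str = "t"
    slr_threshold: float = consensus.DEFAULT_SLR_THRESHOLD
    required_count: int = 4
    lesion_min_count: int = 3
    # locomotion
    noise_level_cm_s: float = locomotion.DEFAULT_NOISE_LEVEL
    speed_window_s: float = locomotion.DEFAULT_SPEED_WINDOW_S
    min_duration_s: float = locomotion.DEFAULT_MIN_DURATION_S
    max_sd_variant: str = "max-speed"
    # spectra
    welch_segment_s: float = 2.0
    band_alpha: float = 0.05
    signal_duration_s: float = 60.0
    # stereology
    fractionator: stereology.FractionatorDesign = field(
        default_factory=stereology.FractionatorDesign
    )
    # qPCR
    qpcr_baseline_condition: str = "nonstim"
    qpcr_experiment_condition: str = "stim"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "fractionator" in raw:
            raw["fractionator"] = stereology.FractionatorDesign(**raw["fractionator"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ScreenResult:
    """Outcome of the consensus expression screen."""

    hfs_pd_records: list
    hfs_control_records: list
    lesion_records: list
    counter_records: list
    comparison_tables: dict[str, list[pd.DataFrame]]

    def table(self) -> pd.DataFrame:
        return consensus.records_to_table(self.hfs_pd_records, self.counter_records)


def run_expression_screen(
    dataset: microarray.ExpressionDataset,
    gamma: float = microarray.DEFAULT_GAMMA,
    call_method: str = "t",
    slr_threshold: float = consensus.DEFAULT_SLR_THRESHOLD,
    required_count: int = 4,
    lesion_min_count: int = 3,
    normalize: bool = True,
) -> ScreenResult:
    """Normalize, build both contrasts, and apply the consensus rules.

    The stimulation (HFS) contrast is evaluated separately per group; the
    lesion contrast compares non-stimulated hemispheres across groups.
    Counter-regulation is assessed for the lesioned group's HFS list
    against the lesion-contrast call summaries.
    """
    data = microarray.normalize_dataset(dataset) if normalize else dataset
    plans = {
        "hfs_pd": consensus.build_hfs_comparisons(data.manifest, "PD"),
        "hfs_control": consensus.build_hfs_comparisons(data.manifest, "control"),
        "lesion": consensus.build_lesion_comparisons(data.manifest),
    }
    tables: dict[str, list[pd.DataFrame]] = {}
    for label, plan in plans.items():
        tables[label] = [
            microarray.change_calls_and_slrs(
                data, exp, base, gamma=gamma, method=call_method, comparison=f"{label}:{exp}-vs-{base}"
            )
            for exp, base, _kind in plan.pairs
        ]
    hfs_pd = consensus.consensus_filter(
        tables["hfs_pd"], required_count, slr_threshold, contrast="hfs_pd"
    )
    hfs_control = consensus.consensus_filter(
        tables["hfs_control"], required_count, slr_threshold, contrast="hfs_control"
    )
    lesion = consensus.consensus_filter(
        tables["lesion"],
        min(lesion_min_count, len(tables["lesion"])),
        slr_threshold,
        contrast="lesion",
    )
    lesion_summary = consensus.summarize_comparisons(tables["lesion"], contrast="lesion")
    counter = consensus.detect_counter_regulation(hfs_pd, lesion_summary, lesion_min_count)
    return ScreenResult(hfs_pd, hfs_control, lesion, counter, tables)


def screen_truth_recovery(result: ScreenResult, truth, probe_set_ids) -> dict:
    """Sensitivity / false-discovery metrics against planted truth."""
    id_of = {g: str(probe_set_ids[g]) for g in range(len(probe_set_ids))}
    planted_down = {id_of[g] for g in truth.hfs_down}
    planted_counter = {id_of[g] for g in truth.counter_regulated}
    hits = {r.probe_set_id for r in result.hfs_pd_records if r.D_count >= r.I_count}
    all_hits = {r.probe_set_id for r in result.hfs_pd_records}
    sensitivity = len(hits & planted_down) / len(planted_down) if planted_down else float("nan")
    false_hits = all_hits - planted_down
    fdr = len(false_hits) / len(all_hits) if all_hits else 0.0
    flagged = {c.probe_set_id for c in result.counter_records if c.counter}
    counter_recall = (
        len(flagged & planted_counter) / len(planted_counter) if planted_counter else float("nan")
    )
    return {
        "sensitivity_hfs_down": sensitivity,
        "empirical_fdr": fdr,
        "counter_regulation_recall": counter_recall,
        "n_detected": len(all_hits),
    }


class _RunLogger:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def log(self, **entry):
        entry["ts"] = time.time()
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry) + "\n")


def run_end_to_end(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every toggled stage on synthetic inputs.

    Returns the run summary (also written as ``summary.json``); every
    output carries the config hash so identically configured runs are
    identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = _RunLogger(out / "log.jsonl")
    summary: dict = {"config_hash": config.config_hash, "seed": config.seed}
    logger.log(event="start", config=config.to_dict(), config_hash=config.config_hash)

    if "microarray" in config.stages or "consensus" in config.stages:
        truth = synthetic.default_expression_truth(
            n_probesets=config.n_probesets, seed=config.seed
        )
        dataset, _ = synthetic.gen_expression_dataset(
            truth,
            n_probesets=config.n_probesets,
            probes_per_set=config.probes_per_set,
            manifest=synthetic.default_manifest(config.animals_per_group),
        )
        screen = run_expression_screen(
            dataset,
            gamma=config.gamma,
            call_method=config.call_method,
            slr_threshold=config.slr_threshold,
            required_count=config.required_count,
            lesion_min_count=config.lesion_min_count,
        )
        table = screen.table()
        table.insert(0, "config_hash", config.config_hash)
        table.to_csv(out / "regulation_table.tsv", sep="\t", index=False)
        summary["expression"] = screen_truth_recovery(screen, truth, dataset.probe_set_ids)
        logger.log(event="stage_done", stage="consensus", **summary["expression"])

    if "locomotion" in config.stages:
        truth = synthetic.default_track_truth(seed=config.seed)
        track, truth = synthetic.gen_locomotion_track(truth)
        episodes, loco_summary = locomotion.analyze_track(
            track,
            noise_level=config.noise_level_cm_s,
            window_s=config.speed_window_s,
            min_duration_s=config.min_duration_s,
            variant=config.max_sd_variant,
        )
        rows = []
        dt = 1.0 / track.rate_hz
        for i, ep in enumerate(episodes.episodes):
            rows.append(
                {
                    "start_s": ep.start * dt,
                    "end_s": ep.end * dt,
                    "label": ep.label,
                    "max_sd": episodes.max_sd.get(i, float("nan")),
                    "full_motion": episodes.full_motion.get(i, False),
                }
            )
        pd.DataFrame(rows).to_csv(out / "episodes.csv", index=False)
        summary["locomotion"] = {
            **loco_summary,
            "n_motion_truth": len(truth.peak_speeds_cm_s),
            "n_motion_detected": len(episodes.motion_indices()),
        }
        logger.log(event="stage_done", stage="locomotion", **summary["locomotion"])

    if "spectra" in config.stages:
        band_rows = []
        group_bands: dict[str, list[dict]] = {"PD": [], "control": []}
        for group, amp in (("PD", 1.0), ("control", 0.0)):
            for ch in range(6):
                truth = synthetic.SignalTruth(
                    duration_s=config.signal_duration_s,
                    oscillation_amplitude=amp,
                    seed=config.seed + 7919 * ch + (0 if group == "PD" else 104729),
                )
                record, _ = synthetic.gen_field_potentials(truth, n_channels=1)
                res = spectra.analyze_record(record, segment_s=config.welch_segment_s)
                group_bands[group].append(res.band_power["ch0"])
        stats_tab = spectra.compare_band_power(
            group_bands["PD"], group_bands["control"], family_alpha=config.band_alpha
        )
        stats_tab.to_csv(out / "band_stats.tsv", sep="\t", index=False)
        summary["spectra"] = {
            "significant_bands": list(stats_tab.loc[stats_tab["significant"], "band"]),
        }
        logger.log(event="stage_done", stage="spectra", **summary["spectra"])

    if "stereology" in config.stages:
        truth = synthetic.StereoTruth(
            density_per_roi={"SNc_PD": 532.3, "SNc_control": 8675.6},
            design=config.fractionator,
            seed=config.seed,
        )
        sample, _ = synthetic.gen_cell_sections(truth)
        densities = stereology.fractionator_density(sample)
        (out / "stereology.json").write_text(json.dumps(densities, indent=1))
        summary["stereology"] = {
            "densities": densities,
            "percent_change": stereology.percent_change(
                densities["SNc_PD"], densities["SNc_control"]
            ),
        }
        logger.log(event="stage_done", stage="stereology", **summary["stereology"])

    if "qpcr" in config.stages:
        plate, truth_slr = synthetic.gen_qpcr_plate(
            {"RT1-Da": -2.4, "Cd74": -1.9},
            conditions=(config.qpcr_experiment_condition, config.qpcr_baseline_condition),
            seed=config.seed,
        )
        rows = []
        for gene, planted in truth_slr.items():
            per = assays.delta_delta_ct(
                plate,
                gene,
                "Rpl13a",
                config.qpcr_experiment_condition,
                config.qpcr_baseline_condition,
            )
            rows.append(
                {"gene": gene, "planted_slr": planted, "recovered_slr": float(per["slr"].mean())}
            )
        qpcr_tab = pd.DataFrame(rows)
        qpcr_tab.to_csv(out / "qpcr_slr.tsv", sep="\t", index=False)
        summary["qpcr"] = qpcr_tab.to_dict(orient="records")
        logger.log(event="stage_done", stage="qpcr", **summary["qpcr"][0])

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    logger.log(event="done")
    return summary
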
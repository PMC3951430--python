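"""Synthetic study data with recorded ground truth.

Every input the pipeline consumes can be generated here: probe-level
expression chips with planted stimulation-down, lesion-up and
counter-regulated genes; two-mode open-field locomotion tracks in a
70x100 cm arena; 1/f field potentials carrying a high-beta oscillation
and 50 Hz line noise; Poisson fractionator count tables; and qPCR CT
plates with known fold changes.  Each generator is deterministic given
its seed, and all stage seeds derive from one top-level seed through
``numpy`` SeedSequence spawn keys (one fixed key per stage), so stages
can be regenerated independently.

The generators emulate the *structure* of the study's data — paired
hemispheres within animals, bilateral lesion effects, probe affinities —
not its biology; defaults are chosen so that regulated genes planted at
|slr| >= 1 are clearly detectable by the consensus screen.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locomotion import LocomotionTrack
from .microarray import ExpressionDataset
from .spectra import SignalRecord
from .stereology import FractionatorDesign, StereologySample

__all__ = [
    "ExpressionTruth",
    "TrackTruth",
    "SignalTruth",
    "StereoTruth",
    "stage_rng",
    "default_manifest",
    "default_expression_truth",
    "gen_expression_dataset",
    "default_track_truth",
    "gen_locomotion_track",
    "gen_field_potentials",
    "gen_cell_sections",
    "gen_qpcr_plate",
    "write_truth_json",
]

#: fixed spawn key per stage (documented splitting rule)
STAGE_KEYS = {
    "expression": 0,
    "locomotion": 1,
    "signals": 2,
    "stereology": 3,
    "qpcr": 4,
}

#: probe sets on the emulated chip family (full size; scaled down by default)
FULL_CHIP_PROBESETS = 31043
DEFAULT_PROBES_PER_SET = 11

ARENA_CM = (70.0, 100.0)
TRACK_RATE_HZ = 12.8
SIGNAL_RATE_HZ = 1000.0
OSCILLATION_HZ = 32.0


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Stage generator: SeedSequence(seed) spawned at the stage's key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],)))


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize a truth dataclass to a JSON sidecar."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(dataclasses.asdict(truth), default=default, indent=1))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted effect structure of a synthetic chip experiment.

    ``hfs_down`` genes carry a negative slr on the stimulated hemisphere
    of lesioned animals; ``lesion_up`` genes a positive slr on both
    hemispheres of lesioned animals; ``counter_regulated`` genes belong to
    both classes, so their stimulation effect opposes their lesion effect.
    Gene ids are probe-set indices.
    """

    hfs_down: list[int]
    lesion_up: list[int]
    counter_regulated: list[int]
    hfs_slr: dict[int, float]      # gene -> planted slr, hfs contrast (log2)
    lesion_slr: dict[int, float]   # gene -> planted slr, lesion contrast (log2)
    animal_sd: float = 0.1
    hemisphere_noise_sd: float = 0.2
    probe_affinity_sd: float = 1.0
    global_mean_log2: float = 8.0
    min_planted_abs_slr: float = 1.0
    seed: int = 0

    def __post_init__(self):
        hfs, les, ctr = set(self.hfs_down), set(self.lesion_up), set(self.counter_regulated)
        if not ctr <= (hfs & les):
            raise ValueError("counter-regulated genes must be both hfs_down and lesion_up")
        for sd in (self.animal_sd, self.hemisphere_noise_sd, self.probe_affinity_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for gene in hfs:
            if abs(self.hfs_slr[gene]) < self.min_planted_abs_slr:
                raise ValueError(f"planted |slr| below threshold for gene {gene}")
        for gene in les:
            if abs(self.lesion_slr[gene]) < self.min_planted_abs_slr:
                raise ValueError(f"planted |slr| below threshold for gene {gene}")

    def null_genes(self, n_probesets: int) -> np.ndarray:
        planted = set(self.hfs_down) | set(self.lesion_up)
        return np.array([g for g in range(n_probesets) if g not in planted])


def default_manifest(n_per_group: int = 2) -> pd.DataFrame:
    """Both hemispheres of ``n_per_group`` lesioned and control animals."""
    rows = []
    for group, prefix in (("PD", "PD"), ("control", "C")):
        for a in range(1, n_per_group + 1):
            animal = f"{prefix}{a}"
            for hemi in ("stim", "nonstim"):
                rows.append(
                    {
                        "sample_id": f"{animal}_{hemi}",
                        "animal_id": animal,
                        "group": group,
                        "hemisphere": hemi,
                    }
                )
    return pd.DataFrame(rows)


def default_expression_truth(
    n_probesets: int = 5000,
    n_hfs_only: int = 15,
    n_lesion_only: int = 15,
    n_counter: int = 15,
    seed: int = 0,
) -> ExpressionTruth:
    """Truth with counter-regulated, stimulation-only and lesion-only genes.

    Planted slr magnitudes are drawn uniformly from [1.0, 2.8], the range
    typical of strongly regulated genes; stimulation effects are negative
    (downregulation), lesion effects positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    genes = rng.choice(n_probesets, size=n_hfs_only + n_lesion_only + n_counter, replace=False)
    counter = sorted(int(g) for g in genes[:n_counter])
    hfs_only = sorted(int(g) for g in genes[n_counter : n_counter + n_hfs_only])
    lesion_only = sorted(int(g) for g in genes[n_counter + n_hfs_only :])
    hfs_down = sorted(counter + hfs_only)
    lesion_up = sorted(counter + lesion_only)
    hfs_slr = {g: float(-rng.uniform(1.0, 2.8)) for g in hfs_down}
    lesion_slr = {g: float(rng.uniform(1.0, 2.0)) for g in lesion_up}
    return ExpressionTruth(
        hfs_down=hfs_down,
        lesion_up=lesion_up,
        counter_regulated=counter,
        hfs_slr=hfs_slr,
        lesion_slr=lesion_slr,
        seed=seed,
    )


def gen_expression_dataset(
    truth: ExpressionTruth,
    n_probesets: int = 5000,
    probes_per_set: int = DEFAULT_PROBES_PER_SET,
    manifest: pd.DataFrame | None = None,
) -> tuple[ExpressionDataset, ExpressionTruth]:
    """Probe-level intensities with planted animal/hemisphere structure.

    log2 intensity = global mean + probe affinity + per-(gene, animal)
    effect + planted contrast effects + residual noise, exponentiated to
    the intensity scale.  The per-animal effect is shared by both
    hemispheres of an animal, so it cancels in intra-animal comparisons
    but contributes to cross-comparisons — the rationale for the study's
    intra-animal design.
    """
    manifest = default_manifest() if manifest is None else manifest.reset_index(drop=True)
    if probes_per_set < 3:
        raise ValueError("need at least 3 probes per set")
    planted = set(truth.hfs_down) | set(truth.lesion_up)
    if planted and (min(planted) < 0 or max(planted) >= n_probesets):
        raise ValueError("planted gene id outside the probe-set range")
    groups = manifest.groupby("group")["animal_id"].nunique()
    if (groups < 2).any():
        raise ValueError("manifest must cover >= 2 animals per group")

    rng = stage_rng(truth.seed, "expression")
    n_samples = len(manifest)
    animals = sorted(manifest["animal_id"].unique())
    animal_idx = manifest["animal_id"].map({a: i for i, a in enumerate(animals)}).to_numpy()

    affinity = rng.normal(0.0, truth.probe_affinity_sd, size=(n_probesets, probes_per_set))
    animal_eff = rng.normal(0.0, truth.animal_sd, size=(n_probesets, len(animals)))
    noise = rng.normal(0.0, truth.hemisphere_noise_sd, size=(n_probesets, probes_per_set, n_samples))

    log2 = (
        truth.global_mean_log2
        + affinity[:, :, None]
        + animal_eff[:, animal_idx][:, None, :]
        + noise
    )
    is_pd = (manifest["group"] == "PD").to_numpy()
    is_stim = (manifest["hemisphere"] == "stim").to_numpy()
    for gene in truth.lesion_up:
        log2[gene, :, is_pd] += truth.lesion_slr[gene]
    for gene in truth.hfs_down:
        log2[gene, :, is_pd & is_stim] += truth.hfs_slr[gene]

    intensities = np.maximum(np.power(2.0, log2), 1e-6)
    probe_set_ids = np.array([f"ps{g:06d}" for g in range(n_probesets)])
    return ExpressionDataset(intensities, probe_set_ids, manifest), truth


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------

@dataclass
class TrackTruth:
    """Scheduled rest/motion episodes of a synthetic open-field track.

    ``schedule`` holds (start_s, end_s, label) tuples tiling the recording
    without overlap; ``peak_speeds_cm_s`` gives the constant bout speed of
    each motion episode in schedule order.  ``realized_path_cm`` is filled
    by the generator with the exact per-bout path length it produced.
    """

    schedule: list[tuple[float, float, str]]
    peak_speeds_cm_s: list[float]
    arena_cm: tuple[float, float] = ARENA_CM
    rate_hz: float = TRACK_RATE_HZ
    rest_jitter_step_cm: float = 0.0
    seed: int = 0
    realized_path_cm: list[float] = field(default_factory=list)

    def __post_init__(self):
        last_end = 0.0
        for start, end, label in self.schedule:
            if start != last_end or end <= start or label not in ("rest", "motion"):
                raise ValueError("schedule must tile the recording without overlap")
            last_end = end
        n_motion = sum(1 for *_, lab in self.schedule if lab == "motion")
        if n_motion != len(self.peak_speeds_cm_s):
            raise ValueError("one peak speed per motion episode is required")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


def default_track_truth(
    n_bouts: int = 20,
    rest_s: float = 8.0,
    bout_s: float = 4.0,
    speed_modes_cm_s: tuple[float, float] = (8.0, 20.0),
    mode_log_sd: float = 0.15,
    rest_jitter_step_cm: float = 0.0,
    seed: int = 0,
) -> TrackTruth:
    """Alternating rest/motion schedule with bimodal bout peak speeds.

    Bout speeds are drawn lognormally around two modes (weak movement vs
    full motion), which makes the log max-SD distribution bimodal as in
    real open-field data.
    """
    rng = stage_rng(seed, "locomotion")
    schedule: list[tuple[float, float, str]] = []
    speeds: list[float] = []
    t = 0.0
    for i in range(n_bouts):
        schedule.append((t, t + rest_s, "rest"))
        t += rest_s
        schedule.append((t, t + bout_s, "motion"))
        t += bout_s
        mode = speed_modes_cm_s[i % 2]
        speeds.append(float(np.exp(np.log(mode) + mode_log_sd * rng.standard_normal())))
    schedule.append((t, t + rest_s, "rest"))
    return TrackTruth(
        schedule=schedule,
        peak_speeds_cm_s=speeds,
        rest_jitter_step_cm=rest_jitter_step_cm,
        seed=seed,
    )


def gen_locomotion_track(truth: TrackTruth) -> tuple[LocomotionTrack, TrackTruth]:
    """Piecewise trajectory realizing the scheduled episodes.

    Rest segments jitter with steps of at most ``rest_jitter_step_cm``
    (zero by default — stationary), keeping instantaneous speeds well
    below the 4 cm/s noise level; motion bouts run in a straight line at
    the scheduled constant speed, with the heading drawn among directions
    that keep the bout inside the arena.
    """
    rng = stage_rng(truth.seed, "locomotion")
    dt = 1.0 / truth.rate_hz
    if truth.rest_jitter_step_cm / dt >= 4.0:
        raise ValueError("rest jitter would exceed the motion noise level")
    w, hgt = truth.arena_cm
    diag = float(np.hypot(w, hgt))
    total_s = truth.schedule[-1][1]
    n = int(round(total_s * truth.rate_hz)) + 1
    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([w / 2.0, hgt / 2.0])
    x[0], y[0] = pos
    margin = 1.0
    realized: list[float] = []
    i = 1
    bout = 0
    for start_s, end_s, label in truth.schedule:
        n_steps = int(round(end_s * truth.rate_hz)) - int(round(start_s * truth.rate_hz))
        if label == "rest":
            for _ in range(n_steps):
                if i >= n:
                    break
                if truth.rest_jitter_step_cm > 0:
                    step = rng.uniform(-truth.rest_jitter_step_cm, truth.rest_jitter_step_cm, 2)
                    cand = np.clip(pos + step, margin, [w - margin, hgt - margin])
                    pos = cand
                x[i], y[i] = pos
                i += 1
        else:
            speed = truth.peak_speeds_cm_s[bout]
            step_len = speed * dt
            if step_len > min(w, hgt) - 2 * margin:
                raise ValueError("arena too small for the requested speed")

            def pick_heading(p):
                angles = rng.uniform(0, 2 * np.pi, 256)
                ends = p[None, :] + 8 * step_len * np.column_stack(
                    [np.cos(angles), np.sin(angles)]
                )
                ok = (
                    (ends[:, 0] > margin)
                    & (ends[:, 0] < w - margin)
                    & (ends[:, 1] > margin)
                    & (ends[:, 1] < hgt - margin)
                )
                if not ok.any():
                    # aim at the arena center
                    c = np.array([w / 2, hgt / 2]) - p
                    return float(np.arctan2(c[1], c[0]))
                return float(angles[np.nonzero(ok)[0][0]])

            ang = pick_heading(pos)
            step_vec = step_len * np.array([np.cos(ang), np.sin(ang)])
            path = 0.0
            for _ in range(n_steps):
                if i >= n:
                    break
                nxt = pos + step_vec
                if not (margin < nxt[0] < w - margin and margin < nxt[1] < hgt - margin):
                    ang = pick_heading(pos)  # turn at the wall, speed unchanged
                    step_vec = step_len * np.array([np.cos(ang), np.sin(ang)])
                    nxt = pos + step_vec
                pos = nxt
                x[i], y[i] = pos
                path += step_len
                i += 1
            realized.append(path)
            bout += 1
    time = np.arange(n) * dt
    truth.realized_path_cm = realized
    return LocomotionTrack(time=time, x=x[:i], y=y[:i]), truth


# ---------------------------------------------------------------------------
# field potentials
# ---------------------------------------------------------------------------

@dataclass
class SignalTruth:
    """Composition of synthetic field potentials.

    Channels are 1/f-shaped Gaussian noise plus a sinusoidal oscillation
    (per-channel amplitude) plus a 50 Hz line component.
    """

    fs_hz: float = SIGNAL_RATE_HZ
    duration_s: float = 60.0
    one_over_f_exponent: float = 1.0
    noise_scale: float = 1.0
    oscillation_hz: float = OSCILLATION_HZ
    oscillation_amplitude: float | list[float] = 1.0
    line_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        max_f = max(self.oscillation_hz, 50.0)
        if self.fs_hz <= 2 * max_f:
            raise ValueError("sampling rate must exceed twice the highest component")
        amps = (
            self.oscillation_amplitude
            if isinstance(self.oscillation_amplitude, list)
            else [self.oscillation_amplitude]
        )
        if any(a < 0 for a in amps) or self.line_amplitude < 0 or self.noise_scale < 0:
            raise ValueError("amplitudes must be non-negative")


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float, scale: float):
    """Gaussian noise with PSD proportional to f**-exponent."""
    white = rng.standard_normal(n)
    if scale == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms * scale if rms > 0 else shaped


def gen_field_potentials(truth: SignalTruth, n_channels: int = 2) -> tuple[SignalRecord, SignalTruth]:
    """Multichannel record per the truth composition (deterministic per seed)."""
    rng = stage_rng(truth.seed, "signals")
    n = int(round(truth.duration_s * truth.fs_hz))
    t = np.arange(n) / truth.fs_hz
    amps = truth.oscillation_amplitude
    if not isinstance(amps, list):
        amps = [amps] * n_channels
    if len(amps) != n_channels:
        raise ValueError("need one oscillation amplitude per channel")
    channels = {}
    for c in range(n_channels):
        noise = _one_over_f_noise(rng, n, truth.fs_hz, truth.one_over_f_exponent, truth.noise_scale)
        osc = amps[c] * np.sin(2 * np.pi * truth.oscillation_hz * t + rng.uniform(0, 2 * np.pi))
        line = truth.line_amplitude * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        channels[f"ch{c}"] = noise + osc + line
    return SignalRecord(channels=channels, fs_hz=truth.fs_hz), truth


# ---------------------------------------------------------------------------
# stereology
# ---------------------------------------------------------------------------

@dataclass
class StereoTruth:
    """True densities and sampling design of a synthetic count table."""

    density_per_roi: dict[str, float]  # cells/mm^3
    n_sections: int = 6
    sites_per_section: int = 100
    design: FractionatorDesign = field(default_factory=FractionatorDesign)
    roi_area_um2: float = 1.0e6
    seed: int = 0

    def __post_init__(self):
        if any(d < 0 for d in self.density_per_roi.values()):
            raise ValueError("densities must be >= 0")
        if self.sites_per_section < 1 or self.n_sections < 1:
            raise ValueError("need >= 1 site and section")


def gen_cell_sections(truth: StereoTruth) -> tuple[StereologySample, StereoTruth]:
    """Poisson dissector counts: mean = density x dissector volume per site."""
    rng = stage_rng(truth.seed, "stereology")
    vol_mm3 = (
        truth.design.frame_width_um
        * truth.design.frame_height_um
        * truth.design.dissector_height_um
        / 1e9
    )
    rows = []
    for roi, density in truth.density_per_roi.items():
        mean_per_site = density * vol_mm3
        for s in range(truth.n_sections):
            count = int(rng.poisson(mean_per_site * truth.sites_per_section))
            rows.append(
                {
                    "section_id": s,
                    "roi": roi,
                    "n_sites": truth.sites_per_section,
                    "count": count,
                    "area_um2": truth.roi_area_um2,
                }
            )
    return StereologySample(pd.DataFrame(rows), truth.design), truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def gen_qpcr_plate(
    true_slr: dict[str, float],
    ct_noise_sd: float = 0.1,
    replicates: int = 3,
    samples: tuple[str, ...] = ("r1", "r2", "r3"),
    conditions: tuple[str, str] = ("stim", "nonstim"),
    reference_gene: str = "Rpl13a",
    baseline_ct: float = 24.0,
    reference_ct: float = 18.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """CT plate with known fold changes.

    The first condition is the experiment: its target CT is lowered by the
    planted slr (one cycle per log2 unit, CT = baseline - slr + noise);
    the reference gene is constant up to noise.  Returns (table, truth).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if ct_noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = stage_rng(seed, "qpcr")
    experiment, baseline = conditions
    rows = []
    for gene, slr in true_slr.items():
        for sample in samples:
            for cond in conditions:
                shift = slr if cond == experiment else 0.0
                for rep in range(replicates):
                    rows.append(
                        {
                            "gene": gene,
                            "sample_id": sample,
                            "condition": cond,
                            "replicate": rep,
                            "ct": baseline_ct - shift + rng.normal(0, ct_noise_sd),
                        }
                    )
    for sample in samples:
        for cond in conditions:
            for rep in range(replicates):
                rows.append(
                    {
                        "gene": reference_gene,
                        "sample_id": sample,
                        "condition": cond,
                        "replicate": rep,
                        "ct": reference_ct + rng.normal(0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows), dict(true_slr)
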
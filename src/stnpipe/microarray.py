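"""Probe-level microarray preprocessing and per-comparison statistics.

The expression screen works at the probe level throughout: intensities are
quantile-normalized across chips, summarized per probe set by median
polish, and every pairwise chip comparison yields a ternary change call
(Increase / Decrease / No Change) from a paired test on per-probe log2
differences together with a signal-log ratio (slr, the base-2 log fold
change).  This mirrors open descriptions of the RMA/GCOS workflow; no
vendor bit-compatibility is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionDataset",
    "ChangeCall",
    "SignalLogRatio",
    "quantile_normalize",
    "median_polish_summarize",
    "scale_trimmed_mean",
    "change_call",
    "signal_log_ratio",
    "change_calls_and_slrs",
]

#: default per-comparison change-call decision threshold
DEFAULT_GAMMA = 0.0025
#: intensities are floored here before taking log2
INTENSITY_FLOOR = 1e-6

REQUIRED_MANIFEST_COLUMNS = ("sample_id", "animal_id", "group", "hemisphere")


@dataclass(frozen=True)
class ChangeCall:
    probe_set_id: str
    call: str  # "I" | "D" | "NC"
    p_value: float
    comparison: str = ""


@dataclass(frozen=True)
class SignalLogRatio:
    probe_set_id: str
    slr: float
    comparison: str = ""


class ExpressionDataset:
    """Probe-level intensities plus the sample manifest.

    ``intensities`` has shape ``(n_probesets, probes_per_set, n_samples)``
    on the linear (positive) intensity scale.  The manifest is a DataFrame
    with columns sample_id, animal_id, group (PD/control) and hemisphere
    (stim/nonstim), one row per sample, aligned with the sample axis.
    """

    def __init__(self, intensities: np.ndarray, probe_set_ids, manifest: pd.DataFrame):
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 3:
            raise ValueError("intensities must be (probesets, probes, samples)")
        if np.any(~np.isfinite(intensities)) or np.any(intensities <= 0):
            raise ValueError("intensities must be finite and positive")
        manifest = manifest.reset_index(drop=True)
        for col in REQUIRED_MANIFEST_COLUMNS:
            if col not in manifest.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if manifest["sample_id"].duplicated().any():
            dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in manifest")
        if len(manifest) != intensities.shape[2]:
            raise ValueError("manifest rows must match the sample axis")
        self.intensities = intensities
        self.probe_set_ids = np.asarray(probe_set_ids)
        if self.probe_set_ids.size != intensities.shape[0]:
            raise ValueError("probe_set_ids must match the probe-set axis")
        self.manifest = manifest

    @property
    def n_probesets(self) -> int:
        return self.intensities.shape[0]

    @property
    def probes_per_set(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.manifest["sample_id"])

    def sample_index(self, sample_id: str) -> int:
        idx = self.manifest.index[self.manifest["sample_id"] == sample_id]
        if len(idx) == 0:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return int(idx[0])

    def log2_matrix(self) -> np.ndarray:
        """Flattened probe-row x sample matrix of log2 intensities."""
        flat = self.intensities.reshape(-1, self.intensities.shape[2])
        return np.log2(np.maximum(flat, INTENSITY_FLOOR))

    # -- I/O ---------------------------------------------------------------
    def to_probe_table(self) -> pd.DataFrame:
        ns, npr, nsa = self.intensities.shape
        sets = np.repeat(self.probe_set_ids, npr * nsa)
        probes = np.tile(np.repeat(np.arange(npr), nsa), ns)
        samples = np.tile(np.asarray(self.sample_ids, dtype=object), ns * npr)
        return pd.DataFrame(
            {
                "probe_set_id": sets,
                "probe_index": probes,
                "sample_id": samples,
                "intensity": self.intensities.ravel(),
            }
        )

    def write(self, probe_tsv: str | Path, manifest_csv: str | Path) -> None:
        self.to_probe_table().to_csv(probe_tsv, sep="\t", index=False)
        self.manifest.to_csv(manifest_csv, index=False)

    @classmethod
    def read(cls, probe_tsv: str | Path, manifest_csv: str | Path) -> "ExpressionDataset":
        table = pd.read_csv(probe_tsv, sep="\t")
        manifest = pd.read_csv(manifest_csv)
        wide = table.pivot_table(
            index=["probe_set_id", "probe_index"],
            columns="sample_id",
            values="intensity",
            sort=False,
        )
        wide = wide[manifest["sample_id"]]
        set_ids = wide.index.get_level_values(0)
        probe_set_ids = list(dict.fromkeys(set_ids))
        counts = {pid: int((set_ids == pid).sum()) for pid in probe_set_ids}
        per_set = set(counts.values())
        if len(per_set) != 1:
            raise ValueError("probe count per probe set must be constant")
        npr = per_set.pop()
        arr = wide.to_numpy().reshape(len(probe_set_ids), npr, len(manifest))
        return cls(arr, probe_set_ids, manifest)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column to the mean empirical distribution.

    After normalization the sorted values of each column equal the
    across-column mean of sorted values; within-column ranks are preserved
    (ties map to the mean reference value of the tied positions).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    if np.any(~np.isfinite(matrix)):
        raise ValueError("missing or non-finite values are not supported")
    reference = np.sort(matrix, axis=0).mean(axis=1)
    n = matrix.shape[0]
    out = np.empty_like(matrix)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(matrix.shape[1]):
        ranks = sps.rankdata(matrix[:, j])  # average rank on ties
        out[:, j] = np.interp(ranks, positions, reference)
    return out


def normalize_dataset(dataset: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize a dataset across samples on the log2 scale."""
    log2 = dataset.log2_matrix()
    norm = quantile_normalize(log2)
    arr = np.power(2.0, norm).reshape(dataset.intensities.shape)
    return ExpressionDataset(arr, dataset.probe_set_ids, dataset.manifest)


def _median_polish(stack: np.ndarray, max_iter: int = 10, tol: float = 1e-8):
    """Tukey median polish over the last two axes of ``stack``.

    Accepts shape (..., rows, cols); returns (overall, row_eff, col_eff,
    residual).  Stops after ``max_iter`` full sweeps or when the residual
    row and column medians all fall below ``tol``.
    """
    residual = np.array(stack, dtype=float)
    if np.any(~np.isfinite(residual)):
        raise ValueError("matrix must be finite")
    lead = residual.shape[:-2]
    overall = np.zeros(lead)
    row_eff = np.zeros(lead + (residual.shape[-2],))
    col_eff = np.zeros(lead + (residual.shape[-1],))
    for _ in range(max_iter):
        rm = np.median(residual, axis=-1)
        residual -= rm[..., None]
        row_eff += rm
        delta = np.median(row_eff, axis=-1)
        row_eff -= delta[..., None]
        overall += delta

        cm = np.median(residual, axis=-2)
        residual -= cm[..., None, :]
        col_eff += cm
        delta = np.median(col_eff, axis=-1)
        col_eff -= delta[..., None]
        overall += delta

        r_gap = np.abs(np.median(residual, axis=-1)).max()
        c_gap = np.abs(np.median(residual, axis=-2)).max()
        if max(r_gap, c_gap) < tol:
            break
    return overall, row_eff, col_eff, residual


def median_polish_summarize(probe_matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-8) -> np.ndarray:
    """Per-sample signal (overall + column effect) of a probes x samples
    log2 matrix, via Tukey median polish."""
    probe_matrix = np.atleast_2d(np.asarray(probe_matrix, dtype=float))
    if probe_matrix.size == 0:
        raise ValueError("need at least one probe and one sample")
    overall, _, col_eff, _ = _median_polish(probe_matrix, max_iter=max_iter, tol=tol)
    return overall + col_eff


def scale_trimmed_mean(signals: np.ndarray, target: float = 300.0, trim_fraction: float = 0.02):
    """Scale intensity-scale signals so their trimmed mean hits ``target``.

    Returns ``(scaled, factor)`` where ``factor = target / trimmed_mean``
    with ``trim_fraction`` cut from each tail.
    """
    signals = np.asarray(signals, dtype=float)
    if np.any(signals <= 0):
        raise ValueError("signals must be positive")
    tm = sps.trim_mean(signals, trim_fraction)
    if tm == 0:
        raise ValueError("trimmed mean is zero")
    factor = target / tm
    return signals * factor, factor


# -- change calls ---------------------------------------------------------

@lru_cache(maxsize=32)
def _signed_rank_pmf(n: int) -> np.ndarray:
    """Counts of W+ (sum of positive-sign ranks) over all 2^n sign vectors."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=np.int64)
    counts[0] = 1
    for rank in range(1, n + 1):
        nxt = counts.copy()
        nxt[rank:] += counts[: max_w + 1 - rank]
        counts = nxt
    return counts


def _signed_rank_p_two_sided(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p (zeros dropped, midranks on ties)."""
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    pmf = _signed_rank_pmf(n)
    w_vals = np.arange(pmf.size, dtype=float)
    total = float(pmf.sum())
    lower = float(pmf[w_vals <= w_pos].sum())
    upper = float(pmf[w_vals >= w_pos].sum())
    return min(1.0, 2.0 * min(lower, upper) / total)


def _paired_t_p_two_sided(diffs: np.ndarray) -> float:
    n = diffs.size
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0 if mean == 0 else 0.0
    t = mean / (sd / np.sqrt(n))
    return float(2.0 * sps.t.sf(abs(t), df=n - 1))


def change_call(
    baseline: np.ndarray,
    experiment: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    method: str = "t",
    probe_set_id: str = "",
    comparison: str = "",
) -> ChangeCall:
    """Ternary change call from paired probe-level log2 differences.

    ``baseline`` and ``experiment`` are intensity-scale probe vectors
    paired by probe index.  A two-sided paired test (Student t by default,
    exact Wilcoxon signed rank with ``method="signed-rank"``) is applied to
    the per-probe log2 differences; the call is I when p < gamma with a
    positive median difference, D when p < gamma with a negative one, and
    NC otherwise.
    """
    baseline = np.asarray(baseline, dtype=float)
    experiment = np.asarray(experiment, dtype=float)
    if baseline.shape != experiment.shape:
        raise ValueError("baseline and experiment must have equal length")
    if baseline.size < 3:
        raise ValueError("need at least 3 probe pairs")
    if np.any(baseline <= 0) or np.any(experiment <= 0):
        raise ValueError("intensities must be positive")
    diffs = np.log2(experiment) - np.log2(baseline)
    if method == "t":
        p = _paired_t_p_two_sided(diffs)
    elif method == "signed-rank":
        p = _signed_rank_p_two_sided(diffs)
    else:
        raise ValueError(f"unknown change-call method {method!r}")
    med = float(np.median(diffs))
    if p < gamma and med > 0:
        call = "I"
    elif p < gamma and med < 0:
        call = "D"
    else:
        call = "NC"
    return ChangeCall(probe_set_id=probe_set_id, call=call, p_value=p, comparison=comparison)


def _tukey_biweight(values: np.ndarray, c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight location (median/MAD scaled)."""
    med = np.median(values)
    s = np.median(np.abs(values - med))
    u = (values - med) / (c * s + eps)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return float(np.sum(w * values) / np.sum(w))


def signal_log_ratio(
    baseline: np.ndarray,
    experiment: np.ndarray,
    method: str = "summary-diff",
    probe_set_id: str = "",
    comparison: str = "",
) -> SignalLogRatio:
    """Signal-log ratio (log2 fold change, experiment vs baseline).

    "summary-diff" takes the difference of median-polish summary signals of
    the two-column probe matrix; "probe-ratio" takes the Tukey biweight
    location of per-probe log2 ratios.
    """
    baseline = np.asarray(baseline, dtype=float)
    experiment = np.asarray(experiment, dtype=float)
    if baseline.shape != experiment.shape:
        raise ValueError("baseline and experiment must have equal length")
    if np.any(baseline <= 0) or np.any(experiment <= 0):
        raise ValueError("intensities must be positive")
    lb = np.log2(baseline)
    le = np.log2(experiment)
    if method == "summary-diff":
        signals = median_polish_summarize(np.column_stack([lb, le]))
        slr = float(signals[1] - signals[0])
    elif method == "probe-ratio":
        slr = _tukey_biweight(le - lb)
    else:
        raise ValueError(f"unknown slr method {method!r}")
    return SignalLogRatio(probe_set_id=probe_set_id, slr=slr, comparison=comparison)


# -- vectorized per-comparison screen ------------------------------------

def change_calls_and_slrs(
    dataset: ExpressionDataset,
    experiment_sample: str,
    baseline_sample: str,
    gamma: float = DEFAULT_GAMMA,
    method: str = "t",
    comparison: str = "",
) -> pd.DataFrame:
    """Calls and slrs for one chip comparison, over all probe sets at once.

    Vectorizes the paired test and the median-polish slr across the
    probe-set axis; returns a DataFrame (probe_set_id, call, p_value, slr).
    """
    bi = dataset.sample_index(baseline_sample)
    ei = dataset.sample_index(experiment_sample)
    lb = np.log2(np.maximum(dataset.intensities[:, :, bi], INTENSITY_FLOOR))
    le = np.log2(np.maximum(dataset.intensities[:, :, ei], INTENSITY_FLOOR))
    diffs = le - lb  # (n_sets, probes)
    n = diffs.shape[1]

    if method == "t":
        mean = diffs.mean(axis=1)
        sd = diffs.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
        p = np.where(sd == 0, np.where(mean == 0, 1.0, 0.0), p)
    elif method == "signed-rank":
        p = np.fromiter(
            (_signed_rank_p_two_sided(row) for row in diffs), dtype=float, count=diffs.shape[0]
        )
    else:
        raise ValueError(f"unknown change-call method {method!r}")

    med = np.median(diffs, axis=1)
    calls = np.where(p < gamma, np.where(med > 0, "I", "D"), "NC")
    calls = np.where((p < gamma) & (med == 0), "NC", calls)

    # summary-diff slr via stacked median polish on (n_sets, probes, 2)
    stack = np.stack([lb, le], axis=-1)
    overall, _, col_eff, _ = _median_polish(stack)
    slr = col_eff[:, 1] - col_eff[:, 0]

    return pd.DataFrame(
        {
            "probe_set_id": dataset.probe_set_ids,
            "call": calls,
            "p_value": p,
            "slr": slr,
            "comparison": comparison,
        }
    )
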
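"""Spectral analysis of ECoG / LFP recordings.

Signals sampled at 1 kHz are re-referenced (bipolar derivation), notch
filtered at 50 Hz, and reduced to Welch power spectral densities.  For
group statistics the PSD is normalized to the total power between 1 and
80 Hz and summed inside seven canonical frequency bands (delta 1-3, theta
4-7, alpha 8-12, low beta 13-24, high beta 25-35, low gamma 36-49, high
gamma 51-80 Hz; the 50 Hz line bin is excluded).  Band powers are compared
between groups with the exact Wilcoxon rank-sum test under a Bonferroni
threshold for the seven bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .stats import bonferroni_alpha, wilcoxon_rank_sum

__all__ = [
    "SignalRecord",
    "BandScheme",
    "SpectralResult",
    "bipolar_derive",
    "notch_50",
    "welch_psd",
    "normalize_psd",
    "frequency_weighted_tf",
    "band_relative_power",
    "compare_band_power",
]

DEFAULT_BANDS = (
    ("delta", 1, 3),
    ("theta", 4, 7),
    ("alpha", 8, 12),
    ("low_beta", 13, 24),
    ("high_beta", 25, 35),
    ("low_gamma", 36, 49),
    ("high_gamma", 51, 80),
)
LINE_FREQ_HZ = 50.0


@dataclass
class SignalRecord:
    """Multichannel field-potential record (equal-length channels)."""

    channels: dict[str, np.ndarray]
    fs_hz: float

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.channels).assign(fs_hz=self.fs_hz).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SignalRecord":
        tab = pd.read_csv(path)
        fs = float(tab.pop("fs_hz").iloc[0])
        return cls({c: tab[c].to_numpy(dtype=float) for c in tab.columns}, fs)


@dataclass(frozen=True)
class BandScheme:
    """Named, non-overlapping frequency bands with inclusive Hz edges."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self):
        edges = sorted((lo, hi, name) for name, lo, hi in self.bands)
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(edges, edges[1:]):
            if lo2 <= hi1:
                raise ValueError(f"bands {n1!r} and {n2!r} overlap")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.bands]


@dataclass
class SpectralResult:
    freqs: np.ndarray
    psd: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    band_power: dict[str, dict[str, float]] = field(default_factory=dict)


def bipolar_derive(ch_a: np.ndarray, ch_b: np.ndarray) -> np.ndarray:
    """Sample-wise difference a - b (rejects common-mode components)."""
    ch_a = np.asarray(ch_a, dtype=float)
    ch_b = np.asarray(ch_b, dtype=float)
    if ch_a.shape != ch_b.shape:
        raise ValueError("channels must have equal length")
    return ch_a - ch_b


def notch_50(signal: np.ndarray, fs: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at 50 Hz (forward-backward)."""
    if fs <= 2 * LINE_FREQ_HZ:
        raise ValueError("sampling rate must exceed twice the line frequency")
    b, a = spsig.iirnotch(LINE_FREQ_HZ, q, fs=fs)
    return spsig.filtfilt(b, a, np.asarray(signal, dtype=float))


def welch_psd(
    signal: np.ndarray,
    fs: float,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with ``segment_s``-second segments (default 2 s Hann,
    50% overlap -> 0.5 Hz resolution).  Returns (freqs, psd)."""
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(segment_s * fs))
    if signal.size < nperseg * (2 - overlap_frac):
        raise ValueError("signal too short for two Welch segments")
    noverlap = int(round(nperseg * overlap_frac))
    return spsig.welch(signal, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)


def normalize_psd(
    freqs: np.ndarray, psd: np.ndarray, lo: float = 1.0, hi: float = 80.0
) -> np.ndarray:
    """Scale the PSD so bins inside [lo, hi] Hz sum to 1."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    in_band = (freqs >= lo) & (freqs <= hi)
    total = psd[in_band].sum()
    if total <= 0:
        raise ValueError("no power inside the normalization band")
    return psd / total


def frequency_weighted_tf(
    freqs: np.ndarray, spectrogram: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted, column-normalized time-frequency display.

    Each cell is multiplied by its frequency, then every time column is
    normalized to unit sum, flattening an exact 1/f spectrum.  Returns
    (display, zero_column_flags); all-zero columns stay zero and are
    flagged.
    """
    freqs = np.asarray(freqs, dtype=float)
    spec = np.asarray(spectrogram, dtype=float)
    weighted = spec * freqs[:, None]
    sums = weighted.sum(axis=0)
    zero_cols = sums == 0
    safe = np.where(zero_cols, 1.0, sums)
    return weighted / safe[None, :], zero_cols


def band_relative_power(
    freqs: np.ndarray,
    normalized_psd: np.ndarray,
    scheme: BandScheme | None = None,
    exclude_line: bool = True,
) -> dict[str, float]:
    """Sum of normalized PSD bins inside each named band (inclusive edges
    mapped onto the discrete grid; the 50 Hz bin is excluded)."""
    scheme = scheme or BandScheme()
    freqs = np.asarray(freqs, dtype=float)
    npsd = np.asarray(normalized_psd, dtype=float)
    df = np.median(np.diff(freqs)) if freqs.size > 1 else 1.0
    out = {}
    for name, lo, hi in scheme.bands:
        sel = (freqs >= lo - df / 2) & (freqs <= hi + df / 2)
        if exclude_line:
            sel &= np.abs(freqs - LINE_FREQ_HZ) > df / 2
        out[name] = float(npsd[sel].sum())
    return out


def compare_band_power(
    group_a: list[dict[str, float]],
    group_b: list[dict[str, float]],
    family_alpha: float = 0.05,
    scheme: BandScheme | None = None,
) -> pd.DataFrame:
    """Per-band rank-sum comparison of two groups of band-power vectors.

    Returns a DataFrame (band, median_a, median_b, p, significant) with
    significance at the Bonferroni threshold family_alpha / n_bands.
    """
    scheme = scheme or BandScheme()
    if not group_a or not group_b:
        raise ValueError("both groups need at least one observation")
    alpha = bonferroni_alpha(family_alpha, len(scheme.names))
    rows = []
    for band in scheme.names:
        a = np.array([obs[band] for obs in group_a])
        b = np.array([obs[band] for obs in group_b])
        res = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "band": band,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "p": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)


def analyze_record(
    record: SignalRecord,
    scheme: BandScheme | None = None,
    segment_s: float = 2.0,
    notch: bool = True,
) -> SpectralResult:
    """Notch, Welch PSD, 1-80 Hz normalization and band powers for every
    channel of a record."""
    scheme = scheme or BandScheme()
    result = SpectralResult(freqs=np.array([]), psd={})
    for name, samples in record.channels.items():
        x = notch_50(samples, record.fs_hz) if notch else np.asarray(samples, float)
        freqs, psd = welch_psd(x, record.fs_hz, segment_s=segment_s)
        result.freqs = freqs
        result.psd[name] = psd
        npsd = normalize_psd(freqs, psd)
        result.normalized[name] = npsd
        result.band_power[name] = band_relative_power(freqs, npsd, scheme)
    return result
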
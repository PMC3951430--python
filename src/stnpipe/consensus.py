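"""Consensus differential-expression screen and counter-regulation.

The screen uses an intra-animal contrast: for each group, every animal's
stimulated hemisphere is compared with its own non-stimulated hemisphere
(intra-animal comparisons) and with the non-stimulated hemispheres of the
other animals (cross-comparisons).  With two animals per group this gives
four comparisons (2 intra + 2 cross).  A separate lesion contrast compares
the non-stimulated hemispheres of lesioned vs control animals.  A gene
enters the regulation list only when it shows the same change call in
enough comparisons and passes the slr gate in each of them; genes whose
stimulation effect opposes their lesion effect are flagged as
counter-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonPlan",
    "RegulationRecord",
    "CounterRegulationRecord",
    "build_hfs_comparisons",
    "build_lesion_comparisons",
    "summarize_comparisons",
    "consensus_filter",
    "detect_counter_regulation",
    "ease_score",
    "records_to_table",
]

DEFAULT_SLR_THRESHOLD = 0.6
EASE_P_FLOOR = 1e-300


@dataclass(frozen=True)
class ComparisonPlan:
    """Ordered chip comparisons for one contrast.

    ``pairs`` holds (experiment_sample, baseline_sample, kind) with kind
    "intra" (same animal) or "cross" (different animals / across groups).
    """

    pairs: tuple[tuple[str, str, str], ...]
    contrast: str  # "hfs_pd" | "hfs_control" | "lesion"

    @property
    def n_comparisons(self) -> int:
        return len(self.pairs)


@dataclass
class RegulationRecord:
    """Per-probe-set consensus summary: change-call counts and mean slr.

    ``mean_slr`` averages the slr over the counted (homonymously called)
    comparisons; it is NaN when the calls are absent or mixed in
    direction, so downstream tables render those entries as missing.
    """

    probe_set_id: str
    D_count: int
    I_count: int
    mean_slr: float
    included: bool
    contrast: str = ""


@dataclass
class CounterRegulationRecord:
    probe_set_id: str
    hfs_slr: float
    lesion_slr: float
    counter: bool


def _hemisphere_map(manifest: pd.DataFrame) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for _, row in manifest.iterrows():
        out.setdefault(row["animal_id"], {})[row["hemisphere"]] = row["sample_id"]
    return out


def build_hfs_comparisons(manifest: pd.DataFrame, group: str) -> ComparisonPlan:
    """Stimulated-vs-nonstimulated comparison plan for one group.

    For k animals this yields k intra-animal pairs plus k(k-1) cross pairs
    (every animal's stim chip against every other animal's nonstim chip);
    two animals give the study design of four comparisons.
    """
    sub = manifest[manifest["group"] == group]
    if sub.empty:
        raise ValueError(f"no samples for group {group!r}")
    hemis = _hemisphere_map(sub)
    for animal, sides in sorted(hemis.items()):
        for side in ("stim", "nonstim"):
            if side not in sides:
                raise ValueError(f"animal {animal!r} is missing the {side} hemisphere")
    animals = sorted(hemis)
    if len(animals) < 2:
        raise ValueError("need at least 2 animals for cross-comparisons")
    pairs = [(hemis[a]["stim"], hemis[a]["nonstim"], "intra") for a in animals]
    pairs += [
        (hemis[a]["stim"], hemis[b]["nonstim"], "cross")
        for a, b in permutations(animals, 2)
    ]
    label = "hfs_pd" if group == "PD" else "hfs_control"
    return ComparisonPlan(pairs=tuple(pairs), contrast=label)


def build_lesion_comparisons(manifest: pd.DataFrame) -> ComparisonPlan:
    """Lesion-effect plan: all PD-nonstim x control-nonstim chip pairs."""
    nonstim = manifest[manifest["hemisphere"] == "nonstim"]
    pd_chips = sorted(nonstim.loc[nonstim["group"] == "PD", "sample_id"])
    ctl_chips = sorted(nonstim.loc[nonstim["group"] == "control", "sample_id"])
    if not pd_chips or not ctl_chips:
        raise ValueError("both groups need at least one nonstim chip")
    pairs = tuple((p, c, "cross") for p, c in product(pd_chips, ctl_chips))
    return ComparisonPlan(pairs=pairs, contrast="lesion")


def _stack_comparisons(comparisons: list[pd.DataFrame]):
    ids = comparisons[0]["probe_set_id"].to_numpy()
    for tab in comparisons[1:]:
        if not np.array_equal(tab["probe_set_id"].to_numpy(), ids):
            raise ValueError("comparisons must cover the same probe sets in order")
    calls = np.stack([tab["call"].to_numpy() for tab in comparisons], axis=1)
    slrs = np.stack([tab["slr"].to_numpy(dtype=float) for tab in comparisons], axis=1)
    return ids, calls, slrs


def summarize_comparisons(
    comparisons: list[pd.DataFrame], contrast: str = ""
) -> list[RegulationRecord]:
    """One RegulationRecord per probe set (no inclusion rule applied).

    The mean slr is taken over the comparisons carrying the dominant call
    direction, and is NaN for probe sets with no calls or with calls in
    both directions.
    """
    ids, calls, slrs = _stack_comparisons(comparisons)
    d_counts = (calls == "D").sum(axis=1)
    i_counts = (calls == "I").sum(axis=1)
    records = []
    for i in range(ids.size):
        d, ic = int(d_counts[i]), int(i_counts[i])
        if d > 0 and ic == 0:
            mean = float(slrs[i, calls[i] == "D"].mean())
        elif ic > 0 and d == 0:
            mean = float(slrs[i, calls[i] == "I"].mean())
        else:
            mean = float("nan")
        records.append(
            RegulationRecord(
                probe_set_id=str(ids[i]),
                D_count=d,
                I_count=ic,
                mean_slr=mean,
                included=False,
                contrast=contrast,
            )
        )
    return records


def consensus_filter(
    comparisons: list[pd.DataFrame],
    required_count: int,
    slr_threshold: float = DEFAULT_SLR_THRESHOLD,
    contrast: str = "",
) -> list[RegulationRecord]:
    """Apply the homonymous-call + slr-gate consensus rule.

    ``comparisons`` are per-comparison call/slr tables over the same probe
    sets (columns probe_set_id, call, slr).  A probe set is included iff it
    collects at least ``required_count`` I calls or D calls and every one
    of those counted comparisons has |slr| >= ``slr_threshold``.  Only
    included records are returned, sorted by |mean_slr| descending.
    """
    if required_count > len(comparisons):
        raise ValueError("required_count exceeds the number of comparisons")
    ids, calls, slrs = _stack_comparisons(comparisons)
    out: list[RegulationRecord] = []
    for direction in ("D", "I"):
        mask = calls == direction
        counts = mask.sum(axis=1)
        gate = np.all(np.where(mask, np.abs(slrs) >= slr_threshold, True), axis=1)
        keep = (counts >= required_count) & gate
        for i in np.nonzero(keep)[0]:
            out.append(
                RegulationRecord(
                    probe_set_id=str(ids[i]),
                    D_count=int((calls[i] == "D").sum()),
                    I_count=int((calls[i] == "I").sum()),
                    mean_slr=float(slrs[i, mask[i]].mean()),
                    included=True,
                    contrast=contrast,
                )
            )
    out.sort(key=lambda r: abs(r.mean_slr), reverse=True)
    return out


def detect_counter_regulation(
    hfs_records: list[RegulationRecord],
    lesion_records: list[RegulationRecord],
    lesion_min_count: int = 3,
) -> list[CounterRegulationRecord]:
    """Flag genes whose stimulation effect opposes their lesion effect.

    A gene from the stimulation (HFS) regulation list is counter-regulated
    when the lesion contrast shows homonymous change calls in at least
    ``lesion_min_count`` comparisons with the opposite slr sign.  Probe
    sets present in the HFS list but absent from the lesion records are
    reported with a clear (False) flag.  Output is sorted by probe set id,
    so it does not depend on input list order.
    """
    lesion_by_id = {r.probe_set_id: r for r in lesion_records}
    out: list[CounterRegulationRecord] = []
    for rec in sorted(hfs_records, key=lambda r: r.probe_set_id):
        les = lesion_by_id.get(rec.probe_set_id)
        if les is None:
            out.append(
                CounterRegulationRecord(rec.probe_set_id, rec.mean_slr, float("nan"), False)
            )
            continue
        homonymous = max(les.D_count, les.I_count)
        counter = (
            homonymous >= lesion_min_count
            and min(les.D_count, les.I_count) == 0
            and np.isfinite(les.mean_slr)
            and np.isfinite(rec.mean_slr)
            and rec.mean_slr != 0
            and np.sign(les.mean_slr) == -np.sign(rec.mean_slr)
        )
        out.append(
            CounterRegulationRecord(rec.probe_set_id, rec.mean_slr, les.mean_slr, bool(counter))
        )
    return out


def ease_score(list_hits: int, list_size: int, population_hits: int, population_size: int) -> float:
    """EASE enrichment score: -log10 of the jackknifed hypergeometric p.

    The one-tailed overrepresentation p-value is the hypergeometric upper
    tail evaluated at ``max(k - 1, 0)`` hits (the EASE jackknife, which
    discounts single-gene support); the score is its minus decadic log,
    with p clamped to [1e-300, 1].
    """
    k, n, K, N = list_hits, list_size, population_hits, population_size
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError("inconsistent enrichment counts")
    k_eff = max(k - 1, 0)
    # P(X >= k_eff) for X ~ Hypergeom(N, K, n)
    p = float(sps.hypergeom.sf(k_eff - 1, N, K, n))
    p = min(1.0, max(p, EASE_P_FLOOR))
    return float(-np.log10(p))


def records_to_table(
    hfs_records: list[RegulationRecord],
    counter_records: list[CounterRegulationRecord] | None = None,
) -> pd.DataFrame:
    """Regulation-list table (probe_set_id, contrast, D/I counts, mean slr,
    counter flag) in the conventional regulation-list layout."""
    counter = {c.probe_set_id: c.counter for c in (counter_records or [])}
    return pd.DataFrame(
        {
            "probe_set_id": [r.probe_set_id for r in hfs_records],
            "contrast": [r.contrast for r in hfs_records],
            "D_count": [r.D_count for r in hfs_records],
            "I_count": [r.I_count for r in hfs_records],
            "mean_slr": [r.mean_slr for r in hfs_records],
            "counter_flag": [counter.get(r.probe_set_id, False) for r in hfs_records],
        }
    )
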
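"""Validation assays: qPCR relative quantification and blot densitometry.

Quantitative PCR cycle-threshold (CT) plates are reduced with the
delta-delta-CT method: per condition, the mean target CT is normalized to
the housekeeping reference gene (dCT), the experiment dCT is referenced
to the baseline condition (ddCT), and the signal-log ratio is its
negative — one PCR cycle corresponds to one log2 unit of expression.
Western-blot band densities become slrs the same way after loading-control
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bonferroni_alpha, wilcoxon_rank_sum

__all__ = ["delta_delta_ct", "delta_delta_ct_table", "densitometric_slr"]

CT_COLUMNS = ("gene", "sample_id", "condition", "replicate", "ct")
DENS_COLUMNS = ("protein", "sample_id", "condition", "band_density", "control_density")


def _validate_ct_table(table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"CT table missing columns {sorted(missing)}")
    ct = table["ct"]
    if (~np.isfinite(ct)).any() or (ct <= 0).any():
        raise ValueError("CT values must be finite and positive")


def _mean_ct(table: pd.DataFrame, gene: str, sample: str, condition: str, agg: str) -> float:
    sel = table[
        (table["gene"] == gene)
        & (table["sample_id"] == sample)
        & (table["condition"] == condition)
    ]
    if sel.empty:
        raise ValueError(f"no CT rows for gene={gene!r} sample={sample!r} condition={condition!r}")
    return float(sel["ct"].median() if agg == "median" else sel["ct"].mean())


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    experiment_condition: str,
    baseline_condition: str,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Per-sample slr of a target gene via the delta-delta-CT method.

    For each sample: dCT = mean CT(target) - mean CT(reference) per
    condition; ddCT = dCT(experiment) - dCT(baseline); slr = -ddCT (one
    cycle equals one log2 unit, so the slr is the log2 fold change).
    Returns a DataFrame (sample_id, delta_ct_experiment,
    delta_ct_baseline, ddct, slr).
    """
    _validate_ct_table(ct_table)
    rows = []
    samples = sorted(ct_table.loc[ct_table["gene"] == target_gene, "sample_id"].unique())
    if not samples:
        raise ValueError(f"target gene {target_gene!r} not present in the table")
    for sample in samples:
        dcts = {}
        for cond in (experiment_condition, baseline_condition):
            t = _mean_ct(ct_table, target_gene, sample, cond, aggregate)
            r = _mean_ct(ct_table, reference_gene, sample, cond, aggregate)
            dcts[cond] = t - r
        ddct = dcts[experiment_condition] - dcts[baseline_condition]
        rows.append(
            {
                "sample_id": sample,
                "delta_ct_experiment": dcts[experiment_condition],
                "delta_ct_baseline": dcts[baseline_condition],
                "ddct": ddct,
                "slr": -ddct,
            }
        )
    return pd.DataFrame(rows)


def delta_delta_ct_table(
    ct_table: pd.DataFrame,
    genes: list[str],
    reference_gene: str,
    experiment_condition: str,
    baseline_condition: str,
    group_by: pd.Series | None = None,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Group summary over several target genes with a Bonferroni threshold.

    Each gene's per-sample slrs are compared between the two levels of
    ``group_by`` (sample_id -> group label) with the rank-sum test; the
    significance threshold is ``family_alpha`` divided by the number of
    genes.  Without ``group_by`` only mean slrs are reported.
    """
    alpha = bonferroni_alpha(family_alpha, len(genes))
    rows = []
    for gene in genes:
        per_sample = delta_delta_ct(
            ct_table, gene, reference_gene, experiment_condition, baseline_condition
        )
        row = {"gene": gene, "mean_slr": float(per_sample["slr"].mean()), "n": len(per_sample)}
        if group_by is not None:
            labels = per_sample["sample_id"].map(group_by)
            levels = sorted(labels.dropna().unique())
            if len(levels) == 2:
                a = per_sample.loc[labels == levels[0], "slr"].to_numpy()
                b = per_sample.loc[labels == levels[1], "slr"].to_numpy()
                res = wilcoxon_rank_sum(a, b)
                row.update(p=res.p_value, significant=res.p_value < alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def densitometric_slr(
    dens_table: pd.DataFrame,
    protein: str,
    experiment_condition: str,
    baseline_condition: str,
) -> pd.DataFrame:
    """Per-sample slr from densitometric band quantification.

    slr = log2 of the loading-control-normalized band density in the
    experiment condition over the baseline condition; invariant to
    lane-wide exposure scaling because the control divides out.
    """
    missing = set(DENS_COLUMNS) - set(dens_table.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns {sorted(missing)}")
    sub = dens_table[dens_table["protein"] == protein]
    if sub.empty:
        raise ValueError(f"protein {protein!r} not present in the table")
    if (sub["control_density"] <= 0).any():
        raise ValueError("loading-control densities must be positive")
    rows = []
    for sample in sorted(sub["sample_id"].unique()):
        ratios = {}
        for cond in (experiment_condition, baseline_condition):
            lane = sub[(sub["sample_id"] == sample) & (sub["condition"] == cond)]
            if lane.empty:
                raise ValueError(f"sample {sample!r} missing condition {cond!r}")
            ratios[cond] = float(lane["band_density"].iloc[0] / lane["control_density"].iloc[0])
        if ratios[baseline_condition] <= 0 or ratios[experiment_condition] <= 0:
            raise ValueError(f"nonpositive normalized density for sample {sample!r}")
        rows.append(
            {
                "sample_id": sample,
                "slr": float(np.log2(ratios[experiment_condition] / ratios[baseline_condition])),
            }
        )
    return pd.DataFrame(rows)
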
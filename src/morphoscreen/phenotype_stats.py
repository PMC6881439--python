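"""Quantitative readouts of the knockdown experiments.

Phenotype tabulation (ordinal P1..P4 grades plus deaths), maximum
fluorescence intensity extraction from a masked image, one-way ANOVA with
Tukey's multiple-comparison test (significance tiers *, **, ***, ****),
and ΔΔCt knockdown efficiency from qPCR Ct pairs.

Input tables are pandas DataFrames with the documented columns (they are
read and written as TSV by io_formats):

phenotypes: larva_id, group, score, timepoint_hpf
mfi:        larva_id, group, mfi
qpcr:       sample_id, group, gene, ct_target, ct_reference
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SCORE_LEVELS = ("P1", "P2", "P3", "P4", "dead")

# significance tiers: *p ≤ 0.05, **p ≤ 0.01, ***p ≤ 0.001, ****p ≤ 0.0001
_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for cutoff, stars in _TIERS:
        if p <= cutoff:
            return stars
    return "n.s."


def tabulate_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-group counts and proportions of each phenotype grade.

    Returns one row per group with n, count_<score> and prop_<score>
    columns; proportions sum to 1 within each group. An unknown score
    token raises ValueError naming the offending row.
    """
    if len(phenotypes) == 0:
        raise ValueError("phenotype table is empty")
    bad = ~phenotypes["score"].isin(SCORE_LEVELS)
    if bad.any():
        row = phenotypes[bad].iloc[0]
        raise ValueError(
            f"unknown score {row['score']!r} for larva {row['larva_id']!r}"
        )
    rows = []
    for group, sub in phenotypes.groupby("group", sort=False):
        n = len(sub)
        counts = sub["score"].value_counts()
        row: dict[str, object] = {"group": group, "n": n}
        for s in SCORE_LEVELS:
            c = int(counts.get(s, 0))
            row[f"count_{s}"] = c
            row[f"prop_{s}"] = c / n
        rows.append(row)
    return pd.DataFrame(rows)


def max_fluorescence_intensity(image: np.ndarray, roi: np.ndarray) -> float:
    """Maximum grayscale value inside the region-of-interest mask (AU)."""
    image = np.asarray(image)
    roi = np.asarray(roi, dtype=bool)
    if image.shape != roi.shape:
        raise ValueError(f"image {image.shape} and mask {roi.shape} shapes differ")
    if not roi.any():
        raise ValueError("empty ROI mask")
    return float(image[roi].max())


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ss_total: float
    ms_within: float


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    return arrays


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA via the between/within sum-of-squares
    decomposition; p from the F distribution."""
    arrays = _as_groups(groups)
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    ss_total = ((all_values - grand) ** 2).sum()
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = 0.0 if ms_between == 0 else float("inf")
    else:
        f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        ms_within=float(ms_within),
    )


@dataclass
class TukeyResult:
    pair: tuple[str, str]
    mean_difference: float
    q_statistic: float
    adjusted_p: float
    tier: str


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[TukeyResult]:
    """Tukey's multiple-comparison test on all group pairs.

    q = |mean_i − mean_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)) (the
    Tukey–Kramer statistic for unequal n); the adjusted p is the survival
    function of the studentized range distribution with k groups and the
    ANOVA within-group degrees of freedom.
    """
    arrays = _as_groups(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels and groups length mismatch")
    anova = anova_oneway(groups)
    k = len(arrays)
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = arrays[i], arrays[j]
            diff = gi.mean() - gj.mean()
            se = np.sqrt(anova.ms_within / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
            if se == 0:
                q = 0.0 if diff == 0 else float("inf")
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, anova.df_within))
            p = min(max(p, 0.0), 1.0)
            results.append(
                TukeyResult(
                    pair=(labels[i], labels[j]),
                    mean_difference=float(diff),
                    q_statistic=float(q),
                    adjusted_p=p,
                    tier=significance_tier(p),
                )
            )
    return results


def tukey_table(results: list[TukeyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.pair[0],
                "group_b": r.pair[1],
                "mean_difference": r.mean_difference,
                "q_statistic": r.q_statistic,
                "adjusted_p": r.adjusted_p,
                "tier": r.tier,
            }
            for r in results
        ]
    )


def knockdown_efficiency(qpcr: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-(group, gene) fold change and knockdown efficiency by ΔΔCt.

    ΔCt = ct_target − ct_reference per sample; ΔΔCt is the knockdown
    group's mean ΔCt minus the control group's mean ΔCt for the same
    gene; fold change = 2^(−ΔΔCt); efficiency % = (1 − fold change)·100.
    Assumes equal amplification efficiencies for target and housekeeper.
    """
    if control_group not in set(qpcr["group"]):
        raise ValueError(f"control group {control_group!r} not in qPCR table")
    df = qpcr.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    control = df[df["group"] == control_group].groupby("gene")["delta_ct"].mean()
    rows = []
    for (group, gene), sub in df[df["group"] != control_group].groupby(
        ["group", "gene"], sort=False
    ):
        if gene not in control.index:
            raise ValueError(
                f"control group has no measurements for gene {gene!r}"
            )
        ddct = sub["delta_ct"].mean() - control[gene]
        fold = 2.0 ** (-ddct)
        rows.append(
            {
                "group": group,
                "gene": gene,
                "delta_delta_ct": ddct,
                "fold_change": fold,
                "efficiency_pct": (1.0 - fold) * 100.0,
            }
        )
    return pd.DataFrame(rows)


def mfi_anova(
    mfi: pd.DataFrame, groups: Sequence[str] | None = None
) -> tuple[AnovaResult, list[TukeyResult]]:
    """One-way ANOVA + Tukey over per-larva MFI values by group."""
    if groups is None:
        groups = list(dict.fromkeys(mfi["group"]))
    samples = [mfi.loc[mfi["group"] == g, "mfi"].to_numpy() for g in groups]
    return anova_oneway(samples), tukey_hsd(samples, labels=list(groups))
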
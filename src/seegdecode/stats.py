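"""Significance testing and reporting of decoding results.

Per grid cell, participant-average AUCs are tested against the 0.5 chance
level with a two-sided one-sample t-test, Bonferroni-corrected over the
number of evaluated cells (66 in the full task x band x components design).
A paired Wilcoxon signed-rank test compares conditions (e.g. decoding with
vs. without motor contacts). The contribution map attributes the first
principal component to channels: |loading| scaled by the component's
explained-variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import FoldTransform

#: full evaluation design: 2 tasks x 3 bands x 11 component counts
N_COMPARISONS_DEFAULT = 66


@dataclass
class SignificanceRow:
    mean_auc: float
    sd_auc: float
    t_statistic: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    n: int


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p_raw * n_comparisons)


def test_vs_chance(per_participant_mean_aucs: np.ndarray,
                   n_comparisons: int = N_COMPARISONS_DEFAULT,
                   alpha: float = 0.05) -> SignificanceRow:
    """Two-sided one-sample t-test of participant mean AUCs against 0.5.

    Zero variance with mean exactly 0.5 gives t = 0, p = 1; zero variance
    off 0.5 is reported as p = 0 (a degenerate certainty, flagged by t=inf).
    """
    x = np.asarray(per_participant_mean_aucs, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 participants")
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0:
        if mean == 0.5:
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat = np.inf if mean > 0.5 else -np.inf
            p_raw = 0.0
    else:
        t_stat, p_raw = sps.ttest_1samp(x, 0.5)
    p_corr = bonferroni(float(p_raw), n_comparisons)
    return SignificanceRow(
        mean_auc=float(mean),
        sd_auc=float(sd),
        t_statistic=float(t_stat),
        p_raw=float(p_raw),
        p_bonferroni=p_corr,
        significant=bool(p_corr < alpha),
        n=int(x.size),
    )


def compare_paired(auc_with: np.ndarray, auc_without: np.ndarray,
                   n_comparisons: int = N_COMPARISONS_DEFAULT
                   ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired AUC differences.

    Exact null distribution for n <= 25 (no ties/zeros), normal approximation
    with continuity correction otherwise. Returns (statistic,
    Bonferroni-corrected p). All-zero differences give p = 1.
    """
    a = np.asarray(auc_with, dtype=float)
    b = np.asarray(auc_without, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized vectors of length >= 2")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    n = a.size
    has_zeros = np.any(diff == 0)
    has_ties = len(np.unique(np.abs(diff[diff != 0]))) < np.count_nonzero(diff)
    if n <= 25 and not has_zeros and not has_ties:
        res = sps.wilcoxon(a, b, method="exact")
    else:
        res = sps.wilcoxon(a, b, method="approx", correction=True)
    return float(res.statistic), bonferroni(float(res.pvalue), n_comparisons)


def pc_contribution_map(t: FoldTransform, squared: bool = False) -> np.ndarray:
    """Per-channel contribution to the first principal component.

    |loading| (or loading^2) of each channel on component 1, scaled by that
    component's explained-variance ratio. Nonnegative; normalize by the max
    for a [0, 1] map.
    """
    if t.pca_components.size == 0:
        raise ValueError("transform has no fitted components")
    w = t.pca_components[0]
    evr = float(t.explained_variance_ratio[0])
    base = w ** 2 if squared else np.abs(w)
    return base * evr


def summarize(results: pd.DataFrame,
              n_comparisons: int | None = None,
              alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate a long-format fold-level grid into per-cell statistics.

    For each (task, band, n_components): mean and SD over participants of the
    participant-average AUC, plus t-test significance when at least two
    participants are present (otherwise the significance columns are NaN).
    """
    if results.empty:
        raise ValueError("empty results")
    per_part = (results
                .groupby(["task", "band", "n_components", "participant"])["auc"]
                .mean()
                .reset_index())
    cells = per_part.groupby(["task", "band", "n_components"])
    if n_comparisons is None:
        n_comparisons = max(1, cells.ngroups)
    rows = []
    for (task, band, n_comp), grp in cells:
        aucs = grp["auc"].to_numpy()
        row = {
            "task": task, "band": band, "n_components": n_comp,
            "n_participants": len(aucs),
            "mean_auc": aucs.mean(),
            "sd_auc": aucs.std(ddof=1) if len(aucs) > 1 else np.nan,
        }
        if len(aucs) >= 2:
            sig = test_vs_chance(aucs, n_comparisons=n_comparisons, alpha=alpha)
            row.update(t_statistic=sig.t_statistic, p_raw=sig.p_raw,
                       p_bonferroni=sig.p_bonferroni, significant=sig.significant)
        else:
            row.update(t_statistic=np.nan, p_raw=np.nan,
                       p_bonferroni=np.nan, significant=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_component_curves(summary: pd.DataFrame, path: str) -> None:
    """Mean AUC vs component count per task (rows) and band (columns).

    Shaded band = SD over participants; dotted line = 0.5 chance level.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tasks = sorted(summary["task"].unique())
    bands = sorted(summary["band"].unique())
    fig, axes = plt.subplots(len(tasks), len(bands),
                             figsize=(4 * len(bands), 3 * len(tasks)),
                             squeeze=False)
    for i, task in enumerate(tasks):
        for j, band in enumerate(bands):
            ax = axes[i][j]
            cell = summary[(summary["task"] == task)
                           & (summary["band"] == band)].sort_values("n_components")
            x = cell["n_components"]
            m = cell["mean_auc"]
            s = cell["sd_auc"].fillna(0)
            ax.fill_between(x, m - s, m + s, alpha=0.25, color="grey")
            ax.plot(x, m, "o-", color="black")
            ax.axhline(0.5, ls=":", color="grey")
            ax.set_title(f"{task} / {band}")
            ax.set_xlabel("components")
            ax.set_ylabel("AUC")
            ax.set_ylim(0.2, 1.0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
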
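"""Aggregation of grid results into the benchmark's summary artifacts.

Three views of the (subject x channel x feature x classifier) result grid:

* ``feature_classifier_table`` — mean +/- SD accuracy (and AUC) per
  feature x classifier combination, averaged over all subjects and channels,
  with row/column marginals.  The convention throughout is the sample SD
  (n - 1 denominator) over the (subject, channel) cells.
* ``best_combination_per_subject`` — the argmax-accuracy cell per subject,
  with deterministic tie-breaking (higher AUC, then lexicographic channel,
  feature, classifier) and a ``no_signal`` flag when even the best accuracy
  stays under 0.6 (the null-data band).
* ``rank_channels`` / ``ranking_table`` — channels (or any other axis)
  ordered by mean accuracy for a fixed feature + classifier.

Accuracies are reported as percentages with one decimal in the formatted
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import RESULT_COLUMNS

#: best-accuracy threshold under which a subject is flagged as "no signal"
NO_SIGNAL_ACC = 0.6

_AXES = ("channel", "classifier", "feature", "subject")


def _check_results(results: pd.DataFrame) -> None:
    missing = set(RESULT_COLUMNS[:4]) | {"acc", "auc"}
    missing -= set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns {sorted(missing)}")
    if len(results) == 0:
        raise ValueError("empty results table")


@dataclass
class SummaryTables:
    """Feature x classifier aggregate tables (accuracy in %, AUC in [0,1])."""

    acc_mean: pd.DataFrame
    acc_sd: pd.DataFrame
    auc_mean: pd.DataFrame
    auc_sd: pd.DataFrame


def feature_classifier_table(results: pd.DataFrame) -> SummaryTables:
    """Mean +/- sample SD of accuracy (%) and AUC per feature x classifier.

    Each cell averages over all (subject, channel) cells of the grid; a
    ``Mean`` row and column hold the marginals (the grand corner cell is the
    overall mean).  Combinations absent from the results appear as NaN, never
    silently dropped.
    """
    _check_results(results)
    acc_pct = results.assign(acc_pct=results["acc"] * 100.0)
    piv_mean = acc_pct.pivot_table(index="classifier", columns="feature",
                                   values="acc_pct", aggfunc="mean", dropna=False)
    piv_sd = acc_pct.pivot_table(index="classifier", columns="feature",
                                 values="acc_pct", aggfunc=lambda v: v.std(ddof=1),
                                 dropna=False)
    auc_mean = results.pivot_table(index="classifier", columns="feature",
                                   values="auc", aggfunc="mean", dropna=False)
    auc_sd = results.pivot_table(index="classifier", columns="feature",
                                 values="auc", aggfunc=lambda v: v.std(ddof=1),
                                 dropna=False)

    def _with_marginals(mean_tbl, raw, value_col, scale):
        tbl = mean_tbl.copy()
        tbl["Mean"] = raw.groupby("classifier")[value_col].mean() * scale
        bottom = raw.groupby("feature")[value_col].mean() * scale
        bottom["Mean"] = raw[value_col].mean() * scale
        tbl.loc["Mean"] = bottom
        return tbl

    acc_mean = _with_marginals(piv_mean, results, "acc", 100.0)
    auc_mean_m = _with_marginals(auc_mean, results, "auc", 1.0)
    return SummaryTables(acc_mean=acc_mean, acc_sd=piv_sd,
                         auc_mean=auc_mean_m, auc_sd=auc_sd)


def format_mean_sd(mean: pd.DataFrame, sd: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Render paired mean/SD tables as '91.8 ± 2.7' strings."""
    out = mean.loc[sd.index, sd.columns].round(decimals).astype(str)
    return out + " ± " + sd.round(decimals).astype(str)


def best_combination_per_subject(results: pd.DataFrame) -> pd.DataFrame:
    """Per-subject best (channel, feature, classifier) cell by accuracy.

    Ties are broken by higher AUC, then lexicographically by (channel,
    feature, classifier).  ``no_signal`` marks subjects whose best accuracy
    stays below 0.6, the level indistinguishable from label-free data.
    """
    _check_results(results)
    ordered = results.sort_values(
        by=["subject", "acc", "auc", "channel", "feature", "classifier"],
        ascending=[True, False, False, True, True, True], kind="mergesort")
    best = ordered.groupby("subject", sort=True).head(1).copy()
    best = best[["subject", "channel", "feature", "classifier", "acc", "auc"]]
    best["no_signal"] = best["acc"] < NO_SIGNAL_ACC
    return best.reset_index(drop=True)


def ranking_table(results: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Mean-accuracy ranking of the keys of one grid axis.

    Rows are sorted by mean accuracy descending (sample-SD columns expose
    how unstable the ordering is); ties break on mean AUC, then on the key
    itself, so the order is deterministic.
    """
    _check_results(results)
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}")
    grouped = results.groupby(axis)
    table = pd.DataFrame({
        "mean_acc": grouped["acc"].mean(),
        "sd_acc": grouped["acc"].std(ddof=1),
        "mean_auc": grouped["auc"].mean(),
        "sd_auc": grouped["auc"].std(ddof=1),
        "n_cells": grouped.size(),
    })
    table = table.reset_index().rename(columns={axis: "key"})
    table = table.sort_values(by=["mean_acc", "mean_auc", "key"],
                              ascending=[False, False, True], kind="mergesort")
    return table.reset_index(drop=True)


def rank_channels(results: pd.DataFrame, feature: str, classifier: str) -> pd.DataFrame:
    """Channel ranking for a fixed (feature, classifier) combination."""
    _check_results(results)
    subset = results[(results["feature"] == feature)
                     & (results["classifier"] == classifier)]
    if len(subset) == 0:
        raise ValueError(f"no results for feature={feature!r}, classifier={classifier!r}")
    return ranking_table(subset, "channel")


def global_best(results: pd.DataFrame) -> pd.Series:
    """The single best (subject, channel, feature, classifier) cell."""
    _check_results(results)
    ordered = results.sort_values(
        by=["acc", "auc", "channel", "feature", "classifier"],
        ascending=[False, False, True, True, True], kind="mergesort")
    return ordered.iloc[0]


def plot_channel_ranking(table: pd.DataFrame, path) -> None:
    """Bar plot of a channel ranking (accuracy % left axis, AUC right axis)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(max(6, 0.3 * len(table)), 4))
    x = np.arange(len(table))
    ax1.bar(x, table["mean_acc"] * 100.0, color="tab:blue", alpha=0.7)
    ax1.set_ylabel("accuracy (%)", color="tab:blue")
    ax1.set_xticks(x)
    ax1.set_xticklabels(table["key"], rotation=90, fontsize=7)
    ax2 = ax1.twinx()
    ax2.plot(x, table["mean_auc"], color="tab:red", marker="o", markersize=3, lw=1)
    ax2.set_ylabel("AUC", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
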
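"""Static-threshold calibration, decile binning and the nonparametric test battery.

The analysis proceeds in three layers, all of which are used:

1. events are binned into equal-occupancy groups by MMFI (or MMFI ratio, or
   size) *independently per cell*, compensating for expression differences;
2. hypothesis tests run on bins *pooled across cells by bin index*
   (Kruskal–Wallis with Dunn's post-test, Bonferroni-adjusted) and on full
   scatters (Mann–Whitney, Spearman with a Fisher-z confidence interval);
3. plots/report aggregates are the mean ± SEM of *per-cell bin medians*.

Every event is classified static or motile against a speed threshold
calibrated as the maximum event speed observed in a fixed (immobilised)
sample — by construction 100% of the calibration sample is then static —
or a default of 0.05 µm/s when no calibration data are supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_STATIC_THRESHOLD = 0.05  # µm/s
SPEED = "speed_um_s"


@dataclass
class StaticThreshold:
    """Speed at or below which an event counts as static/docked."""

    value: float  # µm/s
    source: str  # "fixed_calibration" | "default"
    n_calibration_events: int = 0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("threshold value must be positive")


@dataclass
class DecileBinning:
    """Per-cell equal-occupancy binning of events by one variable.

    ``events`` is a copy of the input table with an added integer ``bin``
    column (0 … n_bins−1, ascending in the binning variable within each cell).
    """

    events: pd.DataFrame
    variable: str
    n_bins: int


@dataclass
class StatReport:
    """Result of one statistical test, JSON-serialisable via :meth:`to_dict`."""

    test: str
    statistic: float
    p_value: float
    n_per_group: list[int] = field(default_factory=list)
    r: float | None = None
    r_ci95: tuple[float, float] | None = None
    posthoc_z: np.ndarray | None = None
    posthoc_p_adjusted: np.ndarray | None = None
    adjustment: str | None = None
    undefined: bool = False
    method_notes: str = ""

    def to_dict(self) -> dict:
        out: dict = {
            "test": self.test,
            "statistic": None if self.statistic is None or not np.isfinite(self.statistic) else float(self.statistic),
            "p_value": None if not np.isfinite(self.p_value) else float(self.p_value),
            "n_per_group": [int(n) for n in self.n_per_group],
            "undefined": self.undefined,
            "method_notes": self.method_notes,
        }
        if self.r is not None:
            out["r"] = None if not np.isfinite(self.r) else float(self.r)
        if self.r_ci95 is not None:
            out["r_ci95"] = [float(v) for v in self.r_ci95]
        if self.posthoc_z is not None:
            out["posthoc_z"] = np.round(self.posthoc_z, 10).tolist()
            out["posthoc_p_adjusted"] = np.round(self.posthoc_p_adjusted, 10).tolist()
            out["adjustment"] = self.adjustment
        return out


# ---------------------------------------------------------------------------
# threshold calibration and classification
# ---------------------------------------------------------------------------

def calibrate_static_threshold(fixed_events: pd.DataFrame | None = None) -> StaticThreshold:
    """Static-speed threshold from a fixed-sample event table.

    The threshold is the *maximum* speed observed in the immobilised sample,
    so classifying that same sample yields 100% static.  With no calibration
    data the conventional default of 0.05 µm/s is returned.
    """
    if fixed_events is None:
        return StaticThreshold(value=DEFAULT_STATIC_THRESHOLD, source="default")
    if len(fixed_events) == 0:
        raise ValueError("calibration requested but the fixed-sample event table is empty")
    return StaticThreshold(
        value=float(fixed_events[SPEED].max()),
        source="fixed_calibration",
        n_calibration_events=int(len(fixed_events)),
    )


def classify_static(events: pd.DataFrame, threshold: StaticThreshold) -> np.ndarray:
    """Boolean array: True where the event is static (speed ≤ threshold).

    The comparison is inclusive so that the calibration sample's own maximum
    classifies static.
    """
    return events[SPEED].to_numpy(dtype=float) <= threshold.value


# ---------------------------------------------------------------------------
# binning and summaries
# ---------------------------------------------------------------------------

def bin_by_variable(events: pd.DataFrame, variable: str, n_bins: int = 10) -> DecileBinning:
    """Equal-occupancy binning by ascending ``variable``, independent per cell.

    Within each cell, events are stably sorted by the variable (ties keep
    input order) and the event of rank r out of N is assigned to bin
    ``floor(r * n_bins / N)``, so bin sizes differ by at most one and sum to N.
    Raises if any cell contributes fewer than ``n_bins`` events (naming it).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if variable not in events.columns:
        raise ValueError(f"binning variable {variable!r} missing from event table")
    out = events.reset_index(drop=True).copy()
    out["bin"] = -1
    for cell_id, group in out.groupby("cell_id", sort=True):
        values = group[variable].to_numpy(dtype=float)
        n = len(values)
        if n < n_bins:
            raise ValueError(
                f"cell {cell_id!r} has only {n} events; at least {n_bins} are required for binning"
            )
        if np.isnan(values).any():
            raise ValueError(f"cell {cell_id!r} has NaN values in {variable!r}")
        order = np.argsort(values, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        out.loc[group.index, "bin"] = (ranks * n_bins) // n
    return DecileBinning(events=out, variable=variable, n_bins=n_bins)


def summarize_bins(binning: DecileBinning, threshold: StaticThreshold) -> pd.DataFrame:
    """Per-cell, per-bin summaries of the speed distribution.

    Columns: ``median_speed_total``, ``median_speed_motile`` (NaN when the bin
    has no motile events — an explicit undefined flag, never a division by
    zero), ``percent_static``, ``n_total``, ``n_motile``.
    """
    df = binning.events
    static = classify_static(df, threshold)
    rows = []
    for (cell_id, bin_index), group in df.groupby(["cell_id", "bin"], sort=True):
        speeds = group[SPEED].to_numpy(dtype=float)
        is_static = static[df.index.get_indexer(group.index)]
        motile_speeds = speeds[~is_static]
        rows.append(
            {
                "cell_id": cell_id,
                "bin": int(bin_index),
                "n_total": len(speeds),
                "n_motile": int(len(motile_speeds)),
                "percent_static": 100.0 * float(is_static.mean()),
                "median_speed_total": float(np.median(speeds)),
                "median_speed_motile": float(np.median(motile_speeds))
                if len(motile_speeds)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def aggregate_cells(summaries: pd.DataFrame) -> pd.DataFrame:
    """Cross-cell aggregation: mean and SEM of per-cell bin statistics.

    SEM is the sample standard deviation (ddof=1) divided by √n_cells and is
    NaN (undefined flag) when only one cell contributes.
    """
    if len(summaries) == 0:
        raise ValueError("no per-cell summaries to aggregate")

    def _mean_sem(values: np.ndarray) -> tuple[float, float]:
        values = values[np.isfinite(values)]
        if values.size == 0:
            return float("nan"), float("nan")
        mean = float(values.mean())
        sem = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else float("nan")
        return mean, sem

    rows = []
    for bin_index, group in summaries.groupby("bin", sort=True):
        row: dict = {"bin": int(bin_index), "n_cells": int(len(group))}
        for col in ("median_speed_total", "median_speed_motile", "percent_static"):
            mean, sem = _mean_sem(group[col].to_numpy(dtype=float))
            row[f"mean_{col}"] = mean
            row[f"sem_{col}"] = sem
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_bins(binning: DecileBinning) -> list[np.ndarray]:
    """Event speeds pooled across cells by bin index (the KW test groups)."""
    df = binning.events
    return [
        df.loc[df["bin"] == b, SPEED].to_numpy(dtype=float) for b in range(binning.n_bins)
    ]


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def kruskal_wallis_dunn(groups: list[np.ndarray]) -> StatReport:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise post-test.

    Dunn z statistics use the pooled mid-ranks with the standard tie
    correction; two-sided normal p-values are Bonferroni-adjusted over all
    k(k−1)/2 pairs.  If every value in every group is identical the test is
    degenerate: H = 0, p = 1, no significant pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    k = len(groups)
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if np.all(pooled == pooled[0]):
        h_stat, p_value = 0.0, 1.0
        z = np.zeros((k, k))
        p_adj = np.ones((k, k))
    else:
        h_stat, p_value = sps.kruskal(*groups)
        ranks = sps.rankdata(pooled)
        sizes = np.array([len(g) for g in groups])
        stops = np.cumsum(sizes)
        starts = stops - sizes
        mean_ranks = np.array([ranks[a:b].mean() for a, b in zip(starts, stops)])
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
        base_var = n_total * (n_total + 1) / 12.0 - tie_term
        z = np.zeros((k, k))
        p_adj = np.ones((k, k))
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
                zij = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
                pij = min(1.0, 2.0 * sps.norm.sf(abs(zij)) * n_pairs)
                z[i, j] = zij
                z[j, i] = -zij
                p_adj[i, j] = p_adj[j, i] = pij
    return StatReport(
        test="kruskal_wallis_dunn",
        statistic=float(h_stat),
        p_value=float(p_value),
        n_per_group=[len(g) for g in groups],
        posthoc_z=z,
        posthoc_p_adjusted=p_adj,
        adjustment="bonferroni",
        method_notes="tie-corrected H; Dunn z on pooled mid-ranks, Bonferroni over all pairs",
    )


def mann_whitney(sample_a: np.ndarray, sample_b: np.ndarray) -> StatReport:
    """Two-sided Mann–Whitney U (exact for small tie-free samples)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return StatReport(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=[len(a), len(b)],
        method_notes="U of the first sample; exact p for small tie-free samples, "
        "normal approximation with tie correction otherwise",
    )


def spearman_with_ci(x: np.ndarray, y: np.ndarray) -> StatReport:
    """Tie-corrected Spearman rank correlation with a 95% Fisher-z CI.

    The CI uses the Fieller-style variance 1.06/(n−3) appropriate for
    Spearman's r.  Zero variance in either variable flags the result
    undefined rather than erroring.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("Spearman correlation needs at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatReport(
            test="spearman",
            statistic=float("nan"),
            p_value=float("nan"),
            n_per_group=[n],
            r=float("nan"),
            undefined=True,
            method_notes="zero variance in one variable; correlation undefined",
        )
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = 1.959963984540054 * math.sqrt(1.06 / (n - 3))
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (float("nan"), float("nan"))
    return StatReport(
        test="spearman",
        statistic=r,
        p_value=float(res.pvalue),
        n_per_group=[n],
        r=r,
        r_ci95=ci,
        method_notes="mid-rank (tie-corrected) r; 95% CI via Fisher z with variance 1.06/(n-3)",
    )


def size_vs_mmfi(events: pd.DataFrame, channel: str = "mmfi_ch1") -> StatReport:
    """Spearman correlation between organelle size and per-event MMFI."""
    return spearman_with_ci(
        events[channel].to_numpy(dtype=float), events["size_um2"].to_numpy(dtype=float)
    )


def distribution_summary(events: pd.DataFrame) -> dict:
    """Five-number speed summary (5/25/50/75/95th percentiles).

    Percentiles use the linear-interpolation definition, recorded in the
    output so box-plot conventions are unambiguous.
    """
    if len(events) == 0:
        raise ValueError("no events to summarise")
    speeds = events[SPEED].to_numpy(dtype=float)
    p5, p25, p50, p75, p95 = np.percentile(speeds, [5, 25, 50, 75, 95])
    return {
        "p5": float(p5),
        "p25": float(p25),
        "median": float(p50),
        "p75": float(p75),
        "p95": float(p95),
        "n": int(len(speeds)),
        "percentile_method": "linear interpolation",
    }
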
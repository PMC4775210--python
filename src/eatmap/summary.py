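"""Study-level aggregation of per-measurement results.

Measurements nest within capillaries, so summaries are reported at both
levels: pooled over all measurements, and as the mean of per-capillary
means (with the per-capillary SD quantifying within-capillary measurement
scatter).  Cortical capillaries are assigned to layers purely by depth;
low-oxygen capillaries are stratified on the capillary-mean interstitial
Po2.  Correlations between quantities are Spearman rank correlations used
descriptively (no significance testing here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import EatmapError, InvariantError

__all__ = [
    "QUANTITIES",
    "CapillarySummary",
    "capillary_summary",
    "summarize_capillaries",
    "pooled_vs_capillary_means",
    "classify_layer",
    "spearman",
    "frequency_distribution",
    "stratify_low_po2",
    "study_report",
]

#: Measurement-level quantities that are aggregated per capillary.
QUANTITIES = ["po2_rbc", "po2_inter_rbc", "po2_mean", "so2",
              "rbc_flow", "hematocrit"]


@dataclass
class CapillarySummary:
    """Mean and sample SD (n-1 denominator) of each quantity for one
    capillary; SD is NaN-flagged when only one measurement exists."""

    capillary_id: str
    n_measurements: int
    means: dict
    sds: dict
    region: str = ""
    depth_um: float = float("nan")
    layer: str = "unclassified"


def capillary_summary(results: pd.DataFrame) -> CapillarySummary:
    """Aggregate the measurements of a single capillary."""
    if len(results) == 0:
        raise EatmapError("no measurements for capillary")
    cap_ids = results["capillary_id"].unique()
    if len(cap_ids) != 1:
        raise InvariantError("capillary_summary expects a single capillary")
    n = len(results)
    means = {q: float(results[q].mean()) for q in QUANTITIES}
    sds = {q: (float(results[q].std(ddof=1)) if n > 1 else float("nan"))
           for q in QUANTITIES}
    depth = float(results["depth_um"].iloc[0])
    return CapillarySummary(
        capillary_id=str(cap_ids[0]), n_measurements=n, means=means, sds=sds,
        region=str(results["region"].iloc[0]), depth_um=depth,
        layer=classify_layer(depth))


def summarize_capillaries(results: pd.DataFrame) -> pd.DataFrame:
    """One summary row per capillary (means, SDs, depth, layer)."""
    rows = []
    for cap_id, grp in results.groupby("capillary_id", sort=True):
        s = capillary_summary(grp)
        row = {"capillary_id": s.capillary_id, "n_measurements": s.n_measurements,
               "region": s.region, "depth_um": s.depth_um, "layer": s.layer}
        for q in QUANTITIES:
            row[f"{q}_mean"] = s.means[q]
            row[f"{q}_sd"] = s.sds[q]
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_vs_capillary_means(results: pd.DataFrame) -> pd.DataFrame:
    """All-measurements mean versus mean-of-capillary-means, per quantity.

    The two agree exactly for balanced designs and stay close when the
    number of measurements per capillary varies moderately.
    """
    if len(results) == 0:
        raise EatmapError("no measurements")
    cap_means = results.groupby("capillary_id")[QUANTITIES].mean()
    out = pd.DataFrame({
        "pooled_mean": results[QUANTITIES].mean(),
        "pooled_sem": results[QUANTITIES].sem(ddof=1),
        "capillary_mean": cap_means.mean(),
        "capillary_sem": cap_means.sem(ddof=1),
        "n_measurements": len(results),
        "n_capillaries": len(cap_means),
    })
    out.index.name = "quantity"
    return out


def classify_layer(depth_um: Union[float, np.ndarray]):
    """Cortical layer from depth below the surface (µm).

    < 60 µm -> "I"; 90-260 µm (inclusive) -> "II/III"; > 340 µm -> "IV";
    the ambiguous bands [60, 90) and (260, 340] -> "unclassified".
    """
    arr = np.asarray(depth_um, dtype=float)
    if np.any(arr < 0):
        raise InvariantError("depth must be >= 0")
    out = np.select(
        [arr < 60, (arr >= 90) & (arr <= 260), arr > 340],
        ["I", "II/III", "IV"], default="unclassified")
    return str(out[()]) if np.isscalar(depth_um) or arr.ndim == 0 else out


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks, with
    average ranks for ties.  Requires equal lengths >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvariantError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise InvariantError("need at least 3 observations")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def frequency_distribution(values, bin_width: float = 5.0,
                           origin: float = 0.0) -> pd.DataFrame:
    """Histogram with half-open bins [k*w, (k+1)*w) anchored at ``origin``.

    Returns a table (bin_left, bin_right, count); counts sum to the input
    length.  Empty input yields an empty table.
    """
    if bin_width <= 0:
        raise InvariantError("bin width must be > 0")
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    k = np.floor((values - origin) / bin_width).astype(int)
    lo, hi = k.min(), k.max()
    idx = np.arange(lo, hi + 1)
    counts = np.bincount(k - lo, minlength=len(idx))
    return pd.DataFrame({
        "bin_left": origin + idx * bin_width,
        "bin_right": origin + (idx + 1) * bin_width,
        "count": counts,
    })


def stratify_low_po2(cap_summaries: pd.DataFrame,
                     threshold: float = 15.0) -> dict:
    """Split capillaries on their mean interstitial Po2.

    ``low`` holds capillaries with mean Po2InterRBC below ``threshold``
    (mm Hg), ``rest`` the others; each group reports mean ± SEM of
    hematocrit and RBC flow for the low-oxygen/low-hematocrit contrast.
    """
    if len(cap_summaries) == 0:
        raise EatmapError("no capillary summaries")
    low_mask = cap_summaries["po2_inter_rbc_mean"] < threshold

    def group_stats(df: pd.DataFrame) -> dict:
        stats = {"n": int(len(df))}
        for q in ("hematocrit", "rbc_flow", "po2_inter_rbc"):
            col = df[f"{q}_mean"]
            stats[f"{q}_mean"] = float(col.mean()) if len(df) else float("nan")
            stats[f"{q}_sem"] = (float(col.sem(ddof=1)) if len(df) > 1
                                 else float("nan"))
        return stats

    return {
        "threshold": threshold,
        "low": group_stats(cap_summaries[low_mask]),
        "rest": group_stats(cap_summaries[~low_mask]),
        "low_capillaries": list(cap_summaries.loc[low_mask, "capillary_id"]),
    }


def study_report(results: pd.DataFrame,
                 histogram_bin_width: float = 5.0) -> dict:
    """Full study-level JSON-serializable report.

    Contains pooled and per-capillary means, frequency distributions
    (5 mm Hg bins for Po2 quantities), layer tables, the low-Po2
    stratification and Spearman correlations of Po2 with flow and
    hematocrit across all measurements.
    """
    caps = summarize_capillaries(results)
    two_level = pooled_vs_capillary_means(results)
    report: dict = {
        "n_measurements": int(len(results)),
        "n_capillaries": int(len(caps)),
        "two_level_means": {
            q: {k: float(two_level.loc[q, k])
                for k in ("pooled_mean", "pooled_sem",
                          "capillary_mean", "capillary_sem")}
            for q in QUANTITIES},
        "histograms": {
            q: frequency_distribution(results[q], histogram_bin_width)
                .to_dict(orient="list")
            for q in ("po2_rbc", "po2_inter_rbc", "po2_mean", "so2")},
        "low_po2": stratify_low_po2(caps),
    }
    layer_tbl = {}
    for layer, grp in caps.groupby("layer"):
        layer_tbl[layer] = {
            "n_capillaries": int(len(grp)),
            **{f"{q}_mean": float(grp[f"{q}_mean"].mean()) for q in QUANTITIES},
        }
    report["layers"] = layer_tbl
    corr = {}
    for q in ("po2_rbc", "po2_inter_rbc", "po2_mean"):
        for v in ("rbc_flow", "hematocrit"):
            if len(results) >= 3:
                corr[f"{q}_vs_{v}"] = spearman(results[q], results[v])
    report["spearman"] = corr
    return report
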
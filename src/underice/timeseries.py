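"""Per-sample, per-class biovolume series and their summaries.

Each syringe draw yields a set of classified images with per-image
biovolumes; dividing the per-class biovolume sums by the analysed volume
gives µm³ mL⁻¹ series by time and depth. 'Other' and 'unclassified' are
kept as explicit series throughout — in field data the catch-all category
can dominate total biovolume, so silently dropping it would misrepresent
the community.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import UNCLASSIFIED

DEFAULT_WINDOW_H = 12.0  # ±12 h moving-average half-width
TOTAL = "Total"


def aggregate_sample(records: pd.DataFrame, analysed_volume_ml: float,
                     classes: Optional[Sequence[str]] = None) -> pd.Series:
    """Per-class biovolume per mL for one sample.

    ``records`` holds the sample's images (columns ``class``,
    ``biovolume_um3``). Classes requested but absent are reported as 0.
    """
    if analysed_volume_ml <= 0:
        raise ValueError("analysed volume must be positive")
    sums = records.groupby("class")["biovolume_um3"].sum() if len(records) else pd.Series(dtype=float)
    if classes is not None:
        sums = sums.reindex(list(classes), fill_value=0.0)
    return (sums / analysed_volume_ml).rename("biovolume_um3_per_ml")


def aggregate_campaign(records: pd.DataFrame, samples: pd.DataFrame,
                       classes: Optional[Sequence[str]] = None,
                       imaged_fraction: float = 1.0,
                       include_total: bool = True) -> pd.DataFrame:
    """Biovolume-per-mL series over a whole campaign.

    One row per (sample, class), zero-filled for samples with no image of a
    class; the analysed volume is the syringe volume times
    ``imaged_fraction`` (the effective imaged volume is instrument-specific
    and configurable). With ``include_total`` an explicit 'Total' class sums
    every class including 'Other' and 'unclassified'.
    """
    if imaged_fraction <= 0:
        raise ValueError("imaged_fraction must be positive")
    if classes is None:
        classes = sorted(records["class"].unique()) if len(records) else []
    rows = []
    grouped = dict(tuple(records.groupby("sample_id"))) if len(records) else {}
    for sample in samples.itertuples(index=False):
        recs = grouped.get(sample.sample_id,
                           pd.DataFrame(columns=["class", "biovolume_um3"]))
        volume = sample.volume_ml * imaged_fraction
        per_class = aggregate_sample(recs, volume, classes)
        for cls, value in per_class.items():
            rows.append({"sample_id": sample.sample_id, "time": sample.time,
                         "depth_m": sample.depth_m, "class": cls,
                         "biovolume_um3_per_ml": value})
        if include_total:
            rows.append({"sample_id": sample.sample_id, "time": sample.time,
                         "depth_m": sample.depth_m, "class": TOTAL,
                         "biovolume_um3_per_ml": float(per_class.sum())})
    return pd.DataFrame(rows, columns=["sample_id", "time", "depth_m", "class",
                                       "biovolume_um3_per_ml"])


def moving_average(series: pd.DataFrame, window_h: float = DEFAULT_WINDOW_H) -> pd.DataFrame:
    """Centred ±``window_h`` moving average per (depth, class).

    At each sample time the mean is taken over all samples of the same depth
    and class within the window; a window with no samples yields NaN (which
    cannot happen at the sample's own time).
    """
    out = series.copy()
    out["biovolume_um3_per_ml_smooth"] = np.nan
    window = pd.Timedelta(hours=window_h)
    for _, idx in out.groupby(["depth_m", "class"]).groups.items():
        grp = out.loc[idx].sort_values("time")
        times = pd.to_datetime(grp["time"]).to_numpy()
        vals = grp["biovolume_um3_per_ml"].to_numpy()
        lo = np.searchsorted(times, times - window, side="left")
        hi = np.searchsorted(times, times + window, side="right")
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        smooth = (csum[hi] - csum[lo]) / (hi - lo)
        out.loc[grp.index, "biovolume_um3_per_ml_smooth"] = smooth
    return out


def depth_frequency_report(samples: pd.DataFrame) -> dict:
    """Samples per depth and the shallow-to-deepest sampling ratio."""
    if samples.empty:
        return {"counts": pd.Series(dtype=int), "shallow_deep_ratio": np.nan,
                "flagged": True}
    counts = samples.groupby("depth_m")["sample_id"].count().sort_index()
    if counts.size < 2:
        return {"counts": counts, "shallow_deep_ratio": np.nan, "flagged": True}
    ratio = float(counts.iloc[:-1].mean() / counts.iloc[-1])
    return {"counts": counts, "shallow_deep_ratio": ratio, "flagged": False}


def export_records(records: pd.DataFrame, samples: pd.DataFrame, path) -> None:
    """CSV of per-image results: sampling time, depth, sample volume,
    phytoplankton class and estimated biovolume (µm³)."""
    meta = samples.set_index("sample_id")
    out = pd.DataFrame({
        "sampling_time": pd.to_datetime(
            records["sample_id"].map(meta["time"])).dt.strftime("%Y-%m-%dT%H:%M:%S"),
        "depth_m": records["sample_id"].map(meta["depth_m"]),
        "sample_volume_ml": records["sample_id"].map(meta["volume_ml"]),
        "phytoplankton_class": records["class"],
        "estimated_biovolume_um3": records["biovolume_um3"],
    })
    out.to_csv(path, index=False)


def plot_biovolume_series(series: pd.DataFrame, path=None,
                          classes: Optional[Sequence[str]] = None,
                          smoothed: bool = False):
    """Multi-panel per-class biovolume-per-mL plot, colour-coded by depth."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    value_col = ("biovolume_um3_per_ml_smooth" if smoothed
                 else "biovolume_um3_per_ml")
    if classes is None:
        classes = [TOTAL] + sorted(c for c in series["class"].unique()
                                   if c != TOTAL)
        classes = [c for c in classes if c in set(series["class"])]
    fig, axes = plt.subplots(len(classes), 1, figsize=(9, 2.2 * len(classes)),
                             sharex=True, squeeze=False)
    for ax, cls in zip(axes[:, 0], classes):
        sub = series[series["class"] == cls]
        for depth, grp in sub.groupby("depth_m"):
            grp = grp.sort_values("time")
            ax.plot(grp["time"], grp[value_col], ".", ms=3, label=f"{depth:g} m")
        ax.set_ylabel("µm³ mL⁻¹")
        ax.set_title(cls, fontsize=9, loc="left")
    axes[0, 0].legend(fontsize=7, ncol=4)
    fig.autofmt_xdate()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
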
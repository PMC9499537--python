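"""Apoptosis-referenced wave kinematics.

Implements the movement statistics measured against the apoptotic
reference point — the distance ``dNuc_{i,t}`` of nucleus *i* from the
event at time *t*, the cumulative approach ``Mov_{i,t} = dNuc_{i,a} -
dNuc_{i,t}`` (zero at the apoptosis frame *a*, positive when the nucleus
is closer than it was at *a*) and the frame-to-frame change ``ΔMov`` —
plus distance-ordered kymographs, the wave speed/extent/duration
estimator, and the ERK-versus-movement cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import ApoptoticEvent


def compute_dnuc(
    tracks: pd.DataFrame, event: ApoptoticEvent
) -> tuple[pd.DataFrame, list[int]]:
    """Euclidean distance of every tracked nucleus from the event.

    Adds columns ``dnuc`` (per frame) and ``dnuc_a`` (distance at the
    apoptosis frame).  Tracks with no observation at the event frame are
    excluded and their ids returned alongside.
    """
    needed = {"track_id", "frame", "x_um", "y_um"}
    if not needed <= set(tracks.columns):
        raise ValueError(f"tracks table needs columns {sorted(needed)}")
    out = tracks.copy()
    out["dnuc"] = np.hypot(out["x_um"] - event.x_um, out["y_um"] - event.y_um)
    at_a = out[out["frame"] == event.frame].set_index("track_id")["dnuc"]
    present = out["track_id"].isin(at_a.index)
    excluded = sorted(out.loc[~present, "track_id"].unique().tolist())
    out = out[present].copy()
    out["dnuc_a"] = out["track_id"].map(at_a)
    return out, excluded


def compute_mov(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``mov`` and ``dmov`` columns to a table carrying dnuc/dnuc_a.

    ``mov = dnuc_a - dnuc`` (exactly 0 at the apoptosis frame, positive =
    closer than at apoptosis); ``dmov`` is the difference of ``mov``
    between consecutive observed frames (NaN at each track's first frame).
    """
    if "dnuc" not in table.columns or "dnuc_a" not in table.columns:
        raise ValueError("run compute_dnuc first")
    out = table.sort_values(["track_id", "frame"]).copy()
    out["mov"] = out["dnuc_a"] - out["dnuc"]
    out["dmov"] = out.groupby("track_id")["mov"].diff()
    return out


def build_kymograph(
    table: pd.DataFrame,
    event: ApoptoticEvent,
    values: tuple[str, ...] = ("cn_ratio", "mov", "dmov"),
) -> dict:
    """Distance-ordered cell × time matrices around one event.

    Rows are tracks sorted by ascending distance at the apoptosis frame
    (closest on top, as in a wave kymograph); columns are frames; one
    matrix per requested value column, all sharing the same row order.
    Returns ``{"track_ids", "distances", "frames", <value>: matrix}``.
    """
    if len(table) == 0:
        raise ValueError("empty track table for kymograph")
    order = (
        table[["track_id", "dnuc_a"]]
        .drop_duplicates("track_id")
        .sort_values("dnuc_a", kind="stable")
    )
    frames = np.sort(table["frame"].unique())
    out = {
        "track_ids": order["track_id"].to_numpy(),
        "distances": order["dnuc_a"].to_numpy(),
        "frames": frames,
    }
    for val in values:
        if val not in table.columns:
            continue
        pivot = table.pivot_table(index="track_id", columns="frame", values=val,
                                  aggfunc="first")
        pivot = pivot.reindex(index=order["track_id"], columns=frames)
        out[val] = pivot.to_numpy()
    return out


@dataclass
class WaveSummary:
    """Estimated kinematics of one apoptosis-induced ERK wave."""

    event_id: int
    detected: bool
    speed: Optional[float]  # µm/min, onset-vs-distance regression slope
    speed_extent_over_duration: Optional[float]  # µm/min, printed-style ratio
    extent: Optional[float]  # µm, largest bin centre with consistent onset
    total_duration: Optional[float]  # min, last onset + its duration - t_a
    n_cells: int
    bins: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        d = {
            "event_id": self.event_id,
            "detected": self.detected,
            "speed_um_min": self.speed,
            "speed_extent_over_duration_um_min": self.speed_extent_over_duration,
            "extent_um": self.extent,
            "total_duration_min": self.total_duration,
            "n_cells": self.n_cells,
        }
        d["bins"] = self.bins.to_dict(orient="records") if len(self.bins) else []
        return d


def estimate_wave(
    table: pd.DataFrame,
    event: ApoptoticEvent,
    frame_interval: float,
    bin_width_um: float = 25.0,
    baseline_frames: int = 6,
    k_sigma: float = 2.0,
    min_rise_frac: float = 0.02,
    min_cells: int = 50,
    min_cells_per_bin: int = 3,
    min_onset_bins: int = 3,
    consensus_resid_frames: float = 2.0,
) -> WaveSummary:
    """Estimate wave speed, extent and distance-resolved duration/peak.

    Cells are grouped into concentric distance bins (by their distance at
    the apoptosis frame).  A bin's onset is the first post-event frame at
    which its mean C/N ratio exceeds its own pre-event baseline by
    ``k_sigma`` baseline standard deviations (with a relative floor of
    ``min_rise_frac`` to remain defined on noiseless data); its active
    duration is the length of the contiguous above-threshold run from
    onset.  The front speed is the slope of the least-squares fit of bin
    centre distance against onset time over onset bins, after one pass of
    outlier rejection against the fitted line (threshold
    ``consensus_resid_frames`` frame intervals); the extent is the largest
    consistent bin centre.  ``extent / total_duration`` is also reported,
    mirroring the distance-over-period speed customarily quoted from a
    single exemplar wave.

    If no bin crosses its threshold the result is "no wave detected"
    (``detected=False``), not an exception; with fewer than
    ``min_onset_bins`` onset bins the speed is undefined (None).
    """
    table = table[~table.get("gapfilled", pd.Series(False, index=table.index)).fillna(False).astype(bool)]
    n_cells = table["track_id"].nunique()
    if n_cells < min_cells:
        raise ValueError(
            f"only {n_cells} tracked cells span the event window "
            f"(need {min_cells})"
        )
    a = event.frame
    frames = np.sort(table["frame"].unique())
    base_lo = a - baseline_frames

    edges = np.arange(0.0, table["dnuc_a"].max() + bin_width_um, bin_width_um)
    table = table.copy()
    table["bin"] = np.digitize(table["dnuc_a"], edges) - 1

    bin_rows = []
    for b, sub in table.groupby("bin"):
        if sub["track_id"].nunique() < min_cells_per_bin:
            continue
        series = sub.groupby("frame")["cn_ratio"].mean().reindex(frames)
        base = series[(series.index >= base_lo) & (series.index < a)].dropna()
        if len(base) < 2:
            continue
        mu, sd = float(base.mean()), float(base.std(ddof=1))
        thr = mu + max(k_sigma * sd, min_rise_frac * abs(mu))
        post = series[series.index >= a]
        above = (post > thr).to_numpy()
        onset_min = np.nan
        duration_min = 0.0
        if above.any():
            i0 = int(np.argmax(above))
            onset_frame = int(post.index[i0])
            onset_min = (onset_frame - a) * frame_interval
            run = 0
            for flag in above[i0:]:
                if not flag:
                    break
                run += 1
            duration_min = run * frame_interval
        peak = float(post.max()) if len(post) else np.nan
        center = edges[b] + bin_width_um / 2.0
        bin_rows.append(
            (center, int(sub["track_id"].nunique()), onset_min, duration_min,
             peak, mu)
        )
    bins = pd.DataFrame(
        bin_rows,
        columns=["bin_center_um", "n_cells", "onset_min", "duration_min",
                 "peak_cn", "baseline_cn"],
    )

    onset_bins = bins.dropna(subset=["onset_min"])
    if len(onset_bins) == 0:
        return WaveSummary(event.event_id, False, None, None, None, None,
                           n_cells, bins)

    consistent = onset_bins
    speed = None
    if len(onset_bins) >= min_onset_bins:
        # least-squares fit of distance vs onset time, one outlier pass
        for _ in range(2):
            t = consistent["onset_min"].to_numpy()
            d = consistent["bin_center_um"].to_numpy()
            if len(consistent) < min_onset_bins or np.ptp(t) == 0:
                break
            slope, intercept = np.polyfit(t, d, 1)
            pred_t = (d - intercept) / slope if slope != 0 else t
            resid = np.abs(t - pred_t)
            keep = resid <= consensus_resid_frames * frame_interval
            if keep.all():
                break
            consistent = consistent[keep]
        t = consistent["onset_min"].to_numpy()
        d = consistent["bin_center_um"].to_numpy()
        if len(consistent) >= min_onset_bins and np.ptp(t) > 0:
            speed = float(np.polyfit(t, d, 1)[0])

    extent = float(consistent["bin_center_um"].max())
    last = consistent.loc[consistent["bin_center_um"].idxmax()]
    total_duration = float(last["onset_min"] + last["duration_min"])
    ratio = extent / total_duration if total_duration > 0 else None
    return WaveSummary(
        event_id=event.event_id,
        detected=True,
        speed=speed,
        speed_extent_over_duration=ratio,
        extent=extent,
        total_duration=total_duration,
        n_cells=n_cells,
        bins=bins,
    )


def crosscorr_erk_movement(
    table: pd.DataFrame, max_lag_frames: int = 6
) -> tuple[pd.DataFrame, dict]:
    """Per-cell lag of peak cross-correlation between C/N ratio and ΔMov.

    For each track the Pearson correlation between the (mean-centred,
    variance-normalised) ERK series and the movement series shifted by
    each lag in ``[-max_lag, +max_lag]`` is computed; the reported lag
    maximises the correlation, with ties broken toward the smaller |lag|.
    Positive lag means ERK precedes movement.  Zero-variance or too-short
    series are excluded and counted.  Returns (per-cell table, summary)
    where summary holds the population median lag and a sign-test p-value
    for "median lag > 0 or == 0" asymmetry.
    """
    rows = []
    n_excluded = 0
    for tid, sub in table.sort_values("frame").groupby("track_id"):
        erk = sub["cn_ratio"].to_numpy(dtype=float)
        mov = sub["dmov"].to_numpy(dtype=float)
        ok = ~(np.isnan(erk) | np.isnan(mov))
        erk, mov = erk[ok], mov[ok]
        if len(erk) < 2 * max_lag_frames + 1 or erk.std() == 0 or mov.std() == 0:
            n_excluded += 1
            continue
        erk = (erk - erk.mean()) / erk.std()
        mov = (mov - mov.mean()) / mov.std()
        best_lag, best_r = 0, -np.inf
        # ties toward smaller |lag|: scan by increasing |lag|
        for lag in sorted(range(-max_lag_frames, max_lag_frames + 1), key=abs):
            if lag >= 0:
                a_s, b_s = erk[: len(erk) - lag], mov[lag:]
            else:
                a_s, b_s = erk[-lag:], mov[: len(mov) + lag]
            if len(a_s) < 3 or a_s.std() == 0 or b_s.std() == 0:
                continue
            r = float(np.corrcoef(a_s, b_s)[0, 1])
            if r > best_r + 1e-12:
                best_lag, best_r = lag, r
        rows.append((tid, best_lag, best_r))
    per_cell = pd.DataFrame(rows, columns=["track_id", "lag_frames", "peak_r"])
    summary: dict = {"n_cells": len(per_cell), "n_excluded": n_excluded}
    if len(per_cell):
        lags = per_cell["lag_frames"].to_numpy()
        summary["median_lag_frames"] = float(np.median(lags))
        pos, neg = int((lags > 0).sum()), int((lags < 0).sum())
        if pos + neg > 0:
            summary["sign_test_p"] = float(
                stats.binomtest(pos, pos + neg, 0.5).pvalue
            )
        else:
            summary["sign_test_p"] = 1.0
    return per_cell, summary
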
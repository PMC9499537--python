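"""Frame-to-frame nucleus linking and apoptotic-event detection.

Linking is per-frame optimal one-to-one assignment (Hungarian algorithm on
squared displacement) with a hard gating radius; unmatched detections seed
new tracks, and tracks unmatched for more than ``max_gap`` frames
terminate.  Gap frames are filled by linear interpolation and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .stack import FrameStack


@dataclass(frozen=True)
class ApoptoticEvent:
    """Reference point anchoring wave kinematics: position (µm) and frame."""

    event_id: int
    frame: int
    x_um: float
    y_um: float


def link_tracks(
    detections: pd.DataFrame,
    gating_radius_um: float = 15.0,
    max_gap: int = 2,
) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    ``detections`` needs columns ``frame, x_um, y_um``; all other columns
    are carried through.  Returns the same rows plus ``track_id`` and a
    ``gapfilled`` flag (interpolated rows are added for interior gaps).
    An empty input yields an empty table.
    """
    if gating_radius_um <= 0:
        raise ValueError("gating radius must be positive")
    if len(detections) == 0:
        out = detections.copy()
        out["track_id"] = pd.Series(dtype=int)
        out["gapfilled"] = pd.Series(dtype=bool)
        return out
    detections = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = detections["frame"].to_numpy()
    xy = detections[["x_um", "y_um"]].to_numpy(dtype=float)

    track_of_row = np.full(len(detections), -1, dtype=int)
    # active tracks: id -> (last row index, last frame)
    active: dict[int, tuple[int, int]] = {}
    next_id = 0
    gate2 = gating_radius_um**2

    for frame in np.unique(frames):
        rows = np.flatnonzero(frames == frame)
        # drop tracks that have been unmatched too long
        active = {tid: (ri, fr) for tid, (ri, fr) in active.items()
                  if frame - fr <= max_gap + 1}
        tids = list(active.keys())
        if tids:
            last_xy = np.array([xy[active[t][0]] for t in tids])
            cost = ((last_xy[:, None, :] - xy[rows][None, :, :]) ** 2).sum(axis=2)
            feasible = cost <= gate2
            big = 1e12
            cost = np.where(feasible, cost, big)
            ri, ci = linear_sum_assignment(cost)
            matched_rows = set()
            for i, j in zip(ri, ci):
                if feasible[i, j]:
                    tid = tids[i]
                    track_of_row[rows[j]] = tid
                    active[tid] = (int(rows[j]), int(frame))
                    matched_rows.add(j)
        else:
            matched_rows = set()
        for j, row in enumerate(rows):
            if j not in matched_rows:
                track_of_row[row] = next_id
                active[next_id] = (int(row), int(frame))
                next_id += 1

    out = detections.copy()
    out["track_id"] = track_of_row
    out["gapfilled"] = False
    out = _fill_gaps(out)
    return out.sort_values(["track_id", "frame"]).reset_index(drop=True)


def _fill_gaps(table: pd.DataFrame) -> pd.DataFrame:
    """Insert linearly interpolated rows for interior missing frames."""
    filler_rows = []
    for tid, sub in table.groupby("track_id"):
        sub = sub.sort_values("frame")
        fr = sub["frame"].to_numpy()
        gaps = np.flatnonzero(np.diff(fr) > 1)
        for gi in gaps:
            f0, f1 = fr[gi], fr[gi + 1]
            r0 = sub.iloc[gi]
            r1 = sub.iloc[gi + 1]
            for f in range(int(f0) + 1, int(f1)):
                w = (f - f0) / (f1 - f0)
                row = {c: np.nan for c in table.columns}
                row.update(
                    frame=f,
                    x_um=r0["x_um"] + w * (r1["x_um"] - r0["x_um"]),
                    y_um=r0["y_um"] + w * (r1["y_um"] - r0["y_um"]),
                    track_id=tid,
                    gapfilled=True,
                )
                filler_rows.append(row)
    if filler_rows:
        filler = pd.DataFrame(filler_rows, columns=table.columns)
        for col in table.columns:  # keep dtypes stable through the concat
            try:
                filler[col] = filler[col].astype(table[col].dtype)
            except (TypeError, ValueError):
                pass
        table = pd.concat([table, filler], ignore_index=True)
    return table


def detect_apoptosis_events(
    source: FrameStack | np.ndarray,
    pixel_size: Optional[float] = None,
    frame_interval: Optional[float] = None,
    threshold: float | str = "half",
    merge_radius_um: float = 30.0,
    merge_gap_frames: int = 2,
    casp_channel: str = "CASP",
) -> list[ApoptoticEvent]:
    """Detect apoptotic events from the caspase channel.

    Per frame, connected regions of caspase signal above threshold are
    reduced to intensity-weighted centroids; detections within
    ``merge_radius_um`` and ``merge_gap_frames`` of each other collapse
    into one event anchored at its first above-threshold frame.  The
    default threshold is half the channel maximum (the caspase flash is
    far brighter than anything else); a channel without significant
    contrast over its background yields no events.
    """
    import scipy.ndimage as ndi
    from skimage.filters import threshold_otsu

    if isinstance(source, FrameStack):
        casp = source.channel(casp_channel)
        pixel_size = source.pixel_size
    else:
        casp = np.asarray(source)
        if pixel_size is None:
            raise ValueError("pixel_size required for a bare caspase array")
    if casp.ndim != 3:
        raise ValueError("caspase channel must be (T, H, W)")
    # contrast guard: a signal-free channel (flat or pure noise) has no events
    med = float(np.median(casp))
    if casp.max() <= med + 10.0 * casp.std():
        return []
    if threshold == "half":
        thr = 0.5 * float(casp.max())
    elif threshold == "otsu":
        thr = threshold_otsu(casp)
    else:
        thr = float(threshold)

    detections: list[tuple[int, float, float, float]] = []  # frame, x, y, mass
    for f in range(casp.shape[0]):
        fg = casp[f] > thr
        if not fg.any():
            continue
        labels, n = ndi.label(fg)
        for lab in range(1, n + 1):
            mask = labels == lab
            mass = float(casp[f][mask].sum())
            cy, cx = ndi.center_of_mass(casp[f], labels, lab)
            detections.append((f, cx * pixel_size, cy * pixel_size, mass))

    events: list[list[tuple[int, float, float, float]]] = []
    for det in sorted(detections):
        placed = False
        for ev in events:
            lf, lx, ly, _ = ev[-1]
            if (det[0] - lf) <= merge_gap_frames and np.hypot(
                det[1] - lx, det[2] - ly
            ) <= merge_radius_um:
                ev.append(det)
                placed = True
                break
        if not placed:
            events.append([det])

    out = []
    for i, ev in enumerate(events):
        f0, x0, y0, _ = ev[0]  # anchored at the first above-threshold frame
        out.append(ApoptoticEvent(event_id=i, frame=int(f0), x_um=x0, y_um=y0))
    return out


def events_to_frame(events: list[ApoptoticEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.event_id, e.frame, e.x_um, e.y_um) for e in events],
        columns=["event_id", "frame", "x_um", "y_um"],
    )
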
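"""Particle image velocimetry on the nuclear channel.

Single-pass windowed normalised cross-correlation: each interrogation
window in frame t is correlated against a padded search region in frame
t+1; the correlation peak, refined to sub-pixel accuracy by a three-point
Gaussian fit, gives the window displacement, converted to µm/min.
Flat windows and weak correlation peaks are flagged invalid.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .stack import FrameStack
from .tracking import ApoptoticEvent


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_px: int = 32,
    overlap: float = 0.5,
    max_shift_px: int = 8,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    quality_min: float = 0.3,
) -> pd.DataFrame:
    """Displacement field between two consecutive frames.

    Returns one row per interrogation window: ``x_um, y_um`` (window
    centre), ``u_um_min, v_um_min`` (x/y velocity), ``quality`` (peak
    normalised correlation) and ``valid``.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("PIV frames must share a shape")
    if window_px < 16:
        raise ValueError("window must be at least 16 px")
    h, w = frame_a.shape
    step = max(int(round(window_px * (1.0 - overlap))), 1)
    rows = []
    for r0 in range(0, h - window_px + 1, step):
        for c0 in range(0, w - window_px + 1, step):
            template = frame_a[r0:r0 + window_px, c0:c0 + window_px]
            cy = r0 + window_px / 2.0
            cx = c0 + window_px / 2.0
            if template.std() <= 1e-12:
                rows.append((cx * pixel_size, cy * pixel_size, 0.0, 0.0, 0.0,
                             False))
                continue
            rs0 = max(r0 - max_shift_px, 0)
            cs0 = max(c0 - max_shift_px, 0)
            rs1 = min(r0 + window_px + max_shift_px, h)
            cs1 = min(c0 + window_px + max_shift_px, w)
            # a clipped search range cannot cover all candidate shifts;
            # such border windows are never trusted
            clipped = (rs0 != r0 - max_shift_px or cs0 != c0 - max_shift_px
                       or rs1 != r0 + window_px + max_shift_px
                       or cs1 != c0 + window_px + max_shift_px)
            search = frame_b[rs0:rs1, cs0:cs1]
            if search.std() <= 1e-12:
                rows.append((cx * pixel_size, cy * pixel_size, 0.0, 0.0, 0.0,
                             False))
                continue
            ncc = match_template(search, template)
            pk = np.unravel_index(np.argmax(ncc), ncc.shape)
            quality = float(ncc[pk])
            # a peak on the search border cannot be trusted (the true
            # displacement may lie outside the searched range) nor refined
            on_border = (pk[0] in (0, ncc.shape[0] - 1)
                         or pk[1] in (0, ncc.shape[1] - 1))
            dy = pk[0] + rs0 - r0
            dx = pk[1] + cs0 - c0
            sy, sx = _subpixel(ncc, pk)
            u = (dx + sx) * pixel_size / frame_interval
            v = (dy + sy) * pixel_size / frame_interval
            rows.append((cx * pixel_size, cy * pixel_size, u, v, quality,
                         quality >= quality_min and not on_border
                         and not clipped))
    return pd.DataFrame(
        rows, columns=["x_um", "y_um", "u_um_min", "v_um_min", "quality",
                       "valid"],
    )


def _subpixel(ncc: np.ndarray, peak: tuple) -> tuple[float, float]:
    """Three-point Gaussian peak interpolation along each axis."""
    def fit(vals: np.ndarray, i: int, n: int) -> float:
        if i <= 0 or i >= n - 1:
            return 0.0
        cm, c0, cp = vals[i - 1], vals[i], vals[i + 1]
        eps = 1e-12
        cm, c0, cp = (max(v, eps) for v in (cm, c0, cp))
        denom = 2.0 * (np.log(cm) + np.log(cp) - 2.0 * np.log(c0))
        if abs(denom) < 1e-15:
            return 0.0
        return float((np.log(cm) - np.log(cp)) / denom)

    r, c = peak
    return (fit(ncc[:, c], r, ncc.shape[0]), fit(ncc[r, :], c, ncc.shape[1]))


def piv_stack(
    stack: FrameStack,
    channel: str = "H2B",
    window_px: int = 32,
    overlap: float = 0.5,
    max_shift_px: int = 8,
    quality_min: float = 0.3,
    frames: Optional[tuple[int, int]] = None,
    time_average: bool = True,
) -> pd.DataFrame:
    """PIV over consecutive frame pairs of a stack.

    With ``time_average`` the per-window vectors are averaged over all
    pairs (the movie-long flow pattern); otherwise per-pair rows are
    returned with a ``frame`` column (time-integrated displacement is the
    per-window sum of ``u / v × frame_interval`` over pairs).
    """
    imgs = stack.channel(channel)
    lo, hi = (0, stack.n_frames - 1) if frames is None else frames
    pairs = []
    for f in range(lo, hi):
        df = piv_pair(
            imgs[f], imgs[f + 1], window_px=window_px, overlap=overlap,
            max_shift_px=max_shift_px, pixel_size=stack.pixel_size,
            frame_interval=stack.frame_interval, quality_min=quality_min,
        )
        df.insert(0, "frame", f)
        pairs.append(df)
    all_df = pd.concat(pairs, ignore_index=True)
    if not time_average:
        return all_df
    valid = all_df[all_df["valid"]]
    agg = valid.groupby(["x_um", "y_um"], as_index=False).agg(
        u_um_min=("u_um_min", "mean"),
        v_um_min=("v_um_min", "mean"),
        quality=("quality", "mean"),
        n_pairs=("frame", "count"),
    )
    agg["valid"] = True
    return agg


def convergence_toward(
    flow: pd.DataFrame,
    event: ApoptoticEvent,
    r_max_um: Optional[float] = None,
) -> Optional[float]:
    """Mean radial inflow toward an event, µm/min (positive = approach).

    Each valid vector is projected onto the unit vector pointing from its
    window centre toward the event, then averaged over vectors within
    ``r_max_um`` of the event.  Returns None when no valid vector is in
    range.
    """
    valid = flow[flow["valid"]].copy()
    if len(valid) == 0:
        return None
    dx = event.x_um - valid["x_um"].to_numpy()
    dy = event.y_um - valid["y_um"].to_numpy()
    dist = np.hypot(dx, dy)
    keep = dist > 1e-9
    if r_max_um is not None:
        keep &= dist <= r_max_um
    if not keep.any():
        return None
    dx, dy, dist = dx[keep], dy[keep], dist[keep]
    u = valid["u_um_min"].to_numpy()[keep]
    v = valid["v_um_min"].to_numpy()[keep]
    inflow = (u * dx + v * dy) / dist
    return float(inflow.mean())
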
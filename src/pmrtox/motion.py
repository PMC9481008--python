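"""Frame-differencing motion quantification.

Replaces the commercial tracking step with a defined, reproducible statistic:
the activity of a well at frame *t* is the fraction of pixels whose intensity
changed by more than ``change_threshold`` between frames *t-1* and *t*.  The
downstream analysis consumes only this changed-pixel fraction, averaged per
second.
"""

from __future__ import annotations

import logging

import numpy as np

from .protocol import PlateLayout
from .trace import ActivityTrace

__all__ = ["quantify_motion", "bin_per_second", "grid_wells", "DEFAULT_CHANGE_THRESHOLD"]

logger = logging.getLogger(__name__)

#: Default intensity-change threshold: ~4% of the 8-bit range, enough to
#: suppress sensor noise without tracking.
DEFAULT_CHANGE_THRESHOLD = 10.0


def quantify_motion(
    stack: np.ndarray,
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
    frame_rate: float = 16.0,
    **trace_meta,
) -> ActivityTrace:
    """Per-frame activity from an image stack.

    Parameters
    ----------
    stack
        ``(T, H, W)`` array of grayscale frames, ``T >= 2``, constant frame
        interval.
    change_threshold
        Absolute intensity difference above which a pixel counts as changed.

    Returns
    -------
    ActivityTrace
        Per-frame trace; the first frame has no predecessor and gets
        activity 0.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a (T, H, W) array")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    # signed arithmetic: uint8 subtraction would wrap around
    diffs = np.abs(np.diff(stack.astype(np.int64), axis=0))
    changed = (diffs > change_threshold).mean(axis=(1, 2))
    activity = np.concatenate([[0.0], changed])
    time_s = np.arange(stack.shape[0]) / frame_rate
    meta = dict(well_id="A1", sampling="frame", frame_rate=frame_rate)
    meta.update(trace_meta)
    return ActivityTrace(time_s=time_s, activity=activity, **meta)


def bin_per_second(trace: ActivityTrace, frame_rate: float | None = None) -> ActivityTrace:
    """Average a per-frame trace to one value per second.

    A 50 s recording at 16 frames/s (800 frames) yields 50 values.  A partial
    trailing second is dropped with a logged warning.  The per-second sample
    at time ``t`` is the arithmetic mean of the frames in ``[t, t+1)``.
    """
    if trace.sampling != "frame":
        raise ValueError("bin_per_second expects a per-frame trace")
    fr = frame_rate if frame_rate is not None else trace.frame_rate
    if not fr > 0 or abs(fr - round(fr)) > 1e-9:
        raise ValueError("frame_rate must be a positive integer count per second")
    fr = int(round(fr))
    n = len(trace)
    n_sec = n // fr
    if n_sec * fr != n:
        logger.warning(
            "dropping partial trailing second (%d of %d frames unused)",
            n - n_sec * fr, n,
        )
    per_sec = trace.activity[: n_sec * fr].reshape(n_sec, fr).mean(axis=1)
    t0 = trace.time_s[0] if n else 0.0
    return trace.with_(
        time_s=t0 + np.arange(n_sec, dtype=float),
        activity=per_sec,
        sampling="second",
    )


def grid_wells(stack: np.ndarray, layout: PlateLayout) -> dict[str, np.ndarray]:
    """Split a whole-plate image stack into per-well sub-stacks.

    Frame dimensions must divide evenly into the layout's rows x columns grid
    of uniform rectangular ROIs.  Returns a dict keyed by well id in row-major
    order A1 ... H12.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a (T, H, W) array")
    _, h, w = stack.shape
    if h % layout.rows or w % layout.columns:
        pad_h = (-h) % layout.rows
        pad_w = (-w) % layout.columns
        raise ValueError(
            f"frame shape ({h}, {w}) not divisible into a "
            f"{layout.rows}x{layout.columns} grid; pad by ({pad_h}, {pad_w})"
        )
    wh, ww = h // layout.rows, w // layout.columns
    wells: dict[str, np.ndarray] = {}
    for ri, r in enumerate(layout.row_labels):
        for ci in range(layout.columns):
            wells[f"{r}{ci + 1}"] = stack[
                :, ri * wh : (ri + 1) * wh, ci * ww : (ci + 1) * ww
            ]
    return wells
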
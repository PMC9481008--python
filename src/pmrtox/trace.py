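"""Per-well activity traces.

An :class:`ActivityTrace` is the unit record of the assay: for one well it
holds the fraction of pixels that changed between consecutive video frames
(per-frame sampling) or the mean of those fractions within each second
(per-second sampling), together with exposure metadata and an embryo status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["ActivityTrace", "STATUSES"]

STATUSES = ("alive", "dead", "untrackable")


@dataclass
class ActivityTrace:
    """Activity time series for a single well.

    Attributes
    ----------
    well_id
        Plate coordinate, e.g. ``"A1"``.
    time_s
        Sample times in seconds from recording start, strictly increasing.
        For per-second traces the time stamps the *start* of the averaged
        second.
    activity
        Changed-pixel fraction in ``[0, 1]``, same length as ``time_s``.
    status
        ``alive``, ``dead`` (at the 24 hpf viability check) or
        ``untrackable`` (well too turbid for imaging).
    concentration
        Nominal exposure concentration (mass/volume units of the study).
    group
        ``"control"`` or ``"treatment"``.
    age_hpf
        Embryo age at recording, hours post-fertilization.
    sampling
        ``"frame"`` or ``"second"``.
    """

    well_id: str
    time_s: np.ndarray
    activity: np.ndarray
    status: Literal["alive", "dead", "untrackable"] = "alive"
    concentration: float = 0.0
    group: Literal["control", "treatment"] = "control"
    age_hpf: float = 30.0
    sampling: Literal["frame", "second"] = "frame"
    frame_rate: float = 16.0
    plate: str = "P1"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.time_s.shape != self.activity.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and activity must be 1-D and equal length")
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if len(self.activity) and (
            np.min(self.activity) < 0 or np.max(self.activity) > 1
        ):
            raise ValueError("activity values must lie in [0, 1]")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    def __len__(self) -> int:
        return len(self.activity)

    def with_(self, **changes) -> "ActivityTrace":
        return replace(self, **changes)
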
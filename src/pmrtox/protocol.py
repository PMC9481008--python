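"""Assay protocol and plate-layout definitions.

The photomotor response (PMR) assay records a 96-well plate of ~30 hpf
zebrafish embryos for 50 seconds: a 30 s dark *background* period, then a 1 s
bright white-light flash (18,000 lx) opening the 10 s *excitatory* phase, then
a second identical flash opening the 10 s *refractory* phase during which the
response is normally muted.  Every scoring operation in this package takes its
temporal skeleton from :class:`PMRProtocol`.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

__all__ = ["PMRProtocol", "PlateLayout", "PHASES"]

#: Canonical phase names, in temporal order.
PHASES = ("background", "excitatory", "refractory")


@dataclass(frozen=True)
class PMRProtocol:
    """Temporal structure of one PMR recording.

    Phase windows are half-open ``[start, end)`` intervals in seconds from the
    start of recording.  The windows must be pairwise disjoint and contiguous,
    and each flash must coincide with the start of the excitatory and
    refractory windows respectively.

    Parameters
    ----------
    background, excitatory, refractory
        ``(start, end)`` second intervals of the three phases.
    flash_times
        Onset times of the light flashes, seconds.
    flash_duration
        Duration of each flash, seconds (metadata; the camera keeps rolling).
    flash_intensity_lux
        Flash intensity (metadata).
    frame_rate
        Camera acquisition rate, frames per second.
    """

    background: tuple[float, float] = (0.0, 30.0)
    excitatory: tuple[float, float] = (30.0, 40.0)
    refractory: tuple[float, float] = (40.0, 50.0)
    flash_times: tuple[float, ...] = (30.0, 40.0)
    flash_duration: float = 1.0
    flash_intensity_lux: float = 18_000.0
    frame_rate: float = 16.0

    def __post_init__(self) -> None:
        for name in PHASES:
            a, b = getattr(self, name)
            if not b > a:
                raise ValueError(f"{name} window {a, b} is empty or reversed")
        if self.background[1] != self.excitatory[0]:
            raise ValueError("background and excitatory windows must be contiguous")
        if self.excitatory[1] != self.refractory[0]:
            raise ValueError("excitatory and refractory windows must be contiguous")
        if tuple(self.flash_times) != (self.excitatory[0], self.refractory[0]):
            raise ValueError(
                "flashes must coincide with the starts of the excitatory "
                "and refractory windows"
            )
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def start(self) -> float:
        return self.background[0]

    @property
    def duration(self) -> float:
        """Total recording length in seconds."""
        return self.refractory[1] - self.background[0]

    @property
    def n_frames(self) -> int:
        """Number of frames in a full recording (duration x frame rate)."""
        n = self.duration * self.frame_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x frame_rate is not a whole frame count")
        return int(round(n))

    @property
    def windows(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in PHASES}

    def phase_duration(self, phase: str) -> float:
        a, b = self.windows[phase]
        return b - a


def _default_pairs() -> tuple[tuple[int, int], ...]:
    # columns 5-1 and 11-7 in increasing concentration; each treatment
    # occupies one column in each plate half
    return tuple((5 - j, 11 - j) for j in range(5))


@dataclass(frozen=True)
class PlateLayout:
    """Well-to-treatment assignment on a 96-well plate.

    The standard design places control embryos in columns 6 and 12 and the
    treatment series on column pairs (5, 11) ... (1, 7) in increasing
    concentration, so each concentration has ``rows x 2`` embryos per plate
    (32 with the default two replicate plates).
    """

    rows: int = 8
    columns: int = 12
    control_columns: frozenset[int] = frozenset({6, 12})
    treatment_column_pairs: tuple[tuple[int, int], ...] = field(
        default_factory=_default_pairs
    )
    replicate_plates: int = 2

    def __post_init__(self) -> None:
        if self.rows < 1 or self.columns < 1 or self.replicate_plates < 1:
            raise ValueError("rows, columns and replicate_plates must be >= 1")
        cols = set(range(1, self.columns + 1))
        used = set(self.control_columns)
        if not used <= cols:
            raise ValueError("control columns outside the plate")
        for pair in self.treatment_column_pairs:
            for c in pair:
                if c not in cols:
                    raise ValueError(f"treatment column {c} outside the plate")
                if c in used:
                    raise ValueError(f"column {c} assigned twice")
                used.add(c)

    @property
    def row_labels(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: self.rows])

    @property
    def max_treatments(self) -> int:
        return len(self.treatment_column_pairs)

    def wells_per_treatment(self) -> int:
        """Embryos per concentration across all replicate plates."""
        return self.rows * 2 * self.replicate_plates

    def column_concentrations(
        self, concentrations: list[float]
    ) -> dict[int, float]:
        """Map plate column -> concentration (controls map to 0).

        ``concentrations`` must be sorted ascending and fit in the available
        treatment column pairs; unused pairs are left unassigned.
        """
        if len(concentrations) > self.max_treatments:
            raise ValueError(
                f"{len(concentrations)} concentrations but only "
                f"{self.max_treatments} treatment column pairs"
            )
        if sorted(concentrations) != list(concentrations):
            raise ValueError("concentrations must be in increasing order")
        mapping = {c: 0.0 for c in self.control_columns}
        for conc, pair in zip(concentrations, self.treatment_column_pairs):
            for col in pair:
                mapping[col] = conc
        return mapping

    def well_ids(self) -> list[str]:
        """Row-major well identifiers A1 ... H12."""
        return [
            f"{r}{c}" for r in self.row_labels for c in range(1, self.columns + 1)
        ]
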
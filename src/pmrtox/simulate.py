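"""Synthetic PMR data generator.

Emulates the statistical structure of the screening assay so every downstream
stage is testable without any recorded data: per-embryo activity traces over
the three-phase protocol, full plate layouts with the standard control/
treatment column convention, toy grayscale well videos whose changed-pixel
fraction encodes a given trace, and binomial quantal mortality tables from a
log-logistic concentration-response curve.

Behavioral dose effects are modelled as multiplicative log-logistic scaling of
the per-phase activity means (interpretable as behavioral EC50s); mortality is
log-logistic in concentration; non-responding embryos and dead embryos both
emit all-zero traces but carry distinct statuses because the analysis filters
them by different rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .protocol import PHASES, PlateLayout, PMRProtocol
from .trace import ActivityTrace

__all__ = [
    "EffectModel",
    "DissolutionProfile",
    "simulate_embryo_trace",
    "simulate_plate",
    "simulate_frames",
    "simulate_plate_frames",
    "simulate_mortality_table",
    "simulate_timeseries_cohort",
    "nanosilver_effect",
    "null_stimulus_effect",
]


@dataclass(frozen=True)
class DissolutionProfile:
    """Free-ion mass fraction of a metal nanomaterial suspension (ICP-MS)."""

    material_id: str
    free_ion_fraction: float
    measurement_date: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.free_ion_fraction <= 1.0:
            raise ValueError("free_ion_fraction must lie in [0, 1]")


def _phase_dict(value) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(PHASES) - set(value)
        if missing:
            raise ValueError(f"missing phases {missing}")
        return {p: float(value[p]) for p in PHASES}
    return {p: float(value) for p in PHASES}


@dataclass
class EffectModel:
    """Dose-effect structure of one simulated exposure scenario.

    ``baseline_activity`` gives the mean per-second changed-pixel fraction of
    an unexposed embryo in each phase; dose effects scale those means by
    log-logistic factors with half-maximal concentrations ``hypo_potency`` /
    ``hyper_potency`` (``inf`` disables the effect).  Mortality is a
    log-logistic quantal curve with parameters ``mortality_lc50`` and
    ``mortality_slope``.  ``excitatory_ramp`` maps age (hpf) to the excitatory
    magnitude multiplier via piecewise-linear interpolation; the default knots
    rise steeply between 30 and 31 hpf and level off just below the 31 hpf
    peak.
    """

    baseline_activity: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.05,
            "excitatory": 0.25,
            "refractory": 0.08,
        }
    )
    hypo_potency: dict[str, float] | float = math.inf
    hyper_potency: dict[str, float] | float = math.inf
    hyper_amplitude: float = 1.0
    hill_slope: float = 2.0
    mortality_lc50: float = math.inf
    mortality_slope: float = 2.0
    nonresponder_rate: float = 0.005
    noise_sd: float = 0.02
    embryo_sd: float = 0.25
    excitatory_ramp: dict[float, float] = field(
        default_factory=lambda: {24.0: 0.35, 30.0: 0.55, 31.0: 1.0, 32.0: 0.97}
    )
    background_ramp: dict[float, float] = field(
        default_factory=lambda: {24.0: 0.7, 32.0: 1.15}
    )
    excitatory_decay_s: float = 3.0

    def __post_init__(self) -> None:
        self.baseline_activity = _phase_dict(self.baseline_activity)
        self.hypo_potency = _phase_dict(self.hypo_potency)
        self.hyper_potency = _phase_dict(self.hyper_potency)
        if not 0.0 <= self.nonresponder_rate <= 1.0:
            raise ValueError("nonresponder_rate must lie in [0, 1]")
        if any(v <= 0 for v in self.hypo_potency.values()):
            raise ValueError("hypo_potency values must be positive")
        if any(v <= 0 for v in self.hyper_potency.values()):
            raise ValueError("hyper_potency values must be positive")
        if self.noise_sd < 0 or self.embryo_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if not self.mortality_lc50 > 0:
            raise ValueError("mortality_lc50 must be positive")

    # -- effect curves -----------------------------------------------------
    def dose_scale(self, phase: str, concentration: float) -> float:
        """Multiplicative activity scaling at a given concentration."""
        c = float(concentration)
        scale = 1.0
        ec_hypo = self.hypo_potency[phase]
        if math.isfinite(ec_hypo) and c > 0:
            scale /= 1.0 + (c / ec_hypo) ** self.hill_slope
        ec_hyper = self.hyper_potency[phase]
        if math.isfinite(ec_hyper) and c > 0:
            frac = c**self.hill_slope / (c**self.hill_slope + ec_hyper**self.hill_slope)
            scale *= 1.0 + self.hyper_amplitude * frac
        return scale

    def mortality_prob(self, concentration: float) -> float:
        c = float(concentration)
        if c <= 0 or not math.isfinite(self.mortality_lc50):
            return 0.0
        return 1.0 / (1.0 + (self.mortality_lc50 / c) ** self.mortality_slope)

    def age_scale(self, phase: str, age_hpf: float) -> float:
        knots = {
            "excitatory": self.excitatory_ramp,
            "background": self.background_ramp,
            "refractory": {24.0: 1.0, 32.0: 1.0},
        }[phase]
        xs = np.array(sorted(knots))
        ys = np.array([knots[x] for x in xs])
        return float(np.interp(age_hpf, xs, ys))


def null_stimulus_effect(level: float = 0.08) -> EffectModel:
    """Scenario preset with no stimulus response: all three phases share one
    activity level, the post-flash burst is flattened and the developmental
    ramps are constant.  Used to calibrate type-I error of the
    excitatory-vs-background comparison."""
    return EffectModel(
        baseline_activity={p: level for p in PHASES},
        excitatory_decay_s=math.inf,
        excitatory_ramp={24.0: 1.0, 32.0: 1.0},
        background_ramp={24.0: 1.0, 32.0: 1.0},
        nonresponder_rate=0.0,
    )


def nanosilver_effect() -> EffectModel:
    """Scenario preset mirroring the 25 nm nanosilver response pattern:
    hypoactivity in the background and excitatory phases and a finite LC50."""
    return EffectModel(
        hypo_potency={"background": 2.0, "excitatory": 5.0, "refractory": math.inf},
        mortality_lc50=25.0,
        mortality_slope=3.0,
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _mean_profile(
    protocol: PMRProtocol, effect: EffectModel, concentration: float, age_hpf: float
) -> np.ndarray:
    """Expected per-frame activity over the full recording."""
    n = protocol.n_frames
    t = protocol.start + (np.arange(n) + 0.5) / protocol.frame_rate
    mean = np.zeros(n)
    for phase in PHASES:
        a, b = protocol.windows[phase]
        sel = (t >= a) & (t < b)
        level = (
            effect.baseline_activity[phase]
            * effect.dose_scale(phase, concentration)
            * effect.age_scale(phase, age_hpf)
        )
        if phase in ("excitatory", "refractory"):
            # post-flash burst decaying within the phase, normalized so the
            # phase mean stays at `level`
            tau = effect.excitatory_decay_s
            if math.isfinite(tau):
                rel = t[sel] - a
                width = b - a
                shape = np.exp(-rel / tau)
                shape /= tau * (1.0 - math.exp(-width / tau)) / width
                mean[sel] = level * shape
            else:
                mean[sel] = level
        else:
            mean[sel] = level
    return mean


def simulate_embryo_trace(
    protocol: PMRProtocol,
    effect: EffectModel,
    concentration: float,
    age_hpf: float = 30.0,
    seed: int | np.random.Generator = 0,
    well_id: str = "A1",
    plate: str = "P1",
    group: str | None = None,
) -> ActivityTrace:
    """Simulate one embryo's per-frame activity trace.

    Dead embryos (log-logistic mortality in concentration) and non-responders
    (Bernoulli with ``effect.nonresponder_rate``) emit all-zero traces with
    statuses ``"dead"`` and ``"alive"`` respectively; all other embryos emit
    the phase-structured mean profile scaled by a per-embryo lognormal factor
    plus Gaussian frame noise, clipped to [0, 1].
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if not 24.0 <= age_hpf <= 32.0:
        raise ValueError("age_hpf must lie in [24, 32]")
    rng = _rng(seed)
    n = protocol.n_frames
    time_s = protocol.start + np.arange(n) / protocol.frame_rate
    if group is None:
        group = "control" if concentration == 0 else "treatment"
    meta = dict(
        well_id=well_id,
        plate=plate,
        concentration=float(concentration),
        group=group,
        age_hpf=float(age_hpf),
        sampling="frame",
        frame_rate=protocol.frame_rate,
    )

    dead = rng.random() < effect.mortality_prob(concentration)
    nonresponder = rng.random() < effect.nonresponder_rate
    if dead or nonresponder:
        return ActivityTrace(
            time_s=time_s,
            activity=np.zeros(n),
            status="dead" if dead else "alive",
            **meta,
        )
    mean = _mean_profile(protocol, effect, concentration, age_hpf)
    embryo_mult = (
        math.exp(rng.normal(0.0, effect.embryo_sd)) if effect.embryo_sd else 1.0
    )
    noise = rng.normal(0.0, effect.noise_sd, n) if effect.noise_sd else 0.0
    activity = np.clip(mean * embryo_mult + noise, 0.0, 1.0)
    return ActivityTrace(time_s=time_s, activity=activity, status="alive", **meta)


def simulate_plate(
    layout: PlateLayout,
    effect: EffectModel,
    concentrations: list[float],
    seed: int = 0,
    protocol: PMRProtocol | None = None,
    age_hpf: float = 30.0,
    turbidity_threshold: float | None = None,
) -> tuple[list[ActivityTrace], "pandas.DataFrame"]:
    """Simulate all wells of ``layout.replicate_plates`` plates.

    Returns the traces plus a tidy plate map (plate, well, row, column,
    concentration, group).  Wells above ``turbidity_threshold`` (if given) are
    marked ``"untrackable"`` without altering their traces.
    """
    import pandas as pd

    protocol = protocol or PMRProtocol()
    col_conc = layout.column_concentrations(list(concentrations))
    ss = np.random.SeedSequence(seed)
    n_wells = layout.rows * layout.columns * layout.replicate_plates
    children = ss.spawn(n_wells)

    traces: list[ActivityTrace] = []
    rows = []
    i = 0
    for p in range(1, layout.replicate_plates + 1):
        plate = f"P{p}"
        for r in layout.row_labels:
            for c in range(1, layout.columns + 1):
                child = children[i]
                i += 1
                if c not in col_conc:
                    continue  # unused treatment column
                conc = col_conc[c]
                group = "control" if c in layout.control_columns else "treatment"
                tr = simulate_embryo_trace(
                    protocol,
                    effect,
                    conc,
                    age_hpf=age_hpf,
                    seed=np.random.default_rng(child),
                    well_id=f"{r}{c}",
                    plate=plate,
                    group=group,
                )
                if (
                    turbidity_threshold is not None
                    and conc > turbidity_threshold
                    and tr.status == "alive"
                ):
                    tr = tr.with_(status="untrackable")
                traces.append(tr)
                rows.append(
                    dict(plate=plate, well=f"{r}{c}", row=r, column=c,
                         concentration=conc, group=group)
                )
    return traces, pd.DataFrame(rows)


def simulate_timeseries_cohort(
    protocol: PMRProtocol,
    effect: EffectModel,
    n_embryos: int,
    ages: Sequence[float] = tuple(range(24, 33)),
    seed: int = 0,
) -> list[ActivityTrace]:
    """Simulate a developmental cohort re-tested at every age.

    Emulates the time-series design in which the *same* plates of control
    embryos are recorded once per hour from 24 to 32 hpf: each embryo keeps
    its individual activity multiplier across ages (a paired design), while
    frame noise and non-responder status are drawn fresh at every age.
    Returns one per-frame trace per embryo per age.
    """
    ss = np.random.SeedSequence(seed)
    embryo_seqs = ss.spawn(n_embryos)
    traces: list[ActivityTrace] = []
    for i, eseq in enumerate(embryo_seqs):
        head = np.random.default_rng(eseq.spawn(1)[0])
        mult = (
            math.exp(head.normal(0.0, effect.embryo_sd)) if effect.embryo_sd else 1.0
        )
        fixed = EffectModel(
            **{
                **{f: getattr(effect, f) for f in (
                    "baseline_activity", "hypo_potency", "hyper_potency",
                    "hyper_amplitude", "hill_slope", "mortality_lc50",
                    "mortality_slope", "nonresponder_rate", "noise_sd",
                    "excitatory_ramp", "background_ramp", "excitatory_decay_s",
                )},
                "embryo_sd": 0.0,
            }
        )
        for age, aseq in zip(ages, eseq.spawn(len(ages))):
            rng = np.random.default_rng(aseq)
            tr = simulate_embryo_trace(
                protocol, fixed, 0.0, age_hpf=float(age), seed=rng,
                well_id=f"W{i}",
            )
            if tr.status == "alive" and tr.activity.any():
                tr = tr.with_(activity=np.clip(tr.activity * mult, 0.0, 1.0))
            traces.append(tr)
    return traces


def simulate_frames(
    trace: ActivityTrace,
    well_size: int = 16,
    seed: int | np.random.Generator = 0,
    low: int = 40,
    high: int = 200,
) -> np.ndarray:
    """Render a trace as a toy grayscale image stack.

    Produces a ``(T, well_size, well_size)`` uint8 stack in which the fraction
    of pixels whose intensity changes between consecutive frames equals the
    trace's activity at that step to within half a pixel (``0.5 / well_size**2``).
    Changed pixels toggle between two gray levels whose difference exceeds any
    reasonable change threshold.  The first activity value has no preceding
    frame and is ignored.
    """
    a = np.asarray(trace.activity, dtype=float)
    if a.size and (a.min() < 0 or a.max() > 1):
        raise ValueError("activity values must lie in [0, 1]")
    rng = _rng(seed)
    npix = well_size * well_size
    frames = np.empty((a.size, well_size, well_size), dtype=np.uint8)
    if a.size == 0:
        return frames
    frames[0] = low
    flat_prev = frames[0].reshape(-1)
    for t in range(1, a.size):
        flat = flat_prev.copy()
        k = int(round(a[t] * npix))
        if k:
            idx = rng.choice(npix, size=k, replace=False)
            flat[idx] = np.where(flat[idx] == low, high, low)
        frames[t] = flat.reshape(well_size, well_size)
        flat_prev = flat
    return frames


def simulate_plate_frames(
    traces: list[ActivityTrace],
    layout: PlateLayout,
    well_size: int = 16,
    seed: int = 0,
    plate: str | None = None,
) -> np.ndarray:
    """Tile single-well stacks into one whole-plate image stack.

    Wells without a trace (unused columns) stay constant.  Only traces from
    one physical plate may be tiled; pass ``plate`` to select.
    """
    if plate is not None:
        traces = [t for t in traces if t.plate == plate]
    by_well = {t.well_id: t for t in traces}
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValueError("all traces must have the same length")
    (nframes,) = lengths
    stack = np.full(
        (nframes, layout.rows * well_size, layout.columns * well_size),
        64,
        dtype=np.uint8,
    )
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(by_well)))
    for ri, r in enumerate(layout.row_labels):
        for ci in range(layout.columns):
            wid = f"{r}{ci + 1}"
            if wid not in by_well:
                continue
            sub = simulate_frames(
                by_well[wid], well_size=well_size,
                seed=np.random.default_rng(next(children)),
            )
            stack[
                :,
                ri * well_size : (ri + 1) * well_size,
                ci * well_size : (ci + 1) * well_size,
            ] = sub
    return stack


def simulate_mortality_table(
    concentrations: list[float],
    n_per_group: int,
    true_lc50: float,
    slope: float = 2.0,
    control_mortality: float = 0.0,
    seed: int | np.random.Generator = 0,
    control_n: int | None = None,
):
    """Binomial quantal mortality counts from a log-logistic curve.

    Death probability ``p(c) = p0 + (1 - p0) / (1 + (LC50 / c)**slope)``.
    Returns a :class:`~pmrtox.doseresponse.ConcResponseTable` with a control
    group of ``control_n`` embryos (default ``n_per_group``).
    """
    from .doseresponse import ConcResponseTable

    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not true_lc50 > 0:
        raise ValueError("true_lc50 must be positive")
    if not 0.0 <= control_mortality < 1.0:
        raise ValueError("control_mortality must lie in [0, 1)")
    conc = np.asarray(sorted(concentrations), dtype=float)
    if conc.size and conc[0] <= 0:
        raise ValueError("concentrations must be positive")
    rng = _rng(seed)
    p = control_mortality + (1.0 - control_mortality) / (
        1.0 + (true_lc50 / conc) ** slope
    )
    deaths = rng.binomial(n_per_group, p)
    control_n = n_per_group if control_n is None else control_n
    control_deaths = int(rng.binomial(control_n, control_mortality))
    return ConcResponseTable(
        concentration=conc,
        n=np.full(conc.size, n_per_group),
        affected=deaths,
        control_n=control_n,
        control_affected=control_deaths,
    )
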
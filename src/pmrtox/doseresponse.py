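"""Trimmed Spearman-Karber (TSK) quantal dose-response estimation.

The headline toxicology statistic: given counts of dead (LC50) or malformed
(EC50) embryos by concentration, the estimator

1. removes baseline response with the Abbott correction
   ``p' = max(0, (p - p0) / (1 - p0))``,
2. makes the corrected proportions non-decreasing by pooled-adjacent-violators
   (PAVA) smoothing, weighted by group size,
3. treats the smoothed proportions as a piecewise-linear cdf ``F`` over
   ``x = log10(concentration)``, clips ``F`` to ``[trim, 1 - trim]`` and
   renormalizes, and
4. reports ``10**mu`` where ``mu`` is the mean of ``x`` under the clipped,
   renormalized distribution, computed segment-wise in closed form.

With trim 0 and proportions spanning 0 to 1 this reduces to the classical
Spearman-Karber mean ``sum (p[i+1] - p[i]) * (x[i] + x[i+1]) / 2``.  The
standard error of ``mu`` comes from the delta method under binomial sampling:
the gradient of ``mu`` with respect to the observed group proportions
(control included) is evaluated by finite differences through the full
correction-smoothing-trimming pipeline.  The 95% interval is
``10**(mu +/- 2 SE)``.

Censoring follows the screening convention: if the smoothed proportions never
rise above 0.5 the LC50 is reported as above the highest tested concentration
(e.g. ">500"); if they never fall below 0.5, as below the lowest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .simulate import DissolutionProfile

__all__ = [
    "ConcResponseTable",
    "TSKEstimationError",
    "TrimmedSpearmanKarber",
    "TSKResults",
    "abbott_correct",
    "smooth_monotone",
    "tsk_estimate",
    "adjust_ionic",
    "ec50_malformation",
    "format_estimate",
]

logger = logging.getLogger(__name__)

AUTO_TRIMS = (0.0, 0.05, 0.10, 0.20)


class TSKEstimationError(ValueError):
    """Raised when an estimate cannot be produced from the given table."""


@dataclass
class ConcResponseTable:
    """Quantal outcome counts by concentration, plus a control group.

    ``concentration`` must be strictly increasing and positive; the control
    group (concentration 0) is held separately.
    """

    concentration: np.ndarray
    n: np.ndarray
    affected: np.ndarray
    control_n: int = 0
    control_affected: int = 0

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.affected = np.asarray(self.affected, dtype=int)
        if not (self.concentration.shape == self.n.shape == self.affected.shape):
            raise ValueError("concentration, n and affected must align")
        if self.concentration.ndim != 1:
            raise ValueError("expected 1-D columns")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be positive (control is separate)")
        if np.any(np.diff(self.concentration) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.n < 1):
            raise ValueError("n must be >= 1 in every group")
        if np.any(self.affected < 0) or np.any(self.affected > self.n):
            bad = int(np.argmax((self.affected < 0) | (self.affected > self.n)))
            raise ValueError(f"row {bad}: affected outside [0, n]")
        if not 0 <= self.control_affected <= max(self.control_n, 0):
            raise ValueError("control_affected outside [0, control_n]")

    @property
    def proportions(self) -> np.ndarray:
        return self.affected / self.n

    @property
    def control_proportion(self) -> float:
        return self.control_affected / self.control_n if self.control_n else 0.0

    def scaled(self, factor: float) -> "ConcResponseTable":
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        return replace(self, concentration=self.concentration * factor)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConcResponseTable":
        """Build from a tidy (concentration, n, affected) table; a row at
        concentration 0 becomes the control group."""
        required = {"concentration", "n", "affected"}
        if not required <= set(df.columns):
            raise ValueError(f"missing columns {required - set(df.columns)}")
        df = df.sort_values("concentration").reset_index(drop=True)
        bad = df.index[(df["affected"] < 0) | (df["affected"] > df["n"])]
        if len(bad):
            raise ValueError(f"row {bad[0]}: affected outside [0, n]")
        ctrl = df[df["concentration"] == 0]
        trt = df[df["concentration"] > 0]
        return cls(
            concentration=trt["concentration"].to_numpy(float),
            n=trt["n"].to_numpy(int),
            affected=trt["affected"].to_numpy(int),
            control_n=int(ctrl["n"].sum()),
            control_affected=int(ctrl["affected"].sum()),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        if self.control_n:
            rows.append(dict(concentration=0.0, n=self.control_n,
                             affected=self.control_affected))
        for c, n, a in zip(self.concentration, self.n, self.affected):
            rows.append(dict(concentration=float(c), n=int(n), affected=int(a)))
        return pd.DataFrame(rows)


def abbott_correct(
    proportions: Sequence[float] | ConcResponseTable,
    control_proportion: float | None = None,
) -> np.ndarray:
    """Abbott baseline correction ``p' = max(0, (p - p0) / (1 - p0))``."""
    if isinstance(proportions, ConcResponseTable):
        p0 = proportions.control_proportion
        p = proportions.proportions
    else:
        p = np.asarray(proportions, dtype=float)
        p0 = float(control_proportion or 0.0)
    if p0 >= 1.0:
        raise TSKEstimationError("control response is total: estimation impossible")
    return np.maximum(0.0, (p - p0) / (1.0 - p0))


def smooth_monotone(
    proportions: Sequence[float], weights: Sequence[float] | None = None
) -> np.ndarray:
    """Weighted pooled-adjacent-violators smoothing to a non-decreasing
    sequence (preserves the weighted mean)."""
    p = np.asarray(proportions, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    return isotonic_regression(p, weights=w).x.copy()


def _trimmed_log_mean(x: np.ndarray, p: np.ndarray, trim: float) -> float:
    """Mean of log10 concentration under the clipped, renormalized
    piecewise-linear cdf through (x, p).  Requires interpolable trim
    quantiles: p[0] <= trim and p[-1] >= 1 - trim."""
    lo, hi = trim, 1.0 - trim
    total = 0.0
    for i in range(len(x) - 1):
        p0, p1 = p[i], p[i + 1]
        if p1 <= p0:
            continue  # flat segment carries no mass
        pl, pu = max(p0, lo), min(p1, hi)
        if pu <= pl:
            continue
        xa = x[i] + (pl - p0) / (p1 - p0) * (x[i + 1] - x[i])
        xb = x[i] + (pu - p0) / (p1 - p0) * (x[i + 1] - x[i])
        total += (pu - pl) * 0.5 * (xa + xb)
    return total / (hi - lo)


def _pipeline_mu(
    x: np.ndarray, p_raw: np.ndarray, p0: float, weights: np.ndarray, trim: float
) -> float:
    """Raw observed proportions -> trimmed log10 mean, or NaN if the trim
    quantiles are not interpolable after correction and smoothing."""
    if p0 >= 1.0:
        return math.nan
    corrected = np.maximum(0.0, (p_raw - p0) / (1.0 - p0))
    smoothed = smooth_monotone(corrected, weights)
    if smoothed[0] > trim + 1e-12 or smoothed[-1] < 1.0 - trim - 1e-12:
        return math.nan
    return _trimmed_log_mean(x, smoothed, trim)


@dataclass
class TSKResults:
    """Fitted Trimmed Spearman-Karber estimate.

    ``estimate`` is ``None`` for censored results, which instead carry the
    bounding concentration in ``bound``.
    """

    estimate: float | None
    ci_lower: float | None
    ci_upper: float | None
    se_log10: float | None
    trim: float
    censoring: Literal["none", "below_lowest", "above_highest"]
    bound: float | None
    endpoint: Literal["LC50", "EC50"]
    table: ConcResponseTable | None = None
    corrected: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def conf_int(self) -> tuple[float, float]:
        if self.censoring != "none":
            raise TSKEstimationError("censored result has no confidence interval")
        return (self.ci_lower, self.ci_upper)

    def __str__(self) -> str:
        return format_estimate(self)

    def summary(self, sig_figs: int = 2) -> str:
        lines = [
            f"Trimmed Spearman-Karber {self.endpoint} estimate",
            "=" * 46,
        ]
        if self.table is not None:
            lines.append(
                "concentrations: "
                + ", ".join(f"{c:g}" for c in self.table.concentration)
            )
            lines.append(
                "raw proportions: "
                + ", ".join(f"{p:.3f}" for p in self.table.proportions)
            )
        if self.smoothed is not None:
            lines.append(
                "smoothed proportions: "
                + ", ".join(f"{p:.3f}" for p in self.smoothed)
            )
        lines.append(f"trim: {self.trim:g}")
        if self.censoring == "none":
            lines.append(f"{self.endpoint}: {_round_sig(self.estimate, sig_figs):g}")
            lines.append(
                f"95% CI: [{_round_sig(self.ci_lower, sig_figs):g}, "
                f"{_round_sig(self.ci_upper, sig_figs):g}]"
            )
        else:
            lines.append(f"{self.endpoint}: {format_estimate(self)} (censored)")
        for k, v in self.provenance.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot raw and smoothed proportions against log10 concentration,
        with the estimate and CI marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.log10(self.table.concentration)
        ax.plot(x, self.table.proportions, "o", label="observed")
        if self.smoothed is not None:
            ax.plot(x, self.smoothed, "-", label="corrected + smoothed")
        if self.censoring == "none":
            ax.axvline(math.log10(self.estimate), color="k", ls="--",
                       label=f"{self.endpoint}")
            ax.axvspan(math.log10(self.ci_lower), math.log10(self.ci_upper),
                       alpha=0.15, color="k")
        ax.axhline(0.5, color="gray", lw=0.5)
        ax.set_xlabel("log10 concentration")
        ax.set_ylabel("affected proportion")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return dict(
            endpoint=self.endpoint,
            estimate=self.estimate,
            ci_lower=self.ci_lower,
            ci_upper=self.ci_upper,
            se_log10=self.se_log10,
            trim=self.trim,
            censoring=self.censoring,
            bound=self.bound,
            report=format_estimate(self),
            provenance=dict(self.provenance),
        )


class TrimmedSpearmanKarber:
    """Model object for TSK estimation from a :class:`ConcResponseTable`.

    Parameters
    ----------
    table
        Quantal outcome counts (validated on construction).
    trim
        Trim fraction in ``[0, 0.5)`` or ``"auto"`` (the smallest of
        0, 0.05, 0.10, 0.20 whose quantiles are interpolable after
        smoothing).
    endpoint
        ``"LC50"`` (mortality) or ``"EC50"`` (malformation).
    """

    def __init__(
        self,
        table: ConcResponseTable | pd.DataFrame,
        trim: float | str = "auto",
        endpoint: str = "LC50",
    ):
        if isinstance(table, pd.DataFrame):
            table = ConcResponseTable.from_dataframe(table)
        self.table = table
        if trim != "auto":
            trim = float(trim)
            if not 0.0 <= trim < 0.5:
                raise TSKEstimationError("trim must lie in [0, 0.5)")
        self.trim = trim
        if endpoint not in ("LC50", "EC50"):
            raise ValueError("endpoint must be LC50 or EC50")
        self.endpoint = endpoint

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TrimmedSpearmanKarber":
        return cls(ConcResponseTable.from_dataframe(df), **kwargs)

    def fit(self) -> TSKResults:
        t = self.table
        if len(t.concentration) < 2:
            raise TSKEstimationError("need at least two positive concentrations")
        x = np.log10(t.concentration)
        w = t.n.astype(float)
        p_raw = t.proportions
        p0 = t.control_proportion
        corrected = abbott_correct(p_raw, p0)
        smoothed = smooth_monotone(corrected, w)

        base = dict(trim=0.0, endpoint=self.endpoint, table=t,
                    corrected=corrected, smoothed=smoothed)
        above = bool(np.all(smoothed <= 0.5))
        below = bool(np.all(smoothed >= 0.5))
        if above and below:
            raise TSKEstimationError("response is 0.5 everywhere: no information")
        if above:
            return TSKResults(None, None, None, None, censoring="above_highest",
                              bound=float(t.concentration[-1]), **base)
        if below:
            return TSKResults(None, None, None, None, censoring="below_lowest",
                              bound=float(t.concentration[0]), **base)

        trim = self._choose_trim(smoothed)
        mu = _trimmed_log_mean(x, smoothed, trim)
        se = self._delta_se(x, p_raw, p0, w, trim)
        est = 10.0**mu
        ci = (10.0 ** (mu - 2.0 * se), 10.0 ** (mu + 2.0 * se))
        base["trim"] = trim
        return TSKResults(est, ci[0], ci[1], se, censoring="none", bound=None, **base)

    # -- internals ---------------------------------------------------------
    def _choose_trim(self, smoothed: np.ndarray) -> float:
        candidates = AUTO_TRIMS if self.trim == "auto" else (self.trim,)
        for a in candidates:
            if smoothed[0] <= a + 1e-12 and smoothed[-1] >= 1.0 - a - 1e-12:
                return a
        raise TSKEstimationError(
            f"trim quantiles not interpolable (smoothed span "
            f"[{smoothed[0]:.3f}, {smoothed[-1]:.3f}], tried {candidates})"
        )

    def _delta_se(
        self, x: np.ndarray, p_raw: np.ndarray, p0: float,
        w: np.ndarray, trim: float,
    ) -> float:
        """Delta-method SE of the trimmed log10 mean under binomial sampling.

        Central finite differences of mu through the full pipeline w.r.t.
        each observed proportion (one-sided at the [0, 1] boundary), with the
        trim held fixed; variance of each proportion is p(1-p)/n at the raw
        observed value, which is what a within-group resampling bootstrap
        sees.
        """
        h = 1e-4

        def mu_of(p_vec: np.ndarray, p0_val: float) -> float:
            return _pipeline_mu(x, p_vec, p0_val, w, trim)

        var = 0.0
        for i in range(len(p_raw) + 1):
            if i < len(p_raw):
                val, n_i = p_raw[i], self.table.n[i]
            else:
                if not self.table.control_n:
                    break
                val, n_i = p0, self.table.control_n
            lo, hi = max(0.0, val - h), min(1.0, val + h)
            if hi <= lo:
                continue

            def perturbed(v: float) -> float:
                if i < len(p_raw):
                    pv = p_raw.copy()
                    pv[i] = v
                    return mu_of(pv, p0)
                return mu_of(p_raw, v)

            f_hi, f_lo = perturbed(hi), perturbed(lo)
            if math.isnan(f_hi) or math.isnan(f_lo):
                continue  # perturbation leaves the interpolable region
            g = (f_hi - f_lo) / (hi - lo)
            var += g * g * val * (1.0 - val) / n_i
        return math.sqrt(var)


def tsk_estimate(
    table: ConcResponseTable | pd.DataFrame,
    trim: float | str = "auto",
    endpoint: str = "LC50",
) -> TSKResults:
    """Convenience wrapper: fit a :class:`TrimmedSpearmanKarber` model."""
    return TrimmedSpearmanKarber(table, trim=trim, endpoint=endpoint).fit()


def adjust_ionic(
    obj: TSKResults | ConcResponseTable, profile: DissolutionProfile
):
    """Re-express nominal nanoparticle doses as free-ion doses.

    Multiplies every concentration by the free-ion mass fraction; by the
    estimator's exact scale equivariance an already-fitted estimate (and its
    CI or censoring bound) is multiplied by the same fraction.  The fraction's
    provenance is recorded on the output.
    """
    f = profile.free_ion_fraction
    if not 0.0 < f <= 1.0:
        raise ValueError("free_ion_fraction must lie in (0, 1]: no ionic dose")
    prov = dict(
        ionic_adjustment=dict(
            material_id=profile.material_id,
            free_ion_fraction=f,
            measurement_date=profile.measurement_date,
        )
    )
    if isinstance(obj, ConcResponseTable):
        return obj.scaled(f)
    scale = lambda v: None if v is None else v * f
    out = replace(
        obj,
        estimate=scale(obj.estimate),
        ci_lower=scale(obj.ci_lower),
        ci_upper=scale(obj.ci_upper),
        bound=scale(obj.bound),
        table=obj.table.scaled(f) if obj.table is not None else None,
    )
    out.provenance = {**obj.provenance, **prov}
    return out


def ec50_malformation(
    endpoints: pd.DataFrame,
    trim: float | str = "auto",
) -> TSKResults:
    """EC50 from per-embryo morphological endpoint vectors.

    ``endpoints`` has one row per embryo with columns ``concentration``,
    ``alive`` (bool) and one boolean column per named endpoint; an embryo is
    affected if any endpoint is abnormal.  Concentration groups with no
    living embryos are excluded with a logged note; the concentration-0 rows
    form the control group.
    """
    meta = {"concentration", "alive"}
    cols = [c for c in endpoints.columns if c not in meta]
    if not cols:
        raise ValueError("no endpoint columns")
    living = endpoints[endpoints["alive"].astype(bool)].copy()
    living["affected"] = living[cols].astype(bool).any(axis=1)
    rows = []
    for conc, grp in endpoints.groupby("concentration"):
        alive = grp["alive"].astype(bool)
        if not alive.any():
            logger.info("concentration %g: all dead, excluded from EC50", conc)
            continue
        sub = grp[alive]
        rows.append(dict(
            concentration=float(conc),
            n=int(len(sub)),
            affected=int(sub[cols].astype(bool).any(axis=1).sum()),
        ))
    table = ConcResponseTable.from_dataframe(pd.DataFrame(rows))
    return tsk_estimate(table, trim=trim, endpoint="EC50")


def _round_sig(value: float, sig_figs: int) -> float:
    if value == 0:
        return 0.0
    return round(value, sig_figs - 1 - int(math.floor(math.log10(abs(value)))))


def format_estimate(
    result: TSKResults, sig_figs: int = 2, decimals: int | None = None
) -> str:
    """Report-style rendering: a number, ``">Cmax"`` or ``"<Cmin"``.

    ``decimals`` switches from significant-figure to fixed-decimal rounding
    (e.g. two decimals for the ionic-adjusted values).
    """
    if result.censoring == "above_highest":
        return f">{result.bound:g}"
    if result.censoring == "below_lowest":
        return f"<{result.bound:g}"
    if decimals is not None:
        return f"{round(result.estimate, decimals):.{decimals}f}"
    return f"{_round_sig(result.estimate, sig_figs):g}"
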
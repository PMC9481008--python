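"""Phase-segmented AUC scoring and hypo/hyperactivity classification.

Each embryo's per-second trace is reduced to a triple of areas under the
activity curve — one per protocol phase.  Dead embryos (24 hpf viability
check) and non-responders (living embryos with an all-zero AUC triple) are
excluded by separate rules before treated groups are compared to controls
with a two-tailed t-test per phase and concentration.

Integration convention: each phase window is half-open ``[a, b)`` and its
trapezoid integral runs from the sample at ``a`` through the first sample of
the *next* phase (the shared boundary sample belongs to the later phase but
closes the earlier phase's integral).  The last phase ends at the final
sample.  This makes the three phase AUCs sum exactly to the whole-trace
trapezoid AUC and gives a 30 s window three times the area of a 10 s window
under constant activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import PHASES, PMRProtocol
from .trace import ActivityTrace

__all__ = [
    "PhaseScores",
    "TreatmentSummary",
    "compute_phase_auc",
    "score_traces",
    "remove_dead",
    "flag_nonresponders",
    "flag_untrackable",
    "classify_response",
    "classify_plate",
    "lowest_effect_concentration",
]

logger = logging.getLogger(__name__)

AUC_COLUMNS = [f"auc_{p}" for p in PHASES]


@dataclass
class PhaseScores:
    """Per-embryo AUC triple (activity x seconds per phase)."""

    well_id: str
    auc_background: float
    auc_excitatory: float
    auc_refractory: float
    included: bool = True
    exclusion_reason: Literal["none", "dead", "nonresponder", "untrackable"] = "none"

    def triple(self) -> tuple[float, float, float]:
        return (self.auc_background, self.auc_excitatory, self.auc_refractory)


@dataclass
class TreatmentSummary:
    """One concentration x phase comparison against controls."""

    concentration: float
    phase: str
    n_included: int
    n_control: int
    mean_auc: float
    sd_auc: float
    control_mean: float
    p_value: float
    label: Literal["normal", "hypoactive", "hyperactive", "not_evaluable"]


def compute_phase_auc(trace: ActivityTrace, protocol: PMRProtocol) -> PhaseScores:
    """Trapezoid AUC of a per-second trace within each protocol phase.

    The trace must span the full protocol duration.
    """
    if trace.sampling != "second":
        raise ValueError("compute_phase_auc expects a per-second trace")
    t = trace.time_s
    v = trace.activity
    if len(t) == 0 or t[0] > protocol.start or t[-1] < protocol.duration + protocol.start - 1:
        raise ValueError("trace does not span the full protocol duration")
    bounds = [w[0] for w in protocol.windows.values()] + [protocol.refractory[1]]
    aucs = {}
    for i, phase in enumerate(PHASES):
        a, b = bounds[i], bounds[i + 1]
        # include the closing boundary sample (first sample of the next phase)
        sel = (t >= a) & (t <= b) if i + 1 < len(PHASES) else (t >= a) & (t < b)
        aucs[phase] = float(np.trapezoid(v[sel], t[sel]))
    return PhaseScores(trace.well_id, *(aucs[p] for p in PHASES))


def score_traces(
    traces: Iterable[ActivityTrace], protocol: PMRProtocol
) -> pd.DataFrame:
    """Score a collection of per-second traces into a tidy PhaseScores table.

    Columns: plate, well_id, status, group, concentration, age_hpf,
    auc_background/excitatory/refractory, included, exclusion_reason.
    """
    rows = []
    for tr in traces:
        ps = compute_phase_auc(tr, protocol)
        rows.append(
            dict(
                plate=tr.plate,
                well_id=tr.well_id,
                status=tr.status,
                group=tr.group,
                concentration=tr.concentration,
                age_hpf=tr.age_hpf,
                auc_background=ps.auc_background,
                auc_excitatory=ps.auc_excitatory,
                auc_refractory=ps.auc_refractory,
                included=True,
                exclusion_reason="none",
            )
        )
    return pd.DataFrame(rows)


def remove_dead(
    scores: pd.DataFrame, viability: Mapping[str, bool] | None = None
) -> pd.DataFrame:
    """Exclude embryos flagged dead at the 24 hpf viability check.

    ``viability`` maps ``(plate, well_id)`` or ``well_id`` to alive=True; if
    omitted, the ``status`` column serves as the flag.  Every embryo must
    have a flag.
    """
    out = scores.copy()
    if viability is None:
        if "status" not in out.columns or out["status"].isna().any():
            raise ValueError("missing viability flag: no status column or NaN status")
        dead = out["status"] == "dead"
    else:
        def lookup(row):
            for key in ((row["plate"], row["well_id"]), row["well_id"]):
                if key in viability:
                    return viability[key]
            raise ValueError(f"missing viability flag for {row['well_id']}")
        alive = out.apply(lookup, axis=1)
        dead = ~alive.astype(bool)
    out.loc[dead, "included"] = False
    out.loc[dead, "exclusion_reason"] = "dead"
    return out


def flag_untrackable(scores: pd.DataFrame) -> pd.DataFrame:
    """Exclude wells whose status marks them too turbid to track."""
    out = scores.copy()
    mask = (out["status"] == "untrackable") & (out["exclusion_reason"] == "none")
    out.loc[mask, "included"] = False
    out.loc[mask, "exclusion_reason"] = "untrackable"
    return out


def flag_nonresponders(
    scores: pd.DataFrame, scope: Literal["controls_only", "all"] = "controls_only"
) -> tuple[pd.DataFrame, float]:
    """Exclude living embryos whose AUC triple is exactly (0, 0, 0).

    Returns the filtered table and the non-responder rate: all-zero living
    embryos as a fraction of living embryos within the chosen scope
    (controls only by default, matching the original filtering rule).
    Idempotent: re-applying changes nothing.
    """
    out = scores.copy()
    living = out["status"] == "alive"
    in_scope = living if scope == "all" else living & (out["group"] == "control")
    zero = (out[AUC_COLUMNS] == 0).all(axis=1)
    rate = float((in_scope & zero).sum() / in_scope.sum()) if in_scope.sum() else 0.0
    mask = in_scope & zero & (out["exclusion_reason"] == "none")
    out.loc[mask, "included"] = False
    out.loc[mask, "exclusion_reason"] = "nonresponder"
    return out, rate


def _welch_p(treated: np.ndarray, control: np.ndarray, equal_var: bool) -> float:
    res = stats.ttest_ind(treated, control, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant: no evidence against equal means
        return 1.0
    return p


def classify_response(
    treated: pd.DataFrame | Sequence[float],
    control: pd.DataFrame | Sequence[float],
    phase: str,
    alpha: float = 0.05,
    equal_var: bool = False,
    concentration: float | None = None,
) -> TreatmentSummary:
    """Two-tailed t-test of one treated group against controls for one phase.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled Student variant).  ``hypoactive``/``hyperactive`` labels require
    ``p < alpha`` and the corresponding direction of the mean difference.
    Turbidity-flagged treated groups are ``not_evaluable``, as are groups
    with fewer than two included embryos.
    """
    col = f"auc_{phase}"
    turbid = False
    if isinstance(treated, pd.DataFrame):
        turbid = (treated["exclusion_reason"] == "untrackable").any() or (
            treated.get("status", pd.Series(dtype=object)) == "untrackable"
        ).any()
        if concentration is None and len(treated):
            concentration = float(treated["concentration"].iloc[0])
        treated = treated.loc[treated["included"], col].to_numpy(float)
    else:
        treated = np.asarray(treated, dtype=float)
    if isinstance(control, pd.DataFrame):
        control = control.loc[control["included"], col].to_numpy(float)
    else:
        control = np.asarray(control, dtype=float)
    conc = float(concentration) if concentration is not None else float("nan")

    if turbid or len(treated) < 2 or len(control) < 2:
        reason = "turbidity" if turbid else "group size < 2"
        logger.info("concentration %s phase %s not evaluable: %s", conc, phase, reason)
        return TreatmentSummary(
            conc, phase, len(treated), len(control),
            float(np.mean(treated)) if len(treated) else float("nan"),
            float(np.std(treated, ddof=1)) if len(treated) > 1 else 0.0,
            float(np.mean(control)) if len(control) else float("nan"),
            float("nan"), "not_evaluable",
        )
    p = _welch_p(treated, control, equal_var)
    tmean, cmean = float(np.mean(treated)), float(np.mean(control))
    if p < alpha and tmean < cmean:
        label = "hypoactive"
    elif p < alpha and tmean > cmean:
        label = "hyperactive"
    else:
        label = "normal"
    return TreatmentSummary(
        conc, phase, len(treated), len(control), tmean,
        float(np.std(treated, ddof=1)), cmean, p, label,
    )


def classify_plate(
    scores: pd.DataFrame, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Run :func:`classify_response` for every concentration x phase."""
    control = scores[scores["group"] == "control"]
    rows = []
    for conc, grp in scores[scores["group"] == "treatment"].groupby("concentration"):
        for phase in PHASES:
            s = classify_response(grp, control, phase, alpha=alpha,
                                  equal_var=equal_var, concentration=conc)
            rows.append(vars(s))
    return pd.DataFrame(rows)


def lowest_effect_concentration(
    summaries: pd.DataFrame, trackable_max: float = 50.0
) -> dict[str, float | str]:
    """Per-phase lowest concentration with a significant behavioral label.

    Only concentrations at or below ``trackable_max`` (the turbidity
    reporting cutoff) yield numeric reports; if significant effects exist
    only above it the phase reports ``"> trackable_max"``; with no
    significant entries at all it reports ``"None"``.
    """
    out: dict[str, float | str] = {}
    sig = summaries[summaries["label"].isin(["hypoactive", "hyperactive"])]
    for phase in PHASES:
        ps = sig[sig["phase"] == phase]
        below = ps[ps["concentration"] <= trackable_max]
        if len(below):
            out[phase] = float(below["concentration"].min())
        elif len(ps):
            out[phase] = f">{trackable_max:g}"
        else:
            out[phase] = "None"
    return out
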
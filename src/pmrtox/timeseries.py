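"""Developmental time-series analysis of the PMR.

Tracks how the response changes as embryos develop from 24 to 32 hpf:
per-age phase AUC summaries, non-responder rates, the age of maximal
excitatory response, and a paired test of whether the excitatory phase shows
more movement than the dark background.  Because the background window (30 s)
is three times the excitatory window (10 s), the comparison defaults to
per-second-normalized activity (AUC divided by phase duration).
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import PHASES, PMRProtocol
from .scoring import AUC_COLUMNS

__all__ = [
    "aggregate_by_age",
    "peak_excitatory_age",
    "excitatory_vs_background_test",
    "PeakAge",
]

logger = logging.getLogger(__name__)


class PeakAge(NamedTuple):
    age_hpf: float
    tied: bool


def excitatory_vs_background_test(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    normalize: bool = True,
    protocol: PMRProtocol | None = None,
) -> tuple[bool, float]:
    """Paired one-tailed test: excitatory activity exceeds background.

    Uses per-embryo paired differences of phase activity, normalized by phase
    duration by default so the 30 s and 10 s windows are comparable.  Returns
    ``(significant, p_value)``.  Degenerate all-tied differences are reported
    non-significant with p = 1.
    """
    protocol = protocol or PMRProtocol()
    df = scores[scores["included"]] if "included" in scores.columns else scores
    if len(df) < 2:
        raise ValueError("need at least two embryos with both phase scores")
    exc = df["auc_excitatory"].to_numpy(float)
    bg = df["auc_background"].to_numpy(float)
    if normalize:
        exc = exc / protocol.phase_duration("excitatory")
        bg = bg / protocol.phase_duration("background")
    if np.allclose(exc, bg):
        return False, 1.0
    res = stats.ttest_rel(exc, bg, alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p):
        return False, 1.0
    return p < alpha, p


def aggregate_by_age(
    scores: pd.DataFrame,
    ages: list[float] | None = None,
    alpha: float = 0.05,
    protocol: PMRProtocol | None = None,
) -> pd.DataFrame:
    """Per-age, per-phase summary of a developmental cohort.

    For each age: mean and SD of each phase AUC over included embryos
    (SD reported as 0 with ``sd_defined=False`` for singleton groups), the
    non-responder rate among living embryos computed *before* exclusion, and
    the excitatory-vs-background paired test.  Ages with no included embryos
    are omitted with a warning.
    """
    if ages is None:
        ages = sorted(scores["age_hpf"].unique())
    rows = []
    for age in ages:
        grp = scores[scores["age_hpf"] == age]
        living = grp[grp["status"] == "alive"] if "status" in grp.columns else grp
        n_living = len(living)
        zero = (living[AUC_COLUMNS] == 0).all(axis=1) if n_living else pd.Series(dtype=bool)
        nonresp_rate = float(zero.sum() / n_living) if n_living else float("nan")
        inc = grp[grp["included"]] if "included" in grp.columns else grp
        if len(inc) == 0:
            logger.warning("age %g hpf: no included embryos, omitted", age)
            continue
        try:
            sig, p = excitatory_vs_background_test(inc, alpha=alpha, protocol=protocol)
        except ValueError:
            sig, p = False, float("nan")
        for phase in PHASES:
            vals = inc[f"auc_{phase}"].to_numpy(float)
            sd_defined = len(vals) > 1
            rows.append(dict(
                age_hpf=float(age),
                phase=phase,
                n_included=len(vals),
                mean_auc=float(np.mean(vals)),
                sd_auc=float(np.std(vals, ddof=1)) if sd_defined else 0.0,
                sd_defined=sd_defined,
                nonresponder_rate=nonresp_rate,
                excitatory_gt_background=sig,
                p_value=p,
            ))
    return pd.DataFrame(rows)


def peak_excitatory_age(summaries: pd.DataFrame) -> PeakAge:
    """Age with the largest mean excitatory AUC.

    Ties are broken toward the earlier age and flagged.
    """
    exc = summaries[summaries["phase"] == "excitatory"].sort_values("age_hpf")
    if len(exc) < 2:
        raise ValueError("need summaries for at least two ages")
    means = exc["mean_auc"].to_numpy(float)
    best = float(np.max(means))
    tied = int(np.sum(means == best)) > 1
    age = float(exc["age_hpf"].to_numpy(float)[int(np.argmax(means))])
    if tied:
        logger.info("peak excitatory AUC tied; reporting earliest age %g", age)
    return PeakAge(age, tied)
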
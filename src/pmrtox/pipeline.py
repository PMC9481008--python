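"""End-to-end screening pipeline: simulate/load -> score -> classify -> LC50.

A :class:`RunConfig` (usually loaded from YAML) drives the stages; every run
writes its resolved configuration next to the outputs, and the report is
byte-identical across runs with the same config and seed.  All report values
come from stage outputs; nothing is computed in the reporting layer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import doseresponse, scoring, simulate, timeseries
from .io import read_conc_response, read_trace_table, frame_to_traces, write_trace_table
from .motion import bin_per_second
from .protocol import PHASES, PlateLayout, PMRProtocol

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    outdir: str = "pmrtox_run"
    # inputs: either a trace table on disk or a simulation scenario
    traces_path: str | None = None
    mortality_path: str | None = None
    concentrations: list[float] = field(
        default_factory=lambda: [2.32, 5.0, 10.7, 23.2, 50.0]
    )
    protocol: dict = field(default_factory=dict)
    layout: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)
    scenario: str | None = None  # "nanosilver" preset overrides `effect`
    age_hpf: float = 30.0
    turbidity_threshold: float | None = None
    # analysis parameters
    alpha: float = 0.05
    trackable_max: float = 50.0
    trim: float | str = "auto"
    equal_var: bool = False
    nonresponder_scope: str = "controls_only"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.nonresponder_scope not in ("controls_only", "all"):
            raise ValueError("nonresponder_scope must be controls_only or all")
        if self.trim != "auto" and not 0 <= float(self.trim) < 0.5:
            raise ValueError("trim must be 'auto' or in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def build_protocol(self) -> PMRProtocol:
        cfg = dict(self.protocol)
        for key in ("background", "excitatory", "refractory", "flash_times"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return PMRProtocol(**cfg)

    def build_layout(self) -> PlateLayout:
        cfg = dict(self.layout)
        if "control_columns" in cfg:
            cfg["control_columns"] = frozenset(cfg["control_columns"])
        if "treatment_column_pairs" in cfg:
            cfg["treatment_column_pairs"] = tuple(tuple(p) for p in cfg["treatment_column_pairs"])
        return PlateLayout(**cfg)

    def build_effect(self) -> simulate.EffectModel:
        if self.scenario == "nanosilver":
            return simulate.nanosilver_effect()
        if self.scenario is not None:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return simulate.EffectModel(**self.effect)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Writes ``scores.csv``, ``summaries.csv``, ``report.json``, ``report.tsv``
    and ``resolved_config.yaml`` under ``config.outdir`` and returns the
    report dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protocol = config.build_protocol()

    # --- acquire traces ---------------------------------------------------
    if config.traces_path:
        traces = _stage("load")(frame_to_traces)(read_trace_table(config.traces_path))
    else:
        layout = config.build_layout()
        effect = config.build_effect()
        traces, _ = _stage("simulate")(simulate.simulate_plate)(
            layout, effect, config.concentrations, seed=config.seed,
            protocol=protocol, age_hpf=config.age_hpf,
            turbidity_threshold=config.turbidity_threshold,
        )
        write_trace_table(traces, outdir / "traces.csv")

    per_second = [
        bin_per_second(t) if t.sampling == "frame" else t for t in traces
    ]

    # --- score and filter -------------------------------------------------
    scores = _stage("score")(scoring.score_traces)(per_second, protocol)
    scores = scoring.remove_dead(scores)
    scores = scoring.flag_untrackable(scores)
    scores, nonresp_rate = scoring.flag_nonresponders(
        scores, scope=config.nonresponder_scope
    )
    scores.to_csv(outdir / "scores.csv", index=False)
    exclusions = scores["exclusion_reason"].value_counts().to_dict()
    logger.info("exclusions: %s", exclusions)

    # --- classify ---------------------------------------------------------
    summaries = _stage("classify")(scoring.classify_plate)(
        scores, alpha=config.alpha, equal_var=config.equal_var
    )
    summaries.to_csv(outdir / "summaries.csv", index=False)
    if len(summaries):
        lowest = scoring.lowest_effect_concentration(
            summaries, trackable_max=config.trackable_max
        )
    else:
        logger.warning("no treatment groups: reporting None for every phase")
        lowest = {phase: "None" for phase in PHASES}

    # --- dose-response ----------------------------------------------------
    estimates: dict[str, dict] = {}
    if config.mortality_path:
        table = read_conc_response(config.mortality_path)
    elif not config.traces_path:
        effect = config.build_effect()
        layout = config.build_layout()
        table = simulate.simulate_mortality_table(
            config.concentrations,
            n_per_group=layout.wells_per_treatment(),
            true_lc50=effect.mortality_lc50,
            slope=effect.mortality_slope,
            seed=config.seed + 1,
        ) if effect.mortality_lc50 != float("inf") else None
    else:
        table = None
    if table is not None:
        try:
            res = _stage("lc50")(doseresponse.tsk_estimate)(table, trim=config.trim)
            estimates["LC50"] = res.to_dict()
        except doseresponse.TSKEstimationError as exc:
            logger.warning("LC50 not estimable: %s", exc)
            estimates["LC50"] = dict(endpoint="LC50", report="ND", error=str(exc))

    # --- timeseries (only when several ages are present) -------------------
    age_summary = None
    if scores["age_hpf"].nunique() > 1:
        age_summary = _stage("timeseries")(timeseries.aggregate_by_age)(
            scores, alpha=config.alpha, protocol=protocol
        )
        age_summary.to_csv(outdir / "age_summary.csv", index=False)

    # --- report -----------------------------------------------------------
    report = dict(
        seed=config.seed,
        n_wells=int(len(scores)),
        exclusions=exclusions,
        nonresponder_rate=nonresp_rate,
        lowest_effect_concentration=lowest,
        estimates=estimates,
    )
    if age_summary is not None:
        peak = timeseries.peak_excitatory_age(age_summary)
        report["peak_excitatory_age_hpf"] = peak.age_hpf
        report["peak_age_tied"] = peak.tied

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )
    _write_table_report(outdir / "report.tsv", lowest, estimates, config)
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )
    return report


def _write_table_report(path: Path, lowest, estimates, config: RunConfig) -> None:
    """Human-readable summary mirroring the screening table's column layout:
    lowest-effect concentration per phase, then LC50/EC50."""
    row = {f"pmr_{phase}": str(lowest[phase]) for phase in PHASES}
    row["highest_concentration"] = (
        max(config.concentrations) if config.concentrations else ""
    )
    for name in ("LC50", "EC50"):
        row[name.lower()] = estimates.get(name, {}).get("report", "ND")
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
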
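"""End-to-end orchestration: clean → select → day length → models → tests.

Every output file is re-derivable from the configuration and seed alone:
the run log records the package version, the seed, and the filter report,
but no timestamps or machine state, so a repeated run with the same
configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from murmuration import __version__
from murmuration.assoc import chi_square_association, one_way_anova, pearson, \
    terminal_behaviour_table
from murmuration.daylength import DayLengthContext, attach_day_length
from murmuration.errors import InsufficientDataError
from murmuration.records import MurmurationRecord, clean_records, parse_records, \
    select_murmurations
from murmuration.revs import build_design, run_revs
from murmuration.seasonal import regress_on_daylength, select_trend_degree, weekly_aggregate
from murmuration.simulate import SimConfig, simulate_records

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """A fully specified run; unknown configuration keys are rejected."""

    input_path: str | None = None
    simulate: dict[str, Any] | None = None
    seed: int = 0
    min_size: int = 500
    require_end_seen: bool = True
    require_roost_descent: bool = False
    uk_only: bool = True
    designs: tuple[str, ...] = ("presence", "activity")
    responses: tuple[str, ...] = ("size", "duration")
    revs_method: str = "best_subsets_frequency"
    delta_threshold: float = 2.0
    candidate_degrees: tuple[int, ...] = (1, 2)
    out_dir: str = "murmuration_out"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("designs", "responses", "candidate_degrees"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _ordered_by_time_within_location(records: Sequence[MurmurationRecord]):
    def key(r: MurmurationRecord):
        loc = (r.latitude if r.latitude is not None else 99.0,
               r.longitude if r.longitude is not None else 999.0)
        return (*loc, r.day_index, r.record_id)
    return sorted(records, key=key)


def _write(out_dir: Path, name: str, text: str) -> None:
    (out_dir / name).write_text(text)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle to ``out_dir``.

    Returns the in-memory report. Any stage failure raises
    :class:`PipelineStageError` naming the stage; stages that merely lack
    enough data (for example the habitat ANOVA on a stream with no
    habitat field) are recorded with an explicit skipped status instead.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": {}}

    # --- acquire records
    if config.simulate is not None:
        sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
        frame, truth = simulate_records(sim_cfg)
        raw_csv = frame.to_csv(index=False)
        _write(out_dir, "simulated_records.csv", raw_csv)
        _write(out_dir, "ground_truth.json", truth.to_json(indent=2, sort_keys=True))
    elif config.input_path is not None:
        try:
            raw_csv = Path(config.input_path).read_text()
        except OSError as exc:
            raise PipelineStageError("input", "missing_input", str(exc)) from exc
    else:
        raise PipelineStageError("input", "no_input", "neither input_path nor simulate given")

    records, issues = parse_records(raw_csv)
    report["stages"]["parse"] = {"records": len(records), "issues": len(issues)}

    # --- clean and select
    cleaned, filter_report = clean_records(records)
    _write(out_dir, "filter_report.json", filter_report.to_json(indent=2, sort_keys=True))
    selected = select_murmurations(
        cleaned,
        min_size=config.min_size,
        require_end_seen=config.require_end_seen,
        require_roost_descent=config.require_roost_descent,
        uk_only=config.uk_only,
    )
    report["stages"]["clean"] = {
        "input": filter_report.input_count,
        "cleaned": filter_report.output_count,
        "selected": len(selected),
    }
    if not selected:
        report["stages"]["status"] = "no_records_after_filtering; downstream stages skipped"
        _write(out_dir, "run_log.json", json.dumps(report, indent=2, sort_keys=True))
        return report

    # --- day length
    selected = attach_day_length(selected, DayLengthContext())

    # --- seasonal trends
    seasonal: dict[str, Any] = {}
    for response in ("size", "duration"):
        y = [r.flock_size if response == "size" else r.duration_min for r in selected]
        x = [r.day_index for r in selected]
        try:
            fit = select_trend_degree(x, y, config.candidate_degrees, response=response)
        except (InsufficientDataError, ValueError) as exc:
            seasonal[response] = {"status": f"skipped: {exc}"}
            continue
        seasonal[response] = json.loads(fit.to_json())
        _write(out_dir, f"seasonal_{response}.json", fit.to_json(indent=2, sort_keys=True))
    weekly = weekly_aggregate(selected, "duration")
    try:
        dl_fit = regress_on_daylength(weekly)
        _write(out_dir, "daylength_regression.json", dl_fit.to_json(indent=2, sort_keys=True))
        seasonal["duration_vs_daylength"] = {
            "slope": dl_fit.coefficients[1], "r2": dl_fit.r2, "p": dl_fit.p_value,
        }
    except InsufficientDataError as exc:
        seasonal["duration_vs_daylength"] = {"status": f"skipped: {exc}"}
    report["stages"]["seasonal"] = seasonal

    # --- REVS
    revs_summary: dict[str, Any] = {}
    ordered = _ordered_by_time_within_location(selected)
    for design in config.designs:
        for response in config.responses:
            key = f"{design}_{response}"
            try:
                pm = build_design(ordered, design=design, response=response)  # type: ignore[arg-type]
                result = run_revs(pm, method=config.revs_method,  # type: ignore[arg-type]
                                  delta_threshold=config.delta_threshold)
            except (ValueError, InsufficientDataError) as exc:
                revs_summary[key] = {"status": f"skipped: {exc}"}
                continue
            _write(out_dir, f"revs_{key}.json", result.to_json(indent=2, sort_keys=True))
            result.to_table().to_csv(out_dir / f"revs_{key}.csv", index=False)
            revs_summary[key] = {
                "optimal_predictors": list(result.optimal_model.predictor_names),
                "optimal_adj_r2": result.optimal_model.adj_r2,
                "durbin_watson": result.durbin_watson,
            }
    report["stages"]["revs"] = revs_summary

    # --- association battery
    assoc: dict[str, Any] = {}
    sizes = [float(r.flock_size) for r in selected]
    durations = [r.duration_min for r in selected]
    try:
        r, n, p = pearson(sizes, durations)
        assoc["size_vs_duration"] = {"r": r, "n": n, "p": p}
    except (InsufficientDataError, ValueError) as exc:
        assoc["size_vs_duration"] = {"status": f"skipped: {exc}"}
    habitats: dict[str, list[float]] = {}
    for r in selected:
        if r.habitat is not None:
            habitats.setdefault(r.habitat, []).append(r.duration_min)
    try:
        f, df1, df2, p = one_way_anova(list(habitats.values()))
        assoc["habitat_vs_duration"] = {"F": f, "df": [df1, df2], "p": p}
    except (InsufficientDataError, ValueError) as exc:
        assoc["habitat_vs_duration"] = {"status": f"skipped: {exc}"}
    try:
        table = terminal_behaviour_table(selected)
        table.to_frame().to_csv(out_dir / "terminal_behaviour_table.csv")
        x2, df, p = chi_square_association(table)
        assoc["terminal_behaviour"] = {"x2": x2, "df": df, "p": p}
    except ValueError as exc:
        assoc["terminal_behaviour"] = {"status": f"skipped: {exc}"}
    report["stages"]["assoc"] = assoc
    _write(out_dir, "assoc.json", json.dumps(assoc, indent=2, sort_keys=True))

    _write(out_dir, "run_log.json", json.dumps(report, indent=2, sort_keys=True))
    return report
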
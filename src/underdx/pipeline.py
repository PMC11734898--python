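"""End-to-end orchestration: simulate -> extract -> rates -> estimate ->
small-area -> reports, from a single config with one root seed.

Every stage writes plain CSV into the run's output directory, and a JSON
manifest records the seed, configuration, input digests and row counts, so
a run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .event_extraction import filter_eligible, tabulate_strata
from .small_area import (aggregate_national, aggregate_to_health_areas,
                         link_estimates_to_areas)
from .strata_rates import build_rate_table
from .synthetic_cohort import (default_params, generate_area_tables,
                               generate_cohort)
from .validation_sensitivity import (correlate_with_comparator, get_scenario,
                                     run_scenario)

logger = logging.getLogger(__name__)

DATE_COLUMNS = ("birth_date", "registration_start", "registration_end",
                "diagnosis_date", "death_date")


@dataclass
class RunConfig:
    """Configuration of a full run (see ``RunConfig.from_yaml``)."""

    conditions: list[str] = field(default_factory=list)  # empty = all defaults
    years: tuple[int, int] = (2008, 2018)
    scenario: str = "main"
    seed: int = 0
    output_dir: str = "underdx_run"
    # either simulate...
    simulate: bool = True
    cohort_size: int = 50_000
    n_areas_per_region: int = 20
    areas_per_health_area: int = 4
    national_population: int = 1_000_000
    # ...or read event logs / area table from CSV
    persons_path: str | None = None
    diagnoses_path: str | None = None
    deaths_path: str | None = None
    areas_path: str | None = None
    comparator_path: str | None = None
    # analysis knobs
    epsilon: float = 1e-4
    cfr_floor: int = 10
    cfr_source: str = "smoothed"
    prevalence: str = "year_start"
    min_event_count: int = 1
    lower_bound_mode: str = "next_year"
    lower_bound_source: str = "smoothed"
    apply_lower_bound: bool = True
    observed_where_available: bool = False
    area_weighting: str = "population"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.years = tuple(int(y) for y in cfg.years)
        return cfg

    def validate(self) -> None:
        if self.years[0] > self.years[1]:
            raise ValueError("year range reversed")
        if not self.simulate:
            for name in ("persons_path", "diagnoses_path", "deaths_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"{name} missing or does not exist: {p}")
        if self.comparator_path and not Path(self.comparator_path).exists():
            raise FileNotFoundError(f"comparator file: {self.comparator_path}")
        get_scenario(self.scenario)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in DATE_COLUMNS:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = {"rows": int(len(df)),
                                      "sha256": _digest(path)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = get_scenario(config.scenario)
    manifest = {"version": __version__, "seed": config.seed,
                "scenario": scenario.name, "config": asdict(config),
                "inputs": {}, "outputs": {}, "stages": {}}

    conditions = config.conditions or None
    years = list(range(config.years[0], config.years[1] + 1))

    # --- stage: inputs ------------------------------------------------------
    if config.simulate:
        params = default_params(conditions=conditions, years=config.years,
                                cohort_size=config.cohort_size, seed=config.seed)
        persons, diagnoses, deaths, truth = generate_cohort(params)
        areas = generate_area_tables(params, config.n_areas_per_region,
                                     seed=config.seed + 1,
                                     areas_per_health_area=config.areas_per_health_area,
                                     national_population=config.national_population)
        conditions = list(params.conditions)
        _write(persons, out / "persons.csv", manifest)
        _write(diagnoses, out / "diagnoses.csv", manifest)
        _write(deaths, out / "deaths.csv", manifest)
        _write(truth, out / "truth.csv", manifest)
        _write(areas, out / "areas.csv", manifest)
    else:
        persons = _read_events(config.persons_path)
        diagnoses = _read_events(config.diagnoses_path)
        deaths = _read_events(config.deaths_path)
        areas = pd.read_csv(config.areas_path) if config.areas_path else None
        if not conditions:
            conditions = sorted(diagnoses["condition"].unique())
        for name in ("persons_path", "diagnoses_path", "deaths_path", "areas_path"):
            p = getattr(config, name)
            if p:
                manifest["inputs"][name] = _digest(Path(p))

    study_start = np.datetime64(f"{years[0]}-01-01")
    study_end = np.datetime64(f"{years[-1]}-12-31")
    eligible = filter_eligible(persons, study_start, study_end)
    manifest["stages"]["eligible_persons"] = int(len(eligible))

    # --- per-condition stages ----------------------------------------------
    options = dict(prevalence=config.prevalence,
                   min_event_count=config.min_event_count,
                   cfr_source=config.cfr_source, cfr_floor=config.cfr_floor,
                   observed_where_available=config.observed_where_available,
                   epsilon=config.epsilon,
                   lower_bound_mode=config.lower_bound_mode,
                   lower_bound_source=config.lower_bound_source,
                   apply_lower_bound=config.apply_lower_bound)
    estimates = {}
    coef_lines = []
    for cond in conditions:
        counts = tabulate_strata(eligible, diagnoses, deaths, cond,
                                 definition=scenario.death_definition,
                                 years=years, prevalence=config.prevalence,
                                 min_event_count=config.min_event_count)
        _write(counts, out / f"strata_counts_{cond}.csv", manifest)
        rates = build_rate_table(counts, cond, cfr_source=config.cfr_source,
                                 cfr_floor=config.cfr_floor,
                                 observed_where_available=config.observed_where_available)
        _write(rates, out / f"rates_{cond}.csv", manifest)
        model = rates.attrs.get("undiagnosed_death_model")
        if model is not None:
            coef_lines.append(f"== {cond} (undiagnosed-death model) ==")
            for name, val in model.params.items():
                coef_lines.append(f"{name:>22s}  {val:+.6f}  "
                                  f"(se {model.bse[name]:.6f})")
            coef_lines.append("")
        est = run_scenario(eligible, diagnoses, deaths, cond, scenario,
                           years, **options)
        _write(est, out / f"estimates_{cond}.csv", manifest)
        estimates[cond] = est
    (out / "model_coefficients.txt").write_text("\n".join(coef_lines))

    # --- small area ---------------------------------------------------------
    if areas is not None:
        area_frames, ha_frames = [], []
        for cond, est in estimates.items():
            ae = link_estimates_to_areas(est, areas, on_missing="drop")
            ae.insert(0, "condition", cond)
            ha = aggregate_to_health_areas(ae, areas,
                                           weighting=config.area_weighting)
            ha.insert(0, "condition", cond)
            area_frames.append(ae)
            ha_frames.append(ha)
        area_estimates = pd.concat(area_frames, ignore_index=True)
        health_area_estimates = pd.concat(ha_frames, ignore_index=True)
        _write(area_estimates, out / "area_estimates.csv", manifest)
        _write(health_area_estimates, out / "health_area_estimates.csv", manifest)
    else:
        health_area_estimates = None

    # --- validation against a comparator series -----------------------------
    if config.comparator_path and health_area_estimates is not None:
        comp = pd.read_csv(config.comparator_path)
        rows = []
        last = health_area_estimates[health_area_estimates["year"] == years[-1]]
        for cond in conditions:
            sub = last[last["condition"] == cond]
            res = correlate_with_comparator(sub, comp)
            rows.append({"condition": cond,
                         "comparator": comp.get("label", pd.Series(["comparator"])).iloc[0],
                         "rho": res.rho, "p": res.p_value, "n": res.n})
        _write(pd.DataFrame(rows), out / "validation_correlations.csv", manifest)

    # --- reports ------------------------------------------------------------
    reports = render_reports(estimates, health_area_estimates, years)
    for name, df in reports.items():
        _write(df, out / f"report_{name}.csv", manifest)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def render_reports(estimates: dict[str, pd.DataFrame],
                   health_area_estimates: pd.DataFrame | None,
                   years: list[int]) -> dict[str, pd.DataFrame]:
    """Summary tables: per-condition national levels for the first and last
    study year, deprivation and age-group trends, and per-health-area
    values.  Percentages are rounded here only; stage CSVs keep full
    precision.
    """
    first, last = years[0], years[-1]
    nat_rows, qimd_frames, age_frames = [], [], []
    for cond, est in estimates.items():
        nat = aggregate_national(est)
        missing = {first, last} - set(nat["year"])
        if missing:
            raise ValueError(f"{cond}: report years missing from estimates: "
                             f"{sorted(missing)}")
        row = {"condition": cond}
        for y in (first, last):
            p = float(nat.loc[nat["year"] == y, "p_undx"].iloc[0])
            row[str(y)] = round(100 * p, 1)
        nat_rows.append(row)
        for by, sink in (("qimd", qimd_frames), ("age_group", age_frames)):
            m = aggregate_national(est, by=[by])
            m.insert(0, "condition", cond)
            m["p_undx_pct"] = (100 * m["p_undx"]).round(1)
            sink.append(m[["condition", "year", by, "p_undx_pct"]])

    reports = {
        "national": pd.DataFrame(nat_rows),
        "by_deprivation": pd.concat(qimd_frames, ignore_index=True),
        "by_age_group": pd.concat(age_frames, ignore_index=True),
    }
    if health_area_estimates is not None:
        ha = health_area_estimates[health_area_estimates["year"] == last].copy()
        ha["p_undx_pct"] = (100 * ha["p_undx"]).round(1)
        reports["by_health_area"] = ha[["condition", "health_area_id", "p_undx_pct"]]
    return reports
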
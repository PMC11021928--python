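"""Shared configuration, I/O and the end-to-end pipeline.

All artefacts are CSV (documented headers) plus JSON manifests; every
stage output starts with a ``# config_hash=...`` comment line so a run
directory is self-describing, and a rerun with identical config and seed
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import compare as compare_mod
from . import haulout as haulout_mod
from . import moultfit, synchrony
from . import synthdata
from .synthdata import GeneratorConfig

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_csv", "write_csv"]

#: category composition of each model run: adults (reproductive + skip,
#: summarised separately post hoc) and the two juvenile groups.
MODEL_RUNS = {
    "adult": ("adult_reproductive", "adult_skip"),
    "juvenile_female": ("juvenile_female",),
    "juvenile_male": ("juvenile_male",),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=synthdata.default_config)
    sightings_path: str | None = None      # ingest a user CSV instead of generating
    surveys_path: str | None = None        # required with sightings_path
    sampler: moultfit.SamplerConfig = field(default_factory=moultfit.SamplerConfig)
    detection: haulout_mod.DetectionConfig = field(default_factory=haulout_mod.DetectionConfig)
    thresholds: moultfit.FilterThresholds = field(default_factory=moultfit.FilterThresholds)
    ci_width_max: float = 6.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig.from_dict(raw.pop("generator"))
        for key, klass in (
            ("sampler", moultfit.SamplerConfig),
            ("detection", haulout_mod.DetectionConfig),
            ("thresholds", moultfit.FilterThresholds),
        ):
            if key in raw:
                kwargs[key] = klass(**raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_csv(frame: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_survey_calendar(path: str | Path) -> dict[int, np.ndarray]:
    frame = read_csv(path)
    return {
        int(y): np.sort(grp["date"].to_numpy(dtype=int))
        for y, grp in frame.groupby("year")
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute synthdata (or ingest) -> moultfit -> haulout -> synchrony ->
    compare, writing every stage's outputs plus a provenance manifest.

    A stage failure raises :class:`PipelineError` naming the stage;
    earlier outputs are preserved in the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    log: dict = {"config_hash": h, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - halt with stage name
                _write_manifest(out, config, log, failed=name)
                raise PipelineError(name, exc) from exc
            log["stages"][name] = result or {}
            return result

        return deco

    # -- stage 1: sightings ------------------------------------------------
    state: dict = {}

    @stage("synthdata")
    def _():
        if config.sightings_path:
            if not Path(config.sightings_path).exists():
                raise FileNotFoundError(config.sightings_path)
            if not config.surveys_path or not Path(config.surveys_path).exists():
                raise FileNotFoundError(config.surveys_path or "<surveys_path unset>")
            state["sightings"] = read_csv(config.sightings_path)
            state["calendar"] = read_survey_calendar(config.surveys_path)
            source = "ingested"
        else:
            truth, calendar, records = synthdata.generate_colony(config.generator)
            state["sightings"] = synthdata.sightings_to_frame(records)
            state["calendar"] = calendar
            write_csv(synthdata.truth_to_frame(truth), out / "truth.csv", h)
            source = "generated"
        write_csv(state["sightings"], out / "sightings.csv", h)
        write_csv(
            synthdata.calendar_to_frame(state["calendar"]), out / "surveys.csv", h
        )
        return {"source": source, "n_sightings": int(len(state["sightings"]))}

    # -- stage 2: moult model ----------------------------------------------
    @stage("moultfit")
    def _():
        cycles = moultfit.group_cycles(state["sightings"])
        eligible, report = moultfit.filter_cycles(cycles, config.thresholds)
        counts = {"n_input": report.n_input, "n_eligible": report.n_eligible,
                  **report.counts}
        events_frames, diag_frames = [], []
        present = {c.category for c in eligible}
        for run, cats in MODEL_RUNS.items():
            run_cycles = [c for c in eligible if c.category in cats]
            if len(run_cycles) < 2:
                continue
            fit = moultfit.fit_hierarchical(run_cycles, config.sampler)
            ev = moultfit.derive_events(fit, allow_unconverged=True)
            ev.insert(0, "model_run", run)
            events_frames.append(ev)
            diag = fit.diagnostics.copy()
            diag.insert(0, "model_run", run)
            diag_frames.append(diag)
        if not events_frames:
            raise ValueError("no category run had >=2 eligible cycles")
        state["events"] = pd.concat(events_frames, ignore_index=True)
        write_csv(state["events"], out / "moult_events.csv", h)
        write_csv(pd.concat(diag_frames, ignore_index=True), out / "diagnostics.csv", h)
        (out / "exclusions.json").write_text(json.dumps(counts, indent=2))
        return {**counts, "categories": sorted(present)}

    # -- stage 3: haul-out --------------------------------------------------
    @stage("haulout")
    def _():
        subset, sel_report = haulout_mod.select_subset(
            state["events"], config.ci_width_max
        )
        estimates = haulout_mod.fit_arrival_departure(
            state["sightings"], state["calendar"], config.detection, subset=subset
        )
        frame = haulout_mod.estimates_to_frame(estimates)
        write_csv(frame, out / "haulout.csv", h)
        cat_summary = haulout_mod.summarize_categories(estimates, state["events"])
        write_csv(cat_summary, out / "haulout_categories.csv", h)
        state["haulout"] = frame
        return sel_report

    # -- stage 4: synchrony -------------------------------------------------
    @stage("synchrony")
    def _():
        merged = state["events"].merge(
            state["haulout"][["animal_id", "year", "arrival_mean", "departure_mean"]],
            on=["animal_id", "year"],
        )
        table = pd.DataFrame({
            "animal_id": merged["animal_id"],
            "year": merged["year"],
            "category": merged["category"],
            "arrival": merged["arrival_mean"],
            "moult_start": merged["start_mean"],
            "moult_end": merged["end_mean"],
            "departure": merged["departure_mean"],
        })
        state["event_dates"] = table
        write_csv(table, out / "event_dates.csv", h)
        schedule = synchrony.build_schedule(table)
        peaks = synchrony.peak_synchrony(schedule)
        peaks["window_present_95"] = synchrony.population_window(
            table["arrival"].to_numpy(), table["departure"].to_numpy()
        )
        peaks["window_moult_95"] = synchrony.population_window(
            table["moult_start"].to_numpy(), table["moult_end"].to_numpy()
        )
        write_csv(schedule.to_frame(), out / "schedule.csv", h)
        (out / "peaks.json").write_text(json.dumps(peaks, indent=2))
        return {"n_individuals": schedule.n_individuals,
                "n_rejected": schedule.n_rejected}

    # -- stage 5: comparisons ----------------------------------------------
    @stage("compare")
    def _():
        tab = state["event_dates"].copy()
        tab["moult_duration"] = tab["moult_end"] - tab["moult_start"]
        tab["haulout_duration"] = tab["departure"] - tab["arrival"]
        tab["moult_start_offset"] = tab["moult_start"] - compare_mod.SEASON_ORIGIN_DAY

        partitions = []
        multi = tab["category"].nunique() > 1 and tab["year"].nunique() > 1
        for metric, col in (
            ("moult_duration", "moult_duration"),
            ("moult_start", "moult_start_offset"),
            ("haulout_duration", "haulout_duration"),
        ):
            try:
                part = compare_mod.partition_variance(
                    tab[col].to_numpy(), tab["category"].to_numpy(),
                    tab["year"].to_numpy(), tab["animal_id"].to_numpy(),
                    metric=metric,
                )
                partitions.append({
                    "metric": metric,
                    "var_fixed": part.var_fixed,
                    "var_individual": part.var_individual,
                    "var_residual": part.var_residual,
                    "share_individual": part.share_individual,
                    "share_individual_excl_residual": part.share_individual_excl_residual,
                    "flagged": part.flagged,
                })
            except ValueError as exc:
                warnings.warn(f"variance partition for {metric} skipped: {exc}")
        if partitions:
            write_csv(pd.DataFrame(partitions), out / "variance_partition.csv", h)

        if multi:
            comp = compare_mod.compare_categories(
                tab["moult_duration"].to_numpy(), tab["category"].to_numpy(),
                tab["animal_id"].to_numpy(), tab["year"].to_numpy(),
            )
            write_csv(comp.table, out / "category_comparison.csv", h)
            write_csv(comp.contrasts, out / "category_contrasts.csv", h)

        fits = compare_mod.compensation_regression(
            tab["haulout_duration"].to_numpy(), tab["arrival"].to_numpy(),
            tab["category"].to_numpy(), tab["animal_id"].to_numpy(),
        )
        if fits:
            write_csv(
                pd.DataFrame([asdict(f) for f in fits.values()]),
                out / "compensation.csv", h,
            )

        ar = tab[tab["category"] == "adult_reproductive"]
        if not ar.empty:
            chain = compare_mod.annual_cycle_chain(ar)
            write_csv(chain, out / "annual_cycle.csv", h)
        return {"n_partitions": len(partitions)}

    _write_manifest(out, config, log)
    return out


def _write_manifest(out: Path, config: PipelineConfig, log: dict, failed: str | None = None) -> None:
    manifest = {
        "package": "phenomoult",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_hash": log.get("config_hash"),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": log.get("stages", {}),
    }
    if failed:
        manifest["failed_stage"] = failed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
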
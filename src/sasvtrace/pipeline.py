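"""End-to-end orchestration: simulate/load → SASV → fit → classify → enrich.

One :class:`PipelineConfig` (constructible from YAML) drives every stage with
a single seed; rerunning with the same config and seed is bit-identical. All
stage products are written to the output directory alongside a JSON manifest
recording parameters, versions, recovered-vs-planted exponents (for simulated
inputs) and any documented methodological deviations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attenuation import (P_VALUE_METHOD, fit_per_interval, fit_power_law)
from .depth_zones import (ABUNDANCE_THRESHOLD, DepthZoneMap, assignment_counts,
                          assignments_frame, classify_and_assign,
                          select_abundant, zone_composition)
from .io_tables import (AbundanceMatrix, load_dataset, read_flux, to_relative,
                        write_results, _jsonable)
from .sasv import (DIRECT_MONTH, direct_reference, fraction_table,
                   interpolate_missing_months, monthly_climatology,
                   profile_over_time, time_averaged_sasv_profiles)
from .sep import SEP_FACTOR, enriched_sasvs, enrichment_frame, flag_sep
from .synthetic import SimConfig, simulate_dataset

logger = logging.getLogger("sasvtrace")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``simulate`` holds a :class:`~sasvtrace.synthetic.SimConfig`, or
    the four input paths must all be given. Numeric defaults follow the study
    design: 75 m export reference depth, 250 m deep reference, 0.1% abundance
    threshold, 150% SEP flux factor, alpha = 0.05.
    """

    simulate: SimConfig | None = None
    water_counts: str | None = None
    trap_counts: str | None = None
    fasta: str | None = None
    metadata: str | None = None
    flux: str | None = None
    mode: str = "climatology"  # or "direct"
    z_ref: float = 75.0
    deep_z_ref: float = 250.0
    upper_window: tuple[float, float] = (75.0, 250.0)
    deep_window: tuple[float, float] = (250.0, 4000.0)
    abundance_threshold: float = ABUNDANCE_THRESHOLD
    sep_factor: float = SEP_FACTOR
    alpha: float = 0.05
    fdr: bool = False
    n_wildcard: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None:
            missing = [f for f in ("water_counts", "trap_counts", "fasta",
                                   "metadata")
                       if getattr(self, f) is None]
            if missing:
                raise ValueError(
                    f"pipeline config missing required input field(s): {missing}")
        if self.mode not in ("climatology", "direct"):
            raise ValueError(f"mode must be climatology|direct, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if k.endswith("_window") else v
                     for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = SimConfig(**sim) if isinstance(sim, dict) else SimConfig()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write all products plus ``manifest.json``.

    Returns a dict of in-memory products (the on-disk files are serializations
    of exactly these objects). Stage failures propagate with the stage name.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[dict] = []

    def stage(name: str):
        logger.info("stage %s", name)
        stages.append({"stage": name, "t": round(time.time() - t0, 3)})

    # --- inputs -----------------------------------------------------------
    stage("load")
    truth = None
    flux_records = None
    if cfg.simulate is not None:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        sim = simulate_dataset(sim_cfg)
        water, trap = sim.water, sim.trap
        water_samples, trap_samples = sim.water_samples, sim.trap_samples
        asvs, flux_records, truth = sim.asvs, sim.flux, sim.truth
    else:
        water, asvs_w, samples_w = load_dataset(
            cfg.water_counts, cfg.fasta, cfg.metadata)
        trap, asvs_t, samples_t = load_dataset(
            cfg.trap_counts, cfg.fasta, cfg.metadata)
        by_id = {a.asv_id: a for a in asvs_w} | {a.asv_id: a for a in asvs_t}
        asvs = list(by_id.values())
        water_samples = [s for s in samples_w if s.compartment == "water"]
        trap_samples = [s for s in samples_t if s.compartment == "trap"]
        if cfg.flux:
            flux_records = read_flux(cfg.flux)
    water_rel = to_relative(water)
    trap_rel = to_relative(trap)

    # --- climatology and SASV fractions -----------------------------------
    stage("sasv")
    if cfg.mode == "direct":
        clim = direct_reference(water_rel, water_samples)
    else:
        clim = monthly_climatology(water_rel, water_samples)
        needed = sorted({s.month for s in trap_samples})
        clim = interpolate_missing_months(clim, months=needed)
    fractions, sasv_sets = fraction_table(
        trap_rel, clim, asvs, trap_samples,
        direct=(cfg.mode == "direct"), n_wildcard=cfg.n_wildcard)
    water_profile = profile_over_time(fractions, "water_fraction")
    trap_profile = profile_over_time(fractions, "trap_fraction")
    write_results(fractions, outdir / "fractions.tsv")
    write_results(water_profile, outdir / "water_profile.tsv")
    write_results(trap_profile, outdir / "trap_profile.tsv")

    # --- power-law fits ----------------------------------------------------
    stage("fit")
    fit_upper = fit_power_law(water_profile, cfg.z_ref, cfg.upper_window)
    fit_deep_water = fit_power_law(water_profile, cfg.deep_z_ref,
                                   cfg.deep_window)
    fit_deep_trap = fit_power_law(trap_profile, cfg.deep_z_ref,
                                  cfg.deep_window)
    b_series = fit_per_interval(fractions, cfg.z_ref, cfg.upper_window)
    write_results(fit_upper, outdir / "fit_upper.json")
    write_results(fit_deep_water, outdir / "fit_deep_water.json")
    write_results(fit_deep_trap, outdir / "fit_deep_trap.json")
    write_results(b_series, outdir / "b_timeseries.tsv")

    # --- depth-zone classification ----------------------------------------
    stage("classify")
    profiles = time_averaged_sasv_profiles(sasv_sets, clim)
    abundant = select_abundant(profiles, cfg.abundance_threshold)
    assignments = classify_and_assign(abundant)
    counts = assignment_counts(assignments)
    taxonomy = {a.asv_id: (a.taxonomy[-1] if a.taxonomy else "") for a in asvs}
    comp, coverage = zone_composition(assignments, taxonomy, abundant)
    write_results(assignments_frame(assignments), outdir / "zone_assignments.tsv")
    write_results(comp, outdir / "zone_composition.tsv")
    write_results(coverage, outdir / "zone_coverage.tsv")

    # --- SEP enrichment ----------------------------------------------------
    stage("enrich")
    calendar = enrichment = None
    if flux_records:
        calendar = flag_sep(flux_records, trap_samples, factor=cfg.sep_factor)
        if len(calendar.sep_ids) >= 2 and len(calendar.nonsep_ids) >= 2:
            enrichment = enriched_sasvs(trap_rel, calendar, alpha=cfg.alpha,
                                        fdr=cfg.fdr)
            write_results(enrichment_frame(enrichment), outdir / "enrichment.tsv")
        else:
            logger.warning("too few SEP/non-SEP intervals; enrichment skipped")
        write_results(calendar, outdir / "sep_calendar.tsv")

    # --- manifest -----------------------------------------------------------
    stage("manifest")
    manifest = {
        "package": "sasvtrace",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": _jsonable(dataclasses.asdict(cfg)),
        "deviations": {
            "p_value_method": P_VALUE_METHOD,
            "welch_direction": "two-sided test with mean_sep > mean_nonsep gate",
        },
        "fits": {
            "upper": fit_upper.to_dict(),
            "deep_water": fit_deep_water.to_dict(),
            "deep_trap": fit_deep_trap.to_dict(),
        },
        "classification_counts": counts,
        "stages": stages,
    }
    if truth is not None:
        manifest["planted"] = {
            "b_upper": truth.b_upper, "b_deep": truth.b_deep,
            "b_trap": truth.b_trap,
        }
        manifest["recovered"] = {
            "b_upper": fit_upper.b, "b_deep": fit_deep_water.b,
            "b_trap": fit_deep_trap.b,
        }
    outputs = sorted(p.name for p in outdir.iterdir() if p.is_file()
                     and p.name != "manifest.json")
    manifest["output_sha256"] = {name: _sha256(outdir / name)
                                 for name in outputs}
    write_results(manifest, outdir / "manifest.json")

    return {
        "fractions": fractions,
        "sasv_sets": sasv_sets,
        "climatology": clim,
        "water_profile": water_profile,
        "trap_profile": trap_profile,
        "fit_upper": fit_upper,
        "fit_deep_water": fit_deep_water,
        "fit_deep_trap": fit_deep_trap,
        "b_series": b_series,
        "profiles": profiles,
        "assignments": assignments,
        "classification_counts": counts,
        "zone_composition": comp,
        "zone_coverage": coverage,
        "sep_calendar": calendar,
        "enrichment": enrichment,
        "manifest": manifest,
        "truth": truth,
    }
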
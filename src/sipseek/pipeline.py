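"""End-to-end forward-model orchestration.

A forward-model run rebuilds the whole prospecting chain on synthetic data:
simulate the gas-well and dry-well SIP microcosms, detect labeling and pick
the heavy fractions, sequence and classify heavy-fraction amplicons, call
the active methanotrophs of each scenario, derive the gas-indicator set,
apply it to a simulated survey line and grid the resulting biotic index into
an anomaly map.  The run is a pure function of (config, master seed):
per-stage seeds are derived as
``SeedSequence(master_seed, spawn_key=(crc32(stage_name),))`` so each stage
is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sipseek import fixtures
from sipseek.community import GenotypeProfile, diversity, relative_abundance
from sipseek.gradient import HeavyCall, detect_labeling
from sipseek.indicator import ZoneContrast, active_set, biotic_index, select_indicators, zone_contrast
from sipseek.simulate import (
    ConsumptionCurve,
    ScenarioConfig,
    SurveyTable,
    make_reference_db,
    simulate_amplicon_reads,
    simulate_gradient,
    simulate_microcosm,
    simulate_site_reads,
    simulate_survey,
)
from sipseek.spatial import AnomalyGrid, delineate_anomaly, idw_interpolate, mask_jaccard, sites_from_frame
from sipseek.taxonomy import assignment_counts, classify_reads, train_classifier

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(master_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Parameters of a forward-model run.

    Problem sizes default to a desk scale that finishes in well under a
    minute; every knob of the underlying modules is exposed here so a run is
    fully described by this object plus the master seed.
    """

    master_seed: int = 20240211
    # reference database
    n_refs_per_genotype: int = 8
    within_divergence: float = 0.02
    between_divergence: float = 0.15
    # classifier
    k: int = 8
    n_bootstrap: int = 100
    confidence_cutoff: float = 80.0
    # sequencing
    depth_sip: int = 5_000            # reads per heavy fraction
    depth_survey: int = 1_000         # reads per survey site
    error_rate: float = 0.01
    # indicator logic
    activity_threshold: float = 5.0
    # survey and map
    n_sites: int = 40
    bi_dispersion: float = 0.65
    idw_power: float = 2.0
    cell_size: float | None = None    # metres; None = extent / 200
    anomaly_threshold: float | None = None  # None = background mean + 2 sd

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ScenarioResult:
    """Per-scenario artifacts of a forward-model run."""

    config: ScenarioConfig
    curve: ConsumptionCurve
    heavy_call: HeavyCall
    heavy_profiles: dict[int, GenotypeProfile]
    active: object                    # indicator.ActiveSet


@dataclass
class ForwardModelResult:
    """Everything a forward-model run computed."""

    config: RunConfig
    scenarios: dict[str, ScenarioResult]
    indicators: frozenset
    survey: SurveyTable
    bi_table: pd.DataFrame            # site_id, easting_m, northing_m, bi_percent, zone
    contrast: ZoneContrast
    grid: AnomalyGrid
    jaccard: float
    report: str


def load_heavy_fraction_fixture() -> dict[str, pd.DataFrame]:
    """The worked-example heavy-fraction genotype table (soils P1 and J3)."""
    return fixtures.heavy_fraction_table()


def _scenario_result(cfg: ScenarioConfig, run: RunConfig, db, model, prefix: str) -> ScenarioResult:
    curve = simulate_microcosm(cfg)
    grown = cfg.incubated_profile or cfg.in_situ_profile
    frac13 = simulate_gradient(grown, cfg.activities, "13C",
                               seed=stage_seed(run.master_seed, f"{prefix}/gradient13"))
    frac12 = simulate_gradient(grown, cfg.activities, "12C",
                               seed=stage_seed(run.master_seed, f"{prefix}/gradient12"))
    call = detect_labeling(frac13, frac12)
    heavy = call.heavy_fractions or tuple(cfg.heavy_mob_composition)
    profiles: dict[int, GenotypeProfile] = {}
    for f in heavy:
        reads = simulate_amplicon_reads(
            cfg.heavy_mob_composition[f], db, depth=run.depth_sip,
            error_rate=run.error_rate,
            seed=stage_seed(run.master_seed, f"{prefix}/reads{f}"),
        )
        calls = classify_reads(reads, model, n_bootstrap=run.n_bootstrap,
                               confidence_cutoff=run.confidence_cutoff,
                               seed=stage_seed(run.master_seed, f"{prefix}/classify{f}"))
        profiles[f] = relative_abundance(
            assignment_counts(calls), sample_id=f"{cfg.label}_f{f}",
            source=f"heavy_fraction_{f}")
    active = active_set([p.abundances for p in profiles.values()],
                        threshold=run.activity_threshold, scenario=cfg.label)
    return ScenarioResult(config=cfg, curve=curve, heavy_call=call,
                          heavy_profiles=profiles, active=active)


def run_forward_model(config: RunConfig | None = None, out_dir=None,
                      gas: ScenarioConfig | None = None,
                      dry: ScenarioConfig | None = None) -> ForwardModelResult:
    """Run the full chain and optionally write its artifacts to ``out_dir``.

    ``gas`` and ``dry`` default to the two scenario presets; passing custom
    scenarios (e.g. two identical ones) exercises degenerate designs.
    """
    run = config or RunConfig()
    db = make_reference_db(
        n_refs_per_genotype=run.n_refs_per_genotype,
        divergence=(run.within_divergence, run.between_divergence),
        seed=stage_seed(run.master_seed, "refdb"),
    )
    model = train_classifier(db, k=run.k)
    gas = gas or ScenarioConfig.gas_well(depth=run.depth_sip)
    dry = dry or ScenarioConfig.dry_well(depth=run.depth_sip)

    try:
        gas_res = _scenario_result(gas, run, db, model, "gas")
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'gas scenario' failed: {exc}") from exc
    try:
        dry_res = _scenario_result(dry, run, db, model, "dry")
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'dry scenario' failed: {exc}") from exc

    if gas_res.active.active:
        indicators = select_indicators(gas_res.active, dry_res.active)
    else:
        indicators = frozenset()

    survey = simulate_survey(n_sites=run.n_sites, bi_dispersion=run.bi_dispersion,
                             seed=stage_seed(run.master_seed, "survey"))
    bi_rows = []
    for site_id, reads in simulate_site_reads(
            survey, db, depth=run.depth_survey, error_rate=run.error_rate,
            seed=stage_seed(run.master_seed, "survey_reads")):
        calls = classify_reads(reads, model, n_bootstrap=run.n_bootstrap,
                               confidence_cutoff=run.confidence_cutoff,
                               seed=stage_seed(run.master_seed, f"survey_classify/{site_id}"))
        profile = relative_abundance(assignment_counts(calls), sample_id=site_id)
        bi_rows.append(biotic_index(profile, indicators, sample_id=site_id))

    sites = survey.sites.copy()
    est = {r.sample_id: r.bi for r in bi_rows}
    sites["bi_percent"] = sites["site_id"].map(est)
    zones = dict(zip(survey.sites["site_id"], survey.sites["zone"]))
    contrast = zone_contrast(bi_rows, zones)

    site_objs = sites_from_frame(sites)
    grid = idw_interpolate(site_objs, power=run.idw_power, cell_size=run.cell_size)
    grid = delineate_anomaly(grid, sites=site_objs, threshold=run.anomaly_threshold)
    jac = mask_jaccard(grid, survey.polygon)

    report = _format_report(run, gas_res, dry_res, indicators, contrast, grid, jac)
    result = ForwardModelResult(config=run, scenarios={"gas_well": gas_res, "dry_well": dry_res},
                                indicators=indicators, survey=survey, bi_table=sites,
                                contrast=contrast, grid=grid, jaccard=jac, report=report)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _format_report(run, gas_res, dry_res, indicators, contrast, grid, jac) -> str:
    lines = ["forward-model report", "===================", ""]
    for res in (gas_res, dry_res):
        cfg = res.config
        lines.append(f"[{cfg.label}]")
        lines.append(f"  termination day: {res.curve.termination_day:g} "
                     f"(threshold crossed: {res.curve.terminated_by_threshold})")
        lines.append(f"  density shift: {res.heavy_call.shift:.4f} g/mL "
                     f"(labelled: {res.heavy_call.labelled})")
        lines.append(f"  heavy fractions: {res.heavy_call.heavy_fractions}")
        means = res.active.mean_abundance
        top = sorted(means.items(), key=lambda kv: -kv[1])[:5]
        lines.append("  mean heavy-fraction abundance (top 5): "
                     + ", ".join(f"{g} {v:.2f}%" for g, v in top))
        lines.append(f"  active set: {sorted(res.active.active)}")
        div = diversity(_mean_profile(res.heavy_profiles))
        lines.append(f"  diversity: H={div.H:.3f} bits, E={div.E:.3f}, S={div.S}")
        lines.append("")
    lines.append(f"indicator genotypes: {sorted(indicators)}")
    lines.append("")
    lines.append("survey zone contrast (site BI, %):")
    lines.append(contrast.summary.to_string())
    fold = "inf" if contrast.infinite_fold else f"{contrast.fold:.2f}"
    lines.append(f"fold difference (gas/background): {fold}")
    lines.append("")
    lines.append(f"anomaly threshold: {grid.threshold:.2f}%")
    lines.append(f"anomaly/polygon Jaccard overlap: {jac:.3f}")
    lines.append("")
    lines.append("effective config:")
    for key, value in sorted(dataclasses.asdict(run).items()):
        lines.append(f"  {key}: {value}")
    return "\n".join(lines) + "\n"


def _mean_profile(profiles: dict[int, GenotypeProfile]) -> dict[str, float]:
    keys = sorted({g for p in profiles.values() for g in p.abundances})
    return {g: float(np.mean([p.abundances.get(g, 0.0) for p in profiles.values()]))
            for g in keys}


def _write_artifacts(result: ForwardModelResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    (out / "report.txt").write_text(result.report)
    result.bi_table.to_csv(out / "bi_sites.tsv", sep="\t", index=False)
    for label, res in result.scenarios.items():
        res.curve.to_frame().to_csv(out / f"curve_{label}.tsv", sep="\t", index=False)
        rows = []
        for f, p in res.heavy_profiles.items():
            for g, v in sorted(p.abundances.items()):
                rows.append({"fraction": f, "genotype": g, "percent": v})
        pd.DataFrame(rows).to_csv(out / f"heavy_profiles_{label}.tsv", sep="\t", index=False)
    result.grid.to_ascii_grid(out / "bi_surface.asc")
    mask_df = pd.DataFrame(np.argwhere(result.grid.mask), columns=["row", "col"])
    mask_df.to_csv(out / "anomaly_cells.tsv", sep="\t", index=False)
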
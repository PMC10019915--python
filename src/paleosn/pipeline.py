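"""Configuration, orchestration and manifests for the end-to-end runs.

A run is described by one declarative YAML file (every key overridable
from the CLI).  Stages: simulate -> diversity -> area -> forcing ->
scan / regional -> recover.  Every stage writes its outputs as CSV (plus
a JSON truth sidecar for simulations) and appends record counts, seeds
and wall-clock to a run manifest that is written success or failure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .occurrences import (ConfigurationError, TimeBinScheme,
                          read_occurrences, filter_major_taxa,
                          bin_occurrences)
from .diversity import QuorumConfig, DiversityCurve, diversity_curve
from .area import (AreaCurve, SeaLevelCurve, load_fractional_area,
                   relative_area, rescale_amplitude, DEFAULT_ALPHA)
from .forcing import SNRateCurve, exp_memory_forcing, mc_forcing_band
from .inference import grid_scan, regional_convergence, ScanResult
from .simulate import GeneratorConfig, SyntheticTruth, gen_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML-loadable)."""

    seed: int = 0
    outdir: str = "paleosn_out"
    regions: tuple[str, ...] = ("global",)
    method: str = "sqs"
    quorum: QuorumConfig = field(default_factory=QuorumConfig)
    simulate: GeneratorConfig | None = None
    inputs: dict = field(default_factory=dict)
    bin_age_oldest: float = 520.0
    bin_width: float = 5.0
    bin_scheme_path: str | None = None
    lambda_grid: tuple[float, ...] = (10.0, 20.0, 40.0)
    alpha_grid: tuple[float, ...] = (0.6, 0.8, 1.0)
    regional_lambda: float = 20.0
    regional_alpha: float = DEFAULT_ALPHA
    ci_method: str = "fisher"
    amplitude_factor: float = 1.0
    binning_rule: str = "contained"
    taxa_filter: bool = True
    detrend: bool = False

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lambda_grid):
            raise ConfigurationError("lambda grid values must be > 0")
        if not self.lambda_grid or not self.alpha_grid:
            raise ConfigurationError("parameter grids must be nonempty")
        if self.ci_method not in ("fisher", "montecarlo"):
            raise ConfigurationError(
                f"unknown ci_method {self.ci_method!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "quorum" in raw and isinstance(raw["quorum"], dict):
            raw["quorum"] = QuorumConfig(**raw["quorum"])
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulate"] = GeneratorConfig(**sim)
        for key in ("lambda_grid", "alpha_grid", "regions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def scheme(self) -> TimeBinScheme:
        if self.bin_scheme_path:
            return TimeBinScheme.from_csv(self.bin_scheme_path)
        if self.simulate is not None:
            return self.simulate.scheme()
        return TimeBinScheme.uniform(self.bin_age_oldest, self.bin_width)


class RunManifest:
    """Per-run record of config, counts, seeds and timings."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data = {
            "version": __version__,
            "seed": config.seed,
            "config": _jsonable(dataclasses.asdict(config)),
            "stages": {},
            "status": "running",
        }

    def stage(self, name: str, **counts) -> None:
        rec = self.data["stages"].setdefault(name, {})
        rec.update(_jsonable(counts))
        self.write()

    def finish(self, status: str = "ok") -> None:
        self.data["status"] = status
        self.write()

    def write(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, default=str)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


class _Timer:
    def __init__(self):
        self.t0 = time.perf_counter()

    def lap(self) -> float:
        return round(time.perf_counter() - self.t0, 3)


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the four synthetic input families plus truth sidecars."""
    if config.simulate is None:
        raise ConfigurationError("run_simulate needs a 'simulate' block")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, out)
    timer = _Timer()
    ds = gen_dataset(config.simulate, regions=tuple(config.regions))
    ds.sn.to_csv(out / "sn_rate.csv")
    ds.sealevel.to_csv(out / "sealevel.csv")
    for region, frame in ds.fractions.items():
        frame.to_csv(out / f"area_fraction_{region}.csv", index=False)
    for region in config.regions:
        ds.occurrences[region].to_csv(out / f"occurrences_{region}.csv")
        ds.truths[region].to_sidecar(out / f"truth_{region}.json")
    manifest.stage("simulate", seconds=timer.lap(),
                   n_occurrence_rows={r: len(t) for r, t in
                                      ds.occurrences.items()},
                   regions=list(config.regions))
    manifest.finish()
    return out


def _diversity_for(config: PipelineConfig, occ_path: Path,
                   region: str, manifest: RunManifest) -> DiversityCurve:
    table = read_occurrences(occ_path)
    n_read = len(table)
    if config.taxa_filter:
        table = filter_major_taxa(table)
    binned = bin_occurrences(table, config.scheme(), config.binning_rule,
                             region=region)
    qc = dataclasses.replace(config.quorum, seed=config.seed)
    curve = diversity_curve(binned, qc, method=config.method)
    manifest.stage(f"diversity:{region}", n_read=n_read,
                   n_dropped=table.n_dropped,
                   n_after_taxa=len(table),
                   n_assigned=binned.n_assigned,
                   n_unassigned=binned.n_unassigned)
    return curve


def _areas_for(config: PipelineConfig, outdir: Path, region: str
               ) -> dict[str, AreaCurve]:
    """Area curves per source (maps and, for the global region, the
    sea-level reconstruction)."""
    areas: dict[str, AreaCurve] = {}
    frac_path = Path(config.inputs.get(
        "areas", {}).get(region, outdir / f"area_fraction_{region}.csv"))
    if frac_path.exists():
        areas["maps"] = load_fractional_area(frac_path, region=region)
    if region == "global":
        sl_path = Path(config.inputs.get("sealevel",
                                         outdir / "sealevel.csv"))
        if sl_path.exists():
            sl = SeaLevelCurve.from_csv(sl_path)
            if config.amplitude_factor != 1.0:
                sl = rescale_amplitude(sl, config.amplitude_factor)
            areas["sealevel"] = relative_area(sl)
    if not areas:
        raise ConfigurationError(
            f"no area inputs found for region {region!r}")
    return areas


def run_scan(config: PipelineConfig) -> ScanResult:
    """Diversity -> areas -> forcing -> (lambda, alpha) correlation scan."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, out)
    try:
        timer = _Timer()
        sn_path = Path(config.inputs.get("sn", out / "sn_rate.csv"))
        if not sn_path.exists():
            raise ConfigurationError(f"SN rate file {sn_path} not found")
        sn = SNRateCurve.from_csv(sn_path)
        div_curves: dict[str, DiversityCurve] = {}
        areas: dict[str, AreaCurve] = {}
        for region in config.regions:
            occ_path = Path(config.inputs.get("occurrences", {}).get(
                region, out / f"occurrences_{region}.csv")) \
                if isinstance(config.inputs.get("occurrences"), dict) \
                else Path(config.inputs.get(
                    "occurrences", out / f"occurrences_{region}.csv"))
            curve = _diversity_for(config, occ_path, region, manifest)
            curve.to_csv(out / f"diversity_{region}.csv")
            div_curves[region] = curve
            for src, ac in _areas_for(config, out, region).items():
                key = src if region == "global" else f"{src}:{region}"
                areas[key] = ac
                ac.to_csv(out / f"area_{region}_{src}.csv")
        scan = grid_scan(div_curves, areas, sn,
                         lambdas=config.lambda_grid,
                         alphas=config.alpha_grid)
        scan.to_csv(out / "scan.csv")
        fc = mc_forcing_band(sn, config.regional_lambda, n_draws=200,
                             seed=config.seed) if sn.sigma is not None \
            else exp_memory_forcing(sn, config.regional_lambda)
        fc.to_csv(out / "forcing.csv")
        manifest.stage("scan", seconds=timer.lap(), n_rows=len(scan.rows))
        manifest.finish()
        return scan
    except Exception:
        manifest.finish("failed")
        raise


def run_regional(config: PipelineConfig):
    """Figure-5-style regional normalization test."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, out)
    try:
        timer = _Timer()
        sn = SNRateCurve.from_csv(
            Path(config.inputs.get("sn", out / "sn_rate.csv")))
        div_by_region, areas_by_region = {}, {}
        for region in config.regions:
            occ_path = Path(config.inputs.get("occurrences", {}).get(
                region, out / f"occurrences_{region}.csv")) \
                if isinstance(config.inputs.get("occurrences"), dict) \
                else Path(out / f"occurrences_{region}.csv")
            div_by_region[region] = _diversity_for(config, occ_path, region,
                                                   manifest)
            srcs = _areas_for(config, out, region)
            area = srcs.get("maps", next(iter(srcs.values())))
            areas_by_region[region] = area.with_alpha(config.regional_alpha)
        fc = exp_memory_forcing(sn, config.regional_lambda)
        result = regional_convergence(div_by_region, areas_by_region, fc,
                                      detrend=config.detrend)
        for region, nd in result.normalized.items():
            pd.DataFrame({"age_Ma": nd.ages, "value": nd.value,
                          "sd": nd.sd}).to_csv(
                out / f"normalized_{region}.csv", index=False)
        with open(out / "regional.json", "w") as fh:
            json.dump({"dispersion_before": result.dispersion_before,
                       "dispersion_after": result.dispersion_after,
                       "dispersion_ratio": result.dispersion_ratio,
                       "regions": list(config.regions)}, fh, indent=1)
        manifest.stage("regional", seconds=timer.lap())
        manifest.finish()
        return result
    except Exception:
        manifest.finish("failed")
        raise


def run_recover(config: PipelineConfig) -> dict:
    """Compare the scan argmax against the simulation truth."""
    out = Path(config.outdir)
    truth_path = Path(config.inputs.get("truth",
                                        out / "truth_global.json"))
    if not truth_path.exists():
        raise ConfigurationError(
            f"truth sidecar {truth_path} not found; run simulate first")
    truth = SyntheticTruth.from_sidecar(truth_path)
    scan = run_scan(config)
    rows = scan.rows[scan.rows["curve_label"] == "global"]
    report: dict = {"true_lambda_Myr": truth.lam, "true_alpha": truth.alpha}
    if truth.lam in set(rows["lambda_Myr"]) and \
            truth.alpha in set(rows["alpha"]):
        sub = rows[np.isfinite(rows["r"])]
        per_cell = sub.groupby(["lambda_Myr", "alpha"])["r"].max()
        ranked = per_cell.sort_values(ascending=False)
        report["truth_rank"] = int(
            list(ranked.index).index((truth.lam, truth.alpha))) + 1
        report["r_at_truth"] = float(per_cell[(truth.lam, truth.alpha)])
        other_lams = [l for l in config.lambda_grid if l != truth.lam]
        if other_lams:
            near = min(other_lams, key=lambda l: abs(np.log(l / truth.lam)))
            report["nearest_lambda_Myr"] = near
            report["r_at_nearest_lambda"] = float(
                per_cell[(near, truth.alpha)])
    else:
        report["truth_rank"] = None
        report["note"] = "truth cell outside the scan grid"
    best = scan.best()
    report["argmax"] = {"lambda_Myr": float(best["lambda_Myr"]),
                        "alpha": float(best["alpha"]),
                        "r": float(best["r"])}
    with open(out / "recovery.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def run_all(config: PipelineConfig) -> dict:
    run_simulate(config)
    run_scan(config)
    if len(config.regions) > 1:
        run_regional(config)
    return run_recover(config)
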
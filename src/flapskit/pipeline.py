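"""End-to-end orchestration: config validation and the full pipeline run.

A run proceeds synthesize -> hydrolysis rates -> imaging -> corrections ->
community statistics from one YAML config, writing every stage's outputs
plus a JSON run report stamped with the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chrom, community, correct, imaging, synth

log = logging.getLogger("flapskit")

DEFAULT_CONFIG = {
    "seed": 1,
    "station": "Stn8",
    "depth_m": 75.0,
    "timepoints_d": [0, 3, 6, 9, 12, 18],
    "substrates": {
        name: {"parent_dp": 100, "monomer_conc": 3500.0,
               "mechanism": "endo_random", "cleavage_rate": 0.002,
               "killed": False}
        for name in synth.SUBSTRATE_NAMES
    },
    "chromatogram": {"noise_sd": 0.01, "n_chains": 800, "replicates": 3,
                     "n_bins": 16},
    "imaging": {"n_fov": 4, "n_cells": 40, "selfish_fraction": 0.3,
                "dapi_sbr": 5.0, "fla_sbr": 5.0, "background_noise_sd": 0.05,
                "pixel_pitch": 0.1, "volume_ml": 10.0,
                "filtration_area_mm2": 200.0, "save_images": False},
    "detection": {"dapi_sbr_min": 2.0, "fla_sbr_min": 2.5, "overlap_min": 0.3},
    "community": {"n_taxa": 25, "bloom_plateau": 0.65, "bloom_midpoint_d": 2.0,
                  "bloom_steepness": 2.0, "n_replicates": 3,
                  "read_depth_median": 65000.0, "n_perm": 199},
    "cellcounts": {"initial": 15000.0, "dynamics": "logistic",
                   "rate_per_day": 2.0, "plateau": 300000.0, "floor": 0.0,
                   "noise_sd": 0.05, "replicates": 3},
    "correction": {"in_situ_temp_c": 3.19},
}

# field path -> (allowed types, predicate, description); dicts recurse
_POS = (lambda v: v > 0, "must be positive")
_NONNEG = (lambda v: v >= 0, "must be >= 0")
_FRAC = (lambda v: 0 <= v <= 1, "must be in [0, 1]")
_NUM = (int, float)

_SUBSTRATE_SCHEMA = {
    "parent_dp": (int, (lambda v: v >= 2, "must be >= 2")),
    "monomer_conc": (_NUM, _POS),
    "mechanism": (str, (lambda v: v in synth.KineticsSpec._MECHANISMS,
                        f"must be one of {synth.KineticsSpec._MECHANISMS}")),
    "cleavage_rate": (_NUM, _NONNEG),
    "killed": (bool, None),
}

SCHEMA = {
    "seed": (int, _NONNEG),
    "station": (str, None),
    "depth_m": (_NUM, _NONNEG),
    "timepoints_d": (list, (lambda v: len(v) >= 2 and v[0] == 0
                            and all(b > a for a, b in zip(v, v[1:])),
                            "must start at 0 and strictly increase")),
    "substrates": "substrate_map",
    "chromatogram": {
        "noise_sd": (_NUM, _NONNEG),
        "n_chains": (int, _POS),
        "replicates": (int, _POS),
        "n_bins": (int, (lambda v: v >= 3, "must be >= 3")),
    },
    "imaging": {
        "n_fov": (int, _POS),
        "n_cells": (int, _NONNEG),
        "selfish_fraction": (_NUM, _FRAC),
        "dapi_sbr": (_NUM, (lambda v: v > 1, "must exceed 1")),
        "fla_sbr": (_NUM, (lambda v: v > 1, "must exceed 1")),
        "background_noise_sd": (_NUM, _NONNEG),
        "pixel_pitch": (_NUM, _POS),
        "volume_ml": (_NUM, _POS),
        "filtration_area_mm2": (_NUM, _POS),
        "save_images": (bool, None),
    },
    "detection": {
        "dapi_sbr_min": (_NUM, _POS),
        "fla_sbr_min": (_NUM, _POS),
        "overlap_min": (_NUM, (lambda v: 0 < v <= 1, "must be in (0, 1]")),
    },
    "community": {
        "n_taxa": (int, (lambda v: v >= 2, "must be >= 2")),
        "bloom_plateau": (_NUM, (lambda v: 0 <= v < 1, "must be in [0, 1)")),
        "bloom_midpoint_d": (_NUM, None),
        "bloom_steepness": (_NUM, None),
        "n_replicates": (int, _POS),
        "read_depth_median": (_NUM, _POS),
        "n_perm": (int, _POS),
    },
    "cellcounts": {
        "initial": (_NUM, _POS),
        "dynamics": (str, (lambda v: v in ("logistic", "decline", "constant"),
                           "must be logistic, decline or constant")),
        "rate_per_day": (_NUM, _NONNEG),
        "plateau": (_NUM, _NONNEG),
        "floor": (_NUM, _NONNEG),
        "noise_sd": (_NUM, _NONNEG),
        "replicates": (int, _POS),
    },
    "correction": {
        "in_situ_temp_c": (_NUM, None),
    },
}


def _validate_node(value, schema, path: str, errors: list[str]) -> None:
    if schema == "substrate_map":
        if not isinstance(value, dict) or not value:
            errors.append(f"{path}: must be a non-empty mapping of substrate specs")
            return
        for name, sub in value.items():
            _validate_node(sub, _SUBSTRATE_SCHEMA, f"{path}.{name}", errors)
        return
    if isinstance(schema, dict):
        if not isinstance(value, dict):
            errors.append(f"{path}: must be a mapping")
            return
        for key in value:
            if key not in schema:
                errors.append(f"{path}.{key}: unknown key")
        for key, sub in schema.items():
            if key not in value:
                errors.append(f"{path}.{key}: missing")
            else:
                _validate_node(value[key], sub, f"{path}.{key}", errors)
        return
    types, pred = schema
    if isinstance(value, bool) and types is not bool:
        errors.append(f"{path}: must be of type {types}, got bool")
        return
    if not isinstance(value, types):
        errors.append(f"{path}: must be of type {types}, "
                      f"got {type(value).__name__}")
        return
    if pred is not None:
        check, msg = pred
        try:
            ok = check(value)
        except Exception:
            ok = False
        if not ok:
            errors.append(f"{path}: {msg}")


def validate_config(config: dict) -> list[str]:
    """Validate a run config against the strict schema; returns error list."""
    errors: list[str] = []
    _validate_node(config, SCHEMA, "config", errors)
    return errors


def load_config(path) -> dict:
    """Load and validate a YAML run config; raises on any violation."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    return cfg


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_chromatograms(cfg, rng, outdir):
    """Synthesize chromatograms and compute killed-corrected rates."""
    ccfg = cfg["chromatogram"]
    timepoints_h = [24.0 * d for d in cfg["timepoints_d"]]
    bins_cache = {}
    all_series, rate_rows = [], []
    for name, scfg in cfg["substrates"].items():
        substrate = synth.SubstrateSpec(name=name, parent_dp=scfg["parent_dp"],
                                        monomer_conc=scfg["monomer_conc"])
        kin = synth.KineticsSpec(mechanism=scfg["mechanism"],
                                 cleavage_rate=scfg["cleavage_rate"],
                                 killed=scfg["killed"])
        killed_kin = synth.KineticsSpec(mechanism=scfg["mechanism"],
                                        cleavage_rate=scfg["cleavage_rate"],
                                        killed=True)
        calib = synth.default_calibration(substrate.parent_dp)
        key = substrate.parent_dp
        if key not in bins_cache:
            bins_cache[key] = chrom.MWBinning.log_spaced(key, ccfg["n_bins"])
        bins = bins_cache[key]

        live_series = []
        for rep in range(ccfg["replicates"]):
            s, _ = synth.generate_chromatogram_series(
                substrate, kin, timepoints_h, calib=calib,
                noise_sd=ccfg["noise_sd"], seed=int(rng.integers(2 ** 31)),
                n_chains=ccfg["n_chains"], sample_id=f"{name}_live_r{rep + 1}")
            live_series.append(s)
            all_series.append(s)
        killed_series, _ = synth.generate_chromatogram_series(
            substrate, killed_kin, timepoints_h, calib=calib,
            noise_sd=ccfg["noise_sd"], seed=int(rng.integers(2 ** 31)),
            n_chains=ccfg["n_chains"], sample_id=f"{name}_killed")
        all_series.append(killed_series)

        live_rates = chrom.rate_timecourse(live_series, substrate, calib, bins)
        killed_rates = chrom.rate_timecourse([killed_series], substrate, calib,
                                             bins)
        killed_by_t = killed_rates.set_index("timepoint_h")[
            "rate_nmol_monomer_L_h"]
        for _, row in live_rates.iterrows():
            t = row["timepoint_h"]
            live_est = chrom.HydrolysisRateEstimate(
                rate=row["rate_nmol_monomer_L_h"], substrate=name,
                elapsed_h=t, replicate=int(row["replicate"]))
            killed_est = chrom.HydrolysisRateEstimate(
                rate=float(killed_by_t[t]), substrate=name, elapsed_h=t)
            corrected = chrom.correct_with_killed(live_est, killed_est)
            rate_rows.append({
                "substrate": name, "station": cfg["station"],
                "depth_m": cfg["depth_m"], "timepoint_d": t / 24.0,
                "replicate": int(row["replicate"]),
                "rate_nmol_monomer_L_h": corrected.rate,
                "killed_corrected": True})

    chrom_path = outdir / "chromatograms.tsv"
    pd.concat([_series_frame(s) for s in all_series],
              ignore_index=True).to_csv(chrom_path, sep="\t", index=False)
    rates = pd.DataFrame(rate_rows)
    rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
    summary = rates.groupby(["substrate", "timepoint_d"])[
        "rate_nmol_monomer_L_h"].agg(["mean", "std"]).reset_index()
    summary.to_csv(outdir / "rates_summary.tsv", sep="\t", index=False)
    return rates, summary


def _series_frame(s: synth.ChromatogramSeries) -> pd.DataFrame:
    frames = []
    for i, t in enumerate(s.timepoints_h):
        frames.append(pd.DataFrame({
            "sample_id": s.sample_id, "substrate": s.substrate,
            "timepoint_h": t, "elution_position": s.elution,
            "signal": s.signals[i]}))
    return pd.concat(frames, ignore_index=True)


def _stage_imaging(cfg, rng, outdir):
    icfg = cfg["imaging"]
    spec = synth.ImageSceneSpec(
        n_cells=icfg["n_cells"], selfish_fraction=icfg["selfish_fraction"],
        pixel_pitch=icfg["pixel_pitch"], dapi_sbr=icfg["dapi_sbr"],
        fla_sbr=icfg["fla_sbr"], background_noise_sd=icfg["background_noise_sd"],
        n_fov=icfg["n_fov"])
    scenes = synth.generate_fov_set(spec, seed=int(rng.integers(2 ** 31)))
    if icfg["save_images"]:
        for i, scene in enumerate(scenes):
            scene.save(outdir / "imaging", stem=f"fov{i:02d}")
    params = imaging.DetectionParams(
        dapi_sbr_min=cfg["detection"]["dapi_sbr_min"],
        fla_sbr_min=cfg["detection"]["fla_sbr_min"],
        overlap_min=cfg["detection"]["overlap_min"],
        pixel_pitch=icfg["pixel_pitch"])
    counts = imaging.enumerate_fovs(scenes, params)
    counts.to_csv(outdir / "fov_counts.tsv", sep="\t", index=False)
    fov_area_mm2 = (spec.fov_shape[0] * spec.pixel_pitch
                    * spec.fov_shape[1] * spec.pixel_pitch) * 1e-6
    geometry = imaging.FilterGeometry(
        filtration_area_mm2=icfg["filtration_area_mm2"],
        fov_area_mm2=fov_area_mm2)
    est = imaging.abundance_estimate(counts["total"], counts["selfish"],
                                     geometry, icfg["volume_ml"])
    pd.DataFrame([{
        "total_per_ml": est.total_per_ml, "selfish_per_ml": est.selfish_per_ml,
        "selfish_percent": est.selfish_percent, "n_fov": est.n_fov,
        "total_sd_per_ml": est.total_sd_per_ml,
        "volume_ml": est.volume_ml}]).to_csv(outdir / "abundance.tsv",
                                             sep="\t", index=False)
    return est


def _stage_corrections(cfg, rng, outdir, rates_summary):
    ccfg = cfg["cellcounts"]
    dynamics = synth.GrowthDynamics(kind=ccfg["dynamics"],
                                    rate_per_day=ccfg["rate_per_day"],
                                    plateau=ccfg["plateau"],
                                    floor=ccfg["floor"])
    cells = synth.generate_cellcount_series(
        ccfg["initial"], dynamics, cfg["timepoints_d"],
        noise_sd=ccfg["noise_sd"], replicates=ccfg["replicates"],
        seed=int(rng.integers(2 ** 31)))
    cells.to_tsv(outdir / "cellcounts.tsv")

    means = cells.data.groupby("timepoint_d")["cells_per_ml"].mean()
    ref_day = 3.0 if 3.0 in means.index else means.index[min(1, len(means) - 1)]
    corr = correct.GrowthCorrection(n_initial=float(means.loc[0.0]),
                                    n_reference=float(means.loc[ref_day]))
    model = correct.TemperatureModel()
    temp_rate = correct.temperature_adjust(model, cfg["correction"]["in_situ_temp_c"])
    rows = []
    for _, row in rates_summary.iterrows():
        rows.append({
            "substrate": row["substrate"], "timepoint_d": row["timepoint_d"],
            "rate_measured_nmol_L_h": row["mean"],
            "rate_temp_corrected_nmol_L_h": temp_rate,
            "rate_insitu_pmol_L_h": correct.growth_adjust(temp_rate, corr),
            "initial_percent_of_reference": correct.fraction_of_reference(
                corr.n_initial, corr.n_reference)})
    corrected = pd.DataFrame(rows)
    corrected.to_csv(outdir / "rates_corrected.tsv", sep="\t", index=False)
    return cells, corrected


def _stage_community(cfg, rng, outdir):
    ccfg = cfg["community"]
    spec = synth.CommunitySpec(
        n_taxa=ccfg["n_taxa"], bloom_plateau=ccfg["bloom_plateau"],
        bloom_midpoint_d=ccfg["bloom_midpoint_d"],
        bloom_steepness=ccfg["bloom_steepness"],
        read_depth_median=ccfg["read_depth_median"],
        timepoints_d=tuple(float(d) for d in cfg["timepoints_d"]),
        n_replicates=ccfg["n_replicates"], station=cfg["station"])
    table, _truth = synth.generate_community_series(
        spec, seed=int(rng.integers(2 ** 31)))
    table.to_tsv(outdir / "community_counts.tsv", outdir / "community_meta.tsv")
    rel = community.normalize_relative(table)
    bc = community.bray_curtis(rel)
    bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
    tree = community.cluster_average(bc)
    tree.merge_table().to_csv(outdir / "cluster_merges.tsv", sep="\t",
                              index=False)
    groups = table.metadata["timepoint_d"]
    stat_rows = []
    for fn in (community.anosim, community.permanova):
        res = fn(bc, groups, n_perm=ccfg["n_perm"],
                 seed=int(rng.integers(2 ** 31)))
        stat_rows.append({"statistic": res.name, "value": res.statistic,
                          "n_perm": res.n_perm, "p_value": res.p_value,
                          "seed": res.seed})
    stats = pd.DataFrame(stat_rows)
    stats.to_csv(outdir / "community_stats.tsv", sep="\t", index=False)
    return table, stats


def run_pipeline(config: dict, outdir) -> dict:
    """Run all stages from a validated config; returns the run report."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed, "config_hash": config_hash(config)}

    def run_stage(name, fn, *args):
        log.info("running stage %s", name)
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    rates, summary = run_stage("rates", _stage_chromatograms, config, rng, outdir)
    report["rates"] = {
        "n_estimates": int(len(rates)),
        "per_substrate_day18_mean": {
            s: round(float(g.loc[g["timepoint_d"] == g["timepoint_d"].max(),
                                 "mean"].iloc[0]), 4)
            for s, g in summary.groupby("substrate")}}

    est = run_stage("imaging", _stage_imaging, config, rng, outdir)
    report["imaging"] = {"total_per_ml": round(est.total_per_ml, 1),
                         "selfish_per_ml": round(est.selfish_per_ml, 1),
                         "selfish_percent": round(est.selfish_percent, 2),
                         "n_fov": est.n_fov}

    cells, corrected = run_stage("corrections", _stage_corrections,
                                 config, rng, outdir, summary)
    report["corrections"] = {
        "in_situ_temp_c": config["correction"]["in_situ_temp_c"],
        "rate_temp_corrected_nmol_L_h": round(
            float(corrected["rate_temp_corrected_nmol_L_h"].iloc[0]), 4),
        "rate_insitu_pmol_L_h": round(
            float(corrected["rate_insitu_pmol_L_h"].iloc[0]), 2),
        "initial_percent_of_reference": round(
            float(corrected["initial_percent_of_reference"].iloc[0]), 2)}

    table, stats = run_stage("community", _stage_community, config, rng, outdir)
    report["community"] = {
        "n_samples": int(len(table.counts)),
        "n_low_read_samples": int(table.low_reads.sum()),
        "tests": {row["statistic"]: {"value": round(float(row["value"]), 4),
                                     "p_value": float(row["p_value"])}
                  for _, row in stats.iterrows()}}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", outdir)
    return report
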
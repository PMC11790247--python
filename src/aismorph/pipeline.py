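"""End-to-end orchestration: configuration, batch measurement, and
figure-level replication runs on synthetic data.

The replication entry points regenerate a synthetic dataset parameterized
from the study's printed condition statistics, run the full image →
measurement pipeline, and report the recovered quantities next to the
generator targets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, morphometry, nanostructure, puncta, stats_report
from . import synthetic
from .errors import AismorphError
from .morphometry import MorphometryConfig
from .nanostructure import AutocorrConfig
from .puncta import PunctaDetectionConfig
from .straighten import (DEFAULT_HALF_WIDTH_UM, extract_profile,
                         profile_from_image, straighten)

logger = logging.getLogger("aismorph")

FIGURE_IDS = ("fig8b", "fig8cd", "fig6cd", "fig5ab", "fig9b", "fig7")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run, fully serialized into
    every output."""

    input_images: list = field(default_factory=list)
    input_rois: list = field(default_factory=list)
    channel: str | int = 0
    half_width_um: float = DEFAULT_HALF_WIDTH_UM
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    autocorr: AutocorrConfig = field(default_factory=AutocorrConfig)
    puncta: PunctaDetectionConfig = field(default_factory=PunctaDetectionConfig)
    dvdt_criterion: float = 20.0
    seed: int | None = None
    output_dir: str = "aismorph_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("morphometry", MorphometryConfig),
                         ("autocorr", AutocorrConfig),
                         ("puncta", PunctaDetectionConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:12]


def measure_ais_end_to_end(image, roi, cfg: MorphometryConfig | None = None,
                           channel: str | int = 0,
                           half_width_um: float = DEFAULT_HALF_WIDTH_UM):
    """Straighten along the trace, extract the normalized profile, apply
    the 40%-threshold extent rule; returns an AISMeasurement."""
    cfg = cfg or MorphometryConfig()
    profile = profile_from_image(image, roi, half_width_um)
    return morphometry.measure_ais(profile, cfg, channel)


def measure_population(samples, cfg: MorphometryConfig | None = None,
                       channel: str | int = 0,
                       half_width_um: float = DEFAULT_HALF_WIDTH_UM) -> pd.DataFrame:
    """Measure every AIS of a synthetic population; one tidy row each."""
    cfg = cfg or MorphometryConfig()
    rows = []
    for s in samples:
        row = {"object_id": s.record.get("object_id"),
               "condition": s.record.get("condition"),
               "otc": s.otc,
               "true_length": s.record.get("true_length")}
        try:
            m = measure_ais_end_to_end(s.image, s.roi, cfg, channel,
                                       half_width_um)
            row.update(length_um=m.length, distance_um=m.distance_to_soma,
                       qc_flags=";".join(m.qc_flags))
        except AismorphError as exc:
            row.update(length_um=np.nan, distance_um=np.nan,
                       qc_flags=f"failed:{type(exc).__name__}")
        rows.append(row)
    return pd.DataFrame(rows)


def grand_mean(measured: pd.DataFrame, value_col: str = "length_um",
               unit_col: str = "otc") -> float:
    """Mean of per-OTC means — the condition-level statistic."""
    return float(measured.groupby(unit_col)[value_col].mean().mean())


def run_morphometry(config: RunConfig) -> Path:
    """File-based batch run: per-object CSV + summary JSON + log."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("aismorph %s | config %s | seed %s", __version__,
                    config.config_hash(), config.seed)
        if len(config.input_images) != len(config.input_rois):
            raise ValueError("one ROI per image required")
        rows = []
        for img_path, roi_path in zip(config.input_images, config.input_rois):
            image = io.load_image_stack(img_path)
            roi = io.load_roi(roi_path)
            object_id = Path(img_path).stem
            try:
                m = measure_ais_end_to_end(image, roi, config.morphometry,
                                           config.channel,
                                           config.half_width_um)
                rows.append({"id": object_id, "length_um": m.length,
                             "distance_um": m.distance_to_soma,
                             "channel": m.channel_used,
                             "qc_flags": ";".join(m.qc_flags)})
            except AismorphError as exc:
                rows.append({"id": object_id, "length_um": np.nan,
                             "distance_um": np.nan, "channel": "",
                             "qc_flags": f"failed:{type(exc).__name__}"})
        df = pd.DataFrame(rows)
        io.save_measurements(out / "measurements.csv", df)
        summary = {
            "software_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "config": config.to_jsonable(),
            "n_objects": int(len(df)),
            "n_failed": int(df["qc_flags"].str.startswith("failed").sum()),
            "mean_length_um": float(df["length_um"].mean()),
            "sd_length_um": float(df["length_um"].std(ddof=1)),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("measured %d objects (%d failed)", summary["n_objects"],
                    summary["n_failed"])
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# Figure-level replication

def _replicate_conditions(names, seed, n_otc=6, n_ais=50):
    """Render + measure one population per named condition."""
    rng = np.random.default_rng(seed)
    cfg = MorphometryConfig()
    frames = []
    for name in names:
        spec = synthetic.ConditionSpec.from_library(
            name, n_otc=n_otc, n_ais_per_otc=n_ais)
        samples, _ = synthetic.generate_condition_population(spec, rng=rng)
        frames.append(measure_population(samples, cfg))
    return pd.concat(frames, ignore_index=True)


def _report_fig8b(seed):
    measured = _replicate_conditions(["ctrl_20d", "mgso4_20d", "kcl_20d"], seed)
    summary, comparison = stats_report.plasticity_summary(measured)
    means = dict(zip(summary["condition"], summary["mean"]))
    return {
        "figure": "fig8b",
        "condition_means_um": means,
        "mgso4_minus_ctrl_um": means["mgso4_20d"] - means["ctrl_20d"],
        "targets_um": {c: synthetic.PLASTICITY_CONDITIONS[c][0]
                       for c in means},
        "test": comparison.test_name,
        "p_value": comparison.p_value,
        "posthoc": comparison.posthoc.to_dict("records"),
    }


def _report_fig8cd(seed):
    measured = _replicate_conditions(
        ["ctrl_10d", "mgso4_10d", "kcl_10d", "mgso4_rescue", "kcl_rescue"],
        seed)
    summary, _ = stats_report.plasticity_summary(measured)
    means = dict(zip(summary["condition"], summary["mean"]))
    per_otc = (measured.groupby(["condition", "otc"])["length_um"]
               .mean().reset_index())
    tests = {}
    for a, b in (("ctrl_10d", "mgso4_10d"), ("ctrl_10d", "kcl_10d")):
        res = stats_report.two_group_ttest(
            per_otc.loc[per_otc.condition == a, "length_um"],
            per_otc.loc[per_otc.condition == b, "length_um"],
            labels=(a, b))
        tests[f"{a}_vs_{b}"] = {"test": res.test_name, "p": res.p_value}
    return {"figure": "fig8cd", "condition_means_um": means,
            "targets_um": {c: synthetic.PLASTICITY_CONDITIONS[c][0]
                           for c in means},
            "tests": tests}


def _report_fig6cd(seed, n_cells=10):
    rng = np.random.default_rng(seed)
    cfg = AutocorrConfig()
    cohorts = {}
    stats_by_cohort = {}
    for cohort in ("untreated", "dcre", "cre"):
        amps, periods = [], []
        for _ in range(n_cells):
            spec = synthetic.StedProfileSpec()
            _, prof = synthetic.generate_sted_profile(spec, rng=rng)
            ac = nanostructure.autocorrelate(prof, spec.sample_spacing, cfg)
            amps.append(nanostructure.amplitude_statistic(ac, cfg))
            try:
                periods.append(nanostructure.detect_period(ac))
            except AismorphError:
                periods.append(np.nan)
        cohorts[cohort] = amps
        stats_by_cohort[cohort] = {
            "mean_amplitude": float(np.mean(amps)),
            "mean_period_nm": float(np.nanmean(periods)),
        }
    labels = np.concatenate([[c] * n_cells for c in cohorts])
    values = np.concatenate(list(cohorts.values()))
    comp = stats_report.compare_groups(stats_report.GroupData(values, labels))
    return {"figure": "fig6cd", "cohorts": stats_by_cohort,
            "test": comp.test_name, "p_value": comp.p_value}


def _report_fig5ab(seed, n_ais=50):
    rng = np.random.default_rng(seed)
    out = {"figure": "fig5ab"}
    for marker, (neg_key, pos_key) in (
            ("synpo", ("synpo_gfp_neg", "synpo_gfp_pos")),
            ("vgat", ("vgat_gfp_neg", "vgat_gfp_pos"))):
        counts = {}
        for key in (neg_key, pos_key):
            counts[key] = measure_puncta_cohort(
                synthetic.PUNCTA_GROUPS[key], n_ais, rng, label=marker)
        res = puncta.compare_puncta_counts(counts[neg_key], counts[pos_key])
        out[marker] = {
            "mean_counts": {k: float(np.mean(v)) for k, v in counts.items()},
            "target_means": {k: synthetic.PUNCTA_GROUPS[k]
                             for k in (neg_key, pos_key)},
            "test": res.test_name, "p_value": res.p_value,
        }
    return out


def measure_puncta_cohort(mean_count: float, n_ais: int,
                          rng: np.random.Generator, label: str = "puncta",
                          detection: PunctaDetectionConfig | None = None,
                          ais_length_mean: float = 27.9,
                          ais_length_sd: float = 3.0) -> list:
    """Render ``n_ais`` two-channel AIS and return detected puncta counts."""
    detection = detection or PunctaDetectionConfig()
    cfg = MorphometryConfig()
    pspec = synthetic.PunctaSpec(mean_count=mean_count, label=label)
    counts = []
    for _ in range(n_ais):
        length = max(5.0, rng.normal(ais_length_mean, ais_length_sd))
        distance = rng.uniform(2.0, 5.0)
        path = synthetic.make_axon_path(distance + length + 5.0,
                                        phase=rng.uniform(0, 2 * np.pi))
        gt = synthetic.AISGroundTruth(true_length=length,
                                      true_distance_to_soma=distance,
                                      path_control_points=path)
        image, roi, _ = synthetic.generate_ais_with_puncta(gt, pspec, rng=rng)
        simg = straighten(image, roi)
        prof = extract_profile(simg)
        ext = morphometry.detect_extent(prof, cfg, channel=0)
        det = puncta.detect_puncta(simg, (ext.start, ext.end), detection,
                                   channel=1)
        counts.append(det.count)
    return counts


def _report_fig9b(seed):
    rng = np.random.default_rng(seed)
    cfg = MorphometryConfig()
    samples, _ = synthetic.generate_longitudinal_pairs(rng=rng)
    w1, w2 = [], []
    for pair, _rec in samples:
        m1 = measure_ais_end_to_end(*pair["week1"], cfg)
        m2 = measure_ais_end_to_end(*pair["week2"], cfg)
        w1.append(m1.length)
        w2.append(m2.length)
    comp, reg = stats_report.longitudinal_analysis(w1, w2)
    return {"figure": "fig9b",
            "mean_week1_um": float(np.mean(w1)),
            "mean_week2_um": float(np.mean(w2)),
            "target_week1_um": synthetic.LONGITUDINAL_DEFAULTS["mean_week1"],
            "paired_test": comp.test_name, "p_value": comp.p_value,
            "r_squared": reg.r_squared, "n": reg.n}


def _report_fig7(seed):
    from . import ephys_features as ef
    spec = synthetic.EphysTraceSpec(
        model=synthetic.MembraneModel(noise_sd_mv=0.2))
    sweeps = synthetic.generate_ephys_traces(spec, seed=seed)
    passive = ef.passive_properties(sweeps)
    rheo, rheo_flags = ef.rheobase(sweeps)
    table, slope = ef.fi_curve_max_slope(sweeps)
    waveform = None
    for s in sweeps.sweeps:
        det = ef.detect_aps(s)
        idx = ef.first_ap_for_waveform(s, det, sweeps.step_onset_ms)
        if idx is not None:
            f = ef.ap_features(s, idx)
            waveform = {"current_pa": s.current_pa,
                        "threshold_mv": f.threshold,
                        "amplitude_mv": f.amplitude,
                        "half_width_ms": f.half_width,
                        "max_rise_mv_per_ms": f.max_rise}
            break
    max_aps = int(table["n_spikes"].max())
    return {"figure": "fig7", "rmp_mv": passive.rmp,
            "input_resistance_mohm": passive.input_resistance,
            "rheobase_pa": rheo, "rheobase_flags": list(rheo_flags),
            "fi_max_slope_hz_per_pa": slope, "max_ap_count": max_aps,
            "first_ap_waveform": waveform,
            "model_targets": {"rmp_mv": spec.model.rest_mv,
                              "input_resistance_mohm":
                                  spec.model.input_resistance_mohm,
                              "amplitude_mv": spec.model.ap_amplitude_mv,
                              "half_width_ms": spec.model.ap_halfwidth_ms}}


_REPORTS = {"fig8b": _report_fig8b, "fig8cd": _report_fig8cd,
            "fig6cd": _report_fig6cd, "fig5ab": _report_fig5ab,
            "fig9b": _report_fig9b, "fig7": _report_fig7}


def run_figure_replication(figure_id: str, seed: int = 0,
                           out_dir=None) -> dict:
    """Regenerate the matching synthetic dataset, run the pipeline, and
    report recovered vs target values; unknown ids list the valid ones."""
    if figure_id not in _REPORTS:
        raise ValueError(f"unknown figure id {figure_id!r}; "
                         f"valid: {', '.join(FIGURE_IDS)}")
    report = _REPORTS[figure_id](seed)
    report["seed"] = seed
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{figure_id}_report.json").write_text(
            json.dumps(report, indent=2, default=float))
    return report
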
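"""End-to-end orchestration: simulate -> register -> extract -> analyze -> report.

The measurement stage consumes either a study directory on disk (manifest +
frame files) or an in-memory :class:`~skintherm.simulate.StudySimulation`
stream, and produces the long measurement table (one row per image x
region). The analysis stage runs the study's t-test suite and the standard
set of mixed models; when ground truth is available (simulated input) a
recovery report compares every estimate to its generative value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats
from .frames import read_thermal
from .registration import estimate_affine
from .roi import (CONTROL_OFFSET_FACTOR, SUPERIOR_SIGN, extract_median,
                  fit_ellipse, make_control_roi)
from .simulate import GenerativeConfig, StudySimulation, simulate_study

__all__ = [
    "RunConfig",
    "extract_from_simulation",
    "extract_from_directory",
    "analyze_measurements",
    "run_pipeline",
    "MODEL_SET",
]

logger = logging.getLogger(__name__)

#: name -> (outcome, fixed terms, restrict-to-E8XT, melanin_centered)
MODEL_SET: dict[str, tuple] = {
    "absolute_camera": ("absolute", ("phase", "camera", "phase:camera"), False, False),
    "differential_camera": ("differential", ("phase", "camera", "phase:camera"), False, False),
    "absolute_distance": ("absolute", ("phase", "distance", "phase:distance"), True, False),
    "differential_distance": ("differential", ("phase", "distance", "phase:distance"), True, False),
    "differential_posture_lighting": ("differential", ("phase", "posture", "lighting"), True, False),
    "differential_melanin": ("differential", ("phase", "melanin", "phase:melanin"), True, False),
}

#: model term -> generative-truth key (see GenerativeConfig.true_effects)
_RECOVERY_MAP = {
    ("absolute_camera", "camera[ONEPro]"): "camera_offset_ONEPro",
    ("absolute_camera", "phase[cooled]"): "cooling_E8XT_abs",
    ("absolute_camera", "phase[cooled]:camera[ONEPro]"): "cooling_x_camera_abs",
    ("differential_camera", "phase[cooled]"): "cooling_E8XT_diff",
    ("differential_camera", "phase[cooled]:camera[ONEPro]"): "cooling_x_camera_diff",
    ("absolute_distance", "distance[50]"): "distance_50cm",
    ("absolute_distance", "phase[cooled]:distance[50]"): "distance_x_cooling",
    ("differential_melanin", "phase[cooled]:melanin"): "melanin_x_cooling",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``simulate=True`` (a synthetic study is generated from
    ``generative``) or ``manifest`` points at an existing study directory.
    A frozen copy of the resolved configuration is written next to the
    outputs of every run.
    """

    outdir: Path
    seed: int = 0
    simulate: bool = True
    manifest: Path | None = None
    write_frames: bool = False
    generative_overrides: dict = field(default_factory=dict)
    superior_sign: int = SUPERIOR_SIGN
    control_offset_factor: float = CONTROL_OFFSET_FACTOR
    models: tuple = tuple(MODEL_SET)

    def generative_config(self) -> GenerativeConfig:
        return GenerativeConfig(rng_seed=self.seed, **self.generative_overrides)

    def freeze(self) -> None:
        d = {
            "outdir": str(self.outdir), "seed": self.seed,
            "simulate": self.simulate,
            "manifest": str(self.manifest) if self.manifest else None,
            "write_frames": self.write_frames,
            "generative_overrides": dict(self.generative_overrides),
            "superior_sign": self.superior_sign,
            "control_offset_factor": self.control_offset_factor,
            "models": list(self.models),
        }
        Path(self.outdir).mkdir(parents=True, exist_ok=True)
        (Path(self.outdir) / "run_config.yaml").write_text(
            yaml.safe_dump(d, sort_keys=False))


# --------------------------------------------------------------------------
# extraction

def _measure_image(grid: np.ndarray, fid_opt, fid_therm, bpts_opt, sticker_bbox,
                   *, superior_sign=SUPERIOR_SIGN,
                   offset_factor=CONTROL_OFFSET_FACTOR) -> dict:
    affine = estimate_affine(fid_opt, fid_therm)
    bpts_thermal = affine.apply(bpts_opt)
    roi = fit_ellipse(bpts_thermal)
    valid = np.ones(grid.shape, dtype=bool)
    if sticker_bbox is not None:
        x0, y0, x1, y1 = sticker_bbox
        valid[max(y0, 0):y1 + 1, max(x0, 0):x1 + 1] = False
    default_cx = roi.cx + superior_sign * offset_factor * roi.a
    control = make_control_roi(roi, grid.shape, valid,
                               superior_sign=superior_sign,
                               offset_factor=offset_factor)
    relocated = abs(control.cx - default_cx) > 1e-9 or abs(control.cy - roi.cy) > 1e-9
    return {
        "roi": roi,
        "control": control,
        "relocated": relocated,
        "roi_median": extract_median(grid, roi),
        "control_median": extract_median(grid, control),
    }


def _records_for(meta: dict, measured: dict, melanin: dict) -> list[dict]:
    base = {
        "image_id": meta["image_id"],
        "subject_id": meta["subject_id"],
        "camera": meta["camera"],
        "distance_cm": int(meta["distance_cm"]),
        "lighting": meta["lighting"],
        "posture": meta["posture"],
        "phase": meta["phase"],
        "melanin_raw": melanin["melanin_raw"],
        "melanin_converted": melanin["melanin_converted"],
    }
    if measured["relocated"]:
        logger.info("control ROI relocated for %s -> center (%.1f, %.1f)",
                    meta["image_id"], measured["control"].cx, measured["control"].cy)
    return [
        {**base, "region": "roi", "median_temp_C": measured["roi_median"]},
        {**base, "region": "control", "median_temp_C": measured["control_median"]},
    ]


def extract_from_simulation(sim: StudySimulation, **roi_kwargs) -> pd.DataFrame:
    """Run registration/ROI extraction over an in-memory simulated study."""
    rows = []
    mel = {s.subject_id: {"melanin_raw": s.melanin_raw,
                          "melanin_converted": s.melanin_converted}
           for s in sim.cohort}
    for img in sim.iter_images():
        try:
            measured = _measure_image(
                img.thermal.grid, img.fiducials_optical, img.fiducials_thermal,
                img.boundary_points_optical, img.sticker_bbox, **roi_kwargs)
        except Exception as exc:
            raise RuntimeError(f"extraction failed for {img.image_id}: {exc}") from exc
        meta = sim.manifest_row(img)
        rows.extend(_records_for(meta, measured, mel[img.subject.subject_id]))
    return pd.DataFrame(rows)


def extract_from_directory(study_dir, **roi_kwargs) -> pd.DataFrame:
    """Run extraction over a study directory (manifest.csv + frames)."""
    study_dir = Path(study_dir)
    manifest = pd.read_csv(study_dir / "manifest.csv")
    colorimetry = pd.read_csv(study_dir / "colorimetry.csv").set_index("subject_id")
    rows = []
    for _, m in manifest.iterrows():
        frame = read_thermal(m["thermal_path"], camera_id=m["camera"])
        try:
            measured = _measure_image(
                frame.grid,
                np.array(json.loads(m["fiducials_optical"])),
                np.array(json.loads(m["fiducials_thermal"])),
                np.array(json.loads(m["boundary_points_optical"])),
                tuple(json.loads(m["sticker_bbox"])),
                **roi_kwargs)
        except Exception as exc:
            raise RuntimeError(f"extraction failed for {m['image_id']}: {exc}") from exc
        mel = colorimetry.loc[m["subject_id"]]
        rows.extend(_records_for(
            dict(m), measured,
            {"melanin_raw": float(mel["melanin_raw"]),
             "melanin_converted": float(mel["melanin_converted"])}))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# analysis

def cooling_response_summary(measurements: pd.DataFrame) -> dict:
    """Subject-level summary of the cooling response (mirrors the study's
    baseline/cooled x region layout) plus the four canonical tests."""
    means = stats.subject_average(measurements)
    wide = means.pivot_table(index="subject_id", columns=["region", "phase"],
                             values="median_temp_C")
    roi_b, roi_c = wide[("roi", "baseline")], wide[("roi", "cooled")]
    ctl_b, ctl_c = wide[("control", "baseline")], wide[("control", "cooled")]

    def cell(x):
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}

    tests = {}
    for name, call in (
            ("roi_change", lambda: stats.one_sample_test(roi_c - roi_b)),
            ("control_change", lambda: stats.one_sample_test(ctl_c - ctl_b)),
            ("baseline_diff", lambda: stats.paired_test(roi_b, ctl_b)),
            ("cooled_diff", lambda: stats.paired_test(roi_c, ctl_c))):
        try:
            tests[name] = call()
        except ValueError as exc:  # e.g. too few subjects for a t-test
            logger.warning("skipping %s: %s", name, exc)
            tests[name] = None
    table = {
        "roi": {"baseline": cell(roi_b), "cooled": cell(roi_c),
                "change": cell(roi_c - roi_b)},
        "control": {"baseline": cell(ctl_b), "cooled": cell(ctl_c),
                    "change": cell(ctl_c - ctl_b)},
        "roi_minus_control": {"baseline": cell(roi_b - ctl_b),
                              "cooled": cell(roi_c - ctl_c)},
    }
    return {"table": table, "tests": tests}


def analyze_measurements(measurements: pd.DataFrame,
                         models: tuple = tuple(MODEL_SET)) -> dict:
    """Fit the requested mixed models and the t-test suite."""
    out = {"summary": cooling_response_summary(measurements), "models": {}}
    for name in models:
        outcome, terms, e8_only, centered = MODEL_SET[name]
        data = measurements
        if e8_only:
            data = measurements[measurements["camera"] == "E8XT"]
        out["models"][name] = stats.fit_lmm(
            data, outcome=outcome, fixed_terms=terms, melanin_centered=centered)
    if "differential_melanin" in out["models"]:
        out["skin_tone"] = stats.skin_tone_report(out["models"]["differential_melanin"])
    return out


def coefficients_frame(results: dict) -> pd.DataFrame:
    frames = []
    for name, res in results["models"].items():
        f = res.to_frame()
        f.insert(0, "model", name)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def recovery_report(results: dict, config: GenerativeConfig) -> pd.DataFrame:
    """Compare fitted coefficients with their generative truths (95% CI)."""
    truths = config.true_effects()
    rows = []
    for (model_name, term), key in _RECOVERY_MAP.items():
        if model_name not in results["models"]:
            continue
        res = results["models"][model_name]
        if term not in res.params.index:
            continue
        ci = res.conf_int().loc[term]
        truth = truths[key]
        rows.append({
            "model": model_name, "term": term, "truth": truth,
            "estimate": float(res.params[term]), "se": float(res.bse[term]),
            "ci_lower": float(ci["lower"]), "ci_upper": float(ci["upper"]),
            "covered": bool(ci["lower"] <= truth <= ci["upper"]),
        })
    return pd.DataFrame(rows)


def _effect_report_text(results: dict) -> str:
    s = results["summary"]
    t = s["table"]
    lines = [
        "Temperature responses during baseline and cooling (mean ± SD, °C)",
        f"{'Region':<30}{'Baseline':>14}{'Cooled':>14}{'Cooled-Baseline':>18}",
    ]

    def fmt(c):
        return f"{c['mean']:.1f} ± {c['sd']:.1f}"

    lines.append(f"{'Cooling ROI':<30}{fmt(t['roi']['baseline']):>14}"
                 f"{fmt(t['roi']['cooled']):>14}{fmt(t['roi']['change']):>18}")
    lines.append(f"{'Control region':<30}{fmt(t['control']['baseline']):>14}"
                 f"{fmt(t['control']['cooled']):>14}{fmt(t['control']['change']):>18}")
    lines.append(f"{'ROI - Control':<30}{fmt(t['roi_minus_control']['baseline']):>14}"
                 f"{fmt(t['roi_minus_control']['cooled']):>14}{'':>18}")
    lines.append("")
    for name, res in s["tests"].items():
        lines.append(f"[{name}]")
        lines.append(res.summary() if res is not None else "skipped (too few subjects)")
        lines.append("")
    for name, res in results["models"].items():
        lines.append(f"=== model: {name} ===")
        lines.append(res.summary())
        lines.append("")
    if "skin_tone" in results:
        st = results["skin_tone"]
        lines.append("Skin tone translation of the melanin x cooling interaction:")
        lines.append(
            f"  {st['per_unit_C']:+.4f} °C per converted unit -> "
            f"{st['per_category_C']:+.3f} °C per category (25 units), "
            f"{st['across_scale_C']:+.3f} °C across Intermediate Low -> High (75 units)")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the results bundle.

    Outputs under ``config.outdir``: measurements.csv, coefficients.csv,
    effects_report.txt, results.json, run_config.yaml, and recovery.csv when
    the input was simulated.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.freeze()

    stage = "simulate"
    try:
        gen_config = None
        if config.simulate:
            gen_config = config.generative_config()
            sim = simulate_study(gen_config)
            logger.info("simulated study: %d subjects, %d images (seed %d)",
                        gen_config.n_subjects, sim.n_images, config.seed)
            stage = "extract"
            measurements = extract_from_simulation(
                sim, superior_sign=config.superior_sign,
                offset_factor=config.control_offset_factor)
        else:
            if config.manifest is None:
                raise ValueError("run needs simulate=True or a manifest directory")
            stage = "extract"
            measurements = extract_from_directory(
                Path(config.manifest),
                superior_sign=config.superior_sign,
                offset_factor=config.control_offset_factor)
        measurements.to_csv(outdir / "measurements.csv", index=False)

        stage = "analyze"
        results = analyze_measurements(measurements, models=config.models)
        coefficients_frame(results).to_csv(outdir / "coefficients.csv", index=False)

        stage = "report"
        (outdir / "effects_report.txt").write_text(_effect_report_text(results))
        bundle = {
            "seed": config.seed,
            "n_measurements": int(len(measurements)),
            "models": {name: res.to_frame().to_dict(orient="records")
                       for name, res in results["models"].items()},
            "summary_table": results["summary"]["table"],
        }
        if "skin_tone" in results:
            bundle["skin_tone"] = results["skin_tone"]
        if gen_config is not None:
            recovery = recovery_report(results, gen_config)
            recovery.to_csv(outdir / "recovery.csv", index=False)
            bundle["recovery"] = recovery.to_dict(orient="records")
        (outdir / "results.json").write_text(json.dumps(bundle, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    results["measurements"] = measurements
    results["bundle"] = bundle
    return results
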
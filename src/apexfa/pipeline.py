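"""End-to-end orchestration: simulate -> segment -> FA -> features ->
rad-score -> survival models -> evaluation.

Stages communicate through plain files in a run directory (CSV tables, JSON
models, PNG images) and are cached: a stage is recomputed only when its
configuration hash — chained through its upstream stages — changes, so
reruns of a downstream stage reuse upstream artifacts byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edges, evaluation, fragments, phantom, radscore, survival, texture
from .image import Radiograph, read_radiograph

log = logging.getLogger("apexfa.pipeline")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration of every pipeline stage."""

    # simulate
    n_patients: int = 254
    beta_boundary: float = -1.2
    dropout_prob: float = 0.25
    split_ratio: float = 0.6
    seed: int = 0
    # segment
    canny_sigma: float = edges.DEFAULT_SIGMA
    canny_low: float = edges.CANNY_LOW
    canny_high: float = edges.CANNY_HIGH
    closing_radius_mm: float = 0.3
    inner_margin_mm: float = 0.5
    outer_margin_mm: float = 0.5
    # fragment analysis
    probe_len_mm: float = 2.0
    side_mm: float = 1.0
    # texture
    glcm_levels: int = 64
    clip_k: float = 3.0
    d_max: int = 5
    # rad-score
    cv_folds: int = 10
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.05
    min_group_frac: float = 0.1
    # survival models
    stepwise: bool = True
    bootstrap_B: int = 0
    # evaluation
    time_points: tuple[float, ...] = (12.0, 15.0, 18.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "time_points" in raw:
            raw["time_points"] = tuple(float(t) for t in raw["time_points"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["time_points"] = list(self.time_points)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def _hash(self, keys: tuple[str, ...], upstream: str = "") -> str:
        payload = {k: getattr(self, k) for k in keys}
        payload["__upstream__"] = upstream
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_STAGE_KEYS = {
    "simulate": ("n_patients", "beta_boundary", "dropout_prob", "split_ratio",
                 "seed"),
    "segment": ("canny_sigma", "canny_low", "canny_high", "closing_radius_mm",
                "inner_margin_mm", "outer_margin_mm"),
    "fa": ("probe_len_mm", "side_mm"),
    "features": ("glcm_levels", "clip_k", "d_max"),
    "radscore": ("cv_folds", "n_lambdas", "lambda_min_ratio",
                 "min_group_frac", "seed"),
    "fit": ("stepwise", "bootstrap_B"),
    "evaluate": ("time_points",),
}
_STAGE_ORDER = ("simulate", "segment", "fa", "features", "radscore", "fit",
                "evaluate")


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = (json.loads(self.path.read_text())
                     if self.path.exists() else {"stages": {}})

    def fresh(self, stage: str, h: str) -> bool:
        return self.data["stages"].get(stage) == h

    def record(self, stage: str, h: str) -> None:
        self.data["stages"][stage] = h
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _chained_hashes(cfg: PipelineConfig) -> dict[str, str]:
    hashes = {}
    upstream = ""
    for stage in _STAGE_ORDER:
        upstream = cfg._hash(_STAGE_KEYS[stage], upstream=upstream)
        hashes[stage] = upstream
    return hashes


# ---------------------------------------------------------------------------
# per-patient imaging chain
# ---------------------------------------------------------------------------

def segment_radiograph(image: Radiograph, seed_point, cfg: PipelineConfig):
    """Canny -> contour around the seed point -> S1/S2/S3 masks."""
    em = edges.canny(image, sigma=cfg.canny_sigma, low=cfg.canny_low,
                     high=cfg.canny_high)
    contour = edges.trace_contour(em, seed_point,
                                  closing_radius_mm=cfg.closing_radius_mm)
    rois = edges.build_rois(contour, image.shape, image.spacing,
                            cfg.inner_margin_mm, cfg.outer_margin_mm)
    return contour, rois


def analyze_boundary(image: Radiograph, contour, cfg: PipelineConfig):
    """Transition band -> square tiling -> fragments -> S4 image."""
    band = fragments.locate_transition(image, contour,
                                       probe_len_mm=cfg.probe_len_mm)
    squares = fragments.tile_boundary(band, side_mm=cfg.side_mm)
    frag_set = fragments.extract_fragments(image, squares)
    s4 = fragments.reassemble(frag_set)
    return band, frag_set, s4


def patient_features(image: Radiograph, rois, s4, cfg: PipelineConfig) -> pd.Series:
    return texture.extract_all(
        image, rois, s4, d_values=tuple(range(1, cfg.d_max + 1)),
        G=cfg.glcm_levels, clip_k=cfg.clip_k,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    cp = phantom.CohortParams(
        n_patients=cfg.n_patients, beta_boundary=cfg.beta_boundary,
        dropout_prob=cfg.dropout_prob, split_ratio=cfg.split_ratio,
        seed=cfg.seed,
    )
    cohort = phantom.generate_cohort(cp)
    phantom.save_cohort(cohort, out)


def _load_images(out: Path) -> dict[str, Radiograph]:
    table = pd.read_csv(out / "cohort.csv")
    return {
        pid: read_radiograph(out / "images" / f"{pid}.png")
        for pid in table["patient_id"]
    }


def stage_segment(cfg: PipelineConfig, out: Path) -> None:
    images = _load_images(out)
    contours = {}
    failed = []
    for pid, img in images.items():
        seed = (img.shape[0] // 2, img.shape[1] // 2)
        try:
            contour, _ = segment_radiograph(img, seed, cfg)
            contours[pid] = edges.export_contour_json(contour)
        except (edges.ContourError, edges.MarginError) as exc:
            log.warning("segment %s failed: %s", pid, exc)
            failed.append(pid)
    if failed:
        warnings.warn(f"segmentation failed for {len(failed)} patient(s)")
    (out / "contours.json").write_text(json.dumps(contours))


def stage_fa(cfg: PipelineConfig, out: Path) -> None:
    images = _load_images(out)
    contours = json.loads((out / "contours.json").read_text())
    s4_dir = out / "s4"
    s4_dir.mkdir(exist_ok=True)
    tilings = {}
    for pid, verts in contours.items():
        img = images[pid]
        contour = edges.LesionContour(np.asarray(verts))
        try:
            band, frag_set, s4 = analyze_boundary(img, contour, cfg)
        except (fragments.TransitionError, fragments.TilingError,
                fragments.ExtractionError) as exc:
            log.warning("FA %s failed: %s", pid, exc)
            continue
        np.save(s4_dir / f"{pid}.npy", s4.pixels)
        tilings[pid] = fragments.tiling_to_json(frag_set.squares)
    (out / "tilings.json").write_text(json.dumps(tilings))


def stage_features(cfg: PipelineConfig, out: Path) -> None:
    images = _load_images(out)
    contours = json.loads((out / "contours.json").read_text())
    rows = {}
    for pid in contours:
        s4_path = out / "s4" / f"{pid}.npy"
        if not s4_path.exists():
            continue
        img = images[pid]
        contour = edges.LesionContour(np.asarray(contours[pid]))
        rois = edges.build_rois(contour, img.shape, img.spacing,
                                cfg.inner_margin_mm, cfg.outer_margin_mm)
        s4_pixels = np.load(s4_path)
        rows[pid] = patient_features(img, rois, s4_pixels, cfg)
    feats = pd.DataFrame(rows).T
    feats.index.name = "patient_id"
    feats.to_csv(out / "features.csv")


ROI_PREFIXES = {1: "S1_", 2: "S2_", 3: "S3_", 4: "S4_"}


def stage_radscore(cfg: PipelineConfig, out: Path) -> None:
    feats = pd.read_csv(out / "features.csv", index_col="patient_id")
    table = pd.read_csv(out / "cohort.csv").set_index("patient_id")
    table = table.loc[feats.index]
    dev = table["cohort"] == "dev"

    scores = pd.DataFrame(index=feats.index)
    validation_rows = []
    for k, prefix in ROI_PREFIXES.items():
        cols = [c for c in feats.columns if c.startswith(prefix)]
        model = radscore.RadScoreCox(
            feats.loc[dev, cols], table.loc[dev, "time_months"],
            table.loc[dev, "event"],
        )
        res = model.fit(cv=cfg.cv_folds, seed=cfg.seed,
                        n_lambdas=cfg.n_lambdas,
                        lambda_min_ratio=cfg.lambda_min_ratio)
        if res.selected:
            res.set_cutpoint(min_group_frac=cfg.min_group_frac)
        res.to_json(out / f"radscore_s{k}.json")
        res.cv_curve.to_csv(out / f"radscore_s{k}_cv.csv", index=False)
        scores[f"radscore_s{k}"] = res.score(feats[cols])

        # validation-cohort stratified KM + G-rho + univariate Cox
        val = ~dev
        row = {"roi": f"S{k}", "lambda": res.lambda_,
               "n_selected": len(res.selected), "cutpoint": res.cutpoint}
        sval = scores.loc[val.to_numpy(), f"radscore_s{k}"].to_numpy()
        tval = table.loc[val, "time_months"].to_numpy()
        eval_ = table.loc[val, "event"].to_numpy()
        if res.cutpoint is not None and len(np.unique(sval > res.cutpoint)) == 2:
            hi = sval > res.cutpoint
            chi2, p = radscore.grho_logrank(tval[~hi], eval_[~hi],
                                            tval[hi], eval_[hi], rho=1.0)
            # HR of healing for the high- vs low-score group: > 1 means
            # higher rad-score patients reach radiographic healing sooner
            cox = radscore.univariate_cox(hi.astype(float), tval, eval_)
            row.update({"grho_chi2": chi2, "grho_p": p, "hr": cox["hr"],
                        "hr_lower": cox["ci_lower"], "hr_upper": cox["ci_upper"],
                        "hr_p": cox["p"]})
        validation_rows.append(row)
    scores.to_csv(out / "radscores.csv")
    pd.DataFrame(validation_rows).to_csv(out / "radscore_validation.csv",
                                         index=False)


def stage_fit(cfg: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(out / "cohort.csv").set_index("patient_id")
    scores = pd.read_csv(out / "radscores.csv", index_col="patient_id")
    data = table.join(scores, how="inner").reset_index()
    dev = data[data["cohort"] == "dev"]

    specs = [survival.ModelSpec.reference()] + [
        survival.ModelSpec.with_radscore(k) for k in (1, 2, 3, 4)
    ]
    models = {}
    for spec in specs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = survival.fit_cox(spec, dev)
            if cfg.stepwise:
                res = survival.stepwise_select(res)
        entry = res.to_json()
        if cfg.bootstrap_B >= 50:
            entry["bootstrap"] = survival.bootstrap_validate(
                spec, dev, B=cfg.bootstrap_B, seed=cfg.seed)
        models[spec.name] = entry
    (out / "models.json").write_text(json.dumps(models, indent=2))


def _rebuild_results(entry: dict, data: pd.DataFrame) -> survival.CoxResults:
    from . import coxph

    model = survival.CoxModel(data, entry["terms"])
    baseline = coxph.BaselineCumHaz(
        np.asarray(entry["baseline_cumhaz"]["times"], float),
        np.asarray(entry["baseline_cumhaz"]["cumhaz"], float),
    )
    return survival.CoxResults(
        model, pd.Series(entry["beta"], index=entry["terms"]),
        np.asarray(entry["covariance"], float), entry["loglik"], baseline,
    )


def stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(out / "cohort.csv").set_index("patient_id")
    scores = pd.read_csv(out / "radscores.csv", index_col="patient_id")
    data = table.join(scores, how="inner").reset_index()
    val = data[data["cohort"] == "val"].reset_index(drop=True)
    models = json.loads((out / "models.json").read_text())

    tval = val["time_months"].to_numpy()
    eval_ = val["event"].to_numpy()
    rows = []
    dca_frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, entry in models.items():
            res = _rebuild_results(entry, val)
            for t in cfg.time_points:
                risk = res.predict_risk(t, val)
                roc = evaluation.time_dependent_roc(risk, tval, eval_, t)
                row = {"model": name, "t": t, "auc": roc.auc,
                       "auc_lower95": roc.ci[0], "auc_upper95": roc.ci[1]}
                if name != "reference":
                    ref = _rebuild_results(models["reference"], val)
                    z, p = evaluation.compare_auc(
                        risk, ref.predict_risk(t, val), tval, eval_, t)
                    row.update({"z_vs_reference": z, "p_vs_reference": p})
                try:
                    slope, intercept, _ = evaluation.calibration_at_time(
                        risk, tval, eval_, t)
                    row.update({"calibration_slope": slope,
                                "calibration_intercept": intercept})
                except evaluation.DegenerateCalibrationError:
                    pass
                rows.append(row)
                nb = evaluation.decision_curve(risk, tval, eval_, t)
                frame = nb.frame()
                frame.insert(0, "model", name)
                frame.insert(1, "t", t)
                dca_frames.append(frame)
    pd.DataFrame(rows).to_csv(out / "evaluation.csv", index=False)
    pd.concat(dca_frames, ignore_index=True).to_csv(out / "dca.csv", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "fa": stage_fa,
    "features": stage_features,
    "radscore": stage_radscore,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
}


def run_stage(stage: str, cfg: PipelineConfig, out_dir: str | Path,
              force: bool = False) -> Path:
    """Run one stage (and nothing else), honoring the cache."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    h = _chained_hashes(cfg)[stage]
    if not force and manifest.fresh(stage, h):
        log.info("stage %s is fresh; reusing cached outputs", stage)
        return out
    _STAGE_FUNCS[stage](cfg, out)
    manifest.record(stage, h)
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 force: bool = False) -> Path:
    """Execute every stage in order, reusing fresh cached stages.

    The run directory receives the cohort tables, images, contours, S4
    images, the feature table, rad-score models, fitted Cox models and the
    evaluation report, plus a manifest of per-stage configuration hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    for stage in _STAGE_ORDER:
        run_stage(stage, cfg, out, force=force)
    return out
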
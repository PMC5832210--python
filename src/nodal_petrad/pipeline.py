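"""End-to-end study pipeline: simulate -> extract -> preselect -> model
-> validate -> report.

Mirrors the model-development workflow of a nodal PET-radiomics study:
synthetic phantom cohort with known outcome drivers, 118-feature
extraction from tumor and nodal structures, ICC/LoA feature
pre-selection, three LASSO-Cox prognostic models (tumor features, node
features, and their union), internal/external concordance, and AIC
model comparison.  Every stochastic stage derives its RNG stream from
the single configured master seed.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import images as img
from . import preselection as presel
from . import radiomics as rad
from . import survival as surv
from . import synthetic as synth

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "build_cohort",
           "extract_structure_features", "COMMON_DESCRIPTORS"]

#: the common PET descriptors screened univariably (Table-3-style report)
COMMON_DESCRIPTORS = ["stats_max", "stats_suv_peak", "stats_mean", "shape_volume_cc"]


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run; CLI flags override it."""

    seed: int | None = None
    out_dir: str = "run"
    n_patients: int = 262
    n_validation: int = 50
    # phantom geometry / uptake
    grid_shape: tuple[int, int, int] = (44, 44, 36)
    spacing: tuple[float, float, float] = img.DEFAULT_SPACING
    max_nodes: int = 5
    tumor_suv_mean: float = 8.0
    node_suv_mean: float = 5.0
    suv_spread: float = 0.5  # between-patient lognormal sigma of blob means
    noise_cv: float = 0.2
    texture_scale: float = 1.0
    background_suv: float = 0.5
    # replicate segmentations for the robustness stage
    retest_magnitude: float = 0.4
    observer_magnitude: float = 0.7
    # extraction / preselection
    bin_width: float = 0.5
    icc_cutoff: float = 0.85
    loa_bound: float = 10.0
    surrogacy_mode: str = "both"
    # outcome model (log-hazard per SD of each ground-truth driver)
    betas: dict = field(default_factory=lambda: {
        "ln__stats_mean": 0.50,
        "ln__glcm_entropy": 0.35,
        "tumor__glrlm_sre": -0.30,
    })
    baseline_shape: float = 1.2
    baseline_scale: float = 24.0
    censoring_rate: float = 0.3
    # modeling
    n_folds: int = 10
    log_transform_ln_volume: bool = True
    save_images: bool = False
    stages: tuple[str, ...] = ("simulate", "extract", "preselect", "model",
                               "validate", "report")

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit master seed")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (1 <= self.max_nodes <= 5):
            raise ValueError("max_nodes must be in 1..5")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("grid_shape", "spacing", "stages"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def config_hash(self) -> str:
        text = json.dumps(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {files: {path: sha256}, seconds, records}

    def add(self, stage: str, files: dict[str, str], seconds: float, records: int) -> None:
        self.stages[stage] = {"files": files, "seconds": round(seconds, 3),
                              "records": records}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "version": self.version,
                       "stages": self.stages}, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _patient_phantom(cfg: RunConfig, patient: int, cohort: str) -> synth.PhantomSpec:
    # one RNG stream per patient keyed by (master seed, cohort, index)
    tag = 0 if cohort == "dev" else 1
    rng = np.random.default_rng((cfg.seed, tag, patient))
    n_nodes = int(rng.integers(1, cfg.max_nodes + 1))
    # wide between-patient uptake spread (printed SUV ranges span ~x30)
    return synth.PhantomSpec(
        grid_shape=cfg.grid_shape, spacing=cfg.spacing, n_nodes=n_nodes,
        tumor_suv_mean=float(rng.lognormal(0.0, cfg.suv_spread) * cfg.tumor_suv_mean),
        node_suv_mean=float(rng.lognormal(0.0, cfg.suv_spread) * cfg.node_suv_mean),
        tumor_radius_vox=float(rng.uniform(3.5, 6.5)),
        node_radius_vox=3.5,
        texture_scale=cfg.texture_scale, noise_cv=cfg.noise_cv,
        background_suv=cfg.background_suv,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def extract_structure_features(image, tumor, nodes, bin_width: float = 0.5) -> dict[str, dict]:
    """118-feature vectors for the tumor and the three nodal structures."""
    merged = img.merge_nodes(nodes)
    largest = img.select_largest_node(nodes)
    active = img.select_most_active_node(nodes, image)
    return {
        "tumor": rad.extract_all(image, tumor, bin_width),
        "ln_merged": rad.extract_all(image, merged, bin_width),
        "ln_volume": rad.extract_all(image, largest, bin_width),
        "ln_max": rad.extract_all(image, active, bin_width),
    }


def _clinical_covariates(cfg: RunConfig, patient: int, n_nodes: int) -> dict:
    rng = np.random.default_rng((cfg.seed, 7, patient))
    return {
        "age": float(np.clip(rng.normal(66, 10), 33, 86)),
        "gender": rng.choice(["male", "female"], p=[0.66, 0.34]),
        "stage": rng.choice(["II", "IIIa", "IIIb"], p=[0.04, 0.41, 0.55]),
        "n_stage": rng.choice(["1", "2", "3"], p=[0.11, 0.58, 0.31]),
        "n_ln_stations": int(n_nodes + rng.integers(0, 3)),
        "histology": rng.choice(["squamous", "adeno", "nos"], p=[0.28, 0.23, 0.49]),
        "rt_dose": float(np.clip(rng.normal(64.4, 7.5), 45, 80)),
        "chemotherapy": rng.choice(["yes", "no"], p=[0.9, 0.1]),
    }


def build_cohort(cfg: RunConfig, cohort: str = "dev", out_dir: Path | None = None):
    """Simulate phantoms, extract all structure features, return the tables.

    Returns ``(features, replicates, clinical)`` where ``features`` has
    one row per patient with ``tumor__``/``ln__``-prefixed columns from
    the tumor and merged-node structures plus per-structure tables, and
    ``replicates`` holds the tumor feature tables for the test-retest
    and inter-observer replicate segmentations.
    """
    n = cfg.n_patients if cohort == "dev" else cfg.n_validation
    per_structure = {k: [] for k in ("tumor", "ln_merged", "ln_volume", "ln_max")}
    replicates = {k: [] for k in ("retest_b", "observer_a", "observer_b")}
    clinical_rows = []
    do_replicates = cohort == "dev"
    for i in range(n):
        spec = _patient_phantom(cfg, i, cohort)
        image, tumor, nodes = synth.simulate_patient_images(spec)
        feats = extract_structure_features(image, tumor, nodes, cfg.bin_width)
        for k, v in feats.items():
            per_structure[k].append(v)
        if do_replicates:
            pr = np.random.default_rng((cfg.seed, 3, i))
            seeds = pr.integers(0, 2 ** 31 - 1, size=3)
            rep_masks = {
                "retest_b": synth.perturb_segmentation(tumor, cfg.retest_magnitude, int(seeds[0])),
                "observer_a": synth.perturb_segmentation(tumor, cfg.observer_magnitude, int(seeds[1])),
                "observer_b": synth.perturb_segmentation(tumor, cfg.observer_magnitude, int(seeds[2])),
            }
            for k, m in rep_masks.items():
                replicates[k].append(rad.extract_all(image, m, cfg.bin_width))
        clinical_rows.append({"patient_id": f"{cohort}_{i:04d}",
                              **_clinical_covariates(cfg, i, len(nodes))})
        if out_dir is not None and cfg.save_images:
            pdir = out_dir / "images"
            pdir.mkdir(parents=True, exist_ok=True)
            pid = f"{cohort}_{i:04d}"
            img.write_nifti(image, pdir / f"{pid}_suv.nii.gz")
            img.write_nifti(tumor, pdir / f"{pid}_tumor.nii.gz")
            for j, nd in enumerate(nodes):
                img.write_nifti(nd, pdir / f"{pid}_node_{j}.nii.gz")
    structure_tables = {k: pd.DataFrame(v) for k, v in per_structure.items()}
    wide = pd.concat(
        [structure_tables["tumor"].add_prefix("tumor__"),
         structure_tables["ln_merged"].add_prefix("ln__")], axis=1)
    clinical = pd.DataFrame(clinical_rows)
    replicate_tables = {k: pd.DataFrame(v) for k, v in replicates.items()} if do_replicates else {}
    return wide, structure_tables, replicate_tables, clinical


def _modeling_matrix(wide: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    X = wide.copy()
    if cfg.log_transform_ln_volume and "ln__shape_volume_cc" in X:
        X["ln__shape_volume_cc"] = np.log(X["ln__shape_volume_cc"])
    return X


def run_pipeline(config: RunConfig, log=print) -> RunManifest:
    """Execute the configured stages in order and write all artifacts.

    Outputs under the run directory: ``images/`` (optional NIfTI),
    ``features/``, ``selection/``, ``models/``, ``report/`` and
    ``manifest.json``.  Stage failure aborts with the failing stage
    named; artifacts of completed stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(config_hash=config.config_hash(), version=_version())
    state: dict = {}

    stage_fns = {"simulate": _stage_simulate_extract, "extract": _stage_noop,
                 "preselect": _stage_preselect, "model": _stage_model,
                 "validate": _stage_validate, "report": _stage_report}
    for stage in config.stages:
        fn = stage_fns.get(stage)
        if fn is None:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = _time.perf_counter()
        try:
            files, records = fn(config, state, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        dt = _time.perf_counter() - t0
        checksums = {str(p.relative_to(out)): _sha256(p) for p in files}
        manifest.add(stage, checksums, dt, records)
        log(f"[{stage}] {records} records, {dt:.1f}s, {len(files)} files")
    manifest.to_json(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__
    return __version__


def _stage_simulate_extract(cfg: RunConfig, state: dict, out: Path):
    # simulation and extraction share one pass so phantoms need not be stored
    wide, structures, reps, clinical = build_cohort(cfg, "dev", out)
    state.update(wide=wide, structures=structures, replicates=reps, clinical=clinical)
    fdir = out / "features"
    fdir.mkdir(exist_ok=True)
    files = []
    for name, table in {**structures, **{f"tumor_{k}": v for k, v in reps.items()}}.items():
        p = fdir / f"dev_{name}.csv"
        table.round(10).to_csv(p, index=False)
        files.append(p)
    cpath = out / "features" / "dev_clinical.csv"
    clinical.to_csv(cpath, index=False)
    files.append(cpath)
    return files, len(wide)


def _stage_noop(cfg, state, out):
    # extraction happens during simulate (single pass over the phantoms)
    return [], len(state.get("wide", []))


def _stage_preselect(cfg: RunConfig, state: dict, out: Path):
    structures = state["structures"]
    reps = state["replicates"]
    candidates = list(structures["tumor"].columns)
    robust = presel.robustness_filter(
        candidates,
        {"retest": (structures["tumor"], reps["retest_b"]),
         "observer": (reps["observer_a"], reps["observer_b"])},
        icc_cutoff=cfg.icc_cutoff)
    ln_candidates = robust.retained
    surrogate = presel.surrogate_filter(
        structures["ln_merged"][ln_candidates],
        structures["ln_volume"][ln_candidates],
        structures["ln_max"][ln_candidates],
        icc_cutoff=cfg.icc_cutoff, loa_bound=cfg.loa_bound,
        mode=cfg.surrogacy_mode)
    state["tumor_features"] = robust.retained
    state["ln_features"] = surrogate.retained
    sdir = out / "selection"
    sdir.mkdir(exist_ok=True)
    robust.to_csv(sdir / "robustness.csv")
    surrogate.to_csv(sdir / "surrogacy.csv")
    for fname, feats in (("retained_tumor.txt", robust.retained),
                         ("retained_ln.txt", surrogate.retained)):
        (sdir / fname).write_text("\n".join(feats) + "\n")
    files = [sdir / "robustness.csv", sdir / "surrogacy.csv",
             sdir / "retained_tumor.txt", sdir / "retained_ln.txt"]
    return files, len(robust.retained) + len(surrogate.retained)


def _simulate_outcomes(cfg: RunConfig, X: pd.DataFrame, cohort: str):
    tag = 11 if cohort == "dev" else 12
    spec = synth.SurvivalSpec(
        n_patients=len(X), betas=dict(cfg.betas),
        baseline_shape=cfg.baseline_shape, baseline_scale=cfg.baseline_scale,
        censoring_rate=cfg.censoring_rate,
        seed=int(np.random.default_rng((cfg.seed, tag)).integers(0, 2 ** 31 - 1)))
    return synth.simulate_survival({c: X[c].to_numpy() for c in X.columns}, spec)


def _drop_degenerate(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=0)
    return X.loc[:, sd > 0]


def _stage_model(cfg: RunConfig, state: dict, out: Path):
    X = _modeling_matrix(state["wide"], cfg)
    time, event = _simulate_outcomes(cfg, X, "dev")
    cohort = state["clinical"].copy()
    cohort["time"] = time
    cohort["event"] = event
    state["cohort"] = cohort
    state["X_dev"] = X

    pools = {
        "tumor": [f"tumor__{f}" for f in state["tumor_features"]],
        "ln": [f"ln__{f}" for f in state["ln_features"]],
    }
    pools["combined"] = pools["tumor"] + pools["ln"]
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    fits: dict[str, surv.ModelFit] = {}
    files = []
    for model_id, pool in pools.items():
        Xp = _drop_degenerate(X[pool])
        lasso = surv.lasso_cox_cv(Xp, time, event, n_folds=cfg.n_folds,
                                  seed=cfg.seed)
        if lasso.selected:
            fit = surv.refit_cox(X, time, event, lasso.selected, model_id=model_id)
        else:
            # null model: no features survived the penalty
            fit = surv.ModelFit(model_id=model_id, features=[], coef={}, hr={},
                                p={}, hr_ci={}, c_internal=0.5,
                                c_internal_ci=(0.5, 0.5),
                                aic=surv.aic(surv.log_partial_likelihood(
                                    np.zeros(len(X)), time, event), 0),
                                log_partial_likelihood=surv.log_partial_likelihood(
                                    np.zeros(len(X)), time, event))
        fit.lasso_alpha = lasso.alpha
        fit.seed = cfg.seed
        for feat in fit.features:
            diag = surv.check_log_linearity(
                X[feat].to_numpy(), time, event, name=feat)
            fit.diagnostics.setdefault("log_linearity", {})[feat] = {
                "verdict": diag["verdict"], "p_nonlinear": diag["p_nonlinear"],
                "recommend_log_transform": diag["recommend_log_transform"]}
        if fit.features:
            ph = surv.check_ph_schoenfeld(X, time, event, fit.features)
            fit.diagnostics["ph_p_values"] = ph["p_values"]
            resid_path = mdir / f"{model_id}_schoenfeld.csv"
            ph["residuals"].to_csv(resid_path, index=False)
            files.append(resid_path)
        p = mdir / f"{model_id}.json"
        fit.to_json(p)
        files.append(p)
        fits[model_id] = fit
    state["fits"] = fits
    return files, len(fits)


def _stage_validate(cfg: RunConfig, state: dict, out: Path):
    wide_val, _, _, clinical_val = build_cohort(cfg, "validation", out)
    Xv = _modeling_matrix(wide_val, cfg)
    time_v, event_v = _simulate_outcomes(cfg, Xv, "validation")
    rows = []
    for model_id, fit in state["fits"].items():
        if fit.features:
            cres = surv.external_validate(fit, Xv, time_v, event_v)
            fit.c_external = cres.c
        else:
            fit.c_external = 0.5
        rows.append({"model": model_id, "c_external": fit.c_external})
    vdir = out / "models"
    vpath = vdir / "external_validation.csv"
    pd.DataFrame(rows).to_csv(vpath, index=False)
    state["validation"] = (Xv, time_v, event_v, clinical_val)
    return [vpath], len(rows)


def _stage_report(cfg: RunConfig, state: dict, out: Path):
    rdir = out / "report"
    rdir.mkdir(exist_ok=True)
    cohort = state["cohort"]
    X = state["X_dev"]
    wide = state["wide"]
    files = []

    # Table-2-style univariable screen of clinical covariates
    clin = cohort.copy()
    screen = surv.univariable_screen(
        clin, ["age", "gender", "stage", "n_stage", "n_ln_stations",
               "histology", "rt_dose", "chemotherapy"])
    p = rdir / "table2_clinical_univariable.csv"
    screen.round(4).to_csv(p, index=False)
    files.append(p)

    # Table-3-style common descriptors: range, mean+/-SD, HR, p, CI, C
    rows = []
    common = {}
    for struct, prefix in (("tumor", "tumor__"), ("ln", "ln__")):
        for feat in COMMON_DESCRIPTORS:
            col = wide[f"{prefix}{feat}"]
            res = surv.univariable_cox(col.to_numpy(), cohort["time"],
                                       cohort["event"], name=feat)
            common[f"{struct}_{feat}"] = col
            rows.append({
                "structure": struct, "feature": feat,
                "range": f"{col.min():.1f}-{col.max():.1f}",
                "mean_sd": f"{col.mean():.1f}+/-{col.std():.1f}",
                "hr": res.hr, "p": res.p,
                "hr_ci": f"{res.hr_ci_low:.2f}-{res.hr_ci_high:.2f}",
                "c_index": res.c,
                "c_ci": f"{res.c_ci_low:.2f}-{res.c_ci_high:.2f}"})
    load = pd.Series(
        [img.tumor_load(tv, lv) for tv, lv in
         zip(wide["tumor__shape_volume_cc"], wide["ln__shape_volume_cc"])],
        index=wide.index, name="tumor_load")
    res = surv.univariable_cox(load.to_numpy(), cohort["time"], cohort["event"],
                               name="tumor_load")
    rows.append({"structure": "both", "feature": "tumor_load",
                 "range": f"{load.min():.1f}-{load.max():.1f}",
                 "mean_sd": f"{load.mean():.1f}+/-{load.std():.1f}",
                 "hr": res.hr, "p": res.p,
                 "hr_ci": f"{res.hr_ci_low:.2f}-{res.hr_ci_high:.2f}",
                 "c_index": res.c,
                 "c_ci": f"{res.c_ci_low:.2f}-{res.c_ci_high:.2f}"})
    p = rdir / "table3_common_descriptors.csv"
    pd.DataFrame(rows).round(4).to_csv(p, index=False)
    files.append(p)

    corr = surv.pearson_correlation_matrix(pd.DataFrame({**common, "tumor_load": load}))
    p = rdir / "correlation_matrix.csv"
    corr.round(4).to_csv(p)
    files.append(p)

    # Table-4-style model report + AIC comparison (ascending AIC first)
    rows = []
    for model_id, fit in state["fits"].items():
        if not fit.features:
            rows.append({"model": model_id, "feature": "(none selected)"})
            continue
        for f in fit.features:
            rows.append({
                "model": model_id, "feature": f, "hr": fit.hr[f], "p": fit.p[f],
                "hr_ci": f"{fit.hr_ci[f][0]:.3f}-{fit.hr_ci[f][1]:.3f}",
                "c_internal": fit.c_internal,
                "c_internal_ci": f"{fit.c_internal_ci[0]:.2f}-{fit.c_internal_ci[1]:.2f}",
                "c_external": fit.c_external, "aic": fit.aic})
    p = rdir / "table4_models.csv"
    pd.DataFrame(rows).round(4).to_csv(p, index=False)
    files.append(p)

    aics = {m: f.aic for m, f in state["fits"].items()}
    order = surv.aic_ordering(aics)
    comp = pd.DataFrame({"model": order, "aic": [aics[m] for m in order],
                         "rank": range(1, len(order) + 1)})
    p = rdir / "model_comparison_aic.csv"
    comp.round(2).to_csv(p, index=False)
    files.append(p)

    cpath = rdir / "cohort.csv"
    cohort.to_csv(cpath, index=False)
    files.append(cpath)
    return files, len(files)
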
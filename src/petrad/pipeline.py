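"""End-to-end orchestration: simulate -> segment -> extract -> crosscombo ->
radscore -> evaluate -> survive, driven by a validated run configuration,
with per-stage logging and a hash manifest for reproducibility."""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
import logging
from pathlib import Path
import time

import numpy as np
import pandas as pd
import yaml

from . import clinical, cohort as cohort_mod, crosscombo, phantom, segmentation, survival
from .features import ALL_FEATURE_NAMES, ExtractionConfig, extract_all
from .volume import read_volume, write_mask, write_volume

__all__ = ["RunConfig", "PipelineError", "Pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "extract", "crosscombo", "radscore", "evaluate", "survive")


class PipelineError(RuntimeError):
    """User-facing pipeline failure (missing stage, bad config)."""


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable)."""

    output_dir: str = "petrad_run"
    seed: int = 0
    # imaging demo
    n_phantoms: int = 4
    phantom_shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    background_noise_sd: float = 0.05
    # cohort
    cohort_n: int = 177
    prevalence: float = 0.40
    test_fraction: float = 0.3
    # extraction
    n_bins: int = 64
    # grid
    k_folds: int = 5
    selection_cv: int = 3
    step: int | str = "auto"
    paper_protocol: bool = False
    grid_features: int | None = 30   # radiomic columns entering the grid (None = all 110)

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise PipelineError("test_fraction must be in (0, 1)")
        if self.k_folds < 2 or self.selection_cv < 2:
            raise PipelineError("CV fold counts must be >= 2")
        if self.n_phantoms < 1 or self.cohort_n < 10:
            raise PipelineError("need at least one phantom and 10 patients")
        if self.step != "auto" and int(self.step) < 1:
            raise PipelineError("elimination step must be >= 1 or 'auto'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("phantom_shape", "spacing"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"

    # ------------------------------------------------------------ helpers

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {"stages": {}}

    def _record(self, stage: str, artifacts: list[Path], started: float) -> None:
        manifest = self._load_manifest()
        manifest["stages"][stage] = {
            "seed": self.config.seed,
            "wall_seconds": round(time.time() - started, 2),
            "artifacts": {str(p.relative_to(self.out)): _sha256(p) for p in artifacts},
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=2))
        logger.info("stage %s: %d artifact(s), %.1fs", stage, len(artifacts),
                    time.time() - started)

    def _require(self, stage: str, *paths: Path) -> None:
        for p in paths:
            if not p.exists():
                raise PipelineError(
                    f"missing artifact {p.name}: run the '{stage}' stage first"
                )

    def _grid_step(self, n_features: int) -> int:
        if self.config.step == "auto":
            return max(1, n_features // 12)
        return int(self.config.step)

    # ------------------------------------------------------------ stages

    def run_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES}")
        getattr(self, f"stage_{stage}")()

    def run_all(self) -> None:
        for stage in STAGES:
            self.run_stage(stage)

    def stage_simulate(self) -> None:
        t0 = time.time()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        artifacts = []
        pdir = self.out / "phantoms"
        pdir.mkdir(exist_ok=True)
        extent = [n * s for n, s in zip(cfg.phantom_shape, cfg.spacing)]
        textures = ("uniform", "gaussian-noise", "checker", "radial-gradient")
        for i in range(cfg.n_phantoms):
            center = [e / 2 + rng.uniform(-8, 8) for e in extent]
            radius = rng.uniform(14.0, 22.0)
            les = phantom.LesionSpec(
                center_mm=tuple(center), radii_mm=(radius,) * 3,
                peak_suv=rng.uniform(8.0, 20.0),
                texture=textures[i % len(textures)],
                texture_params={"sd": 0.8, "period": 2, "low_fraction": 0.6,
                                "edge_fraction": 0.5},
            )
            spec = phantom.PhantomSpec(
                shape=cfg.phantom_shape, spacing=cfg.spacing,
                background_suv=cfg.background_suv,
                background_noise_sd=cfg.background_noise_sd,
                lesions=[les], seed=int(rng.integers(2**31)),
            )
            vol, masks = phantom.make_phantom(spec)
            vol_path = pdir / f"phantom_{i:02d}.nii.gz"
            write_volume(vol, vol_path)
            artifacts.append(vol_path)
            for j, m in enumerate(masks):
                mpath = pdir / f"phantom_{i:02d}_truth_{j}.nii.gz"
                write_mask(m, mpath)
                artifacts.append(mpath)

        spec = cohort_mod.CohortSpec(n=cfg.cohort_n, prevalence=cfg.prevalence, seed=cfg.seed)
        table = cohort_mod.simulate_cohort(spec)
        train, val = cohort_mod.split_cohort(table, cfg.test_fraction, seed=cfg.seed)
        for name, df in (("cohort", table), ("train", train), ("validation", val)):
            path = self.out / f"{name}.csv"
            df.to_csv(path, index=False)
            artifacts.append(path)
        self._record("simulate", artifacts, t0)

    def stage_segment(self) -> None:
        t0 = time.time()
        pdir = self.out / "phantoms"
        self._require("simulate", pdir, self.out / "cohort.csv")
        artifacts = []
        rows = []
        for vol_path in sorted(pdir.glob("phantom_??.nii.gz")):
            vol = read_volume(vol_path)
            hot = np.unravel_index(np.argmax(vol.data), vol.shape)
            seed_box = tuple((max(0, c - 2), min(s, c + 3)) for c, s in zip(hot, vol.shape))
            mask = segmentation.segment_lesion(vol, seed_box)
            kept = segmentation.filter_lesions([mask], vol)
            for m in kept:
                mm = segmentation.metabolic_metrics(vol, m)
                rows.append({"patient": vol_path.stem.replace(".nii", ""),
                             "lesion_id": m.lesion_id, "suvmax": mm.suvmax,
                             "suvmean": mm.suvmean, "mtv_cm3": mm.mtv_cm3, "tlg": mm.tlg})
                mpath = vol_path.with_name(vol_path.name.replace(".nii.gz", "_voi.nii.gz"))
                write_mask(m, mpath)
                artifacts.append(mpath)
        metrics_path = self.out / "metabolic_metrics.csv"
        pd.DataFrame(rows).to_csv(metrics_path, index=False)
        artifacts.append(metrics_path)
        self._record("segment", artifacts, t0)

    def stage_extract(self) -> None:
        t0 = time.time()
        pdir = self.out / "phantoms"
        self._require("segment", self.out / "metabolic_metrics.csv")
        config = ExtractionConfig(n_bins=self.config.n_bins)
        rows = []
        for voi_path in sorted(pdir.glob("phantom_??_voi.nii.gz")):
            vol = read_volume(voi_path.with_name(voi_path.name.replace("_voi", "")))
            from .volume import read_mask
            mask = read_mask(voi_path)
            feats = extract_all(vol, mask, config)
            feats["patient"] = voi_path.stem.replace("_voi.nii", "")
            rows.append(feats)
        fpath = self.out / "phantom_features.csv"
        pd.DataFrame(rows).set_index("patient").to_csv(fpath)
        spath = self.out / "extraction_settings.json"
        spath.write_text(json.dumps(config.as_dict(), indent=2))
        self._record("extract", [fpath, spath], t0)

    def stage_crosscombo(self) -> None:
        t0 = time.time()
        train_path = self.out / "train.csv"
        self._require("simulate", train_path)
        self._require("extract", self.out / "phantom_features.csv")
        train = pd.read_csv(train_path)
        feat_cols = [c for c in ALL_FEATURE_NAMES if c in train.columns]
        if self.config.grid_features is not None and self.config.grid_features < len(feat_cols):
            # keep the strongest univariate discriminators for the grid demo
            aucs = {}
            from sklearn.metrics import roc_auc_score
            for c in feat_cols:
                a = roc_auc_score(train["outcome"], train[c])
                aucs[c] = max(a, 1 - a)
            feat_cols = sorted(feat_cols, key=lambda c: -aucs[c])[: self.config.grid_features]
        X, y = train[feat_cols], train["outcome"].to_numpy()
        model = crosscombo.CrossCombination(
            X, y, k=self.config.k_folds, seed=self.config.seed,
            selection_cv=self.config.selection_cv,
            step=self._grid_step(len(feat_cols)),
            paper_protocol=self.config.paper_protocol,
        )
        res = model.fit()
        heat_path = self.out / "heatmap.csv"
        res.auc_matrix.to_csv(heat_path)
        fold_path = self.out / "fold_aucs.csv"
        res.fold_table().to_csv(fold_path, index=False)
        rs_path = self.out / "radscore.json"
        rs = res.radscore
        rs_path.write_text(json.dumps({
            **rs.as_dict(),
            "mean": {k: float(v) for k, v in rs.mean[rs.feature_names].items()},
            "std": {k: float(v) for k, v in rs.std[rs.feature_names].items()},
            "elected_auc": float(res.auc_matrix.loc[res.elected_pair]),
            "training_auc": res.training_auc,
            "hyperparameters": crosscombo.HYPERPARAMS,
            "seed": self.config.seed,
        }, indent=2))
        (self.out / "summary.txt").write_text(res.summary() + "\n")
        self._record("crosscombo", [heat_path, fold_path, rs_path, self.out / "summary.txt"], t0)

    def _load_radscore(self) -> crosscombo.RadScoreModel:
        rs_path = self.out / "radscore.json"
        self._require("crosscombo", rs_path)
        blob = json.loads(rs_path.read_text())
        return crosscombo.RadScoreModel(
            feature_names=blob["features"],
            weights=np.asarray(blob["weights"]),
            mean=pd.Series(blob["mean"]),
            std=pd.Series(blob["std"]),
            selector=blob["selector"],
            classifier=blob["classifier"],
            weight_source=blob["weight_source"],
            cutoffs=blob.get("cutoffs", {}),
        )

    def stage_radscore(self) -> None:
        t0 = time.time()
        self._require("simulate", self.out / "train.csv", self.out / "validation.csv")
        rs = self._load_radscore()
        artifacts = []
        frames = {}
        for name in ("train", "validation"):
            df = pd.read_csv(self.out / f"{name}.csv")
            df["radscore"] = rs.score(df)
            frames[name] = df
        train = frames["train"]
        cutoffs = {"outcome": clinical.youden_cutoff(train["radscore"], train["outcome"]).threshold}
        for key, (tcol, ecol) in {"pfs": ("pfs_months", "pfs_event"),
                                  "os": ("os_months", "os_event")}.items():
            cutoffs[key] = clinical.youden_cutoff(train["radscore"], train[ecol]).threshold
        suv_cut = clinical.youden_cutoff(train["suvmax"], train["outcome"]).threshold
        for name, df in frames.items():
            df["radscore_high"] = (df["radscore"] >= cutoffs["outcome"]).astype(int)
            df["suvmax_high"] = (df["suvmax"] >= suv_cut).astype(int)
            path = self.out / f"{name}_scored.csv"
            df.to_csv(path, index=False)
            artifacts.append(path)
        cut_path = self.out / "cutoffs.json"
        cut_path.write_text(json.dumps({"radscore": cutoffs, "suvmax": suv_cut}, indent=2))
        artifacts.append(cut_path)
        self._record("radscore", artifacts, t0)

    def stage_evaluate(self) -> None:
        t0 = time.time()
        tr_path, va_path = self.out / "train_scored.csv", self.out / "validation_scored.csv"
        self._require("radscore", tr_path, va_path)
        train, val = pd.read_csv(tr_path), pd.read_csv(va_path)
        models = clinical.build_models(train, val)
        blob = {}
        artifacts = []
        for name, pm in models.items():
            blob[name] = {
                "variables": pm.result.variables,
                "odds_ratios": {v: float(pm.result.table.loc[v, "or"]) for v in pm.result.variables},
                "auc_train": pm.auc_train,
                "auc_validation": pm.auc_validation,
            }
        mpath = self.out / "models.json"
        mpath.write_text(json.dumps(blob, indent=2))
        artifacts.append(mpath)

        combined = models["combined"]
        pred = combined.result.predict(train)
        calib = clinical.calibration_bootstrap(pred, train["outcome"].to_numpy(),
                                              reps=200, seed=self.config.seed)
        cpath = self.out / "calibration.csv"
        calib["curve"].to_csv(cpath, index=False)
        artifacts.append(cpath)

        dca_frames = []
        for name, pm in models.items():
            d = clinical.dca(pm.result.predict(train), train["outcome"].to_numpy())
            d["model"] = name
            dca_frames.append(d)
        dpath = self.out / "dca.csv"
        pd.concat(dca_frames).to_csv(dpath, index=False)
        artifacts.append(dpath)

        nomo = clinical.nomogram_points(combined.result, train)
        npath = self.out / "nomogram.csv"
        pd.concat({v: t for v, t in nomo["per_variable"].items()}, names=["variable"]).to_csv(npath)
        artifacts.append(npath)
        self._record("evaluate", artifacts, t0)

    def stage_survive(self) -> None:
        t0 = time.time()
        tr_path, va_path = self.out / "train_scored.csv", self.out / "validation_scored.csv"
        self._require("radscore", tr_path, va_path)
        cutoffs = json.loads((self.out / "cutoffs.json").read_text())["radscore"]
        artifacts = []
        blob = {}
        for name, path in (("train", tr_path), ("validation", va_path)):
            df = pd.read_csv(path)
            for ep, (tcol, ecol) in {"pfs": ("pfs_months", "pfs_event"),
                                     "os": ("os_months", "os_event")}.items():
                group = (df["radscore"] >= cutoffs[ep]).astype(int)
                curves = []
                for g in (0, 1):
                    sub = df[group == g]
                    km = survival.km_estimate(sub[tcol], sub[ecol])
                    c = km.curve.reset_index()
                    c.columns = ["time", "survival"]
                    c["group"] = "high" if g else "low"
                    curves.append(c)
                kpath = self.out / f"km_{name}_{ep}.csv"
                pd.concat(curves).to_csv(kpath, index=False)
                artifacts.append(kpath)
                stat, p = survival.logrank(df[tcol], df[ecol], group)
                entry = {"logrank_chi2": stat, "logrank_p": p,
                         "n_high": int(group.sum()), "n_low": int((1 - group).sum())}
                try:
                    sdf = df[[tcol, ecol]].copy()
                    sdf["group"] = group
                    hz = survival.cox_hr(sdf, tcol, ecol, "group")
                    entry.update({"hr": hz.hr, "hr_ci": list(hz.ci), "hr_p": hz.p})
                except ValueError as exc:
                    entry["cox_error"] = str(exc)
                blob[f"{name}_{ep}"] = entry
        spath = self.out / "survival.json"
        spath.write_text(json.dumps(blob, indent=2))
        artifacts.append(spath)
        self._record("survive", artifacts, t0)
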
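"""End-to-end orchestration of the habitat-radiomics study on one cohort.

Stages run in a fixed order — simulate, habitats, extract, icc, select,
models, survival, coexpr — each reading only the files earlier stages
declared and writing its own subdirectory of the run directory. A single
run seed fans out to per-stage sub-seeds through named SeedSequence
children, so reruns (including partial reruns with stages toggled off)
are byte-reproducible; the run manifest records the configuration and a
SHA-256 checksum of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression as cx
from . import features as ft
from . import habitats as hb
from . import models as md
from . import selection as sel
from . import survival as sv
from .icc import filter_features as _icc_filter_features
from ._nifti import load_nifti, save_nifti
from .synthetic import CohortSpec, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("habitatomics")

STAGES = (
    "simulate",
    "habitats",
    "extract",
    "icc",
    "select",
    "models",
    "survival",
    "coexpr",
)


@dataclass
class PipelineConfig:
    out_dir: str
    n_patients: int = 60
    seed: int = 7
    k_min: int = 2
    k_max: int = 10
    n_gray_levels: int = 25
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    icc_threshold: float = 0.75
    icc_subset: int = 20
    spearman_threshold: float = 0.9
    cv_folds: int = 5
    split_ratio: float = 0.7
    min_module_size: int = 100
    beta_max: int = 20
    min_subregion_voxels: int = 10
    lasso_loss: str = "mse"
    radscore_region: str = "VOI1"
    stages: tuple[str, ...] = STAGES
    #: extra CohortSpec fields (e.g. {"grade_effect": 0.0})
    spec_overrides: dict = field(default_factory=dict)
    #: optional TSV paths for the coexpression stage
    edge_list: str | None = None
    annotation: str | None = None

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if not 0 < self.icc_threshold < 1 or not 0 < self.spearman_threshold <= 1:
            raise ValueError("thresholds out of documented range")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid K range")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for f in ("target_spacing", "stages"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["target_spacing"] = list(self.target_spacing)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one run seed out to a fixed sub-seed per stage (toggle-independent)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(c.generate_state(1)[0] % 2**31)
        for name, c in zip(STAGES, children)
    }


def _spec_for(config: PipelineConfig, seed: int) -> CohortSpec:
    return CohortSpec(
        n_patients=config.n_patients, seed=seed, **config.spec_overrides
    )


# ---------------------------------------------------------------- stages


def _stage_simulate(config: PipelineConfig, out: Path, seed: int) -> None:
    cohort = generate_cohort(_spec_for(config, seed))
    write_cohort(cohort, out / "cohort")


def _patient_ids(out: Path) -> list[str]:
    return pd.read_csv(out / "cohort" / "clinical.csv")["patient_id"].tolist()


def _load_resampled(config: PipelineConfig, out: Path, pid: str, mask_name: str):
    vdir = out / "cohort" / "volumes"
    image, spacing = load_nifti(vdir / f"{pid}_image.nii.gz")
    mask, _ = load_nifti(vdir / f"{pid}_{mask_name}.nii.gz")
    image_r = ft.resample(image.astype(float), spacing, config.target_spacing, order=1)
    mask_r = ft.resample(mask > 0, spacing, config.target_spacing, order=0)
    return image_r, mask_r


def _stage_habitats(config: PipelineConfig, out: Path, seed: int) -> None:
    hdir = out / "habitats"
    hdir.mkdir(exist_ok=True)
    pids = _patient_ids(out)
    icc_pids = set(pids[: min(config.icc_subset, len(pids))])
    k_range = range(config.k_min, config.k_max + 1)
    bic_rows = []
    for i, pid in enumerate(pids):
        masks = ["mask"] + (["mask_intra", "mask_inter"] if pid in icc_pids else [])
        for mask_name in masks:
            image_r, mask_r = _load_resampled(config, out, pid, mask_name)
            habmap = hb.select_k_and_segment(
                image_r, mask_r, k_range=k_range, seed=seed + i
            )
            save_nifti(
                habmap.labels.astype(np.int16),
                config.target_spacing,
                hdir / f"{pid}_{mask_name}_labels.nii.gz",
            )
            for k, b in sorted(habmap.bic_by_k.items()):
                bic_rows.append(
                    {"patient_id": pid, "mask": mask_name, "k": k, "bic": b,
                     "selected": k == habmap.k_selected}
                )
    pd.DataFrame(bic_rows).to_csv(hdir / "bic_by_k.csv", index=False)


def _stage_extract(config: PipelineConfig, out: Path, seed: int) -> None:
    fdir = out / "features"
    fdir.mkdir(exist_ok=True)
    pids = _patient_ids(out)
    icc_pids = set(pids[: min(config.icc_subset, len(pids))])
    tables: dict[str, list[pd.DataFrame]] = {"mask": [], "mask_intra": [], "mask_inter": []}
    for pid in pids:
        masks = ["mask"] + (["mask_intra", "mask_inter"] if pid in icc_pids else [])
        for mask_name in masks:
            image_r, mask_r = _load_resampled(config, out, pid, mask_name)
            labels, _ = load_nifti(
                out / "habitats" / f"{pid}_{mask_name}_labels.nii.gz"
            )
            tables[mask_name].append(
                ft.extract_all(
                    image_r,
                    labels.astype(int),
                    mask_r,
                    spacing=config.target_spacing,
                    n_levels=config.n_gray_levels,
                    min_voxels=config.min_subregion_voxels,
                    patient_id=pid,
                )
            )
    names = {"mask": "primary", "mask_intra": "intra", "mask_inter": "inter"}
    for mask_name, dfs in tables.items():
        if dfs:
            pd.concat(dfs, ignore_index=True).to_csv(
                fdir / f"features_{names[mask_name]}.csv", index=False
            )


def _wide(features: pd.DataFrame) -> pd.DataFrame:
    """patient x (region_feature) table, excluded rows dropped."""
    kept = features[~features["excluded"]].copy()
    value_cols = [
        c
        for c in kept.columns
        if c not in ("patient_id", "region", "n_voxels", "excluded")
    ]
    wide = kept.pivot(index="patient_id", columns="region", values=value_cols)
    wide.columns = [f"{region}_{feat}" for feat, region in wide.columns]
    return wide.sort_index(axis=1)


def _stage_icc(config: PipelineConfig, out: Path, seed: int) -> None:
    idir = out / "icc"
    idir.mkdir(exist_ok=True)
    fdir = out / "features"
    primary = _wide(pd.read_csv(fdir / "features_primary.csv"))
    intra = _wide(pd.read_csv(fdir / "features_intra.csv"))
    inter = _wide(pd.read_csv(fdir / "features_inter.csv"))
    subset = intra.index.intersection(inter.index).intersection(primary.index)
    tables = [t.loc[t.index.intersection(subset)].dropna(axis=1) for t in (primary, intra, inter)]
    common_cols = set(tables[0].columns) & set(tables[1].columns) & set(tables[2].columns)
    tables = [t[sorted(common_cols)] for t in tables]
    retained, report = _icc_filter_features(
        tables[0], tables[1], tables[2], threshold=config.icc_threshold
    )
    report.to_csv(idir / "icc_report.csv", index=False)
    (idir / "retained.txt").write_text("\n".join(retained) + "\n")


def _stage_select(config: PipelineConfig, out: Path, seed: int) -> None:
    sdir = out / "select"
    sdir.mkdir(exist_ok=True)
    clinical = pd.read_csv(out / "cohort" / "clinical.csv").set_index("patient_id")
    wide = _wide(pd.read_csv(out / "features" / "features_primary.csv"))
    retained = (out / "icc" / "retained.txt").read_text().split()
    wide = wide[[c for c in wide.columns if c in set(retained)]]

    y_all = (clinical["grade"] == "high").astype(int)
    train_ids, test_ids = md.split_cohort(
        clinical.index.to_numpy(), clinical["grade"].to_numpy(),
        ratio=config.split_ratio, seed=seed,
    )
    split = pd.Series("train", index=clinical.index, name="split")
    split.loc[split.index.isin(test_ids)] = "internal_test"
    split.to_frame().reset_index().to_csv(sdir / "split.csv", index=False)

    candidates: dict[str, dict] = {}
    radscore_model = None
    for region in ("VOIe", "VOI1", "VOI2"):
        cols = [c for c in wide.columns if c.startswith(region + "_")]
        X = wide[cols].dropna()
        ids_tr = [i for i in train_ids if i in X.index]
        model, _ = sel.fit_radscore(
            X.loc[ids_tr],
            y_all.loc[ids_tr].to_numpy(),
            folds=config.cv_folds,
            seed=seed,
            spearman_threshold=config.spearman_threshold,
            loss=config.lasso_loss,
        )
        if not model.selected_features:
            # degenerate LASSO path: keep the single best univariate feature
            warnings.warn(f"LASSO selected no features for {region}; using top univariate")
            scaled = model.scale(X.loc[ids_tr])
            cors = scaled.apply(
                lambda c: abs(np.corrcoef(c, y_all.loc[ids_tr])[0, 1])
            ).fillna(0.0)
            top = cors.idxmax()
            model.selected_features = [top]
            model.coefficients = np.array([1.0])
            model.intercept = 0.0
            scores_tr = model.score(X.loc[ids_tr])
            model.cutoff = sel.youden_cutoff(
                scores_tr.to_numpy(), y_all.loc[ids_tr].to_numpy()
            )[0]
        candidates[region] = {
            "features": model.selected_features,
            "coefficients": list(map(float, model.coefficients)),
            "intercept": float(model.intercept),
            "lambda": float(model.lambda_selected),
            "cutoff": float(model.cutoff),
        }
        if region == config.radscore_region:
            radscore_model = model
            scores = model.score(X)
            df = pd.DataFrame(
                {
                    "patient_id": scores.index,
                    "split": split.loc[scores.index].to_numpy(),
                    "radscore": scores.to_numpy(),
                    "risk_group": model.risk_group(scores).to_numpy(),
                }
            )
            df.to_csv(sdir / "scores.csv", index=False)
    assert radscore_model is not None
    model_dump = dict(candidates[config.radscore_region])
    model_dump["region"] = config.radscore_region
    model_dump["bounds"] = {
        f: list(radscore_model.bounds[f]) for f in radscore_model.selected_features
    }
    (sdir / "model.json").write_text(json.dumps(model_dump, indent=2, sort_keys=True))
    (sdir / "candidates.json").write_text(
        json.dumps(candidates, indent=2, sort_keys=True)
    )


def _stage_models(config: PipelineConfig, out: Path, seed: int) -> None:
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    clinical = pd.read_csv(out / "cohort" / "clinical.csv").set_index("patient_id")
    wide = _wide(pd.read_csv(out / "features" / "features_primary.csv"))
    split = pd.read_csv(out / "select" / "split.csv").set_index("patient_id")["split"]
    candidates = json.loads((out / "select" / "candidates.json").read_text())
    y_all = (clinical["grade"] == "high").astype(int)

    rows, roc_rows = [], []
    for region, cand in candidates.items():
        feats = cand["features"]
        X = wide[feats].dropna()
        ids = X.index
        tr = ids[split.loc[ids] == "train"]
        te = ids[split.loc[ids] == "internal_test"]
        fitted = md.train_classifiers(
            X.loc[tr].to_numpy(), y_all.loc[tr].to_numpy(), seed=seed
        )
        for name, clf in fitted.items():
            for split_name, idx in (("train", tr), ("internal_test", te)):
                rep = md.evaluate(
                    clf,
                    X.loc[idx].to_numpy(),
                    y_all.loc[idx].to_numpy(),
                    model_name=name,
                    region=region,
                    split=split_name,
                )
                rows.append(rep.to_row())
                if rep.roc is not None:
                    r = rep.roc.copy()
                    r.insert(0, "model", name)
                    r.insert(1, "region", region)
                    r.insert(2, "split", split_name)
                    roc_rows.append(r)
    pd.DataFrame(rows).to_csv(mdir / "metrics.csv", index=False)
    pd.concat(roc_rows, ignore_index=True).to_csv(mdir / "roc_points.csv", index=False)


def _stage_survival(config: PipelineConfig, out: Path, seed: int) -> None:
    vdir = out / "survival"
    vdir.mkdir(exist_ok=True)
    clinical = pd.read_csv(out / "cohort" / "clinical.csv").set_index("patient_id")
    scores = pd.read_csv(out / "select" / "scores.csv").set_index("patient_id")
    data = clinical.join(scores[["split", "radscore", "risk_group"]], how="inner")

    km_rows, test_rows = [], []
    for split_name, grp in data.groupby("split"):
        for risk, sub in grp.groupby("risk_group"):
            km = sv.km_curve(sub["os_time"], sub["os_event"])
            km.insert(0, "split", split_name)
            km.insert(1, "group", risk)
            km_rows.append(km)
        hi = grp[grp["risk_group"] == "high_risk"]
        lo = grp[grp["risk_group"] == "low_risk"]
        if len(hi) and len(lo):
            try:
                stat, p = sv.logrank_test(
                    hi["os_time"], hi["os_event"], lo["os_time"], lo["os_event"]
                )
            except ValueError:
                stat, p = np.nan, np.nan
            test_rows.append(
                {"split": split_name, "variable": "os", "test": "logrank",
                 "statistic": stat, "p": p}
            )
    train = data[data["split"] == "train"].copy()
    train["grade_group"] = train["grade"]
    for var, kind in (
        ("age", "continuous"), ("sex", "categorical"),
        ("laterality", "categorical"), ("tnm", "categorical"),
        ("radscore", "continuous"),
    ):
        test, stat, p = sv.compare_groups(train, var, "grade_group", kind=kind)
        test_rows.append(
            {"split": "train", "variable": var, "test": test, "statistic": stat, "p": p}
        )
    pd.concat(km_rows, ignore_index=True).to_csv(vdir / "km_curves.csv", index=False)
    pd.DataFrame(test_rows).to_csv(vdir / "tests.csv", index=False)


def _stage_coexpr(config: PipelineConfig, out: Path, seed: int) -> None:
    cdir = out / "coexpr"
    cdir.mkdir(exist_ok=True)
    expr = pd.read_csv(out / "cohort" / "expression.tsv", sep="\t", index_col=0)
    scores = pd.read_csv(out / "select" / "scores.csv").set_index("patient_id")
    expr = expr[[c for c in expr.columns if c in scores.index]]
    traits = scores.loc[expr.columns, ["radscore"]]

    beta, r2s = cx.pick_soft_threshold(expr, betas=range(1, config.beta_max + 1))
    adj = cx.adjacency_matrix(expr, beta)
    tom = cx.tom_matrix(adj.to_numpy())
    modules = cx.detect_modules(1.0 - tom, expr.index, config.min_module_size)
    eig, mt, selected = cx.module_trait(modules, expr, traits)

    edge_list = (
        pd.read_csv(config.edge_list, sep="\t") if config.edge_list else None
    )
    hubs = cx.hub_genes(
        modules[modules == selected].index, adjacency=adj, edge_list=edge_list
    )

    pd.DataFrame({"beta": list(r2s), "scale_free_r2": [r2s[b] for b in r2s],
                  "selected": [b == beta for b in r2s]}).to_csv(
        cdir / "soft_threshold.csv", index=False
    )
    modules.to_frame().reset_index().rename(columns={"index": "gene"}).to_csv(
        cdir / "modules.csv", index=False
    )
    mt.assign(selected=mt["module"] == selected).to_csv(
        cdir / "module_trait.csv", index=False
    )
    eig.to_csv(cdir / "eigengenes.csv")
    (cdir / "hubs.txt").write_text("\n".join(hubs) + "\n")
    if config.annotation:
        annotation = pd.read_csv(config.annotation, sep="\t")
        table, report = cx.hypergeom_enrichment(
            modules[modules == selected].index, annotation, expr.index
        )
        table.to_csv(cdir / "enrichment.csv", index=False)
        report.to_csv(cdir / "enrichment_top.csv", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "habitats": _stage_habitats,
    "extract": _stage_extract,
    "icc": _stage_icc,
    "select": _stage_select,
    "models": _stage_models,
    "survival": _stage_survival,
    "coexpr": _stage_coexpr,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    for name in STAGES:
        if name not in config.stages:
            log.info("stage %s: skipped", name)
            continue
        t0 = time.monotonic()
        try:
            _STAGE_FUNCS[name](config, out, seeds[name])
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s: %.1fs", name, time.monotonic() - t0)

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    cfg = dataclasses.asdict(config)
    cfg["target_spacing"] = list(config.target_spacing)
    cfg["stages"] = list(config.stages)
    manifest = {
        "config": cfg,
        "stage_seeds": seeds,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
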
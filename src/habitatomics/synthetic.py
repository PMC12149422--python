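"""Synthetic ccRCC-like cohort generator.

Emulates the statistical structure a subregion ("habitat") radiomics study
assumes, at desk scale and with no external data:

* contrast-enhanced-CT-like tumor volumes whose masked voxels come from two
  spatially contiguous intensity populations — a low-density habitat
  (necrotic / hypocellular, low HU) and a high-density enhancing habitat;
* a grade-linked texture difference: in high-grade patients the low-density
  habitat carries extra fine-scale intensity noise, which shifts local
  variance and gray-level texture statistics of that habitat only;
* repeat delineations (intra- and inter-observer) produced by random
  morphological boundary perturbation of the primary mask;
* overall-survival times from an exponential hazard proportional to a
  latent per-patient risk score, with independent uniform censoring;
* a gene expression matrix with planted coexpression modules, exactly one
  of which has its latent factor correlated (negatively, by default) with
  the risk score the radscore is meant to estimate.

Habitat geometry uses smoothed-noise thresholding so the habitats are
contiguous blobs rather than i.i.d. voxel labels: co-occurrence texture is
degenerate under i.i.d. noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nifti import save_nifti

__all__ = [
    "CohortSpec",
    "VolumeWithMask",
    "SyntheticCohort",
    "generate_clinical",
    "generate_tumor_volume",
    "generate_survival",
    "generate_expression",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the discovery-cohort design this pipeline targets:
    186 patients, ~60% high grade, two intensity habitats at roughly
    parenchymal-phase CT contrast (40 vs 120 HU), exponential survival
    over a 120-month follow-up window, and an expression matrix with
    three planted modules (each >= 100 genes), the first of which tracks
    the latent risk score with correlation -0.5.
    """

    n_patients: int = 186
    image_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    habitat_fractions: tuple[float, float] = (0.5, 0.5)
    intensity_means: tuple[float, float] = (40.0, 120.0)
    #: per-habitat voxel-wise noise amplitude, HU
    intensity_sds: tuple[float, float] = (10.0, 12.0)
    #: amplitude of the smooth (spatially correlated) intensity component, HU
    spatial_texture_sd: float = 3.0
    #: additive shift of the low-density habitat's voxel-wise noise
    #: amplitude in high-grade patients, HU
    grade_effect: float = 6.0
    prevalence_high_grade: float = 0.60
    #: events per month at latent risk 0
    survival_baseline_hazard: float = 0.02
    #: log-hazard increase per unit latent risk
    survival_risk_coef: float = 0.8
    #: censoring ~ Uniform(0, censor_time_max) months
    censor_time_max: float = 120.0
    n_genes: int = 800
    module_sizes: tuple[int, ...] = (150, 120, 100)
    module_loading: float = 0.8
    #: target correlation of module 1's latent factor with the risk score
    module_trait_cor: float = -0.5
    noise_sd: float = 1.0
    #: probability of flipping each boundary voxel in a repeat delineation
    repeat_perturbation: float = 0.10
    tumor_radius_range: tuple[float, float] = (7.0, 11.0)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.habitat_fractions) - 1.0) > 1e-9:
            raise ValueError("habitat_fractions must sum to 1")
        if any(s <= 0 for s in self.intensity_sds) or self.noise_sd <= 0:
            raise ValueError("all standard deviations must be positive")
        if not 0.0 < self.prevalence_high_grade < 1.0:
            raise ValueError("prevalence_high_grade must lie in (0, 1)")
        if any(m < 100 for m in self.module_sizes):
            raise ValueError("module_sizes must each be >= 100")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes must sum to <= n_genes")
        if abs(self.module_trait_cor) >= 1.0:
            raise ValueError("module_trait_cor must satisfy |r| < 1")
        if self.survival_baseline_hazard <= 0:
            raise ValueError("survival_baseline_hazard must be positive")


@dataclass
class VolumeWithMask:
    """A simulated image volume with its masks and generation ground truth."""

    patient_id: str
    image: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray
    #: observer 1's second delineation (intra-observer repeat)
    mask_intra: np.ndarray
    #: observer 2's delineation (inter-observer repeat)
    mask_inter: np.ndarray
    #: ground-truth habitat labels (0 outside mask, 1 low-density, 2 high-density)
    habitat_truth: np.ndarray


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    clinical: pd.DataFrame
    volumes: list[VolumeWithMask]
    expression: pd.DataFrame
    #: planted module label per gene ("background" for pure-noise genes)
    gene_modules: pd.Series


def _smooth_unit_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit variance."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = g.std()
    return g / sd if sd > 0 else g


def _perturb_mask(mask: np.ndarray, rng: np.random.Generator, p: float) -> np.ndarray:
    """Morphological re-delineation: random flips on the mask boundary."""
    inner_edge = mask & ~ndimage.binary_erosion(mask)
    outer_edge = ndimage.binary_dilation(mask) & ~mask
    out = mask.copy()
    out[inner_edge & (rng.random(mask.shape) < p)] = False
    out[outer_edge & (rng.random(mask.shape) < p)] = True
    if not out.any():  # pathological tiny mask; keep the original
        return mask.copy()
    return out


def generate_clinical(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical table: grade, TNM, demographics and the latent risk score.

    TNM is generated to co-vary with grade (high stage more likely in
    high-grade disease), age/sex/laterality are grade-independent.
    ``latent_risk`` is the hidden per-patient score the radscore is meant
    to recover: grade indicator plus Gaussian jitter.
    """
    spec.validate()
    n = spec.n_patients
    grade_high = rng.random(n) < spec.prevalence_high_grade
    tnm_high = np.where(grade_high, rng.random(n) < 0.55, rng.random(n) < 0.20)
    age = np.round(rng.normal(59.0, 12.0, n)).clip(25, 90)
    sex = np.where(rng.random(n) < 0.65, "M", "F")
    laterality = np.where(rng.random(n) < 0.5, "right", "left")
    latent_risk = grade_high.astype(float) + rng.normal(0.0, 0.5, n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "grade": np.where(grade_high, "high", "low"),
            "tnm": np.where(tnm_high, "high", "low"),
            "age": age,
            "sex": sex,
            "laterality": laterality,
            "latent_risk": latent_risk,
        }
    )


def generate_tumor_volume(
    spec: CohortSpec,
    patient: pd.Series | dict,
    rng: np.random.Generator,
) -> VolumeWithMask:
    """Simulate one patient's volume, masks and habitat ground truth.

    The tumor is an ellipsoid; habitat membership comes from thresholding a
    smoothed noise field at the low-density fraction's quantile, giving two
    contiguous blob populations. High-grade patients get ``grade_effect``
    extra fine-scale noise in the low-density habitat only.
    """
    spec.validate()
    grade = patient["grade"] if isinstance(patient, (pd.Series, dict)) else None
    if grade not in ("high", "low"):
        raise ValueError("patient must carry a grade label of 'high' or 'low'")
    shape = spec.image_shape
    lo, hi = spec.tumor_radius_range
    radii = rng.uniform(lo, hi, size=3)
    center = np.array(shape) / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    bad = [
        "xyz"[d]
        for d in range(3)
        if center[d] - radii[d] < 0 or center[d] + radii[d] > shape[d] - 1
    ]
    if bad:
        raise ValueError(
            f"tumor ellipsoid exceeds image bounds along dimension(s) {','.join(bad)}"
        )

    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask = dist2 <= 1.0

    # contiguous habitat blobs from smoothed-noise thresholding
    habitat_field = _smooth_unit_noise(rng, shape, sigma=2.5)
    thresh = np.quantile(habitat_field[mask], spec.habitat_fractions[0])
    habitat = np.zeros(shape, dtype=np.int8)
    habitat[mask] = np.where(habitat_field[mask] <= thresh, 1, 2)

    image = 20.0 + 5.0 * _smooth_unit_noise(rng, shape, sigma=1.0)  # background
    for h, (mu, sd) in enumerate(zip(spec.intensity_means, spec.intensity_sds), start=1):
        sel = habitat == h
        fine_sd = sd
        if h == 1 and grade == "high":
            fine_sd += spec.grade_effect
        field = (
            mu
            + spec.spatial_texture_sd * _smooth_unit_noise(rng, shape, sigma=1.2)
            + fine_sd * rng.standard_normal(shape)
        )
        image[sel] = field[sel]

    pid = str(patient["patient_id"]) if "patient_id" in patient else "P0000"
    return VolumeWithMask(
        patient_id=pid,
        image=image.astype(np.float32),
        spacing=spec.voxel_spacing,
        mask=mask,
        mask_intra=_perturb_mask(mask, rng, spec.repeat_perturbation),
        mask_inter=_perturb_mask(mask, rng, spec.repeat_perturbation),
        habitat_truth=habitat,
    )


def generate_survival(
    spec: CohortSpec,
    latent_risk: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times with hazard ``h0 * exp(coef * risk)``.

    Censoring is independent Uniform(0, censor_time_max); the recorded time
    is the minimum of event and censoring time, and ``os_event`` is 1 when
    the event was observed.
    """
    if spec.survival_baseline_hazard <= 0:
        raise ValueError("survival_baseline_hazard must be positive")
    latent_risk = np.asarray(latent_risk, dtype=float)
    if not np.all(np.isfinite(latent_risk)):
        raise ValueError("latent_risk must be finite")
    hazard = spec.survival_baseline_hazard * np.exp(
        spec.survival_risk_coef * latent_risk
    )
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, spec.censor_time_max, size=latent_risk.shape)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    os_time = np.maximum(os_time, 1e-6)  # strictly positive follow-up
    return pd.DataFrame({"os_time": os_time, "os_event": os_event})


def generate_expression(
    spec: CohortSpec,
    radscore: np.ndarray,
    rng: np.random.Generator,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x samples expression with planted coexpression modules.

    Each planted module ``m`` has a per-sample latent factor ``f_m``;
    member genes are ``loading * f_m + noise``. The first module's factor
    is constructed to correlate with the supplied score at
    ``module_trait_cor`` (negative by default). Background genes are pure
    noise. Returns the matrix and the planted gene->module labels.
    """
    spec.validate()
    radscore = np.asarray(radscore, dtype=float)
    n_samples = radscore.shape[0]
    if sample_ids is None:
        sample_ids = [f"P{i:04d}" for i in range(n_samples)]
    z = radscore - radscore.mean()
    sd = z.std()
    z = z / sd if sd > 0 else z

    rho = spec.module_trait_cor
    expr = np.empty((spec.n_genes, n_samples))
    truth = np.full(spec.n_genes, "background", dtype=object)
    g0 = 0
    for m, size in enumerate(spec.module_sizes):
        if m == 0:
            f = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_samples)
        else:
            f = rng.standard_normal(n_samples)
        loadings = spec.module_loading * np.ones(size)
        expr[g0 : g0 + size] = (
            loadings[:, None] * f[None, :]
            + spec.noise_sd * rng.standard_normal((size, n_samples))
        )
        truth[g0 : g0 + size] = f"module_{m + 1}"
        g0 += size
    expr[g0:] = spec.noise_sd * rng.standard_normal((spec.n_genes - g0, n_samples))

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    df = pd.DataFrame(expr, index=gene_ids, columns=list(sample_ids))
    df.index.name = "gene"
    return df, pd.Series(truth, index=gene_ids, name="module")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full cohort: clinical table, volumes, survival, expression.

    All randomness descends from ``spec.seed`` through named sub-streams,
    so a fixed spec reproduces the cohort exactly.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_clin, rng_vol, rng_surv, rng_expr = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    clinical = generate_clinical(spec, rng_clin)
    volumes = [
        generate_tumor_volume(spec, row, rng_vol)
        for _, row in clinical.iterrows()
    ]
    surv = generate_survival(spec, clinical["latent_risk"].to_numpy(), rng_surv)
    clinical = pd.concat([clinical, surv], axis=1)
    expression, gene_modules = generate_expression(
        spec,
        clinical["latent_risk"].to_numpy(),
        rng_expr,
        sample_ids=clinical["patient_id"].tolist(),
    )
    return SyntheticCohort(spec, clinical, volumes, expression, gene_modules)


def write_cohort(cohort: SyntheticCohort, out_dir) -> list[Path]:
    """Write the cohort to disk: NIfTI volumes/masks, clinical CSV, expression TSV."""
    out = Path(out_dir)
    vol_dir = out / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for vol in cohort.volumes:
        for suffix, arr in [
            ("image", vol.image),
            ("mask", vol.mask.astype(np.uint8)),
            ("mask_intra", vol.mask_intra.astype(np.uint8)),
            ("mask_inter", vol.mask_inter.astype(np.uint8)),
        ]:
            p = vol_dir / f"{vol.patient_id}_{suffix}.nii.gz"
            save_nifti(arr, vol.spacing, p)
            written.append(p)
    clin_path = out / "clinical.csv"
    cohort.clinical.to_csv(clin_path, index=False)
    written.append(clin_path)
    expr_path = out / "expression.tsv"
    cohort.expression.to_csv(expr_path, sep="\t")
    written.append(expr_path)
    truth_path = out / "gene_modules_truth.csv"
    cohort.gene_modules.to_frame().to_csv(truth_path)
    written.append(truth_path)
    spec_path = out / "cohort_spec.json"
    spec_path.write_text(
        pd.Series(dataclasses.asdict(cohort.spec)).to_json(indent=2)
    )
    written.append(spec_path)
    return written
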
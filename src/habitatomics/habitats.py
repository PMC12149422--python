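"""Tumor subregion ("habitat") segmentation.

Voxels inside the tumor mask are described by intensity plus local first
and second moments, clustered with a full-covariance Gaussian mixture
fitted by EM, and the number of subregions is chosen by the Bayesian
information criterion over a scan of K (2..10 by default, smaller K wins
BIC ties). Clusters are relabeled in ascending order of mean intensity so
that label 1 is always the low-density subregion (VOI_1) and label 2 the
high-density one (VOI_2), giving cross-patient correspondence even though
each patient's mixture is fitted independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GMMFit",
    "HabitatLabelMap",
    "voxel_features",
    "fit_gmm",
    "bic",
    "select_k_and_segment",
]


@dataclass
class GMMFit:
    """Parameters and per-observation responsibilities of a fitted mixture."""

    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    responsibilities: np.ndarray  # (n, k)
    log_likelihood: float
    n_iter: int
    converged: bool

    @property
    def n_params(self) -> int:
        k, d = self.means.shape
        return (k - 1) + k * d + k * d * (d + 1) // 2


@dataclass
class HabitatLabelMap:
    """Per-voxel subregion labels (0 outside the mask) plus model-selection trace."""

    labels: np.ndarray
    k_selected: int
    bic_by_k: dict[int, float]
    #: mean voxel intensity per subregion, ascending (label 1 = lowest density)
    cluster_mean_intensity: np.ndarray


def voxel_features(
    image: np.ndarray, mask: np.ndarray, radius: int | None = None
) -> np.ndarray:
    """Per-voxel descriptors for clustering.

    With ``radius=None`` (default) each voxel is described by its raw
    intensity alone, so a tumor drawn from two intensity populations is a
    well-specified two-component mixture in descriptor space. Passing an
    integer ``radius`` appends the local mean and local standard deviation
    over a cubic neighborhood of that half-width, restricted to the mask
    so background never leaks into tumor statistics; note that with
    neighborhood descriptors the voxels straddling a habitat interface
    form their own intermediate population, which BIC may legitimately
    resolve as additional clusters. Column 0 is always the raw intensity
    (used downstream for label ordering).
    """
    if not mask.any():
        raise ValueError("mask is empty")
    if radius is None:
        X = image[mask].astype(float)[:, None]
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite voxel descriptors")
        return X
    size = 2 * radius + 1
    m = mask.astype(float)
    img = np.where(mask, image, 0.0).astype(float)
    cnt = ndimage.uniform_filter(m, size=size) * size**3
    s1 = ndimage.uniform_filter(img, size=size) * size**3
    s2 = ndimage.uniform_filter(img * img, size=size) * size**3
    cnt = np.maximum(cnt, 1.0)
    local_mean = s1 / cnt
    local_var = np.maximum(s2 / cnt - local_mean**2, 0.0)
    X = np.column_stack(
        [image[mask], local_mean[mask], np.sqrt(local_var[mask])]
    ).astype(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite voxel descriptors")
    return X


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _log_prob_matrix(X, weights, means, covs) -> np.ndarray:
    """(n, k) weighted component log-densities; vectorized univariate path."""
    if X.shape[1] == 1:
        var = covs[:, 0, 0]
        sq = (X[:, 0][:, None] - means[:, 0][None, :]) ** 2
        return np.log(weights)[None, :] - 0.5 * (
            np.log(2.0 * np.pi * var)[None, :] + sq / var[None, :]
        )
    return np.stack(
        [
            np.log(w) + _log_gaussian(X, m, c)
            for w, m, c in zip(weights, means, covs)
        ],
        axis=1,
    )


def fit_gmm(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 200,
    var_floor: float = 1e-6,
) -> GMMFit:
    """Fit a k-component full-covariance Gaussian mixture by EM.

    Best of ``n_init`` random restarts (means initialized at distinct data
    points). Covariances are floored by ``var_floor`` times the mean data
    variance on the diagonal, so degenerate clusters shrink rather than
    raise. The log-likelihood is checked to be non-decreasing at every EM
    iteration.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    floor = var_floor * max(float(X.var(axis=0).mean()), 1e-12)
    eye = np.eye(d)
    rng = np.random.default_rng(seed)
    data_cov = np.cov(X.T, bias=True).reshape(d, d) + floor * eye

    best: GMMFit | None = None
    for _ in range(n_init):
        # random-point centers followed by one hard assignment step, so
        # components start from within-cluster moments (a broad shared
        # covariance stalls EM at the symmetric saddle point)
        means = X[rng.choice(n, size=k, replace=False)].copy()
        assign = np.argmin(
            ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        covs = np.empty((k, d, d))
        weights = np.empty(k)
        for j in range(k):
            sel = X[assign == j]
            weights[j] = max(len(sel), 1) / n
            if len(sel) >= 2:
                means[j] = sel.mean(axis=0)
                covs[j] = np.cov(sel.T, bias=True).reshape(d, d) + floor * eye
            else:
                covs[j] = data_cov.copy()
        weights /= weights.sum()
        prev_ll = -np.inf
        ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            log_prob = _log_prob_matrix(X, weights, means, covs)
            m = log_prob.max(axis=1)
            norm = m + np.log(np.exp(log_prob - m[:, None]).sum(axis=1))
            ll = float(norm.sum())
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                raise RuntimeError(
                    f"EM log-likelihood decreased ({prev_ll} -> {ll})"
                )
            resp = np.exp(log_prob - norm[:, None])
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
                converged = True
                break
            prev_ll = ll
            nk = resp.sum(axis=0)
            for j in range(k):
                if nk[j] < 1e-10:  # empty component: reseed at a random point
                    means[j] = X[rng.integers(n)]
                    covs[j] = data_cov.copy()
                    nk[j] = 1e-10
                    continue
                means[j] = resp[:, j] @ X / nk[j]
                diff = X - means[j]
                covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j] + floor * eye
            weights = nk / nk.sum()
        fit = GMMFit(
            weights=weights,
            means=means,
            covariances=covs,
            responsibilities=resp,
            log_likelihood=ll,
            n_iter=it,
            converged=converged,
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, ``n_params * ln(n_obs) - 2 * loglik``.

    Lower is better.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return n_params * np.log(n_obs) - 2.0 * loglik


def select_k_and_segment(
    image: np.ndarray,
    mask: np.ndarray,
    k_range=range(2, 11),
    seed: int = 0,
    feature_radius: int | None = None,
    **gmm_kwargs,
) -> HabitatLabelMap:
    """Segment a tumor into its BIC-optimal number of intensity habitats.

    Fits one mixture per candidate K on this patient's masked voxel
    descriptors, selects the K minimizing BIC (ties toward smaller K),
    assigns each voxel to its maximum-responsibility component, and
    relabels components in ascending mean-intensity order so label 1 is
    the lowest-density subregion.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    X = voxel_features(image, mask, radius=feature_radius)
    n = X.shape[0]
    ks = sorted(int(k) for k in k_range)
    ss = np.random.SeedSequence(seed)
    sub_seeds = {k: int(c.generate_state(1)[0] % 2**31) for k, c in zip(ks, ss.spawn(len(ks)))}

    bic_by_k: dict[int, float] = {}
    fits: dict[int, GMMFit] = {}
    for k in ks:
        if n < k:
            warnings.warn(f"skipping K={k}: only {n} voxels")
            continue
        try:
            fit = fit_gmm(X, k, seed=sub_seeds[k], **gmm_kwargs)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"GMM failed for K={k}: {exc}")
            continue
        fits[k] = fit
        bic_by_k[k] = bic(fit.log_likelihood, fit.n_params, n)
    if not fits:
        raise RuntimeError("GMM fitting failed for every K in the scan")

    k_sel = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    fit = fits[k_sel]
    assign = np.argmax(fit.responsibilities, axis=1)

    intensity = X[:, 0]
    means = np.array(
        [intensity[assign == j].mean() if np.any(assign == j) else np.inf
         for j in range(k_sel)]
    )
    order = np.argsort(means, kind="stable")
    relabel = np.empty(k_sel, dtype=int)
    relabel[order] = np.arange(1, k_sel + 1)
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[mask] = relabel[assign]

    present = np.unique(relabel[assign])
    cluster_means = np.array(
        [intensity[relabel[assign] == lab].mean() for lab in present]
    )
    return HabitatLabelMap(
        labels=labels,
        k_selected=k_sel,
        bic_by_k=bic_by_k,
        cluster_mean_intensity=cluster_means,
    )
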
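"""Postural-state binning of 4-D eigenworm vectors.

Two binning routes are provided:

* **FAB-GMM** — a Gaussian mixture fitted by an EM-like factorized
  asymptotic Bayes procedure. After each standard E-step the
  responsibilities of component ``k`` are shrunk by
  ``exp(-D_c / (2 N_k))``, where ``D_c`` is the number of free parameters
  per component (4 mean + 10 covariance = 14 in 4-D) and ``N_k`` is the
  component's current effective count; rows are then renormalized and
  components whose mixture ratio falls below a threshold ``eps`` are
  pruned. The procedure therefore selects the number of postural states
  automatically. Convergence is monitored on a factorized-information-
  criterion (FIC) lower bound.

* **K-means** — Lloyd's algorithm from a k-means++ start; each frame is
  binned deterministically to the nearest centroid (one-hot
  responsibilities).

Each converged Gaussian component (or centroid) is one *postural state*;
per-frame state memberships are the model's responsibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, xlogy
from sklearn.cluster import kmeans_plusplus

from .collection import EigenwormSeries, StrainCollection
from .errors import InsufficientSampleError, InvalidInputError, InvalidParameterError

__all__ = [
    "PostureStateModel",
    "ResponsibilityMatrix",
    "sample_frames",
    "fit_kmeans",
    "fit_fab_gmm",
    "responsibilities",
]

_COV_REG = 1e-6  # ridge added to every covariance after each M-step


@dataclass
class PostureStateModel:
    """A fitted set of K postural states.

    For ``method='gmm'`` the states are full-covariance Gaussian components
    ordered by descending mixture weight; for ``method='kmeans'`` the means
    are Lloyd centroids and covariances are zero placeholders.
    """

    method: str  # 'gmm' | 'kmeans'
    weights: np.ndarray  # (K,), simplex
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d); zeros for kmeans
    eps: float | None = None
    k_init: int | None = None
    seed: int | None = None
    n_iter: int = 0
    objective_trace: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


@dataclass
class ResponsibilityMatrix:
    """Per-frame state responsibilities ``(F, K)`` for one worm.

    Rows are on the K-simplex; for a k-means model each row is one-hot.
    """

    values: np.ndarray
    worm_id: str
    strain_id: str | None = None
    model: PostureStateModel | None = None

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def K(self) -> int:
        return self.values.shape[1]


def sample_frames(
    collection: StrainCollection,
    fraction: float = 0.01,
    seed: int = 0,
    min_points: int | None = None,
) -> np.ndarray:
    """Uniformly sample a fraction of all pooled (finite) frames.

    Sampling is without replacement over the pooled frames of every worm;
    the returned count is ``round(fraction * total)``. ``fraction=1`` keeps
    every frame in pooled order.
    """
    if not (0.0 < fraction <= 1.0):
        raise InvalidParameterError("fraction must be in (0, 1]")
    pool = np.concatenate([s.frames[~s.gap_mask] for s in collection.worms()], axis=0)
    pool = pool[np.isfinite(pool).all(axis=1)]
    total = len(pool)
    if fraction == 1.0:
        sample = pool
    else:
        n = int(round(fraction * total))
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=n, replace=False)
        sample = pool[idx]
    if min_points is not None and len(sample) < min_points:
        raise InsufficientSampleError(
            f"sampled {len(sample)} frames; at least {min_points} required"
        )
    return sample


# ---------------------------------------------------------------------------
# K-means (Lloyd baseline)


def fit_kmeans(points: np.ndarray, k: int, seed: int = 0, max_iter: int = 300) -> PostureStateModel:
    """Lloyd's algorithm from a k-means++ start.

    Iterates until the assignment reaches a fixpoint (or ``max_iter``);
    the within-cluster sum of squares is recorded per iteration and is
    non-increasing. An empty cluster is reseeded to the point farthest
    from its assigned centroid.
    """
    x = np.asarray(points, float)
    if k <= 0:
        raise InvalidParameterError("K must be positive")
    if len(x) < k:
        raise InvalidParameterError(f"need at least K={k} points, got {len(x)}")
    centers, _ = kmeans_plusplus(x, n_clusters=k, random_state=seed)
    trace: list[float] = []
    labels = None
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_labels = d2.argmin(axis=1)
        mind2 = d2[np.arange(len(x)), new_labels]
        if labels is not None and np.array_equal(new_labels, labels):
            trace.append(float(mind2.sum()))
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = x[sel].mean(axis=0)
            else:
                far = int(np.argmax(mind2))
                centers[j] = x[far]
                labels[far] = j
                mind2[far] = 0.0
        trace.append(float(((x - centers[labels]) ** 2).sum()))
    order = np.argsort(-np.bincount(labels, minlength=k), kind="stable")
    centers = centers[order]
    counts = np.bincount(labels, minlength=k)[order]
    d = x.shape[1]
    return PostureStateModel(
        method="kmeans",
        weights=counts / counts.sum(),
        means=centers,
        covariances=np.zeros((k, d, d)),
        seed=seed,
        k_init=k,
        n_iter=it,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# FAB-GMM


def _safe_cholesky(covs: np.ndarray) -> np.ndarray:
    """Batched Cholesky; a collapsing covariance gets progressively ridged."""
    ridge = _COV_REG
    eye = np.eye(covs.shape[-1])
    for _ in range(12):
        try:
            return np.linalg.cholesky(covs)
        except np.linalg.LinAlgError:
            covs = covs + ridge * eye
            ridge *= 10.0
    raise np.linalg.LinAlgError("covariance irreparably singular")


def _log_gauss_batch(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Per-component Gaussian log-densities, shape (n, K)."""
    k, d = means.shape
    chols = _safe_cholesky(covs)
    inv = np.linalg.solve(chols, np.broadcast_to(np.eye(d), (k, d, d)).copy())
    dev = x[None, :, :] - means[:, None, :]  # (K, n, d)
    y = np.einsum("kij,knj->kni", inv, dev)
    maha = np.einsum("kni,kni->kn", y, y)
    logdet = 2.0 * np.log(np.diagonal(chols, axis1=1, axis2=2)).sum(axis=1)
    return (-0.5 * (d * np.log(2.0 * np.pi) + logdet[:, None] + maha)).T


def fit_fab_gmm(
    points: np.ndarray,
    eps: float = 0.01,
    k_init: int = 100,
    seed: int = 0,
    max_iter: int = 2000,
    rel_tol: float = 1e-10,
    shrink: bool = True,
    init_means: np.ndarray | None = None,
) -> PostureStateModel:
    """Fit a Gaussian mixture with FAB shrinkage and component pruning.

    Starting from ``k_init`` k-means++ centers (or explicit ``init_means``),
    all with the global data covariance, EM-like iterations run with the
    FAB-modified E-step; after every E-step components with mixture ratio
    below ``eps`` are removed and the responsibilities renormalized.
    Iteration stops when the relative change of the FIC lower bound falls
    below ``rel_tol`` (and every surviving weight is at least ``eps``), or
    at ``max_iter``. The defaults are deliberately patient: redundant
    components that split one true cluster near-symmetrically dissolve
    through a slow weight-mediated competition, and stopping early freezes
    them in.

    ``shrink=False`` together with ``eps=0`` disables both the shrinkage
    factor and pruning, reducing the procedure to plain EM (the objective
    trace is then the log-likelihood, which is non-decreasing).
    """
    x = np.asarray(points, float)
    if x.ndim != 2:
        raise InvalidParameterError("points must be (n, d)")
    n, d = x.shape
    if init_means is not None:
        init_means = np.asarray(init_means, float)
        k_init = len(init_means)
    if n < k_init:
        raise InsufficientSampleError(f"need at least {k_init} points, got {n}")
    if shrink:
        if not (0.0 < eps) or k_init * eps >= 1.0:
            raise InvalidParameterError("require 0 < eps < 1/K_init")
    elif eps < 0:
        raise InvalidParameterError("eps must be >= 0")

    d_c = d + d * (d + 1) // 2  # free parameters per component (mean + covariance)
    eye = np.eye(d)

    if init_means is None:
        means, _ = kmeans_plusplus(x, n_clusters=k_init, random_state=seed)
    else:
        means = init_means.copy()
    weights = np.full(k_init, 1.0 / k_init)
    # broad start: every component carries the global covariance, so
    # redundant components overlap and shrinkage competition can act
    global_cov = np.cov(x, rowvar=False) + _COV_REG * eye
    covs = np.repeat(global_cov[None], k_init, axis=0)

    trace: list[float] = []
    prev_obj = None
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.log(weights)[None, :] + _log_gauss_batch(x, means, covs)
        lse = logsumexp(logp, axis=1)
        r = np.exp(logp - lse[:, None])
        loglik = float(lse.sum())

        pruned = False
        if shrink:
            nk = r.sum(axis=0)
            r = r * np.exp(-d_c / (2.0 * np.maximum(nk, 1e-12)))[None, :]
            r /= r.sum(axis=1, keepdims=True)
        if eps > 0:
            nk = r.sum(axis=0)
            keep = nk / n >= eps
            if not keep.all():
                if not keep.any():  # never remove everything
                    keep[int(np.argmax(nk))] = True
                r = r[:, keep]
                r /= r.sum(axis=1, keepdims=True)
                logp = logp[:, keep]
                pruned = True

        # M-step
        nk = r.sum(axis=0)
        weights = nk / n
        means = (r.T @ x) / nk[:, None]
        second = np.einsum("nk,nd,ne->kde", r, x, x, optimize=True) / nk[:, None, None]
        covs = second - means[:, :, None] * means[:, None, :]
        covs = 0.5 * (covs + covs.transpose(0, 2, 1)) + _COV_REG * eye

        if shrink:
            # FIC lower bound at the current responsibilities
            ecll = float((r * logp).sum())
            entropy = -float(xlogy(r, r).sum())
            penalty = 0.5 * d_c * np.log(np.maximum(nk, 1e-12)).sum()
            penalty += 0.5 * (len(nk) - 1) * np.log(n)
            obj = ecll + entropy - penalty
        else:
            obj = loglik
        trace.append(obj)

        if (
            prev_obj is not None
            and not pruned
            and (eps == 0 or (weights >= eps).all())
            and abs(obj - prev_obj) <= rel_tol * (abs(prev_obj) + 1e-12)
        ):
            break
        prev_obj = obj

    order = np.argsort(-weights, kind="stable")
    return PostureStateModel(
        method="gmm",
        weights=weights[order],
        means=means[order],
        covariances=covs[order],
        eps=eps,
        k_init=k_init,
        seed=seed,
        n_iter=it,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# responsibilities


def responsibilities(model: PostureStateModel, series: EigenwormSeries) -> ResponsibilityMatrix:
    """Per-frame state responsibilities of ``series`` under ``model``.

    GMM: posterior probability of each component (computed in log space).
    K-means: one-hot at the nearest centroid, ties to the lowest state
    index. Frames must be finite (interpolate gaps upstream).
    """
    x = series.frames
    if not np.isfinite(x).all():
        raise InvalidInputError(
            f"worm {series.worm_id!r} has non-finite frames; interpolate gaps first"
        )
    if model.method == "gmm":
        logp = np.log(model.weights)[None, :] + _log_gauss_batch(
            x, model.means, model.covariances
        )
        r = np.exp(logp - logsumexp(logp, axis=1)[:, None])
        r /= r.sum(axis=1, keepdims=True)
    elif model.method == "kmeans":
        d2 = ((x[:, None, :] - model.means[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(axis=1)  # argmin returns the lowest index on ties
        r = np.zeros((len(x), model.K))
        r[np.arange(len(x)), labels] = 1.0
    else:
        raise InvalidParameterError(f"unknown model method {model.method!r}")
    return ResponsibilityMatrix(
        values=r, worm_id=series.worm_id, strain_id=series.strain_id, model=model
    )
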
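"""Artificial reference strains: inactivity removal and uniform acceleration.

A strain's atypical transition pattern may reflect nothing more exotic than
(a) missing quiescence bouts and (b) an overall faster postural change.
This module tests that explanation constructively: transform the reference
strain's series by deleting frames whose instantaneous postural change
speed falls below a threshold ``alpha`` and then accelerating ``beta``-fold
(frame averaging/decimation), choose ``(alpha, beta)`` so the transformed
speed distribution best matches the target strain's, and ask whether the
transformed ("artificial") reference now reproduces the target's
occurrence and transition divergences. The residual of the artificial
comparison under the previously fitted occurrence/transition trend is the
``Z_a`` statistic; a small ``|Z_a|`` means the two simple factors explain
the atypicality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

from .behavior_stats import aggregate_strain, jsd, occurrence, transitions
from .binning import PostureStateModel, responsibilities
from .collection import EigenwormSeries
from .errors import InvalidInputError, InvalidParameterError, TooShortError

__all__ = [
    "SpeedProfile",
    "ArtificialParams",
    "ReproductionResult",
    "instantaneous_speed",
    "remove_inactivity",
    "accelerate",
    "speed_cdf_distance",
    "fit_artificial_params",
    "evaluate_reproduction",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_BETA_GRID",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.3, 1.0 + 1e-9, 0.1), 10))
DEFAULT_BETA_GRID = (1.5, 2.0)


@dataclass
class SpeedProfile:
    """Instantaneous postural change speeds (per frame) for one worm or pool."""

    speeds: np.ndarray  # (F-1,), nonnegative
    owner: str = ""


@dataclass
class ArtificialParams:
    """Selected inactivity threshold, acceleration factor and CDF distance."""

    alpha: float
    beta: float
    distance: float  # D_eigenworm_speed at (alpha, beta)


@dataclass
class ReproductionResult:
    """Divergences of a target strain from the fitted artificial reference."""

    strain_id: str
    delta_r_a: float
    delta_T_a: float
    z_a: float
    params: ArtificialParams | None = None
    original_z: float | None = None


def instantaneous_speed(series: EigenwormSeries) -> SpeedProfile:
    """Euclidean distance between eigenworm vectors of adjacent frames."""
    if series.n_frames < 2:
        raise TooShortError(f"worm {series.worm_id!r} has fewer than 2 frames")
    diffs = np.diff(series.frames, axis=0)
    return SpeedProfile(
        speeds=np.linalg.norm(diffs, axis=1), owner=series.worm_id
    )


def remove_inactivity(series: EigenwormSeries, alpha: float) -> EigenwormSeries:
    """Delete frames whose speed from the *previous original frame* is < alpha.

    One pass over the original adjacency: frame ``f >= 1`` is removed iff
    ``||v_f - v_{f-1}|| < alpha``; frame 0 is always kept and the survivors
    are concatenated in order. ``alpha = 0`` is the identity. A result
    shorter than 2 frames is returned with a warning.
    """
    if alpha < 0:
        raise InvalidParameterError("alpha must be >= 0")
    if alpha == 0:
        return series.copy()
    speeds = np.linalg.norm(np.diff(series.frames, axis=0), axis=1)
    keep = np.concatenate([[True], speeds >= alpha])
    out = series.replace(frames=series.frames[keep].copy(), gap_mask=series.gap_mask[keep].copy())
    if out.n_frames < 2:
        warnings.warn(
            f"worm {series.worm_id!r} degenerated to {out.n_frames} frame(s) "
            f"after inactivity removal at alpha={alpha}",
            stacklevel=2,
        )
    return out


def accelerate(series: EigenwormSeries, beta: float) -> EigenwormSeries:
    """Simulate a ``beta``-fold faster worm by frame averaging/decimation.

    ``beta = 1`` is the identity. ``beta = 2`` keeps every second frame
    (even indices). ``beta = 1.5`` maps each consecutive non-overlapping
    triple ``(v1, v2, v3)`` to ``(v1, (v2 + v3) / 2)``; a trailing
    remainder of one or two frames is kept unchanged.
    """
    if beta == 1.0:
        return series.copy()
    if beta not in (1.5, 2.0):
        raise InvalidParameterError("beta must be one of 1.0, 1.5, 2.0")
    x = series.frames
    mask = series.gap_mask
    if beta == 2.0:
        idx = np.arange(0, len(x), 2)
        frames, gaps = x[idx].copy(), mask[idx].copy()
    else:  # beta == 1.5
        f = len(x)
        n_triples = f // 3
        body = x[: 3 * n_triples].reshape(n_triples, 3, -1)
        first = body[:, 0, :]
        avg = body[:, 1:, :].mean(axis=1)
        frames = np.empty((2 * n_triples, x.shape[1]))
        frames[0::2] = first
        frames[1::2] = avg
        gaps_body = mask[: 3 * n_triples].reshape(n_triples, 3)
        gaps = np.empty(2 * n_triples, dtype=bool)
        gaps[0::2] = gaps_body[:, 0]
        gaps[1::2] = gaps_body[:, 1:].any(axis=1)
        if f % 3:
            frames = np.vstack([frames, x[3 * n_triples :]])
            gaps = np.concatenate([gaps, mask[3 * n_triples :]])
    return series.replace(frames=frames, gap_mask=gaps)


def speed_cdf_distance(a: "SpeedProfile | np.ndarray", b: "SpeedProfile | np.ndarray") -> float:
    """L1 distance between empirical speed CDFs, ``int |F_a(x) - F_b(x)| dx``.

    Computed exactly as the one-dimensional Wasserstein-1 distance between
    the two samples.
    """
    xa = np.asarray(getattr(a, "speeds", a), float)
    xb = np.asarray(getattr(b, "speeds", b), float)
    if xa.size == 0 or xb.size == 0:
        raise InvalidInputError("speed profiles must be non-empty")
    return float(wasserstein_distance(xa, xb))


def _pooled_speeds(series_list: list[EigenwormSeries]) -> np.ndarray:
    return np.concatenate(
        [instantaneous_speed(s).speeds for s in series_list if s.n_frames >= 2]
    )


def transform_strain(
    series_list: list[EigenwormSeries], alpha: float, beta: float
) -> list[EigenwormSeries]:
    """Apply inactivity removal then acceleration to every worm of a strain.

    Worms that degenerate below 2 frames are dropped with a warning.
    """
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in series_list:
            t = accelerate(remove_inactivity(s, alpha), beta)
            if t.n_frames >= 2:
                out.append(t)
    dropped = len(series_list) - len(out)
    if dropped:
        warnings.warn(f"{dropped} worm(s) degenerated during transformation", stacklevel=2)
    if not out:
        raise InvalidInputError("every worm degenerated during transformation")
    return out


def fit_artificial_params(
    wildtype: list[EigenwormSeries],
    target: list[EigenwormSeries],
    alpha_grid=DEFAULT_ALPHA_GRID,
    beta_grid=DEFAULT_BETA_GRID,
    include_identity: bool = False,
) -> tuple[ArtificialParams, list[EigenwormSeries]]:
    """Grid-search ``(alpha, beta)`` minimizing the speed CDF distance.

    Every wild-type worm is transformed by inactivity removal at ``alpha``
    followed by ``beta``-fold acceleration; the transformed strains' pooled
    speeds are compared with the target strain's pooled speeds. Ties are
    broken toward smaller ``alpha``, then smaller ``beta``.
    ``include_identity`` prepends ``alpha = 0`` and ``beta = 1`` to the
    grids so the untransformed reference is a candidate.
    """
    alphas = list(alpha_grid)
    betas = list(beta_grid)
    if include_identity:
        alphas = [0.0] + [a for a in alphas if a != 0.0]
        betas = [1.0] + [b for b in betas if b != 1.0]
    if not alphas or not betas:
        raise InvalidParameterError("empty parameter grid")
    target_speeds = _pooled_speeds(target)
    best: tuple[float, float, float] | None = None
    best_series: list[EigenwormSeries] | None = None
    for alpha in alphas:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slowcut = [remove_inactivity(s, alpha) for s in wildtype]
        for beta in betas:
            candidates = [accelerate(s, beta) for s in slowcut]
            usable = [s for s in candidates if s.n_frames >= 2]
            if not usable:
                continue
            dist = speed_cdf_distance(_pooled_speeds(usable), target_speeds)
            if best is None or dist < best[0]:
                best = (dist, alpha, beta)
                best_series = usable
    if best is None:
        raise InvalidInputError("every grid point degenerated")
    dist, alpha, beta = best
    return ArtificialParams(alpha=alpha, beta=beta, distance=dist), best_series


def evaluate_reproduction(
    artificial: list[EigenwormSeries],
    target: list[EigenwormSeries],
    model: PostureStateModel,
    regression,
    params: ArtificialParams | None = None,
    original_z: float | None = None,
    strain_id: str = "",
) -> ReproductionResult:
    """Bin both strains with the fixed model and compute ``Z_a``.

    ``delta_r_a = JSD(r_S, r_aRef)`` and ``delta_T_a = JSD(T_S, T_aRef)``;
    ``Z_a`` is the residual of ``delta_T_a`` under the previously fitted
    occurrence/transition regression, in residual-sd units.
    """
    def strain_stats(series_list, owner):
        occs, trans = [], []
        for s in series_list:
            resp = responsibilities(model, s)
            occs.append(occurrence(resp))
            trans.append(transitions(resp))
        return aggregate_strain(occs, trans, owner)

    r_a, t_a = strain_stats(artificial, "artificial")
    r_s, t_s = strain_stats(target, strain_id or "target")
    delta_r_a = jsd(r_s, r_a)
    delta_t_a = jsd(np.asarray(t_s).ravel(), np.asarray(t_a).ravel())
    z_a = float(regression.standardize(delta_r_a, delta_t_a))
    return ReproductionResult(
        strain_id=strain_id or "target",
        delta_r_a=delta_r_a,
        delta_T_a=delta_t_a,
        z_a=z_a,
        params=params,
        original_z=original_z,
    )
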
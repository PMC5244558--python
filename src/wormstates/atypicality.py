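"""Detection of strains with atypical transition patterns.

Across strains, the transition divergence from the reference rises almost
linearly with the occurrence divergence: strains that use different
postures necessarily transition differently. Strains whose transition
divergence is *larger than that trend predicts* change how they move
between postures beyond what their posture usage explains. They are
flagged by the standardized residual (Z) of an ordinary least squares fit
of ``delta_T`` on ``delta_r``, with upper-tail normal p-values and
Benjamini-Hochberg correction across strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .behavior_stats import DivergenceRecord, OccurrenceVector, bh_adjust
from .errors import DegenerateFitError, InvalidInputError, InvalidParameterError
from .synthgen import EigenwormBasis

__all__ = [
    "RegressionModel",
    "FoldChangeTable",
    "regress_z",
    "detect_atypical",
    "state_fold_change",
    "reconstruct_posture",
]

_SD_FLOOR = 1e-14


@dataclass
class RegressionModel:
    """OLS fit of transition divergence on occurrence divergence.

    The line itself is ordinary least squares. Residuals are standardized
    by a noise model chosen by ``scale_kind``:

    * ``'robust'`` (default): divergence estimates get noisier roughly in
      proportion to their size, so the per-strain residual scale is
      ``s * (delta_r + delta0)`` with ``delta0`` the median ``delta_r`` of
      the fit and ``s`` a normalized-MAD estimate of the proportionality
      constant. Being median-based, ``s`` is not inflated by the very
      outliers the screen is meant to find (an SSR-based scale masks
      several simultaneous outliers in small strain panels), and for a
      panel of near-identical strains it coincides with the plain robust
      residual scale.
    * ``'classical'``: the constant scale ``sqrt(SSR / (n - 2))``.

    ``residual_sd`` always reports the classical value; ``residual_scale``
    reports the scale at the median ``delta_r``.
    """

    slope: float
    intercept: float
    residual_sd: float  # sqrt(SSR / (n - 2))
    residual_scale: float  # standardization scale at the median delta_r
    adjusted_r2: float
    n_strains: int
    scale_kind: str = "robust"
    scale_unit: float = 0.0  # s in s * (delta_r + delta0)
    scale_offset: float = 0.0  # delta0

    def predict(self, delta_r: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(delta_r, float)

    def scale_at(self, delta_r: float | np.ndarray) -> float | np.ndarray:
        """Residual scale of a strain at occurrence divergence ``delta_r``."""
        if self.scale_kind == "classical":
            return np.broadcast_to(self.residual_sd, np.shape(delta_r)) if np.ndim(delta_r) else self.residual_sd
        return self.scale_unit * (np.asarray(delta_r, float) + self.scale_offset)

    def standardize(self, delta_r, delta_T) -> np.ndarray:
        """Z-value of (delta_r, delta_T) points under the fitted model."""
        resid = np.asarray(delta_T, float) - self.predict(delta_r)
        scale = np.asarray(self.scale_at(delta_r), float)
        if np.all(scale < _SD_FLOOR):
            return np.zeros_like(resid)
        return resid / np.maximum(scale, _SD_FLOOR)


# Divergence scale below which estimation noise stops shrinking with the
# divergence itself (natural-log JSD units). Strains with delta_r below this
# floor share one noise scale; above it the scale grows proportionally.
NOISE_FLOOR_DELTA = 0.02


def regress_z(
    records: list[DivergenceRecord],
    leverage_correction: bool = False,
    scale: str = "robust",
) -> tuple[RegressionModel, list[DivergenceRecord]]:
    """Fit ``delta_T ~ delta_r`` and fill standardized residuals (Z).

    ``scale='robust'`` (default) uses the proportional robust noise model
    described on :class:`RegressionModel`; ``scale='classical'`` divides
    every residual by ``sqrt(SSR / (n - 2))``. With ``leverage_correction``
    the denominator additionally includes the per-point leverage factor
    ``sqrt(1 - h_ii)``. A perfect fit (scale below floor) yields
    all-zero Z.
    """
    if len(records) < 3:
        raise InvalidInputError("need at least 3 strains to regress")
    if scale not in ("robust", "classical"):
        raise InvalidInputError("scale must be 'robust' or 'classical'")
    dr = np.array([r.delta_r for r in records], float)
    dt = np.array([r.delta_T for r in records], float)
    if np.ptp(dr) < _SD_FLOOR:
        raise DegenerateFitError("zero variance in delta_r")
    fit = sm.OLS(dt, sm.add_constant(dr)).fit()
    resid = fit.resid
    n = len(records)
    residual_sd = float(np.sqrt((resid**2).sum() / (n - 2)))
    if scale == "robust":
        delta0 = NOISE_FLOOR_DELTA
        u = resid / (dr + delta0)
        s_unit = float(1.4826 * np.median(np.abs(u - np.median(u))))
        model = RegressionModel(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            residual_sd=residual_sd,
            residual_scale=s_unit * 2 * delta0,
            adjusted_r2=float(fit.rsquared_adj),
            n_strains=n,
            scale_kind="robust",
            scale_unit=s_unit,
            scale_offset=delta0,
        )
    else:
        model = RegressionModel(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            residual_sd=residual_sd,
            residual_scale=residual_sd,
            adjusted_r2=float(fit.rsquared_adj),
            n_strains=n,
            scale_kind="classical",
        )
    z = model.standardize(dr, dt)
    if leverage_correction and not np.allclose(z, 0.0):
        from statsmodels.stats.outliers_influence import OLSInfluence

        h = OLSInfluence(fit).hat_matrix_diag
        z = z / np.sqrt(1.0 - h)
    filled = [
        DivergenceRecord(r.strain_id, r.delta_r, r.delta_T, z=float(zi), q=None)
        for r, zi in zip(records, z)
    ]
    return model, filled


def detect_atypical(
    records: list[DivergenceRecord], q_threshold: float = 0.05
) -> pd.DataFrame:
    """BH-corrected upper-tail test on Z; returns strains sorted by Z.

    ``p_i = 1 - Phi(Z_i)`` (only atypically *large* transition divergence
    counts); the returned DataFrame has columns
    ``strain, delta_r, delta_T, z, q, flagged`` sorted by descending Z.
    """
    if any(r.z is None for r in records):
        raise InvalidInputError("records must carry z (run regress_z first)")
    z = np.array([r.z for r in records], float)
    p = norm.sf(z)
    q = bh_adjust(p)
    df = pd.DataFrame(
        {
            "strain": [r.strain_id for r in records],
            "delta_r": [r.delta_r for r in records],
            "delta_T": [r.delta_T for r in records],
            "z": z,
            "q": q,
            "flagged": q < q_threshold,
        }
    )
    return df.sort_values(["z", "strain"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


@dataclass
class FoldChangeTable:
    """Per-state occurrence ratios of a strain against the reference."""

    ratios: np.ndarray  # (K,)
    order: np.ndarray  # state indices, descending ratio
    over_represented: list[int]  # top_n largest
    under_represented: list[int]  # top_n smallest


def state_fold_change(
    r_strain: "OccurrenceVector | np.ndarray",
    r_ref: "OccurrenceVector | np.ndarray",
    top_n: int = 5,
    mean_frames: float = 4500.0,
) -> FoldChangeTable:
    """Fold change of state occupancy, with a small pseudo-count.

    ``ratio_k = (r_{S,k} + delta) / (r_{ref,k} + delta)`` with
    ``delta = 1 / (10 * K * mean_frames)`` so states absent from the
    reference stay finite. The ``top_n`` largest ratios are the
    over-represented states, the ``top_n`` smallest the under-represented.
    """
    rs = np.asarray(r_strain, float)
    rr = np.asarray(r_ref, float)
    if rs.shape != rr.shape:
        raise InvalidParameterError("occurrence vectors must share K")
    k = len(rs)
    if top_n > k // 2:
        raise InvalidParameterError("top_n must be at most K/2")
    delta = 1.0 / (10.0 * k * mean_frames)
    ratios = (rs + delta) / (rr + delta)
    order = np.argsort(-ratios, kind="stable")
    return FoldChangeTable(
        ratios=ratios,
        order=order,
        over_represented=list(order[:top_n]),
        under_represented=list(order[::-1][:top_n]),
    )


def reconstruct_posture(state_mean: np.ndarray, basis: EigenwormBasis) -> np.ndarray:
    """Map a state mean back to midline tangent angles (``basis @ mean``).

    The basis columns are mean-centered, so the reconstructed angle profile
    has zero mean (body orientation is not represented).
    """
    mean = np.asarray(state_mean, float)
    if mean.shape != (basis.dims,):
        raise InvalidParameterError(
            f"state mean has {mean.shape} entries, basis expects {basis.dims}"
        )
    return basis.matrix @ mean
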
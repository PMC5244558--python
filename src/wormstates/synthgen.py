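"""Synthetic eigenworm strain collections.

The generator emulates the statistical structure that the downstream
analysis assumes of real worm recordings: each individual's 4-D posture
trajectory wanders among a small set of attractor regions in eigenworm
space (multimodal state usage), switches attractors in bouts governed by a
row-stochastic matrix, occasionally enters quiescence bouts during which the
postural change speed collapses to a near-zero mode, and may have randomly
missing frames. Mutant-like perturbations alter rest behaviour, overall
speed, the stationary state usage, or the transition structure at matched
stationary usage.

Dynamics, per worm
------------------
While "active" at attractor ``g`` with mean posture ``m_g``::

    v[t+1] = v[t] + lam * (m_g - v[t]) + sigma_act * xi[t]

(``xi`` a standard-normal 4-vector). The attractor dwell time is geometric
with continuation probability ``A[g, g]``; at a bout boundary the next
attractor is drawn from the off-diagonal of row ``g``. With probability
``p_rest`` a rest bout is inserted at the boundary, during which::

    v[t+1] = v[t] + sigma_rest * xi[t]

until a geometric exit (per-frame probability ``rest_exit_prob``). With
``sigma_rest << sigma_act`` this produces the contiguous near-zero-speed
stretches seen in real recordings as a low mode of the speed distribution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .collection import EigenwormSeries, StrainCollection
from .errors import InvalidParameterError, InvalidPerturbationError

__all__ = [
    "EigenwormBasis",
    "SyntheticConfig",
    "Perturbation",
    "make_basis",
    "simulate_strains",
    "stationary_distribution",
    "metropolis_transition",
    "save_collection",
    "save_basis",
    "load_basis",
]


@dataclass(frozen=True)
class EigenwormBasis:
    """Orthonormal posture basis: ``n_angles`` midline tangent angles per column.

    Columns are pairwise orthonormal and sum to zero (angles are measured
    after removing the mean body orientation), so any 4-vector of amplitudes
    maps back to a mean-centered angle profile.
    """

    matrix: np.ndarray  # (n_angles, dims)

    @property
    def n_angles(self) -> int:
        return self.matrix.shape[0]

    @property
    def dims(self) -> int:
        return self.matrix.shape[1]


def make_basis(n_angles: int = 48, dims: int = 4, seed: int = 0) -> EigenwormBasis:
    """Draw a random orthonormal, zero-column-sum basis.

    The subspace of zero-sum angle profiles has dimension ``n_angles - 1``,
    so ``dims`` must not exceed that. Deterministic for a given seed.
    """
    if dims < 1:
        raise InvalidParameterError("dims must be >= 1")
    if dims > n_angles - 1:
        raise InvalidParameterError(
            f"dims={dims} exceeds the zero-sum subspace dimension {n_angles - 1}"
        )
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((n_angles, dims))
    m -= m.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(m)
    # fix signs for a canonical, seed-stable orientation
    q = q * np.sign(np.diag(r))
    return EigenwormBasis(matrix=q)


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the study conditions.

    Units: eigenworm amplitudes are dimensionless; noise scales are
    amplitude units per frame at ``fps``; probabilities are per bout
    (``rest_entry_prob``) or per frame (``rest_exit_prob``).
    """

    n_strains: int = 10
    worms_per_strain: int = 10
    frames_per_worm: int = 4500  # 900 s at 5 fps
    fps: float = 5.0
    n_attractors: int = 6
    attractor_means: np.ndarray | None = None  # (G, 4); drawn if None
    bout_transition: np.ndarray | None = None  # (G, G) row-stochastic; default if None
    relaxation_rate: float = 0.2  # lam, pull toward the attractor mean per frame
    active_noise: float = 0.35  # sigma_act
    rest_entry_prob: float = 0.2  # p_rest, at bout boundaries
    rest_exit_prob: float = 0.08  # per-frame; mean rest bout = 12.5 frames = 2.5 s
    rest_noise: float = 0.05  # sigma_rest; speed mode ~ 2*sigma_rest = 0.1
    speed_factor: float = 1.0  # default gamma for 'accelerate' perturbations
    gap_fraction: float = 0.0
    seed: int = 0
    attractor_spread: float | None = None  # std of drawn means; default 5*sigma_act

    def validate(self) -> None:
        if self.n_strains < 1 or self.worms_per_strain < 1:
            raise InvalidParameterError("need at least one strain and one worm")
        if self.frames_per_worm < 2:
            raise InvalidParameterError("frames_per_worm must be >= 2")
        if not (0.0 < self.relaxation_rate <= 1.0):
            raise InvalidParameterError("relaxation_rate must be in (0, 1]")
        if not (0.0 <= self.rest_entry_prob < 1.0):
            raise InvalidParameterError("rest_entry_prob must be in [0, 1)")
        if not (0.0 < self.rest_exit_prob <= 1.0):
            raise InvalidParameterError("rest_exit_prob must be in (0, 1]")
        if self.rest_noise >= self.active_noise:
            raise InvalidParameterError("rest_noise must be < active_noise")
        if not (0.0 <= self.gap_fraction < 0.4):
            raise InvalidParameterError("gap_fraction must be in [0, 0.4)")
        if self.speed_factor <= 0:
            raise InvalidParameterError("speed_factor must be > 0")
        if self.bout_transition is not None:
            a = np.asarray(self.bout_transition, float)
            if a.shape != (self.n_attractors, self.n_attractors):
                raise InvalidParameterError("bout_transition shape mismatch")
            if (a < 0).any() or not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidParameterError("bout_transition rows must sum to 1")


@dataclass(frozen=True)
class Perturbation:
    """One mutant-style modification of the base generative parameters.

    kind:
        ``none`` — wild-type parameters.
        ``no_rest`` — rest-entry probability set to 0 (no quiescence).
        ``accelerate`` — relaxation rate and active noise scaled by ``gamma``
        (attractor geometry unchanged), giving a faster speed distribution
        with approximately preserved state usage.
        ``retransition`` — bout matrix replaced by a reversible chain with
        the *same* stationary distribution but altered symmetric edge
        weights: transitions change at matched occurrence.
        ``reweight`` — bout matrix rebuilt around a tilted stationary
        distribution: state usage itself changes.
    """

    kind: str = "none"
    gamma: float | None = None  # accelerate; defaults to config.speed_factor
    strength: float = 1.0  # tilt size (reweight) / mobility factor (retransition)
    matrix: np.ndarray | None = None  # explicit replacement bout matrix (retransition)
    salt: int = 0  # extra entropy for perturbation-specific draws

    KINDS = ("none", "no_rest", "accelerate", "retransition", "reweight")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InvalidPerturbationError(f"unknown perturbation kind {self.kind!r}")


def stationary_distribution(a: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    a = np.asarray(a, float)
    g = a.shape[0]
    # solve pi (A - I) = 0 with sum(pi) = 1
    m = np.vstack([a.T - np.eye(g), np.ones(g)])
    b = np.zeros(g + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(m, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def metropolis_transition(pi: np.ndarray, proposal: np.ndarray) -> np.ndarray:
    """Reversible chain with stationary ``pi`` from a symmetric proposal.

    Off-diagonal ``A[i, j] = Q[i, j] * min(1, pi[j] / pi[i])``; the diagonal
    absorbs the remainder. Requires ``Q`` symmetric with zero diagonal and
    row sums <= 1 so the diagonal stays nonnegative.
    """
    pi = np.asarray(pi, float)
    q = np.asarray(proposal, float)
    if not np.allclose(q, q.T, atol=1e-12):
        raise InvalidPerturbationError("proposal must be symmetric")
    ratio = np.minimum(1.0, pi[None, :] / np.maximum(pi[:, None], 1e-300))
    a = q * ratio
    np.fill_diagonal(a, 0.0)
    diag = 1.0 - a.sum(axis=1)
    if (diag < -1e-12).any():
        raise InvalidPerturbationError("proposal row sums too large for a valid chain")
    a[np.diag_indices_from(a)] = np.clip(diag, 0.0, 1.0)
    return a


def _symmetric_proposal(
    g: int,
    mobility: float,
    rng: np.random.Generator,
    concentration: float = 0.0,
    row_spread: float = 0.0,
) -> np.ndarray:
    """Random symmetric proposal with zero diagonal and controlled row sums.

    ``concentration > 0`` draws log-normal edge weights (``exp(c * Z)``),
    concentrating the transition mass on few edges. ``row_spread > 0``
    additionally draws log-normal per-state mobility targets around
    ``mobility`` (clipped to a well-mixing range), so states differ in how
    quickly they are left — a pure transition-pattern change, since a
    reversible chain with a symmetric edge matrix keeps its stationary law
    whatever the row sums. The weights are symmetrically (Sinkhorn)
    balanced to the target row sums.
    """
    if concentration > 0:
        w = np.exp(concentration * rng.standard_normal((g, g)))
    else:
        w = rng.uniform(0.2, 1.0, size=(g, g))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if row_spread > 0:
        targets = mobility * np.exp(row_spread * rng.standard_normal(g))
        targets = np.clip(targets, 0.25 * mobility, min(0.6, 3.5 * mobility))
    else:
        targets = np.full(g, mobility)
    for _ in range(500):
        scale = np.sqrt(targets / w.sum(axis=1))
        w = w * scale[:, None] * scale[None, :]
        if np.abs(w.sum(axis=1) - targets).max() < 1e-12 * mobility:
            break
    return w * min(1.0, 0.999 / w.sum(axis=1).max())


def _ring_proposal(
    g: int, mobility: float, rng: np.random.Generator, strength: float = 1.0
) -> np.ndarray:
    """Symmetric proposal interpolating from uniform to a relabeled ring.

    At ``strength = 1`` the whole off-diagonal mass sits on a cycle through
    the states in a random order; every row still sums to ``mobility``.
    Against a uniform-off-diagonal base chain, the distance of the
    resulting transition law from the base is the same for every
    relabeling, giving rewired strains a reproducible effect size.
    """
    if g < 3:
        raise InvalidPerturbationError("retransition needs at least 3 states")
    perm = rng.permutation(g)
    ring = np.zeros((g, g))
    for i in range(g):
        a, b = perm[i], perm[(i + 1) % g]
        ring[a, b] += mobility / 2.0
        ring[b, a] += mobility / 2.0
    uniform = np.full((g, g), mobility / (g - 1))
    np.fill_diagonal(uniform, 0.0)
    w = float(np.clip(strength, 0.0, 1.0))
    return (1.0 - w) * uniform + w * ring


def _default_bout_matrix(g: int, stay: float = 0.9) -> np.ndarray:
    a = np.full((g, g), (1.0 - stay) / (g - 1))
    np.fill_diagonal(a, stay)
    return a


def _config_hash(config: SyntheticConfig) -> str:
    d = {
        k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
        for k, v in vars(config).items()
    }
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class _StrainParams:
    bout: np.ndarray
    lam: float
    sigma_act: float
    p_rest: float
    rest_exit: float


def _chain_power(a: np.ndarray, gamma: float) -> np.ndarray:
    """``gamma``-fold time compression of a Markov chain (``A^gamma``).

    Shares eigenvectors with ``A``, hence the stationary distribution is
    preserved exactly. Tiny negative entries from fractional powers are
    clipped and rows renormalized.
    """
    from scipy.linalg import fractional_matrix_power

    if abs(gamma - round(gamma)) < 1e-12:
        out = np.linalg.matrix_power(a, int(round(gamma)))
    else:
        out = np.real(fractional_matrix_power(a, gamma))
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    if np.abs(stationary_distribution(out) - stationary_distribution(a)).max() > 1e-8:
        raise InvalidPerturbationError("chain power failed to preserve the stationary law")
    return out


def _resolve_strain_params(
    config: SyntheticConfig,
    perts: Sequence[Perturbation],
    base_bout: np.ndarray,
    strain_index: int,
) -> _StrainParams:
    bout = base_bout
    lam = config.relaxation_rate
    sigma = config.active_noise
    p_rest = config.rest_entry_prob
    rest_exit = config.rest_exit_prob
    base_pi = stationary_distribution(base_bout)
    mobility0 = float(1.0 - np.diag(base_bout).mean())
    for p in perts:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0xBEEF, strain_index, p.salt))
        )
        if p.kind == "none":
            continue
        elif p.kind == "no_rest":
            p_rest = 0.0
        elif p.kind == "accelerate":
            gamma = config.speed_factor if p.gamma is None else p.gamma
            if gamma <= 0:
                raise InvalidPerturbationError("gamma must be > 0")
            # gamma-fold time compression: every per-frame process advances
            # gamma steps per frame; the stationary posture law is unchanged
            ar = 1.0 - lam
            ar_g = ar**gamma
            if ar < 1.0:
                sigma = sigma * np.sqrt((1.0 - ar_g**2) / (1.0 - ar**2))
            lam = 1.0 - ar_g
            bout = _chain_power(bout, gamma)
            rest_exit = 1.0 - (1.0 - rest_exit) ** gamma
        elif p.kind == "retransition":
            if p.matrix is not None:
                cand = np.asarray(p.matrix, float)
                pi_cand = stationary_distribution(cand)
                if np.abs(pi_cand - stationary_distribution(bout)).max() > 1e-8:
                    raise InvalidPerturbationError(
                        "replacement bout matrix changes the stationary distribution"
                    )
                bout = cand
            else:
                # rewire the off-diagonal onto a randomly relabeled ring:
                # every state keeps the same total exit rate (dwell times
                # matched) and the stationary occupancy is preserved, but
                # which states follow which changes with a magnitude that
                # is the same for every relabeling
                q = _ring_proposal(len(base_pi), mobility0, rng, p.strength)
                bout = metropolis_transition(stationary_distribution(bout), q)
        elif p.kind == "reweight":
            pi_new = base_pi * np.exp(p.strength * rng.standard_normal(len(base_pi)))
            pi_new /= pi_new.sum()
            q = _symmetric_proposal(len(base_pi), mobility0, rng)
            bout = metropolis_transition(pi_new, q)
    return _StrainParams(
        bout=bout, lam=lam, sigma_act=sigma, p_rest=p_rest, rest_exit=rest_exit
    )


def _ar_time_varying(a: np.ndarray, drive: np.ndarray, v0: np.ndarray) -> np.ndarray:
    """Solve ``v[t] = a[t] * v[t-1] + drive[t]`` with ``v[-1] = v0``.

    Vectorized via log-cumulative-products, chunked so the running product
    never underflows. ``a`` entries must be positive (an ``a`` of exactly 0
    is clamped to a negligible memory term).
    """
    f, d = drive.shape
    out = np.empty((f, d))
    log_a = np.log(np.maximum(a, 1e-12))
    # chunk so that the in-chunk product stays within ~e^-60
    worst = max(-float(log_a.min()), 1e-9)
    chunk = int(np.clip(60.0 / worst, 32, 1 << 16))
    v = v0
    for start in range(0, f, chunk):
        end = min(start + chunk, f)
        logp = np.cumsum(log_a[start:end])
        p = np.exp(logp)
        inv_p = np.exp(-logp)
        s = np.cumsum(drive[start:end] * inv_p[:, None], axis=0)
        seg = p[:, None] * (v[None, :] + s)
        out[start:end] = seg
        v = seg[-1]
    return out


@dataclass
class _ChainPlan:
    """Per-strain chain quantities precomputed for fast worm simulation."""

    pi: np.ndarray
    stay: np.ndarray  # diagonal of the bout matrix
    next_cum: np.ndarray  # (G, G) row-wise cumulative off-diagonal law


def _plan_chain(a_mat: np.ndarray) -> _ChainPlan:
    g = a_mat.shape[0]
    off = a_mat.copy()
    off[np.diag_indices(g)] = 0.0
    totals = off.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    cum = np.cumsum(off / safe, axis=1)
    # absorbing rows: "next" stays put
    for j in np.flatnonzero(totals.ravel() <= 0):
        cum[j] = (np.arange(g) >= j).astype(float)
    return _ChainPlan(pi=stationary_distribution(a_mat), stay=np.diag(a_mat).copy(),
                      next_cum=cum)


def _simulate_worm(
    f_total: int,
    params: _StrainParams,
    plan: _ChainPlan,
    means: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    d = means.shape[1]
    lam, sig = params.lam, params.sigma_act
    ar = 1.0 - lam
    g = int(np.searchsorted(np.cumsum(plan.pi), rng.random()))
    # segment plan: (is_rest, attractor, length)
    segments: list[tuple[bool, int, int]] = []
    t = 0
    while t < f_total:
        stay = plan.stay[g]
        length = f_total - t if stay >= 1.0 else min(int(rng.geometric(1.0 - stay)), f_total - t)
        segments.append((False, g, length))
        t += length
        if t >= f_total:
            break
        g_next = int(np.searchsorted(plan.next_cum[g], rng.random()))
        if params.p_rest > 0 and rng.random() < params.p_rest:
            rest_len = min(int(rng.geometric(params.rest_exit)), f_total - t)
            segments.append((True, g, rest_len))
            t += rest_len
        g = g_next

    a_arr = np.empty(f_total)
    pull = np.empty((f_total, d))
    sigma = np.empty(f_total)
    pos = 0
    for is_rest, g_seg, length in segments:
        sl = slice(pos, pos + length)
        if is_rest:
            a_arr[sl] = 1.0
            pull[sl] = 0.0
            sigma[sl] = config.rest_noise
        else:
            a_arr[sl] = ar
            pull[sl] = lam * means[g_seg]
            sigma[sl] = sig
        pos += length

    drive = pull + sigma[:, None] * rng.standard_normal((f_total, d))
    g0 = segments[0][1]
    stat_sd = sig / np.sqrt(max(1.0 - ar * ar, lam)) if lam < 1 else sig
    v0 = means[g0] + stat_sd * rng.standard_normal(d)
    return _ar_time_varying(a_arr, drive, v0)


def simulate_strains(
    config: SyntheticConfig,
    perturbations: Mapping[str, Perturbation | Sequence[Perturbation]] | None = None,
    strain_names: Sequence[str] | None = None,
    basis: EigenwormBasis | None = None,
) -> StrainCollection:
    """Generate a :class:`StrainCollection` under ``config``.

    ``perturbations`` maps strain name -> a :class:`Perturbation` or a
    sequence of them (applied in order). Strains not listed are generated
    with the base (wild-type) parameters. The first strain is named ``N2``
    by default and serves as the conventional reference downstream.

    Reproducible: a single seed sequence is derived from ``config.seed`` and
    per-worm substreams from (strain index, worm index), so the same config
    and seed give bit-identical collections.
    """
    config.validate()
    g = config.n_attractors
    coll_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xC011,)))
    if config.attractor_means is None:
        spread = (
            config.attractor_spread
            if config.attractor_spread is not None
            else 5.0 * config.active_noise
        )
        means = coll_rng.standard_normal((g, 4)) * spread
    else:
        means = np.asarray(config.attractor_means, float)
        if means.shape != (g, 4):
            raise InvalidParameterError("attractor_means must be (n_attractors, 4)")
    base_bout = (
        _default_bout_matrix(g)
        if config.bout_transition is None
        else np.asarray(config.bout_transition, float)
    )

    if strain_names is None:
        strain_names = ["N2"] + [f"MT{i:03d}" for i in range(1, config.n_strains)]
    if len(strain_names) != config.n_strains:
        raise InvalidParameterError("strain_names length must equal n_strains")
    perturbations = dict(perturbations or {})
    unknown = set(perturbations) - set(strain_names)
    if unknown:
        raise InvalidParameterError(f"perturbations for unknown strains: {sorted(unknown)}")

    strains: dict[str, list[EigenwormSeries]] = {}
    strain_meta: dict[str, dict] = {}
    f_total = config.frames_per_worm
    for s_idx, name in enumerate(strain_names):
        perts = perturbations.get(name, Perturbation())
        if isinstance(perts, Perturbation):
            perts = (perts,)
        params = _resolve_strain_params(config, perts, base_bout, s_idx)
        plan = _plan_chain(params.bout)
        series_list = []
        for w_idx in range(config.worms_per_strain):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(s_idx, w_idx))
            )
            frames = _simulate_worm(f_total, params, plan, means, config, rng)
            gap_mask = np.zeros(f_total, dtype=bool)
            if config.gap_fraction > 0 and f_total > 2:
                n_gaps = int(round(config.gap_fraction * (f_total - 2)))
                # interior frames only: interpolation needs both flanks
                idx = rng.choice(np.arange(1, f_total - 1), size=n_gaps, replace=False)
                gap_mask[idx] = True
                frames = frames.copy()
                frames[gap_mask] = np.nan
            series_list.append(
                EigenwormSeries(
                    strain_id=name,
                    worm_id=f"{name}_w{w_idx:03d}",
                    fps=config.fps,
                    frames=frames,
                    gap_mask=gap_mask,
                )
            )
        strains[name] = series_list
        strain_meta[name] = {
            "perturbations": [p.kind for p in perts],
            "stationary": stationary_distribution(params.bout).tolist(),
            "p_rest": params.p_rest,
            "lam": params.lam,
            "sigma_act": params.sigma_act,
        }

    if basis is None:
        basis = make_basis(48, 4, seed=config.seed)
    return StrainCollection(
        strains=strains,
        basis=basis,
        metadata={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "attractor_means": means.tolist(),
            "base_bout_transition": base_bout.tolist(),
            "strain_params": strain_meta,
        },
    )


# ---------------------------------------------------------------------------
# persistence


def save_basis(basis: EigenwormBasis, path: str | Path) -> None:
    """Store a basis as JSON (row-major coefficient array)."""
    payload = {
        "n_angles": basis.n_angles,
        "dims": basis.dims,
        "matrix": basis.matrix.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_basis(path: str | Path) -> EigenwormBasis:
    payload = json.loads(Path(path).read_text())
    return EigenwormBasis(matrix=np.asarray(payload["matrix"], float))


def save_collection(collection: StrainCollection, directory: str | Path,
                    config: SyntheticConfig | None = None) -> None:
    """Write a collection as dataset CSV + YAML provenance + basis JSON."""
    from . import ingest  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ingest.write_dataset(collection, directory / "dataset.csv")
    prov = dict(collection.metadata)
    if config is not None:
        prov["config"] = {
            k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(config).items()
        }
    (directory / "provenance.yaml").write_text(yaml.safe_dump(prov))
    if collection.basis is not None:
        save_basis(collection.basis, directory / "basis.json")
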
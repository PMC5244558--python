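"""Occurrence/transition statistics and divergence tests.

A worm's *relative state occurrence frequency* is the time average of its
responsibility rows, ``r_i = (1/F) sum_f r_{i,f}`` — a distribution over
postural states. Its *relative transition frequency* is the average outer
product of consecutive responsibility rows,
``T_{i,k,l} = (1/(F-1)) sum_f r_{i,f,k} r_{i,f+1,l}`` — a joint
distribution over state pairs at adjacent frames. Distributions are
compared with the Jensen-Shannon divergence (natural log; bounded by
ln 2). Intra- vs inter-strain similarity of occurrence vectors is tested
per strain with a one-sided Wilcoxon-Mann-Whitney test and
Benjamini-Hochberg correction across strains; strain aggregates are
compared against a reference strain (conventionally N2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptySelectionError,
    InvalidDistributionError,
    InvalidInputError,
    ModelMismatchError,
    SamplingError,
    TooShortError,
)

__all__ = [
    "OccurrenceVector",
    "TransitionMatrix",
    "WormDivergencePair",
    "DivergenceRecord",
    "occurrence",
    "transitions",
    "jsd",
    "intra_inter_divergence",
    "wmw_one_sided",
    "bh_adjust",
    "strain_separation_test",
    "aggregate_strain",
    "divergence_from_reference",
]

LN2 = float(np.log(2.0))
_SIMPLEX_ATOL = 1e-9


@dataclass
class OccurrenceVector:
    """Distribution over postural states for one worm or strain."""

    values: np.ndarray
    owner: str

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def K(self) -> int:
        return len(self.values)


@dataclass
class TransitionMatrix:
    """Joint distribution over (state at f, state at f+1) for one worm or strain."""

    values: np.ndarray  # (K, K), grand total 1
    owner: str

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def K(self) -> int:
        return self.values.shape[0]


@dataclass
class WormDivergencePair:
    """Mean within- vs between-strain occurrence divergences for one worm."""

    worm_id: str
    strain_id: str
    delta_intra: float
    delta_inter: float
    n_peers: int  # |S_i| = |S_bar_i|


@dataclass
class DivergenceRecord:
    """A strain's occurrence/transition divergences from the reference."""

    strain_id: str
    delta_r: float
    delta_T: float
    z: float | None = None
    q: float | None = None


def _assert_simplex(v: np.ndarray, what: str) -> None:
    if (v < -1e-12).any():
        raise InvalidDistributionError(f"{what} has negative entries")
    total = float(v.sum())
    if abs(total - 1.0) > _SIMPLEX_ATOL:
        raise InvalidDistributionError(f"{what} sums to {total}, expected 1")


def occurrence(resp, frame_mask: np.ndarray | None = None) -> OccurrenceVector:
    """Time-averaged responsibilities of one worm: ``r_i = mean_f r_{i,f}``.

    ``frame_mask`` restricts the average to selected frames (used, e.g., to
    compare occupancy on slow vs fast frames).
    """
    values = np.asarray(getattr(resp, "values", resp), float)
    owner = getattr(resp, "worm_id", "")
    if frame_mask is not None:
        frame_mask = np.asarray(frame_mask, bool)
        if frame_mask.shape != (len(values),):
            raise InvalidInputError("frame_mask length must match F")
        if not frame_mask.any():
            raise EmptySelectionError("frame mask selects no frames")
        values = values[frame_mask]
    if len(values) < 1:
        raise TooShortError("need at least one frame")
    r = values.mean(axis=0)
    _assert_simplex(r, "occurrence vector")
    return OccurrenceVector(values=r, owner=owner)


def transitions(resp) -> TransitionMatrix:
    """Mean outer product of consecutive responsibility rows."""
    values = np.asarray(getattr(resp, "values", resp), float)
    owner = getattr(resp, "worm_id", "")
    f = len(values)
    if f < 2:
        raise TooShortError("need at least two frames for transitions")
    t = values[:-1].T @ values[1:] / (f - 1)
    _assert_simplex(t.ravel(), "transition matrix")
    return TransitionMatrix(values=t, owner=owner)


def _jsd_raw(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def jsd(p, q) -> float:
    """Jensen-Shannon divergence in natural-log units (``0 <= jsd <= ln 2``).

    Accepts vectors or matrices (matrices are flattened); both arguments
    must be on the simplex. ``0 * log 0`` is taken as 0.
    """
    p = np.asarray(p, float).ravel()
    q = np.asarray(q, float).ravel()
    if p.shape != q.shape:
        raise InvalidDistributionError("distributions must have the same shape")
    if (p < 0).any() or (q < 0).any():
        raise InvalidDistributionError("negative entries are not a distribution")
    _assert_simplex(p, "p")
    _assert_simplex(q, "q")
    return min(_jsd_raw(p, q), LN2)


def intra_inter_divergence(
    occurrences: Mapping[str, "OccurrenceVector | np.ndarray"],
    strains: Mapping[str, str],
    seed: int = 0,
) -> list[WormDivergencePair]:
    """Within- vs between-strain occurrence divergences per worm.

    For each worm ``i``: ``S_i`` is every same-strain worm but ``i``;
    ``S_bar_i`` is a seeded uniform sample (without replacement) of
    other-strain worms of the same size. The returned deltas are the mean
    pairwise JSDs of occurrence vectors against each set.
    """
    ids = list(occurrences)
    vecs = {w: np.asarray(occurrences[w], float) for w in ids}
    by_strain: dict[str, list[str]] = {}
    for w in ids:
        by_strain.setdefault(strains[w], []).append(w)
    rng = np.random.default_rng(seed)
    out: list[WormDivergencePair] = []
    for w in ids:
        strain = strains[w]
        peers = [x for x in by_strain[strain] if x != w]
        if not peers:
            raise SamplingError(f"strain {strain!r} has a single worm")
        others = [x for x in ids if strains[x] != strain]
        if len(others) < len(peers):
            raise SamplingError(
                f"not enough other-strain worms to match |S_i|={len(peers)}"
            )
        pick = rng.choice(len(others), size=len(peers), replace=False)
        d_intra = float(np.mean([_jsd_raw(vecs[w], vecs[j]) for j in peers]))
        d_inter = float(np.mean([_jsd_raw(vecs[w], vecs[others[j]]) for j in pick]))
        out.append(
            WormDivergencePair(
                worm_id=w,
                strain_id=strain,
                delta_intra=d_intra,
                delta_inter=d_inter,
                n_peers=len(peers),
            )
        )
    return out


# ---------------------------------------------------------------------------
# tests


@lru_cache(maxsize=64)
def _rank_combinations(n: int, m: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n + m), n)), dtype=int)


def wmw_one_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided Wilcoxon-Mann-Whitney p (alternative: x stochastically < y).

    Exact by enumeration over rank assignments when ``len(x) + len(y) <= 12``
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and no_ties:
        ranks = pooled.argsort().argsort() + 1  # no ties -> ordinal ranks
        w_obs = ranks[: len(x)].sum()
        combos = _rank_combinations(len(x), len(y))
        w_all = (combos + 1).sum(axis=1)
        return float((w_all <= w_obs).mean())
    return float(mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, in the input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def strain_separation_test(
    pairs: Sequence[WormDivergencePair], q_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-strain test that within-strain divergences are smaller.

    For each strain, the one-sided WMW test compares its worms'
    ``delta_intra`` values against their ``delta_inter`` values; BH
    correction runs across strains. Returns a DataFrame
    ``strain, p, q, significant`` (significant = q < ``q_threshold``).
    """
    by_strain: dict[str, list[WormDivergencePair]] = {}
    for pair in pairs:
        by_strain.setdefault(pair.strain_id, []).append(pair)
    names, pvals = [], []
    for strain, plist in by_strain.items():
        if len(plist) < 2:
            raise InvalidInputError(f"strain {strain!r} has fewer than 2 divergence pairs")
        names.append(strain)
        pvals.append(
            wmw_one_sided([p.delta_intra for p in plist], [p.delta_inter for p in plist])
        )
    q = bh_adjust(pvals)
    return pd.DataFrame(
        {"strain": names, "p": pvals, "q": q, "significant": q < q_threshold}
    )


# ---------------------------------------------------------------------------
# strain aggregates and reference divergences


def aggregate_strain(
    occs: Sequence["OccurrenceVector | np.ndarray"],
    trans: Sequence["TransitionMatrix | np.ndarray"],
    strain_id: str,
) -> tuple[OccurrenceVector, TransitionMatrix]:
    """Unweighted mean of per-worm occurrence vectors and transition matrices."""
    if len(occs) < 1 or len(trans) < 1:
        raise InvalidInputError("need at least one worm to aggregate")
    r = np.mean([np.asarray(o, float) for o in occs], axis=0)
    t = np.mean([np.asarray(m, float) for m in trans], axis=0)
    if abs(r.sum() - 1.0) > 1e-12:
        r = r / r.sum()
    if abs(t.sum() - 1.0) > 1e-12:
        t = t / t.sum()
    _assert_simplex(r, "strain occurrence")
    _assert_simplex(t.ravel(), "strain transitions")
    return OccurrenceVector(values=r, owner=strain_id), TransitionMatrix(values=t, owner=strain_id)


def divergence_from_reference(
    aggregates: Mapping[str, tuple[OccurrenceVector, TransitionMatrix]],
    reference: str,
) -> list[DivergenceRecord]:
    """JSD of each strain's (r_S, T_S) from the reference strain's.

    Returns one :class:`DivergenceRecord` per non-reference strain, with z
    and q left unset (filled by the atypicality screen).
    """
    if reference not in aggregates:
        raise InvalidInputError(f"reference strain {reference!r} not in aggregates")
    r_ref, t_ref = aggregates[reference]
    k = np.asarray(r_ref).shape[0]
    out = []
    for strain, (r_s, t_s) in aggregates.items():
        if strain == reference:
            continue
        if np.asarray(r_s).shape[0] != k or np.asarray(t_s).shape != (k, k):
            raise ModelMismatchError(
                f"strain {strain!r} was binned with a different state model"
            )
        out.append(
            DivergenceRecord(
                strain_id=strain,
                delta_r=jsd(r_s, r_ref),
                delta_T=jsd(np.asarray(t_s).ravel(), np.asarray(t_ref).ravel()),
            )
        )
    return out
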
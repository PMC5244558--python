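"""Reference workflows tying the modules into end-to-end analyses.

These helpers run the standard study on a collection: bin every frame with
one shared postural-state model, compute per-worm occurrence vectors and
transition matrices, aggregate per strain, test within- vs between-strain
similarity, screen for atypical transition patterns against a reference
strain, and dissect a flagged strain with artificial-reference transforms.
They are the building blocks used by the acceptance script and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior_stats as bs
from . import binning
from .atypicality import RegressionModel, detect_atypical, regress_z
from .behavior_stats import DivergenceRecord, OccurrenceVector, TransitionMatrix
from .collection import StrainCollection
from .factor_dissection import evaluate_reproduction, fit_artificial_params

__all__ = [
    "BinnedCollection",
    "bin_collection",
    "strain_aggregates",
    "separation_counts",
    "ScreenResult",
    "atypicality_screen",
    "dissect_strain",
]


@dataclass
class BinnedCollection:
    """A fitted state model plus per-worm occurrence/transition summaries."""

    model: binning.PostureStateModel
    occurrences: dict[str, OccurrenceVector]  # worm_id -> r_i
    transition_mats: dict[str, TransitionMatrix]  # worm_id -> T_i
    strain_of: dict[str, str]


def bin_collection(
    collection: StrainCollection,
    method: str = "gmm",
    eps: float = 0.01,
    k_init: int = 20,
    k: int | None = None,
    sample_fraction: float = 0.01,
    seed: int = 0,
) -> BinnedCollection:
    """Fit one postural-state model on sampled frames and bin every worm."""
    points = binning.sample_frames(collection, fraction=sample_fraction, seed=seed)
    if method == "gmm":
        model = binning.fit_fab_gmm(points, eps=eps, k_init=k_init, seed=seed)
    elif method == "kmeans":
        model = binning.fit_kmeans(points, k=k if k is not None else k_init, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    occs: dict[str, OccurrenceVector] = {}
    trans: dict[str, TransitionMatrix] = {}
    for series in collection.worms():
        resp = binning.responsibilities(model, series)
        occs[series.worm_id] = bs.occurrence(resp)
        trans[series.worm_id] = bs.transitions(resp)
    return BinnedCollection(
        model=model,
        occurrences=occs,
        transition_mats=trans,
        strain_of=collection.strain_of(),
    )


def strain_aggregates(binned: BinnedCollection) -> dict[str, tuple[OccurrenceVector, TransitionMatrix]]:
    by_strain: dict[str, list[str]] = {}
    for worm, strain in binned.strain_of.items():
        by_strain.setdefault(strain, []).append(worm)
    return {
        strain: bs.aggregate_strain(
            [binned.occurrences[w] for w in worms],
            [binned.transition_mats[w] for w in worms],
            strain,
        )
        for strain, worms in by_strain.items()
    }


def separation_counts(binned: BinnedCollection, seed: int = 0) -> pd.DataFrame:
    """Within- vs between-strain separation test over all strains."""
    pairs = bs.intra_inter_divergence(binned.occurrences, binned.strain_of, seed=seed)
    return bs.strain_separation_test(pairs)


@dataclass
class ScreenResult:
    """Output of the atypicality screen on one collection."""

    binned: BinnedCollection
    regression: RegressionModel
    records: list[DivergenceRecord]  # with z filled
    table: pd.DataFrame  # detect_atypical output


def atypicality_screen(
    collection: StrainCollection,
    reference: str = "N2",
    method: str = "gmm",
    eps: float = 0.01,
    k_init: int = 20,
    sample_fraction: float = 0.01,
    seed: int = 0,
    binned: BinnedCollection | None = None,
) -> ScreenResult:
    """Full screen: bin, aggregate, diverge from reference, regress, flag."""
    if binned is None:
        binned = bin_collection(
            collection,
            method=method,
            eps=eps,
            k_init=k_init,
            sample_fraction=sample_fraction,
            seed=seed,
        )
    aggregates = strain_aggregates(binned)
    records = bs.divergence_from_reference(aggregates, reference)
    regression, records = regress_z(records)
    table = detect_atypical(records)
    return ScreenResult(binned=binned, regression=regression, records=records, table=table)


def dissect_strain(
    collection: StrainCollection,
    screen: ScreenResult,
    strain: str,
    reference: str = "N2",
    include_identity: bool = False,
):
    """Artificial-reference dissection of one strain after a screen."""
    params, artificial = fit_artificial_params(
        collection.strains[reference],
        collection.strains[strain],
        include_identity=include_identity,
    )
    original_z = next(r.z for r in screen.records if r.strain_id == strain)
    return evaluate_reproduction(
        artificial,
        collection.strains[strain],
        screen.binned.model,
        screen.regression,
        params=params,
        original_z=original_z,
        strain_id=strain,
    )
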
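"""Dataset I/O, quality control, gap interpolation, and downsampling.

The pipeline order is fixed: QC -> gap interpolation -> downsampling. QC
drops individuals whose recording length is outside [890, 910] seconds
(inclusive) or whose eigenworm vectors are missing in more than 40% of the
raw frames, then drops strains left with fewer than five individuals. Gaps
are filled by per-dimension linear interpolation between the two nearest
observed flanking frames; leading/trailing gaps are trimmed because they
have only one flank. All series are then decimated to a common 5 fps.

Dataset CSV dialect: header ``strain,worm_id,frame_index,time_s,e1,e2,e3,e4``,
UTF-8, missing amplitudes as empty fields, 0-based contiguous frame_index.
A minimal WCON (JSON) import is supported for interchange.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .collection import EigenwormSeries, StrainCollection
from .errors import (
    CannotInterpolateError,
    FormatError,
    UpsamplingError,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "qc_filter",
    "interpolate_gaps",
    "downsample",
    "preprocess",
]

_COLUMNS = ["strain", "worm_id", "frame_index", "time_s", "e1", "e2", "e3", "e4"]
_EDIMS = ["e1", "e2", "e3", "e4"]


def write_dataset(collection: StrainCollection, path: str | Path) -> None:
    """Write a collection in the dataset CSV dialect (gaps as empty fields)."""
    chunks = []
    for series in collection.worms():
        f = series.n_frames
        df = pd.DataFrame(series.frames, columns=_EDIMS)
        df.loc[series.gap_mask, _EDIMS] = np.nan
        df.insert(0, "time_s", np.arange(f) / series.fps)
        df.insert(0, "frame_index", np.arange(f))
        df.insert(0, "worm_id", series.worm_id)
        df.insert(0, "strain", series.strain_id)
        chunks.append(df)
    # %.17g keeps float64 round-trips bit-exact
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def _series_from_frame(df: pd.DataFrame) -> EigenwormSeries:
    worm_id = df["worm_id"].iloc[0]
    strain = df["strain"].iloc[0]
    if df["frame_index"].duplicated().any():
        raise FormatError(f"duplicate (worm_id, frame_index) for worm {worm_id!r}")
    df = df.sort_values("frame_index", kind="stable")
    t = df["time_s"].to_numpy(float)
    observed = np.isfinite(t)
    if (np.diff(t[observed]) <= 0).any():
        raise FormatError(f"non-monotone time within worm {worm_id!r}")
    idx = df["frame_index"].to_numpy(int)
    lo, hi = idx.min(), idx.max()
    if lo != 0:
        raise FormatError(f"frame_index must start at 0 for worm {worm_id!r}")
    # infer fps from the median observed time step
    dt = np.diff(t[observed])
    if len(dt) == 0:
        raise FormatError(f"worm {worm_id!r} has fewer than 2 timed frames")
    fps = 1.0 / float(np.median(dt))
    # reindex to a contiguous frame range; absent rows become gaps
    full = np.full((hi + 1, 4), np.nan)
    full[idx] = df[_EDIMS].to_numpy(float)
    gap = ~np.isfinite(full).all(axis=1)
    return EigenwormSeries(
        strain_id=strain, worm_id=worm_id, fps=fps, frames=full, gap_mask=gap
    )


def read_dataset(path: str | Path, format: str = "csv") -> StrainCollection:
    """Read a dataset into a :class:`StrainCollection`.

    ``format='csv'`` reads the dataset dialect; ``format='wcon-min'`` reads
    a minimal WCON JSON file where each ``data[i]`` entry carries ``id``,
    ``t`` (seconds) and an ``@eigenworm`` block with ``strain`` and a
    per-frame 4-column ``e`` array (nulls = gaps). Any other WCON content
    is ignored.
    """
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"missing columns: {sorted(missing)}")
        strains: dict[str, list[EigenwormSeries]] = {}
        for _, group in df.groupby("worm_id", sort=False):
            series = _series_from_frame(group)
            strains.setdefault(series.strain_id, []).append(series)
        return StrainCollection(strains=strains)
    if format == "wcon-min":
        return _read_wcon_min(path)
    raise FormatError(f"unknown format {format!r}")


def _read_wcon_min(path: str | Path) -> StrainCollection:
    payload = json.loads(Path(path).read_text())
    if "data" not in payload:
        raise FormatError("WCON file has no 'data' array")
    strains: dict[str, list[EigenwormSeries]] = {}
    for entry in payload["data"]:
        worm_id = str(entry["id"])
        block = entry.get("@eigenworm")
        if block is None:
            raise FormatError(f"worm {worm_id!r} lacks an @eigenworm block")
        strain = str(block.get("strain", "unknown"))
        t = np.asarray(entry["t"], float)
        if len(t) < 2:
            raise FormatError(f"worm {worm_id!r} has fewer than 2 frames")
        if (np.diff(t) <= 0).any():
            raise FormatError(f"non-monotone time within worm {worm_id!r}")
        frames = np.array(
            [[np.nan if x is None else float(x) for x in row] for row in block["e"]],
            dtype=float,
        )
        if frames.shape != (len(t), 4):
            raise FormatError(f"worm {worm_id!r}: e block shape mismatch")
        fps = 1.0 / float(np.median(np.diff(t)))
        gap = ~np.isfinite(frames).all(axis=1)
        strains.setdefault(strain, []).append(
            EigenwormSeries(strain_id=strain, worm_id=worm_id, fps=fps,
                            frames=frames, gap_mask=gap)
        )
    return StrainCollection(strains=strains)


def qc_filter(
    collection: StrainCollection,
    min_duration_s: float = 890.0,
    max_duration_s: float = 910.0,
    max_gap_fraction: float = 0.4,
    min_worms_per_strain: int = 5,
) -> tuple[StrainCollection, pd.DataFrame]:
    """Apply quality control and return (filtered collection, exclusion report).

    Rules, in order: ``duration`` (closed interval, raw ``F/fps``),
    ``gap_fraction`` (strict ``>`` on the raw frame count), then
    ``strain_size`` on the survivors. The report has one row per excluded
    worm: ``worm_id, strain, rule, value``.
    """
    import warnings

    records = []
    surviving: dict[str, list[EigenwormSeries]] = {}
    for series in collection.worms():
        dur = series.duration_s
        if not (min_duration_s <= dur <= max_duration_s):
            records.append((series.worm_id, series.strain_id, "duration", dur))
            continue
        gf = series.gap_fraction
        if gf > max_gap_fraction:
            records.append((series.worm_id, series.strain_id, "gap_fraction", gf))
            continue
        surviving.setdefault(series.strain_id, []).append(series)
    kept: dict[str, list[EigenwormSeries]] = {}
    for strain, worms in surviving.items():
        if len(worms) < min_worms_per_strain:
            records.extend(
                (w.worm_id, strain, "strain_size", float(len(worms))) for w in worms
            )
        else:
            kept[strain] = worms
    if not kept:
        warnings.warn("QC excluded every worm", stacklevel=2)
    report = pd.DataFrame(records, columns=["worm_id", "strain", "rule", "value"])
    return (
        StrainCollection(strains=kept, basis=collection.basis,
                         metadata=dict(collection.metadata)),
        report,
    )


def interpolate_gaps(series: EigenwormSeries) -> EigenwormSeries:
    """Fill interior gaps linearly; trim leading/trailing gaps.

    Observed frames are left bit-identical; each interior run of missing
    frames is replaced by the straight line between its two observed
    flanking frames, per dimension. The (trimmed) gap mask is preserved as
    provenance on the result.
    """
    mask = series.gap_mask
    if mask.all():
        raise CannotInterpolateError(f"worm {series.worm_id!r}: every frame is missing")
    if not mask.any():
        return series.copy()
    obs = np.flatnonzero(~mask)
    lo, hi = obs[0], obs[-1]
    frames = series.frames[lo : hi + 1].copy()
    mask = mask[lo : hi + 1]
    inner_obs = np.flatnonzero(~mask)
    inner_gap = np.flatnonzero(mask)
    if inner_gap.size:
        for d in range(frames.shape[1]):
            frames[inner_gap, d] = np.interp(inner_gap, inner_obs, frames[inner_obs, d])
    return EigenwormSeries(
        strain_id=series.strain_id,
        worm_id=series.worm_id,
        fps=series.fps,
        frames=frames,
        gap_mask=mask.copy(),
    )


def downsample(series: EigenwormSeries, target_fps: float = 5.0) -> EigenwormSeries:
    """Decimate to ``target_fps`` by nearest-source-frame selection.

    For an integer rate ratio this keeps frames ``0, rho, 2*rho, ...``;
    otherwise each target time ``j / target_fps`` takes the nearest source
    frame, ties resolved to the earlier frame. Frames are selected, never
    interpolated, so postural change speeds are not smoothed.
    """
    fps = series.fps
    if fps < target_fps - 1e-9:
        raise UpsamplingError(
            f"cannot upsample worm {series.worm_id!r} from {fps} to {target_fps} fps"
        )
    if abs(fps - target_fps) <= 1e-9:
        return series.copy()
    f = series.n_frames
    n_out = int(np.floor((f - 1) * target_fps / fps)) + 1
    j = np.arange(n_out)
    idx = np.ceil(j * (fps / target_fps) - 0.5).astype(int)
    idx = np.clip(idx, 0, f - 1)
    return EigenwormSeries(
        strain_id=series.strain_id,
        worm_id=series.worm_id,
        fps=target_fps,
        frames=series.frames[idx].copy(),
        gap_mask=series.gap_mask[idx].copy(),
    )


def preprocess(
    collection: StrainCollection,
    target_fps: float = 5.0,
    **qc_kwargs,
) -> tuple[StrainCollection, pd.DataFrame]:
    """Full preparation pipeline: QC -> interpolate gaps -> downsample."""
    filtered, report = qc_filter(collection, **qc_kwargs)
    strains = {
        strain: [downsample(interpolate_gaps(w), target_fps) for w in worms]
        for strain, worms in filtered.strains.items()
    }
    return (
        StrainCollection(strains=strains, basis=filtered.basis,
                         metadata=dict(filtered.metadata)),
        report,
    )
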
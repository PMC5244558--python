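"""Core containers: a single worm's eigenworm series and a strain collection.

An :class:`EigenwormSeries` holds one individual's time-ordered posture
amplitudes — an ``(F, 4)`` array of eigenworm coefficients at a fixed frame
rate — together with a boolean gap mask marking frames whose posture was
missing in the source data (tracking failures). A :class:`StrainCollection`
groups series by strain label and carries the shared eigenworm basis and
provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["EigenwormSeries", "StrainCollection"]


@dataclass
class EigenwormSeries:
    """Time-ordered eigenworm vectors for one individual worm.

    Parameters
    ----------
    strain_id, worm_id
        Labels; ``worm_id`` is unique within a collection.
    fps
        Frame rate in frames per second. Frame ``f`` corresponds to time
        ``f / fps`` seconds.
    frames
        ``(F, d)`` float array of eigenworm amplitudes (dimensionless).
        Rows flagged in ``gap_mask`` may be non-finite before interpolation.
    gap_mask
        ``(F,)`` boolean array; ``True`` marks a frame whose eigenworm
        vector was missing in the raw data.
    """

    strain_id: str
    worm_id: str
    fps: float
    frames: np.ndarray
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D (F, d) array")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(len(self.frames), dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != (len(self.frames),):
            raise ValueError("gap_mask length must match number of frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        # observed (non-gap) frames must be finite
        observed = self.frames[~self.gap_mask]
        if observed.size and not np.isfinite(observed).all():
            raise ValueError("non-finite values outside gap frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_dims(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_s(self) -> float:
        """Recording length in seconds (``F / fps``)."""
        return self.n_frames / self.fps

    @property
    def gap_fraction(self) -> float:
        return float(self.gap_mask.mean()) if self.n_frames else 0.0

    def copy(self) -> "EigenwormSeries":
        return EigenwormSeries(
            strain_id=self.strain_id,
            worm_id=self.worm_id,
            fps=self.fps,
            frames=self.frames.copy(),
            gap_mask=self.gap_mask.copy(),
        )

    def replace(self, **kwargs) -> "EigenwormSeries":
        """Return a copy with selected fields replaced."""
        fields = dict(
            strain_id=self.strain_id,
            worm_id=self.worm_id,
            fps=self.fps,
            frames=self.frames,
            gap_mask=self.gap_mask,
        )
        fields.update(kwargs)
        return EigenwormSeries(**fields)


@dataclass
class StrainCollection:
    """Eigenworm series grouped by strain, plus shared basis and provenance.

    ``strains`` maps strain label -> list of :class:`EigenwormSeries`.
    ``metadata`` records how the collection was produced (generator config
    hash, seed, per-strain perturbations, ...).
    """

    strains: dict[str, list[EigenwormSeries]]
    basis: "object | None" = None  # EigenwormBasis; kept loose to avoid a cycle
    metadata: dict = field(default_factory=dict)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.strains)

    @property
    def n_worms(self) -> int:
        return sum(len(v) for v in self.strains.values())

    def worms(self) -> Iterator[EigenwormSeries]:
        for series_list in self.strains.values():
            yield from series_list

    def worm_map(self) -> dict[str, EigenwormSeries]:
        """Map worm_id -> series; worm ids must be unique."""
        out: dict[str, EigenwormSeries] = {}
        for s in self.worms():
            if s.worm_id in out:
                raise ValueError(f"duplicate worm_id {s.worm_id!r}")
            out[s.worm_id] = s
        return out

    def strain_of(self) -> dict[str, str]:
        """Map worm_id -> strain_id."""
        return {s.worm_id: s.strain_id for s in self.worms()}

    def subset(self, strain_ids) -> "StrainCollection":
        return StrainCollection(
            strains={k: list(self.strains[k]) for k in strain_ids},
            basis=self.basis,
            metadata=dict(self.metadata),
        )
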
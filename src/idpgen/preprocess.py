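"""Featurization of ensembles into flat normalized coordinate matrices.

Each frame's heavy-atom coordinates (an [N, 3] block) are flattened into a
length-3N vector, atom-major / axis-minor, and MinMax-normalized
per feature over the *training* frames:

    c_norm = (c - min(c)) / (max(c) - min(c))

The stored per-feature minima/maxima make the transform exactly
invertible, so generated normalized vectors can be mapped back to
Cartesian coordinates for analysis.  Values of test or generated data may
fall outside [0, 1]; they are deliberately not clipped, otherwise the
back-transform would no longer be exact.  Constant features (max == min)
normalize to 0 and invert to the stored constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError
from .trajectory_io import Ensemble

__all__ = [
    "ScalingParams",
    "FlatDataset",
    "flatten",
    "unflatten",
    "fit_minmax",
    "apply_minmax",
    "inverse_minmax",
    "chronological_split",
]


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature minima and maxima fitted on training data (immutable)."""

    feature_min: np.ndarray
    feature_max: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.feature_min, dtype=np.float64)
        hi = np.asarray(self.feature_max, dtype=np.float64)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise DataError("feature_min and feature_max must be 1-D of equal length")
        if np.any(hi < lo):
            raise DataError("feature_max must be >= feature_min")
        object.__setattr__(self, "feature_min", lo)
        object.__setattr__(self, "feature_max", hi)
        object.__setattr__(self, "_scale", hi - lo)

    @property
    def n_features(self) -> int:
        return self.feature_min.shape[0]

    @property
    def constant_mask(self) -> np.ndarray:
        """True for degenerate features where max == min."""
        return self._scale == 0  # type: ignore[attr-defined]


@dataclass(frozen=True)
class FlatDataset:
    """Normalized [n_frames, 3N] matrix tied to its scaling state.

    ``atom_index_map`` is an integer array of shape [3N, 2]: column j of
    the matrix corresponds to atom ``atom_index_map[j, 0]`` (index into the
    heavy-atom topology) along axis ``atom_index_map[j, 1]`` (0=x, 1=y, 2=z).
    """

    matrix: np.ndarray
    scaling: ScalingParams
    atom_index_map: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        amap = np.asarray(self.atom_index_map, dtype=np.int64)
        if m.ndim != 2:
            raise DataError("matrix must be 2-D [n_frames, 3N]")
        if m.shape[1] != self.scaling.n_features:
            raise DataError("matrix width does not match scaling parameters")
        if amap.shape != (m.shape[1], 2):
            raise DataError("atom_index_map must have shape [3N, 2]")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "atom_index_map", amap)

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def raw(self) -> np.ndarray:
        """The matrix back-transformed to Cartesian units (Angstrom)."""
        return inverse_minmax(self.matrix, self.scaling)

    def save(self, path) -> None:
        np.savez(
            Path(path),
            matrix=self.matrix,
            feature_min=self.scaling.feature_min,
            feature_max=self.scaling.feature_max,
            atom_index_map=self.atom_index_map,
        )

    @classmethod
    def load(cls, path) -> "FlatDataset":
        with np.load(Path(path)) as data:
            return cls(
                matrix=data["matrix"],
                scaling=ScalingParams(data["feature_min"], data["feature_max"]),
                atom_index_map=data["atom_index_map"],
            )


def flatten(ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Flatten heavy-atom coordinates into a raw [n_frames, 3N] matrix.

    Returns the matrix (Angstrom, not normalized) and the atom_index_map.
    Hydrogens are excluded; the ensemble should already be aligned so that
    coordinates are comparable across frames.
    """
    heavy = ensemble.topology.heavy_mask
    if not heavy.any():
        raise DataError("ensemble has no heavy atoms to flatten")
    coords = ensemble.coords[:, heavy, :]
    n_frames, n_heavy, _ = coords.shape
    matrix = coords.reshape(n_frames, 3 * n_heavy)
    atom_idx = np.repeat(np.arange(n_heavy), 3)
    axis_idx = np.tile(np.arange(3), n_heavy)
    return matrix, np.stack([atom_idx, axis_idx], axis=1)


def unflatten(matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten`: [n_frames, 3N] -> [n_frames, N, 3]."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] % 3 != 0:
        raise DataError("matrix width must be a multiple of 3")
    return matrix.reshape(matrix.shape[0], matrix.shape[1] // 3, 3)


def fit_minmax(matrix: np.ndarray) -> ScalingParams:
    """Fit per-feature minima/maxima over all rows of a raw matrix."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.size == 0:
        raise DataError("matrix must be a non-empty 2-D array")
    return ScalingParams(matrix.min(axis=0), matrix.max(axis=0))


def _check_width(matrix: np.ndarray, params: ScalingParams) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] != params.n_features:
        raise DataError(
            f"matrix width {matrix.shape[-1]} does not match scaling width {params.n_features}"
        )
    return matrix


def apply_minmax(matrix: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Normalize features to (c - min) / (max - min); constant features map to 0.

    Out-of-range inputs (test or generated data beyond the training
    envelope) produce values outside [0, 1] and are not clipped.
    """
    matrix = _check_width(matrix, params)
    scale = params.feature_max - params.feature_min
    safe = np.where(scale == 0, 1.0, scale)
    out = (matrix - params.feature_min) / safe
    out[:, params.constant_mask] = 0.0
    return out


def inverse_minmax(matrix: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Exact algebraic inverse of :func:`apply_minmax`.

    Constant features restore their stored constant regardless of the
    normalized value.
    """
    matrix = _check_width(matrix, params)
    scale = params.feature_max - params.feature_min
    out = matrix * scale + params.feature_min
    out[:, params.constant_mask] = params.feature_min[params.constant_mask]
    return out


def chronological_split(
    raw_matrix: np.ndarray,
    train_fraction: float,
    atom_index_map: np.ndarray | None = None,
) -> tuple[FlatDataset, FlatDataset]:
    """Split a raw (unnormalized) matrix chronologically and normalize.

    The first ``floor(train_fraction * n_frames)`` rows become the training
    set; the remainder, in order, the test set.  Scaling is fitted on the
    training rows only and shared with the test set, so test values may
    fall outside [0, 1].

    This mirrors how a short MD run is used to train a generator that is
    then judged against the longer tail of the trajectory: early frames
    are more extended and diverse, later frames more compact.
    """
    raw_matrix = np.asarray(raw_matrix, dtype=np.float64)
    if raw_matrix.ndim != 2:
        raise DataError("raw_matrix must be 2-D [n_frames, 3N]")
    if not 0.0 < train_fraction < 1.0:
        raise DataError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = raw_matrix.shape[0]
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1:
        raise DataError(
            f"train_fraction {train_fraction} yields an empty training set for {n} frames"
        )
    if atom_index_map is None:
        idx = np.arange(raw_matrix.shape[1])
        atom_index_map = np.stack([idx // 3, idx % 3], axis=1)
    params = fit_minmax(raw_matrix[:n_train])
    train = FlatDataset(apply_minmax(raw_matrix[:n_train], params), params, atom_index_map)
    test = FlatDataset(apply_minmax(raw_matrix[n_train:], params), params, atom_index_map)
    return train, test
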
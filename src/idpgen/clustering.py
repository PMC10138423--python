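"""Representative-structure selection by k-medoid clustering on RMSD.

Generated conformations are clustered on their all-against-all heavy-atom
RMSD matrix with a seeded PAM-style k-medoids (D-squared seeding, Voronoi
iteration: assign every frame to its nearest medoid, then move each
medoid to the member minimizing the summed within-cluster distance).  The
fitted (per-pair Kabsch-superposed) RMSD is the default distance, since
generated structures may drift in the global frame.

Representatives are the medoids of the three largest clusters at the
smallest k whose top-3 clusters jointly cover at least 80% of the frames.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .trajectory_io import Ensemble

__all__ = [
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "kcentroid_cluster",
    "select_representatives",
]


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of one k-medoids run on a distance matrix."""

    k: int
    medoid_indices: np.ndarray
    assignments: np.ndarray
    sizes: np.ndarray  # frames per cluster, descending
    top3_coverage: float
    objective: float  # summed distance of every frame to its medoid

    @property
    def n_frames(self) -> int:
        return len(self.assignments)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "k": self.k,
                    "medoid_indices": self.medoid_indices.tolist(),
                    "assignments": self.assignments.tolist(),
                    "sizes": self.sizes.tolist(),
                    "top3_coverage": self.top3_coverage,
                    "objective": self.objective,
                },
                fh,
                indent=2,
            )


def pairwise_rmsd_matrix(ensemble: Ensemble, fitted: bool = True) -> np.ndarray:
    """Symmetric all-against-all heavy-atom RMSD matrix (Angstrom).

    ``fitted=True`` superposes each pair (optimal proper rotation about
    their centroids) before measuring; both modes are fully vectorized.
    """
    ens = ensemble.heavy_subset()
    n = ens.n_frames
    if n < 2:
        raise DataError("pairwise RMSD needs at least 2 frames")
    a = ens.n_atoms
    x = ens.coords
    if not fitted:
        flat = x.reshape(n, -1)
        sq = np.sum(flat**2, axis=1)
        g = flat @ flat.T
        d2 = (sq[:, None] + sq[None, :] - 2 * g) / a
        np.fill_diagonal(d2, 0.0)
        return np.sqrt(np.maximum(d2, 0.0))

    xc = x - x.mean(axis=1, keepdims=True)
    ssd = np.sum(xc**2, axis=(1, 2))
    out = np.zeros((n, n))
    for i in range(n - 1):
        rest = xc[i + 1 :]
        h = np.einsum("ak,jal->jkl", xc[i], rest)  # [n-i-1, 3, 3] covariances
        _, s, _ = np.linalg.svd(h)
        sign = np.sign(np.linalg.det(h))
        sign[sign == 0] = 1.0
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        d2 = (ssd[i] + ssd[i + 1 :] - 2.0 * trace) / a
        out[i, i + 1 :] = np.sqrt(np.maximum(d2, 0.0))
    return out + out.T


def _check_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise DataError("distance matrix must be symmetric")
    if np.any(np.diag(m) != 0) or np.any(m < 0):
        raise DataError("distance matrix must be non-negative with zero diagonal")
    return m


def _assign(matrix: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # nearest medoid; ties broken toward the lowest cluster index (argmin)
    assign = np.argmin(matrix[:, medoids], axis=1)
    assign[medoids] = np.arange(len(medoids))  # each medoid anchors its own cluster
    return assign


def _seed_medoids(m: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """D-squared seeding: new medoids drawn proportional to squared distance."""
    n = m.shape[0]
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d2 = np.min(m[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total == 0:  # all remaining points coincide with a medoid
            choices = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(choices)))
        else:
            medoids.append(int(rng.choice(n, p=d2 / total)))
    return np.array(sorted(medoids))


def _voronoi_iterate(
    m: np.ndarray, medoids: np.ndarray, k: int, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    assign = _assign(m, medoids)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            within = m[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[np.argmin(within)]
        new_assign = _assign(m, new_medoids)
        if np.array_equal(new_assign, assign) and np.array_equal(new_medoids, medoids):
            break
        medoids, assign = new_medoids, new_assign
    return medoids, assign


def _objective(m: np.ndarray, medoids: np.ndarray, assign: np.ndarray) -> float:
    return float(m[np.arange(m.shape[0]), medoids[assign]].sum())


# below this many candidate medoid sets the partition is solved exactly
_EXHAUSTIVE_LIMIT = 3000


def kcentroid_cluster(
    matrix: np.ndarray, k: int, seed: int = 0, max_iter: int = 100, n_init: int = 8
) -> ClusterResult:
    """Seeded k-medoids partition of a distance matrix.

    Small instances (up to ~3000 candidate medoid sets) are solved
    exactly by enumeration.  Larger ones use D-squared seeding followed
    by Voronoi iteration (assign every frame to its nearest medoid, move
    each medoid to the member minimizing summed within-cluster distance,
    repeat until stable or ``max_iter``), restarted ``n_init`` times with
    the best objective kept; the objective never increases within a run.
    """
    m = _check_distance_matrix(matrix)
    n = m.shape[0]
    if not 1 <= k <= n:
        raise DataError(f"k must lie in [1, {n}], got {k}")

    if math.comb(n, k) <= _EXHAUSTIVE_LIMIT:
        best_obj = np.inf
        best: np.ndarray | None = None
        for combo in itertools.combinations(range(n), k):
            obj = m[:, combo].min(axis=1).sum()
            if obj < best_obj - 1e-12:
                best_obj = obj
                best = np.array(combo)
        medoids = best
        assign = _assign(m, medoids)
    else:
        rng = np.random.default_rng(seed)
        best_obj = np.inf
        medoids = assign = None
        for _ in range(n_init):
            cand_medoids, cand_assign = _voronoi_iterate(
                m, _seed_medoids(m, k, rng), k, max_iter
            )
            obj = _objective(m, cand_medoids, cand_assign)
            if obj < best_obj:
                best_obj, medoids, assign = obj, cand_medoids, cand_assign

    sizes = np.bincount(assign, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    sizes_desc = sizes[order]
    top3 = sizes_desc[: min(3, k)].sum() / n
    objective = _objective(m, medoids, assign)
    return ClusterResult(
        k=k,
        medoid_indices=medoids,
        assignments=assign,
        sizes=sizes_desc,
        top3_coverage=float(top3),
        objective=objective,
    )


def select_representatives(
    ensemble: Ensemble,
    k_max: int = 10,
    seed: int = 0,
    fitted: bool = True,
) -> tuple[ClusterResult, Ensemble]:
    """Cluster an ensemble and export the medoids of the three largest clusters.

    Searches k = 3..k_max for the smallest k whose top-3 cluster coverage
    reaches 80% of the frames; if none qualifies the best-covering result
    is returned with a warning.  The representative ensemble holds the
    top-3 medoid frames (ordered by descending cluster size).
    """
    if ensemble.n_frames < 3:
        raise DataError("representative selection needs at least 3 frames")
    k_max = min(k_max, ensemble.n_frames)
    matrix = pairwise_rmsd_matrix(ensemble, fitted=fitted)
    best: ClusterResult | None = None
    chosen: ClusterResult | None = None
    for k in range(3, k_max + 1):
        result = kcentroid_cluster(matrix, k, seed=seed)
        if best is None or result.top3_coverage > best.top3_coverage:
            best = result
        if result.top3_coverage >= 0.80:
            chosen = result
            break
    if chosen is None:
        assert best is not None
        warnings.warn(
            f"no k in [3, {k_max}] reaches 80% top-3 coverage; "
            f"best coverage {best.top3_coverage:.2f} at k={best.k}",
            stacklevel=2,
        )
        chosen = best

    sizes = np.bincount(chosen.assignments, minlength=chosen.k)
    order = np.argsort(-sizes, kind="stable")[:3]
    rep_frames = chosen.medoid_indices[order]
    heavy = ensemble.heavy_subset()
    representatives = heavy.subset_frames(rep_frames)
    return chosen, representatives
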
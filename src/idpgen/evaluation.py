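"""Agreement metrics between generated and reference conformational ensembles.

The central report pairs each generated conformation with its source
frame and computes, per pair, the heavy-atom RMSD

    RMSD = sqrt( 1/N * sum_i |r_i^0 - r_i|^2 )

and the Spearman rank correlation over the two flattened 3N coordinate
vectors,

    rho = 1 - 6 * sum d_i^2 / (n (n^2 - 1)),

with average-rank tie handling (Pearson on ranks when ties occur).  RMSD
is computed in the common aligned frame without per-pair re-superposition
by default, because the generator reconstructs absolute coordinates in
that frame; a fitted (per-pair Kabsch) variant is available via
``fitted=True``.

Two models' per-pair RMSD distributions are compared with a two-sided
Wilcoxon rank-sum (Mann-Whitney) test, and ensembles are further profiled
by mass-weighted radius of gyration, PCA co-projection onto the reference
ensemble's first two principal components, and backbone (phi, psi)
dihedrals for Ramachandran checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DataError
from .trajectory_io import Ensemble, kabsch_superpose

__all__ = [
    "EvalReport",
    "rmsd",
    "spearman",
    "evaluate_pairs",
    "radius_of_gyration",
    "rg_profile",
    "compare_models",
    "pca_coproject",
    "backbone_dihedrals",
]


def rmsd(
    ref_frame: np.ndarray,
    gen_frame: np.ndarray,
    heavy_mask: np.ndarray | None = None,
    fitted: bool = False,
) -> float:
    """Heavy-atom coordinate RMSD (Angstrom) between two frames.

    By default no re-superposition is performed (direct coordinate RMSD in
    the shared aligned frame); ``fitted=True`` applies an optimal Kabsch
    fit on the selected atoms first.
    """
    ref_frame = np.asarray(ref_frame, dtype=np.float64)
    gen_frame = np.asarray(gen_frame, dtype=np.float64)
    if ref_frame.shape != gen_frame.shape:
        raise DataError(f"atom-count mismatch: {ref_frame.shape} vs {gen_frame.shape}")
    if heavy_mask is not None:
        m = np.asarray(heavy_mask, dtype=bool)
        ref_frame, gen_frame = ref_frame[m], gen_frame[m]
    if ref_frame.shape[0] == 0:
        raise DataError("no atoms selected for RMSD")
    if fitted:
        _, value = kabsch_superpose(gen_frame, ref_frame)
        return value
    return float(np.sqrt(np.mean(np.sum((ref_frame - gen_frame) ** 2, axis=1))))


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Uses the closed form 1 - 6*sum(d^2)/(n(n^2-1)) when the ranks are
    tie-free, and Pearson correlation of average ranks otherwise (the
    closed form is exact only without ties).  Returns NaN if either input
    has zero variance (correlation undefined).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise DataError("spearman requires at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if ties:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    d = rx - ry
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration (Angstrom) of a single frame."""
    frame = np.asarray(frame, dtype=np.float64)
    masses = np.asarray(masses, dtype=np.float64)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise DataError("frame must have shape [n_atoms, 3]")
    if masses.shape != (frame.shape[0],):
        raise DataError("masses length must match atom count")
    if np.any(masses <= 0):
        raise DataError("masses must be positive")
    com = np.average(frame, axis=0, weights=masses)
    sq = np.sum((frame - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def rg_profile(ensemble: Ensemble, heavy_only: bool = True) -> np.ndarray:
    """Per-frame radius of gyration of an ensemble."""
    ens = ensemble.heavy_subset() if heavy_only else ensemble
    masses = ens.topology.masses
    com = np.einsum("fax,a->fx", ens.coords, masses) / masses.sum()
    sq = np.sum((ens.coords - com[:, None, :]) ** 2, axis=2)
    return np.sqrt(sq @ masses / masses.sum())


def _summary(values: np.ndarray) -> dict[str, float]:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return {
        "mean": float(np.mean(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
    }


@dataclass
class EvalReport:
    """Per-pair agreement statistics between a reference and a generated ensemble."""

    per_pair_rmsd: np.ndarray
    per_pair_spearman: np.ndarray
    rmsd_summary: dict[str, float]
    spearman_summary: dict[str, float]
    rg_reference: np.ndarray
    rg_generated: np.ndarray
    fitted: bool
    wilcoxon: tuple[float, float] | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair_rmsd)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-pair table (one row per conformation pair)."""
        return pd.DataFrame(
            {
                "pair": np.arange(self.n_pairs),
                "rmsd_A": self.per_pair_rmsd,
                "spearman_rho": self.per_pair_spearman,
                "rg_reference_A": self.rg_reference,
                "rg_generated_A": self.rg_generated,
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "n_pairs": self.n_pairs,
            "fitted_rmsd": self.fitted,
            "rmsd_summary": self.rmsd_summary,
            "spearman_summary": self.spearman_summary,
            "rg_reference_mean": float(np.mean(self.rg_reference)),
            "rg_generated_mean": float(np.mean(self.rg_generated)),
        }
        if self.wilcoxon is not None:
            payload["wilcoxon"] = {
                "statistic": self.wilcoxon[0],
                "p_value": self.wilcoxon[1],
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"paired evaluation over {self.n_pairs} conformation pairs "
            f"({'fitted' if self.fitted else 'unfitted'} RMSD)",
            "  RMSD [A]     : mean {mean:.3f}  min {min:.3f}  median {median:.3f}  max {max:.3f}".format(
                **self.rmsd_summary
            ),
            "  Spearman rho : mean {mean:.3f}  min {min:.3f}  median {median:.3f}  max {max:.3f}".format(
                **self.spearman_summary
            ),
            f"  Rg [A]       : reference mean {np.mean(self.rg_reference):.3f}  "
            f"generated mean {np.mean(self.rg_generated):.3f}",
        ]
        if self.wilcoxon is not None:
            lines.append(
                f"  Wilcoxon     : statistic {self.wilcoxon[0]:.4g}  p {self.wilcoxon[1]:.4g}"
            )
        return "\n".join(lines)


def evaluate_pairs(
    reference: Ensemble, generated: Ensemble, fitted: bool = False
) -> EvalReport:
    """Frame-by-frame comparison of a generated ensemble against its source.

    Both ensembles are reduced to heavy atoms; they must pair up frame for
    frame and hold the same number of heavy atoms.
    """
    ref = reference.heavy_subset()
    gen = generated.heavy_subset()
    if ref.n_frames != gen.n_frames:
        raise DataError(
            f"frame-count mismatch: reference {ref.n_frames} vs generated {gen.n_frames}"
        )
    if ref.n_atoms != gen.n_atoms:
        raise DataError(
            f"heavy-atom mismatch: reference {ref.n_atoms} vs generated {gen.n_atoms}"
        )
    n = ref.n_frames
    rmsds = np.empty(n)
    rhos = np.empty(n)
    for i in range(n):
        rmsds[i] = rmsd(ref.coords[i], gen.coords[i], fitted=fitted)
        rhos[i] = spearman(ref.coords[i].ravel(), gen.coords[i].ravel())
    return EvalReport(
        per_pair_rmsd=rmsds,
        per_pair_spearman=rhos,
        rmsd_summary=_summary(rmsds),
        spearman_summary=_summary(rhos),
        rg_reference=rg_profile(ref, heavy_only=False),
        rg_generated=rg_profile(gen, heavy_only=False),
        fitted=fitted,
    )


def compare_models(
    rmsd_a: np.ndarray, rmsd_b: np.ndarray
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum comparison of two per-pair RMSD samples.

    Uses the exact null distribution when both groups have at most 20
    observations and the normal approximation with continuity correction
    above that.  Returns (statistic, p_value, better) where ``better`` is
    the sample with the lower mean RMSD ("a" or "b").
    """
    a = np.asarray(rmsd_a, dtype=np.float64).ravel()
    b = np.asarray(rmsd_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise DataError("both RMSD samples must be non-empty")
    method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    better = "a" if a.mean() <= b.mean() else "b"
    return float(res.statistic), float(res.pvalue), better


def pca_coproject(
    reference: Ensemble, generated: Ensemble
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project both ensembles onto the reference's first two principal components.

    The PCA basis is fitted on the reference flattened heavy-atom
    coordinates only; returns (reference scores, generated scores,
    explained-variance fractions).
    """
    ref = reference.heavy_subset()
    gen = generated.heavy_subset()
    if ref.n_atoms != gen.n_atoms:
        raise DataError("topologies do not match (heavy-atom counts differ)")
    if ref.n_frames < 2:
        raise DataError("PCA needs at least 2 reference frames")
    ref_flat = ref.coords.reshape(ref.n_frames, -1)
    gen_flat = gen.coords.reshape(gen.n_frames, -1)
    pca = PCA(n_components=2)
    ref_scores = pca.fit_transform(ref_flat)
    gen_scores = pca.transform(gen_flat)
    return ref_scores, gen_scores, pca.explained_variance_ratio_


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees, IUPAC sign convention) of four points; NaN if degenerate."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    denom = np.linalg.norm(n1) * np.linalg.norm(n2)
    if denom < 1e-10 or nb1 < 1e-10:  # collinear backbone stretch: undefined
        return float("nan")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b1 / nb1)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame backbone torsions phi and psi in degrees.

    Returns two arrays of shape [n_frames, n_residues]; undefined angles
    (chain termini, residues missing N/CA/C, degenerate geometry) are NaN.
    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    """
    topo = ensemble.topology
    res_ids = np.unique(topo.residue_ids)
    n_res = len(res_ids)
    idx = {}
    missing = []
    for rid in res_ids:
        sel = topo.residue_ids == rid
        names = topo.atom_names[sel]
        pos = np.flatnonzero(sel)
        entry = {}
        for need in ("N", "CA", "C"):
            hits = pos[names == need]
            if hits.size:
                entry[need] = hits[0]
        if len(entry) < 3:
            missing.append(int(rid))
        idx[rid] = entry
    if missing:
        warnings.warn(
            f"residues missing backbone atoms (angles set to NaN): {missing}",
            stacklevel=2,
        )
    phi = np.full((ensemble.n_frames, n_res), np.nan)
    psi = np.full((ensemble.n_frames, n_res), np.nan)
    for f in range(ensemble.n_frames):
        c = ensemble.coords[f]
        for j, rid in enumerate(res_ids):
            cur = idx[rid]
            if len(cur) < 3:
                continue
            if j > 0 and "C" in idx[res_ids[j - 1]]:
                phi[f, j] = _dihedral(
                    c[idx[res_ids[j - 1]]["C"]], c[cur["N"]], c[cur["CA"]], c[cur["C"]]
                )
            if j < n_res - 1 and "N" in idx[res_ids[j + 1]]:
                psi[f, j] = _dihedral(
                    c[cur["N"]], c[cur["CA"]], c[cur["C"]], c[idx[res_ids[j + 1]]["N"]]
                )
    return phi, psi
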
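"""Reading, writing and superposing conformational ensembles.

An :class:`Ensemble` is the universal currency of the pipeline: a protein
topology (atom/residue metadata) plus a stack of Cartesian coordinate
frames in Angstrom, typically one frame per MODEL of a multi-model PDB
file produced from an MD trajectory.  Frames keep their file order, which
for MD input is chronological — the train/test split downstream relies on
that.

Solvent and ion residues (water, Na+, Cl-) are stripped on read so the
topology only ever holds protein atoms.  Hydrogens are kept in the
topology but flagged via ``heavy_mask``; all downstream featurization
uses heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import DataError, FormatError

__all__ = [
    "Topology",
    "Ensemble",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "kabsch_rotation",
    "kabsch_superpose",
    "align_ensemble",
    "BACKBONE_ATOM_NAMES",
    "SOLVENT_RESIDUE_NAMES",
]

#: Atom names driving backbone superposition.
BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")

#: Residue names dropped on read (water and common counter-ions).
SOLVENT_RESIDUE_NAMES = frozenset({"HOH", "WAT", "NA", "CL", "NA+", "CL-"})

# Monoisotopic-ish average masses (Da) for the elements that occur in
# protein heavy/hydrogen atoms; anything else falls back to biotite.
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


def _element_mass(element: str) -> float:
    try:
        return _ELEMENT_MASSES[element.upper()]
    except KeyError:
        from biotite.structure.info import mass

        m = mass(element)
        if m is None:
            raise DataError(f"unknown element {element!r}: cannot assign a mass")
        return float(m)


def _guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in ("SE", "FE", "ZN", "MG", "MN", "CU", "CA"):  # CA element vs C-alpha is
        # ambiguous in hand-made files; protein C-alpha is far more likely here.
        if two != "CA":
            return two
    return stripped[0].upper()


@dataclass(frozen=True)
class Topology:
    """Per-atom metadata of a protein system.

    ``heavy_mask`` and ``masses`` are derived from ``elements`` unless
    masses are supplied explicitly (coarse-grained pseudo-atoms carry a
    residue-average mass instead of an elemental one).
    """

    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray = None  # type: ignore[assignment]
    heavy_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        names = np.asarray(self.atom_names, dtype=str)
        rids = np.asarray(self.residue_ids, dtype=np.int64)
        rnames = np.asarray(self.residue_names, dtype=str)
        elems = np.asarray(self.elements, dtype=str)
        n = len(names)
        if n < 1:
            raise DataError("topology must contain at least one atom")
        for label, arr in (("residue_ids", rids), ("residue_names", rnames), ("elements", elems)):
            if len(arr) != n:
                raise DataError(f"{label} has length {len(arr)}, expected {n}")
        if np.any(np.diff(rids) < 0):
            raise DataError("residue_ids must be non-decreasing")
        heavy = np.char.upper(elems) != "H"
        if self.masses is None:
            masses = np.array([_element_mass(e) for e in elems], dtype=float)
        else:
            masses = np.asarray(self.masses, dtype=float)
            if len(masses) != n:
                raise DataError(f"masses has length {len(masses)}, expected {n}")
        if np.any(masses <= 0):
            raise DataError("atomic masses must be positive")
        object.__setattr__(self, "atom_names", names)
        object.__setattr__(self, "residue_ids", rids)
        object.__setattr__(self, "residue_names", rnames)
        object.__setattr__(self, "elements", elems)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "heavy_mask", heavy)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_ids))

    def subset(self, mask: np.ndarray) -> "Topology":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_atoms,):
            raise DataError("selection mask length does not match atom count")
        if not mask.any():
            raise DataError("selection matches no atoms")
        return Topology(
            atom_names=self.atom_names[mask],
            residue_ids=self.residue_ids[mask],
            residue_names=self.residue_names[mask],
            elements=self.elements[mask],
            masses=self.masses[mask],
        )

    def heavy_subset(self) -> "Topology":
        return self.subset(self.heavy_mask)

    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.atom_names, BACKBONE_ATOM_NAMES)


@dataclass(frozen=True)
class Ensemble:
    """A conformational ensemble: topology plus [n_frames, n_atoms, 3] coordinates (Angstrom)."""

    topology: Topology
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise DataError(f"coords must have shape [n_frames, n_atoms, 3], got {coords.shape}")
        if coords.shape[0] < 1:
            raise DataError("ensemble must contain at least one frame")
        if coords.shape[1] != self.topology.n_atoms:
            raise DataError(
                f"coords hold {coords.shape[1]} atoms but topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(coords)):
            raise DataError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset_atoms(self, mask: np.ndarray) -> "Ensemble":
        sub = self.topology.subset(mask)
        return Ensemble(sub, self.coords[:, np.asarray(mask, dtype=bool), :])

    def heavy_subset(self) -> "Ensemble":
        return self.subset_atoms(self.topology.heavy_mask)

    def subset_frames(self, indices) -> "Ensemble":
        return Ensemble(self.topology, self.coords[np.asarray(indices)])


def _scan_model_atom_counts(path) -> list[int]:
    """Count coordinate records per MODEL block, honoring the implicit single model."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model_record = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model_record = True
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
    if not saw_model_record:
        return [current] if current else []
    if in_model:  # MODEL without ENDMDL terminator
        counts.append(current)
    return counts


def read_multimodel_pdb(path) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    One frame per MODEL record (a file without MODEL records is a single
    implicit model).  Water and counter-ion residues are skipped; hydrogens
    are kept but flagged in ``heavy_mask``.

    Raises
    ------
    FormatError
        If the file is empty or the models have inconsistent atom counts
        (the offending 1-based model index is named).
    """
    counts = _scan_model_atom_counts(path)
    if not counts:
        raise FormatError(f"{path}: no coordinate records found")
    if len(set(counts)) > 1:
        ref = counts[0]
        bad = next(i for i, c in enumerate(counts) if c != ref)
        raise FormatError(
            f"{path}: model {bad + 1} has {counts[bad]} atoms, expected {ref}"
        )
    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    keep = ~np.isin(np.char.upper(stack.res_name), tuple(SOLVENT_RESIDUE_NAMES))
    if not keep.any():
        raise FormatError(f"{path}: no protein atoms after solvent/ion stripping")
    stack = stack[:, keep]
    elements = np.asarray(stack.element, dtype=str)
    if np.any(elements == ""):
        names = np.asarray(stack.atom_name, dtype=str)
        elements = np.array(
            [e if e else _guess_element(n) for e, n in zip(elements, names)], dtype=str
        )
    topo = Topology(
        atom_names=np.asarray(stack.atom_name, dtype=str),
        residue_ids=np.asarray(stack.res_id, dtype=np.int64),
        residue_names=np.asarray(stack.res_name, dtype=str),
        elements=elements,
    )
    return Ensemble(topo, np.asarray(stack.coord, dtype=np.float64))


# PDB coordinate fields are fixed-width %8.3f: representable range.
_PDB_COORD_MIN = -999.999
_PDB_COORD_MAX = 9999.999


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame).

    Coordinates outside the fixed-width %8.3f field range raise
    :class:`FormatError` rather than being silently truncated.
    """
    coords = ensemble.coords
    if coords.min() < _PDB_COORD_MIN or coords.max() > _PDB_COORD_MAX:
        raise FormatError(
            "coordinates exceed the PDB fixed-width field range "
            f"[{_PDB_COORD_MIN}, {_PDB_COORD_MAX}] Angstrom"
        )
    topo = ensemble.topology
    n = topo.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = coords[0]
    arr.atom_name = topo.atom_names
    arr.res_id = topo.residue_ids
    arr.res_name = topo.residue_names
    arr.element = topo.elements
    arr.chain_id = np.full(n, "A")
    arr.hetero = np.full(n, False)
    stack = bst.stack([arr] * ensemble.n_frames)
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation matrix R with R @ centered(mobile) ~ centered(reference).

    Both inputs are [n, 3] point sets of equal length, n >= 3 and not
    collinear.  The returned matrix always has determinant +1 (no
    reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DataError("point sets must both have shape [n, 3]")
    if mobile.shape[0] < 3:
        raise DataError("superposition needs at least 3 selected atoms")
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    # collinear (rank < 2) point sets leave the rotation underdetermined
    if min(np.linalg.matrix_rank(mc, tol=1e-8), np.linalg.matrix_rank(rc, tol=1e-8)) < 2:
        raise DataError("selected atoms are collinear; superposition is underdetermined")
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    atom_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Rigid-body superpose ``mobile`` onto ``reference``.

    Only atoms in ``atom_selection`` (boolean mask; default all) drive the
    fit, but the whole frame is transformed.  Returns the transformed frame
    and the post-fit RMSD (Angstrom) over the selected atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DataError("mobile and reference frames must have identical shapes")
    if atom_selection is None:
        atom_selection = np.ones(mobile.shape[0], dtype=bool)
    sel = np.asarray(atom_selection, dtype=bool)
    if sel.sum() < 3:
        raise DataError("superposition needs at least 3 selected atoms")
    msel, rsel = mobile[sel], reference[sel]
    rot = kabsch_rotation(msel, rsel)
    mcen, rcen = msel.mean(axis=0), rsel.mean(axis=0)
    aligned = (mobile - mcen) @ rot.T + rcen
    rmsd = float(np.sqrt(np.mean(np.sum((aligned[sel] - rsel) ** 2, axis=1))))
    return aligned, rmsd


def align_ensemble(
    ensemble: Ensemble,
    selection: str | np.ndarray = "backbone",
    reference_index: int = 0,
) -> Ensemble:
    """Superpose every frame onto the reference frame (default: the first).

    ``selection`` is either the string ``"backbone"`` (atom names N, CA, C,
    O) or an explicit boolean atom mask.  The reference frame is returned
    unchanged.
    """
    if isinstance(selection, str):
        if selection != "backbone":
            raise DataError(f"unknown selection {selection!r}")
        mask = ensemble.topology.backbone_mask()
        if not mask.any():
            raise DataError("backbone selection (N, CA, C, O) matches no atoms")
    else:
        mask = np.asarray(selection, dtype=bool)
        if not mask.any():
            raise DataError("selection matches no atoms")
    ref = ensemble.coords[reference_index]
    out = np.empty_like(ensemble.coords)
    for i in range(ensemble.n_frames):
        if i == reference_index:
            out[i] = ensemble.coords[i]
        else:
            out[i], _ = kabsch_superpose(ensemble.coords[i], ref, mask)
    return Ensemble(ensemble.topology, out)
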
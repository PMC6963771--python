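"""PDB Cα extraction, rigid-body superposition, and coordinate-matrix construction.

A conformational ensemble is reduced to one Cα atom per residue; the atoms
shared by every entry define the columns of an N-structures × 3M-coordinates
matrix (one structure per row) that downstream projection methods consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "AtomKey",
    "Structure",
    "CoordinateMatrix",
    "read_calpha",
    "common_atom_set",
    "superpose_ensemble",
    "build_matrix",
    "write_matrix",
    "read_matrix",
    "kabsch_rotation",
]


class AtomKey(NamedTuple):
    """Identity of one Cα position: (chain, residue number, insertion code).

    Residue name is deliberately not part of the key, so mutant entries align
    by position.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_number}:{self.insertion_code}"

    @classmethod
    def parse(cls, text: str) -> "AtomKey":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"malformed atom key {text!r}")
        return cls(parts[0], int(parts[1]), parts[2])


@dataclass
class Structure:
    """One entry reduced to labeled Cα coordinates (Å)."""

    entry_id: str
    atoms: dict  # AtomKey -> np.ndarray shape (3,)

    def __post_init__(self) -> None:
        if len(self.atoms) < 3:
            raise ValueError(
                f"structure {self.entry_id!r} has {len(self.atoms)} atoms; need >= 3"
            )
        for key, xyz in self.atoms.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinates for {key} in {self.entry_id!r}")
            self.atoms[key] = xyz

    def __len__(self) -> int:
        return len(self.atoms)

    def keys(self) -> list:
        return sorted(self.atoms)

    def coords(self, atom_keys: Sequence[AtomKey] | None = None) -> np.ndarray:
        """Coordinates as an (n_atoms, 3) array, in canonical key order."""
        keys = self.keys() if atom_keys is None else atom_keys
        try:
            return np.array([self.atoms[k] for k in keys], dtype=float)
        except KeyError as exc:
            raise KeyError(f"structure {self.entry_id!r} lacks atom {exc.args[0]}") from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = {k: rot @ v + t for k, v in self.atoms.items()}
        return Structure(self.entry_id, atoms)


@dataclass
class CoordinateMatrix:
    """N×D matrix of ensemble coordinates, D = 3 × number of shared atoms.

    Row i is structure i's (x, y, z) triplets over ``atom_keys`` in canonical
    order.
    """

    values: np.ndarray
    row_labels: list
    atom_keys: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n, d = self.values.shape
        if d != 3 * len(self.atom_keys):
            raise ValueError(f"D={d} != 3 x {len(self.atom_keys)} atom keys")
        if n < 2:
            raise ValueError("need at least 2 structures")
        if len(self.row_labels) != n:
            raise ValueError("row label count mismatch")
        if len(set(self.row_labels)) != n:
            raise ValueError("row labels must be unique")

    @property
    def shape(self) -> tuple:
        return self.values.shape


# --- PDB parsing (wwPDB v3.3 fixed columns) ---------------------------------

_ALTLOC_POLICIES = ("reject", "take_first", "highest_occupancy")


def _parse_atom_line(line: str):
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    chain = line[21:22].strip()
    try:
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ValueError(f"malformed ATOM record: {line.rstrip()!r}") from exc
    icode = line[26:27].strip()
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    return name, altloc, chain, resseq, icode, np.array([x, y, z]), occupancy


def read_calpha(
    pdb_path,
    chain_filter: Iterable[str] | None = None,
    altloc_policy: str = "highest_occupancy",
) -> Structure:
    """Extract Cα atoms from the first MODEL of a PDB file.

    Parameters
    ----------
    pdb_path
        Path to a PDB-format file containing ATOM records.
    chain_filter
        If given, only chains in this set are kept.
    altloc_policy
        How to treat Cα atoms with alternate locations: ``reject`` aborts the
        read, ``take_first`` keeps the first record, ``highest_occupancy``
        keeps the highest-occupancy record (ties broken by altLoc letter).
    """
    if altloc_policy not in _ALTLOC_POLICIES:
        raise ValueError(f"altloc_policy must be one of {_ALTLOC_POLICIES}")
    path = Path(pdb_path)
    chains = set(chain_filter) if chain_filter is not None else None

    candidates: dict = {}  # AtomKey -> list of (altloc, occupancy, xyz)
    with open(path) as handle:
        saw_model = False
        for line in handle:
            rec = line[:6]
            if rec.startswith("MODEL"):
                if saw_model:
                    break
                saw_model = True
                continue
            if rec.startswith("ENDMDL"):
                break
            if not rec.startswith("ATOM"):
                continue
            name, altloc, chain, resseq, icode, xyz, occ = _parse_atom_line(line)
            if name != "CA":
                continue
            if chains is not None and chain not in chains:
                continue
            key = AtomKey(chain, resseq, icode)
            candidates.setdefault(key, []).append((altloc, occ, xyz))

    if not candidates:
        raise ValueError(f"no CA atoms found in {path}")

    atoms = {}
    for key, records in candidates.items():
        if len(records) > 1 and altloc_policy == "reject":
            raise ValueError(
                f"{path.name}: multiple alternate locations for CA {key} "
                f"(altlocs {[r[0] for r in records]})"
            )
        if altloc_policy == "take_first" or len(records) == 1:
            atoms[key] = records[0][2]
        else:  # highest_occupancy; occupancy ties broken by altLoc ascending
            best = max(records, key=lambda r: (r[1], _neg_altloc(r[0])))
            atoms[key] = best[2]
    return Structure(path.stem, atoms)


def _neg_altloc(altloc: str):
    # max() picks highest occupancy; on ties prefer the *lowest* altLoc letter
    return tuple(-ord(c) for c in altloc)


def common_atom_set(structures: Sequence[Structure]) -> list:
    """Intersection of AtomKeys over all structures, in canonical order."""
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    common = set(structures[0].atoms)
    for s in structures[1:]:
        common &= set(s.atoms)
        if not common:
            raise ValueError(
                f"empty shared atom set after intersecting {s.entry_id!r}"
            )
    return sorted(common)


# --- superposition ----------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) that best maps centered ``mobile`` onto
    centered ``target`` in the least-squares sense. Reflections are never
    emitted."""
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def superpose_ensemble(
    structures: Sequence[Structure],
    atom_keys: Sequence[AtomKey],
    reference: str = "iterative_mean",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> list:
    """Rigidly superpose an ensemble over ``atom_keys``.

    ``reference='first'`` fits everything onto the first structure once;
    ``reference='iterative_mean'`` alternates mean-structure/refit until the
    mean shifts by less than ``tol`` Å (or ``max_iter`` rounds).
    """
    if reference not in ("first", "iterative_mean"):
        raise ValueError("reference must be 'first' or 'iterative_mean'")
    if len(atom_keys) < 3:
        raise ValueError("superposition underdetermined: need >= 3 shared atoms")
    keys = list(atom_keys)
    stack = np.array([s.coords(keys) for s in structures])  # raises on missing key
    centroids = stack.mean(axis=1)
    centered = stack - centroids[:, None, :]

    def refit(target):
        """Fresh proper-rotation fits of the original coordinates onto a
        centered target; returns rotations and fitted (centered) copies."""
        rotations = [kabsch_rotation(c, target) for c in centered]
        return rotations, np.array([c @ r.T for c, r in zip(centered, rotations)])

    target = centered[0]
    rotations, fitted = refit(target)
    if reference == "iterative_mean":
        mean = fitted.mean(axis=0)
        for _ in range(max_iter):
            mean -= mean.mean(axis=0)
            rotations, fitted = refit(mean)
            new_mean = fitted.mean(axis=0)
            if np.abs(new_mean - mean).max() < tol:
                mean = new_mean
                break
            mean = new_mean
        # gauge fixing: orient the converged mean along its principal axes so
        # the result does not depend on the global frame the inputs came in
        canon = _canonical_orientation(mean)
        rotations = [canon @ r for r in rotations]

    out = []
    for s, rot, cm in zip(structures, rotations, centroids):
        out.append(s.transformed(rot, -rot @ cm))
    return out


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Proper rotation taking centered ``coords`` to a canonical frame defined
    by the gyration tensor's eigenvectors (descending), each sign-fixed by its
    largest-magnitude component."""
    centered = coords - coords.mean(axis=0)
    gyration = centered.T @ centered
    eigvals, axes = np.linalg.eigh(gyration)
    axes = axes[:, np.argsort(eigvals)[::-1]]
    for j in range(3):
        pivot = np.argmax(np.abs(axes[:, j]))
        if axes[pivot, j] < 0:
            axes[:, j] = -axes[:, j]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes.T


def build_matrix(structures: Sequence[Structure], atom_keys: Sequence[AtomKey]) -> CoordinateMatrix:
    """Row-per-structure coordinate matrix over ``atom_keys`` (canonical order)."""
    keys = list(atom_keys)
    rows = [s.coords(keys).ravel() for s in structures]
    labels = [s.entry_id for s in structures]
    return CoordinateMatrix(np.array(rows), labels, keys)


# --- text serialization -----------------------------------------------------

_AXES = ("x", "y", "z")


def write_matrix(matrix: CoordinateMatrix, path) -> None:
    """Tab-separated text: header of atom-key columns, then one row per entry."""
    with open(path, "w") as handle:
        header = ["entry_id"]
        for key in matrix.atom_keys:
            header.extend(f"{key}:{ax}" for ax in _AXES)
        handle.write("\t".join(header) + "\n")
        for label, row in zip(matrix.row_labels, matrix.values):
            cells = [str(label)] + [f"{v:.6f}" for v in row]
            handle.write("\t".join(cells) + "\n")


def read_matrix(path) -> CoordinateMatrix:
    with open(path) as handle:
        header_line = handle.readline()
        if not header_line.strip():
            raise ValueError(f"{path}: empty or headerless matrix file")
        header = header_line.rstrip("\n").split("\t")
        if header[0] != "entry_id" or (len(header) - 1) % 3 != 0:
            raise ValueError(f"{path}: malformed header")
        atom_keys = []
        for i in range(1, len(header), 3):
            triplet = header[i : i + 3]
            bases = {cell.rsplit(":", 1)[0] for cell in triplet}
            axes = [cell.rsplit(":", 1)[1] for cell in triplet]
            if len(bases) != 1 or axes != list(_AXES):
                raise ValueError(f"{path}: malformed header triplet {triplet}")
            atom_keys.append(AtomKey.parse(bases.pop()))

        labels, rows = [], []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {len(header)}"
                )
            labels.append(cells[0])
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError:
                for col, cell in enumerate(cells[1:], start=2):
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"{path}: non-numeric cell at row {lineno}, column {col}: {cell!r}"
                        ) from None
        if not rows:
            raise ValueError(f"{path}: no data rows")
    return CoordinateMatrix(np.array(rows), labels, atom_keys)
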
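"""Electronegativity-equalization (EEM) charge solver.

EEM assigns partial atomic charges by requiring that the effective
electronegativity of every atom in the molecule equalizes to a common
molecular value chi_bar, subject to conservation of the total molecular
charge Q.  For atom i with empirical electronegativity parameter A_i and
hardness parameter B_i this reads

    chi_bar = A_i + B_i * q_i + kappa * sum_{j != i} q_j / R_ij

where R_ij is the interatomic distance (angstrom, as read from the input
geometry) and kappa a global distance-coupling constant of the parameter
set.  Collecting the N equalization equations and the charge-conservation
row gives a dense (N+1) x (N+1) linear system in the unknowns
(q_1 ... q_N, chi_bar), solved directly.

Parameter sets are empirical calibrations against quantum-mechanical
charges; each set keys its (A, B) entries on the element and the highest
bond order incident to the atom (aromatic bonds count as order 2), with an
optional per-element wildcard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    InvalidGeometryError,
    MissingParameterError,
    SingularGeometryError,
    SingularSystemError,
)

WILDCARD_ORDER = "*"

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Fe", "Zn", "Br", "I", "Se",
}


@dataclass(frozen=True)
class Bond:
    """A bond between atoms ``i`` and ``j`` with integer order 1-3.

    ``aromatic`` marks bonds flagged aromatic in the source file; for atom
    typing these count as order 2.
    """

    i: int
    j: int
    order: int = 1
    aromatic: bool = False

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError(f"bond connects atom {self.i} to itself")
        if not self.aromatic and self.order not in (1, 2, 3):
            raise ValueError(f"unsupported bond order {self.order}")

    @property
    def effective_order(self) -> int:
        return 2 if self.aromatic else self.order


@dataclass(frozen=True)
class Atom:
    element: str
    position: tuple[float, float, float]
    formal_charge: int = 0

    def __post_init__(self):
        if self.element not in _ELEMENTS:
            raise ValueError(f"unrecognized element symbol {self.element!r}")
        if not all(math.isfinite(c) for c in self.position):
            raise InvalidGeometryError(
                f"non-finite coordinate in atom {self.element} {self.position}"
            )


@dataclass
class MoleculeGeometry:
    """Atoms with 3D coordinates, bonds with orders, and total charge Q."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    total_charge: int = 0

    def __post_init__(self):
        n = len(self.atoms)
        if n < 1:
            raise InvalidGeometryError(f"molecule {self.id!r} has no atoms")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise InvalidGeometryError(
                    f"bond ({b.i},{b.j}) out of range for {n} atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def max_bond_order(self, index: int) -> int:
        """Highest effective order of any bond incident to ``index``.

        Isolated atoms default to order 1 (the single-bond parameter row).
        """
        orders = [
            b.effective_order
            for b in self.bonds
            if b.i == index or b.j == index
        ]
        return max(orders, default=1)

    def neighbors(self, index: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == index:
                out.append(b.j)
            elif b.j == index:
                out.append(b.i)
        return out

    def bond_between(self, i: int, j: int) -> Bond | None:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MoleculeGeometry":
        """Copy with coordinates mapped through x -> R x + t."""
        xyz = self.coordinates() @ np.asarray(rotation, dtype=float).T
        xyz = xyz + np.asarray(translation, dtype=float)
        atoms = [
            replace(a, position=tuple(p)) for a, p in zip(self.atoms, xyz)
        ]
        return MoleculeGeometry(self.id, atoms, list(self.bonds), self.total_charge)

    def permuted(self, perm: list[int]) -> "MoleculeGeometry":
        """Copy with atoms reordered so new atom k is old atom perm[k]."""
        inv = {old: new for new, old in enumerate(perm)}
        atoms = [self.atoms[old] for old in perm]
        bonds = [
            Bond(inv[b.i], inv[b.j], b.order, b.aromatic) for b in self.bonds
        ]
        return MoleculeGeometry(self.id, atoms, bonds, self.total_charge)


@dataclass(frozen=True)
class EemParameterSet:
    """kappa plus per-(element, bond-order) electronegativity/hardness pairs.

    ``entries`` maps (element, order) -> (A, B) where order is 1, 2, 3 or the
    wildcard ``"*"``.  Published sets absorb all unit conventions into the
    calibrated kappa, A and B values, so no unit conversion happens here.
    """

    name: str
    kappa: float
    entries: dict[tuple[str, int | str], tuple[float, float]]
    provenance: str = ""
    qm_scheme: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.kappa >= 0 and math.isfinite(self.kappa)):
            raise ValueError(f"kappa must be finite and >= 0, got {self.kappa}")
        for key, (a, b) in self.entries.items():
            if not (math.isfinite(a) and math.isfinite(b)):
                raise ValueError(f"non-finite A/B for entry {key}")

    def lookup(self, element: str, bond_order: int) -> tuple[float, float] | None:
        """Exact (element, order) match first, then the element wildcard."""
        hit = self.entries.get((element, bond_order))
        if hit is None:
            hit = self.entries.get((element, WILDCARD_ORDER))
        return hit


@dataclass(frozen=True)
class ChargeResult:
    """Per-atom charges q_i (elementary charge units) and chi_bar."""

    charges: np.ndarray
    chi_bar: float
    parameter_set_name: str

    def __post_init__(self):
        object.__setattr__(
            self, "charges", np.asarray(self.charges, dtype=float)
        )


def distance_matrix(mol: MoleculeGeometry) -> np.ndarray:
    """Symmetric N x N matrix of pairwise Euclidean distances in angstrom."""
    xyz = mol.coordinates()
    if not np.all(np.isfinite(xyz)):
        raise InvalidGeometryError(f"non-finite coordinates in {mol.id!r}")
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def assign_atom_types(
    mol: MoleculeGeometry, params: EemParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve each atom to its (A_i, B_i) pair.

    Resolution order: exact (element, max incident bond order) entry, then the
    element's wildcard entry.  An unmatched atom raises
    :class:`MissingParameterError` naming atom, element, bond order and set —
    published sets genuinely lack e.g. triple-bond carbon entries and that
    must fail loudly, not silently.
    """
    A = np.empty(mol.n_atoms)
    B = np.empty(mol.n_atoms)
    for idx, atom in enumerate(mol.atoms):
        order = mol.max_bond_order(idx)
        hit = params.lookup(atom.element, order)
        if hit is None:
            raise MissingParameterError(idx, atom.element, order, params.name)
        A[idx], B[idx] = hit
    return A, B


def build_eem_system(
    mol: MoleculeGeometry, params: EemParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (N+1) x (N+1) EEM matrix M and right-hand side b.

    Unknown vector is (q_1 ... q_N, chi_bar).  Atom row i:
    B_i q_i + kappa/R_ij q_j (j != i) - chi_bar = -A_i.  Last row enforces
    sum q_i = Q.
    """
    A, B = assign_atom_types(mol, params)
    n = mol.n_atoms
    R = distance_matrix(mol)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and np.any(R[off] == 0.0):
        i, j = np.argwhere((R == 0.0) & off)[0]
        raise SingularGeometryError(
            f"atoms {i} and {j} of {mol.id!r} coincide"
        )
    M = np.zeros((n + 1, n + 1))
    with np.errstate(divide="ignore"):
        coupling = np.where(off, params.kappa / np.where(off, R, 1.0), 0.0)
    M[:n, :n] = coupling
    M[np.arange(n), np.arange(n)] = B
    M[:n, n] = -1.0
    M[n, :n] = 1.0
    b = np.empty(n + 1)
    b[:n] = -A
    b[n] = float(mol.total_charge)
    return M, b


def solve_eem(mol: MoleculeGeometry, params: EemParameterSet) -> ChargeResult:
    """Solve the EEM system by dense direct solve.

    The resulting charges depend on the geometry only through the distance
    matrix, so they are invariant to rigid motions and equivariant under atom
    permutations.  |sum q - Q| holds to 1e-10 by construction of the
    conservation row.
    """
    M, b = build_eem_system(mol, params)
    try:
        x = np.linalg.solve(M, b)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(
            f"EEM system for {mol.id!r} with set {params.name!r} is singular"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise SingularSystemError(
            f"EEM solve for {mol.id!r} produced non-finite values"
        )
    return ChargeResult(
        charges=x[:-1], chi_bar=float(x[-1]), parameter_set_name=params.name
    )


def solve_eem_kappa_zero(
    mol: MoleculeGeometry, params: EemParameterSet
) -> ChargeResult:
    """Closed form of the decoupled (kappa = 0) limit.

    With no distance coupling, q_i = (chi_bar - A_i)/B_i and conservation
    fixes chi_bar = (Q + sum A_i/B_i) / (sum 1/B_i).  Used as an independent
    oracle for the dense solver.
    """
    A, B = assign_atom_types(mol, params)
    chi = (mol.total_charge + np.sum(A / B)) / np.sum(1.0 / B)
    return ChargeResult(
        charges=(chi - A) / B, chi_bar=float(chi),
        parameter_set_name=params.name,
    )
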
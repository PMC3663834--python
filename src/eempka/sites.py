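"""Dissociation-site detection, anion construction and descriptor extraction.

The QSPR models use the partial charges of the atoms around the acidic
hydrogen as descriptors: for phenols q_H, q_O and q_C1 from the neutral
molecule plus q_OD and q_C1D from the phenolate anion; for carboxylic acids
additionally the second carboxyl oxygen (q_O2 / q_O2D).  The anion is built
by deleting the acidic hydrogen in place — no geometry relaxation — with the
total charge dropped by one.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .core import ChargeResult, MoleculeGeometry
from .errors import AmbiguousSiteError, ConsistencyError, NoSiteError

PHENOL_SYMBOLS = ("q_H", "q_O", "q_C1", "q_OD", "q_C1D")
ACID_SYMBOLS = ("q_H", "q_O", "q_O2", "q_C1", "q_OD", "q_O2D", "q_C1D")


@dataclass(frozen=True)
class PhenolSite:
    """Indices of the phenolic O-H hydrogen, its oxygen, and the ring carbon."""

    h_index: int
    o_index: int
    c1_index: int


@dataclass(frozen=True)
class CarboxylSite:
    """Indices of the COOH hydrogen, hydroxyl O, carbonyl O2 and carboxyl C."""

    h_index: int
    o_index: int
    o2_index: int
    c1_index: int


def _bond_graph(mol: MoleculeGeometry) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    for b in mol.bonds:
        g.add_edge(b.i, b.j, order=b.order, aromatic=b.aromatic)
    return g


def _aromatic_six_rings(mol: MoleculeGeometry) -> list[list[int]]:
    """Six-membered all-carbon cycles that are aromatic.

    A ring qualifies when all six bonds carry the aromatic flag, or when the
    bond orders alternate 1/2 around the cycle (Kekulé form).  Fused systems
    qualify ring by ring.
    """
    g = _bond_graph(mol)
    rings = []
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) != 6:
            continue
        if not all(mol.atoms[i].element == "C" for i in cycle):
            continue
        edges = [
            g.edges[cycle[k], cycle[(k + 1) % 6]] for k in range(6)
        ]
        if all(e["aromatic"] for e in edges):
            rings.append(cycle)
            continue
        orders = [e["order"] for e in edges]
        if sorted(set(orders)) == [1, 2] and all(
            orders[k] != orders[(k + 1) % 6] for k in range(6)
        ):
            rings.append(cycle)
    return rings


def find_phenol_site(mol: MoleculeGeometry, site: PhenolSite | None = None) -> PhenolSite:
    """Locate the phenolic O-H: an oxygen bonded to exactly one hydrogen and
    one carbon that sits in an aromatic six-membered carbon ring.

    Zero matches raise :class:`NoSiteError`; multiple matches raise
    :class:`AmbiguousSiteError` (pass ``site`` explicitly to override).
    """
    if site is not None:
        return site
    aromatic_carbons = {i for ring in _aromatic_six_rings(mol) for i in ring}
    matches = []
    for o_idx, atom in enumerate(mol.atoms):
        if atom.element != "O":
            continue
        nbrs = mol.neighbors(o_idx)
        if len(nbrs) != 2:
            continue
        hs = [i for i in nbrs if mol.atoms[i].element == "H"]
        cs = [i for i in nbrs if mol.atoms[i].element == "C" and i in aromatic_carbons]
        if len(hs) == 1 and len(cs) == 1:
            matches.append(PhenolSite(hs[0], o_idx, cs[0]))
    if not matches:
        raise NoSiteError(f"no phenolic OH site in {mol.id!r}")
    if len(matches) > 1:
        raise AmbiguousSiteError(matches)
    return matches[0]


def find_carboxyl_site(mol: MoleculeGeometry, site: CarboxylSite | None = None) -> CarboxylSite:
    """Locate the COOH group: carbon single-bonded to O-H and double-bonded
    to a second oxygen."""
    if site is not None:
        return site
    matches = []
    for c_idx, atom in enumerate(mol.atoms):
        if atom.element != "C":
            continue
        hydroxyls, carbonyls = [], []
        for n_idx in mol.neighbors(c_idx):
            if mol.atoms[n_idx].element != "O":
                continue
            bond = mol.bond_between(c_idx, n_idx)
            if bond.effective_order == 2 and not bond.aromatic:
                carbonyls.append(n_idx)
            elif bond.order == 1 and not bond.aromatic:
                o_nbrs = mol.neighbors(n_idx)
                hs = [i for i in o_nbrs if mol.atoms[i].element == "H"]
                if len(o_nbrs) == 2 and len(hs) == 1:
                    hydroxyls.append((n_idx, hs[0]))
        if len(hydroxyls) == 1 and len(carbonyls) == 1:
            o_idx, h_idx = hydroxyls[0]
            matches.append(CarboxylSite(h_idx, o_idx, carbonyls[0], c_idx))
    if not matches:
        raise NoSiteError(f"no COOH site in {mol.id!r}")
    if len(matches) > 1:
        raise AmbiguousSiteError(matches)
    return matches[0]


def make_dissociated(
    mol: MoleculeGeometry, site: PhenolSite | CarboxylSite
) -> tuple[MoleculeGeometry, dict[int, int]]:
    """Delete the acidic hydrogen without moving any other atom.

    Returns the anion (total charge Q - 1, id suffixed ``_diss``) and the
    old-index -> new-index mapping of the surviving atoms.
    """
    h = site.h_index
    if not (0 <= h < mol.n_atoms):
        raise IndexError(f"H index {h} out of range for {mol.id!r}")
    if mol.atoms[h].element != "H":
        raise NoSiteError(
            f"atom {h} of {mol.id!r} is {mol.atoms[h].element}, not an acidic H"
        )
    from dataclasses import replace

    mapping = {old: old if old < h else old - 1 for old in range(mol.n_atoms) if old != h}
    atoms = [a for i, a in enumerate(mol.atoms) if i != h]
    # the negative charge localizes formally on the deprotonated oxygen so
    # the anion's SDF record carries a faithful M  CHG property
    o_new = mapping[site.o_index]
    atoms[o_new] = replace(atoms[o_new], formal_charge=atoms[o_new].formal_charge - 1)
    bonds = [
        type(b)(mapping[b.i], mapping[b.j], b.order, b.aromatic)
        for b in mol.bonds
        if h not in (b.i, b.j)
    ]
    diss = MoleculeGeometry(
        id=f"{mol.id}_diss",
        atoms=atoms,
        bonds=bonds,
        total_charge=mol.total_charge - 1,
    )
    return diss, mapping


def _check_pair(mol, diss_mol, site):
    """Verify diss_mol is mol minus exactly the site hydrogen, in place."""
    if diss_mol.n_atoms != mol.n_atoms - 1:
        raise ConsistencyError(
            f"{diss_mol.id!r} has {diss_mol.n_atoms} atoms; expected "
            f"{mol.n_atoms - 1} (neutral form minus one H)"
        )
    expected, mapping = make_dissociated(mol, site)
    for k, (a, b) in enumerate(zip(expected.atoms, diss_mol.atoms)):
        if a.element != b.element or a.position != b.position:
            raise ConsistencyError(
                f"atom {k} of {diss_mol.id!r} does not match the neutral "
                f"form with the acidic H removed"
            )
    return mapping


def extract_descriptors(
    mol: MoleculeGeometry,
    diss_mol: MoleculeGeometry,
    site: PhenolSite | CarboxylSite,
    charges_neutral: ChargeResult,
    charges_diss: ChargeResult,
) -> dict:
    """Assemble the charge-descriptor record for one neutral/anion pair.

    Neutral-form charges supply q_H, q_O, q_C1 (and q_O2 for acids); the
    anion's charges, indexed through the H-removal mapping, supply q_OD,
    q_C1D (and q_O2D).  Both charge vectors must come from the same charge
    scheme; the anion's total charge is one below the parent's.
    """
    mapping = _check_pair(mol, diss_mol, site)
    if charges_neutral.parameter_set_name != charges_diss.parameter_set_name:
        raise ConsistencyError(
            "neutral and dissociated charges use different schemes: "
            f"{charges_neutral.parameter_set_name!r} vs "
            f"{charges_diss.parameter_set_name!r}"
        )
    qn, qd = charges_neutral.charges, charges_diss.charges
    record = {
        "molecule_id": mol.id,
        "charge_scheme": charges_neutral.parameter_set_name,
        "q_H": float(qn[site.h_index]),
        "q_O": float(qn[site.o_index]),
        "q_C1": float(qn[site.c1_index]),
        "q_OD": float(qd[mapping[site.o_index]]),
        "q_C1D": float(qd[mapping[site.c1_index]]),
    }
    if isinstance(site, CarboxylSite):
        record["chemical_class"] = "carboxylic_acid"
        record["q_O2"] = float(qn[site.o2_index])
        record["q_O2D"] = float(qd[mapping[site.o2_index]])
    else:
        record["chemical_class"] = "phenol"
    return record
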
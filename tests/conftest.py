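"""Shared fixtures: a hand-built parameter set and small reference molecules.

Geometries are approximate but chemically shaped (planar rings, standard
bond lengths); the charge solver only consumes interatomic distances and
the site finder only consumes the bond graph, so exact angles are
irrelevant.
"""

import math

import pytest

from eempka.core import Atom, Bond, EemParameterSet, MoleculeGeometry


@pytest.fixture
def params():
    """Parameter set covering H, C, N, O at bond orders 1 and 2."""
    entries = {}
    base = {"H": (4.0, 14.0), "C": (5.2, 9.0), "N": (6.8, 11.0), "O": (8.5, 12.5)}
    for el, (a, b) in base.items():
        entries[(el, 1)] = (a, b)
        entries[(el, 2)] = (a + 0.4, b + 0.8)
    return EemParameterSet(name="fixture_set", kappa=0.44, entries=entries)


def hexagon(radius=1.39):
    return [
        (radius * math.cos(k * math.pi / 3), radius * math.sin(k * math.pi / 3), 0.0)
        for k in range(6)
    ]


def ring_substituted(substituents, aromatic=False):
    """Benzene ring plus radial substituent atoms.

    ``substituents`` maps ring position -> list of (element, distance) chains
    attached radially outward, each chained atom bonded to the previous one.
    Returns (atoms, bonds).
    """
    coords = hexagon()
    atoms = [Atom("C", p) for p in coords]
    bonds = [
        Bond(k, (k + 1) % 6, order=1 if aromatic else (2 if k % 2 == 0 else 1),
             aromatic=aromatic)
        for k in range(6)
    ]
    for pos, chain in substituents.items():
        x, y, _ = coords[pos]
        r = math.hypot(x, y)
        prev = pos
        dist = r
        for element, bond_len in chain:
            dist += bond_len
            atoms.append(Atom(element, (x * dist / r, y * dist / r, 0.0)))
            bonds.append(Bond(prev, len(atoms) - 1, 1))
            prev = len(atoms) - 1
    return atoms, bonds


@pytest.fixture
def phenol():
    """C6H5OH with Kekulé ring; atom 6 = O, atom 7 = acidic H."""
    subs = {0: [("O", 1.36), ("H", 0.96)]}
    for pos in range(1, 6):
        subs[pos] = [("H", 1.08)]
    atoms, bonds = ring_substituted(subs)
    return MoleculeGeometry("phenol", atoms, bonds, 0)


@pytest.fixture
def phenol_aromatic_flags():
    """Phenol with ring bonds flagged aromatic instead of Kekulé orders."""
    subs = {0: [("O", 1.36), ("H", 0.96)]}
    for pos in range(1, 6):
        subs[pos] = [("H", 1.08)]
    atoms, bonds = ring_substituted(subs, aromatic=True)
    return MoleculeGeometry("phenol_arom", atoms, bonds, 0)


@pytest.fixture
def cyclohexanol():
    """Saturated ring bearing OH: the C1 carbon is not aromatic."""
    coords = hexagon(1.54)
    atoms = [Atom("C", p) for p in coords]
    bonds = [Bond(k, (k + 1) % 6, 1) for k in range(6)]
    x, y, _ = coords[0]
    r = math.hypot(x, y)
    atoms.append(Atom("O", (x * (r + 1.43) / r, y * (r + 1.43) / r, 0.0)))
    bonds.append(Bond(0, 6, 1))
    atoms.append(Atom("H", (x * (r + 2.39) / r, y * (r + 2.39) / r, 0.0)))
    bonds.append(Bond(6, 7, 1))
    return MoleculeGeometry("cyclohexanol", atoms, bonds, 0)


@pytest.fixture
def hydroquinone():
    """Benzene-1,4-diol: two equivalent phenolic OH groups."""
    subs = {
        0: [("O", 1.36), ("H", 0.96)],
        3: [("O", 1.36), ("H", 0.96)],
        1: [("H", 1.08)], 2: [("H", 1.08)], 4: [("H", 1.08)], 5: [("H", 1.08)],
    }
    atoms, bonds = ring_substituted(subs)
    return MoleculeGeometry("hydroquinone", atoms, bonds, 0)


def carboxyl_fragment(attach_xyz, offset):
    """Atoms/bonds of a -COOH group; indices relative to ``offset``.

    Order: C1, O2 (carbonyl), O (hydroxyl), H.  The C1 atom must be bonded
    to the rest of the molecule by the caller.
    """
    x, y, z = attach_xyz
    atoms = [
        Atom("C", (x + 1.51, y, z)),
        Atom("O", (x + 2.13, y + 1.06, z)),
        Atom("O", (x + 2.19, y - 1.18, z)),
        Atom("H", (x + 3.15, y - 1.10, z)),
    ]
    bonds = [
        Bond(offset, offset + 1, 2),
        Bond(offset, offset + 2, 1),
        Bond(offset + 2, offset + 3, 1),
    ]
    return atoms, bonds


@pytest.fixture
def acetic_acid():
    """CH3-COOH; atom 1 = C1, atom 3 = hydroxyl O, atom 4 = acidic H."""
    atoms = [Atom("C", (0.0, 0.0, 0.0))]
    frag, fbonds = carboxyl_fragment((0.0, 0.0, 0.0), 1)
    atoms += frag
    bonds = [Bond(0, 1, 1)] + fbonds
    for k, (dy, dz) in enumerate([(0.9, 0.4), (-0.9, 0.4), (0.0, -1.0)]):
        atoms.append(Atom("H", (-0.63, dy, dz)))
        bonds.append(Bond(0, len(atoms) - 1, 1))
    return MoleculeGeometry("acetic_acid", atoms, bonds, 0)


@pytest.fixture
def methyl_acetate():
    """CH3-CO-O-CH3: ester, no acidic hydrogen."""
    atoms = [
        Atom("C", (0.0, 0.0, 0.0)),       # methyl
        Atom("C", (1.51, 0.0, 0.0)),      # carbonyl C
        Atom("O", (2.13, 1.06, 0.0)),     # C=O
        Atom("O", (2.19, -1.18, 0.0)),    # ester O
        Atom("C", (3.62, -1.30, 0.0)),    # O-methyl
    ]
    bonds = [Bond(0, 1, 1), Bond(1, 2, 2), Bond(1, 3, 1), Bond(3, 4, 1)]
    return MoleculeGeometry("methyl_acetate", atoms, bonds, 0)


@pytest.fixture
def malonic_acid():
    """HOOC-CH2-COOH: two carboxyl groups -> ambiguous site."""
    atoms = [Atom("C", (0.0, 0.0, 0.0))]
    bonds = []
    frag, fbonds = carboxyl_fragment((0.0, 0.0, 0.0), 1)
    atoms += frag
    bonds += [Bond(0, 1, 1)] + fbonds
    mirrored = [
        Atom(a.element, (-a.position[0], a.position[1], a.position[2]))
        for a in frag
    ]
    off = len(atoms)
    atoms += mirrored
    bonds += [Bond(0, off, 1), Bond(off, off + 1, 2), Bond(off, off + 2, 1),
              Bond(off + 2, off + 3, 1)]
    return MoleculeGeometry("malonic_acid", atoms, bonds, 0)
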
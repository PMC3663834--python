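"""Synthetic parameter sets, toy geometries and ground-truth QSPR datasets.

Real phenol/acid structure collections are not redistributable, so every
stage of the pipeline is exercised on generated stand-ins: a planar phenol
(or acetic-acid-like) template carrying one pseudo-substituent atom, a
randomly drawn but schema-valid EEM parameter set, and pKa values produced
from a *known* linear model over the resulting charge descriptors plus
homoscedastic Gaussian noise.  Everything is deterministic per seed.

Substituent effects are emulated by shifting the pseudo-substituent
element's electronegativity parameter A: because the solved charges are
affine in the right-hand side of the EEM system, every descriptor (q_H in
particular) responds exactly affinely — hence monotonically — to the shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Atom, Bond, EemParameterSet, MoleculeGeometry, solve_eem
from .sites import (
    ACID_SYMBOLS,
    PHENOL_SYMBOLS,
    CarboxylSite,
    PhenolSite,
    extract_descriptors,
    make_dissociated,
)

SUBSTITUENT_ELEMENT = "N"

# Default study conditions for a phenol-like dataset: 74 molecules (the size
# of a typical curated phenol series) and generating coefficients chosen once
# so that, with the reference parameter set gen_parameter_set(3), the
# noiseless pKa values span ~1-10 with standard deviation ~2.7 — the spread
# real substituted-phenol series show.  Coefficient magnitudes in the
# hundreds are physical: site charges vary by only a few hundredths of an
# elementary charge across a substituent series.
DEFAULT_PHENOL_COEFFS = (260.0, -90.0, 45.0, -70.0, 35.0)
DEFAULT_PHENOL_INTERCEPT = -77.0
DEFAULT_PARAMETER_SEED = 3
DEFAULT_N_MOLECULES = 74


def phenol_study_spec(
    noise_sigma: float = 0.5, seed: int = 5, n_molecules: int = DEFAULT_N_MOLECULES
) -> "SyntheticSpec":
    """The canonical phenol-like dataset recipe (5-descriptor ground truth)."""
    return SyntheticSpec(
        n_molecules=n_molecules,
        true_coefficients=DEFAULT_PHENOL_COEFFS,
        intercept=DEFAULT_PHENOL_INTERCEPT,
        noise_sigma=noise_sigma,
        seed=seed,
        chemical_class="phenol",
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a ground-truth QSPR dataset."""

    n_molecules: int
    true_coefficients: tuple[float, ...]
    intercept: float
    noise_sigma: float
    seed: int
    chemical_class: str = "phenol"
    shift_range: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.chemical_class not in ("phenol", "carboxylic_acid"):
            raise ValueError(f"unknown chemical class {self.chemical_class!r}")
        k = len(self.true_coefficients)
        if self.n_molecules < k + 2:
            raise ValueError(
                f"need at least {k + 2} molecules for {k} coefficients"
            )


def gen_parameter_set(seed: int) -> EemParameterSet:
    """A schema-valid random EEM set for H, C, N, O (bond orders 1 and 2).

    A in [2, 12], B in [6, 16], kappa in [0.1, 1.0] — the ranges published
    calibrations fall into.
    """
    rng = np.random.default_rng(seed)
    entries = {}
    for element in ("H", "C", "N", "O"):
        for order in (1, 2):
            a = float(rng.uniform(2.0, 12.0))
            b = float(rng.uniform(6.0, 16.0))
            entries[(element, order)] = (a, b)
    return EemParameterSet(
        name=f"synthetic_{seed}",
        kappa=float(rng.uniform(0.1, 1.0)),
        entries=entries,
        provenance="synthetic (random draw, plausible ranges)",
        qm_scheme={"theory_level": "synthetic", "basis_set": "-",
                   "population_analysis": "-"},
    )


def shifted_parameter_set(
    params: EemParameterSet,
    shift: float,
    element: str = SUBSTITUENT_ELEMENT,
) -> EemParameterSet:
    """Copy of ``params`` with the element's A parameters offset by ``shift``.

    Models an electron-withdrawing/donating substituent of tunable strength
    without touching the geometry.
    """
    entries = dict(params.entries)
    for (el, order), (a, b) in params.entries.items():
        if el == element:
            entries[(el, order)] = (a + shift, b)
    return replace(params, entries=entries)


def _hexagon(radius: float) -> list[tuple[float, float, float]]:
    return [
        (radius * math.cos(k * math.pi / 3.0), radius * math.sin(k * math.pi / 3.0), 0.0)
        for k in range(6)
    ]


def _jitter(xyz, rng, amount):
    if amount <= 0:
        return [tuple(p) for p in xyz]
    noise = rng.uniform(-amount, amount, size=(len(xyz), 3))
    return [tuple(np.asarray(p) + d) for p, d in zip(xyz, noise)]


def gen_toy_phenol(
    substituent_shift: float = 0.0,
    seed: int = 0,
    jitter: float = 0.02,
) -> tuple[MoleculeGeometry, PhenolSite]:
    """Planar phenol template with a para pseudo-substituent.

    Hexagonal C6 ring (C-C 1.39 A, Kekulé-alternating bond orders), OH on
    C0 (C-O 1.36 A, O-H 0.96 A), ring hydrogens at 1.08 A, and a
    single-bonded substituent atom at the para carbon.  Small uniform
    coordinate jitter (<= ``jitter`` A per component, seeded) breaks exact
    symmetry the way real conformer generators do.  The substituent shift
    does not alter the geometry; it is applied to the parameter set at
    charge-solve time (see :func:`shifted_parameter_set`).
    """
    rng = np.random.default_rng(seed)
    ring = _hexagon(1.39)
    coords: list[tuple[float, float, float]] = list(ring)
    elements = ["C"] * 6
    bonds = [Bond(k, (k + 1) % 6, 2 if k % 2 == 0 else 1) for k in range(6)]

    def radial(idx, dist):
        x, y, _ = ring[idx]
        r = math.hypot(x, y)
        return (x * (r + dist) / r, y * (r + dist) / r, 0.0)

    o_index = len(coords)
    coords.append(radial(0, 1.36))
    elements.append("O")
    bonds.append(Bond(0, o_index, 1))
    # the acidic H sits on the C1-O axis so the unjittered template keeps an
    # exact mirror plane (meta/ortho carbons pairwise equivalent)
    h_index = len(coords)
    coords.append(radial(0, 1.36 + 0.96))
    elements.append("H")
    bonds.append(Bond(o_index, h_index, 1))
    sub_index = len(coords)
    coords.append(radial(3, 1.40))
    elements.append(SUBSTITUENT_ELEMENT)
    bonds.append(Bond(3, sub_index, 1))
    for ring_pos in (1, 2, 4, 5):
        coords.append(radial(ring_pos, 1.08))
        elements.append("H")
        bonds.append(Bond(ring_pos, len(coords) - 1, 1))

    coords = _jitter(coords, rng, jitter)
    atoms = [Atom(el, pos) for el, pos in zip(elements, coords)]
    mol = MoleculeGeometry(
        id=f"toy_phenol_s{substituent_shift:+.4f}_r{seed}",
        atoms=atoms,
        bonds=bonds,
        total_charge=0,
    )
    return mol, PhenolSite(h_index=h_index, o_index=o_index, c1_index=0)


def gen_toy_acid(
    substituent_shift: float = 0.0,
    seed: int = 0,
    jitter: float = 0.02,
) -> tuple[MoleculeGeometry, CarboxylSite]:
    """Acetic-acid-like template: CH2X-COOH with pseudo-substituent X.

    Carboxyl C at the origin, carbonyl O double-bonded, hydroxyl O-H, a
    methylene carbon carrying two hydrogens and the substituent atom.
    """
    rng = np.random.default_rng(seed)
    coords = [
        (0.0, 0.0, 0.0),       # 0 C1 carboxyl carbon
        (0.62, 1.06, 0.0),     # 1 O2 carbonyl oxygen (C=O 1.23)
        (0.68, -1.18, 0.0),    # 2 O hydroxyl oxygen (C-O 1.36)
        (1.64, -1.10, 0.0),    # 3 H acidic hydrogen (O-H ~0.96)
        (-1.51, 0.0, 0.0),     # 4 C methylene carbon (C-C 1.51)
        (-2.05, 0.92, 0.35),   # 5 H
        (-2.05, -0.92, 0.35),  # 6 H
        (-2.10, 0.02, -1.32),  # 7 X substituent (C-X ~1.45)
    ]
    elements = ["C", "O", "O", "H", "C", "H", "H", SUBSTITUENT_ELEMENT]
    bonds = [
        Bond(0, 1, 2),
        Bond(0, 2, 1),
        Bond(2, 3, 1),
        Bond(0, 4, 1),
        Bond(4, 5, 1),
        Bond(4, 6, 1),
        Bond(4, 7, 1),
    ]
    coords = _jitter(coords, rng, jitter)
    atoms = [Atom(el, pos) for el, pos in zip(elements, coords)]
    mol = MoleculeGeometry(
        id=f"toy_acid_s{substituent_shift:+.4f}_r{seed}",
        atoms=atoms,
        bonds=bonds,
        total_charge=0,
    )
    return mol, CarboxylSite(h_index=3, o_index=2, o2_index=1, c1_index=0)


def descriptor_record(
    mol: MoleculeGeometry,
    site,
    params: EemParameterSet,
    shift: float = 0.0,
) -> dict:
    """Solve neutral + anion charges (anion at Q_parent - 1) and extract the
    descriptor record, applying the substituent parameter shift."""
    p = shifted_parameter_set(params, shift) if shift != 0.0 else params
    diss, _ = make_dissociated(mol, site)
    return extract_descriptors(
        mol, diss, site, solve_eem(mol, p), solve_eem(diss, p)
    )


def gen_qspr_dataset(
    spec: SyntheticSpec, params: EemParameterSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor table plus pKa table with known generating model.

    Substituent shifts are spread evenly over ``spec.shift_range`` (plus
    per-molecule geometric jitter), descriptors come from the actual EEM
    pipeline, and pKa_exp = true linear model + N(0, noise_sigma^2).
    """
    rng = np.random.default_rng(spec.seed)
    make = gen_toy_phenol if spec.chemical_class == "phenol" else gen_toy_acid
    lo, hi = spec.shift_range
    shifts = np.linspace(lo, hi, spec.n_molecules)
    records = []
    for m, shift in enumerate(shifts):
        mol, site = make(float(shift), seed=int(rng.integers(0, 2**31)))
        mol.id = f"syn{m:03d}"
        rec = descriptor_record(mol, site, params, float(shift))
        records.append(rec)
    desc = pd.DataFrame(records)
    symbols = list(
        PHENOL_SYMBOLS if spec.chemical_class == "phenol" else ACID_SYMBOLS
    )
    k = len(spec.true_coefficients)
    used = symbols[:k]
    if len(used) < k:
        raise ValueError(
            f"{k} coefficients but only {len(used)} descriptors available"
        )
    X = desc[used].to_numpy(dtype=float)
    noise = rng.normal(0.0, spec.noise_sigma, size=spec.n_molecules)
    pka = X @ np.asarray(spec.true_coefficients) + spec.intercept + noise
    pka_table = pd.DataFrame(
        {"molecule_id": desc["molecule_id"], "pka_exp": pka}
    )
    return desc, pka_table
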
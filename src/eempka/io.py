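"""Readers and writers for the formats the pipeline touches.

* SDF / MOL V2000 connection tables (multi-record, ``$$$$``-separated),
  including ``M  CHG`` formal-charge properties.  V3000 is rejected.
* Parameter-set documents: one JSON file per EEM set, with kappa, the
  QM scheme the set was calibrated against, and the (element, bond-order)
  -> (A, B) table.  A directory of such files acts as a registry.
* CSV tables for experimental pKa values and charge descriptors
  (comma-separated, "." decimal, UTF-8, mandatory header).
* Fitted-model documents (JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import Atom, Bond, EemParameterSet, MoleculeGeometry, WILDCARD_ORDER
from .errors import ParseError, SchemaError

DESCRIPTOR_SYMBOLS = ("q_H", "q_O", "q_C1", "q_O2", "q_OD", "q_C1D", "q_O2D")

# ---------------------------------------------------------------------------
# SDF / MOL V2000


def _parse_mol_block(lines: list[str], record_index: int, default_id: str) -> MoleculeGeometry:
    if len(lines) < 4:
        raise ParseError(f"record {record_index}: truncated header block")
    title = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise ParseError(f"record {record_index}: V3000 is not supported")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError as exc:
        raise ParseError(
            f"record {record_index}: malformed counts line {counts!r}"
        ) from exc
    atom_lines = lines[4 : 4 + n_atoms]
    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise ParseError(
            f"record {record_index}: truncated atom/bond block "
            f"(expected {n_atoms} atoms, {n_bonds} bonds)"
        )

    elements, positions, charges = [], [], []
    for k, line in enumerate(atom_lines):
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            element = line[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"record {record_index}: bad atom line {k + 1}: {line!r}"
            ) from exc
        elements.append(element)
        positions.append((x, y, z))
        charges.append(0)

    bonds = []
    for k, line in enumerate(bond_lines):
        try:
            i, j, order = int(line[0:3]), int(line[3:6]), int(line[6:9])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"record {record_index}: bad bond line {k + 1}: {line!r}"
            ) from exc
        aromatic = order == 4
        bonds.append(Bond(i - 1, j - 1, 2 if aromatic else order, aromatic))

    # M  CHG property lines override the (legacy) atom-block charge column.
    saw_chg = False
    for line in lines[4 + n_atoms + n_bonds :]:
        if line.startswith("M  CHG"):
            fields = line.split()
            count = int(fields[2])
            pairs = fields[3 : 3 + 2 * count]
            if not saw_chg:
                charges = [0] * n_atoms
                saw_chg = True
            for a, c in zip(pairs[0::2], pairs[1::2]):
                charges[int(a) - 1] = int(c)
        elif line.startswith("M  END"):
            break

    atoms = [
        Atom(el, pos, chg)
        for el, pos, chg in zip(elements, positions, charges)
    ]
    return MoleculeGeometry(
        id=title or default_id,
        atoms=atoms,
        bonds=bonds,
        total_charge=sum(charges),
    )


def read_sdf(path: str | Path) -> list[MoleculeGeometry]:
    """Parse a multi-record V2000 SDF file into molecule geometries.

    Formal charges from ``M  CHG`` lines are summed into the molecule's total
    charge Q.  Empty files yield an empty list.
    """
    text = Path(path).read_text()
    mols: list[MoleculeGeometry] = []
    record: list[str] = []
    index = 0
    for raw in text.splitlines():
        if raw.strip() == "$$$$":
            if any(line.strip() for line in record):
                mols.append(_parse_mol_block(record, index, f"mol_{index}"))
                index += 1
            record = []
        else:
            record.append(raw)
    if any(line.strip() for line in record):
        mols.append(_parse_mol_block(record, index, f"mol_{index}"))
    return mols


def write_sdf(mols: list[MoleculeGeometry] | MoleculeGeometry, path: str | Path) -> None:
    """Write molecules as V2000 SDF; coordinates at the 4-decimal field width."""
    if isinstance(mols, MoleculeGeometry):
        mols = [mols]
    blocks = []
    for mol in mols:
        lines = [mol.id, "  eempka", "", f"{mol.n_atoms:>3}{len(mol.bonds):>3}  0  0  0  0  0  0  0  0999 V2000"]
        for atom in mol.atoms:
            x, y, z = atom.position
            lines.append(
                f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {atom.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
            )
        for b in mol.bonds:
            order = 4 if b.aromatic else b.order
            lines.append(f"{b.i + 1:>3}{b.j + 1:>3}{order:>3}  0  0  0  0")
        charged = [(i + 1, a.formal_charge) for i, a in enumerate(mol.atoms) if a.formal_charge]
        for start in range(0, len(charged), 8):
            chunk = charged[start : start + 8]
            body = "".join(f"{i:>4}{c:>4}" for i, c in chunk)
            lines.append(f"M  CHG{len(chunk):>3}{body}")
        lines.append("M  END")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n$$$$\n".join(blocks) + "\n$$$$\n")


# ---------------------------------------------------------------------------
# Parameter-set documents


def read_parameter_set(path: str | Path) -> EemParameterSet:
    doc = json.loads(Path(path).read_text())
    for key in ("name", "kappa", "entries"):
        if key not in doc:
            raise SchemaError(f"{path}: missing required field {key!r}")
    entries: dict = {}
    for entry in doc["entries"]:
        try:
            element = entry["element"]
            order_raw = str(entry["bond_order"])
            a, b = float(entry["A"]), float(entry["B"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed entry {entry!r}") from exc
        if order_raw == WILDCARD_ORDER:
            order: int | str = WILDCARD_ORDER
        elif order_raw in ("1", "2", "3"):
            order = int(order_raw)
        else:
            raise SchemaError(f"{path}: bond_order must be 1, 2, 3 or '*', got {order_raw!r}")
        key = (element, order)
        if key in entries:
            raise SchemaError(f"{path}: duplicate entry for {key}")
        entries[key] = (a, b)
    return EemParameterSet(
        name=doc["name"],
        kappa=float(doc["kappa"]),
        entries=entries,
        provenance=doc.get("provenance", ""),
        qm_scheme=doc.get("qm_scheme", {}),
    )


def write_parameter_set(params: EemParameterSet, path: str | Path) -> None:
    doc = {
        "name": params.name,
        "qm_scheme": params.qm_scheme,
        "provenance": params.provenance,
        "kappa": params.kappa,
        "entries": [
            {"element": el, "bond_order": str(order), "A": a, "B": b}
            for (el, order), (a, b) in sorted(
                params.entries.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
            )
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_parameter_registry(directory: str | Path) -> dict[str, EemParameterSet]:
    """Read every ``*.json`` parameter document in a directory, keyed by name."""
    registry = {}
    for p in sorted(Path(directory).glob("*.json")):
        params = read_parameter_set(p)
        registry[params.name] = params
    return registry


# ---------------------------------------------------------------------------
# CSV tables


def read_dataset_table(path: str | Path) -> pd.DataFrame:
    """Experimental pKa table: columns molecule_id, pka_exp (+ extras kept)."""
    df = pd.read_csv(path, comment="#")
    if "molecule_id" not in df.columns or "pka_exp" not in df.columns:
        raise SchemaError(f"{path}: needs molecule_id and pka_exp columns")
    df["molecule_id"] = df["molecule_id"].astype(str)
    try:
        df["pka_exp"] = pd.to_numeric(df["pka_exp"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric pka_exp value") from exc
    if df["molecule_id"].duplicated().any():
        dup = df.loc[df["molecule_id"].duplicated(), "molecule_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate molecule_id {dup!r}")
    if not df["pka_exp"].notna().all():
        row = int(df.index[df["pka_exp"].isna()][0])
        raise ParseError(f"{path}: missing pka_exp in row {row}")
    return df


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Charge-descriptor table keyed by molecule_id.

    Descriptor columns are any of q_H, q_O, q_C1, q_O2, q_OD, q_C1D, q_O2D;
    unknown columns are preserved untouched.
    """
    df = pd.read_csv(path, comment="#")
    if "molecule_id" not in df.columns:
        raise SchemaError(f"{path}: needs a molecule_id column")
    df["molecule_id"] = df["molecule_id"].astype(str)
    present = [c for c in DESCRIPTOR_SYMBOLS if c in df.columns]
    if not present:
        raise SchemaError(f"{path}: no recognized descriptor columns")
    for col in present:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ParseError(
                f"{path}: non-numeric {col} in row {int(bad)}"
            ) from exc
        if not df[col].notna().all():
            row = int(df.index[df[col].isna()][0])
            raise ParseError(f"{path}: missing {col} in row {row}")
    return df


# ---------------------------------------------------------------------------
# Fitted-model documents


def save_model(model, path: str | Path) -> None:
    from .qspr import QsprModel  # local import to avoid cycle

    assert isinstance(model, QsprModel)
    doc = {
        "kind": model.kind,
        "descriptor_symbols": list(model.descriptor_symbols),
        "coefficients": list(model.coefficients),
        "intercept": model.intercept,
        "charge_scheme": model.charge_scheme,
        "training_ids": list(model.training_ids),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path):
    from .qspr import QsprModel

    doc = json.loads(Path(path).read_text())
    try:
        return QsprModel(
            kind=doc["kind"],
            descriptor_symbols=tuple(doc["descriptor_symbols"]),
            coefficients=tuple(doc["coefficients"]),
            intercept=float(doc["intercept"]),
            charge_scheme=doc.get("charge_scheme", ""),
            training_ids=tuple(doc.get("training_ids", ())),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing model field {exc}") from exc
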
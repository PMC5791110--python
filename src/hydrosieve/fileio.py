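"""Structure file I/O: PDB, SYBYL MOL2 and (extended) XYZ.

MOL2 is the canonical on-disk form because it round-trips partial charges
and bonds; PDB carries neither and XYZ optionally carries a fourth charge
column.  ``write_structure`` followed by ``read_structure`` restores
coordinates to 1e-3 Å and elements/charges exactly (where the format can
express them).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .core import ArgumentError, Atom, Bond, Molecule, ParseError

log = logging.getLogger(__name__)

FORMATS = ("pdb", "mol2", "xyz")

_MOL2_LABEL_TO_SUBST = {"PVA": "PVA", "linker": "LNK", "DMT": "DMT", "water": "WAT",
                        "other": "UNK"}
_SUBST_TO_LABEL = {v: k for k, v in _MOL2_LABEL_TO_SUBST.items()}


def _infer_format(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in FORMATS:
        raise ArgumentError(f"unsupported structure format {fmt!r}; use one of {FORMATS}")
    return fmt


def read_structure(path, format: str | None = None) -> Molecule:
    fmt = _infer_format(path, format)
    text = Path(path).read_text()
    reader = {"pdb": _read_pdb, "mol2": _read_mol2, "xyz": _read_xyz}[fmt]
    mol = reader(text, str(path))
    mol.name = mol.name or Path(path).stem
    return mol


def write_structure(mol: Molecule, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    writer = {"pdb": _write_pdb, "mol2": _write_mol2, "xyz": _write_xyz}[fmt]
    Path(path).write_text(writer(mol))


# ---------------------------------------------------------------- MOL2

def _write_mol2(mol: Molecule) -> str:
    lines = ["@<TRIPOS>MOLECULE", mol.name or "molecule",
             f"{len(mol.atoms)} {len(mol.bonds)} 0 0 0", "SMALL", "USER_CHARGES", "",
             "@<TRIPOS>ATOM"]
    idmap = {a.atom_id: i + 1 for i, a in enumerate(mol.atoms)}
    for a in mol.atoms:
        x, y, z = a.position
        subst = _MOL2_LABEL_TO_SUBST.get(a.label, "UNK")
        lines.append(
            f"{idmap[a.atom_id]:>7d} {a.element}{a.atom_id:<6d} "
            f"{x:>12.4f} {y:>12.4f} {z:>12.4f} {a.element:<5s} 1 {subst:<4s} "
            f"{a.partial_charge:>12.6f}"
        )
    lines.append("@<TRIPOS>BOND")
    for i, b in enumerate(mol.bonds):
        order = "ar" if b.order == 1.5 else str(int(b.order))
        lines.append(f"{i + 1:>6d} {idmap[b.a]:>6d} {idmap[b.b]:>6d} {order:>4s}")
    return "\n".join(lines) + "\n"


def _read_mol2(text: str, origin: str) -> Molecule:
    section = None
    counts = None
    name = ""
    mol_lines_seen = 0
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            mol_lines_seen = 0
            continue
        if not line or line.startswith("#"):
            continue
        try:
            if section == "MOLECULE":
                mol_lines_seen += 1
                if mol_lines_seen == 1:
                    name = line
                elif mol_lines_seen == 2:
                    counts = tuple(int(t) for t in line.split()[:2])
            elif section == "ATOM":
                t = line.split()
                x, y, z = float(t[2]), float(t[3]), float(t[4])
                element = t[5].split(".")[0]
                charge = float(t[8]) if len(t) > 8 else 0.0
                label = _SUBST_TO_LABEL.get(t[7], "other") if len(t) > 7 else "other"
                atoms.append(Atom(element=element, position=(x, y, z),
                                  partial_charge=charge, label=label,
                                  atom_id=int(t[0]) - 1))
            elif section == "BOND":
                t = line.split()
                order = 1.5 if t[3] in ("ar", "am") else float(t[3])
                bonds.append(Bond(int(t[1]) - 1, int(t[2]) - 1, order))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{origin}: malformed MOL2 at line {lineno}: {raw!r}") from exc
    if counts is None:
        raise ParseError(f"{origin}: missing @<TRIPOS>MOLECULE header")
    if counts[0] != len(atoms) or counts[1] != len(bonds):
        raise ParseError(
            f"{origin}: header promises {counts[0]} atoms/{counts[1]} bonds, "
            f"found {len(atoms)}/{len(bonds)} (truncated file?)"
        )
    return Molecule(atoms=atoms, bonds=bonds, name=name)


# ---------------------------------------------------------------- PDB

_LABEL_TO_RESNAME = {"PVA": "PVA", "linker": "LNK", "DMT": "DMT", "water": "HOH",
                     "other": "UNK"}
_RESNAME_TO_LABEL = {v: k for k, v in _LABEL_TO_RESNAME.items()}


def _write_pdb(mol: Molecule, model: int | None = None) -> str:
    lines = []
    if model is not None:
        lines.append(f"MODEL     {model:>4d}")
    idmap = {}
    for i, a in enumerate(mol.atoms, start=1):
        idmap[a.atom_id] = i
        x, y, z = a.position
        resname = _LABEL_TO_RESNAME.get(a.label, "UNK")
        atname = (a.element + str(a.atom_id % 100))[:4]
        lines.append(
            f"HETATM{i % 100000:>5d} {atname:<4s} {resname:<3s} A{1:>4d}    "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}          "
            f"{a.element:>2s}"
        )
    for b in mol.bonds:
        lines.append(f"CONECT{idmap[b.a] % 100000:>5d}{idmap[b.b] % 100000:>5d}")
    lines.append("ENDMDL" if model is not None else "END")
    return "\n".join(lines) + "\n"


def _read_pdb(text: str, origin: str) -> Molecule:
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    saw_end = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                x = float(raw[30:38])
                y = float(raw[38:46])
                z = float(raw[46:54])
                element = raw[76:78].strip() or raw[12:16].strip()[:1]
                resname = raw[17:20].strip()
            except ValueError as exc:
                raise ParseError(f"{origin}: malformed PDB at line {lineno}: {raw!r}") from exc
            atoms.append(Atom(element=element, position=(x, y, z),
                              label=_RESNAME_TO_LABEL.get(resname, "other"),
                              atom_id=len(atoms)))
        elif rec == "CONECT":
            try:
                ids = [int(raw[6 + 5 * k: 11 + 5 * k]) for k in range(2)
                       if raw[6 + 5 * k: 11 + 5 * k].strip()]
            except ValueError as exc:
                raise ParseError(f"{origin}: malformed CONECT at line {lineno}") from exc
            if len(ids) == 2:
                bonds.append(Bond(ids[0] - 1, ids[1] - 1))
        elif rec in ("END", "ENDMDL"):
            saw_end = True
    if not atoms:
        raise ParseError(f"{origin}: no ATOM/HETATM records found")
    if not saw_end:
        raise ParseError(f"{origin}: missing END record (truncated file?)")
    if atoms and all(a.partial_charge == 0 for a in atoms):
        log.warning("%s: PDB carries no partial charges; charges set to 0", origin)
    return Molecule(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------- XYZ

def _write_xyz(mol: Molecule) -> str:
    lines = [str(len(mol.atoms)), f"{mol.name or 'molecule'} charge-column=e"]
    for a in mol.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<3s} {x:>14.6f} {y:>14.6f} {z:>14.6f} "
                     f"{a.partial_charge:>12.6f}")
    return "\n".join(lines) + "\n"


def _read_xyz(text: str, origin: str) -> Molecule:
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{origin}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{origin}: bad XYZ atom count at line 1") from exc
    body = lines[2: 2 + n]
    if len(body) < n:
        raise ParseError(f"{origin}: XYZ promises {n} atoms, found {len(body)}")
    atoms = []
    missing_charges = False
    for k, raw in enumerate(body):
        lineno = k + 3
        t = raw.split()
        try:
            el = t[0]
            x, y, z = float(t[1]), float(t[2]), float(t[3])
            if len(t) > 4:
                q = float(t[4])
            else:
                q = 0.0
                missing_charges = True
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{origin}: malformed XYZ at line {lineno}: {raw!r}") from exc
        atoms.append(Atom(element=el, position=(x, y, z), partial_charge=q, atom_id=k))
    if missing_charges:
        log.warning("%s: XYZ file lacks a charge column; charges set to 0", origin)
    name = lines[1].split("charge-column")[0].strip() if len(lines) > 1 else ""
    return Molecule(atoms=atoms, name=name)


# ------------------------------------------------------- trajectories

def write_multimodel_pdb(frames_coords, template: Molecule, path) -> None:
    """Write a multi-model PDB: one MODEL per frame over a fixed topology."""
    chunks = []
    for m, coords in enumerate(frames_coords, start=1):
        chunks.append(_write_pdb(template.with_coordinates(coords), model=m))
    Path(path).write_text("".join(chunks) + "END\n")


def read_multimodel_pdb(path) -> list[np.ndarray]:
    """Read per-frame coordinate arrays from a multi-model PDB."""
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    in_model = False
    for raw in Path(path).read_text().splitlines():
        rec = raw[:6].strip()
        if rec == "MODEL":
            in_model, current = True, []
        elif rec == "ENDMDL":
            frames.append(np.array(current))
            in_model = False
        elif rec in ("ATOM", "HETATM") and in_model:
            current.append([float(raw[30:38]), float(raw[38:46]), float(raw[46:54])])
    if not frames:
        raise ParseError(f"{path}: no MODEL records found")
    return frames
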
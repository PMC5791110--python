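"""Molecular data model shared by every pipeline stage.

A :class:`Molecule` is an ordered list of :class:`Atom` records plus a bond
list.  It is deliberately minimal — element, position, partial charge, vdW
radius and a role label are the only per-atom quantities any downstream
computation needs (contact placement, surrogate energies, observables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    ATOMIC_MASSES,
    BONDI_RADII,
    CARBOXYL_H_CHARGE,
    DEFAULT_VDW_RADIUS,
    HYDROXYL_H_CHARGE,
    OH_BOND,
    PKA_CARBOXYL,
    PKA_HYDROXYL,
)

VALID_LABELS = ("PVA", "linker", "DMT", "water", "other")


class HydrosieveError(Exception):
    """Base class for package errors."""


class ArgumentError(HydrosieveError, ValueError):
    """Invalid argument to an operation."""


class ParseError(HydrosieveError, ValueError):
    """Malformed structure file."""


class TemplateNotFoundError(HydrosieveError, KeyError):
    """Unknown molecule template name."""


@dataclass(frozen=True)
class Atom:
    """A point atom: element, Cartesian position (Å), partial charge (e),
    van der Waals radius (Å) and a role label."""

    element: str
    position: tuple[float, float, float]
    partial_charge: float = 0.0
    vdw_radius: float | None = None
    label: str = "other"
    atom_id: int = 0

    def __post_init__(self):
        if self.vdw_radius is None:
            object.__setattr__(
                self, "vdw_radius", BONDI_RADII.get(self.element, DEFAULT_VDW_RADIUS)
            )
        if self.vdw_radius <= 0:
            raise ArgumentError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if not all(math.isfinite(c) for c in self.position):
            raise ArgumentError(f"non-finite position {self.position}")

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element]
        except KeyError:
            raise ArgumentError(f"no atomic mass tabulated for element {self.element!r}")


@dataclass
class Bond:
    a: int
    b: int
    order: float = 1.0

    def as_tuple(self) -> tuple[int, int]:
        return (self.a, self.b)


@dataclass
class Molecule:
    """Ordered atoms + bonds.  ``net_charge`` always equals the sum of the
    atomic partial charges (enforced at construction and after edits)."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ArgumentError(f"duplicate atom ids in molecule {self.name!r}")
        idset = set(ids)
        for b in self.bonds:
            if b.a not in idset or b.b not in idset:
                raise ArgumentError(f"bond ({b.a},{b.b}) references missing atom")

    # ---- basic views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def formula(self) -> str:
        """Hill-order molecular formula."""
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        parts = []
        for el in ("C", "H"):
            if el in counts:
                n = counts.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(counts):
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def molar_mass(self) -> float:
        return float(self.masses.sum())

    def index_of(self, atom_id: int) -> int:
        for i, a in enumerate(self.atoms):
            if a.atom_id == atom_id:
                return i
        raise ArgumentError(f"atom id {atom_id} not in molecule {self.name!r}")

    def atom(self, atom_id: int) -> Atom:
        return self.atoms[self.index_of(atom_id)]

    def neighbors(self, atom_id: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == atom_id:
                out.append(b.b)
            elif b.b == atom_id:
                out.append(b.a)
        return out

    # ---- edits (return new objects; Molecule is cheap to copy) -------

    def with_coordinates(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ArgumentError(
                f"coordinate array shape {coords.shape} != ({len(self.atoms)}, 3)"
            )
        atoms = [
            replace(a, position=tuple(float(x) for x in coords[i]))
            for i, a in enumerate(self.atoms)
        ]
        return Molecule(atoms=atoms, bonds=list(self.bonds), name=self.name,
                        meta=dict(self.meta))

    def translated(self, shift) -> "Molecule":
        return self.with_coordinates(self.coordinates + np.asarray(shift, float))

    def rotated(self, R: np.ndarray) -> "Molecule":
        return self.with_coordinates(self.coordinates @ np.asarray(R, float).T)

    def relabeled(self, label: str) -> "Molecule":
        if label not in VALID_LABELS:
            raise ArgumentError(f"unknown role label {label!r}")
        atoms = [replace(a, label=label) for a in self.atoms]
        return Molecule(atoms=atoms, bonds=list(self.bonds), name=self.name,
                        meta=dict(self.meta))

    def copy(self) -> "Molecule":
        return Molecule(atoms=list(self.atoms), bonds=list(self.bonds), name=self.name,
                        meta=dict(self.meta))


def center_of_mass(mol: Molecule) -> np.ndarray:
    """Mass-weighted mean position (Å) using standard atomic weights."""
    if len(mol) == 0:
        raise ArgumentError("center_of_mass of an empty molecule")
    m = mol.masses
    return (m[:, None] * mol.coordinates).sum(axis=0) / m.sum()


def centered(mol: Molecule) -> Molecule:
    """Molecule translated so its mass center sits at the origin."""
    return mol.translated(-center_of_mass(mol))


def merge(mols: list[Molecule], name: str = "") -> Molecule:
    """Concatenate molecules into one, renumbering atom ids contiguously."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    offset = 0
    for mol in mols:
        idmap = {}
        for a in mol.atoms:
            idmap[a.atom_id] = offset
            atoms.append(replace(a, atom_id=offset))
            offset += 1
        bonds.extend(Bond(idmap[b.a], idmap[b.b], b.order) for b in mol.bonds)
    return Molecule(atoms=atoms, bonds=bonds, name=name)


# ---------------------------------------------------------------------
# Ionizable-group detection and the two-state protonation model
# ---------------------------------------------------------------------

@dataclass
class IonizableGroup:
    kind: str              # "carboxyl" | "hydroxyl"
    pka: float
    atoms: list[int]       # atom ids: carboxyl = [C, O, O]; hydroxyl = [O]
    acidic_h: int | None   # atom id of the acidic proton, None if deprotonated

    @property
    def protonated(self) -> bool:
        return self.acidic_h is not None


def find_ionizable_groups(mol: Molecule) -> list[IonizableGroup]:
    """Detect carboxyl(ate) and alcohol hydroxyl groups from the bond graph.

    A carboxyl carbon is a C bonded to exactly two oxygens that have no
    further heavy-atom neighbors; a hydroxyl is an O bonded to one C (and
    optionally one H) that is not part of a carboxyl.
    """
    groups: list[IonizableGroup] = []
    by_id = {a.atom_id: a for a in mol.atoms}
    carboxyl_oxygens: set[int] = set()

    for a in mol.atoms:
        if a.element != "C":
            continue
        oxys = [n for n in mol.neighbors(a.atom_id) if by_id[n].element == "O"]
        terminal_oxys = []
        for o in oxys:
            o_nb = [n for n in mol.neighbors(o) if n != a.atom_id]
            heavy = [n for n in o_nb if by_id[n].element != "H"]
            if not heavy:
                terminal_oxys.append((o, [n for n in o_nb if by_id[n].element == "H"]))
        if len(terminal_oxys) == 2:
            h_ids = [h for _, hs in terminal_oxys for h in hs]
            acidic = h_ids[0] if h_ids else None
            groups.append(
                IonizableGroup(
                    kind="carboxyl",
                    pka=PKA_CARBOXYL,
                    atoms=[a.atom_id] + [o for o, _ in terminal_oxys],
                    acidic_h=acidic,
                )
            )
            carboxyl_oxygens.update(o for o, _ in terminal_oxys)

    for a in mol.atoms:
        if a.element != "O" or a.atom_id in carboxyl_oxygens:
            continue
        nb = mol.neighbors(a.atom_id)
        heavy = [n for n in nb if by_id[n].element != "H"]
        hs = [n for n in nb if by_id[n].element == "H"]
        if len(heavy) == 1 and by_id[heavy[0]].element == "C" and len(hs) <= 1:
            groups.append(
                IonizableGroup(
                    kind="hydroxyl",
                    pka=PKA_HYDROXYL,
                    atoms=[a.atom_id],
                    acidic_h=hs[0] if hs else None,
                )
            )
    return groups


def assign_protonation(mol: Molecule, pH: float) -> Molecule:
    """Set every ionizable group to its majority state at ``pH``.

    Two-state Henderson–Hasselbalch threshold: a group with pKa < pH is
    deprotonated, pKa > pH protonated.  Deprotonation removes the acidic
    proton and spreads (q_H − 1) over the group oxygens so the net charge
    drops by exactly 1; protonation is the inverse.  Idempotent.
    """
    mol = mol.copy()
    changed = True
    # re-detect after each edit: atom ids shift when protons are added/removed
    while changed:
        changed = False
        for g in find_ionizable_groups(mol):
            want_protonated = g.pka > pH
            if want_protonated == g.protonated:
                continue
            if g.protonated:
                mol = _remove_proton(mol, g)
            else:
                mol = _add_proton(mol, g)
            changed = True
            break
    return mol


def _spread_charge(mol: Molecule, atom_ids: list[int], dq: float) -> Molecule:
    atoms = list(mol.atoms)
    per = dq / len(atom_ids)
    for aid in atom_ids:
        i = mol.index_of(aid)
        atoms[i] = replace(atoms[i], partial_charge=atoms[i].partial_charge + per)
    return Molecule(atoms=atoms, bonds=list(mol.bonds), name=mol.name, meta=dict(mol.meta))


def _remove_proton(mol: Molecule, g: IonizableGroup) -> Molecule:
    h_id = g.acidic_h
    q_h = mol.atom(h_id).partial_charge
    oxygens = g.atoms if g.kind == "hydroxyl" else g.atoms[1:]
    atoms = [a for a in mol.atoms if a.atom_id != h_id]
    bonds = [b for b in mol.bonds if h_id not in (b.a, b.b)]
    out = Molecule(atoms=atoms, bonds=bonds, name=mol.name, meta=dict(mol.meta))
    return _spread_charge(out, oxygens, q_h - 1.0)


def _add_proton(mol: Molecule, g: IonizableGroup) -> Molecule:
    oxygens = g.atoms if g.kind == "hydroxyl" else g.atoms[1:]
    o_id = oxygens[0]
    o = mol.atom(o_id)
    q_h = HYDROXYL_H_CHARGE if g.kind == "hydroxyl" else CARBOXYL_H_CHARGE
    # place H along the direction away from the oxygen's heavy neighbor
    by_id = {a.atom_id: a for a in mol.atoms}
    heavy = [n for n in mol.neighbors(o_id) if by_id[n].element != "H"]
    opos = np.array(o.position)
    if heavy:
        d = opos - np.array(by_id[heavy[0]].position)
        nrm = np.linalg.norm(d)
        d = d / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
    else:
        d = np.array([0.0, 0.0, 1.0])
    new_id = max(a.atom_id for a in mol.atoms) + 1
    h = Atom(
        element="H",
        position=tuple(opos + OH_BOND * d),
        partial_charge=q_h,
        label=o.label,
        atom_id=new_id,
    )
    out = Molecule(atoms=mol.atoms + [h], bonds=mol.bonds + [Bond(o_id, new_id)],
                   name=mol.name, meta=dict(mol.meta))
    return _spread_charge(out, oxygens, -q_h + 1.0)
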
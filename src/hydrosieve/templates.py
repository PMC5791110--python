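"""Built-in molecule templates and the idealized PVA chain builder.

Seventeen templates are available: dimethoate (the organophosphate guest),
water, a PVA monomer, and the fourteen dicarboxylic-acid crosslinker
candidates (oxalic through azelaic).  Diacid templates carry both
carboxylates deprotonated (net charge −2), the state relevant at the
working pH of 5.5; PVA hydroxyls are protonated.

Geometries are generated once per process from curated SMILES with RDKit's
ETKDGv3 embedding at a fixed seed, so they are bit-reproducible.  Partial
charges are Gasteiger charges normalized to the formal net charge; pass a
``charge_fn`` to :func:`load_template` to substitute your own scheme.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .constants import (
    CC_BOND,
    CH_BOND,
    CO_BOND,
    HYDROXYL_H_CHARGE,
    OH_BOND,
    TETRAHEDRAL_ANGLE_DEG,
)
from .core import ArgumentError, Atom, Bond, Molecule, TemplateNotFoundError

_EMBED_SEED = 0xC0FFEE % (2**31)

# deprotonated dicarboxylates, in the conventional screening order
DIACID_SMILES = {
    "oxalic": "[O-]C(=O)C(=O)[O-]",
    "malonic": "[O-]C(=O)CC(=O)[O-]",
    "succinic": "[O-]C(=O)CCC(=O)[O-]",
    "malic": "[O-]C(=O)CC(O)C(=O)[O-]",
    "fumaric": "[O-]C(=O)/C=C/C(=O)[O-]",
    "maleic": "[O-]C(=O)/C=C\\C(=O)[O-]",
    "citraconic": "[O-]C(=O)/C(C)=C\\C(=O)[O-]",
    "itaconic": "[O-]C(=O)CC(=C)C(=O)[O-]",
    "tartaric": "[O-]C(=O)[C@H](O)[C@@H](O)C(=O)[O-]",
    "glutaric": "[O-]C(=O)CCCC(=O)[O-]",
    "adipic": "[O-]C(=O)CCCCC(=O)[O-]",
    "pimelic": "[O-]C(=O)CCCCCC(=O)[O-]",
    "suberic": "[O-]C(=O)CCCCCCC(=O)[O-]",
    "azelaic": "[O-]C(=O)CCCCCCCC(=O)[O-]",
}

_OTHER_SMILES = {
    "dimethoate": "CNC(=O)CSP(=S)(OC)OC",
    "water": "O",
    "pva_monomer": "CC(O)C",  # isopropanol stand-in for one -CH2-CH(OH)- unit
}

TEMPLATE_NAMES = tuple(_OTHER_SMILES) + tuple(DIACID_SMILES)

_LABELS = {"dimethoate": "DMT", "water": "water", "pva_monomer": "PVA"}


def gasteiger_charges(rdmol: Chem.Mol) -> np.ndarray:
    """Gasteiger partial charges, shifted so they sum to the formal charge."""
    AllChem.ComputeGasteigerCharges(rdmol)
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in rdmol.GetAtoms()], dtype=float
    )
    q[~np.isfinite(q)] = 0.0
    formal = float(Chem.GetFormalCharge(rdmol))
    q += (formal - q.sum()) / len(q)
    return q


def _embed(smiles: str) -> Chem.Mol:
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ArgumentError(f"bad template SMILES {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise ArgumentError(f"3-D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
    return rdmol


def from_rdkit(rdmol: Chem.Mol, name: str, label: str, charges=None) -> Molecule:
    conf = rdmol.GetConformer()
    if charges is None:
        charges = gasteiger_charges(rdmol)
    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                position=(p.x, p.y, p.z),
                partial_charge=float(charges[i]),
                label=label,
                atom_id=i,
            )
        )
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=bonds, name=name)


@functools.lru_cache(maxsize=None)
def _template_cached(name: str) -> Molecule:
    smiles = _OTHER_SMILES.get(name) or DIACID_SMILES.get(name)
    if smiles is None:
        raise TemplateNotFoundError(
            f"unknown template {name!r}; valid names: {', '.join(TEMPLATE_NAMES)}"
        )
    label = _LABELS.get(name, "linker")
    return from_rdkit(_embed(smiles), name, label)


def load_template(name: str, charge_fn=None) -> Molecule:
    """Return a fresh copy of a built-in template by name.

    ``charge_fn(molecule) -> array`` optionally overrides the shipped
    Gasteiger charges.
    """
    mol = _template_cached(name).copy()
    if charge_fn is not None:
        q = np.asarray(charge_fn(mol), dtype=float)
        if q.shape != (len(mol),):
            raise ArgumentError("charge_fn must return one charge per atom")
        from dataclasses import replace

        mol = Molecule(
            atoms=[replace(a, partial_charge=float(q[i])) for i, a in enumerate(mol.atoms)],
            bonds=list(mol.bonds),
            name=mol.name,
        )
    return mol


def carboxylate_carbons(mol: Molecule) -> list[int]:
    """Atom ids of carboxylate carbons (C bonded to two terminal oxygens)."""
    by_id = {a.atom_id: a for a in mol.atoms}
    out = []
    for a in mol.atoms:
        if a.element != "C":
            continue
        term_o = 0
        for n in mol.neighbors(a.atom_id):
            if by_id[n].element != "O":
                continue
            others = [
                m for m in mol.neighbors(n) if m != a.atom_id and by_id[m].element != "H"
            ]
            if not others:
                term_o += 1
        if term_o == 2:
            out.append(a.atom_id)
    return out


# ---------------------------------------------------------------------
# Idealized PVA chain
# ---------------------------------------------------------------------

_COS_T = -1.0 / 3.0  # cos(109.471°)


def _complete_tetrahedron(existing: list[np.ndarray], n_new: int) -> list[np.ndarray]:
    """Unit bond directions completing an sp3 center given existing ones."""
    existing = [np.asarray(d, float) / np.linalg.norm(d) for d in existing]
    if len(existing) == 3:
        s = -(existing[0] + existing[1] + existing[2])
        return [s / np.linalg.norm(s)][:n_new]
    if len(existing) == 2:
        b = -(existing[0] + existing[1])
        b /= np.linalg.norm(b)
        p = np.cross(existing[0], existing[1])
        p /= np.linalg.norm(p)
        alpha = math.sqrt(1.0 / 3.0)
        beta = math.sqrt(2.0 / 3.0)
        return [alpha * b + beta * p, alpha * b - beta * p][:n_new]
    if len(existing) == 1:
        d = existing[0]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(d, ref)
        v /= np.linalg.norm(v)
        w = np.cross(d, v)
        out = []
        for k in range(3):
            phi = 2.0 * math.pi * k / 3.0
            out.append(
                _COS_T * d
                + math.sqrt(1 - _COS_T**2) * (math.cos(phi) * v + math.sin(phi) * w)
            )
        return out[:n_new]
    raise ArgumentError("tetrahedral completion needs 1-3 existing bonds")


def build_pva_chain(
    n_monomers: int,
    tacticity_seed: int = 0,
    tacticity: str = "atactic",
    oh_sides=None,
) -> Molecule:
    """Build an idealized all-trans poly(vinyl alcohol) chain.

    The backbone is a planar zig-zag of 2n+1 sp3 carbons — a terminal
    methyl cap followed by n vinyl-alcohol units of two carbons each
    (C–C 1.54 Å, tetrahedral angles) — laid along +x.  Every unit carries
    one pendant hydroxyl on its second carbon, tagged in
    ``mol.meta["hydroxyl_sites"]`` as a crosslinkable site.  The side each
    hydroxyl points to (±z) is drawn from ``tacticity_seed`` when
    ``tacticity="atactic"`` and fixed to +z for ``"isotactic"``.  Charges:
    O −0.40 e, hydroxyl H +0.40 e, everything else neutral (net-neutral
    chain).

    End-to-end length is conventionally measured across the n monomer
    units (first to last monomer backbone carbon): ≈11.3 Å for n = 5, the
    pore-wall scale matching the guest molecule's ~10 Å maximum length.
    """
    if n_monomers < 1:
        raise ArgumentError(f"n_monomers must be >= 1, got {n_monomers}")
    if tacticity not in ("atactic", "isotactic"):
        raise ArgumentError(f"unknown tacticity {tacticity!r}")
    if oh_sides is not None and len(oh_sides) != n_monomers:
        raise ArgumentError("oh_sides must give one ±1 per monomer")
    rng = np.random.default_rng(tacticity_seed)

    half = math.radians(TETRAHEDRAL_ANGLE_DEG / 2.0)
    dx = CC_BOND * math.sin(half)  # axial advance per C-C bond
    dy = CC_BOND * math.cos(half)  # zig-zag amplitude
    n_c = 2 * n_monomers + 1

    atoms: list[Atom] = []
    bonds: list[Bond] = []

    def add(element, pos, q=0.0):
        aid = len(atoms)
        atoms.append(
            Atom(
                element=element,
                position=tuple(float(v) for v in pos),
                partial_charge=q,
                label="PVA",
                atom_id=aid,
            )
        )
        return aid

    carbon_ids = [add("C", (i * dx, (i % 2) * dy, 0.0)) for i in range(n_c)]
    for i in range(1, n_c):
        bonds.append(Bond(carbon_ids[i - 1], carbon_ids[i]))

    pos = lambda aid: np.array(atoms[aid].position)

    # pendant hydroxyls on C2, C4, ..., C2n (second carbon of each unit)
    hydroxyl_oxygens = []
    oh_of_carbon: dict[int, int] = {}
    for m in range(n_monomers):
        ci = carbon_ids[2 * (m + 1)]
        if oh_sides is not None:
            side = float(np.sign(oh_sides[m])) or 1.0
        elif tacticity == "isotactic":
            side = 1.0
        else:
            side = 1.0 if rng.random() < 0.5 else -1.0
        nb_dirs = [pos(n) - pos(ci) for n in (carbon_ids[2 * m + 1],
                                              *([carbon_ids[2 * m + 3]] if 2 * (m + 1) + 1 < n_c else []))]
        if len(nb_dirs) == 2:
            slots = _complete_tetrahedron(nb_dirs, 2)
            o_dir = slots[0] if (slots[0][2] * side > 0) else slots[1]
        else:
            slots = _complete_tetrahedron(nb_dirs, 3)
            o_dir = max(slots, key=lambda s: s[2] * side)
        oid = add("O", pos(ci) + CO_BOND * o_dir, q=-HYDROXYL_H_CHARGE)
        bonds.append(Bond(ci, oid))
        hydroxyl_oxygens.append(oid)
        oh_of_carbon[ci] = oid
        # hydroxyl H: tetrahedral off the O, azimuth pointing away from the
        # backbone (-y) so it cannot crowd the neighboring monomer's oxygen
        oc = -o_dir
        azim = np.array([0.0, -1.0, 0.0]) - (np.array([0.0, -1.0, 0.0]) @ oc) * oc
        azim /= np.linalg.norm(azim)
        h_dir = _COS_T * oc + math.sqrt(1 - _COS_T**2) * azim
        hid = add("H", pos(oid) + OH_BOND * h_dir, q=HYDROXYL_H_CHARGE)
        bonds.append(Bond(oid, hid))

    # fill every backbone carbon to sp3 valence with hydrogens
    for i, ci in enumerate(carbon_ids):
        nb = [n for b in bonds for n in (b.a, b.b) if ci in (b.a, b.b) and n != ci]
        nb = [n for b in bonds if ci in (b.a, b.b) for n in [b.b if b.a == ci else b.a]]
        dirs = [pos(n) - pos(ci) for n in nb]
        for h_dir in _complete_tetrahedron(dirs, 4 - len(dirs)):
            hid = add("H", pos(ci) + CH_BOND * h_dir)
            bonds.append(Bond(ci, hid))

    mol = Molecule(
        atoms=atoms,
        bonds=bonds,
        name=f"pva_{n_monomers}mer",
        meta={"backbone_carbons": list(carbon_ids),
              "hydroxyl_sites": list(hydroxyl_oxygens)},
    )
    return mol


def chain_end_to_end(mol: Molecule) -> float:
    """End-to-end distance across the monomer units (Å)."""
    cids = mol.meta.get("backbone_carbons")
    if cids is None:
        raise ArgumentError("molecule was not built by build_pva_chain")
    c = mol.coordinates
    return float(np.linalg.norm(c[mol.index_of(cids[1])] - c[mol.index_of(cids[-1])]))
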
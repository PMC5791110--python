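"""Nanopore assembly and rigid-body Monte-Carlo interaction-energy screening.

A *nanopore* is the model cavity used to rank crosslinker candidates: two
five-monomer PVA chains bridged by two dicarboxylate linkers through ester
bonds, in one of eight canonical topologies.  The screen samples random
rigid orientations of the guest molecule (dimethoate), slides it along a
random direction until the van der Waals surfaces touch, and evaluates the
supermolecular interaction energy

    ΔE = E(complex) − [E(molecule1) + E(molecule2)]

at the frozen contact geometry.  Energies come from a pluggable backend:
the default is a Lennard-Jones + Coulomb surrogate (UFF parameters,
Gasteiger-derived charges); an adapter for an external semi-empirical
program (MOPAC-style PM7 single points) is provided for users who have one
installed.  Absolute energies are backend-dependent; rankings built from a
user-supplied mean table (e.g. published screening results) are exact.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import COULOMB_KCAL, UFF_EPSILON, UFF_SIGMA
from .core import (
    ArgumentError,
    HydrosieveError,
    Bond,
    Molecule,
    center_of_mass,
    centered,
    merge,
)
from .ester import remove_atoms, strip_hydroxyl_hydrogen
from .templates import (
    DIACID_SMILES,
    build_pva_chain,
    carboxylate_carbons,
    load_template,
)

ESTER_CO_BOND = 1.43  # Å, ester C(=O)-O single bond


class ContactFailureError(HydrosieveError):
    """No atom pair ever intersects along the approach ray."""


class SamplingError(HydrosieveError):
    """Too many contact failures during Monte-Carlo sampling."""


class BackendError(HydrosieveError):
    """Energy backend failed."""


class BackendUnavailableError(BackendError):
    """The requested external energy program is not installed."""


class ParameterizationError(BackendError):
    """Missing per-element parameters for the surrogate backend."""


class AssemblyError(HydrosieveError):
    """Nanopore assembly produced an unresolvable steric clash."""


# ---------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """One sampled rigid placement of the guest molecule."""

    euler: tuple[float, float, float]   # ZYZ angles, radians
    direction: tuple[float, float, float]
    contact_t: float                    # Å, translation magnitude at contact

    def __post_init__(self):
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ArgumentError("pose direction must be a unit vector")
        if self.contact_t < 0:
            raise ArgumentError("contact translation must be non-negative")


@dataclass(frozen=True)
class EnergySample:
    pose: Pose
    e_complex: float
    e_mol1: float
    e_mol2: float

    @property
    def delta_e(self) -> float:
        return self.e_complex - (self.e_mol1 + self.e_mol2)


@dataclass
class EnergyEnsemble:
    """Sampled configurations with per-sample ΔE and summary statistics."""

    samples: list[EnergySample]
    acid_id: str = ""
    form_id: int = 0
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def delta_e(self) -> np.ndarray:
        return np.array([s.delta_e for s in self.samples])

    @property
    def mean(self) -> float:
        return float(self.delta_e.mean())

    @property
    def sd(self) -> float:
        d = self.delta_e
        return float(d.std(ddof=1)) if len(d) > 1 else 0.0

    @property
    def min(self) -> float:
        return float(self.delta_e.min())


@dataclass
class NanoporeComplex:
    """Two short PVA chains bridged by two diacid linkers (one topology)."""

    molecule: Molecule            # assembled complex with ester bonds
    chain_atoms: tuple[list[int], list[int]]  # atom ids per chain
    linker_atoms: tuple[list[int], list[int]]
    form_id: int
    acid_id: str

    def cavity_width(self) -> float:
        """Minimum backbone–backbone distance across the pore mouth (Å)."""
        coords = self.molecule.coordinates
        ids = {a.atom_id: i for i, a in enumerate(self.molecule.atoms)}
        heavy_a = [ids[i] for i in self.chain_atoms[0]
                   if self.molecule.atoms[ids[i]].element != "H"]
        heavy_b = [ids[i] for i in self.chain_atoms[1]
                   if self.molecule.atoms[ids[i]].element != "H"]
        d = np.linalg.norm(coords[heavy_a][:, None, :] - coords[heavy_b][None, :, :],
                           axis=-1)
        return float(d.min())


# ---------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------

# Forms 1-8: attachment registers on each chain (0-based monomer indices)
# crossed with chain orientation.  Register (0,4) spans the whole wall
# (wide pore); (1,3) spans the middle (narrow pore).
FORM_TABLE = {
    1: ((0, 4), (0, 4), "parallel"),
    2: ((0, 4), (0, 4), "antiparallel"),
    3: ((0, 4), (1, 3), "parallel"),
    4: ((0, 4), (1, 3), "antiparallel"),
    5: ((1, 3), (0, 4), "parallel"),
    6: ((1, 3), (0, 4), "antiparallel"),
    7: ((1, 3), (1, 3), "parallel"),
    8: ((1, 3), (1, 3), "antiparallel"),
}

_CLASH_RATIO = 0.7
_CLASH_BOND_EXCLUSION = 3  # ignore pairs within this many bonds


def exclusion_mask(mol: Molecule, bond_exclusion: int = _CLASH_BOND_EXCLUSION) -> np.ndarray:
    """Boolean (n, n) mask of pairs to ignore in clash checks: self and
    pairs within ``bond_exclusion`` bonds."""
    import networkx as nx

    idx = {a.atom_id: i for i, a in enumerate(mol.atoms)}
    n = len(mol.atoms)
    mask = np.eye(n, dtype=bool)
    G = nx.Graph()
    G.add_nodes_from(idx)
    G.add_edges_from((b.a, b.b) for b in mol.bonds)
    for src, lengths in nx.all_pairs_shortest_path_length(G, cutoff=bond_exclusion):
        for dst in lengths:
            mask[idx[src], idx[dst]] = True
    return mask


def hbond_flags(mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
    """(donor_h, acceptor) boolean flags per atom: H bonded to O/N, and
    O/N/S heavy atoms."""
    by_id = {a.atom_id: a for a in mol.atoms}
    donor_h = np.zeros(len(mol.atoms), dtype=bool)
    acceptor = np.zeros(len(mol.atoms), dtype=bool)
    for i, a in enumerate(mol.atoms):
        if a.element in ("O", "N", "S"):
            acceptor[i] = True
        elif a.element == "H":
            donor_h[i] = any(by_id[n].element in ("O", "N") for n in mol.neighbors(a.atom_id))
    return donor_h, acceptor


def clash_ratio(mol: Molecule, bond_exclusion: int = _CLASH_BOND_EXCLUSION,
                mask: np.ndarray | None = None) -> float:
    """Minimum pair distance over summed vdW radii, excluding bonded
    neighborhoods (pairs within ``bond_exclusion`` bonds) and potential
    hydrogen-bond pairs (donor H against O/N/S acceptor), which
    legitimately approach closer than the vdW sum."""
    coords = mol.coordinates
    radii = mol.radii
    if mask is None:
        mask = exclusion_mask(mol, bond_exclusion)
    dh, acc = hbond_flags(mol)
    hb = (dh[:, None] & acc[None, :]) | (acc[:, None] & dh[None, :])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ratio = d / (radii[:, None] + radii[None, :])
    ratio[mask | hb] = np.inf
    return float(ratio.min())


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(angle * axis / np.linalg.norm(axis)).as_matrix()


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180°: rotate about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        return _axis_rotation(axis, math.pi)
    return Rotation.from_rotvec(v / np.linalg.norm(v) * math.acos(np.clip(c, -1, 1))).as_matrix()


def assemble_nanopore(acid_id: str, form_id: int) -> NanoporeComplex:
    """Build one of the eight nanopore topologies for a given diacid.

    The two chains face each other along y, bridging hydroxyls pointing
    into the gap and spectator hydroxyls pointing outward; the chain
    separation is solved so each linker's carboxylate carbons sit exactly
    one ester bond (1.43 Å) from their chain oxygens.  The linker spin
    about its own axis, the leaving carboxylate oxygens, and a small
    chain-stagger along x are chosen deterministically to maximize steric
    clearance.  Raises :class:`AssemblyError` if no combination clears
    the 0.7× summed-vdW-radii hard-sphere limit (hydrogen-bond capable
    pairs exempt).
    """
    if acid_id not in DIACID_SMILES:
        raise ArgumentError(f"{acid_id!r} is not one of the 14 diacid templates")
    if form_id not in FORM_TABLE:
        raise ArgumentError(f"form_id must be 1..8, got {form_id}")
    reg_a, reg_b, orientation = FORM_TABLE[form_id]

    import networkx as nx

    linker_t = load_template(acid_id)
    carbs = carboxylate_carbons(linker_t)
    if len(carbs) != 2:
        raise ArgumentError(f"{acid_id}: expected 2 carboxylate carbons, found {len(carbs)}")
    ct = linker_t.coordinates
    c1t = ct[linker_t.index_of(carbs[0])]
    c2t = ct[linker_t.index_of(carbs[1])]
    span = float(np.linalg.norm(c2t - c1t))
    target_len = span + 2.0 * ESTER_CO_BOND  # ester O ... ester O distance

    lg = nx.Graph()
    lg.add_nodes_from(a.atom_id for a in linker_t.atoms)
    lg.add_edges_from((b.a, b.b) for b in linker_t.bonds)
    l_index = {a.atom_id: i for i, a in enumerate(linker_t.atoms)}
    nL = len(linker_t.atoms)

    def hops_from(graph, index, n, source) -> np.ndarray:
        out = np.full(n, 99)
        for aid, d in nx.single_source_shortest_path_length(graph, source, cutoff=2).items():
            out[index[aid]] = d
        return out

    dl = {end: hops_from(lg, l_index, nL, carbs[end]) for end in (0, 1)}
    term_o = {end: _terminal_oxygens(linker_t, carbs[end]) for end in (0, 1)}
    l_coords0 = linker_t.coordinates
    l_radii = linker_t.radii
    l_dh, l_acc = hbond_flags(linker_t)

    # spectator hydroxyls point away from the gap; bridging ones into it
    sides_a = [1.0 if m in reg_a else -1.0 for m in range(5)]
    sides_b = [1.0 if m in reg_b else -1.0 for m in range(5)]
    chain0_a = build_pva_chain(5, tacticity_seed=0, oh_sides=sides_a)
    chain0_b = build_pva_chain(5, tacticity_seed=0, oh_sides=sides_b)
    rot_a = Rotation.from_euler("x", -90, degrees=True).as_matrix()  # +z -> +y
    rot_b = Rotation.from_euler("x", +90, degrees=True).as_matrix()  # +z -> -y
    chain_a = chain0_a.rotated(rot_a)
    chain_bb = chain0_b.rotated(rot_b)
    if orientation == "antiparallel":
        # reverse the chain direction (x -> -x), hydroxyl facing unchanged
        chain_bb = chain_bb.rotated(Rotation.from_euler("y", 180, degrees=True).as_matrix())
    ca = chain_a.coordinates.mean(axis=0)
    cb = chain_bb.coordinates.mean(axis=0)
    chain_bb = chain_bb.translated((ca[0] - cb[0], 0.0, ca[2] - cb[2]))

    half_step = 0.5 * 1.54 * math.sin(math.radians(109.471 / 2.0))
    # stagger candidates: fixed grid plus shifts centering each pairing's
    # x-mismatch (asymmetric registers need offsets beyond the grid)
    xa = [chain_a.coordinates[chain_a.index_of(chain_a.meta["hydroxyl_sites"][m])][0]
          for m in reg_a]
    xb = [chain_bb.coordinates[chain_bb.index_of(chain_bb.meta["hydroxyl_sites"][m])][0]
          for m in reg_b]
    shifts = [0.0, 2 * half_step, -2 * half_step, half_step, -half_step]
    for (i0, j0), (i1, j1) in (((0, 0), (1, 1)), ((0, 1), (1, 0))):
        s = 0.5 * ((xa[i0] - xb[j0]) + (xa[i1] - xb[j1]))
        shifts.extend([s, s + half_step, s - half_step])
    seen = set()
    shifts = [s for s in shifts
              if not (round(s, 6) in seen or seen.add(round(s, 6)))]
    best = None
    feasible = False
    # search order: collinear ester axes first, then bowed variants that
    # push the carboxyl carbons off the pore axis (short linkers only
    # need these in skewed registers)
    _bows = [(0.0, None)]
    for h in (0.7, 1.1, 1.3):
        _bows.extend((h, k) for k in range(8))
    for bow_h, bow_dir in _bows:
        for xshift in shifts:
            out = _attempt_assembly(
                acid_id, form_id, reg_a, reg_b, chain_a,
                chain_bb.translated((xshift, 0, 0)),
                linker_t, carbs, c1t, c2t, span, dl, term_o,
                l_coords0, l_radii, l_dh, l_acc, bow_h, bow_dir,
            )
            if out is None:
                continue
            feasible = True
            ratio, compl = out
            if best is None or ratio > best[0]:
                best = (ratio, compl)
            if ratio >= _CLASH_RATIO:
                return compl
    if not feasible:
        raise AssemblyError(f"{acid_id} form {form_id}: linker too short for register")
    raise AssemblyError(
        f"{acid_id} form {form_id}: hard-sphere clash "
        f"(best ratio {best[0]:.3f} < {_CLASH_RATIO})"
    )


def _attempt_assembly(acid_id, form_id, reg_a, reg_b, chain_a, chain_b0,
                      linker_t, carbs, c1t, c2t, span, dl, term_o,
                      l_coords0, l_radii, l_dh, l_acc,
                      bow_h=0.0, bow_dir=None):
    """One assembly attempt at a fixed chain stagger and ester-bow height;
    returns (clash ratio, complex) or None when the linker cannot reach."""
    import networkx as nx

    # ester C sits at axial offset a and perpendicular offset bow_h from
    # its chain oxygen, preserving |O-C| = 1.43 Å
    a_off = math.sqrt(max(ESTER_CO_BOND**2 - bow_h**2, 1e-12))
    target_len = span + 2.0 * a_off

    sites_a = [chain_a.meta["hydroxyl_sites"][m] for m in range(5) if m in reg_a]
    sites_b = [chain_b0.meta["hydroxyl_sites"][m] for m in range(5) if m in reg_b]
    pa = [chain_a.coordinates[chain_a.index_of(s)] for s in sites_a]
    pb0 = [chain_b0.coordinates[chain_b0.index_of(s)] for s in sites_b]

    # pair the sites to minimize x-mismatch, then solve the chain offset D
    # (translation of chain B along +y) so |O_A - O_B| = target_len
    pairings = [((0, 0), (1, 1)), ((0, 1), (1, 0))]
    pairing = min(pairings, key=lambda p: max(abs(pa[i][0] - pb0[j][0]) for i, j in p))

    # least-squares chain offset D along +y: both linker anchors should
    # sit one ester bond from their oxygens; asymmetric registers split
    # any residual strain between the two bridges
    lat = []   # per pair: lateral offset, y gap at D=0
    for i, j in pairing:
        dxk = pa[i][0] - pb0[j][0]
        dzk = pa[i][2] - pb0[j][2]
        lat.append((math.hypot(dxk, dzk), pa[i][1] - pb0[j][1]))
    if any(l >= target_len - 0.5 for l, _ in lat):
        return None

    from scipy.optimize import minimize_scalar

    def strain(D):
        return sum(
            (math.sqrt(l * l + (D - y0) ** 2) - target_len) ** 2 for l, y0 in lat
        )
    lo = max(y0 for _, y0 in lat) + 0.1
    opt = minimize_scalar(strain, bounds=(lo, lo + target_len + 3.0), method="bounded")
    D = float(opt.x)
    if strain(D) > 0.25:
        return None
    chain_b = chain_b0.translated((0.0, D, 0.0))
    pb = [chain_b.coordinates[chain_b.index_of(s)] for s in sites_b]

    # strip the hydroxyl hydrogens at all four ester sites up front
    chains = [chain_a, chain_b]
    for idx, sites in ((0, [sites_a[i] for i, _ in pairing]),
                       (1, [sites_b[j] for _, j in pairing])):
        for s in sites:
            chains[idx] = strip_hydroxyl_hydrogen(chains[idx], s)

    def chain_arrays_for(cidx, site_o):
        ch = chains[cidx]
        g = nx.Graph()
        g.add_nodes_from(a.atom_id for a in ch.atoms)
        g.add_edges_from((b.a, b.b) for b in ch.bonds)
        idx = {a.atom_id: i for i, a in enumerate(ch.atoms)}
        hops = np.full(len(ch.atoms), 99)
        for aid, d in nx.single_source_shortest_path_length(g, site_o, cutoff=2).items():
            hops[idx[aid]] = d
        dh, acc = hbond_flags(ch)
        return ch.coordinates, ch.radii, hops, dh, acc

    # place each linker; search spin angle x leaving-oxygen choice
    # (greedily, linker 2 seeing linker 1) for maximal steric clearance
    linkers = []
    ester_specs = []  # (chain_idx, site_o, linker_idx, carboxyl_c)
    placed_coords = []
    i_c1 = linker_t.index_of(carbs[0])
    for link_idx, (ia, jb) in enumerate(pairing):
        p1, p2 = pa[ia], pb[jb]
        u = (p2 - p1) / np.linalg.norm(p2 - p1)
        if bow_dir is None:
            w = np.zeros(3)
        else:
            v1 = np.array([1.0, 0.0, 0.0]) - u[0] * u
            if np.linalg.norm(v1) < 1e-6:
                v1 = np.array([0.0, 0.0, 1.0]) - u[2] * u
            v1 /= np.linalg.norm(v1)
            v2 = np.cross(u, v1)
            phi = math.pi / 4.0 * bow_dir
            w = math.cos(phi) * v1 + math.sin(phi) * v2
        t1 = p1 + a_off * u + bow_h * w
        t2 = p2 - a_off * u + bow_h * w
        R0 = _align_rotation(c2t - c1t, t2 - t1)
        chain_arrays = [chain_arrays_for(0, sites_a[ia]) + (dl[0],),
                        chain_arrays_for(1, sites_b[jb]) + (dl[1],)]

        best = None
        for angle_deg in range(0, 360, 10):
            spin = _axis_rotation(u, math.radians(angle_deg))
            R = spin @ R0
            coords = l_coords0 @ R.T
            coords = coords + (t1 - coords[i_c1])
            for drop_a in term_o[0]:
                for drop_b in term_o[1]:
                    keep = np.array(
                        [i for i, a in enumerate(linker_t.atoms)
                         if a.atom_id not in (drop_a, drop_b)]
                    )
                    lc, lr = coords[keep], l_radii[keep]
                    ldh, lac = l_dh[keep], l_acc[keep]
                    score = np.inf
                    for ccoords, cradii, chops, cdh, cacc, lhops in chain_arrays:
                        d = np.linalg.norm(lc[:, None, :] - ccoords[None, :, :], axis=-1)
                        ratio = d / (lr[:, None] + cradii[None, :])
                        # pairs within 3 bonds through the new ester bond
                        excl = (lhops[keep][:, None] + chops[None, :]) <= 2
                        hb = (ldh[:, None] & cacc[None, :]) | (lac[:, None] & cdh[None, :])
                        ratio[excl | hb] = np.inf
                        score = min(score, float(ratio.min()))
                    for oc, orad, odh, oacc in placed_coords:
                        d = np.linalg.norm(lc[:, None, :] - oc[None, :, :], axis=-1)
                        ratio = d / (lr[:, None] + orad[None, :])
                        hb = (ldh[:, None] & oacc[None, :]) | (lac[:, None] & odh[None, :])
                        ratio[hb] = np.inf
                        score = min(score, float(ratio.min()))
                    if best is None or score > best[0]:
                        best = (score, coords.copy(), drop_a, drop_b)
        _, coords, drop_a, drop_b = best
        stripped = remove_atoms(
            linker_t.with_coordinates(coords), [drop_a, drop_b]
        ).relabeled("linker")
        keep_idx = [i for i, a in enumerate(linker_t.atoms)
                    if a.atom_id not in (drop_a, drop_b)]
        placed_coords.append((coords[keep_idx], l_radii[keep_idx],
                              l_dh[keep_idx], l_acc[keep_idx]))
        linkers.append(stripped)
        ester_specs.append((0, sites_a[ia], link_idx, carbs[0]))
        ester_specs.append((1, sites_b[jb], link_idx, carbs[1]))

    parts = [chains[0], chains[1], linkers[0], linkers[1]]
    complex_mol, idmaps = _merge_with_maps(parts, name=f"{acid_id}_form{form_id}")
    for chain_idx, site_o, link_idx, carb_c in ester_specs:
        a = idmaps[chain_idx][site_o]
        b = idmaps[2 + link_idx][carb_c]
        complex_mol.bonds.append(Bond(a, b))

    ratio = clash_ratio(complex_mol)
    compl = NanoporeComplex(
        molecule=complex_mol,
        chain_atoms=(list(idmaps[0].values()), list(idmaps[1].values())),
        linker_atoms=(list(idmaps[2].values()), list(idmaps[3].values())),
        form_id=form_id,
        acid_id=acid_id,
    )
    return ratio, compl


def _terminal_oxygens(mol: Molecule, carboxyl_c: int) -> list[int]:
    """Atom ids of the two terminal oxygens of a carboxylate carbon."""
    by_id = {a.atom_id: a for a in mol.atoms}
    out = []
    for n in mol.neighbors(carboxyl_c):
        if by_id[n].element != "O":
            continue
        others = [m for m in mol.neighbors(n)
                  if m != carboxyl_c and by_id[m].element != "H"]
        if not others:
            out.append(n)
    if len(out) < 2:
        raise ArgumentError(f"atom {carboxyl_c} is not a carboxylate carbon")
    return out


def _merge_with_maps(mols, name=""):
    from dataclasses import replace

    atoms, bonds, idmaps = [], [], []
    offset = 0
    for mol in mols:
        idmap = {}
        for a in mol.atoms:
            idmap[a.atom_id] = offset
            atoms.append(replace(a, atom_id=offset))
            offset += 1
        bonds.extend(Bond(idmap[b.a], idmap[b.b], b.order) for b in mol.bonds)
        idmaps.append(idmap)
    return Molecule(atoms=atoms, bonds=bonds, name=name), idmaps


# ---------------------------------------------------------------------
# Rotation and contact placement
# ---------------------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> tuple[float, float, float]:
    """Draw a uniform (Haar) random rotation, returned as ZYZ Euler angles.

    Sampling is via uniform unit quaternions; naive independent Euler
    angles would oversample the poles.
    """
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    a, b, g = Rotation.from_quat(q).as_euler("ZYZ")
    return (float(a), float(b), float(g))


def rotation_matrix(euler: tuple[float, float, float]) -> np.ndarray:
    return Rotation.from_euler("ZYZ", euler).as_matrix()


def random_direction(rng: np.random.Generator) -> np.ndarray:
    """Uniform unit vector via a normalized Gaussian 3-vector."""
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def contact_distance(
    static_coords: np.ndarray,
    static_radii: np.ndarray,
    mobile_coords: np.ndarray,
    mobile_radii: np.ndarray,
    direction: np.ndarray,
) -> float:
    """Largest translation t along ``direction`` at which some atom pair of
    the mobile molecule touches the static one (and none overlaps).

    Per pair (i, j) the touching condition |p_i − (q_j + t·u)| = r_i + r_j
    is a quadratic in t; the contact translation is the maximum over pairs
    of the larger real root.  Pairs whose spheres never intersect the ray
    are ignored; if no pair has a real root a
    :class:`ContactFailureError` is raised.
    """
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    a = static_coords[:, None, :] - mobile_coords[None, :, :]   # (Ns, Nm, 3)
    s = static_radii[:, None] + mobile_radii[None, :]
    au = a @ u
    disc = au**2 - (a * a).sum(axis=-1) + s**2
    ok = disc >= 0.0
    if not ok.any():
        raise ContactFailureError("no atom pair intersects the approach ray")
    t = float((au[ok] + np.sqrt(disc[ok])).max())
    if t < 0.0:
        # every touching point lies behind the start: sliding forward
        # along the ray only separates the molecules further
        raise ContactFailureError("surfaces only touch behind the start point")
    return t


def place_at_contact(
    static_mol: Molecule,
    mobile_mol: Molecule,
    euler: tuple[float, float, float],
    direction,
) -> tuple[Pose, Molecule]:
    """Rotate the mobile molecule, then slide it along ``direction`` until
    the vdW surfaces touch.  Both molecules must be mass-centered."""
    u = np.asarray(direction, float)
    n = np.linalg.norm(u)
    if n < 1e-12:
        raise ArgumentError("direction must be nonzero")
    u = u / n
    R = rotation_matrix(euler)
    rotated = mobile_mol.coordinates @ R.T
    t = contact_distance(static_mol.coordinates, static_mol.radii,
                         rotated, mobile_mol.radii, u)
    pose = Pose(euler=tuple(euler), direction=tuple(u), contact_t=t)
    return pose, mobile_mol.with_coordinates(rotated + t * u)


# ---------------------------------------------------------------------
# Energy backends
# ---------------------------------------------------------------------

class SurrogateBackend:
    """Pairwise Lennard-Jones + Coulomb intermolecular energy (kcal/mol).

    E(geometry) sums 4ε_ij[(σ_ij/d)¹² − (σ_ij/d)⁶] + 332.0637 q_i q_j / d
    over *intermolecular* atom pairs (ε_ij geometric mean, σ_ij arithmetic
    mean; UFF per-element parameters by default).  Isolated molecules have
    E = 0, so ΔE equals the intermolecular sum directly.
    """

    name = "surrogate"

    def __init__(self, epsilon: dict | None = None, sigma: dict | None = None,
                 lj_scale: float = 1.0, coulomb_scale: float = 1.0):
        self.epsilon = dict(UFF_EPSILON if epsilon is None else epsilon)
        self.sigma = dict(UFF_SIGMA if sigma is None else sigma)
        self.lj_scale = lj_scale
        self.coulomb_scale = coulomb_scale

    def _params(self, mol: Molecule):
        try:
            eps = np.array([self.epsilon[e] for e in mol.elements])
            sig = np.array([self.sigma[e] for e in mol.elements])
        except KeyError as exc:
            raise ParameterizationError(f"no LJ parameters for element {exc}") from exc
        return eps, sig

    def energy(self, molecules: list[Molecule]) -> float:
        if len(molecules) < 2:
            return 0.0
        total = 0.0
        for i in range(len(molecules)):
            for j in range(i + 1, len(molecules)):
                total += self.pair_energy(molecules[i], molecules[j])
        return total

    def pair_energy(self, m1: Molecule, m2: Molecule) -> float:
        e1, s1 = self._params(m1)
        e2, s2 = self._params(m2)
        d = np.linalg.norm(
            m1.coordinates[:, None, :] - m2.coordinates[None, :, :], axis=-1
        )
        d = np.maximum(d, 1e-12)
        eps = np.sqrt(e1[:, None] * e2[None, :])
        sig = 0.5 * (s1[:, None] + s2[None, :])
        sr6 = (sig / d) ** 6
        lj = 4.0 * eps * (sr6**2 - sr6)
        coul = COULOMB_KCAL * m1.charges[:, None] * m2.charges[None, :] / d
        return float(self.lj_scale * lj.sum() + self.coulomb_scale * coul.sum())


def surrogate_energy_backend(**kwargs) -> SurrogateBackend:
    return SurrogateBackend(**kwargs)


class PM7Backend:
    """Adapter for an external MOPAC-style semi-empirical program.

    Writes a ``1SCF PM7`` single-point input for the given geometry (charge
    taken from the molecule's net charge, rounded) and parses the final
    heat of formation in kcal/mol.  Entirely optional: construction fails
    with :class:`BackendUnavailableError` when the executable is absent.
    """

    name = "pm7"

    def __init__(self, executable: str = "mopac"):
        path = shutil.which(executable) or (
            executable if Path(executable).is_file() else None
        )
        if path is None:
            raise BackendUnavailableError(
                f"PM7 backend: executable {executable!r} not found on PATH"
            )
        self.executable = path

    def energy(self, molecules: list[Molecule]) -> float:
        mol = merge(list(molecules)) if len(molecules) > 1 else molecules[0]
        charge = int(round(mol.net_charge))
        lines = [f"1SCF PM7 CHARGE={charge}", mol.name or "hydrosieve", ""]
        for a in mol.atoms:
            x, y, z = a.position
            lines.append(f"{a.element} {x:.6f} 1 {y:.6f} 1 {z:.6f} 1")
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "job.mop"
            inp.write_text("\n".join(lines) + "\n")
            proc = subprocess.run(
                [self.executable, str(inp)], capture_output=True, text=True
            )
            out_file = inp.with_suffix(".out")
            text = out_file.read_text() if out_file.exists() else proc.stdout
            if proc.returncode != 0 and not out_file.exists():
                raise BackendError(f"pm7 backend failed: {proc.stderr[:500]}")
            for line in text.splitlines():
                if "FINAL HEAT OF FORMATION" in line and "KCAL/MOL" in line:
                    for tok in line.split():
                        try:
                            return float(tok)
                        except ValueError:
                            continue
            raise BackendError(
                f"pm7 backend: could not parse heat of formation; output began:\n"
                f"{text[:500]}"
            )


def pm7_backend(executable: str = "mopac") -> PM7Backend:
    return PM7Backend(executable)


def interaction_energy(static_mol: Molecule, mobile_mol: Molecule, pose: Pose,
                       backend) -> EnergySample:
    """Single-point supermolecular ΔE at a frozen geometry."""
    try:
        e_complex = backend.energy([static_mol, mobile_mol])
        e1 = backend.energy([static_mol])
        e2 = backend.energy([mobile_mol])
    except HydrosieveError:
        raise
    except Exception as exc:
        raise BackendError(f"{getattr(backend, 'name', backend)!r} backend failed: {exc}") from exc
    return EnergySample(pose=pose, e_complex=e_complex, e_mol1=e1, e_mol2=e2)


# ---------------------------------------------------------------------
# The Monte-Carlo screen
# ---------------------------------------------------------------------

def mc_screen(
    pore: NanoporeComplex | Molecule,
    ligand: Molecule,
    n_samples: int = 100_000,
    backend=None,
    seed: int = 0,
) -> EnergyEnsemble:
    """Rigid-body Monte-Carlo screen of guest poses at vdW contact.

    Repeats: mass-center both molecules, draw a Haar-uniform rotation for
    the guest, draw a uniform random approach direction, slide to contact,
    and evaluate the supermolecular ΔE.  Fully reproducible for a fixed
    seed.  Raises :class:`SamplingError` if more than 1% of draws cannot
    reach contact.
    """
    if n_samples < 1:
        raise ArgumentError(f"n_samples must be >= 1, got {n_samples}")
    backend = backend or SurrogateBackend()
    host = pore.molecule if isinstance(pore, NanoporeComplex) else pore
    host = centered(host)
    guest = centered(ligand)
    rng = np.random.default_rng(seed)

    samples: list[EnergySample] = []
    failures = 0
    max_failures = max(1, int(0.01 * n_samples))
    while len(samples) < n_samples:
        euler = random_rotation(rng)
        direction = random_direction(rng)
        try:
            pose, placed = place_at_contact(host, guest, euler, direction)
        except ContactFailureError:
            failures += 1
            if failures > max_failures:
                raise SamplingError(
                    f"{failures} contact failures in {len(samples) + failures} draws"
                )
            continue
        samples.append(interaction_energy(host, placed, pose, backend))
    return EnergyEnsemble(
        samples=samples,
        acid_id=getattr(pore, "acid_id", ""),
        form_id=getattr(pore, "form_id", 0),
        seed=seed,
    )


def screen_all_acids(
    acids=None,
    ligand: Molecule | None = None,
    n_samples: int = 1000,
    backend=None,
    seed: int = 0,
    forms=range(1, 9),
) -> pd.DataFrame:
    """Screen each diacid over the eight nanopore forms.

    ``n_samples`` applies per form.  Returns a tidy frame with one row per
    (acid, form) plus the per-acid grand mean — the unweighted mean of the
    form means — in the ``acid_mean`` column, mirroring a
    one-number-per-acid screening table.
    """
    acids = list(acids) if acids is not None else list(DIACID_SMILES)
    if not acids:
        raise ArgumentError("need at least one acid")
    ligand = ligand if ligand is not None else load_template("dimethoate")
    backend = backend or SurrogateBackend()

    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(len(acids) * len(list(forms)) * 2))
    rows = []
    for acid in acids:
        form_means = []
        for form in forms:
            sub_seed = int(next(child_seeds)) % (2**31)
            pore = assemble_nanopore(acid, form)
            ens = mc_screen(pore, ligand, n_samples=n_samples, backend=backend,
                            seed=sub_seed)
            form_means.append(ens.mean)
            rows.append({"acid": acid, "form": form, "n": ens.n,
                         "mean_kcal_mol": ens.mean, "sd": ens.sd, "min": ens.min})
    df = pd.DataFrame(rows)
    grand = df.groupby("acid", sort=False)["mean_kcal_mol"].mean().rename("acid_mean")
    return df.merge(grand, on="acid")


def rank_crosslinkers(mean_table) -> pd.DataFrame:
    """Rank crosslinker candidates by mean interaction energy.

    ``mean_table``: mapping acid -> mean ΔE (kcal/mol) or a DataFrame with
    ``acid`` and a mean column.  Stable ascending sort (most negative =
    strongest affinity first); ties break alphabetically.
    """
    if isinstance(mean_table, dict):
        df = pd.DataFrame({"acid": list(mean_table), "mean_kcal_mol": list(mean_table.values())})
    else:
        df = pd.DataFrame(mean_table).copy()
        if "mean_kcal_mol" not in df.columns:
            cand = [c for c in df.columns if "mean" in c]
            if not cand:
                raise ArgumentError("mean_table needs a mean column")
            df = df.rename(columns={cand[0]: "mean_kcal_mol"})
        if "acid_mean" in df.columns or df.duplicated("acid").any():
            df = (df.groupby("acid", sort=False)["mean_kcal_mol"].mean().reset_index())
    if df.empty:
        raise ArgumentError("cannot rank an empty table")
    return (df.sort_values(["mean_kcal_mol", "acid"], kind="stable")
              .reset_index(drop=True))


def load_reference_energies() -> pd.DataFrame:
    """Published per-acid mean interaction energies (PM7 protocol), as a
    two-column frame (acid, mean_kcal_mol).  These are reference inputs for
    ranking, not desk-reproducible outputs."""
    with resources.files("hydrosieve.data").joinpath("screening_energies.csv").open() as fh:
        return pd.read_csv(fh)
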
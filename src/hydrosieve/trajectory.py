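"""Trajectory observables for hydrogel + pesticide + water systems.

Frames carry plain coordinate arrays over a fixed :class:`Topology` that
labels every atom with a role (``hydrogel`` | ``DMT`` | ``water``), a
molecule id, its element, and hydrogen-bond donor/acceptor capability
derived from the bond list.  Observables:

* **SASA** — Shrake–Rupley solvent-accessible surface area with a
  deterministic Fibonacci-lattice point set (no RNG, reproducible).
* **RGYR** — mass-weighted radius of gyration.
* **water shell** — waters within 3 Å of the hydrogel or inside a sphere
  around its center of mass (the union criterion).
* **capture** — percentage of pesticide molecules with any atom within a
  contact cutoff (default 4.5 Å) of any hydrogel atom.
* **hydrogen bonds** — geometric criterion: donor–acceptor ≤ 3.0 Å
  (3.5 Å for sulfur acceptors), D–H···A within 30° of linear.

Periodic minimum-image distances are used for the water/capture/hbond
criteria; SASA and RGYR treat the selection as whole (unwrapped).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import ATOMIC_MASSES, BONDI_RADII, DEFAULT_VDW_RADIUS
from .core import ArgumentError, HydrosieveError, Molecule

ROLES = ("hydrogel", "DMT", "water", "other")


class TopologyError(HydrosieveError):
    """Inconsistent topology (e.g. donors without hydrogens)."""


@dataclass
class Topology:
    """Fixed per-atom metadata shared by every frame of a trajectory."""

    elements: list[str]
    roles: list[str]                      # per atom, one of ROLES
    mol_ids: np.ndarray                   # per atom molecule index
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        n = len(self.elements)
        if len(self.roles) != n or len(self.mol_ids) != n:
            raise ArgumentError("topology arrays must have equal lengths")
        self._neighbors = [[] for _ in range(n)]
        for i, j in self.bonds:
            self._neighbors[i].append(j)
            self._neighbors[j].append(i)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def radii(self) -> np.ndarray:
        return np.array([BONDI_RADII.get(e, DEFAULT_VDW_RADIUS) for e in self.elements])

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    def select(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ArgumentError(f"unknown role {role!r}")
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def heavy(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.roles)
             if r == role and self.elements[i] != "H"], dtype=int)

    def donor_hydrogens(self, role: str):
        """[(donor_heavy, H), ...] within a role: H bonded to O or N."""
        out = []
        for i, el in enumerate(self.elements):
            if el != "H" or self.roles[i] != role:
                continue
            heavies = [j for j in self._neighbors[i] if self.elements[j] in ("O", "N")]
            if heavies:
                out.append((heavies[0], i))
        return out

    def acceptors(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, el in enumerate(self.elements)
             if el in ("O", "N", "S") and self.roles[i] == role], dtype=int)

    # ---- JSON sidecar ------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "elements": self.elements,
            "roles": self.roles,
            "mol_ids": self.mol_ids.tolist(),
            "bonds": [list(b) for b in self.bonds],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Topology":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(elements=doc["elements"], roles=doc["roles"],
                   mol_ids=np.array(doc["mol_ids"]),
                   bonds=[tuple(b) for b in doc["bonds"]])

    @classmethod
    def from_molecules(cls, mols: list[Molecule], roles: list[str]) -> "Topology":
        """Build a topology from molecules with one role label per molecule."""
        elements, role_list, mol_ids, bonds = [], [], [], []
        offset = 0
        for mid, (mol, role) in enumerate(zip(mols, roles)):
            idx = {a.atom_id: offset + k for k, a in enumerate(mol.atoms)}
            for a in mol.atoms:
                elements.append(a.element)
                role_list.append(role)
                mol_ids.append(mid)
            bonds.extend((idx[b.a], idx[b.b]) for b in mol.bonds)
            offset += len(mol.atoms)
        return cls(elements=elements, roles=role_list,
                   mol_ids=np.array(mol_ids), bonds=bonds)


@dataclass
class TrajectoryFrame:
    coordinates: np.ndarray            # (n, 3) Å
    topology: Topology
    box: np.ndarray | None = None      # (3,) Å or None for non-periodic
    time: float = 0.0                  # ns

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.topology), 3):
            raise ArgumentError("frame coordinates do not match topology size")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if (self.box <= 0).any():
                raise ArgumentError("box lengths must be positive")


@dataclass
class ObservableSeries:
    observable_name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ArgumentError("times and values must have equal length")
        if not np.isfinite(self.values).all():
            raise ArgumentError("observable values must be finite")


def _min_image(dr: np.ndarray, box) -> np.ndarray:
    if box is None:
        return dr
    return dr - box * np.round(dr / box)


# ---------------------------------------------------------------------
# Per-frame observables
# ---------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * np.arange(n)
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(frame: TrajectoryFrame, selection, probe_radius: float = 1.4,
         n_points: int = 960) -> float:
    """Shrake–Rupley solvent-accessible surface area (Å²) of a selection.

    Each atom's sphere of radius r_vdw + probe is sampled with a Fibonacci
    lattice; a point is exposed when outside every other selected atom's
    probe-expanded sphere.  Non-periodic (selection treated as whole).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ArgumentError("sasa: empty selection")
    coords = frame.coordinates[selection]
    radii = frame.topology.radii[selection] + probe_radius
    pts = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = float(radii.max())
    area = 0.0
    for i in range(len(selection)):
        sphere = coords[i] + radii[i] * pts
        nbrs = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                if j != i]
        if nbrs:
            d = np.linalg.norm(sphere[:, None, :] - coords[nbrs][None, :, :], axis=-1)
            exposed = (d >= radii[nbrs][None, :]).all(axis=1)
        else:
            exposed = np.ones(n_points, dtype=bool)
        area += exposed.mean() * 4.0 * math.pi * radii[i] ** 2
    return float(area)


def rgyr(frame: TrajectoryFrame, selection) -> float:
    """Mass-weighted radius of gyration (Å) of a selection."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ArgumentError("rgyr: empty selection")
    m = frame.topology.masses[selection]
    c = frame.coordinates[selection]
    com = (m[:, None] * c).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((c - com) ** 2).sum(axis=1)).sum() / m.sum()))


def hydrogel_com(frame: TrajectoryFrame) -> np.ndarray:
    sel = frame.topology.select("hydrogel")
    m = frame.topology.masses[sel]
    return (m[:, None] * frame.coordinates[sel]).sum(axis=0) / m.sum()


def water_shell_count(frame: TrajectoryFrame, backbone_cutoff: float = 3.0,
                      com_radius: float | None = None) -> int:
    """Waters bound to or inside the hydrogel.

    A water molecule counts when its oxygen is within ``backbone_cutoff``
    of any hydrogel heavy atom OR within ``com_radius`` of the hydrogel
    center of mass (union).  ``com_radius`` defaults to the hydrogel
    radius of gyration of the frame.
    """
    if com_radius is None:
        com_radius = rgyr(frame, frame.topology.select("hydrogel"))
    if com_radius <= 0:
        raise ArgumentError("com_radius must be positive")
    top = frame.topology
    gel = top.heavy("hydrogel")
    if gel.size == 0:
        raise ArgumentError("no hydrogel atoms in topology")
    water_o = np.array([i for i in top.select("water") if top.elements[i] == "O"],
                       dtype=int)
    if water_o.size == 0:
        return 0
    wpos = frame.coordinates[water_o]
    gpos = frame.coordinates[gel]
    dr = _min_image(wpos[:, None, :] - gpos[None, :, :], frame.box)
    near_backbone = (np.linalg.norm(dr, axis=-1) <= backbone_cutoff).any(axis=1)
    com = hydrogel_com(frame)
    in_sphere = np.linalg.norm(
        _min_image(wpos - com, frame.box), axis=-1) <= com_radius
    return int((near_backbone | in_sphere).sum())


def capture_fraction(frame: TrajectoryFrame, cutoff: float = 4.5) -> float:
    """Percentage of pesticide molecules in contact with the hydrogel:
    any atom within ``cutoff`` (minimum image) of any hydrogel atom."""
    top = frame.topology
    dmt = top.select("DMT")
    if dmt.size == 0:
        raise ArgumentError("no DMT molecules in topology")
    gel = top.select("hydrogel")
    gpos = frame.coordinates[gel]
    dr = _min_image(frame.coordinates[dmt][:, None, :] - gpos[None, :, :], frame.box)
    close = (np.linalg.norm(dr, axis=-1) <= cutoff).any(axis=1)
    mol_ids = top.mol_ids[dmt]
    captured = {m for m, c in zip(mol_ids, close) if c}
    total = len(set(mol_ids.tolist()))
    return 100.0 * len(captured) / total


def hbond_count(frame: TrajectoryFrame, donors_from: str = "hydrogel",
                acceptors_from: str = "DMT", d_cut: float = 3.0,
                s_cut: float = 3.5, angle_cut: float = 30.0) -> int:
    """Count hydrogen bonds between two selections.

    A (D, H, A) triple is a hydrogen bond when the donor–acceptor distance
    is at most ``d_cut`` (``s_cut`` when A is sulfur) and the D–H···A
    angle deviates from linearity by at most ``angle_cut`` degrees.
    """
    top = frame.topology
    donors = top.donor_hydrogens(donors_from)
    role_hs = [i for i, e in enumerate(top.elements)
               if e == "H" and top.roles[i] == donors_from]
    has_on = any(top.elements[i] in ("O", "N") and top.roles[i] == donors_from
                 for i in range(len(top)))
    if has_on and role_hs and not any(top._neighbors[h] for h in role_hs):
        raise TopologyError(
            f"topology records no bonds for {donors_from!r} hydrogens; "
            f"donor H positions cannot be resolved")
    acceptors = top.acceptors(acceptors_from)
    if not donors or acceptors.size == 0:
        return 0
    dpos = frame.coordinates[[d for d, _ in donors]]
    hpos = frame.coordinates[[h for _, h in donors]]
    apos = frame.coordinates[acceptors]
    cuts = np.where(np.array([top.elements[a] for a in acceptors]) == "S",
                    s_cut, d_cut)
    da = _min_image(apos[None, :, :] - dpos[:, None, :], frame.box)
    d_da = np.linalg.norm(da, axis=-1)
    dh = _min_image(hpos - dpos, frame.box)
    ha = _min_image(apos[None, :, :] - hpos[:, None, :], frame.box)
    d_ha = np.maximum(np.linalg.norm(ha, axis=-1), 1e-9)
    nh = np.maximum(np.linalg.norm(dh, axis=-1), 1e-9)
    # angle at H between H->D and H->A; linear D-H...A means 180°
    cosang = ((-dh)[:, None, :] * ha).sum(axis=-1) / (nh[:, None] * d_ha)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = (d_da <= cuts[None, :]) & (180.0 - ang <= angle_cut)
    return int(ok.sum())


# ---------------------------------------------------------------------
# Whole-trajectory driver
# ---------------------------------------------------------------------

DEFAULT_OBSERVABLES = ("sasa", "rgyr", "waters", "capture", "hbonds")


def analyze_trajectory(frames: list[TrajectoryFrame],
                       observables=DEFAULT_OBSERVABLES,
                       capture_cutoff: float = 4.5,
                       backbone_cutoff: float = 3.0,
                       com_radius: float | None = None,
                       sasa_points: int = 960) -> pd.DataFrame:
    """Evaluate observables per frame; returns a tidy frame indexed by time.

    The ``capture`` column carries per-frame percentages; the result's
    ``attrs['first_full_capture_ns']`` records the first time the capture
    reaches 100% (NaN if never).
    """
    if not frames:
        raise ArgumentError("no frames to analyze")
    rows = []
    for fr in frames:
        row = {"time_ns": fr.time}
        gel = fr.topology.select("hydrogel")
        for obs in observables:
            if obs == "sasa":
                row["sasa_A2"] = sasa(fr, gel, n_points=sasa_points)
            elif obs == "rgyr":
                row["rgyr_A"] = rgyr(fr, gel)
            elif obs == "waters":
                row["waters"] = water_shell_count(fr, backbone_cutoff, com_radius)
            elif obs == "capture":
                row["capture_pct"] = capture_fraction(fr, capture_cutoff)
            elif obs == "hbonds":
                row["hbonds"] = (hbond_count(fr, "hydrogel", "DMT")
                                 + hbond_count(fr, "DMT", "hydrogel"))
            else:
                raise ArgumentError(f"unknown observable {obs!r}")
        rows.append(row)
    df = pd.DataFrame(rows)
    if "capture_pct" in df.columns:
        full = df.loc[df["capture_pct"] >= 100.0 - 1e-9, "time_ns"]
        df.attrs["first_full_capture_ns"] = float(full.iloc[0]) if len(full) else float("nan")
    return df
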
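"""Synthetic fixtures with planted ground truth.

Everything the analysis stages measure can be generated here with known
answers: solvated hydrogel + pesticide frames whose capture percentage,
hydrogen-bond count and bound-water count follow prescribed per-frame
schedules; water boxes with a minimum O–O separation; and factorial
response tables drawn from known coefficients plus Gaussian noise.  All
generators are deterministic per seed, and the trajectory generator
self-verifies each frame against the analysis criteria before accepting
it, so planted observables are recovered exactly by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ArgumentError, Atom, Bond, HydrosieveError, Molecule, merge
from .doe import FactorialDesign
from .network import CrosslinkNetwork, minimum_image
from .templates import load_template
from .trajectory import (
    Topology,
    TrajectoryFrame,
    capture_fraction,
    hbond_count,
    rgyr,
    water_shell_count,
)


class PlacementError(HydrosieveError):
    """Could not realize the requested placement density."""


# ---------------------------------------------------------------------
# Factorial designs with known coefficients
# ---------------------------------------------------------------------

def evaluate_design(coefficients, coded_points) -> np.ndarray:
    """Noise-free responses b0 + b1·A + b2·B + b3·AB at coded points."""
    b0, b1, b2, b3 = coefficients
    pts = np.asarray(coded_points, float)
    return b0 + b1 * pts[:, 0] + b2 * pts[:, 1] + b3 * pts[:, 0] * pts[:, 1]


def make_noisy_design(true_coefficients, coded_points, noise_sd: float = 0.0,
                      seed: int = 0) -> FactorialDesign:
    """A factorial design whose responses follow known coefficients plus
    Gaussian noise (responses clipped to the [0, 100] percent scale)."""
    if noise_sd < 0:
        raise ArgumentError("noise_sd must be non-negative")
    pts = np.asarray(coded_points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ArgumentError("need >= 5 coded (A, B) points for df >= 1")
    rng = np.random.default_rng(seed)
    y = evaluate_design(true_coefficients, pts)
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=len(y))
    y = np.clip(y, 0.0, 100.0)
    return FactorialDesign(runs=pd.DataFrame(
        {"coded_A": pts[:, 0], "coded_B": pts[:, 1], "response": y}))


# ---------------------------------------------------------------------
# Water boxes
# ---------------------------------------------------------------------

_TIP3_OH = 0.9572
_TIP3_ANGLE = math.radians(104.52)


def _water_molecule(origin: np.ndarray, rot: np.ndarray, mol_index: int) -> Molecule:
    h1 = np.array([_TIP3_OH, 0.0, 0.0])
    h2 = np.array([_TIP3_OH * math.cos(_TIP3_ANGLE),
                   _TIP3_OH * math.sin(_TIP3_ANGLE), 0.0])
    pos = [origin, origin + rot @ h1, origin + rot @ h2]
    atoms = [
        Atom(element="O", position=tuple(pos[0]), partial_charge=-0.834,
             label="water", atom_id=0),
        Atom(element="H", position=tuple(pos[1]), partial_charge=0.417,
             label="water", atom_id=1),
        Atom(element="H", position=tuple(pos[2]), partial_charge=0.417,
             label="water", atom_id=2),
    ]
    return Molecule(atoms=atoms, bonds=[Bond(0, 1), Bond(0, 2)],
                    name=f"water{mol_index}")


def make_water_box(n_waters: int, box=30.0, seed: int = 0,
                   min_oo: float = 2.4, max_attempts: int = 200) -> list[Molecule]:
    """Rigid three-site waters placed uniformly in a periodic box with no
    O–O pair closer than ``min_oo`` (minimum image).  Deterministic."""
    if n_waters < 0:
        raise ArgumentError("n_waters must be non-negative")
    box = np.asarray([box] * 3 if np.isscalar(box) else box, dtype=float)
    # each accepted O excludes a min_oo-radius sphere
    if n_waters * (4.0 / 3.0) * math.pi * min_oo**3 > 6.0 * float(np.prod(box)):
        raise PlacementError(f"{n_waters} waters cannot fit box {box.tolist()}")
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    placed_o: list[np.ndarray] = []
    out: list[Molecule] = []
    for k in range(n_waters):
        for _ in range(max_attempts):
            o = rng.uniform(0.0, box)
            if placed_o:
                dr = minimum_image(np.array(placed_o) - o, box)
                if (np.linalg.norm(dr, axis=-1) < min_oo).any():
                    continue
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            R = Rotation.from_quat(q).as_matrix()
            out.append(_water_molecule(o, R, k))
            placed_o.append(o)
            break
        else:
            raise PlacementError(
                f"placed only {k}/{n_waters} waters after {max_attempts} attempts each")
    return out


# ---------------------------------------------------------------------
# Planted trajectories
# ---------------------------------------------------------------------

@dataclass
class PlantedTrajectorySpec:
    """Schedules for a synthetic solvated hydrogel + pesticide trajectory.

    ``capture_schedule`` holds per-frame capture percentages (multiples of
    100/n_dmt); ``hbond_schedule`` per-frame planted hydrogen-bond triple
    counts; ``water_shell_schedule`` per-frame bound-water counts.  Frame
    times are ``frame_dt_ns`` apart.
    """

    n_frames: int
    n_dmt: int = 50
    capture_schedule: list = field(default_factory=list)
    hbond_schedule: list | None = None
    water_shell_schedule: list | None = None
    n_waters: int | None = None
    box: float | np.ndarray = 110.0
    frame_dt_ns: float = 0.1
    seed: int = 0
    capture_cutoff: float = 4.5
    backbone_cutoff: float = 3.0
    com_radius: float | None = None

    def __post_init__(self):
        if self.n_frames < 1 or self.n_dmt < 1:
            raise ArgumentError("n_frames and n_dmt must be positive")
        if len(self.capture_schedule) != self.n_frames:
            raise ArgumentError("capture_schedule length must equal n_frames")
        per = 100.0 / self.n_dmt
        for pct in self.capture_schedule:
            if abs(pct / per - round(pct / per)) > 1e-6:
                raise ArgumentError(
                    f"capture {pct}% is not a multiple of 100/n_dmt = {per:.3f}%")
        for name in ("hbond_schedule", "water_shell_schedule"):
            sched = getattr(self, name)
            if sched is not None and len(sched) != self.n_frames:
                raise ArgumentError(f"{name} length must equal n_frames")


def _gel_molecules(network) -> list[Molecule]:
    if isinstance(network, CrosslinkNetwork):
        return network.all_molecules()
    if isinstance(network, Molecule):
        return [network]
    return list(network)


def make_planted_trajectory(spec: PlantedTrajectorySpec, network):
    """Generate frames matching the planted schedules exactly.

    Returns ``(frames, topology, template)``: per-frame
    :class:`TrajectoryFrame` objects, the shared topology, and a merged
    template molecule (for writing a multi-model PDB).  Each frame is
    verified against the analysis criteria and re-drawn on the rare
    collision, so the planted capture / hbond / water counts are recovered
    exactly by the observable code.
    """
    box = np.asarray([spec.box] * 3 if np.isscalar(spec.box) else spec.box, float)
    rng = np.random.default_rng(spec.seed)

    gel_mols = [m.relabeled("PVA") for m in _gel_molecules(network)]
    dmt_t = load_template("dimethoate")
    n_waters = spec.n_waters
    if n_waters is None:
        n_waters = max(spec.water_shell_schedule) if spec.water_shell_schedule else 0

    mols = gel_mols + [dmt_t.copy() for _ in range(spec.n_dmt)]
    roles = ["hydrogel"] * len(gel_mols) + ["DMT"] * spec.n_dmt
    water_start = len(mols)
    if n_waters:
        waters = make_water_box(n_waters, box=box, seed=spec.seed + 1)
        mols += waters
        roles += ["water"] * n_waters
    topo = Topology.from_molecules(mols, roles)
    template = merge(mols, name="planted_trajectory")

    # static pieces
    gel_coords = np.vstack([m.coordinates for m in gel_mols])
    gel_center = gel_coords.mean(axis=0)
    com_radius = spec.com_radius
    n_gel = gel_coords.shape[0]
    n_dmt_atoms = len(dmt_t)
    dmt_base = dmt_t.coordinates - dmt_t.coordinates.mean(axis=0)

    # hydrogel donor OH groups for hydrogen-bond planting
    donors = Topology.from_molecules(gel_mols, ["hydrogel"] * len(gel_mols))
    donor_pairs = donors.donor_hydrogens("hydrogel")
    # DMT acceptor: the thiophosphoryl sulfur (double-bonded S), else first S/O
    acc_local = next(
        (i for i, a in enumerate(dmt_t.atoms) if a.element == "S"), 0)

    from scipy.spatial.transform import Rotation

    frames = []
    for f in range(spec.n_frames):
        n_cap = int(round(spec.capture_schedule[f] * spec.n_dmt / 100.0))
        n_hb = spec.hbond_schedule[f] if spec.hbond_schedule else 0
        n_wat_in = (spec.water_shell_schedule[f]
                    if spec.water_shell_schedule else None)
        if n_hb > n_cap:
            raise ArgumentError(
                f"frame {f}: {n_hb} hbonds require at least that many captured guests")
        if n_hb > len(donor_pairs):
            raise PlacementError(
                f"frame {f}: network has only {len(donor_pairs)} donor hydroxyls")
        for attempt in range(60):
            coords = _build_frame(
                rng, spec, box, gel_coords, gel_center, dmt_base, n_dmt_atoms,
                gel_mols, donor_pairs, acc_local, n_cap, n_hb, n_wat_in,
                n_waters, template, topo)
            if coords is None:
                continue
            frame = TrajectoryFrame(coords, topo, box=box,
                                    time=f * spec.frame_dt_ns)
            if not _frame_matches(frame, spec, n_cap, n_hb, n_wat_in):
                continue
            frames.append(frame)
            break
        else:
            raise PlacementError(f"frame {f}: could not realize schedule in 60 draws")
    return frames, topo, template


def _frame_matches(frame, spec, n_cap, n_hb, n_wat_in) -> bool:
    pct = capture_fraction(frame, spec.capture_cutoff)
    if abs(pct - 100.0 * n_cap / spec.n_dmt) > 1e-9:
        return False
    if spec.hbond_schedule is not None:
        total = (hbond_count(frame, "hydrogel", "DMT")
                 + hbond_count(frame, "DMT", "hydrogel"))
        if total != n_hb:
            return False
    if n_wat_in is not None:
        if water_shell_count(frame, spec.backbone_cutoff,
                             spec.com_radius) != n_wat_in:
            return False
    return True


def _build_frame(rng, spec, box, gel_coords, gel_center, dmt_base, n_dmt_atoms,
                 gel_mols, donor_pairs, acc_local, n_cap, n_hb, n_wat_in,
                 n_waters, template, topo):
    from scipy.spatial.transform import Rotation

    n_gel = gel_coords.shape[0]
    parts = [gel_coords]
    placed_centers: list[np.ndarray] = []

    def random_rot():
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        return Rotation.from_quat(q).as_matrix()

    chosen_donors = list(rng.choice(len(donor_pairs), size=n_hb, replace=False)) \
        if n_hb else []

    for k in range(spec.n_dmt):
        if k < n_hb:
            # plant a textbook O-H···S geometry on a distinct donor
            d_idx, h_idx = donor_pairs[chosen_donors[k]]
            dpos = gel_coords[d_idx]
            hpos = gel_coords[h_idx]
            u = hpos - dpos
            u /= np.linalg.norm(u)
            apos = dpos + 2.8 * u           # collinear D-H...A, 2.8 Å
            R = random_rot()
            coords = dmt_base @ R.T
            coords = coords + (apos - coords[acc_local])
        elif k < n_cap:
            # captured: one atom inside the 3-4 Å contact band
            g = gel_coords[int(rng.integers(n_gel))]
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            atom = int(rng.integers(n_dmt_atoms))
            R = random_rot()
            coords = dmt_base @ R.T
            coords = coords + (g + float(rng.uniform(3.2, 3.9)) * v - coords[atom])
        else:
            # free: all atoms at least twice the cutoff from the hydrogel
            for _ in range(200):
                pos = rng.uniform(0.0, box)
                dr = minimum_image(pos - gel_coords, box)
                if np.linalg.norm(dr, axis=-1).min() < 2.0 * spec.capture_cutoff + 4.0:
                    continue
                if placed_centers:
                    dc = minimum_image(np.array(placed_centers) - pos, box)
                    if (np.linalg.norm(dc, axis=-1) < 6.0).any():
                        continue
                break
            else:
                return None
            coords = dmt_base @ random_rot().T + pos
        placed_centers.append(coords.mean(axis=0))
        parts.append(coords)

    if n_waters:
        wcoords = _place_waters(rng, spec, box, gel_coords, gel_center,
                                n_wat_in, n_waters)
        if wcoords is None:
            return None
        parts.append(wcoords)
    return np.vstack(parts)


def _place_waters(rng, spec, box, gel_coords, gel_center, n_wat_in, n_waters):
    from scipy.spatial.transform import Rotation

    if n_wat_in is None:
        n_wat_in = 0
    com_radius = spec.com_radius if spec.com_radius is not None else 20.0
    placed_o: list[np.ndarray] = []
    rows = []
    for k in range(n_waters):
        inside = k < n_wat_in
        for _ in range(300):
            if inside:
                # within the COM sphere (the union criterion's second arm)
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                o = gel_center + v * float(rng.uniform(0.0, max(com_radius - 1.5, 0.5)))
            else:
                o = rng.uniform(0.0, box)
                dr = minimum_image(o - gel_center, box)
                if np.linalg.norm(dr) <= com_radius + 2.0:
                    continue
            drg = minimum_image(o - gel_coords, box)
            dg = np.linalg.norm(drg, axis=-1).min()
            if inside:
                if dg < 2.6:
                    continue
            else:
                if dg <= spec.backbone_cutoff + 1.0:
                    continue
            if placed_o:
                doo = minimum_image(np.array(placed_o) - o, box)
                if (np.linalg.norm(doo, axis=-1) < 2.4).any():
                    continue
            break
        else:
            return None
        placed_o.append(o)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        h1 = o + R @ np.array([_TIP3_OH, 0.0, 0.0])
        h2 = o + R @ np.array([_TIP3_OH * math.cos(_TIP3_ANGLE),
                               _TIP3_OH * math.sin(_TIP3_ANGLE), 0.0])
        rows.extend([o, h1, h2])
    return np.array(rows)


def write_planted_trajectory(frames, topo, template, pdb_path, topology_path):
    """Write the multi-model PDB and JSON topology sidecar."""
    from .fileio import write_multimodel_pdb

    write_multimodel_pdb([f.coordinates for f in frames], template, pdb_path)
    topo.to_json(topology_path)
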
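"""Periodic packing of PVA chains and the cyclic random-esterification
algorithm that turns them into a crosslinked hydrogel topology.

The pipeline mirrors wet-lab crosslinking at the topology level: pack
chains into a periodic box with a minimum separation, then repeat cycles
of (1) picking two unused hydroxyls on *different* chains within a capture
radius, (2) bridging them with one diacid through two ester bonds, and
(3) a capped steepest-descent relaxation to relieve steric strain.  At the
reference composition — 25 chains × 25 monomers = 625 monomers in a
70 Å box — monomer:diacid ratios 10:2 / 10:4 / 10:6 give 125 / 250 / 375
bridges (the 20 / 40 / 60 weight-percent crosslinking series).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import UFF_EPSILON, UFF_SIGMA
from .core import ArgumentError, HydrosieveError, Molecule, centered
from .ester import remove_atoms, strip_hydroxyl_hydrogen
from .nanopore import ESTER_CO_BOND, _align_rotation, _axis_rotation, _terminal_oxygens
from .templates import DIACID_SMILES, build_pva_chain, carboxylate_carbons, load_template


class PackingInfeasibleError(HydrosieveError):
    """Rejection sampling could not place all chains."""


class SaturationError(HydrosieveError):
    """No eligible hydroxyl pair remains before reaching the target."""

    def __init__(self, msg, links_achieved=0):
        super().__init__(msg)
        self.links_achieved = links_achieved


class StateError(HydrosieveError):
    """Operation violates the site registry (e.g. reusing a hydroxyl)."""


class ConstraintError(HydrosieveError):
    """Crosslink constraint violated (e.g. both sites on one chain)."""


class GeometryError(HydrosieveError):
    """Non-finite energy or broken geometry."""


# ---------------------------------------------------------------------
# Periodic helpers
# ---------------------------------------------------------------------

def minimum_image(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    return dr - box * np.round(dr / box)


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


# ---------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------

@dataclass
class PolymerSystem:
    """Packed PVA chains in a periodic box plus the hydroxyl-site registry."""

    chains: list[Molecule]
    box: np.ndarray              # (3,) Å
    seed: int | None = None
    used_sites: set = field(default_factory=set)   # {(chain_idx, site_o)}

    def all_sites(self):
        """[(chain_idx, site_o), ...] over every hydroxyl site."""
        return [(ci, s) for ci, ch in enumerate(self.chains)
                for s in ch.meta.get("hydroxyl_sites", [])]

    def free_sites(self):
        return [t for t in self.all_sites() if t not in self.used_sites]

    def site_position(self, chain_idx: int, site_o: int) -> np.ndarray:
        ch = self.chains[chain_idx]
        return ch.coordinates[ch.index_of(site_o)]

    @property
    def n_monomers(self) -> int:
        return sum(len(ch.meta.get("hydroxyl_sites", [])) +
                   len([t for t in self.used_sites if t[0] == ci])
                   for ci, ch in enumerate(self.chains))

    def copy(self) -> "PolymerSystem":
        return PolymerSystem(chains=[c.copy() for c in self.chains],
                             box=self.box.copy(), seed=self.seed,
                             used_sites=set(self.used_sites))


@dataclass
class LinkRecord:
    cycle: int
    chain_i: int
    site_i: int
    chain_j: int
    site_j: int
    acid_id: str
    distance: float     # O-O minimum-image distance at formation, Å


@dataclass
class CrosslinkNetwork:
    """Crosslinked polymer system: chains + inserted diacid bridges."""

    system: PolymerSystem
    links: list[LinkRecord] = field(default_factory=list)
    linker_mols: list[Molecule] = field(default_factory=list)
    acid_id: str = ""

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def ratio_label(self) -> str:
        """Monomer:diacid label (e.g. '10:2') when it matches a standard one."""
        n_mono = sum(len(ch.meta.get("hydroxyl_sites", [])) for ch in self.system.chains)
        # sites were consumed by links: total monomers = free sites + 2/link
        n_mono += 2 * self.n_links
        for q in (2, 4, 6):
            if self.n_links == (n_mono * q) // 10:
                return f"10:{q}"
        return f"custom({self.n_links} links / {n_mono} monomers)"

    def all_molecules(self) -> list[Molecule]:
        return list(self.system.chains) + list(self.linker_mols)


# ---------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------

def pack_chains(
    n_chains: int,
    chain_length: int,
    box=70.0,
    min_sep: float = 5.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> PolymerSystem:
    """Randomly place rigid PVA chains in a periodic box by rejection
    sampling until every inter-chain atom distance is at least ``min_sep``
    under minimum image.  Deterministic per seed."""
    if n_chains < 1 or chain_length < 1:
        raise ArgumentError("n_chains and chain_length must be positive")
    box = np.asarray([box] * 3 if np.isscalar(box) else box, dtype=float)

    # excluded-volume feasibility: each atom blocks a small sphere (radius
    # capped so a generous min_sep is not mistaken for infeasibility)
    template = build_pva_chain(chain_length, tacticity_seed=seed)
    r_block = min(min_sep / 2.0, 3.0)
    v_block = n_chains * len(template) * (4.0 / 3.0) * math.pi * r_block**3
    if v_block > 4.0 * float(np.prod(box)):
        raise PackingInfeasibleError(
            f"{n_chains} chains of {chain_length} monomers cannot fit a "
            f"{box.tolist()} box at min_sep {min_sep}"
        )

    last_err = None
    for restart in range(5):
        try:
            chains = _pack_once(n_chains, chain_length, box, min_sep,
                                seed + 1000003 * restart, max_attempts)
            return PolymerSystem(chains=chains, box=box, seed=seed)
        except PackingInfeasibleError as err:
            last_err = err
    raise last_err


def _pack_once(n_chains, chain_length, box, min_sep, seed, max_attempts):
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    chains: list[Molecule] = []
    placed_tree = None
    placed_coords = np.empty((0, 3))
    needs_refine = False
    for ci in range(n_chains):
        base = centered(build_pva_chain(chain_length, tacticity_seed=seed + ci))
        best = None   # (worst-gap, coords)
        # once refinement is inevitable, don't burn the full attempt budget
        budget = max_attempts if not needs_refine else max(max_attempts // 10, 100)
        for attempt in range(budget):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            R = Rotation.from_quat(q).as_matrix()
            t = rng.uniform(0.0, box)
            coords = base.coordinates @ R.T + t
            if placed_tree is None:
                best = (np.inf, coords)
                break
            d, _ = placed_tree.query(wrap(coords, box), k=1)
            dmin = float(d.min())
            if best is None or dmin > best[0]:
                best = (dmin, coords)
            if dmin >= min_sep:
                break
        if best[0] < min_sep:
            needs_refine = True   # keep the least-bad placement, fix below
        coords = best[1]
        chains.append(base.with_coordinates(coords))
        placed_coords = np.vstack([placed_coords, wrap(coords, box)])
        placed_tree = cKDTree(placed_coords, boxsize=box)

    if needs_refine:
        chains = _push_apart(chains, box, min_sep, max_iters=500)
    return chains


def _push_apart(chains: list[Molecule], box: np.ndarray, min_sep: float,
                max_iters: int = 500) -> list[Molecule]:
    """Deterministic rigid-body de-overlap: translate chains along the sum
    of their violation vectors until every inter-chain distance clears
    ``min_sep`` (the refinement used when pure rejection sampling stalls
    in a crowded box)."""
    coords = [c.coordinates for c in chains]
    sizes = [len(c) for c in coords]
    chain_of = np.concatenate([np.full(n, k) for k, n in enumerate(sizes)])
    for _ in range(max_iters):
        allc = np.vstack(coords)
        wrapped = wrap(allc, box)
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if pairs.size:
            keep = chain_of[pairs[:, 0]] != chain_of[pairs[:, 1]]
            pairs = pairs[keep]
        if not pairs.size:
            return [c.with_coordinates(x) for c, x in zip(chains, coords)]
        disp = np.zeros((len(chains), 3))
        cnt = np.zeros(len(chains))
        dr = minimum_image(wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]], box)
        d = np.maximum(np.linalg.norm(dr, axis=-1), 1e-6)
        push = (min_sep - d + 0.1)[:, None] * dr / d[:, None]
        for k in range(pairs.shape[0]):
            a, b = chain_of[pairs[k, 0]], chain_of[pairs[k, 1]]
            disp[a] += 0.5 * push[k]
            disp[b] -= 0.5 * push[k]
            cnt[a] += 1
            cnt[b] += 1
        moved = cnt > 0
        disp[moved] /= cnt[moved, None]
        for k in np.nonzero(moved)[0]:
            coords[k] = coords[k] + disp[k]
    raise PackingInfeasibleError(
        f"push-apart failed to reach min_sep {min_sep} within {max_iters} iterations"
    )


def min_interchain_distance(system: PolymerSystem) -> float:
    """Brute-force all-pairs minimum inter-chain distance (minimum image)."""
    best = np.inf
    for i in range(len(system.chains)):
        ci = system.chains[i].coordinates
        for j in range(i + 1, len(system.chains)):
            cj = system.chains[j].coordinates
            dr = minimum_image(ci[:, None, :] - cj[None, :, :], system.box)
            best = min(best, float(np.linalg.norm(dr, axis=-1).min()))
    return best


# ---------------------------------------------------------------------
# Crosslinking cycle
# ---------------------------------------------------------------------

def composition_to_links(n_monomers: int, ratio) -> int:
    """Number of diacid bridges implied by a monomer:diacid ratio.

    ``ratio`` may be a string '10:2' or a (p, q) pair; the answer is
    floor(n_monomers * q / p).
    """
    if isinstance(ratio, str):
        p, q = (int(t) for t in ratio.split(":"))
    else:
        p, q = ratio
    if n_monomers <= 0 or p <= 0 or q <= 0:
        raise ArgumentError("composition_to_links needs positive inputs")
    return (n_monomers * q) // p


def eligible_pairs(system: PolymerSystem, max_dist: float = 10.0):
    """All unused different-chain hydroxyl pairs with O–O minimum-image
    distance <= max_dist, with their distances."""
    sites = system.free_sites()
    if len(sites) < 2:
        return []
    pos = wrap(np.array([system.site_position(*t) for t in sites]), system.box)
    tree = cKDTree(pos, boxsize=system.box)
    out = []
    for i, j in sorted(tree.query_pairs(max_dist)):
        if sites[i][0] == sites[j][0]:
            continue
        d = float(np.linalg.norm(minimum_image(pos[i] - pos[j], system.box)))
        out.append((sites[i], sites[j], d))
    return out


def select_crosslink_pair(system: PolymerSystem, max_dist: float = 10.0,
                          rng: np.random.Generator | None = None):
    """Uniformly random eligible hydroxyl pair, or None if none exists."""
    rng = rng if rng is not None else np.random.default_rng()
    pairs = eligible_pairs(system, max_dist)
    if not pairs:
        return None
    return pairs[int(rng.integers(len(pairs)))]


def form_ester_link(
    network: CrosslinkNetwork,
    site_i: tuple[int, int],
    site_j: tuple[int, int],
    acid_id: str,
    cycle: int = 0,
) -> LinkRecord:
    """Bridge two hydroxyl sites with one diacid via two ester bonds.

    Consumes both sites (one H each) and one terminal oxygen per
    carboxylate; the diacid is rigidly placed along the minimum-image O–O
    axis.  Mutates ``network`` in place and returns the link record.
    """
    system = network.system
    ci, oi = site_i
    cj, oj = site_j
    if ci == cj:
        raise ConstraintError("crosslink sites must be on different chains")
    for t in (site_i, site_j):
        if t in system.used_sites:
            raise StateError(f"hydroxyl site {t} already used")
        if t[1] not in system.chains[t[0]].meta.get("hydroxyl_sites", []):
            raise ArgumentError(f"{t} is not a hydroxyl site")
    if acid_id not in DIACID_SMILES:
        raise ArgumentError(f"{acid_id!r} is not a diacid template")

    p1 = system.site_position(ci, oi)
    p2_raw = system.site_position(cj, oj)
    dvec = minimum_image(p2_raw - p1, system.box)
    dist = float(np.linalg.norm(dvec))
    p2 = p1 + dvec

    linker = load_template(acid_id)
    carbs = carboxylate_carbons(linker)
    ct = linker.coordinates
    c1t = ct[linker.index_of(carbs[0])]
    c2t = ct[linker.index_of(carbs[1])]
    u = dvec / dist
    t1 = p1 + ESTER_CO_BOND * u
    t2 = p2 - ESTER_CO_BOND * u
    R0 = _align_rotation(c2t - c1t, t2 - t1)

    # pick the spin angle with most clearance from nearby system atoms
    near = _nearby_coords(network, 0.5 * (p1 + p2), radius=9.0,
                          exclude={(ci, oi), (cj, oj)})
    best = None
    for angle_deg in range(0, 360, 30):
        R = _axis_rotation(u, math.radians(angle_deg)) @ R0
        coords = ct @ R.T
        coords = coords + (t1 - coords[linker.index_of(carbs[0])])
        if near.shape[0]:
            dmin = float(np.linalg.norm(
                minimum_image(coords[:, None, :] - near[None, :, :], system.box),
                axis=-1).min())
        else:
            dmin = np.inf
        if best is None or dmin > best[0]:
            best = (dmin, coords)
    placed = linker.with_coordinates(best[1])
    placed = strip_carboxylate_oxygen_pair(placed, carbs, toward=(p1, p2))
    placed = placed.relabeled("linker")
    placed.meta["ester_sites"] = [(ci, oi), (cj, oj)]
    placed.meta["carboxyl_carbons"] = list(carbs)

    system.chains[ci] = strip_hydroxyl_hydrogen(system.chains[ci], oi)
    system.chains[cj] = strip_hydroxyl_hydrogen(system.chains[cj], oj)
    system.used_sites.update((site_i, site_j))
    # the site remains a registry entry no longer offered: remove from meta
    for cidx, o in (site_i, site_j):
        meta_sites = system.chains[cidx].meta.get("hydroxyl_sites", [])
        system.chains[cidx].meta["hydroxyl_sites"] = [s for s in meta_sites if s != o]

    rec = LinkRecord(cycle=cycle, chain_i=ci, site_i=oi, chain_j=cj, site_j=oj,
                     acid_id=acid_id, distance=dist)
    network.links.append(rec)
    network.linker_mols.append(placed)
    return rec


def strip_carboxylate_oxygen_pair(linker: Molecule, carbs, toward) -> Molecule:
    """Remove one terminal oxygen per carboxylate (the one facing its
    incoming ester bond)."""
    from .ester import strip_carboxylate_oxygen

    coords = linker.coordinates
    out = linker
    for c, target in zip(carbs, toward):
        cpos = coords[linker.index_of(c)]
        out = strip_carboxylate_oxygen(out, c, keep_toward=np.asarray(target) - cpos)
    return out


def _nearby_coords(network: CrosslinkNetwork, center: np.ndarray, radius: float,
                   exclude=frozenset()) -> np.ndarray:
    pts = []
    for ci, ch in enumerate(network.system.chains):
        coords = ch.coordinates
        dr = minimum_image(coords - center, network.system.box)
        mask = (np.linalg.norm(dr, axis=-1) < radius)
        pts.append(coords[mask])
    for lm in network.linker_mols:
        coords = lm.coordinates
        dr = minimum_image(coords - center, network.system.box)
        pts.append(coords[np.linalg.norm(dr, axis=-1) < radius])
    return np.vstack(pts) if pts else np.empty((0, 3))


# ---------------------------------------------------------------------
# Steepest-descent relaxation
# ---------------------------------------------------------------------

_KBOND = 300.0    # kcal/mol/Å², generic stretch constant
_LJ_CUTOFF = 6.0  # Å


class _SystemArrays:
    """Flattened coordinate/bond view over chains + linkers for relax()."""

    def __init__(self, network: CrosslinkNetwork):
        self.network = network
        mols = network.all_molecules()
        self.mols = mols
        self.sizes = [len(m) for m in mols]
        self.offsets = np.cumsum([0] + self.sizes[:-1])
        self.coords = np.vstack([m.coordinates for m in mols])
        self.mol_of = np.concatenate(
            [np.full(n, k) for k, n in enumerate(self.sizes)]
        )
        # intramolecular bonds with current lengths as rest lengths
        bonds = []
        for k, m in enumerate(mols):
            off = self.offsets[k]
            idx = {a.atom_id: i for i, a in enumerate(m.atoms)}
            for b in m.bonds:
                bonds.append((off + idx[b.a], off + idx[b.b]))
        # ester cross-bonds: chain O to carboxyl C, rest length 1.43
        n_chain = len(network.system.chains)
        self.cross = []
        for li, lm in enumerate(network.linker_mols):
            carbs = lm.meta.get("carboxyl_carbons", [])
            sites = lm.meta.get("ester_sites", [])
            lidx = {a.atom_id: i for i, a in enumerate(lm.atoms)}
            loff = self.offsets[n_chain + li]
            for (cidx, o), c in zip(sites, carbs):
                ch = network.system.chains[cidx]
                try:
                    oi = ch.index_of(o)
                except ArgumentError:
                    continue
                self.cross.append((self.offsets[cidx] + oi, loff + lidx[c]))
        self.bond_idx = np.array(bonds + self.cross, dtype=int).reshape(-1, 2)
        d = np.linalg.norm(
            minimum_image(self.coords[self.bond_idx[:, 0]] - self.coords[self.bond_idx[:, 1]],
                          network.system.box), axis=-1)
        self.rest = d.copy()
        if self.cross:
            self.rest[-len(self.cross):] = ESTER_CO_BOND
        self.box = network.system.box
        eps = np.array([UFF_EPSILON.get(a.element, 0.05)
                        for m in mols for a in m.atoms])
        sig = np.array([UFF_SIGMA.get(a.element, 3.0)
                        for m in mols for a in m.atoms])
        self.eps, self.sig = eps, sig
        n_tot = len(self.coords)
        keys = []
        for a, b in self.cross:
            keys.extend((a * n_tot + b, b * n_tot + a))
        self.cross_keys = np.array(sorted(keys), dtype=np.int64)
        self.n_tot = n_tot

    def energy_forces(self, coords):
        box = self.box
        f = np.zeros_like(coords)
        # bonds
        i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
        dr = minimum_image(coords[i] - coords[j], box)
        d = np.linalg.norm(dr, axis=-1)
        d = np.maximum(d, 1e-8)
        e_bond = (_KBOND * (d - self.rest) ** 2).sum()
        fb = (-2.0 * _KBOND * (d - self.rest) / d)[:, None] * dr
        np.add.at(f, i, fb)
        np.add.at(f, j, -fb)
        # intermolecular LJ within cutoff
        tree = cKDTree(wrap(coords, box), boxsize=box)
        pairs = tree.query_pairs(_LJ_CUTOFF, output_type="ndarray")
        if pairs.size:
            pi, pj = pairs[:, 0], pairs[:, 1]
            keep = self.mol_of[pi] != self.mol_of[pj]
            pi, pj = pi[keep], pj[keep]
            if pi.size and self.cross_keys.size:
                excl = np.isin(pi.astype(np.int64) * self.n_tot + pj, self.cross_keys)
                pi, pj = pi[~excl], pj[~excl]
        else:
            pi = pj = np.array([], dtype=int)
        e_lj = 0.0
        if pi.size:
            dr = minimum_image(coords[pi] - coords[pj], box)
            d = np.maximum(np.linalg.norm(dr, axis=-1), 0.5)
            eps = np.sqrt(self.eps[pi] * self.eps[pj])
            sig = 0.5 * (self.sig[pi] + self.sig[pj])
            sr6 = (sig / d) ** 6
            e_lj = float((4 * eps * (sr6**2 - sr6)).sum())
            dmag = (24 * eps / d) * (2 * sr6**2 - sr6)
            flj = (dmag / d)[:, None] * dr
            np.add.at(f, pi, flj)
            np.add.at(f, pj, -flj)
        return float(e_bond + e_lj), f

    def write_back(self, coords):
        for k, m in enumerate(self.mols):
            o, n = self.offsets[k], self.sizes[k]
            self.mols[k] = m.with_coordinates(coords[o:o + n])
        nch = len(self.network.system.chains)
        self.network.system.chains = self.mols[:nch]
        self.network.linker_mols = self.mols[nch:]


def relax(network: CrosslinkNetwork, max_steps: int = 50,
          force_tol: float = 10.0, step0: float = 2e-4) -> CrosslinkNetwork:
    """Steepest-descent relaxation of the whole system (capped).

    Energy: harmonic stretches on every covalent bond (rest lengths taken
    from construction; ester cross-bonds at 1.43 Å) plus intermolecular
    Lennard-Jones inside a 6 Å cutoff.  The step is backtracked until the
    energy does not increase, so the energy trace is non-increasing;
    returns after ``max_steps`` accepted steps or when the maximum force
    falls below ``force_tol`` (kcal/mol/Å).
    """
    arrays = _SystemArrays(network)
    coords = arrays.coords.copy()
    e, f = arrays.energy_forces(coords)
    if not np.isfinite(e):
        raise GeometryError("non-finite energy at entry to relax()")
    step = step0
    for _ in range(max_steps):
        fmax = float(np.abs(f).max()) if f.size else 0.0
        if fmax <= force_tol:
            break
        # never displace an atom by more than 0.5 Å in one step
        trial_step = min(step, 0.5 / fmax)
        for _ in range(12):
            new = coords + trial_step * f
            e_new, f_new = arrays.energy_forces(new)
            if np.isfinite(e_new) and e_new <= e:
                coords, e, f = new, e_new, f_new
                step = min(trial_step * 1.5, 1e-2)
                break
            trial_step *= 0.5
        else:
            break
    arrays.write_back(coords)
    return network


# ---------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------

def build_network(
    system: PolymerSystem,
    acid_id: str,
    target_links: int,
    seed: int = 0,
    max_dist: float = 10.0,
    relax_steps: int = 5,
    relax_every: int = 1,
) -> CrosslinkNetwork:
    """Run select → bond → relax cycles until ``target_links`` bridges.

    Deterministic per seed.  Raises :class:`SaturationError` (carrying the
    number of links achieved) if no eligible pair remains early.
    ``relax_steps``/``relax_every`` cap the per-cycle relaxation so large
    systems stay tractable; 0 disables it.
    """
    if target_links < 0:
        raise ArgumentError("target_links must be >= 0")
    rng = np.random.default_rng(seed)
    network = CrosslinkNetwork(system=system.copy(), acid_id=acid_id)
    for cycle in range(1, target_links + 1):
        picked = select_crosslink_pair(network.system, max_dist, rng)
        if picked is None:
            raise SaturationError(
                f"no eligible pair at cycle {cycle}; achieved "
                f"{network.n_links}/{target_links} links",
                links_achieved=network.n_links,
            )
        site_i, site_j, _ = picked
        form_ester_link(network, site_i, site_j, acid_id, cycle=cycle)
        if relax_steps > 0 and cycle % relax_every == 0:
            relax(network, max_steps=relax_steps)
    return network
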
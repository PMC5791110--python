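"""Nanopore assembly, uniform rotations, contact placement, surrogate
energies and the Monte-Carlo screen."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from hydrosieve.constants import COULOMB_KCAL, UFF_SIGMA
from hydrosieve.core import ArgumentError, Atom, Molecule, centered
from hydrosieve.nanopore import (
    BackendUnavailableError,
    ContactFailureError,
    EnergySample,
    Pose,
    SurrogateBackend,
    assemble_nanopore,
    clash_ratio,
    contact_distance,
    interaction_energy,
    mc_screen,
    place_at_contact,
    pm7_backend,
    random_direction,
    random_rotation,
    rank_crosslinkers,
    rotation_matrix,
    load_reference_energies,
    screen_all_acids,
)
from hydrosieve.templates import DIACID_SMILES, load_template


def single_atom(element, pos, q=0.0, radius=None):
    return Molecule(atoms=[Atom(element=element, position=pos,
                                partial_charge=q, vdw_radius=radius, atom_id=0)])


# ---------------------------------------------------------------- assembly

class TestAssembly:
    def test_malic_form1_has_two_linkers_four_esters(self, malic_pore):
        assert len(malic_pore.linker_atoms) == 2
        # each ester: one bond from a chain O to a linker carboxyl C
        chain_ids = set(malic_pore.chain_atoms[0]) | set(malic_pore.chain_atoms[1])
        linker_ids = set(malic_pore.linker_atoms[0]) | set(malic_pore.linker_atoms[1])
        cross = [b for b in malic_pore.molecule.bonds
                 if (b.a in chain_ids) != (b.b in chain_ids)
                 and (b.a in linker_ids or b.b in linker_ids)]
        assert len(cross) == 4

    def test_all_112_assemblies_clash_free(self):
        for acid in DIACID_SMILES:
            for form in range(1, 9):
                pore = assemble_nanopore(acid, form)
                assert clash_ratio(pore.molecule) >= 0.7, (acid, form)

    def test_cavity_width_grows_with_linker_length(self):
        spans, widths = [], []
        for acid in DIACID_SMILES:
            mol = load_template(acid)
            from hydrosieve.templates import carboxylate_carbons
            cc = carboxylate_carbons(mol)
            c = mol.coordinates
            spans.append(np.linalg.norm(c[mol.index_of(cc[0])] - c[mol.index_of(cc[1])]))
            widths.append(assemble_nanopore(acid, 1).cavity_width())
        order = np.argsort(spans)
        w = np.array(widths)[order]
        assert np.all(np.diff(w) >= -1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ArgumentError):
            assemble_nanopore("malic", 9)
        with pytest.raises(ArgumentError):
            assemble_nanopore("citric", 1)

    def test_deterministic(self):
        a = assemble_nanopore("glutaric", 3)
        b = assemble_nanopore("glutaric", 3)
        assert np.array_equal(a.molecule.coordinates, b.molecule.coordinates)


# ---------------------------------------------------------------- rotations

class TestRandomRotation:
    def test_deterministic_sequence(self):
        a = [random_rotation(np.random.default_rng(5)) for _ in range(1)]
        b = [random_rotation(np.random.default_rng(5)) for _ in range(1)]
        assert a == b

    def test_haar_mean_matrix_vanishes(self, rng):
        n = 10_000
        acc = np.zeros((3, 3))
        for _ in range(n):
            acc += rotation_matrix(random_rotation(rng))
        assert np.abs(acc / n).max() < 0.05

    def test_rotated_vector_uniform_on_octants(self, rng):
        v = np.array([1.0, 0.0, 0.0])
        counts = np.zeros(8)
        n = 10_000
        for _ in range(n):
            w = rotation_matrix(random_rotation(rng)) @ v
            octant = (w[0] > 0) * 4 + (w[1] > 0) * 2 + (w[2] > 0)
            counts[octant] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_direction_is_unit(self, rng):
        for _ in range(100):
            assert np.linalg.norm(random_direction(rng)) == pytest.approx(1.0)


# ---------------------------------------------------------------- contact

def bisection_contact(static, mobile_coords, mobile_radii, u, tol=1e-6):
    """Independent 1-D root-finding oracle on the minimum-gap function."""
    sc, sr = static.coordinates, static.radii

    def min_gap(t):
        d = np.linalg.norm(sc[:, None, :] - (mobile_coords + t * u)[None, :, :],
                           axis=-1)
        return (d - (sr[:, None] + mobile_radii[None, :])).min()

    t_hi = (np.abs(sc).max() + np.abs(mobile_coords).max()
            + sr.max() + mobile_radii.max() + 5.0)
    grid = np.linspace(0.0, t_hi, 4000)
    # each pair's gap is minimal at its closest-approach time along u;
    # include those so grazing contacts are not missed by the grid
    approach = ((sc[:, None, :] - mobile_coords[None, :, :]) @ u).ravel()
    candidates = np.concatenate([grid, approach[(approach > 0) & (approach < t_hi)]])
    candidates.sort()
    gaps = np.array([min_gap(t) for t in candidates])
    neg = np.nonzero(gaps < 0)[0]
    if neg.size == 0:
        return None
    lo = candidates[neg[-1]]
    hi = t_hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestContactPlacement:
    def test_two_spheres_touch_at_sum_of_radii(self):
        a = single_atom("C", (0, 0, 0), radius=1.70)
        b = single_atom("O", (0, 0, 0), radius=1.52)
        pose, placed = place_at_contact(a, b, (0, 0, 0), (1, 0, 0))
        assert pose.contact_t == pytest.approx(3.22, abs=1e-9)
        assert np.linalg.norm(placed.coordinates[0]) == pytest.approx(3.22)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bisection_oracle_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        static = Molecule(atoms=[
            Atom(element="C", position=tuple(rng.normal(scale=1.5, size=3)), atom_id=i)
            for i in range(n1)])
        mobile = Molecule(atoms=[
            Atom(element="O", position=tuple(rng.normal(scale=1.5, size=3)), atom_id=i)
            for i in range(n2)])
        euler = random_rotation(rng)
        u = random_direction(rng)
        R = rotation_matrix(euler)
        rotated = mobile.coordinates @ R.T
        t_fast = contact_distance(static.coordinates, static.radii,
                                  rotated, mobile.radii, u)
        t_ref = bisection_contact(static, rotated, mobile.radii, u)
        assert t_ref is not None
        assert t_fast == pytest.approx(t_ref, abs=1e-4)

    def test_rotational_invariance(self, rng):
        static = Molecule(atoms=[
            Atom(element="C", position=tuple(rng.normal(size=3)), atom_id=i)
            for i in range(4)])
        mobile = Molecule(atoms=[
            Atom(element="O", position=tuple(rng.normal(size=3)), atom_id=i)
            for i in range(3)])
        u = random_direction(rng)
        t0 = contact_distance(static.coordinates, static.radii,
                              mobile.coordinates, mobile.radii, u)
        Q = rotation_matrix(random_rotation(rng))
        t1 = contact_distance(static.coordinates @ Q.T, static.radii,
                              mobile.coordinates @ Q.T, mobile.radii, Q @ u)
        assert t0 == pytest.approx(t1, abs=1e-9)

    def test_zero_gap_and_no_overlap_at_pose(self, malic_pore, dmt, rng):
        host = centered(malic_pore.molecule)
        guest = centered(dmt)
        for _ in range(200):
            pose, placed = place_at_contact(host, guest, random_rotation(rng),
                                            random_direction(rng))
            d = np.linalg.norm(host.coordinates[:, None, :]
                               - placed.coordinates[None, :, :], axis=-1)
            gap = d - (host.radii[:, None] + placed.radii[None, :])
            assert abs(gap.min()) < 1e-6

    def test_contact_failure_when_ray_misses(self):
        # mobile off-axis: sliding along +x never touches the static atom
        a = single_atom("C", (0, 0, 0))
        b = Molecule(atoms=[Atom(element="O", position=(0, 50.0, 0), atom_id=0)])
        with pytest.raises(ContactFailureError):
            contact_distance(a.coordinates, a.radii, b.coordinates, b.radii,
                             np.array([1.0, 0, 0]))

    def test_zero_direction_rejected(self, dmt):
        with pytest.raises(ArgumentError):
            place_at_contact(dmt, dmt, (0, 0, 0), (0, 0, 0))


# ---------------------------------------------------------------- energies

class TestSurrogateBackend:
    def test_isolated_molecule_energy_zero(self, dmt):
        assert SurrogateBackend().energy([dmt]) == 0.0

    def test_lj_zero_crossing_at_sigma(self):
        sigma = UFF_SIGMA["C"]
        a = single_atom("C", (0, 0, 0))
        b = single_atom("C", (sigma, 0, 0))
        assert SurrogateBackend(coulomb_scale=0.0).energy([a, b]) == pytest.approx(0.0, abs=1e-12)

    def test_pure_coulomb_hand_value(self):
        a = single_atom("C", (0, 0, 0), q=+0.2)
        b = single_atom("C", (3.40, 0, 0), q=-0.2)
        expected = COULOMB_KCAL * (0.2 * -0.2) / 3.40
        got = SurrogateBackend(lj_scale=0.0).energy([a, b])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_three_atom_system_matches_pairwise_hand_sum(self):
        from hydrosieve.constants import UFF_EPSILON
        m1 = Molecule(atoms=[Atom(element="C", position=(0, 0, 0),
                                  partial_charge=0.1, atom_id=0),
                             Atom(element="O", position=(1.2, 0, 0),
                                  partial_charge=-0.2, atom_id=1)])
        m2 = single_atom("H", (0.0, 3.0, 0.0), q=0.1)
        total = 0.0
        for el, pos, q in (("C", (0, 0, 0), 0.1), ("O", (1.2, 0, 0), -0.2)):
            d = np.linalg.norm(np.array(pos) - np.array([0.0, 3.0, 0.0]))
            eps = np.sqrt(UFF_EPSILON[el] * UFF_EPSILON["H"])
            sig = 0.5 * (UFF_SIGMA[el] + UFF_SIGMA["H"])
            sr6 = (sig / d) ** 6
            total += 4 * eps * (sr6**2 - sr6) + COULOMB_KCAL * q * 0.1 / d
        assert SurrogateBackend().energy([m1, m2]) == pytest.approx(total, abs=1e-10)

    def test_missing_parameters_raise(self):
        from hydrosieve.nanopore import ParameterizationError
        na = single_atom("Na", (0, 0, 0))
        c = single_atom("C", (3, 0, 0))
        with pytest.raises(ParameterizationError):
            SurrogateBackend().energy([na, c])


class TestInteractionEnergy:
    def test_delta_e_arithmetic(self):
        s = EnergySample(pose=Pose((0, 0, 0), (1, 0, 0), 1.0),
                         e_complex=-100.0, e_mol1=-60.0, e_mol2=-38.0)
        assert s.delta_e == pytest.approx(-2.0, abs=1e-12)

    def test_neutral_pair_vanishes_at_500A(self, dmt):
        guest = centered(dmt)
        far = guest.translated((500.0, 0, 0))
        s = interaction_energy(guest, far, Pose((0, 0, 0), (1, 0, 0), 500.0),
                               SurrogateBackend())
        assert abs(s.delta_e) < 1e-3

    def test_decay_is_monotone_in_separation(self, malic_pore, dmt):
        host = centered(malic_pore.molecule)
        guest = centered(dmt)
        pose, placed = place_at_contact(host, guest, (0.3, 0.9, -0.2),
                                        (0.0, 1.0, 0.0))
        be = SurrogateBackend()
        mags = []
        for extra in (0.0, 5.0, 20.0, 100.0):
            shifted = placed.translated((0.0, extra, 0.0))
            mags.append(abs(interaction_energy(host, shifted, pose, be).delta_e))
        assert mags[0] > mags[1] > mags[2] > mags[3]

    def test_bookkeeping_identity_on_samples(self, malic_pore, dmt):
        ens = mc_screen(malic_pore, dmt, n_samples=50, seed=4)
        for s in ens.samples:
            assert s.delta_e == pytest.approx(
                s.e_complex - s.e_mol1 - s.e_mol2, abs=1e-9)


class TestPM7Backend:
    def test_absent_executable_is_a_clear_error(self):
        with pytest.raises(BackendUnavailableError):
            pm7_backend("definitely-not-a-real-mopac-binary")


# ---------------------------------------------------------------- screen

class TestMCScreen:
    def test_seeded_reproducibility(self, malic_pore, dmt):
        a = mc_screen(malic_pore, dmt, n_samples=100, seed=77)
        b = mc_screen(malic_pore, dmt, n_samples=100, seed=77)
        assert a.delta_e.tolist() == b.delta_e.tolist()
        assert (a.mean, a.sd, a.min) == (b.mean, b.sd, b.min)

    def test_summary_matches_recomputed_statistics(self, malic_pore, dmt):
        ens = mc_screen(malic_pore, dmt, n_samples=200, seed=3)
        d = np.array([s.delta_e for s in ens.samples])
        assert ens.n == 200
        assert ens.mean == pytest.approx(d.mean(), abs=1e-12)
        assert ens.min == pytest.approx(d.min(), abs=1e-12)

    def test_two_seeds_agree_within_monte_carlo_error(self, malic_pore, dmt):
        n = 2000
        a = mc_screen(malic_pore, dmt, n_samples=n, seed=101)
        b = mc_screen(malic_pore, dmt, n_samples=n, seed=202)
        tol = 3.0 * max(a.sd, b.sd) / np.sqrt(n)
        assert abs(a.mean - b.mean) < tol

    def test_invalid_sample_count(self, malic_pore, dmt):
        with pytest.raises(ArgumentError):
            mc_screen(malic_pore, dmt, n_samples=0)

    def test_single_acid_single_form_equals_mc_screen(self, dmt):
        df = screen_all_acids(["succinic"], dmt, n_samples=40, seed=9, forms=[2])
        pore = assemble_nanopore("succinic", 2)
        seed = int(np.random.SeedSequence(9).generate_state(2)[0]) % (2**31)
        ens = mc_screen(pore, dmt, n_samples=40, seed=seed)
        assert df["mean_kcal_mol"].iloc[0] == pytest.approx(ens.mean, abs=1e-12)
        assert df["acid_mean"].iloc[0] == pytest.approx(ens.mean, abs=1e-12)

    def test_grand_mean_is_unweighted_mean_of_form_means(self, dmt):
        df = screen_all_acids(["oxalic"], dmt, n_samples=15, seed=5,
                              forms=[1, 2, 3])
        by_hand = df["mean_kcal_mol"].mean()
        assert df["acid_mean"].iloc[0] == pytest.approx(by_hand, abs=1e-12)


class TestRanking:
    def test_published_table_puts_malic_first(self):
        table = load_reference_energies()
        ranked = rank_crosslinkers(table)
        assert ranked.iloc[0]["acid"] == "malic"
        assert ranked.iloc[0]["mean_kcal_mol"] == pytest.approx(-1.998)

    def test_permutation_invariance(self, rng):
        table = load_reference_energies()
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        assert rank_crosslinkers(table)["acid"].tolist() == \
            rank_crosslinkers(shuffled)["acid"].tolist()

    def test_single_entry(self):
        out = rank_crosslinkers({"oxalic": -1.0})
        assert out["acid"].tolist() == ["oxalic"]

    def test_ties_break_alphabetically(self):
        out = rank_crosslinkers({"b_acid": -1.0, "a_acid": -1.0, "c_acid": -2.0})
        assert out["acid"].tolist() == ["c_acid", "a_acid", "b_acid"]

    def test_empty_table_rejected(self):
        with pytest.raises(ArgumentError):
            rank_crosslinkers({})
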
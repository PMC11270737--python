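import numpy as np
import pytest

from regscape.chem_topology import charged_groups, parse_sequence
from regscape.contacts import (
    contact_mask,
    group_distance_series,
    hbond_occupancy,
    min_group_distance,
    occupancy_difference,
    saltbridge_occupancy,
)
from regscape.synthetic import plant_contact_ensemble, plant_contacts


@pytest.fixture(scope="module")
def groups(np_topology):
    return {g.author_number: g for g in charged_groups(np_topology)}


class TestMinGroupDistance:
    def test_single_atom_groups(self):
        frame = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        assert min_group_distance(frame, [0], [1]) == pytest.approx(0.2)

    def test_identical_groups_zero(self):
        frame = np.array([[0.1, 0.2, 0.3]])
        assert min_group_distance(frame, [0], [0]) == 0.0

    def test_brute_force_oracle(self, rng):
        frame = rng.normal(size=(12, 3))
        ia, ib = [0, 3, 5], [7, 8, 9, 11]
        expected = min(
            np.linalg.norm(frame[i] - frame[j]) for i in ia for j in ib
        )
        assert min_group_distance(frame, ia, ib) == pytest.approx(expected)


class TestSaltbridgeOccupancy:
    def test_planted_fraction_recovered_exactly(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.25, n_frames=1000)
        occ = saltbridge_occupancy(t, np_topology)
        assert occ.pair("K357", "E358") == 0.250

    def test_far_groups_zero(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.0, n_frames=100)
        occ = saltbridge_occupancy(t, np_topology)
        m = occ.matrix.to_numpy(float)
        assert np.nansum(m) == 0.0

    def test_opposite_signs_only(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.5, n_frames=10)
        occ = saltbridge_occupancy(t, np_topology)
        assert np.isnan(occ.matrix.loc["K357", "K351"])  # like charges unscored

    def test_multi_pair_mean_matches_plan(self, np_topology):
        plan = {(357, 358): 0.2, (386, 388): 0.6, (379, 391): 0.4}
        t = plant_contacts(np_topology, plan, n_frames=500)
        occ = saltbridge_occupancy(t, np_topology)
        vals = occ.matrix.to_numpy(float)
        planted = [occ.pair("K357", "E358"), occ.pair("K386", "E388"),
                   occ.pair("R379", "D391")]
        assert planted == pytest.approx([0.2, 0.6, 0.4])
        total = np.nansum(np.triu(vals, 1))
        assert total == pytest.approx(sum(plan.values()))


class TestHbondOccupancy:
    def test_always_bonded_pair(self, np_topology, groups):
        t = plant_contact_ensemble(np_topology, (357, 358), 1.0, 0.30, n_frames=50)
        occ = hbond_occupancy(t, [groups[357]], [groups[358]], cutoff=0.30)
        assert occ.pair("K357", "E358") == 1.0

    def test_monotone_in_cutoff(self, np_topology, groups):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.5, n_frames=200)
        occ_small = hbond_occupancy(t, [groups[357]], [groups[358]], cutoff=0.10)
        occ_large = hbond_occupancy(t, [groups[357]], [groups[358]], cutoff=0.50)
        assert occ_small.pair("K357", "E358") <= occ_large.pair("K357", "E358")

    def test_same_criterion_as_saltbridge_on_same_groups(self, np_topology, groups):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.3, n_frames=100)
        sb = saltbridge_occupancy(t, np_topology, cutoff=0.35)
        hb = hbond_occupancy(t, [groups[357]], [groups[358]], cutoff=0.35)
        assert hb.pair("K357", "E358") == sb.pair("K357", "E358")


class TestDifferencesAndMask:
    def test_identical_difference_zero(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.3, n_frames=100)
        occ = saltbridge_occupancy(t, np_topology)
        d = occupancy_difference(occ, occ)
        assert np.nansum(np.abs(d.to_numpy(float))) == 0.0

    def test_planted_delta_recovered_and_antisymmetric(self, np_topology):
        a = saltbridge_occupancy(
            plant_contact_ensemble(np_topology, (357, 358), 0.42, n_frames=100),
            np_topology,
        )
        b = saltbridge_occupancy(
            plant_contact_ensemble(np_topology, (357, 358), 0.30, n_frames=100),
            np_topology,
        )
        d = occupancy_difference(a, b)
        assert d.loc["K357", "E358"] == pytest.approx(0.12)
        d_rev = occupancy_difference(b, a)
        assert np.allclose(
            d.to_numpy(float), -d_rev.to_numpy(float), equal_nan=True
        )

    def test_mask_count_equals_occupancy_times_frames(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.25, n_frames=1000)
        mask = contact_mask(t, np_topology, (357, 358))
        occ = saltbridge_occupancy(t, np_topology)
        assert mask.sum() == occ.pair("K357", "E358") * 1000

    def test_all_far_mask_false(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.0, n_frames=50)
        assert not contact_mask(t, np_topology, (357, 358)).any()

    def test_atom_permutation_invariance(self, np_topology):
        from regscape.trajectory_io import Trajectory

        t = plant_contact_ensemble(np_topology, (357, 358), 0.3, n_frames=60)
        rng = np.random.default_rng(0)
        perm = rng.permutation(t.n_atoms)
        shuffled = Trajectory(
            coords=t.coords[:, perm],
            atoms=t.atoms.iloc[perm].reset_index(drop=True),
            times=t.times,
        )
        a = saltbridge_occupancy(t, np_topology).matrix
        b = saltbridge_occupancy(shuffled, np_topology).matrix
        assert a.equals(b)

    def test_occupancies_within_unit_interval(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.7, n_frames=40)
        occ = saltbridge_occupancy(t, np_topology)
        vals = occ.matrix.to_numpy(float)
        vals = vals[~np.isnan(vals)]
        assert np.all((vals >= 0) & (vals <= 1))


def test_conditional_rg_shift_detected(np_topology):
    """Frames where a planted bond is formed have a different Rg: the
    contact-conditioned summary separates the two sub-ensembles."""
    from regscape.ensemble_stats import conditional_summary
    from regscape.geometry import radius_of_gyration

    t = plant_contact_ensemble(np_topology, (357, 393), 0.4, n_frames=200)
    rg = radius_of_gyration(t, mass_weighted=False)
    mask = contact_mask(t, np_topology, (357, 393))
    s_bound, s_free = conditional_summary(rg.values, mask)
    assert s_bound.mean != pytest.approx(s_free.mean, abs=1e-6)
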
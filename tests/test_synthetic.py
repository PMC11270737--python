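import numpy as np
import pytest

from regscape.chem_topology import parse_sequence
from regscape.contacts import contact_mask
from regscape.ramachandran import compute_dihedrals
from regscape.synthetic import (
    MarkovDihedralModel,
    build_peptide,
    dihedral_ensemble,
    freely_jointed_chain,
    markov_dihedral_walk,
    plant_contact_ensemble,
    plant_contacts,
)


class TestBuildPeptide:
    def test_helical_rise(self):
        t = build_peptide("A" * 10, (-57.0, -47.0))
        ca = t.select(name="CA")
        span = np.linalg.norm(ca.coords[0, -1] - ca.coords[0, 0])
        # alpha-helical rise ~0.15 nm per residue over 9 steps
        assert 9 * 0.14 < span < 9 * 0.18

    @pytest.mark.parametrize("phi,psi", [(-75.0, 145.0), (-57.0, -47.0), (60.0, 45.0)])
    def test_dihedral_round_trip(self, phi, psi):
        t = build_peptide("A" * 6, (phi, psi))
        got_phi, got_psi = compute_dihedrals(t)
        assert np.allclose(got_phi[0, 1:], phi, atol=1e-3)
        assert np.allclose(got_psi[0, :-1], psi, atol=1e-3)

    def test_fully_extended_is_maximal(self):
        spans = {}
        for phi, psi in [(180, 180), (-57, -47), (-75, 145), (-120, 130)]:
            t = build_peptide("A" * 10, (float(phi), float(psi)))
            ca = t.select(name="CA")
            spans[(phi, psi)] = np.linalg.norm(ca.coords[0, -1] - ca.coords[0, 0])
        assert max(spans, key=spans.get) == (180, 180)

    def test_bond_lengths_canonical(self):
        t = build_peptide("AGA", (-75.0, 145.0))
        X = t.coords[0]
        for r in (1, 2, 3):
            n = X[t.atom_index(r, "N")]
            ca = X[t.atom_index(r, "CA")]
            c = X[t.atom_index(r, "C")]
            assert abs(np.linalg.norm(ca - n) - 0.1458) < 1e-4
            assert abs(np.linalg.norm(c - ca) - 0.1525) < 1e-4
            if r < 3:
                n_next = X[t.atom_index(r + 1, "N")]
                assert abs(np.linalg.norm(n_next - c) - 0.1329) < 1e-4

    def test_glycine_has_no_cb(self):
        t = build_peptide("AGA", (-75.0, 145.0))
        names = t.atoms[t.atoms["resid"] == 2]["name"].tolist()
        assert "CB" not in names

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            build_peptide("AXZ", (180.0, 180.0))


class TestMarkovWalk:
    def test_symmetric_chain_equifrequency(self, two_state_model):
        _, states = markov_dihedral_walk(two_state_model, 100_000, 1, seed=3)
        assert abs(states.mean() - 0.5) < 0.01

    def test_slowest_mode_autocorrelation(self, two_state_model):
        # lambda_2 = 1 - p - q = 0.8 for the symmetric 0.9/0.1 chain
        assert two_state_model.slowest_eigenvalue() == pytest.approx(0.8)
        _, states = markov_dihedral_walk(two_state_model, 200_000, 1, seed=5)
        s = states - states.mean()
        rho1 = (s[:-1] @ s[1:]) / (s @ s)
        assert abs(rho1 - 0.8) < 0.01

    def test_identity_transition_is_constant(self):
        model = MarkovDihedralModel(
            centers=((-75.0, 145.0), (-63.0, -43.0)),
            transition=((1.0, 0.0), (0.0, 1.0)),
        )
        _, states = markov_dihedral_walk(model, 500, 2, seed=0)
        assert len(np.unique(states)) == 1

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            MarkovDihedralModel(
                centers=((0.0, 0.0), (1.0, 1.0)),
                transition=((0.5, 0.4), (0.1, 0.9)),
            )

    def test_emissions_center_on_basins(self, two_state_model):
        angles, states = markov_dihedral_walk(two_state_model, 20_000, 3, seed=9)
        centers = np.asarray(two_state_model.centers)
        for s in (0, 1):
            mean = angles[states == s].reshape(-1, 2).mean(axis=0)
            assert np.allclose(mean, centers[s], atol=0.5)


class TestFreelyJointedChain:
    def test_closed_form_size_statistics(self):
        n, b = 100, 0.38
        t = freely_jointed_chain(n, b, n_frames=3000, seed=11)
        ends = t.coords[:, -1] - t.coords[:, 0]
        r2 = (ends**2).sum(axis=1)
        se = r2.std() / np.sqrt(len(r2))
        assert abs(r2.mean() - n * b * b) < 3 * se

        centered = t.coords - t.coords.mean(axis=1, keepdims=True)
        rg2 = (centered**2).sum(axis=2).mean(axis=1)
        se_rg = rg2.std() / np.sqrt(len(rg2))
        # Debye: <Rg^2> = (N b^2 / 6) * (1 + O(1/N))
        expected = n * b * b / 6.0 * (1 + 3.0 / n)
        assert abs(rg2.mean() - expected) < 3 * se_rg + 0.01 * expected

    def test_single_bond_exact_length(self):
        t = freely_jointed_chain(1, 0.38, n_frames=50, seed=2)
        d = np.linalg.norm(t.coords[:, 1] - t.coords[:, 0], axis=1)
        assert np.allclose(d, 0.38)

    def test_seed_determinism(self):
        a = freely_jointed_chain(10, n_frames=20, seed=42)
        b = freely_jointed_chain(10, n_frames=20, seed=42)
        assert np.array_equal(a.coords, b.coords)


class TestPlantedContacts:
    def test_exact_occupancy(self, np_topology):
        t = plant_contact_ensemble(np_topology, (357, 358), 0.25, n_frames=1000)
        mask = contact_mask(t, np_topology, (357, 358), 0.35)
        assert mask.sum() == 250

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_boundary_occupancies(self, np_topology, f):
        t = plant_contact_ensemble(np_topology, (363, 352), f, n_frames=200)
        mask = contact_mask(t, np_topology, (363, 352), 0.35)
        assert mask.mean() == f

    def test_multi_pair_plan(self, np_topology):
        plan = {(357, 358): 0.3, (386, 388): 0.5}
        t = plant_contacts(np_topology, plan, n_frames=500)
        for pair, f in plan.items():
            assert contact_mask(t, np_topology, pair, 0.35).mean() == pytest.approx(f)

    def test_unbonded_frames_beyond_twice_cutoff(self, np_topology):
        from regscape.chem_topology import charged_groups
        from regscape.contacts import group_distance_series

        t = plant_contact_ensemble(np_topology, (357, 358), 0.5, 0.35, n_frames=100)
        groups = {g.author_number: g for g in charged_groups(np_topology)}
        d = group_distance_series(t, groups[357], groups[358])
        assert np.all((d < 0.35) | (d > 0.70))


def test_dihedral_ensemble_seed_determinism(two_state_model):
    a, sa = dihedral_ensemble("KDAQA", two_state_model, 10, seed=5)
    b, sb = dihedral_ensemble("KDAQA", two_state_model, 10, seed=5)
    assert np.array_equal(a.coords, b.coords)
    assert np.array_equal(sa, sb)


def test_pin_first_keeps_origin(two_state_model):
    t, _ = dihedral_ensemble("KDAQA", two_state_model, 8, seed=5, pin_first=True)
    first_n = t.coords[:, 0]
    assert np.allclose(first_n, first_n[0])
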
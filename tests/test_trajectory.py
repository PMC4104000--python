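"""traj_analysis: RMSD/RMSF/Rgyr, H-bonds, catalytic series, energies."""

import numpy as np
import pytest

from colefuse.errors import EmptyInputError, InputError, MappingError, ParameterError
from colefuse.structure import Atom, Chain, Residue, Selection, Structure, select
from colefuse.trajectory import (
    CatalyticMapping,
    Ensemble,
    HBondCriterion,
    NonbondedParams,
    block_average,
    catalytic_observables,
    detect_hbonds,
    hbond_count_series,
    interaction_energy,
    radius_of_gyration,
    rmsd_series,
    rmsf_profile,
)

from _oracles import brute_hbonds_heavy, brute_interaction_energy
from conftest import random_rotation


def _static_ensemble(structure, n_frames):
    base = structure.coords_array()
    return Ensemble(structure, np.repeat(base[None], n_frames, axis=0))


class TestRmsd:
    def test_identical_frames_are_zero(self, hnh_complex):
        ens = _static_ensemble(hnh_complex, 5)
        np.testing.assert_allclose(rmsd_series(ens), 0.0, atol=1e-12)

    def test_fit_removes_rigid_motion(self, hnh_complex):
        base = hnh_complex.coords_array()
        rng = np.random.default_rng(0)
        frames = [base]
        for seed in range(4):
            r = random_rotation(np.random.default_rng(seed))
            frames.append(base @ r.T + rng.normal(size=3))
        ens = Ensemble(hnh_complex, np.stack(frames))
        np.testing.assert_allclose(rmsd_series(ens, fit=True), 0.0, atol=1e-9)

    def test_unfitted_two_frame_closed_form(self, hnh_complex):
        base = hnh_complex.coords_array()
        moved = base.copy()
        d = 0.3
        moved[7, 0] += d
        ens = Ensemble(hnh_complex, np.stack([base, moved]))
        series = rmsd_series(ens, fit=False)
        assert series[0] == 0.0
        assert series[1] == pytest.approx(d / np.sqrt(base.shape[0]), rel=1e-12)

    def test_empty_selection_raises(self, hnh_complex):
        ens = _static_ensemble(hnh_complex, 2)
        with pytest.raises(EmptyInputError):
            rmsd_series(ens, sel=Selection(chain_ids=("?",)))


class TestRmsf:
    def test_static_ensemble_is_zero_everywhere(self, hnh_complex):
        ens = _static_ensemble(hnh_complex, 4)
        assert all(v == pytest.approx(0.0, abs=1e-12) for _, v in rmsf_profile(ens))

    def test_two_point_alternation_gives_amplitude(self, hnh_complex):
        base = hnh_complex.coords_array()
        up, down = base.copy(), base.copy()
        d = 0.12
        up[0, 0] += d
        down[0, 0] -= d
        ens = Ensemble(hnh_complex, np.stack([up, down, up, down]))
        profile = dict(rmsf_profile(ens, fit=False))
        refs = list(hnh_complex.iter_atoms())
        chain, res, _ = refs[0]
        moving_res = (chain.chain_id, res.seq_id)
        n_in_res = len(res.atoms)
        # the residue mean averages one fluctuating atom with its static mates
        assert profile[moving_res] == pytest.approx(d / n_in_res, rel=1e-9)

    def test_single_frame_warns_and_returns_zero(self, hnh_complex):
        ens = _static_ensemble(hnh_complex, 1)
        with pytest.warns(UserWarning, match="single-frame"):
            profile = rmsf_profile(ens)
        assert all(v == 0.0 for _, v in profile)

    def test_renumbering_shifts_labels_only(self, hnh_complex):
        ens = _static_ensemble(hnh_complex, 3)
        sel = Selection(chain_ids=("P",))
        plain = rmsf_profile(ens, sel=sel)
        shifted = rmsf_profile(ens, sel=sel, renumber_from=1)
        assert [k[1] for k, _ in shifted] == list(range(1, len(plain) + 1))
        assert [v for _, v in shifted] == [v for _, v in plain]


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        s = Structure("one", [Chain("A", [Residue(1, "ALA", [Atom("CA", "C", np.zeros(3))])])])
        assert radius_of_gyration(s) == 0.0

    def test_two_unit_masses_at_known_separation(self):
        atoms = [
            Atom("C1", "C", np.array([0.0, 0.0, 0.0])),
            Atom("C2", "C", np.array([0.2, 0.0, 0.0])),
        ]
        s = Structure("two", [Chain("A", [Residue(1, "UNK", atoms)])])
        assert radius_of_gyration(s, mass_weighted=False) == pytest.approx(0.1, abs=1e-12)

    def test_invariant_under_rigid_rotation(self, hnh_complex):
        before = radius_of_gyration(hnh_complex)
        rotated = hnh_complex.copy()
        rotated.transform(random_rotation(np.random.default_rng(5)), np.array([1.0, 2.0, 3.0]))
        assert radius_of_gyration(rotated) == pytest.approx(before, abs=1e-12)


def _hbond_toy(ha=0.20, angle_deg=180.0):
    """Donor N-H ... acceptor O with controllable H-A distance and angle."""
    nh = 0.10
    theta = np.radians(180.0 - angle_deg)
    h = np.array([nh, 0.0, 0.0])
    a = h + ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    donor_res = Residue(1, "ASN", [Atom("ND2", "N", np.zeros(3)), Atom("HD21", "H", h)])
    acceptor_res = Residue(2, "HOH", [Atom("O", "O", a)])
    s = Structure("hb", [Chain("D", [donor_res]), Chain("A", [acceptor_res])])
    donors = select(s, Selection(atom_names=("ND2",)))
    acceptors = select(s, Selection(atom_names=("O",)))
    return s, donors, acceptors


class TestHbonds:
    def test_collinear_short_contact_detected(self):
        s, donors, acceptors = _hbond_toy(ha=0.20, angle_deg=180.0)
        bonds = detect_hbonds(s, s.coords_array(), donors, acceptors)
        assert len(bonds) == 1

    def test_right_angle_rejected_with_explicit_hydrogen(self):
        s, donors, acceptors = _hbond_toy(ha=0.20, angle_deg=90.0)
        assert detect_hbonds(s, s.coords_array(), donors, acceptors) == []

    def test_heavy_atom_fallback_without_hydrogens(self):
        s, donors, acceptors = _hbond_toy(ha=0.20, angle_deg=90.0)
        donors[0].residue.atoms = [a for a in donors[0].residue.atoms if a.element != "H"]
        # re-resolve both groups: atom removal shifted the flat indices
        donors = select(s, Selection(atom_names=("ND2",)))
        acceptors = select(s, Selection(atom_names=("O",)))
        bonds = detect_hbonds(s, s.coords_array(), donors, acceptors)
        # D-A distance decides alone once no H is present
        da = np.linalg.norm(donors[0].atom.coords - acceptors[0].atom.coords)
        assert (len(bonds) == 1) == (da <= 0.35)

    def test_count_non_decreasing_in_da_max(self, two_site_complex):
        s = two_site_complex
        donors = select(s, Selection(atom_names=("NE2",)))
        acceptors = select(s, Selection(atom_names=("O", "OP1", "P")))
        counts = []
        for da in (0.25, 0.35, 0.6, 1.0, 2.0):
            crit = HBondCriterion(da_max=da, ha_max=min(0.24, da / 2))
            counts.append(len(detect_hbonds(s, s.coords_array(), donors, acceptors, crit)))
        assert counts == sorted(counts)

    def test_matches_brute_force_heavy_atom_scan(self, two_site_complex):
        s = two_site_complex
        coords = s.coords_array()
        donors = select(s, Selection(atom_names=("NE2", "N")))
        acceptors = select(s, Selection(atom_names=("O", "P")))
        crit = HBondCriterion(da_max=0.8, ha_max=0.3)
        got = {
            (d.index, a.index)
            for d, a in detect_hbonds(s, coords, donors, acceptors, crit)
        }
        same_res = lambda i, j: _residue_of(s, i) is _residue_of(s, j)
        expected = set(
            brute_hbonds_heavy(
                coords,
                [d.index for d in donors],
                [a.index for a in acceptors],
                same_res,
                0.8,
            )
        )
        assert got == expected

    def test_series_equals_framewise_detection(self, hnh_complex):
        base = hnh_complex.coords_array()
        rng = np.random.default_rng(2)
        frames = np.stack([base + rng.normal(0, 0.02, base.shape) for _ in range(6)])
        ens = Ensemble(hnh_complex, frames)
        donors_sel = Selection(atom_names=("NE2",))
        acceptors_sel = Selection(atom_names=("P",))
        crit = HBondCriterion(da_max=0.9, ha_max=0.4)
        series = hbond_count_series(ens, donors_sel, acceptors_sel, crit)
        donors = select(hnh_complex, donors_sel)
        acceptors = select(hnh_complex, acceptors_sel)
        for f in range(6):
            frame_bonds = detect_hbonds(hnh_complex, frames[f], donors, acceptors, crit)
            assert series[f] == len(frame_bonds)

    def test_groups_without_polar_atoms_count_zero(self, hnh_complex):
        ens = _static_ensemble(hnh_complex, 3)
        series = hbond_count_series(
            ens, Selection(atom_names=("CA",)), Selection(atom_names=("CA",))
        )
        assert np.all(series == 0)

    def test_criterion_validation(self):
        with pytest.raises(InputError):
            HBondCriterion(da_max=0.2, ha_max=0.25)


def _residue_of(s, index):
    for i, (_, res, _) in enumerate(s.iter_atoms()):
        if i == index:
            return res
    raise IndexError(index)


def _catalytic_toy():
    """Minimal model carrying every catalytic role at known coordinates."""
    arg = Residue(10, "ARG", [Atom("CA", "C", np.array([1.0, 0.0, 0.0])),
                              Atom("NE", "N", np.array([0.5, 0.0, 0.0]))])
    his = Residue(45, "HIS", [Atom("CA", "C", np.array([0.0, 0.45, 0.0])),
                              Atom("NE2", "N", np.array([0.0, 0.30, 0.0]))])
    val = Residue(55, "VAL", [Atom("CA", "C", np.array([0.0, 0.0, 0.45])),
                              Atom("O", "O", np.array([0.0, 0.28, 0.28]))])
    asn = Residue(60, "ASN", [Atom("CG", "C", np.array([0.0, 0.0, 0.0]))])
    protein = Chain("P", [arg, his, val, asn])
    zn = Chain("Z", [Residue(1, "ZN", [Atom("ZN", "ZN", np.array([0.0, 0.0, 0.0]))])])
    dna = Chain("D", [Residue(5, "DG", [Atom("P", "P", np.array([0.35, 0.0, 0.0])),
                                        Atom("OP1", "O", np.array([0.2, 0.0, 0.0]))])])
    return Structure("cat", [protein, zn, dna])


class TestCatalyticObservables:
    MAPPING = CatalyticMapping(
        arg447=("P", 10), his545=("P", 45), val555=("P", 55), asn560=("P", 60),
        zinc=("Z", 1), scissile_p=("D", 5),
    )

    def test_known_geometry_distances(self):
        s = _catalytic_toy()
        ens = _static_ensemble(s, 3)
        obs = catalytic_observables(ens, self.MAPPING)
        np.testing.assert_allclose(obs["d_Zn_O"], 0.2, atol=1e-12)
        np.testing.assert_allclose(obs["d_ArgNE_P"], 0.15, atol=1e-12)
        np.testing.assert_allclose(obs["d_N560CG_H545CA"], np.sqrt(0.45**2), atol=1e-12)
        # His NE2 at (0,0.30,0), Val O at (0,0.28,0.28): D-A 0.281 nm < 0.35
        np.testing.assert_array_equal(obs["hb_H545_V555"], 1)

    def test_all_series_share_the_frame_count(self):
        ens = _static_ensemble(_catalytic_toy(), 7)
        obs = catalytic_observables(ens, self.MAPPING)
        assert {len(v) for v in obs.values()} == {7}

    def test_missing_arginine_is_a_mapping_error(self):
        s = _catalytic_toy()
        s.chain("P").residues[0].atoms = [
            a for a in s.chain("P").residues[0].atoms if a.name != "NE"
        ]
        ens = _static_ensemble(s, 2)
        with pytest.raises(MappingError, match="R447"):
            catalytic_observables(ens, self.MAPPING)


def _charged_pair(q1, q2, r, c6=0.0, c12=0.0):
    a = Residue(1, "UNK", [Atom("Q1", "C", np.zeros(3))])
    b = Residue(1, "UNK", [Atom("Q2", "C", np.array([r, 0.0, 0.0]))])
    s = Structure("pair", [Chain("A", [a]), Chain("B", [b])])
    params = NonbondedParams(by_name={"Q1": (q1, c6, c12), "Q2": (q2, c6, c12)})
    return s, params


class TestInteractionEnergy:
    def test_unit_charges_at_one_nm(self):
        s, params = _charged_pair(+1.0, -1.0, 1.0)
        vdw, elec, total = interaction_energy(
            s, s.coords_array(), Selection(chain_ids=("A",)), Selection(chain_ids=("B",)), params
        )
        assert vdw == 0.0
        assert elec == pytest.approx(-138.935, abs=1e-9)
        assert total == elec

    def test_symmetric_in_group_order(self, two_site_complex):
        s = two_site_complex
        params = _uniform_params(s)
        a, b = Selection(chain_ids=("A", "B")), Selection(chain_ids=("P",))
        e1 = interaction_energy(s, s.coords_array(), a, b, params)
        e2 = interaction_energy(s, s.coords_array(), b, a, params)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_charge_doubling_quadruples_electrostatics_only(self):
        s, params = _charged_pair(+1.0, -1.0, 0.8, c6=1e-4, c12=1e-7)
        sel_a, sel_b = Selection(chain_ids=("A",)), Selection(chain_ids=("B",))
        vdw1, elec1, _ = interaction_energy(s, s.coords_array(), sel_a, sel_b, params)
        doubled = NonbondedParams(
            by_name={k: (2 * q, c6, c12) for k, (q, c6, c12) in params.by_name.items()}
        )
        vdw2, elec2, _ = interaction_energy(s, s.coords_array(), sel_a, sel_b, doubled)
        assert elec2 == pytest.approx(4 * elec1, rel=1e-12)
        assert vdw2 == pytest.approx(vdw1, rel=1e-12)

    def test_matches_brute_force_double_loop(self, two_site_complex):
        s = two_site_complex
        params = _uniform_params(s)
        sel_a = Selection(chain_ids=("A", "B"))
        sel_b = Selection(chain_ids=("P", "L"))
        got = interaction_energy(s, s.coords_array(), sel_a, sel_b, params)
        idx_a = [r.index for r in select(s, sel_a)]
        idx_b = [r.index for r in select(s, sel_b)]
        lookup = {r.index: params.lookup(r) for r in select(s, Selection())}
        expected = brute_interaction_energy(
            s.coords_array(), idx_a, idx_b, lookup.__getitem__
        )
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=1e-9)

    def test_overlapping_groups_count_each_pair_once(self):
        s, params = _charged_pair(+1.0, -1.0, 1.0)
        everything = Selection()
        _, elec, _ = interaction_energy(
            s, s.coords_array(), everything, everything, params
        )
        assert elec == pytest.approx(-138.935, abs=1e-9)

    def test_missing_parameter_names_the_atom(self, hnh_complex):
        params = NonbondedParams(by_name={})
        with pytest.raises(ParameterError, match="P"):
            interaction_energy(
                hnh_complex,
                hnh_complex.coords_array(),
                Selection(chain_ids=("A",)),
                Selection(chain_ids=("P",)),
                params,
            )

    def test_relative_permittivity_scales_coulomb(self):
        s, params = _charged_pair(+1.0, -1.0, 1.0)
        params.relative_permittivity = 2.0
        _, elec, _ = interaction_energy(
            s, s.coords_array(), Selection(chain_ids=("A",)), Selection(chain_ids=("B",)), params
        )
        assert elec == pytest.approx(-138.935 / 2.0, abs=1e-9)


def _uniform_params(s):
    names = {atom.name for _, _, atom in s.iter_atoms()}
    return NonbondedParams(
        by_name={n: (0.1 if n[0] in "NP" else -0.05, 1e-4, 1e-7) for n in names}
    )


class TestBlockAverage:
    def test_constant_series(self):
        mean, err = block_average([3.5] * 20, n_blocks=4)
        assert mean == 3.5 and err == 0.0

    def test_alternating_series_mean_zero(self):
        mean, _ = block_average([1.0, -1.0] * 10, n_blocks=2)
        assert mean == pytest.approx(0.0, abs=1e-15)

    def test_error_tracks_sampling_statistics(self):
        # i.i.d. normal: SE over block means ~ sigma/sqrt(n_blocks * block)
        rng = np.random.default_rng(0)
        sigma, n_blocks, block = 1.0, 5, 40
        errors = []
        for _ in range(100):
            series = rng.normal(0.0, sigma, n_blocks * block)
            errors.append(block_average(series, n_blocks)[1])
        theory = sigma / np.sqrt(n_blocks * block)
        assert np.mean(errors) == pytest.approx(theory, rel=0.2)
        assert max(errors) < 3 * theory * np.sqrt(n_blocks)

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            block_average([1.0, 2.0], n_blocks=3)


class TestRigidInvariance:
    """Every observable must ignore a global rigid transform of all frames."""

    def _transformed(self, ens, seed=8):
        r = random_rotation(np.random.default_rng(seed))
        t = np.array([0.7, -1.1, 2.3])
        return Ensemble(ens.topology, ens.frames @ r.T + t, ens.time_step_ps)

    @pytest.fixture
    def noisy_ensemble(self, two_site_complex):
        base = two_site_complex.coords_array()
        rng = np.random.default_rng(3)
        frames = np.stack([base + rng.normal(0, 0.01, base.shape) for _ in range(5)])
        return Ensemble(two_site_complex, frames)

    def test_fitted_rmsd_invariant(self, noisy_ensemble):
        moved = self._transformed(noisy_ensemble)
        np.testing.assert_allclose(
            rmsd_series(noisy_ensemble, fit=True), rmsd_series(moved, fit=True), atol=1e-9
        )

    def test_hbond_counts_invariant(self, noisy_ensemble):
        crit = HBondCriterion(da_max=0.9, ha_max=0.4)
        donors = Selection(atom_names=("NE2",))
        acceptors = Selection(atom_names=("P",))
        np.testing.assert_array_equal(
            hbond_count_series(noisy_ensemble, donors, acceptors, crit),
            hbond_count_series(self._transformed(noisy_ensemble), donors, acceptors, crit),
        )

    def test_interaction_energy_invariant(self, noisy_ensemble):
        s = noisy_ensemble.topology
        params = _uniform_params(s)
        a, b = Selection(chain_ids=("A",)), Selection(chain_ids=("P",))
        moved = self._transformed(noisy_ensemble)
        for f in range(noisy_ensemble.n_frames):
            e1 = interaction_energy(s, noisy_ensemble.frames[f], a, b, params)
            e2 = interaction_energy(s, moved.frames[f], a, b, params)
            assert e1[2] == pytest.approx(e2[2], abs=1e-9)
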
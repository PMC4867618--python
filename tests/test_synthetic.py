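"""Generator determinism, geometric calibration and self-consistency."""

import numpy as np
import pytest

from hed.ensemble_geom import ca_window_distance
from hed.errors import ValidationError
from hed.synthetic import (SyntheticSpec, build_ideal_peptide,
                           perturb_ensemble, simulate_hetex, simulate_shifts,
                           simulate_score_table)


def screw_prediction(ca: np.ndarray, steps: int) -> float:
    """Independent helix-distance oracle from the chain's screw symmetry.

    Estimates the rigid transform mapping Cα(i) -> Cα(i+1) (Kabsch on the
    shifted point sets is avoided: use the mean consecutive transform from
    three consecutive points via circumcenter geometry).  For an exact
    screw (helix), |Cα(i+k) − Cα(i)|² = (k·rise)² + (2ρ·sin(k·Ω/2))².
    Parameters (rise, Ω, ρ) are recovered from the first three interatomic
    distances d1, d2, d3 by solving the closed-form system numerically.
    """
    from scipy.optimize import brentq

    d = [np.linalg.norm(ca[k] - ca[0]) for k in (1, 2, 3)]

    def dist(rise, omega, rho, k):
        return np.hypot(k * rise, 2 * rho * np.sin(k * omega / 2))

    def solve(omega):
        # given omega, rise and rho follow from d1 and d2
        a1, b1 = 1.0, (2 * np.sin(omega / 2)) ** 2
        a2, b2 = 4.0, (2 * np.sin(omega)) ** 2
        m = np.array([[a1, b1], [a2, b2]])
        rhs = np.array([d[0] ** 2, d[1] ** 2])
        rise2, rho2 = np.linalg.solve(m, rhs)
        return rise2, rho2

    def mismatch(omega):
        rise2, rho2 = solve(omega)
        if rise2 < 0 or rho2 < 0:
            return np.inf
        return dist(np.sqrt(rise2), omega, np.sqrt(rho2), 3) - d[2]

    grid = np.linspace(0.3, np.pi - 0.05, 400)
    vals = [mismatch(w) for w in grid]
    omega = None
    for i in range(len(grid) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) \
                and vals[i] * vals[i + 1] < 0:
            omega = brentq(mismatch, grid[i], grid[i + 1])
            break
    assert omega is not None, "no screw solution found"
    rise2, rho2 = solve(omega)
    return dist(np.sqrt(rise2), omega, np.sqrt(rho2), steps)


class TestBuildIdealPeptide:
    def test_same_seed_bitwise_identical(self):
        spec = SyntheticSpec(sequence="AGKLV" * 4, ss_string="C" * 20, seed=5)
        a = build_ideal_peptide(spec)
        b = build_ideal_peptide(spec)
        assert np.array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self):
        s1 = SyntheticSpec(sequence="A" * 20, ss_string="C" * 20, seed=1)
        s2 = SyntheticSpec(sequence="A" * 20, ss_string="C" * 20, seed=2)
        assert not np.allclose(build_ideal_peptide(s1).coords,
                               build_ideal_peptide(s2).coords)

    def test_helix_window_distance_matches_screw_oracle(self, helix_model):
        ca = np.array([helix_model.coords[i]
                       for i, s in enumerate(helix_model.sites)
                       if s.atom_name == "CA"])
        predicted = screw_prediction(ca, steps=8)
        measured = ca_window_distance(helix_model)["d_window"].mean()
        assert measured == pytest.approx(predicted, abs=0.05)

    def test_strand_window_distance_near_printed_reference(self, strand_model):
        d = ca_window_distance(strand_model)["d_window"].mean()
        assert d == pytest.approx(28.0, abs=2.0)

    def test_helix_strand_coil_ordering(self, helix_model, strand_model):
        spec = SyntheticSpec(sequence="A" * 20, ss_string="C" * 20, seed=3)
        coil = ca_window_distance(build_ideal_peptide(spec))["d_window"].mean()
        dh = ca_window_distance(helix_model)["d_window"].mean()
        de = ca_window_distance(strand_model)["d_window"].mean()
        assert dh < coil < de

    def test_unknown_ss_class_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(sequence="AAA", ss_string="HXH")

    def test_gly_has_no_cb(self):
        spec = SyntheticSpec(sequence="AGA", ss_string="HHH")
        m = build_ideal_peptide(spec)
        gly_atoms = {s.atom_name for s in m.sites if s.residue_name == "GLY"}
        assert "CB" not in gly_atoms and "CA" in gly_atoms


class TestPerturbEnsemble:
    def test_zero_noise_identical_models(self, helix_model):
        spec = SyntheticSpec(sequence="A" * 20, ss_string="H" * 20,
                             noise_core=0.0, noise_tail=0.0, n_models=4)
        ens = perturb_ensemble(helix_model, spec)
        assert np.allclose(ens.coords, ens.coords[0])

    def test_seeded_reproducibility(self, helix_model):
        spec = SyntheticSpec(sequence="A" * 20, ss_string="H" * 20,
                             core_range=(5, 15), n_models=3, seed=8)
        a = perturb_ensemble(helix_model, spec)
        b = perturb_ensemble(helix_model, spec)
        assert np.array_equal(a.coords, b.coords)
        spec2 = SyntheticSpec(sequence="A" * 20, ss_string="H" * 20,
                              core_range=(5, 15), n_models=3, seed=9)
        assert not np.allclose(a.coords,
                               perturb_ensemble(helix_model, spec2).coords)

    def test_core_noise_smaller_than_tail(self, helix_model):
        spec = SyntheticSpec(sequence="A" * 20, ss_string="H" * 20,
                             core_range=(6, 15), noise_core=0.1,
                             noise_tail=2.0, n_models=50, seed=2)
        ens = perturb_ensemble(helix_model, spec)
        dev = np.linalg.norm(ens.coords - helix_model.coords, axis=2)
        core_cols = [i for i, s in enumerate(ens.sites)
                     if 6 <= s.residue_number <= 15]
        tail_cols = [i for i, s in enumerate(ens.sites)
                     if not 6 <= s.residue_number <= 15]
        assert dev[:, tail_cols].mean() > 5 * dev[:, core_cols].mean()


class TestSimulators:
    def test_shift_table_reproducible_and_noisy(self):
        spec = SyntheticSpec(sequence="ALVKE", ss_string="HHHHH", seed=4)
        a = simulate_shifts(spec, noise_ppm=0.3)
        b = simulate_shifts(spec, noise_ppm=0.3)
        assert np.array_equal(a["shift"], b["shift"])
        clean = simulate_shifts(spec, noise_ppm=0.0)
        assert not np.allclose(a["shift"], clean["shift"])

    def test_hetex_round_trip_noise_free(self):
        from hed.exchange import fit_kex_table
        table = simulate_hetex([0.7], r1=2.0, i_eq=3.0)
        fit = fit_kex_table(table).iloc[0]
        assert fit["kex"] == pytest.approx(0.7, rel=1e-3)
        assert fit["i_eq"] == pytest.approx(3.0, rel=1e-3)

    def test_score_table_requires_twenty(self):
        with pytest.raises(ValidationError):
            simulate_score_table(10)

    def test_score_table_shapes_and_determinism(self):
        scores, ens = simulate_score_table(25, seed=6)
        scores2, ens2 = simulate_score_table(25, seed=6)
        assert list(scores["model_id"]) == list(scores2["model_id"])
        assert np.array_equal(ens.coords, ens2.coords)
        assert ens.n_models == 25 and len(scores) == 25
        assert (scores["chi2"] >= 0).all()
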
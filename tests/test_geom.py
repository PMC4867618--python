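"""Superposition, RMSF, window-distance and ASA geometry."""

import numpy as np
import pytest

from hed.ensemble_geom import (atom_asa, backbone_asa, ca_rmsf,
                               ca_window_distance, kabsch, parse_selection,
                               superpose)
from hed.errors import SelectionError
from hed.io import Model, StructureEnsemble
from hed.synthetic import SyntheticSpec, build_ideal_peptide, perturb_ensemble

from helpers import quaternion_rmsd, random_rotation


class TestSuperpose:
    def test_identity_fit(self, helix_model):
        sup = superpose(helix_model, helix_model)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_translation_recovered(self, helix_model):
        moved = Model(helix_model.sites, helix_model.coords + [5.0, 0.0, 0.0])
        sup = superpose(moved, helix_model)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(sup.translation, [-5.0, 0.0, 0.0], atol=1e-8)

    def test_matches_quaternion_oracle_on_toy_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.normal(size=(4, 3))
            b = rng.normal(size=(4, 3))
            assert kabsch(a, b).rmsd == pytest.approx(quaternion_rmsd(a, b),
                                                      abs=1e-9)

    def test_beats_random_rotation_search(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        best = kabsch(a, b).rmsd
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        for _ in range(1000):
            r = random_rotation(rng)
            trial = np.sqrt(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1)))
            assert best <= trial + 1e-9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(SelectionError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(SelectionError, match="degenerate"):
            kabsch(line, line)

    def test_selection_parsing(self):
        keys = parse_selection("A:27-30,B:5,A:-3-0")
        assert ("A", 27) in keys and ("B", 5) in keys
        assert ("A", -3) in keys and ("A", 0) in keys
        assert len(keys) == 9


@pytest.fixture(scope="module")
def core_tail_ensemble():
    spec = SyntheticSpec(sequence="A" * 30, ss_string="H" * 30,
                         core_range=(6, 25), noise_core=0.2, noise_tail=3.0,
                         n_models=12, seed=9)
    return perturb_ensemble(build_ideal_peptide(spec), spec), spec


class TestCaRmsf:
    def test_identical_models_zero(self, helix_model):
        ens = StructureEnsemble(helix_model.sites,
                                np.repeat(helix_model.coords[None], 4, axis=0))
        assert np.allclose(ca_rmsf(ens)["rmsf"], 0.0, atol=1e-10)

    def test_tail_exceeds_core(self, core_tail_ensemble):
        ens, spec = core_tail_ensemble
        lo, hi = spec.core_range
        prof = ca_rmsf(ens, {("A", r) for r in range(lo, hi + 1)})
        core = prof[(prof["residue"] >= lo) & (prof["residue"] <= hi)]["rmsf"]
        tail = prof[(prof["residue"] < lo) | (prof["residue"] > hi)]["rmsf"]
        assert tail.mean() / core.mean() > 5

    def test_invariant_to_global_rigid_motion(self, core_tail_ensemble):
        ens, spec = core_tail_ensemble
        rng = np.random.default_rng(4)
        rot = random_rotation(rng)
        moved = StructureEnsemble(
            ens.sites, ens.coords @ rot.T + np.array([3.0, -7.0, 1.0]),
            list(ens.model_ids))
        a = ca_rmsf(ens)["rmsf"].to_numpy()
        b = ca_rmsf(moved)["rmsf"].to_numpy()
        assert np.allclose(a, b, atol=1e-8)

    def test_single_model_warns_and_zeroes(self, helix_model, caplog):
        ens = StructureEnsemble(helix_model.sites, helix_model.coords[None])
        with caplog.at_level("WARNING"):
            prof = ca_rmsf(ens)
        assert np.allclose(prof["rmsf"], 0.0)
        assert "single" in caplog.text


class TestWindowDistance:
    def test_collinear_trace_exact(self):
        n = 12
        sites = []
        coords = []
        from hed.io import AtomSite
        for i in range(n):
            sites.append(AtomSite("A", i + 1, "ALA", "CA"))
            coords.append([3.8 * i, 0.0, 0.0])
        model = Model(sites, np.array(coords))
        prof = ca_window_distance(model)
        assert np.allclose(prof["d_window"], 8 * 3.8)
        assert len(prof) == n - 8

    def test_helix_below_strand(self, helix_model, strand_model):
        dh = ca_window_distance(helix_model)["d_window"].mean()
        de = ca_window_distance(strand_model)["d_window"].mean()
        assert dh < 15 < de

    def test_rigid_motion_and_mirror_invariance(self, helix_model):
        rng = np.random.default_rng(8)
        rot = random_rotation(rng)
        base = ca_window_distance(helix_model)["d_window"].to_numpy()
        moved = Model(helix_model.sites,
                      helix_model.coords @ rot.T + [1.0, 2.0, 3.0])
        mirrored = Model(helix_model.sites, helix_model.coords * [-1, 1, 1])
        assert np.allclose(ca_window_distance(moved)["d_window"], base)
        assert np.allclose(ca_window_distance(mirrored)["d_window"], base)

    def test_short_chain_empty(self):
        spec = SyntheticSpec(sequence="AAAA", ss_string="HHHH")
        prof = ca_window_distance(build_ideal_peptide(spec))
        assert prof.empty

    def test_ensemble_averages_models(self, core_tail_ensemble):
        ens, _ = core_tail_ensemble
        prof = ca_window_distance(ens)
        per_model = np.mean(
            [ca_window_distance(ens.model(i))["d_window"].to_numpy()
             for i in range(ens.n_models)], axis=0)
        assert np.allclose(prof["d_window"], per_model)


class TestBackboneAsa:
    def test_isolated_residue_fully_exposed(self):
        spec = SyntheticSpec(sequence="A", ss_string="C", seed=1)
        df = backbone_asa(build_ideal_peptide(spec))
        assert df["relative"].iloc[0] >= 0.95

    def test_buried_atom_zero(self):
        # central atom caged by 26 blockers on a 3 Å lattice
        centers = [[0.0, 0.0, 0.0]]
        for dx in (-3, 0, 3):
            for dy in (-3, 0, 3):
                for dz in (-3, 0, 3):
                    if (dx, dy, dz) != (0, 0, 0):
                        centers.append([dx, dy, dz])
        radii = np.full(len(centers), 1.7)
        asa = atom_asa(np.array(centers), radii, probe_radius=1.4)
        assert asa[0] == 0.0

    def test_two_atom_analytic_cap(self):
        r1, r2, probe, d = 1.7, 1.52, 1.4, 2.0
        e1, e2 = r1 + probe, r2 + probe
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        asa = atom_asa(coords, np.array([r1, r2]), probe, n_points=4000)
        x = (d * d + e1 * e1 - e2 * e2) / (2 * d)
        buried = 2 * np.pi * e1 * (e1 - x)
        expected = 4 * np.pi * e1 ** 2 - buried
        assert asa[0] == pytest.approx(expected, rel=0.02)

    def test_point_count_convergence(self, helix_model):
        coarse = backbone_asa(helix_model, n_points=960)["backbone_asa"]
        fine = backbone_asa(helix_model, n_points=4000)["backbone_asa"]
        rel = np.abs(coarse.sum() - fine.sum()) / fine.sum()
        assert rel < 0.02

    def test_tails_more_exposed_than_core(self, core_tail_ensemble):
        ens, spec = core_tail_ensemble
        df = backbone_asa(ens.model(0), n_points=480)
        lo, hi = spec.core_range
        core = df[(df["residue"] >= lo) & (df["residue"] <= hi)]["relative"]
        tail = df[(df["residue"] < lo) | (df["residue"] > hi)]["relative"]
        assert tail.mean() > core.mean()
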
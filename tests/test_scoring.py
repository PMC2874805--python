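"""Pair, single-residue, depth and total log-odds scores."""

import json
import math

import numpy as np
import pytest

from bbscore import fixtures as fx
from bbscore.density import Density1D, GMMDensity, fit_kde_1d
from bbscore.geometry import relative_coordinates, residue_frame
from bbscore.scoring import (
    DepthModel,
    ScoringModel,
    SingleResidueModel,
    canonical_omega,
    depth_score,
    extract_pair_geometry,
    extract_pairs,
    fit_scoring_model,
    map_classify,
    model_from_dict,
    model_to_dict,
    pair_score,
    pair_score_tables,
    single_residue_score,
    total_score,
    train,
    train_depth,
    train_single_residue,
)
from bbscore.structure import AMINO_ACIDS, BackboneResidue, ProteinStructure

from conftest import random_frame


def _uniform_gmm(dim, scale=6.0):
    return GMMDensity(
        dim=dim,
        weights=[1.0],
        means=[np.zeros(dim)],
        covariances=[np.eye(dim) * scale**2],
    )


class TestExtractPairs:
    def test_six_residue_chain_is_empty(self):
        s = fx.make_ideal_helix(6)
        assert extract_pairs(s) == []

    def test_matches_brute_force_double_loop(self):
        s = fx.make_toy_protein(16, "hairpin", 0)
        frames = [residue_frame(r) for r in s.residues]
        expected = 0
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                if j - i >= 6 and np.linalg.norm(
                    s.residues[j].CB - s.residues[i].CB
                ) <= 10.0:
                    expected += 1
        obs = extract_pairs(s)
        assert len(obs) == expected
        assert expected >= 4

    def test_postconditions(self):
        s = fx.make_toy_protein(60, "globule", 1)
        for o in extract_pairs(s):
            assert o.omega.r <= 10.0
            assert o.j - o.i >= 6
            assert o.t1 <= o.t2  # canonical order


class TestPairScore:
    def test_native_equals_background_gives_zero(self, rng):
        m = ScoringModel(
            dim=3,
            native_densities={("A", "C"): _uniform_gmm(3)},
            background_density=_uniform_gmm(3),
        )
        for _ in range(20):
            f1, f2 = random_frame(rng), random_frame(rng)
            omega = relative_coordinates(f1, f2)
            if omega.r > 10:
                continue
            assert pair_score(m, "A", "C", omega) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_gaussian_difference(self, rng):
        mu = np.array([5.0, 1.5, 0.0])
        native = GMMDensity(dim=3, weights=[1.0], means=[mu], covariances=[np.eye(3)])
        background = _uniform_gmm(3)
        m = ScoringModel(
            dim=3, native_densities={("A", "A"): native}, background_density=background
        )
        omega = None
        while omega is None or omega.r > 10.0:
            f1, f2 = random_frame(rng, scale=2.0), random_frame(rng, scale=2.0)
            omega = relative_coordinates(f1, f2)
        x = omega.as_vector(3)
        expected = (
            -0.5 * float((x - mu) @ (x - mu))
            - 1.5 * math.log(2 * math.pi)
        ) - (
            -0.5 * float(x @ x) / 36.0
            - 1.5 * math.log(2 * math.pi)
            - 3.0 * math.log(6.0)
        )
        assert pair_score(m, "A", "A", omega) == pytest.approx(expected, abs=1e-10)

    def test_symmetry_under_canonicalization(self, rng):
        native = GMMDensity(
            dim=6,
            weights=[1.0],
            means=[np.array([6.0, 1.5, 0.5, -0.5, 1.0, 0.3])],
            covariances=[np.diag([2.0, 0.5, 0.8, 0.9, 0.4, 0.7])],
        )
        m = ScoringModel(
            dim=6, native_densities={("A", "C"): native}, background_density=_uniform_gmm(6)
        )
        for _ in range(100):
            f1, f2 = random_frame(rng), random_frame(rng)
            try:
                o12 = relative_coordinates(f1, f2)
                o21 = relative_coordinates(f2, f1)
            except Exception:
                continue
            if o12.r > 10:
                continue
            assert pair_score(m, "A", "C", o12) == pytest.approx(
                pair_score(m, "C", "A", o21), abs=1e-12
            )

    def test_absent_pair_scores_zero(self, rng):
        m = ScoringModel(
            dim=3, native_densities={}, background_density=_uniform_gmm(3)
        )
        f1, f2 = random_frame(rng), random_frame(rng)
        omega = relative_coordinates(f1, f2)
        if omega.r <= 10:
            assert pair_score(m, "W", "Y", omega) == 0.0

    def test_out_of_range_pair_rejected(self, rng):
        m = ScoringModel(dim=3, native_densities={}, background_density=_uniform_gmm(3))
        f1 = random_frame(rng)
        f2 = random_frame(rng)
        f2 = type(f2)(origin=f1.origin + np.array([20.0, 0, 0]), u_x=f2.u_x, u_y=f2.u_y, u_z=f2.u_z)
        with pytest.raises(ValueError):
            pair_score(m, "A", "A", relative_coordinates(f1, f2))


class TestTrain:
    def test_null_spec_scores_near_zero(self):
        spec = fx.null_planted_spec()
        structures, _ = fx.sample_training_set(spec, n_structures=8, n_residues=50, seed=4)
        model = train(structures, dim=1, seed=0)
        scores = []
        for s in structures[:4]:
            for o in extract_pairs(s):
                scores.append(pair_score(model, o.t1, o.t2, o.omega))
        assert abs(np.mean(scores)) < 0.1

    def test_planted_cys_cys_distance_peak(self):
        obs = fx.sample_planted_distance_observations(n_per_pair=10000, seed=3)
        model = fit_scoring_model(obs, dim=1, seed=3)
        grid = np.linspace(2.0, 10.0, 801)
        cc = model.native_densities[("C", "C")]
        score = np.log(np.maximum(cc.pdf(grid), model.density_floor)) - np.log(
            np.maximum(model.background_density.pdf(grid), model.density_floor)
        )
        peak = grid[np.argmax(score)]
        assert 3.5 <= peak <= 4.0

    def test_sparse_pair_marked_absent(self):
        obs = fx.sample_planted_distance_observations(n_per_pair=200, seed=1)
        # Add a type pair with only 3 observations.
        rng = np.random.default_rng(0)
        extra = [
            type(obs[0])(
                t1="W", t2="W", omega=fx.random_relative_coordinates(rng, 7.0),
                protein_id="x", i=0, j=10,
            )
            for _ in range(3)
        ]
        model = fit_scoring_model(obs + extra, dim=1, seed=0)
        assert ("W", "W") not in model.native_densities
        assert pair_score(model, "W", "W", extra[0].omega) == 0.0


class TestPairScoreTables:
    def test_tables_agree_with_pair_score(self):
        spec = fx.default_planted_spec()
        structures, _ = fx.sample_training_set(spec, n_structures=6, n_residues=40, seed=9)
        model = train(structures, dim=3, seed=1, max_components=3)
        s = structures[0]
        geometry = extract_pair_geometry(s)
        tables = pair_score_tables(model, geometry)
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = int(rng.integers(len(geometry)))
            a, b = rng.choice(list("ACEKLW"), size=2)
            pg = geometry[p]
            t1, t2, omega = canonical_omega(pg, a, b)
            expected = pair_score(model, t1, t2, omega)
            got = tables[p, AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)]
            assert got == pytest.approx(expected, abs=1e-10)


class TestSingleResidueScore:
    def test_identical_counts_give_zero(self):
        counts = np.array([[10.0, 20.0, 30.0], [15.0, 10.0, 15.0]])
        m = SingleResidueModel.from_counts(counts, counts)
        assert np.allclose(m.log_odds, 0.0)

    def test_hand_arithmetic(self):
        native = np.array([[30.0, 20.0, 10.0], [10.0, 10.0, 20.0]])
        background = np.array([[15.0, 20.0, 10.0], [10.0, 10.0, 35.0]])
        m = SingleResidueModel.from_counts(native, background)
        assert single_residue_score(m, "A", "buried", "H") == pytest.approx(
            math.log(2.0), abs=1e-12
        )

    def test_gibbs_inequality_nonpositive_mean(self, rng):
        native = rng.uniform(1, 50, size=(2, 3))
        background = rng.uniform(1, 50, size=(2, 3))
        m = SingleResidueModel.from_counts(native, background)
        p_bg = background / background.sum()
        mean = float((p_bg * m.log_odds[0]) .sum())
        assert mean <= 1e-12

    def test_trained_table_is_finite(self):
        structures, _ = fx.sample_training_set(
            fx.default_planted_spec(), n_structures=3, n_residues=30, seed=2
        )
        m = train_single_residue(structures)
        assert np.all(np.isfinite(m.log_odds))


class TestDepthScore:
    def test_equal_densities_score_zero(self, rng):
        d = fit_kde_1d(rng.uniform(0, 20, size=500), bandwidth=2.0)
        m = DepthModel(per_aa_density={"L": d}, background_density=d)
        for z in rng.uniform(-20, 20, size=20):
            assert depth_score(m, "L", z) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_z(self, rng):
        m = train_depth(fx.sample_depth_data(1000, seed=0))
        for z in rng.uniform(0, 20, size=100):
            for aa in ("L", "K", "A"):
                assert depth_score(m, aa, z) == depth_score(m, aa, -z)

    def test_planted_leucine_center_preference(self, rng):
        # Leu |z| ~ folded N(0, 5); background uniform on [0, 20].
        leu = np.abs(rng.normal(0, 5, size=4000))
        leu = leu[leu <= 20]
        bg = rng.uniform(0, 20, size=4000)
        m = DepthModel(
            per_aa_density={"L": fit_kde_1d(leu, bandwidth=0.8)},
            background_density=fit_kde_1d(bg, bandwidth=0.8),
        )
        score0 = depth_score(m, "L", 0.0)
        # Closed form: log(2 N(0;0,5)) - log(1/20).
        expected = math.log(2.0 / (5.0 * math.sqrt(2 * math.pi))) - math.log(1.0 / 20.0)
        assert score0 == pytest.approx(expected, abs=0.1)
        assert score0 > depth_score(m, "L", 15.0)

    def test_unknown_aa_rejected(self, rng):
        m = train_depth(fx.sample_depth_data(200, seed=0))
        with pytest.raises(ValueError):
            depth_score(m, "X", 0.0)


class TestTotalScore:
    def test_no_qualifying_pairs_scores_zero(self):
        s = fx.make_ideal_helix(6)
        m = ScoringModel(dim=1, native_densities={}, background_density=_dummy_kde())
        assert total_score(s, s.sequence, m) == 0.0

    def test_additivity_of_disjoint_substructures(self):
        spec = fx.default_planted_spec()
        structures, _ = fx.sample_training_set(spec, n_structures=2, n_residues=30, seed=6)
        a, b = structures
        model = train(structures, dim=1, seed=0, min_count=20)
        shifted = [
            BackboneResidue(
                chain_id="A", residue_index=len(a) + r.residue_index, aa_type=r.aa_type,
                N=r.N + 300.0, CA=r.CA + 300.0, C=r.C + 300.0, CB=r.CB + 300.0,
            )
            for r in b.residues
        ]
        combined = ProteinStructure(residues=a.residues + shifted, id="combined")
        seq = a.sequence + b.sequence
        expected = total_score(a, a.sequence, model) + total_score(b, b.sequence, model)
        assert total_score(combined, seq, model) == pytest.approx(expected, abs=1e-9)

    def test_matches_hand_summed_pair_scores(self):
        s = fx.make_toy_protein(16, "hairpin", 0)
        obs = extract_pairs(s)
        model = ScoringModel(
            dim=3,
            native_densities={
                ("A", "A"): GMMDensity(
                    dim=3, weights=[1.0], means=[np.array([6.0, 1.5, 0.0])],
                    covariances=[np.eye(3) * 4.0],
                )
            },
            background_density=_uniform_gmm(3),
        )
        expected = sum(pair_score(model, o.t1, o.t2, o.omega) for o in obs)
        assert total_score(s, s.sequence, model) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        s = fx.make_ideal_helix(8)
        m = ScoringModel(dim=1, native_densities={}, background_density=_dummy_kde())
        with pytest.raises(ValueError):
            total_score(s, "AAA", m)


def _dummy_kde():
    return fit_kde_1d([5.0, 6.0, 7.0], bandwidth=1.0)


class TestMapClassify:
    @pytest.mark.parametrize(
        "total,r_prior,expected",
        [
            (0.001, 1.0, "native"),
            (-0.5, math.e, "native"),
            (0.0, 1.0, "non_native"),  # tie goes non-native
            (-1.0, math.e, "non_native"),
        ],
    )
    def test_threshold_rule(self, total, r_prior, expected):
        assert map_classify(total, r_prior) == expected

    def test_bad_prior(self):
        with pytest.raises(ValueError):
            map_classify(0.0, 0.0)


class TestSerialization:
    def test_round_trip_reproduces_scores_exactly(self):
        spec = fx.default_planted_spec()
        structures, _ = fx.sample_training_set(spec, n_structures=4, n_residues=30, seed=8)
        model = train(structures, dim=3, seed=2, max_components=3, min_count=20)
        payload = json.dumps(model_to_dict(model))
        model2 = model_from_dict(json.loads(payload))
        s = structures[0]
        assert total_score(s, s.sequence, model) == total_score(s, s.sequence, model2)
        payload2 = json.dumps(model_to_dict(model2))
        assert payload == payload2
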
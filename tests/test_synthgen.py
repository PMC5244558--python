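"""Generator contracts: basis geometry, dynamics structure, perturbations."""

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from wormstates import (
    Perturbation,
    SyntheticConfig,
    make_basis,
    simulate_strains,
)
from wormstates.errors import InvalidParameterError, InvalidPerturbationError
from wormstates.synthgen import (
    metropolis_transition,
    stationary_distribution,
    _default_bout_matrix,
)


class TestMakeBasis:
    def test_columns_orthonormal_and_centered(self):
        basis = make_basis(48, 4, seed=1)
        gram = basis.matrix.T @ basis.matrix
        assert np.abs(gram - np.eye(4)).max() < 1e-10
        assert np.abs(basis.matrix.sum(axis=0)).max() < 1e-10
        assert basis.matrix.shape == (48, 4)

    def test_deterministic_per_seed(self):
        a = make_basis(48, 4, seed=1)
        b = make_basis(48, 4, seed=1)
        assert np.array_equal(a.matrix, b.matrix)
        c = make_basis(48, 4, seed=2)
        assert not np.array_equal(a.matrix, c.matrix)

    def test_too_many_dims_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_basis(4, 5, seed=0)
        with pytest.raises(InvalidParameterError):
            make_basis(48, 0, seed=0)


class TestSimulateStrains:
    def test_shape_contract(self):
        config = SyntheticConfig(
            n_strains=1, worms_per_strain=20, frames_per_worm=4500,
            n_attractors=5, seed=3,
        )
        coll = simulate_strains(config)
        series = coll.strains["N2"]
        assert len(series) == 20
        assert all(s.frames.shape == (4500, 4) for s in series)
        assert all(s.fps == 5.0 for s in series)

    def test_bit_identical_per_seed(self):
        config = SyntheticConfig(
            n_strains=2, worms_per_strain=3, frames_per_worm=500, seed=5,
            gap_fraction=0.1,
        )
        a = simulate_strains(config)
        b = simulate_strains(config)
        for wa, wb in zip(a.worms(), b.worms()):
            assert np.array_equal(wa.frames, wb.frames, equal_nan=True)
            assert np.array_equal(wa.gap_mask, wb.gap_mask)

    def test_speed_distribution_bimodal_with_rest(self):
        """Rest bouts put a low mode in the speed distribution.

        Oracle: kernel-density mode count on pooled speeds of 20 worms.
        """
        config = SyntheticConfig(
            n_strains=1, worms_per_strain=20, frames_per_worm=1500,
            rest_entry_prob=0.3, rest_noise=0.02, active_noise=0.2,
            relaxation_rate=0.2, seed=21,
        )
        coll = simulate_strains(config)
        speeds = np.concatenate(
            [np.linalg.norm(np.diff(w.frames, axis=0), axis=1) for w in coll.worms()]
        )
        kde = gaussian_kde(speeds, bw_method=0.08)
        grid = np.linspace(0, np.quantile(speeds, 0.995), 400)
        dens = kde(grid)
        is_peak = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        peaks = grid[1:-1][is_peak & (dens[1:-1] > 0.05 * dens.max())]
        assert len(peaks) >= 2
        low, high = peaks.min(), peaks.max()
        assert low < 0.15  # rest mode near 2 * rest_noise
        assert high > 3 * low  # clearly separated active mode

    def test_no_rest_removes_low_mode(self):
        base = SyntheticConfig(
            n_strains=2, worms_per_strain=8, frames_per_worm=1000,
            rest_entry_prob=0.4, seed=9,
        )
        coll = simulate_strains(base, {"MT001": Perturbation(kind="no_rest")})

        def frac_slow(strain):
            speeds = np.concatenate(
                [np.linalg.norm(np.diff(w.frames, axis=0), axis=1)
                 for w in coll.strains[strain]]
            )
            return (speeds < 0.2).mean()

        assert frac_slow("N2") > 0.05
        assert frac_slow("MT001") < 0.01

    def test_gap_fraction_zero_means_no_gaps(self):
        coll = simulate_strains(
            SyntheticConfig(n_strains=1, worms_per_strain=3,
                            frames_per_worm=400, gap_fraction=0.0, seed=2)
        )
        assert all(not w.gap_mask.any() for w in coll.worms())

    def test_gaps_interior_only(self):
        coll = simulate_strains(
            SyntheticConfig(n_strains=1, worms_per_strain=5,
                            frames_per_worm=400, gap_fraction=0.2, seed=2)
        )
        for w in coll.worms():
            assert not w.gap_mask[0] and not w.gap_mask[-1]
            assert w.gap_mask.sum() == round(0.2 * (400 - 2))

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidParameterError):
            SyntheticConfig(rest_noise=0.5, active_noise=0.3).validate()
        with pytest.raises(InvalidParameterError):
            SyntheticConfig(gap_fraction=0.5).validate()
        with pytest.raises(InvalidParameterError):
            SyntheticConfig(relaxation_rate=0.0).validate()


class TestPerturbations:
    def test_retransition_preserves_stationary(self):
        config = SyntheticConfig(n_strains=2, worms_per_strain=2,
                                 frames_per_worm=100, seed=13)
        coll = simulate_strains(
            config, {"MT001": Perturbation(kind="retransition")}
        )
        meta = coll.metadata["strain_params"]
        pi_base = np.asarray(meta["N2"]["stationary"])
        pi_re = np.asarray(meta["MT001"]["stationary"])
        assert np.abs(pi_base - pi_re).max() < 1e-8

    def test_explicit_retransition_matrix_validated(self):
        bad = _default_bout_matrix(6, stay=0.8)
        bad[0] = [0.5, 0.5, 0, 0, 0, 0]  # different stationary law
        config = SyntheticConfig(n_strains=2, worms_per_strain=2,
                                 frames_per_worm=100, seed=1)
        with pytest.raises(InvalidPerturbationError):
            simulate_strains(
                config,
                {"MT001": Perturbation(kind="retransition", matrix=bad)},
            )

    def test_reweight_changes_stationary(self):
        config = SyntheticConfig(n_strains=2, worms_per_strain=2,
                                 frames_per_worm=100, seed=13)
        coll = simulate_strains(
            config, {"MT001": Perturbation(kind="reweight", strength=1.0)}
        )
        meta = coll.metadata["strain_params"]
        diff = np.abs(
            np.asarray(meta["N2"]["stationary"])
            - np.asarray(meta["MT001"]["stationary"])
        ).max()
        assert diff > 0.01

    def test_accelerate_preserves_posture_marginal_and_doubles_speed(self):
        config = SyntheticConfig(
            n_strains=2, worms_per_strain=10, frames_per_worm=2000,
            rest_entry_prob=0.0, seed=17,
        )
        coll = simulate_strains(
            config, {"MT001": Perturbation(kind="accelerate", gamma=2.0)}
        )

        def pooled(strain):
            return np.concatenate([w.frames for w in coll.strains[strain]])

        def speeds(strain):
            return np.concatenate(
                [np.linalg.norm(np.diff(w.frames, axis=0), axis=1)
                 for w in coll.strains[strain]]
            )

        # time compression leaves the marginal posture distribution alone
        sd_base = pooled("N2").std(axis=0)
        sd_fast = pooled("MT001").std(axis=0)
        assert np.abs(sd_fast / sd_base - 1).max() < 0.15
        # but speeds scale up clearly
        assert np.median(speeds("MT001")) > 1.2 * np.median(speeds("N2"))

    def test_retransition_occurrence_jsd_below_transition_jsd(self):
        """Matched stationary usage: after binning, a rewired strain differs
        from its base far more in transitions than in occupancy."""
        from wormstates import fit_kmeans, occurrence, responsibilities, sample_frames, transitions
        from wormstates import aggregate_strain, jsd

        wins = 0
        for seed in range(10):
            config = SyntheticConfig(
                n_strains=2, worms_per_strain=6, frames_per_worm=1000,
                n_attractors=5, rest_entry_prob=0.0, seed=300 + seed,
            )
            coll = simulate_strains(
                config, {"MT001": Perturbation(kind="retransition", strength=1.0)}
            )
            pts = sample_frames(coll, fraction=0.1, seed=seed)
            model = fit_kmeans(pts, 6, seed=seed)
            aggs = {}
            for strain, worms in coll.strains.items():
                occs, trans = [], []
                for w in worms:
                    resp = responsibilities(model, w)
                    occs.append(occurrence(resp))
                    trans.append(transitions(resp))
                aggs[strain] = aggregate_strain(occs, trans, strain)
            d_r = jsd(aggs["N2"][0].values, aggs["MT001"][0].values)
            d_t = jsd(aggs["N2"][1].values.ravel(), aggs["MT001"][1].values.ravel())
            wins += d_r < d_t
        assert wins >= 9

    def test_clone_strains_are_exchangeable(self):
        """Worms of two identically parameterized strains have overlapping
        within- vs between-strain divergence distributions."""
        from wormstates import (fit_kmeans, intra_inter_divergence, occurrence,
                                responsibilities, sample_frames, wmw_one_sided)

        wins = 0
        for seed in range(10):
            config = SyntheticConfig(
                n_strains=2, worms_per_strain=6, frames_per_worm=800,
                n_attractors=4, seed=400 + seed,
            )
            coll = simulate_strains(config)  # both strains unperturbed
            pts = sample_frames(coll, fraction=0.1, seed=seed)
            model = fit_kmeans(pts, 6, seed=seed)
            occs = {
                w.worm_id: occurrence(responsibilities(model, w))
                for w in coll.worms()
            }
            pairs = intra_inter_divergence(occs, coll.strain_of(), seed=seed)
            p = wmw_one_sided([q.delta_intra for q in pairs],
                              [q.delta_inter for q in pairs])
            wins += p > 0.05
        assert wins >= 8

    def test_metropolis_construction_is_exact(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(5))
        q = rng.uniform(0.1, 1.0, (5, 5))
        q = (q + q.T) / 2
        np.fill_diagonal(q, 0)
        q *= 0.4 / q.sum(axis=1).max()
        a = metropolis_transition(pi, q)
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-12)
        assert np.abs(stationary_distribution(a) - pi).max() < 1e-10
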
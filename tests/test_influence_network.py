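import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eesnet.influence_network import (
    GenerationError,
    InfluenceNetwork,
    NetworkConfig,
    build_synthetic_network,
    coupling_ratio,
    dynamics,
    hill_derivative,
    hill_response,
    jacobian_at,
    make_stable_jacobian,
    validate_network,
)


class TestHillResponse:
    def test_half_saturation(self):
        assert hill_response(1.0, 1.0, 2) == pytest.approx(0.5)

    def test_zero_input(self):
        assert hill_response(0.0, 0.7, 2) == 0.0

    def test_direct_evaluation(self):
        # x^2 / (theta^2 + x^2) = 4/5 at x=2, theta=1
        assert hill_response(2.0, 1.0, 2) == pytest.approx(0.8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_response(1.0, 0.0, 2)
        with pytest.raises(ValueError):
            hill_response(-0.1, 1.0, 2)

    @given(
        x=st.floats(0, 50),
        dx=st.floats(0.001, 10),
        theta=st.floats(0.01, 5),
        n=st.integers(1, 4),
    )
    def test_monotone_and_bounded(self, x, dx, theta, n):
        lo, hi = hill_response(x, theta, n), hill_response(x + dx, theta, n)
        assert 0 <= lo <= hi < 1

    @given(theta=st.floats(0.05, 5), n=st.integers(1, 4))
    def test_half_at_theta(self, theta, n):
        assert hill_response(theta, theta, n) == pytest.approx(0.5)

    def test_derivative_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, theta = rng.uniform(0.1, 3), rng.uniform(0.1, 3)
            h = 1e-6
            fd = (hill_response(x + h, theta, 2) - hill_response(x - h, theta, 2)) / (2 * h)
            assert hill_derivative(x, theta, 2) == pytest.approx(fd, abs=1e-8)


class TestNetworkConfig:
    def test_defaults_match_reference_scale(self):
        cfg = NetworkConfig()
        assert cfg.n_clusters == 3
        assert cfg.cluster_size == 7
        assert cfg.b_range == (0.5, 1.5)
        assert cfg.theta_range == (0.0, 2.0)
        assert cfg.hill_index == 2
        assert cfg.inter_coupling_ratio == 0.1
        assert cfg.n_genes == 21

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"b_range": (0.0, 1.5)},
            {"b_range": (1.5, 0.5)},
            {"theta_range": (-0.1, 2.0)},
            {"eig_range": (-2.0, 0.5)},
            {"eig_range": (-2.0, 0.0)},
            {"inter_coupling_ratio": 0.0},
            {"n_clusters": 0},
            {"hill_index": 0},
            {"viability_residual_tol": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)


class TestDynamics:
    def test_equilibrium_residual(self, default_net):
        res = dynamics(default_net, default_net.x_star)
        assert np.max(np.abs(res)) < 1e-10

    def test_pure_decay_single_gene(self):
        net = InfluenceNetwork(
            cluster_of=np.array([0]),
            b=np.array([1.0]),
            theta=np.ones((1, 1)),
            w=np.zeros((1, 1)),
            basal=np.zeros(1),
            hill_index=2,
            x_star=np.zeros(1),
            jacobian_design=np.array([[-1.0]]),
        )
        assert dynamics(net, np.array([2.0])) == pytest.approx([-2.0])

    def test_wrong_shape_raises(self, default_net):
        with pytest.raises(ValueError):
            dynamics(default_net, np.ones(5))

    def test_jacobian_matches_finite_differences(self, default_net):
        rng = np.random.default_rng(3)
        state = rng.uniform(0.3, 1.8, size=default_net.n_genes)
        jac = jacobian_at(default_net, state)
        h = 1e-6
        for j in range(default_net.n_genes):
            ej = np.zeros(default_net.n_genes)
            ej[j] = h
            fd = (dynamics(default_net, state + ej) - dynamics(default_net, state - ej)) / (2 * h)
            assert np.max(np.abs(fd - jac[:, j])) < 1e-5


class TestJacobian:
    def test_isolated_gene_row(self):
        net = InfluenceNetwork(
            cluster_of=np.zeros(3, dtype=int),
            b=np.array([1.0, 2.0, 3.0]),
            theta=np.ones((3, 3)),
            w=np.zeros((3, 3)),
            basal=np.array([1.0, 2.0, 3.0]),
            hill_index=2,
            x_star=np.ones(3),
            jacobian_design=np.zeros((3, 3)),
        )
        jac = jacobian_at(net, np.ones(3))
        assert np.allclose(jac, np.diag([-1.0, -2.0, -3.0]))

    def test_monotone_interaction_signs(self, default_net):
        rng = np.random.default_rng(7)
        for _ in range(200):
            state = rng.uniform(0.01, 3.0, size=default_net.n_genes)
            jac = jacobian_at(default_net, state)
            off = ~np.eye(default_net.n_genes, dtype=bool)
            s = np.sign(jac[off])
            assert np.all((s == 0) | (s == np.sign(default_net.w[off])))


class TestMakeStableJacobian:
    def test_size_one(self):
        rng = np.random.default_rng(0)
        j = make_stable_jacobian(1, (-1.0 - 1e-12, -1.0), rng)
        assert j.shape == (1, 1) and -1.0 - 1e-9 < j[0, 0] < -1.0 + 1e-9

    def test_symmetric(self):
        j = make_stable_jacobian(8, (-2.0, -0.5), np.random.default_rng(1))
        assert np.max(np.abs(j - j.T)) < 1e-12

    def test_spectrum_matches_sampled_diagonal(self):
        # eigendecomposition oracle: same seed reproduces the sampled entries
        rng = np.random.default_rng(5)
        eigs_expected = np.sort(rng.uniform(-2.0, -0.5, size=8))
        j = make_stable_jacobian(8, (-2.0, -0.5), np.random.default_rng(5))
        assert np.allclose(np.sort(np.linalg.eigvalsh(j)), eigs_expected, atol=1e-10)

    def test_rejects_nonnegative_range(self):
        with pytest.raises(ValueError):
            make_stable_jacobian(3, (-1.0, 0.5), np.random.default_rng(0))


class TestBuildSyntheticNetwork:
    def test_default_shape(self, default_net):
        assert default_net.n_genes == 21
        counts = np.bincount(default_net.cluster_of)
        assert list(counts) == [7, 7, 7]

    def test_parameter_ranges(self, default_net):
        assert np.all(default_net.b >= 0.5) and np.all(default_net.b <= 1.5)
        used = default_net.w != 0
        assert np.all(default_net.theta[used] > 0)
        assert np.all(default_net.theta[used] <= 2.0)

    def test_coupling_ratio(self, default_net):
        assert 0.095 <= coupling_ratio(default_net) <= 0.105

    def test_stability(self, default_net):
        eigs = np.linalg.eigvals(jacobian_at(default_net, default_net.x_star))
        assert np.max(eigs.real) < 0

    def test_intra_block_matches_design(self, default_net):
        # at x_star the full Jacobian restricted to a cluster equals the
        # designed block (inter-cluster couplings only touch foreign columns)
        jac = jacobian_at(default_net, default_net.x_star)
        for c in range(3):
            idx = np.where(default_net.cluster_of == c)[0]
            block = jac[np.ix_(idx, idx)]
            assert np.allclose(
                block, default_net.jacobian_design[np.ix_(idx, idx)], atol=1e-10
            )

    def test_seed_reproducibility(self):
        a = build_synthetic_network(NetworkConfig(seed=123))
        b = build_synthetic_network(NetworkConfig(seed=123))
        assert np.array_equal(a.w, b.w)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.b, b.b)
        assert np.array_equal(a.basal, b.basal)

    def test_different_seeds_differ(self):
        a = build_synthetic_network(NetworkConfig(seed=1))
        b = build_synthetic_network(NetworkConfig(seed=2))
        assert not np.array_equal(a.w, b.w)

    @pytest.mark.parametrize("seed", range(5))
    def test_equilibrium_and_stability_across_seeds(self, seed):
        net = build_synthetic_network(NetworkConfig(seed=seed))
        validate_network(net)

    def test_generation_error_names_retries(self):
        # an eig_range this close to zero combined with 1 retry cannot
        # stabilize the coupled system every time; force failure determinism
        # by monkeypatching is overkill — use an impossible retry budget of 1
        # with a pathological ratio instead.
        cfg = NetworkConfig(
            seed=0, inter_coupling_ratio=500.0, max_stability_retries=2
        )
        with pytest.raises(GenerationError, match="2"):
            build_synthetic_network(cfg)


class TestSerialization:
    def test_json_round_trip(self, default_net, tmp_path):
        p = tmp_path / "net.json"
        default_net.to_json(p)
        loaded = InfluenceNetwork.from_json(p)
        assert np.allclose(loaded.w, default_net.w, atol=1e-12)
        assert np.allclose(loaded.theta, default_net.theta, atol=1e-12)
        assert np.allclose(loaded.basal, default_net.basal, atol=1e-12)
        assert loaded.gene_ids == default_net.gene_ids

    def test_unknown_major_version_rejected(self, default_net, tmp_path):
        d = default_net.to_dict()
        d["format_version"] = "99.0"
        with pytest.raises(ValueError, match="format_version"):
            InfluenceNetwork.from_dict(d)

    def test_loader_revalidates(self, default_net):
        d = default_net.to_dict()
        d["basal"] = [v + 0.5 for v in d["basal"]]  # breaks the equilibrium
        with pytest.raises(ValueError, match="residual"):
            InfluenceNetwork.from_dict(d)
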
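"""Synthetic clustered Hill-function influence network.

Each gene collapses transcript and protein into one variable x_i (mRNA
level).  The dynamics are

    dx_i/dt = beta_i - b_i * x_i + sum_j w_ij * H_n(x_j; theta_ij)

with H_n(x; theta) = x**n / (theta**n + x**n) a sigmoidal Hill response.
Networks are built cluster by cluster: a stable symmetric Jacobian is drawn
for every cluster (negative spectrum under a random orthogonal
transformation) and inverted through the Hill derivative at the designed
equilibrium to obtain interaction weights; clusters are then tied together
by sparse weak couplings and the basal rates beta are chosen so the designed
equilibrium is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FORMAT_VERSION = "1.0"


class GenerationError(RuntimeError):
    """Raised when a stable network cannot be generated within the retry budget."""


def _check_range(name: str, lo: float, hi: float) -> None:
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError(f"{name} must be a finite increasing pair, got ({lo}, {hi})")


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters controlling synthetic network generation."""

    n_clusters: int = 3
    cluster_size: int = 7
    b_range: tuple[float, float] = (0.5, 1.5)
    theta_range: tuple[float, float] = (0.0, 2.0)
    hill_index: int = 2
    eig_range: tuple[float, float] = (-2.0, -0.5)
    inter_coupling_ratio: float = 0.1
    seed: int = 0
    max_stability_retries: int = 50
    viability_residual_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise ValueError("n_clusters and cluster_size must be positive")
        _check_range("b_range", *self.b_range)
        if self.b_range[0] <= 0:
            raise ValueError("b_range lower bound must be > 0")
        _check_range("theta_range", *self.theta_range)
        if self.theta_range[0] < 0:
            raise ValueError("theta_range lower bound must be >= 0")
        if self.hill_index < 1:
            raise ValueError("hill_index must be a positive integer")
        _check_range("eig_range", *self.eig_range)
        if self.eig_range[1] >= 0:
            raise ValueError("eig_range must be strictly negative")
        if self.inter_coupling_ratio <= 0:
            raise ValueError("inter_coupling_ratio must be positive")
        if self.max_stability_retries < 1:
            raise ValueError("max_stability_retries must be positive")
        if self.viability_residual_tol <= 0:
            raise ValueError("viability_residual_tol must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_clusters * self.cluster_size

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "cluster_size": self.cluster_size,
            "b_range": list(self.b_range),
            "theta_range": list(self.theta_range),
            "hill_index": self.hill_index,
            "eig_range": list(self.eig_range),
            "inter_coupling_ratio": self.inter_coupling_ratio,
            "seed": self.seed,
            "max_stability_retries": self.max_stability_retries,
            "viability_residual_tol": self.viability_residual_tol,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("b_range", "theta_range", "eig_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def hill_response(x, theta, n: int):
    """Sigmoidal response x^n / (theta^n + x^n); equals 1/2 at x == theta.

    Accepts scalars or arrays (broadcast).  theta must be positive and x
    non-negative.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("hill_response requires theta > 0")
    if np.any(x < 0):
        raise ValueError("hill_response requires x >= 0")
    xn = x**n
    out = xn / (theta**n + xn)
    return float(out) if out.ndim == 0 else out


def hill_derivative(x, theta, n: int):
    """d/dx of hill_response: n * theta^n * x^(n-1) / (theta^n + x^n)^2."""
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("hill_derivative requires theta > 0")
    tn = theta**n
    xn = x**n
    out = n * tn * x ** (n - 1) / (tn + xn) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass
class InfluenceNetwork:
    """A fully parameterized Hill-function influence network with a designed
    equilibrium ``x_star``.

    ``theta`` entries on unused edges (w == 0) are kept at 1.0 as inert
    placeholders so vectorized Hill evaluation never divides by zero.
    """

    cluster_of: np.ndarray  # (N,) int cluster labels
    b: np.ndarray  # (N,) positive degradation rates
    theta: np.ndarray  # (N, N) Hill thresholds
    w: np.ndarray  # (N, N) signed interaction weights
    basal: np.ndarray  # (N,) basal production rates
    hill_index: int
    x_star: np.ndarray  # (N,) designed equilibrium
    jacobian_design: np.ndarray  # (N, N) block Jacobian before coupling
    config: NetworkConfig | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.b.shape[0]
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(n)]
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length mismatch")

    @property
    def n_genes(self) -> int:
        return int(self.b.shape[0])

    def dynamics(self, state: np.ndarray) -> np.ndarray:
        return dynamics(self, state)

    def jacobian(self, state: np.ndarray) -> np.ndarray:
        return jacobian_at(self, state)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "influence_network",
            "gene_ids": self.gene_ids,
            "cluster_of": self.cluster_of.tolist(),
            "b": self.b.tolist(),
            "theta": self.theta.tolist(),
            "w": self.w.tolist(),
            "basal": self.basal.tolist(),
            "hill_index": self.hill_index,
            "x_star": self.x_star.tolist(),
            "jacobian_design": self.jacobian_design.tolist(),
            "config": self.config.to_dict() if self.config else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "InfluenceNetwork":
        major = str(d.get("format_version", "0")).split(".")[0]
        if major != FORMAT_VERSION.split(".")[0]:
            raise ValueError(f"unsupported format_version {d.get('format_version')}")
        net = cls(
            cluster_of=np.asarray(d["cluster_of"], dtype=int),
            b=np.asarray(d["b"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            w=np.asarray(d["w"], dtype=float),
            basal=np.asarray(d["basal"], dtype=float),
            hill_index=int(d["hill_index"]),
            x_star=np.asarray(d["x_star"], dtype=float),
            jacobian_design=np.asarray(d["jacobian_design"], dtype=float),
            config=NetworkConfig.from_dict(d["config"]) if d.get("config") else None,
            gene_ids=list(d.get("gene_ids") or []),
        )
        validate_network(net)
        return net

    @classmethod
    def from_json(cls, path) -> "InfluenceNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def dynamics(net: InfluenceNetwork, state: np.ndarray) -> np.ndarray:
    """Time derivative of every gene at ``state``.

    Component i is ``basal_i - b_i*state_i + sum_j w_ij*H(state_j)``.
    For states explored by the least-squares solver components may go
    slightly negative; the Hill term is evaluated at max(state, 0) so the
    monotone-response contract holds on the solver's whole search space.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n_genes,):
        raise ValueError(f"state must have shape ({net.n_genes},), got {state.shape}")
    xs = np.maximum(state, 0.0)
    h = hill_response(xs[None, :], net.theta, net.hill_index)
    return net.basal - net.b * state + np.sum(net.w * h, axis=1)


def jacobian_at(net: InfluenceNetwork, state: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`dynamics` at ``state``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n_genes,):
        raise ValueError(f"state must have shape ({net.n_genes},), got {state.shape}")
    xs = np.maximum(state, 0.0)
    hprime = hill_derivative(xs[None, :], net.theta, net.hill_index)
    jac = net.w * hprime
    jac[np.diag_indices(net.n_genes)] -= net.b
    return jac


def make_stable_jacobian(
    size: int, eig_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Symmetric matrix Q D Q^T with spectrum drawn uniformly in eig_range.

    D is diagonal with entries in the (strictly negative) eig_range and Q is
    a Haar-random orthogonal matrix, so the result is stable by construction.
    """
    lo, hi = eig_range
    if lo >= 0 or hi >= 0:
        raise ValueError("eig_range entries must be strictly negative")
    if lo >= hi:
        raise ValueError("eig_range must be increasing")
    eigs = rng.uniform(lo, hi, size=size)
    q, r = np.linalg.qr(rng.standard_normal((size, size)))
    q *= np.sign(np.diag(r))  # fix QR sign ambiguity -> Haar measure
    return q @ np.diag(eigs) @ q.T


def _sample_theta(rng: np.random.Generator, size, theta_range) -> np.ndarray:
    """Uniform thresholds with exact zeros resampled (theta must be > 0 on
    any used edge)."""
    lo, hi = theta_range
    th = rng.uniform(lo, hi, size=size)
    while np.any(th <= 0):
        th[th <= 0] = rng.uniform(lo, hi, size=int(np.sum(th <= 0)))
    return th


def build_synthetic_network(config: NetworkConfig) -> InfluenceNetwork:
    """Generate a clustered network whose equilibrium is exactly ``x_star``
    (all ones) and whose full Jacobian there is stable.

    Per cluster the designed Jacobian block is inverted through the Hill
    derivative at the equilibrium to obtain weights; the block diagonal
    absorbs the degradation term.  Every node then receives exactly one
    incoming edge from each foreign cluster, with magnitudes rescaled so
    that mean inter-cluster |w| equals ``inter_coupling_ratio`` times the
    mean intra-cluster |w|.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    csize = config.cluster_size
    x_star = np.ones(n)

    last_err = ""
    for attempt in range(config.max_stability_retries):
        cluster_of = np.repeat(np.arange(config.n_clusters), csize)
        b = rng.uniform(*config.b_range, size=n)
        theta = np.ones((n, n))
        w = np.zeros((n, n))
        jac_design = np.zeros((n, n))

        for c in range(config.n_clusters):
            idx = np.arange(c * csize, (c + 1) * csize)
            th_block = _sample_theta(rng, (csize, csize), config.theta_range)
            j_block = make_stable_jacobian(csize, config.eig_range, rng)
            hp = hill_derivative(x_star[idx][None, :], th_block, config.hill_index)
            # J_ij = w_ij * H'(x*_j) off-diagonal; diagonal adds -b_i.
            w_block = j_block / hp
            w_block[np.diag_indices(csize)] = (
                np.diag(j_block) + b[idx]
            ) / np.diag(hp)
            theta[np.ix_(idx, idx)] = th_block
            w[np.ix_(idx, idx)] = w_block
            jac_design[np.ix_(idx, idx)] = j_block

        intra_mask = cluster_of[:, None] == cluster_of[None, :]
        mean_intra = float(np.mean(np.abs(w[intra_mask])))

        # one incoming edge per node from each foreign cluster
        inter_edges = []
        for i in range(n):
            for c in range(config.n_clusters):
                if c == cluster_of[i]:
                    continue
                j = int(rng.integers(c * csize, (c + 1) * csize))
                inter_edges.append((i, j))
        raw_mag = rng.uniform(0.5, 1.5, size=len(inter_edges))
        signs = rng.choice([-1.0, 1.0], size=len(inter_edges))
        target_mean = config.inter_coupling_ratio * mean_intra
        mag = raw_mag * (target_mean / np.mean(raw_mag))
        for (i, j), m, s in zip(inter_edges, mag, signs):
            w[i, j] = s * m
            theta[i, j] = _sample_theta(rng, (), config.theta_range)

        # basal rates make x_star an exact equilibrium
        h_star = hill_response(x_star[None, :], theta, config.hill_index)
        basal = b * x_star - np.sum(w * h_star, axis=1)

        net = InfluenceNetwork(
            cluster_of=cluster_of,
            b=b,
            theta=theta,
            w=w,
            basal=basal,
            hill_index=config.hill_index,
            x_star=x_star,
            jacobian_design=jac_design,
            config=config,
        )
        eigs = np.linalg.eigvals(jacobian_at(net, x_star))
        if np.max(eigs.real) < 0:
            return net
        last_err = f"max Re(eig) = {np.max(eigs.real):.3e}"

    raise GenerationError(
        f"no stable network after {config.max_stability_retries} retries ({last_err})"
    )


def validate_network(net: InfluenceNetwork, residual_tol: float = 1e-10) -> None:
    """Re-check construction invariants; raises ValueError on violation."""
    if np.any(net.b <= 0):
        raise ValueError("degradation rates must be positive")
    used = net.w != 0
    if np.any(net.theta[used] <= 0):
        raise ValueError("theta must be positive on used edges")
    res = np.max(np.abs(dynamics(net, net.x_star)))
    if res >= residual_tol:
        raise ValueError(f"equilibrium residual {res:.3e} exceeds {residual_tol:.1e}")
    eigs = np.linalg.eigvals(jacobian_at(net, net.x_star))
    if np.max(eigs.real) >= 0:
        raise ValueError("equilibrium is not stable")


def coupling_ratio(net: InfluenceNetwork) -> float:
    """Mean inter-cluster |w| over mean intra-cluster |w|."""
    intra = net.cluster_of[:, None] == net.cluster_of[None, :]
    inter = (~intra) & (net.w != 0)
    return float(np.mean(np.abs(net.w[inter])) / np.mean(np.abs(net.w[intra])))
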
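"""Affine surrogate network: dx/dt = A (x - x_star).

The steady-state surface of this system is exactly affine, so every model
quantity (knockout equilibria, fitted plane, clamp predictions, steering
projections) has a closed-form linear-algebra answer.  Used as an
independent oracle in tests and as a small exactly-solvable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def random_stable_affine(
    n: int, rng: np.random.Generator, eig_range: tuple[float, float] = (-2.0, -0.5)
) -> "AffineNetwork":
    """Symmetric negative-definite A with spectrum in eig_range, x_star = 1."""
    eigs = rng.uniform(*eig_range, size=n)
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    q *= np.sign(np.diag(r))
    return AffineNetwork(A=q @ np.diag(eigs) @ q.T, x_star=np.ones(n))


@dataclass
class AffineNetwork:
    A: np.ndarray  # (N, N) stable matrix
    x_star: np.ndarray  # (N,) equilibrium
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.n_genes)]

    @property
    def n_genes(self) -> int:
        return int(self.A.shape[0])

    def dynamics(self, state: np.ndarray) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_genes,):
            raise ValueError(
                f"state must have shape ({self.n_genes},), got {state.shape}"
            )
        return self.A @ (state - self.x_star)

    def jacobian(self, state: np.ndarray) -> np.ndarray:
        return self.A.copy()

    def clamped_equilibrium(self, clamps: dict[int, float]) -> np.ndarray:
        """Direct block linear solve for the equilibrium under clamping.

        With clamped set C at values v and free set F, the free block solves
        A_FF (x_F - x*_F) = -A_FC (v - x*_C).
        """
        n = self.n_genes
        cidx = np.array(sorted(clamps), dtype=int)
        fidx = np.array([i for i in range(n) if i not in clamps], dtype=int)
        x = self.x_star.astype(float).copy()
        if cidx.size:
            v = np.array([clamps[i] for i in cidx], dtype=float)
            x[cidx] = v
            if fidx.size:
                rhs = -self.A[np.ix_(fidx, cidx)] @ (v - self.x_star[cidx])
                x[fidx] = self.x_star[fidx] + np.linalg.solve(
                    self.A[np.ix_(fidx, fidx)], rhs
                )
        return x
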
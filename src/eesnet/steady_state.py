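"""Equilibria of the full network under gene clamping.

A mutant clamps a subset of genes at fixed values (0 for a knockout, half
the wildtype level for a heterozygote); its equilibrium solves the remaining
dynamics components as a nonlinear least-squares problem.  A mutant is
viable when the RMS residual of the unclamped components falls below the
viability tolerance and no expression level is meaningfully negative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

NEGATIVE_GUARD = -1e-9


@dataclass(frozen=True)
class MutantSpec:
    """A set of externally clamped genes.  Empty clamps denote wildtype."""

    clamps: dict[int, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for g, v in self.clamps.items():
            if v < 0:
                raise ValueError(f"clamp value for gene {g} must be >= 0, got {v}")

    @classmethod
    def knockout(cls, *genes: int) -> "MutantSpec":
        label = "wildtype" if not genes else "ko_" + "_".join(map(str, genes))
        return cls(clamps={g: 0.0 for g in genes}, label=label)

    @classmethod
    def heterozygote(cls, gene: int, wildtype_level: float) -> "MutantSpec":
        return cls(clamps={gene: 0.5 * wildtype_level}, label=f"het_{gene}")


@dataclass
class SteadyState:
    x: np.ndarray
    residual: float  # RMS over unclamped dynamics components
    viable: bool
    mutant: MutantSpec
    iterations: int


def solve_steady_state(
    net,
    mutant: MutantSpec | None = None,
    init: np.ndarray | None = None,
    *,
    residual_tol: float | None = None,
    max_iter: int = 500,
) -> SteadyState:
    """Solve the unclamped dynamics components for a clamped mutant.

    ``net`` is any object exposing ``n_genes``, ``x_star`` and
    ``dynamics(state)``.  Never raises on non-convergence: a residual floor
    above tolerance simply yields ``viable=False``.
    """
    mutant = mutant or MutantSpec()
    n = net.n_genes
    if residual_tol is None:
        residual_tol = getattr(
            getattr(net, "config", None), "viability_residual_tol", 1e-8
        )

    for g in mutant.clamps:
        if not (0 <= g < n):
            raise IndexError(f"gene index {g} out of range for {n} genes")
    if init is None:
        init = np.asarray(net.x_star, dtype=float).copy()
    else:
        init = np.asarray(init, dtype=float).copy()
        if init.shape != (n,):
            raise ValueError(f"init must have shape ({n},)")
        if np.any(~np.isfinite(init)):
            raise ValueError("init contains non-finite values")

    cidx = np.array(sorted(mutant.clamps), dtype=int)
    fidx = np.array([i for i in range(n) if i not in mutant.clamps], dtype=int)
    x_full = init.copy()
    if cidx.size:
        x_full[cidx] = [mutant.clamps[i] for i in cidx]

    if fidx.size == 0:
        return SteadyState(x=x_full, residual=0.0, viable=True, mutant=mutant,
                           iterations=0)

    def residuals(x_free: np.ndarray) -> np.ndarray:
        x_full[fidx] = x_free
        return net.dynamics(x_full)[fidx]

    sol = least_squares(residuals, x_full[fidx], method="trf", max_nfev=max_iter,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    x_full[fidx] = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    viable = rms < residual_tol and float(np.min(x_full)) > NEGATIVE_GUARD
    return SteadyState(x=x_full.copy(), residual=rms, viable=viable, mutant=mutant,
                       iterations=int(sol.nfev))


def knockout_panel(net, genes, **kwargs) -> list[SteadyState]:
    """Single-knockout steady states for ``genes``, in input order."""
    panel = [solve_steady_state(net, MutantSpec.knockout(g), **kwargs) for g in genes]
    n_viable = sum(s.viable for s in panel)
    logger.info("knockout panel: %d/%d viable", n_viable, len(panel))
    return panel


def viable_double_knockouts(net, internal_genes, **kwargs) -> list[SteadyState]:
    """Steady states for every unordered pair of internal genes clamped to 0."""
    internal_genes = list(internal_genes)
    if len(internal_genes) < 2:
        raise ValueError("need at least 2 internal genes for double knockouts")
    panel = [
        solve_steady_state(net, MutantSpec.knockout(a, b), **kwargs)
        for a, b in itertools.combinations(internal_genes, 2)
    ]
    logger.info(
        "double knockouts: %d/%d viable", sum(s.viable for s in panel), len(panel)
    )
    return panel
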
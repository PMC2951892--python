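"""Steering the network equilibrium toward a prescribed target state.

The fitted plane is parametrized by the internal coordinates u as
X(u) = T0 + B u.  The closest plane point Pr to a target Q solves the normal
equations (B^T B) u = B^T (Q - T0); clamping the internal genes at those
coordinates in the full model realizes an equilibrium Q' that is near Pr
whenever the plane approximates the steady-state surface well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from eesnet.ees_core import EESModel, plane_point
from eesnet.steady_state import MutantSpec, solve_steady_state

FORMAT_VERSION = "1.0"


class SteeringError(RuntimeError):
    """Rank-deficient plane parametrization."""


@dataclass
class SteeringResult:
    target_Q: np.ndarray
    projection_Pr: np.ndarray
    internal_settings: np.ndarray  # internal coordinates of Pr
    distances: dict[str, float]
    realized_Qprime: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "steering_result",
            "target_Q": self.target_Q.tolist(),
            "projection_Pr": self.projection_Pr.tolist(),
            "internal_settings": self.internal_settings.tolist(),
            "realized_Qprime": (
                None if self.realized_Qprime is None else self.realized_Qprime.tolist()
            ),
            "distances": self.distances,
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _parametrization(ees: EESModel, weights=None):
    """Origin T0 and spanning matrix B (N x m) of the plane; optionally
    row-weighted for a weighted Euclidean metric."""
    t0 = plane_point(ees, np.zeros(ees.m))
    b = np.column_stack(
        [plane_point(ees, np.eye(ees.m)[k]) - t0 for k in range(ees.m)]
    )
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        return t0, b, sw
    return t0, b, None


def project_onto_plane(ees: EESModel, Q: np.ndarray, weights=None) -> SteeringResult:
    """Orthogonal projection of target Q onto the fitted plane.

    ``weights`` optionally defines a diagonally weighted Euclidean metric;
    the default is the plain Euclidean distance over all genes.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (ees.n_genes,):
        raise ValueError(f"target must have shape ({ees.n_genes},)")
    if np.any(~np.isfinite(Q)):
        raise ValueError("target contains non-finite values")

    t0, b, sw = _parametrization(ees, weights)
    bw = b if sw is None else b * sw[:, None]
    rw = (Q - t0) if sw is None else (Q - t0) * sw
    gram = bw.T @ bw
    cond = float(np.linalg.cond(gram))
    if cond > 1e12:
        raise SteeringError(
            f"plane parametrization rank-deficient (Gram condition {cond:.3e})"
        )
    u = np.linalg.solve(gram, bw.T @ rw)
    pr = plane_point(ees, u)

    p0 = ees.training_points[0]
    result = SteeringResult(
        target_Q=Q,
        projection_Pr=pr,
        internal_settings=u,
        distances={
            "d(P0,Q)": float(np.linalg.norm(p0 - Q)),
            "d(Pr,Q)": float(np.linalg.norm(pr - Q)),
        },
    )
    if np.any(u < 0):
        result.warnings.append(
            "negative internal settings: biologically unreachable clamp levels"
        )
    return result


def evaluate_steering(
    net, ees: EESModel, Q: np.ndarray, weights=None, **solve_kwargs
) -> SteeringResult:
    """Project Q onto the plane, then realize the clamped equilibrium Q'.

    All internal genes are clamped at the projection's internal coordinates
    and the full model is solved for the remaining genes.  If that solve is
    non-viable the result carries a warning and no realized point.
    """
    result = project_onto_plane(ees, Q, weights=weights)
    pos = {g: i for i, g in enumerate(ees.gene_ids)}
    clamps = {
        pos[g]: float(v) for g, v in zip(ees.internal, result.internal_settings)
    }
    if any(v < 0 for v in clamps.values()):
        result.warnings.append("clamp levels truncated at 0 for the realized solve")
        clamps = {g: max(v, 0.0) for g, v in clamps.items()}
    state = solve_steady_state(net, MutantSpec(clamps=clamps, label="steering"),
                               **solve_kwargs)
    if state.viable:
        result.realized_Qprime = state.x
        result.distances["d(Qprime,Pr)"] = float(
            np.linalg.norm(state.x - result.projection_Pr)
        )
        result.distances["d(Qprime,Q)"] = float(np.linalg.norm(state.x - Q))
    else:
        result.warnings.append(
            f"clamped solve non-viable (residual {state.residual:.3e}); "
            "realized equilibrium omitted"
        )
    return result
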
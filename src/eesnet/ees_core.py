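"""Construction of the effective empirical subnetwork (EES).

Given the wildtype steady state P0 and the m single-knockout steady states
P1..Pm of a chosen internal gene set S, the m+1 points define a unique
m-dimensional affine plane in gene-expression space.  Two families of affine
relations are fitted:

* external relations — every gene outside S is an affine function of the m
  internal levels (one (m+1)x(m+1) linear solve per external gene, one row
  per training point);
* internal inter-relations — each internal gene k is an affine function of
  the other m-1 internal genes, fitted on the m points {P0} u {P_l : l != k}
  (knocking out k makes k behave as external, so P_k is excluded).

Predictions for arbitrary clamp patterns on S solve the internal relations
of the free internal genes as a small linear system, then evaluate the
external relations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

FORMAT_VERSION = "1.0"
DEFAULT_COND_CAP = 1e8


class FitError(RuntimeError):
    """Affinely degenerate training points (condition number above cap)."""


class PredictionError(RuntimeError):
    """Singular reduced system when predicting a clamp pattern."""


@dataclass
class EESModel:
    gene_ids: list[str]
    internal: list[str]  # ordered internal gene ids (the set S)
    external: list[str]
    external_coeffs: np.ndarray  # (N-m, m+1): [intercept, coeff per internal]
    internal_coeffs: np.ndarray  # (m, m+1): [intercept, coeff per internal];
    # the self column is identically 0
    training_points: np.ndarray  # (m+1, N): rows P0, P1..Pm
    condition_report: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.internal)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def internal_idx(self) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in self.internal], dtype=int)

    @property
    def external_idx(self) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in self.external], dtype=int)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "ees_model",
            "gene_ids": self.gene_ids,
            "internal": self.internal,
            "external": self.external,
            "external_coeffs": self.external_coeffs.tolist(),
            "internal_coeffs": self.internal_coeffs.tolist(),
            "training_points": self.training_points.tolist(),
            "condition_report": self.condition_report,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "EESModel":
        major = str(d.get("format_version", "0")).split(".")[0]
        if major != FORMAT_VERSION.split(".")[0]:
            raise ValueError(f"unsupported format_version {d.get('format_version')}")
        return cls(
            gene_ids=list(d["gene_ids"]),
            internal=list(d["internal"]),
            external=list(d["external"]),
            external_coeffs=np.asarray(d["external_coeffs"], dtype=float),
            internal_coeffs=np.asarray(d["internal_coeffs"], dtype=float),
            training_points=np.asarray(d["training_points"], dtype=float),
            condition_report=dict(d.get("condition_report", {})),
        )

    @classmethod
    def from_json(cls, path) -> "EESModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_ees(
    wildtype: np.ndarray,
    knockouts,
    internal,
    gene_ids=None,
    *,
    zero_knocked_out: bool = True,
    cond_cap: float = DEFAULT_COND_CAP,
) -> EESModel:
    """Fit the affine plane through the wildtype and m single-knockout points.

    Parameters
    ----------
    wildtype : (N,) wildtype steady-state levels (P0).
    knockouts : (m, N) array-like; row k is the steady state with internal
        gene k knocked out, in the order of ``internal``.
    internal : ordered internal gene ids (or integer indices when
        ``gene_ids`` is None).
    zero_knocked_out : force each knockout point's own gene level to exactly
        0 before fitting (measured residual signal of a knocked-out gene is
        non-functional).
    """
    wildtype = np.asarray(wildtype, dtype=float)
    knockouts = np.asarray(knockouts, dtype=float)
    n = wildtype.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    gene_ids = list(gene_ids)
    internal = [gene_ids[g] if isinstance(g, (int, np.integer)) else str(g)
                for g in internal]
    m = len(internal)
    if m < 1:
        raise ValueError("need at least one internal gene")
    if knockouts.shape != (m, n):
        raise ValueError(f"knockouts must have shape ({m}, {n})")
    unknown = set(internal) - set(gene_ids)
    if unknown:
        raise ValueError(f"internal genes not in gene_ids: {sorted(unknown)}")
    if len(set(internal)) != m:
        raise ValueError("internal gene ids must be distinct")

    pos = {g: i for i, g in enumerate(gene_ids)}
    iidx = np.array([pos[g] for g in internal], dtype=int)
    external = [g for g in gene_ids if g not in set(internal)]
    eidx = np.array([pos[g] for g in external], dtype=int)

    pts = np.vstack([wildtype, knockouts])  # (m+1, N)
    if zero_knocked_out:
        for k in range(m):
            pts[k + 1, iidx[k]] = 0.0

    # external relations: one (m+1)x(m+1) system, shared design matrix
    design = np.hstack([np.ones((m + 1, 1)), pts[:, iidx]])
    cond_ext = float(np.linalg.cond(design))
    if cond_ext > cond_cap:
        raise FitError(
            f"training points affinely degenerate in internal coordinates: "
            f"condition number {cond_ext:.3e} exceeds {cond_cap:.1e}"
        )
    if eidx.size:
        ext_coeffs = np.linalg.solve(design, pts[:, eidx]).T  # (N-m, m+1)
    else:
        ext_coeffs = np.zeros((0, m + 1))

    # internal inter-relations: gene k from {P0} u {P_l : l != k}
    int_coeffs = np.zeros((m, m + 1))
    cond_int = {}
    for k in range(m):
        rows = [0] + [l + 1 for l in range(m) if l != k]
        others = [l for l in range(m) if l != k]
        a = np.hstack(
            [np.ones((m, 1)), pts[np.ix_(rows, iidx[others])]]
        )  # (m, m)
        rhs = pts[rows, iidx[k]]
        ck = float(np.linalg.cond(a))
        cond_int[internal[k]] = ck
        if ck > cond_cap:
            raise FitError(
                f"internal relation for {internal[k]} degenerate: "
                f"condition number {ck:.3e} exceeds {cond_cap:.1e}"
            )
        sol = np.linalg.solve(a, rhs)
        int_coeffs[k, 0] = sol[0]
        for j, l in enumerate(others):
            int_coeffs[k, 1 + l] = sol[1 + j]

    return EESModel(
        gene_ids=gene_ids,
        internal=internal,
        external=external,
        external_coeffs=ext_coeffs,
        internal_coeffs=int_coeffs,
        training_points=pts,
        condition_report={"external": cond_ext, "internal": cond_int},
    )


def plane_point(ees: EESModel, internal_values: np.ndarray) -> np.ndarray:
    """Full N-vector on the plane with the given internal coordinates."""
    u = np.asarray(internal_values, dtype=float)
    if u.shape != (ees.m,):
        raise ValueError(f"internal_values must have shape ({ees.m},)")
    x = np.empty(ees.n_genes)
    x[ees.internal_idx] = u
    if len(ees.external):
        x[ees.external_idx] = ees.external_coeffs[:, 0] + ees.external_coeffs[:, 1:] @ u
    return x


def predict_mutant(ees: EESModel, clamps: dict) -> np.ndarray:
    """Predict the full expression vector with internal genes clamped.

    ``clamps`` maps internal gene ids (or internal-order indices) to clamp
    values.  Free internal genes solve the linear system of their
    inter-relations with the clamped values substituted; external genes then
    follow from the plane.
    """
    if not clamps:
        raise ValueError("at least one clamp is required")
    key = {g: k for k, g in enumerate(ees.internal)}
    cl: dict[int, float] = {}
    for g, v in clamps.items():
        if isinstance(g, (int, np.integer)):
            if not (0 <= g < ees.m):
                raise ValueError(f"internal index {g} out of range")
            cl[int(g)] = float(v)
        elif g in key:
            cl[key[g]] = float(v)
        else:
            raise ValueError(f"clamp target {g!r} is not an internal gene")

    u = np.zeros(ees.m)
    for k, v in cl.items():
        u[k] = v
    free = [k for k in range(ees.m) if k not in cl]
    if free:
        # relation k: u_k - sum_{l free, l != k} a_kl u_l
        #           = a_k0 + sum_{l clamped} a_kl u_l
        a = ees.internal_coeffs
        mat = np.eye(len(free))
        rhs = np.empty(len(free))
        for i, k in enumerate(free):
            for j, l in enumerate(free):
                if l != k:
                    mat[i, j] = -a[k, 1 + l]
            rhs[i] = a[k, 0] + sum(a[k, 1 + l] * u[l] for l in cl)
        cond = float(np.linalg.cond(mat))
        if cond > 1e12:
            raise PredictionError(
                f"reduced internal system singular (condition number {cond:.3e})"
            )
        u[free] = np.linalg.solve(mat, rhs)
    return plane_point(ees, u)


def training_consistency_check(ees: EESModel) -> dict:
    """Max absolute residuals of both relation families on the training points."""
    pts = ees.training_points
    ext_res = 0.0
    if len(ees.external):
        design = np.hstack([np.ones((pts.shape[0], 1)), pts[:, ees.internal_idx]])
        pred = design @ ees.external_coeffs.T
        ext_res = float(np.max(np.abs(pred - pts[:, ees.external_idx])))
    int_res = 0.0
    a = ees.internal_coeffs
    for k in range(ees.m):
        rows = [0] + [l + 1 for l in range(ees.m) if l != k]
        u = pts[np.ix_(rows, ees.internal_idx)]
        pred = a[k, 0] + u @ a[k, 1:]
        int_res = max(int_res, float(np.max(np.abs(pred - pts[rows, ees.internal_idx[k]]))))
    return {"max_external_residual": ext_res, "max_internal_residual": int_res}


def rank_internal_candidates(panel, gene_ids=None) -> list[dict]:
    """Rank genes as internal-set candidates by single-knockout viability and
    residual.  ``panel`` is a list of single-knockout SteadyState results.
    Never auto-selects: returns a ranked report for the caller to choose from.
    """
    rows = []
    for st in panel:
        (gene,) = st.mutant.clamps.keys()
        rows.append(
            {
                "gene": gene_ids[gene] if gene_ids else gene,
                "viable": bool(st.viable),
                "residual": float(st.residual),
            }
        )
    return sorted(rows, key=lambda r: (not r["viable"], r["residual"]))
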
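"""Post-fit sensitivity and uncertainty analysis at the MLE.

Sensitivity scores which variables (weight bins, ξ, background)
dominate the local curvature of χ² around the solution; uncertainty
back-propagates the observational error through the conditionally
linear forward map to per-bin standard deviations δw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import forward
from .exceptions import ShapeError
from .greens import GreenTensor, hard_sphere_structure
from .inverse import IntensityData, SolutionState

__all__ = [
    "FlattenedVariables",
    "SensitivityResult",
    "UncertaintyResult",
    "flatten_variables",
    "sensitivity",
    "uncertainty",
]

#: relative singular-value cutoff for the pseudo-inverse in `uncertainty`
PINV_RCOND = 1e-10


@dataclass
class FlattenedVariables:
    """All variables concatenated into one vector with an index map."""

    x: np.ndarray
    index: dict  # name -> slice or int

    def get(self, name: str):
        return self.x[self.index[name]]


@dataclass
class SensitivityResult:
    """Per-variable normalized sensitivity in [0, 1] (max = 1)."""

    values: FlattenedVariables
    warning: str | None = None


@dataclass
class UncertaintyResult:
    """Per-bin standard deviations δw and covariance diagnostics."""

    delta_w: list
    rank: list = field(default_factory=list)
    condition: list = field(default_factory=list)
    rank_deficient: bool = False


def flatten_variables(solution: SolutionState) -> FlattenedVariables:
    """Concatenate [w^1 … w^N, ξ, background scalars] into one vector."""
    mle = solution.mle
    parts, index, off = [], {}, 0
    for name, w in zip(solution.param_names, mle.weights):
        index[f"w:{name}"] = slice(off, off + w.size)
        parts.append(w)
        off += w.size
    index["xi"] = off
    parts.append([mle.xi])
    off += 1
    bg = mle.background
    if bg.kind == "power_law":
        index["A"], index["B"] = off, off + 1
        parts.append([bg.A, bg.B])
        off += 2
    else:
        index["b"] = off
        parts.append([bg.b])
        off += 1
    return FlattenedVariables(x=np.concatenate([np.atleast_1d(p) for p in parts]),
                              index=index)


def _structure_s(solution: SolutionState, data: IntensityData):
    if solution.extras and "r_eff" in solution.extras:
        return hard_sphere_structure(data.q, solution.extras["r_eff"],
                                     solution.extras["v_f"]).ravel()
    return None


def _model_columns(solution: SolutionState, g: GreenTensor, data: IntensityData):
    """∂I/∂X_a columns (flattened q) for every natural variable."""
    mle = solution.mle
    s_q = _structure_s(solution, data)
    gt = []
    for k in range(g.n_params):
        col = forward.partial_contract(g.data, mle.weights, g.m, k)
        col = col.reshape(-1, col.shape[-1])
        if s_q is not None:
            col = col * s_q[:, None]
        gt.append(col)
    p = gt[0] @ mle.weights[0] if g.n_params else np.zeros(data.mean.size)
    qmag = data.q.magnitude().ravel()
    cols = [mle.xi * c for c in gt]
    cols.append(p[:, None])  # xi
    bg = mle.background
    if bg.kind == "power_law":
        e_a = np.abs(qmag) ** (-bg.B)
        cols.append(e_a[:, None])
        cols.append((-bg.A * np.log(np.abs(qmag)) * e_a)[:, None])
    else:
        cols.append(np.ones((qmag.size, 1)))
    return np.hstack(cols), gt, p


def sensitivity(solution: SolutionState, g: GreenTensor,
                data: IntensityData) -> SensitivityResult:
    """Curvature-based normalized sensitivity at the MLE.

    The score of variable a is |H_aa| X̂_a² normalized to unit maximum,
    where H is the Hessian of χ²; because the forward map is multi-linear
    the diagonal curvature is exactly 2 Σ_i (∂I_i/∂X_a)²/σ_i².  The
    score is implementation-defined up to this normalization and should
    be read comparatively, not absolutely.
    """
    fv = flatten_variables(solution)
    jac, _, _ = _model_columns(solution, g, data)
    u = 1.0 / data.std.ravel() ** 2
    h_diag = 2.0 * np.einsum("ia,i,ia->a", jac, u, jac)
    raw = np.abs(h_diag) * fv.x**2
    top = raw.max()
    warning = None
    if top <= 0.0:
        warning = "all sensitivities vanish (zero curvature and gradient)"
        warnings.warn(warning, stacklevel=2)
        values = raw
    else:
        values = raw / top
    return SensitivityResult(values=FlattenedVariables(values, fv.index),
                             warning=warning)


def uncertainty(solution: SolutionState, g: GreenTensor,
                data: IntensityData) -> UncertaintyResult:
    """Linearized posterior error bars δw for every parameter density.

    For parameter k the forward map is linear: I = ξ G̃ w^k + b with G̃
    the Green tensor contracted with all other MLE weights; the
    observational covariance C = diag(σ²) then propagates to
    cov(w^k) = (ξ² G̃ᵀ C⁻¹ G̃)⁻¹ (no-prior linear-Gaussian case).  A
    pseudo-inverse with relative cutoff ``PINV_RCOND`` is used and rank
    deficiency is flagged.
    """
    if data.mean.shape != g.q_grid.shape:
        raise ShapeError("data and Green tensor are not on the same q grid")
    mle = solution.mle
    u = 1.0 / data.std.ravel() ** 2
    _, gt, _ = _model_columns(solution, g, data)
    delta_w, ranks, conds = [], [], []
    deficient = False
    for col in gt:
        m = (mle.xi**2) * (col.T * u) @ col
        sv = np.linalg.svd(m, compute_uv=False)
        rank = int(np.sum(sv > PINV_RCOND * sv[0])) if sv[0] > 0 else 0
        ranks.append(rank)
        conds.append(float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf)
        if rank < m.shape[0]:
            deficient = True
            warnings.warn("curvature matrix is rank deficient; using pseudo-inverse",
                          stacklevel=2)
        cov = np.linalg.pinv(m, rcond=PINV_RCOND, hermitian=True)
        delta_w.append(np.sqrt(np.clip(np.diag(cov), 0.0, None)))
    return UncertaintyResult(delta_w=delta_w, rank=ranks, condition=conds,
                             rank_deficient=deficient)
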
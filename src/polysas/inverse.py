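"""Constrained maximum-likelihood inversion of the multi-linear forward map.

The inverse problem minimizes the σ-normalized squared intensity misfit
(χ²) over the N parameter densities (each non-negative, summing to 1),
the scale ξ and the background.  The simplex inequalities are removed by
a slack reparametrization w_i = s_i² with the single equality constraint
Σ s_i² = 1 per parameter; the resulting equality-constrained program is
solved by the Byrd–Omojokun trust-region method (SciPy ``trust-constr``)
with analytic gradient and, by default, an analytic dense Hessian.

Inputs are automatically rescaled so that all working quantities are
O(1); the solution maps back exactly and χ² is invariant under the
scaling.  An optional monitor freezes parameters whose distribution has
stopped moving (L1 distance between successive records below a
threshold), contracting them out of the Green tensor so later
trust-region iterations run on a smaller problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import BFGS, NonlinearConstraint, minimize

from . import forward
from .exceptions import (
    DataError,
    DegenerateStateError,
    ShapeError,
    SolverError,
)
from .forward import BackgroundSpec, DistributionSet
from .greens import GreenTensor, QGrid, hard_sphere_structure

__all__ = [
    "IntensityData",
    "SlackState",
    "ScaleFactors",
    "SolverOptions",
    "SolutionState",
    "StructureFactor",
    "GridSearchResult",
    "normalized_misfit",
    "chi_squared",
    "slack_encode",
    "slack_decode",
    "autoscale",
    "solve",
    "monitor_and_reduce",
    "grid_search_structure_init",
]


# ----------------------------------------------------------------------
# data containers
# ----------------------------------------------------------------------

@dataclass
class IntensityData:
    """Observed mean and standard deviation of the intensity.

    If ``std`` is omitted the mean is used in its place (the measurement
    error is then assumed to scale with the measured amplitude); a
    warning is emitted.
    """

    q: QGrid
    mean: np.ndarray
    std: np.ndarray | None = None
    dq: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != self.q.shape:
            raise ShapeError(f"mean shape {self.mean.shape} != q grid {self.q.shape}")
        if not np.all(np.isfinite(self.mean)):
            raise DataError("mean intensity must be finite")
        if self.std is None:
            warnings.warn("no standard deviation supplied; using the mean in its place",
                          stacklevel=2)
            self.std = np.abs(self.mean).copy()
        self.std = np.asarray(self.std, dtype=float)
        if self.std.shape != self.mean.shape:
            raise ShapeError("std shape does not match mean")
        if np.any(self.std <= 0) or not np.all(np.isfinite(self.std)):
            raise DataError("std must be strictly positive and finite")
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
            if self.dq.shape != self.mean.shape:
                raise ShapeError("dq shape does not match mean")


@dataclass
class SlackState:
    """Unconstrained counterpart of a :class:`DistributionSet`."""

    s: list
    xi_raw: float
    b_raw: float
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScaleFactors:
    """Intensity and Green-tensor scales used by :func:`autoscale`."""

    c_i: float
    c_g: float

    def __post_init__(self):
        if not (self.c_i > 0 and self.c_g > 0):
            raise DataError("scale factors must be strictly positive")


@dataclass
class SolverOptions:
    """Knobs of :func:`solve`; defaults favour maximum accuracy."""

    max_iter: int = 1000
    gtol: float = 1e-16
    xtol: float = 1e-16
    monitor_every: int = 10
    reduce_tol: float | None = None  # L1 threshold for freezing; None = off
    seed: int = 0
    chunk_size: int | None = None
    hessian: str = "auto"  # "exact", "bfgs" or "auto" (exact up to 2000 vars)
    presolve: bool = True  # conditionally-linear presolve for N = 1
    polish: bool = True  # conditionally-linear block polish after the TR stage
    target_chi2: float | None = 1e-13  # stop the TR stage below this χ²
    rounds: int | None = None  # TR+polish alternations; None = 1 (N=1) / 8
    prep_decimate: int | None = None  # 2-D prep-solve stride; None = auto, 0 = off
    verbose: int = 0

    def __post_init__(self):
        if self.max_iter < 1 or self.monitor_every < 1:
            raise DataError("max_iter and monitor_every must be >= 1")
        if self.gtol <= 0 or self.xtol <= 0:
            raise DataError("tolerances must be positive")


@dataclass
class StructureFactor:
    """Hard-sphere structure-factor block; variables may be free or fixed."""

    r_eff: float
    v_f: float
    free: bool = False
    kind: str = "hard_sphere"


@dataclass
class SolutionState:
    """Result of :func:`solve`."""

    mle: DistributionSet
    chi2: float
    trace: dict
    frozen: dict
    scale: ScaleFactors
    converged: bool
    param_names: list
    extras: dict = field(default_factory=dict)
    message: str = ""


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------

def normalized_misfit(pred: np.ndarray, data: IntensityData) -> np.ndarray:
    """(I_pred − μ)/σ, element-wise on the q grid."""
    pred = np.asarray(pred, dtype=float)
    if pred.shape != data.mean.shape:
        raise ShapeError(f"prediction shape {pred.shape} != data shape {data.mean.shape}")
    return (pred - data.mean) / data.std


def chi_squared(eps: np.ndarray) -> float:
    """Squared Frobenius norm of the normalized misfit."""
    eps = np.asarray(eps, dtype=float)
    return float(np.sum(eps * eps))


def slack_encode(d: DistributionSet) -> SlackState:
    """Map a feasible DistributionSet to slack variables s with w = s²."""
    s = [np.sqrt(w) for w in d.weights]
    bg = d.background
    extras = {}
    if bg.kind == "power_law":
        extras = {"A": bg.A, "B": bg.B}
        b_raw = 0.0
    else:
        b_raw = bg.b
    return SlackState(s=s, xi_raw=float(d.xi), b_raw=float(b_raw), extras=extras)


def slack_decode(state: SlackState, background_kind: str = "flat") -> DistributionSet:
    """Decode slack variables to a feasible DistributionSet.

    Weights are w_i = s_i² normalized by Σ s_i², so the result satisfies
    the simplex constraints for any sign and (non-degenerate) norm of s.
    """
    weights = []
    for s in state.s:
        s = np.asarray(s, dtype=float)
        nrm2 = float(np.dot(s, s))
        if nrm2 < 1e-300:
            raise DegenerateStateError("slack vector has zero norm")
        weights.append(s * s / nrm2)
    if background_kind == "power_law":
        bg = BackgroundSpec("power_law", A=state.extras.get("A", 0.0),
                            B=state.extras.get("B", 0.0))
    else:
        bg = BackgroundSpec("flat", b=state.b_raw)
    return DistributionSet(weights=weights, xi=max(state.xi_raw, 0.0), background=bg)


def autoscale(g: GreenTensor, data: IntensityData):
    """Rescale data and Green tensor so both have unit maximum.

    Returns (scaled G, scaled data, ScaleFactors).  The MLE maps back
    exactly (ξ = ξ_s·c_I/c_G, b = b_s·c_I) and χ² is invariant because
    mean and std are scaled together.
    """
    c_i = float(np.max(np.abs(data.mean)))
    c_g = float(np.max(g.data))
    if c_i == 0.0 or c_g == 0.0:
        raise DataError("cannot autoscale all-zero inputs")
    g_s = g.copy_with(data=g.data / c_g)
    data_s = IntensityData(q=data.q, mean=data.mean / c_i, std=data.std / c_i, dq=data.dq)
    return g_s, data_s, ScaleFactors(c_i=c_i, c_g=c_g)


def monitor_and_reduce(current: dict, previous: dict, reduce_tol: float,
                       frozen: dict) -> tuple[dict, dict]:
    """Decide which parameters have converged between two records.

    ``current`` and ``previous`` map parameter names to decoded weight
    vectors.  A parameter whose successive-record L1 distance falls
    below ``reduce_tol`` is marked frozen.  Returns (updated frozen
    flags, L1 distances).
    """
    frozen = dict(frozen)
    l1 = {}
    for name, w in current.items():
        if frozen.get(name, False):
            continue
        prev = previous.get(name)
        if prev is None:
            continue
        dist = float(np.sum(np.abs(np.asarray(w) - np.asarray(prev))))
        l1[name] = dist
        if dist < reduce_tol:
            frozen[name] = True
    return frozen, l1


# ----------------------------------------------------------------------
# objective
# ----------------------------------------------------------------------

def _contract_axes(data: np.ndarray, m: int, weights_by_axis: dict) -> np.ndarray:
    """Contract the given parameter axes (keys are axis indices among the
    parameter dimensions) with the given weight vectors."""
    out = data
    for k in sorted(weights_by_axis, reverse=True):
        out = np.tensordot(out, weights_by_axis[k], axes=(m + k, 0))
    return out


class _Problem:
    """χ² objective over the flattened slack/scalar variable vector.

    Variable layout: [s^1 … s^K | ξ | bg vars | structure extras], where
    K is the number of active (unfrozen) parameters, bg vars are (b,) for
    a flat background and (A, B) for a power law, and structure extras
    (r_eff, V_f) appear only when the structure factor is free.
    """

    def __init__(self, g_data, m, mu_flat, sig_flat, qmag_flat, bg_kind,
                 structure: StructureFactor | None, names):
        self.g = g_data  # (nq_flat, n_1, ..., n_K)
        self.m = m
        self.n_k = list(g_data.shape[1:])
        self.k = len(self.n_k)
        self.names = list(names)
        self.mu = mu_flat
        self.u = 1.0 / sig_flat**2
        self.qmag = qmag_flat
        self.bg_kind = bg_kind
        self.structure = structure
        self.n_bg = 2 if bg_kind == "power_law" else 1
        self.n_ex = 2 if (structure is not None and structure.free) else 0
        if self.n_ex:
            # optimize extras as O(1) multiples of their initial values
            self.ex_scale = np.array([max(structure.r_eff, 1e-6),
                                      max(structure.v_f, 1e-2)])
        else:
            self.ex_scale = np.ones(2)
        self.n_var = sum(self.n_k) + 1 + self.n_bg + self.n_ex
        self._cache_key = None
        self._c = {}
        if structure is not None and not structure.free:
            s_q = hard_sphere_structure(np.abs(qmag_flat), structure.r_eff, structure.v_f)
            self.g = self.g * s_q.reshape((-1,) + (1,) * self.k)
            self.structure_fixed_s = s_q
        else:
            self.structure_fixed_s = None

    # -- packing ----------------------------------------------------

    def pack(self, s_list, xi, bg_vars, extras=()):
        return np.concatenate([np.concatenate(s_list) if s_list else np.empty(0),
                               [xi], bg_vars, extras])

    def unpack(self, z):
        s_list, off = [], 0
        for n in self.n_k:
            s_list.append(z[off:off + n])
            off += n
        xi = z[off]
        bg = z[off + 1: off + 1 + self.n_bg]
        extras = z[off + 1 + self.n_bg:]
        return s_list, xi, bg, extras

    # -- constraints ------------------------------------------------

    def constraint(self):
        def cfun(z):
            s_list, _, _, _ = self.unpack(z)
            return np.array([float(np.dot(s, s)) - 1.0 for s in s_list])

        def cjac(z):
            jac = np.zeros((self.k, self.n_var))
            off = 0
            for i, n in enumerate(self.n_k):
                jac[i, off:off + n] = 2.0 * z[off:off + n]
                off += n
            return jac

        def chess(z, v):
            h = np.zeros((self.n_var, self.n_var))
            off = 0
            for i, n in enumerate(self.n_k):
                idx = np.arange(off, off + n)
                h[idx, idx] = 2.0 * v[i]
                off += n
            return h

        return NonlinearConstraint(cfun, 0.0, 0.0, jac=cjac, hess=chess)

    # -- model evaluation -------------------------------------------

    def _background(self, bg_vars):
        if self.bg_kind == "power_law":
            a, b = bg_vars
            e_a = np.abs(self.qmag) ** (-b)
            return a * e_a, e_a
        return np.full_like(self.mu, bg_vars[0]), None

    def _structure_s(self, extras):
        if self.structure is None:
            return None
        if self.structure.free:
            r_eff = max(float(extras[0] * self.ex_scale[0]), 1e-6)
            v_f = float(np.clip(extras[1] * self.ex_scale[1], 0.0, 0.7399))
            return hard_sphere_structure(np.abs(self.qmag), r_eff, v_f)
        return None  # already folded into self.g

    def _ensure(self, z):
        key = z.tobytes()
        if key == self._cache_key:
            return self._c
        s_list, xi, bg_vars, extras = self.unpack(z)
        w_list = [s * s for s in s_list]
        s_q = self._structure_s(extras)
        g_eff = self.g if s_q is None else self.g * s_q.reshape((-1,) + (1,) * self.k)
        # partial contractions: all weights except k -> (nq, n_k)
        gt = forward.all_partial_contracts(g_eff, w_list, 1) if self.k else []
        p = gt[0] @ w_list[0] if self.k else g_eff
        bg, e_a = self._background(bg_vars)
        pred = xi * p + bg
        d = pred - self.mu
        r = self.u * d
        f = float(np.dot(d, r))
        self._c = dict(s_list=s_list, w_list=w_list, xi=xi, bg_vars=bg_vars,
                       extras=extras, g_eff=g_eff, gt=gt, p=p, bg=bg, e_a=e_a,
                       pred=pred, d=d, r=r, f=f, s_q=s_q)
        self._cache_key = key
        return self._c

    def fun_and_grad(self, z):
        c = self._ensure(z)
        g = np.zeros(self.n_var)
        off = 0
        for k in range(self.k):
            g_w = 2.0 * c["xi"] * (c["gt"][k].T @ c["r"])
            g[off:off + self.n_k[k]] = 2.0 * c["s_list"][k] * g_w
            off += self.n_k[k]
        g[off] = 2.0 * float(np.dot(c["p"], c["r"]))
        if self.bg_kind == "power_law":
            a, b = c["bg_vars"]
            lnq = np.log(np.abs(self.qmag))
            g[off + 1] = 2.0 * float(np.dot(c["e_a"], c["r"]))
            g[off + 2] = 2.0 * float(np.dot(-a * lnq * c["e_a"], c["r"]))
        else:
            g[off + 1] = 2.0 * float(np.sum(c["r"]))
        if self.n_ex:
            g[off + 1 + self.n_bg:] = self._extras_grad_fd(z, c)
        return c["f"], g

    def _extras_grad_fd(self, z, c):
        """Central finite differences on the structure-factor scalars.

        Only S(q) is re-evaluated; the contraction P is reused, so the
        cost is O(n_q) per variable.
        """
        p_raw = self.g @ c["w_list"][0] if self.k == 1 else None
        if p_raw is None:
            p_raw = forward.contract(self.g, c["w_list"], 1)
        out = np.empty(2)
        for i, x in enumerate(c["extras"]):
            h = 1e-6 * max(abs(x), 1e-3)
            ex_p, ex_m = list(c["extras"]), list(c["extras"])
            ex_p[i] = x + h
            ex_m[i] = x - h
            s_p = self._structure_s(ex_p)
            s_m = self._structure_s(ex_m)
            dpred = c["xi"] * p_raw * (s_p - s_m) / (2.0 * h)
            out[i] = 2.0 * float(np.dot(dpred, c["r"]))
        return out

    def hess(self, z):
        """Exact dense Hessian in slack space (structure extras excluded)."""
        c = self._ensure(z)
        u, r, xi = self.u, c["r"], c["xi"]
        n_w = sum(self.n_k)
        n_nat = n_w + 1 + self.n_bg
        h_w = np.zeros((n_nat, n_nat))
        offs = np.concatenate([[0], np.cumsum(self.n_k)]).astype(int)
        i_xi = n_w
        # derivative columns of the model wrt natural variables
        cols = {}
        for k in range(self.k):
            cols[k] = xi * c["gt"][k]  # (nq, n_k)
        p_col = c["p"]
        # w-w blocks
        for k in range(self.k):
            a, b = offs[k], offs[k + 1]
            h_w[a:b, a:b] = 2.0 * (cols[k].T * u) @ cols[k]
            for m2 in range(k + 1, self.k):
                a2, b2 = offs[m2], offs[m2 + 1]
                blk = 2.0 * (cols[k].T * u) @ cols[m2]
                # residual term: second derivative of I wrt w^k, w^m,
                # from the residual-weighted parameter tensor
                t_r = self._residual_tensor(c)
                w_other = {j: c["w_list"][j] for j in range(self.k)
                           if j not in (k, m2)}
                g_km = _contract_axes(t_r, 0, w_other)
                blk += 2.0 * xi * g_km
                h_w[a:b, a2:b2] = blk
                h_w[a2:b2, a:b] = blk.T
        # w-xi and w-bg
        for k in range(self.k):
            a, b = offs[k], offs[k + 1]
            h_w[a:b, i_xi] = 2.0 * (cols[k].T @ (u * p_col)) + 2.0 * (c["gt"][k].T @ r)
            h_w[i_xi, a:b] = h_w[a:b, i_xi]
        h_w[i_xi, i_xi] = 2.0 * float(np.dot(p_col, u * p_col))
        if self.bg_kind == "power_law":
            a_c, b_c = c["bg_vars"]
            lnq = np.log(np.abs(self.qmag))
            e_a = c["e_a"]
            e_b = -a_c * lnq * e_a
            i_a, i_b = i_xi + 1, i_xi + 2
            for k in range(self.k):
                a, b = offs[k], offs[k + 1]
                h_w[a:b, i_a] = 2.0 * (cols[k].T @ (u * e_a))
                h_w[i_a, a:b] = h_w[a:b, i_a]
                h_w[a:b, i_b] = 2.0 * (cols[k].T @ (u * e_b))
                h_w[i_b, a:b] = h_w[a:b, i_b]
            h_w[i_xi, i_a] = h_w[i_a, i_xi] = 2.0 * float(np.dot(p_col, u * e_a))
            h_w[i_xi, i_b] = h_w[i_b, i_xi] = 2.0 * float(np.dot(p_col, u * e_b))
            h_w[i_a, i_a] = 2.0 * float(np.dot(e_a, u * e_a))
            h_ab = 2.0 * float(np.dot(e_a, u * e_b)) + 2.0 * float(np.dot(r, -lnq * e_a))
            h_w[i_a, i_b] = h_w[i_b, i_a] = h_ab
            h_w[i_b, i_b] = (2.0 * float(np.dot(e_b, u * e_b))
                             + 2.0 * float(np.dot(r, a_c * lnq**2 * e_a)))
        else:
            i_b0 = i_xi + 1
            for k in range(self.k):
                a, b = offs[k], offs[k + 1]
                h_w[a:b, i_b0] = 2.0 * (cols[k].T @ u)
                h_w[i_b0, a:b] = h_w[a:b, i_b0]
            h_w[i_xi, i_b0] = h_w[i_b0, i_xi] = 2.0 * float(np.dot(p_col, u))
            h_w[i_b0, i_b0] = 2.0 * float(np.sum(u))
        # slack-space transform: dw/ds = 2s on the weight part
        dvec = np.ones(n_nat)
        if self.k:
            dvec[:n_w] = 2.0 * np.concatenate(c["s_list"])
        h_z = h_w * np.outer(dvec, dvec)
        # + diagonal term 2 * g_w from d²w/ds²
        diag_extra = np.zeros(n_nat)
        for k in range(self.k):
            a, b = offs[k], offs[k + 1]
            diag_extra[a:b] = 2.0 * (2.0 * xi * (c["gt"][k].T @ r))
        h_z[np.diag_indices(n_nat)] += diag_extra
        if self.n_ex:  # pad (finite-difference extras handled by BFGS instead)
            h = np.zeros((self.n_var, self.n_var))
            h[:n_nat, :n_nat] = h_z
            return h
        return h_z

    def _residual_tensor(self, c):
        """Residual-weighted parameter tensor Σ_i r_i G_i… (cached).

        One pass over the full tensor yields every pairwise residual
        Hessian term by cheap low-rank contractions afterwards.
        """
        if "t_r" not in c:
            g2 = c["g_eff"].reshape(c["g_eff"].shape[0], -1)
            c["t_r"] = (c["r"] @ g2).reshape(c["g_eff"].shape[1:])
        return c["t_r"]


# ----------------------------------------------------------------------
# solver
# ----------------------------------------------------------------------

def _init_scalars(p, mu, u, nonneg_xi_floor=1e-8):
    """Weighted 2-variable least squares of μ against (P, 1)."""
    a11 = float(np.dot(p, u * p))
    a12 = float(np.dot(p, u))
    a22 = float(np.sum(u))
    b1 = float(np.dot(p, u * mu))
    b2 = float(np.dot(u, mu))
    det = a11 * a22 - a12 * a12
    if det <= 0:
        xi, b = 1.0, 0.0
    else:
        xi = (b1 * a22 - b2 * a12) / det
        b = (a11 * b2 - a12 * b1) / det
    xi = max(xi, nonneg_xi_floor)
    return xi, b


def _refit_scalars(p, bg_basis, mu, u):
    """Exact linear refit of (ξ, b) for a flat background; returns (ξ, b)."""
    return _init_scalars(p, mu, u, nonneg_xi_floor=0.0)


def _nonneg_min_change(a, bcol, y, v0, b0, max_sweeps=60, f_target=1e-28):
    """Minimum-change non-negative refinement of a linear model.

    Solves min ‖a v + bcol·b − y‖² over v ≥ 0 and free scalar b,
    starting from (v0, b0) and moving by the smallest correction at each
    step, so components of v invisible to the data are left untouched
    (this preserves the implicit regularization of the optimization
    path).  Active sets are handled Lawson–Hanson style: a partial step
    to the first blocking non-negativity bound pins that bin at zero,
    and a pinned bin whose dual gradient turns favourable is released
    through an exact one-dimensional coordinate step.

    Each subproblem is solved on the row-equilibrated whitened system
    (the rows span many decades because of the 1/σ weighting; a global
    SVD cutoff on the raw system would discard the small rows as noise).
    If plain minimum-norm sweeps stall above ``f_target``, the solver
    escalates to a truncated-SVD rank scan, accepting the lowest-rank
    (smallest-correction) candidate that sufficiently reduces the
    residual.
    """
    n = v0.size
    v = np.clip(np.asarray(v0, dtype=float), 0.0, None)
    b = float(b0)
    free = v > 0
    if not free.any():
        free = np.ones(n, dtype=bool)

    def resid(v_, b_):
        return a @ v_ + bcol * b_ - y

    def try_step(dz, free_idx):
        """Full or partial (blocking-bound) step along dz; returns
        (chi2, v, b, newly-pinned indices or None)."""
        v_new = v.copy()
        v_new[free_idx] = v[free_idx] + dz[:-1]
        b_new = b + float(dz[-1])
        neg = v_new[free_idx] < 0.0
        if not neg.any():
            return (float(np.sum(resid(v_new, b_new) ** 2)), v_new, b_new, None)
        dv = v_new[free_idx] - v[free_idx]
        ratios = v[free_idx][neg] / -dv[neg]
        alpha = float(np.min(ratios))
        v_t = v.copy()
        v_t[free_idx] = np.clip(v[free_idx] + alpha * dv, 0.0, None)
        b_t = b + alpha * float(dz[-1])
        jblk = free_idx[neg][ratios <= alpha * (1.0 + 1e-10)]
        v_t[jblk] = 0.0
        return (float(np.sum(resid(v_t, b_t) ** 2)), v_t, b_t, jblk)

    def try_release():
        """Exact coordinate step into the most promising pinned bin."""
        nonlocal v, f, free
        pinned = ~free
        if not pinned.any():
            return False
        r0 = resid(v, b)
        grad = 2.0 * (a[:, pinned].T @ r0)
        j_rel = int(np.argmin(grad))
        if grad[j_rel] >= -1e-10 * max(1.0, np.sqrt(f)):
            return False
        j = np.where(pinned)[0][j_rel]
        denom = float(a[:, j] @ a[:, j])
        step = -float(a[:, j] @ r0) / denom if denom > 0 else 0.0
        if step <= 0:
            return False
        v_try = v.copy()
        v_try[j] = step
        f_try = float(np.sum(resid(v_try, b) ** 2))
        if f_try >= f:
            return False
        v, f = v_try, f_try
        free[j] = True
        return True

    f = float(np.sum(resid(v, b) ** 2))
    escalated = False
    for _sweep in range(max_sweeps + 2 * n):
        if f < f_target or not free.any():
            break
        free_idx = np.where(free)[0]
        cols = np.hstack([a[:, free], bcol[:, None]])
        rn = np.linalg.norm(cols, axis=1)
        rn[rn == 0] = 1.0
        rhs = -resid(v, b) / rn
        if not escalated:
            dz, *_ = np.linalg.lstsq(cols / rn[:, None], rhs, rcond=None)
            cand = try_step(dz, free_idx)
        else:
            u_m, s_v, vt_m = np.linalg.svd(cols / rn[:, None], full_matrices=False)
            coef = u_m.T @ rhs
            nsv = int((s_v > s_v[0] * 1e-17).sum()) if s_v[0] > 0 else 0
            if nsv == 0:
                break
            ranks = sorted(set(np.clip(
                np.geomspace(1, nsv, 20).astype(int), 1, nsv)))
            cand = None
            for k in ranks:
                dz = vt_m[:k].T @ (coef[:k] / s_v[:k])
                c_k = try_step(dz, free_idx)
                if cand is None or c_k[0] < cand[0]:
                    cand = c_k
                if c_k[0] <= 0.2 * f or c_k[0] < f_target:
                    cand = c_k
                    break
        if cand[0] < f:
            f, v, b, jblk = cand
            if jblk is not None and jblk.size:
                free[jblk] = False
            continue
        if try_release():
            continue
        if not escalated:
            escalated = True
            continue
        break
    return v, b, f


def _linear_block_refine(g_eff, mu, sig, qmag, w_list, xi, bg_vars, bg_kind,
                         update=None, max_cycles=4, max_sweeps=60,
                         f_target=1e-20):
    """Exact conditionally-linear refinement of the MLE, one parameter block
    at a time.

    The forward map is linear in v = ξ·w^k once the other distributions
    are fixed, so the optimal (v, background scalar) is a convex
    non-negative least-squares problem.  It is solved by minimum-change
    corrections from the current iterate (projected onto the data-fitting
    manifold) with active-set pinning of negative bins; the whitened
    system is row-equilibrated before each solve, which keeps the
    correction accurate despite the ~10-decade dynamic range of 1/σ.
    Minimum-change steps preserve the implicit regularization of the
    optimization path: components invisible to the data are not moved.

    ``g_eff`` is the (scaled) Green tensor flattened over q with any
    structure factor already folded in; the power-law exponent B is held
    fixed (only the linear coefficient A is refined).  Returns updated
    (w_list, xi, bg_vars, chi2).
    """
    su = 1.0 / sig
    n_params = len(w_list)
    w_list = [np.asarray(w, dtype=float).copy() for w in w_list]
    bg_vars = np.asarray(bg_vars, dtype=float).copy()
    if update is None:
        update = [True] * n_params
    bcol = su * (np.abs(qmag) ** (-bg_vars[1]) if bg_kind == "power_law"
                 else np.ones_like(mu))
    y = su * mu

    def chi2_now():
        p = forward.contract(g_eff, w_list, 1)
        return float(np.sum((su * (xi * p) + bcol * bg_vars[0] - y) ** 2))

    f = chi2_now()
    for _cycle in range(max_cycles):
        f_start = f
        for k in range(n_params):
            if not update[k]:
                continue
            gt = forward.partial_contract(g_eff, w_list, 1, k)  # (nq, n_k)
            v, bsc, f = _nonneg_min_change(su[:, None] * gt, bcol, y,
                                           xi * w_list[k], float(bg_vars[0]),
                                           max_sweeps, f_target)
            xi_new = float(v.sum())
            if xi_new > 0.0:
                xi = xi_new
                w_list[k] = v / xi_new
            else:
                xi = 0.0
            bg_vars[0] = bsc
            if f < f_target:
                break
        if f >= f_start * (1.0 - 1e-9) or f < f_target:
            break
    return w_list, xi, bg_vars, f


def solve(g: GreenTensor, data: IntensityData, opts: SolverOptions | None = None,
          init: DistributionSet | None = None,
          structure: StructureFactor | None = None) -> SolutionState:
    """Maximum-likelihood inversion of ``data`` under the model ``g``.

    Returns a feasible MLE with the χ² recomputed independently from the
    returned state.  ξ and the background scalars are unconstrained
    during optimization (negativity is not observed in practice since it
    can only worsen the fit); each weight vector is constrained to the
    probability simplex through the slack reformulation.
    """
    opts = opts or SolverOptions()
    if g.q_grid.shape != data.q.shape or any(
            a.shape != b.shape or not np.allclose(a, b)
            for a, b in zip(g.q_grid.axes, data.q.axes)):
        raise ShapeError("Green tensor and data are not on the same q grid")

    # 2-D preparatory solve on a decimated image: a cheap low-resolution
    # inversion provides the initial guess for the full-resolution one
    stride = opts.prep_decimate
    if stride is None:
        stride = 4 if (g.m == 2 and g.n_params > 1 and init is None
                       and min(g.q_grid.shape) >= 16) else 0
    if stride and g.m == 2 and init is None:
        g_dec = g.copy_with(
            data=g.data[::stride, ::stride],
            q_grid=QGrid((g.q_grid.axes[0][::stride], g.q_grid.axes[1][::stride])))
        data_dec = IntensityData(
            q=g_dec.q_grid, mean=data.mean[::stride, ::stride],
            std=data.std[::stride, ::stride])
        prep_opts = replace(opts, prep_decimate=0,
                            max_iter=max(opts.max_iter, 1500))
        init = solve(g_dec, data_dec, prep_opts, structure=structure).mle

    g_s, data_s, scale = autoscale(g, data)
    bg_kind = init.background.kind if init is not None else "flat"
    names = [pg.name for pg in g.param_grids]
    n_params = g.n_params

    m = g.m
    mu = data_s.mean.ravel()
    sig = data_s.std.ravel()
    qmag = data_s.q.magnitude().ravel()
    g_flat = g_s.data.reshape((mu.size,) + g.param_shape)

    # initial state
    if init is not None:
        w_init = [np.asarray(w, dtype=float).copy() for w in init.weights]
    else:
        w_init = [np.full(n, 1.0 / n) for n in g.param_shape]

    frozen = {nm: False for nm in names}
    frozen_w = {}
    active = list(range(n_params))
    trace = {"chi2": [], "l1": [], "niter": 0, "stages": 0}
    structure_now = replace(structure) if structure is not None else None

    def s_folded(gf):
        """Fold the current structure factor into a q-flattened tensor."""
        if structure_now is None:
            return gf
        s_q = hard_sphere_structure(np.abs(qmag), structure_now.r_eff,
                                    structure_now.v_f)
        return gf * s_q.reshape((-1,) + (1,) * (gf.ndim - 1))

    xi_cur = None
    bg_cur = None
    converged = False
    message = ""

    # conditionally-linear presolve: for a single distribution the MLE
    # subproblem in v = ξ·w is convex, so solve it exactly up front; the
    # trust-region stage then starts at (or very near) the optimum
    if opts.presolve and n_params == 1:
        p0 = s_folded(g_flat) @ w_init[0]
        xi0, b0 = _init_scalars(p0, mu, 1.0 / sig**2)
        if init is not None and init.xi > 0:
            xi0 = init.xi * scale.c_g / scale.c_i
        bg0 = np.array([b0]) if bg_kind == "flat" else np.array(
            [init.background.A / scale.c_i if init is not None else max(b0, 1e-8),
             init.background.B if init is not None else 0.0])
        w_init, xi_cur, bg_cur, _f = _linear_block_refine(
            s_folded(g_flat), mu, sig, qmag, w_init, xi0, bg0, bg_kind)

    simple = (n_params == 1 and bg_kind == "flat"
              and (structure is None or not structure.free))
    n_rounds = opts.rounds if opts.rounds is not None else (1 if simple else 8)
    f_round = None
    for _round in range(max(1, n_rounds)):
      while True:
        act_names = [names[k] for k in active]
        g_act = _contract_axes(g_flat, 1, {k: frozen_w[names[k]]
                                           for k in range(n_params) if frozen[names[k]]})
        prob = _Problem(g_act, m, mu, sig, qmag, bg_kind, structure_now, act_names)

        s0 = [np.sqrt(w_init[k]) for k in active]
        p0 = forward.contract(prob.g, [w_init[k] for k in active], 1) \
            if active else np.asarray(prob.g, dtype=float)
        if structure_now is not None and structure_now.free:
            s_q0 = hard_sphere_structure(np.abs(qmag), structure_now.r_eff, structure_now.v_f)
            p0 = p0 * s_q0
        if xi_cur is None:
            xi0, b0 = _init_scalars(p0, mu, 1.0 / sig**2)
            if init is not None:
                xi0 = init.xi * scale.c_g / scale.c_i if init.xi > 0 else xi0
                if bg_kind == "flat":
                    b0 = init.background.b / scale.c_i
            bg0 = np.array([b0]) if bg_kind == "flat" else np.array(
                [init.background.A / scale.c_i if init is not None else max(b0, 1e-8),
                 init.background.B if init is not None else 0.0])
        else:
            xi0, bg0 = xi_cur, bg_cur
        ex0 = np.array([1.0, 1.0]) if prob.n_ex else np.empty(0)
        z0 = prob.pack(s0, xi0, bg0, ex0)

        if not active:
            # all parameters frozen: exact scalar refit closes the solve
            if bg_kind == "flat":
                xi_cur, b_scal = _refit_scalars(p0, None, mu, 1.0 / sig**2)
                bg_cur = np.array([b_scal])
            converged = True
            message = "all parameters frozen"
            break

        use_exact = (prob.n_ex == 0 and
                     (opts.hessian == "exact" or
                      (opts.hessian == "auto" and prob.n_var <= 2000)))
        mon = _Monitor(prob, opts, trace, act_names)
        res = minimize(
            prob.fun_and_grad, z0, jac=True,
            hess=prob.hess if use_exact else BFGS(),
            method="trust-constr",
            constraints=[prob.constraint()],
            callback=mon,
            options={"maxiter": opts.max_iter, "gtol": opts.gtol,
                     "xtol": opts.xtol, "verbose": opts.verbose},
        )
        z_fin = res.x
        s_fin, xi_fin, bg_fin, ex_fin = prob.unpack(z_fin)
        for idx, k in enumerate(active):
            nrm2 = float(np.dot(s_fin[idx], s_fin[idx]))
            if nrm2 < 1e-300:
                raise DegenerateStateError("slack vector collapsed to zero")
            w_init[k] = s_fin[idx] ** 2 / nrm2
        xi_cur, bg_cur = float(xi_fin), np.asarray(bg_fin, dtype=float)
        if prob.n_ex:
            structure_now = replace(
                structure_now,
                r_eff=max(float(ex_fin[0] * prob.ex_scale[0]), 1e-6),
                v_f=float(np.clip(ex_fin[1] * prob.ex_scale[1], 0.0, 0.7399)))
        trace["stages"] += 1

        if mon.freeze_names:
            for nm in mon.freeze_names:
                frozen[nm] = True
                frozen_w[nm] = w_init[names.index(nm)]
            active = [k for k in active if not frozen[names[k]]]
            continue
        converged = bool(res.status in (1, 2) or mon.target_hit)
        message = "target chi2 reached" if mon.target_hit else res.message
        break

      # conditionally-linear block polish on the scaled problem (frozen
      # parameters stay fixed; only their companions and scalars move)
      upd = [not frozen[names[k]] for k in range(n_params)]
      if opts.polish and any(upd):
          w_init, xi_cur, bg_cur, f_new = _linear_block_refine(
              s_folded(g_flat), mu, sig, qmag, w_init, float(xi_cur), bg_cur,
              bg_kind, update=upd)
      else:
          p_now = forward.contract(s_folded(g_flat), w_init, 1)
          bg_now = (bg_cur[0] * np.abs(qmag) ** (-bg_cur[1])
                    if bg_kind == "power_law" else bg_cur[0])
          f_new = float(np.sum(((float(xi_cur) * p_now + bg_now - mu) / sig) ** 2))
      trace["chi2"].append(f_new)
      if opts.target_chi2 is not None and f_new < opts.target_chi2:
          converged = True
          message = "target chi2 reached"
          break
      if not any(upd):
          break
      if f_round is not None and f_new > 0.5 * f_round:
          break  # stagnating: further rounds will not gain much
      f_round = f_new

    # assemble the solution on the original scale
    if bg_kind == "flat":
        bg_spec = BackgroundSpec("flat", b=float(bg_cur[0]) * scale.c_i)
    else:
        bg_spec = BackgroundSpec("power_law", A=float(bg_cur[0]) * scale.c_i,
                                 B=float(bg_cur[1]))
    xi_out = max(float(xi_cur), 0.0) * scale.c_i / scale.c_g
    mle = DistributionSet(weights=[w_init[k] for k in range(n_params)],
                          xi=xi_out, background=bg_spec)

    extras = {}
    s_q_full = None
    if structure_now is not None:
        extras = {"r_eff": structure_now.r_eff, "v_f": structure_now.v_f}
        s_q_full = hard_sphere_structure(data.q, structure_now.r_eff, structure_now.v_f)

    chi2 = _recompute_chi2(g, mle, data, s_q_full)
    return SolutionState(mle=mle, chi2=chi2, trace=trace, frozen=frozen,
                         scale=scale, converged=converged, param_names=names,
                         extras=extras, message=str(message))


def _recompute_chi2(g, d, data, s_q=None):
    pred = forward.intensity(g, d, structure=s_q)
    return chi_squared(normalized_misfit(pred, data))


class _Monitor:
    """trust-constr callback: χ² trace, records, freeze decisions."""

    def __init__(self, prob, opts, trace, act_names):
        self.prob = prob
        self.opts = opts
        self.trace = trace
        self.act_names = act_names
        self.prev_record = None
        self.freeze_names = []
        self.last_z = None
        self.target_hit = False

    def _decode_ws(self, z):
        s_list, _, _, _ = self.prob.unpack(z)
        out = {}
        for nm, s in zip(self.act_names, s_list):
            nrm2 = float(np.dot(s, s))
            out[nm] = s * s / nrm2 if nrm2 > 0 else s * 0
        return out

    def __call__(self, z, state):
        self.last_z = np.array(z, copy=True)
        self.trace["chi2"].append(float(state.fun))
        self.trace["niter"] += 1
        if (self.opts.target_chi2 is not None
                and state.fun < self.opts.target_chi2
                and state.constr_violation < 1e-10):
            self.target_hit = True
            return True
        if self.opts.reduce_tol is None:
            return False
        if state.niter % self.opts.monitor_every != 0:
            return False
        record = self._decode_ws(z)
        if self.prev_record is not None:
            frozen, l1 = monitor_and_reduce(record, self.prev_record,
                                            self.opts.reduce_tol, {})
            self.trace["l1"].append(l1)
            newly = [nm for nm, fl in frozen.items() if fl]
            if newly:
                self.freeze_names = newly
                return True
        self.prev_record = record
        return False


# ----------------------------------------------------------------------
# structure-factor initialization
# ----------------------------------------------------------------------

@dataclass
class GridSearchResult:
    r_eff: float
    v_f: float
    chi2: float
    n_solves: int
    table: np.ndarray  # (n_r_eff, n_v_f) array of short-solve χ²


def grid_search_structure_init(g: GreenTensor, data: IntensityData,
                               r_eff_candidates, v_f_candidates,
                               opts: SolverOptions | None = None,
                               short_iter: int = 25) -> GridSearchResult:
    """Brute-force search over (r_eff, V_f) initial guesses.

    Runs one short solve (with the structure factor held fixed) per
    candidate pair and returns the pair with the lowest χ²; ties break
    toward the smaller volume fraction.  The full solve should then
    start from the returned pair.
    """
    r_cands = list(r_eff_candidates)
    v_cands = list(v_f_candidates)
    if not r_cands or not v_cands:
        raise DataError("candidate lists must be non-empty")
    base = opts or SolverOptions()
    short = replace(base, max_iter=short_iter, reduce_tol=None,
                    gtol=1e-10, xtol=1e-10)
    table = np.full((len(r_cands), len(v_cands)), np.inf)
    n_solves = 0
    failures = []
    best = None
    # iterate V_f in the outer loop so ties resolve toward smaller V_f
    for j, v_f in enumerate(v_cands):
        for i, r_eff in enumerate(r_cands):
            n_solves += 1
            try:
                sol = solve(g, data, short,
                            structure=StructureFactor(r_eff=r_eff, v_f=v_f, free=False))
            except Exception as exc:  # noqa: BLE001 - aggregated below
                failures.append((r_eff, v_f, repr(exc)))
                continue
            table[i, j] = sol.chi2
            if best is None or sol.chi2 < best[2]:
                best = (r_eff, v_f, sol.chi2)
    if best is None:
        raise SolverError(f"all {n_solves} candidate solves failed: {failures}")
    return GridSearchResult(r_eff=best[0], v_f=best[1], chi2=best[2],
                            n_solves=n_solves, table=table)
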
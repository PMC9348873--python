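"""Green tensors of polydispersity for sphere and cylinder geometries.

A Green tensor maps N discretized parameter distributions to an
M-dimensional scattering intensity through a multi-linear contraction.
Entries are squared scattering amplitudes evaluated on the outer product
of the q grid(s) and the parameter grids, so every entry is finite and
non-negative.  Physical and instrumental corrections (structure factor,
resolution smearing, volume weighting) act on the tensor itself, which
keeps the inverse problem strictly multi-linear.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import j1

from .exceptions import (
    ConfigurationError,
    DomainError,
    InvalidGridError,
    MemoryBudgetError,
    ShapeError,
)

__all__ = [
    "ParameterGrid",
    "QGrid",
    "GreenTensor",
    "SmearingMatrix",
    "sphere_form_green",
    "cylinder_form_green_2d",
    "hard_sphere_structure",
    "apply_structure_factor",
    "smearing_matrix",
    "apply_smearing",
    "volume_weight",
    "save_green_hdf5",
    "load_green_hdf5",
    "estimate_tensor_bytes",
]

#: arguments below this threshold are evaluated by series limits
_SMALL_ARG = 1e-4

#: default in-core memory budget for dense tensors (bytes)
DEFAULT_MEMORY_BUDGET = 4 * 1024**3


# ----------------------------------------------------------------------
# grids
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterGrid:
    """One model parameter's discretized axis.

    Parameters
    ----------
    name : str
        Label, e.g. ``"radius"``.
    values : array-like
        Strictly increasing axis values (Å for lengths, radians for
        angles).
    spacing : {"linear", "logarithmic"}
        Informational tag describing how the axis was generated.
    """

    name: str
    values: np.ndarray
    spacing: str = "linear"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InvalidGridError(
                f"parameter grid '{self.name}' must be a 1-D axis of length >= 2"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidGridError(f"parameter grid '{self.name}' has non-finite values")
        if np.any(np.diff(values) <= 0):
            raise InvalidGridError(f"parameter grid '{self.name}' must be strictly increasing")
        if self.spacing not in ("linear", "logarithmic"):
            raise InvalidGridError(f"unknown spacing '{self.spacing}'")

    @property
    def n(self) -> int:
        return self.values.size

    def require_positive(self) -> "ParameterGrid":
        """Raise unless every value is > 0 (lengths, radii)."""
        if self.values[0] <= 0:
            raise InvalidGridError(f"parameter grid '{self.name}' must be strictly positive")
        return self

    @staticmethod
    def from_spec(name: str, vmin: float, vmax: float, n: int,
                  spacing: str = "linear") -> "ParameterGrid":
        """Build a grid from (min, max, n, spacing) as used in config files."""
        if spacing == "linear":
            values = np.linspace(vmin, vmax, n)
        elif spacing == "logarithmic":
            if vmin <= 0:
                raise InvalidGridError("logarithmic spacing requires min > 0")
            values = np.logspace(np.log10(vmin), np.log10(vmax), n)
        else:
            raise InvalidGridError(f"unknown spacing '{spacing}'")
        return ParameterGrid(name, values, spacing)


@dataclass(frozen=True)
class QGrid:
    """Scattering-vector grid: one axis (1-D curve) or two (2-D image)."""

    axes: tuple

    def __post_init__(self):
        axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        object.__setattr__(self, "axes", axes)
        if len(axes) not in (1, 2):
            raise InvalidGridError("QGrid supports 1 or 2 axes")
        for a in axes:
            if a.ndim != 1 or a.size < 1:
                raise InvalidGridError("each q axis must be a non-empty 1-D array")
            if not np.all(np.isfinite(a)):
                raise InvalidGridError("q axis has non-finite values")
            if a.size > 1 and np.any(np.diff(a) <= 0):
                raise InvalidGridError("q axes must be strictly increasing")

    @property
    def m(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple:
        return tuple(a.size for a in self.axes)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def magnitude(self) -> np.ndarray:
        """|q| on the full grid (rank-M array)."""
        if self.m == 1:
            return np.abs(self.axes[0])
        qx, qy = np.meshgrid(self.axes[0], self.axes[1], indexing="ij")
        return np.hypot(qx, qy)


@dataclass
class GreenTensor:
    """Rank-(M+N) squared-amplitude tensor over q grids x parameter grids."""

    data: np.ndarray
    q_grid: QGrid
    param_grids: list
    contrast: float = 1.0
    volumes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        expected = self.q_grid.shape + tuple(g.n for g in self.param_grids)
        if self.data.shape != expected:
            raise ShapeError(
                f"Green tensor shape {self.data.shape} does not match grids {expected}"
            )
        if self.volumes is not None:
            self.volumes = np.asarray(self.volumes, dtype=float)

    @property
    def m(self) -> int:
        return self.q_grid.m

    @property
    def n_params(self) -> int:
        return len(self.param_grids)

    @property
    def param_shape(self) -> tuple:
        return tuple(g.n for g in self.param_grids)

    def copy_with(self, **kwargs) -> "GreenTensor":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SmearingMatrix:
    """Row-stochastic resolution operator on a 1-D q axis."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ShapeError("smearing matrix must be square")
        if np.any(w < 0):
            raise ShapeError("smearing matrix must be non-negative")
        rows = w.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ShapeError("smearing matrix rows must sum to 1 within 1e-12")


# ----------------------------------------------------------------------
# kernels
# ----------------------------------------------------------------------

def sphere_amplitude_factor(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude 3(sin x - x cos x)/x^3, with the
    removable singularity at x = 0 evaluated by its series."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SMALL_ARG
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def _sinc_half(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with series limit at 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SMALL_ARG
    xs = x[small]
    out[small] = 1.0 - xs**2 / 6.0 + xs**4 / 120.0
    xl = x[~small]
    out[~small] = np.sin(xl) / xl
    return out


def _bessel_factor(x: np.ndarray) -> np.ndarray:
    """2 J1(x)/x with series limit at 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SMALL_ARG
    xs = x[small]
    out[small] = 1.0 - xs**2 / 8.0 + xs**4 / 192.0
    xl = x[~small]
    out[~small] = 2.0 * j1(xl) / xl
    return out


def sphere_form_green(q: QGrid, r: ParameterGrid, contrast: float = 1.0) -> GreenTensor:
    """Dilute polydisperse-sphere Green tensor.

    G_ij = v_j^2 (Δρ)^2 Φ^2(q_i r_j) with Φ(x) = 3(sin x - x cos x)/x^3
    and v_j = (4/3)π r_j^3.
    """
    if q.m != 1:
        raise InvalidGridError("sphere_form_green requires a 1-D q grid")
    qv = q.axes[0]
    if qv[0] <= 0:
        raise InvalidGridError("q values must be strictly positive")
    r.require_positive()
    rv = r.values
    volumes = 4.0 / 3.0 * np.pi * rv**3
    phi = sphere_amplitude_factor(np.outer(qv, rv))
    data = (volumes**2 * contrast**2) * phi**2
    return GreenTensor(
        data=data, q_grid=q, param_grids=[r], contrast=contrast, volumes=volumes,
        meta={"model": "sphere", "corrections": []},
    )


def _cylinder_angle_factors(qx, qy, theta, phi):
    """cos α and sin α between in-plane q and the cylinder axis.

    The cylinder axis is n = (sinθ cosϕ, sinθ sinϕ, cosθ) with the beam
    along z; θ is the angle from the beam to the axis and ϕ the rotation
    of the axis projection in the detector plane.  Returns arrays of
    shape (|qx|, |qy|, |θ|, |ϕ|) plus |q| of shape (|qx|, |qy|).
    """
    qmag = np.hypot(qx[:, None], qy[None, :])
    st = np.sin(theta)
    qdotn = (qx[:, None, None, None] * st[None, None, :, None] * np.cos(phi)[None, None, None, :]
             + qy[None, :, None, None] * st[None, None, :, None] * np.sin(phi)[None, None, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_a = np.where(qmag[..., None, None] > 0, qdotn / np.where(qmag[..., None, None] > 0, qmag[..., None, None], 1.0), 0.0)
    cos_a = np.clip(cos_a, -1.0, 1.0)
    sin_a = np.sqrt(np.clip(1.0 - cos_a**2, 0.0, 1.0))
    return cos_a, sin_a, qmag


def cylinder_form_green_2d(qx, qy, l: ParameterGrid, r: ParameterGrid,
                           theta: ParameterGrid, phi: ParameterGrid,
                           contrast: float = 1.0,
                           memory_budget: int = DEFAULT_MEMORY_BUDGET,
                           out: str | None = None) -> GreenTensor:
    """Rank-6 cylinder Green tensor over a 2-D detector grid.

    Amplitude: A = v Δρ sinc(q l cos α / 2) · 2J1(q r sin α)/(q r sin α),
    G = A², with α the angle between the in-plane scattering vector and
    the cylinder axis parametrized by (θ, ϕ); v = π r² l.  Removable
    singularities (forward scattering, α = 0 or π/2) are evaluated by
    series limits.

    When the dense tensor exceeds ``memory_budget`` an HDF5 target path
    ``out`` must be supplied; the tensor is then built and stored in
    chunks along the first q axis and a lazily-backed tensor handle is
    not returned — callers reload with :func:`load_green_hdf5` drivers.
    """
    qx = np.asarray(qx, dtype=float)
    qy = np.asarray(qy, dtype=float)
    q = QGrid((qx, qy))
    for g in (l, r):
        g.require_positive()
    for g in (theta, phi):
        if not np.all(np.isfinite(g.values)):
            raise InvalidGridError("angle grids must be finite")

    shape = (qx.size, qy.size, l.n, r.n, theta.n, phi.n)
    nbytes = estimate_tensor_bytes(shape)
    if nbytes > memory_budget:
        if out is None:
            raise MemoryBudgetError(
                f"cylinder Green tensor of shape {shape} would occupy "
                f"{nbytes / 1024**3:.1f} GB, exceeding the {memory_budget / 1024**3:.1f} GB "
                "budget; pass an HDF5 'out' path for the chunked build",
                estimated_bytes=nbytes,
            )
        _cylinder_green_chunked_hdf5(out, qx, qy, l, r, theta, phi, contrast, memory_budget)
        return load_green_hdf5(out)

    data = _cylinder_green_block(qx, qy, l.values, r.values, theta.values, phi.values, contrast)
    volumes = (np.pi * r.values**2 * l.values[:, None]).reshape(l.n, r.n, 1, 1)
    return GreenTensor(
        data=data, q_grid=q, param_grids=[l, r, theta, phi], contrast=contrast,
        volumes=volumes, meta={"model": "cylinder", "corrections": []},
    )


def _cylinder_green_block(qx, qy, lv, rv, tv, pv, contrast):
    """Dense cylinder G over the given (sub-)axes; shape (qx,qy,l,r,θ,ϕ)."""
    cos_a, sin_a, qmag = _cylinder_angle_factors(qx, qy, tv, pv)
    # sinc factor: shape (qx, qy, l, θ, ϕ)
    arg_l = 0.5 * qmag[:, :, None, None, None] * lv[None, None, :, None, None] * cos_a[:, :, None, :, :]
    f_l = _sinc_half(arg_l)
    # bessel factor: shape (qx, qy, r, θ, ϕ)
    arg_r = qmag[:, :, None, None, None] * rv[None, None, :, None, None] * sin_a[:, :, None, :, :]
    f_r = _bessel_factor(arg_r)
    vol = np.pi * rv**2 * lv[:, None]  # (l, r)
    amp = (f_l[:, :, :, None, :, :] * f_r[:, :, None, :, :, :]
           * vol[None, None, :, :, None, None] * contrast)
    return amp**2


def _cylinder_green_chunked_hdf5(path, qx, qy, l, r, theta, phi, contrast, memory_budget):
    """Build the cylinder tensor slab-by-slab along qx into HDF5."""
    shape = (qx.size, qy.size, l.n, r.n, theta.n, phi.n)
    per_row = estimate_tensor_bytes(shape[1:])
    rows = max(1, int((memory_budget // 4) // max(per_row, 1)))
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("G", shape=shape, dtype="f8",
                                chunks=(min(rows, shape[0]),) + shape[1:])
        for i0 in range(0, shape[0], rows):
            i1 = min(i0 + rows, shape[0])
            dset[i0:i1] = _cylinder_green_block(
                qx[i0:i1], qy, l.values, r.values, theta.values, phi.values, contrast)
        _write_green_meta(f, QGrid((qx, qy)), [l, r, theta, phi], contrast,
                          (np.pi * r.values**2 * l.values[:, None]).reshape(l.n, r.n, 1, 1),
                          {"model": "cylinder", "corrections": []})


def estimate_tensor_bytes(shape) -> int:
    """Dense double-precision size of a tensor of the given shape."""
    return int(np.prod([int(s) for s in shape], dtype=np.int64)) * 8


# ----------------------------------------------------------------------
# structure factor
# ----------------------------------------------------------------------

def hard_sphere_structure(q: QGrid | np.ndarray, r_eff: float, v_f: float) -> np.ndarray:
    """Percus–Yevick hard-sphere structure factor S(q).

    Evaluated on |q| of the grid; returns a rank-M array.  ``v_f`` must
    lie in [0, 0.74) (close packing).  Small arguments A = 2 q r_eff use
    an eighth-order series to avoid catastrophic cancellation.
    """
    if not (0.0 <= v_f < 0.74):
        raise DomainError(f"volume fraction {v_f} outside [0, 0.74)")
    if r_eff <= 0:
        raise DomainError("effective radius must be > 0")
    if isinstance(q, QGrid):
        qmag = q.magnitude()
    else:
        qmag = np.abs(np.asarray(q, dtype=float))
    if v_f == 0.0:
        return np.ones_like(qmag)

    eta = v_f
    denom = (1.0 - eta) ** 4
    alpha = (1.0 + 2.0 * eta) ** 2 / denom
    beta = -6.0 * eta * (1.0 + 0.5 * eta) ** 2 / denom
    gamma = 0.5 * eta * alpha

    a = 2.0 * qmag * r_eff
    out = np.empty_like(a)

    small = a < 0.5
    asq = a[small] ** 2
    # series of G(A)/A (sympy-derived, stable for A < 0.5)
    g_over_a = (alpha / 3.0 + beta / 4.0 + gamma / 6.0
                + asq * (-(alpha / 30.0 + beta / 36.0 + gamma / 48.0)
                + asq * (alpha / 840.0 + beta / 960.0 + gamma / 1200.0
                + asq * (-(alpha / 45360.0 + beta / 50400.0 + gamma / 60480.0)
                + asq * (alpha / 3991680.0 + beta / 4354560.0 + gamma / 5080320.0)))))
    out[small] = 1.0 / (1.0 + 24.0 * eta * g_over_a)

    al = a[~small]
    sin_a, cos_a = np.sin(al), np.cos(al)
    g = (alpha * (sin_a - al * cos_a) / al**2
         + beta * (2.0 * al * sin_a + (2.0 - al**2) * cos_a - 2.0) / al**3
         + gamma * (-(al**4) * cos_a
                    + 4.0 * ((3.0 * al**2 - 6.0) * cos_a
                             + (al**3 - 6.0 * al) * sin_a + 6.0)) / al**5)
    out[~small] = 1.0 / (1.0 + 24.0 * eta * g / al)
    return out


def apply_structure_factor(g: GreenTensor, s: np.ndarray) -> GreenTensor:
    """Multiply G by S(q) along the q axes (the P·S factorization)."""
    s = np.asarray(s, dtype=float)
    if s.shape != g.q_grid.shape:
        raise ShapeError(f"S shape {s.shape} does not match q grid {g.q_grid.shape}")
    data = g.data * s.reshape(s.shape + (1,) * g.n_params)
    meta = dict(g.meta)
    meta["corrections"] = list(meta.get("corrections", [])) + ["structure_factor"]
    return g.copy_with(data=data, meta=meta)


# ----------------------------------------------------------------------
# resolution smearing
# ----------------------------------------------------------------------

def smearing_matrix(q: QGrid, dq: np.ndarray) -> SmearingMatrix:
    """Row-stochastic Gaussian smearing matrix on a 1-D q axis.

    Row i is a Gaussian of standard deviation dq_i centred at q_i,
    truncated at ±3 dq_i and renormalized; dq_i = 0 gives an identity
    row.
    """
    if q.m != 1:
        raise InvalidGridError("smearing is supported on 1-D q grids")
    qv = q.axes[0]
    dq = np.asarray(dq, dtype=float)
    if dq.shape != qv.shape:
        raise ShapeError(f"dq length {dq.size} does not match q length {qv.size}")
    if np.any(dq < 0):
        raise DomainError("dq must be non-negative")
    n = qv.size
    w = np.zeros((n, n))
    for i in range(n):
        if dq[i] == 0.0:
            w[i, i] = 1.0
            continue
        d = qv - qv[i]
        inside = np.abs(d) <= 3.0 * dq[i]
        row = np.zeros(n)
        row[inside] = np.exp(-0.5 * (d[inside] / dq[i]) ** 2)
        w[i] = row / row.sum()
    return SmearingMatrix(w)


def apply_smearing(g: GreenTensor, w: SmearingMatrix) -> GreenTensor:
    """Apply a smearing matrix along the (single) q axis of G."""
    if g.m != 1:
        raise InvalidGridError("apply_smearing supports M = 1 tensors")
    if w.weights.shape[0] != g.data.shape[0]:
        raise ShapeError("smearing matrix size does not match the q axis")
    data = np.tensordot(w.weights, g.data, axes=(1, 0))
    meta = dict(g.meta)
    meta["corrections"] = list(meta.get("corrections", [])) + ["smearing"]
    return g.copy_with(data=data, meta=meta)


def volume_weight(g: GreenTensor) -> GreenTensor:
    """Divide G entry-wise by the particle volume v_j.

    Inverting with the weighted tensor yields the volume-weighted
    distribution directly.
    """
    if g.volumes is None:
        raise ConfigurationError("Green tensor has no volume metadata")
    v = g.volumes
    if np.any(v <= 0):
        raise ConfigurationError("volumes must be strictly positive")
    if v.ndim != g.n_params:
        raise ShapeError("volumes rank does not match the parameter axes")
    data = g.data / v.reshape((1,) * g.m + v.shape)
    meta = dict(g.meta)
    meta["corrections"] = list(meta.get("corrections", [])) + ["volume_weight"]
    return g.copy_with(data=data, meta=meta)


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def _write_green_meta(f, q_grid, param_grids, contrast, volumes, meta):
    f.attrs["model"] = meta.get("model", "unknown")
    f.attrs["corrections"] = ",".join(meta.get("corrections", []))
    f.attrs["contrast"] = contrast
    f.attrs["m"] = q_grid.m
    for i, a in enumerate(q_grid.axes):
        f.create_dataset(f"q{i}", data=a)
    for i, g in enumerate(param_grids):
        d = f.create_dataset(f"p{i}", data=g.values)
        d.attrs["name"] = g.name
        d.attrs["spacing"] = g.spacing
    if volumes is not None:
        f.create_dataset("volumes", data=volumes)


def save_green_hdf5(g: GreenTensor, path: str, chunk_rows: int | None = None) -> None:
    """Persist a Green tensor; dataset 'G' is chunked along the first q axis."""
    with h5py.File(path, "w") as f:
        if chunk_rows is None:
            chunk_rows = max(1, min(g.data.shape[0], 64))
        f.create_dataset("G", data=g.data,
                         chunks=(chunk_rows,) + g.data.shape[1:])
        _write_green_meta(f, g.q_grid, g.param_grids, g.contrast, g.volumes, g.meta)


def load_green_hdf5(path: str) -> GreenTensor:
    """Load a Green tensor saved by :func:`save_green_hdf5` (fully in-core)."""
    with h5py.File(path, "r") as f:
        m = int(f.attrs["m"])
        q_grid = QGrid(tuple(f[f"q{i}"][()] for i in range(m)))
        param_grids = []
        i = 0
        while f"p{i}" in f:
            d = f[f"p{i}"]
            param_grids.append(ParameterGrid(str(d.attrs["name"]), d[()],
                                             str(d.attrs.get("spacing", "linear"))))
            i += 1
        volumes = f["volumes"][()] if "volumes" in f else None
        meta = {"model": str(f.attrs.get("model", "unknown")),
                "corrections": [c for c in str(f.attrs.get("corrections", "")).split(",") if c]}
        return GreenTensor(data=f["G"][()], q_grid=q_grid, param_grids=param_grids,
                           contrast=float(f.attrs.get("contrast", 1.0)),
                           volumes=volumes, meta=meta)
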
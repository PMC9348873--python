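"""Multi-linear forward map: intensity from a Green tensor and distributions.

I = ξ · Σ_{j1..jN} G_{i,j1..jN} Π_k w^k_{jk} + background(q)

The contraction is linear in each distribution separately and in ξ; the
background is added after scaling.  Chunking along the q axes is pure
plumbing and never changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ShapeError
from .greens import GreenTensor, QGrid

__all__ = [
    "BackgroundSpec",
    "DistributionSet",
    "contract",
    "partial_contract",
    "intensity",
    "power_law_background",
    "uniform_contrast_equivalence",
]

SIMPLEX_TOL = 1e-10


@dataclass
class BackgroundSpec:
    """Source background: flat level b or power law A·q^(−B)."""

    kind: str = "flat"
    b: float = 0.0
    A: float = 0.0
    B: float = 0.0

    def __post_init__(self):
        if self.kind not in ("flat", "power_law"):
            raise DomainError(f"unknown background kind '{self.kind}'")

    def evaluate(self, q: QGrid) -> np.ndarray:
        if self.kind == "flat":
            return np.full(q.shape, float(self.b))
        return power_law_background(q, self.A, self.B)


@dataclass
class DistributionSet:
    """The N parameter densities plus the scalars of the forward map.

    ``xi`` compounds contrast and volume fraction (they trade off through
    their product and are not separable in inversion).
    """

    weights: list
    xi: float = 1.0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)

    def __post_init__(self):
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        for w in self.weights:
            if w.ndim != 1:
                raise ShapeError("each weight vector must be 1-D")
            if np.any(w < -SIMPLEX_TOL):
                raise DomainError("weights must be non-negative")
            if abs(w.sum() - 1.0) > SIMPLEX_TOL:
                raise DomainError(f"weights must sum to 1 (got {w.sum()!r})")

    @property
    def n_params(self) -> int:
        return len(self.weights)


def _check_weights_match(g: GreenTensor, weights) -> None:
    if len(weights) != g.n_params:
        raise ShapeError(f"{len(weights)} weight vectors for {g.n_params} parameter axes")
    for w, pg in zip(weights, g.param_grids):
        if np.asarray(w).size != pg.n:
            raise ShapeError(f"weight length {np.asarray(w).size} != grid '{pg.name}' ({pg.n})")


def contract(data: np.ndarray, weights, m: int, chunk_size: int | None = None) -> np.ndarray:
    """Contract the trailing parameter axes of ``data`` with ``weights``.

    ``data`` has rank m + len(weights).  Contraction proceeds largest
    parameter axis first to minimize intermediates.  ``chunk_size``
    optionally splits the (flattened) q axes into blocks; the result is
    bit-wise independent of the partition.
    """
    weights = [np.asarray(w, dtype=float) for w in weights]
    if chunk_size is not None:
        q_shape = data.shape[:m]
        flat = data.reshape((int(np.prod(q_shape)),) + data.shape[m:])
        parts = [contract(flat[i:i + chunk_size], weights, 1)
                 for i in range(0, flat.shape[0], chunk_size)]
        return np.concatenate(parts).reshape(q_shape)

    out = data
    remaining = list(range(len(weights)))
    while remaining:
        k = max(remaining, key=lambda j: weights[j].size)
        axis = m + sum(1 for j in remaining if j < k)
        out = np.tensordot(out, weights[k], axes=(axis, 0))
        remaining.remove(k)
    return out


def partial_contract(data: np.ndarray, weights, m: int, skip: int) -> np.ndarray:
    """Contract all parameter axes except ``skip``; result (q..., n_skip)."""
    out = data
    remaining = [j for j in range(len(weights)) if j != skip]
    while remaining:
        k = max(remaining, key=lambda j: weights[j].size)
        axis = m + sum(1 for j in remaining if j < k) + (1 if skip < k else 0)
        out = np.tensordot(out, weights[k], axes=(axis, 0))
        remaining.remove(k)
    return out


def all_partial_contracts(data: np.ndarray, weights, m: int) -> list:
    """All N leave-one-out contractions, via prefix/suffix chains.

    Returns [G̃^1, …, G̃^N] with G̃^k of shape (q…, n_k); equivalent to
    calling :func:`partial_contract` for every k but touching the full
    tensor only twice.
    """
    n = len(weights)
    weights = [np.asarray(w, dtype=float) for w in weights]
    if n == 1:
        return [data]
    # prefix[k]: data contracted with weights 0..k-1 -> axes (q..., p_k..p_{N-1})
    prefix = data
    prefixes = [prefix]
    for k in range(n - 1):
        prefix = np.tensordot(prefix, weights[k], axes=(m, 0))
        prefixes.append(prefix)
    out = []
    for k in range(n):
        gt = prefixes[k]  # axes (q..., p_k, ..., p_{N-1})
        for j in range(n - 1, k, -1):
            gt = np.tensordot(gt, weights[j], axes=(m + 1 + (j - k - 1), 0))
        out.append(gt)
    return out


def intensity(g: GreenTensor, d: DistributionSet,
              chunk_size: int | None = None,
              structure: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the forward map on the q grid of ``g``.

    ``structure`` optionally multiplies the contracted form factor by a
    precomputed S(q) (rank-M array) before scaling by ξ.
    """
    if d.xi < 0:
        raise DomainError("xi must be non-negative")
    _check_weights_match(g, d.weights)
    p = contract(g.data, d.weights, g.m, chunk_size=chunk_size)
    if structure is not None:
        structure = np.asarray(structure, dtype=float)
        if structure.shape != p.shape:
            raise ShapeError("structure factor shape does not match the q grid")
        p = p * structure
    return d.xi * p + d.background.evaluate(g.q_grid)


def power_law_background(q: QGrid, a: float, b: float) -> np.ndarray:
    """b(q) = A·|q|^(−B); for M = 2 the background is isotropic in |q|."""
    qmag = q.magnitude()
    if b != 0.0 and np.any(qmag == 0.0):
        raise DomainError("power-law background undefined at q = 0")
    if a == 0.0:
        return np.zeros(q.shape)
    with np.errstate(divide="ignore"):
        return a * qmag ** (-b)


def uniform_contrast_equivalence(xi_a: float, w_a: np.ndarray,
                                 xi_b: float, w_b: np.ndarray):
    """Merge two same-model populations into one uniform-contrast system.

    ξ_U w_U = ξ_A w_A + ξ_B w_B with ξ_U = ξ_A + ξ_B; the merged system
    produces the same intensity (background excluded) as the sum of the
    two populations.
    """
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_a.shape != w_b.shape:
        raise ShapeError("populations must share one parameter grid")
    xi_u = xi_a + xi_b
    if xi_u == 0.0:
        return 0.0, w_a.copy()
    w_u = (xi_a * w_a + xi_b * w_b) / xi_u
    return xi_u, w_u
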
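"""Tensor-product cosine sieve basis on the unit hypercube.

The function class used by every meta-learner in this package is a truncated
tensor-product expansion: products of univariate cosine functions

    psi_0(u) = 1,   psi_j(u) = sqrt(2) * cos(j * pi * u),  j >= 1,

which form an orthonormal system in L2[0,1].  A multi-index
``(j_1, ..., j_q)`` denotes the product ``prod_k psi_{j_k}(u_k)``; the
all-zeros index is the constant function.  Basis functions are enumerated in
a deterministic order that prioritizes low-order terms (small weight
``prod_{k: j_k>0} (j_k + 1)``), keeps products of at most ``D'`` variables,
and is prefix-closed: the list of the first J functions is a prefix of the
list of the first J+1.

Covariates are mapped to the unit cube by an affine min-max rescaling whose
ranges are learned from training data; out-of-range values at prediction
time are clipped to [0, 1] to avoid extrapolated oscillation of the cosines.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SieveBasis",
    "univariate_cosine",
    "enumerate_basis",
    "learn_ranges",
    "rescale",
    "design_matrix",
    "default_basis_size",
]

_SQRT2 = np.sqrt(2.0)

#: number of basis functions used in the simulation tables, per dim(Z)
DEFAULT_J_BY_DIM = {2: 10, 5: 20, 20: 50}


def univariate_cosine(u, j: int):
    """Evaluate the j-th univariate cosine basis function on [0, 1].

    ``j=0`` is the constant function 1; ``j>=1`` is sqrt(2)*cos(j*pi*u).
    Inputs outside [0, 1] are rejected: callers must rescale first.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("univariate_cosine requires inputs in [0, 1]; rescale first")
    if j < 0:
        raise ValueError("basis degree must be a non-negative integer")
    if j == 0:
        return np.ones_like(u) if u.ndim else 1.0
    out = _SQRT2 * np.cos(j * np.pi * u)
    return out if u.ndim else float(out)


def _index_weight(idx: tuple) -> int:
    w = 1
    for j in idx:
        if j > 0:
            w *= j + 1
    return w


def _sort_key(idx: tuple):
    # weight ascending, then smaller index-sum, then earlier coordinates first
    # (descending lexicographic puts (1,0) ahead of (0,1))
    return (_index_weight(idx), sum(idx), tuple(-j for j in idx))


def _indices_up_to_weight(q: int, d_prime: int, wmax: int) -> list:
    out = [tuple([0] * q)]
    coords = range(q)
    for s in range(1, d_prime + 1):
        for support in itertools.combinations(coords, s):
            # degrees >= 1 on the support, product of (degree+1) <= wmax
            stack = [((), wmax)]
            for pos in range(s):
                new = []
                for prefix, budget in stack:
                    jmax = budget // (2 ** (s - pos - 1)) - 1
                    for j in range(1, jmax + 1):
                        new.append((prefix + (j,), budget // (j + 1)))
                stack = new
            for degrees, _ in stack:
                idx = [0] * q
                for c, j in zip(support, degrees):
                    idx[c] = j
                out.append(tuple(idx))
    return out


def enumerate_basis(q: int, D_prime: int, J: int) -> list:
    """First ``J`` multi-indices of the tensor-product cosine basis.

    Indices have at most ``D_prime`` nonzero entries and are ordered by the
    weight prod(j_k + 1) over active coordinates, with ties broken by smaller
    index-sum and then by preferring earlier coordinates.  The ordering is
    prefix-closed in ``J``.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if not 1 <= D_prime <= q:
        raise ValueError("D_prime must satisfy 1 <= D_prime <= q")
    if J < 1:
        raise ValueError("J must be >= 1")
    wmax = 4
    while True:
        cand = _indices_up_to_weight(q, D_prime, wmax)
        if len(cand) >= J:
            break
        if wmax > 2**40:
            raise ValueError(
                f"cannot enumerate {J} basis functions with q={q}, D'={D_prime}"
            )
        wmax *= 2
    cand.sort(key=_sort_key)
    return cand[:J]


def learn_ranges(Z: np.ndarray) -> np.ndarray:
    """Per-column (min, max) pairs used for min-max rescaling, shape (q, 2)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("Z must be a 2-d array")
    ranges = np.column_stack([Z.min(axis=0), Z.max(axis=0)])
    return ranges


def rescale(Z: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    """Affine min-max map of each column onto [0, 1], clipping out-of-range values.

    Degenerate columns (min == max in the training data) map to the constant
    0.5 with a warning.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    ranges = np.asarray(ranges, dtype=float)
    if Z.shape[1] != ranges.shape[0]:
        raise ValueError(
            f"Z has {Z.shape[1]} columns but ranges were learned for {ranges.shape[0]}"
        )
    lo, hi = ranges[:, 0], ranges[:, 1]
    span = hi - lo
    degenerate = span <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate column(s) (min == max); mapped to 0.5",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    U = (Z - lo) / safe
    U[:, degenerate] = 0.5
    return np.clip(U, 0.0, 1.0)


@dataclass
class SieveBasis:
    """Ordered tensor-product cosine basis with training-data ranges."""

    q: int
    D_prime: int
    J: int
    index_list: list = field(repr=False)
    ranges: np.ndarray = field(repr=False)

    @classmethod
    def from_data(cls, Z: np.ndarray, J: int | None = None, D_prime: int = 2) -> "SieveBasis":
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        q = Z.shape[1]
        d_prime = min(D_prime, q)
        if J is None:
            J = default_basis_size(q, n=Z.shape[0])
        return cls(
            q=q,
            D_prime=d_prime,
            J=J,
            index_list=enumerate_basis(q, d_prime, J),
            ranges=learn_ranges(Z),
        )

    def design(self, Z: np.ndarray) -> np.ndarray:
        """Design matrix at raw covariate values (rescaled internally)."""
        return design_matrix(rescale(Z, self.ranges), self)


def design_matrix(U: np.ndarray, basis: SieveBasis) -> np.ndarray:
    """n x J design matrix of tensor-product cosine evaluations.

    ``U`` must already be rescaled to the unit cube via ``basis.ranges``.
    Column 0 (the all-zeros index) is identically one.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[1] != basis.q:
        raise ValueError(f"expected {basis.q} columns, got {U.shape[1]}")
    if np.any(U < 0.0) or np.any(U > 1.0):
        raise ValueError("design_matrix requires inputs in [0, 1]; rescale first")
    n = U.shape[0]
    # cache univariate evaluations per (column, degree)
    max_deg = max((max(idx) for idx in basis.index_list), default=0)
    cache = np.ones((basis.q, max_deg + 1, n))
    for k in range(basis.q):
        for j in range(1, max_deg + 1):
            cache[k, j] = _SQRT2 * np.cos(j * np.pi * U[:, k])
    B = np.ones((n, basis.J))
    for col, idx in enumerate(basis.index_list):
        for k, j in enumerate(idx):
            if j > 0:
                B[:, col] *= cache[k, j]
    return B


def default_basis_size(q: int, n: int | None = None, D_prime: int = 1, C: float = 0.7937) -> int:
    """Default number of basis functions for a dim-q conditioning set.

    For q in {2, 5, 20} the defaults are the simulation-table settings
    (10, 20, 50).  Otherwise the sample-size rule
    ``round(C * q**D' * n**(1/3) * log(n)**(D'-1))`` is used (see
    :func:`ilearner.targeting.default_Jn`).
    """
    if q in DEFAULT_J_BY_DIM:
        return DEFAULT_J_BY_DIM[q]
    if n is None:
        raise ValueError(f"no table default for q={q}; provide n for the J_n rule")
    from .targeting import default_Jn

    return default_Jn(n, q, D_prime, C)
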
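"""Semi-tensor product (STP) of matrices, with a sparse canonical-vector fast path.

The semi-tensor product generalizes ordinary matrix multiplication to
arbitrarily shaped factors: for ``A`` (m x n) and ``B`` (p x q) and
``r = lcm(n, p)``,

    A |x| B := (A (x) I_{r/n}) (B (x) I_{r/p}),

where ``(x)`` is the Kronecker product.  When ``n == p`` this is the ordinary
matrix product, and the product of two column vectors stacks all pairwise
products: ``x |x| y = (x_1 y, ..., x_m y)``.  Canonical basis columns are
closed under STP, which is what makes an exponential pattern space tractable:
``d_M^i |x| d_N^j = d_{MN}^{(i-1)N + j}`` without ever touching a dense array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CanonicalVector", "kron", "stp", "stp_canonical"]


@dataclass(frozen=True)
class CanonicalVector:
    """The i-th column of the N x N identity matrix, written d_N^i.

    Indices are 1-based throughout the public interface, matching the
    standard delta notation of the algebraic state-space literature.

    Parameters
    ----------
    dim : int
        N, the length of the vector (>= 1).
    index : int
        i, the position of the single 1 entry, with 1 <= i <= N.
    """

    dim: int
    index: int

    def __post_init__(self) -> None:
        if not (isinstance(self.dim, (int, np.integer)) and self.dim >= 1):
            raise ValueError(f"dim must be a positive integer, got {self.dim!r}")
        if not (isinstance(self.index, (int, np.integer)) and 1 <= self.index <= self.dim):
            raise ValueError(
                f"index must lie in 1..{self.dim}, got {self.index!r}"
            )
        # normalize numpy integer types so equality/hash behave predictably
        object.__setattr__(self, "dim", int(self.dim))
        object.__setattr__(self, "index", int(self.index))

    def dense(self) -> np.ndarray:
        """Densify to a (dim, 1) integer column with a single 1 at ``index``."""
        v = np.zeros((self.dim, 1), dtype=np.int64)
        v[self.index - 1, 0] = 1
        return v

    @classmethod
    def from_dense(cls, v: np.ndarray) -> "CanonicalVector":
        """Recover a canonical vector from a dense one-hot column."""
        v = np.asarray(v).reshape(-1)
        nz = np.flatnonzero(v)
        if nz.size != 1 or v[nz[0]] != 1:
            raise ValueError("vector is not a canonical (one-hot) column")
        return cls(dim=v.size, index=int(nz[0]) + 1)

    def __repr__(self) -> str:  # d_32^5 style
        return f"delta_{self.dim}^{self.index}"


def _as_matrix(a) -> np.ndarray:
    """Coerce input to a 2-D array; 1-D input is treated as a column vector."""
    if isinstance(a, CanonicalVector):
        return a.dense()
    m = np.asarray(a)
    if m.ndim == 0:
        m = m.reshape(1, 1)
    elif m.ndim == 1:
        m = m.reshape(-1, 1)
    elif m.ndim != 2:
        raise ValueError(f"expected a matrix or vector, got ndim={m.ndim}")
    if not np.issubdtype(m.dtype, np.number):
        raise TypeError(f"expected numeric entries, got dtype {m.dtype}")
    return m


def kron(a, b) -> np.ndarray:
    """Kronecker product of two matrices.

    Entry formula: ``(a kron b)[(i-1)p + k, (j-1)q + l] = a[i, j] * b[k, l]``
    for ``b`` of shape (p, q) (1-based indices).
    """
    return np.kron(_as_matrix(a), _as_matrix(b))


def stp(a, b) -> np.ndarray:
    """Semi-tensor product ``A |x| B = (A (x) I_{r/n})(B (x) I_{r/p})``.

    ``r = lcm(n, p)`` with n = cols(A), p = rows(B).  Defined for all shapes;
    reduces to ``A @ B`` when n == p.  Integer inputs are multiplied in exact
    integer arithmetic (object dtype is avoided; int64 suffices for the sizes
    this package manipulates densely).
    """
    A = _as_matrix(a)
    B = _as_matrix(b)
    n = A.shape[1]
    p = B.shape[0]
    r = math.lcm(n, p)
    if np.issubdtype(A.dtype, np.integer) and np.issubdtype(B.dtype, np.integer):
        eye = np.eye
        A = A.astype(np.int64, copy=False)
        B = B.astype(np.int64, copy=False)
        left = np.kron(A, eye(r // n, dtype=np.int64))
        right = np.kron(B, eye(r // p, dtype=np.int64))
    else:
        left = np.kron(A, np.eye(r // n))
        right = np.kron(B, np.eye(r // p))
    return left @ right


def stp_canonical(u: CanonicalVector, v: CanonicalVector) -> CanonicalVector:
    """STP of two canonical vectors, computed on indices alone.

    ``d_M^i |x| d_N^j = d_{MN}^{(i-1)N + j}`` — the sparse consequence of the
    Kronecker lifting; agrees with densify -> stp -> re-sparsify.
    """
    if not isinstance(u, CanonicalVector) or not isinstance(v, CanonicalVector):
        raise TypeError("stp_canonical expects two CanonicalVector operands")
    return CanonicalVector(dim=u.dim * v.dim, index=(u.index - 1) * v.dim + v.index)
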
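"""Pattern encodings: bipolar {-1,1}^n <-> binary {0,1}^n <-> index <-> canonical vector.

A pattern over n binary neurons has four equivalent representations:

* bipolar mode  X = (l_1, ..., l_n), l_i in {-1, +1}  (active / inhibited);
* binary mode   Y = (k_1, ..., k_n), k_i = 1 iff l_i = 1;
* mode index    r in {1, ..., 2^n}, via
  r = (1-k_1) 2^(n-1) + (1-k_2) 2^(n-2) + ... + (1-k_{n-1}) 2 + (2-k_n);
* canonical vector d_{2^n}^r, the algebraic form used by the memory matrix.

Component 1 is the most significant bit: the leftmost character of a
bitstring line carries weight 2^(n-1) in the index formula.  The index chain
is exactly the semi-tensor product of the per-neuron factors
d_2^(2-k_1) |x| ... |x| d_2^(2-k_n); both routes are implemented and agree.

Indices are Python ints, so n is limited only by memory; dense test oracles
elsewhere cap themselves at small n.
"""

from __future__ import annotations

from functools import reduce

import numpy as np

from .stp import CanonicalVector, stp_canonical

__all__ = [
    "as_bipolar",
    "as_binary",
    "bipolar_to_binary",
    "binary_to_bipolar",
    "binary_to_index",
    "index_to_binary",
    "index_to_bipolar",
    "encode",
    "encode_index",
    "decode",
    "hamming",
]


def as_bipolar(x) -> np.ndarray:
    """Validate and return a bipolar mode as an int8 array of -1/+1."""
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a bipolar mode must be a non-empty 1-D sequence")
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isin(arr, (-1, 1))):
        raise ValueError(f"bipolar components must be -1 or +1, got {list(arr)!r}")
    return arr.astype(np.int8)


def as_binary(y) -> np.ndarray:
    """Validate and return a binary mode as an int8 array of 0/1."""
    arr = np.asarray(y)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a binary mode must be a non-empty 1-D sequence")
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isin(arr, (0, 1))):
        raise ValueError(f"binary components must be 0 or 1, got {list(arr)!r}")
    return arr.astype(np.int8)


def bipolar_to_binary(x) -> np.ndarray:
    """Map l_i = 1 -> k_i = 1 and l_i = -1 -> k_i = 0."""
    arr = as_bipolar(x)
    return ((arr + 1) // 2).astype(np.int8)


def binary_to_bipolar(y) -> np.ndarray:
    """Inverse of :func:`bipolar_to_binary`."""
    arr = as_binary(y)
    return (2 * arr.astype(np.int8) - 1).astype(np.int8)


def binary_to_index(y) -> int:
    """Mode index r of a binary pattern, 1-based, component 1 most significant.

    Closed form: ``r - 1 = sum_j (1 - k_j) 2^(n-j)`` — the complemented bits of
    Y read as a base-2 number.
    """
    arr = as_binary(y)
    r = 1
    for bit in arr:
        r = (r << 1) - int(bit)  # Horner form of 1 + sum_j (1-k_j) 2^(n-j)
    return int(r)


def index_to_binary(r: int, n: int) -> np.ndarray:
    """Binary pattern of length ``n`` whose mode index is ``r``."""
    if not 1 <= r <= (1 << n):
        raise ValueError(f"index {r} out of range 1..2^{n}")
    x = r - 1
    bits = [(1 - ((x >> (n - 1 - j)) & 1)) for j in range(n)]
    return np.array(bits, dtype=np.int8)


def index_to_bipolar(r: int, n: int) -> np.ndarray:
    """Bipolar pattern of length ``n`` whose mode index is ``r``."""
    return binary_to_bipolar(index_to_binary(r, n))


def encode(x) -> CanonicalVector:
    """Algebraic form d_{2^n}^r of a bipolar mode, via the STP factor chain.

    Each neuron contributes d_2^1 (active) or d_2^2 (inhibited); the chain
    d_2^(2-k_1) |x| ... |x| d_2^(2-k_n) collapses to a single canonical
    vector of dimension 2^n.
    """
    k = bipolar_to_binary(x)
    factors = [CanonicalVector(2, 2 - int(b)) for b in k]
    return reduce(stp_canonical, factors)


def encode_index(x) -> int:
    """Mode index of a bipolar mode (closed form, no STP chain)."""
    return binary_to_index(bipolar_to_binary(x))


def decode(v: CanonicalVector) -> np.ndarray:
    """Bipolar mode corresponding to a canonical vector of dimension 2^n."""
    n = v.dim.bit_length() - 1
    if 1 << n != v.dim:
        raise ValueError(f"dimension {v.dim} is not a power of two")
    return index_to_bipolar(v.index, n)


def _normalize_binary(v) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a mode must be a non-empty 1-D sequence")
    if np.all(np.isin(arr, (-1, 1))):
        return bipolar_to_binary(arr)
    return as_binary(arr)


def hamming(a, b) -> int:
    """Number of differing components between two modes of equal length.

    Accepts bipolar or binary forms (each normalized to binary first, so the
    distance is invariant under the bipolar <-> binary conversion).
    """
    ya = _normalize_binary(a)
    yb = _normalize_binary(b)
    if ya.size != yb.size:
        raise ValueError(f"length mismatch: {ya.size} vs {yb.size}")
    return int(np.count_nonzero(ya != yb))
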
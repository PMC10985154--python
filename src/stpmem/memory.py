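"""The STP associative memory: exact exponential storage with on-demand association.

The memory matrix L for stored patterns with mode indices r_1, ..., r_m is

    L = sum_k  d_{2^n}^{r_k} (d_{2^n}^{r_k})^T,

a 0/1 diagonal matrix of size 2^n x 2^n whose action on a stored pattern's
canonical vector is the identity: every stored pattern is an exact fixed
point, so capacity is 2^n by construction (contrast the ~0.15 n Hebbian
Hopfield regime).  L is never materialized: only the stored index set and a
cache of learned columns exist; the dense form is a capped test oracle.

Association is added on demand.  For a probe with index r_i not stored, the
column update computes Hamming distances s_ki from the probe to each stored
pattern and, over the stored patterns inside the bit-error-control window
0 < s_ki <= E_c, assigns inverse-distance-normalized probabilities

    l_{r_k, r_i} = (1 / s_ki) / sum_{j : 0 < s_ji <= E_c} (1 / s_ji).

Closer stored patterns are therefore more probable, equal distances tie at
equal probability, and probability x distance is constant across a column.
A probe farther than E_c from every stored pattern is rejected (and not
cached, so a later increase of E_c can reconsider it).

Probabilities are kept as exact rationals (:class:`fractions.Fraction`)
internally and serialized as "num/den" strings; floats appear only at the
reporting edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .encoding import (
    as_bipolar,
    bipolar_to_binary,
    encode_index,
    hamming,
    index_to_binary,
)

__all__ = [
    "ProbColumn",
    "RecognitionStatus",
    "RecognitionResult",
    "AssociativeMemory",
    "build_memory",
]

#: A sparse column of L: stored index -> probability.  Empty means the zero
#: column; otherwise probabilities are positive and sum to exactly 1.
ProbColumn = dict[int, Fraction]


class RecognitionStatus(str, Enum):
    RECOGNIZED_EXACT = "recognized_exact"
    CLASSIFIED_BY_ASSOCIATION = "classified_by_association"
    REJECTED = "rejected"


@dataclass(frozen=True)
class RecognitionResult:
    """Outcome of presenting one probe pattern to the memory.

    ``distribution`` maps stored indices to classification probabilities;
    it is a point mass on ``query_index`` for an exact match and empty for
    a rejected probe.
    """

    status: RecognitionStatus
    distribution: ProbColumn
    query_index: int

    def probabilities(self) -> dict[int, float]:
        """Distribution with probabilities as floats, for display."""
        return {r: float(p) for r, p in self.distribution.items()}


def _check_column(col: ProbColumn) -> None:
    if col and sum(col.values()) != 1:
        raise AssertionError("nonzero column does not sum to 1")


class AssociativeMemory:
    """Content-addressable memory over n-bit patterns with BEC association.

    Parameters
    ----------
    modes : iterable of bipolar patterns
        The patterns to store, each a length-n sequence over {-1, +1}.
        Their encoded indices must be pairwise distinct.
    bec : int
        Bit error control parameter E_c >= 0: the largest Hamming distance at
        which a non-stored probe may still be associated to stored patterns.
        0 disables association (exact recall only).

    Notes
    -----
    Learned columns are cached per (stored set, E_c); mutating either via
    :meth:`add_mode`, :meth:`remove_mode` or the ``bec`` setter clears the
    cache, because every transition probability depends on both.
    """

    def __init__(self, modes: Iterable, bec: int = 0, n: int | None = None):
        modes = [as_bipolar(m) for m in modes]
        if modes:
            n_seen = {m.size for m in modes}
            if len(n_seen) > 1:
                raise ValueError(f"patterns of mixed lengths {sorted(n_seen)}")
            inferred = n_seen.pop()
            if n is not None and n != inferred:
                raise ValueError(f"n={n} does not match pattern length {inferred}")
            n = inferred
        elif n is None:
            raise ValueError("an empty memory needs an explicit n")
        if not (isinstance(bec, (int, np.integer)) and bec >= 0):
            raise ValueError(f"bec must be a nonnegative integer, got {bec!r}")

        self._n = int(n)
        self._bec = int(bec)
        self._stored: list[int] = []
        self._learned: dict[int, ProbColumn] = {}
        for m in modes:
            self._insert(m)

    # -- construction & mutation -------------------------------------------

    def _insert(self, mode: np.ndarray) -> None:
        r = encode_index(mode)
        if r in self._stored:
            raise ValueError(
                f"duplicate pattern {list(mode)} (index {r}) already stored"
            )
        self._stored.append(r)

    @classmethod
    def from_indices(cls, n: int, indices: Iterable[int], bec: int = 0) -> "AssociativeMemory":
        """Build from 1-based mode indices instead of raw patterns."""
        from .encoding import index_to_bipolar

        return cls([index_to_bipolar(r, n) for r in indices], bec=bec, n=n)

    def add_mode(self, mode) -> int:
        """Store one more pattern; clears all learned columns."""
        self._insert(as_bipolar(mode))
        self._learned.clear()
        return self._stored[-1]

    def remove_mode(self, mode_or_index) -> None:
        """Forget a stored pattern; clears all learned columns."""
        r = (
            int(mode_or_index)
            if isinstance(mode_or_index, (int, np.integer))
            else encode_index(mode_or_index)
        )
        try:
            self._stored.remove(r)
        except ValueError:
            raise KeyError(f"index {r} is not stored") from None
        self._learned.clear()

    # -- basic properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return self._n

    @property
    def m(self) -> int:
        """Number of stored patterns."""
        return len(self._stored)

    @property
    def stored(self) -> tuple[int, ...]:
        """Stored mode indices, in insertion order (k = 1..m)."""
        return tuple(self._stored)

    @property
    def learned(self) -> Mapping[int, ProbColumn]:
        """Read-only view of the learned-column cache."""
        return dict(self._learned)

    @property
    def bec(self) -> int:
        return self._bec

    @bec.setter
    def bec(self, value: int) -> None:
        if not (isinstance(value, (int, np.integer)) and value >= 0):
            raise ValueError(f"bec must be a nonnegative integer, got {value!r}")
        if int(value) != self._bec:
            self._bec = int(value)
            self._learned.clear()

    def __repr__(self) -> str:
        return (
            f"AssociativeMemory(n={self._n}, m={self.m}, bec={self._bec}, "
            f"learned={len(self._learned)})"
        )

    # -- columns of L -------------------------------------------------------

    def column(self, r: int) -> ProbColumn:
        """Conceptual column r of L, computed lazily.

        A stored index yields a point mass on itself (the exact-recall fixed
        point); a previously learned index yields its cached distribution;
        anything else is the zero column.
        """
        if not 1 <= r <= (1 << self._n):
            raise ValueError(f"index {r} out of range 1..2^{self._n}")
        r = int(r)
        if r in self._stored:
            return {r: Fraction(1)}
        return dict(self._learned.get(r, {}))

    def update_column(self, r_i: int) -> ProbColumn:
        """Learn column r_i by the inverse-distance rule; cache if nonzero.

        Only stored patterns with 0 < s_ki <= E_c participate.  An exact
        match (s = 0) cannot occur here because stored indices short-circuit
        in :meth:`column`; the guard is kept defensively.
        """
        if not 1 <= r_i <= (1 << self._n):
            raise ValueError(f"index {r_i} out of range 1..2^{self._n}")
        r_i = int(r_i)
        if r_i in self._stored:
            raise ValueError(
                f"index {r_i} is stored; exact recognition applies, not learning"
            )
        probe = index_to_binary(r_i, self._n)
        weights: dict[int, Fraction] = {}
        for r_k in self._stored:
            s = hamming(probe, index_to_binary(r_k, self._n))
            if 0 < s <= self._bec:
                weights[r_k] = Fraction(1, s)
        if not weights:
            return {}
        z = sum(weights.values())
        col = {r_k: w / z for r_k, w in weights.items()}
        _check_column(col)
        self._learned[r_i] = col
        return dict(col)

    def distances(self, mode) -> list[int]:
        """Hamming distances from a probe to each stored pattern, in order."""
        probe = bipolar_to_binary(mode)
        return [hamming(probe, index_to_binary(r, self._n)) for r in self._stored]

    # -- recognition --------------------------------------------------------

    def recognize(self, mode) -> RecognitionResult:
        """Present one bipolar probe: exact recall, association, or rejection.

        The procedure encodes the probe, reads its column of L, and — only if
        that column is zero — learns it via :meth:`update_column` before
        reading again.  A still-zero column means the probe is farther than
        E_c from every stored pattern and does not belong to any of them.
        """
        x = as_bipolar(mode)
        if x.size != self._n:
            raise ValueError(f"probe length {x.size} != memory n {self._n}")
        r_i = encode_index(x)
        col = self.column(r_i)
        if col:
            status = (
                RecognitionStatus.RECOGNIZED_EXACT
                if r_i in self._stored
                else RecognitionStatus.CLASSIFIED_BY_ASSOCIATION
            )
            return RecognitionResult(status, col, r_i)
        col = self.update_column(r_i)
        if col:
            return RecognitionResult(
                RecognitionStatus.CLASSIFIED_BY_ASSOCIATION, col, r_i
            )
        return RecognitionResult(RecognitionStatus.REJECTED, {}, r_i)

    def classify_sample(self, result: RecognitionResult, seed: int) -> int:
        """Draw one hard assignment from a recognition distribution.

        Deterministic given ``seed``; a point mass returns its index for any
        seed.  Rejected results carry no distribution and raise.
        """
        if result.status is RecognitionStatus.REJECTED:
            raise ValueError("cannot sample a hard assignment for a rejected probe")
        indices = list(result.distribution)
        probs = [float(p) for p in result.distribution.values()]
        rng = np.random.default_rng(seed)
        return int(rng.choice(indices, p=np.asarray(probs) / np.sum(probs)))

    def learn_all(self, cap: int = 16) -> dict[int, ProbColumn]:
        """Recognize every mode in {1..2^n}; return the full column map.

        Stored indices map to their point masses, associable indices to their
        learned distributions, unreachable indices to empty columns.  Guarded
        by ``cap`` because the sweep is exponential in n; prefer lazy
        per-query use above it.
        """
        if self._n > cap:
            raise ValueError(
                f"n={self._n} exceeds learn_all cap {cap}; "
                "query columns lazily instead"
            )
        out: dict[int, ProbColumn] = {}
        for r in range(1, (1 << self._n) + 1):
            col = self.column(r)
            if not col and r not in self._stored:
                col = self.update_column(r)
            out[r] = col
        return out

    # -- dense oracle -------------------------------------------------------

    def dense_matrix(self, cap: int = 8) -> np.ndarray:
        """Materialize L as a 2^n x 2^n float array (test oracle; n <= cap).

        Before any column update this is a 0/1 matrix supported on the
        diagonal at the stored indices.
        """
        if self._n > cap:
            raise ValueError(f"n={self._n} exceeds dense cap {cap}")
        size = 1 << self._n
        L = np.zeros((size, size))
        for r in range(1, size + 1):
            for r_k, p in self.column(r).items():
                L[r_k - 1, r - 1] = float(p)
        return L

    # -- serialization ------------------------------------------------------

    def to_json(self, indent: int | None = 2) -> str:
        """Serialize to JSON: stored order, E_c, and exact learned columns."""
        doc = {
            "n": self._n,
            "bec": self._bec,
            "stored": list(self._stored),
            "learned": {
                str(r): {str(k): f"{p.numerator}/{p.denominator}" for k, p in col.items()}
                for r, col in self._learned.items()
            },
        }
        return json.dumps(doc, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "AssociativeMemory":
        doc = json.loads(text)
        mem = cls.from_indices(doc["n"], doc["stored"], bec=doc["bec"])
        for r, col in doc.get("learned", {}).items():
            parsed = {int(k): Fraction(v) for k, v in col.items()}
            _check_column(parsed)
            bad = set(parsed) - set(mem._stored)
            if bad:
                raise ValueError(f"learned column {r} references non-stored {sorted(bad)}")
            mem._learned[int(r)] = parsed
        return mem

    # -- transition graph ---------------------------------------------------

    def transition_graph(self) -> nx.DiGraph:
        """Directed graph of L's nonzero action: query index -> stored index.

        Stored indices carry self-loops of probability 1; learned columns
        contribute weighted edges.  Mirrors a state-transition diagram of L.
        """
        g = nx.DiGraph()
        for r in self._stored:
            g.add_node(r, stored=True)
            g.add_edge(r, r, probability=1.0, rational="1")
        for r_i, col in self._learned.items():
            g.add_node(r_i, stored=False)
            for r_k, p in col.items():
                g.add_edge(
                    r_i,
                    r_k,
                    probability=float(p),
                    rational=f"{p.numerator}/{p.denominator}",
                )
        return g

    def to_dot(self) -> str:
        """DOT text of :meth:`transition_graph` (stored nodes doubled)."""
        g = self.transition_graph()
        lines = ["digraph L {"]
        for node, data in sorted(g.nodes(data=True)):
            shape = "doublecircle" if data.get("stored") else "circle"
            lines.append(f'  {node} [shape={shape}];')
        for u, v, data in sorted(g.edges(data=True)):
            lines.append(f'  {u} -> {v} [label="{data["rational"]}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def edge_table(self):
        """Edge list as a DataFrame: source, target, probability, rational."""
        import pandas as pd

        g = self.transition_graph()
        rows = [
            {
                "source": u,
                "target": v,
                "probability": data["probability"],
                "rational": data["rational"],
            }
            for u, v, data in sorted(g.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "probability", "rational"])


def build_memory(modes: Iterable, bec: int = 0, n: int | None = None) -> AssociativeMemory:
    """Construct the memory matrix L from bipolar patterns (functional form)."""
    return AssociativeMemory(modes, bec=bec, n=n)
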
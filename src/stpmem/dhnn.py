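"""Classical discrete Hopfield network (DHNN) with Hebbian outer-product weights.

Serves as the capacity baseline.  Weights for m bipolar patterns X^k are

    W = alpha * sum_k (X^k (X^k)^T - I),

symmetric with zero diagonal.  Recall is the synchronous update
``X <- sgn(W X)``; a stored pattern is exactly recalled when one step maps it
to itself.  For non-orthogonal random patterns interference limits reliable
storage to roughly 0.13 n - 0.15 n patterns, which the capacity experiment
demonstrates by Monte Carlo against the STP memory's exact 2^n storage.

The sign of a zero pre-activation is a convention; the default maps 0 to -1
(the convention consistent with the worked five-node example this package
reproduces), with 0 -> +1 and 0 -> keep-previous-state available.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .encoding import as_bipolar
from .memory import AssociativeMemory, RecognitionStatus

__all__ = [
    "SgnZero",
    "hebbian_weights",
    "sgn",
    "recall_step",
    "recall",
    "capacity_experiment",
]

SgnZero = Literal["minus", "plus", "keep"]


def hebbian_weights(modes: Iterable, alpha: float = 1.0) -> np.ndarray:
    """Hebbian outer-product weight matrix W = alpha * sum_k (X^k X^k^T - I).

    Symmetric with zero diagonal since every bipolar component squares to 1.
    With alpha = 1 and integer patterns the entries stay exact integers.
    """
    modes = [as_bipolar(m) for m in modes]
    if not modes:
        raise ValueError("at least one learning mode is required")
    n = modes[0].size
    if any(m.size != n for m in modes):
        raise ValueError("learning modes have mixed lengths")
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    X = np.stack([m.astype(np.int64) for m in modes])  # (m, n)
    W = X.T @ X - len(modes) * np.eye(n, dtype=np.int64)
    return alpha * W if alpha != 1 else W


def sgn(
    v: Sequence[float],
    zero: SgnZero = "minus",
    previous: Sequence[int] | None = None,
) -> np.ndarray:
    """Component-wise sign onto {-1, +1} with an explicit zero convention.

    ``zero="minus"`` (default) maps 0 to -1, ``"plus"`` maps 0 to +1, and
    ``"keep"`` retains the corresponding component of ``previous``.
    """
    arr = np.asarray(v, dtype=float)
    out = np.where(arr > 0, 1, -1).astype(np.int8)
    zeros = arr == 0
    if zeros.any():
        if zero == "minus":
            out[zeros] = -1
        elif zero == "plus":
            out[zeros] = 1
        elif zero == "keep":
            if previous is None:
                raise ValueError('zero="keep" requires the previous state')
            out[zeros] = as_bipolar(previous)[zeros]
        else:
            raise ValueError(f"unknown zero convention {zero!r}")
    return out


def recall_step(W: np.ndarray, x, zero: SgnZero = "minus") -> np.ndarray:
    """One synchronous update sgn(W x)."""
    x = as_bipolar(x)
    W = np.asarray(W)
    if W.shape != (x.size, x.size):
        raise ValueError(f"weight shape {W.shape} does not match pattern length {x.size}")
    return sgn(W @ x.astype(W.dtype), zero=zero, previous=x)


def recall(
    W: np.ndarray, x, max_iter: int = 50, zero: SgnZero = "minus"
) -> tuple[np.ndarray, str]:
    """Iterate synchronous updates until a fixed point, a cycle, or the cap.

    Returns the last state and a flag: ``"fixed_point"`` if sgn(W x*) = x*,
    else ``"cycle_or_cap"`` (synchronous Hopfield dynamics can 2-cycle).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    state = as_bipolar(x)
    seen = {state.tobytes()}
    for _ in range(max_iter):
        nxt = recall_step(W, state, zero=zero)
        if np.array_equal(nxt, state):
            return state, "fixed_point"
        state = nxt
        key = state.tobytes()
        if key in seen:
            return state, "cycle_or_cap"
        seen.add(key)
    return state, "cycle_or_cap"


def _stp_exact_recall(mem: AssociativeMemory, probe, original_index: int) -> bool:
    """Whether the STP memory recovers the original pattern from the probe.

    Exact recognition of the original counts; so does an associated
    distribution whose unique most-probable stored index is the original.
    """
    result = mem.recognize(probe)
    if result.status is RecognitionStatus.RECOGNIZED_EXACT:
        return result.query_index == original_index
    if result.status is RecognitionStatus.REJECTED:
        return False
    best = max(result.distribution.values())
    winners = [r for r, p in result.distribution.items() if p == best]
    return winners == [original_index]


def capacity_experiment(
    n: int,
    m_values: Sequence[int],
    trials: int = 10,
    flips: int = 0,
    seed: int = 0,
    alpha: float = 1.0,
    zero: SgnZero = "minus",
) -> pd.DataFrame:
    """Monte-Carlo storage-capacity comparison: Hebbian DHNN vs STP memory.

    For each m in ``m_values`` and each trial, m distinct uniform bipolar
    patterns are stored in both models (the STP memory with E_c = ``flips``),
    then every stored pattern — corrupted by exactly ``flips`` bit flips — is
    probed.  DHNN success means one synchronous step returns the original
    pattern; STP success means the original is recovered exactly or as the
    unique most-probable association.

    Returns a tidy table with columns
    (model, n, m, flips, trials, recall_fraction, seed).
    """
    from .patterns import corrupt, generate_patterns

    if flips > n:
        raise ValueError("flips cannot exceed n")
    rows = []
    for m_i, m in enumerate(m_values):
        if m > (1 << n):
            raise ValueError(f"m={m} exceeds 2^{n} distinct patterns")
        ok = {"dhnn": 0, "stp": 0}
        total = 0
        for t in range(trials):
            # per-(m, trial) substreams: adding an m value never shifts others
            child_seeds = np.random.SeedSequence(
                entropy=seed, spawn_key=(m_i, t)
            ).generate_state(2)
            patterns = generate_patterns(n, m, seed=int(child_seeds[0]))
            W = hebbian_weights(patterns, alpha=alpha)
            mem = AssociativeMemory(patterns, bec=flips)
            flip_rng = np.random.default_rng(int(child_seeds[1]))
            for pattern, r in zip(patterns, mem.stored):
                probe = corrupt(
                    pattern, flips, seed=int(flip_rng.integers(0, 2**31))
                )
                if np.array_equal(recall_step(W, probe, zero=zero), pattern):
                    ok["dhnn"] += 1
                if _stp_exact_recall(mem, probe, r):
                    ok["stp"] += 1
                total += 1
        for model in ("dhnn", "stp"):
            rows.append(
                {
                    "model": model,
                    "n": n,
                    "m": m,
                    "flips": flips,
                    "trials": trials,
                    "recall_fraction": ok[model] / total,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
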
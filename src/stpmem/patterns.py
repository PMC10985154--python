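"""Pattern file I/O and the synthetic pattern / corruption generator.

File format: one pattern per line; blank lines and lines starting with ``#``
are ignored.  Two dialects, never mixed within a file:

* ``bitstring`` — a run of ``0``/``1`` characters (the binary form Y);
  the leftmost character is component 1, the most significant bit of the
  mode index.  ``1`` maps to +1, ``0`` to -1.
* ``signed_tokens`` — whitespace-separated ``1`` / ``-1`` tokens (the
  bipolar form X).

All patterns in a file must share one length.  Anything else is rejected
with the offending line number — never coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .encoding import as_bipolar, binary_to_bipolar, index_to_bipolar

__all__ = ["PatternFile", "read_patterns", "write_patterns", "generate_patterns", "corrupt"]

Dialect = Literal["bitstring", "signed_tokens"]


@dataclass(frozen=True)
class PatternFile:
    """Parsed pattern file: ordered bipolar patterns plus the dialect used."""

    path: str
    patterns: tuple[np.ndarray, ...]
    dialect: Dialect

    @property
    def n(self) -> int:
        return self.patterns[0].size


def _parse_line(line: str, lineno: int) -> tuple[np.ndarray, Dialect]:
    tokens = line.split()
    if len(tokens) == 1 and set(tokens[0]) <= {"0", "1"}:
        bits = np.array([int(c) for c in tokens[0]], dtype=np.int8)
        return binary_to_bipolar(bits), "bitstring"
    if all(t in ("1", "-1") for t in tokens):
        return as_bipolar([int(t) for t in tokens]), "signed_tokens"
    raise ValueError(
        f"line {lineno}: {line!r} is neither a 0/1 bitstring "
        "nor whitespace-separated 1/-1 tokens"
    )


def read_patterns(path) -> PatternFile:
    """Read a pattern file, enforcing a single dialect and a single length."""
    path = Path(path)
    patterns: list[np.ndarray] = []
    dialect: Dialect | None = None
    n: int | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        pattern, this_dialect = _parse_line(line, lineno)
        if dialect is None:
            dialect = this_dialect
        elif dialect != this_dialect:
            raise ValueError(
                f"line {lineno}: dialect {this_dialect} mixed with {dialect}"
            )
        if n is None:
            n = pattern.size
        elif pattern.size != n:
            raise ValueError(f"line {lineno}: length {pattern.size} != {n}")
        patterns.append(pattern)
    if not patterns:
        raise ValueError(f"{path}: no patterns")
    return PatternFile(path=str(path), patterns=tuple(patterns), dialect=dialect)


def write_patterns(path, patterns: Sequence, dialect: Dialect = "bitstring") -> None:
    """Write bipolar patterns in the given dialect, one per line."""
    lines = []
    for p in patterns:
        x = as_bipolar(p)
        if dialect == "bitstring":
            lines.append("".join("1" if c == 1 else "0" for c in x))
        elif dialect == "signed_tokens":
            lines.append(" ".join(str(int(c)) for c in x))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_patterns(n: int, m: int, seed: int) -> list[np.ndarray]:
    """m distinct bipolar patterns of length n, uniform over {-1,1}^n.

    Deterministic given ``seed``.  When the full space is small (or m is a
    large fraction of it) indices are sampled without replacement; otherwise
    rejection sampling of random vectors is used, which almost never rejects
    for m << 2^n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= m <= (1 << n):
        raise ValueError(f"m must lie in 0..2^{n}, got {m}")
    rng = np.random.default_rng(seed)
    space = 1 << n
    if space <= (1 << 20) and m * 4 >= space:
        indices = rng.choice(space, size=m, replace=False)
        return [index_to_bipolar(int(r) + 1, n) for r in indices]
    seen: set[bytes] = set()
    out: list[np.ndarray] = []
    while len(out) < m:
        x = (2 * rng.integers(0, 2, size=n) - 1).astype(np.int8)
        key = x.tobytes()
        if key not in seen:
            seen.add(key)
            out.append(x)
    return out


def corrupt(x, flips: int, seed: int) -> np.ndarray:
    """Flip exactly ``flips`` distinct components of a bipolar pattern.

    The result is at Hamming distance exactly ``flips`` from the input;
    deterministic given ``seed``.
    """
    x = as_bipolar(x)
    if not 0 <= flips <= x.size:
        raise ValueError(f"flips must lie in 0..{x.size}, got {flips}")
    out = x.copy()
    if flips:
        rng = np.random.default_rng(seed)
        positions = rng.choice(x.size, size=flips, replace=False)
        out[positions] = -out[positions]
    return out
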
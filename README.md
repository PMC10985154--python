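# stpmem

Associative memory on the semi-tensor product (STP) of matrices, for people
studying content-addressable storage in binary attractor networks — plus a
classical Hebbian discrete Hopfield network (DHNN) as the capacity baseline.

## The problem and the model

A Hopfield network with `n` binary neurons stores patterns as attractors of
`X <- sgn(W X)` with Hebbian weights `W = α Σ_k (X^k (X^k)ᵀ − I)`. For
non-orthogonal random patterns this works only up to roughly `0.13 n – 0.15 n`
stored patterns; past that, recall errors and spurious attractors appear —
even a stored pattern may fail to be a fixed point.

`stpmem` implements an alternative that trades the `n × n` weight matrix for
a sparse view of a `2^n × 2^n` one. Each bipolar pattern
`X ∈ {−1, 1}^n` is converted to its binary form `Y ∈ {0, 1}^n` and lifted to
a canonical basis vector `δ_{2^n}^r` (the r-th column of the identity),
where

    r = (1 − k_1) 2^(n−1) + (1 − k_2) 2^(n−2) + ⋯ + (1 − k_{n−1}) 2 + (2 − k_n),

equivalently the STP chain `δ_2^(2−k_1) ⋉ ⋯ ⋉ δ_2^(2−k_n)`. The memory
matrix is

    L = Σ_k δ_{2^n}^{r_k} (δ_{2^n}^{r_k})ᵀ,

a 0/1 diagonal matrix satisfying `L δ_{2^n}^{r_i} = δ_{2^n}^{r_i}` for every
stored index: all lifted patterns are mutually orthogonal, so **every**
pattern — up to all `2^n` of them — is an exact fixed point.

Robustness to bit errors is added on demand. When a probe with index `r_i`
is not stored, its column of `L` is learned from the Hamming distances
`s_ki` to the stored patterns, inside a bit-error-control window `E_c`:

    l_{r_k, r_i} = (1 / s_ki) / Σ_{j : 0 < s_ji ≤ E_c} (1 / s_ji),

an inverse-distance probability distribution over the nearby stored
patterns (closer ⇒ more probable; equal distance ⇒ equal probability). A
probe farther than `E_c` from everything is rejected. `L` is never
materialized: only the stored index set and the learned columns exist.

## Worked example

Store the four 5-neuron patterns `11011, 10100, 01101, 00011` (bitstring
dialect: leftmost character is component 1; `1 → +1`, `0 → −1`):

```
$ stpmem encode modes.txt
Y1 = (1,1,0,1,1)^T = 11011 ~ delta_32^5
Y2 = (1,0,1,0,0)^T = 10100 ~ delta_32^12
Y3 = (0,1,1,0,1)^T = 01101 ~ delta_32^19
Y4 = (0,0,0,1,1)^T = 00011 ~ delta_32^29

$ stpmem memorize modes.txt --bec 2 -o memory.json
$ stpmem recognize memory.json 01011
{
  "query_index": 21,
  "status": "classified_by_association",
  "distribution": {
    "5":  {"probability": 0.4, "rational": "2/5"},
    "19": {"probability": 0.2, "rational": "1/5"},
    "29": {"probability": 0.4, "rational": "2/5"}
  }
}
```

The probe `01011` is pattern `11011` with its first bit flipped; its index
is 21 and it is not stored. Its Hamming distances to the four stored
patterns are (1, 5, 2, 1); with `E_c = 2` the distance-5 pattern is outside
the window and the rest receive inverse-distance probabilities 2/5, 1/5 and
2/5 — the probe is most likely a corrupted `11011` or `00011`, and half as
likely a corrupted `01101`. The same patterns defeat the Hebbian baseline
even uncorrupted:

```
$ stpmem dhnn modes.txt
W =
  0 0 0 0 -2
  0 0 0 0 2
  0 0 0 -4 -2
  0 0 -4 0 2
  -2 2 -2 2 0
sgn(W X1) = (-1,1,-1,1,1)^T != X1
sgn(W X2) = (1,-1,1,-1,-1)^T = X2 (recalled)
sgn(W X3) = (-1,1,1,-1,-1)^T != X3
sgn(W X4) = (-1,1,-1,1,1)^T != X4
single-step exact recall: 1/4
```

Only one of the four stored patterns is a fixed point of the DHNN, while
the STP memory recalls all four exactly (and, by construction, would recall
all 32). `stpmem transitions` exports the learned state-transition graph as
TSV or DOT, and `stpmem simulate` runs a seeded Monte-Carlo capacity
comparison of the two models.

The same functionality is available as a library:

```python
from stpmem import AssociativeMemory

mem = AssociativeMemory([[1, 1, -1, 1, 1], [1, -1, 1, -1, -1],
                         [-1, 1, 1, -1, 1], [-1, -1, -1, 1, 1]], bec=2)
result = mem.recognize([-1, 1, -1, 1, 1])
result.probabilities()   # {5: 0.4, 19: 0.2, 29: 0.4}
```

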
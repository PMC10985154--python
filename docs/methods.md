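# Methods

## Model

`stpmem` implements two associative memories over bipolar patterns
`X ∈ {−1, 1}^n` and compares them.

**STP memory.** Every pattern is lifted to a canonical basis vector
`δ_{2^n}^r` of the `2^n`-dimensional space via the semi-tensor product (STP)
chain of per-neuron factors: an active neuron contributes `δ_2^1`, an
inhibited one `δ_2^2`, and `δ_M^i ⋉ δ_N^j = δ_{MN}^{(i−1)N + j}`. Component 1
of the pattern is the most significant bit of the resulting index (the
leftmost character of a bitstring line). Because the lifted patterns are
orthonormal, the memory matrix `L = Σ_k δ^{r_k} (δ^{r_k})ᵀ` is a 0/1
diagonal projection and every stored pattern is an exact fixed point of
`v ↦ L v`; capacity is `2^n` by construction. The price is the exponential
index space, which is why `L` exists only as (a) the ordered stored index
set and (b) a cache of learned columns; a dense `2^n × 2^n` array is built
solely as a test oracle, capped at `n ≤ 8`.

**Association (bit error control).** A probe whose index is not stored is
associated to stored patterns by an inverse-Hamming-distance rule over the
window `0 < s ≤ E_c`: probability proportional to `1/s`, normalized over the
eligible stored patterns. Consequences used as test invariants: a nonzero
learned column sums to exactly 1; probability × distance is constant within
a column; strictly closer patterns get strictly larger probability; ties in
distance get equal probability with no tie-break needed. `E_c` is in bits
(0 ≤ E_c ≤ n); `E_c = 0` disables association entirely. Large `E_c` spreads
probability over many stored patterns — the model then deliberately returns
the full distribution and leaves hard assignment to seeded sampling
(`classify_sample`), rather than inventing a resolution rule.

**Recognition procedure.** Encode the probe; read its column of `L`. A
nonzero column classifies immediately (a point mass on itself for a stored
pattern, the cached distribution for a previously learned probe). A zero
column triggers the column update; if the updated column is still zero the
probe is rejected as belonging to no stored pattern. Rejected probes are
*not* cached, so raising `E_c` later can reconsider them. Learned columns
are valid only for one (stored set, `E_c`) pair: adding or removing a
pattern, or changing `E_c`, clears the cache. Learned columns are never
treated as stored patterns for subsequent queries.

**Hebbian DHNN baseline.** Weights `W = α Σ_k (X^k (X^k)ᵀ − I)` (symmetric,
zero diagonal; `α > 0`, default 1, a pure scale that cannot change recall).
Recall is one synchronous pass `sgn(W X)` by default, matching the worked
five-node example's arithmetic; iterated recall (`recall`) runs to a fixed
point or reports `cycle_or_cap`, since synchronous symmetric dynamics can
2-cycle. The sign of a zero pre-activation is a convention: the default maps
0 → −1, which is the convention consistent with the worked example's
`sgn(W X³)` case; 0 → +1 and 0 → keep-previous are opt-in.

## Numerical choices

- Probabilities are exact `fractions.Fraction` values internally; column
  normalization and the invariants above therefore hold exactly, not to a
  tolerance. Floats appear only in reporting (12 significant digits in CLI
  JSON, alongside the exact `"num/den"` form).
- Mode indices are 1-based Python ints (arbitrary precision), so `n` is
  bounded only by memory for index arithmetic; dense oracles cap at
  `n ≤ 8`, the exhaustive `learn_all` sweep at `n ≤ 16` by default.
- Dense STP uses exact int64 arithmetic when both operands are integer,
  floats otherwise; STP is total (any shapes), computed via Kronecker
  lifting to `r = lcm(cols_A, rows_B)`.
- Pattern inputs are validated strictly: components outside `{−1, 1}` /
  `{0, 1}`, mixed lengths, mixed file dialects and illegal characters are
  rejected with the offending line number, never coerced.

## Synthetic data

`generate_patterns(n, m, seed)` draws `m` distinct patterns uniformly from
`{−1, 1}^n` (index sampling without replacement when the space is small,
rejection sampling otherwise); `corrupt(x, flips, seed)` flips exactly
`flips` distinct positions, so the probe sits at a known Hamming distance.
This emulates independent uniform patterns under symmetric bit-flip noise —
the standard setting for Hopfield capacity analysis. It does **not** emulate
correlated or structured patterns (e.g., visual scenes), asymmetric noise,
or analog corruption; passing capacity tests therefore demonstrate the
storage/association mechanics, not performance on structured real data,
where pattern similarity is exactly what makes the Hebbian baseline fail
earlier and makes the choice of `E_c` delicate.

## Capacity experiment

`capacity_experiment(n, m_values, trials, flips, seed)` stores the same
random pattern sets in both models and probes each stored pattern corrupted
by `flips` bit flips (the STP memory runs with `E_c = flips`). "Exact
recall" means: for the DHNN, one synchronous step returns the original
pattern; for the STP memory, the original is recognized exactly or is the
unique most-probable entry of the association distribution. Per-(m, trial)
random substreams are derived from the one seed via `SeedSequence` spawn
keys, so extending `m_values` never shifts existing rows. The shipped tests
run `n = 32`, `m ∈ {2, 3, 5, 8, 12, 16, 20}`, 5 trials, `flips = 0` — small
enough to run in seconds, large enough that the Hebbian recall fraction
visibly degrades past a handful of patterns while the STP fraction stays at
exactly 1; the acceptance checks assert that trend, not a literature point
value. The full-capacity demonstration stores all `2^10` patterns at
`n = 10` and recalls each exactly.

## Known limitations

- No iterated attractor dynamics on `L` (it is applied once per query); no
  energy-function analysis; no asynchronous DHNN updates; no learning of
  `E_c` from data.
- The inverse-distance rule is the only association law implemented; it is
  scale-free in `s` and ignores pattern structure beyond Hamming distance.
- Exhaustive operations (`learn_all`, dense oracles) are exponential in `n`
  and guarded by explicit caps; the lazy per-query path has no such limit.
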
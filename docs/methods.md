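# Methods

## Setting and threat model

Three computing parties run the protocol: proxies P0 and P1 hold 2-out-of-2
additive shares of every private value, and a helper P2 deals correlated
randomness and computes on masked values. All parties are assumed
semi-honest (they follow the protocol but may try to infer secrets from
their view). Security degrades to nothing if two parties collude; that is
inherent to 2-out-of-2 sharing and out of scope here. The external users —
a model owner and a sequence owner — only ever upload shares and download
prediction shares.

## Number system

Private arithmetic happens in `Z_L` with `L = 2^n` (default `n = 64`), with
the companion ring `K = 2^(n-1)` used by share conversion and the small
prime field `Z_67` carrying per-bit shares for private comparison (67 > n
is needed so sums of bit indicators never wrap). Reals are embedded in
two's-complement fixed point with `f = 20` fractional bits:
`raw = round(x * 2^f) mod L`, representable range `|x| < 2^(n-1-f)`.
Encoding rounds half away from zero; a round trip is exact to `2^-21`.
`n ∈ {8, 16, 32, 64}` is configurable so that every protocol can be tested
*exhaustively* on the 8-bit ring; nothing in the code depends on n = 64.

## Building blocks

* **ADD** — local share addition, no communication.
* **MUL / MP** — Beaver-triple multiplication (the helper deals shares of
  `(a, b, ab)` per batch; the proxies open `x - a` and `y - b`). The matrix
  version uses one matrix triple and accumulates exactly in the ring,
  truncating once per output entry.
* **PC (private compare)** — given per-bit `Z_67` shares of `x` and a public
  `r`, the proxies emit per-position masked values whose reconstruction
  contains a zero exactly when `x > r` (prefix sums of bit differences,
  most-significant bit first), blind them with common random non-zero
  scalars and a common per-row permutation, and the helper reports whether a
  zero occurs — XOR-masked by a common random bit, so the helper learns
  nothing about the outcome. The all-ones corner case plants a deterministic
  zero because `x > r` is then impossible.
* **MOC (modulus conversion)** — converts shares over `Z_K` to fresh shares
  of the same value over `Z_L`. The helper deals shares of a random `r ∈ Z_K`,
  Boolean shares of the wrap of its own share-sum, and bit shares of `r`;
  the proxies open `y = (x + r) mod K`, learn Boolean shares of the wrap of
  `x + r` from `PC(r > y)`, lift `y` and `r` to `Z_L` by conditional
  additions of `K`, and unmask. Exhaustive at n = 8 over every secret.
* **MSB** — the low `n-1` bits are split off share-locally (`x mod K`),
  lifted back via MOC and subtracted, leaving `z = x - (x mod K) ∈ {0, K}`;
  P0 sends the two candidates `z_0`, `z_0 + K` in tape-randomized order,
  the helper divides the two openings by `K` and returns fresh bit shares of
  both, and the proxies select using the common order bit.
* **CMP** — `x > y` as `MSB(y - x)` on fixed-point values.
* **MUX** — oblivious selection `z = x - b(x - y)` with a raw (unscaled)
  selector bit. The two cross-share products are outsourced through a
  randomized encoding: with tape randoms `r0..r3`, P0 sends
  `M2 = ⟨b⟩0 + r0`, `M3 = (⟨x⟩0 - ⟨y⟩0) + r3`, P1 sends
  `M5 = (⟨x⟩1 - ⟨y⟩1) + r1`, `M6 = ⟨b⟩1 + r2`; the helper returns fresh
  shares of `M2·M5 + M3·M6`, and each proxy cancels the tape cross-terms
  locally. Because the selector is a raw bit, MUX needs no truncation.
* **EXP** — exact exponential of a public base `b` to a shared fixed-point
  power, square-and-multiply style: one MSB reads the sign; one vectorized
  MUX selects between `{x, Cp}` and `{-x, Cn}`, where `Cp[j] = b^(2^(j-f))`
  and `Cn[j] = b^(-2^(j-f))` are the per-bit contribution tables (held in
  plaintext by P0, zeros by P1 — a valid sharing); one vectorized MSB over
  left-shifted copies of the magnitude exposes each covered bit; one
  vectorized MUX picks contribution-or-1 per bit; and a binary-tree product
  over the table padded to a power of two costs `log2(table size)` MUL
  calls. For base e at n=64/f=20 the table covers bit weights `2^-20..2^4`
  (25 entries, padded to 32, hence 5 MUL levels): window `|x| < 32`, with
  positive powers additionally bounded by `ln(2^(n-3-2f)) ≈ 14.5` so tree
  partials respect the truncation headroom. The caller must guarantee the
  window (it cannot be checked privately); the RKN circuit validates
  `2*alpha` against it at model load since its powers lie in `[-2α, 0]`.

### Truncation

Every fixed-point product carries `2f` fractional bits and must shed `f`
(fused affine chains shed `2f` at once). We use a helper-dealt masked
opening: the helper shares a random `r` uniform on `[0, 2^(n-2))` together
with `r >> s`; the proxies open `v + Δ + r` with `Δ = 2^(n-2)`, which never
wraps while the signed pre-shift value satisfies `|v| < 2^(n-2)`, then
shift the public sum and unmask. The result is `floor(v / 2^s)` plus a
stochastic-rounding term in `{0, 1}` ulp whose expectation makes the
estimate exactly unbiased. Two properties drove this choice over the
common local-shift trick (each proxy shifting its own share): the local
trick fails catastrophically (error `~2^(n-s)`) with probability
`~2^(ℓ+1-n)` per element for `ℓ`-bit values — at the `~10^7` truncations of
one inference study that is a handful of gross errors per run — and its
`+0.5` ulp bias compounds through the RKN recurrence. The cost is one
extra masked opening revealed between the proxies per truncation batch;
the opened value is statistically masked with ratio `|v|_max / 2^(n-2)`,
which should be kept in mind when the pre-shift magnitude approaches the
contract bound. The helper sees nothing new.

## The RKN circuit

Anchors are flattened to a `(k·q) × |Σ|` matrix so each position costs one
MP for all anchor dot products. The affine step `alpha * (dot - 1)` is
local (public scalars stay plaintext at the proxies) and fused with the
matrix product's truncation into a single `2f`-bit shed, one vectorized
EXP produces `b`, one batched MUL forms `b ⊙ c_shifted`, and the decay
term `lambda * c` is again local and fused into a single `f`-bit shed per
position. Positions are strictly serial (the recurrence demands it); all
per-position work is batched over `(j, i)`. The epilogue is one MP with
`G`, one dot product with `w`, a local bias addition and one final
truncation. Consequently: EXP invocations = `|x|`, and per-position
communication volume is linear in `k·q` — the transcript byte counts are
the portable proxy this package reports for the wall-clock linearity of
the service in `q`, `k` and `|x|`.

## Synthetic study conditions

The generator draws anchor characters i.i.d. normal and normalizes each
column (so similarities satisfy `0 < b ≤ 1` and EXP powers lie in
`[-2α, 0]`), uses `alpha = 0.6` and `lambda = 0.5` by default, classifier
`w, β ~ N(0, 1)`, and uniform i.i.d. sequences over the 20-letter
alphabet — fixed length 128 for the scaling study, lengths 30–200 for the
correctness study. `G` is the inverse square root of the Gram matrix of
flattened anchors via eigendecomposition with *spectral truncation*:
eigendirections below `10^-6` contribute zero (pseudo-inverse convention).
Clamping instead of truncating would put `~10^3`-scale entries into `G`
whenever the anchors span fewer than `q` dimensions (e.g. q=128, k=2 ⇒
rank ≤ 40) and amplify both predictions and fixed-point noise by three
orders of magnitude. What the generator does *not* emulate: trained
(non-random) anchors and classifiers, residue composition bias, homology
structure, or class labels — so passing correctness tests here says the
arithmetic is faithful, not that the scores are biologically meaningful.

The correctness study (also `scripts/acceptance.py`) runs 50 pairs over
q ∈ {8, 32, 128} × k ∈ {2, 5, 10} and reports the maximum
|private − plaintext| prediction difference. These problem sizes keep the
full study at a few minutes on one CPU while covering the production model
scale (q=128, k=10).

## Accuracy model and a known limitation

Three error sources separate the private prediction from the
double-precision oracle, all tied to `f = 20`:

1. **Parameter quantization.** Shared tensors are encoded to `2^-21` per
   entry before sharing. Through `⟨w, G c_k⟩` this contributes roughly
   `||c||·2^-21·||w||`-scale error — of order `10^-5`–`10^-4` at q=128 —
   and it grows like the prediction magnitude itself. It is present even
   if every secure operation were exact.
2. **Contribution-table quantization.** Rounding `b^(±2^(j-f))` to fixed
   point biases each similarity by about half an ulp low (for small-weight
   entries the `+ε²/2` term of `e^-ε` falls below the rounding grid);
   the recurrence accumulates this into a few tens of ulps on `c_k`.
3. **Stochastic rounding noise.** Each truncation adds a zero-mean
   sub-ulp term; variance, not bias, accumulates.

Net effect: `|private − plaintext| ≈ |prediction| × 1e-5` on this
generator. Synthetic models with `w ~ N(0,1)` at q=128 score tens of
units, so the study's maximum deviation lands in the `10^-4` range —
whereas a trained fold classifier scoring `O(1)` sits comfortably below
`2·10^-5`. The absolute-deviation figure must therefore be read against
the prediction scale of the model under test; raising `f` (trading
dynamic range) tightens all three sources proportionally.

## Numerical and design choices

* Encode rounding is half-away-from-zero; any consistent rule works.
* Bit order in bitwise shares is most-significant first everywhere.
* Selector bits (MSB/CMP outputs, MUX selectors) are raw ring bits, never
  fixed-point scaled — MUX therefore needs no truncation.
* Beaver triples and truncation pairs are dealt by the helper per batch,
  which matches its role of supplying correlated randomness; triple
  generation ahead of time would change latency, not correctness.
* The binary-tree product pads with encoded 1s; multiplying by an exactly
  encoded 1 is exact (the low `f` bits of the product are zero), so
  padding adds no error.
* The helper's fresh-share randomness comes from its own seeded generator,
  independent of the proxies' common tape; a run is fully reproducible
  from the four seeds (common, P0, P1, helper) plus the owners' seeds.
* Message framing is a 4-byte little-endian length prefix; share arrays
  travel as little-endian 64-bit words, bit/Boolean shares as single
  bytes. In-process and socket transports produce byte-identical
  per-channel streams for equal seeds (global interleaving is
  scheduler-dependent and not part of the contract).
* Degenerate inputs: empty sequences are rejected; unknown residues are
  rejected by default or mapped to an all-zero row on request (such a row
  scores `exp(-alpha)` against every anchor); sequences shorter than `k`
  are legal in the recurrence (the mapping simply stays 0 at unreachable
  levels) but the generator refuses to produce them.

## Known limitations

* Inference only — no training or fine-tuning; `G` is computed in
  plaintext by the model owner.
* Semi-honest, honest-majority security only; no malicious-adversary
  checks, no TLS on the socket transport.
* The truncation opening weakens the "only Beaver openings travel between
  proxies" property to a statistically-masked one (see above).
* The EXP window is asymmetric (negative powers to −32, positive to
  ~14.5 for base e); the secret-shared-base variant is not implemented.
* Wall-clock time is not asserted anywhere; invocation and byte counts
  are the portable scalability metric.
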
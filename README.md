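# rknmpc — privacy-preserving protein fold recognition

Protein fold recognition asks whether a query sequence adopts a known
structural fold. Recurrent kernel networks (RKNs) answer it by scoring the
sequence against `q` learned anchor motifs of length `k`: position `t` of the
one-hot encoded sequence `x` is compared to character `j` of every anchor
through

    b_j[t][i] = exp(alpha * (<z_{j,.,i}, x_t> - 1)),

the substring-kernel recurrence

    c_j[t] = lambda * c_j[t-1] + b_j[t] ⊙ c_{j-1}[t-1],        c_0 ≡ 1,

embeds the sequence as `c_k[|x|]`, and a projection by the inverse square root
`G` of the anchor Gram matrix followed by a linear classifier `⟨w, G c_k⟩ + β`
yields the fold score.

Sending a patient-derived sequence to a cloud scorer in plaintext leaks
sensitive information, and shipping the trained model to clients leaks the
model. `rknmpc` runs the whole forward pass as a three-party secure
computation: the sequence owner and the model owner each split their data into
2-out-of-2 additive fixed-point shares (64-bit ring, 20 fractional bits) for
two proxies, a helper party deals correlated randomness, and the proxies
finish holding only shares of the prediction. It is aimed at practitioners of
privacy-preserving genomic/proteomic analysis who want a working, tested MPC
stack with a real sequence model on top.

The package provides:

* `rknmpc.ring` — configurable fixed-point rings (n ∈ {8,16,32,64}) and all
  sharing/reconstruction primitives, including per-bit shares over Z_67.
* `rknmpc.runtime` — three-party sessions over an in-process simulator or TCP
  sockets, common random tapes, per-protocol transcript accounting.
* `rknmpc.protocols` — the building blocks: Beaver multiplication and matrix
  products with fused truncation, private compare, modulus conversion
  (Z_K → Z_L), most-significant-bit, comparison, a randomized-encoding
  multiplexer, and an exact exponential of a public base to a shared power.
* `rknmpc.rkn` — the double-precision plaintext RKN (the correctness oracle
  and a standalone scorer), FASTA input, a plain-text model container.
* `rknmpc.private` — outsourcing and the private inference circuit.
* `rknmpc.datagen` / `rknmpc.evaluate` — synthetic models/sequences, the
  scaling report and the private-vs-plaintext correctness study.

## Worked example

```python
import numpy as np
from rknmpc import (GeneratorConfig, generate_model, generate_sequences,
                    SessionConfig, infer_private, forward, one_hot_encode,
                    count_invocations)

cfg = GeneratorConfig(q=8, k=3, length=40, n_sequences=1, seed=11)
model = generate_model(cfg)              # random RKN: unit-norm anchors,
(_, seq), = generate_sequences(cfg)      # alpha=0.6, lambda=0.5, w ~ N(0,1)

session_cfg = SessionConfig(common_seed=1, p0_seed=2, p1_seed=3, helper_seed=4)
private_pred, session = infer_private(model, seq, session_cfg, owner_seed=5)
plain_pred, _ = forward(model, one_hot_encode(seq))

print(f"private   : {private_pred:.6f}")
print(f"plaintext : {plain_pred:.6f}")
print(f"|diff|    : {abs(private_pred - plain_pred):.2e}")
print(f"EXP calls : {count_invocations(session.transcript, 'EXP')}")
```

prints

```
private   : -3.407807
plaintext : -3.407819
|diff|    : 1.19e-05
EXP calls : 40
```

The two scores agree to about a dozen fixed-point units in the last place
(2⁻²⁰ ≈ 9.5·10⁻⁷); one vectorized secure exponential is spent per sequence
position, matching the circuit structure. The same flow is available from the
shell (`rknmpc gen model`, `rknmpc outsource-model`, `rknmpc infer`,
`rknmpc verify`, `rknmpc run-party --role p0 --config cfg.yaml` for a real
TCP deployment).

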
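"""Machine-learning-as-a-service flow: outsourcing and private inference.

The model owner and the data owner each split their inputs into additive
fixed-point shares and hand one share to each proxy; the proxies then run
the RKN circuit position by position with the MPC building blocks (matrix
products for the anchor dot products, one vectorized exponential per
position, one batched multiplication per recurrence step) and end up with
shares of the prediction, which only the data owner can reconstruct.

Public scalars (the similarity scale alpha, the decay lambda, the
exponential base) stay plaintext at the proxies; multiplying by them and
subtracting public constants are local share operations, fused so that
each affine chain costs a single truncation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import protocols
from .ring import RingSpec, decode_fixed, encode_fixed, share_additive
from .rkn import ALPHABET, RKNModel, one_hot_encode
from .runtime import Party, Session, SessionConfig

__all__ = [
    "SharedModel",
    "SharedSequence",
    "outsource_model",
    "outsource_sequence",
    "private_forward",
    "reconstruct_prediction",
    "infer_private",
    "save_shares",
    "load_shares",
]


@dataclass
class SharedModel:
    """One proxy's share of an outsourced RKN model.

    Tensor shares are fixed-point encodings over Z_L; the public scalars
    ride along in plaintext.  ``Zmat`` holds the anchor tensor flattened
    to (k*q, |alphabet|) with row ``j*q + i`` = character j of anchor i,
    ready for the per-position matrix product.
    """

    Zmat: np.ndarray
    G: np.ndarray
    w: np.ndarray
    beta: np.ndarray  # shape-(1,1) share
    alpha: float
    lam: float
    k: int
    q: int
    alphabet: str = ALPHABET


@dataclass
class SharedSequence:
    """One proxy's share of a one-hot encoded, fixed-point sequence."""

    onehot: np.ndarray  # (|x|, |alphabet|) shares over Z_L

    @property
    def length(self) -> int:
        return self.onehot.shape[0]


def outsource_model(model: RKNModel, spec: RingSpec,
                    rng: np.random.Generator) -> tuple[SharedModel, SharedModel]:
    """Secret-share a model's tensors; alpha/lambda stay public."""
    model.validate()
    k, q = model.k, model.q
    zmat = np.transpose(model.Z, (0, 2, 1)).reshape(k * q, len(model.alphabet))
    pieces = {
        "Zmat": share_additive(encode_fixed(zmat, spec), spec, rng),
        "G": share_additive(encode_fixed(model.G, spec), spec, rng),
        "w": share_additive(encode_fixed(model.w[None, :], spec), spec, rng),
        "beta": share_additive(encode_fixed(np.array([[model.beta]]), spec), spec, rng),
    }
    out = []
    for i in (0, 1):
        out.append(SharedModel(
            Zmat=pieces["Zmat"][i], G=pieces["G"][i], w=pieces["w"][i],
            beta=pieces["beta"][i], alpha=model.alpha, lam=model.lam,
            k=k, q=q, alphabet=model.alphabet,
        ))
    return out[0], out[1]


def outsource_sequence(sequence: str, spec: RingSpec, rng: np.random.Generator,
                       alphabet: str = ALPHABET,
                       unknown: str = "error") -> tuple[SharedSequence, SharedSequence]:
    """One-hot encode a sequence and secret-share the encoding."""
    onehot = one_hot_encode(sequence, alphabet, unknown=unknown)
    s0, s1 = share_additive(encode_fixed(onehot, spec), spec, rng)
    return SharedSequence(s0), SharedSequence(s1)


def _check_window(spec: RingSpec, alpha: float, table: protocols.ExpTable) -> None:
    # the EXP power alpha*(dot-1) lies in [-2*alpha, 0] by unit-norm anchors
    if 2.0 * alpha >= table.window(spec.f):
        raise ValueError(
            f"similarity scale alpha={alpha} exceeds the exponential "
            f"coverage window |x| < {table.window(spec.f):g}"
        )


def private_forward(party: Party, sm: SharedModel, ss: SharedSequence,
                    base: float = float(np.e),
                    table: protocols.ExpTable | None = None) -> np.ndarray:
    """The Fig.-style RKN circuit on shares; returns this proxy's
    prediction share (a 0-d uint64 array, fixed-point scale f).

    Per position t: one matrix product for all k*q anchor dot products,
    local affine adjustment (subtract 1, scale by alpha) fused into a
    single 2f-bit truncation, one vectorized EXP, one batched share
    multiplication for ``b * c_shifted``, local lambda-scaling and a
    single f-bit truncation for the recurrence update.  Sequence
    positions are strictly serial; all per-position work is batched.
    """
    sp = party.spec
    if table is None:
        table = protocols.contribution_table(base, sp)
    _check_window(sp, sm.alpha, table)
    k, q = sm.k, sm.q
    f = sp.f
    alpha_raw = int(encode_fixed(sm.alpha, sp))
    lam_raw = int(encode_fixed(sm.lam, sp))
    one_2f = np.uint64(1) << np.uint64(2 * f)

    # c rows: level 0 is the all-ones boundary (public), levels 1..k start 0
    c = np.zeros((k + 1, q), dtype=np.uint64)
    c[0, :] = protocols.share_public(party, np.full(q, int(encode_fixed(1.0, sp)), dtype=np.uint64), sp)

    for t in range(ss.length):
        x_t = ss.onehot[t][:, None]  # (|alphabet|, 1)
        dots2 = protocols.matmul(party, sm.Zmat, x_t, shift=0)  # scale 2f
        u2 = dots2
        if party.pid == 0:
            u2 = sp.sub(u2, one_2f)
        v3 = sp.mul(u2, np.uint64(alpha_raw))  # scale 3f
        power = protocols.truncate(party, v3, shift=2 * f).ravel()  # scale f
        b = protocols.exp(party, power, table=table)  # (k*q,)

        prev = c[:-1, :].reshape(k * q)
        prod2 = protocols.mul(party, b, prev, truncate_result=False)  # scale 2f
        lam2 = sp.mul(c[1:, :], np.uint64(lam_raw))  # scale 2f
        upd = sp.add(prod2.reshape(k, q), lam2)
        c = c.copy()
        c[1:, :] = protocols.truncate(party, upd, shift=f)

    psi = protocols.matmul(party, sm.G, c[k][:, None], shift=None)  # scale f
    pred2 = protocols.matmul(party, sm.w, psi, shift=0)  # scale 2f
    pred2 = sp.add(pred2, sp.mul(sm.beta, np.uint64(1) << np.uint64(f)))
    pred = protocols.truncate(party, pred2, shift=f)
    return pred.reshape(())


def reconstruct_prediction(s0, s1, spec: RingSpec) -> float:
    """Combine the two proxies' prediction shares into the plaintext score."""
    return float(decode_fixed(spec.add(s0, s1), spec))


def infer_private(model: RKNModel, sequence: str, config: SessionConfig,
                  owner_seed: int = 1234) -> tuple[float, Session]:
    """Convenience wrapper: outsource, run one session, reconstruct.

    Returns (prediction, closed session with transcript).  The
    outsourcing randomness is the owners' own and is seeded separately
    from the computing parties.
    """
    spec = config.spec
    rng = np.random.Generator(np.random.Philox(owner_seed))
    sm0, sm1 = outsource_model(model, spec, rng)
    ss0, ss1 = outsource_sequence(sequence, spec, rng, alphabet=model.alphabet)
    shares = {0: (sm0, ss0), 1: (sm1, ss1)}
    base = config.exp_base

    def circuit(party: Party):
        sm, ss = shares[party.pid]
        return private_forward(party, sm, ss, base=base)

    session = Session(config)
    out0, out1 = session.run(circuit)
    return reconstruct_prediction(out0, out1, spec), session


# --------------------------------------------------------------------------
# share-file serialization: versioned, little-endian 64-bit words


_MAGIC = "rknmpc-shares/1"


def save_shares(path, arrays: dict[str, np.ndarray], meta: dict | None = None) -> None:
    """Write named uint64 share arrays with a JSON manifest header."""
    manifest = {
        "format": _MAGIC,
        "meta": meta or {},
        "arrays": [
            {"name": name, "shape": list(arr.shape)} for name, arr in arrays.items()
        ],
    }
    header = json.dumps(manifest, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(len(header).to_bytes(4, "little"))
        fh.write(header)
        for arr in arrays.values():
            fh.write(np.ascontiguousarray(arr, dtype="<u8").tobytes())


def load_shares(path) -> tuple[dict[str, np.ndarray], dict]:
    with open(path, "rb") as fh:
        hlen = int.from_bytes(fh.read(4), "little")
        manifest = json.loads(fh.read(hlen))
        if manifest.get("format") != _MAGIC:
            raise ValueError("unrecognised share file")
        arrays = {}
        for entry in manifest["arrays"]:
            shape = tuple(entry["shape"])
            count = int(np.prod(shape)) if shape else 1
            buf = fh.read(8 * count)
            arrays[entry["name"]] = np.frombuffer(buf, dtype="<u8").reshape(shape).copy()
    return arrays, manifest["meta"]
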
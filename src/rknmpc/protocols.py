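"""Secure building blocks over 2-out-of-2 additive shares.

Every protocol here is written SPMD-style: the same function runs on both
proxies (branching on ``party.pid`` where the roles differ), while the
helper sits in :func:`serve_helper` answering dealing/masking requests
announced by P0 via small JSON headers.  All protocols are vectorized: a
call on an array of shares is one invocation and produces per-element
results identical to element-wise calls.

The suite:

====  =====================================================================
ADD   local modular addition, zero communication
MUL   Beaver-triple multiplication with fused fixed-point truncation
MP    matrix product (matrix Beaver triple, one truncation per entry)
TRUNC helper-assisted truncation (unbiased stochastic rounding)
PC    private compare: Boolean share of (x > r), x bit-shared over Z_67
MOC   modulus conversion Z_K -> Z_L
MSB   most-significant-bit extraction
CMP   comparison x > y via MSB(y - x)
MUX   oblivious selection z = x - b(x - y) via randomized encoding
EXP   exact exponential of a public base to a shared fixed-point power
====  =====================================================================

Truncation semantics: values carry ``f`` fractional bits, so every real
product must shed ``f`` (or ``2f`` for fused affine chains) bits.  We use
a helper-dealt masked opening: the helper shares a bounded-range random
``r`` together with ``r >> shift``; the proxies open ``v + D + r`` (which
never wraps for ``|v| < 2**(n-2)``), shift the public sum, and unmask.
The result is ``floor(v / 2**shift)`` plus an unbiased {0,1}-ulp
stochastic-rounding term — no catastrophic wrap failures, at the price of
revealing one statistically masked opening between the proxies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .ring import (
    RingSpec,
    bits_of,
    encode_fixed,
    share_additive,
    share_boolean,
)
from .runtime import Party

__all__ = [
    "add",
    "mul",
    "matmul",
    "truncate",
    "scale_public",
    "private_compare",
    "modulus_conversion",
    "msb",
    "compare",
    "mux",
    "exp",
    "ExpTable",
    "contribution_table",
    "share_public",
    "serve_helper",
    "close_helper",
]

_U64 = np.uint64


def _count(party: Party, name: str) -> None:
    # invocation counters live on P0 so that session-level merging is
    # double-count free
    if not party.is_helper and party.pid == 0:
        party.count(name)


def share_public(party: Party, value, spec: RingSpec | None = None) -> np.ndarray:
    """Trivial sharing of a public plaintext: P0 holds it, P1 holds zeros."""
    spec = spec or party.spec
    value = np.asarray(value, dtype=_U64)
    if party.pid == 0:
        return spec.reduce(value.copy())
    return np.zeros_like(value)


# --------------------------------------------------------------------------
# ADD


def add(party: Party, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Local share addition; no messages, no helper."""
    _count(party, "ADD")
    return party.spec.add(x, y)


def sub(party: Party, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return party.spec.sub(x, y)


# --------------------------------------------------------------------------
# TRUNC

def _delta(spec: RingSpec) -> int:
    # positive offset making the masked opening wrap-free for pre-shift
    # magnitudes |v| < 2**(n-2): v + delta < 2**(n-1) and the mask r is
    # below 2**(n-2), so the opened sum stays under 2**n
    return 1 << (spec.n - 2)


def _trunc_with_dealt(party: Party, z: np.ndarray, shift: int,
                      r_i: np.ndarray, rt_i: np.ndarray) -> np.ndarray:
    sp = party.spec
    delta = _U64(_delta(sp))
    masked = sp.add(z, r_i)
    if party.pid == 0:
        masked = sp.add(masked, delta)
    theirs = party.exchange_array(masked)
    opened = sp.add(masked, theirs)
    t_pub = np.right_shift(opened, _U64(shift))
    if party.pid == 0:
        return sp.sub(sp.sub(t_pub, rt_i), _U64(int(delta) >> shift))
    return sp.neg(rt_i)


def _deal_trunc(party: Party, shape, shift: int):
    """Helper side: share (r, r >> shift) with r uniform over [0, 2**(n-2))."""
    sp = party.spec
    r = np.bitwise_and(sp.uniform(party.rng, shape), _U64((1 << (sp.n - 2)) - 1))
    rt = np.right_shift(r, _U64(shift))
    r0, r1 = share_additive(r, sp, party.rng)
    rt0, rt1 = share_additive(rt, sp, party.rng)
    return (r0, rt0), (r1, rt1)


def truncate(party: Party, z: np.ndarray, shift: int | None = None) -> np.ndarray:
    """Drop ``shift`` fractional bits from a shared fixed-point value.

    Caller contract: the signed pre-shift value is below ``2**(n-2)`` in magnitude.
    """
    sp = party.spec
    shift = sp.f if shift is None else shift
    _count(party, "TRUNC")
    if party.pid == 0:
        party.send_header({"op": "trunc", "shape": list(z.shape), "shift": shift})
    blob = party.recv_array("helper", _U64, (2,) + z.shape)
    return _trunc_with_dealt(party, z, shift, blob[0], blob[1])


def scale_public(party: Party, x: np.ndarray, scalar_raw: int,
                 shift: int | None = None) -> np.ndarray:
    """Multiply shares by a public fixed-point scalar, then truncate."""
    sp = party.spec
    prod = sp.mul(x, _U64(scalar_raw))
    return truncate(party, prod, shift)


# --------------------------------------------------------------------------
# MUL / MP


def mul(party: Party, x: np.ndarray, y: np.ndarray,
        truncate_result: bool = True) -> np.ndarray:
    """Beaver multiplication; fixed-point truncation fused in by default.

    With ``truncate_result=False`` the exact ring product ``x*y mod L``
    is returned (used on raw ring values and in small-ring tests).
    """
    sp = party.spec
    x = np.asarray(x, dtype=_U64)
    y = np.asarray(y, dtype=_U64)
    if x.shape != y.shape:
        raise ValueError("mul operands must have identical shapes")
    _count(party, "MUL")
    shift = sp.f if truncate_result else 0
    if party.pid == 0:
        party.send_header({"op": "mul", "shape": list(x.shape), "shift": shift})
    rows = 5 if shift else 3
    blob = party.recv_array("helper", _U64, (rows,) + x.shape)
    a_i, b_i, c_i = blob[0], blob[1], blob[2]

    e_i = sp.sub(x, a_i)
    f_i = sp.sub(y, b_i)
    packed = np.stack([e_i, f_i])
    theirs = party.exchange_array(packed)
    e = sp.add(e_i, theirs[0])
    f = sp.add(f_i, theirs[1])

    z = sp.add(sp.add(sp.mul(e, b_i), sp.mul(f, a_i)), c_i)
    if party.pid == 1:
        z = sp.add(z, sp.mul(e, f))
    if not shift:
        return z
    return _trunc_with_dealt(party, z, shift, blob[3], blob[4])


def _deal_mul(party: Party, shape, shift: int):
    sp = party.spec
    a = sp.uniform(party.rng, shape)
    b = sp.uniform(party.rng, shape)
    c = sp.mul(a, b)
    a0, a1 = share_additive(a, sp, party.rng)
    b0, b1 = share_additive(b, sp, party.rng)
    c0, c1 = share_additive(c, sp, party.rng)
    p0 = [a0, b0, c0]
    p1 = [a1, b1, c1]
    if shift:
        (r0, rt0), (r1, rt1) = _deal_trunc(party, shape, shift)
        p0 += [r0, rt0]
        p1 += [r1, rt1]
    party.send_array("p0", np.stack(p0))
    party.send_array("p1", np.stack(p1))


def _matmul_mod(sp: RingSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return sp.reduce(A @ B)


def matmul(party: Party, A: np.ndarray, B: np.ndarray,
           shift: int | None = 0) -> np.ndarray:
    """Secure matrix product with a matrix Beaver triple.

    ``shift`` controls the fused truncation: 0 returns the raw
    ``2**(2f)``-scaled accumulation (useful for fusing follow-up affine
    steps into a single truncation), ``None`` truncates by ``f``.
    Dot products are the 1xm . mx1 case.
    """
    sp = party.spec
    A = np.asarray(A, dtype=_U64)
    B = np.asarray(B, dtype=_U64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[0]:
        raise ValueError(f"incompatible matmul shapes {A.shape} x {B.shape}")
    shift = sp.f if shift is None else shift
    _count(party, "MP")
    if party.pid == 0:
        party.send_header({
            "op": "matmul", "a_shape": list(A.shape), "b_shape": list(B.shape),
            "shift": shift,
        })
    out_shape = (A.shape[0], B.shape[1])
    na, nb = A.size, B.size
    blob = party.recv("helper")
    buf = np.frombuffer(blob, dtype=_U64)
    Ap = buf[:na].reshape(A.shape)
    Bp = buf[na:na + nb].reshape(B.shape)
    Cp = buf[na + nb:na + nb + out_shape[0] * out_shape[1]].reshape(out_shape)
    rest = buf[na + nb + Cp.size:]

    E_i = sp.sub(A, Ap)
    F_i = sp.sub(B, Bp)
    theirs = party.exchange(E_i.tobytes() + F_i.tobytes())
    tb = np.frombuffer(theirs, dtype=_U64)
    E = sp.add(E_i, tb[:na].reshape(A.shape))
    F = sp.add(F_i, tb[na:].reshape(B.shape))

    Z = sp.add(sp.add(_matmul_mod(sp, E, Bp), _matmul_mod(sp, Ap, F)), Cp)
    if party.pid == 1:
        Z = sp.add(Z, _matmul_mod(sp, E, F))
    if not shift:
        return Z
    r_i = rest[:Z.size].reshape(out_shape)
    rt_i = rest[Z.size:].reshape(out_shape)
    return _trunc_with_dealt(party, Z, shift, r_i, rt_i)


def _deal_matmul(party: Party, a_shape, b_shape, shift: int):
    sp = party.spec
    out_shape = (a_shape[0], b_shape[1])
    Ap = sp.uniform(party.rng, tuple(a_shape))
    Bp = sp.uniform(party.rng, tuple(b_shape))
    Cp = _matmul_mod(sp, Ap, Bp)
    A0, A1 = share_additive(Ap, sp, party.rng)
    B0, B1 = share_additive(Bp, sp, party.rng)
    C0, C1 = share_additive(Cp, sp, party.rng)
    part0 = [A0.ravel(), B0.ravel(), C0.ravel()]
    part1 = [A1.ravel(), B1.ravel(), C1.ravel()]
    if shift:
        (r0, rt0), (r1, rt1) = _deal_trunc(party, out_shape, shift)
        part0 += [r0.ravel(), rt0.ravel()]
        part1 += [r1.ravel(), rt1.ravel()]
    party.send_array("p0", np.concatenate(part0))
    party.send_array("p1", np.concatenate(part1))


# --------------------------------------------------------------------------
# PC

_VP = 67


def private_compare(party: Party, xbits_i: np.ndarray, r_pub: np.ndarray,
                    beta: np.ndarray | None = None) -> np.ndarray:
    """Boolean share of (x > r): x bit-shared over Z_67, r public.

    Follows the masked per-bit difference construction: the proxies build
    per-bit values whose reconstruction hits zero exactly when the strict
    inequality holds, blind them with common random non-zero scalars and
    a common permutation, and let the helper look for a zero.  The helper
    only learns ``u' = u XOR (x > r)`` for the common random bit ``u``.
    """
    sp = party.spec
    xbits_i = np.asarray(xbits_i, dtype=np.int16)
    m = xbits_i.shape[:-1]
    n = sp.n
    if xbits_i.shape[-1] != n:
        raise ValueError("bit-share vector must have length n")
    r_pub = np.broadcast_to(np.asarray(r_pub, dtype=_U64), m)
    _count(party, "PC")

    tape = party.tape
    if beta is None:
        beta = tape.integers(0, 2, size=m, dtype=np.uint8)
    else:
        # caller supplied the common bit; keep the draw anyway so both
        # proxies' tapes stay in lock-step no matter who supplied it
        _ = tape.integers(0, 2, size=m, dtype=np.uint8)
        beta = np.asarray(beta, dtype=np.uint8)
    scal = tape.integers(1, _VP, size=m + (n,), dtype=np.int16)
    perm = np.argsort(tape.integers(0, 1 << 32, size=m + (n,), dtype=np.uint32), axis=-1)

    j = party.pid
    rmax = r_pub == sp.mask  # the all-ones corner case
    flat_bits = xbits_i.reshape(-1, n)
    flat_beta = beta.reshape(-1)
    flat_r = r_pub.reshape(-1)
    flat_rmax = rmax.reshape(-1)
    c = np.empty_like(flat_bits)

    def branch(rows, pub_vals, sign_flip):
        # w reconstructs to x XOR pub; W_i = sum_{k<i} w_k counts the
        # differing bits above position i (bit order is MSB first)
        x = flat_bits[rows]
        pub = bits_of(pub_vals, sp)
        w = np.where(pub == 1, np.int16(j) - x, x)
        W = np.cumsum(w, axis=-1, dtype=np.int32) - w
        if sign_flip:
            core = pub * j - x  # zero at first difference iff x=1, r=0: x > r
        else:
            core = x - pub * j  # zero at first difference iff x=0, t=1: x < t
        c[rows] = np.mod(core + j + W, _VP)

    rows_a = np.nonzero(flat_beta == 0)[0]
    rows_b = np.nonzero((flat_beta == 1) & ~flat_rmax)[0]
    rows_c = np.nonzero((flat_beta == 1) & flat_rmax)[0]
    if rows_a.size:
        branch(rows_a, flat_r[rows_a], sign_flip=True)
    if rows_b.size:
        branch(rows_b, sp.add(flat_r[rows_b], _U64(1)), sign_flip=False)
    if rows_c.size:
        # x > r is impossible for the all-ones r; plant exactly one zero
        u = tape.integers(1, _VP, size=(rows_c.size, n), dtype=np.int16)
        cc = np.mod(u + 1, _VP) if j == 0 else np.mod(-u, _VP)
        cc[:, 0] = u[:, 0] if j == 0 else np.mod(-u[:, 0], _VP)
        c[rows_c] = cc.astype(np.int16)

    c = c.reshape(m + (n,))
    c = np.mod(c * scal, _VP)
    c = np.take_along_axis(c, perm, axis=-1).astype(np.uint8)

    if j == 0:
        party.send_header({"op": "pc", "shape": list(m), "n": n})
    party.send_array("helper", c)
    u_prime_i = party.recv_array("helper", np.uint8, m)
    if j == 0:
        return np.bitwise_xor(u_prime_i, beta)
    return u_prime_i


def _serve_pc(party: Party, shape, n):
    shape = tuple(shape)
    c0 = party.recv_array("p0", np.uint8, shape + (n,)).astype(np.int16)
    c1 = party.recv_array("p1", np.uint8, shape + (n,)).astype(np.int16)
    d = np.mod(c0 + c1, _VP)
    found = np.any(d == 0, axis=-1).astype(np.uint8)
    h0, h1 = share_boolean(found, party.rng)
    party.send_array("p0", h0)
    party.send_array("p1", h1)


# --------------------------------------------------------------------------
# MOC


def modulus_conversion(party: Party, xk_i: np.ndarray) -> np.ndarray:
    """Convert shares over Z_K into fresh shares of the same value over Z_L.

    The helper deals shares of a random ``r in Z_K``, Boolean shares of
    its share-sum wrap, and Z_67 bit shares of ``r``; the proxies open
    ``y = (x + r) mod K``, learn the wrap of ``x + r`` from a private
    compare ``r > y``, lift everything to Z_L and unmask.
    """
    sp = party.spec
    xk_i = np.asarray(xk_i, dtype=_U64)
    shape = xk_i.shape
    _count(party, "MOC")
    if party.pid == 0:
        party.send_header({"op": "moc", "shape": list(shape)})

    payload = party.recv("helper")
    nb = xk_i.size * 8
    rk_i = np.frombuffer(payload[:nb], dtype=_U64).reshape(shape)
    w_i = np.frombuffer(payload[nb:nb + xk_i.size], dtype=np.uint8).reshape(shape)
    rbits_i = np.frombuffer(payload[nb + xk_i.size:], dtype=np.uint8).reshape(shape + (sp.n,)).astype(np.int16)

    y_i = np.bitwise_and(np.add(xk_i, rk_i), sp.mask_k)
    y_their = party.exchange_array(y_i)
    y_sum = np.add(y_i, y_their)  # < 2**64, exact
    y = np.bitwise_and(y_sum, sp.mask_k)
    wrap_y = (y_sum >> _U64(sp.n - 1)).astype(np.uint8)

    c_i = private_compare(party, rbits_i, y)  # Boolean share of (r > y)

    K = _U64(sp.K)
    yl_i = y_i.copy()
    if party.pid == 0:
        yl_i = sp.add(yl_i, K * wrap_y.astype(_U64))
    yl_i = sp.add(yl_i, K * c_i.astype(_U64))
    rl_i = sp.add(rk_i, K * w_i.astype(_U64))
    return sp.sub(yl_i, rl_i)


def _serve_moc(party: Party, shape):
    sp = party.spec
    shape = tuple(shape)
    r = sp.uniform_k(party.rng, shape)
    r0, r1 = share_additive(r, sp, party.rng, ring="K")
    wrap = ((np.add(r0, r1) >> _U64(sp.n - 1)) & _U64(1)).astype(np.uint8)
    w0, w1 = share_boolean(wrap, party.rng)
    b0, b1 = share_additive(bits_of(r, sp), sp, party.rng, ring="V")
    party.send("p0", r0.tobytes() + w0.tobytes() + b0.astype(np.uint8).tobytes())
    party.send("p1", r1.tobytes() + w1.tobytes() + b1.astype(np.uint8).tobytes())


# --------------------------------------------------------------------------
# MSB / CMP


def msb(party: Party, x_i: np.ndarray) -> np.ndarray:
    """Shares over Z_L of the top bit of x (1 for negative fixed point).

    Extracts the low n-1 bits share-locally, lifts them back to Z_L via
    MOC, leaving ``z = x - (x mod K)`` which is 0 or K; the helper maps
    the two order-randomized candidates to fresh bit shares.
    """
    sp = party.spec
    x_i = np.asarray(x_i, dtype=_U64)
    shape = x_i.shape
    _count(party, "MSB")

    d_k = np.bitwise_and(x_i, sp.mask_k)
    d_l = modulus_conversion(party, d_k)
    z_i = sp.sub(x_i, d_l)

    s = party.tape.integers(0, 2, size=shape, dtype=np.uint8)
    K = _U64(sp.K)
    if party.pid == 0:
        party.send_header({"op": "msb", "shape": list(shape)})
        cand_a = sp.add(z_i, K * s.astype(_U64))
        cand_b = sp.add(z_i, K * (1 - s).astype(_U64))
        party.send_array("helper", np.stack([cand_a, cand_b]))
    else:
        party.send_array("helper", z_i)

    pair = party.recv_array("helper", _U64, (2,) + shape)
    return np.where(s == 0, pair[0], pair[1])


def _serve_msb(party: Party, shape):
    sp = party.spec
    shape = tuple(shape)
    cands = party.recv_array("p0", _U64, (2,) + shape)
    z1 = party.recv_array("p1", _U64, shape)
    out0, out1 = [], []
    for idx in range(2):
        v = sp.add(cands[idx], z1)
        bit = (v >> _U64(sp.n - 1)).astype(_U64)
        b0, b1 = share_additive(bit, sp, party.rng)
        out0.append(b0)
        out1.append(b1)
    party.send_array("p0", np.stack(out0))
    party.send_array("p1", np.stack(out1))


def compare(party: Party, x_i: np.ndarray, y_i: np.ndarray) -> np.ndarray:
    """Shares of the bit (x > y), computed as MSB(y - x)."""
    _count(party, "CMP")
    z_i = party.spec.sub(y_i, x_i)
    return msb(party, z_i)


# --------------------------------------------------------------------------
# MUX


def mux(party: Party, x_i: np.ndarray, y_i: np.ndarray,
        b_i: np.ndarray) -> np.ndarray:
    """Oblivious selection ``z = x - b(x - y)`` = x if b=0 else y.

    The selector is a raw ring bit (not fixed-point scaled), so no
    truncation is needed.  The proxies outsource the two cross-share
    products to the helper through a randomized encoding: P0 contributes
    ``M2 = <b>_0 + r0`` and ``M3 = (<x>_0 - <y>_0) + r3``, P1 contributes
    ``M5 = (<x>_1 - <y>_1) + r1`` and ``M6 = <b>_1 + r2``; the helper
    returns fresh shares of ``M2*M5 + M3*M6`` and the proxies cancel the
    tape terms locally.
    """
    sp = party.spec
    x_i = np.asarray(x_i, dtype=_U64)
    y_i = np.broadcast_to(np.asarray(y_i, dtype=_U64), x_i.shape)
    b_i = np.broadcast_to(np.asarray(b_i, dtype=_U64), x_i.shape)
    shape = x_i.shape
    _count(party, "MUX")

    tape = party.tape
    r0 = sp.uniform(tape, shape)
    r1 = sp.uniform(tape, shape)
    r2 = sp.uniform(tape, shape)
    r3 = sp.uniform(tape, shape)

    diff_i = sp.sub(x_i, y_i)
    if party.pid == 0:
        party.send_header({"op": "mux", "shape": list(shape)})
        m2 = sp.add(b_i, r0)
        m3 = sp.add(diff_i, r3)
        party.send_array("helper", np.stack([m2, m3]))
    else:
        m5 = sp.add(diff_i, r1)
        m6 = sp.add(b_i, r2)
        party.send_array("helper", np.stack([m5, m6]))

    m_i = party.recv_array("helper", _U64, shape)

    z_i = sp.sub(x_i, sp.mul(b_i, diff_i))
    if party.pid == 0:
        local = sp.add(sp.add(sp.mul(r1, b_i), sp.mul(r2, diff_i)), sp.mul(r2, r3))
    else:
        local = sp.add(sp.add(sp.mul(r0, diff_i), sp.mul(r0, r1)), sp.mul(r3, b_i))
    return sp.sub(sp.add(z_i, local), m_i)


def _serve_mux(party: Party, shape):
    sp = party.spec
    shape = tuple(shape)
    p0 = party.recv_array("p0", _U64, (2,) + shape)
    p1 = party.recv_array("p1", _U64, (2,) + shape)
    m = sp.add(sp.mul(p0[0], p1[0]), sp.mul(p0[1], p1[1]))
    m0, m1 = share_additive(m, sp, party.rng)
    party.send_array("p0", m0)
    party.send_array("p1", m1)


# --------------------------------------------------------------------------
# EXP


@dataclass(frozen=True)
class ExpTable:
    """Per-bit contributions of a fixed-point power for a public base.

    ``positions[i]`` is a raw bit index ``j`` (from the LSB); setting that
    bit of the power adds ``2**(j-f)`` to it, so the bit contributes a
    factor ``base**(2**(j-f))`` (``cp``) to a positive power and
    ``base**(-2**(j-f))`` (``cn``) to a negative one.  Only positions
    whose positive contribution is representable in the ring are covered,
    which bounds the valid power window.
    """

    base: float
    positions: np.ndarray  # ascending raw bit indices
    cp: np.ndarray         # float contributions for positive powers
    cn: np.ndarray         # float contributions for negative powers
    cp_raw: np.ndarray     # fixed-point encodings
    cn_raw: np.ndarray

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def padded_size(self) -> int:
        return 1 << int(np.ceil(np.log2(max(self.size, 1))))

    def window(self, f: int) -> float:
        """Largest |power| whose binary expansion is fully covered."""
        top = int(self.positions[-1])
        return 2.0 ** (top + 1 - f)


def contribution_table(base: float, spec: RingSpec) -> ExpTable:
    """Build the covered contribution table for ``base`` under ``spec``.

    A bit position is covered when ``base**(2**(j-f))`` still fits the
    signed fixed-point range; negative contributions always fit (they may
    round to 0, costing at most one ulp).
    """
    if base <= 1.0:
        raise ValueError("base must exceed 1")
    positions = []
    for j in range(spec.n):
        weight = 2.0 ** (j - spec.f)
        if base ** weight >= spec.max_abs:
            break
        positions.append(j)
    if not positions:
        raise ValueError("no representable contributions for this base/ring")
    positions = np.array(positions, dtype=np.int64)
    weights = 2.0 ** (positions - spec.f)
    cp = base ** weights
    cn = base ** (-weights)
    return ExpTable(
        base=float(base), positions=positions, cp=cp, cn=cn,
        cp_raw=encode_fixed(cp, spec), cn_raw=encode_fixed(cn, spec),
    )


def exp(party: Party, x_i: np.ndarray, base: float | None = None,
        table: ExpTable | None = None) -> np.ndarray:
    """Exact secret-shared exponential ``base ** x`` for shared power x.

    Square-and-multiply adapted to shared fixed point: (1) one MSB reads
    the sign; (2) one vectorized MUX picks {x, Cp} or {|x|, Cn}; (3) one
    vectorized MSB over left-shifted copies exposes every covered bit of
    the magnitude; (4) one vectorized MUX picks contribution-or-1 per
    bit; (5) a binary-tree product over the padded table needs
    log2(table size) MUL calls.

    Caller contract (not privately checkable): the decoded power lies in
    the covered window (for base e at n=64, f=20: |x| < 32), and positive
    powers are further bounded by ``ln(2**(n-3-2f))`` ~ 14.5 so the tree
    partial products stay inside the truncation headroom.
    """
    sp = party.spec
    x_i = np.asarray(x_i, dtype=_U64)
    shape = x_i.shape
    if table is None:
        table = contribution_table(base if base is not None else float(np.e), sp)
    _count(party, "EXP")

    sign = msb(party, x_i)  # 1 => negative power

    T = table.size
    cp_sh = share_public(party, np.broadcast_to(table.cp_raw, shape + (T,)), sp)
    cn_sh = share_public(party, np.broadcast_to(table.cn_raw, shape + (T,)), sp)
    pos_vec = np.concatenate([x_i[..., None], cp_sh], axis=-1)
    neg_vec = np.concatenate([sp.neg(x_i)[..., None], cn_sh], axis=-1)
    sel = mux(party, pos_vec, neg_vec, sign[..., None])
    mag = sel[..., 0]
    contrib = sel[..., 1:]

    shifts = (sp.n - 1 - table.positions).astype(np.int64)
    mult = sp.reduce(_U64(1) << shifts.astype(_U64))
    shifted = sp.mul(mag[..., None], mult)
    bits = msb(party, shifted)

    ones_sh = share_public(
        party, np.broadcast_to(encode_fixed(1.0, sp), shape + (T,)), sp)
    factors = mux(party, ones_sh, contrib, bits)

    pad = table.padded_size - T
    if pad:
        pad_sh = share_public(
            party, np.broadcast_to(encode_fixed(1.0, sp), shape + (pad,)), sp)
        factors = np.concatenate([factors, pad_sh], axis=-1)

    while factors.shape[-1] > 1:
        factors = mul(party, factors[..., 0::2], factors[..., 1::2])
    return factors[..., 0]


# --------------------------------------------------------------------------
# helper dispatcher


def serve_helper(party: Party) -> None:
    """Helper main loop: answer P0-announced requests until 'close'."""
    if not party.is_helper:
        raise ValueError("serve_helper must run on the helper")
    while True:
        header = json.loads(party.recv("p0"))
        op = header["op"]
        if op == "close":
            return
        if op == "mul":
            _deal_mul(party, tuple(header["shape"]), header["shift"])
        elif op == "matmul":
            _deal_matmul(party, header["a_shape"], header["b_shape"], header["shift"])
        elif op == "trunc":
            (r0, rt0), (r1, rt1) = _deal_trunc(party, tuple(header["shape"]), header["shift"])
            party.send_array("p0", np.stack([r0, rt0]))
            party.send_array("p1", np.stack([r1, rt1]))
        elif op == "pc":
            _serve_pc(party, header["shape"], header["n"])
        elif op == "moc":
            _serve_moc(party, header["shape"])
        elif op == "msb":
            _serve_msb(party, header["shape"])
        elif op == "mux":
            _serve_mux(party, header["shape"])
        else:
            raise ValueError(f"unknown helper op {op!r}")


def close_helper(party: Party) -> None:
    if party.pid == 0:
        party.send_header({"op": "close"})
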
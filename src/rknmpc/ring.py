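"""Fixed-point number format and additive secret sharing over power-of-two rings.

All secure computation in this package happens on unsigned integers modulo
``L = 2**n`` (and its companion ring ``K = 2**(n-1)``), with real numbers
embedded in two's-complement fixed point: a real ``x`` is stored as
``round(x * 2**f) mod L``.  Signed semantics exist only at the
encode/decode boundary; everything in between is plain modular wraparound,
which is exactly the algebra 2-out-of-2 additive sharing needs.

A third, small prime ring ``Z_V`` (V = 67) carries per-bit shares used by
the private-compare protocol; V > n is required so that sums of up to n
bit indicators never wrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RingSpec",
    "encode_fixed",
    "decode_fixed",
    "share_additive",
    "reconstruct",
    "share_bitwise",
    "reconstruct_bitwise",
    "share_boolean",
    "neg_share",
    "to_signed",
]

#: prime modulus for bitwise shares (must exceed the bit width n)
V = 67

_U64 = np.uint64


@dataclass(frozen=True)
class RingSpec:
    """The configurable number system: bit width, fractional bits, moduli.

    Parameters
    ----------
    n : int
        Ring bit width.  ``L = 2**n`` and ``K = 2**(n-1)``.  Values of
        8/16/32 let every protocol be tested exhaustively; 64 is the
        production width.
    f : int
        Number of fractional bits in the fixed-point embedding.
        Must satisfy ``0 < f < n - 2`` (and in practice ``2*f <= n - 3``
        for fused double-truncations).
    """

    n: int = 64
    f: int = 20

    def __post_init__(self) -> None:
        if self.n not in (8, 16, 32, 64):
            raise ValueError(f"unsupported ring width n={self.n}")
        if not (0 < self.f < self.n - 2):
            raise ValueError(f"need 0 < f < n-2, got f={self.f}, n={self.n}")
        if V <= self.n:
            raise ValueError("prime bit-share modulus must exceed n")

    @property
    def L(self) -> int:
        return 1 << self.n

    @property
    def K(self) -> int:
        return 1 << (self.n - 1)

    @property
    def V(self) -> int:
        return V

    @property
    def mask(self) -> np.uint64:
        """Bit mask reducing uint64 arithmetic modulo L."""
        return _U64((1 << self.n) - 1)

    @property
    def mask_k(self) -> np.uint64:
        return _U64((1 << (self.n - 1)) - 1)

    @property
    def scale(self) -> float:
        return float(1 << self.f)

    @property
    def max_abs(self) -> float:
        """Largest representable magnitude, 2**(n-1-f)."""
        return float(1 << (self.n - 1 - self.f))

    # -- modular helpers (uint64 arrays carrying n-bit values) ------------

    def reduce(self, a: np.ndarray) -> np.ndarray:
        return np.bitwise_and(a, self.mask)

    def add(self, a, b) -> np.ndarray:
        return self.reduce(np.add(a, b, dtype=_U64))

    def sub(self, a, b) -> np.ndarray:
        a = np.asarray(a, dtype=_U64)
        b = np.asarray(b, dtype=_U64)
        return self.reduce(np.subtract(a, b))

    def mul(self, a, b) -> np.ndarray:
        return self.reduce(np.multiply(np.asarray(a, dtype=_U64), np.asarray(b, dtype=_U64)))

    def neg(self, a) -> np.ndarray:
        return self.reduce(np.negative(np.asarray(a, dtype=_U64)))

    def uniform(self, rng: np.random.Generator, shape=()) -> np.ndarray:
        """Uniform ring elements in [0, L)."""
        raw = rng.integers(0, 1 << 64, size=shape, dtype=np.uint64)
        return self.reduce(raw)

    def uniform_k(self, rng: np.random.Generator, shape=()) -> np.ndarray:
        raw = rng.integers(0, 1 << 64, size=shape, dtype=np.uint64)
        return np.bitwise_and(raw, self.mask_k)


DEFAULT_SPEC = RingSpec()


def to_signed(raw: np.ndarray, spec: RingSpec) -> np.ndarray:
    """Two's-complement interpretation of n-bit raw values, as int64/float."""
    raw = np.asarray(raw, dtype=_U64)
    if spec.n == 64:
        return raw.astype(np.int64)
    signed = raw.astype(np.int64)
    k = np.int64(spec.K)
    return np.where(signed >= k, signed - np.int64(spec.L), signed)


def encode_fixed(x, spec: RingSpec = DEFAULT_SPEC) -> np.ndarray:
    """Encode reals into raw fixed-point ring elements.

    Rounds half away from zero; raises on values outside the
    representable range ``|x| < 2**(n-1-f)``.
    """
    x = np.asarray(x, dtype=np.float64)
    # two's complement: the most negative value -2^(n-1-f) is representable
    if np.any((x >= spec.max_abs) | (x < -spec.max_abs)):
        raise OverflowError(
            f"value out of representable range |x| < {spec.max_abs:g}"
        )
    scaled = x * spec.scale
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return spec.reduce(rounded.astype(np.int64).astype(_U64))


def decode_fixed(raw, spec: RingSpec = DEFAULT_SPEC) -> np.ndarray:
    """Inverse of :func:`encode_fixed` up to one unit in the last place."""
    return to_signed(raw, spec).astype(np.float64) / spec.scale


def share_additive(x, spec: RingSpec, rng: np.random.Generator, ring: str = "L"):
    """Split ring elements into two additive shares.

    share0 is uniform; share1 = (x - share0) mod modulus.  ``ring`` is
    "L", "K" or "V"; V-sharing operates elementwise on small ints.
    """
    if ring == "V":
        x = np.asarray(x)
        s0 = rng.integers(0, V, size=x.shape, dtype=np.int16)
        s1 = np.mod(x - s0, V).astype(np.int16)
        return s0, s1
    x = np.asarray(x, dtype=_U64)
    if ring == "L":
        s0 = spec.uniform(rng, x.shape)
        s1 = spec.sub(x, s0)
    elif ring == "K":
        s0 = spec.uniform_k(rng, x.shape)
        s1 = np.bitwise_and(np.subtract(x, s0), spec.mask_k)
    else:
        raise ValueError(f"unknown ring {ring!r}")
    return s0, s1


def reconstruct(s0, s1, spec: RingSpec, ring: str = "L") -> np.ndarray:
    """(s0 + s1) mod modulus."""
    if ring == "V":
        return np.mod(np.asarray(s0, dtype=np.int64) + np.asarray(s1, dtype=np.int64), V).astype(np.int16)
    if ring == "L":
        return spec.add(s0, s1)
    if ring == "K":
        return np.bitwise_and(np.add(np.asarray(s0, _U64), np.asarray(s1, _U64)), spec.mask_k)
    raise ValueError(f"unknown ring {ring!r}")


def bits_of(x, spec: RingSpec) -> np.ndarray:
    """Binary expansion of ring elements, most-significant bit first.

    Returns an int16 array with a trailing axis of length n.
    """
    x = np.asarray(x, dtype=_U64)
    shifts = np.arange(spec.n - 1, -1, -1, dtype=_U64)
    return (np.right_shift(x[..., None], shifts) & _U64(1)).astype(np.int16)


def share_bitwise(x, spec: RingSpec, rng: np.random.Generator):
    """Per-bit additive shares over Z_V of the binary expansion of x.

    Bit order is most-significant first; the trailing axis has length n.
    """
    return share_additive(bits_of(x, spec), spec, rng, ring="V")


def reconstruct_bitwise(b0, b1, spec: RingSpec) -> np.ndarray:
    """Reassemble the secret from reconstructed Z_V bit shares."""
    bits = reconstruct(b0, b1, spec, ring="V").astype(_U64)
    weights = _U64(1) << np.arange(spec.n - 1, -1, -1, dtype=_U64)
    return spec.reduce((bits * weights).sum(axis=-1, dtype=_U64))


def share_boolean(bit, rng: np.random.Generator):
    """XOR-sharing of single bits: share0 random, share1 = bit ^ share0."""
    bit = np.asarray(bit, dtype=np.uint8)
    s0 = rng.integers(0, 2, size=bit.shape, dtype=np.uint8)
    return s0, np.bitwise_xor(bit, s0)


def neg_share(s, spec: RingSpec) -> np.ndarray:
    """Local negation of a share; negating both shares negates the secret."""
    return spec.neg(s)
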
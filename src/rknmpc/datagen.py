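"""Synthetic RKN models and protein sequences, plus the scaling report.

Nothing in the test suite or the examples needs a download: models with
the right shapes and invariants (unit-norm anchor columns, symmetric
Gram inverse square root, Gaussian classifier) and uniform random
sequences are generated from explicit seeds.

The scaling report replays the paper-style scalability study with a
portable metric: instead of wall-clock time (hardware-bound), it counts
protocol invocations and transferred bytes while one RKN parameter
(anchors q, k-mer length k, or sequence length) sweeps a grid and the
others stay fixed at 8 (sequence length fixed at 128 residues).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rkn import ALPHABET, RKNModel
from .runtime import SessionConfig
from .private import infer_private

__all__ = [
    "GeneratorConfig",
    "generate_model",
    "generate_sequences",
    "write_fasta",
    "scaling_report",
    "linear_r2",
]

#: eigenvalues of the anchor Gram matrix below this are treated as exact
#: zeros (spectral truncation) when forming the inverse square root
EIG_FLOOR = 1e-6


@dataclass
class GeneratorConfig:
    q: int = 8
    k: int = 8
    alphabet_size: int = 20
    length: int | tuple[int, int] = 128
    n_sequences: int = 5
    alpha: float = 0.6
    lam: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 1 or self.k < 1:
            raise ValueError("need q, k >= 1")
        if not (1 <= self.alphabet_size <= len(ALPHABET)):
            raise ValueError("alphabet size must be 1..20")
        lo = self.length if isinstance(self.length, int) else self.length[0]
        if lo < self.k:
            raise ValueError("sequences must be at least k long")

    @property
    def alphabet(self) -> str:
        return ALPHABET[: self.alphabet_size]


def _inv_sqrt(gram: np.ndarray) -> np.ndarray:
    """Inverse square root via eigendecomposition with spectral truncation.

    Eigendirections with eigenvalue below ``EIG_FLOOR`` contribute zero
    (pseudo-inverse convention), keeping ||G|| bounded even when the
    anchors span fewer than q dimensions.
    """
    vals, vecs = np.linalg.eigh(gram)
    inv = np.where(vals >= EIG_FLOOR, 1.0 / np.sqrt(np.maximum(vals, EIG_FLOOR)), 0.0)
    G = (vecs * inv) @ vecs.T
    return (G + G.T) / 2.0


def generate_model(cfg: GeneratorConfig) -> RKNModel:
    """Draw a random RKN model: a pure function of (seed, config)."""
    rng = np.random.Generator(np.random.Philox(cfg.seed))
    sigma = cfg.alphabet_size
    Z = rng.normal(size=(cfg.k, sigma, cfg.q))
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    flat = np.transpose(Z, (2, 0, 1)).reshape(cfg.q, cfg.k * sigma)
    gram = flat @ flat.T
    model = RKNModel(
        Z=Z,
        alpha=cfg.alpha,
        lam=cfg.lam,
        G=_inv_sqrt(gram),
        w=rng.normal(size=cfg.q),
        beta=float(rng.normal()),
        alphabet=cfg.alphabet,
    )
    model.validate()
    return model


def generate_sequences(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    """Uniform i.i.d. residue sequences as (id, sequence) records.

    ``cfg.length`` may be a fixed length or an inclusive (lo, hi) range.
    """
    rng = np.random.Generator(np.random.Philox(cfg.seed + 1))
    alphabet = np.array(list(cfg.alphabet))
    records = []
    for i in range(cfg.n_sequences):
        if isinstance(cfg.length, int):
            length = cfg.length
        else:
            lo, hi = cfg.length
            length = int(rng.integers(lo, hi + 1))
        seq = "".join(alphabet[rng.integers(0, len(alphabet), size=length)])
        records.append((f"synth_{i}", seq))
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start:start + 60] + "\n")


def linear_r2(x, y) -> float:
    """R^2 of the least-squares straight line through (x, y).

    A constant series is fit perfectly by a flat line (zero residual), so
    it reports 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-9 else 0.0
    return 1.0 - ss_res / ss_tot


_COUNT_COLS = ("MUL", "MP", "EXP", "MUX", "MSB", "MOC", "TRUNC")


def scaling_report(param: str, grid=None, *, fixed: int = 8,
                   fixed_length: int = 128, trials: int = 1,
                   config: SessionConfig | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sweep one RKN parameter; tabulate invocation and byte counts.

    ``param`` is one of "q", "k", "length"; the other two stay fixed
    (q = k = 8, length 128 by default).  Returns the per-grid-point table
    and the linear-fit R^2 of every counter column, the portable stand-in
    for the wall-clock linearity observation.
    """
    if param not in ("q", "k", "length"):
        raise ValueError("param must be 'q', 'k' or 'length'")
    if grid is None:
        grid = {"q": (4, 8, 16, 32), "k": (2, 4, 8, 16),
                "length": (32, 64, 128, 192)}[param]
    config = config or SessionConfig()

    rows = []
    for value in grid:
        q = value if param == "q" else fixed
        k = value if param == "k" else fixed
        length = value if param == "length" else fixed_length
        totals = {col: 0 for col in _COUNT_COLS}
        total_bytes = 0
        for trial in range(trials):
            cfg = GeneratorConfig(q=q, k=k, length=length, n_sequences=1,
                                  seed=seed * 7919 + trial)
            model = generate_model(cfg)
            (_, seq), = generate_sequences(cfg)
            _, session = infer_private(model, seq, config,
                                       owner_seed=seed * 104729 + trial + 1)
            tr = session.transcript
            for col in _COUNT_COLS:
                totals[col] += tr.invocations.get(col, 0)
            total_bytes += tr.total_bytes
        row = {"param": param, "value": value}
        row.update({col: totals[col] / trials for col in _COUNT_COLS})
        row["bytes"] = total_bytes / trials
        rows.append(row)

    df = pd.DataFrame(rows)
    fits = {col: linear_r2(df["value"], df[col]) for col in (*_COUNT_COLS, "bytes")}
    return df, fits
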
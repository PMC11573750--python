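"""Plaintext recurrent kernel network (RKN) forward pass.

The RKN scores a protein sequence against ``q`` learned anchor motifs of
length ``k``.  Position ``t`` of the one-hot encoded sequence is compared
to character ``j`` of every anchor through a Gaussian-like similarity

    b_j[t][i] = exp(alpha * (<z_{j,.,i}, x_t> - 1)),

which feeds the substring-kernel recurrence

    c_j[t] = lambda * c_j[t-1] + b_j[t] * c_{j-1}[t-1],      c_0 == 1,

so that ``c_k[|x|]`` embeds the sequence in the anchor space.  A
projection by the inverse square root of the anchor Gram matrix and a
linear classifier produce the fold-recognition score.

This double-precision implementation is the correctness oracle for the
private three-party circuit and a standalone scorer in its own right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "RKNModel",
    "one_hot_encode",
    "similarity",
    "forward",
    "save_model",
    "load_model",
    "read_fasta",
]

#: the 20 standard amino acids, in the conventional order
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass
class RKNModel:
    """Parameters of a trained RKN binary classifier.

    Attributes
    ----------
    Z : (k, |alphabet|, q) array
        Anchor tensor; ``Z[j, :, i]`` is character ``j`` of anchor ``i``,
        constrained to unit Euclidean norm so the similarity power
        ``alpha * (dot - 1)`` stays in ``[-2*alpha, 0]``.
    alpha : float
        Similarity scale (> 0).
    lam : float
        Gap/decay factor in [0, 1].
    G : (q, q) array
        Inverse square root of the anchor Gram matrix (symmetric).
    w : (q,) array
        Linear classifier weights.
    beta : float
        Classifier bias.
    alphabet : str
        Residue alphabet, defaults to the 20 standard amino acids.
    """

    Z: np.ndarray
    alpha: float
    lam: float
    G: np.ndarray
    w: np.ndarray
    beta: float
    alphabet: str = ALPHABET

    @property
    def k(self) -> int:
        return self.Z.shape[0]

    @property
    def q(self) -> int:
        return self.Z.shape[2]

    def validate(self) -> None:
        k, sigma, q = self.Z.shape
        if sigma != len(self.alphabet):
            raise ValueError("anchor tensor alphabet axis mismatch")
        if self.G.shape != (q, q):
            raise ValueError("gram inverse square root must be q x q")
        if not np.allclose(self.G, self.G.T, atol=1e-8):
            raise ValueError("gram inverse square root must be symmetric")
        if self.w.shape != (q,):
            raise ValueError("classifier weight length mismatch")
        norms = np.linalg.norm(self.Z, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("anchor columns must have unit norm")
        if not (self.alpha > 0 and 0.0 <= self.lam <= 1.0):
            raise ValueError("need alpha > 0 and 0 <= lambda <= 1")


def one_hot_encode(sequence: str, alphabet: str = ALPHABET,
                   unknown: str = "error") -> np.ndarray:
    """One-hot encode a residue string into a |x| x |alphabet| 0/1 matrix.

    ``unknown`` controls handling of characters outside the alphabet:
    ``"error"`` raises, ``"zero"`` maps them to an all-zero row (the row
    then contributes exp(-alpha) similarity everywhere).
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    idx = {aa: i for i, aa in enumerate(alphabet)} if alphabet != ALPHABET else _INDEX
    out = np.zeros((len(sequence), len(alphabet)), dtype=np.float64)
    for t, ch in enumerate(sequence):
        i = idx.get(ch)
        if i is None:
            if unknown == "zero":
                continue
            raise ValueError(f"unknown residue {ch!r} at position {t}")
        out[t, i] = 1.0
    return out


def similarity(model: RKNModel, x_t: np.ndarray, base: float = np.e) -> np.ndarray:
    """Per-level anchor similarities of one one-hot row: (k, q) array.

    ``b[j, i] = base ** (alpha * (<Z[j,:,i], x_t> - 1))``; for one-hot
    rows the dot product is just the matching anchor component.
    """
    dots = np.einsum("jsi,s->ji", model.Z, x_t)
    return np.power(base, model.alpha * (dots - 1.0))


def forward(model: RKNModel, onehot: np.ndarray,
            base: float = np.e) -> tuple[float, np.ndarray]:
    """Run the RKN recurrence; return (prediction, final mapping psi).

    Deterministic double precision; bit-identical for identical inputs.
    """
    k, q = model.k, model.q
    if onehot.ndim != 2 or onehot.shape[1] != model.Z.shape[1]:
        raise ValueError("sequence/model alphabet mismatch")
    c = np.zeros((k + 1, q), dtype=np.float64)
    c[0, :] = 1.0
    for t in range(onehot.shape[0]):
        b = similarity(model, onehot[t], base=base)
        c[1:, :] = model.lam * c[1:, :] + b * c[:-1, :]
    psi = model.G @ c[k]
    prediction = float(model.w @ psi + model.beta)
    return prediction, psi


# --------------------------------------------------------------------------
# model container: a directory of plain-text matrices plus a manifest


def save_model(model: RKNModel, directory) -> None:
    """Write a model as text matrices + JSON manifest (one file per tensor)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "anchors.tsv", model.Z.reshape(model.k * len(model.alphabet), model.q), delimiter="\t")
    np.savetxt(directory / "gram_inv_sqrt.tsv", model.G, delimiter="\t")
    np.savetxt(directory / "weights.tsv", model.w[None, :], delimiter="\t")
    manifest = {
        "format": "rkn-model/1",
        "q": model.q,
        "k": model.k,
        "alpha": model.alpha,
        "lambda": model.lam,
        "beta": model.beta,
        "alphabet": model.alphabet,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory) -> RKNModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format") != "rkn-model/1":
        raise ValueError("unrecognised model container")
    q, k = int(manifest["q"]), int(manifest["k"])
    alphabet = manifest["alphabet"]
    Z = np.loadtxt(directory / "anchors.tsv", delimiter="\t", ndmin=2)
    Z = Z.reshape(k, len(alphabet), q)
    model = RKNModel(
        Z=Z,
        alpha=float(manifest["alpha"]),
        lam=float(manifest["lambda"]),
        G=np.loadtxt(directory / "gram_inv_sqrt.tsv", delimiter="\t", ndmin=2),
        w=np.loadtxt(directory / "weights.tsv", delimiter="\t", ndmin=2).ravel(),
        beta=float(manifest["beta"]),
        alphabet=alphabet,
    )
    model.validate()
    return model


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
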
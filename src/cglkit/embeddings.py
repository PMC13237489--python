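"""Per-residue embedding contract, synthetic embedder, and pooling.

Embeddings are frozen model inputs: an L x D real matrix per sequence with
a validity mask used for batch padding.  The production provider is any
pretrained protein language model whose matrices are loaded from an archive
keyed by sequence id; the synthetic embedder here satisfies the same
contract deterministically, mapping each residue's local context window to
a seeded random projection so that label rules depending on residue
co-occurrence are representable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .seqio import _CANONICAL_SET

__all__ = [
    "ResidueEmbedding",
    "EmbedderSpec",
    "synthetic_embed",
    "mean_pool",
    "pad_batch",
    "save_archive",
    "load_archive",
]


@dataclass(frozen=True)
class ResidueEmbedding:
    """L x D matrix with an L-long validity mask."""

    sequence_id: str
    matrix: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if self.mask.shape != (self.matrix.shape[0],):
            raise ValueError("mask length must equal the row count")

    @property
    def length(self) -> int:
        return int(self.mask.sum())

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class EmbedderSpec:
    """Synthetic embedder configuration: output dim, context half-window, seed."""

    dim: int = 1152
    window: int = 2
    seed: int = 0


_BOUNDARY = "-"
_window_cache: dict[tuple, np.ndarray] = {}


def _window_vector(window: str, spec: EmbedderSpec) -> np.ndarray:
    key = (window, spec.dim, spec.seed)
    vec = _window_cache.get(key)
    if vec is None:
        digest = hashlib.blake2b(
            f"{spec.seed}|{spec.dim}|{window}".encode(), digest_size=8).digest()
        sub = np.random.default_rng(int.from_bytes(digest, "big") % (2**63))
        vec = sub.standard_normal(spec.dim) / np.sqrt(spec.dim)
        _window_cache[key] = vec
    return vec


def synthetic_embed(sequence: str, spec: EmbedderSpec = EmbedderSpec()
                    ) -> ResidueEmbedding:
    """Deterministic multi-scale context embedding of a canonical sequence.

    Row i sums seeded random projections of the k-mers centered on position
    i at every odd width from 1 (the residue identity) up to
    ``2 * window + 1`` (boundary-padded), scaled to roughly unit norm.
    Local sequence features therefore embed consistently wherever they
    occur, while two sequences differing at one position still differ
    exactly in the rows whose +-window context covers it.
    """
    bad = set(sequence) - _CANONICAL_SET
    if bad or not sequence:
        raise ValueError(f"non-canonical or empty sequence (bad={sorted(bad)})")
    w = spec.window
    padded = _BOUNDARY * w + sequence + _BOUNDARY * w
    widths = list(range(1, 2 * w + 2, 2))
    norm = np.sqrt(len(widths))
    rows = []
    for i in range(len(sequence)):
        c = i + w  # center in padded coordinates
        vec = sum(_window_vector(padded[c - k // 2: c + k // 2 + 1], spec)
                  for k in widths)
        rows.append(vec / norm)
    return ResidueEmbedding(
        sequence_id="", matrix=np.array(rows),
        mask=np.ones(len(sequence), dtype=bool))


def mean_pool(embedding: ResidueEmbedding) -> np.ndarray:
    """Arithmetic mean of the unmasked rows."""
    mask = embedding.mask
    if not mask.any():
        raise ValueError("cannot pool an embedding whose mask is all false")
    return embedding.matrix[mask].mean(axis=0)


def pad_batch(embeddings) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length embeddings into (B, Lmax, D) + (B, Lmax) mask."""
    embeddings = list(embeddings)
    if not embeddings:
        raise ValueError("empty batch")
    lmax = max(e.matrix.shape[0] for e in embeddings)
    d = embeddings[0].dim
    x = np.zeros((len(embeddings), lmax, d))
    mask = np.zeros((len(embeddings), lmax), dtype=bool)
    for i, e in enumerate(embeddings):
        li = e.matrix.shape[0]
        x[i, :li] = e.matrix
        mask[i, :li] = e.mask
    return x, mask


def save_archive(path, embeddings: dict[str, ResidueEmbedding],
                 provider: str = "synthetic") -> None:
    """One matrix per sequence_id plus a manifest, in an npz archive."""
    arrays = {}
    manifest = []
    for sid, emb in embeddings.items():
        arrays[f"mat::{sid}"] = emb.matrix
        arrays[f"mask::{sid}"] = emb.mask
        manifest.append(f"{sid}\t{emb.matrix.shape[0]}\t{emb.dim}\t{provider}")
    arrays["manifest"] = np.array(manifest)
    np.savez_compressed(path, **arrays)


def load_archive(path) -> dict[str, ResidueEmbedding]:
    data = np.load(path, allow_pickle=False)
    out = {}
    for line in data["manifest"]:
        sid = str(line).split("\t")[0]
        out[sid] = ResidueEmbedding(
            sequence_id=sid, matrix=data[f"mat::{sid}"],
            mask=data[f"mask::{sid}"].astype(bool))
    return out
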
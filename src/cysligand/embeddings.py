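"""Per-residue embedding providers.

The package treats embeddings as a pluggable contract: any provider that
returns an L x D matrix for a protein sequence can feed the clustering and
modeling stages.  Two providers ship here:

* :class:`SyntheticEmbeddingProvider` — deterministic, seed-driven vectors
  built from local sequence windows.  Cysteines whose windows hash to the
  same latent *archetype* share a centroid, and cysteines with identical
  windows (planted motifs in the synthetic proteome) are near-duplicates up
  to isotropic noise.  This geometry is the ground-truth driver the
  synthetic generator uses for true ligandability.
* :class:`CachedModelAdapter` — the interface for a real protein language
  model: it only reads pre-computed matrices from an on-disk cache (one
  ``.npy`` per uid plus a JSON sidecar carrying provider tag, layer,
  dimension and a sequence hash).  Without a cache hit it raises
  :class:`~cysligand.errors.CapabilityError`; there is never a silent
  fallback to the synthetic backend.
"""

from __future__ import annotations

import hashlib
import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._hash import rng_for, stable_u31
from .errors import CapabilityError, ContractError
from .records import ProteinEntry

PAD = "-"


@dataclass
class EmbeddingMatrix:
    uid: str
    matrix: np.ndarray  # L x D
    provider_tag: str
    layer_index: int = 0


def window_of(sequence: str, pos0: int, k: int) -> str:
    """Length-k window centered at 0-based ``pos0``, padded with '-'."""
    half = k // 2
    lo, hi = pos0 - half, pos0 + half + 1
    left = PAD * max(0, -lo)
    right = PAD * max(0, hi - len(sequence))
    return left + sequence[max(0, lo):min(len(sequence), hi)] + right


def window_archetype(window: str, n_archetypes: int, seed: int) -> int:
    """Deterministic latent-archetype id for a sequence window.

    Shared between the synthetic embedding provider and the synthetic data
    generator so that embedding geometry and ground-truth ligandability agree.
    """
    return stable_u31(seed, "arch", window) % n_archetypes


class EmbeddingProvider(ABC):
    name: str = "abstract"
    dim: int = 0
    deterministic: bool = True

    @abstractmethod
    def embed_positions(self, protein: ProteinEntry, positions0: list[int]) -> np.ndarray:
        """Rows for the given 0-based positions; shape (len(positions0), dim)."""

    def embed(self, protein: ProteinEntry) -> EmbeddingMatrix:
        mat = self.embed_positions(protein, list(range(len(protein.sequence))))
        return EmbeddingMatrix(uid=protein.uid, matrix=mat, provider_tag=self.name)


class SyntheticEmbeddingProvider(EmbeddingProvider):
    """Deterministic synthetic per-residue embeddings.

    Cysteine rows are built as ``normalize(centroid[archetype] + delta *
    motif_direction) + sigma * noise``; archetype and motif direction are both
    hash-functions of the k-residue window, the noise of the full sequence
    and position.  Defaults put same-window cosine near 0.97, same-archetype /
    different-window cosine near 0.7, and cross-archetype near 0, so a 0.9
    clustering threshold isolates motif-level clusters while a 0.5 threshold
    merges whole archetypes.  Non-cysteine residues get independent
    background directions.
    """

    def __init__(self, dim: int = 64, n_archetypes: int = 6, seed: int = 0,
                 window: int = 9, motif_spread: float = 0.655,
                 noise_sigma: float = 0.022):
        self.dim = dim
        self.n_archetypes = n_archetypes
        self.seed = seed
        self.window = window
        self.motif_spread = motif_spread
        self.noise_sigma = noise_sigma
        self.name = f"synthetic-d{dim}-a{n_archetypes}-s{seed}"
        self.deterministic = True
        self._centroids = np.stack([
            _unit(rng_for(seed, "centroid", a).standard_normal(dim))
            for a in range(n_archetypes)
        ])

    def embed_positions(self, protein: ProteinEntry, positions0: list[int]) -> np.ndarray:
        seq = protein.sequence
        seq_tag = hashlib.sha256(seq.encode()).hexdigest()[:16]
        rows = np.empty((len(positions0), self.dim))
        for i, p in enumerate(positions0):
            w = window_of(seq, p, self.window)
            if seq[p] == "C":
                a = window_archetype(w, self.n_archetypes, self.seed)
                sub = _unit(rng_for(self.seed, "sub", w).standard_normal(self.dim))
                base = _unit(self._centroids[a] + self.motif_spread * sub)
            else:
                base = _unit(rng_for(self.seed, "bg", w).standard_normal(self.dim))
            noise = rng_for(self.seed, "noise", seq_tag, p).standard_normal(self.dim)
            rows[i] = base + self.noise_sigma * noise
        return rows


class CachedModelAdapter(EmbeddingProvider):
    """Adapter for a real per-residue language model via an on-disk cache.

    The cache layout is ``<dir>/<uid>.npy`` + ``<dir>/<uid>.json`` with keys
    ``provider_tag``, ``layer_index``, ``dim`` and ``sequence_sha256``.  A hit
    requires the stored sequence hash to match; anything else is a
    :class:`CapabilityError` (model weights and inference are out of scope).
    """

    def __init__(self, cache_dir, name: str = "plm-adapter", dim: int = 2560,
                 layer_index: int = 76):
        self.cache_dir = Path(cache_dir) if cache_dir is not None else None
        self.name = name
        self.dim = dim
        self.layer_index = layer_index
        self.deterministic = True

    def _load(self, protein: ProteinEntry) -> np.ndarray:
        if self.cache_dir is None or not self.cache_dir.is_dir():
            raise CapabilityError(
                f"{self.name}: no embedding cache available; real-model "
                "inference is not provided")
        npy = self.cache_dir / f"{protein.uid}.npy"
        sidecar = self.cache_dir / f"{protein.uid}.json"
        if not npy.exists() or not sidecar.exists():
            raise CapabilityError(f"{self.name}: no cached embedding for {protein.uid}")
        meta = json.loads(sidecar.read_text())
        seq_hash = hashlib.sha256(protein.sequence.encode()).hexdigest()
        if meta.get("sequence_sha256") != seq_hash:
            raise CapabilityError(
                f"{self.name}: cached embedding for {protein.uid} was computed "
                "for a different sequence")
        mat = np.load(npy)
        if mat.shape != (len(protein.sequence), self.dim):
            raise ContractError(
                f"cached matrix for {protein.uid} has shape {mat.shape}, "
                f"expected ({len(protein.sequence)}, {self.dim})")
        return mat

    def embed_positions(self, protein: ProteinEntry, positions0: list[int]) -> np.ndarray:
        return self._load(protein)[positions0]

    @staticmethod
    def write_cache(cache_dir, protein: ProteinEntry, matrix: np.ndarray,
                    provider_tag: str, layer_index: int) -> None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        np.save(cache_dir / f"{protein.uid}.npy", matrix)
        (cache_dir / f"{protein.uid}.json").write_text(json.dumps({
            "provider_tag": provider_tag,
            "layer_index": layer_index,
            "dim": int(matrix.shape[1]),
            "sequence_sha256": hashlib.sha256(protein.sequence.encode()).hexdigest(),
        }, sort_keys=True))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ContractError("zero-norm vector")
    return v / n


def embed_protein(provider: EmbeddingProvider, protein: ProteinEntry) -> EmbeddingMatrix:
    mat = provider.embed(protein)
    if mat.matrix.shape[0] != len(protein.sequence):
        raise ContractError("row count does not match sequence length")
    if not np.all(np.isfinite(mat.matrix)):
        raise ContractError("non-finite values in embedding matrix")
    return mat


def pairwise_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity; raises on zero-norm input or dimension mismatch."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ContractError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def site_embeddings(provider: EmbeddingProvider, proteins: dict[str, ProteinEntry],
                    sites: list[tuple[str, int]]) -> dict[tuple[str, int], np.ndarray]:
    """Embed only the requested (uid, 1-based position) sites, grouped per uid."""
    by_uid: dict[str, list[int]] = {}
    for uid, pos in sites:
        by_uid.setdefault(uid, []).append(pos)
    out: dict[tuple[str, int], np.ndarray] = {}
    for uid in sorted(by_uid):
        positions = sorted(by_uid[uid])
        rows = provider.embed_positions(proteins[uid], [p - 1 for p in positions])
        for p, row in zip(positions, rows):
            out[(uid, p)] = row
    return out


__all__ = [
    "EmbeddingMatrix", "EmbeddingProvider", "SyntheticEmbeddingProvider",
    "CachedModelAdapter", "embed_protein", "pairwise_similarity",
    "site_embeddings", "window_of", "window_archetype",
]
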
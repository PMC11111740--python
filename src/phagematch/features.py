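"""Multi-instance feature representations for phage-host pairs.

Each protein is embedded as a fixed-length real vector; the vectors of a
phage's RBPs (or a bacterium's K-locus proteins) are averaged column-wise
into one multi-instance representation per entity; a phage and a bacterium
representation are concatenated — phage block first — into a pair feature
of twice the embedding dimension.

Two embedders are provided.  :class:`Esm2Embedder` adapts the pre-trained
ESM-2 protein language model (t33_650M_UR50D, 1280-d, final-layer per-residue
states mean-pooled over positions); it requires the external model weights.
:class:`KmerHashEmbedder` is a deterministic built-in stand-in — L2-normalized
counts of all length-k subsequences hashed into ``dim`` buckets — that is
sequence-sensitive, needs no downloads, and carries all hermetic tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import AA_ALPHABET


@dataclass(frozen=True)
class ProteinEmbedding:
    protein_id: str
    vector: np.ndarray


@dataclass(frozen=True)
class EntityRepresentation:
    """Column-wise mean of an entity's protein embeddings."""

    entity_id: str
    kind: str  # "phage" or "bacterium"
    vector: np.ndarray
    n_instances: int


@dataclass(frozen=True)
class PairFeature:
    """Concatenated phage+host vector of length 2d, phage block first."""

    phage_id: str
    bacterium_id: str
    vector: np.ndarray
    label: int | None = None


class KmerHashEmbedder(TransformerMixin, BaseEstimator):
    """Deterministic k-mer-composition protein embedder.

    For a sequence s the vector is built by counting every overlapping
    k-mer, adding each count to bucket

        ``int(blake2b(kmer, digest_size=8, key=str(hash_seed)), 16) % dim``,

    and L2-normalizing the bucket counts.  Stateless (``fit`` is a no-op),
    bit-reproducible across processes, and sensitive to sequence motifs,
    which is all the downstream classifier needs from an embedding.

    Parameters
    ----------
    dim : embedding dimension (number of hash buckets).
    k : k-mer length; sequences shorter than k are rejected.
    hash_seed : keys the hash so alternative bucketings can be produced.
    """

    def __init__(self, dim: int = 64, k: int = 3, hash_seed: int = 0):
        self.dim = dim
        self.k = k
        self.hash_seed = hash_seed

    def fit(self, X: Sequence[str], y=None):
        self.n_features_in_ = self.dim
        return self

    def _bucket(self, kmer: str) -> int:
        digest = hashlib.blake2b(
            kmer.encode("ascii"), digest_size=8,
            key=str(self.hash_seed).encode("ascii"),
        ).digest()
        return int.from_bytes(digest, "big") % self.dim

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if self.dim < 1 or self.k < 1:
            raise ValueError("dim and k must be positive")
        out = np.zeros((len(X), self.dim), dtype=np.float64)
        bucket_cache: dict[str, int] = {}
        for row, seq in enumerate(X):
            seq = seq.upper()
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"illegal amino-acid characters {sorted(bad)} in sequence {row}"
                )
            if len(seq) < self.k:
                raise ValueError(
                    f"sequence {row} shorter than k={self.k}"
                )
            for i in range(len(seq) - self.k + 1):
                kmer = seq[i : i + self.k]
                b = bucket_cache.get(kmer)
                if b is None:
                    b = bucket_cache[kmer] = self._bucket(kmer)
                out[row, b] += 1.0
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        return out / norms

    def __call__(self, sequences: Sequence[str]) -> np.ndarray:
        return self.transform(sequences)


class Esm2Embedder:
    """Adapter for the pre-trained ESM-2 protein language model.

    Uses the 650M-parameter ``t33_650M_UR50D`` configuration: final-layer
    (layer 33) per-residue representations, mean-pooled over residue
    positions, giving one 1280-dimensional vector per protein.  The model
    weights are an external dependency; constructing this adapter without
    them raises with instructions to use :class:`KmerHashEmbedder` instead.
    """

    name = "esm2_t33_650M_UR50D"
    dim = 1280
    layer = 33
    pooling = "mean"

    def __init__(self, device: str = "cpu"):
        try:
            import esm  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "The ESM-2 external model is unavailable (fair-esm/torch not "
                "installed). Use the built-in KmerHashEmbedder stand-in, or "
                "install fair-esm to embed with the language model."
            ) from exc
        self._torch = torch
        model, alphabet = esm.pretrained.esm2_t33_650M_UR50D()
        self._model = model.eval().to(device)
        self._batch_converter = alphabet.get_batch_converter()
        self._device = device

    def __call__(self, sequences: Sequence[str]) -> np.ndarray:
        torch = self._torch
        data = [(f"p{i}", s) for i, s in enumerate(sequences)]
        _, _, tokens = self._batch_converter(data)
        with torch.no_grad():
            out = self._model(
                tokens.to(self._device), repr_layers=[self.layer]
            )["representations"][self.layer]
        vectors = []
        for i, (_, seq) in enumerate(data):
            vectors.append(out[i, 1 : len(seq) + 1].mean(0).cpu().numpy())
        return np.vstack(vectors)


def embed_proteins(
    sequences: Sequence[tuple[str, str]], embedder
) -> list[ProteinEmbedding]:
    """Embed (protein_id, sequence) pairs; one vector per input, in order."""
    if not sequences:
        return []
    ids = [pid for pid, _ in sequences]
    matrix = np.asarray(embedder([seq for _, seq in sequences]), dtype=np.float64)
    if not np.isfinite(matrix).all():
        raise ValueError("embedder produced non-finite values")
    return [ProteinEmbedding(pid, matrix[i]) for i, pid in enumerate(ids)]


def aggregate_multi_instance(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise arithmetic mean of ≥1 equal-length vectors.

    Permutation-invariant by construction; the mean of n copies of v is v.
    """
    if len(vectors) == 0:
        raise ValueError("cannot aggregate an empty set of vectors")
    dims = {len(np.atleast_1d(v)) for v in vectors}
    if len(dims) != 1:
        raise ValueError(f"ragged vector dimensions: {sorted(dims)}")
    return np.mean(np.vstack(vectors), axis=0)


def entity_representation(
    entity_id: str,
    kind: str,
    protein_sequences: Sequence[tuple[str, str]],
    embedder,
) -> EntityRepresentation:
    """Embed an entity's proteins and aggregate to one vector."""
    embeddings = embed_proteins(protein_sequences, embedder)
    if not embeddings:
        raise ValueError(f"{kind} {entity_id!r} has no proteins to embed")
    vector = aggregate_multi_instance([e.vector for e in embeddings])
    return EntityRepresentation(entity_id, kind, vector, len(embeddings))


def build_pair_feature(
    phage_rep: EntityRepresentation,
    bacterium_rep: EntityRepresentation,
    label: int | None = None,
) -> PairFeature:
    """Concatenate phage and bacterium representations (phage block first).

    With d-dimensional inputs the result has length exactly 2d — e.g. 2560
    for the 1280-d language-model embeddings.
    """
    pv, bv = np.atleast_1d(phage_rep.vector), np.atleast_1d(bacterium_rep.vector)
    if pv.shape != bv.shape:
        raise ValueError(
            f"dimension mismatch: phage d={pv.shape}, bacterium d={bv.shape}"
        )
    return PairFeature(
        phage_rep.entity_id, bacterium_rep.entity_id,
        np.concatenate([pv, bv]), label,
    )


def build_pair_matrix(
    pairs: pd.DataFrame,
    phage_reps: Mapping[str, EntityRepresentation],
    bacterium_reps: Mapping[str, EntityRepresentation],
) -> np.ndarray:
    """Stack pair features for each row of a (phage_id, bacterium_id) frame."""
    rows = []
    for row in pairs.itertuples(index=False):
        pf = build_pair_feature(phage_reps[row.phage_id],
                                bacterium_reps[row.bacterium_id])
        rows.append(pf.vector)
    return np.vstack(rows) if rows else np.empty((0, 0))


def represent_entities(
    entities: Iterable[tuple[str, str, Sequence[tuple[str, str]]]],
    embedder,
) -> dict[str, EntityRepresentation]:
    """Bulk helper: (entity_id, kind, proteins) triples -> representations."""
    return {
        eid: entity_representation(eid, kind, prots, embedder)
        for eid, kind, prots in entities
    }
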
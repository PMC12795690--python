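"""Sequence-embedding providers behind one interface.

Two providers share the contract "amino-acid string in, (L, 1024) per-residue
matrix plus its mean-pooled 1024-vector out":

* ``mock`` — a deterministic seeded-hash embedding used throughout the test
  suite; identical sequences always embed identically and no model download
  is needed.  Each residue vector is a letter-specific base direction plus a
  smaller letter-and-position-specific perturbation, so pooled vectors carry
  composition information while remaining position sensitive.
* ``prostt5`` — an adapter for the frozen ProstT5 protein language-model
  encoder (half precision, batched).  It requires the external pretrained
  weights and the ``transformers`` library; when they are absent a
  :class:`ProviderUnavailableError` names the mock fallback.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import ProviderUnavailableError, ValidationError

EMBED_DIM = 1024
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_MOCK_BASE_SEED = 908_377


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino-acid sequence in uppercase canonical form."""

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        seq = "".join(c if c in STANDARD_AA else "X" for c in seq)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding rows and their column-wise mean."""

    per_residue: np.ndarray   # (L, 1024)
    pooled: np.ndarray        # (1024,)

    def __post_init__(self):
        self.per_residue = np.asarray(self.per_residue, float)
        self.pooled = np.asarray(self.pooled, float)
        if self.per_residue.shape[1] != EMBED_DIM or self.pooled.shape != (EMBED_DIM,):
            raise ValidationError("embedding width must be 1024")
        if np.max(np.abs(self.pooled - self.per_residue.mean(axis=0))) > 1e-6:
            raise ValidationError("pooled vector must equal the column mean")

    @classmethod
    def from_rows(cls, rows: np.ndarray) -> "EmbeddingMatrix":
        rows = np.asarray(rows, float)
        return cls(rows, rows.mean(axis=0))


@lru_cache(maxsize=65536)
def _letter_vector(letter: str) -> np.ndarray:
    seed = (_MOCK_BASE_SEED * 31 + ord(letter)) % (2**31)
    return np.random.default_rng(seed).standard_normal(EMBED_DIM)


@lru_cache(maxsize=262144)
def _letter_position_vector(letter: str, position: int) -> np.ndarray:
    seed = (_MOCK_BASE_SEED + ord(letter) * 1_000_003 + position * 9_176) % (2**31)
    return np.random.default_rng(seed).standard_normal(EMBED_DIM)


def _mock_embed(record: SequenceRecord) -> EmbeddingMatrix:
    rows = np.stack([
        _letter_vector(c) + 0.5 * _letter_position_vector(c, i)
        for i, c in enumerate(record.sequence)
    ])
    return EmbeddingMatrix.from_rows(rows)


def _prostt5_embed(record: SequenceRecord) -> EmbeddingMatrix:
    try:
        import transformers  # noqa: F401
    except ImportError as exc:
        raise ProviderUnavailableError(
            "the 'prostt5' provider needs the transformers library and the "
            "pretrained ProstT5 weights; use provider='mock' for a "
            "deterministic desk-scale embedding") from exc
    raise ProviderUnavailableError(
        "ProstT5 weights are not bundled; download them and wire a cache "
        "directory, or use provider='mock'")


PROVIDERS = {"mock": _mock_embed, "prostt5": _prostt5_embed}


def embed(record: SequenceRecord, provider: str = "mock") -> EmbeddingMatrix:
    """Embed one sequence as an (L, 1024) matrix plus pooled 1024-vector."""
    if provider not in PROVIDERS:
        raise ValidationError(f"unknown provider {provider!r}")
    return PROVIDERS[provider](record)


def batch_embed(records: list[SequenceRecord], provider: str = "mock",
                batch_size: int = 8) -> list[EmbeddingMatrix]:
    """Order-preserving batched embedding; results do not depend on batch_size."""
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    out: list[EmbeddingMatrix] = []
    for lo in range(0, len(records), batch_size):
        out.extend(embed(r, provider) for r in records[lo:lo + batch_size])
    return out


# ---------------------------------------------------------------------------
# FASTA input and a small on-disk cache
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def cached_embed(record: SequenceRecord, provider: str = "mock",
                 cache_dir=None) -> EmbeddingMatrix:
    """Embed with an npz cache keyed by (provider, sequence hash)."""
    if cache_dir is None:
        return embed(record, provider)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = hashlib.sha1(f"{provider}:{record.sequence}".encode()).hexdigest()
    path = cache_dir / f"{key}.npz"
    if path.exists():
        d = np.load(path)
        return EmbeddingMatrix(d["per_residue"], d["pooled"])
    mat = embed(record, provider)
    np.savez(path, per_residue=mat.per_residue, pooled=mat.pooled)
    return mat
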
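"""Semantic similarity between written summaries and heard speech segments.

Three complementary scores quantify how much of a heard segment a written
summary captures:

* **written-summary score** — for every summary word, the maximum cosine
  similarity to any segment word, summed over summary words.  Sensitive to
  summary length, so a single verbatim match cannot dominate, while longer
  conceptual summaries are rewarded.
* **heard-segment score** — for every segment word, the maximum cosine
  similarity to any summary word, averaged.  Normalizes by segment length,
  rewarding coverage of the heard material.
* **contextual score** — cosine similarity of single-vector encodings of the
  two texts, produced by any deterministic text encoder (context-sensitive
  sentence encoders fit this contract; the packaged encoder mean-pools word
  vectors).

Word vectors are abstracted behind :class:`EmbeddingTable`, readable from the
word2vec text format.  Out-of-vocabulary words are skipped and counted, never
replaced by zero vectors (a zero vector would silently corrupt max-cosine
scores).  Stop words are retained by default — scores take the texts as
written — with an optional filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .slider import pentile_split

_TOKEN_RE = re.compile(r"[a-z0-9']+")


class VocabularyError(ValueError):
    """Raised when no in-vocabulary words remain for a required text."""


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace; order preserved."""
    return _TOKEN_RE.findall(text.lower())


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u, v) / (|u| |v|); zero-norm inputs are a domain error."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


class EmbeddingTable:
    """Word -> vector lookup with a defined miss (KeyError, never a zero vector)."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table needs at least one word")
        dims = {len(np.atleast_1d(v)) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        self._vectors = {w: np.asarray(v, float) for w, v in vectors.items()}
        self.dim = dims.pop()

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def vocabulary(self) -> set[str]:
        return set(self._vectors)

    def filter_known(self, words: Iterable[str]) -> tuple[list[str], int]:
        """Split words into (in-vocabulary list, out-of-vocabulary count)."""
        known = [w for w in words if w in self._vectors]
        return known, sum(1 for w in words if w not in self._vectors)

    # -- word2vec text format ------------------------------------------------

    @classmethod
    def from_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        """Read the word2vec text format: a "<vocab> <dim>" header line, then
        one "word v1 ... vd" line per word."""
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError("expected a '<vocab> <dim>' header line")
            n_words, dim = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"bad vector line for {parts[0]!r}")
                vectors[parts[0]] = np.array(parts[1:], dtype=float)
        if len(vectors) != n_words:
            raise ValueError(f"header declared {n_words} words, file has {len(vectors)}")
        return cls(vectors)

    def to_word2vec(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self)} {self.dim}\n")
            for word, vec in self._vectors.items():
                fh.write(word + " " + " ".join(repr(float(x)) for x in vec) + "\n")


#: Contract for context-sensitive encoders: a deterministic text -> vector map.
ContextualEncoder = Callable[[str], np.ndarray]


class MeanPoolEncoder:
    """Deterministic text encoder: mean of in-vocabulary word vectors.

    Serves as the packaged implementation of the :data:`ContextualEncoder`
    contract (and as a transparent test double for sentence encoders).
    """

    def __init__(self, table: EmbeddingTable):
        self.table = table

    def __call__(self, text: str) -> np.ndarray:
        known, _ = self.table.filter_known(tokenize(text))
        if not known:
            raise VocabularyError("no in-vocabulary words to encode")
        return np.mean([self.table[w] for w in known], axis=0)


@dataclass
class ScoredSummary:
    """The three similarity scores for one trial's summary, with word counts."""

    trial_id: str
    written_summary_score: float
    heard_segment_score: float
    contextual_score: float
    n_summary_words: int
    n_segment_words: int
    n_summary_oov: int = 0
    n_segment_oov: int = 0


def _max_cosines(targets: Sequence[str], pool: Sequence[str], emb: EmbeddingTable) -> np.ndarray:
    """For each target word, the max cosine against any pool word (all in-vocab)."""
    T = np.array([emb[w] for w in targets])
    P = np.array([emb[w] for w in pool])
    T = T / np.linalg.norm(T, axis=1, keepdims=True)
    P = P / np.linalg.norm(P, axis=1, keepdims=True)
    return (T @ P.T).max(axis=1)


def written_summary_score(
    summary: Sequence[str], segment: Sequence[str], emb: EmbeddingTable
) -> float:
    """Sum over summary words of each word's best cosine match in the segment."""
    seg_known, _ = emb.filter_known(segment)
    if not seg_known:
        raise VocabularyError("segment has no in-vocabulary words")
    sum_known, _ = emb.filter_known(summary)
    if not sum_known:
        return 0.0
    return float(_max_cosines(sum_known, seg_known, emb).sum())


def heard_segment_score(
    summary: Sequence[str], segment: Sequence[str], emb: EmbeddingTable
) -> float:
    """Mean over segment words of each word's best cosine match in the summary."""
    sum_known, _ = emb.filter_known(summary)
    if not sum_known:
        raise VocabularyError("summary has no in-vocabulary words")
    seg_known, _ = emb.filter_known(segment)
    if not seg_known:
        raise VocabularyError("segment has no in-vocabulary words")
    return float(_max_cosines(seg_known, sum_known, emb).mean())


def contextual_similarity(summary_text: str, segment_text: str, enc: ContextualEncoder) -> float:
    """Cosine similarity of the two encoder vectors."""
    if not summary_text.strip() or not segment_text.strip():
        raise ValueError("contextual similarity needs two non-empty texts")
    return cosine(enc(summary_text), enc(segment_text))


def score_summary(
    trial_id: str,
    summary_text: str,
    segment_text: str,
    emb: EmbeddingTable,
    enc: ContextualEncoder | None = None,
) -> ScoredSummary:
    """All three scores for one trial (encoder defaults to mean pooling)."""
    summary = tokenize(summary_text)
    segment = tokenize(segment_text)
    enc = enc or MeanPoolEncoder(emb)
    _, sum_oov = emb.filter_known(summary)
    _, seg_oov = emb.filter_known(segment)
    return ScoredSummary(
        trial_id=trial_id,
        written_summary_score=written_summary_score(summary, segment, emb),
        heard_segment_score=heard_segment_score(summary, segment, emb),
        contextual_score=contextual_similarity(summary_text, segment_text, enc),
        n_summary_words=len(summary),
        n_segment_words=len(segment),
        n_summary_oov=sum_oov,
        n_segment_oov=seg_oov,
    )


def pentile_similarity_profile(
    summary: Sequence[str],
    segment: Sequence[str],
    method: str,
    emb_or_enc,
) -> np.ndarray:
    """Similarity of the summary to each contiguous fifth of the segment words.

    The segment is split into five word pentiles (sizes differing by at most
    one, remainder to the earliest bins) and the chosen score — ``written``,
    ``heard`` or ``contextual`` — is computed summary-vs-pentile.  A profile
    rising across bins indicates a recency bias in what the summary covers.
    """
    bins = pentile_split(list(segment))
    if method == "written":
        return np.array([written_summary_score(summary, list(b), emb_or_enc) for b in bins])
    if method == "heard":
        return np.array([heard_segment_score(summary, list(b), emb_or_enc) for b in bins])
    if method == "contextual":
        return np.array(
            [contextual_similarity(" ".join(summary), " ".join(b), emb_or_enc) for b in bins]
        )
    raise ValueError(f"unknown method {method!r}")


def correlate_measures(scores: Sequence[ScoredSummary]) -> pd.DataFrame:
    """Pairwise Pearson correlations between the three similarity measures."""
    if len(scores) < 3:
        raise ValueError("correlating the measures needs at least 3 trials")
    df = pd.DataFrame(
        {
            "written": [s.written_summary_score for s in scores],
            "heard": [s.heard_segment_score for s in scores],
            "contextual": [s.contextual_score for s in scores],
        }
    )
    if (df.std(ddof=0) == 0).any():
        flat = df.columns[(df.std(ddof=0) == 0)].tolist()
        raise ValueError(f"correlation undefined: zero variance in {flat}")
    return df.corr(method="pearson")


def scores_to_frame(scores: Sequence[ScoredSummary]) -> pd.DataFrame:
    """Long-format (trial_id, method, score) table for CSV export."""
    rows = []
    for s in scores:
        rows.append({"trial_id": s.trial_id, "method": "written", "score": s.written_summary_score})
        rows.append({"trial_id": s.trial_id, "method": "heard", "score": s.heard_segment_score})
        rows.append({"trial_id": s.trial_id, "method": "contextual", "score": s.contextual_score})
    return pd.DataFrame(rows)
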
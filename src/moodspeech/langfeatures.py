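"""NLP and semantic indices from word-timestamped transcripts.

Computes, for a prose-recall retelling against a reference story: word count,
story-match count, latency to first word, mean intraword time, and word
mover's distance (WMD) in an externally supplied word-embedding space. The
transcript format mirrors ASR output: an ordered list of words with onset
and offset times in seconds.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

_PUNCT = re.compile(r"[^\w\s]", flags=re.UNICODE)


def normalize_tokens(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace. Deterministic and
    idempotent (tokens contain only word characters)."""
    return _PUNCT.sub("", text.lower()).split()


@dataclass(frozen=True)
class Word:
    token: str
    start_s: float
    end_s: float


@dataclass(frozen=True)
class TimedTranscript:
    """Ordered words with onset/offset seconds; task_start_s is the clock
    origin for latency (default 0 = recording start)."""

    words: Sequence[Word]
    task_start_s: float = 0.0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_start = -np.inf
        for w in self.words:
            if not w.start_s < w.end_s:
                raise ValueError(f"word {w.token!r}: start must precede end")
            if w.start_s < prev_start:
                raise ValueError("words must be sorted by onset")
            if w.start_s < prev_end:
                raise ValueError(f"word {w.token!r} overlaps its predecessor")
            prev_start, prev_end = w.start_s, w.end_s

    @property
    def tokens(self) -> list[str]:
        return [w.token for w in self.words]

    @property
    def n_words(self) -> int:
        return len(self.words)

    @classmethod
    def from_json(cls, text: str) -> "TimedTranscript":
        obj = json.loads(text)
        return cls(
            words=[Word(w["w"], float(w["start_s"]), float(w["end_s"]))
                   for w in obj["words"]],
            task_start_s=float(obj.get("task_start_s", 0.0)),
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "TimedTranscript":
        return cls.from_json(Path(path).read_text())

    def to_json(self) -> str:
        return json.dumps(
            {
                "task_start_s": self.task_start_s,
                "words": [
                    {"w": w.token, "start_s": w.start_s, "end_s": w.end_s}
                    for w in self.words
                ],
            }
        )


@dataclass(frozen=True)
class ReferenceStory:
    """The correct prose-recall story; tokens are the normalized word list."""

    raw_text: str

    @property
    def tokens(self) -> list[str]:
        return normalize_tokens(self.raw_text)

    @property
    def token_set(self) -> frozenset[str]:
        return frozenset(self.tokens)

    @classmethod
    def read_text(cls, path: str | Path) -> "ReferenceStory":
        return cls(raw_text=Path(path).read_text(encoding="utf-8"))


class EmbeddingTable:
    """word -> fixed-dimension real vector, loaded from word2vec-style text
    (whitespace-delimited, optional "<count> <dim>" header line)."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table is empty")
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")
        self._vectors = {w: np.asarray(v, dtype=np.float64) for w, v in vectors.items()}
        self.dim = next(iter(self._vectors.values())).size

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def vocabulary(self) -> set[str]:
        return set(self._vectors)

    @classmethod
    def read_text(cls, path: str | Path) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            parts = first.split()
            header = len(parts) == 2 and all(p.isdigit() for p in parts)
            if not header and parts:
                vectors[parts[0]] = np.array(parts[1:], dtype=np.float64)
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                word = parts[0]
                if word in vectors:
                    raise ValueError(f"duplicate word in embedding table: {word!r}")
                vectors[word] = np.array(parts[1:], dtype=np.float64)
        return cls(vectors)

    def write_text(self, path: str | Path, header: bool = True) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"{len(self._vectors)} {self.dim}\n")
            for word, vec in self._vectors.items():
                fh.write(word + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def count_features(transcript: TimedTranscript, story: ReferenceStory) -> tuple[int, int]:
    """(n_words, n_matched): total transcript tokens, and how many of them
    (counted with multiplicity) normalize to a token present in the story."""
    story_set = story.token_set
    norm = [t for token in transcript.tokens for t in normalize_tokens(token)[:1]]
    n_matched = sum(1 for t in norm if t in story_set)
    return transcript.n_words, n_matched


def timing_scores(
    transcript: TimedTranscript, convention: str = "onset"
) -> tuple[float, float]:
    """(latency_s, mean_intraword_s).

    Latency is first-word onset minus task start. Mean intraword time is the
    mean onset-to-onset interval between successive words ("onset"), or the
    mean offset-to-next-onset gap ("gap"). Missing values are NaN.
    """
    if convention not in ("onset", "gap"):
        raise ValueError("convention must be 'onset' or 'gap'")
    if transcript.n_words == 0:
        return float("nan"), float("nan")
    latency = transcript.words[0].start_s - transcript.task_start_s
    if transcript.n_words < 2:
        return latency, float("nan")
    starts = np.array([w.start_s for w in transcript.words])
    ends = np.array([w.end_s for w in transcript.words])
    if convention == "onset":
        intra = float(np.mean(np.diff(starts)))
    else:
        intra = float(np.mean(starts[1:] - ends[:-1]))
    return latency, intra


def _bag_of_words(
    tokens: Iterable[str], emb: EmbeddingTable
) -> tuple[list[str], np.ndarray, int]:
    """Distinct in-vocabulary tokens, normalized mass vector, OOV count."""
    in_vocab: list[str] = []
    counts: dict[str, int] = {}
    oov = 0
    for t in tokens:
        if t in emb:
            counts[t] = counts.get(t, 0) + 1
        else:
            oov += 1
    words = sorted(counts)
    if not words:
        return [], np.array([]), oov
    mass = np.array([counts[w] for w in words], dtype=np.float64)
    return words, mass / mass.sum(), oov


def word_movers_distance(
    doc_tokens: Sequence[str],
    ref_tokens: Sequence[str],
    embeddings: EmbeddingTable,
) -> tuple[float, int, int]:
    """Minimum-cost transport between the two normalized bag-of-words mass
    distributions, with Euclidean ground distance between embedding vectors.

    Returns (wmd, doc_oov_count, ref_oov_count); wmd is NaN when either side
    is empty after out-of-vocabulary filtering. The transportation LP is
    solved exactly (HiGHS); the distance is symmetric in its arguments.
    """
    doc_words, a, doc_oov = _bag_of_words(doc_tokens, embeddings)
    ref_words, b, ref_oov = _bag_of_words(ref_tokens, embeddings)
    if not doc_words or not ref_words:
        return float("nan"), doc_oov, ref_oov

    x = np.stack([embeddings[w] for w in doc_words])
    y = np.stack([embeddings[w] for w in ref_words])
    cost = cdist(x, y, metric="euclidean")
    m, n = cost.shape
    if m == 1 and n == 1:
        return float(cost[0, 0]), doc_oov, ref_oov

    # transportation LP: min <C, F>, F >= 0, row sums = a, col sums = b
    a_eq = []
    for i in range(m):
        row = np.zeros(m * n)
        row[i * n:(i + 1) * n] = 1.0
        a_eq.append(row)
    for j in range(n - 1):  # drop one redundant constraint for full rank
        col = np.zeros(m * n)
        col[j::n] = 1.0
        a_eq.append(col)
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(cost.ravel(), A_eq=np.stack(a_eq), b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - LP on a feasible polytope
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun), doc_oov, ref_oov


class LanguageFeatureExtractor(BaseEstimator):
    """Transforms timed transcripts into the language-feature panel.

    Parameters
    ----------
    story : ReferenceStory
        The correct prose-recall story.
    embeddings : EmbeddingTable
        Word vectors for the word mover's distance; never bundled, always an
        explicit input.
    intraword_convention : {"onset", "gap"}
        Interval definition for mean intraword time.
    """

    def __init__(self, story: ReferenceStory, embeddings: EmbeddingTable,
                 intraword_convention: str = "onset"):
        self.story = story
        self.embeddings = embeddings
        self.intraword_convention = intraword_convention

    def fit(self, X=None, y=None):  # stateless; present for sklearn composition
        return self

    def extract(self, transcript: TimedTranscript) -> dict[str, float]:
        n_words, n_matched = count_features(transcript, self.story)
        latency, intra = timing_scores(transcript, self.intraword_convention)
        doc = [t for token in transcript.tokens for t in normalize_tokens(token)]
        wmd, doc_oov, ref_oov = word_movers_distance(
            doc, self.story.tokens, self.embeddings
        )
        return {
            "n_words": float(n_words),
            "n_matched": float(n_matched),
            "latency_s": latency,
            "mean_intraword_s": intra,
            "wmd": wmd,
            "wmd_doc_oov": float(doc_oov),
            "wmd_ref_oov": float(ref_oov),
        }

    def transform(self, transcripts: Iterable[TimedTranscript]) -> pd.DataFrame:
        return pd.DataFrame([self.extract(t) for t in transcripts])


LANGUAGE_FEATURES = ["n_words", "n_matched", "latency_s", "mean_intraword_s", "wmd"]
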
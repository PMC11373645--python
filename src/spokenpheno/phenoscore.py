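"""Per-observation height signals from free text.

Two scoring routes are provided, mirroring the two ways a spoken field
observation can be turned into a number:

* **semantic similarity** — cosine similarity between an embedding of the
  observation text and an embedding of a height query phrase ("tall",
  "tall plant", "tall height"), clipped to [0, 1];
* **phrase binning** — lookup of curated height phrases on an ordinal
  0–7 scale (0: no growth … 6: tall plants, 7: very tall plants).

The embedding backend is a pluggable contract so a pretrained sentence
encoder can be dropped in; the default backend is a deterministic hashed
bag-of-words vectorizer, which keeps the pipeline free of model weights.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import HashingVectorizer

__all__ = [
    "EmbeddingBackend",
    "HashedBowBackend",
    "PhraseLexicon",
    "BinAssignment",
    "get_backend",
    "similarity",
    "score_transcripts_semantic",
    "match_height_phrases",
    "score_transcripts_bins",
    "retention_stats",
    "default_lexicon",
    "DEFAULT_QUERIES",
]

DEFAULT_QUERIES = ("tall", "tall plant", "tall height")

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


class EmbeddingBackend(Protocol):
    """Contract for text embedding: deterministic, fixed dimension."""

    @property
    def dimension(self) -> int: ...

    def embed(self, text: str) -> np.ndarray: ...


class HashedBowBackend:
    """Hashed bag-of-words embedding (deterministic, weight-free).

    Tokens are lowercased \\w+ sequences hashed into a fixed-dimension
    count vector (murmurhash via scikit-learn, no sign alternation), so
    identical text always embeds identically and token-disjoint texts are
    orthogonal up to hash collisions.
    """

    name = "hashed-bow"

    def __init__(self, n_features: int = 2**18):
        self._vec = HashingVectorizer(
            n_features=n_features,
            alternate_sign=False,
            norm=None,
            lowercase=True,
            token_pattern=r"\w+",
        )
        self._dim = n_features

    @property
    def dimension(self) -> int:
        return self._dim

    def embed(self, text: str) -> np.ndarray:
        return np.asarray(self._vec.transform([text]).todense()).ravel()

    # bulk path used by score_transcripts_semantic; sparse, no densify
    def _embed_many(self, texts: Sequence[str]):
        return self._vec.transform(texts)


_BACKENDS = {"hashed-bow": HashedBowBackend}


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Look up an embedding backend by registry name."""
    try:
        return _BACKENDS[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown embedding backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None


def similarity(text: str, query: str, backend: EmbeddingBackend) -> float:
    """Cosine similarity of two texts' embeddings, clipped to [0, 1].

    Symmetric in its text arguments.  A zero-norm embedding (for the
    default backend: no tokens at all) yields 0.0 with a warning.
    """
    if not text or not query:
        raise ValueError("text and query must be non-empty")
    a = backend.embed(text)
    b = backend.embed(query)
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        warnings.warn("zero-norm embedding; similarity set to 0", stacklevel=2)
        return 0.0
    return float(np.clip(float(a @ b) / (na * nb), 0.0, 1.0))


def score_transcripts_semantic(
    observations: pd.DataFrame,
    queries: Sequence[str] = DEFAULT_QUERIES,
    backend: EmbeddingBackend | None = None,
    text_col: str = "text",
) -> pd.DataFrame:
    """Score every observation against every height query phrase.

    Returns a copy of ``observations`` with one similarity column per
    query (named after the query).  Downstream analyses use the "tall"
    column.
    """
    if backend is None:
        backend = HashedBowBackend()
    out = observations.copy()
    texts = out[text_col].astype(str).tolist()
    if isinstance(backend, HashedBowBackend) and texts:
        X = backend._embed_many(texts)  # n_obs x dim, sparse
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1))).ravel()
        for q in queries:
            qv = backend._embed_many([q])
            qn = float(np.sqrt(qv.multiply(qv).sum()))
            dots = np.asarray((X @ qv.T).todense()).ravel()
            with np.errstate(invalid="ignore", divide="ignore"):
                sims = dots / (norms * qn)
            sims = np.nan_to_num(sims, nan=0.0)
            out[q] = np.clip(sims, 0.0, 1.0)
    else:
        for q in queries:
            out[q] = [similarity(t, q, backend) if _tokens(t) else 0.0 for t in texts]
    return out


# ---------------------------------------------------------------------------
# Phrase binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhraseLexicon:
    """Curated height phrases mapped to ordinal bins 0–7.

    Bin semantics: 0 no growth, 1 very short, 2 short, 3 short–medium,
    4 medium, 5 medium–tall, 6 tall, 7 very tall plants.  Phrases are
    stored lowercase-normalized and tokenized on word characters, so
    hyphenation ("medium-tall") and case differences never matter.
    """

    phrase_bins: Mapping[str, int]
    _token_map: dict[tuple[str, ...], int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.phrase_bins:
            raise ValueError("lexicon is empty")
        token_map: dict[tuple[str, ...], int] = {}
        for phrase, b in self.phrase_bins.items():
            b = int(b)
            if not 0 <= b <= 7:
                raise ValueError(f"bin {b} for phrase {phrase!r} outside 0–7")
            toks = tuple(_tokens(phrase))
            if not toks:
                raise ValueError(f"phrase {phrase!r} has no tokens")
            if toks in token_map and token_map[toks] != b:
                raise ValueError(f"phrase {phrase!r} mapped to two bins")
            token_map[toks] = b
        object.__setattr__(self, "_token_map", token_map)

    @property
    def bins_covered(self) -> set[int]:
        return set(self._token_map.values())

    def phrases_for_bin(self, b: int) -> list[str]:
        return [" ".join(t) for t, bb in self._token_map.items() if bb == b]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhraseLexicon":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["phrase"].astype(str), df["bin"].astype(int))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"phrase": list(self.phrase_bins), "bin": list(self.phrase_bins.values())}
        ).to_csv(path, sep="\t", index=False)


def default_lexicon() -> PhraseLexicon:
    """The shipped height-phrase lexicon covering all eight bins."""
    with resources.as_file(
        resources.files("spokenpheno").joinpath("data/height_lexicon.tsv")
    ) as p:
        return PhraseLexicon.from_tsv(p)


@dataclass(frozen=True)
class BinAssignment:
    """Outcome of matching one observation against the lexicon."""

    bin: int | None
    matched: tuple[str, ...]


def match_height_phrases(text: str, lexicon: PhraseLexicon) -> BinAssignment:
    """Assign an ordinal height bin to a free-text observation.

    All lexicon phrases occurring in the text as contiguous token runs are
    collected; the assignment is the bin of the longest matched phrase
    (token count).  Ties on length take the arithmetic mean of the tied
    bins, rounded half away from zero.  No match yields ``bin=None``.
    """
    toks = _tokens(text)
    n = len(toks)
    hits: list[tuple[tuple[str, ...], int]] = []
    for ptoks, b in lexicon._token_map.items():
        k = len(ptoks)
        if k > n:
            continue
        for i in range(n - k + 1):
            if tuple(toks[i : i + k]) == ptoks:
                hits.append((ptoks, b))
                break
    if not hits:
        return BinAssignment(None, ())
    maxlen = max(len(p) for p, _ in hits)
    top = [(p, b) for p, b in hits if len(p) == maxlen]
    bins = [b for _, b in top]
    mean = float(np.mean(bins))
    # round half away from zero (bins are non-negative, so: floor(x + .5))
    assigned = int(np.floor(mean + 0.5))
    return BinAssignment(assigned, tuple(" ".join(p) for p, _ in hits))


def score_transcripts_bins(
    observations: pd.DataFrame,
    lexicon: PhraseLexicon | None = None,
    text_col: str = "text",
) -> pd.DataFrame:
    """Apply :func:`match_height_phrases` to every observation.

    Adds ``bin`` (nullable integer) and ``matched_phrases`` columns.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    out = observations.copy()
    assigns = [match_height_phrases(t, lexicon) for t in out[text_col].astype(str)]
    out["bin"] = pd.array([a.bin for a in assigns], dtype="Int64")
    out["matched_phrases"] = ["; ".join(a.matched) for a in assigns]
    return out


def retention_stats(
    observations: pd.DataFrame,
    scored: pd.DataFrame,
    participant_col: str = "participant",
    phrase_bearing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Observation-retention accounting per participant and overall.

    ``scored`` is the subset of ``observations`` that yielded a usable
    value under a scoring method.  Reports retained counts and the
    proportion of total observed rows; when ``phrase_bearing`` is given
    (observations containing at least one height phrase), additionally
    the proportion of those retained — the two parenthesized proportions
    of the retention table.
    """
    def _counts(df: pd.DataFrame) -> pd.Series:
        return df.groupby(participant_col).size()

    total = _counts(observations)
    kept = _counts(scored).reindex(total.index, fill_value=0)
    res = pd.DataFrame({"total": total, "retained": kept})
    res["proportion"] = res["retained"] / res["total"]
    if phrase_bearing is not None:
        pb = _counts(phrase_bearing).reindex(total.index, fill_value=0)
        res["phrase_bearing"] = pb
        with np.errstate(invalid="ignore"):
            res["proportion_of_phrase_bearing"] = np.where(
                pb > 0, res["retained"] / pb, np.nan
            )
    overall = {
        "total": res["total"].sum(),
        "retained": res["retained"].sum(),
        "proportion": res["retained"].sum() / res["total"].sum(),
    }
    if phrase_bearing is not None:
        pbs = res["phrase_bearing"].sum()
        overall["phrase_bearing"] = pbs
        overall["proportion_of_phrase_bearing"] = (
            res["retained"].sum() / pbs if pbs else np.nan
        )
    res.loc["Sum"] = overall
    return res
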
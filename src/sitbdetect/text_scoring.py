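"""Clinical-text scoring chains for encounter-level SITB evidence.

Three chains produce one score per encounter:

* ``knn_general`` — semisupervised sentence scoring: sentences are
  embedded, the K nearest labeled sentences (angular distance) vote, a
  sentence score is the mean of the K neighbor labels, and the encounter
  score is the mean over its sentences.
* ``knn_medical`` — the identical chain under a second embedding backend.
* ``likert`` — per-note integer scores on a -3..+3 scale (definitely no
  SITB .. definitely SITB), max-aggregated over the encounter's notes.
  A deterministic lexicon/ladder scorer plays the role of the language
  model; real model output is consumed through the same JSON parsing
  contract.

The default embedding backends are deterministic hashed bag-of-token
vectors (L2-normalized), so the whole chain runs offline and reproducibly;
pretrained sentence encoders can be plugged in behind the same interface.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .synthetic_ehr import Note

__all__ = [
    "EmbeddingBackend",
    "HashedEmbedding",
    "get_backend",
    "KnnConfig",
    "LabeledSentenceIndex",
    "LikertScore",
    "EncounterTextScore",
    "segment_sentences",
    "build_labeled_index",
    "knn_sentence_score",
    "encounter_score_mean",
    "rule_based_likert",
    "parse_model_output",
    "encounter_score_max",
    "score_encounters_knn",
    "score_encounters_likert",
    "IndexConfigurationError",
]


class IndexConfigurationError(ValueError):
    """Neighbor-index configuration violates its preconditions."""


# --------------------------------------------------------------------------
# sentence segmentation

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+|\n+")


def segment_sentences(text: str) -> list[str]:
    """Split note text into sentences at terminal punctuation or newlines.

    The concatenation of the returned sentences reconstructs the input
    modulo boundary whitespace; text without terminal punctuation comes
    back as a single span, and empty text yields an empty list.
    """
    if not text or not text.strip():
        return []
    parts = [p.strip() for p in _SENT_BOUNDARY.split(text)]
    return [p for p in parts if p]


# --------------------------------------------------------------------------
# embedding backends

@dataclass(frozen=True)
class EmbeddingBackend:
    """A named sentence-embedding function with fixed output dimension."""

    name: str
    dimension: int
    embed_fn: Callable[[str], np.ndarray]

    def embed(self, text: str) -> np.ndarray:
        v = np.asarray(self.embed_fn(text), dtype=float)
        if v.shape != (self.dimension,) or not np.all(np.isfinite(v)):
            raise ValueError(f"backend {self.name!r} produced an invalid vector")
        return v

    def embed_many(self, texts: Sequence[str]) -> np.ndarray:
        if len(texts) == 0:
            return np.zeros((0, self.dimension))
        return np.vstack([self.embed(t) for t in texts])


_TOKEN = re.compile(r"[a-z0-9]+")


def _hash_index(token: str, salt: str, dim: int) -> tuple[int, float]:
    h = hashlib.md5(f"{salt}|{token}".encode()).digest()
    idx = int.from_bytes(h[:4], "little") % dim
    sign = 1.0 if h[4] % 2 == 0 else -1.0
    return idx, sign


def HashedEmbedding(name: str, dimension: int, salt: str, use_bigrams: bool = False) -> EmbeddingBackend:
    """Deterministic hashed bag-of-tokens embedding (signed, L2-normalized).

    Tokens (optionally plus adjacent-token bigrams) are hashed into a
    fixed-dimension signed count vector; identical text always maps to the
    identical vector, on any machine, with no external weights.
    """

    def embed(text: str) -> np.ndarray:
        v = np.zeros(dimension)
        toks = _TOKEN.findall(text.lower())
        feats: Iterable[str] = toks
        if use_bigrams:
            feats = list(toks) + [f"{a}_{b}" for a, b in zip(toks, toks[1:])]
        for t in feats:
            idx, sign = _hash_index(t, salt, dimension)
            v[idx] += sign
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    return EmbeddingBackend(name, dimension, embed)


_BACKENDS: dict[str, Callable[[], EmbeddingBackend]] = {
    # general-purpose sentence embedding stand-in
    "hashed-general": lambda: HashedEmbedding("hashed-general", 256, "general"),
    # medical-text variant: different hash space + bigram features
    "hashed-medical": lambda: HashedEmbedding("hashed-medical", 384, "medical", use_bigrams=True),
}


def get_backend(name: str) -> EmbeddingBackend:
    try:
        return _BACKENDS[name]()
    except KeyError as exc:
        raise IndexConfigurationError(
            f"unknown embedding backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from exc


# --------------------------------------------------------------------------
# angular-distance nearest-neighbor index

@dataclass
class KnnConfig:
    """K nearest neighbors by angular distance on the labeled pool."""

    k: int = 5
    index_type: str = "exact"  # exact | approximate
    n_trees: int = 12
    leaf_size: int = 32
    seed: int = 0

    def validate(self, pool_size: int | None = None) -> None:
        if self.k < 1:
            raise IndexConfigurationError(f"K must be >= 1, got {self.k}")
        if pool_size is not None and self.k > pool_size:
            raise IndexConfigurationError(
                f"K={self.k} exceeds labeled pool size {pool_size}"
            )
        if self.index_type not in ("exact", "approximate"):
            raise IndexConfigurationError(f"unknown index type {self.index_type!r}")


def angular_distance(u: np.ndarray, v: np.ndarray) -> float:
    """sqrt(2 - 2 cos) on L2-normalized vectors (unit-sphere chord length)."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    cos = float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * np.clip(cos, -1.0, 1.0))))


class _RPForest:
    """Annoy-style forest of random-projection trees for candidate recall."""

    def __init__(self, X: np.ndarray, n_trees: int, leaf_size: int, seed: int):
        self.X = X
        rng = np.random.default_rng(seed)
        self.trees = [
            self._build(np.arange(len(X)), rng, leaf_size) for _ in range(n_trees)
        ]

    def _build(self, idx: np.ndarray, rng: np.random.Generator, leaf_size: int):
        if len(idx) <= leaf_size:
            return ("leaf", idx)
        # hyperplane through the midpoint of two random members (annoy's split)
        a, b = rng.choice(idx, size=2, replace=False)
        normal = self.X[a] - self.X[b]
        if np.allclose(normal, 0):
            return ("leaf", idx)
        mid = (self.X[a] + self.X[b]) / 2.0
        side = (self.X[idx] - mid) @ normal > 0
        left, right = idx[side], idx[~side]
        if len(left) == 0 or len(right) == 0:
            return ("leaf", idx)
        return ("node", normal, mid, self._build(left, rng, leaf_size),
                self._build(right, rng, leaf_size))

    def candidates(self, q: np.ndarray) -> np.ndarray:
        out: list[np.ndarray] = []
        for tree in self.trees:
            node = tree
            while node[0] == "node":
                _, normal, mid, left, right = node
                node = left if (q - mid) @ normal > 0 else right
            out.append(node[1])
        return np.unique(np.concatenate(out))


@dataclass
class LabeledSentenceIndex:
    """Labeled development-pool sentences behind a neighbor-search facade."""

    backend: EmbeddingBackend
    config: KnnConfig
    vectors: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    texts: list[str] = field(repr=False)
    _forest: _RPForest | None = field(default=None, repr=False)

    def query(self, vector: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (neighbor indices, angular distances), K nearest.

        Exact mode ranks the whole pool; approximate mode exact-ranks the
        union of the forest's leaf candidates.  Ties in distance are broken
        by pool insertion order (stable sort on index).
        """
        k = self.config.k
        if self.config.index_type == "approximate" and self._forest is not None:
            cand = self._forest.candidates(vector)
            if len(cand) < k:
                cand = np.arange(len(self.vectors))
        else:
            cand = np.arange(len(self.vectors))
        q = vector / max(np.linalg.norm(vector), 1e-12)
        # pool vectors are pre-normalized; chord distance is monotone in -cos
        cos = np.clip(self.vectors[cand] @ q, -1.0, 1.0)
        dist = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * cos))
        order = np.argsort(dist, kind="stable")[:k]
        return cand[order], dist[order]

    def score(self, vector: np.ndarray) -> float:
        idx, _ = self.query(vector)
        return float(np.mean(self.labels[idx]))


def build_labeled_index(
    sentences: Sequence[str],
    labels: Sequence[float],
    backend: EmbeddingBackend,
    config: KnnConfig | None = None,
) -> LabeledSentenceIndex:
    """Embed and index the labeled sentence pool for K-NN retrieval."""
    config = config or KnnConfig()
    if len(sentences) != len(labels):
        raise IndexConfigurationError("sentences and labels must align")
    config.validate(pool_size=len(sentences))
    labels = np.asarray(labels, dtype=float)
    if labels.size and (labels.min() < 0 or labels.max() > 1):
        raise IndexConfigurationError("sentence labels must lie in [0, 1]")
    V = backend.embed_many(list(sentences))
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    V = V / np.maximum(norms, 1e-12)
    forest = None
    if config.index_type == "approximate":
        forest = _RPForest(V, config.n_trees, config.leaf_size, config.seed)
    return LabeledSentenceIndex(backend, config, V, labels, list(sentences), forest)


def knn_sentence_score(
    sentence: str, index: LabeledSentenceIndex, config: KnnConfig | None = None
) -> float:
    """Mean label of the K nearest labeled sentences; lies in [0, 1]."""
    if config is not None and config.k != index.config.k:
        index = LabeledSentenceIndex(
            index.backend, config, index.vectors, index.labels, index.texts, index._forest
        )
        config.validate(pool_size=len(index.labels))
    return index.score(index.backend.embed(sentence))


def encounter_score_mean(sentence_scores: Sequence[float]) -> tuple[float, bool]:
    """Encounter score = mean sentence score; (0.0, no_text=True) if empty."""
    scores = np.asarray(list(sentence_scores), dtype=float)
    if scores.size == 0:
        return 0.0, True
    return float(scores.mean()), False


# --------------------------------------------------------------------------
# Likert chain

LIKERT_MIN, LIKERT_MAX = -3, 3


_MODALITY_RANGE = {
    "knn_general": (0.0, 1.0),
    "knn_medical": (0.0, 1.0),
    "likert": (-3.0, 3.0),
}


@dataclass
class EncounterTextScore:
    """Encounter-level text score for one modality."""

    encounter_id: str
    modality: str  # knn_general | knn_medical | likert
    score: float
    n_units: int  # sentences (kNN chains) or notes (Likert chain) used
    flagged: bool = False  # no-text (kNN) or unscorable (Likert)

    def __post_init__(self) -> None:
        if self.modality not in _MODALITY_RANGE:
            raise ValueError(f"unknown modality {self.modality!r}")
        lo, hi = _MODALITY_RANGE[self.modality]
        if not (lo <= self.score <= hi):
            raise ValueError(
                f"{self.modality} score {self.score} outside [{lo}, {hi}]"
            )
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")


@dataclass
class LikertScore:
    """Note score on the -3 (definitely no SITB) .. +3 (definitely SITB) scale."""

    value: int
    rationale: str | None = None
    parse_ok: bool = True

    def __post_init__(self) -> None:
        if self.parse_ok and not (LIKERT_MIN <= self.value <= LIKERT_MAX):
            raise ValueError(f"Likert value {self.value} outside [-3, 3]")


# Lexicon and modifier cues for the deterministic rule scorer.  The scoring
# ladder (documented here and in the default config):
#   +3  affirmed, present-tense, patient-referent SITB mention
#   +1  historical-only SITB mention (patient, not current)
#   -1  SITB mention about someone other than the patient
#   -2  negated SITB mention
#   -3  no SITB lexicon hit at all
# Cue precedence within a sentence: negation > other-subject > historical.
DEFAULT_LEXICON = {
    "sitb_terms": [
        "suicidal ideation", "suicide", "self-harm", "self harm", "cutting",
        "overdose", "wish to be dead", "self-injury", "self injury",
        "hurt himself", "hurt herself", "hurt themselves", "kill himself",
        "kill herself", "kill themselves",
    ],
    "negation_cues": [
        "denies", "denied", "no evidence of", "without any", "negative for",
        "no thoughts of", "not having",
    ],
    "historical_cues": [
        "history of", "in the past", "last year", "years ago", "prior episode",
        "previously", "month ago", "months ago",
    ],
    "other_subject_cues": [
        "mother", "father", "sibling", "brother", "sister", "friend",
        "classmate", "peer", "cousin", "family reports", "family history",
    ],
}

_LADDER = {"affirmed": 3, "historical": 1, "other_subject": -1, "negated": -2, "none": -3}


def _score_sentence_rule(sentence: str, lexicon: dict) -> int:
    s = sentence.lower()
    if not any(term in s for term in lexicon["sitb_terms"]):
        return _LADDER["none"]
    if any(cue in s for cue in lexicon["negation_cues"]):
        return _LADDER["negated"]
    if any(cue in s for cue in lexicon["other_subject_cues"]):
        return _LADDER["other_subject"]
    if any(cue in s for cue in lexicon["historical_cues"]):
        return _LADDER["historical"]
    return _LADDER["affirmed"]


def rule_based_likert(note: Note | str, lexicon: dict | None = None) -> LikertScore:
    """Deterministic lexicon/ladder note scorer (language-model stand-in).

    The note score is the maximum sentence-level ladder score, so a single
    affirmed current patient SITB mention dominates any amount of negated
    or historical text, mirroring how a note either does or does not
    contain SITB evidence.
    """
    lexicon = lexicon or DEFAULT_LEXICON
    if not lexicon.get("sitb_terms"):
        raise IndexConfigurationError("rule scorer lexicon is empty")
    if isinstance(note, Note):
        sentences = [s.text for s in note.sentences]
    else:
        sentences = segment_sentences(note)
    if not sentences:
        return LikertScore(LIKERT_MIN, rationale="empty note")
    best = max(_score_sentence_rule(s, lexicon) for s in sentences)
    return LikertScore(best, rationale="rule ladder max over sentences")


_JSON_OBJ = re.compile(r"\{.*?\}", re.DOTALL)


def parse_model_output(raw: str) -> LikertScore:
    """Extract a Likert score from model output carrying a JSON object.

    The contract expects an embedded object with an integer ``score`` in
    [-3, 3] and optional ``rationale`` text.  Anything malformed — no JSON,
    non-integer score, out-of-range value — yields ``parse_ok=False`` with
    the score treated as missing (never an exception).
    """
    for match in _JSON_OBJ.finditer(raw or ""):
        try:
            obj = json.loads(match.group(0))
        except json.JSONDecodeError:
            continue
        if not isinstance(obj, dict) or "score" not in obj:
            continue
        score = obj["score"]
        if isinstance(score, bool) or not isinstance(score, int):
            return LikertScore(LIKERT_MIN, parse_ok=False)
        if not (LIKERT_MIN <= score <= LIKERT_MAX):
            return LikertScore(LIKERT_MIN, parse_ok=False)
        return LikertScore(score, rationale=obj.get("rationale"), parse_ok=True)
    return LikertScore(LIKERT_MIN, parse_ok=False)


def encounter_score_max(note_scores: Sequence[LikertScore]) -> tuple[int, bool]:
    """Encounter Likert score = max over parseable note scores.

    Returns (value, unscorable).  With no parseable notes the encounter is
    flagged unscorable and assigned the scale minimum.
    """
    ok = [s.value for s in note_scores if s.parse_ok]
    if not ok:
        return LIKERT_MIN, True
    return max(ok), False


# --------------------------------------------------------------------------
# batch encounter scoring

def score_encounters_knn(
    notes_by_encounter: dict[str, list[Note]],
    index: LabeledSentenceIndex,
    chunk_size: int = 4096,
) -> dict[str, float]:
    """kNN-chain encounter scores for a mapping encounter id -> notes.

    Embeds all sentences once and scores them in chunks against the
    labeled index (exact mode is a blocked matrix product).
    """
    enc_ids: list[str] = []
    texts: list[str] = []
    for eid, notes in notes_by_encounter.items():
        for note in notes:
            for s in note.sentences:
                enc_ids.append(eid)
                texts.append(s.text)
    scores = np.zeros(len(texts))
    for start in range(0, len(texts), chunk_size):
        block = texts[start : start + chunk_size]
        V = index.backend.embed_many(block)
        V = V / np.maximum(np.linalg.norm(V, axis=1, keepdims=True), 1e-12)
        if index.config.index_type == "exact":
            cos = np.clip(V @ index.vectors.T, -1.0, 1.0)
            dist = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * cos))
            order = np.argsort(dist, axis=1, kind="stable")[:, : index.config.k]
            scores[start : start + len(block)] = index.labels[order].mean(axis=1)
        else:
            for i in range(len(block)):
                scores[start + i] = index.score(V[i])
    out: dict[str, float] = {}
    per_enc: dict[str, list[float]] = {eid: [] for eid in notes_by_encounter}
    for eid, sc in zip(enc_ids, scores):
        per_enc[eid].append(float(sc))
    for eid in notes_by_encounter:
        out[eid], _ = encounter_score_mean(per_enc[eid])
    return out


def score_encounters_likert(
    notes_by_encounter: dict[str, list[Note]],
    lexicon: dict | None = None,
) -> dict[str, float]:
    """Likert-chain encounter scores (max over rule-scored notes)."""
    out: dict[str, float] = {}
    for eid, notes in notes_by_encounter.items():
        note_scores = [rule_based_likert(n, lexicon) for n in notes]
        value, _ = encounter_score_max(note_scores)
        out[eid] = float(value)
    return out
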
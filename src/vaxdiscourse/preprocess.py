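"""Text pre-processing for keyword extraction.

The pipeline applied to every comment is, in order:

1. strip markup — URLs, #hashtags, @mentions, and emoji are deleted whole;
2. translate — through a pluggable translator (default: identity);
3. normalize — lowercase, delete digits and punctuation, drop stopwords;
4. lemmatize — through a pluggable lemmatizer (default: a POS-free
   rule-based suffix stripper).

Stopword filtering happens before lemmatization, so inflected stopword forms
that the list does not contain survive into the lemmatizer; the packaged
stopword list is versioned in-repo to keep results reproducible.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

from .corpus import Corpus
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

Lemmatizer = Callable[[str], str]
Translator = Callable[[str], str]

_LEMMATIZERS: dict[str, Lemmatizer] = {}
_TRANSLATORS: dict[str, Translator] = {}


def register_lemmatizer(name: str, fn: Lemmatizer) -> None:
    _LEMMATIZERS[name] = fn


def register_translator(name: str, fn: Translator) -> None:
    _TRANSLATORS[name] = fn


def get_lemmatizer(name: str) -> Lemmatizer:
    try:
        return _LEMMATIZERS[name]
    except KeyError:
        raise ConfigurationError(
            f"unregistered lemmatizer {name!r}; known: {sorted(_LEMMATIZERS)}"
        )


def get_translator(name: str) -> Translator:
    try:
        return _TRANSLATORS[name]
    except KeyError:
        raise ConfigurationError(
            f"unregistered translator {name!r}; known: {sorted(_TRANSLATORS)}"
        )


def _identity(text: str) -> str:
    return text


_PLURAL_EXCEPTIONS = {
    "people": "people",
    "data": "data",
    "news": "news",
    "vaccines": "vaccine",
    "children": "child",
    "men": "man",
    "women": "woman",
}


def suffix_lemmatize(token: str) -> str:
    """Heuristic English lemmatizer: strips common plural suffixes.

    Deliberately conservative and POS-free; words ending in -ss/-us/-is and
    short words are left alone.  Idempotent on its own outputs.
    """
    if token in _PLURAL_EXCEPTIONS:
        return _PLURAL_EXCEPTIONS[token]
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 4 and token.endswith(("sses", "shes", "ches", "xes", "zes", "oes")):
        return token[:-2]
    if (
        len(token) > 3
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


register_lemmatizer("identity", _identity)
register_lemmatizer("english-suffix", suffix_lemmatize)
register_translator("identity", _identity)


def make_table_translator(table: dict[str, str]) -> Translator:
    """Build a whole-word lookup translator from a mapping (for tests/stubs)."""

    def translate(text: str) -> str:
        return " ".join(table.get(w, w) for w in text.split())

    return translate


# --- markup stripping -------------------------------------------------------

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_HASHTAG_RE = re.compile(r"#\w+", re.UNICODE)
_MENTION_RE = re.compile(r"@\w+", re.UNICODE)

# Unicode emoji / pictograph blocks, deleted wholesale (including skin-tone
# modifiers, variation selectors, and the zero-width joiner used in sequences).
_EMOJI_RE = re.compile(
    "["
    "\U0001F000-\U0001FAFF"  # mahjong..symbols-extended (emoji, pictographs)
    "\U00002600-\U000027BF"  # misc symbols, dingbats
    "\U0001F1E6-\U0001F1FF"  # regional indicators (flags)
    "\U00002190-\U000021FF"  # arrows
    "\U00002B00-\U00002BFF"  # misc symbols and arrows
    "\U0000FE00-\U0000FE0F"  # variation selectors
    "\U0001F3FB-\U0001F3FF"  # skin tone modifiers
    "\U0000200D"             # zero-width joiner
    "\U000020E3"             # combining enclosing keycap
    "\U00002122\U00002139"   # trade mark, information
    "]+"
)

_WS_RE = re.compile(r"\s+")


def strip_markup(text: str) -> str:
    """Delete URLs, #hashtags, @mentions, and emoji; collapse whitespace."""
    text = _URL_RE.sub(" ", text)
    text = _HASHTAG_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = _EMOJI_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


# --- normalization ----------------------------------------------------------


def default_stopwords() -> frozenset[str]:
    """The packaged English stopword list (one lowercase term per line)."""
    text = (
        resources.files("vaxdiscourse").joinpath("data/stopwords.txt").read_text("utf-8")
    )
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_stopwords(path: str | Path) -> frozenset[str]:
    return frozenset(
        w.strip().lower()
        for w in Path(path).read_text(encoding="utf-8").splitlines()
        if w.strip()
    )


@dataclass(frozen=True)
class PreprocessConfig:
    """Names the pluggable pieces and the stopword list for one run."""

    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    lemmatizer: str = "english-suffix"
    translator: str = "identity"

    def __post_init__(self) -> None:
        if not self.stopwords:
            raise ConfigurationError("stopword list must be non-empty")

    def to_dict(self) -> dict:
        return {
            "lemmatizer": self.lemmatizer,
            "translator": self.translator,
            "n_stopwords": len(self.stopwords),
        }


@dataclass(frozen=True)
class TokenDoc:
    """The token sequence of one comment after the full pipeline."""

    comment_id: str
    label: int | None
    tokens: tuple[str, ...]


def translate_text(text: str, translator: str = "identity") -> str:
    """Run the named translator over the text (identity by default)."""
    fn = get_translator(translator)
    logger.debug("translating with %r", translator)
    return fn(text)


def _is_letter(ch: str) -> bool:
    return unicodedata.category(ch).startswith("L")


def tokenize_normalize(text: str, config: PreprocessConfig) -> tuple[str, ...]:
    """Lowercase, delete digits/punctuation, drop stopwords, lemmatize.

    Tokens that become empty after character filtering (e.g. ``100%``) are
    dropped entirely.  Order and multiplicity of surviving tokens are kept.
    """
    lemmatize = get_lemmatizer(config.lemmatizer)
    out: list[str] = []
    for raw in text.lower().split():
        word = "".join(ch for ch in raw if _is_letter(ch))
        if not word or word in config.stopwords:
            continue
        lemma = lemmatize(word)
        # a lemma can itself be a stopword (e.g. an inflected form whose
        # dictionary form is on the list); keep the token set stopword-free
        if lemma in config.stopwords:
            continue
        out.append(lemma)
    return tuple(out)


def preprocess_text(text: str, config: PreprocessConfig) -> tuple[str, ...]:
    """Full pipeline on one string: strip markup, translate, normalize."""
    return tokenize_normalize(
        translate_text(strip_markup(text), config.translator), config
    )


def preprocess_corpus(corpus: Corpus, config: PreprocessConfig | None = None) -> list[TokenDoc]:
    """One :class:`TokenDoc` per comment, in corpus order; empty docs retained."""
    config = config or PreprocessConfig()
    return [
        TokenDoc(c.id, c.label, preprocess_text(c.text, config)) for c in corpus
    ]


def canonical_tokens(words: Iterable[str], config: PreprocessConfig | None = None) -> tuple[str, ...]:
    """Canonicalize a word list through the normalization pipeline.

    Used to seed keyword pools so that planted tokens are fixed points of
    preprocessing (not stopwords, already lemmatized).
    """
    config = config or PreprocessConfig()
    return tokenize_normalize(" ".join(words), config)
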
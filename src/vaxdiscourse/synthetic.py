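"""Synthetic labeled comment corpora with the structure the analysis assumes.

The generator emulates the study design: four platforms, 250 top comments
each, a 15-category codebook (1 positive + 14 anti-vaccine themes) with
per-platform category probabilities, per-category keyword pools planted into
otherwise shared filler vocabulary, Poisson comment lengths with platform
means matching the published averages (facebook 30, instagram 32, tiktok 12,
twitter 22 words), heavy-tailed (discretized log-normal) reaction counts, and
double-coded annotations at a target agreement level.

Text is English-like token sequences, not natural language: downstream
statistics depend only on token counts.  All sampling is driven by a single
integer seed; identical configs produce identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import Codebook, Comment, Corpus, default_codebook
from .errors import ConfigurationError, ValidationError
from .preprocess import canonical_tokens
from .reliability import AnnotationMatrix

#: Published marginal category fractions (category id 0..14) used as the
#: homogeneous default: every platform shares this distribution.
MARGINAL_CATEGORY_PROBS: tuple[float, ...] = (
    0.271, 0.156, 0.116, 0.102, 0.085, 0.084, 0.043, 0.036,
    0.027, 0.021, 0.020, 0.013, 0.012, 0.009, 0.005,
)

#: Per-platform mean comment lengths in words (from the published summary).
DEFAULT_LENGTH_MEANS: Mapping[str, float] = {
    "facebook": 30.0,
    "instagram": 32.0,
    "tiktok": 12.0,
    "twitter": 22.0,
}

#: Per-platform mean reaction counts (published reaction sums / 250).
DEFAULT_REACTION_MEANS: Mapping[str, float] = {
    "facebook": 39960 / 250,
    "instagram": 6918 / 250,
    "tiktok": 34865 / 250,
    "twitter": 32449 / 250,
}

#: Log-normal shape for reaction counts (heavy tail, non-degenerate top-N cut).
REACTION_SIGMA = 1.5

#: Raw per-category keyword pools; canonicalized through the preprocessing
#: pipeline at config construction so planted tokens are preprocessing fixed
#: points (lowercase, non-stopword, lemmatized).
RAW_KEYWORD_POOLS: Mapping[int, tuple[str, ...]] = {
    0: ("vaccination", "vaccinate", "dose", "get", "people", "second"),
    1: ("vaccinate", "choice", "freedom", "never", "get", "everyone"),
    2: ("people", "lie", "gift", "anymore", "pinocchio", "propaganda"),
    3: ("die", "death", "people", "heart", "get", "complication"),
    4: ("protection", "data", "infect", "dose", "basis", "get"),
    5: ("experiment", "test", "medical", "vaccine", "pig", "guinea"),
    6: ("brag", "understand", "advertise", "sympathize", "publicly", "celebrity"),
    7: ("vitamin", "saline", "syringe", "placebo", "teleconsultation", "inoculate"),
    8: ("normality", "cover", "weirdos", "warning", "victim", "unprecedented"),
    9: ("pay", "traitor", "stink", "much", "advertising", "ad"),
    10: ("virus", "alive", "similar", "global", "evolution", "topic"),
    11: ("responsibility", "raid", "composition", "manufacturer", "responsible", "compensation"),
    12: ("pharmaceutical", "viruses", "interested", "diet", "widely", "revenue"),
    13: ("medication", "amantadine", "condition", "mess", "authoritarianism", "treatment"),
    14: ("natural", "vaccinophobia", "sugar", "recovered", "preach", "junk"),
}

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def make_filler_vocab(size: int = 200) -> tuple[str, ...]:
    """Deterministic synthetic filler words (three consonant-vowel syllables)."""
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    n_syl = len(syllables)
    space = n_syl**3
    if size > space:
        raise ConfigurationError(f"filler vocabulary capped at {space} words")
    words = []
    for i in range(size):
        # multiplying by a unit modulo n_syl^3 enumerates distinct triples
        j = (i * 40087 + 11) % space
        words.append(
            syllables[j % n_syl]
            + syllables[(j // n_syl) % n_syl]
            + syllables[(j // n_syl**2) % n_syl]
        )
    return tuple(words)


def _filler_weights(n: int) -> np.ndarray:
    # bounded-head Zipf-like weights: common words exist but none dominates
    w = 1.0 / (np.arange(n) + 10.0)
    return w / w.sum()


def default_keyword_pools() -> dict[int, tuple[str, ...]]:
    """Raw pools canonicalized through the default preprocessing pipeline."""
    pools = {}
    for k, words in RAW_KEYWORD_POOLS.items():
        canon = canonical_tokens(words)
        # preserve order, drop duplicates introduced by canonicalization
        seen: list[str] = []
        for w in canon:
            if w not in seen:
                seen.append(w)
        pools[k] = tuple(seen)
    return pools


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; the defaults are the study conditions."""

    seed: int
    platforms: tuple[str, ...] = ("facebook", "twitter", "instagram", "tiktok")
    category_probs: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    n_per_platform: int = 250
    keyword_pools: Mapping[int, tuple[str, ...]] = field(
        default_factory=default_keyword_pools
    )
    filler_vocab: tuple[str, ...] = field(default_factory=make_filler_vocab)
    length_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MEANS)
    )
    reaction_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REACTION_MEANS)
    )
    planting_rate: float = 0.3
    agreement_q: float = 0.95
    n_annotation_items: int = 100
    codebook: Codebook = field(default_factory=default_codebook)

    def __post_init__(self) -> None:
        if not self.category_probs:
            object.__setattr__(
                self,
                "category_probs",
                {p: MARGINAL_CATEGORY_PROBS for p in self.platforms},
            )
        if self.n_per_platform < 1:
            raise ConfigurationError("n_per_platform must be >= 1")
        if not 0.0 <= self.agreement_q <= 1.0:
            raise ConfigurationError("agreement_q must be in [0, 1]")
        if not 0.0 <= self.planting_rate <= 1.0:
            raise ConfigurationError("planting_rate must be in [0, 1]")
        n_cat = len(self.codebook)
        for p in self.platforms:
            probs = np.asarray(self.category_probs[p], dtype=float)
            if probs.shape != (n_cat,):
                raise ConfigurationError(
                    f"category_probs[{p!r}] must have length {n_cat}"
                )
            if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
                raise ConfigurationError(
                    f"category_probs[{p!r}] must be a probability vector"
                )
            for k, prob in zip(self.codebook.ids, probs):
                if prob > 0 and not self.keyword_pools.get(k):
                    raise ConfigurationError(
                        f"category {k} has positive probability but an empty keyword pool"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    labels: dict[str, int]  # comment id -> true category
    platform_probs: dict[str, tuple[float, ...]]
    keyword_pools: dict[int, tuple[str, ...]]
    comment_ids: tuple[str, ...]


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Sample one labeled corpus (and its ground truth) from the config."""
    rng = np.random.default_rng(config.seed)
    cat_ids = np.asarray(config.codebook.ids)
    vocab = np.asarray(config.filler_vocab, dtype=object)
    fw = _filler_weights(len(vocab))

    # flatten pools for vectorized lookup
    flat_pool: list[str] = []
    offsets = np.zeros(int(cat_ids.max()) + 1, dtype=int)
    sizes = np.zeros(int(cat_ids.max()) + 1, dtype=int)
    for k in config.codebook.ids:
        pool = list(config.keyword_pools.get(k, ()))
        offsets[k] = len(flat_pool)
        sizes[k] = max(len(pool), 1)
        flat_pool.extend(pool or ["_"])
    flat_pool_arr = np.asarray(flat_pool, dtype=object)

    comments: list[Comment] = []
    truth_labels: dict[str, int] = {}
    for platform in config.platforms:
        n = config.n_per_platform
        probs = np.asarray(config.category_probs[platform], dtype=float)
        probs = probs / probs.sum()
        labels = rng.choice(cat_ids, size=n, p=probs)
        lengths = rng.poisson(config.length_means[platform], size=n)
        mean_r = config.reaction_means[platform]
        mu = np.log(mean_r) - REACTION_SIGMA**2 / 2.0
        reactions = np.floor(rng.lognormal(mu, REACTION_SIGMA, size=n)).astype(int)

        total = int(lengths.sum())
        tok_label = np.repeat(labels, lengths)
        planted = rng.random(total) < config.planting_rate
        filler_idx = rng.choice(len(vocab), size=total, p=fw)
        slot = rng.integers(0, 1 << 30, size=total)
        kw_idx = offsets[tok_label] + slot % sizes[tok_label]
        tokens = np.where(planted, flat_pool_arr[kw_idx], vocab[filler_idx])

        bounds = np.cumsum(lengths)[:-1]
        docs = np.split(tokens, bounds)
        for i in range(n):
            cid = f"{platform}-{i:04d}"
            label = int(labels[i])
            comments.append(
                Comment(
                    id=cid,
                    platform=platform,
                    text=" ".join(docs[i]),
                    reactions=int(reactions[i]),
                    label=label,
                )
            )
            truth_labels[cid] = label

    corpus = Corpus(tuple(comments), config.codebook)
    truth = GroundTruth(
        labels=truth_labels,
        platform_probs={
            p: tuple(config.category_probs[p]) for p in config.platforms
        },
        keyword_pools={k: tuple(v) for k, v in config.keyword_pools.items()},
        comment_ids=tuple(c.id for c in comments),
    )
    return corpus, truth


def generate_annotations(
    truth: GroundTruth, config: SyntheticConfig
) -> AnnotationMatrix:
    """Double-code a random item subset at the configured agreement level.

    Coder 1 reports the true label; coder 2 copies it with probability
    ``agreement_q`` and otherwise draws uniformly from the other categories
    (symmetric-uniform coder-error model).
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = list(truth.comment_ids)
    n_items = min(config.n_annotation_items, len(ids))
    chosen = rng.choice(len(ids), size=n_items, replace=False)
    cat_ids = list(config.codebook.ids)
    rows = []
    for idx in chosen:
        true = truth.labels[ids[int(idx)]]
        if rng.random() < config.agreement_q:
            other = true
        else:
            alternatives = [c for c in cat_ids if c != true]
            other = int(rng.choice(alternatives))
        rows.append((true, other))
    return AnnotationMatrix(tuple(rows))


#: Hand-designed per-platform anti-category weights (categories 1..14) for the
#: distinct-platform preset: facebook/twitter government+safety+efficacy heavy
#: and near-identical, tiktok freedom-heavy, instagram testing/bragging-heavy.
#: Category 9 is absent on facebook/twitter and category 13 absent on
#: tiktok/instagram, so zero-expected pruning always removes {9, 13} (rare
#: small categories can occasionally join them at n = 250 per platform).
_PRESET_ANTI_WEIGHTS: Mapping[str, tuple[float, ...]] = {
    "facebook": (0.150, 0.205, 0.180, 0.148, 0.085, 0.040, 0.095,
                 0.050, 0.0, 0.020, 0.018, 0.015, 0.025, 0.008),
    "twitter": (0.070, 0.255, 0.210, 0.172, 0.073, 0.033, 0.095,
                0.055, 0.0, 0.020, 0.016, 0.016, 0.025, 0.006),
    "tiktok": (0.490, 0.069, 0.070, 0.057, 0.095, 0.044, 0.012,
               0.020, 0.055, 0.036, 0.018, 0.015, 0.0, 0.012),
    "instagram": (0.135, 0.109, 0.100, 0.087, 0.205, 0.119, 0.020,
                  0.021, 0.060, 0.034, 0.019, 0.020, 0.0, 0.004),
}

#: Positive-category share per platform; the four shares average 0.271 so the
#: preset's overall anti-vaccine share is 0.729, matching the published
#: marginal split.  Twitter has the highest anti share, instagram the lowest.
_PRESET_POSITIVE_SHARE: Mapping[str, float] = {
    "facebook": 0.270,
    "twitter": 0.200,
    "tiktok": 0.214,
    "instagram": 0.400,
}


def preset_platform_profiles(seed: int = 0, **overrides) -> SyntheticConfig:
    """The distinct-platform preset mirroring the published narrative.

    The tiktok profile is freedom-of-choice heavy (category 1); facebook and
    twitter emphasize government distrust and safety/efficacy doubts
    (categories 2-4) and are near-identical to each other; instagram is
    testing/bragging heavy (categories 5-6).  Marginals track the published
    category fractions.
    """
    probs = {}
    for platform in ("facebook", "twitter", "instagram", "tiktok"):
        anti = np.asarray(_PRESET_ANTI_WEIGHTS[platform], dtype=float)
        anti = anti / anti.sum()
        pos = _PRESET_POSITIVE_SHARE[platform]
        vec = np.concatenate([[pos], (1.0 - pos) * anti])
        probs[platform] = tuple(vec / vec.sum())
    return SyntheticConfig(seed=seed, category_probs=probs, **overrides)


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Homogeneous config: every platform shares the marginal distribution."""
    return SyntheticConfig(seed=seed, **overrides)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Same config, different seed."""
    return replace(config, seed=seed)
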
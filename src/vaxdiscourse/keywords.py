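"""Category keyword extraction via a lambda-weighted relevance score.

For term w and category k, with phi_{k,w} the within-category term probability
and p_w the corpus-wide term probability, the relevance is

    r(w, k | lambda) = lambda * log(phi_{k,w}) + (1 - lambda) * log(phi_{k,w} / p_w)

blending the term's empirical within-category probability with its lift (the
ratio of within-category to marginal probability, which down-weights globally
frequent terms).  The default weight is lambda = 0.5.  Natural logarithms are
used; rankings are invariant to the log base since both components scale by
the same constant.  Pairs with phi_{k,w} = 0 are excluded rather than scored
-inf.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .preprocess import TokenDoc


@dataclass(frozen=True)
class TermStats:
    """Per-category and corpus term counts and probabilities."""

    category_counts: dict[int, Counter]  # k -> term -> count
    corpus_counts: Counter
    category_totals: dict[int, int]
    corpus_total: int

    @property
    def V(self) -> int:
        """Number of unique terms in the corpus."""
        return len(self.corpus_counts)

    @property
    def K(self) -> int:
        """Number of categories (including empty ones)."""
        return len(self.category_counts)

    def phi(self, category: int, term: str) -> float:
        total = self.category_totals[category]
        if total == 0:
            return 0.0
        return self.category_counts[category][term] / total

    def p(self, term: str) -> float:
        return self.corpus_counts[term] / self.corpus_total


def compute_term_stats(docs: Sequence[TokenDoc]) -> TermStats:
    """Pool token counts over documents by label.

    Every document must carry a label; categories that occur only with empty
    documents are recorded with zero totals.
    """
    unlabeled = [d.comment_id for d in docs if d.label is None]
    if unlabeled:
        raise ValidationError(f"unlabeled documents: {unlabeled[:10]}")
    category_counts: dict[int, Counter] = {}
    corpus_counts: Counter = Counter()
    for d in docs:
        category_counts.setdefault(d.label, Counter()).update(d.tokens)
        corpus_counts.update(d.tokens)
    corpus_total = sum(corpus_counts.values())
    if corpus_total == 0:
        raise InsufficientDataError("all documents are empty; no terms to count")
    category_totals = {k: sum(c.values()) for k, c in category_counts.items()}
    return TermStats(category_counts, corpus_counts, category_totals, corpus_total)


@dataclass(frozen=True)
class RelevanceTable:
    """(term, category, r) entries for all pairs with phi > 0."""

    lam: float
    entries: pd.DataFrame  # columns: category, term, relevance


def relevance_score(stats: TermStats, lam: float = 0.5) -> RelevanceTable:
    """Score every (category, term) pair with positive within-category count."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0, 1], got {lam}")
    rows = []
    for k in sorted(stats.category_counts):
        total_k = stats.category_totals[k]
        if total_k == 0:
            continue
        for term, count in stats.category_counts[k].items():
            phi = count / total_k
            p = stats.p(term)
            r = lam * np.log(phi) + (1.0 - lam) * np.log(phi / p)
            rows.append((k, term, r))
    df = pd.DataFrame(rows, columns=["category", "term", "relevance"])
    # r descending, then lexicographic term order for deterministic ties
    df = df.sort_values(
        ["category", "relevance", "term"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return RelevanceTable(lam, df)


def rank_keywords(table: RelevanceTable, top_n: int = 6) -> dict[int, list[str]]:
    """Top ``top_n`` terms per category by relevance (default 6).

    Categories with no scored terms map to empty lists.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    out: dict[int, list[str]] = {}
    for k, group in table.entries.groupby("category", sort=True):
        out[int(k)] = group["term"].head(top_n).tolist()
    return out


def write_keywords_tsv(
    table: RelevanceTable, path: str | Path, top_n: int = 6
) -> None:
    """Write ranked keywords as TSV: category_id, rank, term, relevance."""
    rows = []
    for k, group in table.entries.groupby("category", sort=True):
        for rank, (_, row) in enumerate(group.head(top_n).iterrows(), start=1):
            rows.append((int(k), rank, row["term"], row["relevance"]))
    pd.DataFrame(
        rows, columns=["category_id", "rank", "term", "relevance"]
    ).to_csv(path, sep="\t", index=False)
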
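"""Cross-platform comparison of anti-vaccine category distributions.

Two complementary views of the category x platform contingency table:

* **Cosine similarity** between per-platform anti-category frequency vectors
  (each platform's anti-category counts normalized by its total number of
  anti-vaccine comments), cos(x, y) = sum(x_i y_i) / (||x|| * ||y||).  Since
  all entries are non-negative the score lies in [0, 1]: 1 for identical
  distributions, 0 for disjoint support.

* **Chi-square test of homogeneity** (Pearson, no continuity correction) of
  the hypothesis that all platforms share one category distribution, with
  Bonferroni-corrected pairwise post-hoc tests.  Categories whose expected
  cell values would be exactly zero in some pairwise comparison — i.e. with a
  zero count on at least two platforms — are removed first and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .corpus import Codebook, ContingencyTable
from .errors import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class CategoryDistribution:
    """A platform's normalized frequency vector over the anti categories."""

    platform: str
    categories: tuple[int, ...]
    freq: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if (freq < 0).any():
            raise ValidationError("frequencies must be non-negative")
        object.__setattr__(self, "freq", freq)


def anti_category_distributions(
    table: ContingencyTable, codebook: Codebook
) -> list[CategoryDistribution]:
    """Per-platform anti-category frequencies (positive category excluded).

    Each vector is the platform's anti-category counts divided by its total
    number of anti-vaccine comments.
    """
    anti_ids = [k for k in codebook.anti_ids if k in table.categories]
    sub = table.counts.loc[anti_ids]
    out = []
    for platform in table.platforms:
        col = sub[platform].to_numpy(dtype=float)
        total = col.sum()
        if total == 0:
            raise ValidationError(
                f"platform {platform!r} has no anti-vaccine comments; "
                "its distribution is undefined"
            )
        out.append(CategoryDistribution(platform, tuple(anti_ids), col / total))
    return out


def cosine_similarity(x: CategoryDistribution, y: CategoryDistribution) -> float:
    """Cosine of two non-negative frequency vectors, clamped to [0, 1]."""
    if len(x.freq) != len(y.freq):
        raise ValidationError("vectors must have the same length")
    nx = float(np.linalg.norm(x.freq))
    ny = float(np.linalg.norm(y.freq))
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    value = float(np.dot(x.freq, y.freq)) / (nx * ny)
    # guard only against floating-point overshoot
    return min(max(value, 0.0), 1.0)


@dataclass(frozen=True)
class SimilarityMatrix:
    platforms: tuple[str, ...]
    scores: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.platforms, columns=self.platforms)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def off_diagonal_pairs(self) -> list[tuple[str, str, float]]:
        """Unique platform pairs with their scores, in input order."""
        out = []
        for i, j in combinations(range(len(self.platforms)), 2):
            out.append((self.platforms[i], self.platforms[j], float(self.scores[i, j])))
        return out


def similarity_matrix(dists: list[CategoryDistribution]) -> SimilarityMatrix:
    """All pairwise cosines between platform distributions."""
    if len(dists) < 2:
        raise ValidationError("need at least 2 platforms")
    n = len(dists)
    scores = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        s = cosine_similarity(dists[i], dists[j])
        scores[i, j] = scores[j, i] = s
    for i in range(n):
        scores[i, i] = cosine_similarity(dists[i], dists[i])
    return SimilarityMatrix(tuple(d.platform for d in dists), scores)


def prune_zero_expected(
    table: ContingencyTable,
) -> tuple[ContingencyTable, list[int]]:
    """Remove categories with zero counts on two or more platforms.

    A zero count on >= 2 platforms is exactly the condition under which some
    pairwise platform subtable has a zero row total for the category, making
    its expected cell values 0 and the chi-square statistic undefined there.
    """
    if len(table.platforms) < 2:
        raise ValidationError("pruning requires at least 2 platforms")
    zeros = (table.counts == 0).sum(axis=1)
    removed = [int(k) for k in table.categories if zeros.loc[k] >= 2]
    kept = [k for k in table.categories if k not in removed]
    if not kept:
        raise InsufficientDataError("all categories removed by zero-expected pruning")
    return table.subset(categories=kept), removed


@dataclass(frozen=True)
class HomogeneityResult:
    chi2: float
    df: int
    p: float
    removed_categories: tuple[int, ...]
    table_used: ContingencyTable


def chi_square_homogeneity(
    table: ContingencyTable, removed_categories: tuple[int, ...] = ()
) -> HomogeneityResult:
    """Pearson chi-square test that all platforms share one distribution.

    The table must already be pruned: any expected count of zero raises.
    """
    counts = table.counts.to_numpy(dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    n = counts.sum()
    if n == 0:
        raise InsufficientDataError("empty table")
    expected = row @ col / n
    if (expected == 0).any():
        raise ValidationError(
            "zero expected cell; remove degenerate categories with "
            "prune_zero_expected first"
        )
    chi2, p, df, _ = chi2_contingency(counts, correction=False)
    return HomogeneityResult(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        removed_categories=tuple(removed_categories),
        table_used=table,
    )


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    chi2: float | None
    df: int | None
    p_raw: float | None
    p_adjusted: float | None
    significant: bool | None
    removed_categories: tuple[int, ...] = ()
    error: str | None = None


def pairwise_posthoc(
    table: ContingencyTable, alpha: float = 0.05
) -> list[PairwiseResult]:
    """Bonferroni-corrected pairwise chi-square tests between platforms.

    Each pair's subtable is pruned by the zero-row rule before testing;
    adjusted p-values are min(1, m * p_raw) with m the number of pairs.
    A pair whose test fails is reported as untestable, not raised.
    """
    platforms = table.platforms
    pairs = list(combinations(platforms, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        sub = table.subset(platforms=[a, b])
        try:
            pruned, removed = prune_zero_expected(sub)
            res = chi_square_homogeneity(pruned, tuple(removed))
        except (ValidationError, InsufficientDataError) as exc:
            results.append(PairwiseResult((a, b), None, None, None, None, None, (), str(exc)))
            continue
        p_adj = min(1.0, m * res.p)
        results.append(
            PairwiseResult(
                pair=(a, b),
                chi2=res.chi2,
                df=res.df,
                p_raw=res.p,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
                removed_categories=res.removed_categories,
            )
        )
    return results
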
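"""Shared fixtures: published-table arithmetic encoded as programmatic corpora."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from vaxdiscourse.corpus import Comment, ContingencyTable, Corpus, default_codebook
from vaxdiscourse.preprocess import TokenDoc

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Published marginal category counts (id -> count over the 1000-comment set).
TABLE2_COUNTS = {
    0: 271, 1: 156, 2: 116, 3: 102, 4: 85, 5: 84, 6: 43, 7: 36,
    8: 27, 9: 21, 10: 20, 11: 13, 12: 12, 13: 9, 14: 5,
}

#: Published per-platform summary: (n comments, reaction sum, mean words).
TABLE1_ROWS = {
    "facebook": (250, 39960, 30),
    "instagram": (250, 6918, 32),
    "tiktok": (250, 34865, 12),
    "twitter": (250, 32449, 22),
}


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def table2_corpus(codebook):
    """1000 labeled comments on one platform with the published marginal counts."""
    comments = []
    i = 0
    for cat, count in TABLE2_COUNTS.items():
        for _ in range(count):
            comments.append(
                Comment(id=str(i), platform="facebook", text="x", reactions=0, label=cat)
            )
            i += 1
    return Corpus(tuple(comments), codebook)


@pytest.fixture(scope="session")
def table1_corpus(codebook):
    """Per-platform comments whose word counts and reactions reproduce the
    published summary exactly: every comment has the platform's mean length,
    and the integer reaction sum is split as evenly as integers allow."""
    comments = []
    for platform, (n, sum_reactions, mean_words) in TABLE1_ROWS.items():
        base, rem = divmod(sum_reactions, n)
        for i in range(n):
            comments.append(
                Comment(
                    id=f"{platform}-{i}",
                    platform=platform,
                    text=" ".join(["word"] * mean_words),
                    reactions=base + (1 if i < rem else 0),
                    label=0,
                )
            )
    return Corpus(tuple(comments), codebook)


@pytest.fixture(scope="session")
def table2_identical_table(codebook):
    """Category x platform table with four identical columns, each the
    published marginal counts; every platform's anti distribution then equals
    the marginal anti distribution exactly."""
    platforms = ["facebook", "twitter", "instagram", "tiktok"]
    df = pd.DataFrame(
        {p: [TABLE2_COUNTS[k] for k in sorted(TABLE2_COUNTS)] for p in platforms},
        index=sorted(TABLE2_COUNTS),
    )
    return ContingencyTable(df)


@pytest.fixture()
def toy_docs():
    """Two-category toy corpus for relevance hand computations.

    Category A tokens: vaccine, freedom, freedom, choice
    Category B tokens: vaccine, government, lie, lie
    """
    return [
        TokenDoc("a1", 1, ("vaccine", "freedom", "freedom", "choice")),
        TokenDoc("b1", 2, ("vaccine", "government", "lie", "lie")),
    ]


@pytest.fixture()
def worked_annotations():
    """The hand-computable 2-coder grid (a,a),(a,b),(b,b),(b,b), a=0, b=1."""
    from vaxdiscourse.reliability import AnnotationMatrix

    return AnnotationMatrix(((0, 0), (0, 1), (1, 1), (1, 1)))
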
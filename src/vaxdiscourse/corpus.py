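"""Domain model for labeled social-media comment corpora.

A :class:`Corpus` is a flat collection of :class:`Comment` objects tied to a
:class:`Codebook` of content categories (one pro-vaccine category plus a set
of anti-vaccine argument themes).  The module also provides the tabular
derivations the analysis starts from: per-platform summaries (comment counts,
reaction sums, mean comment length in words), the category-by-platform
contingency table, and the overall anti-vaccine share.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

CANONICAL_PLATFORMS = ("facebook", "twitter", "instagram", "tiktok")

Polarity = Literal["positive", "anti"]


def canonical_platform(name: str) -> str:
    """Normalize a platform name to its lowercase canonical form."""
    name = str(name).strip().lower()
    if not name:
        raise ValidationError("platform name must be non-empty")
    return name


@dataclass(frozen=True)
class Category:
    """One codebook category: an integer id, a description, and a polarity."""

    id: int
    description: str
    polarity: Polarity

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "anti"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        if self.id < 0:
            raise ValidationError("category id must be non-negative")


@dataclass(frozen=True)
class Codebook:
    """Ordered set of categories with unique, strictly increasing ids."""

    categories: tuple[Category, ...]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValidationError("codebook must contain at least one category")
        ids = [c.id for c in self.categories]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValidationError("category ids must be strictly increasing")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.categories)

    @property
    def anti_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.categories if c.polarity == "anti")

    @property
    def positive_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.categories if c.polarity == "positive")

    def __contains__(self, category_id: int) -> bool:
        return category_id in set(self.ids)

    def __getitem__(self, category_id: int) -> Category:
        for c in self.categories:
            if c.id == category_id:
                return c
        raise KeyError(category_id)

    def __len__(self) -> int:
        return len(self.categories)


#: Descriptions of the default 15-category codebook: one positive category
#: (id 0) and fourteen anti-vaccine argument themes (ids 1-14).
_DEFAULT_CATEGORY_DESCRIPTIONS: tuple[tuple[int, str, str], ...] = (
    (0, "Positive attitude", "positive"),
    (1, "Refusal on personal freedom-of-choice grounds", "anti"),
    (2, "Lack of trust in the government", "anti"),
    (3, "The vaccines are dangerous to health", "anti"),
    (4, "The vaccines do not work", "anti"),
    (5, "The vaccines are not adequately tested / developed too quickly", "anti"),
    (6, "Criticizing boasting about being vaccinated", "anti"),
    (7, "Public figures vaccinated with inert substances (e.g. saline)", "anti"),
    (8, "Conspiracy theories, hidden vaccine effects (e.g. chips)", "anti"),
    (9, "Poster profiting from the encouragement of vaccination", "anti"),
    (10, "COVID-19 disease is not dangerous to health", "anti"),
    (11, "No one is responsible for potential side effects", "anti"),
    (12, "The vaccine was created only for pharmaceutical profit", "anti"),
    (13, "Better to treat COVID-19 than to vaccinate", "anti"),
    (14, "Natural methods of protection are better than vaccines", "anti"),
)


def default_codebook() -> Codebook:
    """The default 15-category codebook (1 positive + 14 anti themes)."""
    return Codebook(
        tuple(Category(i, d, p) for i, d, p in _DEFAULT_CATEGORY_DESCRIPTIONS)  # type: ignore[arg-type]
    )


def read_codebook(path: str | Path) -> Codebook:
    """Load a codebook from a JSON or YAML list of {id, description, polarity}."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, list):
        raise SchemaError("codebook file must contain a list of categories")
    cats = []
    for entry in raw:
        try:
            cats.append(
                Category(int(entry["id"]), str(entry["description"]), entry["polarity"])
            )
        except KeyError as exc:
            raise SchemaError(f"codebook entry missing key {exc}") from exc
    return Codebook(tuple(sorted(cats, key=lambda c: c.id)))


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    path = Path(path)
    payload = [
        {"id": c.id, "description": c.description, "polarity": c.polarity}
        for c in codebook.categories
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


@dataclass(frozen=True)
class Comment:
    """One social-media comment with its platform, text, and reaction count."""

    id: str
    platform: str
    text: str
    reactions: int
    label: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "platform", canonical_platform(self.platform))
        if self.reactions < 0:
            raise ValidationError(
                f"comment {self.id!r}: reactions must be non-negative, got {self.reactions}"
            )

    @property
    def n_words(self) -> int:
        """Whitespace-delimited word count of the raw text."""
        return len(self.text.split())


@dataclass(frozen=True)
class Corpus:
    """An immutable collection of comments plus the codebook labeling them."""

    comments: tuple[Comment, ...]
    codebook: Codebook = field(default_factory=default_codebook)

    def __post_init__(self) -> None:
        object.__setattr__(self, "comments", tuple(self.comments))
        seen: set[str] = set()
        valid = set(self.codebook.ids)
        bad_rows = []
        for c in self.comments:
            if c.id in seen:
                raise ValidationError(f"duplicate comment id {c.id!r}")
            seen.add(c.id)
            if c.label is not None and c.label not in valid:
                bad_rows.append(c.id)
        if bad_rows:
            raise ValidationError(
                f"labels not in codebook for comments: {bad_rows[:10]}"
            )

    def __len__(self) -> int:
        return len(self.comments)

    def __iter__(self):
        return iter(self.comments)

    @property
    def platforms(self) -> tuple[str, ...]:
        """Platforms in deterministic first-appearance order."""
        out: list[str] = []
        for c in self.comments:
            if c.platform not in out:
                out.append(c.platform)
        return tuple(out)

    def by_platform(self) -> dict[str, list[Comment]]:
        groups: dict[str, list[Comment]] = {p: [] for p in self.platforms}
        for c in self.comments:
            groups[c.platform].append(c)
        return groups


@dataclass(frozen=True)
class PlatformSummary:
    """Per-platform counts mirroring the study's data-overview table."""

    platform: str
    n_comments: int
    sum_reactions: int
    mean_length_words: float


_REQUIRED_COLUMNS = ("platform", "text", "reactions")


def _rows_to_comments(rows: Iterable[Mapping[str, object]], codebook: Codebook) -> Corpus:
    comments: list[Comment] = []
    bad_labels: list[tuple[int, object]] = []
    valid = set(codebook.ids)
    for i, row in enumerate(rows):
        for col in _REQUIRED_COLUMNS:
            if col not in row or row[col] is None:
                raise SchemaError(f"row {i}: missing required column {col!r}")
        raw_label = row.get("label")
        label: int | None
        if raw_label is None or (isinstance(raw_label, str) and raw_label.strip() == ""):
            label = None
        else:
            try:
                label = int(raw_label)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValidationError(f"row {i}: label {raw_label!r} is not an integer")
            if label not in valid:
                bad_labels.append((i, label))
                continue
        try:
            reactions = int(row["reactions"])  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValidationError(f"row {i}: reactions {row['reactions']!r} is not an integer")
        cid = row.get("id")
        cid = str(cid) if cid not in (None, "") else str(i)
        comments.append(
            Comment(
                id=cid,
                platform=str(row["platform"]),
                text=str(row["text"]),
                reactions=reactions,
                label=label,
            )
        )
    if bad_labels:
        raise ValidationError(f"unknown label ids on rows: {bad_labels[:10]}")
    return Corpus(tuple(comments), codebook)


def read_corpus(
    path: str | Path,
    format: Literal["csv", "jsonl"] | None = None,
    codebook: Codebook | None = None,
) -> Corpus:
    """Read a comment table (CSV or JSONL) into a :class:`Corpus`.

    Missing ``id`` values are auto-assigned sequentially; text is preserved
    verbatim (UTF-8, emoji intact).  An empty file yields an empty corpus.
    """
    path = Path(path)
    codebook = codebook or default_codebook()
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    if format == "jsonl":
        rows = [
            json.loads(line)
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        return _rows_to_comments(rows, codebook)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return Corpus((), codebook)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"CSV is missing required column {col!r}")
    return _rows_to_comments(df.to_dict(orient="records"), codebook)


def write_corpus(
    corpus: Corpus,
    path: str | Path,
    format: Literal["csv", "jsonl"] | None = None,
) -> None:
    """Write a corpus as CSV (RFC-4180 quoting) or JSONL."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for c in corpus:
                fh.write(
                    json.dumps(
                        {
                            "id": c.id,
                            "platform": c.platform,
                            "text": c.text,
                            "reactions": c.reactions,
                            "label": c.label,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
        return
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    writer.writerow(["id", "platform", "text", "reactions", "label"])
    for c in corpus:
        writer.writerow(
            [c.id, c.platform, c.text, c.reactions, "" if c.label is None else c.label]
        )
    path.write_text(buf.getvalue(), encoding="utf-8")


def select_top_by_reactions(corpus: Corpus, n_per_platform: int) -> Corpus:
    """Keep, per platform, the ``n_per_platform`` comments with most reactions.

    Ties at the cut are broken by stable input order (earlier comments win).
    Platforms with fewer comments than requested are kept whole with a logged
    warning.  Retained comments keep their original corpus order.
    """
    if n_per_platform < 1:
        raise ValidationError("n_per_platform must be >= 1")
    keep_ids: set[str] = set()
    for platform, comments in corpus.by_platform().items():
        if len(comments) < n_per_platform:
            logger.warning(
                "platform %s has only %d comments (< %d requested); keeping all",
                platform,
                len(comments),
                n_per_platform,
            )
        ranked = sorted(comments, key=lambda c: -c.reactions)  # stable sort
        keep_ids.update(c.id for c in ranked[:n_per_platform])
    return Corpus(tuple(c for c in corpus if c.id in keep_ids), corpus.codebook)


def summarize_platforms(corpus: Corpus) -> list[PlatformSummary]:
    """Per-platform comment count, reaction sum, and mean word length."""
    if len(corpus) == 0:
        raise ValidationError("cannot summarize an empty corpus")
    out = []
    for platform, comments in corpus.by_platform().items():
        if not comments:
            continue
        n = len(comments)
        out.append(
            PlatformSummary(
                platform=platform,
                n_comments=n,
                sum_reactions=sum(c.reactions for c in comments),
                mean_length_words=sum(c.n_words for c in comments) / n,
            )
        )
    return out


@dataclass(frozen=True)
class ContingencyTable:
    """Immutable category x platform count table with marginals."""

    counts: pd.DataFrame  # index: category ids, columns: platforms

    def __post_init__(self) -> None:
        df = self.counts.copy()
        if (df.to_numpy() < 0).any():
            raise ValidationError("contingency counts must be non-negative")
        df.index.name = "category"
        df.columns.name = "platform"
        object.__setattr__(self, "counts", df)

    @property
    def categories(self) -> tuple[int, ...]:
        return tuple(int(i) for i in self.counts.index)

    @property
    def platforms(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.counts.columns)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def fractions(self) -> pd.Series:
        """Marginal category fractions (row totals / grand total)."""
        total = self.grand_total
        if total == 0:
            raise ValidationError("fractions undefined on an empty table")
        return self.row_totals / total

    def subset(self, categories: Sequence[int] | None = None,
               platforms: Sequence[str] | None = None) -> "ContingencyTable":
        df = self.counts
        if categories is not None:
            df = df.loc[list(categories)]
        if platforms is not None:
            df = df[list(platforms)]
        return ContingencyTable(df.copy())


def tabulate_categories(corpus: Corpus) -> ContingencyTable:
    """Count labeled comments per (category, platform).

    Every codebook category appears as a row, even with zero counts; every
    corpus platform appears as a column.  Unlabeled comments are an error.
    """
    unlabeled = [c.id for c in corpus if c.label is None]
    if unlabeled:
        raise ValidationError(f"unlabeled comments: {unlabeled[:10]}")
    platforms = list(corpus.platforms)
    df = (
        pd.crosstab(
            pd.Series([c.label for c in corpus], name="category"),
            pd.Series([c.platform for c in corpus], name="platform"),
        )
        .reindex(index=list(corpus.codebook.ids), columns=platforms, fill_value=0)
        .astype(int)
    )
    return ContingencyTable(df)


def table_from_marginals(
    counts_by_category: Mapping[int, int], platforms: Sequence[str]
) -> ContingencyTable:
    """Build a table by spreading marginal category counts equally across platforms.

    Useful for encoding published marginal counts as a fixture table; remainders
    from integer division go to the earliest platforms.
    """
    n_p = len(platforms)
    data = {}
    for cat, total in counts_by_category.items():
        base, rem = divmod(int(total), n_p)
        data[cat] = [base + (1 if j < rem else 0) for j in range(n_p)]
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(platforms))
    return ContingencyTable(df.sort_index())


def anti_vaccine_share(table: ContingencyTable, codebook: Codebook) -> float:
    """Fraction of comments in anti-polarity categories (exact integer ratio)."""
    total = table.grand_total
    if total == 0:
        raise ValidationError("anti-vaccine share undefined on an empty table")
    anti = int(table.row_totals.loc[list(codebook.anti_ids)].sum())
    return anti / total
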
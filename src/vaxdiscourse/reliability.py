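"""Interrater agreement for the manual comment categorization.

Implements Krippendorff's alpha for nominal data via the coincidence-matrix
construction: every item with m >= 2 non-missing labels contributes one
ordered pair of labels per (coder, coder') combination, each weighted
1/(m-1), so that each item contributes m pairable values in total.  Alpha is

    alpha = 1 - D_o / D_e

with observed disagreement D_o = (sum of off-diagonal coincidences) / n and
expected disagreement D_e = (sum over c != k of n_c * n_k) / (n * (n - 1)),
where n_c are the category marginals of the coincidence matrix and n the
total number of pairable values.  Raw percent agreement is provided as a
simple cross-check for the two-coder, complete-data case.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class AnnotationMatrix:
    """Items x coders grid of optional category labels (``None`` = missing)."""

    labels: tuple[tuple[int | None, ...], ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("annotation matrix has no items")
        widths = {len(row) for row in self.labels}
        if len(widths) != 1:
            raise ValidationError("all items must have the same number of coders")
        if widths.pop() < 2:
            raise ValidationError("at least 2 coders are required")
        if not any(
            sum(v is not None for v in row) >= 2 for row in self.labels
        ):
            raise InsufficientDataError(
                "no item has >= 2 non-missing labels; nothing is pairable"
            )

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def n_coders(self) -> int:
        return len(self.labels[0])


def read_annotations(path: str | Path) -> AnnotationMatrix:
    """Read long-format annotations (item_id, coder_id, label) and pivot."""
    df = pd.read_csv(path)
    for col in ("item_id", "coder_id", "label"):
        if col not in df.columns:
            raise ValidationError(f"annotation CSV missing column {col!r}")
    wide = df.pivot(index="item_id", columns="coder_id", values="label")
    rows = tuple(
        tuple(None if pd.isna(v) else int(v) for v in row)
        for row in wide.itertuples(index=False)
    )
    return AnnotationMatrix(rows)


@dataclass(frozen=True)
class CoincidenceMatrix:
    """Symmetric category x category coincidence counts from pairable values."""

    categories: tuple[int, ...]
    o: np.ndarray  # (C, C), float — 1/(m-1) weights make entries fractional
    n: float  # total pairable values = sum of all entries
    n_items_used: int
    n_items_skipped: int

    @property
    def marginals(self) -> np.ndarray:
        return self.o.sum(axis=1)


def build_coincidence(annotations: AnnotationMatrix) -> CoincidenceMatrix:
    """Tally ordered label pairs within items, weighted 1/(m-1).

    Items with fewer than two non-missing labels are skipped (reported in
    ``n_items_skipped``) and contribute nothing.
    """
    values = sorted(
        {v for row in annotations.labels for v in row if v is not None}
    )
    index = {v: i for i, v in enumerate(values)}
    C = len(values)
    o = np.zeros((C, C))
    used = skipped = 0
    for row in annotations.labels:
        present = [v for v in row if v is not None]
        m = len(present)
        if m < 2:
            skipped += 1
            continue
        used += 1
        w = 1.0 / (m - 1)
        for a, b in permutations(present, 2):
            o[index[a], index[b]] += w
    n = float(o.sum())
    if n <= 0:
        raise InsufficientDataError("no pairable values in the annotation matrix")
    return CoincidenceMatrix(tuple(values), o, n, used, skipped)


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    D_o: float
    D_e: float
    n_items_used: int


def krippendorff_alpha(
    annotations: AnnotationMatrix, metric: str = "nominal"
) -> ReliabilityResult:
    """Nominal-metric Krippendorff's alpha from the coincidence matrix."""
    if metric != "nominal":
        raise ValidationError(f"only the nominal metric is supported, got {metric!r}")
    cm = build_coincidence(annotations)
    n = cm.n
    off_diag = cm.n - float(np.trace(cm.o))
    D_o = off_diag / n
    nc = cm.marginals
    D_e = float(nc.sum() ** 2 - (nc**2).sum()) / (n * (n - 1.0))
    if D_e <= 0:
        raise DegenerateDataError(
            "expected disagreement is zero (all values in one category); "
            "alpha is undefined"
        )
    alpha = 1.0 if D_o == 0.0 else 1.0 - D_o / D_e
    return ReliabilityResult(alpha=alpha, D_o=D_o, D_e=D_e, n_items_used=cm.n_items_used)


def percent_agreement(annotations: AnnotationMatrix) -> float:
    """Fraction of items where both coders agree (2 coders, complete data)."""
    if annotations.n_coders != 2:
        raise ValidationError("percent agreement requires exactly 2 coders")
    if any(None in row for row in annotations.labels):
        raise ValidationError("percent agreement requires complete data")
    agree = sum(row[0] == row[1] for row in annotations.labels)
    return agree / annotations.n_items
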
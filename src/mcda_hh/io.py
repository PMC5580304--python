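"""CSV readers/writers for the study's standard formats.

Formats (all UTF-8, "." decimal, header rows required):

* Likert responses, long: columns ``expert_id, alternative_id,
  criterion_id, rating``.
* Decision matrix, wide: first column ``alternative``, one column per
  criterion id.
* Pairwise matrix: square grid with item ids as both header row and
  first column; entries decimal or rational strings like ``1/5``.

Floats are written with ``repr`` so a write/read round trip reproduces
the object bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ahp import PairwiseMatrix, validate_pairwise
from .decision_core import DecisionMatrix, LikertResponseSet
from .errors import InputIOError, ValidationError

_RESPONSE_COLUMNS = ["expert_id", "alternative_id", "criterion_id", "rating"]


def _read_rows(path) -> list[list[str]]:
    path = Path(path)
    try:
        with path.open(newline="", encoding="utf-8") as fh:
            return [row for row in csv.reader(fh) if row]
    except OSError as exc:
        raise InputIOError(f"cannot read {path}: {exc}") from exc


def read_likert_responses(path) -> list[LikertResponseSet]:
    """Read long-format Likert responses into per-expert response sets."""
    rows = _read_rows(path)
    if not rows:
        raise InputIOError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    if header != _RESPONSE_COLUMNS:
        raise InputIOError(
            f"{path}: expected header {_RESPONSE_COLUMNS}, got {header}"
        )
    by_expert: dict[str, dict[tuple[str, str], int]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise InputIOError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
        expert, alt, crit, rating = (f.strip() for f in row)
        try:
            value = int(rating)
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: rating {rating!r} is not an integer"
            ) from None
        cells = by_expert.setdefault(expert, {})
        if (alt, crit) in cells:
            raise ValidationError(
                f"{path}:{lineno}: duplicate rating for expert {expert!r}, "
                f"cell ({alt!r}, {crit!r})"
            )
        cells[(alt, crit)] = value
    return [LikertResponseSet(expert_id=e, ratings=r) for e, r in by_expert.items()]


def read_decision_matrix(path) -> DecisionMatrix:
    """Read a wide-format decision matrix CSV."""
    rows = _read_rows(path)
    if len(rows) < 2 or len(rows[0]) < 2:
        raise InputIOError(f"{path}: expected a header row and at least one "
                           "alternative row with at least one criterion column")
    criteria = [c.strip() for c in rows[0][1:]]
    index, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(criteria) + 1:
            raise InputIOError(
                f"{path}:{lineno}: expected {len(criteria) + 1} fields, got {len(row)}"
            )
        index.append(row[0].strip())
        try:
            data.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(data, index=pd.Index(index, name="alternative"), columns=criteria)
    return DecisionMatrix(df)


def write_decision_matrix(D: DecisionMatrix, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["alternative", *D.criteria])
        for alt, row in D.data.iterrows():
            writer.writerow([alt, *[repr(float(v)) for v in row]])


def read_pairwise_matrix(path, *, raw_scale: bool = True) -> PairwiseMatrix:
    """Read a square pairwise-comparison CSV (ids in header row and first
    column; entries decimal or 'a/b')."""
    rows = _read_rows(path)
    if len(rows) < 2:
        raise InputIOError(f"{path}: expected a header row and matrix rows")
    labels = [c.strip() for c in rows[0][1:]]
    grid, row_labels = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(labels) + 1:
            raise InputIOError(
                f"{path}:{lineno}: expected {len(labels) + 1} fields, got {len(row)}"
            )
        row_labels.append(row[0].strip())
        grid.append([v.strip() for v in row[1:]])
    if row_labels != labels:
        raise InputIOError(
            f"{path}: row labels {row_labels} do not match column labels {labels}"
        )
    return validate_pairwise(grid, labels, raw_scale=raw_scale)


def write_pairwise_matrix(M: PairwiseMatrix, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["item", *M.labels])
        for label, row in zip(M.labels, M.values):
            writer.writerow([label, *[repr(float(v)) for v in row]])


def read_item_response_table(path) -> pd.DataFrame:
    """Read a respondents x items score table (first column respondent id)."""
    rows = _read_rows(path)
    if len(rows) < 3 or len(rows[0]) < 3:
        raise InputIOError(f"{path}: need >= 2 respondents and >= 2 items")
    items = [c.strip() for c in rows[0][1:]]
    index, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(items) + 1:
            raise InputIOError(
                f"{path}:{lineno}: expected {len(items) + 1} fields, got {len(row)}"
            )
        index.append(row[0].strip())
        try:
            data.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(data, index=index, columns=items)


def write_likert_responses(panel: Sequence[LikertResponseSet], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESPONSE_COLUMNS)
        for expert in panel:
            for (alt, crit), rating in expert.ratings.items():
                writer.writerow([expert.expert_id, alt, crit, rating])
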
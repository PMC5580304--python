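"""Domain types for expert-panel decision studies and decision-matrix assembly.

A study poses one question — which of m alternatives is best? — against n
criteria. A panel of experts rates every (alternative, criterion) cell on a
1-5 Likert scale ("not important at all" ... "very important"); the decision
matrix holds the per-cell arithmetic mean over experts. All criteria are
benefit-type: a higher rating always favours the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

LIKERT_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class Criterion:
    """A single evaluation criterion.

    Parameters
    ----------
    id : str
        Short machine name, unique within a study.
    label : str
        Display text; defaults to ``id``.
    benefit : bool
        Whether a higher score is better. Always True in this study design;
        kept explicit so the assumption is visible at the type level.
    """

    id: str
    label: str = ""
    benefit: bool = True

    def __post_init__(self):
        if not self.id:
            raise ValidationError("criterion id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class Alternative:
    """A candidate course of action (e.g. one hand-hygiene method)."""

    id: str
    label: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("alternative id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class LikertResponseSet:
    """One expert's complete grid of Likert ratings.

    ``ratings`` maps ``(alternative_id, criterion_id)`` to an integer in 1-5.
    Completeness against a study's alternative/criterion sets is enforced at
    decision-matrix build time, where the full design is known.
    """

    expert_id: str
    ratings: Mapping[tuple[str, str], int]

    def __post_init__(self):
        for cell, value in self.ratings.items():
            if not (isinstance(value, (int, np.integer)) and not isinstance(value, bool)):
                raise ValidationError(
                    f"expert {self.expert_id!r}, cell {cell}: rating {value!r} "
                    "is not an integer (non-integer ratings are rejected, not clamped)"
                )
            if int(value) not in LIKERT_LEVELS:
                raise ValidationError(
                    f"expert {self.expert_id!r}, cell {cell}: rating {value} "
                    f"outside the Likert range {LIKERT_LEVELS}"
                )

    def rating(self, alternative_id: str, criterion_id: str) -> int:
        return int(self.ratings[(alternative_id, criterion_id)])


@dataclass(frozen=True)
class DecisionMatrix:
    """m x n grid of mean ratings: alternatives in rows, criteria in columns.

    Entries must be strictly positive (guaranteed when built from 1-5 Likert
    data). ``n_experts`` records the provenance of the means; it is None for
    matrices loaded directly from file.
    """

    data: pd.DataFrame = field(repr=False)
    n_experts: int | None = None

    def __post_init__(self):
        df = self.data
        if df.shape[0] < 2:
            raise ValidationError(f"decision matrix needs >= 2 alternatives, got {df.shape[0]}")
        if df.shape[1] < 1:
            raise ValidationError("decision matrix needs >= 1 criterion")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("decision matrix contains non-finite entries")
        if np.any(values <= 0):
            i, j = np.argwhere(values <= 0)[0]
            raise ValidationError(
                f"decision matrix entry ({df.index[i]!r}, {df.columns[j]!r}) = "
                f"{values[i, j]} is not strictly positive"
            )
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError("alternative and criterion ids must be unique")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def alternatives(self) -> list[str]:
        return list(self.data.index)

    @property
    def criteria(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def build_decision_matrix(
    panel: Iterable[LikertResponseSet],
    criteria: Sequence[Criterion | str],
    alternatives: Sequence[Alternative | str],
) -> DecisionMatrix:
    """Aggregate a panel of Likert responses into a decision matrix.

    Each cell is the unweighted arithmetic mean over experts of the rating
    for that (alternative, criterion); all experts count equally. Every
    expert must have rated every cell — a missing cell is a data-entry
    error, reported with the offending (expert, cell) pair.
    """
    crit_ids = [c.id if isinstance(c, Criterion) else str(c) for c in criteria]
    alt_ids = [a.id if isinstance(a, Alternative) else str(a) for a in alternatives]
    if len(set(crit_ids)) != len(crit_ids):
        raise ValidationError("duplicate criterion ids")
    if len(set(alt_ids)) != len(alt_ids):
        raise ValidationError("duplicate alternative ids")
    if len(alt_ids) < 2:
        raise ValidationError("a study needs at least 2 alternatives")

    experts = list(panel)
    if not experts:
        raise ValidationError("cannot build a decision matrix from zero experts")

    grids = []
    for expert in experts:
        grid = np.empty((len(alt_ids), len(crit_ids)), dtype=float)
        for i, alt in enumerate(alt_ids):
            for j, crit in enumerate(crit_ids):
                try:
                    grid[i, j] = expert.rating(alt, crit)
                except KeyError:
                    raise ValidationError(
                        f"expert {expert.expert_id!r} is missing a rating for "
                        f"cell ({alt!r}, {crit!r})"
                    ) from None
        grids.append(grid)

    mean = np.mean(grids, axis=0)
    df = pd.DataFrame(mean, index=pd.Index(alt_ids, name="alternative"), columns=crit_ids)
    return DecisionMatrix(df, n_experts=len(experts))
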
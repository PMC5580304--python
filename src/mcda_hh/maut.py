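"""Entropy-based criterion weighting and multi-attribute utility ranking.

The weighting step derives criterion weights from the Shannon entropy of
the column-normalized decision matrix: a criterion on which the
alternatives score almost identically carries near-maximal entropy and
hence near-zero weight, while a discriminating criterion gets the weight.
The utility step rescales each criterion column to [0, 1] between the
worst- and best-scoring alternative and ranks alternatives by the
weighted sum of utilities.

Pipeline: ``normalize_matrix`` -> ``entropy_values`` -> ``entropy_weights``,
then ``utility_matrix`` -> ``total_utilities``. ``maut_report`` runs all of
it and returns one JSON-serialisable report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision_core import DecisionMatrix
from .errors import ValidationError

_COLSUM_TOL = 1e-9


class TiedCriterionWarning(UserWarning):
    """All alternatives score identically on a criterion; utilities set to 0.5."""


@dataclass(frozen=True)
class NormalizedMatrix:
    """Column-normalized shares r_ij = x_ij / sum_i x_ij; columns sum to 1."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise ValidationError("normalized entries must lie in [0, 1]")
        colsums = values.sum(axis=0)
        bad = np.abs(colsums - 1.0) > _COLSUM_TOL
        if np.any(bad):
            j = int(np.argmax(bad))
            raise ValidationError(
                f"column {self.data.columns[j]!r} sums to {colsums[j]!r}, not 1"
            )

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def normalize_matrix(D: DecisionMatrix) -> NormalizedMatrix:
    """Divide each column by its sum (strict positivity of D guarantees a
    positive divisor)."""
    x = D.values()
    r = x / x.sum(axis=0, keepdims=True)
    return NormalizedMatrix(pd.DataFrame(r, index=D.data.index, columns=D.data.columns))


def column_entropy(shares: np.ndarray) -> float:
    """Shannon entropy of one normalized column, scaled by 1/ln m to [0, 1].

    Uses the convention 0 * ln 0 = 0, so degenerate columns (one
    alternative holds the whole share) get entropy 0. A uniform column
    gets exactly 1.
    """
    r = np.asarray(shares, dtype=float)
    m = r.size
    if m < 2:
        raise ValidationError("entropy needs at least 2 alternatives")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(r > 0, r * np.log(r), 0.0)
    return float(-terms.sum() / np.log(m))


def entropy_values(R: NormalizedMatrix) -> pd.Series:
    """Per-criterion entropy e_j of the normalized matrix, each in [0, 1]."""
    r = R.values()
    e = np.array([column_entropy(r[:, j]) for j in range(r.shape[1])])
    # guard against tiny negative round-off
    e = np.clip(e, 0.0, 1.0)
    return pd.Series(e, index=R.data.columns, name="entropy")


def entropy_weights(e: pd.Series | np.ndarray) -> pd.Series:
    """Weights w_j = (1 - e_j) / sum_p (1 - e_p).

    A criterion with maximal entropy (uniform column — it cannot tell the
    alternatives apart) receives weight 0. If *every* criterion is uniform
    the method is undefined and the input is rejected rather than silently
    defaulting to equal weights.
    """
    if isinstance(e, pd.Series):
        index = e.index
        vals = e.to_numpy(dtype=float)
    else:
        vals = np.asarray(e, dtype=float)
        index = pd.RangeIndex(vals.size)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("entropy values must lie in [0, 1]")
    d = 1.0 - vals
    total = d.sum()
    if total <= _COLSUM_TOL:
        raise ValidationError(
            "no discriminating criteria: every entropy value is 1 "
            "(all columns uniform), so entropy weights are undefined"
        )
    return pd.Series(d / total, index=index, name="weight")


def utility_matrix(D: DecisionMatrix) -> pd.DataFrame:
    """Per-criterion utilities u_ij = (x_ij - min_i) / (max_i - min_i).

    The best alternative on a criterion gets utility 1, the worst 0; with
    exactly two alternatives this reduces to the 1/0 assignment. A tied
    column (max = min) makes the formula 0/0, so every alternative gets
    the neutral 0.5 and a :class:`TiedCriterionWarning` is emitted.
    """
    x = D.values()
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    u = np.empty_like(x)
    for j in range(x.shape[1]):
        if span[j] == 0:
            warnings.warn(
                f"criterion {D.data.columns[j]!r}: all alternatives tied at "
                f"{hi[j]}; assigning neutral utility 0.5",
                TiedCriterionWarning,
                stacklevel=2,
            )
            u[:, j] = 0.5
        else:
            u[:, j] = (x[:, j] - lo[j]) / span[j]
    return pd.DataFrame(u, index=D.data.index, columns=D.data.columns)


@dataclass(frozen=True)
class UtilityTable:
    """Utilities, total utilities and the resulting preference ranking."""

    utilities: pd.DataFrame = field(repr=False)
    total: pd.Series = field(repr=False)
    ranking: tuple[str, ...]
    tied: bool

    @property
    def best(self) -> str:
        return self.ranking[0]


def total_utilities(u: pd.DataFrame, weights: pd.Series | np.ndarray) -> UtilityTable:
    """Weighted total utility U_i = sum_j w_j u_ij, highest first.

    Ties in total utility are broken by input (row) order and flagged.
    """
    if isinstance(weights, pd.Series):
        if list(weights.index) != list(u.columns):
            if set(weights.index) != set(u.columns):
                raise ValidationError("weight criteria do not match utility criteria")
            weights = weights.reindex(u.columns)
        w = weights.to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != u.shape[1]:
            raise ValidationError(
                f"{w.size} weights for {u.shape[1]} criteria"
            )
    total = pd.Series(u.to_numpy(dtype=float) @ w, index=u.index, name="total_utility")
    # stable sort keeps input order among exact ties
    order = np.argsort(-total.to_numpy(), kind="stable")
    ranking = tuple(str(total.index[i]) for i in order)
    rounded = total.to_numpy()[order]
    tied = bool(np.any(np.diff(rounded) == 0))
    return UtilityTable(utilities=u, total=total, ranking=ranking, tied=tied)


def maut_report(D: DecisionMatrix, weights: pd.Series | None = None) -> dict:
    """Run the full entropy-MAUT pipeline on a decision matrix.

    If ``weights`` is given (e.g. externally derived criterion weights) the
    entropy stage still runs for the report but the supplied weights drive
    the utilities.
    """
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", TiedCriterionWarning)
        R = normalize_matrix(D)
        e = entropy_values(R)
        try:
            w_entropy = entropy_weights(e)
            entropy_error = None
        except ValidationError as exc:
            if weights is None:
                raise
            w_entropy, entropy_error = None, str(exc)
        w = weights if weights is not None else w_entropy
        u = utility_matrix(D)
        table = total_utilities(u, w)
    return {
        "alternatives": D.alternatives,
        "criteria": D.criteria,
        "n_experts": D.n_experts,
        "decision_matrix": D.data.to_dict(orient="index"),
        "normalized": R.data.to_dict(orient="index"),
        "entropy": None if entropy_error else e.to_dict(),
        "entropy_weights": None if w_entropy is None else w_entropy.to_dict(),
        "weights_used": (w.to_dict() if isinstance(w, pd.Series)
                         else dict(zip(D.criteria, np.asarray(w, float)))),
        "weights_source": "supplied" if weights is not None else "entropy",
        "utilities": table.utilities.to_dict(orient="index"),
        "total_utility": table.total.to_dict(),
        "ranking": list(table.ranking),
        "tied_ranking": table.tied,
        "warnings": [str(w_.message) for w_ in caught],
    }
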
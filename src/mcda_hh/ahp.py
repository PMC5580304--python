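"""Analytic hierarchy process: pairwise matrices, priorities, consistency,
group aggregation and hierarchical synthesis.

Judgments are positive reciprocal n x n matrices on the Saaty 1-9 scale
(a_ij = how many times more important item i is than item j, a_ji = 1/a_ij).
Priorities come from the principal right eigenvector (power iteration, the
classical Saaty derivation); the row geometric mean is kept as a second,
independent derivation for cross-checking. Judgment consistency is scored
by CR = CI / RI with CI = (lambda_max - n)/(n - 1) and RI the expected CI
of random reciprocal matrices of order n; CR below 0.10 is conventionally
acceptable. A panel of experts is combined by the entry-wise geometric
mean, which is the only separable aggregation that preserves reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Expected consistency index of random reciprocal matrices, by order
#: (Saaty's random-index table; order 1 and 2 matrices are always consistent).
RANDOM_INDEX: dict[int, float] = {
    1: 0.00, 2: 0.00, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Admissible raw judgment values: 1/9 ... 1/2, 1, 2 ... 9.
SAATY_SCALE: tuple[float, ...] = tuple(
    [1.0 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)

CR_THRESHOLD_DEFAULT = 0.10
_RECIPROCITY_TOL = 1e-6
_SCALE_TOL = 1e-9


def parse_judgment(token) -> Fraction:
    """Parse one judgment entry: a number, a decimal string, or 'a/b'.

    Rational strings are kept exact (as :class:`fractions.Fraction`) so
    reciprocity can be verified without floating-point slack.
    """
    if isinstance(token, Fraction):
        value = token
    elif isinstance(token, (int, np.integer)):
        value = Fraction(int(token))
    elif isinstance(token, (float, np.floating)):
        if not np.isfinite(token):
            raise ValidationError(f"non-finite judgment {token!r}")
        value = Fraction(float(token))
    elif isinstance(token, str):
        text = token.strip()
        try:
            if "/" in text:
                num, den = text.split("/")
                value = Fraction(int(num), int(den))
            else:
                value = Fraction(text)
        except (ValueError, ZeroDivisionError) as exc:
            raise ValidationError(f"cannot parse judgment {token!r}") from exc
    else:
        raise ValidationError(f"cannot parse judgment of type {type(token).__name__}")
    if value <= 0:
        raise ValidationError(f"judgment {token!r} is not positive")
    return value


@dataclass(frozen=True)
class PairwiseMatrix:
    """Validated positive reciprocal judgment matrix.

    Construct via :func:`validate_pairwise`; the float array in ``values``
    is what all numerics operate on.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __eq__(self, other):
        if not isinstance(other, PairwiseMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.values, other.values)


def validate_pairwise(
    raw,
    labels: Sequence[str] | None = None,
    *,
    raw_scale: bool = True,
) -> PairwiseMatrix:
    """Check and wrap a raw judgment matrix.

    ``raw`` may hold numbers, Fractions or strings like ``"1/5"``. Checks:
    square, all entries positive, unit diagonal, reciprocity
    (|a_ij * a_ji - 1| <= 1e-6, exact when both entries are rational), and
    — for raw expert input (``raw_scale=True``) — every entry within
    [1/9, 9]. Aggregated matrices legitimately leave the discrete scale
    (a geometric mean of scale values need not be a scale value), so
    aggregation re-wraps with ``raw_scale=False``.
    """
    rows = [list(r) for r in raw]
    n = len(rows)
    if n < 1 or any(len(r) != n for r in rows):
        raise ValidationError(f"pairwise matrix must be square, got rows of lengths "
                              f"{[len(r) for r in rows]}")
    if labels is None:
        labels = tuple(f"item{i + 1}" for i in range(n))
    else:
        labels = tuple(str(l) for l in labels)
        if len(labels) != n:
            raise ValidationError(f"{len(labels)} labels for a {n}x{n} matrix")
        if len(set(labels)) != n:
            raise ValidationError("duplicate item labels")

    exact = [[parse_judgment(rows[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        # tolerate float round-off from constructions like w_i/w_i
        if abs(float(exact[i][i]) - 1.0) > 1e-9:
            raise ValidationError(
                f"diagonal entry ({labels[i]}, {labels[i]}) = "
                f"{float(exact[i][i])!r}, must be 1"
            )
        exact[i][i] = Fraction(1)
    for i in range(n):
        for j in range(i + 1, n):
            prod = exact[i][j] * exact[j][i]
            if abs(float(prod) - 1.0) > _RECIPROCITY_TOL:
                raise ValidationError(
                    f"reciprocity violated at ({labels[i]}, {labels[j]}): "
                    f"a_ij = {float(exact[i][j])!r}, a_ji = {float(exact[j][i])!r}"
                )
    if raw_scale:
        for i in range(n):
            for j in range(n):
                v = float(exact[i][j])
                if v < SAATY_SCALE[0] - _SCALE_TOL or v > SAATY_SCALE[-1] + _SCALE_TOL:
                    raise ValidationError(
                        f"entry ({labels[i]}, {labels[j]}) = {v!r} outside the "
                        "1/9..9 judgment scale"
                    )
    values = np.array([[float(v) for v in row] for row in exact], dtype=float)
    return PairwiseMatrix(labels=labels, values=values)


def required_comparison_count(n: int) -> int:
    """Number of independent judgments for n items: n(n-1)/2 (the upper
    triangle; the diagonal is fixed and the lower triangle is implied)."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValidationError(f"item count must be a positive integer, got {n!r}")
    return int(n) * (int(n) - 1) // 2


def principal_priorities(
    M: PairwiseMatrix,
    *,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Principal right eigenvector by power iteration, and lambda_max.

    Starts from the uniform vector, renormalises to sum 1 each step, and
    stops when the L1 change falls below ``tol``. For a positive matrix
    Perron-Frobenius guarantees convergence to the unique positive
    eigenvector; the iteration cap is a guard only. lambda_max is
    estimated as the mean of the component-wise Rayleigh ratios
    (Mp)_i / p_i, exact at the fixed point.
    """
    A = M.values
    n = M.n
    if n == 1:
        return np.array([1.0]), 1.0
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        q = A @ p
        q /= q.sum()
        if np.abs(q - p).sum() < tol:
            p = q
            break
        p = q
    else:
        raise ValidationError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(last L1 step {np.abs(A @ p / (A @ p).sum() - p).sum():.3e})"
        )
    lambda_max = float(np.mean((A @ p) / p))
    return p, lambda_max


def row_geometric_mean_priorities(M: PairwiseMatrix) -> np.ndarray:
    """Row-geometric-mean priorities: p_i proportional to (prod_j a_ij)^(1/n).

    Exact for consistent matrices and close to the eigenvector for
    near-consistent ones; serves as an independent derivation.
    """
    logs = np.log(M.values)
    g = np.exp(logs.mean(axis=1))
    return g / g.sum()


@dataclass(frozen=True)
class ConsistencyReport:
    """lambda_max, CI, RI, CR and the pass/fail verdict at the threshold."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    threshold: float
    acceptable: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "lambda_max": self.lambda_max,
            "CI": self.ci,
            "RI": self.ri,
            "CR": self.cr,
            "threshold": self.threshold,
            "acceptable": self.acceptable,
        }


def consistency(
    M: PairwiseMatrix,
    lambda_max: float | None = None,
    *,
    threshold: float = CR_THRESHOLD_DEFAULT,
    ri_table: Mapping[int, float] | None = None,
) -> ConsistencyReport:
    """Consistency report for a judgment matrix.

    CI = (lambda_max - n)/(n - 1); CR = CI/RI. Matrices of order 1 or 2
    are reciprocally determined and always consistent, so CR is defined
    as 0 there. Orders above 10 need an extended RI table passed in
    ``ri_table``.
    """
    if not (0 < threshold < 1):
        raise ValidationError(f"CR threshold must be in (0, 1), got {threshold}")
    table = dict(RANDOM_INDEX)
    if ri_table:
        table.update({int(k): float(v) for k, v in ri_table.items()})
    n = M.n
    if n not in table:
        raise ValidationError(
            f"no random index for order {n}; supply an extended RI table"
        )
    if lambda_max is None:
        _, lambda_max = principal_priorities(M)
    ci = 0.0 if n <= 1 else (lambda_max - n) / (n - 1)
    ri = table[n]
    cr = 0.0 if n <= 2 else ci / ri
    return ConsistencyReport(
        n=n, lambda_max=float(lambda_max), ci=float(ci), ri=ri, cr=float(cr),
        threshold=threshold, acceptable=bool(cr < threshold),
    )


def aggregate_experts_geometric(panel: Iterable[PairwiseMatrix]) -> PairwiseMatrix:
    """Combine expert judgment matrices by the entry-wise geometric mean.

    Experts are weighted equally. The geometric mean of reciprocal
    matrices is reciprocal by construction, so the result is re-validated
    with the discrete-scale check switched off (aggregates may fall
    between scale values).
    """
    matrices = list(panel)
    if not matrices:
        raise ValidationError("cannot aggregate an empty panel")
    labels = matrices[0].labels
    for k, m in enumerate(matrices):
        if m.labels != labels:
            raise ValidationError(
                f"expert matrix {k} has labels {m.labels}, expected {labels}"
            )
    stack = np.stack([m.values for m in matrices])
    combined = np.exp(np.log(stack).mean(axis=0))
    # enforce exact unit diagonal / reciprocity against rounding drift
    n = len(labels)
    combined[np.diag_indices(n)] = 1.0
    iu = np.triu_indices(n, k=1)
    combined[(iu[1], iu[0])] = 1.0 / combined[iu]
    return validate_pairwise(combined, labels, raw_scale=False)


@dataclass(frozen=True)
class Hierarchy:
    """Three-level AHP model: goal, criteria, alternatives.

    One pairwise matrix compares the criteria against the goal; one
    pairwise matrix per criterion compares the alternatives against that
    criterion. All alternative-level matrices must cover the same
    alternatives in the same order.
    """

    goal: str
    criteria_matrix: PairwiseMatrix
    alternative_matrices: Mapping[str, PairwiseMatrix]

    def __post_init__(self):
        crit = self.criteria_matrix.labels
        missing = [c for c in crit if c not in self.alternative_matrices]
        if missing:
            raise ValidationError(
                f"no alternative-level matrix for criteria: {missing}"
            )
        extra = [c for c in self.alternative_matrices if c not in crit]
        if extra:
            raise ValidationError(
                f"alternative-level matrices for unknown criteria: {extra}"
            )
        alt_labels = {m.labels for m in self.alternative_matrices.values()}
        if len(alt_labels) != 1:
            raise ValidationError(
                "alternative-level matrices disagree on the alternative set: "
                f"{sorted(alt_labels)}"
            )

    @property
    def alternatives(self) -> tuple[str, ...]:
        return next(iter(self.alternative_matrices.values())).labels


def synthesize_global_priorities(
    H: Hierarchy,
    *,
    method: str = "eigenvector",
) -> dict:
    """Distributive synthesis: global_i = sum_j w_j * p_ij.

    ``w`` are the criterion priorities from the criteria-level matrix and
    ``p_ij`` the local priority of alternative i under criterion j; the
    global vector sums to 1 because each factor does. ``method`` selects
    the derivation ('eigenvector' or 'rowgm') used at both levels.
    """
    derive = _priority_fn(method)
    w = derive(H.criteria_matrix)
    locals_ = {c: derive(H.alternative_matrices[c]) for c in H.criteria_matrix.labels}
    alts = H.alternatives
    global_p = np.zeros(len(alts))
    for j, c in enumerate(H.criteria_matrix.labels):
        global_p += w[j] * locals_[c]
    return {
        "goal": H.goal,
        "method": method,
        "criterion_weights": dict(zip(H.criteria_matrix.labels, w.tolist())),
        "local_priorities": {c: dict(zip(alts, p.tolist())) for c, p in locals_.items()},
        "global_priorities": dict(zip(alts, global_p.tolist())),
        "ranking": [a for _, a in sorted(zip(-global_p, alts))],
    }


def _priority_fn(method: str):
    if method == "eigenvector":
        return lambda M: principal_priorities(M)[0]
    if method == "rowgm":
        return row_geometric_mean_priorities
    raise ValidationError(f"unknown priority method {method!r} "
                          "(expected 'eigenvector' or 'rowgm')")
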
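"""Internal-consistency reliability (Cronbach's alpha) for the Likert
instrument.

alpha = k/(k-1) * (1 - sum of item variances / variance of the total
score), with sample (n-1) variances. Values near 1 indicate a scale whose
items measure a common construct; 0.7 is the conventional floor for an
acceptable questionnaire.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def cronbach_alpha(table: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha of a respondents x items score table.

    Requires at least 2 items, at least 2 respondents, no missing cells,
    and a total score that actually varies across respondents (alpha is
    undefined otherwise). Missing data are rejected, not imputed.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D respondents x items table")
    n, k = X.shape
    if k < 2:
        raise ValidationError(f"alpha needs >= 2 items, got {k}")
    if n < 2:
        raise ValidationError(f"alpha needs >= 2 respondents, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("missing or non-finite scores are rejected, not imputed")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
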
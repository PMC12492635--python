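"""Inter-rater agreement statistics over multi-annotator tiers.

Multiple annotators — human or machine — may label the same session under
the same scheme.  Their tiers are binned onto a common interval grid and
stacked into an items x raters :class:`RatingMatrix`; agreement is then
summarized with Cohen's kappa (chance-corrected agreement of two
categorical raters) or Cronbach's alpha (internal consistency of numeric
raters treated as parallel items).

Missing entries (intervals a rater left unlabeled) are handled by
complete-case (listwise) deletion, the standard convention.  Variances in
alpha use the unbiased n-1 denominator; the two textbook conventions
differ only by a common factor that cancels in the variance ratio when
applied consistently, but the n-1 form is stated here for definiteness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import AnnotationTier
from .fusion import bin_stream

__all__ = [
    "RatingMatrix",
    "align_tiers_to_matrix",
    "cohens_kappa",
    "cronbachs_alpha",
]


@dataclass
class RatingMatrix:
    """Items x raters matrix of labels or numbers; NaN/None = missing."""

    values: pd.DataFrame  # index: item ids, columns: rater ids

    @property
    def items(self) -> list:
        return list(self.values.index)

    @property
    def raters(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def complete_cases(self) -> pd.DataFrame:
        return self.values.dropna(axis=0, how="any")

    @property
    def n_dropped(self) -> int:
        return len(self.values) - len(self.complete_cases())


def align_tiers_to_matrix(
    tiers: Sequence[AnnotationTier], interval_length: float = 1.0
) -> RatingMatrix:
    """Bin each rater's tier and stack the columns on a shared grid.

    All tiers must share session, role and scheme.  Rows are the union of
    the raters' labeled intervals; an interval a rater did not label is
    missing in that rater's column.  Rows labeled by nobody do not occur
    (the grid is the union); downstream statistics drop incomplete rows.
    """
    if len(tiers) < 2:
        raise ValueError("need at least 2 raters")
    ref = tiers[0]
    for t in tiers[1:]:
        if (t.session, t.role, t.scheme) != (ref.session, ref.role, ref.scheme):
            raise ValueError(
                "tiers must share session, role and scheme "
                f"(got {t.annotator!r} vs {ref.annotator!r})"
            )
    columns = {}
    for t in tiers:
        if t.annotator in columns:
            raise ValueError(f"duplicate annotator {t.annotator!r}")
        columns[t.annotator] = bin_stream(t, interval_length)
    index = sorted(set().union(*[set(c) for c in columns.values()]))
    frame = pd.DataFrame(
        {rater: [col.get(i) for i in index] for rater, col in columns.items()},
        index=pd.Index(index, name="interval_index"),
    )
    return RatingMatrix(values=frame)


def cohens_kappa(m: RatingMatrix) -> float:
    """Cohen's kappa for exactly two categorical raters.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the product of the two raters' marginal
    label frequencies.  Computed on complete cases.  The degenerate case
    p_e = 1 (both raters constant on the same label) returns 1.0 when
    p_o = 1 and raises otherwise.
    """
    if len(m.raters) != 2:
        raise ValueError(f"Cohen's kappa needs exactly 2 raters, got {len(m.raters)}")
    data = m.complete_cases()
    n = len(data)
    if n < 2:
        raise ValueError(f"need >= 2 complete items, got {n}")
    a = data.iloc[:, 0].astype(str).to_numpy()
    b = data.iloc[:, 1].astype(str).to_numpy()
    labels = sorted(set(a) | set(b))
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for lab in labels:
        p_e += float(np.mean(a == lab)) * float(np.mean(b == lab))
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 with disagreement")
    return (p_o - p_e) / (1.0 - p_e)


def cronbachs_alpha(m: RatingMatrix) -> float:
    """Cronbach's alpha across numeric raters.

    alpha = k/(k-1) * (1 - sum(var_rater) / var_total), with k raters,
    per-rater sample variances over items and var_total the variance of
    the per-item rater sums (all with ddof=1), on complete cases.
    Invariant under adding a constant to any rater's column.
    """
    data = m.complete_cases()
    k = data.shape[1]
    if k < 2:
        raise ValueError(f"Cronbach's alpha needs >= 2 raters, got {k}")
    if len(data) < 2:
        raise ValueError(f"need >= 2 complete items, got {len(data)}")
    x = data.to_numpy(dtype=float)
    var_raters = x.var(axis=0, ddof=1)
    var_total = x.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("alpha undefined: zero total variance")
    return float(k / (k - 1) * (1.0 - var_raters.sum() / var_total))
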
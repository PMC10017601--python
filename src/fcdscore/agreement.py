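"""Two-observer agreement: cross-tabulation, Cohen's kappa, and strength bands.

The kappa standard error is the asymptotic (non-null) variance of
Fleiss, Cohen & Everitt (1969), the same large-sample formula SPSS
reports; the 95% CI is ``kappa +/- 1.96*se`` clipped to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import DegenerateTableError, ValidationError


class Strength(str, Enum):
    BELOW_SLIGHT = "below_slight"
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class CrossTab:
    """Square two-observer contingency table.

    Rows index observer 2's category, columns observer 1's.
    """

    counts: np.ndarray
    category_labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError(f"crosstab must be square, got shape {counts.shape}")
        if counts.shape[0] != len(self.category_labels):
            raise ValidationError("category_labels length must match table size")
        if (counts < 0).any():
            raise ValidationError("crosstab counts must be non-negative")
        if counts.sum() <= 0:
            raise ValidationError("crosstab grand total must be positive")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "CrossTab":
        return CrossTab(self.counts.T.copy(), self.category_labels)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    se: float
    ci_low: float
    ci_high: float
    strength: Strength

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("kappa", "p_observed", "p_expected", "se", "ci_low", "ci_high")}
        d["strength"] = self.strength.value
        return d


def crosstab(
    ratings_obs1: Sequence, ratings_obs2: Sequence, categories: Sequence
) -> CrossTab:
    """Cross-tabulate paired ratings: rows = observer 2, columns = observer 1."""
    if len(ratings_obs1) != len(ratings_obs2):
        raise ValidationError(
            f"paired rating lists differ in length "
            f"({len(ratings_obs1)} vs {len(ratings_obs2)})"
        )
    if len(ratings_obs1) == 0:
        raise ValidationError("cannot cross-tabulate empty rating lists")
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(ratings_obs1, ratings_obs2):
        if a not in index or b not in index:
            raise ValidationError(f"rating outside declared categories: {(a, b)!r}")
        counts[index[b], index[a]] += 1
    return CrossTab(counts, tuple(categories))


def agreement_strength(kappa: float) -> Strength:
    """Map kappa to the printed strength bands after rounding to 2 decimals.

    Bands: slight 0.00-0.20, fair 0.21-0.40, moderate 0.41-0.60,
    good 0.61-0.80, excellent 0.81-1.00; negative kappa falls below them.
    """
    if not -1 - 1e-12 <= kappa <= 1 + 1e-12:
        raise ValidationError(f"kappa must lie in [-1, 1], got {kappa!r}")
    # half-up decimal rounding so 0.205 lands in the 0.21-0.40 band
    k = float(
        Decimal(str(float(kappa))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
    if k < 0:
        return Strength.BELOW_SLIGHT
    if k <= 0.20:
        return Strength.SLIGHT
    if k <= 0.40:
        return Strength.FAIR
    if k <= 0.60:
        return Strength.MODERATE
    if k <= 0.80:
        return Strength.GOOD
    return Strength.EXCELLENT


def cohen_kappa(tab: CrossTab) -> KappaResult:
    """Unweighted Cohen's kappa with the Fleiss-Cohen-Everitt asymptotic CI."""
    n = tab.n
    p = tab.counts / n
    row = p.sum(axis=1)  # observer 2 marginal
    col = p.sum(axis=0)  # observer 1 marginal
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateTableError(
            "expected agreement is 1 (all mass in one category); kappa undefined"
        )
    kappa = (p_o - p_e) / (1 - p_e)

    k = p.shape[0]
    idx = np.arange(k)
    a = float(
        sum(
            p[i, i] * ((1 - p_e) - (col[i] + row[i]) * (1 - p_o)) ** 2
            for i in idx
        )
    )
    off = np.ones((k, k), dtype=bool)
    off[idx, idx] = False
    # (col_i + row_j)^2 for cell (i, j): i = observer-2 category, j = observer-1
    sums = (col[np.newaxis, :] + row[:, np.newaxis]) ** 2
    b = float((1 - p_o) ** 2 * (p[off] * sums[off]).sum())
    c = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (a + b - c) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))

    ci_low = max(kappa - 1.96 * se, -1.0)
    ci_high = min(kappa + 1.96 * se, 1.0)
    return KappaResult(
        kappa=float(kappa),
        p_observed=p_o,
        p_expected=p_e,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        strength=agreement_strength(kappa),
    )


def wall_agreement(records, wall: str) -> KappaResult:
    """Kappa for one wall from a cohort of two-observer records."""
    attr = "L" if wall == "lateral" else "I"
    obs1 = [getattr(r, f"obs1_{attr}") for r in records]
    obs2 = [getattr(r, f"obs2_{attr}") for r in records]
    return cohen_kappa(crosstab(obs1, obs2, categories=(0, 1, 2, 3)))
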
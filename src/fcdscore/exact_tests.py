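"""Group-comparison tests on score distributions.

Implements the Freeman-Halton generalization of Fisher's exact test for
r x c tables by exhaustive enumeration of all tables sharing the observed
margins (two-sided probability-mass criterion), plus the Pearson
chi-square test and the selection rule used to pick between them: the
exact test whenever any *observed* cell count is below 5.

The margin-constrained enumeration is deliberately hand-rolled — it is
the point of this module — with per-table probabilities computed in log
space via log-gamma and accumulated with log-sum-exp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .errors import CapacityError, DegenerateTableError, ValidationError

logger = logging.getLogger(__name__)

#: Relative slack when comparing a candidate table's probability with the
#: observed table's, so borderline-equal tables never flip membership
#: across platforms.
PROBABILITY_TOLERANCE = 1e-7

DEFAULT_TABLE_CAP = 10_000_000


class Method(str, Enum):
    EXACT = "exact"
    PEARSON = "pearson_chi_square"


@dataclass(frozen=True)
class RxCTable:
    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError(
                f"table must have at least 2 rows and 2 columns, got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValidationError("table counts must be non-negative")
        if counts.sum() <= 0:
            raise ValidationError("table grand total must be positive")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if not self.row_labels:
            object.__setattr__(self, "row_labels", tuple(range(counts.shape[0])))
        if not self.col_labels:
            object.__setattr__(self, "col_labels", tuple(range(counts.shape[1])))


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    method: Method
    n_tables_enumerated: int = 1
    statistic: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "method": self.method.value,
            "n_tables_enumerated": self.n_tables_enumerated,
            "statistic": self.statistic,
        }


def _log_table_probability(cells: np.ndarray, log_const: float) -> float:
    # P(table) = prod(row!) prod(col!) / (N! prod(cell!)); log_const holds
    # the margin-only part.
    return log_const - gammaln(cells + 1.0).sum()


def enumerate_log_probabilities(
    table: RxCTable, cap: int = DEFAULT_TABLE_CAP
) -> np.ndarray:
    """Log-probabilities of every table with the observed margins.

    Recursive row-by-row cell filling; partial rows are pruned as soon as a
    running column margin would go negative.
    """
    counts = table.counts
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    log_const = float(
        gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() - gammaln(n + 1.0)
    )
    r, c = counts.shape
    out: list[float] = []

    def fill_row(i: int, j: int, rem: int, cols_left: np.ndarray, flat: list[int]) -> None:
        if len(out) > cap:
            raise CapacityError(
                f"exact enumeration exceeded the cap of {cap} tables"
            )
        if j == c - 1:
            if rem > cols_left[j]:
                return
            flat.append(rem)
            nxt = cols_left.copy()
            nxt[j] -= rem
            if i == r - 1:
                out.append(
                    _log_table_probability(np.asarray(flat, dtype=float), log_const)
                )
            else:
                fill_row(i + 1, 0, int(rows[i + 1]), nxt, flat)
            flat.pop()
            return
        for v in range(min(rem, int(cols_left[j])) + 1):
            flat.append(v)
            nxt = cols_left.copy()
            nxt[j] -= v
            fill_row(i, j + 1, rem - v, nxt, flat)
            flat.pop()

    fill_row(0, 0, int(rows[0]), cols.copy(), [])
    return np.asarray(out)


def freeman_halton_p(table: RxCTable, cap: int = DEFAULT_TABLE_CAP) -> ExactTestResult:
    """Two-sided exact p for an r x c table (probability-mass criterion).

    p is the total probability of margin-compatible tables whose
    probability does not exceed the observed table's (within a small
    relative tolerance), normalized by the enumerated total mass.
    """
    log_probs = enumerate_log_probabilities(table, cap=cap)
    rows = table.counts.sum(axis=1)
    cols = table.counts.sum(axis=0)
    log_const = float(
        gammaln(rows + 1.0).sum()
        + gammaln(cols + 1.0).sum()
        - gammaln(table.counts.sum() + 1.0)
    )
    log_obs = _log_table_probability(table.counts.astype(float), log_const)
    in_tail = log_probs <= log_obs + np.log1p(PROBABILITY_TOLERANCE)
    # total enumerated mass is 1 up to float error; normalizing guards it
    p = float(np.exp(logsumexp(log_probs[in_tail]) - logsumexp(log_probs)))
    return ExactTestResult(
        p_value=min(p, 1.0),
        method=Method.EXACT,
        n_tables_enumerated=len(log_probs),
    )


def pearson_chi_square(table: RxCTable) -> ExactTestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = table.counts.astype(float)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError(
            "a zero row or column margin leaves expected counts undefined"
        )
    expected = np.outer(rows, cols) / counts.sum()
    stat = float(((counts - expected) ** 2 / expected).sum())
    dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return ExactTestResult(
        p_value=float(chi2.sf(stat, dof)),
        method=Method.PEARSON,
        statistic=stat,
    )


def select_and_test(table: RxCTable, cap: int = DEFAULT_TABLE_CAP) -> ExactTestResult:
    """Pick the exact test when any observed cell is < 5, else Pearson chi-square.

    The rule intentionally inspects *observed* counts.  When it disagrees
    with the textbook expected-count rule the discrepancy is logged.
    """
    counts = table.counts
    observed_small = bool((counts < 5).any())
    rows = counts.sum(axis=1).astype(float)
    cols = counts.sum(axis=0).astype(float)
    if (rows > 0).all() and (cols > 0).all():
        expected_small = bool((np.outer(rows, cols) / counts.sum() < 5).any())
        if observed_small != expected_small:
            logger.info(
                "observed-count rule (%s) disagrees with expected-count rule (%s)",
                "exact" if observed_small else "chi-square",
                "exact" if expected_small else "chi-square",
            )
    if observed_small:
        return freeman_halton_p(table, cap=cap)
    return pearson_chi_square(table)


def table_from_columns(
    col_a: Sequence[int], col_b: Sequence[int], labels: tuple[str, str] = ("a", "b")
) -> RxCTable:
    """Convenience: build an r x 2 table from two per-category count vectors."""
    return RxCTable(
        np.column_stack([col_a, col_b]), col_labels=labels
    )
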
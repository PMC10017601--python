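"""Ordinal wall scoring, composite score, classification rule, and cohort I/O.

Each wall of the bony canal is assigned an ordinal appearance score 0-3
(0 = no evident bony covering, 1 = discontinuous covering with linear
deficiency, 2 = discontinuous covering with dotted deficiency,
3 = continuous bony covering).  The composite score is the sum of the
lateral- and inferior-wall scores (0-6); ears scoring strictly below a
cutoff are classified as dehiscent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import MissingConsensusError, ValidationError

logger = logging.getLogger(__name__)

SCORE_VALUES = (0, 1, 2, 3)

SCORE_LABELS = {
    0: "no evident bony covering",
    1: "discontinuous bony covering, linear deficiency",
    2: "discontinuous bony covering, dotted deficiency",
    3: "continuous bony covering",
}

MAX_COMPOSITE = 6


class Wall(str, Enum):
    LATERAL = "lateral"
    INFERIOR = "inferior"


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Finding(str, Enum):
    DEHISCENT = "dehiscent"
    INTACT = "intact"
    UNKNOWN = "unknown"


def validate_score(value: int, field: str = "score") -> int:
    """Return ``value`` as int if it is a valid wall score, else raise.

    The error message names the offending field so CSV ingestion can point
    at the exact column.
    """
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{field}: expected an integer score, got {value!r}")
    if v != value or v not in SCORE_VALUES:
        raise ValidationError(f"{field}: score must be one of {SCORE_VALUES}, got {value!r}")
    return v


@dataclass(frozen=True)
class CompositeScore:
    """Sum of the two wall scores; ``total`` is always ``L + I``."""

    L: int
    I: int

    def __post_init__(self) -> None:
        validate_score(self.L, "L")
        validate_score(self.I, "I")

    @property
    def total(self) -> int:
        return self.L + self.I


def fcd_score(L: int, I: int) -> CompositeScore:
    """Combine the lateral and inferior wall scores into a composite score."""
    return CompositeScore(L=validate_score(L, "L"), I=validate_score(I, "I"))


def _validate_cutoff(cutoff: int) -> int:
    try:
        c = int(cutoff)
    except (TypeError, ValueError):
        raise ValidationError(f"cutoff: expected an integer, got {cutoff!r}")
    if c != cutoff or not 0 <= c <= 7:
        raise ValidationError(f"cutoff: must be in 0..7, got {cutoff!r}")
    return c


def classify(score: CompositeScore | int, cutoff: int) -> Finding:
    """Classify an ear from its composite score under a strict cutoff.

    The ear is called dehiscent iff ``total < cutoff`` (strict inequality).
    """
    c = _validate_cutoff(cutoff)
    total = score.total if isinstance(score, CompositeScore) else int(score)
    if not 0 <= total <= MAX_COMPOSITE:
        raise ValidationError(f"score: composite total must be in 0..6, got {total!r}")
    return Finding.DEHISCENT if total < c else Finding.INTACT


def dehiscent_combinations(cutoff: int) -> frozenset[tuple[int, int]]:
    """All (L, I) wall-score pairs classified dehiscent at the given cutoff."""
    c = _validate_cutoff(cutoff)
    return frozenset(
        (L, I) for L in SCORE_VALUES for I in SCORE_VALUES if L + I < c
    )


def consensus_merge(obs1: int, obs2: int, adjudicated: Optional[int] = None) -> int:
    """Merge two observer scores into a consensus score.

    Agreement passes through; a discrepancy requires an adjudicated value.
    """
    a = validate_score(obs1, "obs1")
    b = validate_score(obs2, "obs2")
    if a == b:
        return a
    if adjudicated is None:
        raise MissingConsensusError(
            f"observers disagree ({a} vs {b}) and no adjudicated value was supplied"
        )
    return validate_score(adjudicated, "adjudicated")


@dataclass(frozen=True)
class EarRecord:
    """One ear's two-observer and consensus wall scores plus the surgical finding."""

    ear_id: str
    laterality: Laterality
    obs1_L: int
    obs1_I: int
    obs2_L: int
    obs2_I: int
    consensus_L: Optional[int] = None
    consensus_I: Optional[int] = None
    surgical_finding: Finding = Finding.UNKNOWN

    def __post_init__(self) -> None:
        for field in ("obs1_L", "obs1_I", "obs2_L", "obs2_I"):
            validate_score(getattr(self, field), field)
        for field in ("consensus_L", "consensus_I"):
            v = getattr(self, field)
            if v is not None:
                validate_score(v, field)

    def composite(self) -> CompositeScore:
        """Composite score from the consensus reads; requires both walls."""
        if self.consensus_L is None or self.consensus_I is None:
            raise MissingConsensusError(
                f"ear {self.ear_id}: consensus scores required for classification"
            )
        return fcd_score(self.consensus_L, self.consensus_I)


def derive_consensus(record: EarRecord) -> EarRecord:
    """Fill in consensus fields where the observers already agree."""
    updates = {}
    if record.consensus_L is None and record.obs1_L == record.obs2_L:
        updates["consensus_L"] = record.obs1_L
    if record.consensus_I is None and record.obs1_I == record.obs2_I:
        updates["consensus_I"] = record.obs1_I
    return replace(record, **updates) if updates else record


# ---------------------------------------------------------------------------
# CSV schemas
#
# Ratings (long format): ear_id, laterality, observer, lateral_score,
#   inferior_score with observer in {1, 2, consensus}.
# Gold standard: ear_id, surgical_finding in {dehiscent, intact, unknown}.
# ---------------------------------------------------------------------------

RATINGS_COLUMNS = ["ear_id", "laterality", "observer", "lateral_score", "inferior_score"]
GOLD_COLUMNS = ["ear_id", "surgical_finding"]


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format ratings CSV."""
    df = pd.read_csv(path, dtype={"ear_id": str, "observer": str})
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing ratings columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["observer"] not in ("1", "2", "consensus"):
            raise ValidationError(
                f"{path}:{line}: observer must be 1, 2 or consensus, got {row['observer']!r}"
            )
        if row["laterality"] not in ("left", "right"):
            raise ValidationError(
                f"{path}:{line}: laterality must be left or right, got {row['laterality']!r}"
            )
        validate_score(row["lateral_score"], f"{path}:{line}:lateral_score")
        validate_score(row["inferior_score"], f"{path}:{line}:inferior_score")
    return df


def read_gold_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a gold-standard CSV."""
    df = pd.read_csv(path, dtype={"ear_id": str})
    missing = [c for c in GOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing gold-standard columns {missing}")
    bad = ~df["surgical_finding"].isin([f.value for f in Finding])
    if bad.any():
        line = df.index[bad][0] + 2
        raise ValidationError(f"{path}:{line}: unknown surgical_finding value")
    return df


def build_cohort(
    ratings: pd.DataFrame, gold: Optional[pd.DataFrame] = None
) -> list[EarRecord]:
    """Assemble per-ear records from long-format ratings plus optional gold standard.

    Enforces ear_id uniqueness (one ear per patient is the unit of analysis)
    and auto-derives consensus where observers agree.
    """
    findings: dict[str, Finding] = {}
    if gold is not None:
        if gold["ear_id"].duplicated().any():
            dup = gold.loc[gold["ear_id"].duplicated(), "ear_id"].iloc[0]
            raise ValidationError(f"duplicate ear_id {dup!r} in gold standard")
        findings = {
            str(r.ear_id): Finding(r.surgical_finding) for r in gold.itertuples()
        }

    records = []
    for ear_id, grp in ratings.groupby("ear_id", sort=True):
        by_obs = {}
        for r in grp.itertuples():
            if r.observer in by_obs:
                raise ValidationError(
                    f"ear {ear_id}: duplicate row for observer {r.observer}"
                )
            by_obs[r.observer] = r
        for obs in ("1", "2"):
            if obs not in by_obs:
                raise ValidationError(f"ear {ear_id}: missing observer {obs}")
        lats = {r.laterality for r in by_obs.values()}
        if len(lats) != 1:
            raise ValidationError(f"ear {ear_id}: inconsistent laterality across rows")
        cons = by_obs.get("consensus")
        rec = EarRecord(
            ear_id=str(ear_id),
            laterality=Laterality(lats.pop()),
            obs1_L=int(by_obs["1"].lateral_score),
            obs1_I=int(by_obs["1"].inferior_score),
            obs2_L=int(by_obs["2"].lateral_score),
            obs2_I=int(by_obs["2"].inferior_score),
            consensus_L=int(cons.lateral_score) if cons is not None else None,
            consensus_I=int(cons.inferior_score) if cons is not None else None,
            surgical_finding=findings.get(str(ear_id), Finding.UNKNOWN),
        )
        records.append(derive_consensus(rec))
    return records


def cohort_to_ratings_frame(records: Iterable[EarRecord]) -> pd.DataFrame:
    """Serialize records back to the long-format ratings schema."""
    rows = []
    for rec in records:
        rows.append((rec.ear_id, rec.laterality.value, "1", rec.obs1_L, rec.obs1_I))
        rows.append((rec.ear_id, rec.laterality.value, "2", rec.obs2_L, rec.obs2_I))
        if rec.consensus_L is not None and rec.consensus_I is not None:
            rows.append(
                (rec.ear_id, rec.laterality.value, "consensus", rec.consensus_L, rec.consensus_I)
            )
    return pd.DataFrame(rows, columns=RATINGS_COLUMNS)


def cohort_to_gold_frame(records: Iterable[EarRecord]) -> pd.DataFrame:
    rows = [(rec.ear_id, rec.surgical_finding.value) for rec in records]
    return pd.DataFrame(rows, columns=GOLD_COLUMNS)


def split_by_finding(
    records: Sequence[EarRecord],
) -> tuple[list[EarRecord], list[EarRecord]]:
    """Partition records into (dehiscent, intact), dropping unknowns with a log."""
    pos = [r for r in records if r.surgical_finding is Finding.DEHISCENT]
    neg = [r for r in records if r.surgical_finding is Finding.INTACT]
    n_unknown = len(records) - len(pos) - len(neg)
    if n_unknown:
        logger.info("excluded %d ear(s) with unknown surgical finding", n_unknown)
    return pos, neg
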
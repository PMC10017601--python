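"""Synthetic two-observer cohorts with known generative parameters.

Each ear gets a latent dehiscence status, truth-conditional latent wall
scores (lateral and inferior walls independent given truth — the published
aggregates give only marginal per-wall distributions, so no dependence
structure is invented), adjacency-weighted observer misreads, a consensus
read with its own error rate, and an optionally imperfect surgical probe.

Closed-form oracles (:func:`theoretical_kappa`, :func:`theoretical_auc`,
:func:`theoretical_metrics`) give the exact large-sample values implied by
a model, for parameter-recovery testing of the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .agreement import CrossTab, cohen_kappa
from .diagnostics import GroupScoreDistribution, auc as _dist_auc
from .errors import DegenerateTableError, ValidationError
from .scoring import EarRecord, Finding, Laterality

N_CATEGORIES = 4

# Default truth-conditional wall-score probabilities: the published
# per-group consensus proportions (FCD group n=29, control n=11).
DEFAULT_PI_L_POS = (2 / 29, 22 / 29, 3 / 29, 2 / 29)
DEFAULT_PI_L_NEG = (0 / 11, 1 / 11, 4 / 11, 6 / 11)
DEFAULT_PI_I_POS = (10 / 29, 15 / 29, 4 / 29, 0 / 29)
DEFAULT_PI_I_NEG = (0 / 11, 4 / 11, 5 / 11, 2 / 11)


def _check_probs(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (N_CATEGORIES,):
        raise ValidationError(f"{name}: need {N_CATEGORIES} probabilities")
    if (arr < 0).any():
        raise ValidationError(f"{name}: probabilities must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-12:
        raise ValidationError(f"{name}: probabilities must sum to 1 (got {arr.sum()!r})")
    return arr


def _check_rate(x: float, name: str, upper_open: bool = True) -> float:
    hi_ok = x < 1.0 if upper_open else x <= 1.0
    if not (0.0 <= x and hi_ok):
        raise ValidationError(f"{name}: rate out of range: {x!r}")
    return float(x)


@dataclass(frozen=True)
class CohortModel:
    """Generative parameters for a synthetic cohort."""

    n_ears: int = 40
    prevalence: float = 29 / 40
    pi_L_pos: tuple = DEFAULT_PI_L_POS
    pi_L_neg: tuple = DEFAULT_PI_L_NEG
    pi_I_pos: tuple = DEFAULT_PI_I_POS
    pi_I_neg: tuple = DEFAULT_PI_I_NEG
    epsilon_obs: float = 0.15
    epsilon_consensus: float = 0.05
    probe_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ears <= 0:
            raise ValidationError("n_ears must be positive")
        # the degenerate endpoints are permitted for simulation; downstream
        # metrics flag the empty group explicitly
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(f"prevalence out of [0, 1]: {self.prevalence!r}")
        for name in ("pi_L_pos", "pi_L_neg", "pi_I_pos", "pi_I_neg"):
            object.__setattr__(self, name, tuple(_check_probs(getattr(self, name), name)))
        _check_rate(self.epsilon_obs, "epsilon_obs")
        _check_rate(self.epsilon_consensus, "epsilon_consensus")
        _check_rate(self.probe_error, "probe_error")

    def pi(self, wall: str, positive: bool) -> np.ndarray:
        key = f"pi_{'L' if wall == 'lateral' else 'I'}_{'pos' if positive else 'neg'}"
        return np.asarray(getattr(self, key))

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortModel":
        return cls(**cfg)


@dataclass(frozen=True)
class SyntheticCohort:
    """Simulated ears with the latent truth retained for oracle checks."""

    records: tuple
    model: CohortModel
    truth: np.ndarray = field(repr=False)          # latent dehiscence status
    latent_L: np.ndarray = field(repr=False)       # pre-misread wall scores
    latent_I: np.ndarray = field(repr=False)


def confusion_kernel(epsilon: float) -> np.ndarray:
    """Adjacency-weighted misread kernel K[latent, observed].

    With probability 1-epsilon the latent category is kept; otherwise the
    error mass moves to the adjacent categories, split evenly, with the
    whole mass going to the single neighbour at the 0 and 3 edges.
    """
    eps = _check_rate(epsilon, "epsilon")
    K = np.eye(N_CATEGORIES) * (1.0 - eps)
    for s in range(N_CATEGORIES):
        neighbours = [t for t in (s - 1, s + 1) if 0 <= t < N_CATEGORIES]
        for t in neighbours:
            K[s, t] += eps / len(neighbours)
    return K


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw: probs has shape (n, k)."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random((probs.shape[0], 1))
    return (u > cdf[:, :-1]).sum(axis=1)


def simulate(model: CohortModel) -> SyntheticCohort:
    """Draw a cohort; fully reproducible from ``model.seed``."""
    rng = np.random.default_rng(model.seed)
    n = model.n_ears
    truth = rng.random(n) < model.prevalence

    def latent_for(wall: str) -> np.ndarray:
        probs = np.where(
            truth[:, None], model.pi(wall, True)[None, :], model.pi(wall, False)[None, :]
        )
        return _sample_categorical(rng, probs)

    latent_L = latent_for("lateral")
    latent_I = latent_for("inferior")

    K_obs = confusion_kernel(model.epsilon_obs)
    K_con = confusion_kernel(model.epsilon_consensus)

    def misread(latent: np.ndarray, K: np.ndarray) -> np.ndarray:
        return _sample_categorical(rng, K[latent])

    obs1_L, obs2_L = misread(latent_L, K_obs), misread(latent_L, K_obs)
    obs1_I, obs2_I = misread(latent_I, K_obs), misread(latent_I, K_obs)
    cons_L, cons_I = misread(latent_L, K_con), misread(latent_I, K_con)

    flip = rng.random(n) < model.probe_error
    surgical = truth ^ flip

    sides = (Laterality.LEFT, Laterality.RIGHT)
    laterality = [sides[i] for i in rng.integers(0, 2, size=n)]
    width = len(str(n - 1))
    records = tuple(
        EarRecord(
            ear_id=f"ear{i:0{width}d}",
            laterality=laterality[i],
            obs1_L=int(obs1_L[i]),
            obs1_I=int(obs1_I[i]),
            obs2_L=int(obs2_L[i]),
            obs2_I=int(obs2_I[i]),
            consensus_L=int(cons_L[i]),
            consensus_I=int(cons_I[i]),
            surgical_finding=Finding.DEHISCENT if surgical[i] else Finding.INTACT,
        )
        for i in range(n)
    )
    return SyntheticCohort(
        records=records, model=model, truth=truth, latent_L=latent_L, latent_I=latent_I
    )


# ---------------------------------------------------------------------------
# Closed-form oracles
# ---------------------------------------------------------------------------

def _latent_mixture(model: CohortModel, wall: str) -> np.ndarray:
    return (
        model.prevalence * model.pi(wall, True)
        + (1.0 - model.prevalence) * model.pi(wall, False)
    )


def theoretical_kappa(model: CohortModel, wall: str) -> float:
    """Exact large-sample Cohen's kappa implied by the model for one wall.

    Both observers read the same latent score, independently misread, so the
    joint observer distribution mixes outer products of kernel rows over the
    latent-score mixture.
    """
    K = confusion_kernel(model.epsilon_obs)
    mix = _latent_mixture(model, wall)
    joint = np.einsum("s,si,sj->ij", mix, K, K)
    p_o = float(np.trace(joint))
    marg1 = joint.sum(axis=0)
    marg2 = joint.sum(axis=1)
    p_e = float(marg1 @ marg2)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateTableError("model puts all observer mass in one category")
    return (p_o - p_e) / (1.0 - p_e)


def total_score_distributions(model: CohortModel) -> tuple[np.ndarray, np.ndarray]:
    """Truth-conditional distributions of the consensus composite score (0..6)."""
    K = confusion_kernel(model.epsilon_consensus)
    out = []
    for positive in (True, False):
        pL = model.pi("lateral", positive) @ K
        pI = model.pi("inferior", positive) @ K
        out.append(np.convolve(pL, pI))
    return out[0], out[1]


def theoretical_auc(model: CohortModel) -> float:
    """AUC of the consensus composite score for the latent truth (lower = positive)."""
    pos, neg = total_score_distributions(model)
    wins = float(np.triu(np.outer(pos, neg), k=1).sum())
    ties = float(pos @ neg)
    return wins + 0.5 * ties


def theoretical_metrics(model: CohortModel, cutoff: int) -> dict[str, float]:
    """Closed-form sensitivity/specificity/Youden of ``score < cutoff``.

    Relative to the *surgical finding*, so ``probe_error`` dilutes both rates.
    """
    pos, neg = total_score_distributions(model)
    p_lt_pos = float(pos[:cutoff].sum())
    p_lt_neg = float(neg[:cutoff].sum())
    e = model.probe_error
    # P(score < c | surgical positive) mixes true and probe-flipped ears
    prev = model.prevalence
    p_surg_pos = prev * (1 - e) + (1 - prev) * e
    if p_surg_pos in (0.0, 1.0):
        raise ValidationError("one surgical group is empty in expectation")
    sens = (prev * (1 - e) * p_lt_pos + (1 - prev) * e * p_lt_neg) / p_surg_pos
    spec = 1.0 - (
        (1 - prev) * (1 - e) * p_lt_neg + prev * e * p_lt_pos
    ) / (1.0 - p_surg_pos)
    return {"sensitivity": sens, "specificity": spec, "youden": sens + spec - 1.0}


def theoretical_optimal_cutoff(model: CohortModel) -> int:
    best, best_key = None, None
    for c in range(7):
        m = theoretical_metrics(model, c)
        key = (-m["youden"], -m["specificity"], c)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return int(best)


def empirical_kappa(cohort: SyntheticCohort, wall: str) -> float:
    """Kappa of the two simulated observers, for recovery tests."""
    attr = "L" if wall == "lateral" else "I"
    obs1 = [getattr(r, f"obs1_{attr}") for r in cohort.records]
    obs2 = [getattr(r, f"obs2_{attr}") for r in cohort.records]
    k = len({*obs1, *obs2})
    counts = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    for a, b in zip(obs1, obs2):
        counts[b, a] += 1
    if k < 2:
        raise DegenerateTableError("single observed category")
    return cohen_kappa(CrossTab(counts, (0, 1, 2, 3))).kappa


def cohort_distributions(
    cohort: SyntheticCohort,
) -> tuple[GroupScoreDistribution, GroupScoreDistribution]:
    """Per-surgical-group consensus composite-score distributions."""
    pos_scores, neg_scores = [], []
    for rec in cohort.records:
        total = rec.composite().total
        (pos_scores if rec.surgical_finding is Finding.DEHISCENT else neg_scores).append(total)
    if not pos_scores or not neg_scores:
        raise DegenerateTableError(
            "a surgical group is empty; sensitivity/specificity undefined"
        )
    return (
        GroupScoreDistribution.from_scores("FCD", pos_scores),
        GroupScoreDistribution.from_scores("control", neg_scores),
    )


def empirical_auc(cohort: SyntheticCohort) -> float:
    pos, neg = cohort_distributions(cohort)
    return _dist_auc(pos, neg)
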
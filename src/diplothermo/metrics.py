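"""Genetic-interaction and dominance metrics for double mutants.

Within-allele (intra-molecular epistasis) and between-allele combinations are
scored against two null models, both floored at a lower bound C:

* additive:      W_exp_add = max(C, W_A + W_B - W_WT)
* log-additive:  W_exp_log = max(C, W_A * W_B / W_WT)

C = 0.5 for within-allele combinations (the untouched second allele keeps half
the wild-type output) and 0 for between-allele combinations.  Interaction
scores are observed-minus-expected on the plain or log scale; negative means
worse than expected.

Compound heterozygotes are scored as dominance: the expectation is the
midpoint of the two homozygote phenotypes, and the degree of dominance is the
heterozygote's signed deviation from that midpoint in units of the midpoint
distance.  +1 means the fitter allele is completely dominant, -1 completely
recessive, 0 no dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WITHIN",
    "BETWEEN",
    "lower_bound",
    "ExpectedDouble",
    "InteractionRecord",
    "DominanceRecord",
    "expected_double",
    "interaction_scores",
    "score_pair",
    "degree_of_dominance",
]

WITHIN = "within"
BETWEEN = "between"

#: absolute tolerance below which two homozygote phenotypes are "equal" and
#: the degree of dominance is undefined (zero midpoint distance)
EQUAL_HOMOZYGOTE_TOL = 1e-9


def lower_bound(combination_kind: str) -> float:
    """Lower bound C of the expected phenotype for a combination kind."""
    if combination_kind == WITHIN:
        return 0.5
    if combination_kind == BETWEEN:
        return 0.0
    raise ValueError(
        f"combination_kind must be {WITHIN!r} or {BETWEEN!r}, got {combination_kind!r}"
    )


@dataclass(frozen=True)
class ExpectedDouble:
    W_exp_add: float
    W_exp_log: float
    C: float
    add_clamped: bool
    log_clamped: bool


@dataclass(frozen=True)
class InteractionRecord:
    W_obs: float
    W_exp_add: float
    W_exp_log: float
    e_add: float
    E_log: float  # nan when undefined
    log_defined: bool
    C: float = math.nan
    combination_kind: str = ""
    add_clamped: bool = False
    log_clamped: bool = False


@dataclass(frozen=True)
class DominanceRecord:
    W_AA: float
    W_BB: float
    W_het: float
    W_exp_het: float
    degree: float  # nan when undefined
    defined: bool


def expected_double(
    W_A: float, W_B: float, W_wt: float, combination_kind: str
) -> ExpectedDouble:
    """Additive and log-additive expected double-mutant phenotypes.

    Both expectations are floored at C (0.5 within-allele, 0 between-allele);
    whether the floor bound is recorded so clamp activations can be counted.
    """
    if not (math.isfinite(W_wt) and W_wt > 0):
        raise ValueError(f"wild-type reference phenotype must be > 0, got {W_wt}")
    for name, w in (("W_A", W_A), ("W_B", W_B)):
        if not (math.isfinite(w) and w >= 0):
            raise ValueError(f"{name} must be finite and >= 0, got {w}")
    C = lower_bound(combination_kind)
    raw_add = W_A + W_B - W_wt
    raw_log = W_A * W_B / W_wt
    return ExpectedDouble(
        W_exp_add=max(C, raw_add),
        W_exp_log=max(C, raw_log),
        C=C,
        add_clamped=raw_add < C,
        log_clamped=raw_log < C,
    )


def interaction_scores(
    W_obs: float, W_exp_add: float, W_exp_log: float
) -> InteractionRecord:
    """Observed-vs-expected interaction scores on the plain and log scales.

    The log-scale score is flagged undefined (nan, not raised) when either
    the observed or the expected phenotype is non-positive.
    """
    if not (math.isfinite(W_obs) and W_obs >= 0):
        raise ValueError(f"W_obs must be finite and >= 0, got {W_obs}")
    e_add = W_obs - W_exp_add
    log_defined = W_obs > 0 and W_exp_log > 0
    E_log = math.log(W_obs) - math.log(W_exp_log) if log_defined else math.nan
    return InteractionRecord(
        W_obs=W_obs,
        W_exp_add=W_exp_add,
        W_exp_log=W_exp_log,
        e_add=e_add,
        E_log=E_log,
        log_defined=log_defined,
    )


def score_pair(
    W_A: float, W_B: float, W_obs: float, W_wt: float, combination_kind: str
) -> InteractionRecord:
    """Expectation + scoring in one step, carrying C and clamp flags."""
    exp = expected_double(W_A, W_B, W_wt, combination_kind)
    rec = interaction_scores(W_obs, exp.W_exp_add, exp.W_exp_log)
    return InteractionRecord(
        W_obs=rec.W_obs,
        W_exp_add=rec.W_exp_add,
        W_exp_log=rec.W_exp_log,
        e_add=rec.e_add,
        E_log=rec.E_log,
        log_defined=rec.log_defined,
        C=exp.C,
        combination_kind=combination_kind,
        add_clamped=exp.add_clamped,
        log_clamped=exp.log_clamped,
    )


def degree_of_dominance(W_AA: float, W_BB: float, W_het: float) -> DominanceRecord:
    """Degree of dominance of a compound heterozygote.

    degree = (W_het - midpoint) / |W_less_fit - midpoint|, where midpoint is
    the mean of the homozygote phenotypes.  Dividing by the distance of the
    *less fit* homozygote from the midpoint fixes the sign convention:
    positive means the fitter allele is dominant.  The magnitude is invariant
    under swapping the homozygote labels.  When the homozygotes are equal
    (midpoint distance below tolerance) the degree is flagged undefined.
    """
    for name, w in (("W_AA", W_AA), ("W_BB", W_BB), ("W_het", W_het)):
        if not (math.isfinite(w) and w >= 0):
            raise ValueError(f"{name} must be finite and >= 0, got {w}")
    mid = 0.5 * (W_AA + W_BB)
    less_fit = min(W_AA, W_BB)
    denom = abs(less_fit - mid)
    if denom <= EQUAL_HOMOZYGOTE_TOL:
        return DominanceRecord(W_AA, W_BB, W_het, mid, math.nan, defined=False)
    return DominanceRecord(W_AA, W_BB, W_het, mid, (W_het - mid) / denom, defined=True)
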
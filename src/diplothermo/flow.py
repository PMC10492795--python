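"""Flow-cytometry scoring: gating, GFP normalization and SE propagation.

Event tables are plain pandas DataFrames with columns ``fsc_a``, ``ssc_a``,
``gfp``, ``genotype``, ``replicate``, ``batch``.  The analysis chain is:

1. :func:`gate_events` — keep events inside the scatter gate (an FSC-A window
   and an SSC-A band whose upper boundary is linear in FSC-A).
2. :func:`replicate_means` / :func:`normalize_with_se` — per-replicate mean
   GFP, autofluorescence-subtracted and normalized to the batch-matched wild
   type, with the standard error of the normalized signal propagated through
   the printed error formula (kept exactly as printed, nested radicals and
   all, rather than algebraically simplified).
3. :func:`interaction_with_se` — interaction scores for a double mutant with
   the SE of the expectation and of the score propagated in quadrature.

Normalization is strictly within batch; only normalized values are comparable
across batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import InteractionRecord, expected_double, interaction_scores

__all__ = [
    "EVENT_COLUMNS",
    "GateSpec",
    "GatingError",
    "MutantSummary",
    "FlowInteractionRecord",
    "gate_events",
    "replicate_means",
    "normalize_with_se",
    "summarize_batch",
    "interaction_with_se",
]

EVENT_COLUMNS = ["fsc_a", "ssc_a", "gfp", "genotype", "replicate", "batch"]


@dataclass(frozen=True)
class GateSpec:
    """Scatter gate: FSC-A window plus an SSC-A band.

    The SSC-A upper boundary is ``ssc_slope_coeff * FSC-A + ssc_intercept``;
    the default slope is log10(0.93), i.e. a shallow negative slope, which is
    our reading of the published boundary expression (the printed form is
    ambiguous, so both coefficients are configurable).
    """

    fsc_min: float = 900.0
    fsc_max: float = 9800.0
    ssc_min: float = 110.0
    ssc_slope_coeff: float = math.log10(0.93)
    ssc_intercept: float = 530.0

    def __post_init__(self) -> None:
        if not self.fsc_min < self.fsc_max:
            raise ValueError(
                f"fsc_min ({self.fsc_min}) must be < fsc_max ({self.fsc_max})"
            )

    def ssc_upper(self, fsc_a):
        return self.ssc_slope_coeff * np.asarray(fsc_a, dtype=float) + self.ssc_intercept


class GatingError(ValueError):
    """A required population is empty after gating."""


def gate_events(
    events: pd.DataFrame,
    gate: GateSpec = GateSpec(),
    *,
    return_counts: bool = False,
):
    """Apply the scatter gate; optionally also return retention counts.

    Raises :class:`GatingError` naming the first (genotype, replicate, batch)
    population that is left empty — a silently vanished population would
    poison every downstream normalization in its batch.
    """
    _require_columns(events)
    fsc = events["fsc_a"].to_numpy(dtype=float)
    ssc = events["ssc_a"].to_numpy(dtype=float)
    keep = (
        (fsc >= gate.fsc_min)
        & (fsc <= gate.fsc_max)
        & (ssc >= gate.ssc_min)
        & (ssc <= gate.ssc_upper(fsc))
    )
    gated = events.loc[keep]
    group_cols = ["batch", "genotype", "replicate"]
    before = events.groupby(group_cols, sort=True).size()
    after = gated.groupby(group_cols, sort=True).size().reindex(before.index, fill_value=0)
    empty = after[after == 0]
    if len(empty):
        batch, genotype, replicate = empty.index[0]
        raise GatingError(
            f"no events survive the gate for genotype {genotype!r} "
            f"(replicate {replicate!r}, batch {batch!r})"
        )
    if return_counts:
        counts = pd.DataFrame(
            {"n_events": before, "n_retained": after}
        ).reset_index()
        return gated.reset_index(drop=True), counts
    return gated.reset_index(drop=True)


def _require_columns(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    if len(events) == 0:
        raise ValueError("event table is empty")


@dataclass(frozen=True)
class MutantSummary:
    """Normalized phenotype of one genotype in one batch."""

    genotype: str
    gfp_obs: float
    se_obs: float
    n_replicates: int
    batch: object = None


def replicate_means(events: pd.DataFrame) -> pd.DataFrame:
    """Mean GFP per (batch, genotype, replicate), long format."""
    _require_columns(events)
    out = (
        events.groupby(["batch", "genotype", "replicate"], sort=True)["gfp"]
        .mean()
        .rename("mean_gfp")
        .reset_index()
    )
    return out


def _mean_se(means) -> tuple[float, float, int]:
    x = np.asarray(means, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need >= 2 replicates for a standard error, got {n}")
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(n)), n


def normalize_with_se(
    mut_means,
    wt_means,
    control_means,
    *,
    genotype: str = "",
    batch=None,
) -> MutantSummary:
    """Autofluorescence-subtracted, WT-normalized GFP with its standard error.

    Inputs are the per-replicate mean GFP values of the mutant, the wild type
    and the autofluorescence-only control, all from the same batch.  The
    normalized signal is

        GFP_obs = (mu_mut - mu_ctrl) / (mu_wt - mu_ctrl)

    and its SE combines the relative errors of the numerator and denominator
    exactly as the published formula writes them.
    """
    mu_mut, se_mut, n = _mean_se(mut_means)
    mu_wt, se_wt, _ = _mean_se(wt_means)
    mu_ctl, se_ctl, _ = _mean_se(control_means)
    if mu_wt <= mu_ctl:
        raise ValueError(
            f"degenerate reference: wild-type mean GFP ({mu_wt:g}) must exceed "
            f"the autofluorescence control ({mu_ctl:g})"
        )
    gfp_obs = (mu_mut - mu_ctl) / (mu_wt - mu_ctl)
    if mu_mut == mu_ctl:
        # the relative-error formula divides by (mu_mut - mu_ctl): an
        # autofluorescence-level mutant has an unbounded relative SE
        se_obs = math.inf
    else:
        se_obs = math.sqrt(
            (math.sqrt(se_mut**2 + se_ctl**2) / (mu_mut - mu_ctl)) ** 2
            + (math.sqrt(se_wt**2 + se_ctl**2) / (mu_wt - mu_ctl)) ** 2
        )
    return MutantSummary(
        genotype=genotype, gfp_obs=gfp_obs, se_obs=se_obs, n_replicates=n, batch=batch
    )


def summarize_batch(
    events: pd.DataFrame,
    *,
    wt_label: str = "WT",
    control_label: str = "backbone",
    gate: GateSpec | None = None,
) -> pd.DataFrame:
    """Per-genotype normalized summaries for every batch in an event table.

    Pass ``gate`` to gate first; with ``gate=None`` the table is assumed to be
    gated already.  The wild type and the autofluorescence control themselves
    are summarized too (their expected values are 1 and 0).
    """
    if gate is not None:
        events = gate_events(events, gate)
    means = replicate_means(events)
    rows = []
    for batch, sub in means.groupby("batch", sort=True):
        by_geno = {g: grp["mean_gfp"].to_numpy() for g, grp in sub.groupby("genotype")}
        for label in (wt_label, control_label):
            if label not in by_geno:
                raise ValueError(f"batch {batch!r} lacks required genotype {label!r}")
        for geno in sorted(by_geno):
            s = normalize_with_se(
                by_geno[geno],
                by_geno[wt_label],
                by_geno[control_label],
                genotype=geno,
                batch=batch,
            )
            rows.append(
                {
                    "batch": batch,
                    "genotype": geno,
                    "gfp_obs": s.gfp_obs,
                    "se_obs": s.se_obs,
                    "n_replicates": s.n_replicates,
                }
            )
    return pd.DataFrame(rows, columns=["batch", "genotype", "gfp_obs", "se_obs", "n_replicates"])


@dataclass(frozen=True)
class FlowInteractionRecord:
    """Interaction scores of one double mutant with propagated SEs."""

    scores: InteractionRecord
    se_exp_add: float
    se_exp_log: float  # nan when a single phenotype is 0
    se_interaction_add: float
    se_interaction_log: float


def interaction_with_se(
    A: MutantSummary,
    B: MutantSummary,
    WT: MutantSummary,
    AB_obs: MutantSummary,
    combination_kind: str,
) -> FlowInteractionRecord:
    """Score a measured double mutant against its single mutants.

    Expected phenotypes follow the additive / log-additive null models with
    the combination-appropriate lower bound; SEs propagate in quadrature:
    the additive expectation sums the three input variances, the log-additive
    one sums the singles' squared relative errors, and each interaction score
    combines the observed double's SE with its expectation's SE.
    """
    batches = {S.batch for S in (A, B, WT, AB_obs)}
    if len(batches) > 1:
        raise ValueError(f"summaries span multiple batches: {sorted(map(str, batches))}")
    exp = expected_double(A.gfp_obs, B.gfp_obs, WT.gfp_obs, combination_kind)
    rec = interaction_scores(AB_obs.gfp_obs, exp.W_exp_add, exp.W_exp_log)
    rec = InteractionRecord(
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
    se_exp_add = math.sqrt(A.se_obs**2 + B.se_obs**2 + WT.se_obs**2)
    if A.gfp_obs > 0 and B.gfp_obs > 0:
        se_exp_log = math.sqrt(
            (A.se_obs / A.gfp_obs) ** 2 + (B.se_obs / B.gfp_obs) ** 2
        )
        se_int_log = math.sqrt(AB_obs.se_obs**2 + se_exp_log**2)
    else:
        se_exp_log = math.nan
        se_int_log = math.nan
    se_int_add = math.sqrt(AB_obs.se_obs**2 + se_exp_add**2)
    return FlowInteractionRecord(
        scores=rec,
        se_exp_add=se_exp_add,
        se_exp_log=se_exp_log,
        se_interaction_add=se_int_add,
        se_interaction_log=se_int_log,
    )
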
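"""Mutation grids, phenotype->ddG inversion and scenario sweeps.

This module generates the deterministic single-mutant grids (either directly
as ddG values or as target phenotypes inverted to ddG), enumerates
within-allele / between-allele / compound-heterozygote combinations, and emits
long-format scored tables.  All sweeps are deterministic; no random seeds are
involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .linking import LinkingSpec, apply_linking, invert_linking
from .metrics import BETWEEN, WITHIN, degree_of_dominance, score_pair
from .thermo import (
    EnergyParams,
    Genotype,
    SystemConfig,
    model1_phenotype,
    model2_phenotype,
)

__all__ = [
    "GridSpec",
    "ScenarioResult",
    "build_grid",
    "phenotype_to_ddg",
    "run_scenario",
    "deduplicate_pairs",
    "COMPOUND_HET",
]

log = logging.getLogger(__name__)

COMPOUND_HET = "compound_het"

FOLDING = "folding"
BINDING = "binding"

#: ddG bracket for phenotype inversion (kcal/mol).  -30 saturates every
#: phenotype at its stabilised maximum and +60 at its destabilised minimum
#: for all parameter regimes considered.
_DDG_BRACKET = (-30.0, 60.0)


@dataclass(frozen=True)
class GridSpec:
    """An inclusive, evenly spaced single-mutant grid.

    ``mode`` selects the grid variable: raw ddG values, target heterozygous
    single-mutant phenotypes, or target homozygote phenotypes (the latter two
    are inverted to ddG before use).
    """

    mode: str = "ddg"
    start: float = -2.0
    stop: float = 13.0
    step: float = 0.125
    mutation_type: str = FOLDING

    _MODES = ("ddg", "phenotype_single", "phenotype_homozygote")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if self.mutation_type not in (FOLDING, BINDING):
            raise ValueError(
                f"mutation_type must be '{FOLDING}' or '{BINDING}', "
                f"got {self.mutation_type!r}"
            )
        if not (self.step > 0):
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.start > self.stop:
            raise ValueError(f"start ({self.start}) must be <= stop ({self.stop})")

    @classmethod
    def ddg(cls, mutation_type: str = FOLDING) -> "GridSpec":
        """Default ddG grid: -2 to 13 kcal/mol, step 0.125 (121 values)."""
        return cls("ddg", -2.0, 13.0, 0.125, mutation_type)

    @classmethod
    def phenotype_single(cls, mutation_type: str = FOLDING) -> "GridSpec":
        """Default heterozygous-single phenotype grid: 0.5-1.02 AU, step 0.005."""
        return cls("phenotype_single", 0.5, 1.02, 0.005, mutation_type)

    @classmethod
    def phenotype_homozygote(cls, mutation_type: str = FOLDING) -> "GridSpec":
        """Default homozygote phenotype grid: 0-1.02 AU, step 0.01."""
        return cls("phenotype_homozygote", 0.0, 1.02, 0.01, mutation_type)


def build_grid(spec: GridSpec) -> np.ndarray:
    """Materialise the grid values, both endpoints included."""
    n = int(math.floor((spec.stop - spec.start) / spec.step + 1e-9))
    return spec.start + spec.step * np.arange(n + 1)


def _mutant_kwargs(mutation_type: str, ddg: float) -> dict:
    if mutation_type == FOLDING:
        return {"ddG_folding": ddg}
    return {"ddG_binding": ddg}


def _phenotype_fn(model: int, params: EnergyParams, config: SystemConfig | None):
    if model == 1:
        return lambda g: model1_phenotype(g, params)
    if model == 2:
        if config is None:
            raise ValueError("Model 2 requires a SystemConfig")
        return lambda g: model2_phenotype(g, params, config)
    raise ValueError(f"model must be 1 or 2, got {model}")


def phenotype_to_ddg(
    W_target: float,
    mutation_type: str,
    zygosity: str,
    model: int,
    params: EnergyParams,
    config: SystemConfig | None = None,
    *,
    residual_tol: float = 1e-9,
) -> float:
    """Invert a target phenotype to the ddG producing it; nan if infeasible.

    ``zygosity`` is ``"heterozygous-single"`` (a^A / a^WT) or ``"homozygous"``
    (a^A / a^A).  The phenotype is strictly decreasing in ddG, so the root is
    unique when the target lies strictly inside the attainable range;
    targets outside it (including exactly at an asymptotic bound) are flagged
    infeasible with a logged warning rather than raised.
    """
    if zygosity == "heterozygous-single":
        make = lambda d: Genotype.single_het(**_mutant_kwargs(mutation_type, d))
    elif zygosity == "homozygous":
        make = lambda d: Genotype.homozygote(**_mutant_kwargs(mutation_type, d))
    else:
        raise ValueError(
            "zygosity must be 'heterozygous-single' or 'homozygous', "
            f"got {zygosity!r}"
        )
    if model == 1 and mutation_type == BINDING:
        raise ValueError("binding mutations are undefined in Model 1")
    W = _phenotype_fn(model, params, config)
    lo, hi = _DDG_BRACKET
    W_max, W_min = W(make(lo)), W(make(hi))
    if not (W_min < W_target < W_max):
        log.warning(
            "phenotype target %g infeasible (attainable range (%g, %g))",
            W_target,
            W_min,
            W_max,
        )
        return math.nan
    ddg = brentq(lambda d: W(make(d)) - W_target, lo, hi, xtol=1e-12, maxiter=200)
    if abs(W(make(ddg)) - W_target) > residual_tol:  # pragma: no cover
        log.warning("phenotype inversion residual above tolerance at %g", W_target)
        return math.nan
    return float(ddg)


@dataclass
class ScenarioResult:
    """Scored tables of one sweep plus a run summary.

    ``interactions`` holds within/between-allele rows; ``dominance`` holds
    compound-heterozygote rows.  ``summary`` counts dropped (infeasible) grid
    points and clamp activations.
    """

    interactions: pd.DataFrame
    dominance: pd.DataFrame
    summary: dict = field(default_factory=dict)


# stable column orders for the exported tables
INTERACTION_COLUMNS = [
    "model", "mutation_type", "ligand_ratio", "linking_kind", "linking_m",
    "combination", "ddG_A", "ddG_B",
    "W_A_raw", "W_B_raw", "W_obs_raw", "W_A", "W_B", "W_obs",
    "W_exp_add", "W_exp_log", "e_add", "E_log", "C",
    "add_clamped", "log_clamped",
]
DOMINANCE_COLUMNS = [
    "model", "mutation_type", "ligand_ratio", "linking_kind", "linking_m",
    "combination", "ddG_A", "ddG_B",
    "W_AA_raw", "W_BB_raw", "W_het_raw", "W_AA", "W_BB", "W_het",
    "W_exp_het", "degree", "degree_defined",
]


def run_scenario(
    model: int,
    params: EnergyParams,
    config: SystemConfig | None,
    gridspec: GridSpec,
    linking: LinkingSpec = LinkingSpec(),
    combinations: set[str] = frozenset({WITHIN, BETWEEN}),
) -> ScenarioResult:
    """Sweep all ordered single-mutant pairs and score every combination kind.

    Phenotype-mode grids are inverted to ddG first (infeasible targets are
    dropped and counted).  Observed phenotypes are passed through the linking
    function *before* expectations and scores are computed, so the C = 0.5
    within-allele floor applies on the transformed scale.
    """
    bad = set(combinations) - {WITHIN, BETWEEN, COMPOUND_HET}
    if bad:
        raise ValueError(f"unknown combination kinds: {sorted(bad)}")
    mtype = gridspec.mutation_type
    if model == 1 and mtype == BINDING:
        raise ValueError("binding mutations are undefined in Model 1")
    W = _phenotype_fn(model, params, config)
    grid = build_grid(gridspec)

    dropped = 0
    if gridspec.mode == "ddg":
        ddgs = list(grid)
    else:
        zyg = (
            "heterozygous-single"
            if gridspec.mode == "phenotype_single"
            else "homozygous"
        )
        ddgs = []
        for target in grid:
            d = phenotype_to_ddg(target, mtype, zyg, model, params, config)
            if math.isnan(d):
                dropped += 1
            else:
                ddgs.append(d)

    def link(x: float) -> float:
        return float(apply_linking(x, linking))

    W_wt_t = link(1.0)
    # raw single-het and homozygote phenotypes, cached per ddG
    het = {d: W(Genotype.single_het(**_mutant_kwargs(mtype, d))) for d in ddgs}
    homo: dict[float, float] = {}
    if COMPOUND_HET in combinations:
        homo = {d: W(Genotype.homozygote(**_mutant_kwargs(mtype, d))) for d in ddgs}

    meta = {
        "model": model,
        "mutation_type": mtype,
        "ligand_ratio": config.ligand_ratio if config is not None else math.nan,
        "linking_kind": linking.kind,
        "linking_m": linking.m,
    }

    inter_rows: list[dict] = []
    dom_rows: list[dict] = []
    clamp_add = clamp_log = 0
    for dA, dB in product(ddgs, ddgs):
        if WITHIN in combinations:
            kwA, kwB = _mutant_kwargs(mtype, dA), _mutant_kwargs(mtype, dB)
            g = Genotype.within_allele(
                **{k + "_A": v for k, v in kwA.items()},
                **{k + "_B": v for k, v in kwB.items()},
            )
            inter_rows.append(
                _interaction_row(meta, WITHIN, dA, dB, het[dA], het[dB], W(g), link, W_wt_t)
            )
        if BETWEEN in combinations:
            kwA, kwB = _mutant_kwargs(mtype, dA), _mutant_kwargs(mtype, dB)
            g = Genotype.between_allele(
                **{k + "_A": v for k, v in kwA.items()},
                **{k + "_B": v for k, v in kwB.items()},
            )
            inter_rows.append(
                _interaction_row(meta, BETWEEN, dA, dB, het[dA], het[dB], W(g), link, W_wt_t)
            )
        if COMPOUND_HET in combinations:
            kwA, kwB = _mutant_kwargs(mtype, dA), _mutant_kwargs(mtype, dB)
            g = Genotype.between_allele(
                **{k + "_A": v for k, v in kwA.items()},
                **{k + "_B": v for k, v in kwB.items()},
            )
            W_het_raw = W(g)
            rec = degree_of_dominance(link(homo[dA]), link(homo[dB]), link(W_het_raw))
            dom_rows.append(
                {
                    **meta,
                    "combination": COMPOUND_HET,
                    "ddG_A": dA,
                    "ddG_B": dB,
                    "W_AA_raw": homo[dA],
                    "W_BB_raw": homo[dB],
                    "W_het_raw": W_het_raw,
                    "W_AA": rec.W_AA,
                    "W_BB": rec.W_BB,
                    "W_het": rec.W_het,
                    "W_exp_het": rec.W_exp_het,
                    "degree": rec.degree,
                    "degree_defined": rec.defined,
                }
            )

    interactions = pd.DataFrame(inter_rows, columns=INTERACTION_COLUMNS)
    dominance = pd.DataFrame(dom_rows, columns=DOMINANCE_COLUMNS)
    if len(interactions):
        clamp_add = int(interactions["add_clamped"].sum())
        clamp_log = int(interactions["log_clamped"].sum())
    summary = {
        "n_singles": len(ddgs),
        "n_dropped_grid_points": dropped,
        "n_interaction_rows": len(interactions),
        "n_dominance_rows": len(dominance),
        "n_add_clamped": clamp_add,
        "n_log_clamped": clamp_log,
    }
    return ScenarioResult(interactions, dominance, summary)


def _interaction_row(meta, kind, dA, dB, wA_raw, wB_raw, wObs_raw, link, W_wt_t):
    rec = score_pair(link(wA_raw), link(wB_raw), link(wObs_raw), W_wt_t, kind)
    return {
        **meta,
        "combination": kind,
        "ddG_A": dA,
        "ddG_B": dB,
        "W_A_raw": wA_raw,
        "W_B_raw": wB_raw,
        "W_obs_raw": wObs_raw,
        "W_A": link(wA_raw),
        "W_B": link(wB_raw),
        "W_obs": rec.W_obs,
        "W_exp_add": rec.W_exp_add,
        "W_exp_log": rec.W_exp_log,
        "e_add": rec.e_add,
        "E_log": rec.E_log,
        "C": rec.C,
        "add_clamped": rec.add_clamped,
        "log_clamped": rec.log_clamped,
    }


def deduplicate_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse ordered (A, B)/(B, A) rows to one unordered pair per kind."""
    key = pd.DataFrame(
        {
            "lo": np.minimum(table["ddG_A"], table["ddG_B"]),
            "hi": np.maximum(table["ddG_A"], table["ddG_B"]),
            "combination": table["combination"],
        }
    )
    return table.loc[~key.duplicated().to_numpy()].reset_index(drop=True)
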
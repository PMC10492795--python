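"""Synthetic flow-cytometry event tables and mutation panels.

The event generator emulates what the scoring stage needs from a real
cytometry run — nothing more: per-event GFP is autofluorescence plus the
genotype's true phenotype times the wild-type signal, with lognormal noise at
the event, replicate and batch levels; scatter channels carry two SSC
sub-populations (the high-SSC one with a biased GFP signal) so that gating is
consequential; an autofluorescence-only control population and a wild-type
population are always present per batch.  Ground truth is returned alongside,
so parameter-recovery tests need no external data.

This is an emulation for exercising the pipeline, not a cytometer model:
there is no spectral physics, no compensation, no doublet structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .flow import EVENT_COLUMNS
from .thermo import Allele

__all__ = ["FlowSimSpec", "gen_flow_events", "gen_mutation_panel", "CI_MUTATION_LABELS"]

#: labels of the eight lambda-repressor CI single mutants used as the
#: experimental panel (labels only; no phenotype values are claimed)
CI_MUTATION_LABELS = (
    "M23L", "L33F", "K53N", "S55R", "V56I", "E57K", "E58D", "F59L",
)


@dataclass(frozen=True)
class FlowSimSpec:
    """World description for one synthetic cytometry experiment.

    ``genotypes`` maps genotype label -> true phenotype (AU, wild type = 1).
    A wild-type population (truth 1) and an autofluorescence-only control
    (truth 0) are added automatically if absent.  Noise scales are standard
    deviations on the log signal; defaults are chosen once for realism (see
    docs/methods.md) and double as the documented knobs.
    """

    genotypes: Mapping[str, float]
    events_per_replicate: int = 5000
    replicates: int = 3
    batches: int = 1
    seed: int = 0
    wt_label: str = "WT"
    control_label: str = "backbone"
    wt_signal: float = 1000.0
    autofluorescence: float = 100.0
    event_noise_sd: float = 0.35
    replicate_signal_sd: float = 0.05
    replicate_autofluor_sd: float = 0.15
    batch_effect_sd: float = 0.10
    fsc_log_mean: float = math.log(3000.0)
    fsc_log_sd: float = 0.30
    ssc_low_log_mean: float = math.log(200.0)
    ssc_high_log_mean: float = math.log(800.0)
    ssc_log_sd: float = 0.25
    high_ssc_fraction: float = 0.25
    high_ssc_gfp_bias: float = 1.4

    def __post_init__(self) -> None:
        if self.events_per_replicate < 1 or self.replicates < 1 or self.batches < 1:
            raise ValueError("events_per_replicate, replicates and batches must be >= 1")
        for label, w in self.genotypes.items():
            if not (math.isfinite(w) and w >= 0):
                raise ValueError(f"true phenotype of {label!r} must be >= 0, got {w}")
        if not 0.0 <= self.high_ssc_fraction < 1.0:
            raise ValueError("high_ssc_fraction must be in [0, 1)")

    def all_genotypes(self) -> dict[str, float]:
        out = dict(self.genotypes)
        out.setdefault(self.wt_label, 1.0)
        out.setdefault(self.control_label, 0.0)
        return out


def gen_flow_events(spec: FlowSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an event table; returns ``(events, truth)``.

    ``events`` has the standard event columns; ``truth`` is one row per
    genotype with its true phenotype.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    genos = spec.all_genotypes()
    n = spec.events_per_replicate
    frames = []
    for b in range(1, spec.batches + 1):
        batch_sig = spec.wt_signal * _ln_factor(rng, spec.batch_effect_sd)
        batch_auto = spec.autofluorescence * _ln_factor(rng, spec.batch_effect_sd)
        for geno, truth in genos.items():
            is_control = geno == spec.control_label
            for r in range(1, spec.replicates + 1):
                rep_sig = batch_sig * _ln_factor(rng, spec.replicate_signal_sd)
                rep_auto = batch_auto * _ln_factor(rng, spec.replicate_autofluor_sd)
                gfp = rep_auto * _ln_factor(rng, spec.event_noise_sd, n)
                if not is_control and truth > 0:
                    gfp = gfp + truth * rep_sig * _ln_factor(rng, spec.event_noise_sd, n)
                high = rng.random(n) < spec.high_ssc_fraction
                gfp = np.where(high, gfp * spec.high_ssc_gfp_bias, gfp)
                fsc = np.exp(rng.normal(spec.fsc_log_mean, spec.fsc_log_sd, n))
                ssc_mu = np.where(high, spec.ssc_high_log_mean, spec.ssc_low_log_mean)
                ssc = np.exp(rng.normal(ssc_mu, spec.ssc_log_sd))
                frames.append(
                    pd.DataFrame(
                        {
                            "fsc_a": fsc,
                            "ssc_a": ssc,
                            "gfp": gfp,
                            "genotype": geno,
                            "replicate": r,
                            "batch": b,
                        }
                    )
                )
    events = pd.concat(frames, ignore_index=True)[EVENT_COLUMNS]
    truth = pd.DataFrame(
        {"genotype": list(genos), "true_phenotype": list(genos.values())}
    )
    return events, truth


def _ln_factor(rng: np.random.Generator, sd: float, n: int | None = None):
    """Mean-one lognormal factor(s): exp(N(-sd^2/2, sd))."""
    if sd == 0.0:
        return 1.0 if n is None else np.ones(n)
    return np.exp(rng.normal(-0.5 * sd * sd, sd, n))


def gen_mutation_panel(
    n: int,
    seed: int,
    *,
    folding_mean: float = 1.0,
    folding_sd: float = 2.0,
    binding_mean: float = 0.0,
    binding_sd: float = 0.0,
) -> list[Allele]:
    """Draw a reproducible panel of mutant alleles for stress testing.

    ddG values are normal draws per energy term; a zero mean and sd for a
    term leaves it at the wild-type value.  ``n`` must be >= 1 (an empty
    panel is an error by contract).
    """
    if n < 1:
        raise ValueError(f"panel size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    dfold = rng.normal(folding_mean, folding_sd, n) if folding_sd or folding_mean else np.zeros(n)
    dbind = rng.normal(binding_mean, binding_sd, n) if binding_sd or binding_mean else np.zeros(n)
    return [Allele(ddG_folding=float(f), ddG_binding=float(b)) for f, b in zip(dfold, dbind)]
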
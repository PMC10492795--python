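"""Equilibrium thermodynamics of a one-gene diploid protein system.

Two genotype->phenotype models are implemented:

* **Model 1** (folding only): each allele expresses protein that exists in an
  unfolded and a folded state, Boltzmann-distributed according to its folding
  free energy.  The phenotype is the total folded-protein concentration
  normalized to the homozygous wild type.

* **Model 2** (folding + ligand binding): a third, ligand-bound state is added
  and the two alleles compete for a shared, finite pool of ligand.  The free
  ligand concentration is obtained by solving the scalar mass-conservation
  equation; the phenotype is the total protein-ligand complex concentration
  normalized to the homozygous wild type.

Free energies are in kcal/mol; concentrations are on the arbitrary
standard-state scale in which the Boltzmann factor ``exp(dG/RT)`` is a
concentration (the paper trail for this choice lives in ``docs/methods.md``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EnergyParams",
    "Allele",
    "Genotype",
    "SystemConfig",
    "EquilibriumState",
    "EquilibriumError",
    "folded_fraction",
    "model1_phenotype",
    "model2_equilibrium",
    "model2_phenotype",
    "kd_from_energy",
]

# Boltzmann exponents are clipped here: exp(500) ~ 1e217 keeps every downstream
# ratio finite in double precision while leaving limits (fraction -> 0 or 1)
# exact to far beyond 1e-12.
_EXP_CLIP = 500.0


def _boltz(x):
    """exp(x) with the exponent clipped to +-_EXP_CLIP (array-safe)."""
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


@dataclass(frozen=True)
class EnergyParams:
    """Wild-type free energies and thermodynamic constants.

    Parameters
    ----------
    dG_folding_wt:
        Wild-type folding free energy (folded minus unfolded), kcal/mol.
        Negative values mean the folded state is favoured.
    dG_binding_wt:
        Wild-type binding free energy (complex minus folded + free ligand),
        kcal/mol.  Only used by Model 2.
    R:
        Gas constant, kcal/mol/K.
    T:
        Absolute temperature, K.
    """

    dG_folding_wt: float = -2.0
    dG_binding_wt: float = -5.0
    R: float = 1.98e-3
    T: float = 310.15

    def __post_init__(self) -> None:
        if not (math.isfinite(self.R) and self.R > 0):
            raise ValueError(f"R must be finite and > 0, got {self.R}")
        if not (math.isfinite(self.T) and self.T > 0):
            raise ValueError(f"T must be finite and > 0, got {self.T}")
        if not math.isfinite(self.dG_folding_wt):
            raise ValueError("dG_folding_wt must be finite")
        if not math.isfinite(self.dG_binding_wt):
            raise ValueError("dG_binding_wt must be finite")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class Allele:
    """One gene copy: mutational free-energy shifts plus an expression flag.

    A null (unexpressed) allele contributes protein to no species at all; it
    is deliberately *not* modelled as a large finite ddG, which would leave a
    residual unfolded-protein pool and risk overflow.
    """

    ddG_folding: float = 0.0
    ddG_binding: float = 0.0
    expressed: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddG_folding):
            raise ValueError("ddG_folding must be finite")
        if not math.isfinite(self.ddG_binding):
            raise ValueError("ddG_binding must be finite")


WT_ALLELE = Allele()
NULL_ALLELE = Allele(expressed=False)


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype: exactly two alleles, each expressing 0.5 X_T."""

    allele1: Allele = WT_ALLELE
    allele2: Allele = WT_ALLELE

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.allele1, self.allele2)

    # -- constructors for the genotype shapes used throughout ---------------
    @classmethod
    def wildtype(cls) -> "Genotype":
        return cls()

    @classmethod
    def single_het(cls, ddG_folding: float = 0.0, ddG_binding: float = 0.0) -> "Genotype":
        """Single mutant over a wild-type allele (a^A / a^WT)."""
        return cls(Allele(ddG_folding, ddG_binding), WT_ALLELE)

    @classmethod
    def within_allele(
        cls,
        ddG_folding_A: float = 0.0,
        ddG_folding_B: float = 0.0,
        ddG_binding_A: float = 0.0,
        ddG_binding_B: float = 0.0,
    ) -> "Genotype":
        """Double mutant on one allele (a^AB / a^WT); ddG values add."""
        return cls(
            Allele(ddG_folding_A + ddG_folding_B, ddG_binding_A + ddG_binding_B),
            WT_ALLELE,
        )

    @classmethod
    def between_allele(
        cls,
        ddG_folding_A: float = 0.0,
        ddG_folding_B: float = 0.0,
        ddG_binding_A: float = 0.0,
        ddG_binding_B: float = 0.0,
    ) -> "Genotype":
        """Compound heterozygote (a^A / a^B): one mutation per allele."""
        return cls(
            Allele(ddG_folding_A, ddG_binding_A),
            Allele(ddG_folding_B, ddG_binding_B),
        )

    @classmethod
    def homozygote(cls, ddG_folding: float = 0.0, ddG_binding: float = 0.0) -> "Genotype":
        a = Allele(ddG_folding, ddG_binding)
        return cls(a, a)

    @classmethod
    def hemizygote(cls, ddG_folding: float = 0.0, ddG_binding: float = 0.0) -> "Genotype":
        """One expressed allele, the other null (a^A / a^null)."""
        return cls(Allele(ddG_folding, ddG_binding), NULL_ALLELE)


@dataclass(frozen=True)
class SystemConfig:
    """Concentration scale of the system.

    ``X_T`` is the total protein concentration (both alleles combined) and
    ``ligand_ratio`` the ratio L_T / X_T of total ligand to total protein.
    The default X_T = 1 puts the system deep in the tight-binding regime
    (X_T >> K_D ~ 2.9e-4) for the default binding energy.
    """

    X_T: float = 1.0
    ligand_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.X_T) and self.X_T > 0):
            raise ValueError(f"X_T must be finite and > 0, got {self.X_T}")
        if not (math.isfinite(self.ligand_ratio) and self.ligand_ratio >= 0):
            raise ValueError(f"ligand_ratio must be >= 0, got {self.ligand_ratio}")

    @property
    def L_T(self) -> float:
        return self.ligand_ratio * self.X_T


class EquilibriumError(RuntimeError):
    """Raised when the ligand-conservation root-find fails to converge."""

    def __init__(self, message: str, bracket: tuple[float, float], residual: float):
        super().__init__(f"{message} (bracket={bracket}, residual={residual:.3e})")
        self.bracket = bracket
        self.residual = residual


@dataclass(frozen=True)
class EquilibriumState:
    """Solved per-allele species concentrations for one Model 2 genotype."""

    unfolded: tuple[float, float]
    folded: tuple[float, float]
    bound: tuple[float, float]
    free_ligand: float
    X_T: float = 1.0
    L_T: float = 0.0

    @property
    def total_bound(self) -> float:
        return self.bound[0] + self.bound[1]

    @property
    def total_folded(self) -> float:
        return self.folded[0] + self.folded[1]


def folded_fraction(dG, params: EnergyParams):
    """Fraction of a two-state protein in the folded state.

    F = exp(-dG/RT) / (1 + exp(-dG/RT)) = 1 / (1 + exp(dG/RT)),
    evaluated through the overflow-safe form so that |dG/RT| up to the clip
    limit is handled exactly at the 0/1 boundaries.  Accepts scalars or
    arrays.
    """
    dG = np.asarray(dG, dtype=float)
    if not np.all(np.isfinite(dG)):
        raise ValueError("dG must be finite")
    out = 1.0 / (1.0 + _boltz(dG / params.RT))
    return float(out) if out.ndim == 0 else out


def kd_from_energy(dG: float, params: EnergyParams) -> float:
    """Dissociation constant exp(dG/RT) in the model's concentration unit."""
    return float(_boltz(dG / params.RT))


def _allele_folded_fraction(allele: Allele, params: EnergyParams) -> float:
    return folded_fraction(params.dG_folding_wt + allele.ddG_folding, params)


def model1_phenotype(genotype: Genotype, params: EnergyParams) -> float:
    """Folded-protein phenotype W (wild type = 1) under Model 1.

    Each expressed allele contributes ``0.5 X_T * F(dG_wt + ddG_folding)`` of
    folded protein; the genotype total is normalized by the wild-type diploid
    total ``2 * 0.5 X_T * F(dG_wt)``.  X_T cancels, so no SystemConfig is
    needed.
    """
    f_wt = folded_fraction(params.dG_folding_wt, params)
    total = sum(
        _allele_folded_fraction(a, params) for a in genotype.alleles if a.expressed
    )
    return total / (2.0 * f_wt)


def _allele_bound_scale(allele: Allele, params: EnergyParams) -> float:
    """K-like constant of the per-allele binding isotherm (Eq.-22 denominator).

    bound_i(L) = 0.5 X_T * L / (L + scale_i), with
    scale_i = exp(dGb_i/RT) * (1 + exp(dGf_i/RT)).
    """
    rt = params.RT
    kb = _boltz((params.dG_binding_wt + allele.ddG_binding) / rt)
    uf = _boltz((params.dG_folding_wt + allele.ddG_folding) / rt)
    return float(kb * (1.0 + uf))


def model2_equilibrium(
    genotype: Genotype,
    params: EnergyParams,
    config: SystemConfig,
    *,
    rtol: float = 4 * np.finfo(float).eps,
    maxiter: int = 200,
) -> EquilibriumState:
    """Solve the shared-ligand equilibrium for one diploid genotype.

    The free-ligand concentration L is the unique root in [0, L_T] of the
    strictly increasing conservation map ``L + sum_i bound_i(L) = L_T``.
    A bracketed Brent solve is used; the returned state satisfies both the
    ligand and the per-allele protein conservation identities to <=1e-10
    relative.
    """
    L_T = config.L_T
    half = 0.5 * config.X_T
    scales = [
        _allele_bound_scale(a, params) if a.expressed else None
        for a in genotype.alleles
    ]

    def total_bound(L: float) -> float:
        return sum(half * L / (L + s) for s in scales if s is not None)

    if L_T == 0.0:
        L = 0.0
    else:

        def g(L: float) -> float:
            return L + total_bound(L) - L_T

        try:
            L = brentq(g, 0.0, L_T, rtol=rtol, maxiter=maxiter)
        except RuntimeError as exc:  # pragma: no cover - monotone map converges
            raise EquilibriumError(
                f"ligand conservation solve failed: {exc}",
                bracket=(0.0, L_T),
                residual=g(L_T),
            ) from exc

    bound, folded, unfolded = [], [], []
    for allele, s in zip(genotype.alleles, scales):
        if s is None:
            bound.append(0.0)
            folded.append(0.0)
            unfolded.append(0.0)
            continue
        b = half * L / (L + s) if L > 0 else 0.0
        free_protein = half - b
        f = _allele_folded_fraction(allele, params)
        bound.append(b)
        folded.append(free_protein * f)
        unfolded.append(free_protein * (1.0 - f))

    state = EquilibriumState(
        unfolded=tuple(unfolded),
        folded=tuple(folded),
        bound=tuple(bound),
        free_ligand=L,
        X_T=config.X_T,
        L_T=L_T,
    )
    if L_T > 0:
        resid = abs(state.free_ligand + state.total_bound - L_T) / L_T
        if resid > 1e-10:
            raise EquilibriumError(
                "ligand conservation residual above tolerance",
                bracket=(0.0, L_T),
                residual=resid,
            )
    return state


@lru_cache(maxsize=128)
def _wt_reference(params: EnergyParams, config: SystemConfig) -> EquilibriumState:
    """Wild-type diploid equilibrium, cached per (params, config)."""
    return model2_equilibrium(Genotype.wildtype(), params, config)


def model2_phenotype(
    genotype: Genotype, params: EnergyParams, config: SystemConfig
) -> float:
    """Protein-ligand-complex phenotype W (wild type = 1) under Model 2.

    The genotype's own equilibrium and the wild-type reference equilibrium
    are solved separately (each cell has its own free-ligand concentration);
    W = total bound complex / wild-type total bound complex.
    """
    wt = _wt_reference(params, config)
    if wt.total_bound == 0.0:
        raise ValueError(
            "wild-type reference has no bound complex (L_T = 0); phenotype undefined"
        )
    state = model2_equilibrium(genotype, params, config)
    return state.total_bound / wt.total_bound
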
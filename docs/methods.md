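# Methods

## The models and their assumptions

The system is one gene in a diploid cell. Both alleles are expressed equally,
each contributing 0.5·X_T of total protein; all reactions are at
thermodynamic equilibrium; mutational free-energy changes (ΔΔG) are additive
within one molecule. There is no dimerization, no cooperativity, no
allele-specific expression imbalance, and no dynamics — these are stated
non-goals, not omissions.

**Model 1 (folding only).** Each allele's protein partitions between an
unfolded and a folded state. The folded fraction is
F(ΔG) = 1/(1 + e^{ΔG/RT}); the phenotype W is total folded protein
normalized so the wild-type diploid is exactly 1 AU. Because the two alleles
are independent (nothing couples them), the between-allele double mutant
equals the additive expectation W_A + W_B − 1 *identically* — protein
folding alone produces intra-molecular epistasis but no dominance.

**Model 2 (folding + single ligand binding).** A folded protein can bind one
ligand molecule; the complex is the functional species. The two alleles now
share a finite ligand pool, which couples them. Per allele the bound
concentration at free-ligand concentration L is

    bound_i(L) = 0.5 X_T · L / (L + K_i),
    K_i = e^{(ΔG_B,wt + ΔΔG_B,i)/RT} · (1 + e^{(ΔG_F,wt + ΔΔG_F,i)/RT})

and L is the unique root of L + Σ_i bound_i(L) = L_T on [0, L_T]. The map is
strictly increasing in L, so a bracketed Brent solve is guaranteed to
converge; we run it at relative tolerance 4·eps (≈9e-16), max 200
iterations, and verify both conservation identities (ligand, and
unfolded+folded+bound = 0.5·X_T per expressed allele) to ≤1e-10 relative
before returning a state. Each genotype's cell has its own free-ligand
concentration; phenotypes are normalized by the wild-type cell's own
equilibrium, which is solved once per (parameter, concentration) pair and
cached.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| ΔG_folding_wt | −2 (variants −3.5, −0.5) | kcal/mol | wild-type folding stability |
| ΔG_binding_wt | −5 | kcal/mol | wild-type binding energy |
| R | 1.98×10⁻³ | kcal/mol/K | gas constant |
| T | 310.15 | K | 37 °C |
| X_T | 1 | model conc. unit | total protein |
| ligand_ratio | 1 (examined 0.8, 2, 10) | — | L_T / X_T |
| linking m | 1.5 (concave/convex), 5 (sigmoidal) | — | curvature |

**Concentration scale.** The binding isotherm adds e^{ΔG/RT} to L, so the
model's implicit concentration unit is the standard-state unit of the
Boltzmann factor; the absolute scale of X_T is not determined by the theory.
We default X_T = 1 unit, which puts the system deep in the tight-binding
regime (X_T/K_D ≈ 3400 at ΔG_B = −5, where K_D = e^{ΔG_B/RT} ≈ 2.91×10⁻⁴
unit). This choice reproduces the ligand-limitation regime in which ~80% of
protein is bound at ligand_ratio 0.8. Lowering X_T toward K_D weakens all
competition effects; X_T is a config knob for exactly that sensitivity
analysis. The frequently quoted "K_D = 291 nM" corresponds to the same
significand under a different (unstated) standard state; we report the
significand only.

**Null alleles** are represented as `expressed=False` — zero contribution to
every species — rather than as a large finite ΔΔG, which would leave a
residual unfolded pool and invite overflow. All Boltzmann exponents are
clipped at ±500 (e^{500} ≈ 1e217), which keeps every ratio finite while
leaving saturated fractions exact far beyond any asserted tolerance. The
folded fraction saturates to exactly 0/1 in double precision once
|ΔG/RT| ≳ 36; strict monotonicity is therefore only asserted inside that
range.

## Interaction and dominance metrics

Expected double-mutant phenotypes: additive max(C, W_A + W_B − W_WT) and
log-additive max(C, W_A·W_B/W_WT), with C = 0.5 for within-allele
combinations (the untouched allele keeps half the wild-type output) and
C = 0 between alleles. Whether the floor bound is recorded per row
("clamp" flags), and the run summary counts activations. Scores are
observed − expected (plain or log scale); a non-positive phenotype makes the
log score undefined — flagged, never raised or dropped.

Degree of dominance: (W_het − mid)/|W_B − mid| with mid the homozygote
midpoint. We order the alleles so B is the *less fit* homozygote, which
makes the sign convention "positive ⇔ the fitter allele is dominant"; the
magnitude is invariant under relabeling. When the homozygotes differ by
≤1e-9 AU the midpoint distance is zero and the degree is flagged undefined.
No lower bound is applied to the midpoint expectation.

## Linking functions

Concave, convex and sigmoidal transforms with curvature m ≥ 0, all anchored
at (0,0) and (1,1) and strictly increasing; closed-form inverses are used
for inversion. The printed formulas are 0/0 at m = 0, so m < 1e-6 is
evaluated as the identity (the curves differ from the identity by O(m) — far
below any tolerance at that cutoff). The working domain extends to x = 1.02
because the phenotype grids do; the anchoring claims apply on [0,1].
Pipeline order: observed phenotypes are transformed first, then expectations
and scores are computed on the transformed scale — including the C = 0.5
floor, which therefore lives on the transformed scale.

## Grids and inversion

Default grids: ΔΔG from −2 to 13 kcal/mol, step 0.125 (121 values);
heterozygous-single phenotype targets 0.5–1.02 AU step 0.005 (105);
homozygote targets 0–1.02 AU step 0.01 (103). Phenotypes are strictly
decreasing in ΔΔG, so inversion is a bracketed root-find on
ΔΔG ∈ [−30, 60]; targets outside the attainable range — including exactly at
an asymptotic bound, e.g. 0.5 for a Model 1 heterozygous single (limit as
ΔΔG→∞) or 1.02 above the stabilized maximum ≈1.019 — are flagged
infeasible, dropped, counted in the run summary, and logged. When
phenotype-matched sets are compared across mutation types, infeasible points
are excluded from both sides so the sets stay paired. Sweeps store ordered
pairs (symmetry is asserted in tests); deduplication to unordered pairs is
an export-time option.

## Synthetic cytometry data

The generator emulates only what the scoring stage consumes: per-event
GFP = autofluorescence·ε₁ + truth·(WT signal)·ε₂ with mean-one lognormal
noise ε at three levels — per event (sd 0.35 on the log, ≈36% CV), per
replicate (sd 0.05 on signal for colony-to-colony induction variability,
sd 0.15 on autofluorescence), and per batch (sd 0.10 on both). Defaults:
WT signal 1000, autofluorescence 100 fluorescence units, 5000 events ×
3 replicates per genotype. Scatter channels carry a 25% high-SSC
sub-population whose GFP is biased ×1.4, so the low-SSC gate is
consequential, as in real bacterial data. These values were fixed once, for
realism, before any recovery test was run.

What a green recovery test establishes: that gating, batch-matched
normalization and the printed SE propagation recover known truths without
bias under this noise model. It does *not* establish robustness to
instrument effects the generator omits (spillover, doublets, drift,
non-lognormal tails).

A note on the SE formulas: the normalized-signal SE and the log-additive
expectation SE are implemented exactly as printed, i.e. as root-sum-squares
of *relative* errors not multiplied back by the ratio/product. For
phenotypes below 1 this overstates the absolute SE, making the reported
intervals conservative; we keep the printed form deliberately.

## Known limitations and honest failure modes

* **Ligand-excess decoupling is a limit, not a threshold.** The
  between-allele additivity residual decays like ~1/(L_T/X_T): ≈7×10⁻⁵ at
  ratio 10³, ≤10⁻⁶ only by ratio ≈10⁵. An acceptance check pinned at 10⁻⁶
  for ratio 10³ fails for physical reasons; the property suite asserts the
  true monotone decay instead.
* **The within-allele phenotype floor exceeds 0.5 when ligand is limiting.**
  At ligand_ratio 1 the hemizygote phenotype is ≈0.5085, so within-allele
  doubles whose additive expectation falls in (0.5, 0.5085) show *positive*
  epistasis — the same competition mechanism that produces the 62.5% floor
  at ratio 0.8. "Within-allele epistasis is negative at ratio 1" is
  therefore true except in that narrow band near the floor.
* Equilibrium only; no kinetics, no expression imbalance, no specific
  (contact) epistasis in ΔΔG.
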
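# Methods

## The coarse-grained chain model

The tetramer is a linear bead chain with pattern `C C (G G C C) × 4`:
five rigid aryl-diester blocks (two carbonyl beads `C` joined by one long
through-ring bond) linked by four glycol `G–G` bonds. The only degrees of
freedom are the four Ψ dihedrals about the `G–G` bonds (the OC–CO torsion
of each ethylene-glycol moiety); all other torsions are held trans and
bond lengths/angles are fixed. Chains are built by natural-extension
forward kinematics, and the terminal distance d1 is the Euclidean
distance between the first and last carbonyl beads (the minimum over
marker pairs when a terminus exposes several; no periodic images exist in
the implicit-solvent model).

Placing all four glycol links between the terminal markers is a
deliberate idealization. A chemically literal tetramer with a
hydroxyethyl tail would leave one Ψ dangling outside the restrained span;
here the terminal-distance restraint must control every torsion, because
the whole point of the model is that d1 steers the full gauche/trans
equilibrium.

### Geometry calibration (two anchors)

The bond lengths and angles (ring 0.514 nm, ester 0.24 nm, glycol
0.15 nm; 112° at carbonyl beads, 77.5° at glycol beads) were fixed once
against the two experimental anchor points the model exists to
reproduce:

1. **Crystalline anchor.** The all-trans chain spans 4.05 nm — just above
   the 4.0 nm restraint — and *every* torsion-state combination
   containing at least one gauche falls below 4.0 nm (checked by
   enumeration over all 3⁴ minima combinations; the worst case is
   3.53 nm). A lower wall at 4.0 nm with k = 1500 kJ mol⁻¹ nm⁻² therefore
   makes any gauche-classified angle cost ≳ 15 kJ/mol and enforces the
   fully trans state.
2. **Amorphous anchor.** Gauche-rich chains compact to d1 ≈ 2.2–3.0 nm,
   so a lower wall at 2.4 nm penalizes the most compact of them and trims
   the unrestrained 91:9 equilibrium (ratio 10.1) to the 9:1 ratio
   characteristic of amorphous PET. With a first-draft geometry whose
   gauche states all sat above 3 nm the 2.4 nm wall was inert and the
   ratio stayed at 10.1; the restraint value carrying the ratio is the
   behavior the model is meant to have, so the glycol angle was sharpened
   until the 2.4 nm anchor held (9.2 ± 0.2 over seeds at 1.5·10⁵ sweeps).

Between the anchors the trans fraction rises monotonically with the wall
position, reproducing the sigmoidal population curve of a restrained
scan (see `results/d1_scan.dat`).

### Torsion potential

`U(Ψ) = Σ_{k=1..3} a_k cos(kΨ)`, with the three coefficients solved
linearly from: the gauche-trans gap `U(70°) − U(180°) = ΔE_gt`, a
stationary point at the gauche minimum `U′(70°) = 0`, and the barrier
height `U(125°) − U(180°) = B` at the midpoint between the wells
(default B = 12 kJ/mol: high enough for distinct states, low enough for
Monte Carlo mixing). The construction pins minima at exactly ±70° and
180°; a grid check rejects parameter sets that develop extra minima.
Gauche degeneracy 2 (±70°) enters every closed-form population formula.
The boundary ±120° classifies as trans, making gauche/trans an exact
partition of the circle.

### Sampling and calibration

Metropolis Monte Carlo over torsion space: one sweep attempts one move
per torsion; a proposal is a wrapped Gaussian step (30°) or, with
probability 0.25, a uniform resample of the angle (ergodicity across
barriers). Both proposals are symmetric, so acceptance uses only the
energy difference (torsion potential + wall + optional metadynamics bias
on d1). Pivot geometry means a move changes d1 only; the hot loop is
numba-compiled. By default the first max(200, n/10) sweeps are discarded
as burn-in, and a watchdog raises if acceptance collapses below 0.1%.
Temperatures: 303.15 K for calibration against the 30 °C experimental
ratio, 300 K for all other chain sampling. Seeds are explicit arguments
everywhere; there is no hidden global RNG state.

`calibrate_gt_gap` inverts the sampled gauche fraction: it starts from
the two-state closed form `ΔE = −kBT ln(p_g/(2 p_t))` and bisects
against the unrestrained sampler (6·10⁴ sweeps per evaluation, tolerance
0.002 on the fraction) because the continuous basins have unequal widths
and shift the true gap ≈ 0.6 kJ/mol below the two-state estimate.

## Enhanced sampling

**Well-tempered metadynamics.** Gaussians (default σ = 0.05 nm,
w₀ = 0.5 kJ/mol, pace 1 deposit per 500 sampler steps, bias factor
γ = 15) are deposited with heights `w₀ exp(−V/(kB(γ−1)T))` and summed
directly — kernels are never dropped or merged at desk scale. On an
analytic 1D double well (10 kJ/mol barrier), 3·10⁵ steps reconstruct the
potential within ≈ 0.4 kJ/mol RMSE over the basins both from the bias
(`F = −γ/(γ−1)·V`) and by reweighting.

**Solute tempering.** The ladder is geometric,
`λ_i = λ_min^(i/(n−1))`, default eight replicas down to
λ_min = 0.426934 (the rounded 0.43 endpoint does not reproduce the
standard printed ladder; the unrounded value does, to 1e-6). The chain
has no explicit environment, so the REST2 charge-scaling convention for
solute–solvent cross terms is moot and scaling reduces to multiplying
the solute-scalable terms (the torsion potential, and pairwise well
depths if present) by λ; wall restraints belong to the unscaled part of
the Hamiltonian in every replica. Gaussian heights in replica i are
boosted as `w₀/λ_i`. Exchanges are coordinate swaps between nearest
ladder neighbors, alternating even/odd pairs every interval (default
500 steps), accepted with
`min(1, exp(−[E_i(x_j)+E_j(x_i)−E_i(x_i)−E_j(x_j)]/kBT))` where each
replica's energy includes its own bias — statistically equivalent to
λ-swapping. Deposit pace and exchange interval are expressed in sampler
steps; Monte Carlo has no physical time scale. All analysis statistics
come from the λ = 1 replica.

## Free-energy analysis

**Reweighting.** Final-bias (umbrella-like) estimator: each frame gets
`w_i ∝ exp(+V_final(s_i)/kBT)` with the fully deposited bias evaluated
at the frame's biased CVs, applied after discarding a transient (default
first 20% of frames — the early bias is far from its asymptotic shape).
Time-dependent-offset estimators would also be defensible; the choice is
recorded in trajectory metadata (`reweighting: final-bias`) so results
are auditable.

**Surfaces.** `F(bin) = −kBT ln(Σ weights)` on 1D/2D grids (default bin
widths 0.01 nm for distances, 5° for angles, set in config), minimum
shifted to exactly 0, unoccupied bins NaN-flagged rather than zeroed.
Errors come from contiguous equal blocks (default 5; remainder frames
join the last block): per-block surfaces are aligned on their common
bins (making the error invariant to constant bias shifts) and the
per-bin spread gives the standard error. For i.i.d. frames this agrees
with a bootstrap over frames within ~20%.

**State integration.** Bound/unbound partition on one CV (default
d_COM at 3 nm, equality counting as bound);
`ΔF = −kBT ln(W_bound/W_unbound)`, antisymmetric under swapping the
regions, with a block standard error (blocks missing a region are
skipped). Convergence series recompute ΔF on growing prefixes at a
stride; the final entry is exactly the full-trajectory estimate. ΔΔF is
reported as ΔF(aPET) − ΔF(cPET) so the crystalline penalty is positive
(≈ +35 kJ/mol from the printed −25/−60 inputs), and errors add in
quadrature.

## Thermodynamic bookkeeping

Constants: kB = 0.0083144621 kJ mol⁻¹ K⁻¹, N_A = 6.02214076·10²³,
V° = 1.66054 nm³ per molecule at 1 M. Default temperature 298.15 K (the
25 °C equilibration temperature); the depletion factor is insensitive to
the 298 vs 300 K choice (2.38 vs 2.45 ·10⁴). Sign conventions:
standard-state corrections are reported in the binding direction
(negative for boxes larger than V°), unbinding quantities positive. The
fold-surface conversion `2 σ_e A_chain N_A` uses 1 nm² = 10⁻¹⁸ m² and
J → kJ, giving 25.5 kJ/mol per repeat unit for σ_e = 0.106 J/m² and
A_chain = 0.20 nm². The per-monomer convention divides by the four
repeat units of the tetramer.

## Synthetic data: what it does and does not emulate

The generators (`fixtures`) draw i.i.d. frames from distributions whose
target statistics are closed-form: exact two-state torsion labels with
gauche degeneracy 2, inverse-CDF samples of the double-well Boltzmann
density, and two-basin d_COM mixtures with a prescribed bound/unbound
ΔF (optionally switching probability mid-run for convergence tests).
They emulate the *statistical structure* the estimators assume —
Boltzmann-distributed populations, two-basin CV densities, deposited
bias histories — not real PET: no solvent, no inter-chain packing, no
time correlation beyond what the MC sampler itself produces, and
π-stacking intermediates appear only as a single effective bound basin.
Detachment demonstrations with deep planted minima (−60 kJ/mol ≈ 24 kBT)
use flat two-basin coverage plus importance weights, because an
unweighted sampler would never visit the unbound state — precisely the
regime metadynamics exists for. Passing tests therefore validate the
estimators and engines, not force-field realism.

## Problem sizes and numerical choices

Chain runs use 10⁵–1.5·10⁵ sweeps (the two-anchor conformational results
are stable to ±0.2 in the g:t ratio at this length); calibration uses
6·10⁴-sweep bisection evaluations; the double-well benchmark uses
2.5–3·10⁵ steps and 3·10³ kernels; detachment fixtures use 2·10⁵ frames.
Ties and degenerate inputs: ±120° → trans; CV exactly at a partition
threshold → bound; empty trajectory regions raise rather than return
infinities; zero-weight histograms are errors; wall exponent must be
even and ≥ 2 (energy `k·violation^p` with no ½ prefactor, matching the
convention the quoted force constants come from).

## Known limitations

The torsional model freezes bond lengths/angles, so d1 fluctuations come
from torsions alone and the mapping wall-position → g:t ratio is sharper
than in a fully flexible chain. The HREX driver re-evaluates energies in
Python per move (fine at 10⁴–10⁵ steps; the plain-chain sampler is the
compiled fast path). Exchange acceptance on the coarse chain (80–97%) is
far above atomistic values — the model has few solute degrees of
freedom, so neighboring λ ensembles overlap strongly, and no acceptance
target is asserted. Block errors assume block length exceeds the
correlation time; for strongly correlated runs they underestimate.
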
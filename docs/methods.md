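# Methods

This note documents the models, conventions and numerical choices behind
pamscope, and what the synthetic validation does and does not demonstrate
about real simulation data.

## Units and conventions

Internal units are nm, ps, kJ/mol, amu and K throughout; angstrom appears
only at the PDB boundary and in reported geometric quantities (RMSF, RMSD,
COM distances), kcal/mol only in free-energy reports. In this unit system
1 amu·nm²/ps² = 1 kJ/mol exactly, so mass-weighted covariance eigenvalues
λ (nm²·amu) convert to angular frequencies ω = sqrt(k_BT/λ) in 1/ps with
no further constants. Residue numbering is the author numbering of the
input PDB, never renumbered; the highest-occupancy alternate location is
kept; insertion codes pass through verbatim.

## Contact statistics

A pair is a *candidate* when its COM distance is below the cutoff
(0.6 nm arginine–base, 0.5 nm arginine–phosphate) in at least 5% of the
pooled (all replicates concatenated) trajectory; a per-replicate variant
is available behind a flag. A frame is an *effective contact* when the
distance criterion holds **and** the interaction energy is attractive
(negative) with magnitude at or above the threshold (100 kJ/mol base,
350 kJ/mol phosphate). "Interaction strength" is interpreted as the
magnitude of favourable attraction; repulsive frames never count.

The occupancy series is modelled as Bernoulli. The integrated
autocorrelation time is `τ = dt·(1 + 2·Σ_{k≥1} ρ(k))` with the sum
truncated at the first negative empirical autocorrelation
(initial-positive-sequence window); a constant series returns τ = dt and
is flagged by construction. τ is computed on the interaction-energy
series — a continuous proxy carrying the same switching dynamics — and
the largest τ across replicates is used, giving
`n_eff = T_total/τ` and `stderr = sqrt(p(1−p)/n_eff)`. The
replicate-SEM alternative (standard deviation of per-replicate means /
√R) is always reported alongside, since both error conventions are in
common use. Per-category aggregation uses any-pair semantics: a frame
counts for PAM-NB if *any* base pair of that category is in contact;
categories are not mutually exclusive.

## Hydrogen bonds and specificity

Detection is purely geometric: donor–acceptor distance ≤ 0.35 nm and
hydrogen–donor–acceptor angle (vertex at the donor) ≤ 30°. The angle
convention follows the H–D–A wording exactly; some tools use the
complementary D–H···A convention, which is *not* what is implemented.
Donor hydrogens come from a shipped residue-template table (arginine
NE/NH1/NH2 and backbone N) with a geometric first-frame fallback
(same-residue hydrogens within 0.125 nm); a donor with no hydrogen is an
error, not a silent skip. Acceptor categories: atoms of PAM residues
split into nucleobase vs sugar-phosphate by atom name; everything outside
the PAM residues is non-PAM. Frequencies are event-frames over total
frames per category; normalization divides by the sum of the category
values. The specificity index is `(f_PAM + ε)/(f_nonPAM + ε)` with
ε = 0 by default and an `inf` sentinel for a zero denominator — the
pseudocount is this implementation's addition for degenerate inputs.

## RMSF and quasi-harmonic entropy

Rigid-body motion is removed by mass-weighted least-squares (Kabsch)
superposition of every frame onto a reference frame over the analysis
group itself (for a single residue this removes its own rotation and
translation). RMSF is the per-atom root-mean-square deviation about the
time-mean position; the group value is the unweighted mean over heavy
atoms, reported in Å.

Entropy uses the quantum harmonic-oscillator (Andricioaei–Karplus) form
per eigenmode of the mass-weighted fluctuation covariance,

    S = R Σᵢ [ xᵢ/(e^{xᵢ}−1) − ln(1−e^{−xᵢ}) ],   xᵢ = ħωᵢ/(k_B T),

chosen because the classical form diverges for stiff modes; the classical
variant is available behind a flag for comparison. Eigenvalues at or
below 1e-12 nm²·amu are treated as frozen rigid-body remnants, excluded
from the sum, and reported via `n_modes_used`. The temperature is always
an explicit argument (equilibrium production and biased runs may sit at
different temperatures) and is never hard-coded.

## Well-tempered metadynamics

The bias is a sum of Gaussian hills deposited every t_G = 10 ps with
deposition rate ω = 1.0 kJ/mol/ps (nominal height ω·t_G = 10 kJ/mol),
bias factor γ = 4 at T = 300 K, and one-sided harmonic walls of
3500 kJ/(mol·nm²) restricting the CVs to 0.3–1.2 nm. Each hill is scaled
at deposition time by exp(−V(s)/(k_B ΔT)) with ΔT = (γ−1)T; the
tempering exponent is made dimensionless with k_B (the common shorthand
"V/ΔT" is an energy over a temperature). The free energy is recovered as
F(s) = −γ/(γ−1)·V(s); the additive constant C(T) is fixed by shifting
min F to 0 on the evaluation grid (default 0.25–1.25 nm, 201 nodes per
CV). Hill widths are not part of the production setup this models;
σ = 0.05 nm per CV is the default and is explicit in every record.

The validation engine integrates overdamped Langevin dynamics
(`x ← x − ∇(U+V+walls)/γ_f·dt + sqrt(2k_BT·dt/γ_f)·ξ`) with the bias kept
on a linear-interpolation grid, so the per-step cost is independent of
the hill count. Multiple walkers share one bias and deposit round-robin.
Basin free-energy differences are computed by Boltzmann integration of
exp(−F/k_BT) over basin intervals rather than by comparing minima, which
is far less sensitive to grid resolution. The acceptance-scale validation
uses an asymmetric double well (barrier 12 kJ/mol, tilt 6 kJ/mol/nm) and
10⁶ total Langevin steps (two walkers × 5·10⁵ steps, dt = 0.01 ps,
friction 50 amu/ps), recovering the quadrature ΔF to well within 0.3 kT.
Short unit-test runs use a finer hill stride (t_G = 1–2 ps) so that
enough hills are deposited within the reduced run length; the production
default stays t_G = 10 ps.

## MBAR and λ-schedule design

Reduced potentials are kept in kT. The MBAR equations are solved by
quasi-Newton minimization of the convex objective
`Σₙ ln Σₖ Nₖ e^{fₖ−u_{kn}} − Σₖ Nₖ fₖ` followed by self-consistent
polishing to 1e-8 kT on the increments; states with zero samples are
evaluation-only (free-energy-perturbation style). Uncertainties come from
the asymptotic covariance of the normalized weight matrix (SVD form);
`Var(Δf_{0k}) = Θ_kk + Θ_00 − 2Θ_0k`. With two states the solution
coincides with the Bennett acceptance ratio to numerical precision, which
the tests verify against an independent root-finding implementation.

Replica-exchange acceptance between neighbouring windows is
`⟨min(1, e^{−Δ})⟩` with the standard swap energy
`Δ = u_i(y) + u_j(x) − u_i(x) − u_j(y)`. The λ-schedule optimizer does
plain gradient descent (finite-difference gradient, backtracking step) on
an *acceptance-equalization* loss — the variance of neighbour acceptances
plus a quadratic penalty when the minimum drops below the 10% target —
in an increment (softmax) parameterization that keeps the schedule
strictly monotone with fixed endpoints. Acceptances during optimization
are estimated under common random numbers through the model's
`transform(λ, z)` map, which makes the loss smooth and the whole
procedure deterministic under a seed. The loss definition is included in
the diagnostics so alternative objectives are auditable. An unreachable
target raises with advice to add windows.

The thermodynamic cycle combines the two transformation legs as
ΔΔG = ΔG_m2 − ΔG_m1 (DNA-bound minus free) with errors in quadrature.
The enthalpic decomposition consumes precomputed per-group end-state
(λ = 0, 1) interaction-energy series, discards the first 10% of frames
as equilibration, and uses the standard error of five contiguous block
means, combined across end states in quadrature; the `prot-rest`
remainder is computed frame-wise so group terms plus remainder equal the
total exactly. Re-deriving force-field energies for real systems is out
of scope; only the synthetic generators produce energies here.

## Structure comparison

Domain COM distances are mass-weighted over heavy atoms; the shipped
defaults for the two Cas9 domains whose separation reports the
recognition-lobe opening are REC3 498–718 and HNH 775–908 (standard
SpCas9 domain annotation; configurable, and printed in every CLI header).
Kabsch superposition enforces a proper rotation (det = +1); structures
are matched by (chain, residue number, atom name) with backbone defined
as N, CA, C, O (CA-only and all-heavy selectable). The two-tailed Z test
uses population variances and effective sample sizes from the
autocorrelation machinery, so duplicating correlated frames cannot
inflate significance.

## Synthetic generators: what they do and do not show

The generators produce every input class with exact ground truth: the
two-state Markov contact process has its stationary occupancy and
relaxation time exact by construction (transition probabilities from the
matrix exponential at step dt, not an Euler approximation); harmonic
ensembles have prescribed covariances; alchemical ladders have
closed-form ΔG = ½ln(k_j/k_i); Langevin trajectories obey equipartition.
Defaults describe a strongly bound/unbound contact (bound −120 ± 10
kJ/mol, unbound −10 ± 10 kJ/mol, 0.4 vs 0.9 nm), i.e. states whose
energies straddle the 100 kJ/mol threshold with modest overlap.

Passing tests on these inputs demonstrate the estimators — not the
simulations: real MD has non-Markovian switching, non-Gaussian
fluctuations, force-field and sampling error, and none of that is
emulated. Two consequences are documented deliberately: (i) when the
bound-state energy distribution overlaps the classification threshold,
the classified frequency is biased low relative to the hidden-state
occupancy — a property of the contact definition, not of the error
model; the error-calibration test therefore uses a spread (±3 kJ/mol)
small enough that classification is exact, and the classification bias
is exercised separately. (ii) The energy-autocorrelation τ slightly
underestimates the occupancy τ when uncorrelated noise rides on the
switching signal; with the default separation the effect on the error
bar is ~2%.

## Reference structures

The X-ray geometry checks (REC3–HNH COM distances of the closed/open
crystal structures; backbone RMSD between the two TGG-bound structures)
require the PDB entries 4UN3, 6AEB and 6K4P, which are not redistributed
with the package; the corresponding acceptance test reads
`data/structures/` and fails with instructions when they are absent.

## Problem sizes

Default validation scales, chosen to make every statistical assertion
sharp on one CPU: 200 seeded four-replicate runs of 10⁴ frames for error
calibration; 10⁵ frames for covariance/entropy convergence (sampling
error ~0.5% per eigenvalue); 10⁴ samples per state for MBAR recovery
(replicated at 10²–10⁴ for bias scaling); 10⁶ total Langevin steps for
the metadynamics reconstruction.
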
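# pamscope

Statistics of protein–DNA recognition from molecular-simulation data, built
around the question of how a CRISPR–Cas9 PAM-interacting domain reads its
protospacer-adjacent motif: which arginine–nucleotide contacts are real,
how flexible the reading residues are, what that flexibility costs or buys
thermodynamically, and how mutations shift the DNA-binding free energy.

The package provides, as a library and a CLI:

- **Contact occupancy with honest error bars.** A residue–nucleotide pair
  is in contact when its centre-of-mass distance is below 0.6 nm
  (arginine–base) or 0.5 nm (arginine–phosphate) *and* the attractive
  interaction energy is at least 100 / 350 kJ/mol. Candidate pairs must
  satisfy the distance criterion in ≥ 5% of the pooled trajectory. The
  binary occupancy is treated as Bernoulli with an effective sample count
  `n_eff = T/τ`, where τ is the largest integrated autocorrelation time of
  the interaction-energy series across replicates:
  `stderr = sqrt(p(1−p)/n_eff)`.
- **Hydrogen bonds and a specificity index.** Geometric detection
  (donor–acceptor ≤ 3.5 Å, hydrogen–donor–acceptor angle ≤ 30°),
  per-category frequencies (PAM nucleobase / PAM backbone / non-PAM),
  normalization to unit sum, and the specificity index
  `(f_PAM + ε)/(f_nonPAM + ε)`.
- **Flexibility and quasi-harmonic entropy.** Side-chain RMSF after
  mass-weighted superposition, and the entropy of the mass-weighted
  fluctuation covariance eigenmodes,
  `S = R Σᵢ [xᵢ/(e^{xᵢ}−1) − ln(1−e^{−xᵢ})]` with `xᵢ = ħωᵢ/k_BT`,
  `ωᵢ = sqrt(k_BT/λᵢ)`.
- **Well-tempered metadynamics.** Bias assembly from Gaussian hills with
  tempered heights `ω t_G e^{−V/(k_B ΔT)}`, free-energy recovery
  `F(s) = −γ/(γ−1) · V(s)` (γ = bias factor), one-sided harmonic wall
  restraints, PLUMED-dialect HILLS I/O, and a multiple-walker Langevin toy
  engine on analytic potentials for validation.
- **Alchemical free energies.** MBAR over λ windows (self-consistent +
  quasi-Newton, asymptotic-covariance errors), replica-exchange acceptance
  estimation, gradient-descent λ-schedule optimization toward a ≥ 10%
  minimum neighbour acceptance, thermodynamic-cycle
  ΔΔG = ΔG_m2 − ΔG_m1 with quadrature-propagated errors, and per-residue
  enthalpic decomposition with five-block error bars.
- **Structure comparison.** Mass-weighted domain COM distances (default
  domains: REC3 residues 498–718, HNH residues 775–908), Kabsch RMSD with
  atom matching, two-tailed Z tests on effective sample sizes, kernel
  density estimates.
- **Synthetic data with exact ground truth** (`pamscope.synthetic`):
  two-state Markov contact dynamics, Gaussian positional ensembles,
  hydrogen-bond geometries, harmonic alchemical ladders with closed-form
  ΔG, and overdamped Langevin dynamics — every generator seeded and
  bit-reproducible.

## Worked example

Estimate a contact frequency on a synthetic two-state trajectory whose
ground truth is known (stationary occupancy 0.3, correlation time 10 ps):

```python
import pamscope as ps

spec = ps.MarkovContactSpec(p_on=0.3, tau=10.0, dt=1.0,
                            n_frames=10_000, seed=11)
traj, energies, truth = ps.gen_markov_contact(spec)
d = ps.com_distance_series(traj,
                           ps.select(traj.structure, "name TGT"),
                           ps.select(traj.structure, "name PRB"))
occ = ps.classify_contacts(d, energies, ps.ContactCriteria(), "base", dt=1.0)
est = ps.frequency_with_error([occ], [energies], dt=1.0)
print(f"occupancy {est.mean:.3f} +/- {est.stderr:.3f} "
      f"(tau {est.tau:.1f} ps, n_eff {est.n_eff:.0f}; truth {truth.occupancy:.3f})")
```

prints

```
occupancy 0.274 +/- 0.020 (tau 20.2 ps, n_eff 496; truth 0.280)
```

The estimate sits within one standard error of the hidden-state truth, and
the error bar reflects the ~20 ps energy autocorrelation rather than the
raw 10 000-frame count. The same pipeline is available from the shell:

```sh
pamscope simulate markov-contact --out sim --seed 11 --n-frames 10000
pamscope contacts --traj sim.pdb --energies sim.xvg \
    --group-a "name TGT" --group-b "name PRB"
```

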
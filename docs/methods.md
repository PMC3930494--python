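# Methods

This note documents the model, its parameters, the numerical choices, and
what the synthetic fixtures do and do not establish.

## Coarse-grained representation

Each saccharide ring is one bead (GlcNAc 221 Da, MurNAc 275 Da) with a fixed
rise of 0.515 nm along the strand, so a disaccharide spans ~1.03 nm. Each
MurNAc carries exactly one peptide stem, reduced to a single effective tip
bead (460 Da, the average of stems with and without the terminal D-Ala) on a
spring. This is the smallest representation in which every measured geometry
remains literal: the "ring centers four saccharides apart" rule of the
strand-angle metric, the one-stem-per-MurNAc bookkeeping of cross-link
fractions, and per-saccharide unit areas all apply bead-for-bead.

Coordinates: x is the circumferential (glycan) direction, y the axial
(peptide) direction, z the wall normal. The box is periodic in x and y only;
"inf" constructs close each strand covalently across the x boundary.
Engineering strain is ε = ΔL/L on the relaxed box.

## Energetics (reduced units: k_BT = 1, lengths in nm)

| term | form | default | why |
|---|---|---|---|
| backbone bond | ½ k (r−r₀)² | k = 1000 k_BT/nm², r₀ = 0.515 nm | glycan backbone nearly inextensible at thermal forces |
| bending | ε_b (1−cos θ) per joint | ε_b from κ = 13.6 k_BT·nm (see below) | sets strand persistence length |
| stem torsion | k_φ Δφ², minimum at 90° | k_φ = 1 k_BT/rad² | native four-per-turn periodicity, softly held |
| stem spring | harmonic, rest 1.0 nm; stiff wall past 2.0 nm contour | k = 1.5 k_BT/nm² | peptides an order of magnitude floppier than glycans |
| cross-link spring | harmonic, rest 0.5 nm; wall past 4.0 nm | k = 2 k_BT/nm² | finite extensibility without unphysical stretch |
| excluded volume | ε(1−r/σ)² for r<σ | ε = 5 k_BT, σ = 0.5 nm | bounded repulsion, finite force at full overlap |

The contour walls are harmonic with a 100× stiffness multiplier, keeping
forces continuous (no FENE singularity). Temperature 310 K enters only
through the stress conversion 1 k_BT/nm³ = 4.28 MPa.

**Discrete bending stiffness.** The naive mapping ε_b = κ/(b·k_BT) makes a
discrete chain ~2 % too flexible. We instead invert the exact relation for
the (1−cos) joint potential, ⟨cos θ⟩ = coth ε_b − 1/ε_b, against the target
single-step correlation exp(−b/l_p), so the discrete chain's tangent
correlation is exp(−s/l_p) exactly. The same inversion drives the worm-like
chain generator, which samples cos θ from the joint Boltzmann distribution
by inverse CDF — generator and force field are therefore mutually
consistent, and the persistence-length estimator closes on either within
sampling error.

## Dynamics and protocols

BAOAB Langevin integration (friction γ = 1/τ, timestep 0.005 τ, masses in
GlcNAc units); with the thermostat off it reduces to velocity Verlet and
conserves energy to the tolerance asserted in the tests. Excluded-volume
pairs come from a periodic KD-tree rebuilt every 10 steps with a 0.4 nm
skin.

*Relaxation to equilibrium dimensions*: a proportional in-plane barostat
rescales Lx and Ly every 20 steps toward zero time-averaged in-plane stress
(capped at 0.2 % per update); the "relaxed dimensions" are the average of
the box series over the final half of the run. z is open and unregulated —
there is no solvent, so nothing sets a normal pressure.

*Clamped-strain protocol*: one in-plane dimension is scaled affinely by
(1+ε), the other held at its relaxed value; stresses are the time-averaged
virial (kinetic + configurational, minimum-image convention, multibody
terms decomposed into reference-particle arms) over the final 70 % of the
run, converted to MPa with the cross-section transverse-length × h_eff.
h_eff defaults to 4 nm and is recorded in every record; CG stresses rescale
trivially with it. Default strain sets follow the measurement protocol:
six glycan strains in 1.25–17.5 % and six peptide strains in 5–45 %, each
repeated, pooled at the record level (pooled fits behave better than
averaging per-repeat moduli at this sample size).

*Slab-resolved stress*: bonded and pairwise contributions are spread over
slabs in proportion to the fraction of each interaction arm inside the slab
(Irving–Kirkwood convention), the kinetic part as k_BT per particle in its
slab; the slab integral therefore equals the total virial identically. A
0.5 nm running average smooths the profile before the 10 %-of-peak width is
taken; the far-field baseline (outer 20 % of slabs) is subtracted first.

## Cross-linking construction

Strands are laid along x at rows spaced 2.5 ± 0.5 nm with uniform random
x-offsets (the layout offset rule is not constrained by any measurement we
reproduce; it is exposed as `randomize_offsets`). Stems explore thermally
for 4000 steps with strands frozen; every donor/acceptor pair on different
strands that ever comes within 1.6 nm becomes a candidate, ranked by first
contact under the stricter 1.1 nm criterion (ties: higher residence
fraction, then donor strand/index — the procedure must be a total order to
be reproducible). Candidates are accepted greedily under stem exclusivity,
subject to a minimum residence fraction of 0.01, until the linked-stem
fraction reaches the 0.5 target. The cutoffs and stem stiffness were tuned
once against that 50 % construction target (the target is part of the
construction, as in the source protocol), not against any downstream
measurement. The realized fraction counts linked stems over total stems;
counting linked pairs instead would halve it.

Greedy assignment under exclusivity is *not* monotone in the residence
threshold: discarding one early candidate can unblock two later links. The
test suite asserts the properties that do hold (monotone eligible set;
monotone link count for stem-disjoint candidates).

Strand deletion removes a strand, its stems, and incident links;
reinsertion places the saved strand back, re-runs the stem relaxation with
existing links retained, and restricts new assignments to pairs involving
the reinserted stems.

## Synthetic fixtures: what they establish

* The WLC ensembles have *exactly* exponential tangent correlations, so
  they validate the estimator (fit over the initial decay, s below the 1/e
  point unless a cutoff is given, origin-constrained in log space), not the
  simulation. The simulated-strand calibration test closes the loop at 10 %.
* The forward orthotropic records are noiseless and self-consistent by
  construction; the round trip validates the fitting chain to 0.1 %,
  including on 100 fuzzed parameter sets.
* Analytic density profiles (Gaussian, rectangle, triangle) pin the
  10 %-width operation against closed forms, e.g. width = 2σ√(2 ln 10).

None of these fixtures emulate sampling noise, finite trajectory length, or
construction disorder; the CG property tests (anisotropy pattern, rank
order with strand length, thickness/pore directions under strain) cover
those, qualitatively, at reduced patch sizes.

## Problem sizes

Default study conditions are the avg17 construct (12 strands of 17 ± 5.8
disaccharides, ~660 particles) for builder and property checks, with
8000-step relaxations and 2000–2500-step stress averages; the elasticity
property sweep uses 3 strains per axis × 2 repeats. The persistence-length
ensemble is 500 chains × 320 segments. Unit tests use 4–6-strand patches.
These sizes were chosen so the full suite and the acceptance script each
run in minutes on one CPU while every asserted property is comfortably
outside its noise band; all stochastic stages take explicit seeds and there
is no hidden global RNG state.

## Known limitations

* Absolute moduli in MPa are order-of-magnitude only: they inherit the CG
  spring constants and the nominal h_eff = 4 nm; the reference atomistic
  values come from solvated, atomic-resolution force fields. Anisotropy
  ratios and rank orders are the meaningful comparisons.
* Thickness responds to strain only through suppressed out-of-plane
  fluctuations; at CG tension levels the effect is clear under glycan
  strain but weak under peptide strain.
* There is no solvent, electrostatics, turgor, or chemistry: transpeptidation
  is purely topological, and the terminal D-Ala cleavage is represented only
  by the stem mass average.
* Elastic moduli can be extracted from the clamped-transverse protocol's
  stress ratios because the relaxed state is stress-free by construction;
  Poisson ratios are taken from transverse/axial stress-slope ratios under
  that protocol, mirroring the source derivation. A noise-induced slightly
  negative ν product is admitted (the stability bound is ν_gp·ν_pg < 1).
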
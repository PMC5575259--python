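# Methods

## The model

`dsxchange` studies spontaneous thiol–disulfide isomerization in a
force-clamped protein domain with a deliberately minimal, fully
classical model.  The chain is one bead per residue at the Cα position;
cysteine beads double as the position of their sulfur.  The fixture
system is an 89-residue immunoglobulin-like domain carrying five
cysteines (residues 24, 32, 47, 55, 63) and one disulfide cross-link,
24–55, which leaves 32, 47 and 63 as free thiols.  Under a constant
stretching force the domain unfolds until the cross-link takes the
load; the 24–55 loop then remains unstretched and confines 32 and 47
near the disulfide, while 63, outside the loop, is carried away with
the taut C-terminal strand.  Exchange is modeled as a geometric /
energetic event, not a chemical one: whenever a free thiol's sulfur
first comes within a cutoff of a disulfide sulfur, the bond may be
rewired there.  The method deliberately carries no information about
the reaction barrier or transition state — the question it addresses is
how far sterics and accessibility alone go.

### Hamiltonian

    V = Σ ½ k_b (r − r0)²                      bonds
      + Σ ½ k_a (θ − θ0)²                      bends
      + ½ k_x (r_SS − r_x0)²                   disulfide cross-link
      + Σ V_LJ(r) or V_soft(r)                 nonbonded, |i−j| ≥ 3
      − F (x_pulled − x_fixed)·n̂               force clamp

| parameter | default | units | rationale |
|---|---|---|---|
| `bond_r0` | 0.38 | nm | Cα–Cα virtual bond |
| `bond_k` | 15000 | kJ/mol/nm² | stiff but integrable at the default step; stretches ~1.1 nm over 57 loaded bonds at 480 pN |
| `angle_theta0` | 2.12 | rad | ~121°, a common Cα pseudo-bond angle |
| `angle_k` | 2.0 | kJ/mol/rad² | weak: the chain is flexible, ~0.8 kT per radian² |
| `sigma`, `epsilon` | 0.47, 1.0 | nm, kJ/mol | generic one-bead-per-residue excluded volume with a sub-kT well |
| `sigma_ss`, `epsilon_ss` | 0.356, 1.046 | nm, kJ/mol | Amber-style sulfur nonbonded parameters |
| `crosslink_r0`, `crosslink_k` | 0.39, 15000 | nm, kJ/mol/nm² | S–S bond treated as an inviolable stiff spring |
| `lj_cutoff` | 1.0 | nm | plain truncation |
| force | 480 | pN | the clamp force of the protocol |
| temperature | 300 | K | kT = 2.494 kJ/mol |

Nonbonded exclusions cover 1–2 and 1–3 neighbors and the cross-linked
pair.  Forces are analytic for every term; a test checks them against
central differences at 1e-4 relative.

### Softcore sulfur–sulfur interaction

A plain r⁻¹² wall would make the sub-0.35 nm approaches that precede an
exchange event astronomically expensive and numerically dangerous.
Sulfur–sulfur pairs therefore interact through a softcore curve that

* equals the plain 12-6 Lennard-Jones curve **exactly** at and beyond a
  crossover distance (0.35 nm by default, on the repulsive flank just
  below the S–S well minimum at 2^(1/6)·0.356 ≈ 0.40 nm), and
* below the crossover continues as the quadratic `A + C r²` whose value
  and slope match LJ at the crossover, giving a finite core
  (V(0) ≈ 17 kJ/mol ≈ 7 kT with the defaults) and a force that decays
  linearly to zero at r = 0.

The construction is C¹ everywhere and makes reactive approaches (0.25
nm costs ≈ 3.5 kT) thermally accessible, which is its entire purpose.
The conventional (α, λ, p) = (0.3, 0.9, 1) softcore parameter triple is
stored on `PotentialParams` for provenance, but the functional form
shipped here is the piecewise construction: the physically binding
contract is "finite core, identical to LJ beyond the crossover", and
the standard free-energy-perturbation softcore formula with λ = 0.9
does not actually reduce to plain LJ at any finite distance.
`dsxchange dump-table` writes the tabulated curve for inspection.

## Dynamics

Propagation is overdamped (Brownian) Langevin by Euler–Maruyama:

    x(t+dt) = x(t) + (dt/γ) F(x) + sqrt(2 kT dt/γ) ξ

with friction γ = 50 kJ/mol·ps/nm² and dt = 0.001 ps by default
(k_b·dt/γ = 0.3, comfortably stable).  Solvent is implicit; "ps" is a
nominal CG time unit that is not calibrated against physical time — all
downstream statistics depend on orderings and ensembles, not absolute
rates.  One terminus is frozen at its initial position (the infinitely
stiff limit of the position restraint); the constant force acts on the
other terminus along +x.  The hot loop is numba-compiled; 10⁶ steps of
the 89-bead chain take ~10 s on one core.  Euler–Maruyama inflates
stationary variances by ≈ k·dt/(2γ_rel); the equipartition test uses a
20× smaller step so the bias sits below its 5% tolerance.

The per-replicate default is 1.5·10⁶ steps (1.5 ns nominal): unfolding
completes at ~0.13 ns, leaving ~1.4 ns of unfolded-loop sampling, which
is the same “several times the unfolding time” proportion as the
original 100 ns protocol.  The default campaign is 100 seeded
replicates.  The test suite and acceptance script run scaled-down
versions (10 replicates × 0.5 ns for the plateau; 24 replicates × 1 ns
for the campaign shape checks) chosen as the smallest ensembles whose
qualitative statistics are stable.

## The folded-state stand-in

The starting conformation is a seeded compact self-avoiding chain:
biased random growth at fixed bond length with a 0.42 nm
self-avoidance, followed by a deterministic staged minimization that
ramps the cross-link spring (50 → 15000 kJ/mol/nm²) to close the 24–55
bond at its rest length.  The ramp treats the two halves of the
enclosed loop identically, so the builder injects no directional bias
into which thiol starts nearer the disulfide (an earlier leashed-growth
construction did, measurably).  During the closure stages the
sulfur–sulfur interaction runs with a hard-wall (tiny-crossover)
parameter set so the flat softcore core cannot let sulfur beads fuse; a
final relaxation under the production Hamiltonian leaves maximum forces
below ~500 kJ/mol/nm, so dynamics can start at the full timestep.

What this stand-in does **not** emulate is the native fold: it is a
generic liquid-like globule with no β-sheet topology locking the
cysteines apart.  Two consequences matter:

* contacts sampled *inside* the globule are artifacts of the stand-in,
  so the hybrid runner arms its first-passage watch only once the chain
  has unfolded (end-to-end > 20 nm, the same boundary the analysis uses
  to define the folded prefix).  `SwapCriterion(arm_end_to_end=None)`
  restores ungated detection.
* the folded-phase distances still reproduce the right gross shape:
  63's pair-distance distribution is bimodal (short while folded, ~3 nm
  once stretched), because bimodality only needs "compact, then
  stretched".

## The hybrid MC step

The swap criterion is evaluated **inside** the integration kernel at
every step (not on saved frames): each (free thiol, disulfide sulfur)
pair is watched and the integrator returns early on the first
sub-cutoff approach.  This is strictly more accurate than post-hoc
scanning at any output stride and writes no extra trajectory data.  The
default cutoff is 0.5 nm.

Tie-breaks and policies:

* when both disulfide sulfurs are within the cutoff, the nearer one is
  the target;
* at most one exchange event is counted per trajectory (tension makes
  the reaction irreversible), and after an accepted swap the dynamics
  continue on the rewired topology without further checks;
* the optional attack-angle filter (S–S–S angle at the attacked sulfur)
  is off by default — it is a post-hoc analysis, not part of the
  headline protocol;
* under the energy criterion, a rejected proposal is re-tested at every
  subsequent step while the geometry persists, with no cooldown;
* the campaign counts exchanges **virtually** by default
  (`virtual_swaps: true`): the accepted event is recorded and detection
  stops, but the dynamics continue on the native topology.  This is the
  post-hoc counting protocol, and it keeps every downstream analysis
  (distance distributions, loop PCA, SASA groups) sampling the native
  24–55 loop for the whole run.  `run_hybrid(rewire=True)` — the
  default for direct library use — instead physically rewires the
  cross-link and continues on the product topology, which reproduces
  the extension jump that follows a real isomerization (the new, shorter
  loop frees contour length).

The Metropolis mode relaxes both the reactant and the proposed product
conformation by steepest descent (adaptive step: grow 1.2× on a
downhill move, halve and reject otherwise; converged when the largest
mobile force drops below 10 kJ/mol/nm) with only the residues within
0.5 nm of the three reactive sulfurs mobile.  All other coordinates are
bit-identical before and after — a tested contract.  The energy
compared is the mobile-subsystem energy (all terms touching at least
one mobile residue); frozen–frozen terms are constants that cancel in
ΔE, so this choice changes nothing while conditioning the arithmetic.
Acceptance is min(1, exp(−ΔE/kT)) with kT = 2.494 kJ/mol, drawn from a
dedicated stream (`SeedSequence([seed, 0x5A9])`) so dynamics and MC
decisions are independently reproducible.

## Analyses

* **Distance distributions** — per-pair densities over [0, 4] nm with a
  close-up below the cutoff.
* **Regioselectivity** — counts of accepted events per attacked sulfur;
  the ratio N55/N24 for the fixture.  The standard error resamples
  *trajectories* (one counted event each) with replacement; resamples
  with an empty denominator are redrawn and counted.  The reported SE
  is the resampling SD; note that the first-order delta linearization
  of the ratio underestimates this SD by ~25% at n = 30 because the
  ratio x/(n−x) is convex and right-skewed — the test suite pins the
  bootstrap against exact enumeration of the resample distribution
  instead.
* **Attack angles** — survival curves P(angle > θ) per target over a θ
  grid, plus their ratio.
* **Unfolding** — per-trajectory first crossing of end-to-end > 20 nm;
  fraction unfolded and the cumulative frequency curve.
* **Loop PCA** — residues 24–55, unfolded frames only (folded prefix
  discarded).  Frames are iteratively superposed on their running mean
  (Kabsch via scipy, repeat to convergence) before the covariance
  eigendecomposition; scores, spectrum and the mode-1+2 variance
  fraction are returned, and the full-mode reconstruction identity is
  tested.  Ensembles larger than `max_frames` (4000) are strided.
* **SASA** — Shrake–Rupley with 960 Fibonacci sphere points per bead,
  probe 0.14 nm, bead radius σ/2; points exactly on a neighbor's
  surface are tie-broken lexicographically so coincident beads count
  their shared surface once.  Verified against an isolated-sphere
  closed form and a Monte-Carlo surface integration.  Reactive groups
  (attacker within 0.6 nm of one disulfide sulfur) are compared by a
  two-sample KS test on samples subsampled at the autocorrelation
  zero-crossing stride — the CG analogue of "every 2 ns, where the SASA
  autocorrelation is zero".

## What the coarse-grained analogue can and cannot show

The CG campaign reproduces the *mechanical* skeleton of the phenomenon:
unfolding to a ~22.6 nm plateau (the loop-shortened contour 23·0.38 +
0.39 + 34·0.38 ≈ 22.1 nm plus bond stretch minus thermal contraction),
the confinement of 32/47 and the exile of 63, bimodal 63 distances, a
loop whose first two collective modes carry roughly half the positional
variance, and reactive-conformation compactness differences.

It does **not** reproduce the all-atom regioselectivity direction.
With one bead per residue and no sequence, the fixture has an
approximate mirror symmetry (32↔47, 24↔55) broken only by the clamp
boundary conditions: the frozen-terminus strand is transversely quiet
near 24, while the force-pulled strand swings and crowds the region
near 55, and the tails differ in length.  Measured at steady state the
model therefore mildly favors attacker 47 and target 24 — the opposite
of the experimentally confirmed 32→55 preference, which in the all-atom
system is set by side-chain packing this resolution deliberately
discards.  The campaign reports whatever the model produces; the
corresponding qualitative checks in the acceptance suite document this
divergence rather than hiding it.  No parameter was adjusted to steer
these outcomes.

## Known limitations

* Chemistry is absent by construction: no pKa, no base catalysis, no
  transition-state energetics; the Metropolis step weighs only
  classical conformational energies.
* The folded stand-in has no native topology; folded-phase observables
  (other than "compact") are not meaningful, hence the arming gate.
* Time is nominal; rates and unfolding-time distributions are
  comparable across runs of this model only.
* The per-residue homopolymer cannot encode sequence effects; all
  asymmetries trace to connectivity and boundary conditions.
* Euler–Maruyama has O(dt) sampling bias; at the default step the bond
  variance inflation is ~3% on the stiffest mode, immaterial for the
  geometric statistics used here.
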
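# Methods

`hydrosieve` models the computational side of designing a crosslinked
poly(vinyl alcohol) (PVA) hydrogel that absorbs the organophosphate
pesticide dimethoate (DMT) from water.  Four stages share one molecular
data model: a nanopore screen that ranks dicarboxylic-acid crosslinkers by
host–guest interaction energy, a builder that assembles crosslinked
polymer networks at prescribed compositions, trajectory observables that
quantify hydrogel porosity and pesticide capture, and a factorial
regression for the absorption kinetics.  This note records the models,
the parameters that matter, and the boundaries of what the package (and
its tests) can and cannot show.

## Molecular data model

A `Molecule` is an ordered list of atoms (element, Cartesian position in
Å, partial charge in elementary units, Bondi van der Waals radius, role
label) plus a bond list.  Templates for dimethoate, water, a PVA monomer
and the fourteen dicarboxylate candidates (oxalic through azelaic) are
generated once per process from curated SMILES using RDKit's ETKDGv3
embedding at a fixed seed followed by a short MMFF cleanup, so geometries
are bit-reproducible.  Partial charges are Gasteiger charges shifted to
sum exactly to the formal charge; `load_template` exposes a `charge_fn`
hook for users who prefer another scheme.  Diacid templates carry both
carboxylates deprotonated (net −2), the dominant state at the working
pH of 5.5 given a carboxyl pKa near 4.7; PVA hydroxyls (pKa ≈ 10.6) stay
protonated.  `assign_protonation` applies this two-state
Henderson–Hasselbalch rule to any molecule whose carboxyl/hydroxyl groups
are recognizable from its bond graph, moving exactly one elementary
charge per site and staying idempotent.

PVA chains are idealized all-trans zig-zags: 2n+1 sp3 backbone carbons
(a terminal methyl cap plus n two-carbon vinyl-alcohol units), C–C
1.54 Å, tetrahedral angles, one pendant hydroxyl per unit whose side
(±z) is drawn from a tacticity seed.  The chain "wall length" is measured
across the n monomer units — ≈11.3 Å for n = 5, matching the ~10 Å
maximum extent of the guest molecule that sets the target pore size.
No torsional disorder is modeled; chains are rigid objects until the
network relaxation stage.

## Nanopore screen

A nanopore is two five-monomer PVA chains bridged by two diacid linkers
through ester bonds.  Eight topologies are enumerated as the product of
attachment registers {monomers 1&5, monomers 2&4} on each chain and chain
orientation {parallel, antiparallel}; this spans wide/narrow and
symmetric/skewed cavities.  Assembly solves the chain separation so each
linker's carboxylate carbons sit exactly one ester bond (1.43 Å) from
their chain oxygens (least squares over both bridges when registers are
asymmetric), then searches deterministic discrete variables — linker spin
about the pore axis (10° grid), the choice of leaving carboxylate oxygen
at each end, a chain stagger along the chain axis, and, for short linkers
in skewed registers, an "ester bow" that moves the carboxyl carbons off
the O···O axis while preserving bond lengths — for the placement with the
most steric clearance.  The result must pass a hard-sphere audit: no atom
pair closer than 0.7× the sum of Bondi radii, excluding pairs within
three bonds and donor-H···acceptor pairs (hydrogen bonds legitimately
come that close; the malic and tartaric templates contain intramolecular
O–H···O contacts at ~0.65×).  All 112 acid × form assemblies pass.

Esterification bookkeeping: each ester bond deletes the chain hydroxyl
hydrogen and one terminal carboxylate oxygen, then bonds the chain oxygen
to the carboxyl carbon — two atoms leave per ester, the water-equivalent
of a condensation starting from a deprotonated acid.  The mass-balance
test audits exactly this convention.

The Monte-Carlo screen repeats: mass-center host and guest; draw a
Haar-uniform rotation for the guest (uniform unit quaternions, reported
as ZYZ Euler angles — independently sampled Euler angles would oversample
the poles); draw a uniform direction on the sphere; translate the guest
along it to van der Waals contact; evaluate the supermolecular
interaction energy at the frozen geometry,

    ΔE = E(complex) − [E(host) + E(guest)].

Contact is solved analytically: for each atom pair the touching condition
is a quadratic in the translation t, and the contact translation is the
maximum larger root over pairs (tolerance 1e-6 Å; verified against a
bisection line search to 1e-4 Å).  If no pair's sphere intersects the
ray, or all touching points lie behind the start, the draw fails and is
redrawn; more than 1% failures aborts the run.

Energies come from pluggable backends.  The default surrogate sums
intermolecular Lennard-Jones (UFF per-element ε, σ; geometric/arithmetic
mixing) and Coulomb (332.0637·q₁q₂/d kcal/mol) terms; isolated molecules
have E = 0, so ΔE is the intermolecular sum directly.  An adapter for an
external MOPAC-style program runs `1SCF PM7` single points when such a
program is installed; nothing in the package or tests requires it.
Consequences worth stating plainly: surrogate ΔE values are *not*
semi-empirical quantum-mechanical energies, and published per-acid
averages (malic acid best at −1.998 kcal/mol) are treated as reference
inputs for the ranking machinery, not as desk-reproducible outputs.  The
per-acid score is the unweighted mean of the eight form means; ranking
sorts ascending with alphabetical tie-break.

Default sampling is 100,000 configurations per form (the study-scale
protocol); the command-line default is 1,000 per form so that a full
14-acid × 8-form screen finishes in minutes on one core.  Monte-Carlo
standard errors scale as sd/√n, and the self-consistency test checks two
seeds agree within 3 sd/√n at n = 2,000.

## Network builder

`pack_chains` places rigid chains (default 25 chains × 25 monomers) in a
periodic box (default 70 Å cube) by rejection sampling with a ≥5 Å
inter-chain minimum-image separation.  Rigid 63 Å rods at this density
leave little room for the last few chains, so when rejection stalls the
least-bad placement is kept and a deterministic rigid-body push-apart
refinement translates chains along their violation vectors until the
constraint holds (with up to five derived-seed restarts).  An O(N²)
brute-force distance scan is the test oracle.

`build_network` then iterates the crosslinking cycle: (1) choose
uniformly at random among all eligible pairs — unused hydroxyls, on
different chains, oxygen–oxygen minimum-image distance ≤10 Å (uniformity
is chi-square-tested against exhaustive enumeration); (2) bridge them
with one diacid (both carboxylates ester-bonded in the same cycle, so
one linker = one inter-chain bridge), placing it along the O···O axis
with a clearance-maximizing spin; (3) a capped steepest-descent
relaxation.  The relaxation energy is harmonic stretches on every
covalent bond (rest lengths from construction; ester cross-bonds at
1.43 Å; k = 300 kcal/mol/Å²) plus intermolecular Lennard-Jones inside a
6 Å cutoff; angle terms are omitted because the step is a steric-relief
heuristic, not a physical observable.  Steps are backtracked until the
energy does not increase and per-atom displacement is capped at 0.5 Å,
so the energy trace is non-increasing.  Defaults at reference scale:
3 descent steps every 5 cycles; the audit (different chains, ≤10 Å at
formation, single-use) is re-checked post hoc for every link.

Composition arithmetic: a monomer:diacid ratio p:q implies
⌊n_monomers·q/p⌋ bridges — 125, 250 and 375 for the 625-monomer matrix
at 10:2, 10:4 and 10:6 (the 20/40/60 weight-percent series).  A known
limitation: 375 *doubly esterified* bridges would consume 750 hydroxyls,
more than the 625 available, so the highest composition cannot be
realized as bridges alone; in the real material part of the crosslinker
attaches singly.  Singly-attached linkers are outside this builder's
scope, and full network construction is exercised at the 10:2
composition that the absorption study selected.

## Trajectory observables

Frames are coordinate arrays over a fixed topology (per-atom element,
role ∈ {hydrogel, DMT, water}, molecule id, bonds), stored as multi-model
PDB plus a JSON sidecar.  Observables:

* **SASA** — Shrake–Rupley with a deterministic Fibonacci-lattice point
  set (default 960 points/atom, probe 1.4 Å).  Exact for an isolated
  sphere; within 2% of a 10,000-point oracle for overlapping pairs.
  Because the lattice is lab-fixed, SASA is rotation-invariant only to
  its quadrature resolution (≈0.5% at 960 points); all other observables
  are exactly invariant under rigid motions.
* **RGYR** — mass-weighted RMS distance to the center of mass.
* **Water shell** — waters whose oxygen is within 3.0 Å of any hydrogel
  heavy atom OR inside a sphere around the hydrogel center of mass
  (radius defaulting to the frame's RGYR); the union is the default
  reading of the two criteria, both arms are parameters.
* **Capture** — a guest molecule is captured when any of its atoms is
  within 4.5 Å (minimum image) of any hydrogel atom; reported as a
  percentage, with the first time 100% is reached recorded.  "Hydrogel"
  means all hydrogel atoms — the conservative superset reading of
  "backbone".
* **Hydrogen bonds** — geometric criterion: donor–acceptor ≤3.0 Å
  (3.5 Å for sulfur acceptors, which matters because the guest's
  thiophosphoryl sulfur is a genuine acceptor), D–H···A within 30° of
  linear.  These thresholds are the common visualization-tool defaults;
  the source protocol did not state its own.

Periodic minimum-image distances are used for water/capture/hbond
criteria; SASA and RGYR treat the selection as whole.  Brute-force
double-loop implementations of every criterion serve as test oracles on
small frames.

## Factorial absorption model

The retention percentage of the pesticide after contact with the
hydrogel is modeled as

    retention% = b0 + b1·A + b2·B + b3·A·B + ε,

with A the coded contact time and B the coded hydrogel mass.  The
reference design ships with the package: a 2² factorial (10–90 min,
34.2–101.3 mg) plus three replicated center points, seven runs in all,
with the *printed* coded levels used verbatim — including the center
points' small nonzero B codes (−0.228 to −0.065), which is what
reproduces the published fit.  `FactorialModel.fit()` performs OLS (via
statsmodels) and returns a results object carrying coefficients,
standard errors, t statistics, the residual degrees of freedom
(n − 4 = 3), R² on the percent scale, and a `summary()` table.  On the
reference design the fit gives b = (98.6, 2.66, 2.53, −2.70) and
R² = 84.36% — time and mass help retention, their interaction hurts it —
and no |t| (max 2.37) reaches the two-sided 95% Student-t critical value
of 3.18, so no effect is statistically significant at this sample size.
The standardized-effects table is exactly a Pareto chart's content;
`response_surface` evaluates the model on a coded [−1,1]² grid and
reports the grid argmax without asserting where the optimum "should" be
(with these coefficients the corner values are nearly tied, and the
(+1,−1) corner edges out (+1,+1) numerically).  Absorbance arithmetic is
`absorption% = 100·(A₀ − A)/A₀` at the guest's 280 nm absorption maximum.

Coding utilities map natural units to [−1, 1] and back exactly;
`recover_coding` retrieves (center, half-range) from printed
(value, code) pairs by least squares — (67.77 mg, 33.56 mg) for the mass
factor of the reference design.

## Synthetic data

The generators exist so every analysis stage can be tested against known
ground truth with no external data:

* **Planted trajectories** — frames over a real (toy-scale) crosslinked
  network in which per-frame capture percentages, hydrogen-bond counts
  and bound-water counts follow prescribed schedules.  Captured guests
  get one atom placed 3.2–3.9 Å from the network (safely inside the
  4.5 Å criterion), free guests sit ≥2× the cutoff away plus margin;
  hydrogen bonds are planted as collinear O–H···S geometries at 2.8 Å on
  distinct donors; waters are split between the center-of-mass sphere
  and the far field with a 2.4 Å O–O minimum.  Each frame is verified
  against the actual analysis criteria and redrawn on the rare accidental
  contact, so recovery is exact by construction — which is precisely what
  the round-trip tests assert.
* **Water boxes** — rigid three-site waters (0.9572 Å, 104.52°, TIP3P-like
  geometry without any claim about its energetics) with no O–O pair
  under 2.4 Å.
* **Noisy factorial designs** — responses from known coefficients plus
  Gaussian noise, for estimator bias and interval-coverage checks.

What passing these tests shows: the observables implement their stated
geometric criteria exactly, and the regression machinery recovers known
signals.  What they do not show: agreement with any real solvated-MD
ensemble — synthetic frames have no thermal motion, no realistic water
structure, and guest placements are geometric, not Boltzmann-weighted.

## Problem sizes and determinism

Reference-scale runs used throughout the package's own checks: 25×25
chain packing with brute-force verification (~10 s), a 125-bridge 10:2
network with capped relaxation (~30 s), 2,000-sample Monte-Carlo screens
per pore, and 112-assembly sweeps (~4 s) — all single-core.  Every
stochastic routine takes an explicit seed and is reproducible to the
byte at fixed seed; the only intentional nondeterminism-like effect is
the SASA quadrature orientation dependence noted above.

## Known limitations

* Surrogate energies are classical pairwise terms; they rank and test
  the sampling machinery but are not substitutes for semi-empirical
  single points, and absolute screening averages are backend-dependent.
* Template geometries are idealized embeddings, not the (unpublished)
  DFT-optimized structures behind the reference energy table.
* Chains are rigid at assembly time; conformational disorder enters only
  through the capped relaxation.
* The network builder makes doubly-esterified bridges only (see the
  10:6 note above).
* The hydrogen-bond thresholds and the water-count union rule are
  documented choices where the source protocol was silent; both are
  parameters.
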
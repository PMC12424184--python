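# Methods

## Equilibrium model

The network contains six species — free `A`, `B`, `L`, binary `AL`, `BL`,
and ternary `ALB` — linked by two binary dissociation constants and the
cooperativity α (dimensionless, "of the ligand": α = K_AL/K_A–BL =
[ALB][L]/([AL][BL])).  Free proteins are assumed noninteracting, so no `AB`
species enters the mass balance; intrinsic protein–protein affinity enters
only through the free-energy layer (reduced cooperativity).  Note the two
published conventions for α differ by inversion; this package uses the one
consistent with K₃ = K_AL·K_BL/α, under which α > 1 is positive
cooperativity.

Given the free ligand `[L]`, `[ALB]` follows from a quadratic whose root is
evaluated in product form, `2·A_tot·B_tot/(C + √(C²−4·A_tot·B_tot))`, to
avoid cancellation when `C` is large (weak effective binding).  `[L]` itself
solves the ligand-conservation equation, which is strictly monotone in
`[L]`; the solver brackets on `(0, L_tot]` and runs Brent's method on
`ln [L]` so that nM–mM dynamic ranges pose no bracketing risk.  Totals of
zero short-circuit to the exact binary isotherm or trivial solution instead
of entering the root solve.

Numerical contracts: free-ligand relative tolerance 1e-10 (default);
mass-balance and equilibrium-relation residuals are reported on every state
and are ≤ 1e-8 for converged solves; the quadratic discriminant is clipped
to zero when within 1e-12 relative (rounding near complete sequestration).
Equivalence with an independent simultaneous solve of the full six-species
network (damped fixed point + Newton in log-monomer space) holds to ≤ 1e-6
relative on every species over the tested parameter box (K ∈ [1 nM, 1 mM],
α ∈ [0.01, 1000], totals ∈ [10 nM, 100 μM]).

### Dose–response quantities

`f₃ = [ALB]/min(A_tot, B_tot, L_tot)`.  A subtlety worth documenting: in
strong-binding regimes (`A_tot/K_AL > 1`) f₃ does *not* vanish at low dose —
as `L_tot → 0` it tends to the probability that a ligand molecule carries
both proteins, `(α·A·B/K_AL·K_BL)/(1 + A/K_AL + B/K_BL + α·A·B/K_AL·K_BL)`,
which is ≈ 0.69 for K = 0.2 μM, totals 1 μM, α = 1.  The *peak* of the dose
response is therefore defined on `[ALB]`, which is maximised exactly at
`[L]opt = √(K_AL·K_BL)` (where the ligand-bound fractions of the two
proteins sum to one, making the closed-form optimal dose exact) and at the
α-independent `[L_tot]opt`.  `hook_severity` quantifies the post-peak
decline as `1 − f₃(10·L_tot_peak)/f₃_peak` with the peak located on `[ALB]`
and the post-peak value log-interpolated; the numeric argmax used to verify
the closed forms is conditioning-limited to ~1e-4 relative when protein
totals dominate the binding polynomial (the peak flattens), which sets the
verification tolerance.

## Free-energy layer

Thermal energy uses k_B = 0.0083145 kJ/mol/K with default T = 298 K
(k_B·T ≈ 2.478 kJ/mol); the standard concentration c₀ is fixed at 1 M, and
all conversions (`ΔG_α = −k_B·T·ln α`, `K = c₀·e^{βΔG}`) are exact inverses.
Where reduced cooperativity mixes φ with K_A–B (K₃ = φ⁻¹·K_A–B·K_AL·K_BL),
K_A–B is divided by c₀ so K₃ keeps units M²; φ itself is dimensionless.

The decomposition ledger carries the four contributions to ΔG_α — induced
PPIs, cooperative solvation, gas-phase correlation, net geometric cost —
and closes by construction; the two-term approximation (induced PPIs +
cooperative solvation) differs by exactly the dropped terms, reported as the
gap.  Geometric confinement costs are constrained non-negative (free
ensembles are at least as favourable as stabilized ones).  Perturbation
classification (nonperturbative / noncooperative / binary-perturbative /
unary-perturbative) uses a tie tolerance of 0.1 kJ/mol — well below thermal
noise, well above rounding — with nonperturbative taking precedence (all
geometric costs below tolerance), then noncooperative (vanishing induced
PPIs).

### Apparent cooperativity

The EC50 shift is simulated on protein A's ligand-bound fraction
`(AL+ALB)/A_tot` — the asymmetric convention in which B is the partner held
at a saturating concentration (a warning is issued below 10× K_BL).  The
EC50 is the dose at which the bound fraction crosses half its plateau,
located by monotone interpolation on log-dose; the plateau must have
flattened to within 1% over the top decade of the grid, otherwise an
insufficient-range error is raised.  The ratio EC50(binary)/EC50(ternary)
equals 1 for α = 1 (to grid tolerance) and approaches α from below when the
monitored protein is dilute; ligand depletion by A near the shifted EC50
biases the ratio low — a genuine property of the measurement, not of the
solver (e.g. α = 100 reads as ≈ 67 with A_tot = 10 nM, K = 1 μM, B at
100 μM).

## Frame-energy estimator

All seven subsystem energies are evaluated on ternary-trajectory frames
(single-trajectory approximation); the table schema enforces exactly one row
per subsystem per frame, and incomplete frames are rejected rather than
imputed (silent imputation biases means).  Entropy contributions are
neglected.  Because frames within a trajectory are autocorrelated, replicate
means are the statistical unit: the SEM is the sample standard deviation of
per-replicate means over √N, and a single replicate yields an undefined
(NaN) SEM with a warning.  Energies default to kJ/mol; kcal/mol input is
converted with the factor 4.184 exactly.

Kendall τ between predicted and experimental cooperative free energies is
computed by explicit pair counting with the standard tie adjustment (τ-b);
ordinary least-squares fits are reported in both orientations
(experimental-on-predicted and the reverse) since either axis convention
appears in practice, and the experimental α kind (absolute vs apparent) is
carried through so users can filter.

## Synthetic data

The generator emulates MM/PBSA-style per-frame tables with known ground
truth.  Subsystem baselines are drawn once per complex in [−2000, −500]
kJ/mol (typical magnitudes for solvated protein systems; the exact range is
arbitrary and cancels in both estimators).  The induced-PPI truth is split
60/40 between a gas-phase A–B interaction and AB desolvation; compound
solvation energies are assembled additively from per-frame unary primitives
and interface terms, so in additive mode the cooperative-solvation
combination cancels on every frame to float rounding (≲ 1e-12 kJ/mol against
~10³ kJ/mol baselines) regardless of noise.  Frame noise (default σ = 5
kJ/mol) is applied per estimator channel — so the per-frame estimate
fluctuates with exactly the stated σ — and independently to the unary
primitives, where it cancels; replicate offsets (default σ = 2 kJ/mol) are
drawn before any frame noise so that changing the frame count never
reshuffles the replicate structure.  Defaults mirror the production
conditions the estimator targets: 10 replicates × 2000 frames (10 ns
sampled every 5 ps).

What the generator does *not* emulate: force-field-specific energy
distributions, intra-trajectory autocorrelation beyond a per-replicate mean
offset, conformational transitions between binary and ternary binding
poses, or explicit-water effects (e.g. water-mediated interface hydrogen
bonds).  Passing recovery tests therefore demonstrates the correctness of
the estimator arithmetic and statistics, not the accuracy of MM/PBSA
energies on real complexes.

The benchmark-panel generator draws ground-truth cooperative free energies
log-uniformly over an α range (default 0.1–100), assigns 0–20% of each to
cooperative solvation, and emits matched experimental α values, optionally
perturbed by lognormal measurement noise; with all noise terms zero the
estimate/compare pipeline returns τ = 1 exactly.

## Interfaces and determinism

Concentrations are molar internally; the CLI accepts suffixed quantities
(pM/nM/uM/µM/mM/M, kJ/mol, kcal/mol).  CSV output uses 17 significant
digits and the readers parse with round-trip float precision, so
write→read is bit-exact.  All randomness is owned by the synthetic
generators and is a pure function of the seed; compute subcommands take no
seed by design.  Outputs are written atomically with a JSON provenance
sidecar (tool version, subcommand, parameters, seed).

## Known limitations

- The equilibrium model excludes a free `AB` species; systems with strong
  intrinsic PPIs (PPI stabilizers proper) violate this assumption at the
  mass-balance level.
- Geometric costs are user inputs; the package does not estimate stabilized
  geometric spaces from structures.
- Near-complete sequestration (free species ~1e-10 of totals) erodes the
  relative accuracy of the smallest species to roughly the 1e-7 level —
  inherent to double precision, shared by any solver of this network.
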
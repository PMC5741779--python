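# Methods

## Model

catfield implements the electrostatic leading term of differential
transition-state stabilization (DTSS). A reaction is represented by two
rigid structures — the substrate-state well S and the transition state TS —
superimposed into one frame, each carrying atom-centered electrostatic
parameters. The environment's effect on the activation barrier is the
difference of its electrostatic interaction with the two states:

    Δ = Σ_i q_i (V^TS(r_i) − V^S(r_i)),        Δs(r) = −(V^TS(r) − V^S(r)),

with Δ in kcal mol⁻¹ (negative = catalysis), q_i in e, and the potentials
in kcal mol⁻¹ e⁻¹. Δs is the barrier lowering per unit positive charge; Δ
is exactly additive over environment charges because electrostatics is
linear in the sources. Everything downstream (surface maps, substituent
ranking, the linear substituent model) is bookkeeping on these two
equations.

Assumptions worth keeping in mind:

- vacuum electrostatics — no dielectric screening, polarization,
  charge penetration or exchange effects;
- frozen geometries and frozen charge distributions for both states;
- for substituent prediction, the substituent is reduced to a net point
  charge near the old C–H axis, so mesomeric/resonance redistribution in
  conjugated systems is outside the model.

## Electrostatic potential

The MEP is an atom-centered multipole expansion truncated at quadrupoles.
With R the atom→point vector in bohr,

    V = Σ_a [ q_a/R + (μ_a·R)/R³ + Σ_ij Θ_a,ij (3 R_i R_j − R² δ_ij) / (2 R⁵) ],

converted with 1 hartree e⁻¹ = 627.509474 kcal mol⁻¹ e⁻¹ and
1 Å = 1.8897259886 bohr (the Å-per-bohr constant is the exact reciprocal, so
unit round-trips are lossless). Units: q in e, μ in e·bohr, Θ in e·bohr².

**Quadrupole convention.** Θ is the *detraced Cartesian second moment*,
Θ_ij = Σ q (x_i x_j − r² δ_ij/3). Under this normalization the formula
above is exact; tensors normalized as (3xx − r²)/2 must be scaled by 2/3 on
import. Tables with a residual trace are detraced on load (with a warning
above 1e-8) rather than rejected, since QM codes disagree about the
convention. The whole-molecule moment diagnostic (`molecular_moments`) uses
the matching origin-shift formulas.

Numerical guards: evaluation points closer than 0.3 bohr to any expansion
center raise a `ProximityError` naming the atom — the series diverges at
centers, and failing loudly beats returning garbage. The truncation order
is a parameter (default: the multipole set's own order, at most 2);
quadrupole truncation is adequate at the ≥1.5 Å probe offsets used here,
and the order-1 vs order-2 difference at a probe is an easy diagnostic for
doubtful geometries.

## Superposition

TS coordinates are aligned onto the substrate frame by least squares over
an explicit atom pairing (Kabsch). The pairing should cover the conserved
skeleton only — the geometries differ most near the reacting bond, and
including reacting atoms biases the frame. At least three non-collinear
reference atoms are required; the reflection branch of the SVD is corrected
so the rotation is always proper. The minimized RMSD is recomputed from the
transformed coordinates rather than taken from the solver, whose residual
formula loses ~1e-7 Å to cancellation at zero residual. The substrate frame
is the reporting frame throughout: probes are defined once, on the
substrate geometry, and serve both potentials.

## Probes

*Bond-directed* probes model substitution sites: for each candidate
hydrogen (which must have exactly one heavy neighbor within 1.3 Å) the
probe sits at r_H + d·û with û the heavy-atom→H unit vector and d = 1.5 Å
by default. The bond direction is a modeling choice — it is where a
substituent's charge center roughly sits; a fixed-offset-vector variant can
be had by constructing `ProbePoint`s directly.

*Surface* probes sample the solvent-accessible surface: each atom's sphere
of radius r_vdW + r_probe (Bondi radii; r_probe = 1.4 Å, water) is covered
by a deterministic Fibonacci lattice with ≈ density·4πr² points, and points
inside any other atom's enlarged sphere (tolerance 1e-6 Å) are discarded.
Buried atoms therefore contribute no points. The lattice is deterministic,
so surface maps are reproducible without a seed.

## Substituent model

Observed barrier changes Δ (from explicit QM recomputation of substituted
paths, supplied as a table) are regressed on Δs at the site probes by OLS,
intercept included by default — the intercept absorbs systematic
non-electrostatic offsets; the no-intercept variant is one flag away. The
reported `residual_sd` is sqrt(SSR/(n − p)). A saturated fit (zero residual
degrees of freedom) reports SD 0 with a warning. Sites whose hydrogen lies
within 3.0 Å (strict inequality, so cutoff 0 flags nothing) of a declared
reacting atom are flagged `near_reaction` and excluded from the fit by
default while still receiving predictions: at such sites the substituent
participates in the reaction itself and the point-potential picture is
expected to fail.

Ranking derives its sign from the consistency identity Δ = −q·Δs rather
than a hardcoded rule: for a substituent of net charge q (default −1 e,
appropriate for H→F), the predicted contribution is −q·Δs and sites are
ordered ascending for objective "lower" (ties by site index). Choosing the
identity over any per-case sign table keeps the ranking consistent with the
Δ machinery by construction.

## Synthetic fixtures

The generators define the test conditions:

- `make_proton_shift_pair` — an abstract proton transfer: −0.5 e anchors at
  x = 0 and x = s (s = 2.5 Å default), a +1 e proton at s/4 moved by
  `shift` toward the acceptor in the TS. The s/4 start makes
  shift = s/2 an exactly mirror-symmetric pair (Δs = 0 on the bisector
  plane, an analytic check). Point charges only, so every potential is a
  hand-summable Coulomb sum.
- `make_random_multipole_cloud` — n atoms ≥1.2 Å apart in a 6 Å box;
  charges N(0, 0.3 e) shifted to exact neutrality; dipoles N(0, 0.1 e·bohr);
  quadrupoles symmetrized, detraced N(0, 0.05 e·bohr²). Exercises the
  order-1/2 paths separately from the field logic.
- `make_linear_dataset` — Δs ~ U(−10, 10) kcal mol⁻¹ e⁻¹, Δ = 0.15·Δs +
  0.5 + N(0, 1) by default, n = 50: a substituent series whose ground truth
  is known exactly.

These fixtures emulate the *structure* of real reactant pairs (paired
states, neutral systems, multipole orders, linear Δ–Δs response with
scatter) but not real chemistry: no bonding topology, no conjugation, no
QM-derived charge sets. Passing tests demonstrate that the machinery
computes its defining quantities exactly and recovers known parameters —
not that a particular reaction's substituent effects are reproduced, which
additionally depends on the quality of the input geometries and multipole
tables.

## Verification choices and problem sizes

The acceptance script and test suite use deliberately small, fast systems:
5–6-atom clouds, 100 random systems for the expansion-vs-cluster check
(evaluation at 20 bohr, finite-charge realizations with δ = 0.01 bohr so
the cluster's spurious higher moments are O(δ²)), 10-atom superposition
problems with σ = 0.05 Å coordinate noise, 50-site regression designs with
200 replicates for CI coverage. The independent oracles are: plain-loop
Coulomb sums; symmetric finite-charge realizations of dipoles/quadrupoles;
a rotation-sampling search (random sweep + shrinking perturbations, no SVD)
for the minimum RMSD; and closed-form normal equations for OLS.

## Known limitations

- No mesomeric or polarization corrections: conjugated systems can deviate
  qualitatively at individual sites.
- Single shared TS per pair; reverse reactions need their own pair built
  from the opposite well (sign-flipping the forward field is only valid
  when both wells share one TS geometry).
- The CSV multipole dialect is the only charge input; users convert QM
  output themselves, and the package is agnostic about which charge model
  produced it.
- PDB output abuses the B-factor column (clamped to ±999.99) for Δs; cube
  output requires values on a declared regular grid.
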
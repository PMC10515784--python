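# Methods

## Model

The double helix is coarse-grained to one degree of freedom per base
pair: the transverse hydrogen-bond stretching `y_n` (Å), related to the
per-strand displacements by `y_n = (u_n − v_n)/√2`. The potential energy
is the EPBD form: an on-site Morse well `V(y) = D(e^{−ay} − 1)²` per base
pair plus an anharmonic stacking coupling
`W(y_n, y_{n−1}) = (k/2)(1 + ρ e^{−b(y_n+y_{n−1})})(y_n − y_{n−1})²`
between neighbours. `D` and `a` depend only on the base-pair class (A·T
or G·C); `k` is keyed by the ordered dinucleotide step, with an optional
10-class canonicalization under reverse-complement symmetry. Because the
common strand mode `(u + v)/√2` carries no potential energy, the code
works in `y` throughout and treats `u, v` as an optional bookkeeping
layer; a per-strand Gaussian proposal of width σ is exactly a `y`
proposal of width σ/√2.

The chain is open (N−1 stacking terms); periodic boundaries are available
behind a switch and are used in tests of translational symmetry. The
Morse potential plateaus at `D`, so the unbounded partition function
diverges; sampling is therefore restricted to a hard domain, default
`[−2, +20]` Å, with proposals outside rejected. All quadrature oracles
integrate over exactly the same bounds, so sampler-vs-oracle comparisons
involve no truncation mismatch. A corollary worth keeping in mind: on
this bounded domain an *isolated* base pair at 310 K is mostly open (the
plateau dominates the partition function); it is the stacking coupling in
a chain that keeps DNA closed at physiological temperature.

## Parameters

The default file (`src/epbdsim/data/default_params.yaml`) carries the
melting-fit constants D_AT = 0.05 eV, a_AT = 4.2 Å⁻¹, D_GC = 0.075 eV,
a_GC = 6.9 Å⁻¹, ρ = 2, b = 0.35 Å⁻¹, k = 0.025 eV/Å² (Campa–Giansanti
parameterization). The stacking table is structurally per-dinucleotide
but uniform by default; we deliberately did not invent a heterogeneous
table, and users with a melting-derived sequence-specific table can drop
it into the YAML file. Every test and observable holds for any valid
parameter set; only the physical-ordering checks additionally assume
D_AT < D_GC, which any melting-derived set satisfies. kB is
8.617333262×10⁻⁵ eV/K.

## Sampling

One Metropolis proposal perturbs one randomly chosen coordinate by a
zero-mean Gaussian; the kernel is symmetric, so plain Metropolis is
exact. A "step" is either a sweep of N single-site attempts (default, so
schedules transfer across lengths) or a single attempt. `proposal_sigma
= "auto"` sets the per-site width to `2·sqrt(kB T / (2 D_n a_n²))` —
twice the thermal width of the local harmonic approximation. The factor
2 is a fixed calibration: it keeps the acceptance rate near 0.65 (inside
the 0.2–0.7 band that random-walk Metropolis practice targets) and, more
importantly, lets an open base pair diffuse across the ~22 Å plateau in
~10⁴ proposals, so burn-in budgets of 10⁴–10⁵ steps genuinely reach the
equilibrium exchange between closed and open states.

Runs start from `y = 0` (an option draws initial displacements uniformly
in [0, 0.1] Å); the M runs differ by independently seeded streams, which
supplies the run-to-run variability that the error bars measure.
Equilibration is not tested for — the preheat budget is trusted — but
the running energy is maintained from the exact per-move deltas and can
be checked against a from-scratch recomputation at any time.

Randomness: each run i uses `SeedSequence(base_seed, spawn_key=(i,))`
feeding PCG64, with variates generated in fixed-size blocks, so an
ensemble is reproducible bit-for-bit and run i's stream is independent
of M and of execution order. The hot loop is a numba kernel; a readable
pure-Python twin (`mcmc_step`) is cross-validated against it in the
tests. Measurement executes exactly `⌊measure_steps/record_interval⌋`
recording intervals; a trailing partial interval would never be recorded
and is not run.

## Observables

Averages are computed per run first, then across the M runs; quoted
standard errors are the run-to-run SE, which absorbs within-run
autocorrelation honestly (no autocorrelation-corrected single-run errors
are attempted). Threshold exceedance is strict (`y > thr`); ties are
closed — a measure-zero convention fixed for determinism.

The bubble tensor uses the inclusive-window convention: P(n, l, thr) is
the probability that *all* `l` base pairs starting at `n` exceed `thr`
at a recorded time, i.e. the time average of the accumulated bubble
durations with time counted in recorded snapshots (openings are only
observed at recording times). This convention makes P non-increasing in
`l` and `thr` and makes the `l = 1` slice identically the flipping
profile — both checked exactly in the tests. A maximal-run variant
(bubble flanked by closed base pairs or chain ends) is available behind
a flag for users who want bubbles of an exact length; it sacrifices
those two laws. Windows running past an open chain end are reported as
undefined (NaN, omitted from text output).

## Dynamic length

Per-run flipping profiles (default threshold 1.0 Å) of the two alleles
are compared position by position with a Welch unequal-variance t-test
on the M per-run values; p-values are converted to q-values either by
Benjamini–Hochberg step-up (via statsmodels) or by Storey rescaling with
the λ = 0.5 null-proportion estimator (falling back to BH below 20
tests). The dynamic length is the count of positions with q ≤ α
(default 0.05); the longest contiguous significant block is reported as
a secondary summary. Positions where both groups are exactly constant
get p = 1 when the constants agree and p = 0 when they differ.

The 1.0 Å default for the *comparison* threshold (the bubble tensor's
headline threshold remains 1.5 Å) is a deliberate choice: at 1.5 Å the
per-run fractions are dominated by rare, long-lived large-amplitude
bubble episodes and are heavy-tailed across runs, which wastes the
t-test's power; at 1.0 Å the statistic is continuous and well behaved
while still measuring hydrogen-bond disruption. Only equal-length
substitution alleles are compared; indel alignment is out of scope.

The CLI `compare` command runs both alleles with the same seed stream
(common random numbers): identical inputs then give a dynamic length of
exactly zero, and paired noise partially cancels. Null-calibration
studies should instead seed the two ensembles independently, as the test
suite and acceptance script do.

## Oracles and numerical checks

For one base pair, Boltzmann expectations are adaptive quadratures
(`scipy.integrate.quad`) split at the well mouth and at thresholds; for
two coupled base pairs, tensor-product Gauss–Legendre quadrature with
1200 nodes per dimension, laid out piecewise (half the nodes below
1.5 Å) so the ~0.1 Å well is resolved inside the 22 Å domain; the
indicator observable for joint opening is integrated on its exact
subdomain rather than through its discontinuity. Self-convergence under
refinement is at machine level (~1e−14 relative). Sampler-vs-oracle
agreement is asserted at 3 run-to-run standard errors.

Energy bookkeeping: `delta_energy` touches only the local Morse term and
the ≤2 adjacent stacking terms and is compared against full
recomputation at 1e−10 relative to the *larger* of the two total
energies — a move off the steep repulsive wall (~10¹⁰ eV for G·C at
−2 Å) makes the recomputed difference itself cancel catastrophically
while the local delta stays exact.

## Synthetic data and study sizes

The fixture generator supplies homopolymer A·T and G·C tracts, a
promoter-like sequence (AT-rich core, GC-richer flanks, deterministic in
its seed) and a wild/mutant pair differing by a class-swapping
substitution at two adjacent same-class positions near the centre — the
substitution swaps A·T ↔ G·C so it perturbs the Morse wells under any
parameter set (a substitution that preserves pair class only acts
through a heterogeneous stacking table, which the default file does not
carry). These sequences emulate composition and architecture, not real
promoter motifs, TF sites, methylation or salt effects; passing tests
demonstrate correctness of the sampler and statistics under the model,
not biological predictions for any real locus.

Default schedules mirror common practice for this model (310 K, 50,000
preheat and 80,000 measurement steps, M = 100 runs). The test suite and
acceptance script run desk-scale versions chosen for statistical
resolution at interactive cost: 1–2 bp oracle checks use M = 20 runs of
20,000 sweeps after 200,000 preheat sweeps (burn-in ≫ the plateau
diffusion time, so initialization bias is far below the run-to-run SE);
temperature/composition orderings use 30-mers with M = 20 × 20,000
sweeps; the perturbation-recovery study uses a 60-mer with M = 25 ×
15,000 sweeps; the null-FDR study uses 20 replicate comparisons of
M = 20 × 1,500-sweep ensembles (test calibration holds at any run length
because run means are i.i.d. across runs).

## Known limitations

No helicoidal/torsional degrees of freedom, salt or solvent corrections,
or kinetic (Langevin) dynamics — observables are equilibrium
time-averages in MCMC "time". Bubble lifetimes in physical units are out
of scope. Error bars are run-to-run only. Whole-genome tiling is left to
the user; the package treats one sequence (50–1000 bp is the intended
range) per invocation.
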
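# epbdsim

Sequence-resolved simulation of **DNA breathing** — the spontaneous,
thermally driven transient opening of the double helix — under the
Extended Peyrard–Bishop–Dauxois (EPBD) mesoscopic model, for researchers
studying how local opening dynamics at promoters, transcription-factor
sites and SNPs relate to function.

## The model

Each base pair `n` of a sequence is reduced to one transverse coordinate
`y_n` (Å), the stretching of its hydrogen bonds. The energy of a
configuration `y = (y_1 … y_N)` is

```
E(y) = Σ_n  D_n (e^{−a_n y_n} − 1)²                     (Morse wells)
     + Σ_n (k_n/2)(1 + ρ e^{−b(y_n + y_{n−1})})(y_n − y_{n−1})²   (stacking)
```

with `D_n, a_n` set by the base-pair class (A·T vs G·C) and `k_n` by the
dinucleotide step. The anharmonic stacking (ρ, b) weakens once both
neighbours are displaced, producing cooperative melting and long-lived
bubbles. Equilibrium configurations at temperature `T` are sampled with a
Metropolis Monte Carlo random walk (single-site Gaussian proposals,
acceptance `min(1, e^{−ΔE/k_B T})`) on the hard-bounded domain
`y ∈ [−2, 20]` Å, with a preheating phase followed by a measurement phase
recorded every Δt steps, repeated over M independently seeded runs.

From the sampled ensemble the package computes:

* the **average-coordinate profile** ⟨y_n⟩;
* the **base-flipping probability** P(y_n > thr);
* the **bubble-probability tensor** P(n, l, thr): probability that the
  `l` base pairs starting at `n` are simultaneously open beyond `thr`;
* the **dynamic length** between two alleles: per-position Welch tests on
  per-run flipping profiles, FDR-adjusted into a q-value ("q-factor")
  profile; the dynamic length is the number of positions with q ≤ α.

Exact Boltzmann quadratures for 1- and 2-bp systems serve as independent
oracles validating the sampler.

## Worked example

Comparing a promoter-like 60-mer against a mutant carrying a
class-swapping dinucleotide substitution at positions 29–30
(`examples/allele_comparison.py`):

```sh
$ python examples/allele_comparison.py
substituted positions: [29, 30]
dynamic length: 3 of 60 positions (alpha = 0.05, method = storey)
significant positions: [28, 29, 30]
longest contiguous block: 3
```

The two substituted base pairs plus one stacking-coupled neighbour breathe
significantly differently at FDR 5% — the mutation's dynamic footprint.
The other scripts in `examples/` print an opening/flipping profile, the
decay of bubble probability with bubble length, and the sampler-vs-
quadrature validation for a single base pair, e.g.

```
<y>      MCMC 8.813 ± 0.378 Å   quadrature 9.070 Å
P(y>1.5) MCMC 0.832 ± 0.016     quadrature 0.838
```

A thin CLI wraps the same library:

```sh
epbdsim simulate --fasta promoter.fa --runs 100 --seed 0 --out-dir out/
epbdsim compare --fasta-a wild.fa --fasta-b mutant.fa --runs 50 --seed 0 --out-dir cmp/
epbdsim oracle --pair-class AT --temp 310
```

Every run writes a manifest (schedule, seeds, checksums) from which the
outputs are reproducible bit-for-bit.

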
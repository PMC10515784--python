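"""Dynamic length: breathing footprint of a central dinucleotide SNP.

Builds a wild/mutant promoter-like pair differing at two adjacent central
positions, samples both alleles, and tests position by position whether
the flipping profile changed (Welch t-test across runs, q-values for FDR
control).  The dynamic length is the number of base pairs whose breathing
changed significantly — typically the substituted sites plus stacking-
coupled neighbours.
"""

import epbdsim as E

wild, mutant = E.generate_fixture("snp_pair", 60, seed=4)
params = E.EPBDParameters.default()
schedule = E.MCMCSchedule(
    temperature=310.0, preheat_steps=3000, measure_steps=15_000,
    record_interval=10, n_runs=50, base_seed=0,
)

ens_w = E.run_ensemble(wild, params, schedule)
ens_m = E.run_ensemble(mutant, params, schedule)
result = E.compute_dynamic_length(
    E.ProfileSampleSet.from_ensemble(ens_w, thr=1.0, label="wild"),
    E.ProfileSampleSet.from_ensemble(ens_m, thr=1.0, label="mutant"),
    alpha=0.05,
)

diff = [i + 1 for i in range(60) if wild.bases[i] != mutant.bases[i]]
print(f"substituted positions: {diff}")
print(f"dynamic length: {result.dynamic_length} of 60 positions "
      f"(alpha = {result.alpha}, method = {result.method})")
print(f"significant positions: {sorted(result.significant_positions)}")
print(f"longest contiguous block: {result.longest_block}")
print(
    "\nEach significant position breathes differently between the alleles "
    "at FDR 5%;\nthe footprint can extend past the substituted sites because "
    "stacking couples neighbours."
)
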
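"""Average opening and base-flipping profiles of a promoter-like 60-mer.

Samples an equilibrium ensemble at 310 K and prints, for a window around
the AT-rich core, the mean hydrogen-bond stretching <y_n> (Å) and the
probability that each base pair is open beyond 1.5 Å.  Soft A·T tracts
breathe visibly more than their GC-richer flanks.
"""

import epbdsim as E

seq = E.generate_fixture("promoter_like", 60, seed=5)
params = E.EPBDParameters.default()
schedule = E.MCMCSchedule(
    temperature=310.0, preheat_steps=3000, measure_steps=15_000,
    record_interval=10, n_runs=10, base_seed=0,
)

ensemble = E.run_ensemble(seq, params, schedule)
avg = E.average_coordinates(ensemble)
flip = E.flipping_probability(ensemble, thr=1.5)

print(f"sequence ({len(seq)} bp): {seq.bases}")
print(f"{'pos':>4} {'base':>4} {'<y> (A)':>10} {'P(y>1.5)':>10}")
for i in range(20, 40):
    print(f"{i + 1:>4} {seq.bases[i]:>4} {avg.values[i]:>10.4f} {flip.values[i]:>10.4f}")
print(
    "\n<y> is the thermal average stretching of each base pair's hydrogen "
    "bonds;\nP(y>1.5) is the fraction of time the pair is open beyond 1.5 Å "
    "(base flipping)."
)
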
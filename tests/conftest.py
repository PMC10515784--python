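import numpy as np
import pytest

import epbdsim as E


@pytest.fixture(scope="session")
def params():
    return E.EPBDParameters.default()


@pytest.fixture(scope="session")
def small_ensemble(params):
    """A quick promoter-like 20-mer ensemble shared by observable tests."""
    seq = E.generate_fixture("promoter_like", 20, seed=1)
    sched = E.MCMCSchedule(
        preheat_steps=500, measure_steps=2000, record_interval=10, n_runs=4, base_seed=42
    )
    return E.run_ensemble(seq, params, sched)


def make_fake_ensemble(snapshot_stacks, params=None):
    """Ensemble with hand-written snapshots, for exact observable checks.

    ``snapshot_stacks`` is a list of (S, N) arrays, one per run.
    """
    if params is None:
        params = E.EPBDParameters.default()
    n = np.asarray(snapshot_stacks[0]).shape[1]
    sp = E.SiteParameters(
        D=np.full(n, 0.05), a=np.full(n, 4.2), k=np.full(max(n - 1, 0), 0.025),
        rho=params.stacking_rho, b=params.stacking_b, kB=params.kB,
        y_min=params.y_min_bound, y_max=params.y_max_bound,
    )
    sched = E.MCMCSchedule(
        preheat_steps=0, measure_steps=len(snapshot_stacks[0]), record_interval=1,
        n_runs=len(snapshot_stacks), base_seed=0,
    )
    trajs = [
        E.Trajectory(
            snapshots=np.asarray(s, dtype=float), run_seed=i, acceptance_count=0,
            proposal_count=0, initial_energy=0.0, final_energy=0.0,
            final_state=np.asarray(s, dtype=float)[-1],
        )
        for i, s in enumerate(snapshot_stacks)
    ]
    return E.Ensemble(trajectories=trajs, schedule=sched, sequence=None, site_params=sp)
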
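"""Metropolis Monte Carlo sampling of DNA breathing configurations.

The sampler draws equilibrium configurations of the transverse base-pair
displacements at a fixed temperature: a preheating (burn-in) phase brings
the chain from its initial state to thermal equilibrium, then a measurement
phase records a snapshot of all displacements every ``record_interval``
steps.  Repeating the run M times with independently seeded streams gives
the ensemble from which the breathing observables are averaged, together
with honest run-to-run error bars.

One Metropolis proposal perturbs a single randomly chosen coordinate by a
zero-mean Gaussian of width sigma (a symmetric random walk, so no Hastings
correction is needed) and accepts with probability 1 when the energy drops
and exp(-dE / kB T) otherwise.  Proposals leaving the hard displacement
bounds are rejected as moves.  The hot loop is compiled with numba; all
randomness is drawn from numpy PCG64 streams in fixed-size blocks so a run
is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .model import (
    Configuration,
    DNASequence,
    EPBDParameters,
    ScheduleError,
    SiteParameters,
    resolve_site_parameters,
    total_energy,
)

#: Fixed multiplier applied to the per-site thermal width
#: sqrt(kB T / (2 D a^2)) when proposal_sigma="auto".  A proposal a little
#: wider than the local well keeps the acceptance rate in the 0.2-0.7 band
#: and lets open base pairs diffuse across the flat Morse plateau within
#: practical preheating budgets.
AUTO_SIGMA_SCALE = 2.0

_CHUNK_PROPOSALS = 1 << 20


@dataclass(frozen=True)
class MCMCSchedule:
    """Temperature, step counts and seeding for one ensemble.

    A "step" is one sweep (N single-site proposals at independently random
    sites) under ``step_convention="sweep"``, or a single proposal under
    ``"single"``.  ``record_interval`` counts steps between recorded
    snapshots, so each run stores ``measure_steps // record_interval``
    snapshots.
    """

    temperature: float = 310.0
    preheat_steps: int = 50_000
    measure_steps: int = 80_000
    record_interval: int = 100
    proposal_sigma: float | str = "auto"
    step_convention: str = "sweep"
    base_seed: int = 0
    n_runs: int = 100
    initial_condition: str = "zero"

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ScheduleError("temperature must be positive")
        if self.preheat_steps < 0:
            raise ScheduleError("preheat_steps must be >= 0")
        if not self.measure_steps >= self.record_interval >= 1:
            raise ScheduleError("need measure_steps >= record_interval >= 1")
        if self.n_runs < 1:
            raise ScheduleError("n_runs must be >= 1")
        if self.step_convention not in ("sweep", "single"):
            raise ScheduleError("step_convention must be 'sweep' or 'single'")
        if self.initial_condition not in ("zero", "uniform"):
            raise ScheduleError("initial_condition must be 'zero' or 'uniform'")
        if isinstance(self.proposal_sigma, str):
            if self.proposal_sigma != "auto":
                raise ScheduleError("proposal_sigma must be a number or 'auto'")
        elif not self.proposal_sigma >= 0:
            raise ScheduleError("proposal_sigma must be >= 0")

    @property
    def n_snapshots(self) -> int:
        return self.measure_steps // self.record_interval


@dataclass
class Trajectory:
    """Recorded snapshots of one run plus its bookkeeping.

    ``snapshots`` is an (S, N) array of displacement vectors; the running
    energy is maintained from exact single-move energy differences and can
    be compared against a from-scratch recomputation.
    """

    snapshots: np.ndarray
    run_seed: int
    acceptance_count: int
    proposal_count: int
    initial_energy: float
    final_energy: float
    final_state: np.ndarray

    @property
    def acceptance_rate(self) -> float:
        return self.acceptance_count / max(self.proposal_count, 1)

    @property
    def n_snapshots(self) -> int:
        return self.snapshots.shape[0]


@dataclass
class Ensemble:
    """M independently seeded trajectories sharing one schedule."""

    trajectories: list[Trajectory]
    schedule: MCMCSchedule
    sequence: DNASequence | None
    site_params: SiteParameters

    @property
    def n_runs(self) -> int:
        return len(self.trajectories)

    @property
    def n_basepairs(self) -> int:
        return self.site_params.n

    def stacked(self) -> np.ndarray:
        """All snapshots as an (M, S, N) array."""
        return np.stack([t.snapshots for t in self.trajectories])

    def per_run_means(self) -> np.ndarray:
        """(M, N) matrix of per-run time-averaged displacements."""
        return np.stack([t.snapshots.mean(axis=0) for t in self.trajectories])

    def per_run_flipping(self, thr: float) -> np.ndarray:
        """(M, N) matrix of per-run fractions of snapshots with y > thr."""
        return np.stack([(t.snapshots > thr).mean(axis=0) for t in self.trajectories])


@njit(cache=False, inline="always")
def _morse_nb(y, D, a):
    t = math.exp(-a * y) - 1.0
    return D * t * t


@njit(cache=False, inline="always")
def _stack_nb(yn, yp, k, rho, b):
    d = yn - yp
    return 0.5 * k * (1.0 + rho * math.exp(-b * (yn + yp))) * d * d


@njit(cache=False)
def _metropolis_chunk(
    y, D, a, k, rho, b, beta, y_min, y_max, periodic,
    sites, gauss, unif, sigma, rec, snapshots, snap_start,
):
    """Run len(sites) single-site proposals in place.

    Records a snapshot every ``rec`` proposals (rec <= 0 disables
    recording).  Returns (accepted count, summed energy change, next
    snapshot index).
    """
    n = y.shape[0]
    n_acc = 0
    de_sum = 0.0
    snap_i = snap_start
    for p in range(sites.shape[0]):
        i = sites[p]
        old = y[i]
        new = old + gauss[p] * sigma[i]
        if y_min <= new <= y_max:
            de = _morse_nb(new, D[i], a[i]) - _morse_nb(old, D[i], a[i])
            if n >= 2:
                if i > 0:
                    yl = y[i - 1]
                    de += _stack_nb(new, yl, k[i - 1], rho, b) - _stack_nb(old, yl, k[i - 1], rho, b)
                elif periodic:
                    yl = y[n - 1]
                    de += _stack_nb(new, yl, k[n - 1], rho, b) - _stack_nb(old, yl, k[n - 1], rho, b)
                if i < n - 1:
                    yr = y[i + 1]
                    de += _stack_nb(yr, new, k[i], rho, b) - _stack_nb(yr, old, k[i], rho, b)
                elif periodic:
                    yr = y[0]
                    de += _stack_nb(yr, new, k[n - 1], rho, b) - _stack_nb(yr, old, k[n - 1], rho, b)
            if de <= 0.0 or unif[p] < math.exp(-beta * de):
                y[i] = new
                n_acc += 1
                de_sum += de
        if rec > 0 and (p + 1) % rec == 0:
            for j in range(n):
                snapshots[snap_i, j] = y[j]
            snap_i += 1
    return n_acc, de_sum, snap_i


def proposal_sigmas(sp: SiteParameters, schedule: MCMCSchedule) -> np.ndarray:
    """Per-site Gaussian proposal widths for y-moves, in Å."""
    if schedule.proposal_sigma == "auto":
        thermal = np.sqrt(sp.kB * schedule.temperature / (2.0 * sp.D * sp.a**2))
        return AUTO_SIGMA_SCALE * thermal
    return np.full(sp.n, float(schedule.proposal_sigma))


def propose_move(
    config, site: int, strand_choice: str | None, sigma: float, rng: np.random.Generator
) -> float:
    """Candidate displacement for one coordinate.

    With ``strand_choice`` in {"left", "right"} the Gaussian of width sigma
    is applied to one strand coordinate (u or v), which moves y by
    sigma/sqrt(2); with ``strand_choice=None`` the width acts on y
    directly.  The kernel is symmetric either way.
    """
    y = config.y if isinstance(config, Configuration) else np.asarray(config)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if strand_choice is None:
        eff = sigma
    elif strand_choice in ("left", "right", "u", "v"):
        eff = sigma / np.sqrt(2.0)
    else:
        raise ValueError(f"unknown strand_choice {strand_choice!r}")
    return float(y[site] + rng.standard_normal() * eff)


def metropolis_accept(delta_E: float, T: float, kB: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept downhill, exp(-dE/kB T) uphill."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_E <= 0.0:
        return True
    return rng.random() < math.exp(-delta_E / (kB * T))


def mcmc_step(
    y: np.ndarray,
    sp: SiteParameters,
    temperature: float,
    sigma: np.ndarray,
    rng: np.random.Generator,
    convention: str = "single",
):
    """Pure-Python reference Metropolis step; mutates ``y`` in place.

    One step is a single proposal (``convention="single"``) or N proposals
    at independently random sites (``"sweep"``).  Returns (accepted,
    summed energy change).  This is the readable twin of the compiled
    kernel and is used to cross-validate it.
    """
    from .model import delta_energy

    n = sp.n
    n_prop = n if convention == "sweep" else 1
    beta = 1.0 / (sp.kB * temperature)
    accepted = 0
    de_sum = 0.0
    for _ in range(n_prop):
        i = int(rng.integers(0, n))
        new = y[i] + rng.standard_normal() * sigma[i]
        u = rng.random()
        if not sp.y_min <= new <= sp.y_max:
            continue
        de = delta_energy(y, i, new, sp)
        if de <= 0.0 or u < math.exp(-beta * de):
            y[i] = new
            accepted += 1
            de_sum += de
    return accepted, de_sum


def _initial_state(sp: SiteParameters, schedule: MCMCSchedule, rng: np.random.Generator) -> np.ndarray:
    if schedule.initial_condition == "uniform":
        return rng.uniform(0.0, 0.1, size=sp.n)
    return np.zeros(sp.n)


def run_simulation(
    seq: DNASequence | None,
    params: EPBDParameters | None,
    schedule: MCMCSchedule,
    run_seed: int,
    site_params: SiteParameters | None = None,
) -> Trajectory:
    """One independently seeded run: preheat, then record snapshots.

    Either a (sequence, parameters) pair or a prebuilt ``site_params``
    bundle must be given; the latter admits synthetic systems such as a
    single base pair or site-wise perturbed wells.  The run is
    deterministic given (inputs, schedule.base_seed, run_seed).
    """
    if site_params is None:
        if seq is None or params is None:
            raise ValueError("need either (seq, params) or site_params")
        site_params = resolve_site_parameters(seq, params)
    sp = site_params
    if schedule.n_snapshots < 1:
        raise ScheduleError(
            "schedule records zero snapshots "
            f"(measure_steps={schedule.measure_steps}, record_interval={schedule.record_interval})"
        )
    ss = np.random.SeedSequence(entropy=schedule.base_seed, spawn_key=(run_seed,))
    rng = np.random.Generator(np.random.PCG64(ss))

    sigma = proposal_sigmas(sp, schedule)
    y = _initial_state(sp, schedule, rng)
    e0 = total_energy(y, sp)

    pps = sp.n if schedule.step_convention == "sweep" else 1
    beta = 1.0 / (sp.kB * schedule.temperature)
    n_snap = schedule.n_snapshots
    snapshots = np.empty((n_snap, sp.n))

    n_acc = 0
    n_prop = 0
    de_total = 0.0

    def run_block(total_proposals: int, rec: int, snap_i: int) -> int:
        nonlocal n_acc, n_prop, de_total
        chunk = _CHUNK_PROPOSALS if rec <= 0 else max(rec, (_CHUNK_PROPOSALS // rec) * rec)
        done = 0
        while done < total_proposals:
            c = min(chunk, total_proposals - done)
            sites = rng.integers(0, sp.n, size=c)
            gauss = rng.standard_normal(c)
            unif = rng.random(c)
            acc, de, snap_i = _metropolis_chunk(
                y, sp.D, sp.a, sp.k, sp.rho, sp.b, beta, sp.y_min, sp.y_max,
                sp.periodic, sites, gauss, unif, sigma, rec, snapshots, snap_i,
            )
            n_acc += acc
            de_total += de
            n_prop += c
            done += c
        return snap_i

    run_block(schedule.preheat_steps * pps, 0, 0)
    rec = schedule.record_interval * pps
    filled = run_block(n_snap * rec, rec, 0)
    assert filled == n_snap

    return Trajectory(
        snapshots=snapshots,
        run_seed=run_seed,
        acceptance_count=n_acc,
        proposal_count=n_prop,
        initial_energy=e0,
        final_energy=e0 + de_total,
        final_state=y.copy(),
    )


def run_ensemble(
    seq: DNASequence | None,
    params: EPBDParameters | None,
    schedule: MCMCSchedule,
    site_params: SiteParameters | None = None,
) -> Ensemble:
    """M runs with seeds split deterministically from the base seed.

    Run i uses the stream SeedSequence(base_seed, spawn_key=(i,)), so the
    ensemble is identical regardless of execution order and of M.
    """
    if site_params is None:
        if seq is None or params is None:
            raise ValueError("need either (seq, params) or site_params")
        site_params = resolve_site_parameters(seq, params)
    trajectories = [
        run_simulation(seq, params, schedule, run_seed=i, site_params=site_params)
        for i in range(schedule.n_runs)
    ]
    return Ensemble(
        trajectories=trajectories, schedule=schedule, sequence=seq, site_params=site_params
    )
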
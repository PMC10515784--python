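"""Breathing characteristics derived from a sampled ensemble.

Three observables summarise the equilibrium opening dynamics:

* the **average-coordinate profile** <y_n>: how far each base pair's
  hydrogen bonds are stretched on average;
* the **flipping-probability profile**: the probability that y_n exceeds a
  threshold displacement, i.e. that at least one base at position n has
  swung out of the stack;
* the **bubble-probability tensor** P(n, l, thr): the probability that the
  l consecutive base pairs starting at position n are simultaneously open
  beyond thr — the propensity for a denaturation bubble of that location,
  length and amplitude.

All averages are taken per run first and then across the M runs, so the
quoted standard errors reflect genuine run-to-run scatter (which absorbs
within-run autocorrelation) rather than a naive per-snapshot count.
Openings are only observed at recording times, so "time" in the bubble
tensor is measured in recorded snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcmc import Ensemble


@dataclass
class OpeningProfile:
    """A per-position profile with run-to-run standard errors.

    ``kind`` is "average" (values in Å) or "flipping" (probabilities);
    ``threshold`` is the Å threshold for flipping profiles, None otherwise.
    Positions are 1-based in all written output.
    """

    values: np.ndarray
    stderr: np.ndarray
    kind: str
    threshold: float | None = None

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class BubbleTensor:
    """P(n, l, thr) on a (position, length, threshold) grid.

    ``P`` has shape (N, L_max, len(thr_grid)); entries whose window would
    run past the end of an open chain (n + l - 1 > N) are NaN.  Under the
    inclusive-window convention P is non-increasing in l and thr, and the
    l=1 slice is exactly the flipping profile.
    """

    P: np.ndarray
    thr_grid: np.ndarray
    L_max: int
    convention: str = "inclusive"

    @property
    def n_basepairs(self) -> int:
        return self.P.shape[0]

    def at(self, n: int, l: int, thr: float) -> float:
        """Entry at 1-based start position n, length l, threshold thr."""
        t = int(np.argmin(np.abs(self.thr_grid - thr)))
        if not np.isclose(self.thr_grid[t], thr):
            raise KeyError(f"threshold {thr} not on the grid {self.thr_grid}")
        return float(self.P[n - 1, l - 1, t])


def _per_run_stats(per_run: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = per_run.shape[0]
    values = per_run.mean(axis=0)
    if m >= 2:
        stderr = per_run.std(axis=0, ddof=1) / np.sqrt(m)
    else:
        stderr = np.zeros_like(values)
    return values, stderr


def average_coordinates(ensemble: Ensemble) -> OpeningProfile:
    """Mean transverse displacement <y_n> over all snapshots of all runs."""
    if ensemble.n_runs == 0 or ensemble.trajectories[0].n_snapshots == 0:
        raise ValueError("ensemble holds no snapshots")
    values, stderr = _per_run_stats(ensemble.per_run_means())
    return OpeningProfile(values=values, stderr=stderr, kind="average")


def flipping_probability(ensemble: Ensemble, thr: float) -> OpeningProfile:
    """Per-position probability that y_n strictly exceeds ``thr`` (Å)."""
    if ensemble.n_runs == 0 or ensemble.trajectories[0].n_snapshots == 0:
        raise ValueError("ensemble holds no snapshots")
    values, stderr = _per_run_stats(ensemble.per_run_flipping(thr))
    return OpeningProfile(values=values, stderr=stderr, kind="flipping", threshold=thr)


def bubble_occupancy(snapshot: np.ndarray, thr: float, L_max: int) -> np.ndarray:
    """Boolean window map omega(n, l): all of y_n .. y_{n+l-1} exceed thr.

    Returns an (N, L_max) array, 0-based in both axes; windows running past
    the chain end are False.  Built by the recursion
    omega(n, l) = omega(n, l-1) AND (y_{n+l-1} > thr), which is O(N L_max).
    """
    y = np.asarray(snapshot)
    n = y.shape[0]
    if L_max > n:
        raise ValueError(f"L_max={L_max} exceeds sequence length {n}")
    open_ = y > thr
    omega = np.zeros((n, L_max), dtype=bool)
    omega[:, 0] = open_
    for l in range(1, L_max):
        omega[: n - l, l] = omega[: n - l, l - 1] & open_[l:]
    return omega


def _window_occupancy(open_: np.ndarray, L_max: int) -> np.ndarray:
    """(S, N, L_max) inclusive-window maps for a stack of snapshots."""
    s, n = open_.shape
    omega = np.zeros((s, n, L_max), dtype=bool)
    omega[:, :, 0] = open_
    for l in range(1, L_max):
        omega[:, : n - l, l] = omega[:, : n - l, l - 1] & open_[:, l:]
    return omega


def _maximal_from_inclusive(open_: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Restrict inclusive windows to maximal runs (closed on both flanks)."""
    s, n, l_max = omega.shape
    closed = ~open_
    left_ok = np.ones((s, n), dtype=bool)
    left_ok[:, 1:] = closed[:, :-1]
    out = np.zeros_like(omega)
    for l in range(l_max):
        right_ok = np.ones((s, n), dtype=bool)
        # window [n, n+l] must be followed by a closed bp (or the chain end)
        end = np.arange(n) + l + 1
        valid = end < n
        right_ok[:, valid] = closed[:, end[valid]]
        out[:, :, l] = omega[:, :, l] & left_ok & right_ok
    return out


def bubble_tensor(
    ensemble: Ensemble,
    thr_grid=(0.5, 1.0, 1.5, 2.0, 2.5),
    L_max: int | None = None,
    convention: str = "inclusive",
) -> BubbleTensor:
    """Bubble-probability tensor P(n, l, thr) from recorded snapshots.

    P(n, l, thr) is the ensemble average, over the M runs, of the fraction
    of each run's snapshots in which the window of l base pairs starting at
    n is entirely open beyond thr — the time-average of the accumulated
    bubble durations with time counted in recorded snapshots.

    ``convention="inclusive"`` counts every fully open window;
    ``"maximal"`` counts only windows that are exact maximal runs (closed
    or chain-end on both flanks), which breaks the monotonicity and the
    flipping identity but localises bubbles of an exact length.
    """
    thr_grid = np.asarray(sorted(thr_grid), dtype=float)
    if np.unique(thr_grid).shape[0] != thr_grid.shape[0]:
        raise ValueError("thr_grid entries must be distinct")
    if convention not in ("inclusive", "maximal"):
        raise ValueError("convention must be 'inclusive' or 'maximal'")
    n = ensemble.n_basepairs
    if L_max is None:
        L_max = min(n, 20)
    if L_max > n:
        raise ValueError(f"L_max={L_max} exceeds sequence length {n}")

    P = np.zeros((n, L_max, thr_grid.shape[0]))
    for t, thr in enumerate(thr_grid):
        per_run = np.empty((ensemble.n_runs, n, L_max))
        for m, traj in enumerate(ensemble.trajectories):
            open_ = traj.snapshots > thr
            omega = _window_occupancy(open_, L_max)
            if convention == "maximal":
                omega = _maximal_from_inclusive(open_, omega)
            per_run[m] = omega.mean(axis=0)
        P[:, :, t] = per_run.mean(axis=0)

    # windows that would run past an open chain end are undefined
    for l in range(1, L_max):
        P[n - l :, l, :] = np.nan
    return BubbleTensor(P=P, thr_grid=thr_grid, L_max=L_max, convention=convention)
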
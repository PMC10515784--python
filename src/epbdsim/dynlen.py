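"""Dynamic length: which base pairs breathe differently between two alleles.

A point mutation perturbs the breathing profile not just at the substituted
base pairs but over a neighbourhood, because stacking couples adjacent
sites.  The dynamic length quantifies that footprint: for each position the
per-run profile values of the two alleles (wild vs mutant) are compared
with a Welch two-sample t-test, the per-position p-values are converted to
q-values (FDR-adjusted, the "q-factor" profile), and the dynamic length is
the number of positions significant at a chosen FDR level alpha.

Only substitution alleles of equal length are compared; alignment of
indel-bearing alleles is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mcmc import Ensemble


@dataclass
class ProfileSampleSet:
    """Per-run profile values for one allele: an (M runs, N positions) matrix."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile sample set must be a 2-D (runs x positions) matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 runs to estimate a variance")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile sample set contains non-finite entries")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_ensemble(
        cls, ensemble: Ensemble, kind: str = "flipping", thr: float = 1.0, label: str = ""
    ) -> "ProfileSampleSet":
        """Per-run flipping fractions (default) or mean displacements."""
        if kind == "flipping":
            return cls(ensemble.per_run_flipping(thr), label=label)
        if kind == "average":
            return cls(ensemble.per_run_means(), label=label)
        raise ValueError("kind must be 'flipping' or 'average'")


@dataclass
class DynamicLengthResult:
    """Per-position significance of the profile difference of two alleles.

    ``significant_positions`` is the 1-based set with q <= alpha, and
    ``dynamic_length`` its size.  ``longest_block`` is the length of the
    longest contiguous run of significant positions, a secondary summary
    for users who read the footprint as an interval.
    """

    p_values: np.ndarray
    q_values: np.ndarray
    significant_positions: set[int]
    dynamic_length: int
    alpha: float
    method: str
    longest_block: int
    alignment_note: str = "equal-length substitution alleles; positions compared 1:1"


def per_position_pvalues(set_a: ProfileSampleSet, set_b: ProfileSampleSet) -> np.ndarray:
    """Welch unequal-variance t-test at every position.

    Positions where both groups are constant get p = 1 when the constants
    agree (no evidence of change) and p = 0 when they differ (the groups
    are unequivocally separated); both are conventions for the
    zero-variance degenerate case.
    """
    if set_a.n_positions != set_b.n_positions:
        raise ValueError(
            f"allele profiles have different lengths ({set_a.n_positions} vs "
            f"{set_b.n_positions}); compare alleles on aligned, equal-length coordinates"
        )
    a, b = set_a.values, set_b.values
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    # exactly-constant groups (zero spread, not merely tiny variance)
    const_a = np.ptp(a, axis=0) == 0
    const_b = np.ptp(b, axis=0) == 0
    degenerate = const_a & const_b
    same = a[0] == b[0]
    p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    # residual nan (one group constant, no usable df): no evidence either way
    return np.nan_to_num(p, nan=1.0)


def _storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    pi0 = np.count_nonzero(p > lam) / (p.shape[0] * (1.0 - lam))
    return float(min(max(pi0, 0.0), 1.0))


def qvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """FDR q-values from raw p-values.

    ``"bh"`` is the Benjamini-Hochberg step-up adjustment; ``"storey"``
    rescales it by the estimated null proportion pi0 (lambda = 0.5
    estimator), falling back to bh when there are fewer than 20 tests or
    when pi0 degenerates to 0.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.shape[0] == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "storey"):
        raise ValueError("method must be 'bh' or 'storey'")
    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q_bh
    if p.shape[0] < 20:
        return q_bh
    pi0 = _storey_pi0(p)
    if pi0 <= 0.0:
        return q_bh
    return np.minimum(pi0 * q_bh, 1.0)


def compute_dynamic_length(
    set_a: ProfileSampleSet,
    set_b: ProfileSampleSet,
    alpha: float = 0.05,
    method: str = "storey",
) -> DynamicLengthResult:
    """Full allele comparison: p-values, q-factor profile, significant set."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = per_position_pvalues(set_a, set_b)
    q = qvalues(p, method=method)
    sig = np.flatnonzero(q <= alpha)
    positions = {int(i) + 1 for i in sig}

    longest = 0
    run = 0
    prev = None
    for i in sorted(sig):
        run = run + 1 if prev is not None and i == prev + 1 else 1
        longest = max(longest, run)
        prev = i

    return DynamicLengthResult(
        p_values=p,
        q_values=q,
        significant_positions=positions,
        dynamic_length=len(positions),
        alpha=alpha,
        method=method,
        longest_block=longest,
    )
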
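"""Potential-energy model for DNA breathing.

The double helix is coarse-grained to one transverse coordinate per base
pair: ``y_n`` (Å) is the stretching of the hydrogen bonds between the two
complementary bases at position ``n`` away from their equilibrium distance.
Each base pair sits in an on-site Morse well

    V(y) = D (exp(-a y) - 1)^2

whose depth ``D`` and inverse width ``a`` depend on whether the pair is A·T
(two hydrogen bonds) or G·C (three), and neighbouring base pairs are coupled
by an anharmonic stacking term

    W(y_n, y_{n-1}) = (k/2) (1 + rho exp(-b (y_n + y_{n-1}))) (y_n - y_{n-1})^2

whose harmonic constant ``k`` may depend on the dinucleotide step.  The
``rho``/``b`` anharmonicity weakens the stacking once both neighbours are
displaced, which is what gives the model its sharp, cooperative melting and
long-lived denaturation bubbles.

Because the Morse potential plateaus at ``D`` for large ``y``, the partition
function over an unbounded domain diverges; equilibrium sampling therefore
lives on a hard-bounded domain ``[y_min_bound, y_max_bound]`` and every
quadrature oracle in :mod:`epbdsim.oracles` integrates over exactly the same
bounds.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

#: Boltzmann constant in eV/K.
KB_EV_PER_K = 8.617333262e-5

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: The 16 ordered dinucleotide steps (base at n-1, base at n) on the
#: reference strand.
DINUCLEOTIDE_STEPS = tuple(x + y for x in "ACGT" for y in "ACGT")


class SequenceError(ValueError):
    """A DNA sequence failed validation (bad alphabet, too short, ...)."""


class ParameterError(ValueError):
    """A model-parameter set failed validation."""


class BoundsError(ValueError):
    """A proposed displacement lies outside the hard domain bounds.

    Raised by :func:`delta_energy` to signal rejection-by-contract; it is
    distinct from any numerical failure of the energy computation itself.
    """


class ScheduleError(ValueError):
    """A simulation schedule is inconsistent or degenerate."""


def reverse_complement_step(step: str) -> str:
    """Reverse-complement of an ordered dinucleotide step.

    Reading the step on the opposite strand reverses the order and
    complements both bases, e.g. ``"AG" -> "CT"``.
    """
    return _COMPLEMENT[step[1]] + _COMPLEMENT[step[0]]


def canonical_step(step: str) -> str:
    """Lexicographically smaller of a step and its reverse complement.

    Collapses the 16 ordered steps onto the 10 classes that are physically
    equivalent when the stacking energy does not distinguish strands.
    """
    return min(step, reverse_complement_step(step))


@dataclass(frozen=True)
class DNASequence:
    """A validated DNA sequence over {A, C, G, T}, at least 2 bp long."""

    bases: str

    def __post_init__(self) -> None:
        normalized = "".join(self.bases.split()).upper()
        for i, ch in enumerate(normalized):
            if ch not in _VALID_BASES:
                raise SequenceError(
                    f"invalid base {ch!r} at position {i + 1} (1-based); "
                    "allowed characters are A, C, G, T"
                )
        if len(normalized) < 2:
            raise SequenceError(
                f"sequence must contain at least 2 base pairs, got {len(normalized)}"
            )
        object.__setattr__(self, "bases", normalized)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_basepairs(self) -> int:
        return len(self.bases)

    def steps(self) -> list[str]:
        """Ordered dinucleotide steps (base n-1, base n), length N-1."""
        return [self.bases[i : i + 2] for i in range(len(self.bases) - 1)]


def _pair_class(base: str) -> str:
    return "AT" if base in ("A", "T") else "GC"


@dataclass(frozen=True)
class EPBDParameters:
    """Morse and stacking constants plus physical constants and bounds.

    ``morse_depth``/``morse_width`` map the base-pair class (``"AT"`` or
    ``"GC"``) to D (eV) and a (Å⁻¹).  ``stacking_k`` maps each of the 16
    ordered dinucleotide steps to its harmonic stacking constant (eV/Å²);
    a 10-entry table keyed by canonical steps is accepted by
    :meth:`from_dict` and expanded under reverse-complement symmetry.
    """

    morse_depth: Mapping[str, float]
    morse_width: Mapping[str, float]
    stacking_k: Mapping[str, float]
    stacking_rho: float
    stacking_b: float
    kB: float = KB_EV_PER_K
    y_min_bound: float = -2.0
    y_max_bound: float = 20.0

    def __post_init__(self) -> None:
        for name, table in (("morse_depth", self.morse_depth), ("morse_width", self.morse_width)):
            if set(table) != {"AT", "GC"}:
                raise ParameterError(f"{name} must have exactly the keys 'AT' and 'GC'")
            for key, value in table.items():
                if not value > 0:
                    raise ParameterError(f"{name}[{key}] must be positive, got {value}")
        if set(self.stacking_k) != set(DINUCLEOTIDE_STEPS):
            missing = set(DINUCLEOTIDE_STEPS) - set(self.stacking_k)
            extra = set(self.stacking_k) - set(DINUCLEOTIDE_STEPS)
            raise ParameterError(
                f"stacking_k must cover the 16 ordered steps; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for step, k in self.stacking_k.items():
            if not k > 0:
                raise ParameterError(f"stacking_k[{step}] must be positive, got {k}")
        if self.stacking_rho < 0:
            raise ParameterError("stacking_rho must be >= 0")
        if self.stacking_b < 0:
            raise ParameterError("stacking_b must be >= 0")
        if not self.kB > 0:
            raise ParameterError("kB must be positive")
        if not self.y_min_bound < 0 < self.y_max_bound:
            raise ParameterError(
                "displacement bounds must straddle 0: "
                f"got ({self.y_min_bound}, {self.y_max_bound})"
            )

    def is_strand_symmetric(self) -> bool:
        """True when stacking_k is consistent under reverse-complement symmetry."""
        return all(
            self.stacking_k[s] == self.stacking_k[reverse_complement_step(s)]
            for s in DINUCLEOTIDE_STEPS
        )

    @classmethod
    def from_dict(cls, data: dict) -> "EPBDParameters":
        """Build from a plain dict (the parameter-file schema), strictly.

        Unknown keys are errors.  ``stacking_k`` may be given either as the
        full 16-entry table or as the 10 canonical entries, which are then
        expanded under reverse-complement step symmetry.
        """
        allowed = {
            "morse_depth", "morse_width", "stacking_k", "stacking_rho",
            "stacking_b", "kB", "y_min_bound", "y_max_bound",
        }
        unknown = set(data) - allowed
        if unknown:
            raise ParameterError(f"unknown parameter-file keys: {sorted(unknown)}")
        missing = {"morse_depth", "morse_width", "stacking_k", "stacking_rho", "stacking_b"} - set(data)
        if missing:
            raise ParameterError(f"missing parameter-file keys: {sorted(missing)}")
        stacking = dict(data["stacking_k"])
        canonical = {canonical_step(s) for s in DINUCLEOTIDE_STEPS}
        if set(stacking) == canonical:
            stacking = {s: stacking[canonical_step(s)] for s in DINUCLEOTIDE_STEPS}
        kwargs = {k: v for k, v in data.items() if k != "stacking_k"}
        return cls(stacking_k=stacking, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "EPBDParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ParameterError(f"parameter file {path} does not hold a key/value table")
        return cls.from_dict(data)

    @classmethod
    def default(cls) -> "EPBDParameters":
        """The packaged default parameter set (DNA-melting-fit constants)."""
        ref = importlib.resources.files("epbdsim").joinpath("data/default_params.yaml")
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def to_dict(self) -> dict:
        return {
            "morse_depth": dict(self.morse_depth),
            "morse_width": dict(self.morse_width),
            "stacking_k": dict(self.stacking_k),
            "stacking_rho": self.stacking_rho,
            "stacking_b": self.stacking_b,
            "kB": self.kB,
            "y_min_bound": self.y_min_bound,
            "y_max_bound": self.y_max_bound,
        }


@dataclass
class Configuration:
    """One MCMC state: the vector of transverse displacements y_n (Å).

    Optionally carries the per-strand coordinates u_n, v_n with
    ``y = (u - v)/sqrt(2)``.  The common mode ``(u + v)/sqrt(2)`` carries no
    potential energy, so the model works in y throughout; the strand layer
    is bookkeeping only.
    """

    y: np.ndarray
    u: np.ndarray | None = None
    v: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.ndim != 1:
            raise ValueError("Configuration.y must be one-dimensional")
        if self.u is not None and self.v is not None:
            expected = (np.asarray(self.u) - np.asarray(self.v)) / np.sqrt(2.0)
            if not np.allclose(expected, self.y, atol=1e-12):
                raise ValueError("u, v inconsistent with y = (u - v)/sqrt(2)")

    @classmethod
    def from_strands(cls, u: np.ndarray, v: np.ndarray) -> "Configuration":
        u = np.asarray(u, dtype=np.float64)
        v = np.asarray(v, dtype=np.float64)
        return cls(y=(u - v) / np.sqrt(2.0), u=u, v=v)

    def __len__(self) -> int:
        return self.y.shape[0]


@dataclass(frozen=True)
class SiteParameters:
    """Per-site model vectors resolved for one sequence.

    ``D``/``a`` have length N; ``k`` has length N-1 for an open chain or N
    when ``periodic`` (the last entry couples base pair N to base pair 1).
    """

    D: np.ndarray
    a: np.ndarray
    k: np.ndarray
    rho: float
    b: float
    kB: float = KB_EV_PER_K
    y_min: float = -2.0
    y_max: float = 20.0
    periodic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "D", np.ascontiguousarray(self.D, dtype=np.float64))
        object.__setattr__(self, "a", np.ascontiguousarray(self.a, dtype=np.float64))
        object.__setattr__(self, "k", np.ascontiguousarray(self.k, dtype=np.float64))
        n = self.D.shape[0]
        expected_k = n if self.periodic else n - 1
        if self.a.shape[0] != n or self.k.shape[0] != max(expected_k, 0):
            raise ParameterError(
                f"inconsistent site-parameter lengths: D:{n} a:{self.a.shape[0]} "
                f"k:{self.k.shape[0]} (expected k:{expected_k})"
            )

    @property
    def n(self) -> int:
        return self.D.shape[0]


def resolve_site_parameters(
    seq: DNASequence, params: EPBDParameters, periodic: bool = False
) -> SiteParameters:
    """Map a sequence onto per-site Morse vectors and per-step stacking.

    ``D_n``/``a_n`` follow the base-pair class of base n (A·T vs G·C);
    ``k`` follows the ordered dinucleotide (base n-1, base n).  With
    ``periodic`` an extra wrap step (base N, base 1) is appended.
    """
    classes = [_pair_class(b) for b in seq.bases]
    D = np.array([params.morse_depth[c] for c in classes])
    a = np.array([params.morse_width[c] for c in classes])
    steps = seq.steps()
    if periodic:
        steps = steps + [seq.bases[-1] + seq.bases[0]]
    k = np.array([params.stacking_k[s] for s in steps])
    return SiteParameters(
        D=D, a=a, k=k, rho=params.stacking_rho, b=params.stacking_b,
        kB=params.kB, y_min=params.y_min_bound, y_max=params.y_max_bound,
        periodic=periodic,
    )


def single_bp_site_params(
    params: EPBDParameters, pair_class: str = "AT"
) -> SiteParameters:
    """SiteParameters for an isolated base pair (no stacking terms).

    Used by the quadrature oracles and sampler cross-checks; a single base
    pair is below the 2-bp minimum of :class:`DNASequence` so it is built
    directly.
    """
    if pair_class not in ("AT", "GC"):
        raise ParameterError(f"pair_class must be 'AT' or 'GC', got {pair_class!r}")
    return SiteParameters(
        D=np.array([params.morse_depth[pair_class]]),
        a=np.array([params.morse_width[pair_class]]),
        k=np.empty(0),
        rho=params.stacking_rho, b=params.stacking_b, kB=params.kB,
        y_min=params.y_min_bound, y_max=params.y_max_bound,
    )


def morse_potential(y, D, a):
    """On-site Morse energy V(y) = D (exp(-a y) - 1)^2 in eV (vectorized)."""
    t = np.exp(-np.multiply(a, y)) - 1.0
    return D * t * t


def stacking_potential(y_n, y_prev, k, rho, b):
    """Anharmonic stacking energy between adjacent base pairs, in eV.

    W = (k/2) (1 + rho exp(-b (y_n + y_prev))) (y_n - y_prev)^2; symmetric
    in its two displacement arguments and zero when they coincide.
    """
    d = np.subtract(y_n, y_prev)
    return 0.5 * k * (1.0 + rho * np.exp(-b * (np.add(y_n, y_prev)))) * d * d


def _as_y(config) -> np.ndarray:
    if isinstance(config, Configuration):
        return config.y
    return np.asarray(config, dtype=np.float64)


def total_energy(config, sp: SiteParameters) -> float:
    """Total EPBD energy: N Morse terms + N-1 stacking terms (open chain).

    With ``sp.periodic`` an extra stacking term couples the two chain ends.
    """
    y = _as_y(config)
    if y.shape[0] != sp.n:
        raise ValueError(
            f"configuration length {y.shape[0]} does not match site parameters ({sp.n})"
        )
    e = float(np.sum(morse_potential(y, sp.D, sp.a)))
    if sp.n >= 2:
        n_open = sp.n - 1
        e += float(np.sum(stacking_potential(y[1:], y[:-1], sp.k[:n_open], sp.rho, sp.b)))
        if sp.periodic:
            e += float(stacking_potential(y[0], y[-1], sp.k[-1], sp.rho, sp.b))
    return e


def delta_energy(config, site: int, new_y: float, sp: SiteParameters) -> float:
    """Exact energy difference for moving one coordinate to ``new_y``.

    Touches only the Morse term at ``site`` and the (at most two) adjacent
    stacking terms; equals the difference of full :func:`total_energy`
    evaluations up to floating point.  ``site`` is a 0-based index.
    """
    y = _as_y(config)
    n = sp.n
    if not 0 <= site < n:
        raise IndexError(f"site {site} out of range for {n} base pairs")
    if not sp.y_min <= new_y <= sp.y_max:
        raise BoundsError(
            f"proposed displacement {new_y} outside bounds [{sp.y_min}, {sp.y_max}]"
        )
    old = y[site]
    d = float(morse_potential(new_y, sp.D[site], sp.a[site])) - float(
        morse_potential(old, sp.D[site], sp.a[site])
    )
    if n >= 2:
        if site > 0:
            yl = y[site - 1]
            d += float(stacking_potential(new_y, yl, sp.k[site - 1], sp.rho, sp.b))
            d -= float(stacking_potential(old, yl, sp.k[site - 1], sp.rho, sp.b))
        elif sp.periodic:
            yl = y[n - 1]
            d += float(stacking_potential(new_y, yl, sp.k[n - 1], sp.rho, sp.b))
            d -= float(stacking_potential(old, yl, sp.k[n - 1], sp.rho, sp.b))
        if site < n - 1:
            yr = y[site + 1]
            d += float(stacking_potential(yr, new_y, sp.k[site], sp.rho, sp.b))
            d -= float(stacking_potential(yr, old, sp.k[site], sp.rho, sp.b))
        elif sp.periodic:
            yr = y[0]
            d += float(stacking_potential(yr, new_y, sp.k[n - 1], sp.rho, sp.b))
            d -= float(stacking_potential(yr, old, sp.k[n - 1], sp.rho, sp.b))
    return d
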
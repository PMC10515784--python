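"""Deterministic synthetic sequences for tests, examples and benchmarks.

Four kinds are provided: homopolymer A·T and G·C tracts (the extreme soft
and stiff cases), a promoter-like sequence with an AT-rich core flanked by
mixed GC-richer arms (mimicking the architecture around a transcription
start site), and a wild/mutant pair differing by a dinucleotide
substitution at the centre, for allele comparisons.
"""

from __future__ import annotations

import numpy as np

from .model import DNASequence

FIXTURE_KINDS = ("homoAT", "homoGC", "promoter_like", "snp_pair")

# class-swapping substitutions (A·T <-> G·C), so the mutation perturbs the
# Morse wells and hence the breathing profile under any parameter set
_SUBSTITUTE = {"A": "G", "G": "A", "T": "C", "C": "T"}


def _promoter_like(length: int, seed: int) -> str:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    core_len = max(4, length // 5)
    core_start = (length - core_len) // 2
    bases = []
    for i in range(length):
        if core_start <= i < core_start + core_len:
            probs = (0.45, 0.05, 0.05, 0.45)  # AT-rich breathing core
        else:
            probs = (0.2, 0.3, 0.3, 0.2)
        bases.append("ACGT"[rng.choice(4, p=probs)])
    return "".join(bases)


def generate_fixture(kind: str, length: int, seed: int = 0):
    """Build one sequence (or a wild/mutant pair for ``snp_pair``).

    Deterministic in (kind, length, seed).  ``snp_pair`` returns a tuple of
    two :class:`DNASequence` differing at exactly two adjacent central
    positions.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if kind == "homoAT":
        return DNASequence("A" * length)
    if kind == "homoGC":
        return DNASequence("G" * length)
    if kind == "promoter_like":
        return DNASequence(_promoter_like(length, seed))
    if kind == "snp_pair":
        wild = _promoter_like(length, seed)
        # substitute the same-class adjacent pair nearest the centre, so
        # both sites swap class in the same direction (a coherent
        # softening or stiffening, as a dinucleotide variant would cause)
        centre = length // 2 - 1
        classes = ["AT" if b in "AT" else "GC" for b in wild]
        candidates = sorted(
            (i for i in range(length - 1) if classes[i] == classes[i + 1]),
            key=lambda i: abs(i - centre),
        )
        pos = candidates[0] if candidates else centre
        mutant = list(wild)
        for i in (pos, pos + 1):
            mutant[i] = _SUBSTITUTE[wild[i]]
        return DNASequence(wild), DNASequence("".join(mutant))
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
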
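"""File input/output: sequences, config files, profiles, tensors, manifests.

Sequences come in as FASTA (first record, with a warning if the file holds
more) or plain text; both are validated into :class:`DNASequence`.  All
numeric output is tab-separated text with floats printed at 17 significant
digits so files round-trip losslessly, and every pipeline run writes a
manifest (YAML) carrying checksums, the full schedule and the seeds needed
to reproduce the outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .dynlen import DynamicLengthResult
from .mcmc import MCMCSchedule
from .model import DNASequence, EPBDParameters, ScheduleError, SequenceError
from .observables import BubbleTensor, OpeningProfile

_FLOAT_FMT = "%.17g"


def read_sequence(path, fmt: str = "auto") -> DNASequence:
    """Read a DNA sequence from FASTA or plain text.

    ``fmt="auto"`` sniffs FASTA by a leading '>'.  Multi-record FASTA files
    trigger a warning and the first record is used.  Positions in error
    messages and all downstream output are 1-based.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SequenceError(f"{path} is empty")
    if fmt == "auto":
        fmt = "fasta" if text.lstrip().startswith(">") else "text"
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise SequenceError(f"{path} holds no FASTA records")
        if len(records) > 1:
            warnings.warn(
                f"{path} holds {len(records)} FASTA records; using the first "
                f"({records[0].id})",
                stacklevel=2,
            )
        return DNASequence(str(records[0].seq))
    if fmt == "text":
        return DNASequence(text)
    raise ValueError(f"unknown sequence format {fmt!r}")


def write_sequence_fasta(path, seq: DNASequence, name: str = "seq") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq.bases[i : i + 70] + "\n")


def load_schedule(path) -> MCMCSchedule:
    """Strict YAML loader for the simulation schedule; unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ScheduleError(f"schedule file {path} does not hold a key/value table")
    allowed = set(MCMCSchedule.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ScheduleError(f"unknown schedule keys: {sorted(unknown)}")
    return MCMCSchedule(**data)


def save_schedule(path, schedule: MCMCSchedule) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(schedule), fh, sort_keys=False)


def write_profile(path, profile: OpeningProfile, seq: DNASequence | None = None, metadata: dict | None = None) -> None:
    """Profile TSV: 1-based position, base, value, stderr; '#' metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# kind: {profile.kind}\n")
        if profile.threshold is not None:
            fh.write(f"# threshold: {_FLOAT_FMT % profile.threshold}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("position\tbase\tvalue\tstderr\n")
        for i, (v, s) in enumerate(zip(profile.values, profile.stderr)):
            base = seq.bases[i] if seq is not None else "."
            fh.write(f"{i + 1}\t{base}\t{_FLOAT_FMT % v}\t{_FLOAT_FMT % s}\n")


def read_profile(path) -> OpeningProfile:
    kind = "average"
    threshold = None
    values, stderr = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# kind:"):
                kind = line.split(":", 1)[1].strip()
            elif line.startswith("# threshold:"):
                threshold = float(line.split(":", 1)[1])
            elif line.startswith("#") or line.startswith("position\t") or not line:
                continue
            else:
                _, _, v, s = line.split("\t")
                values.append(float(v))
                stderr.append(float(s))
    return OpeningProfile(
        values=np.array(values), stderr=np.array(stderr), kind=kind, threshold=threshold
    )


def write_bubble_tensor(path, tensor: BubbleTensor, metadata: dict | None = None) -> None:
    """Long-format TSV: n, l, thr, P; undefined (chain-end) entries omitted."""
    with open(path, "w") as fh:
        fh.write(f"# convention: {tensor.convention}\n")
        fh.write(f"# L_max: {tensor.L_max}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("n\tl\tthr\tP\n")
        n_bp, l_max, n_thr = tensor.P.shape
        for t in range(n_thr):
            thr = tensor.thr_grid[t]
            for l in range(l_max):
                for n in range(n_bp):
                    v = tensor.P[n, l, t]
                    if np.isnan(v):
                        continue
                    fh.write(
                        f"{n + 1}\t{l + 1}\t{_FLOAT_FMT % thr}\t{_FLOAT_FMT % v}\n"
                    )


def read_bubble_tensor(path) -> BubbleTensor:
    convention = "inclusive"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# convention:"):
                convention = line.split(":", 1)[1].strip()
            elif line.startswith("#") or line.startswith("n\t") or not line:
                continue
            else:
                n, l, thr, p = line.split("\t")
                rows.append((int(n), int(l), float(thr), float(p)))
    if not rows:
        raise ValueError(f"{path} holds no tensor entries")
    thr_grid = np.array(sorted({r[2] for r in rows}))
    n_bp = max(r[0] for r in rows)
    l_max = max(r[1] for r in rows)
    P = np.full((n_bp, l_max, thr_grid.shape[0]), np.nan)
    thr_index = {t: i for i, t in enumerate(thr_grid)}
    for n, l, thr, p in rows:
        P[n - 1, l - 1, thr_index[thr]] = p
    return BubbleTensor(P=P, thr_grid=thr_grid, L_max=l_max, convention=convention)


def write_dynamic_length(
    path,
    result: DynamicLengthResult,
    seq_a: DNASequence | None = None,
    seq_b: DNASequence | None = None,
) -> None:
    """Per-position comparison table plus a one-line summary header."""
    n = result.p_values.shape[0]
    with open(path, "w") as fh:
        fh.write(
            f"# dynamic_length: {result.dynamic_length}  alpha: {result.alpha}  "
            f"method: {result.method}  longest_block: {result.longest_block}\n"
        )
        fh.write(f"# alignment: {result.alignment_note}\n")
        fh.write("position\tbase_A\tbase_B\tp\tq\tsignificant\n")
        for i in range(n):
            ba = seq_a.bases[i] if seq_a is not None else "."
            bb = seq_b.bases[i] if seq_b is not None else "."
            sig = 1 if (i + 1) in result.significant_positions else 0
            fh.write(
                f"{i + 1}\t{ba}\t{bb}\t{_FLOAT_FMT % result.p_values[i]}\t"
                f"{_FLOAT_FMT % result.q_values[i]}\t{sig}\n"
            )


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run bit-for-bit."""

    tool_version: str
    command: str
    sequence_source: str
    sequence_sha256: str
    parameter_source: str
    parameter_sha256: str
    schedule: dict
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def make_manifest(
    command: str,
    seq: DNASequence,
    seq_source: str,
    params: EPBDParameters,
    params_source: str,
    schedule: MCMCSchedule,
    timestamp: str = "",
) -> RunManifest:
    seq_digest = hashlib.sha256(seq.bases.encode()).hexdigest()
    params_digest = hashlib.sha256(
        yaml.safe_dump(params.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    return RunManifest(
        tool_version=__version__,
        command=command,
        sequence_source=seq_source,
        sequence_sha256=seq_digest,
        parameter_source=params_source,
        parameter_sha256=params_digest,
        schedule=asdict(schedule),
        timestamp=timestamp,
    )
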
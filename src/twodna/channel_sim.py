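"""Synthesis -> PCR -> sequencing channel simulator.

The channel is the substitution/dropout abstraction of an amplicon
sequencing run over an oligo pool: each designed oligo is independently
lost with probability ``p_drop`` (synthesis dropout), each surviving
oligo yields a Poisson-distributed number of full-length reads around a
mean coverage, and every read base is substituted with probability
``p_sub`` to a uniformly random different base.  Optional insertion and
deletion rates are available for robustness experiments but default to
zero.  Qualities are not modelled; FASTQ records carry a constant
placeholder quality.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_TO_INT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_INT[ord(_b)] = _i
_INT_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

PLACEHOLDER_QUALITY = 40


@dataclass(frozen=True)
class ChannelModel:
    """Parameters of the simulated storage channel.

    ``p_sub``: per-base substitution probability; the experimentally
    observed value in the system this emulates is 0.8%.
    ``p_drop``: per-oligo dropout probability (observed: 0.7%).
    ``coverage``: mean reads per surviving oligo (Poisson).
    """

    p_sub: float = 0.008
    p_drop: float = 0.007
    coverage: float = 30.0
    p_ins: float = 0.0
    p_del: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_drop", "p_ins", "p_del"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class Read:
    id: str
    seq: str


def seqs_to_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as a (N, L) uint8 matrix over {0..3}."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    mat = _BASE_TO_INT[arr].reshape(len(seqs), -1)
    if (mat == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return mat


def matrix_to_seqs(mat: np.ndarray) -> list[str]:
    chars = _INT_TO_BASE[mat]
    flat = chars.tobytes().decode()
    L = mat.shape[1]
    return [flat[i * L : (i + 1) * L] for i in range(mat.shape[0])]


def simulate_reads(
    oligos: list[tuple[str, str]],
    model: ChannelModel,
) -> list[Read]:
    """Simulate the channel over ``(id, sequence)`` oligos.

    Deterministic for a fixed model seed.  Read ids are
    ``"<oligo id>/<read index>"`` so the pool label in the oligo id is
    carried through to every read.
    """
    if not oligos:
        raise ValueError("empty oligo set")
    rng = np.random.default_rng(model.seed)
    ids = [o[0] for o in oligos]
    seqs = [o[1].upper() for o in oligos]
    lengths = {len(s) for s in seqs}
    survive = rng.random(len(seqs)) >= model.p_drop
    if not survive.any():
        return []
    surv_idx = np.flatnonzero(survive)
    counts = rng.poisson(model.coverage, size=len(surv_idx))
    reads: list[Read] = []
    if len(lengths) == 1 and model.p_ins == 0 and model.p_del == 0:
        # fast path: equal-length, substitution-only
        mat = seqs_to_matrix(seqs)[surv_idx]
        src = np.repeat(np.arange(len(surv_idx)), counts)
        read_mat = mat[src]
        if model.p_sub > 0 and read_mat.size:
            sub_mask = rng.random(read_mat.shape) < model.p_sub
            shift = rng.integers(1, 4, size=read_mat.shape, dtype=np.uint8)
            read_mat = np.where(sub_mask, (read_mat + shift) % 4, read_mat)
        read_seqs = matrix_to_seqs(read_mat) if read_mat.size else []
        per_oligo_counter = np.concatenate(
            [np.arange(c) for c in counts if c > 0]
        ) if counts.sum() else np.array([], dtype=int)
        for k, (si, j) in enumerate(zip(src, per_oligo_counter)):
            reads.append(Read(id=f"{ids[surv_idx[si]]}/{j}", seq=read_seqs[k]))
        return reads
    # general path with optional indels
    for si, c in zip(surv_idx, counts):
        for j in range(c):
            seq = list(seqs[si])
            out = []
            for b in seq:
                if model.p_del > 0 and rng.random() < model.p_del:
                    continue
                if model.p_ins > 0 and rng.random() < model.p_ins:
                    out.append(BASES[rng.integers(0, 4)])
                if model.p_sub > 0 and rng.random() < model.p_sub:
                    alt = BASES[(BASE_INDEX_OF(b) + rng.integers(1, 4)) % 4]
                    out.append(alt)
                else:
                    out.append(b)
            reads.append(Read(id=f"{ids[si]}/{j}", seq="".join(out)))
    return reads


def BASE_INDEX_OF(b: str) -> int:
    return BASES.index(b)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Biopython-backed, uppercase normalization)
# ---------------------------------------------------------------------------


class SequenceParseError(ValueError):
    pass


def write_fasta(records: list[tuple[str, str]], path) -> None:
    bio = [
        SeqRecord(Seq(seq.upper()), id=rid.split()[0], description=rid)
        for rid, seq in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    try:
        return [
            (rec.description, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # pragma: no cover - malformed input path
        raise SequenceParseError(f"malformed FASTA {path}: {exc}") from exc


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq.upper()}\n+\n{'I' * len(r.seq)}\n")


def read_fastq(path) -> list[Read]:
    """Parse FASTQ; malformed records raise with the offending line number."""
    reads: list[Read] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise SequenceParseError(
            f"{path}: truncated FASTQ record starting at line {4 * (len(lines) // 4) + 1}"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise SequenceParseError(f"{path}: line {i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise SequenceParseError(f"{path}: line {i + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise SequenceParseError(
                f"{path}: line {i + 4}: quality length differs from sequence length"
            )
        reads.append(Read(id=header[1:], seq=seq.upper()))
    return reads


def reads_from_string(text: str) -> list[Read]:
    """Parse FASTQ content from an in-memory string (test convenience)."""
    buf = io.StringIO(text)
    reads = []
    for rec in SeqIO.parse(buf, "fastq"):
        reads.append(Read(id=rec.description, seq=str(rec.seq).upper()))
    return reads
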
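"""Constrained binary <-> DNA block codes and 196-nt oligo assembly.

Binary data is mapped onto DNA through enumerative (rank/unrank) coding
over a constrained language: fixed block length, a per-block GC-count
window, G runs limited to three, and no "GG" at either block boundary so
that concatenated blocks never build a longer G run.  Two codes are
used: 22 information bits -> 13 nt for payload blocks and 16 bits ->
10 nt for addresses.  An oligo is 196 nt: a 20-nt forward primer, a 3-nt
colour tag, a 10-nt address, eleven 13-nt payload blocks and a 20-nt
reverse primer.

The per-block GC windows (6-7 of 13, 4-6 of 10) are chosen so that any
concatenation of valid blocks with compliant primers keeps whole-oligo
GC inside 40-60%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def max_g_run(seq: str) -> int:
    best = run = 0
    for b in seq:
        run = run + 1 if b == "G" else 0
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# constrained language and enumerative coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintSpec:
    """Combinatorial synthesis constraints for one block."""

    n: int
    gc_lo: int
    gc_hi: int
    max_g_run: int = 3
    forbid_gg_ends: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.gc_lo <= self.gc_hi <= self.n):
            raise ValueError("invalid GC range")

    def is_valid(self, seq: str) -> bool:
        if len(seq) != self.n:
            return False
        if not (self.gc_lo <= gc_count(seq) <= self.gc_hi):
            return False
        if max_g_run(seq) > self.max_g_run:
            return False
        if self.forbid_gg_ends and self.n >= 2:
            if seq[:2] == "GG" or seq[-2:] == "GG":
                return False
        return True


@lru_cache(maxsize=None)
def _count_from(spec: ConstraintSpec, pos: int, gc: int, grun: int) -> int:
    """Valid completions of a prefix with ``pos`` bases placed, ``gc`` G/C
    among them and a trailing G run of length ``grun``."""
    if pos == spec.n:
        if not (spec.gc_lo <= gc <= spec.gc_hi):
            return 0
        if spec.forbid_gg_ends and spec.n >= 2 and grun >= 2:
            return 0
        return 1
    # prune: remaining positions cannot reach the GC window
    remaining = spec.n - pos
    if gc > spec.gc_hi or gc + remaining < spec.gc_lo:
        return 0
    total = 0
    for base in BASES:
        new_grun = grun + 1 if base == "G" else 0
        if new_grun > spec.max_g_run:
            continue
        if spec.forbid_gg_ends and pos + 1 == 2 and new_grun >= 2:
            continue  # leading GG
        total += _count_from(
            spec, pos + 1, gc + (1 if base in "GC" else 0), new_grun
        )
    return total


def count_valid(spec: ConstraintSpec) -> int:
    """Exact number of n-mers satisfying the constraints (transfer-matrix DP)."""
    return _count_from(spec, 0, 0, 0)


def enumerate_valid(spec: ConstraintSpec):
    """Brute-force enumeration, for cross-checking the DP at small n."""
    for tup in itertools.product(BASES, repeat=spec.n):
        seq = "".join(tup)
        if spec.is_valid(seq):
            yield seq


class BlockCode:
    """Enumerative code mapping k-bit values to valid n-mers in lexicographic order."""

    def __init__(self, spec: ConstraintSpec, k_bits: int):
        self.spec = spec
        self.k_bits = k_bits
        self.n_valid = count_valid(spec)
        if self.n_valid < (1 << k_bits):
            raise ValueError(
                f"constrained language has {self.n_valid} words < 2^{k_bits}"
            )

    def encode(self, value: int) -> str:
        """Unrank: the ``value``-th valid n-mer in lexicographic order."""
        if not (0 <= value < (1 << self.k_bits)):
            raise ValueError(f"value {value} does not fit in {self.k_bits} bits")
        spec = self.spec
        out = []
        gc = grun = 0
        rank = value
        for pos in range(spec.n):
            for base in BASES:
                new_grun = grun + 1 if base == "G" else 0
                if new_grun > spec.max_g_run:
                    continue
                if spec.forbid_gg_ends and pos + 1 == 2 and new_grun >= 2:
                    continue
                new_gc = gc + (1 if base in "GC" else 0)
                c = _count_from(spec, pos + 1, new_gc, new_grun)
                if rank < c:
                    out.append(base)
                    gc, grun = new_gc, new_grun
                    break
                rank -= c
            else:  # pragma: no cover - unreachable given the capacity check
                raise RuntimeError("unrank walked off the language")
        return "".join(out)

    def rank(self, seq: str) -> int:
        """Lexicographic rank of a *valid* n-mer within the language."""
        spec = self.spec
        gc = grun = 0
        rank = 0
        for pos, actual in enumerate(seq):
            for base in BASES:
                new_grun = grun + 1 if base == "G" else 0
                if new_grun > spec.max_g_run:
                    continue
                if spec.forbid_gg_ends and pos + 1 == 2 and new_grun >= 2:
                    continue
                new_gc = gc + (1 if base in "GC" else 0)
                if base == actual:
                    gc, grun = new_gc, new_grun
                    break
                rank += _count_from(spec, pos + 1, new_gc, new_grun)
            else:
                raise ValueError(f"{seq!r} is not in the constrained language")
        return rank

    def decode(self, nmer: str) -> tuple[int, bool]:
        """Rank a block back to its bit value.

        A valid, in-range block inverts exactly (flag True).  An invalid or
        out-of-range block is mapped to the nearest valid in-range codeword
        by Hamming distance (ties to the lexicographically smallest) and
        flagged False: the downstream restoration stage is the error
        handler, so decoding never raises on content.
        """
        if len(nmer) != self.spec.n:
            raise ValueError(f"expected {self.spec.n}-mer, got {len(nmer)}")
        if self.spec.is_valid(nmer):
            r = self.rank(nmer)
            if r < (1 << self.k_bits):
                return r, True
        return self.rank(self._nearest_valid(nmer)), False

    def _nearest_valid(self, nmer: str) -> str:
        limit = 1 << self.k_bits
        for dist in range(1, self.spec.n + 1):
            best = None
            for pos_combo in itertools.combinations(range(self.spec.n), dist):
                for subs in itertools.product(BASES, repeat=dist):
                    if any(nmer[p] == s for p, s in zip(pos_combo, subs)):
                        continue
                    cand = list(nmer)
                    for p, s in zip(pos_combo, subs):
                        cand[p] = s
                    cand_s = "".join(cand)
                    if self.spec.is_valid(cand_s) and self.rank(cand_s) < limit:
                        if best is None or cand_s < best:
                            best = cand_s
            if best is not None:
                return best
        raise RuntimeError("no valid codeword found")  # pragma: no cover


# the two production codes
PAYLOAD_SPEC = ConstraintSpec(n=13, gc_lo=6, gc_hi=7)
ADDRESS_SPEC = ConstraintSpec(n=10, gc_lo=4, gc_hi=6)
PAYLOAD_BITS_PER_BLOCK = 22
ADDRESS_BITS = 16


def payload_code() -> BlockCode:
    return BlockCode(PAYLOAD_SPEC, PAYLOAD_BITS_PER_BLOCK)


def address_code() -> BlockCode:
    return BlockCode(ADDRESS_SPEC, ADDRESS_BITS)


# ---------------------------------------------------------------------------
# oligo layout and assembly
# ---------------------------------------------------------------------------


def _first_color_tags() -> dict[str, str]:
    """First lexicographic triple of 3-mers at pairwise Hamming distance 3,
    excluding tags containing "GG" (keeps cross-boundary G runs short)."""
    mers = ["".join(t) for t in itertools.product(BASES, repeat=3)]
    mers = [m for m in mers if "GG" not in m]

    def dist(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    for t1 in mers:
        for t2 in mers:
            if t2 <= t1 or dist(t1, t2) < 3:
                continue
            for t3 in mers:
                if t3 <= t2 or dist(t1, t3) < 3 or dist(t2, t3) < 3:
                    continue
                return {"R": t1, "G": t2, "B": t3}
    raise RuntimeError("no colour tag triple found")  # pragma: no cover


COLOR_TAGS = _first_color_tags()  # {'R': 'AAA', 'G': 'CCC', 'B': 'GTG'}
TAG_BY_SEQ = {v: k for k, v in COLOR_TAGS.items()}


@dataclass(frozen=True)
class OligoLayout:
    """Fixed anatomy of a 196-nt oligo."""

    primer_len: int = 20
    tag_len: int = 3
    address_len: int = 10
    n_payload_blocks: int = 11
    payload_block_len: int = 13

    @property
    def total_len(self) -> int:
        return (
            2 * self.primer_len
            + self.tag_len
            + self.address_len
            + self.n_payload_blocks * self.payload_block_len
        )

    @property
    def payload_capacity_bits(self) -> int:
        return self.n_payload_blocks * PAYLOAD_BITS_PER_BLOCK

    @property
    def overhead_nt(self) -> int:
        """Primer + tag + address nucleotides per oligo."""
        return 2 * self.primer_len + self.tag_len + self.address_len


DEFAULT_LAYOUT = OligoLayout()
assert DEFAULT_LAYOUT.total_len == 196
assert DEFAULT_LAYOUT.payload_capacity_bits == 242


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    pool: int  # intensity level 0..7


PRIMER_SPEC = ConstraintSpec(n=20, gc_lo=8, gc_hi=12)


class PrimerDesignError(RuntimeError):
    pass


def _three_prime_dimer(p: str, q: str, m: int) -> bool:
    """Proxy primer-dimer test: does the reverse complement of the 3'-terminal
    m nt of ``p`` occur anywhere in ``q``?"""
    return revcomp(p[-m:]) in q


def design_primers(
    n_pairs: int = 8,
    spec: ConstraintSpec = PRIMER_SPEC,
    min_pairwise_hamming: int = 8,
    max_3prime_complement: int = 5,
    seed: int = 0,
    budget: int = 200_000,
) -> list[PrimerPair]:
    """Rejection-sample primer pairs under combinatorial proxies for the
    Hamming-distance, correlation, balance and primer-dimer constraints."""
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    tries = 0
    while len(accepted) < 2 * n_pairs:
        if tries >= budget:
            raise PrimerDesignError(
                f"primer sampling budget exhausted after {tries} draws "
                f"({len(accepted)}/{2 * n_pairs} accepted)"
            )
        tries += 1
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=spec.n))
        if not spec.is_valid(cand):
            continue
        if _three_prime_dimer(cand, cand, max_3prime_complement):
            continue
        ok = True
        for prev in accepted:
            if sum(a != b for a, b in zip(cand, prev)) < min_pairwise_hamming:
                ok = False
                break
            if _three_prime_dimer(cand, prev, max_3prime_complement) or _three_prime_dimer(
                prev, cand, max_3prime_complement
            ):
                ok = False
                break
        if ok:
            accepted.append(cand)
    return [
        PrimerPair(forward=accepted[2 * i], reverse=accepted[2 * i + 1], pool=i)
        for i in range(n_pairs)
    ]


def audit_primers(
    primers: list[PrimerPair],
    spec: ConstraintSpec = PRIMER_SPEC,
    min_pairwise_hamming: int = 8,
    max_3prime_complement: int = 5,
) -> bool:
    seqs = [s for p in primers for s in (p.forward, p.reverse)]
    for s in seqs:
        if not spec.is_valid(s):
            return False
    for a, b in itertools.combinations(seqs, 2):
        if sum(x != y for x, y in zip(a, b)) < min_pairwise_hamming:
            return False
    for a in seqs:
        for b in seqs:
            if _three_prime_dimer(a, b, max_3prime_complement):
                return False
    return True


@dataclass
class ParsedOligo:
    pool: int | None
    primer_mismatches: int | None
    channel: str | None
    address: int
    address_valid: bool
    payload_bits: np.ndarray  # (242,) uint8
    payload_valid: list[bool]  # per block

    @property
    def all_valid(self) -> bool:
        return (
            self.pool is not None
            and self.channel is not None
            and self.address_valid
            and all(self.payload_valid)
        )


def assemble_oligo(
    primers: PrimerPair,
    channel: str,
    address: int,
    payload_bits: np.ndarray,
    layout: OligoLayout = DEFAULT_LAYOUT,
    addr_code: BlockCode | None = None,
    pay_code: BlockCode | None = None,
) -> str:
    """Assemble a full 196-nt oligo from its logical fields."""
    addr_code = addr_code or address_code()
    pay_code = pay_code or payload_code()
    if not primers.forward or not primers.reverse:
        raise ValueError("primer pair incomplete")
    for s in (primers.forward, primers.reverse):
        if not PRIMER_SPEC.is_valid(s):
            raise ValueError(f"primer {s!r} violates the constraint spec")
    bits = np.zeros(layout.payload_capacity_bits, dtype=np.uint8)
    payload_bits = np.asarray(payload_bits, dtype=np.uint8)
    if len(payload_bits) > layout.payload_capacity_bits:
        raise ValueError("payload exceeds oligo capacity")
    bits[: len(payload_bits)] = payload_bits
    blocks = []
    w = PAYLOAD_BITS_PER_BLOCK
    for i in range(layout.n_payload_blocks):
        value = int("".join(map(str, bits[i * w : (i + 1) * w])), 2)
        blocks.append(pay_code.encode(value))
    seq = (
        primers.forward
        + COLOR_TAGS[channel]
        + addr_code.encode(address)
        + "".join(blocks)
        + primers.reverse
    )
    assert len(seq) == layout.total_len
    return seq


def parse_oligo(
    seq: str,
    primer_book: list[PrimerPair],
    layout: OligoLayout = DEFAULT_LAYOUT,
    addr_code: BlockCode | None = None,
    pay_code: BlockCode | None = None,
    max_primer_mismatch: int = 2,
) -> ParsedOligo:
    """Split a 196-nt sequence at fixed offsets and decode every block."""
    if len(seq) != layout.total_len:
        raise ValueError(f"expected length {layout.total_len}, got {len(seq)}")
    addr_code = addr_code or address_code()
    pay_code = pay_code or payload_code()
    fwd = seq[: layout.primer_len]
    pool = None
    primer_mm = None
    for pair in primer_book:
        mm = sum(a != b for a, b in zip(fwd, pair.forward))
        if primer_mm is None or mm < primer_mm:
            primer_mm, pool = mm, pair.pool
    if primer_mm is None or primer_mm > max_primer_mismatch:
        pool = None
    off = layout.primer_len
    tag = seq[off : off + layout.tag_len]
    channel = None
    for tseq, ch in TAG_BY_SEQ.items():
        if sum(a != b for a, b in zip(tag, tseq)) <= 1:
            channel = ch
            break
    off += layout.tag_len
    addr_block = seq[off : off + layout.address_len]
    address, address_valid = addr_code.decode(addr_block)
    off += layout.address_len
    w = PAYLOAD_BITS_PER_BLOCK
    bits = np.zeros(layout.payload_capacity_bits, dtype=np.uint8)
    payload_valid = []
    for i in range(layout.n_payload_blocks):
        block = seq[off : off + layout.payload_block_len]
        value, valid = pay_code.decode(block)
        payload_valid.append(valid)
        for j in range(w):
            bits[i * w + j] = (value >> (w - 1 - j)) & 1
        off += layout.payload_block_len
    return ParsedOligo(
        pool=pool,
        primer_mismatches=primer_mm,
        channel=channel,
        address=address,
        address_valid=address_valid,
        payload_bits=bits,
        payload_valid=payload_valid,
    )


# ---------------------------------------------------------------------------
# oligo records and FASTA headers
# ---------------------------------------------------------------------------


@dataclass
class OligoRecord:
    """A designed oligo plus the structured metadata carried in its FASTA header."""

    seq: str
    pool: int
    image_id: int
    channel: str
    address: int
    kind: str = "data"  # data | header | parity
    copy: int = 0  # replicate index (headers may be replicated)

    @property
    def record_id(self) -> str:
        return (
            f"pool={self.pool} img={self.image_id} ch={self.channel} "
            f"addr={self.address} kind={self.kind} copy={self.copy}"
        )


def record_id_fields(record_id: str) -> dict[str, str]:
    fields = {}
    for token in record_id.split():
        if "=" in token:
            k, v = token.split("=", 1)
            fields[k] = v
    return fields
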
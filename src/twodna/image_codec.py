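"""Image <-> per-level bitstream codec.

An RGB image is split into its three colour channels, each channel is
quantized from 256 to 8 intensity levels (3 bits), linearized along a
Hilbert space-filling curve, and partitioned into eight subsets by
quantized level.  Within each level subset the pixel positions along the
curve are gap-encoded (differences of consecutive positions) and Huffman
coded, then chopped into independently decodable segments sized to the
payload capacity of a single oligo.  Each segment starts with a
fixed-width absolute position anchor so that the loss of one oligo
erases only the contiguous pixel run it carried.

Bit conventions: integer fields inside a segment are most-significant
bit first; byte containers written to disk use little-endian bit packing
(``numpy.packbits(bitorder="little")``).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

QUANT_LEVELS = 8
QUANT_STEP = 256 // QUANT_LEVELS  # 32

# Gap alphabet: gaps 1..15 are coded directly; larger gaps are coded as
# an escape symbol followed by a 20-bit literal.
ESCAPE_SYMBOL = 0
MAX_DIRECT_GAP = 15
GAP_ALPHABET = tuple(range(0, MAX_DIRECT_GAP + 1))  # 0 is the escape
LITERAL_BITS = 20
ANCHOR_BITS_CAP = 20
COUNT_BITS = 8  # per-segment gap-count field
CODE_LENGTH_BITS = 5  # fixed width of one serialized code length


class CapacityError(ValueError):
    """Oligo payload capacity too small to hold anchor + one symbol."""


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


@dataclass
class QuantizedImage:
    """Per-channel 3-bit raster plus decode-side provenance masks."""

    levels: np.ndarray  # (3, H, W) uint8, values 0..7
    missing_mask: np.ndarray  # (3, H, W) bool
    conflict_mask: np.ndarray  # (3, H, W) bool

    @property
    def height(self) -> int:
        return self.levels.shape[1]

    @property
    def width(self) -> int:
        return self.levels.shape[2]


def quantize(image: np.ndarray) -> QuantizedImage:
    """Quantize an ``(H, W, 3)`` uint8 RGB image to 8 levels per channel.

    Level = floor(intensity / 32); the encode side carries all-false masks.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    levels = (img.astype(np.uint16) // QUANT_STEP).astype(np.uint8)
    levels = np.moveaxis(levels, 2, 0)
    shape = levels.shape
    return QuantizedImage(
        levels=levels,
        missing_mask=np.zeros(shape, dtype=bool),
        conflict_mask=np.zeros(shape, dtype=bool),
    )


def dequantize(qimg: QuantizedImage) -> np.ndarray:
    """Map levels back to 8-bit intensities at the bin midpoint 32*level + 16."""
    levels = np.moveaxis(qimg.levels, 0, 2)
    return (levels.astype(np.uint16) * QUANT_STEP + QUANT_STEP // 2).astype(np.uint8)


# ---------------------------------------------------------------------------
# Hilbert order
# ---------------------------------------------------------------------------


@dataclass
class HilbertOrder:
    """Hilbert-curve visiting order of the in-image cells of a padded square."""

    cells: np.ndarray  # (N, 2) int64 of (row, col), N = height * width
    side: int  # padded side length, a power of two
    height: int
    width: int

    def __len__(self) -> int:
        return len(self.cells)

    def flat_index(self) -> np.ndarray:
        """Row-major flat index of each visited cell."""
        return self.cells[:, 0] * self.width + self.cells[:, 1]


def _hilbert_d2xy(order_k: int, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized curve-index -> (x, y) on a 2^k x 2^k grid (first cell (0,0))."""
    x = np.zeros_like(d)
    y = np.zeros_like(d)
    t = d.copy()
    s = 1
    while s < (1 << order_k):
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        # rotate quadrant
        flip = ry == 0
        swap = flip & (rx == 1)
        x[swap], y[swap] = (s - 1 - x[swap]), (s - 1 - y[swap])
        x[flip], y[flip] = y[flip].copy(), x[flip].copy()
        x = x + s * rx
        y = y + s * ry
        t //= 4
        s *= 2
    return x, y


def hilbert_order(height: int, width: int) -> HilbertOrder:
    """Hilbert order over the minimal padded 2^k square, out-of-image cells dropped."""
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be >= 1")
    side = 1
    k = 0
    while side < max(height, width):
        side *= 2
        k += 1
    d = np.arange(side * side, dtype=np.int64)
    x, y = _hilbert_d2xy(k, d)
    # convention: x is the column, y is the row
    keep = (y < height) & (x < width)
    cells = np.stack([y[keep], x[keep]], axis=1)
    return HilbertOrder(cells=cells, side=side, height=height, width=width)


# ---------------------------------------------------------------------------
# Huffman coding
# ---------------------------------------------------------------------------


@dataclass
class HuffmanCodebook:
    """Canonical prefix code over a small integer alphabet.

    Codes are assigned canonically from the code lengths: symbols sorted by
    (length, symbol value) receive consecutive codewords.  Ties during tree
    construction are broken deterministically (lowest total weight first,
    then smallest contained symbol), so identical counts always yield an
    identical codebook.
    """

    lengths: dict[int, int]  # symbol -> code length in bits
    codes: dict[int, tuple[int, int]] = field(default_factory=dict)  # symbol -> (code, length)

    def __post_init__(self) -> None:
        if not self.codes:
            self.codes = _canonical_codes(self.lengths)
        # decode table: (length, code) -> symbol
        self._decode = {(ln, code): sym for sym, (code, ln) in self.codes.items()}

    def encode_symbol(self, symbol: int) -> list[int]:
        code, ln = self.codes[symbol]
        return [(code >> (ln - 1 - i)) & 1 for i in range(ln)]

    def mean_length(self, counts: dict[int, int]) -> float:
        total = sum(counts.values())
        return sum(self.lengths[s] * c for s, c in counts.items() if c) / total


def _canonical_codes(lengths: dict[int, int]) -> dict[int, tuple[int, int]]:
    codes: dict[int, tuple[int, int]] = {}
    code = 0
    prev_len = 0
    for sym in sorted(lengths, key=lambda s: (lengths[s], s)):
        ln = lengths[sym]
        code <<= ln - prev_len
        codes[sym] = (code, ln)
        code += 1
        prev_len = ln
    return codes


def build_huffman(counts: dict[int, int]) -> HuffmanCodebook:
    """Optimal canonical prefix code for the given symbol frequencies."""
    active = {s: c for s, c in counts.items() if c > 0}
    if not active:
        raise ValueError("empty frequency table")
    if len(active) == 1:
        # degenerate code: a single symbol still gets one bit
        return HuffmanCodebook(lengths={next(iter(active)): 1})
    # heap items: (weight, smallest contained symbol, member symbols)
    heap = [(c, s, (s,)) for s, c in active.items()]
    heapq.heapify(heap)
    lengths = dict.fromkeys(active, 0)
    while len(heap) > 1:
        w1, s1, m1 = heapq.heappop(heap)
        w2, s2, m2 = heapq.heappop(heap)
        for s in m1 + m2:
            lengths[s] += 1
        heapq.heappush(heap, (w1 + w2, min(s1, s2), m1 + m2))
    return HuffmanCodebook(lengths=lengths)


def serialize_codebook(book: HuffmanCodebook) -> np.ndarray:
    """Fixed-width code-length list over the full gap alphabet (0 = absent)."""
    bits: list[int] = []
    for sym in GAP_ALPHABET:
        ln = book.lengths.get(sym, 0)
        if ln >= (1 << CODE_LENGTH_BITS):
            raise ValueError(f"code length {ln} exceeds the serialized width")
        bits.extend(int_to_bits(ln, CODE_LENGTH_BITS))
    return np.array(bits, dtype=np.uint8)


def deserialize_codebook(bits: np.ndarray) -> HuffmanCodebook:
    lengths: dict[int, int] = {}
    for i, sym in enumerate(GAP_ALPHABET):
        ln = bits_to_int(bits[i * CODE_LENGTH_BITS : (i + 1) * CODE_LENGTH_BITS])
        if ln:
            lengths[sym] = ln
    if not lengths:
        raise ValueError("serialized codebook is empty")
    return HuffmanCodebook(lengths=lengths)


CODEBOOK_BITS = len(GAP_ALPHABET) * CODE_LENGTH_BITS


# ---------------------------------------------------------------------------
# bit helpers
# ---------------------------------------------------------------------------


def int_to_bits(value: int, width: int) -> list[int]:
    if value < 0 or value >= (1 << width):
        raise ValueError(f"value {value} does not fit in {width} bits")
    return [(value >> (width - 1 - i)) & 1 for i in range(width)]


def bits_to_int(bits) -> int:
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value


class _BitReader:
    def __init__(self, bits: np.ndarray):
        self.bits = np.asarray(bits, dtype=np.uint8)
        self.pos = 0

    def read_int(self, width: int) -> int:
        if self.pos + width > len(self.bits):
            raise ValueError("bit stream exhausted")
        value = bits_to_int(self.bits[self.pos : self.pos + width])
        self.pos += width
        return value

    def read_symbol(self, book: HuffmanCodebook) -> int:
        code = 0
        ln = 0
        max_len = max(book.lengths.values())
        while ln <= max_len:
            if self.pos >= len(self.bits):
                raise ValueError("bit stream exhausted mid-symbol")
            code = (code << 1) | int(self.bits[self.pos])
            self.pos += 1
            ln += 1
            sym = book._decode.get((ln, code))
            if sym is not None:
                return sym
        raise ValueError("invalid Huffman code in stream")


# ---------------------------------------------------------------------------
# level segments
# ---------------------------------------------------------------------------


@dataclass
class LevelSegment:
    """One oligo-sized, independently decodable slice of a level stream."""

    channel: str  # 'R' | 'G' | 'B'
    level: int  # 0..7
    index: int  # 1-based data-segment index within the level stream
    anchor: int  # absolute Hilbert position of the first pixel
    n_gaps: int
    bits: np.ndarray  # payload bits, padded to capacity


@dataclass
class LevelStream:
    """All segments of one (channel, level) subset plus its codebook."""

    channel: str
    level: int
    codebook: HuffmanCodebook | None
    segments: list[LevelSegment]

    def header_bits(self, capacity_bits: int) -> np.ndarray:
        """Serialized header payload: 3-bit level tag + codebook lengths."""
        bits = int_to_bits(self.level, 3)
        if self.codebook is not None:
            bits = bits + list(serialize_codebook(self.codebook))
        out = np.zeros(capacity_bits, dtype=np.uint8)
        out[: len(bits)] = bits
        return out


def anchor_width(n_pixels: int) -> int:
    width = max(1, int(np.ceil(np.log2(max(n_pixels, 2)))))
    return min(width, ANCHOR_BITS_CAP)


def _gap_symbols(gap: int) -> tuple[int, int | None]:
    """Symbol (and literal, if escaped) coding one positive gap."""
    if gap <= 0:
        raise ValueError("gaps must be positive")
    if gap <= MAX_DIRECT_GAP:
        return gap, None
    if gap >= (1 << LITERAL_BITS):
        raise ValueError(f"gap {gap} exceeds the {LITERAL_BITS}-bit literal")
    return ESCAPE_SYMBOL, gap


def encode_channel(
    qchannel: np.ndarray,
    order: HilbertOrder,
    capacity_bits: int,
    channel: str = "R",
) -> dict[int, LevelStream]:
    """Encode one quantized channel into per-level segment streams.

    Pixels are walked in Hilbert order; for every intensity level the
    positions of its pixels are gap-coded and Huffman-coded, then packed
    greedily into segments of at most ``capacity_bits`` bits.  Every
    segment opens with an absolute anchor and a gap count so it decodes
    in isolation.
    """
    flat = np.asarray(qchannel).ravel()
    linear = flat[order.flat_index()]
    n_pix = len(linear)
    a_bits = anchor_width(n_pix)
    streams: dict[int, LevelStream] = {}
    for lvl in range(QUANT_LEVELS):
        positions = np.flatnonzero(linear == lvl)
        if len(positions) == 0:
            continue
        gaps = np.diff(positions)
        counts = dict.fromkeys(GAP_ALPHABET, 0)
        for g in gaps:
            sym, _ = _gap_symbols(int(g))
            counts[sym] += 1
        book = build_huffman(counts) if any(counts.values()) else None
        max_sym_bits = (
            max(book.lengths.values()) + LITERAL_BITS if book is not None else 0
        )
        if capacity_bits < a_bits + COUNT_BITS + max_sym_bits:
            raise CapacityError(
                f"capacity {capacity_bits} bits cannot hold anchor + one coded gap"
            )
        segments: list[LevelSegment] = []
        i = 0  # index into positions
        while i < len(positions):
            anchor = int(positions[i])
            seg_bits: list[int] = int_to_bits(anchor, a_bits)
            n_gaps = 0
            j = i + 1
            budget = capacity_bits - a_bits - COUNT_BITS
            used = 0
            while j < len(positions) and n_gaps < (1 << COUNT_BITS) - 1:
                sym, literal = _gap_symbols(int(positions[j] - positions[j - 1]))
                cost = book.lengths[sym] + (LITERAL_BITS if literal is not None else 0)
                if used + cost > budget:
                    break
                seg_bits.extend(book.encode_symbol(sym))
                if literal is not None:
                    seg_bits.extend(int_to_bits(literal, LITERAL_BITS))
                used += cost
                n_gaps += 1
                j += 1
            # splice the gap count in after the anchor
            count_field = int_to_bits(n_gaps, COUNT_BITS)
            seg_bits[a_bits:a_bits] = count_field
            padded = np.zeros(capacity_bits, dtype=np.uint8)
            padded[: len(seg_bits)] = seg_bits
            segments.append(
                LevelSegment(
                    channel=channel,
                    level=lvl,
                    index=len(segments) + 1,
                    anchor=anchor,
                    n_gaps=n_gaps,
                    bits=padded,
                )
            )
            i = j
        streams[lvl] = LevelStream(channel=channel, level=lvl, codebook=book, segments=segments)
    return streams


def decode_segment_positions(
    bits: np.ndarray, book: HuffmanCodebook | None, n_pixels: int
) -> np.ndarray:
    """Recover the absolute Hilbert positions claimed by one segment.

    Raises ``ValueError`` when the payload is internally inconsistent
    (anchor out of range, non-increasing positions, truncated stream);
    callers demote such segments to *corrupt*.
    """
    a_bits = anchor_width(n_pixels)
    reader = _BitReader(bits)
    anchor = reader.read_int(a_bits)
    if anchor >= n_pixels:
        raise ValueError(f"anchor {anchor} out of range (n_pixels={n_pixels})")
    n_gaps = reader.read_int(COUNT_BITS)
    positions = [anchor]
    pos = anchor
    for _ in range(n_gaps):
        if book is None:
            raise ValueError("segment declares gaps but the stream has no codebook")
        sym = reader.read_symbol(book)
        gap = reader.read_int(LITERAL_BITS) if sym == ESCAPE_SYMBOL else sym
        if gap <= 0:
            raise ValueError("non-positive decoded gap")
        pos += gap
        if pos >= n_pixels:
            raise ValueError("decoded position overflows the image")
        positions.append(pos)
    return np.array(positions, dtype=np.int64)


def decode_channel(
    streams: dict[int, LevelStream],
    statuses: dict[tuple[int, int], str],
    order: HilbertOrder,
    height: int,
    width: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reassemble one channel from surviving segments.

    ``statuses`` maps ``(level, segment_index)`` to ``"ok"``, ``"errored"``
    (decode attempted; damage is caught downstream), ``"missing"`` or
    ``"corrupt"``.  Pixels claimed by no surviving segment are flagged in
    the missing mask and filled with level 0; pixels claimed by more than
    one segment are flagged as conflicts and the lowest claiming level
    wins.
    """
    n_pix = height * width
    claim_count = np.zeros(n_pix, dtype=np.int32)
    claim_level = np.full(n_pix, QUANT_LEVELS, dtype=np.int16)
    for lvl, stream in streams.items():
        for seg in stream.segments:
            status = statuses.get((lvl, seg.index), "missing")
            if status in ("missing", "corrupt"):
                continue
            try:
                positions = decode_segment_positions(seg.bits, stream.codebook, n_pix)
            except ValueError:
                continue  # demoted to corrupt: claims nothing
            claim_count[positions] += 1
            claim_level[positions] = np.minimum(claim_level[positions], lvl)
    levels_linear = np.where(claim_count > 0, claim_level, 0).astype(np.uint8)
    missing_linear = claim_count == 0
    conflict_linear = claim_count > 1
    flat_idx = order.flat_index()
    raster = np.zeros(n_pix, dtype=np.uint8)
    missing = np.zeros(n_pix, dtype=bool)
    conflict = np.zeros(n_pix, dtype=bool)
    raster[flat_idx] = levels_linear
    missing[flat_idx] = missing_linear
    conflict[flat_idx] = conflict_linear
    shape = (height, width)
    return raster.reshape(shape), missing.reshape(shape), conflict.reshape(shape)


def encode_image(qimg: QuantizedImage, order: HilbertOrder, capacity_bits: int) -> dict[str, dict[int, LevelStream]]:
    """Encode all three channels; returns ``{channel: {level: stream}}``."""
    out = {}
    for ci, ch in enumerate("RGB"):
        out[ch] = encode_channel(qimg.levels[ci], order, capacity_bits, channel=ch)
    return out


def decode_image(
    streams_by_channel: dict[str, dict[int, LevelStream]],
    statuses_by_channel: dict[str, dict[tuple[int, int], str]],
    order: HilbertOrder,
    height: int,
    width: int,
) -> QuantizedImage:
    levels = np.zeros((3, height, width), dtype=np.uint8)
    missing = np.zeros((3, height, width), dtype=bool)
    conflict = np.zeros((3, height, width), dtype=bool)
    for ci, ch in enumerate("RGB"):
        raster, miss, conf = decode_channel(
            streams_by_channel.get(ch, {}),
            statuses_by_channel.get(ch, {}),
            order,
            height,
            width,
        )
        levels[ci], missing[ci], conflict[ci] = raster, miss, conf
    return QuantizedImage(levels=levels, missing_mask=missing, conflict_mask=conflict)


def total_coded_bits(streams_by_channel: dict[str, dict[int, LevelStream]], capacity_bits: int) -> int:
    """Total payload bits across all data and header segments."""
    total = 0
    for streams in streams_by_channel.values():
        for stream in streams.values():
            total += capacity_bits  # header segment
            total += capacity_bits * len(stream.segments)
    return total


def pack_bits_le(bits: np.ndarray) -> bytes:
    """Little-endian bit packing for on-disk containers."""
    return np.packbits(np.asarray(bits, dtype=np.uint8), bitorder="little").tobytes()


def unpack_bits_le(data: bytes, n_bits: int) -> np.ndarray:
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8), bitorder="little")
    return bits[:n_bits]
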
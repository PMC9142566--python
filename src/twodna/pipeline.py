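"""End-to-end pipeline: image -> oligos -> channel -> consensus -> image.

Address semantics: of the 16 address bits, the high 4 bits index the
image and the low 12 bits index the segment within its (channel, level)
stream; segment 0 is the stream's header (Huffman codebook), data
segments count from 1.  Pools are global across images within a run:
pool i holds every oligo of intensity level i, and the colour tag
carries the channel, so an oligo's identity is (pool, tag, address).
Header oligos are replicated (default 3 copies) because each one is the
decoding key for its whole level stream.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import consensus as cons
from . import dna_codec, image_codec, restoration
from .channel_sim import ChannelModel, Read, simulate_reads
from .dna_codec import DEFAULT_LAYOUT, OligoLayout, OligoRecord, PrimerPair
from .image_codec import HilbertOrder, LevelSegment, LevelStream, QuantizedImage

logger = logging.getLogger("twodna")

IMAGE_ID_BITS = 4
SEG_INDEX_BITS = 12


@dataclass
class PipelineConfig:
    """Serializable description of one storage run."""

    p_sub: float = 0.008
    p_drop: float = 0.007
    coverage: float = 30.0
    seed: int = 0
    primer_seed: int = 12345
    header_copies: int = 3
    max_primer_mismatch: int = 2
    min_cluster_size: int = 1
    # restoration
    tau_agree: int = 1
    tau_floor: int = 3
    tail: float = 0.01
    min_run: int = 4
    do_smooth: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def make_address(image_id: int, seg_index: int) -> int:
    if not (0 <= image_id < (1 << IMAGE_ID_BITS)):
        raise ValueError(f"image id {image_id} exceeds {IMAGE_ID_BITS} bits")
    if not (0 <= seg_index < (1 << SEG_INDEX_BITS)):
        raise ValueError(f"segment index {seg_index} exceeds {SEG_INDEX_BITS} bits")
    return (image_id << SEG_INDEX_BITS) | seg_index


def split_address(address: int) -> tuple[int, int]:
    return address >> SEG_INDEX_BITS, address & ((1 << SEG_INDEX_BITS) - 1)


@dataclass
class EncodedImage:
    height: int
    width: int
    image_id: int
    order: HilbertOrder
    streams: dict[str, dict[int, LevelStream]]
    records: list[OligoRecord]

    def data_records(self) -> list[OligoRecord]:
        return [r for r in self.records if r.kind == "data"]


def encode_image_to_oligos(
    image: np.ndarray,
    image_id: int,
    primer_book: list[PrimerPair],
    layout: OligoLayout = DEFAULT_LAYOUT,
    header_copies: int = 3,
) -> EncodedImage:
    """Quantize, compress and map one RGB image to designed oligos."""
    qimg = image_codec.quantize(image)
    h, w = qimg.height, qimg.width
    order = image_codec.hilbert_order(h, w)
    streams = image_codec.encode_image(qimg, order, layout.payload_capacity_bits)
    addr_code = dna_codec.address_code()
    pay_code = dna_codec.payload_code()
    primers = {p.pool: p for p in primer_book}
    records: list[OligoRecord] = []
    for ch, by_level in streams.items():
        for lvl, stream in by_level.items():
            if len(stream.segments) >= (1 << SEG_INDEX_BITS):
                raise ValueError("level stream exceeds the 12-bit segment index")
            header_bits = stream.header_bits(layout.payload_capacity_bits)
            addr = make_address(image_id, 0)
            seq = dna_codec.assemble_oligo(
                primers[lvl], ch, addr, header_bits, layout, addr_code, pay_code
            )
            for copy in range(header_copies):
                records.append(
                    OligoRecord(
                        seq=seq,
                        pool=lvl,
                        image_id=image_id,
                        channel=ch,
                        address=addr,
                        kind="header",
                        copy=copy,
                    )
                )
            for seg in stream.segments:
                addr = make_address(image_id, seg.index)
                seq = dna_codec.assemble_oligo(
                    primers[lvl], ch, addr, seg.bits, layout, addr_code, pay_code
                )
                records.append(
                    OligoRecord(
                        seq=seq,
                        pool=lvl,
                        image_id=image_id,
                        channel=ch,
                        address=addr,
                        kind="data",
                    )
                )
    return EncodedImage(
        height=h, width=w, image_id=image_id, order=order, streams=streams, records=records
    )


@dataclass
class DecodedImage:
    qimg: QuantizedImage
    image: np.ndarray  # dequantized 8-bit RGB
    report: cons.RecoveryReport
    stats: cons.BinningStats


def decode_reads_to_image(
    reads: list[Read],
    encoded: EncodedImage,
    primer_book: list[PrimerPair],
    layout: OligoLayout = DEFAULT_LAYOUT,
    max_primer_mismatch: int = 2,
    min_cluster_size: int = 1,
) -> DecodedImage:
    """Consensus-decode reads and rebuild the quantized image with masks.

    Only the design manifest (which addresses exist, their kinds and the
    per-stream geometry) is consulted; payload content comes from the
    reads alone.
    """
    addr_code = dna_codec.address_code()
    pay_code = dna_codec.payload_code()
    clusters, stats = cons.bin_reads(
        reads, primer_book, layout, addr_code, max_primer_mismatch
    )
    report, parsed = cons.classify(
        clusters,
        encoded.records,
        primer_book,
        layout,
        addr_code,
        pay_code,
        min_cluster_size,
    )
    # rebuild per-(channel, level) streams from consensus payloads
    streams: dict[str, dict[int, LevelStream]] = {ch: {} for ch in "RGB"}
    statuses: dict[str, dict[tuple[int, int], str]] = {ch: {} for ch in "RGB"}
    design = {}
    for rec in encoded.records:
        design.setdefault((rec.pool, rec.channel, rec.address), rec)
    for (pool, ch, addr), rec in design.items():
        _, seg_idx = split_address(addr)
        status = report.statuses[(pool, ch, addr)]
        if seg_idx == 0:  # header: recover the codebook
            codebook = None
            if status != "missing":
                bits = parsed[(pool, ch, addr)].payload_bits
                try:
                    lvl_tag = image_codec.bits_to_int(bits[:3])
                    codebook = image_codec.deserialize_codebook(
                        bits[3 : 3 + image_codec.CODEBOOK_BITS]
                    )
                    if lvl_tag != pool:
                        logger.warning(
                            "header level tag %d != pool %d", lvl_tag, pool
                        )
                except ValueError:
                    codebook = None
            stream = streams[ch].setdefault(
                pool, LevelStream(channel=ch, level=pool, codebook=None, segments=[])
            )
            stream.codebook = codebook
        else:
            stream = streams[ch].setdefault(
                pool, LevelStream(channel=ch, level=pool, codebook=None, segments=[])
            )
            if status == "missing":
                bits = np.zeros(layout.payload_capacity_bits, dtype=np.uint8)
            else:
                bits = parsed[(pool, ch, addr)].payload_bits
            stream.segments.append(
                LevelSegment(
                    channel=ch, level=pool, index=seg_idx, anchor=0, n_gaps=0, bits=bits
                )
            )
            statuses[ch][(pool, seg_idx)] = (
                "ok" if status == "recovered" else ("errored" if status == "errored" else "missing")
            )
    # NB: a stream whose header (codebook) did not survive still decodes its
    # anchor-only segments; gap-bearing segments fail inside the image
    # decoder and are demoted to corrupt there.
    for ch in "RGB":
        for stream in streams[ch].values():
            stream.segments.sort(key=lambda s: s.index)
    qimg = image_codec.decode_image(
        streams, statuses, encoded.order, encoded.height, encoded.width
    )
    return DecodedImage(
        qimg=qimg,
        image=image_codec.dequantize(qimg),
        report=report,
        stats=stats,
    )


# ---------------------------------------------------------------------------
# densities and reporting
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    n_oligos: int = 0
    n_data: int = 0
    n_header: int = 0
    n_parity: int = 0
    n_recovered: int = 0
    n_errored: int = 0
    n_missing: int = 0
    total_raw_bits: int = 0
    total_nts: int = 0
    raw_density: float = 0.0
    quantized_density: float = 0.0
    overhead_pct: float = 0.0
    coded_bits: int = 0
    compression_ratio: float = 0.0  # coded bits / (3 bits x pixels x channels)
    psnr_raw: float = 0.0
    psnr_restored: float = 0.0
    ssim_raw: float = 0.0
    ssim_restored: float = 0.0
    extras: dict = field(default_factory=dict)


def report_densities(
    total_raw_bits: int, total_nts: int, layout: OligoLayout = DEFAULT_LAYOUT
) -> dict[str, float]:
    """Information densities and structural overhead.

    raw density: stored bits per designed nucleotide, measured against the
    original 8-bit image files; quantized density: the same against the
    3-bit quantized files (a factor 3/8); overhead: primer + tag + address
    nucleotides as a fraction of the 196-nt oligo.
    """
    if total_nts <= 0:
        raise ValueError("total nucleotides must be positive")
    raw = total_raw_bits / total_nts
    return {
        "raw_density": raw,
        "quantized_density": raw * 3.0 / 8.0,
        "overhead_pct": 100.0 * layout.overhead_nt / layout.total_len,
    }


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig,
    primer_book: list[PrimerPair] | None = None,
    layout: OligoLayout = DEFAULT_LAYOUT,
) -> tuple[RunReport, DecodedImage, np.ndarray, EncodedImage]:
    """Encode -> simulate -> decode -> restore one image; fully seeded."""
    if primer_book is None:
        primer_book = dna_codec.design_primers(seed=config.primer_seed)
    encoded = encode_image_to_oligos(
        image, 0, primer_book, layout, header_copies=config.header_copies
    )
    model = ChannelModel(
        p_sub=config.p_sub,
        p_drop=config.p_drop,
        coverage=config.coverage,
        seed=config.seed,
    )
    reads = simulate_reads([(r.record_id, r.seq) for r in encoded.records], model)
    decoded = decode_reads_to_image(
        reads,
        encoded,
        primer_book,
        layout,
        max_primer_mismatch=config.max_primer_mismatch,
        min_cluster_size=config.min_cluster_size,
    )
    restored, mask = restoration.restore(
        decoded.image,
        decoded.qimg,
        encoded.order,
        do_smooth=config.do_smooth,
        tau_agree=config.tau_agree,
        tau_floor=config.tau_floor,
        tail=config.tail,
        min_run=config.min_run,
    )
    qref = image_codec.dequantize(image_codec.quantize(image))
    h, w = qref.shape[:2]
    raw_bits = h * w * 24
    total_nts = len(encoded.records) * layout.total_len
    dens = report_densities(raw_bits, total_nts, layout)
    coded_bits = image_codec.total_coded_bits(
        encoded.streams, layout.payload_capacity_bits
    )
    report = RunReport(
        n_oligos=len(encoded.records),
        n_data=sum(1 for r in encoded.records if r.kind == "data"),
        n_header=sum(1 for r in encoded.records if r.kind == "header"),
        n_recovered=decoded.report.n_recovered,
        n_errored=decoded.report.n_errored,
        n_missing=decoded.report.n_missing,
        total_raw_bits=raw_bits,
        total_nts=total_nts,
        raw_density=dens["raw_density"],
        quantized_density=dens["quantized_density"],
        overhead_pct=dens["overhead_pct"],
        coded_bits=coded_bits,
        compression_ratio=coded_bits / (h * w * 3 * 3),
        psnr_raw=restoration.psnr(decoded.image, qref),
        psnr_restored=restoration.psnr(restored, qref),
        ssim_raw=restoration.ssim(decoded.image, qref),
        ssim_restored=restoration.ssim(restored, qref),
        extras={"n_masked": int(mask.flags.sum()), "binned": decoded.stats.binned},
    )
    return report, decoded, restored, encoded


def write_manifest(records: list[OligoRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("pool\timg\tch\taddr\tkind\tcopy\n")
        for r in records:
            fh.write(
                f"{r.pool}\t{r.image_id}\t{r.channel}\t{r.address}\t{r.kind}\t{r.copy}\n"
            )
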
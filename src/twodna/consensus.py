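"""Address-binned consensus reconstruction of oligos from reads.

Reads of the designed length whose address block decodes to a valid
codeword and whose forward primer matches a pool within a small Hamming
tolerance are grouped by (pool, colour tag, address value).  Each
cluster is reduced to a per-position majority consensus (ties to the
lexicographically smallest base).  Designed oligos are then classified
as recovered, errored or missing; those statuses drive the missing /
corrupt flags consumed by the image decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna_codec
from .channel_sim import Read, matrix_to_seqs, seqs_to_matrix
from .dna_codec import BlockCode, OligoLayout, OligoRecord, PrimerPair

ClusterKey = tuple[int, str, int]  # (pool, channel, address value)


@dataclass
class ReadCluster:
    pool: int
    channel: str
    address: int
    reads: list[str] = field(default_factory=list)
    consensus: str | None = None
    agreement: float | None = None  # mean per-position majority fraction

    @property
    def key(self) -> ClusterKey:
        return (self.pool, self.channel, self.address)


@dataclass
class BinningStats:
    n_reads: int = 0
    wrong_length: int = 0
    no_primer_match: int = 0
    invalid_tag: int = 0
    invalid_address: int = 0
    binned: int = 0


@dataclass
class RecoveryReport:
    """Per-oligo recovery outcome over the design manifest."""

    statuses: dict[ClusterKey, str]  # recovered | errored | missing
    n_recovered: int
    n_errored: int
    n_missing: int
    n_designed: int
    n_exact: int | None = None  # consensus identical to design (when known)

    def counts_partition(self) -> bool:
        return self.n_recovered + self.n_errored + self.n_missing == self.n_designed


def bin_reads(
    reads: list[Read],
    primer_book: list[PrimerPair],
    layout: OligoLayout = dna_codec.DEFAULT_LAYOUT,
    addr_code: BlockCode | None = None,
    max_primer_mismatch: int = 2,
) -> tuple[dict[ClusterKey, ReadCluster], BinningStats]:
    """Bin reads by (pool, tag, address); invalid-address reads are discarded."""
    addr_code = addr_code or dna_codec.address_code()
    stats = BinningStats(n_reads=len(reads))
    good = [r for r in reads if len(r.seq) == layout.total_len]
    stats.wrong_length = len(reads) - len(good)
    clusters: dict[ClusterKey, ReadCluster] = {}
    if not good:
        return clusters, stats
    mat = seqs_to_matrix([r.seq for r in good])
    # vectorized primer assignment over the forward primer window
    fwd = mat[:, : layout.primer_len]
    primer_mat = seqs_to_matrix([p.forward for p in primer_book])
    mism = (fwd[:, None, :] != primer_mat[None, :, :]).sum(axis=2)
    best_pool = mism.argmin(axis=1)
    best_mm = mism[np.arange(len(good)), best_pool]
    pools = np.array([p.pool for p in primer_book])[best_pool]
    # vectorized tag assignment
    t0 = layout.primer_len
    tags = mat[:, t0 : t0 + layout.tag_len]
    tag_seqs = list(dna_codec.TAG_BY_SEQ)
    tag_mat = seqs_to_matrix(tag_seqs)
    tag_mism = (tags[:, None, :] != tag_mat[None, :, :]).sum(axis=2)
    best_tag = tag_mism.argmin(axis=1)
    tag_ok = tag_mism[np.arange(len(good)), best_tag] <= 1
    channels = [dna_codec.TAG_BY_SEQ[tag_seqs[i]] for i in best_tag]
    a0 = t0 + layout.tag_len
    addr_strs = matrix_to_seqs(mat[:, a0 : a0 + layout.address_len])
    limit = 1 << addr_code.k_bits
    for i, read in enumerate(good):
        if best_mm[i] > max_primer_mismatch:
            stats.no_primer_match += 1
            continue
        if not tag_ok[i]:
            stats.invalid_tag += 1
            continue
        addr_s = addr_strs[i]
        if not addr_code.spec.is_valid(addr_s):
            stats.invalid_address += 1
            continue
        addr = addr_code.rank(addr_s)
        if addr >= limit:
            stats.invalid_address += 1
            continue
        key = (int(pools[i]), channels[i], addr)
        cluster = clusters.get(key)
        if cluster is None:
            cluster = clusters[key] = ReadCluster(*key)
        cluster.reads.append(read.seq)
        stats.binned += 1
    return clusters, stats


def consensus_call(cluster: ReadCluster) -> str:
    """Per-position majority base; ties break to the smallest base (A<C<G<T)."""
    if not cluster.reads:
        raise ValueError("cluster has no member reads")
    mat = seqs_to_matrix(cluster.reads)
    votes = np.zeros((4, mat.shape[1]), dtype=np.int32)
    for b in range(4):
        votes[b] = (mat == b).sum(axis=0)
    winners = votes.argmax(axis=0).astype(np.uint8)  # argmax -> first max: A wins ties
    cluster.consensus = matrix_to_seqs(winners[None, :])[0]
    cluster.agreement = float(votes.max(axis=0).mean() / mat.shape[0])
    return cluster.consensus


def classify(
    clusters: dict[ClusterKey, ReadCluster],
    designed: list[OligoRecord],
    primer_book: list[PrimerPair],
    layout: OligoLayout = dna_codec.DEFAULT_LAYOUT,
    addr_code: BlockCode | None = None,
    pay_code: BlockCode | None = None,
    min_cluster_size: int = 1,
) -> tuple[RecoveryReport, dict[ClusterKey, dna_codec.ParsedOligo]]:
    """Classify every designed oligo and parse the usable consensus payloads.

    recovered: a cluster exists, meets the size floor, and its consensus
    parses with every block valid at the expected address.  errored: a
    cluster exists but some block is invalid (nearest-codeword payloads are
    still handed downstream; restoration is the error handler).  missing:
    no cluster.
    """
    addr_code = addr_code or dna_codec.address_code()
    pay_code = pay_code or dna_codec.payload_code()
    design_keys: dict[ClusterKey, str] = {}
    design_seqs: dict[ClusterKey, str] = {}
    for rec in designed:
        key = (rec.pool, rec.channel, rec.address)
        design_keys[key] = rec.kind
        design_seqs.setdefault(key, rec.seq)
    statuses: dict[ClusterKey, str] = {}
    parsed: dict[ClusterKey, dna_codec.ParsedOligo] = {}
    n_exact = 0
    for key in design_keys:
        cluster = clusters.get(key)
        if cluster is None or len(cluster.reads) < min_cluster_size:
            statuses[key] = "missing"
            continue
        cons = cluster.consensus or consensus_call(cluster)
        po = dna_codec.parse_oligo(
            cons, primer_book, layout, addr_code=addr_code, pay_code=pay_code
        )
        parsed[key] = po
        if po.all_valid and po.address == key[2]:
            statuses[key] = "recovered"
        else:
            statuses[key] = "errored"
        if cons == design_seqs[key]:
            n_exact += 1
    report = RecoveryReport(
        statuses=statuses,
        n_recovered=sum(1 for s in statuses.values() if s == "recovered"),
        n_errored=sum(1 for s in statuses.values() if s == "errored"),
        n_missing=sum(1 for s in statuses.values() if s == "missing"),
        n_designed=len(design_keys),
        n_exact=n_exact,
    )
    return report, parsed


def write_recovery_report(report: RecoveryReport, clusters, path) -> None:
    """Delimited-text dump: pool, channel, address, status, agreement."""
    with open(path, "w") as fh:
        fh.write("pool\tchannel\taddress\tstatus\tagreement\n")
        for (pool, ch, addr), status in sorted(report.statuses.items()):
            cl = clusters.get((pool, ch, addr))
            agree = f"{cl.agreement:.4f}" if cl is not None and cl.agreement else "NA"
            fh.write(f"{pool}\t{ch}\t{addr}\t{status}\t{agree}\n")
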
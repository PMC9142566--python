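"""Topological dimension: rewritable metadata recorded as backbone nicks.

Seven nicking endonucleases are assigned to the seven bits of the ASCII
code (enzyme 1 <-> most significant bit).  One letter is recorded per
intensity pool: the enzymes whose bit is 1 are added to that pool's
nicking mixture (ON), the others are left out (OFF).  Nicking splits
the top strand of each site-bearing oligo into single-stranded
fragments whose boundaries sit at the enzymes' cut offsets.  Decoding
counts, per enzyme, the fragment boundaries flanked by the enzyme's
site prefix (end of one fragment) and suffix (start of the adjacent
fragment); an enzyme is declared ON when its count reaches a fraction
``alpha`` of the pool's largest count.  Ligation rejoins fragments and
erases the metadata; rewriting is ligation followed by a fresh round of
nicking.

Only the top strand is modelled; duplex geometry and bottom-strand nick
sites are outside this abstraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

ASCII_BITS = 7


@dataclass(frozen=True)
class Enzyme:
    """A nicking endonuclease: recognition site + top-strand cut offset.

    The offset is measured from the site start and must fall strictly
    inside the site so that both the prefix and the suffix signature of a
    cut are non-empty.
    """

    name: str
    site: str
    offset: int

    def __post_init__(self) -> None:
        if not (4 <= len(self.site) <= 7):
            raise ValueError("recognition sites are 4-7 nt")
        if set(self.site) - set("ACGT"):
            raise ValueError(f"invalid site {self.site!r}")
        if not (1 <= self.offset <= len(self.site) - 1):
            raise ValueError("cut offset must be strictly inside the site")

    @property
    def prefix(self) -> str:
        return self.site[: self.offset]

    @property
    def suffix(self) -> str:
        return self.site[self.offset :]


@dataclass
class EnzymePanel:
    """Seven enzymes, index i (1-based) <-> bit i of the 7-bit ASCII code,
    bit 1 being the most significant."""

    enzymes: list[Enzyme]

    def __post_init__(self) -> None:
        if len(self.enzymes) != ASCII_BITS:
            raise ValueError("a panel holds exactly 7 enzymes")

    def __iter__(self):
        return iter(self.enzymes)

    def __getitem__(self, i: int) -> Enzyme:  # 1-based bit index
        return self.enzymes[i - 1]


def sliding_distance(a: str, b: str) -> int:
    """Minimum Hamming distance over all end-to-end slidings of the shorter
    site against the longer (padding-free)."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        d = sum(x != y for x, y in zip(a, b[off : off + len(a)]))
        best = min(best, d)
    return best


class PanelSelectionError(RuntimeError):
    pass


def select_panel(
    candidates: list[Enzyme],
    pools: dict[int, dict[str, str]],
    d_min: int = 2,
) -> EnzymePanel:
    """Pick 7 enzymes whose sites occur in every pool and sit at pairwise
    sliding distance >= d_min; depth-first search over the candidate order."""
    if len(candidates) < ASCII_BITS:
        raise PanelSelectionError(f"only {len(candidates)} candidates (< 7)")
    usable = []
    for enz in candidates:
        if all(
            any(enz.site in seq for seq in pool.values()) for pool in pools.values()
        ):
            usable.append(enz)
    if len(usable) < ASCII_BITS:
        raise PanelSelectionError(
            f"only {len(usable)} candidate sites occur in every pool "
            f"(binding constraint: per-pool site occurrence)"
        )

    chosen: list[Enzyme] = []

    def feasible(enz: Enzyme) -> bool:
        return all(sliding_distance(enz.site, c.site) >= d_min for c in chosen)

    def dfs(start: int) -> bool:
        if len(chosen) == ASCII_BITS:
            return True
        for i in range(start, len(usable)):
            if feasible(usable[i]):
                chosen.append(usable[i])
                if dfs(i + 1):
                    return True
                chosen.pop()
        return False

    if not dfs(0):
        raise PanelSelectionError(
            f"no 7-subset of {len(usable)} usable candidates satisfies "
            f"pairwise sliding distance >= {d_min}"
        )
    return EnzymePanel(enzymes=list(chosen))


# ---------------------------------------------------------------------------
# ON/OFF encoding
# ---------------------------------------------------------------------------


def letter_bits(letter: str) -> list[int]:
    """7-bit ASCII code of one letter, most significant bit first."""
    code = ord(letter)
    if not (0 <= code < 128):
        raise ValueError(f"{letter!r} has no 7-bit ASCII code")
    return [(code >> (ASCII_BITS - 1 - i)) & 1 for i in range(ASCII_BITS)]


def encode_word(word: str, panel: EnzymePanel, n_pools: int = 8) -> list[set[int]]:
    """Per-pool ON enzyme subsets (1-based indices); letter i -> pool i."""
    if len(word) > n_pools:
        raise ValueError(f"word longer than the {n_pools} intensity pools")
    subsets: list[set[int]] = []
    for letter in word:
        bits = letter_bits(letter)
        subsets.append({i + 1 for i, b in enumerate(bits) if b})
    subsets.extend(set() for _ in range(n_pools - len(word)))
    return subsets


# ---------------------------------------------------------------------------
# nicking, fragmentation, decoding
# ---------------------------------------------------------------------------


@dataclass
class Fragment:
    parent: str
    start: int
    end: int
    seq: str


@dataclass
class FragmentPool:
    fragments: list[Fragment] = field(default_factory=list)

    def by_parent(self) -> dict[str, list[Fragment]]:
        out: dict[str, list[Fragment]] = {}
        for f in self.fragments:
            out.setdefault(f.parent, []).append(f)
        for frags in out.values():
            frags.sort(key=lambda f: f.start)
        return out

    def total_bases(self) -> int:
        return sum(len(f.seq) for f in self.fragments)


def _site_occurrences(seq: str, site: str) -> list[int]:
    """All (possibly overlapping) start positions of ``site`` in ``seq``."""
    hits = []
    start = 0
    while True:
        i = seq.find(site, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def nick_and_fragment(
    pool: dict[str, str],
    on_enzymes: set[int],
    panel: EnzymePanel,
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> FragmentPool:
    """Nick every occurrence of each ON enzyme's site (plus spurious nicks at
    OFF sites with the given per-site probability) and split the oligos."""
    if not (0.0 <= spurious_rate < 1.0):
        raise ValueError("spurious_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = FragmentPool()
    for oid, seq in pool.items():
        cuts: set[int] = set()
        for bit in range(1, ASCII_BITS + 1):
            enz = panel[bit]
            for pos in _site_occurrences(seq, enz.site):
                cut = pos + enz.offset
                if cut <= 0 or cut >= len(seq):
                    continue
                if bit in on_enzymes:
                    cuts.add(cut)
                elif spurious_rate > 0 and rng.random() < spurious_rate:
                    cuts.add(cut)
        bounds = [0, *sorted(cuts), len(seq)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            out.fragments.append(Fragment(parent=oid, start=a, end=b, seq=seq[a:b]))
    return out


@dataclass
class CountTable:
    """Per-enzyme prefix-suffix boundary counts for one pool."""

    counts: dict[int, int]  # 1-based enzyme index -> count

    def on_set(self, alpha: float) -> set[int]:
        peak = max(self.counts.values(), default=0)
        if peak == 0:
            return set()
        return {i for i, c in self.counts.items() if c >= alpha * peak}


def _matches(text: str, pattern: str, where: str, tol: int) -> bool:
    if len(text) < len(pattern):
        return False
    window = text[-len(pattern) :] if where == "end" else text[: len(pattern)]
    return sum(a != b for a, b in zip(window, pattern)) <= tol


def count_signatures(
    fragments: FragmentPool, panel: EnzymePanel, mismatch_tol: int = 0
) -> CountTable:
    """Count, per enzyme, adjacent fragment boundaries whose flanks match the
    enzyme's site prefix (fragment end) and suffix (next fragment start)."""
    counts = dict.fromkeys(range(1, ASCII_BITS + 1), 0)
    for frags in fragments.by_parent().values():
        for f1, f2 in zip(frags[:-1], frags[1:]):
            if f1.end != f2.start:
                continue
            for bit in range(1, ASCII_BITS + 1):
                enz = panel[bit]
                if _matches(f1.seq, enz.prefix, "end", mismatch_tol) and _matches(
                    f2.seq, enz.suffix, "start", mismatch_tol
                ):
                    counts[bit] += 1
    return CountTable(counts=counts)


def decode_letter(
    fragments: FragmentPool,
    panel: EnzymePanel,
    alpha: float = 0.2,
    mismatch_tol: int = 0,
) -> tuple[str, CountTable]:
    """Threshold the count table into 7 ON/OFF bits and map them to a letter.

    An all-OFF pool (no nicks) is reported as a blank, consistent with an
    unwritten pool.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if not fragments.fragments:
        raise ValueError("empty fragment pool")
    table = count_signatures(fragments, panel, mismatch_tol)
    on = table.on_set(alpha)
    if not on:
        return "", table
    code = 0
    for bit in range(1, ASCII_BITS + 1):
        code = (code << 1) | (1 if bit in on else 0)
    return chr(code), table


def decode_word(
    pools_fragments: list[FragmentPool],
    panel: EnzymePanel,
    alpha: float = 0.2,
    mismatch_tol: int = 0,
) -> tuple[str, list[CountTable]]:
    letters = []
    tables = []
    for frags in pools_fragments:
        letter, table = decode_letter(frags, panel, alpha, mismatch_tol)
        letters.append(letter)
        tables.append(table)
    return "".join(letters), tables


# ---------------------------------------------------------------------------
# erase and rewrite
# ---------------------------------------------------------------------------


@dataclass
class LigationResult:
    oligos: dict[str, str]
    incomplete: list[str]  # parents whose fragments do not tile the oligo


def ligate(fragments: FragmentPool) -> LigationResult:
    """Rejoin fragments per parent.  Parents with gaps between fragment
    coordinates are reported as incomplete, not raised."""
    oligos: dict[str, str] = {}
    incomplete: list[str] = []
    for parent, frags in fragments.by_parent().items():
        ok = frags[0].start == 0
        for f1, f2 in zip(frags[:-1], frags[1:]):
            if f1.end != f2.start:
                ok = False
        seq = "".join(f.seq for f in frags)
        if not ok:
            incomplete.append(parent)
        oligos[parent] = seq
    return LigationResult(oligos=oligos, incomplete=incomplete)


def rewrite(
    fragments_per_pool: list[FragmentPool],
    new_word: str,
    panel: EnzymePanel,
    pools_order: list[FragmentPool] | None = None,
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[FragmentPool], list[str]]:
    """Erase (ligate) every pool, then nick the new word into the sealed pools."""
    subsets = encode_word(new_word, panel, n_pools=len(fragments_per_pool))
    out: list[FragmentPool] = []
    incomplete: list[str] = []
    for i, frags in enumerate(fragments_per_pool):
        lig = ligate(frags)
        incomplete.extend(lig.incomplete)
        out.append(
            nick_and_fragment(
                lig.oligos, subsets[i], panel, spurious_rate=spurious_rate, seed=seed + i
            )
        )
    return out, incomplete


# ---------------------------------------------------------------------------
# synthetic candidate enzymes and pools
# ---------------------------------------------------------------------------


def generate_enzyme_candidates(
    n: int = 10,
    site_len: int = 6,
    d_min: int = 2,
    seed: int = 0,
    max_tries: int = 100_000,
) -> list[Enzyme]:
    """Synthetic stand-in for a nicking-enzyme catalogue: random sites at
    pairwise sliding distance >= d_min with interior cut offsets."""
    rng = np.random.default_rng(seed)
    sites: list[str] = []
    tries = 0
    while len(sites) < n:
        tries += 1
        if tries > max_tries:
            raise PanelSelectionError("candidate sampling budget exhausted")
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=site_len))
        if "GGGG" in cand:
            continue
        if all(sliding_distance(cand, s) >= d_min for s in sites):
            sites.append(cand)
    return [
        Enzyme(name=f"Nt.Syn{i + 1}", site=s, offset=1 + int(i % (site_len - 1)))
        for i, s in enumerate(sites)
    ]


def make_topo_pools(
    candidates: list[Enzyme],
    n_pools: int = 8,
    oligos_per_pool: int = 20,
    copies_per_site: int = 5,
    oligo_len: int = 196,
    seed: int = 0,
) -> dict[int, dict[str, str]]:
    """Synthetic oligo pools in which every candidate site is implanted into
    ``copies_per_site`` oligos of every pool (round-robin)."""
    rng = np.random.default_rng(seed)
    pools: dict[int, dict[str, str]] = {}
    for p in range(n_pools):
        pool: dict[str, str] = {}
        for j in range(oligos_per_pool):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=oligo_len))
            pool[f"p{p}o{j}"] = seq
        # implant sites away from the oligo ends so cuts are interior;
        # each oligo keeps a cursor so implants never overwrite each other
        oids = list(pool)
        site_len = max(len(e.site) for e in candidates)
        per_oligo = -(-len(candidates) * copies_per_site // len(oids))
        if 10 + per_oligo * (site_len + 2) > oligo_len - 10:
            raise ValueError(
                "pools too small to implant every candidate site; "
                "increase oligos_per_pool or oligo_len"
            )
        cursor = dict.fromkeys(oids, 10)
        slot = 0
        for enz in candidates:
            for _ in range(copies_per_site):
                oid = oids[slot % len(oids)]
                slot += 1
                lo = cursor[oid]
                cursor[oid] = lo + len(enz.site) + 2
                seq = pool[oid]
                pool[oid] = seq[:lo] + enz.site + seq[lo + len(enz.site) :]
        pools[p] = pool
    return pools


def write_enzyme_table(enzymes: list[Enzyme], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsite\toffset\n")
        for e in enzymes:
            fh.write(f"{e.name}\t{e.site}\t{e.offset}\n")


def read_enzyme_table(path) -> list[Enzyme]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("name"):
            raise ValueError(f"{path}: expected 'name\\tsite\\toffset' header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                name, site, offset = line.split()
                out.append(Enzyme(name=name, site=site, offset=int(offset)))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
    return out
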
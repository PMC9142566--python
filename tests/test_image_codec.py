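"""Image codec: quantization, Hilbert order, Huffman, segment streams."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twodna import image_codec as ic

CAP = 242


def _all_ok(streams):
    return {(l, s.index): "ok" for l, st_ in streams.items() for s in st_.segments}


class TestQuantize:
    @pytest.mark.parametrize(
        "intensity,level", [(255, 7), (0, 0), (100, 3), (31, 0), (32, 1)]
    )
    def test_bin_rule(self, intensity, level):
        img = np.full((4, 4, 3), intensity, dtype=np.uint8)
        assert (ic.quantize(img).levels == level).all()

    def test_dequantize_midpoints(self):
        for lvl, mid in [(7, 240), (0, 16)]:
            q = ic.QuantizedImage(
                np.full((3, 2, 2), lvl, np.uint8),
                np.zeros((3, 2, 2), bool),
                np.zeros((3, 2, 2), bool),
            )
            assert (ic.dequantize(q) == mid).all()

    def test_quantize_dequantize_fixed_point(self):
        # midpoints fall back into their own bins for all 8 levels
        levels = np.arange(8, dtype=np.uint8).reshape(1, 8)
        q = ic.QuantizedImage(
            np.stack([levels] * 3), np.zeros((3, 1, 8), bool), np.zeros((3, 1, 8), bool)
        )
        assert (ic.quantize(ic.dequantize(q)).levels == q.levels).all()

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            ic.quantize(np.zeros((4, 4), dtype=np.uint8))


class TestHilbert:
    def test_single_cell(self):
        o = ic.hilbert_order(1, 1)
        assert o.cells.tolist() == [[0, 0]]

    @pytest.mark.parametrize("h,w", [(2, 2), (4, 4), (8, 8), (16, 16)])
    def test_full_square_adjacency(self, h, w):
        o = ic.hilbert_order(h, w)
        assert len(o) == h * w
        assert len({tuple(c) for c in o.cells}) == h * w
        steps = np.abs(np.diff(o.cells, axis=0)).sum(axis=1)
        assert (steps == 1).all()

    @pytest.mark.parametrize("h,w", [(3, 5), (7, 2), (5, 5), (9, 16)])
    def test_rectangles_visit_every_pixel_once(self, h, w):
        o = ic.hilbert_order(h, w)
        assert sorted(map(tuple, o.cells)) == [
            (r, c) for r in range(h) for c in range(w)
        ]

    def test_deterministic(self):
        a, b = ic.hilbert_order(13, 7), ic.hilbert_order(13, 7)
        assert (a.cells == b.cells).all()

    def test_starts_at_origin(self):
        assert ic.hilbert_order(8, 8).cells[0].tolist() == [0, 0]


def _kraft_complete_length_multisets(n_symbols, max_len=8):
    """All non-decreasing length vectors of complete prefix codes."""
    out = []

    def rec(prefix, remaining, budget, min_len):
        if remaining == 0:
            if budget == 0:
                out.append(tuple(prefix))
            return
        for ln in range(min_len, max_len + 1):
            take = 2 ** (max_len - ln)
            if take * remaining >= budget and take <= budget:
                prefix.append(ln)
                rec(prefix, remaining - 1, budget - take, ln)
                prefix.pop()

    rec([], n_symbols, 2**max_len, 1)
    return out


def brute_force_optimal_mean_length(counts):
    """Independent oracle: minimum weighted length over all complete prefix
    codes, assigning short lengths to frequent symbols."""
    freqs = sorted((c for c in counts.values() if c > 0), reverse=True)
    total = sum(freqs)
    best = None
    for lengths in _kraft_complete_length_multisets(len(freqs)):
        cost = sum(f * ln for f, ln in zip(freqs, sorted(lengths)))
        best = cost if best is None else min(best, cost)
    return best / total


class TestHuffman:
    def test_known_example(self):
        counts = {0: 8, 1: 4, 2: 2, 3: 2}
        book = ic.build_huffman(counts)
        assert book.lengths == {0: 1, 1: 2, 2: 3, 3: 3}
        assert book.mean_length(counts) == pytest.approx(1.75)

    def test_single_symbol_degenerate(self):
        book = ic.build_huffman({5: 10})
        assert book.lengths == {5: 1}

    def test_uniform_four_symbols(self):
        book = ic.build_huffman({0: 3, 1: 3, 2: 3, 3: 3})
        assert set(book.lengths.values()) == {2}

    @pytest.mark.parametrize("seed", range(8))
    def test_optimality_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        counts = {s: int(rng.integers(1, 50)) for s in range(n)}
        book = ic.build_huffman(counts)
        assert book.mean_length(counts) == pytest.approx(
            brute_force_optimal_mean_length(counts)
        )

    def test_kraft_inequality(self):
        book = ic.build_huffman({0: 7, 1: 1, 2: 1, 3: 1, 4: 1})
        assert sum(2.0 ** -ln for ln in book.lengths.values()) <= 1.0 + 1e-12

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_stream_roundtrip(self, symbols):
        counts = {s: symbols.count(s) + (1 if s in symbols else 0) for s in set(symbols)}
        book = ic.build_huffman(counts)
        bits = []
        for s in symbols:
            bits.extend(book.encode_symbol(s))
        reader = ic._BitReader(np.array(bits, dtype=np.uint8))
        assert [reader.read_symbol(book) for _ in symbols] == symbols

    def test_serialization_roundtrip(self):
        book = ic.build_huffman({0: 9, 1: 5, 4: 2, 15: 1})
        again = ic.deserialize_codebook(ic.serialize_codebook(book))
        assert again.lengths == book.lengths

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ic.build_huffman({})


class TestChannelCodec:
    def test_constant_channel_single_level(self):
        ch = np.full((8, 8), 5, dtype=np.uint8)
        order = ic.hilbert_order(8, 8)
        streams = ic.encode_channel(ch, order, CAP)
        assert set(streams) == {5}
        seg = streams[5].segments[0]
        pos = ic.decode_segment_positions(seg.bits, streams[5].codebook, 64)
        assert (np.diff(pos) == 1).all()

    def test_explicit_gap_example(self):
        # level-2 pixels at Hilbert positions 0, 1 and 5
        order = ic.hilbert_order(4, 4)
        ch = np.zeros(16, dtype=np.uint8)
        ch[order.flat_index()[[0, 1, 5]]] = 2
        streams = ic.encode_channel(ch.reshape(4, 4), order, CAP)
        seg = streams[2].segments[0]
        assert seg.anchor == 0 and seg.n_gaps == 2
        pos = ic.decode_segment_positions(seg.bits, streams[2].codebook, 16)
        assert pos.tolist() == [0, 1, 5]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(8, 33, size=2)
        ch = rng.integers(0, 8, size=(h, w)).astype(np.uint8)
        order = ic.hilbert_order(h, w)
        streams = ic.encode_channel(ch, order, CAP)
        raster, miss, conf = ic.decode_channel(
            streams, _all_ok(streams), order, h, w
        )
        assert (raster == ch).all()
        assert not miss.any() and not conf.any()

    def test_levels_partition_pixels(self):
        rng = np.random.default_rng(3)
        ch = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        order = ic.hilbert_order(16, 16)
        streams = ic.encode_channel(ch, order, CAP)
        claimed = []
        for lvl, stream in streams.items():
            for seg in stream.segments:
                claimed.extend(
                    ic.decode_segment_positions(seg.bits, stream.codebook, 256)
                )
        assert sorted(claimed) == list(range(256))

    def test_dropout_localization(self):
        rng = np.random.default_rng(11)
        ch = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        order = ic.hilbert_order(16, 16)
        streams = ic.encode_channel(ch, order, CAP)
        statuses = _all_ok(streams)
        victim = sorted(statuses)[len(statuses) // 2]
        lvl, idx = victim
        seg = next(s for s in streams[lvl].segments if s.index == idx)
        victim_pos = set(
            ic.decode_segment_positions(seg.bits, streams[lvl].codebook, 256).tolist()
        )
        statuses[victim] = "missing"
        raster, miss, conf = ic.decode_channel(streams, statuses, order, 16, 16)
        flat = order.flat_index()
        miss_linear = {i for i in range(256) if miss.ravel()[flat[i]]}
        assert miss_linear == victim_pos
        ok = ~miss
        assert (raster[ok] == ch[ok]).all() and not conf.any()

    def test_bitflip_confined_and_flagged(self):
        rng = np.random.default_rng(21)
        ch = rng.integers(0, 4, size=(16, 16)).astype(np.uint8)
        order = ic.hilbert_order(16, 16)
        streams = ic.encode_channel(ch, order, CAP)
        statuses = _all_ok(streams)
        lvl = next(l for l, s in streams.items() if s.segments)
        seg = streams[lvl].segments[0]
        orig = set(
            ic.decode_segment_positions(seg.bits, streams[lvl].codebook, 256).tolist()
        )
        seg.bits[3] ^= 1  # corrupt the anchor region
        raster, miss, conf = ic.decode_channel(streams, statuses, order, 16, 16)
        # every discrepant pixel is flagged (missing or conflict), never silent
        wrong = raster != ch
        assert (miss | conf)[wrong].all()
        # pixels claimed by no other segment than the victim are the only losses
        flat = order.flat_index()
        damaged = {i for i in range(256) if (miss | conf).ravel()[flat[i]]}
        new_claims = set()
        try:
            new_claims = set(
                ic.decode_segment_positions(
                    seg.bits, streams[lvl].codebook, 256
                ).tolist()
            )
        except ValueError:
            pass
        assert damaged <= (orig | new_claims)

    def test_anchor_out_of_range_demoted(self):
        ch = np.full((4, 4), 1, dtype=np.uint8)
        order = ic.hilbert_order(4, 4)
        streams = ic.encode_channel(ch, order, CAP)
        seg = streams[1].segments[0]
        width = ic.anchor_width(16)
        seg.bits[:width] = 1  # anchor = 15 -> still in range; force overflow
        seg.bits[: width] = [1] * width
        raster, miss, conf = ic.decode_channel(
            streams, _all_ok(streams), order, 4, 4
        )
        # decode either succeeds partially or the segment is demoted; pixels
        # not claimed are flagged missing, nothing raises
        assert miss.shape == (4, 4)

    def test_capacity_error(self):
        ch = np.arange(64, dtype=np.uint8).reshape(8, 8) % 8
        order = ic.hilbert_order(8, 8)
        with pytest.raises(ic.CapacityError):
            ic.encode_channel(ch, order, capacity_bits=10)


class TestCompression:
    def test_smooth_gradient_compresses(self):
        from twodna.fixtures import generate_fixture

        img = generate_fixture("gradient", (64, 64), seed=0)
        q = ic.quantize(img)
        order = ic.hilbert_order(64, 64)
        streams = ic.encode_image(q, order, CAP)
        coded = ic.total_coded_bits(streams, CAP)
        raw_quantized = 3 * 64 * 64 * 3
        assert coded <= 0.75 * raw_quantized

    def test_bit_packing_roundtrip(self):
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, 131).astype(np.uint8)
        assert (ic.unpack_bits_le(ic.pack_bits_le(bits), 131) == bits).all()
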
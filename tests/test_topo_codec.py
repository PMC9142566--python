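"""Nick-based metadata: panel selection, ON/OFF writing, fragment decoding,
ligation erase and rewrite."""

import numpy as np
import pytest

from twodna import topo_codec as tc


@pytest.fixture(scope="module")
def panel_and_pools():
    candidates = tc.generate_enzyme_candidates(n=10, seed=4)
    pools = tc.make_topo_pools(
        candidates, oligos_per_pool=20, copies_per_site=8, seed=4
    )
    panel = tc.select_panel(candidates, pools, d_min=2)
    return panel, pools


class TestSites:
    def test_sliding_distance_examples(self):
        assert tc.sliding_distance("GAGTC", "GAATC") == 1
        assert tc.sliding_distance("GAGTC", "GAGTC") == 0
        assert tc.sliding_distance("ACGT", "TTACGTTT") == 0  # contained

    def test_panel_audit(self, panel_and_pools):
        panel, pools = panel_and_pools
        sites = [e.site for e in panel]
        assert len(sites) == 7
        for i in range(7):
            for j in range(i + 1, 7):
                assert tc.sliding_distance(sites[i], sites[j]) >= 2
        for pool in pools.values():
            for e in panel:
                assert any(e.site in seq for seq in pool.values())

    def test_close_sites_rejected(self):
        # exactly 7 candidates of which two sit at sliding distance 1:
        # no 7-subset can satisfy d_min=2
        cands = [
            tc.Enzyme("a", "GAGTC", 2),
            tc.Enzyme("b", "GAATC", 2),  # distance 1 from a
        ] + [tc.Enzyme(f"c{i}", s, 2) for i, s in enumerate(
            ["ACACAC", "TGTGTG", "CATCAT", "GTAGTA", "CCTTCC"]
        )]
        pools = {0: {"o": "".join(e.site for e in cands) + "ACGT" * 20}}
        with pytest.raises(tc.PanelSelectionError):
            tc.select_panel(cands, pools, d_min=2)

    def test_too_few_candidates(self):
        with pytest.raises(tc.PanelSelectionError):
            tc.select_panel([tc.Enzyme("x", "ACGTAC", 2)], {}, 2)

    def test_enzyme_table_roundtrip(self, tmp_path):
        enzymes = tc.generate_enzyme_candidates(n=5, seed=1)
        path = tmp_path / "enzymes.tsv"
        tc.write_enzyme_table(enzymes, path)
        back = tc.read_enzyme_table(path)
        assert back == enzymes


class TestEncodeWord:
    def test_letter_I_enzyme_subset(self, panel_and_pools):
        panel, _ = panel_and_pools
        subsets = tc.encode_word("I", panel)
        assert subsets[0] == {1, 4, 7}  # 'I' = 73 = 1001001b

    def test_illinois_total_bits(self, panel_and_pools):
        panel, _ = panel_and_pools
        subsets = tc.encode_word("ILLINOIS", panel)
        assert len(subsets) == 8
        assert sum(7 for _ in "ILLINOIS") == 56

    def test_empty_word_all_off(self, panel_and_pools):
        panel, _ = panel_and_pools
        assert tc.encode_word("", panel) == [set()] * 8

    def test_too_long_word(self, panel_and_pools):
        panel, _ = panel_and_pools
        with pytest.raises(ValueError):
            tc.encode_word("ABCDEFGHI", panel)

    def test_non_ascii_letter(self, panel_and_pools):
        panel, _ = panel_and_pools
        with pytest.raises(ValueError):
            tc.encode_word("é", panel)


class TestFragments:
    def test_no_enzymes_intact(self, panel_and_pools):
        panel, pools = panel_and_pools
        frags = tc.nick_and_fragment(pools[0], set(), panel, 0.0, seed=0)
        assert {f.seq for f in frags.fragments} == set(pools[0].values())

    def test_base_conservation(self, panel_and_pools):
        panel, pools = panel_and_pools
        rng = np.random.default_rng(0)
        for trial in range(5):
            on = set(rng.choice(range(1, 8), size=rng.integers(0, 8), replace=False))
            frags = tc.nick_and_fragment(pools[1], on, panel, 0.02, seed=trial)
            assert frags.total_bases() == sum(len(s) for s in pools[1].values())

    def test_fragment_concatenation_reconstructs_parent(self, panel_and_pools):
        panel, pools = panel_and_pools
        frags = tc.nick_and_fragment(pools[2], {1, 3, 5}, panel, 0.01, seed=9)
        for parent, group in frags.by_parent().items():
            assert "".join(f.seq for f in group) == pools[2][parent]


class TestDecode:
    def test_threshold_rule_on_printed_counts(self):
        """Counts like those of the first write experiment: large counts
        declare ON, counts far below the peak (4 << 81, 5 << 40) stay OFF."""
        table = tc.CountTable(
            counts={1: 81, 2: 40, 3: 4, 4: 5, 5: 0, 6: 0, 7: 0}
        )
        assert table.on_set(alpha=0.2) == {1, 2}

    def test_all_128_letter_codes_roundtrip(self, panel_and_pools):
        panel, pools = panel_and_pools
        for code in range(128):
            letter = chr(code)
            on = {i + 1 for i, b in enumerate(tc.letter_bits(letter)) if b}
            frags = tc.nick_and_fragment(pools[0], on, panel, 0.0, seed=0)
            decoded, _ = tc.decode_letter(frags, panel)
            assert decoded == (letter if on else "")

    def test_unfragmented_pool_blank(self, panel_and_pools):
        panel, pools = panel_and_pools
        frags = tc.nick_and_fragment(pools[3], set(), panel, 0.0, seed=0)
        decoded, table = tc.decode_letter(frags, panel)
        assert decoded == "" and all(c == 0 for c in table.counts.values())

    def test_empty_pool_rejected(self, panel_and_pools):
        panel, _ = panel_and_pools
        with pytest.raises(ValueError):
            tc.decode_letter(tc.FragmentPool(), panel)

    def test_word_roundtrip_with_spurious_nicks(self, panel_and_pools):
        panel, pools = panel_and_pools
        subsets = tc.encode_word("ILLINOIS", panel)
        frags = [
            tc.nick_and_fragment(pools[i], subsets[i], panel, 0.01, seed=100 + i)
            for i in range(8)
        ]
        word, _ = tc.decode_word(frags, panel)
        assert word == "ILLINOIS"

    def test_threshold_robust_over_alpha(self):
        """With pools large enough for count statistics (50 copies per site),
        the relative threshold recovers the word for every alpha in
        [0.1, 0.4] at up to 2% spurious nicking."""
        candidates = tc.generate_enzyme_candidates(n=10, seed=4)
        pools = tc.make_topo_pools(
            candidates, oligos_per_pool=100, copies_per_site=50, seed=4
        )
        panel = tc.select_panel(candidates, pools, d_min=2)
        subsets = tc.encode_word("ILLINOIS", panel)
        frags = [
            tc.nick_and_fragment(pools[i], subsets[i], panel, 0.02, seed=200 + i)
            for i in range(8)
        ]
        for alpha in (0.1, 0.2, 0.3, 0.4):
            word, _ = tc.decode_word(frags, panel, alpha=alpha)
            assert word == "ILLINOIS"


class TestEraseRewrite:
    def test_ligate_inverts_nicking(self, panel_and_pools):
        panel, pools = panel_and_pools
        frags = tc.nick_and_fragment(pools[4], {2, 6}, panel, 0.0, seed=0)
        lig = tc.ligate(frags)
        assert lig.oligos == pools[4] and not lig.incomplete

    def test_decode_after_erase_all_off(self, panel_and_pools):
        panel, pools = panel_and_pools
        subsets = tc.encode_word("ILLINOIS", panel)
        frags = [
            tc.nick_and_fragment(pools[i], subsets[i], panel, 0.0, seed=i)
            for i in range(8)
        ]
        erased = [
            tc.nick_and_fragment(tc.ligate(f).oligos, set(), panel, 0.0, seed=0)
            for f in frags
        ]
        word, tables = tc.decode_word(erased, panel)
        assert word == ""
        assert all(c == 0 for t in tables for c in t.counts.values())

    def test_missing_fragment_reported(self, panel_and_pools):
        panel, pools = panel_and_pools
        frags = tc.nick_and_fragment(pools[5], {1}, panel, 0.0, seed=0)
        nicked_parents = {
            p for p, g in frags.by_parent().items() if len(g) > 1
        }
        victim = sorted(nicked_parents)[0]
        frags.fragments = [
            f for f in frags.fragments if not (f.parent == victim and f.start == 0)
        ]
        lig = tc.ligate(frags)
        assert victim in lig.incomplete

    def test_rewrite_roundtrip(self, panel_and_pools):
        panel, pools = panel_and_pools
        subsets = tc.encode_word("ILLINOIS", panel)
        frags = [
            tc.nick_and_fragment(pools[i], subsets[i], panel, 0.0, seed=i)
            for i in range(8)
        ]
        new_frags, incomplete = tc.rewrite(frags, "GRAINGER", panel)
        assert not incomplete
        word, _ = tc.decode_word(new_frags, panel)
        assert word == "GRAINGER"

    def test_rewrite_idempotent(self, panel_and_pools):
        panel, pools = panel_and_pools
        subsets = tc.encode_word("AB", panel)
        frags = [
            tc.nick_and_fragment(pools[i], subsets[i], panel, 0.0, seed=i)
            for i in range(8)
        ]
        again, _ = tc.rewrite(frags, "AB", panel)
        w1, _ = tc.decode_word(frags, panel)
        w2, _ = tc.decode_word(again, panel)
        assert w1 == w2 == "AB"
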
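"""Curation pipeline: canonicalization, frequency augmentation, shuffling."""

import json
import math
from collections import Counter

import numpy as np
import pytest

from chemlm import corpus as C
from chemlm.tokenizer import regex_tokenize


class TestCanonicalization:
    def test_already_canonical_is_fixed_point(self):
        out = C.sanitize_and_canonicalize("c1ccccc1")
        assert C.sanitize_and_canonicalize(out) == out

    def test_equivalent_forms_share_canonical(self):
        # two hand-written aspirin SMILES must collapse to one string
        a = C.sanitize_and_canonicalize("OC(=O)c1ccccc1OC(C)=O")
        b = C.sanitize_and_canonicalize("CC(=O)Oc1ccccc1C(=O)O")
        assert a == b

    @pytest.mark.parametrize("bad,reason", [
        ("C1CC", C.RejectionReason.PARSE_ERROR),          # unclosed ring
        ("C(C)(C)(C)(C)C", C.RejectionReason.SANITIZATION_ERROR),  # valence
        ("", C.RejectionReason.EMPTY),
        ("not smiles", C.RejectionReason.PARSE_ERROR),
    ])
    def test_invalid_chemistry_rejected_with_reason(self, bad, reason):
        with pytest.raises(C.SmilesRejection) as err:
            C.sanitize_and_canonicalize(bad)
        assert err.value.reason == reason

    def test_salt_stripped_to_largest_fragment(self):
        out = C.sanitize_and_canonicalize("CC(=O)O.[Na+]")
        assert "." not in out and "Na" not in out

    def test_idempotent_on_corpus(self, tiny_corpus):
        for s in tiny_corpus[:50]:
            c1 = C.sanitize_and_canonicalize(s)
            assert C.sanitize_and_canonicalize(c1) == c1


class TestReactionExtraction:
    def test_three_fields_enumerated_in_order(self):
        assert C.extract_molecules_from_reaction(
            "CCO.CC(=O)O>>CC(=O)OCC") == ["CCO", "CC(=O)O", "CC(=O)OCC"]

    def test_duplicates_preserved(self):
        assert C.extract_molecules_from_reaction("CCO>O>CCO") == ["CCO", "O", "CCO"]

    def test_empty_reaction(self):
        assert C.extract_molecules_from_reaction(">>") == []

    @pytest.mark.parametrize("bad", ["CCO>CCO", "a>b>c>d", "CCO"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            C.extract_molecules_from_reaction(bad)


class TestFrequencyAnalysis:
    def test_counts(self):
        assert C.frequency_analysis(["A", "A", "B"]) == {"A": 2, "B": 1}
        assert C.frequency_analysis([]) == {}

    def test_planted_zipf_counts_recovered(self):
        from chemlm.fixtures import FixtureSpec, gen_corpus
        fx = gen_corpus(FixtureSpec(n_molecules=150, seed=9))
        canon = [C.sanitize_and_canonicalize(s) for s in fx.lines]
        assert C.frequency_analysis(canon) == fx.counts

    def test_conservation(self):
        records = ["A"] * 5 + ["B"] * 2 + ["C"]
        freq = C.frequency_analysis(records)
        assert sum(freq.values()) == len(records)


class TestTopFraction:
    def test_half_of_duplicates(self):
        assert C.select_top_fraction({"A": 5, "B": 3, "C": 1, "D": 1}, 0.5) == {"A"}

    def test_fraction_one_returns_all_duplicates(self):
        freq = {"A": 5, "B": 3, "C": 1}
        assert C.select_top_fraction(freq, 1.0) == {"A", "B"}

    def test_empty_map(self):
        assert C.select_top_fraction({}, 0.5) == set()

    def test_boundary_ties_stable(self, rng):
        """Selection with many tied counts matches a brute-force sort."""
        freq = {f"M{i:03d}": int(c) for i, c in
                enumerate(rng.integers(1, 5, size=100))}
        got = C.select_top_fraction(freq, 0.3)
        dup = sorted(((c, k) for k, c in freq.items() if c > 1),
                     key=lambda kv: (-kv[0], kv[1]))
        want = {k for _, k in dup[:math.ceil(0.3 * len(dup))]}
        assert got == want
        assert got == C.select_top_fraction(dict(reversed(list(freq.items()))), 0.3)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            C.select_top_fraction({"A": 2}, 0.0)


class TestAugment:
    def test_round_trip_invariant(self):
        for s in ["CCO", "CC(=O)Oc1ccccc1C(=O)O", "c1ccc2[nH]ccc2c1"]:
            canon = C.sanitize_and_canonicalize(s)
            for out in C.augment(canon, 5, seed=7):
                assert C.sanitize_and_canonicalize(out) == canon

    def test_single_atom_repeats(self):
        assert C.augment("C", 2, seed=0) == ["C", "C"]

    def test_rich_molecule_yields_distinct_permutations(self):
        outs = C.augment("CC(=O)Oc1ccccc1C(=O)O", 10, seed=1)
        assert len(set(outs)) >= 2

    def test_seeded_reproducibility(self):
        assert C.augment("CCO", 4, seed=3) == C.augment("CCO", 4, seed=3)

    def test_zero_n(self):
        assert C.augment("CCO", 0, seed=0) == []


def _brute_force_expected_lines(sources, cfg):
    """Independent reference for build_pretraining_corpus emission counts."""
    canon = []
    for stream in sources.values():
        for s in stream:
            try:
                canon.append(C.sanitize_and_canonicalize(s))
            except C.SmilesRejection:
                pass
    freq = Counter(canon)
    top = C.select_top_fraction(dict(freq), cfg.top_fraction)
    total = 0
    for k, c in freq.items():
        total += math.ceil(c * cfg.augment_ratio) if k in top else 1
    return len(freq), total


class TestBuildCorpus:
    def make_sources(self):
        from chemlm.fixtures import FixtureSpec, gen_corpus
        fx = gen_corpus(FixtureSpec(n_molecules=120, seed=4))
        half = len(fx.lines) // 2
        return {"a": fx.lines[:half] + ["C1CC"],  # one invalid record
                "b": fx.lines[half:]}

    def test_manifest_matches_brute_force(self, tmp_path):
        sources = self.make_sources()
        cfg = C.CurationConfig(top_fraction=0.2, shuffle_seed=0)
        out = tmp_path / "corpus.txt"
        manifest = C.build_pretraining_corpus(sources, cfg, out,
                                              manifest_path=tmp_path / "m.json")
        n_unique, n_lines = _brute_force_expected_lines(sources, cfg)
        assert manifest["n_unique"] == n_unique
        assert manifest["n_lines"] + manifest["n_length_filtered"] == n_lines
        assert len(out.read_text().splitlines()) == manifest["n_lines"]
        saved = json.loads((tmp_path / "m.json").read_text())
        assert saved["n_lines"] == manifest["n_lines"]

    def test_conservation_per_source(self, tmp_path):
        sources = self.make_sources()
        cfg = C.CurationConfig(shuffle_seed=1)
        manifest = C.build_pretraining_corpus(sources, cfg, tmp_path / "c.txt")
        for stats in manifest["per_source"].values():
            assert stats["retained"] + stats["rejected"] == stats["input"]
        assert manifest["per_source"]["a"]["rejected"] == 1

    def test_non_top_molecules_appear_once(self, tmp_path):
        sources = self.make_sources()
        cfg = C.CurationConfig(top_fraction=0.2, shuffle_seed=0)
        out = tmp_path / "corpus.txt"
        C.build_pretraining_corpus(sources, cfg, out)
        lines = out.read_text().splitlines()
        canon_counts = Counter(C.sanitize_and_canonicalize(s) for s in lines)
        raw = Counter()
        for stream in sources.values():
            for s in stream:
                try:
                    raw[C.sanitize_and_canonicalize(s)] += 1
                except C.SmilesRejection:
                    pass
        top = C.select_top_fraction(dict(raw), cfg.top_fraction)
        for k, c in canon_counts.items():
            if k not in top:
                assert c == 1

    def test_byte_identical_under_same_seed(self, tmp_path):
        sources = self.make_sources()
        cfg = C.CurationConfig(shuffle_seed=42)
        a, b = tmp_path / "a.txt", tmp_path / "b.txt"
        C.build_pretraining_corpus(sources, cfg, a)
        C.build_pretraining_corpus(sources, cfg, b)
        assert a.read_bytes() == b.read_bytes()

    def test_single_molecule_source(self, tmp_path):
        out = tmp_path / "one.txt"
        C.build_pretraining_corpus({"s": ["CCO"]}, C.CurationConfig(), out)
        assert out.read_text().splitlines() == ["CCO"]

    def test_zero_retained_errors(self, tmp_path):
        with pytest.raises(ValueError):
            C.build_pretraining_corpus({"s": ["C1CC"]}, C.CurationConfig(),
                                       tmp_path / "x.txt")

    def test_length_filter(self, tmp_path):
        long_mol = "C" * 80  # 80 atom tokens
        cfg = C.CurationConfig(max_token_length=50, shuffle_seed=0)
        manifest = C.build_pretraining_corpus({"s": ["CCO", long_mol]}, cfg,
                                              tmp_path / "c.txt")
        assert manifest["n_length_filtered"] == 1
        assert manifest["n_lines"] == 1


class TestChunkedShuffle:
    def test_permutation_and_determinism(self):
        lines = [str(i) for i in range(1000)]
        out = C.chunked_shuffle(lines, seed=7, chunk_size=128)
        assert sorted(out) == sorted(lines)
        assert out != lines
        assert out == C.chunked_shuffle(lines, seed=7, chunk_size=128)
        assert out != C.chunked_shuffle(lines, seed=8, chunk_size=128)


class TestGroupProfile:
    def test_single_hydroxyl(self):
        prof = C.functional_group_profile(["CCO"], {"hydroxyl": "[OX2H]"})
        assert prof.counts == {"hydroxyl": 1}

    def test_no_match_all_zero(self):
        prof = C.functional_group_profile(["CCC"])
        assert all(v == 0 for v in prof.counts.values())

    def test_invalid_smiles_counted_not_raised(self):
        prof = C.functional_group_profile(["CCO", "C1CC"],
                                          {"hydroxyl": "[OX2H]"})
        assert prof.n_invalid == 1
        assert prof.counts["hydroxyl"] == 1

    def test_planted_counts_recovered(self):
        # 20 alcohols, 15 nitros, 15 plain alkanes; molecule-level counts
        sample = (["CCCO"] * 20 + ["CCC[N+](=O)[O-]"] * 15 + ["CCCC"] * 15)
        prof = C.functional_group_profile(
            sample, {"hydroxyl": "[OX2H]", "nitro": "[NX3+](=O)[O-]"})
        assert prof.counts == {"hydroxyl": 20, "nitro": 15}
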
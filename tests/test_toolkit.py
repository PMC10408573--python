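import numpy as np
import pytest

from selgram.constraints import ConstraintSet, default_constraints
from selgram.decoder import decode_to_graph
from selgram.exceptions import EncodingError, MalformedStringError
from selgram.molgraph import check_valences
from selgram.toolkit import (
    EncodingVocabulary,
    encoding_to_selfies,
    get_alphabet_from_selfies,
    get_chain_growth_alphabet,
    get_semantic_robust_alphabet,
    len_selfies,
    sample_random_selfies,
    selfies_to_encoding,
    split_selfies,
)


class TestStringHelpers:
    @pytest.mark.parametrize(
        "s,length",
        [("[C][O][C]", 3), ("[C].[C]", 3), ("", 0), ("[C][nop][nop]", 3)],
    )
    def test_len_counts_symbols(self, s, length):
        assert len_selfies(s) == length

    def test_split_yields_tokens_in_order(self):
        assert split_selfies("[C].[O]") == ["[C]", ".", "[O]"]

    def test_malformed_string_raises(self):
        with pytest.raises(MalformedStringError):
            len_selfies("[C][O")


class TestCorpusAlphabet:
    def test_distinct_tokens_of_the_corpus(self):
        assert get_alphabet_from_selfies(["[C][O]", "[C][F]"]) == {"[C]", "[O]", "[F]"}

    def test_empty_corpus(self):
        assert get_alphabet_from_selfies([]) == set()

    def test_nop_excluded(self):
        assert get_alphabet_from_selfies(["[C][nop]"]) == {"[C]"}

    def test_offending_string_identified(self):
        with pytest.raises(MalformedStringError, match="bad"):
            get_alphabet_from_selfies(["[C]", "bad"])


class TestSemanticRobustAlphabet:
    def test_default_has_69_symbols(self):
        alphabet = get_semantic_robust_alphabet()
        assert len(alphabet) == 69
        atoms = [t for t in alphabet if "Branch" not in t and "Ring" not in t]
        branches = [t for t in alphabet if "Branch" in t]
        rings = [t for t in alphabet if "Ring" in t]
        assert (len(atoms), len(branches), len(rings)) == (54, 9, 6)

    def test_filtered_has_19_symbols(self):
        filtered = get_chain_growth_alphabet()
        assert len(filtered) == 19
        assert filtered < get_semantic_robust_alphabet()
        assert {"[Branch1]", "[Ring1]"} < filtered
        assert not any(t.startswith(("[=", "[#")) for t in filtered)
        assert "[F]" not in filtered and "[Cl]" not in filtered

    def test_bond_prefixes_respect_the_valence(self):
        alphabet = get_semantic_robust_alphabet()
        assert "[#C]" in alphabet
        assert "[=O]" in alphabet and "[#O]" not in alphabet
        assert "[F]" in alphabet and "[=F]" not in alphabet
        assert "[#O+1]" in alphabet  # nu(O,+1) = 3

    def test_single_carbon_constraint_set(self):
        cs = ConstraintSet(entries={("C", 0): 4}, catch_all=8)
        alphabet = get_semantic_robust_alphabet(cs)
        assert len(alphabet) == 3 + 9 + 6  # [C],[=C],[#C] + branches + rings

    def test_no_hash_ring_in_sampling_alphabet_but_decodable(self):
        alphabet = get_semantic_robust_alphabet()
        assert "[#Ring1]" not in alphabet
        graph, _ = decode_to_graph("[C][C][C][C][#Ring1][C]")
        assert check_valences(graph) == []


class TestSampler:
    def test_shapes_and_determinism(self):
        alphabet = get_semantic_robust_alphabet()
        a = sample_random_selfies(alphabet, 20, 10, seed=5)
        b = sample_random_selfies(alphabet, 20, 10, seed=5)
        assert a == b
        assert len(a) == 10
        assert all(len_selfies(s) == 20 for s in a)

    def test_zero_length_gives_empty_strings(self):
        assert sample_random_selfies({"[C]"}, 0, 3, seed=1) == ["", "", ""]

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            sample_random_selfies(set(), 5, 1, seed=1)

    def test_filtered_alphabet_grows_larger_molecules(self):
        # molecules from the multi-bond-free alphabet keep growing with the
        # string length, while the full alphabet saturates at small sizes
        full = get_semantic_robust_alphabet()
        filtered = get_chain_growth_alphabet()

        def mean_size(alphabet, length, n=150, seed=67):
            total = 0
            for s in sample_random_selfies(alphabet, length, n, seed=seed):
                graph, _ = decode_to_graph(s)
                total += sum(1 for a in graph.atoms if a.atom_type.element != "H")
            return total / n

        filt = [mean_size(filtered, L) for L in (10, 30, 100)]
        assert filt[0] < filt[1] < filt[2]
        assert filt[2] > 2 * mean_size(full, 100)


class TestEncodings:
    VOCAB = EncodingVocabulary(stoi={"[nop]": 0, "[C]": 1, "[O]": 2})

    def test_label_and_one_hot(self):
        labels, one_hot = selfies_to_encoding("[C][O]", self.VOCAB, pad_to_len=3)
        assert labels == [1, 2, 0]
        assert one_hot.shape == (3, 3)
        assert (one_hot.sum(axis=1) == 1).all()
        assert one_hot[0, 1] == 1 and one_hot[2, 0] == 1

    def test_inverse_strips_padding(self):
        assert encoding_to_selfies([1, 2, 0], self.VOCAB, enc_type="label") == "[C][O]"
        one_hot = selfies_to_encoding("[C]", self.VOCAB, pad_to_len=3, enc_type="one_hot")
        assert encoding_to_selfies(one_hot, self.VOCAB, enc_type="one_hot") == "[C]"

    def test_roundtrip_over_random_strings(self, default_alphabet):
        vocab = EncodingVocabulary.from_alphabet(default_alphabet)
        for s in sample_random_selfies(default_alphabet, 15, 100, seed=71):
            labels = selfies_to_encoding(s, vocab, pad_to_len=20, enc_type="label")
            assert encoding_to_selfies(labels, vocab, enc_type="label") == s

    @pytest.mark.parametrize(
        "s,vocab,pad",
        [
            ("[N]", {"[nop]": 0, "[C]": 1}, 3),  # unknown token
            ("[C]", {"[C]": 0}, 3),  # missing [nop]
            ("[C][C]", {"[nop]": 0, "[C]": 1}, 1),  # over-length
        ],
    )
    def test_encoding_errors(self, s, vocab, pad):
        with pytest.raises(EncodingError):
            selfies_to_encoding(s, vocab, pad_to_len=pad)

    def test_vocabulary_must_be_bijective(self):
        with pytest.raises(EncodingError):
            EncodingVocabulary(stoi={"[C]": 0, "[O]": 0})
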
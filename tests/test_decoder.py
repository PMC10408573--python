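import random

import pytest

from selgram.constraints import ConstraintSet, default_constraints
from selgram.decoder import decode, decode_to_graph, demote_bond
from selgram.exceptions import DecodeError
from selgram.molgraph import check_valences
from selgram.toolkit import get_semantic_robust_alphabet, sample_random_selfies


class TestDemoteBond:
    @pytest.mark.parametrize(
        "bond,order,expected",
        [
            ("", 1, ""),
            ("=", 1, ""),
            ("=", 2, "="),
            ("#", 1, ""),
            ("#", 2, "="),
            ("#", 3, "#"),
            ("/", 1, "/"),
            ("\\", 1, "\\"),
        ],
    )
    def test_full_domain(self, bond, order, expected):
        assert demote_bond(bond, order) == expected

    @pytest.mark.parametrize("bond,order", [("", 2), ("=", 3), ("/", 2), ("#", 4)])
    def test_over_demotion_is_internal_error(self, bond, order):
        with pytest.raises(AssertionError):
            demote_bond(bond, order)


class TestChainDerivation:
    def test_bond_demoted_to_fit_remaining_capacity(self):
        # O has one bond left after C-O, so [=C] derives a single bond
        assert decode("[C][O][=C][F]") == "COCF"

    def test_hydrogen_counts_decrement_valence(self):
        # [CH3] can make exactly one further bond
        assert decode("[CH3][13CH1][O]") == "[CH3][13CH1]O"

    def test_chain_stops_when_capacity_exhausted(self):
        # F is monovalent: everything after it is discarded
        assert decode("[C][F][O][N]") == "CF"

    def test_zero_capacity_atom_is_isolated(self):
        assert decode("[CH4][C][C]") == "[CH4]"

    def test_empty_string(self):
        assert decode("") == ""

    @pytest.mark.parametrize("bad", ["[C][O", "[N+]", "[CH]", "[CH5]"])
    def test_lexical_failures_raise(self, bad):
        with pytest.raises(DecodeError):
            decode(bad)


class TestBranchDerivation:
    def test_acetic_acid_worked_example(self):
        assert decode("[O][C][Branch1][C][O][C]") == "OC(O)C"

    def test_branch_skipped_at_start_consumes_only_itself(self):
        # [Branch1] at the start is ignored; [C][O] then derive normally
        assert decode("[Branch1][C][O]") == "CO"

    def test_branch_at_x1_skipped(self):
        # after [O][O] the head O is at X_1; the branch symbol is a no-op
        # there and its would-be index/payload symbols derive as plain atoms
        assert decode("[O][O][Branch1][C][C]") == "OOCC"

    def test_empty_branch_payload_still_reduces_state(self):
        # queue exhausts immediately after the branch symbol: rho = epsilon
        assert decode("[C][Branch1]") == "C"

    def test_double_bonded_branch(self):
        assert decode("[C][C][=Branch1][C][=O][O]") == "CC(=O)O"

    def test_nested_branches(self):
        # oxalic-acid-like: branch containing a branch
        s = "[C][Branch1][=Branch1][C][Branch1][C][O][O][O]"
        out = decode(s)
        assert out == "C(C(O)O)O"

    def test_payload_beginning_with_branch_attaches_to_parent(self):
        # a branch payload that itself starts with a branch symbol must not
        # emit "((" - the sub-branch becomes a sibling of its parent
        s = "[C][Branch2][Ring1][C][Branch1][C][F][F][F][C]"
        out = decode(s)
        assert "((" not in out
        graph, _ = decode_to_graph(s)
        assert check_valences(graph) == []


class TestRingDerivation:
    def test_methylcyclobutane_worked_example(self):
        assert decode("[C][C][C][C][C][Ring1][Ring2]") == "CC1CCC1"

    def test_incrementing_the_index_symbol_grows_the_ring(self):
        assert decode("[C][C][C][C][C][Ring1][Branch1]") == "C1CCCC1"

    def test_duplicate_ring_promotes_bond_order(self):
        assert decode("[C][C][C][C][C][Ring1][Ring2][Ring1][Ring2]") == "CC=1CCC=1"

    def test_offset_past_first_atom_clamps(self):
        # N = 16 with only 5 preceding atoms: left atom clamps to the first
        assert decode("[C][C][C][C][C][Ring1][P]") == "C1CCCC1"

    def test_self_loop_rejected(self):
        assert decode("[C][Ring1][C]") == "C"

    def test_saturated_endpoint_rejected(self):
        # F at the far end has no remaining capacity: no ring is formed
        assert decode("[F][C][C][C][Ring1][Ring2]") == "FCCC"

    def test_stereo_ring_markers_attach_to_the_tags(self):
        assert decode("[C][C][C][C][C][/-Ring1][Ring2]") == "CC/1CCC1"

    def test_ring_at_start_skipped(self):
        assert decode("[Ring1][C][C]") == "CC"

    def test_five_membered_ring_with_methyl_from_branch_digit(self):
        smi = decode("[C][C][C][C][C][C][Ring1][Branch1]")
        assert smi == "CC1CCCC1"
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smi)
        assert [len(r) for r in mol.GetRingInfo().AtomRings()] == [5]

    def test_benzene_selfies(self):
        assert decode("[C][=C][C][=C][C][=C][Ring1][=Branch1]") == "C1=CC=CC=C1"


class TestDotsAndPadding:
    def test_dot_splits_fragments(self):
        assert decode("[C].[C]") == "C.C"

    def test_dot_homomorphism(self):
        rng = random.Random(13)
        alphabet = sorted(get_semantic_robust_alphabet())
        checked = 0
        while checked < 50:
            a, b = sample_random_selfies(alphabet, 12, 2, rng=rng)
            if not decode(a) or not decode(b):
                continue
            assert decode(a + "." + b) == decode(a) + "." + decode(b)
            checked += 1

    def test_nop_is_invisible_everywhere(self):
        rng = random.Random(17)
        alphabet = sorted(get_semantic_robust_alphabet())
        for _ in range(100):
            tokens = [rng.choice(alphabet) for _ in range(rng.randint(1, 25))]
            pos = rng.randint(0, len(tokens))
            plain = "".join(tokens)
            padded = "".join(tokens[:pos] + ["[nop]"] + tokens[pos:])
            assert decode(plain) == decode(padded)

    def test_nop_never_serves_as_index_digit_or_payload(self):
        # [nop] stripped before derivation: the digit is [O] (=9), not [nop]
        assert decode("[C][C][C][Ring1][nop][C]") == decode("[C][C][C][Ring1][C]")


class TestRobustness:
    def test_every_random_string_decodes_validly(self, default_alphabet):
        rng = random.Random(23)
        for _ in range(2000):
            length = rng.randint(5, 100)
            s = "".join(rng.choice(default_alphabet) for _ in range(length))
            graph, _ = decode_to_graph(s)
            assert check_valences(graph) == []

    def test_prefix_monotonicity_of_atom_count(self, default_alphabet):
        rng = random.Random(29)
        for _ in range(200):
            tokens = [rng.choice(default_alphabet) for _ in range(30)]
            counts = []
            for cut in range(0, 31, 5):
                graph, _ = decode_to_graph("".join(tokens[:cut]))
                counts.append(len(graph.atoms))
            assert counts == sorted(counts)

    def test_robust_under_custom_constraints(self):
        cs = ConstraintSet(entries={("C", 0): 4, ("C", +1): 5, ("C", -1): 3}, catch_all=4)
        rng = random.Random(31)
        alphabet = sorted(get_semantic_robust_alphabet(cs))
        for _ in range(300):
            s = "".join(rng.choice(alphabet) for _ in range(25))
            graph, _ = decode_to_graph(s, cs)
            assert check_valences(graph, cs) == []

    def test_decoded_smiles_is_syntactically_valid_per_rdkit(self, default_alphabet):
        from rdkit import Chem

        for s in sample_random_selfies(default_alphabet, 40, 200, seed=37):
            smi = decode(s)
            if smi:
                assert Chem.MolFromSmiles(smi, sanitize=False) is not None, smi
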
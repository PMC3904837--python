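"""Tree and state-table I/O: parsing, validation, pruning, round trips."""

import numpy as np
import pytest

from geodiv import (
    Biome,
    BiomeStateTable,
    LatitudeRange,
    TreeValidationError,
    extract_clade,
    match_tree_and_states,
    parse_newick,
    read_newick,
    read_state_table,
    write_newick,
)
from conftest import clade_ages


class TestParsing:
    def test_four_tip_topology_and_height(self, four_tip_tree):
        t = four_tip_tree
        assert t.n_tips == 4
        assert set(t.tip_labels) == {"A", "B", "C", "D"}
        assert t.height == pytest.approx(2.0)
        ages = clade_ages(t)
        assert ages[frozenset("AB")] == pytest.approx(1.0)
        assert ages[frozenset("CD")] == pytest.approx(1.5)
        assert ages[frozenset("ABCD")] == pytest.approx(2.0)

    def test_polytomy_rejected(self):
        with pytest.raises(TreeValidationError, match="non-binary"):
            parse_newick("(A:1,B:1,C:1);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeValidationError, match="branch length"):
            parse_newick("((A:1,B):1,C:2);")

    def test_zero_branch_length_rejected(self):
        with pytest.raises(TreeValidationError, match="branch length"):
            parse_newick("((A:1,B:0):1,C:2);")

    def test_non_ultrametric_rejected(self):
        # tip depths 2, 3, 2
        with pytest.raises(TreeValidationError, match="ultrametric"):
            parse_newick("((A:1,B:2):1,C:2);", ultrametric_tol=1e-6)

    def test_non_ultrametric_warns_when_configured(self):
        with pytest.warns(UserWarning, match="ultrametric"):
            parse_newick(
                "((A:1,B:2):1,C:2);", ultrametric_tol=1e-6,
                on_nonultrametric="warn",
            )

    def test_small_violation_within_tolerance_accepted(self):
        t = parse_newick("((A:1.0005,B:1):1,C:2);", ultrametric_tol=1e-3)
        assert t.n_tips == 3

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_parse_garbage_raises(self):
        with pytest.raises(TreeValidationError):
            parse_newick("not a newick ((")


class TestRoundTrip:
    def test_read_write_read_preserves_structure(self, four_tip_tree, tmp_path):
        path = tmp_path / "t.nwk"
        write_newick(four_tip_tree, path)
        back = read_newick(path)
        a1, a2 = clade_ages(four_tip_tree), clade_ages(back)
        assert set(a1) == set(a2)
        for clade, age in a1.items():
            assert a2[clade] == pytest.approx(age, rel=1e-9, abs=1e-12)


class TestMatching:
    def test_identity_when_all_matched(self, four_tip_tree):
        table = BiomeStateTable({l: Biome.TROPICAL for l in "ABCD"})
        tree2, table2, dropped = match_tree_and_states(four_tip_tree, table)
        assert dropped == []
        assert tree2 is four_tip_tree
        assert set(table2) == set("ABCD")

    def test_drop_prunes_and_sums_branches(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        table = BiomeStateTable({"B": Biome.TROPICAL, "C": Biome.TEMPERATE})
        pruned, table2, dropped = match_tree_and_states(tree, table, policy="drop")
        assert dropped == ["A"]
        assert pruned.n_tips == 2
        # manual suppression of the degree-2 node: (B:2,C:2);
        ages = clade_ages(pruned)
        assert ages[frozenset("BC")] == pytest.approx(2.0)
        assert pruned.height == pytest.approx(2.0)

    def test_drop_preserves_depths_of_retained_tips(self, oot_dataset):
        tree, states, _ = oot_dataset
        keep = list(tree.tip_labels)[: tree.n_tips // 2]
        sub = states.subset(keep)
        pruned, _, dropped = match_tree_and_states(tree, sub, policy="drop")
        assert len(dropped) == tree.n_tips - len(keep)
        assert pruned.height <= tree.height + 1e-9
        # ultrametric tips stay at the present
        assert np.allclose(pruned.ages[: pruned.n_tips], 0.0)

    def test_error_policy(self, four_tip_tree):
        table = BiomeStateTable({"A": Biome.TROPICAL})
        with pytest.raises(ValueError, match="without state"):
            match_tree_and_states(four_tip_tree, table, policy="error")


class TestExtractClade:
    def test_mrca_subtree(self, four_tip_tree):
        sub = extract_clade(four_tip_tree, ["A", "B"])
        assert set(sub.tip_labels) == {"A", "B"}
        assert sub.height == pytest.approx(1.0)

    def test_spanning_pair_gives_whole_tree(self, four_tip_tree):
        sub = extract_clade(four_tip_tree, ["A", "C"])
        assert set(sub.tip_labels) == {"A", "B", "C", "D"}
        assert sub.height == pytest.approx(2.0)

    def test_clade_includes_unlisted_descendants(self, four_tip_tree):
        # C and D share their MRCA; listing only C,D yields both
        sub = extract_clade(four_tip_tree, ["C", "D"])
        assert set(sub.tip_labels) == {"C", "D"}
        assert sub.height == pytest.approx(1.5)

    def test_unknown_tip_rejected(self, four_tip_tree):
        with pytest.raises(ValueError, match="not in tree"):
            extract_clade(four_tip_tree, ["A", "Z"])


class TestStateTables:
    def test_states_schema(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("species,state\nsp1,TROPICAL\nsp2,temperate\n")
        t = read_state_table(p, schema="states")
        assert t["sp1"] is Biome.TROPICAL
        assert t["sp2"] is Biome.TEMPERATE

    def test_latitudes_schema(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("species,min_lat,max_lat\nsp1,-10,15\n")
        (r,) = read_state_table(p, schema="latitudes")
        assert r == LatitudeRange("sp1", -10.0, 15.0)

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("species,state\nsp1,TROPICAL\nsp1,TEMPERATE\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_state_table(p, schema="states")

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,min_lat\nsp1,-10\n")
        with pytest.raises(ValueError, match="max_lat"):
            read_state_table(p, schema="latitudes")

    def test_latitude_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,min_lat,max_lat\nsp1,-100,15\n")
        with pytest.raises(ValueError, match=r"\[-90, 90\]"):
            read_state_table(p, schema="latitudes")
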
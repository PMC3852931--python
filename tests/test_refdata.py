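"""Loading, validation and grouping of reference profiles and query signatures."""

import numpy as np
import pytest

from connmap.refdata import (
    GeneUniverse,
    RefDataError,
    RefSet,
    ReferenceProfile,
    group_refsets,
    load_reference_database,
    load_reference_profile,
    load_signature,
    load_universe,
    parse_profile_filename,
)
from connmap.synthdata import standard_manifest, write_fixture_tree

from conftest import make_profile, make_signature


def write_ref(path, rows):
    path.write_text("".join(f"{g}\t{r}\n" for g, r in rows))


class TestUniverse:
    def test_single_file_defines_universe(self, tmp_path):
        write_ref(tmp_path / "a.tab", [("g1", 5), ("g2", -4), ("g3", 3), ("g4", -2), ("g5", 1)])
        u = load_universe(tmp_path)
        assert u.gene_ids == ("g1", "g2", "g3", "g4", "g5")
        assert u.N == 5

    def test_first_file_lexicographic_order_fixes_universe(self, tmp_path):
        write_ref(tmp_path / "b.tab", [("x1", 1), ("x2", -2)])
        write_ref(tmp_path / "a.tab", [("g2", 1), ("g1", -2)])
        assert load_universe(tmp_path).gene_ids == ("g2", "g1")

    def test_empty_folder_is_fatal(self, tmp_path):
        with pytest.raises(RefDataError, match="no reference files"):
            load_universe(tmp_path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(RefDataError, match="duplicate"):
            GeneUniverse(("g1", "g1", "g2"))


class TestProfileValidation:
    def test_valid_signed_permutation(self, tmp_path, universe5):
        write_ref(tmp_path / "drugA_MCF7_1e-6_01.tab",
                  [("g1", 5), ("g2", -4), ("g3", 3), ("g4", -2), ("g5", 1)])
        p = load_reference_profile(tmp_path / "drugA_MCF7_1e-6_01.tab", universe5)
        assert p.rank_of("g2") == -4
        assert (p.drug, p.cell, p.dose) == ("drugA", "MCF7", "1e-6")

    def test_duplicate_gene_is_fatal(self, tmp_path, universe5):
        write_ref(tmp_path / "p.tab", [("g1", 5), ("g1", -4), ("g3", 3), ("g4", -2), ("g5", 1)])
        with pytest.raises(RefDataError, match="duplicate gene 'g1'"):
            load_reference_profile(tmp_path / "p.tab", universe5)

    def test_permutation_violation_is_fatal(self, tmp_path, universe5):
        write_ref(tmp_path / "p.tab", [("g1", 5), ("g2", 5), ("g3", 3), ("g4", -2), ("g5", 1)])
        with pytest.raises(RefDataError, match="not a permutation"):
            load_reference_profile(tmp_path / "p.tab", universe5)

    def test_missing_gene_is_fatal(self, tmp_path, universe5):
        write_ref(tmp_path / "p.tab", [("g1", 4), ("g2", -3), ("g3", 2), ("g4", -1)])
        with pytest.raises(RefDataError, match="missing"):
            load_reference_profile(tmp_path / "p.tab", universe5)

    def test_unknown_gene_is_fatal(self, tmp_path, universe5):
        write_ref(tmp_path / "p.tab",
                  [("gX", 5), ("g2", -4), ("g3", 3), ("g4", -2), ("g5", 1)])
        with pytest.raises(RefDataError, match="'gX' not in universe"):
            load_reference_profile(tmp_path / "p.tab", universe5)

    def test_non_integer_rank_is_fatal(self, tmp_path, universe5):
        write_ref(tmp_path / "p.tab",
                  [("g1", 5.0), ("g2", -4), ("g3", 3), ("g4", -2), ("g5", 1)])
        with pytest.raises(RefDataError, match="not an integer"):
            load_reference_profile(tmp_path / "p.tab", universe5)

    def test_line_order_does_not_matter(self, tmp_path, universe5):
        rows = [("g1", 5), ("g2", -4), ("g3", 3), ("g4", -2), ("g5", 1)]
        write_ref(tmp_path / "fwd.tab", rows)
        write_ref(tmp_path / "rev.tab", rows[::-1])
        fwd = load_reference_profile(tmp_path / "fwd.tab", universe5)
        rev = load_reference_profile(tmp_path / "rev.tab", universe5)
        assert np.array_equal(fwd.ranks, rev.ranks)


class TestFilenameMetadata:
    @pytest.mark.parametrize(
        "filename,expected",
        [
            ("drugA_MCF7_1e-6_01.tab", ("drugA", "MCF7", "1e-6")),
            ("my_long_drug_PC3_1e-5_02.tab", ("my_long_drug", "PC3", "1e-5")),
            ("drugA.tab", ("drugA", "", "")),
        ],
    )
    def test_right_to_left_parse(self, filename, expected):
        assert parse_profile_filename(filename) == expected

    def test_sidecar_overrides_filename(self, tmp_path, universe5):
        write_ref(tmp_path / "weird-name.tab",
                  [("g1", 5), ("g2", -4), ("g3", 3), ("g4", -2), ("g5", 1)])
        (tmp_path / "metadata.tsv").write_text(
            "filename\tdrug\tcell\tdose\nweird-name.tab\tdrugZ\tHL60\t1e-7\n"
        )
        _, profiles = load_reference_database(tmp_path, universe5)
        assert (profiles[0].drug, profiles[0].cell, profiles[0].dose) == ("drugZ", "HL60", "1e-7")


class TestGrouping:
    def _profiles(self, universe5):
        names = [
            ("A_MCF7_1e-6_01", "A", "MCF7", "1e-6"),
            ("A_MCF7_1e-6_02", "A", "MCF7", "1e-6"),
            ("A_PC3_1e-6_01", "A", "PC3", "1e-6"),
            ("B_MCF7_1e-6_01", "B", "MCF7", "1e-6"),
        ]
        ranks = np.array([5, -4, 3, -2, 1])
        return [
            make_profile(universe5, ranks, profile_id=pid, drug=d, cell=c, dose=o)
            for pid, d, c, o in names
        ]

    def test_by_drug_partition(self, universe5):
        refsets = group_refsets(self._profiles(universe5), "by_drug")
        assert [(rs.set_id, rs.K) for rs in refsets] == [("A", 3), ("B", 1)]

    def test_by_drug_cell_dose_partition(self, universe5):
        refsets = group_refsets(self._profiles(universe5), "by_drug_cell_dose")
        assert [(rs.set_id, rs.K) for rs in refsets] == [
            ("A_MCF7_1e-6", 2),
            ("A_PC3_1e-6", 1),
            ("B_MCF7_1e-6", 1),
        ]

    @pytest.mark.parametrize("mode", ["by_drug", "by_drug_cell_dose"])
    def test_grouping_is_a_partition(self, universe5, mode):
        profiles = self._profiles(universe5)
        refsets = group_refsets(profiles, mode)
        members = [p.profile_id for rs in refsets for p in rs.members]
        assert sorted(members) == sorted(p.profile_id for p in profiles)
        assert sum(rs.K for rs in refsets) == len(profiles)

    def test_singleton_group_legal(self, universe5):
        p = self._profiles(universe5)[0]
        refsets = group_refsets([p], "by_drug")
        assert len(refsets) == 1 and refsets[0].K == 1

    def test_unknown_mode_rejected(self, universe5):
        with pytest.raises(RefDataError, match="unknown refset mode"):
            group_refsets(self._profiles(universe5), "by_cell")


class TestSignatures:
    def test_basic_load(self, tmp_path, universe5):
        (tmp_path / "q.tab").write_text("g1\t+1\ng2\t-1\n")
        sig = load_signature(tmp_path / "q.tab", universe5)
        assert sig.entries == (("g1", 1), ("g2", -1))
        assert sig.m == 2

    def test_bare_1_spelling(self, tmp_path, universe5):
        (tmp_path / "q.tab").write_text("g1\t1\ng2\t-1\n")
        assert load_signature(tmp_path / "q.tab", universe5).flags().tolist() == [1, -1]

    def test_unknown_gene_dropped_with_warning(self, tmp_path, universe5, caplog):
        (tmp_path / "q.tab").write_text("g1\t+1\ngX\t-1\n")
        with caplog.at_level("WARNING", logger="connmap"):
            sig = load_signature(tmp_path / "q.tab", universe5)
        assert sig.m == 1 and sig.genes() == ("g1",)
        assert any("gX" in rec.getMessage() for rec in caplog.records)

    def test_empty_after_filter_is_fatal(self, tmp_path, universe5):
        (tmp_path / "q.tab").write_text("gX\t+1\n")
        with pytest.raises(RefDataError, match="no signature genes remain"):
            load_signature(tmp_path / "q.tab", universe5)

    def test_unparseable_flag_is_fatal(self, tmp_path, universe5):
        (tmp_path / "q.tab").write_text("g1\tup\n")
        with pytest.raises(RefDataError, match=":1: unparseable flag"):
            load_signature(tmp_path / "q.tab", universe5)

    def test_duplicate_gene_is_fatal(self, tmp_path, universe5):
        (tmp_path / "q.tab").write_text("g1\t+1\ng1\t-1\n")
        with pytest.raises(RefDataError, match="duplicate gene"):
            load_signature(tmp_path / "q.tab", universe5)


class TestRoundTrip:
    def test_fixture_tree_round_trips(self, tmp_path):
        manifest = standard_manifest(N=120, n_profiles=12, query_lengths=(5, 10), n_drugs=4)
        truth = write_fixture_tree(tmp_path, manifest, seed=11)
        universe, profiles = load_reference_database(tmp_path / "ref-files")
        assert universe.gene_ids == truth["universe"].gene_ids
        assert len(profiles) == manifest.n_profiles
        # grouping matches the manifest's metadata truth
        by_key = {}
        for fn, d, c, o in manifest.profiles:
            by_key.setdefault("_".join((d, c, o)), []).append(fn)
        refsets = group_refsets(profiles, "by_drug_cell_dose")
        assert {rs.set_id: rs.K for rs in refsets} == {
            k: len(v) for k, v in by_key.items()
        }
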
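"""Catalog construction: merging, keyword flags, TM and localization consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbiotrans import catalog as cat


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "source", "accession", "description", "evalue"]
    )


class TestMergeAnnotations:
    def test_two_sources_both_descriptions_kept(self):
        merged = cat.merge_annotations(
            _hits([
                ("p1", "interpro", "IPR000001", "sugar transporter", 1e-10),
                ("p1", "eggnog", "OG123", "hexose carrier", 1e-8),
            ])
        )
        assert sorted(merged.loc["p1", "descriptions"]) == [
            "hexose carrier", "sugar transporter",
        ]

    def test_empty_table_gives_empty_catalog(self):
        merged = cat.merge_annotations(_hits([]))
        assert len(merged) == 0

    def test_conflicting_scores_keep_best_evalue(self):
        merged = cat.merge_annotations(
            _hits([
                ("p1", "pfam_hmm", "PF00083", "x", 1e-5),
                ("p1", "pfam_hmm", "PF00083", "x", 1e-9),
                ("p1", "pfam_hmm", "PF00083", "x", 1e-7),
            ])
        )
        assert merged.loc["p1", "accessions"]["PF00083"] == 1e-9

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            cat.merge_annotations(_hits([("p1", "tcdb", "A", "x", -1.0)]))


class TestKeywordFlags:
    @pytest.mark.parametrize(
        "description,expected",
        [
            ("sugar transporter family protein", True),
            ("ribosomal protein L7", False),
            ("DNA transposase", False),
            ("amino acid permease", True),
            ("CATION CHANNEL", True),  # case-insensitive
        ],
    )
    def test_transporter_keyword_token_mode(self, description, expected):
        merged = cat.merge_annotations(_hits([("p", "tcdb", "A", description, 1e-9)]))
        assert cat.flag_transporters(merged).loc["p"] == expected

    def test_ose_is_token_suffix_only(self):
        """'glucose'/'triose' match the -ose rule; 'permease' and short 'ose'-
        containing words do not."""
        merged = cat.merge_annotations(
            _hits([
                ("p1", "tcdb", "A", "glucose transporter", 1e-9),
                ("p2", "tcdb", "A", "ammonium transporter", 1e-9),
                ("p3", "tcdb", "A", "triose-phosphate transporter", 1e-9),
            ])
        )
        is_tr = cat.flag_transporters(merged)
        sugar = cat.flag_sugar_transporters(merged, is_tr)
        assert bool(sugar.loc["p1"]) and bool(sugar.loc["p3"])
        assert not sugar.loc["p2"]

    def test_core_pfam_implies_sugar_without_keyword(self):
        merged = cat.merge_annotations(
            _hits([("p1", "pfam_hmm", "PF03151", "hypothetical protein", 1e-30)])
        )
        is_tr = cat.flag_transporters(merged)
        sugar = cat.flag_sugar_transporters(merged, is_tr)
        assert sugar.loc["p1"]

    def test_empty_keyword_list_rejected(self):
        merged = cat.merge_annotations(_hits([("p", "tcdb", "A", "x", 1e-9)]))
        with pytest.raises(ValueError):
            cat.flag_transporters(merged, keywords=[])

    @settings(deadline=None, max_examples=30)
    @given(extra=st.sampled_from(["ferredoxin", "kinase", "cytochrome b559"]))
    def test_monotonicity_adding_nonmatching_hit_keeps_flag(self, extra):
        base = [("p1", "tcdb", "A", "sugar transporter", 1e-9)]
        with_extra = base + [("p1", "eggnog", "B", extra, 1e-5)]
        f1 = cat.flag_transporters(cat.merge_annotations(_hits(base))).loc["p1"]
        f2 = cat.flag_transporters(cat.merge_annotations(_hits(with_extra))).loc["p1"]
        assert f1 and f2


class TestSubfamily:
    def _merged_pf00083(self):
        return cat.merge_annotations(
            _hits([("p1", "pfam_hmm", "PF00083", "sugar transporter", 1e-30)])
        )

    def test_passing_hit_assigned(self):
        sub = cat.assign_subfamily(
            self._merged_pf00083(),
            pd.DataFrame({"protein_id": ["p1"], "accession": ["IPR002439"],
                          "evalue": [1e-30]}),
        )
        assert sub.loc["p1"] == "GLUT"

    def test_hit_above_threshold_not_assigned(self):
        sub = cat.assign_subfamily(
            self._merged_pf00083(),
            pd.DataFrame({"protein_id": ["p1"], "accession": ["IPR002439"],
                          "evalue": [1e-10]}),
        )
        assert pd.isna(sub.loc["p1"])

    def test_best_evalue_wins(self):
        sub = cat.assign_subfamily(
            self._merged_pf00083(),
            pd.DataFrame({
                "protein_id": ["p1", "p1"],
                "accession": ["IPR045262", "IPR044775"],
                "evalue": [1e-40, 1e-25],
            }),
        )
        assert sub.loc["p1"] == "STP/PLT"

    def test_non_parent_family_ignored(self):
        merged = cat.merge_annotations(
            _hits([("p2", "pfam_hmm", "PF03151", "TPT", 1e-30)])
        )
        sub = cat.assign_subfamily(
            merged,
            pd.DataFrame({"protein_id": ["p2"], "accession": ["IPR002439"],
                          "evalue": [1e-40]}),
        )
        assert pd.isna(sub.loc["p2"])

    def test_evalue_tie_breaks_lexicographically(self):
        sub = cat.assign_subfamily(
            self._merged_pf00083(),
            pd.DataFrame({
                "protein_id": ["p1", "p1"],
                "accession": ["IPR044775", "IPR002439"],
                "evalue": [1e-40, 1e-40],
            }),
        )
        assert sub.loc["p1"] == "GLUT"  # IPR002439 < IPR044775


class TestTMConsensus:
    @pytest.mark.parametrize(
        "n1,n2,expected",
        [
            (4, 3, True),
            (1, 1, False),   # fewer than two domains
            (2, 5, False),   # difference of 3 is not allowed
            (2, 4, True),    # difference of 2 is
            (2, 2, True),
            (0, 0, False),
            (10, 2, False),
        ],
    )
    def test_boundary_enumeration(self, n1, n2, expected):
        tm = pd.DataFrame({"protein_id": ["p"], "n_tm_tool1": [n1], "n_tm_tool2": [n2]})
        assert cat.tm_consensus_filter(tm).loc["p"] == expected

    @settings(deadline=None, max_examples=50)
    @given(n1=st.integers(0, 20), n2=st.integers(0, 20))
    def test_symmetric_in_tools(self, n1, n2):
        a = pd.DataFrame({"protein_id": ["p"], "n_tm_tool1": [n1], "n_tm_tool2": [n2]})
        b = pd.DataFrame({"protein_id": ["p"], "n_tm_tool1": [n2], "n_tm_tool2": [n1]})
        assert cat.tm_consensus_filter(a).loc["p"] == cat.tm_consensus_filter(b).loc["p"]

    def test_missing_prediction_fails(self):
        tm = pd.DataFrame(
            {"protein_id": ["p"], "n_tm_tool1": [np.nan], "n_tm_tool2": [4.0]}
        )
        assert not cat.tm_consensus_filter(tm).loc["p"]

    def test_negative_counts_raise(self):
        tm = pd.DataFrame({"protein_id": ["p"], "n_tm_tool1": [-1], "n_tm_tool2": [4]})
        with pytest.raises(ValueError):
            cat.tm_consensus_filter(tm)


def _loc(rows):
    return pd.DataFrame(rows, columns=["protein_id", "tool", "raw_label", "score"])


class TestLocalizationConsensus:
    def test_two_tool_agreement_with_passing_deeploc(self):
        out = cat.localization_consensus(
            _loc([
                ("p", "deeploc", "Cell membrane", 0.8),
                ("p", "wolf_psort", "plas", ""),
            ])
        )
        assert out.loc["p"] == "cell_membrane"

    def test_five_different_labels_unassigned(self):
        out = cat.localization_consensus(
            _loc([
                ("p", "deeploc", "Cell membrane", 0.9),
                ("p", "targetp", "mTP", ""),
                ("p", "hectar", "chloroplast", ""),
                ("p", "wolf_psort", "golg", ""),
                ("p", "mulocdeep", "ER", ""),
            ])
        )
        assert out.loc["p"] == "unassigned"

    def test_two_two_tie_is_unassigned_even_with_strong_deeploc(self):
        out = cat.localization_consensus(
            _loc([
                ("p", "deeploc", "Golgi apparatus", 0.9),
                ("p", "wolf_psort", "golg", ""),
                ("p", "hectar", "signal peptide", ""),
                ("p", "targetp", "SP", ""),
            ])
        )
        assert out.loc["p"] == "unassigned"

    def test_weak_deeploc_needs_two_other_tools(self):
        # Deeploc votes for the winner below threshold: one co-voter is not enough
        out = cat.localization_consensus(
            _loc([
                ("p", "deeploc", "Plastid", 0.4),
                ("p", "hectar", "chloroplast", ""),
            ])
        )
        assert out.loc["p"] == "unassigned"
        # but two non-Deeploc voters carry the assignment
        out = cat.localization_consensus(
            _loc([
                ("p", "deeploc", "Plastid", 0.4),
                ("p", "hectar", "chloroplast", ""),
                ("p", "wolf_psort", "chlo", ""),
            ])
        )
        assert out.loc["p"] == "plastid"

    def test_strict_and_mode_requires_deeploc(self):
        votes = _loc([
            ("p", "hectar", "chloroplast", ""),
            ("p", "wolf_psort", "chlo", ""),
            ("p", "deeploc", "Cytoplasm", 0.9),
        ])
        assert cat.localization_consensus(votes).loc["p"] == "plastid"
        assert cat.localization_consensus(votes, strict_and=True).loc["p"] == "unassigned"

    def test_unmapped_label_raises(self):
        with pytest.raises(ValueError, match="unmapped"):
            cat.localization_consensus(_loc([("p", "deeploc", "Moonbase", 0.9)]))


class TestBuildCatalog:
    def test_zero_noise_recovery_is_exact(self, catalog_truth):
        hits, tm, locs, truth = catalog_truth
        catalog_df, summary = cat.build_catalog(hits, tm=tm, localizations=locs)
        assert set(catalog_df.index[catalog_df["is_sugar_transporter"]]) == (
            truth.sugar_transporters
        )
        assert set(catalog_df.index[catalog_df["is_transporter"]]) == truth.transporters

    def test_sugar_implies_transporter(self, catalog_truth):
        hits, tm, locs, _ = catalog_truth
        catalog_df, _ = cat.build_catalog(hits, tm=tm, localizations=locs)
        assert (
            catalog_df["is_transporter"] | ~catalog_df["is_sugar_transporter"]
        ).all()

    def test_per_pfam_counts_match_planted_accessions(self, catalog_truth):
        hits, tm, locs, truth = catalog_truth
        catalog_df, summary = cat.build_catalog(hits, tm=tm, localizations=locs)
        planted = (
            hits[hits["protein_id"].isin(truth.sugar_transporters)]
            .query("accession.str.startswith('PF')")
            .groupby("accession")["protein_id"].nunique().to_dict()
        )
        assert summary["sugar_genes_per_pfam"] == planted
        assert sum(summary["sugar_genes_per_pfam"].values()) == (
            summary["n_sugar_transporters"]
        )

    def test_empty_inputs_give_empty_catalog(self):
        catalog_df, summary = cat.build_catalog(
            pd.DataFrame(columns=["protein_id", "source", "accession",
                                  "description", "evalue"])
        )
        assert len(catalog_df) == 0
        assert summary["n_transporters"] == 0

    def test_id_mismatch_aborts(self, catalog_truth):
        hits, tm, locs, _ = catalog_truth
        bad_tm = tm.copy()
        bad_tm["protein_id"] = "X" + bad_tm["protein_id"]
        with pytest.raises(ValueError, match="unknown"):
            cat.build_catalog(hits, tm=bad_tm)
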
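"""Catalog data model: localization parsing, screen merging, counting."""
import pytest

from y2hnet.catalog import (
    Catalog,
    Copurification,
    InteractorRecord,
    LocalizationCall,
    LocalizationParseError,
    MergeConflictError,
    ProteinRef,
    ScreenConfig,
    merge_screens,
    parse_localization,
    summarize_counts,
    tally_localization,
)
from y2hnet.datasets import hoxa1_ad_screen, hoxa1_bait, hoxa1_db_screen


def _rec(symbol, eid, configs=("DB",), copurif="Y", bifc="Nuclear",
         prev=False, note=""):
    return InteractorRecord(
        protein=ProteinRef(symbol=symbol, entrez_id=eid),
        configs=frozenset(ScreenConfig(c) for c in configs),
        previously_described=prev,
        copurification=Copurification(copurif),
        bifc=parse_localization(bifc),
        function_note=note,
    )


class TestParseLocalization:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Nuclear, and vesicular", {"nuclear", "vesicular"}),
            ("Vesicular and cytoplasmic", {"vesicular", "cytoplasmic"}),
            ("Nuclear, vesicular, cytoplasmic",
             {"nuclear", "vesicular", "cytoplasmic"}),
            ("NUCLEAR", {"nuclear"}),
            ("nuclear and nuclear", {"nuclear"}),  # repeats collapse
        ],
    )
    def test_patterns(self, text, expected):
        call = parse_localization(text)
        assert call.is_pattern
        assert call.compartments == expected

    def test_sentinels(self):
        assert parse_localization("/") == LocalizationCall.no_signal()
        assert parse_localization("n.d.") == LocalizationCall.not_determined()
        assert parse_localization("N.D.") == LocalizationCall.not_determined()

    @pytest.mark.parametrize("bad", ["membranous", "nuclear, golgi", "  "])
    def test_unknown_token_or_empty_raises(self, bad):
        with pytest.raises(LocalizationParseError):
            parse_localization(bad)

    def test_error_names_the_token(self):
        with pytest.raises(LocalizationParseError, match="golgi"):
            parse_localization("nuclear, golgi")

    def test_total_over_packaged_fixture_cells(self):
        # every BiFC cell that occurs in the packaged tables must parse
        for rec in hoxa1_db_screen() + hoxa1_ad_screen():
            assert isinstance(rec.bifc, LocalizationCall)


class TestMergeScreens:
    def test_union_and_overlap(self):
        db = [_rec("A", 1), _rec("B", 2), _rec("C", 3)]
        ad = [_rec("B", 2, configs=("AD",)), _rec("C", 3, configs=("AD",)),
              _rec("D", 4, configs=("AD",))]
        bait = ProteinRef(symbol="X", entrez_id=99)
        merged = merge_screens(db, ad, bait)
        assert len(merged) == 4
        assert sum(r.overlap for r in merged.records.values()) == 2

    def test_empty_ad_list_is_identity(self):
        db = [_rec("A", 1), _rec("B", 2)]
        bait = ProteinRef(symbol="X", entrez_id=99)
        merged = merge_screens(db, [], bait)
        assert set(merged.records) == {1, 2}
        assert all(not r.overlap for r in merged.records.values())

    def test_commutative(self):
        db = [_rec("A", 1), _rec("B", 2)]
        ad = [_rec("B", 2, configs=("AD",)), _rec("D", 4, configs=("AD",))]
        bait = ProteinRef(symbol="X", entrez_id=99)
        assert merge_screens(db, ad, bait) == merge_screens(ad, db, bait)

    def test_idempotent_on_remerge(self):
        db = [_rec("A", 1), _rec("B", 2)]
        ad = [_rec("B", 2, configs=("AD",)), _rec("D", 4, configs=("AD",))]
        bait = ProteinRef(symbol="X", entrez_id=99)
        merged = merge_screens(db, ad, bait)
        again = merge_screens(db, list(merged.records.values()), bait)
        assert again == merged

    def test_duplicate_within_list_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            merge_screens([_rec("A", 1), _rec("A2", 1)], [],
                          ProteinRef(symbol="X", entrez_id=99))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"copurif": "N"},
            {"bifc": "Cytoplasmic"},
            {"prev": True},
        ],
    )
    def test_annotation_conflicts_raise(self, kwargs):
        db = [_rec("B", 2)]
        ad = [_rec("B", 2, configs=("AD",), **kwargs)]
        with pytest.raises(MergeConflictError):
            merge_screens(db, ad, ProteinRef(symbol="X", entrez_id=99))

    def test_overlap_mark_validated_against_derived_flag(self):
        db = [
            InteractorRecord(
                protein=ProteinRef(symbol="B", entrez_id=2),
                configs=frozenset({ScreenConfig.DB_BAIT}),
                bifc=LocalizationCall.not_determined(),
                claimed_overlap=True,  # claims both orientations, has one
            )
        ]
        with pytest.raises(MergeConflictError, match="overlap"):
            merge_screens(db, [], ProteinRef(symbol="X", entrez_id=99))


class TestCounts:
    def _catalog(self):
        bait = ProteinRef(symbol="X", entrez_id=99)
        records = {
            1: _rec("A", 1, copurif="Y", bifc="Nuclear"),
            2: _rec("B", 2, configs=("DB", "AD"), copurif="Y",
                    bifc="Nuclear and cytoplasmic"),
            3: _rec("C", 3, copurif="N", bifc="/"),
            99: _rec("X", 99, copurif="Y", bifc="Nuclear"),  # bait homodimer
        }
        for eid, r in records.items():
            if r.overlap:
                records[eid] = r
        return Catalog(bait=bait, records=records)

    def test_bait_toggle(self):
        catalog = self._catalog()
        assert summarize_counts(catalog, include_bait_self=False)["n_partners"] == 3
        assert summarize_counts(catalog, include_bait_self=True)["n_partners"] == 4

    def test_count_fields(self):
        counts = summarize_counts(self._catalog(), include_bait_self=True)
        assert counts["n_overlap"] == 1
        assert counts["n_confirmed"] == 3
        assert counts["n_bifc_positive"] == 3

    def test_variant_partition_sums_to_partner_count(self, hoxa1_merged):
        recs = hoxa1_merged.partner_records(include_bait_self=True)
        kinds = [r.bifc.kind for r in recs]
        assert (
            kinds.count("pattern")
            + kinds.count("no_signal")
            + kinds.count("not_determined")
            == len(recs)
        )

    def test_bifc_positive_within_confirmed(self, hoxa1_merged):
        counts = summarize_counts(hoxa1_merged, include_bait_self=True)
        assert counts["n_bifc_positive"] <= counts["n_confirmed"]

    def test_overlap_bounded_by_list_sizes(self, hoxa1_merged):
        counts = summarize_counts(hoxa1_merged, include_bait_self=True)
        assert counts["n_overlap"] <= min(
            counts["n_db_config"], counts["n_ad_config"]
        )

    def test_tally_exclusive_vs_any(self):
        tally = tally_localization(self._catalog(), include_bait_self=False)
        assert tally.loc["nuclear", "n_any"] == 2
        assert tally.loc["nuclear", "n_exclusive"] == 1
        assert tally.loc["cytoplasmic", "n_any"] == 1
        assert tally.loc["vesicular", "n_any"] == 0

    def test_bait_only_catalog_tallies_zero(self):
        bait = ProteinRef(symbol="X", entrez_id=99)
        catalog = Catalog(bait=bait, records={99: _rec("X", 99)})
        tally = tally_localization(catalog, include_bait_self=False)
        assert (tally == 0).all().all()


class TestFixtureParsing:
    def test_row_counts(self):
        assert len(hoxa1_db_screen()) == 40
        assert len(hoxa1_ad_screen()) == 28

    def test_alias_stripped_to_first_token(self):
        symbols = {r.protein.symbol: r for r in hoxa1_db_screen()}
        assert "ADAMTSL4" in symbols
        assert symbols["ADAMTSL4"].protein.aliases == ("TSRC1",)

    def test_marks_parsed(self):
        recs = {r.protein.symbol: r for r in hoxa1_db_screen()}
        assert recs["EFEMP2"].previously_described
        assert recs["EFEMP2"].claimed_overlap
        assert recs["LPXN"].previously_described
        assert not recs["LPXN"].claimed_overlap

    def test_previously_described_union_is_eight(self):
        merged = merge_screens(
            hoxa1_db_screen(), hoxa1_ad_screen(), hoxa1_bait()
        )
        assert sum(
            r.previously_described for r in merged.records.values()
        ) == 8

    def test_entrez_ids_unique_within_each_list(self):
        for recs in (hoxa1_db_screen(), hoxa1_ad_screen()):
            ids = [r.protein.entrez_id for r in recs]
            assert len(ids) == len(set(ids))
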
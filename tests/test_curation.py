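import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.curation import (MeddraMap, build_corpus, code_events,
                               deduplicate, load_toy_meddra,
                               normalize_drug_name, primary_suspect_caseids,
                               select_primary_suspect)
from pvsignal.synth import SynthConfig, generate_quarter

from conftest import TARGET, make_coded_corpus, planted_config


def demo_frame(rows):
    return pd.DataFrame(rows, columns=["PRIMARYID", "CASEID", "FDA_DT"],
                        dtype=str)


class TestDeduplicate:
    def test_most_recent_receipt_date_wins(self):
        demo = demo_frame([("10", "1", "20230101"), ("11", "1", "20230301")])
        assert deduplicate(demo) == ["11"]

    def test_exact_tie_goes_to_larger_primaryid(self):
        demo = demo_frame([("5", "2", "20230101"), ("9", "2", "20230101")])
        assert deduplicate(demo) == ["9"]

    def test_numeric_comparison_used_for_numeric_ids(self):
        # lexicographically '9' > '10'; numerically 10 wins
        demo = demo_frame([("9", "2", "20230101"), ("10", "2", "20230101")])
        assert deduplicate(demo) == ["10"]

    def test_deletion_list_removes_case(self):
        demo = demo_frame([
            ("10", "1", "20230101"), ("20", "3", "20230201")])
        assert deduplicate(demo, deletion_list={"3"}) == ["10"]

    def test_empty_input_gives_empty_output(self):
        assert deduplicate(demo_frame([])) == []

    def test_caseid_set_preserved_minus_deletions(self):
        bundle = generate_quarter(
            SynthConfig(n_cases=800, seed=6, duplicate_rate=0.25,
                        deletion_rate=0.05))
        retained = deduplicate(bundle.demo, bundle.deleted)
        kept = bundle.demo[bundle.demo["PRIMARYID"].isin(retained)]
        expected = set(bundle.demo["CASEID"]) - set(bundle.deleted)
        assert set(kept["CASEID"]) == expected

    def test_idempotent(self):
        bundle = generate_quarter(
            SynthConfig(n_cases=500, seed=8, duplicate_rate=0.3))
        once = deduplicate(bundle.demo)
        kept = bundle.demo[bundle.demo["PRIMARYID"].isin(once)]
        assert deduplicate(kept) == once

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(1, 5), st.integers(0, 99),
                  st.integers(20200101, 20200128)),
        min_size=1, max_size=20))
    def test_one_version_retained_per_case(self, raw):
        demo = demo_frame([
            (str(1000 + pid), str(cid), str(dt)) for cid, pid, dt in raw])
        demo = demo.drop_duplicates("PRIMARYID")
        retained = deduplicate(demo)
        kept = demo[demo["PRIMARYID"].isin(retained)]
        assert kept["CASEID"].is_unique
        assert set(kept["CASEID"]) == set(demo["CASEID"])

    def test_synth_ground_truth_recovered_exactly(self):
        bundle = generate_quarter(
            planted_config(n_cases=3000, seed=13, duplicate_rate=0.2,
                           deletion_rate=0.05))
        corpus, _ = build_corpus(bundle)
        got = dict(zip(corpus.cases["caseid"], corpus.cases["primaryid"]))
        expected = {
            c: p for c, p in bundle.truth.retained_primaryids.items()
            if c not in bundle.truth.deleted_caseids}
        assert got == expected


class TestPrimarySuspectSelection:
    def _corpus(self, drug_rows):
        cases = pd.DataFrame({
            "caseid": [c for c, _, _ in drug_rows],
        }).drop_duplicates().reset_index(drop=True)
        for col in ("primaryid", "fda_dt", "sex", "age_group", "reporter",
                    "country", "event_year", "event_dt", "start_dt"):
            cases[col] = ""
        from pvsignal.curation import CaseCorpus
        return CaseCorpus(
            cases=cases,
            drugs=pd.DataFrame(
                drug_rows, columns=["caseid", "role_cod", "drugname"]),
            reactions=pd.DataFrame(columns=["caseid", "pt"]),
            outcomes=pd.DataFrame(columns=["caseid", "outc_cod"]))

    def test_ps_match_is_retained(self):
        corpus = self._corpus([("1", "PS", "CHOLESTYRAMINE")])
        assert primary_suspect_caseids(corpus, ["CHOLESTYRAMINE"]) == {"1"}

    def test_concomitant_only_is_excluded(self):
        corpus = self._corpus([("1", "C", "CHOLESTYRAMINE"),
                               ("1", "PS", "ATORVASTATIN")])
        assert primary_suspect_caseids(corpus, ["CHOLESTYRAMINE"]) == set()

    def test_normalization_handles_suffix_and_case(self):
        corpus = self._corpus([("1", "PS", " Cholestyramine  Light ")])
        filtered = select_primary_suspect(corpus, ["CHOLESTYRAMINE"])
        assert filtered.n_cases == 1

    def test_punctuation_collapses(self):
        assert normalize_drug_name("Chole-styr/amine.") == "CHOLE STYR AMINE"

    def test_empty_pattern_list_is_error(self):
        corpus = self._corpus([("1", "PS", "X")])
        with pytest.raises(ValueError):
            primary_suspect_caseids(corpus, [])


class TestMeddraCoding:
    def test_constipation_maps_to_gastrointestinal(self, toy_map):
        assert toy_map.soc("Constipation") == "Gastrointestinal disorders"
        assert toy_map.soc("  constipation ") == "Gastrointestinal disorders"

    def test_unknown_pt_gets_unmapped_and_is_reported(self):
        corpus, _ = make_coded_corpus(
            SynthConfig(
                n_cases=30, seed=1,
                events={"Zyzzyx syndrome": "Nowhere"},
                background_event_probs={"Zyzzyx syndrome": 0.5}))
        coded = corpus.reactions
        assert (coded.loc[coded["pt"] == "Zyzzyx syndrome", "soc"]
                == "UNMAPPED").all()

    def test_unmapped_report_counts(self, toy_map):
        from pvsignal.curation import CaseCorpus

        corpus = CaseCorpus(
            cases=pd.DataFrame({"caseid": ["1"]}),
            drugs=pd.DataFrame(columns=["caseid", "role_cod", "drugname"]),
            reactions=pd.DataFrame(
                {"caseid": ["1", "1"], "pt": ["Nausea", "Gibberish"]}),
            outcomes=pd.DataFrame(columns=["caseid", "outc_cod"]))
        coded, unmapped = code_events(corpus, toy_map)
        assert unmapped == {"Gibberish": 1}

    def test_case_without_reactions_passes_through(self, toy_map):
        from pvsignal.curation import CaseCorpus

        corpus = CaseCorpus(
            cases=pd.DataFrame({"caseid": ["1"]}),
            drugs=pd.DataFrame(columns=["caseid", "role_cod", "drugname"]),
            reactions=pd.DataFrame(columns=["caseid", "pt"]),
            outcomes=pd.DataFrame(columns=["caseid", "outc_cod"]))
        coded, unmapped = code_events(corpus, toy_map)
        assert coded.n_cases == 1 and unmapped == {}

    def test_mapping_file_roundtrip(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("PT\tSOC\nNausea\tGastrointestinal disorders\n")
        m = MeddraMap.from_file(path, version="v1")
        assert m.soc("Nausea") == "Gastrointestinal disorders"
        assert m.version == "v1"

    def test_malformed_mapping_line_is_error(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("PT\tSOC\nonly-one-column\n")
        with pytest.raises(ValueError):
            MeddraMap.from_file(path)

    def test_toy_map_covers_default_synth_events(self, toy_map):
        cfg = SynthConfig()
        for pt in list(cfg.events) + [cfg.filler_pt]:
            assert toy_map.soc(pt) is not None, pt
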
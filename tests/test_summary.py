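import pytest

from litcooc.miner import write_cooccurrence_tsv
from litcooc.model import Cooccurrence
from litcooc.summary import (
    JOIN_FILENAME,
    compute_stats,
    render_summary,
    summarize_basic,
    summarize_spread,
)


def cooc(pmid, a, b, type_, terms=()):
    return Cooccurrence(
        pmid=pmid,
        entity_a=a,
        entity_b=b,
        type=type_,
        evidence_sentence_index=0 if type_ in (1, 2, 3) else None,
        terms=tuple(terms),
        concepts=(),
    )


def write_folder(folder, files):
    folder.mkdir(parents=True, exist_ok=True)
    for name, rows in files.items():
        write_cooccurrence_tsv(rows, folder / f"{name}.cooc.tsv")
    return folder


class TestComputeStats:
    def test_hand_tally(self):
        # hand tally: rows (A,B,t1), (A,B,t2), (A,C,t4)
        rows = [
            cooc("1", "A", "B", 1, ["activates"]),
            cooc("2", "A", "B", 2, ["induced"]),
            cooc("3", "A", "C", 4),
        ]
        report = compute_stats(rows)
        t = report.totals
        assert t["absolute_cooccurrences"] == 3
        assert t["nonredundant_cooccurrences"] == 2
        assert (t["type_1"], t["type_2"], t["type_3"], t["type_4"]) == (1, 1, 0, 1)
        assert t["absolute_proteins"] == 6
        assert t["nonredundant_proteins"] == 3
        assert t["absolute_terms"] == 2 and t["nonredundant_terms"] == 2

    def test_empty_input_all_zero(self):
        report = compute_stats([])
        assert all(v == 0 for v in report.totals.values())

    def test_per_type_totals_sum_to_absolute(self):
        rows = [cooc(str(i), "A", "B", 1 + i % 4) for i in range(11)]
        t = compute_stats(rows).totals
        assert sum(t[f"type_{k}"] for k in (1, 2, 3, 4)) == t["absolute_cooccurrences"]

    def test_pair_seen_twice_is_poorly_described(self):
        rows = [cooc("1", "A", "B", 4), cooc("2", "A", "B", 4)]
        report = compute_stats(rows)
        assert report.poorly_described["cooccurrences"] == ["A -- B"]
        report3 = compute_stats(rows + [cooc("3", "A", "B", 4)])
        assert report3.poorly_described["cooccurrences"] == []

    def test_threshold_configurable(self):
        rows = [cooc(str(i), "A", "B", 4) for i in range(3)]
        assert compute_stats(rows, threshold=3).poorly_described["cooccurrences"] == ["A -- B"]

    def test_extra_section_totals_match_term_stats(self):
        rows = [
            cooc("1", "A", "B", 1, ["activates"]),
            cooc("2", "A", "B", 2, ["activates", "induced"]),
            cooc("3", "B", "C", 4),  # type 4 carries no terms
        ]
        report = compute_stats(rows)
        for term, per_pair in report.extra_section.items():
            assert sum(per_pair.values()) == report.term_stats[term]
        assert set(report.extra_section) == set(report.term_stats)

    def test_every_extra_pair_exists_in_cooccurrence_stats(self):
        rows = [cooc("1", "A", "B", 1, ["binds"])]
        report = compute_stats(rows)
        for per_pair in report.extra_section.values():
            for pair in per_pair:
                assert pair in report.cooccurrence_stats


class TestSummarizeBasic:
    def test_three_inputs_write_four_summaries(self, tmp_path):
        folder = write_folder(
            tmp_path / "res",
            {
                "f1": [cooc("1", "A", "B", 1, ["binds"])],
                "f2": [cooc("2", "A", "C", 2, ["binds"])],
                "f3": [cooc("3", "B", "C", 4)],
            },
        )
        written = summarize_basic(folder)
        assert len(written) == 4
        assert written[-1].name == JOIN_FILENAME

    def test_single_input_differs_only_by_extra_section(self, tmp_path):
        folder = write_folder(
            tmp_path / "res", {"f1": [cooc("1", "A", "B", 1, ["binds"])]}
        )
        per_file, join = summarize_basic(folder)
        per_text = per_file.read_text()
        join_text = join.read_text()
        assert "== EXTRA SECTION ==" in per_text
        assert "== EXTRA SECTION ==" not in join_text
        assert per_text.startswith(join_text.rstrip("\n"))

    def test_join_counts_concatenation_not_sum(self, tmp_path):
        # two files share pair (A,B): join nonredundant < sum of per-file
        folder = write_folder(
            tmp_path / "res",
            {
                "f1": [cooc("1", "A", "B", 1, ["binds"])],
                "f2": [cooc("2", "A", "B", 2, ["binds"]), cooc("3", "A", "C", 4)],
            },
        )
        summarize_basic(folder)
        join = (folder / JOIN_FILENAME).read_text()
        assert "cooccurrences\tabsolute=3\tnonredundant=2" in join

    def test_empty_folder_is_an_error_naming_it(self, tmp_path):
        empty = tmp_path / "nothing"
        empty.mkdir()
        with pytest.raises(FileNotFoundError, match="nothing"):
            summarize_basic(empty)

    def test_rerun_byte_idempotent(self, tmp_path):
        folder = write_folder(
            tmp_path / "res", {"f1": [cooc("1", "A", "B", 1, ["binds"])]}
        )
        first = [p.read_bytes() for p in summarize_basic(folder)]
        second = [p.read_bytes() for p in summarize_basic(folder)]
        assert first == second


class TestSummarizeSpread:
    def test_disjoint_folders_sum(self, tmp_path):
        a = write_folder(tmp_path / "sp_a", {"f": [cooc("1", "A", "B", 1, ["binds"])]})
        b = write_folder(tmp_path / "sp_b", {"f": [cooc("2", "C", "D", 2, ["binds"])]})
        out = summarize_spread([a, b], tmp_path / "spread.summary")
        text = out.read_text()
        pooled = text.split("==== POOLED ====")[1]
        assert "cooccurrences\tabsolute=2\tnonredundant=2" in pooled

    def test_shared_pair_pooled_nonredundant_minus_one(self, tmp_path):
        a = write_folder(tmp_path / "sh_a", {"f": [cooc("1", "A", "B", 1, ["binds"])]})
        b = write_folder(tmp_path / "sh_b", {"f": [cooc("2", "A", "B", 2, ["binds"])]})
        out = summarize_spread([a, b], tmp_path / "spread.summary")
        pooled = out.read_text().split("==== POOLED ====")[1]
        assert "cooccurrences\tabsolute=2\tnonredundant=1" in pooled

    def test_single_folder_pooled_equals_basic_join(self, tmp_path):
        folder = write_folder(
            tmp_path / "one", {"f": [cooc("1", "A", "B", 1, ["binds"])]}
        )
        summarize_basic(folder)
        join_text = (folder / JOIN_FILENAME).read_text()
        out = summarize_spread([folder], tmp_path / "spread.summary")
        pooled = out.read_text().split("==== POOLED ====\n")[1]
        assert pooled.rstrip("\n") == join_text.rstrip("\n")

    def test_folder_without_summaries_skipped(self, tmp_path, caplog):
        import logging

        good = write_folder(tmp_path / "good", {"f": [cooc("1", "A", "B", 4)]})
        empty = tmp_path / "void"
        empty.mkdir()
        with caplog.at_level(logging.WARNING, logger="litcooc.summary"):
            out = summarize_spread([good, empty], tmp_path / "spread.summary")
        assert "FOLDER good" in out.read_text()
        assert "void" not in out.read_text()
        assert any("void" in r.message for r in caplog.records)


class TestRenderSummary:
    def test_sections_present(self):
        report = compute_stats([cooc("1", "A", "B", 1, ["binds"])])
        text = render_summary(report, with_extra=True)
        for header in ("== TOTALS ==", "== PROTEINS", "== COOCCURRENCES", "== TERMS",
                       "== POORLY DESCRIBED ==", "== EXTRA SECTION =="):
            assert header in text
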
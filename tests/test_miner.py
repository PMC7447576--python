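import io
import random

import pytest

from litcooc.miner import (
    classify_pair_in_sentence,
    filter_by_taxon,
    mine_abstract,
    mine_record,
    read_cooccurrence_tsv,
    select_type,
    write_cooccurrence_tsv,
)
from litcooc.model import Cooccurrence, EntityMention
from litcooc.synthetic import generate_hard_records
from litcooc.tagger import tag_concepts, tag_entities, tag_terms

from oracles import brute_force_mine


def mine(record, lexicon):
    return mine_abstract(
        record,
        tag_entities(record, lexicon),
        tag_terms(record, lexicon),
        tag_concepts(record, lexicon),
    )


def typed_set(cooccurrences):
    return {(c.pmid, c.entity_a, c.entity_b): c.type for c in cooccurrences}


class TestClassifyPairInSentence:
    def _parts(self, lexicon, text, pmid="1"):
        from litcooc.model import AbstractRecord

        record = AbstractRecord.build(pmid=pmid, title="A study.", abstract=text)
        entities = [m for m in tag_entities(record, lexicon) if m.sentence_index == 1]
        terms = [t for t in tag_terms(record, lexicon) if t.sentence_index == 1]
        return entities, terms

    def test_exact_term_between_is_type_1(self, mini_lexicon):
        (a, b), terms = self._parts(mini_lexicon, "rbcL activates psbA.")
        assert classify_pair_in_sentence(a, b, terms) == 1

    def test_exact_term_outside_is_type_2(self, mini_lexicon):
        (a, b), terms = self._parts(mini_lexicon, "rbcL and psbA are induced.")
        assert classify_pair_in_sentence(a, b, terms) == 2

    def test_permissive_only_is_type_3(self, mini_lexicon):
        # brute-force check: "activation" matches no exact term in any mode
        (a, b), terms = self._parts(mini_lexicon, "rbcL and psbA activation.")
        assert all(t.match_mode == "permissive" for t in terms)
        assert classify_pair_in_sentence(a, b, terms) == 3

    def test_no_term_is_none(self, mini_lexicon):
        (a, b), terms = self._parts(mini_lexicon, "rbcL and psbA in leaves.")
        assert terms == []
        assert classify_pair_in_sentence(a, b, terms) is None

    def test_different_sentences_rejected(self, mini_lexicon):
        a = EntityMention("1", 0, 0, 4, "rbcL", "rbcL", "protein")
        b = EntityMention("1", 1, 10, 14, "psbA", "psbA", "protein")
        with pytest.raises(ValueError):
            classify_pair_in_sentence(a, b, [])


class TestMineAbstract:
    def test_minimum_type_over_sentences(self, mini_lexicon, make_record):
        record = make_record("rbcL activates psbA. Also psbA and rbcL are induced.")
        (c,) = mine(record, mini_lexicon)
        assert c.type == 1
        assert c.pair == ("psbA", "rbcL")
        assert "activates" in c.terms

    def test_cross_sentence_pair_is_type_4(self, mini_lexicon, make_record):
        record = make_record("Here rbcL was seen. Also matK was seen.")
        (c,) = mine(record, mini_lexicon)
        assert (c.pair, c.type) == (("matK", "rbcL"), 4)
        assert c.evidence_sentence_index is None and c.terms == ()

    def test_three_names_exhaustive_pairs(self, mini_lexicon, make_record):
        # brute-force oracle over all C(3,2)=3 pairs and term positions:
        # "activates" sits between rbcL and psbA, and between rbcL and matK,
        # but before both psbA and matK -> types 1, 1, 2.
        record = make_record("rbcL activates psbA and matK.")
        result = typed_set(mine(record, mini_lexicon))
        expected = brute_force_mine(
            record, tag_entities(record, mini_lexicon), tag_terms(record, mini_lexicon)
        )
        assert result == expected
        assert result == {
            ("1", "psbA", "rbcL"): 1,
            ("1", "matK", "rbcL"): 1,
            ("1", "matK", "psbA"): 2,
        }

    def test_repeated_single_name_yields_nothing(self, mini_lexicon, make_record):
        record = make_record("rbcL was studied and rbcL was sequenced.")
        assert mine(record, mini_lexicon) == []

    def test_exactly_one_record_per_pair(self, mini_lexicon, make_record):
        record = make_record(
            "rbcL activates psbA. Again rbcL activates psbA. And psbA binds rbcL."
        )
        result = mine(record, mini_lexicon)
        assert len(result) == 1

    def test_evidence_sentence_is_earliest_minimal(self, mini_lexicon, make_record):
        record = make_record("Both rbcL and psbA are induced. Then rbcL activates psbA.")
        (c,) = mine(record, mini_lexicon)
        # sentence 2 (0 = title) achieves the minimum type 1
        assert c.type == 1 and c.evidence_sentence_index == 2

    def test_concepts_attached_from_evidence_sentence(self, mini_lexicon, make_record):
        record = make_record("During photosynthesis rbcL activates psbA. More text here.")
        (c,) = mine(record, mini_lexicon)
        assert c.concepts == ("photosynthesis",)

    def test_symmetry_under_mention_order(self, lexicon):
        for record in generate_hard_records(10, lexicon, seed=21):
            entities = tag_entities(record, lexicon)
            terms = tag_terms(record, lexicon)
            baseline = mine_abstract(record, entities, terms)
            rng = random.Random(1)
            for _ in range(3):
                shuffled_e, shuffled_t = entities[:], terms[:]
                rng.shuffle(shuffled_e)
                rng.shuffle(shuffled_t)
                assert mine_abstract(record, shuffled_e, shuffled_t) == baseline

    def test_oracle_equivalence_on_hard_corpus(self, lexicon):
        for record in generate_hard_records(60, lexicon, seed=13):
            entities = tag_entities(record, lexicon)
            terms = tag_terms(record, lexicon)
            assert typed_set(mine_abstract(record, entities, terms)) == brute_force_mine(
                record, entities, terms
            )

    def test_type1_evidence_contains_between_term(self, lexicon):
        for record in generate_hard_records(40, lexicon, seed=17):
            entities = tag_entities(record, lexicon)
            terms = tag_terms(record, lexicon)
            for c in mine_abstract(record, entities, terms):
                if c.type == 1:
                    assert c.terms
                    assert c.evidence_sentence_index is not None


class TestFilters:
    def test_taxon_filter_keeps_matching_abstract(self, mini_lexicon, make_record):
        soy = make_record("In Glycine max rbcL activates psbA.", pmid="1")
        other = make_record("Elsewhere rbcL activates psbA.", pmid="2")
        records = [soy, other]
        cooccurrences = [c for r in records for c in mine_record(r, mini_lexicon)]
        kept = filter_by_taxon(cooccurrences, records, 3847, mini_lexicon)
        assert {c.pmid for c in kept} == {"1"}

    def test_absent_taxon_selects_nothing(self, mini_lexicon, make_record):
        record = make_record("Plain rbcL activates psbA.")
        cooccurrences = mine_record(record, mini_lexicon)
        assert filter_by_taxon(cooccurrences, [record], 9606, mini_lexicon) == []

    def test_one_resolving_mention_suffices(self, lexicon, make_record):
        record = make_record("In Glycine max and Zea mays rbcL activates psbA.")
        cooccurrences = mine_record(record, lexicon)
        assert filter_by_taxon(cooccurrences, [record], 3847, lexicon) == cooccurrences

    def test_select_type_filters(self):
        rows = [
            Cooccurrence("1", "A", "B", t, 1 if t < 4 else None, (), ())
            for t in (1, 2, 3, 4)
        ]
        assert [c.type for c in select_type(rows, 1)] == [1]
        assert select_type(rows, 4) == rows
        assert select_type([], 2) == []

    def test_select_type_invalid_max(self):
        with pytest.raises(ValueError):
            select_type([], 5)


class TestCooccurrenceTsv:
    def test_round_trip(self, mini_lexicon, make_record):
        record = make_record(
            "During photosynthesis rbcL activates psbA. Also matK was seen."
        )
        rows = mine(record, mini_lexicon)
        buf = io.StringIO()
        write_cooccurrence_tsv(rows, buf)
        buf.seek(0)
        assert read_cooccurrence_tsv(buf) == rows

    def test_malformed_row_skipped(self, caplog):
        import logging

        text = (
            "pmid\tentity_a\tentity_b\ttype\tsentence_index\tterms\tconcepts\tevidence_sentence_text\n"
            "1\tA\tB\tnot_a_type\t\t\t\t\n"
            "1\tA\tB\t4\t\t\t\t\n"
        )
        with caplog.at_level(logging.WARNING, logger="litcooc.miner"):
            rows = read_cooccurrence_tsv(io.StringIO(text))
        assert len(rows) == 1 and rows[0].type == 4
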
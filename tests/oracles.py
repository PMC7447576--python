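"""Independent brute-force oracles used to check the miner.

Deliberately naive: enumerate every (pair, sentence, mention combination,
term, mode) tuple and take minima.  Kept structurally different from the
library implementation so the two can disagree.
"""

from collections import defaultdict
from itertools import combinations

from litcooc.model import PAIRABLE_CLASSES, canonical_pair


def combo_type(earlier, later, term):
    """Type contributed by one (mention pair, term mention) combination."""
    if earlier.start > later.start:
        earlier, later = later, earlier
    if term.match_mode == "exact":
        if earlier.end <= term.start and term.end <= later.start:
            return 1
        return 2
    return 3


def brute_force_mine(record, entity_mentions, term_mentions):
    """All typed co-occurrences of one abstract as {(pmid, a, b): type}."""
    by_name = defaultdict(list)
    for m in entity_mentions:
        if m.entity_class in PAIRABLE_CLASSES:
            by_name[m.normalized].append(m)

    result = {}
    for name_a, name_b in combinations(sorted(by_name), 2):
        candidates = []
        for ma in by_name[name_a]:
            for mb in by_name[name_b]:
                if ma.sentence_index != mb.sentence_index:
                    continue
                sentence_terms = [
                    t for t in term_mentions if t.sentence_index == ma.sentence_index
                ]
                if not sentence_terms:
                    continue
                for term in sentence_terms:
                    candidates.append(combo_type(ma, mb, term))
        a, b = canonical_pair(name_a, name_b)
        result[(record.pmid, a, b)] = min(candidates) if candidates else 4
    return result


def min_qualifying_rule(mentions_a, mentions_b, sentence_terms):
    """Minimal rule number a single-sentence pair qualifies under, else None."""
    exact = [t for t in sentence_terms if t.match_mode == "exact"]
    for ma in mentions_a:
        for mb in mentions_b:
            earlier, later = sorted((ma, mb), key=lambda m: m.start)
            for t in exact:
                if earlier.end <= t.start and t.end <= later.start:
                    return 1
    if exact:
        return 2
    if sentence_terms:
        return 3
    return None
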
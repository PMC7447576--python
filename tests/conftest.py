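import textwrap

import pytest

from litcooc.lexicon import default_lexicon_path, load_lexicon
from litcooc.model import AbstractRecord


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon(default_lexicon_path())


@pytest.fixture
def make_record():
    def _make(abstract, title="A study.", pmid="1"):
        return AbstractRecord.build(pmid=pmid, title=title, abstract=abstract)

    return _make


def pubmed_xml(articles):
    """Minimal PubmedArticleSet XML for (pmid, title, abstract) triples."""
    parts = ["<?xml version='1.0' encoding='utf-8'?>", "<PubmedArticleSet>"]
    for pmid, title, abstract in articles:
        abstract_el = (
            f"<Abstract><AbstractText>{abstract}</AbstractText></Abstract>"
            if abstract is not None
            else ""
        )
        pmid_el = f"<PMID>{pmid}</PMID>" if pmid is not None else ""
        parts.append(
            "<PubmedArticle><MedlineCitation>"
            f"{pmid_el}<Article><ArticleTitle>{title}</ArticleTitle>{abstract_el}"
            "</Article></MedlineCitation></PubmedArticle>"
        )
    parts.append("</PubmedArticleSet>")
    return "\n".join(parts)


@pytest.fixture
def mini_lexicon(tmp_path):
    """Small custom lexicon exercising multi-word and nested names."""
    content = textwrap.dedent(
        """\
        BIOENTITY\trbcL\trbcL\tprotein
        BIOENTITY\tpsbA\tpsbA\tprotein
        BIOENTITY\tmatK\tmatK\tprotein
        BIOENTITY\tglutathione S-transferase\tglutathione S-transferase\tprotein
        BIOENTITY\ttransferase\ttransferase\tprotein
        TERM\tactivates
        TERM\tinduced
        CONCEPT\tphotosynthesis
        TAXON\tGlycine max\t3847
        TAXON\tsoybean\t3847
        """
    )
    path = tmp_path / "mini_lexicon.tsv"
    path.write_text(content, encoding="utf-8")
    return load_lexicon(path)
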
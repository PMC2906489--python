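import pytest

from ppidict.model import ProteinMention, Sentence, Document, Corpus


def annotate(text, names, index=0):
    """Build a Sentence annotating the first occurrence of each name.

    ``names`` is a list of surface strings or (surface, class) tuples.
    """
    mentions = []
    used = []
    for item in names:
        surface, cls = item if isinstance(item, tuple) else (item,
                                                             "protein_molecule")
        start = 0
        while True:
            i = text.index(surface, start)
            span = (i, i + len(surface))
            if span not in used:
                used.append(span)
                break
            start = i + 1
        mentions.append(ProteinMention.from_span(text, *span, cls))
    return Sentence(text=text, mentions=mentions, index=index)


def corpus_of(*docs):
    """docs: (doc_id, [sentence, ...]) tuples."""
    return Corpus(documents=[
        Document(doc_id=d, title=f"title {d}", sentences=list(sents))
        for d, sents in docs])


@pytest.fixture
def il2_sentence():
    return annotate("IL-2 binds IL-2R .", ["IL-2", "IL-2R"])


@pytest.fixture
def small_corpus():
    """Three documents, five annotated mentions in total."""
    return corpus_of(
        ("D1", [annotate("IL-2 interacts with IL-2R .", ["IL-2", "IL-2R"])]),
        ("D2", [annotate("NF-kappa B was measured .",
                         [("NF-kappa B", "protein_family_or_group")]),
                annotate("No proteins here .", [])]),
        ("D3", [annotate("STAT5 and JAK1 were purified .",
                         ["STAT5", "JAK1"])]),
    )
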
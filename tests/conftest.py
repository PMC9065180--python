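import pytest

from glycopg.chem import GlycanComposition
from glycopg.isoforms import translate_transcript
from glycopg.synthetic import generate_toy_cd44_grammar


@pytest.fixture(scope="session")
def toy_grammar():
    """The 19-exon CD44-shaped grammar and its four reference transcripts."""
    return generate_toy_cd44_grammar()


@pytest.fixture(scope="session")
def toy_isoforms(toy_grammar):
    model, transcripts = toy_grammar
    return [translate_transcript(model, t, isoform_id=t.transcript_id)
            for t in transcripts]


@pytest.fixture(scope="session")
def cd44s_isoform(toy_isoforms):
    return next(i for i in toy_isoforms if i.isoform_id == "CD44s_like")


@pytest.fixture(scope="session")
def glycan_space():
    """A sialidase-aware search space: sialyl-T plus its stripped forms."""
    return [
        GlycanComposition(hexnac=1),
        GlycanComposition(hexnac=1, hex=1),
        GlycanComposition(hexnac=1, hex=1, neuac=1),
    ]
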
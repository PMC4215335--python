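import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from biofluidminer import count_document_frequencies, score_markers
from biofluidminer.entities import dictionary_match, load_dictionary, normalize_mentions

DICTIONARY_TEXT = """\
00001\tBRCA1\tNM_007294\tbrca-1;RNF53
00002\tCEACAM5\tNM_004363\tCEA;CD66e
00003\tCEACAM8\tNM_001816\tCEA;CD66b
00004\tEGFR\tNM_005228\tepidermal growth factor receptor;ERBB1
00005\tGF1\tNM_000001\tgrowth factor
00006\tTP53\tNM_000546\tp53
"""

MEDLINE_TWO_RECORDS = """\
PMID- 111
TI  - A title about BRCA1.
AB  - First abstract mentions brca-1 and
      continues on a second line.

PMID- 222
TI  - Second title.
AB  - Second abstract body with p53.
"""


@pytest.fixture
def tiny_dictionary():
    return load_dictionary(DICTIONARY_TEXT)


@pytest.fixture
def medline_two_records():
    return MEDLINE_TWO_RECORDS


def run_scoring_pipeline(corpus, config):
    """Full tag -> normalize -> count -> score pipeline on a generated corpus."""
    dictionary = config.dictionary()
    m1 = [m for rec in corpus.s1 for m in dictionary_match(rec, dictionary)]
    m2 = [m for rec in corpus.s2 for m in dictionary_match(rec, dictionary)]
    n1 = normalize_mentions(m1, dictionary)
    n2 = normalize_mentions(m2, dictionary)
    freqs = count_document_frequencies(n1.mentions, n2.mentions)
    return score_markers(freqs, config.n1, config.n2)
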
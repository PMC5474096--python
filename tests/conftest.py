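import pathlib
import sys

import pytest
from hypothesis import settings

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # for _oracles

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=100)
settings.load_profile("suite")


ANNOTATION_TSV = """\
contig_id\tgene_id\tgene_index\tlineage\tbit_score\te_value
c1\tc1_1\t1\tSulfolobus spindle-shaped virus 1\t120.0\t1e-30
c1\tc1_2\t2\t\t\t
c1\tc1_3\t3\tProchlorococcus phage P-SSM2\t80.0\t1e-12
"""


@pytest.fixture
def three_row_tsv() -> str:
    """A 3-gene contig: 2 annotated (one archaeal virus, one phage), 1 blank."""
    return ANNOTATION_TSV
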
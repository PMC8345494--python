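import numpy as np
import pytest

from emsner.lexicon import starter_lexicon
from emsner.preprocessing import TokenizedReport


@pytest.fixture(scope="session")
def lexicon():
    return starter_lexicon()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_report(text: str, report_id: str = "r0") -> TokenizedReport:
    return TokenizedReport(report_id, tuple(text.split()))
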
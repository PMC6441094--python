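import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle.py importable

from atommap.chemgraph import parse_reaction  # noqa: E402


@pytest.fixture(scope="session")
def small_reactions():
    """A handful of parsed small reactions reused across modules."""
    smis = [
        "CC>>CC",
        "CCO>>CC=O",
        "C=CCOC=C>>C=CCCC=O",
        "CC=C.CC=C>>CC=CC.C=C",
    ]
    return {s: parse_reaction(s) for s in smis}
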
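import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from genelink.gene_tagging import GeneDictionary


@pytest.fixture
def toy_dictionary() -> GeneDictionary:
    """Small dictionary with one ambiguous symbol (APC -> two identifiers)."""
    gd = GeneDictionary()
    for symbol, gene_id, official in [
        ("GRB2", "2885", True),
        ("SOS1", "6654", True),
        ("TP53", "7157", True),
        ("MDM2", "4193", True),
        ("APC", "324", True),
        ("APC", "10297", False),
        ("P53", "7157", False),  # alternate symbol for the TP53 identifier
    ]:
        gd.add(symbol, gene_id, official)
    return gd
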
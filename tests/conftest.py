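import io

import numpy as np
import pytest

from consensify import ConsensifyParams, ScaffoldIndex, SiteCounts

# The five-row read-stack worked example: depths (3, 2, 2, 4, 5), expected
# consensus TGNAC (third row is a 1/1 disagreement -> N).
TABLE1_ROWS = [(0, 0, 1, 2), (0, 0, 2, 0), (1, 0, 0, 1), (4, 0, 0, 0), (0, 4, 1, 0)]
TABLE1_CONSENSUS = "TGNAC"


@pytest.fixture
def table1_sites():
    return [SiteCounts("scaf1", i + 1, row) for i, row in enumerate(TABLE1_ROWS)]


@pytest.fixture
def table1_index():
    return ScaffoldIndex((("scaf1", 5),))


@pytest.fixture
def table1_files():
    """The worked example in the paired pos/counts text dialect."""
    pos = io.StringIO(
        "chr\tpos\ttotDepth\n"
        + "".join(f"scaf1\t{i + 1}\t{sum(row)}\n" for i, row in enumerate(TABLE1_ROWS))
    )
    counts = io.StringIO(
        "totA\ttotC\ttotG\ttotT\n"
        + "".join("\t".join(map(str, row)) + "\n" for row in TABLE1_ROWS)
    )
    return pos, counts


@pytest.fixture
def default_params():
    return ConsensifyParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
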
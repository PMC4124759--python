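import numpy as np
import pytest

from ipr2go import load_demo_matrix

# Printed reference values for the 5x6 worked example (4 d.p.).
DEMO_CORR = np.array([
    [1.0000, 0.4082, 0.1667, -0.6667, 0.6124, 0.1667],
    [0.4082, 1.0000, 0.4082, 0.4082, 0.2500, -0.6124],
    [0.1667, 0.4082, 1.0000, 0.1667, -0.4082, 0.1667],
    [-0.6667, 0.4082, 0.1667, 1.0000, -0.4082, -0.6667],
    [0.6124, 0.2500, -0.4082, -0.4082, 1.0000, -0.4082],
    [0.1667, -0.6124, 0.1667, -0.6667, -0.4082, 1.0000],
])

DEMO_WEIGHTED = np.array([
    [0.5251, 0.2076, 0.1462, 0.1462, 0.1376, -0.1628],
    [0.2008, 0.1295, -0.2501, 0.3750, 0.1697, 0.3750],
    [0.1389, 0.3934, 0.0889, -0.1334, 0.0122, 0.5000],
    [0.2633, 0.0725, 0.2633, 0.2500, 0.2500, -0.0991],
    [0.7990, 0.2500, -0.0633, 0.2500, -0.1724, -0.0633],
])


@pytest.fixture(scope="session")
def demo_matrix():
    return load_demo_matrix()
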
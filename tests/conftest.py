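import numpy as np
import pytest

from poetrio.poe_model import TransmissionTally
from poetrio.trio_io import MENDEL_COMPAT


def random_tally(rng: np.random.Generator, n_trios: int = 50,
                 allow_ambiguous: bool = True) -> TransmissionTally:
    """Random Mendelian-consistent tally with at most ``n_trios`` trios."""
    cells = np.argwhere(MENDEL_COMPAT)
    if not allow_ambiguous:
        cells = cells[~np.all(cells == 1, axis=1)]
    counts = np.zeros((3, 3, 3), int)
    n = int(rng.integers(1, n_trios + 1))
    picks = rng.integers(0, len(cells), size=n)
    for k in picks:
        f, m, c = cells[k]
        counts[f, m, c] += 1
    return TransmissionTally(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def write_ped_map_text(tmp_path, ped_text: str, map_text: str):
    ped = tmp_path / "trios.ped"
    mp = tmp_path / "trios.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp
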
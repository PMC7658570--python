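import math

import numpy as np
import pytest

from aavfish import (
    InfectionModel,
    RenderParams,
    TissueParams,
    render_volume,
    simulate_genomes,
    simulate_tissue,
)
from aavfish.simulate import tissue_mask_for

# ---------------------------------------------------------------------------
# independent nearest-neighbor Tm oracle (unified parameter set, written
# against the published enthalpy/entropy tables, not against the package)

_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}


def oracle_tm(seq: str, na: float = 0.05, ct: float = 2.5e-8) -> float:
    """Brute-force NN enthalpy/entropy summation with the 0.368(N-1)ln[Na+]
    entropy salt correction and the c_T/4 two-state concentration term."""
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i:i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    return dh * 1000.0 / (ds + 1.987 * math.log(ct / 4.0)) - 273.15


def random_genome_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# shared simulated scene (small but fully rendered)

SCENE_TISSUE = TissueParams(shape=(32, 128, 128), n_cells=60)
SCENE_INFECTION = InfectionModel(lam=2.0)


@pytest.fixture(scope="session")
def scene():
    """One rendered 60-cell volume with truth, reused across test modules."""
    labels, nuclei, cells = simulate_tissue(SCENE_TISSUE, 1)
    truth = simulate_genomes(labels, nuclei, SCENE_INFECTION, 2)
    vol = render_volume(labels, nuclei, truth, RenderParams(), 3)
    mask = tissue_mask_for(SCENE_TISSUE)
    return {
        "tissue": SCENE_TISSUE,
        "labels": labels,
        "nuclei": nuclei,
        "cells": cells,
        "truth": truth,
        "volume": vol,
        "mask": mask,
    }
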
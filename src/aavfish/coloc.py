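"""Two-channel puncta colocalization.

Puncta from two channels are matched one-to-one on their continuous 3D
centroids within a micron radius. The colocalization probability is the
average of the two per-channel matched fractions: the fraction of
channel-A puncta with a partner in B, and of B puncta with a partner in
A. For the 5'/3' halves of one genome this approaches the probe-set
detection efficiency; for two independently packaged vectors it falls to
the chance rate set by puncta density and match radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def match_positions(
    pos_a: np.ndarray, pos_b: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-first matching of two point sets.

    Candidate pairs within ``radius`` are sorted by distance (ties broken
    by lower index in A, then in B) and accepted greedily, skipping
    points already matched. Returns (index_a, index_b) pairs.
    """
    if radius <= 0:
        raise ValueError("match radius must be > 0")
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 3)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 3)
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    pairs = cKDTree(pos_a).sparse_distance_matrix(
        cKDTree(pos_b), radius, output_type="coo_matrix"
    )
    order = np.lexsort((pairs.col, pairs.row, pairs.data))
    used_a = np.zeros(len(pos_a), dtype=bool)
    used_b = np.zeros(len(pos_b), dtype=bool)
    out: list[tuple[int, int]] = []
    for k in order:
        i, j = int(pairs.row[k]), int(pairs.col[k])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        out.append((i, j))
    return out


def match_puncta(
    puncta_a: pd.DataFrame, puncta_b: pd.DataFrame, radius: float
) -> pd.DataFrame:
    """Match two puncta tables; rows must carry z/y/x in microns.

    Returns a frame of matched pairs with both punctum ids (table row
    positions when no ``punctum_id`` column exists) and the pair
    distance in microns.
    """
    pos_a = puncta_a[["z", "y", "x"]].to_numpy()
    pos_b = puncta_b[["z", "y", "x"]].to_numpy()
    pairs = match_positions(pos_a, pos_b, radius)
    ids_a = (
        puncta_a["punctum_id"].to_numpy()
        if "punctum_id" in puncta_a.columns
        else np.arange(len(puncta_a))
    )
    ids_b = (
        puncta_b["punctum_id"].to_numpy()
        if "punctum_id" in puncta_b.columns
        else np.arange(len(puncta_b))
    )
    rows = [
        {
            "punctum_id_a": ids_a[i],
            "punctum_id_b": ids_b[j],
            "distance": float(np.linalg.norm(pos_a[i] - pos_b[j])),
        }
        for i, j in pairs
    ]
    return pd.DataFrame(rows, columns=["punctum_id_a", "punctum_id_b", "distance"])


@dataclass(frozen=True)
class ColocResult:
    """Colocalization counts and the averaged probability."""

    n_a: int
    n_b: int
    n_matched: int
    frac_a: float | None
    frac_b: float | None
    probability: float
    radius: float

    def __post_init__(self) -> None:
        if self.n_matched > min(self.n_a, self.n_b) and min(self.n_a, self.n_b) > 0:
            raise ValueError("more matches than puncta in a channel")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def coloc_probability(
    pairs: pd.DataFrame | int, n_a: int, n_b: int, radius: float = float("nan")
) -> ColocResult:
    """Averaged colocalization probability from matched pairs.

    ``probability = (frac_a + frac_b) / 2`` where frac_a = matched / n_a
    and frac_b = matched / n_b. A fraction over an empty channel is
    reported as None and the probability falls back to the defined
    fraction alone. Both channels empty is an error.
    """
    n_matched = len(pairs) if hasattr(pairs, "__len__") else int(pairs)
    if n_a < 0 or n_b < 0:
        raise ValueError("channel counts must be >= 0")
    if n_a == 0 and n_b == 0:
        raise ValueError("both channels empty: colocalization probability undefined")
    frac_a = n_matched / n_a if n_a > 0 else None
    frac_b = n_matched / n_b if n_b > 0 else None
    defined = [f for f in (frac_a, frac_b) if f is not None]
    probability = float(sum(defined) / len(defined))
    return ColocResult(
        n_a=int(n_a), n_b=int(n_b), n_matched=int(n_matched),
        frac_a=frac_a, frac_b=frac_b, probability=probability,
        radius=float(radius),
    )


def chance_coloc_rate(density_other: float, radius: float) -> float:
    """Analytic chance rate: P(any partner within r) for a Poisson field.

    ``1 - exp(-rho * (4/3) pi r^3)`` with rho the density of the other
    channel's puncta per cubic micron. The expected probability for two
    independent populations at sparse density.
    """
    vol = 4.0 / 3.0 * np.pi * radius**3
    return float(1.0 - np.exp(-density_other * vol))
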
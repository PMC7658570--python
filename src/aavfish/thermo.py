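"""Nearest-neighbor duplex melting temperatures for probe design.

Hybridization oligos are selected by predicted duplex Tm. The engine is
the unified nearest-neighbor thermodynamic model (Allawi & SantaLucia
1997 parameters with the SantaLucia 1998 entropy salt correction), with
salt and oligo concentrations exposed so users can recalibrate against
whatever prediction tool their probe sets were historically designed with.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

_VALID = frozenset("ACGT")

#: Registered nearest-neighbor parameter tables.
NN_TABLES = {
    "santalucia_unified": _mt.DNA_NN3,   # Allawi & SantaLucia 1997
    "santalucia2004": _mt.DNA_NN4,
    "sugimoto1996": _mt.DNA_NN2,
}


@dataclass(frozen=True)
class TmConditions:
    """Solution conditions for the nearest-neighbor Tm prediction.

    Parameters
    ----------
    monovalent_salt : float
        Total monovalent cation concentration in mol/L.
    oligo_conc : float
        Total strand concentration c_T in mol/L; the effective duplex
        concentration entering the two-state formula is c_T / 4
        (non-self-complementary strands at equal concentration).
    nn_set : str
        Key into :data:`NN_TABLES`.
    """

    monovalent_salt: float = 0.05
    oligo_conc: float = 2.5e-8
    nn_set: str = "santalucia_unified"

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0 or self.oligo_conc <= 0:
            raise ValueError("salt and oligo concentrations must be > 0")
        if self.nn_set not in NN_TABLES:
            raise ValueError(
                f"unknown nn_set {self.nn_set!r}; choose from {sorted(NN_TABLES)}"
            )


def melting_temp(seq: str, cond: TmConditions = TmConditions()) -> float:
    """Two-state nearest-neighbor duplex Tm of ``seq`` in deg C.

    Pure and deterministic; by duplex symmetry the value is identical for
    a sequence and its reverse complement.
    """
    if len(seq) < 8:
        raise ValueError(
            f"sequence of length {len(seq)} too short for a NN Tm (need >= 8 nt)"
        )
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid character(s) {sorted(bad)} in sequence")
    half_nM = cond.oligo_conc * 1e9 / 2.0  # dnac1 = dnac2 = c_T/2 -> c_T/4 rule
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=NN_TABLES[cond.nn_set],
            Na=cond.monovalent_salt * 1000.0,
            dnac1=half_nM,
            dnac2=half_nM,
            saltcorr=5,
        )
    )
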
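"""SABER-FISH primary probe tiling against a vector genome.

Probes are non-overlapping oligos, each at least ``min_len`` nt long with
a predicted duplex melting temperature inside a configured window
(67-71 deg C by default). Bodies are emitted in plus (mRNA) sense so they
hybridize to the packaged negative-sense strand only. A finished probe is
the body plus a TTT linker and one of the registered 9-nt concatemer
primers appended at the 3' end.

The tiler is a greedy leftmost-first scan: at the leftmost unused
position, a candidate is grown from ``min_len`` upward until its Tm
enters the window; the candidate is accepted and the scan resumes after
its end. If the Tm overshoots the window (or the sequence runs out) the
start advances by one position. Deterministic, and exhaustively checkable
against a brute-force replay on small genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from aavfish.genome import VectorGenome
from aavfish.thermo import TmConditions, melting_temp

log = logging.getLogger(__name__)

LINKER = "TTT"

#: The two concatemer-extension primers appended to probe 3' ends.
PRIMERS: dict[str, str] = {
    "p27": "CATCATCAT",
    "p28": "CAACTTAAC",
}
# Allow lookup by literal sequence as well as by short id.
_PRIMER_SEQS = {seq: seq for seq in PRIMERS.values()}


def resolve_primer(primer_id: str) -> str:
    """Return the 9-nt primer sequence for an id or literal sequence."""
    seq = PRIMERS.get(primer_id) or _PRIMER_SEQS.get(primer_id)
    if seq is None:
        raise ValueError(
            f"unknown primer {primer_id!r}; registered: "
            f"{sorted(PRIMERS)} or a literal registered sequence"
        )
    if len(seq) != 9:
        raise ValueError(f"primer {primer_id!r} has length {len(seq)}, need 9")
    return seq


@dataclass(frozen=True)
class Probe:
    """One tiled hybridization oligo.

    ``body`` equals the plus-strand genome subsequence at [start, end);
    ``full_sequence`` (set by assembly) is body + TTT + 9-nt primer.
    """

    start: int
    end: int
    body: str
    tm: float
    primer_id: str | None = None
    full_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.body):
            raise ValueError("probe interval length disagrees with body length")
        if self.full_sequence is not None:
            expected = self.body + LINKER + resolve_primer(self.primer_id)
            if self.full_sequence != expected:
                raise ValueError("full_sequence != body + TTT + primer")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class ProbeSet:
    """Ordered, non-overlapping probes for one genome."""

    genome_name: str
    probes: tuple[Probe, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -1
        for p in self.probes:
            if p.start < prev_end:
                raise ValueError("probes overlap or are unsorted")
            prev_end = p.end

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": f"{self.genome_name}_probe_{i:03d}",
                "start": p.start,
                "end": p.end,
                "body": p.body,
                "tm": p.tm,
                "primer_id": p.primer_id,
                "full_sequence": p.full_sequence,
            }
            for i, p in enumerate(self.probes)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "name", "start", "end", "body", "tm", "primer_id",
                "full_sequence",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, row in self.to_frame().iterrows():
                seq = row["full_sequence"] or row["body"]
                fh.write(f">{row['name']}\n{seq}\n")


def tile_probes(
    genome: VectorGenome,
    min_len: int = 36,
    tm_window: tuple[float, float] = (67.0, 71.0),
    cond: TmConditions = TmConditions(),
    exclude: list[tuple[int, int]] | None = None,
) -> ProbeSet:
    """Greedy left-to-right probe tiling (bodies only, no primer).

    ``exclude`` lists (start, end) genome intervals no probe may overlap
    (e.g. ITRs). A genome admitting no probe yields an empty set with a
    logged warning.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8 for a meaningful Tm")
    lo, hi = tm_window
    if not lo < hi:
        raise ValueError(f"tm_window low must be < high, got {tm_window}")
    exclude = sorted(exclude or [])

    def blocked(start: int, end: int) -> int | None:
        """First excluded interval overlapping [start, end), else None."""
        for i, (xs, xe) in enumerate(exclude):
            if start < xe and xs < end:
                return i
        return None

    seq = genome.sequence
    n = len(seq)
    probes: list[Probe] = []
    pos = 0
    while pos + min_len <= n:
        hit = blocked(pos, pos + min_len)
        if hit is not None:
            pos = exclude[hit][1]  # jump past the excluded interval
            continue
        accepted = None
        for end in range(pos + min_len, n + 1):
            if blocked(pos, end) is not None:
                break
            tm = melting_temp(seq[pos:end], cond)
            if tm > hi:
                break  # overshot: longer candidates only get hotter
            if tm >= lo:
                accepted = Probe(pos, end, seq[pos:end], tm)
                break
        if accepted is None:
            pos += 1
        else:
            probes.append(accepted)
            pos = accepted.end
    if not probes:
        log.warning(
            "genome %r (%d nt) admits no probe with min_len=%d, Tm in %s",
            genome.name, n, min_len, tm_window,
        )
    return ProbeSet(
        genome.name,
        tuple(probes),
        params={
            "min_len": min_len,
            "tm_window": tuple(tm_window),
            "monovalent_salt": cond.monovalent_salt,
            "oligo_conc": cond.oligo_conc,
            "nn_set": cond.nn_set,
        },
    )


def assemble_probes(probes: ProbeSet, primer_id: str) -> ProbeSet:
    """Append the TTT linker and a registered 9-nt primer to each body."""
    primer = resolve_primer(primer_id)
    assembled = tuple(
        replace(p, primer_id=primer_id, full_sequence=p.body + LINKER + primer)
        for p in probes
    )
    return ProbeSet(probes.genome_name, assembled,
                    {**probes.params, "primer_id": primer_id})


def split_probe_set(
    probes: ProbeSet,
    boundary: int,
    primer_5prime: str,
    primer_3prime: str,
) -> tuple[ProbeSet, ProbeSet]:
    """Split a probe set at a genome coordinate for two-channel detection.

    A probe joins the 5' set when its body midpoint lies left of
    ``boundary``, otherwise the 3' set; each half is assembled with its
    own primer so the two halves of the genome report in separate
    channels. The two primers must differ.
    """
    if resolve_primer(primer_5prime) == resolve_primer(primer_3prime):
        raise ValueError(
            "5' and 3' primers must differ, or the channels are indistinguishable"
        )
    five = tuple(p for p in probes if p.midpoint < boundary)
    three = tuple(p for p in probes if p.midpoint >= boundary)
    base = {**probes.params, "split_at": boundary}
    return (
        assemble_probes(ProbeSet(probes.genome_name, five, base), primer_5prime),
        assemble_probes(ProbeSet(probes.genome_name, three, base), primer_3prime),
    )
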
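"""Vector genome sequences and coordinate conventions.

The package works in plus-strand (mRNA-sense) coordinates, 0-based and
half-open, throughout. An AAV vector packages a single-stranded genome;
probes designed here are emitted in plus sense so that they hybridize to
the packaged negative-sense strand and not to transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class VectorGenome:
    """A vector genome given as its plus-strand nucleotide sequence.

    ``features`` is an optional list of ``(label, start, end)`` intervals
    (0-based, half-open) annotating elements such as ITRs, promoter,
    transgene and polyA, usable as exclusion intervals in probe design.
    """

    name: str
    sequence: str
    features: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"genome {self.name!r}: invalid character(s) "
                f"{sorted(bad)} in sequence (alphabet is A/C/G/T)"
            )
        for label, start, end in self.features:
            if not (0 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"feature {label!r} interval [{start}, {end}) outside "
                    f"[0, {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Plus-strand subsequence at [start, end)."""
        if not (0 <= start <= end <= len(self.sequence)):
            raise ValueError(f"interval [{start}, {end}) out of bounds")
        return self.sequence[start:end]

    def reverse_complement(self) -> "VectorGenome":
        n = len(self.sequence)
        rc = str(Seq(self.sequence).reverse_complement())
        feats = tuple(
            (label, n - end, n - start) for label, start, end in self.features
        )
        return VectorGenome(self.name + "_rc", rc, feats)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T only)."""
    return str(Seq(seq).reverse_complement())


def read_genome_fasta(path: str | Path, name: str | None = None) -> VectorGenome:
    """Load a single-record FASTA as a :class:`VectorGenome`.

    The record is validated against the A/C/G/T alphabet (lowercase is
    upper-cased first); ambiguity codes such as N are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly 1 FASTA record, found {len(records)}"
        )
    rec = records[0]
    return VectorGenome(name or rec.id, str(rec.seq).upper())


def read_exclusion_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read 3-column BED-like intervals (0-based half-open) to exclude."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{i + 1}: need >= 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
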
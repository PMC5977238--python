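"""Core containers shared across the pipeline, and their plain-text IO.

The pipeline works on four kinds of objects:

* :class:`Genome` -- a named nucleotide sequence (host chromosome or phage
  genome) with a circularity flag.  Bacterial hosts are circular by default,
  phage genomes linear.
* :class:`InsertionEvent` -- one replicative-transposition event: the target
  molecule (host chromosome or an already-inserted phage copy), the 1-based
  junction coordinate and the insertion orientation.
* :class:`ReadSet` -- simulated virion sequencing reads plus the ground-truth
  association read id -> generating event.
* :class:`SiteTable` -- the central data structure of the analysis: per
  position, per orientation counts of integration events on a reference.

Coordinates are 0-based half-open internally (``Genome.fetch``) and 1-based
inclusive in every reported table, matching standard genome coordinates.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FORWARD = "forward"
REVERSE = "reverse"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, K<->M, ... are honoured)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with a circularity flag."""

    name: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("genome sequence must be nonempty")
        if set(self.seq) - set("ACGT"):
            bad = sorted(set(self.seq) - set("ACGT"))
            raise ValueError(f"genome alphabet restricted to ACGT, found {bad}")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for 0-based half-open [start, end).

        Out-of-range coordinates wrap on circular genomes and raise on
        linear ones.
        """
        L = len(self.seq)
        if end < start:
            raise ValueError(f"end < start ({end} < {start})")
        if 0 <= start and end <= L:
            return self.seq[start:end]
        if not self.circular:
            raise IndexError(
                f"[{start}, {end}) outside linear genome of length {L}")
        if end - start > L:
            raise ValueError("requested span longer than circular genome")
        n = end - start
        start %= L
        span = self.seq[start:min(start + n, L)]
        if len(span) < n:
            span += self.seq[:n - len(span)]
        return span

    def gc(self) -> float:
        """Overall G+C fraction."""
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)

    def to_fasta(self, path: str) -> None:
        rec = SeqRecord(Seq(self.seq), id=self.name,
                        description="circular" if self.circular else "linear")
        with open(path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str, circular: bool | None = None) -> "Genome":
        rec = next(SeqIO.parse(path, "fasta"))
        if circular is None:
            circular = "circular" in rec.description
        return cls(name=rec.id, seq=str(rec.seq).upper(), circular=circular)


@dataclass(frozen=True)
class InsertionEvent:
    """One transposition event.

    ``target`` is ``"host"`` (the bacterial chromosome) or ``"phage"`` (a
    previously transposed phage copy -- a target-immunity escape).
    ``position`` is the 1-based junction coordinate on the target: the first
    target base adjacent to the phage end.  Reverse-orientation events carry
    the coordinate already shifted by the target-site duplication offset, so
    that forward and reverse junction peaks of one site appear a fixed few
    base-pairs apart, as seen in real per-position profiles.
    """

    target: str
    position: int
    orientation: str

    def __post_init__(self) -> None:
        if self.target not in ("host", "phage"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass
class ReadSet:
    """Simulated reads with ground truth.

    ``reads`` is a list of (read_id, sequence); ``truth`` maps the read ids of
    junction-bearing reads to their generating :class:`InsertionEvent`.
    ``dropped`` counts events discarded because a flank would run off a
    linear genome end.
    """

    reads: list[tuple[str, str]] = field(default_factory=list)
    truth: dict[str, InsertionEvent] = field(default_factory=dict)
    dropped: int = 0

    def __post_init__(self) -> None:
        ids = [r for r, _ in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate read ids")
        extra = set(self.truth) - set(ids)
        if extra:
            raise ValueError(f"truth refers to unknown read ids: {sorted(extra)[:3]}")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.reads)

    def subset(self, read_ids: Iterable[str]) -> "ReadSet":
        keep = set(read_ids)
        return ReadSet(reads=[(r, s) for r, s in self.reads if r in keep],
                       truth={r: e for r, e in self.truth.items() if r in keep})

    def write_fastq(self, path: str, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path: str) -> "ReadSet":
        reads = [(rec.id, str(rec.seq).upper())
                 for rec in SeqIO.parse(path, "fastq")]
        return cls(reads=reads)

    def write_truth_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttarget\tposition\torientation\n")
            for rid in sorted(self.truth):
                ev = self.truth[rid]
                fh.write(f"{rid}\t{ev.target}\t{ev.position}\t{ev.orientation}\n")

    @classmethod
    def read_truth_tsv(cls, path: str) -> dict[str, InsertionEvent]:
        truth: dict[str, InsertionEvent] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                rid, target, pos, orient = line.rstrip("\n").split("\t")
                truth[rid] = InsertionEvent(target, int(pos), orient)
        return truth


@dataclass
class Placement:
    """Placement of one trimmed host fragment on a reference.

    ``position`` is the 1-based junction base (first host base adjacent to
    the phage end); it is ``None`` unless ``status == "unique"``.
    """

    fragment_id: str
    position: int | None
    orientation: str | None
    mismatches: int
    gaps: int
    status: str  # unique | ambiguous | unmapped
    ref_start: int | None = None  # 1-based leftmost base of the aligned interval


class SiteTable:
    """Per-position, per-orientation integration-event counts."""

    def __init__(self, reference: str, length: int,
                 counts: dict[tuple[int, str], int] | None = None) -> None:
        if length < 1:
            raise ValueError("reference length must be positive")
        self.reference = reference
        self.length = length
        self.counts: dict[tuple[int, str], int] = dict(counts or {})
        for (pos, orient), n in self.counts.items():
            self._check_key(pos, orient)
            if n < 0:
                raise ValueError("counts must be nonnegative")

    def _check_key(self, pos: int, orient: str) -> None:
        if not (1 <= pos <= self.length):
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        if orient not in (FORWARD, REVERSE):
            raise ValueError(f"unknown orientation {orient!r}")

    def add(self, pos: int, orient: str, n: int = 1) -> None:
        self._check_key(pos, orient)
        self.counts[(pos, orient)] = self.counts.get((pos, orient), 0) + n

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())

    def position_totals(self) -> Counter:
        """Orientation-summed counts per position."""
        totals: Counter = Counter()
        for (pos, _), n in self.counts.items():
            totals[pos] += n
        return totals

    def orientation_totals(self) -> tuple[int, int]:
        fwd = sum(n for (_, o), n in self.counts.items() if o == FORWARD)
        rev = sum(n for (_, o), n in self.counts.items() if o == REVERSE)
        return fwd, rev

    @classmethod
    def from_events(cls, events: Iterable[InsertionEvent], reference: Genome,
                    target: str = "host") -> "SiteTable":
        """Tally the events hitting ``target`` directly from a truth list."""
        table = cls(reference.name, len(reference))
        for ev in events:
            if ev.target == target:
                table.add(ev.position, ev.orientation)
        return table

    @classmethod
    def from_placements(cls, placements: Iterable[Placement],
                        reference: Genome) -> "SiteTable":
        table = cls(reference.name, len(reference))
        for pl in placements:
            if pl.status == "unique":
                table.add(pl.position, pl.orientation)
        return table

    # ---- plain-text export -------------------------------------------------

    def to_tsv(self, path: str) -> None:
        """BED-like TSV: 1-based position, orientation, count."""
        with open(path, "w") as fh:
            fh.write(f"#reference={self.reference}\tlength={self.length}\n")
            fh.write("position\torientation\tcount\n")
            for (pos, orient) in sorted(self.counts):
                fh.write(f"{pos}\t{orient}\t{self.counts[(pos, orient)]}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "SiteTable":
        with open(path) as fh:
            meta = fh.readline().lstrip("#").rstrip("\n")
            fields = dict(kv.split("=") for kv in meta.split("\t"))
            fh.readline()  # column header
            counts: dict[tuple[int, str], int] = {}
            for line in fh:
                pos, orient, n = line.rstrip("\n").split("\t")
                counts[(int(pos), orient)] = int(n)
        return cls(fields["reference"], int(fields["length"]), counts)

    def to_bedgraph(self, path: str) -> None:
        """Dense per-base count track (orientations summed), 0-based bedGraph."""
        totals = self.position_totals()
        with open(path, "w") as fh:
            for pos in sorted(totals):
                fh.write(f"{self.reference}\t{pos - 1}\t{pos}\t{totals[pos]}\n")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"SiteTable({self.reference!r}, length={self.length}, "
                f"positions={len(self.position_totals())}, "
                f"total={self.total_events})")
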
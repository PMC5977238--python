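"""Insertion hotspots and the adjacent degenerate consensus motif.

Hotspot calling finds genome positions whose event count exceeds a
threshold (3000 per position in a 13-million-event experiment; the
threshold can be auto-scaled to smaller simulations) and merges positions
closer than a small gap into one hotspot, recording both peaks: the
forward and reverse junction peaks of a single site sit a few base-pairs
apart because of the target-site duplication.

The hotspots of this phage group sit next to palindromic-repeat (REP/BIME)
elements.  The consensus of those elements is recovered by aligning the
280 bp flanks of the top hotspots on a shared gapless block and expressing
each column as the IUPAC code of the bases reaching a frequency threshold;
the genome is then scanned for degenerate-motif occurrences with a
mismatch tolerance, and the share of all events falling near any
occurrence quantifies the insertion bias towards these elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from .model import FORWARD, Genome, SiteTable, revcomp

logger = logging.getLogger("saltosites")

#: IUPAC code -> frozenset of bases, e.g. "Y" -> {C, T} (the 15 standard
#: nucleotide codes; Biopython's legacy "X" alias is excluded)
IUPAC_SET: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
    if code in "ACGTRYSWKMBDHVN"
}
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SET.items()}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_IUPAC_MASK = {code: sum(_BASE_BIT[b] for b in bases)
               for code, bases in IUPAC_SET.items()}


@dataclass
class Hotspot:
    """A called insertion hotspot.

    ``peaks`` holds one or two 1-based coordinates (the paired forward and
    reverse junction peaks); ``span`` the 1-based inclusive extent of the
    merged above-threshold positions; ``forward_ratio`` the forward share
    of the events in the span; ``rank`` 1 for the strongest hotspot.
    """

    peaks: tuple[int, ...]
    span: tuple[int, int]
    event_count: int
    forward_ratio: float
    rank: int = 0


@dataclass
class Flank:
    seq: str
    side: str  # left | right
    truncated: bool = False


@dataclass
class ConsensusMotif:
    """Degenerate consensus over IUPAC codes, with per-flank offsets of the
    conserved block from the hotspot-proximal flank end."""

    iupac: str
    offsets: list[int] = field(default_factory=list)
    found: bool = True

    def __len__(self) -> int:
        return len(self.iupac)

    def __post_init__(self) -> None:
        bad = set(self.iupac) - set(IUPAC_SET)
        if bad:
            raise ValueError(f"invalid IUPAC characters {sorted(bad)}")


@dataclass
class MotifHit:
    position: int  # 1-based window start on the plus strand
    strand: str    # + | -
    mismatches: int
    length: int


def scaled_threshold(total_events: int, min_events_per_position: int = 3000,
                     reference_total: int = 13_000_000) -> int:
    """Per-position threshold rescaled to a smaller experiment: keeps the
    per-event fraction of the 13-million-event reference design."""
    return max(1, round(min_events_per_position * total_events
                        / reference_total))


def call_hotspots(table: SiteTable, min_events_per_position: int = 3000,
                  pair_gap: int = 20) -> list[Hotspot]:
    """Positions with >= threshold events, merged within ``pair_gap`` bp.

    The output is permutation-invariant in the input counts; hotspots are
    ranked by event count in the span (rank 1 strongest).
    """
    totals = table.position_totals()
    hot = sorted(p for p, n in totals.items() if n >= min_events_per_position)
    if not hot:
        return []
    clusters: list[list[int]] = [[hot[0]]]
    for p in hot[1:]:
        if p - clusters[-1][-1] <= pair_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    spots = []
    for cl in clusters:
        span = (cl[0], cl[-1])
        peaks = tuple(sorted(sorted(cl, key=lambda p: -totals[p])[:2]))
        fwd = sum(n for (pos, o), n in table.counts.items()
                  if span[0] <= pos <= span[1] and o == FORWARD)
        tot = sum(n for pos, n in totals.items() if span[0] <= pos <= span[1])
        spots.append(Hotspot(peaks=peaks, span=span, event_count=tot,
                             forward_ratio=fwd / tot if tot else 0.0))
    spots.sort(key=lambda h: (-h.event_count, h.span[0]))
    for r, h in enumerate(spots, start=1):
        h.rank = r
    return spots


def extract_flanks(h: Hotspot, genome: Genome, width: int = 280
                   ) -> tuple[Flank, Flank]:
    """The ``width`` bp on each side of the hotspot span (wraps on circular
    genomes; truncated and flagged at linear ends)."""
    if width > len(genome):
        raise ValueError("width larger than genome")
    a, b = h.span  # 1-based inclusive
    if genome.circular:
        left = Flank(genome.fetch(a - 1 - width, a - 1), "left")
        right = Flank(genome.fetch(b, b + width), "right")
    else:
        lo = max(0, a - 1 - width)
        left = Flank(genome.seq[lo:a - 1], "left", truncated=lo > a - 1 - width)
        hi = min(len(genome), b + width)
        right = Flank(genome.seq[b:hi], "right", truncated=hi < b + width)
    return left, right


def iupac_code(bases: set[str] | frozenset[str]) -> str:
    """IUPAC code covering a nonempty subset of {A, C, G, T}."""
    return _SET_TO_CODE[frozenset(bases)]


def _column_sets(columns: list[list[str]], threshold: float
                 ) -> list[frozenset[str]]:
    out = []
    for col in columns:
        n = len(col)
        counts = {b: col.count(b) for b in set(col)}
        sel = frozenset(b for b, c in counts.items() if c / n >= threshold)
        out.append(sel if sel else frozenset(counts))
    return out


def build_consensus(flanks: list[str], min_block: int = 20,
                    ambiguity_rule: float = 0.25,
                    seed_k: int = 8, max_degeneracy: int = 2,
                    min_coverage: float = 0.9) -> ConsensusMotif:
    """Best-conserved gapless block across flank sequences.

    Flanks must be oriented with position 0 at the hotspot-proximal end.
    A ``seed_k``-mer shared by the largest number of flanks anchors a
    column-wise extension.  A column counts as conserved iff the set of
    bases at frequency >= ``ambiguity_rule`` has at most ``max_degeneracy``
    members (two-base IUPAC codes like R/Y/S are conserved) AND that set
    covers >= ``min_coverage`` of the rows -- unaligned random columns have
    their mass spread over three or four bases and terminate the block.
    Blocks shorter than ``min_block`` yield an empty motif flagged
    not-found.
    """
    if len(flanks) < 2:
        raise ValueError("need at least two flanks")
    flanks = [f.upper() for f in flanks]
    # most widely shared seed k-mer, first occurrence per flank
    occ: dict[str, dict[int, int]] = {}
    for fi, f in enumerate(flanks):
        for off in range(len(f) - seed_k + 1):
            kmer = f[off:off + seed_k]
            occ.setdefault(kmer, {}).setdefault(fi, off)
    if not occ:
        return ConsensusMotif("", [], found=False)
    best_kmer = max(occ, key=lambda km: (len(occ[km]), km))
    members = occ[best_kmer]
    if len(members) < max(2, len(flanks) // 2 + 1):
        return ConsensusMotif("", [], found=False)

    anchors = {fi: off for fi, off in members.items()}

    def column(delta: int) -> list[str] | None:
        col = []
        for fi, off in anchors.items():
            j = off + delta
            if 0 <= j < len(flanks[fi]):
                col.append(flanks[fi][j])
        return col if len(col) == len(anchors) else None

    def conserved(col: list[str]) -> bool:
        sel = _column_sets([col], ambiguity_rule)[0]
        if len(sel) > max_degeneracy:
            return False
        cover = sum(1 for b in col if b in sel) / len(col)
        return cover >= min_coverage

    lo = 0
    while True:
        col = column(lo - 1)
        if col is None or not conserved(col):
            break
        lo -= 1
    hi = seed_k
    while True:
        col = column(hi)
        if col is None or not conserved(col):
            break
        hi += 1
    if hi - lo < min_block:
        logger.info("build_consensus: conserved block of %d bp < min_block",
                    hi - lo)
        return ConsensusMotif("", [], found=False)
    cols = [column(d) for d in range(lo, hi)]
    sets = _column_sets(cols, ambiguity_rule)
    iupac = "".join(iupac_code(s) for s in sets)
    offsets = [anchors[fi] + lo for fi in sorted(anchors)]
    return ConsensusMotif(iupac=iupac, offsets=offsets, found=True)


def _mask_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for code, m in _IUPAC_MASK.items():
        lut[ord(code)] = m
    masks = lut[arr]
    if (masks == 0).any():
        raise ValueError("invalid IUPAC character in sequence")
    return masks


def scan_iupac(genome: Genome, motif: ConsensusMotif | str,
               max_mismatches: int = 3, both_strands: bool = True
               ) -> list[MotifHit]:
    """All windows matching a degenerate motif with a mismatch tolerance.

    A window position mismatches iff the genome base is not a member of the
    IUPAC set of the motif base.  Both strands are scanned when flagged;
    opposite-strand hits whose windows overlap by more than half the motif
    are deduplicated to the fewer-mismatch hit (plus strand on ties).
    """
    pattern = motif.iupac if isinstance(motif, ConsensusMotif) else motif
    if not pattern:
        raise ValueError("empty motif")
    m = len(pattern)
    if m > len(genome):
        raise ValueError("motif longer than genome")
    gmask = _mask_array(genome.seq)
    if genome.circular:
        gmask = np.concatenate([gmask, gmask[:m - 1]])
    n_win = len(gmask) - m + 1

    def _mismatch_counts(pat: str) -> np.ndarray:
        pmask = _mask_array(pat)
        mism = np.zeros(n_win, dtype=np.int32)
        for j in range(m):
            mism += (gmask[j:j + n_win] & pmask[j]) == 0
        return mism

    hits: list[MotifHit] = []
    strands = [("+", pattern)]
    if both_strands:
        strands.append(("-", revcomp(pattern)))
    for strand, pat in strands:
        mism = _mismatch_counts(pat)
        for w in np.nonzero(mism <= max_mismatches)[0]:
            hits.append(MotifHit(position=int(w) + 1, strand=strand,
                                 mismatches=int(mism[w]), length=m))
    hits.sort(key=lambda h: (h.position, h.strand))
    # deduplicate opposite-strand overlaps (palindromic motifs hit twice)
    dedup: list[MotifHit] = []
    for h in hits:
        if (dedup and dedup[-1].strand != h.strand
                and h.position - dedup[-1].position < (m + 1) // 2):
            keep = dedup[-1]
            if (h.mismatches, h.strand) < (keep.mismatches, keep.strand):
                dedup[-1] = h
            continue
        dedup.append(h)
    return dedup


def motif_event_share(table: SiteTable, hits: list[MotifHit],
                      window: int = 120, circular: bool = True
                      ) -> tuple[float, float]:
    """(share, fold_bias) of events falling within ``window`` bp of any
    motif occurrence.

    share is the fraction of all events inside the deduplicated footprint
    (each hit extended by ``window`` bp on both sides); fold_bias is
    share / (footprint_bp / genome_length).  No hits -> (0, 0).
    """
    if not hits:
        return 0.0, 0.0
    N = table.length
    covered = np.zeros(N, dtype=bool)
    for h in hits:
        lo = h.position - 1 - window
        hi = h.position - 1 + h.length + window  # exclusive
        if circular:
            idx = np.arange(lo, hi) % N
            covered[idx] = True
        else:
            covered[max(0, lo):min(N, hi)] = True
    total = table.total_events
    if total == 0:
        return 0.0, 0.0
    inside = sum(n for pos, n in table.position_totals().items()
                 if covered[pos - 1])
    share = inside / total
    fold = share / (covered.sum() / N)
    return share, fold


def write_hotspots_tsv(spots: list[Hotspot], path: str,
                       motif_info: dict[int, tuple[int, int]] | None = None
                       ) -> None:
    """TSV mirroring the hotspot table columns: rank, peaks, span, count,
    forward ratio, and optionally motif offset/mismatches per rank."""
    with open(path, "w") as fh:
        fh.write("rank\tpeaks\tspan_start\tspan_end\tevent_count\t"
                 "forward_ratio\tmotif_offset\tmotif_mismatches\n")
        for h in spots:
            off, mm = (motif_info or {}).get(h.rank, ("", ""))
            fh.write(f"{h.rank}\t{';'.join(map(str, h.peaks))}\t{h.span[0]}\t"
                     f"{h.span[1]}\t{h.event_count}\t{h.forward_ratio:.3f}\t"
                     f"{off}\t{mm}\n")


def write_hotspots_bed(spots: list[Hotspot], reference: str, path: str
                       ) -> None:
    with open(path, "w") as fh:
        for h in spots:
            fh.write(f"{reference}\t{h.span[0] - 1}\t{h.span[1]}\t"
                     f"hotspot_{h.rank}\t{h.event_count}\t.\n")


def write_hits_bed(hits: list[MotifHit], reference: str, path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{reference}\t{h.position - 1}\t"
                     f"{h.position - 1 + h.length}\tmotif\t{h.mismatches}\t"
                     f"{h.strand}\n")
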
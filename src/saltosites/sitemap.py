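"""Placement of trimmed host fragments on a reference genome.

Short junction fragments (down to ~12 bp of host DNA for the left-end
route, typically 30-70 bp) are placed by exact k-mer seeding over a sorted
integer index of the reference followed by extension: an ungapped Hamming
check first and, when gaps are allowed and the ungapped check fails, a
banded edit-distance alignment (edlib) whose cigar is split into mismatch
and gap counts.  A candidate passes iff

    mismatches <= floor(max_mismatch_frac * length)
    gaps       <= floor(max_gap_frac * length)
    identity   >= min_identity

(fractional limits are floored per fragment, so 2% of a 34 bp flank allows
zero mismatches).  A fragment is ``unique`` iff exactly one best-scoring
location passes, ``ambiguous`` for several co-optimal loci (excluded from
the site table, counted), ``unmapped`` otherwise.

The reported coordinate is the junction base -- the first host base
adjacent to the phage end: for right-end fragments (host follows the
phage, ``junction_side="start"``) the fragment start; for left-end
fragments (host precedes the phage, ``junction_side="end"``) the fragment
end.  On the minus strand the respective other extremity of the reference
interval is reported.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable

import edlib
import numpy as np

from .junctions import TrimmedFragment
from .model import FORWARD, REVERSE, Genome, Placement, SiteTable, revcomp

logger = logging.getLogger("saltosites")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit integer of every k-mer (len(codes) - k + 1 values)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = (out << 2) | codes[j:j + n].astype(np.int64)
    return out


class SeedIndex:
    """Sorted-array k-mer index of the plus strand of a reference.

    Circular references contribute the wrap-around k-mers, so every one of
    the L (circular) or L - k + 1 (linear) plus-strand seed positions is
    retrievable.  Minus-strand placement is handled by querying the
    reverse complement of the fragment.
    """

    def __init__(self, reference: Genome, k: int = 15) -> None:
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31]")
        self.reference = reference
        self.k = k
        codes = _encode(reference.seq)
        if reference.circular:
            codes = np.concatenate([codes, codes[:k - 1]])
        kmers = _kmer_ints(codes, k)
        self._order = np.argsort(kmers, kind="stable")
        self._sorted = kmers[self._order]

    @property
    def n_seeds(self) -> int:
        return len(self._sorted)

    def lookup(self, kmer: str) -> np.ndarray:
        """0-based plus-strand start positions of an exact k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"need a {self.k}-mer")
        q = _kmer_ints(_encode(kmer), self.k)[0]
        lo = np.searchsorted(self._sorted, q, side="left")
        hi = np.searchsorted(self._sorted, q, side="right")
        return np.sort(self._order[lo:hi])


def build_index(reference: Genome, k: int = 15) -> SeedIndex:
    """Build the seed index (thin constructor wrapper)."""
    return SeedIndex(reference, k)


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches, gap_bases) from an extended cigar (=/X/I/D)."""
    match = mism = gaps = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            match += n
        elif ch == "X":
            mism += n
        elif ch in "ID":
            gaps += n
        else:  # pragma: no cover
            raise ValueError(f"unexpected cigar op {ch!r}")
    return match, mism, gaps


def place_fragment(fragment: str, index: SeedIndex,
                   max_mismatch_frac: float = 0.02,
                   max_gap_frac: float = 0.03,
                   min_identity: float = 0.95,
                   junction_side: str = "start",
                   fragment_id: str = "") -> Placement:
    """Seed-and-extend placement of one fragment; see module docstring."""
    if not fragment:
        raise ValueError("empty fragment")
    if junction_side not in ("start", "end"):
        raise ValueError("junction_side must be 'start' or 'end'")
    L = len(fragment)
    k = index.k
    if L < k:
        raise ValueError(f"fragment shorter than seed size {k}")
    max_mm = math.floor(max_mismatch_frac * L)
    max_gap = math.floor(max_gap_frac * L)
    ref = index.reference
    RL = len(ref)

    # seed offsets: enough non-overlapping seeds that one must be exact
    # (pigeonhole over max_mm + max_gap errors), plus the final window
    n_seeds = max_mm + max_gap + 1
    offsets = sorted({min(i * k, L - k) for i in range(n_seeds)} | {L - k})

    # candidate loci: (strand, 0-based ref start of the fragment)
    candidates: set[tuple[str, int]] = set()
    for strand, query in ((FORWARD, fragment), (REVERSE, revcomp(fragment))):
        for off in offsets:
            for pos in index.lookup(query[off:off + k]):
                start = int(pos) - off
                if ref.circular:
                    start %= RL
                elif start < 0 or start + L > RL:
                    continue
                candidates.add((strand, start))

    passing: list[tuple[int, str, int, int, int, int]] = []
    # (score, strand, ref_start, ref_end_inclusive, mism, gaps)
    for strand, start in candidates:
        query = fragment if strand == FORWARD else revcomp(fragment)
        window = ref.fetch(start, start + L)
        mism = sum(1 for a, b in zip(query, window) if a != b)
        gaps = 0
        rs, re = start, start + L - 1
        if mism > max_mm and max_gap > 0:
            lo = start - max_gap
            hi = start + L + max_gap
            if not ref.circular:
                lo, hi = max(0, lo), min(RL, hi)
            target = ref.fetch(lo, hi)
            aln = edlib.align(query, target, mode="HW", task="path")
            if aln["editDistance"] < 0 or not aln["locations"]:
                continue
            t0, t1 = aln["locations"][0]
            _, mism, gaps = _cigar_stats(aln["cigar"])
            rs, re = lo + t0, lo + t1
        aligned = L + gaps
        identity = (aligned - mism - gaps) / aligned
        if mism <= max_mm and gaps <= max_gap and identity >= min_identity:
            passing.append((mism + gaps, strand, rs, re, mism, gaps))

    if not passing:
        return Placement(fragment_id, None, None, 0, 0, "unmapped")
    best_score = min(p[0] for p in passing)
    best = [p for p in passing if p[0] == best_score]
    # collapse near-identical gapped loci on one strand
    loci: list[tuple[int, str, int, int, int, int]] = []
    for p in sorted(best, key=lambda p: (p[1], p[2])):
        if loci and p[1] == loci[-1][1] and abs(p[2] - loci[-1][2]) <= max_gap:
            continue
        loci.append(p)
    if len(loci) > 1:
        return Placement(fragment_id, None, None, 0, 0, "ambiguous")
    _, strand, rs, re, mism, gaps = loci[0]
    if junction_side == "start":
        pos0 = rs if strand == FORWARD else re
    else:
        pos0 = re if strand == FORWARD else rs
    return Placement(fragment_id, pos0 % RL + 1, strand, mism, gaps, "unique",
                     ref_start=rs % RL + 1)


def map_fragments(fragments: Iterable[TrimmedFragment], index: SeedIndex,
                  max_mismatch_frac: float = 0.02, max_gap_frac: float = 0.03,
                  min_identity: float = 0.95) -> list[Placement]:
    """Place every fragment; the junction side follows the fragment's end
    of origin (left-end fragments end at the junction, right-end fragments
    start at it)."""
    out = []
    for fr in fragments:
        side = "end" if fr.end == "left" else "start"
        out.append(place_fragment(fr.seq, index,
                                  max_mismatch_frac=max_mismatch_frac,
                                  max_gap_frac=max_gap_frac,
                                  min_identity=min_identity,
                                  junction_side=side,
                                  fragment_id=fr.fragment_id))
    return out


def build_site_table(placements: Iterable[Placement],
                     reference: Genome) -> SiteTable:
    """Per-position, per-orientation counts over unique placements only;
    ambiguous and unmapped fragments are counted and logged."""
    placements = list(placements)
    table = SiteTable.from_placements(placements, reference)
    status = Counter(p.status for p in placements)
    logger.info("build_site_table: %d fragments -> unique=%d ambiguous=%d "
                "unmapped=%d", len(placements), status["unique"],
                status["ambiguous"], status["unmapped"])
    return table


def write_sam(placements: Iterable[Placement], fragments: dict[str, str],
              reference: Genome, path: str) -> None:
    """Minimal SAM export (ungapped M cigar; NM carries mismatches+gaps)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference.name}\tLN:{len(reference)}\n")
        for pl in placements:
            seq = fragments.get(pl.fragment_id, "*")
            if pl.status != "unique":
                fh.write(f"{pl.fragment_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            flag = 0 if pl.orientation == FORWARD else 16
            s = seq if pl.orientation == FORWARD else revcomp(seq)
            cigar = f"{len(seq)}M" if seq != "*" else "*"
            fh.write(f"{pl.fragment_id}\t{flag}\t{reference.name}\t"
                     f"{pl.ref_start}\t255\t{cigar}\t*\t0\t0\t{s}\t*\t"
                     f"NM:i:{pl.mismatches + pl.gaps}\n")
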
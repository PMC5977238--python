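"""Phage-host junction extraction from virion reads.

Two extraction routes match the two experimental read types:

* :func:`extract_left_junctions` -- whole-virion reads that span the phage
  LEFT end carry 31-36 bp of host DNA followed by the phage terminus; the
  host prefix is the junction fragment.
* :func:`filter_valid_right` -- enrichment reads must start *precisely*
  with the terminal right-end phage fragment (181 bp under the default
  layout) and carry at least ``min_host`` bp of host DNA beyond it; only
  such "valid reads" are kept, and the phage prefix is trimmed off.

Both routes examine each read in both orientations, tally every rejection
by reason, and mark the first host base of the emitted fragment as the
"start" annotation that the mapping stage transfers onto the reference.

:func:`chimera_control` quantifies library chimeras (PCR joins that mimic
junctions) by hunting pseudo-junctions at artificially truncated phage
ends, where no genuine junction can exist.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass

from .model import Genome, ReadSet, revcomp

logger = logging.getLogger("saltosites")


@dataclass
class JunctionRead:
    """One read carrying a phage-host junction.

    ``host_fragment`` is written so that its base adjacent to the phage end
    is: the LAST base for left-end junctions (host precedes phage in the
    read) and the FIRST base for right-end junctions (host follows the
    trimmed phage prefix).  ``start_mark`` is the offset of the first host
    base within the (orientation-normalised) read.  ``read_orientation``
    records which orientation of the read matched ('+' as given, '-'
    reverse-complemented).
    """

    read_id: str
    end: str  # left | right
    host_fragment: str
    start_mark: int
    phage_overlap: int
    read_orientation: str = "+"


@dataclass
class TrimmedFragment:
    """A host fragment ready for mapping, with provenance."""

    fragment_id: str
    seq: str
    end: str
    read_id: str
    start_mark: int = 0


@dataclass
class ChimeraReport:
    truncation_offsets: list[int]
    candidate_junctions_per_end: dict[int, int]
    bona_fide_junctions: int

    @property
    def mean_candidates_per_end(self) -> float:
        k = len(self.candidate_junctions_per_end)
        return sum(self.candidate_junctions_per_end.values()) / k if k else 0.0

    def to_text(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "truncation_offsets": self.truncation_offsets,
                "candidate_junctions_per_end":
                    {str(k): v for k, v in
                     sorted(self.candidate_junctions_per_end.items())},
                "mean_candidates_per_end": self.mean_candidates_per_end,
                "bona_fide_junctions": self.bona_fide_junctions,
            }, fh, indent=1)


def _prefix_match_len(s: str, ref: str) -> int:
    """Length of the exact common prefix of s and ref."""
    n = min(len(s), len(ref))
    for i in range(n):
        if s[i] != ref[i]:
            return i
    return n


def _find_end_match(s: str, seed: str, phage_from_seed: str, min_host: int
                    ) -> tuple[int, int] | None:
    """Locate ``seed`` in s at offset >= min_host and extend the match into
    ``phage_from_seed``; returns (host_len, phage_overlap) or None."""
    i = s.find(seed)
    while i != -1:
        if i >= min_host:
            overlap = _prefix_match_len(s[i:], phage_from_seed)
            return i, overlap
        i = s.find(seed, i + 1)
    return None


def extract_left_junctions(reads: ReadSet, phage: Genome,
                           min_host: int = 12, min_phage_overlap: int = 20,
                           tally: Counter | None = None) -> list[JunctionRead]:
    """Reads whose (possibly reverse-complemented) suffix matches the phage
    left end, preceded by >= ``min_host`` bases of host DNA.

    Detection seeds on the exact terminal ``min_phage_overlap``-mer of the
    phage left end and extends; reads matching both phage ends are assigned
    to the end with the longer phage overlap, ties discarded and counted.
    Rejections land in ``tally`` (a Counter, optional).
    """
    if min_phage_overlap < 8:
        raise ValueError("min_phage_overlap too short to seed reliably")
    left_seed = phage.seq[:min_phage_overlap]
    # a right-end junction read is phage-suffix + host; reverse-complemented
    # it reads host + rc(phage suffix), i.e. host followed by a prefix of
    # the reverse-complemented phage -- detected with the rc seed below and
    # used only for the both-ends assignment policy
    rc_phage = revcomp(phage.seq)
    rc_right_seed = rc_phage[:min_phage_overlap]

    out: list[JunctionRead] = []
    tally = tally if tally is not None else Counter()
    for rid, seq in reads:
        if len(seq) < min_host + min_phage_overlap:
            tally["too_short"] += 1
            continue
        cands = []  # (phage_overlap, end, host_len, read_orientation)
        for orient, s in (("+", seq), ("-", revcomp(seq))):
            m = _find_end_match(s, left_seed, phage.seq, min_host)
            if m is not None:
                cands.append((m[1], "left", m[0], orient))
            m = _find_end_match(s, rc_right_seed, rc_phage, min_host)
            if m is not None:
                cands.append((m[1], "right", m[0], orient))
        if not cands:
            tally["no_junction"] += 1
            continue
        cands.sort(key=lambda c: -c[0])
        if (len(cands) > 1 and cands[0][0] == cands[1][0]
                and cands[0][1] != cands[1][1]):
            tally["both_ends_tie"] += 1
            continue
        overlap, end, host_len, orient = cands[0]
        if end != "left":
            tally["right_end_read"] += 1
            continue
        s = seq if orient == "+" else revcomp(seq)
        out.append(JunctionRead(read_id=rid, end="left",
                                host_fragment=s[:host_len], start_mark=0,
                                phage_overlap=overlap,
                                read_orientation=orient))
        tally["accepted"] += 1
    return out


def filter_valid_right(reads: ReadSet, right_end_seq: str,
                       min_host: int = 12, max_mismatches: int = 0
                       ) -> tuple[list[JunctionRead], Counter]:
    """The strict valid-read filter of the enrichment route.

    A read is valid iff its first ``len(right_end_seq)`` bases equal the
    terminal right-end phage sequence (in either orientation) with at most
    ``max_mismatches`` substitutions (default 0: "starting precisely"), and
    at least ``min_host`` bases follow.  The host fragment is everything
    after the phage prefix.  Returns (accepted, rejection tally); accepted +
    rejected == input count.
    """
    m = len(right_end_seq)
    if m < 20:
        raise ValueError("right_end_seq implausibly short")
    tally: Counter = Counter()
    out: list[JunctionRead] = []
    for rid, seq in reads:
        if len(seq) < m:
            tally["too_short"] += 1
            continue
        hit = None
        for orient, s in (("+", seq), ("-", revcomp(seq))):
            mm = sum(1 for a, b in zip(s[:m], right_end_seq) if a != b)
            if mm <= max_mismatches:
                hit = (orient, s, mm)
                break
        if hit is None:
            tally["no_right_end_prefix"] += 1
            continue
        orient, s, mm = hit
        host = s[m:]
        if len(host) < min_host:
            tally["host_too_short"] += 1
            continue
        out.append(JunctionRead(read_id=rid, end="right", host_fragment=host,
                                start_mark=m, phage_overlap=m - mm,
                                read_orientation=orient))
        tally["accepted"] += 1
    return out, tally


def trim_and_annotate(j: JunctionRead) -> TrimmedFragment:
    """Strip the phage portion; the emitted fragment is the host fragment
    with the start annotation at offset 0 and provenance retained."""
    return TrimmedFragment(fragment_id=f"{j.read_id}|{j.end}",
                           seq=j.host_fragment, end=j.end,
                           read_id=j.read_id, start_mark=0)


def write_fragments_fasta(fragments: list[TrimmedFragment], path: str) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            fh.write(f">{fr.fragment_id} end={fr.end} start={fr.start_mark}\n"
                     f"{fr.seq}\n")


def write_tally_tsv(tally: Counter, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason in sorted(tally):
            fh.write(f"{reason}\t{tally[reason]}\n")


def _maps_to(fragment: str, host: Genome) -> bool:
    """Exact-match lookup of a fragment (either strand) in the host,
    honouring circularity."""
    hay = host.seq + (host.seq[:len(fragment) - 1] if host.circular else "")
    return fragment in hay or revcomp(fragment) in hay


def chimera_control(reads: ReadSet, phage: Genome, host: Genome,
                    truncations: tuple[int, ...] = (1000, 10_000, 20_000, 30_000),
                    min_host: int = 12, seed_len: int = 20) -> ChimeraReport:
    """Estimate the chimeric pseudo-junction rate.

    For each truncation t, the phage genome shortened of t bp at its left
    end exposes an artificial terminus; reads that look like host DNA
    followed by that artificial end (host prefix >= ``min_host`` mapping to
    the host genome) can only be chimeric artifacts.  Their count per end,
    against the bona fide left-end junction count, bounds the artifact
    proportion.
    """
    for t in truncations:
        if t >= len(phage):
            raise ValueError(f"truncation {t} >= phage length")
    candidates: dict[int, int] = {}
    for t in truncations:
        art_seed = phage.seq[t:t + seed_len]
        n = 0
        for rid, seq in reads:
            for s in (seq, revcomp(seq)):
                m = _find_end_match(s, art_seed, phage.seq[t:], min_host)
                if m is not None and _maps_to(s[:m[0]], host):
                    n += 1
                    break
        candidates[t] = n
    bona = len(extract_left_junctions(reads, phage, min_host=min_host,
                                      min_phage_overlap=seed_len))
    report = ChimeraReport(truncation_offsets=list(truncations),
                           candidate_junctions_per_end=candidates,
                           bona_fide_junctions=bona)
    logger.info("chimera_control: %s candidates vs %d bona fide junctions",
                candidates, bona)
    return report
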
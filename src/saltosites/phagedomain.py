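"""Self-insertion topology of the phage genome.

The small fraction of transposition events that escape target immunity and
land in an already inserted phage copy is far from uniform along the phage
genome: the per-50-bp profile shows sharp boundary peaks delimiting
density domains, interpreted as the supercoiled loops of the phage
chromosomal domain held by the transposome.  This module

* bins a phage-referenced site table into 50 bp bins,
* segments the profile into domains at sharp local maxima (a bin exceeding
  q times the running median), with optional exclusion zones masking
  enrichment artifacts around restriction sites,
* computes per-domain densities and pairs domains symmetrically into
  loops (outermost pair first, the central domain alone at the apex),
* hunts the transposition-free gap near the genome middle -- the candidate
  protected core of the strong gyrase site (SGS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FORWARD, SiteTable

logger = logging.getLogger("saltosites")


@dataclass
class BinnedProfile:
    """Non-overlapping fixed-width bin counts, orientations separate."""

    bin_size: int
    forward: np.ndarray
    reverse: np.ndarray
    length: int

    @property
    def total(self) -> np.ndarray:
        return self.forward + self.reverse

    def __len__(self) -> int:
        return len(self.forward)


@dataclass
class PhageDomain:
    label: str
    start: int  # 1-based inclusive
    end: int
    event_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def density(self) -> float:
        """Events per kilobase."""
        return domain_density(self)


def domain_density(d: PhageDomain) -> float:
    """Events per kilobase of a domain span."""
    if d.length <= 0:
        raise ValueError("domain span must be positive")
    return d.event_count / (d.length / 1000.0)


@dataclass
class Loop:
    label: str
    members: tuple[str, ...]          # one (apex) or two domain labels
    shares: dict[str, float]          # member label -> event share


@dataclass
class LoopModel:
    loops: list[Loop]
    apex: str


@dataclass
class Gap:
    start: int
    end: int
    offset_from_middle: int  # gap midpoint minus genome midpoint


@dataclass
class GapReport:
    gaps: list[Gap] = field(default_factory=list)
    uninformative: bool = False


def bin_profile(table: SiteTable, bin: int = 50) -> BinnedProfile:
    """Counts per non-overlapping bin; orientations kept separately (their
    sum is the ``total`` profile).  Total over bins conserves the table
    total."""
    if bin < 1:
        raise ValueError("bin size must be positive")
    nbins = (table.length + bin - 1) // bin
    fwd = np.zeros(nbins, dtype=np.int64)
    rev = np.zeros(nbins, dtype=np.int64)
    for (pos, orient), n in table.counts.items():
        b = (pos - 1) // bin
        if orient == FORWARD:
            fwd[b] += n
        else:
            rev[b] += n
    return BinnedProfile(bin_size=bin, forward=fwd, reverse=rev,
                         length=table.length)


def _running_median(x: np.ndarray, window_bins: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window_bins, center=True, min_periods=1).median().to_numpy()


def segment_domains(profile: BinnedProfile,
                    n_boundaries: int | None = None,
                    exclusion_zones: tuple[tuple[int, int], ...] = (),
                    q: float = 5.0, min_separation_bins: int = 10,
                    median_window_bins: int = 41) -> list[PhageDomain]:
    """Domains delimited by sharp profile peaks.

    A boundary peak is a bin whose count exceeds ``q`` times the running
    median of the (unmasked) profile; peaks are taken greedily by height
    with a minimum mutual separation.  ``exclusion_zones`` (1-based bp
    spans, e.g. +/-1 kb around a restriction site whose enrichment creates
    artifact peaks) are masked before peak calling, and their events are
    excluded from domain counts.  ``n_boundaries`` caps the number of
    boundaries at the strongest ones.  Domains tile the genome; each
    boundary bin opens the following domain.  With no peak the whole
    genome is one flagged domain.
    """
    if len(profile) < 2:
        raise ValueError("profile too short to segment")
    total = profile.total.astype(np.float64)
    nbins = len(total)
    bin_size = profile.bin_size
    masked = np.zeros(nbins, dtype=bool)
    for a, b in exclusion_zones:
        masked[(a - 1) // bin_size:(b - 1) // bin_size + 1] = True

    work = total.copy()
    work[masked] = np.nan
    med = _running_median(work, median_window_bins)
    med = np.nan_to_num(med, nan=np.nanmedian(work) if np.isfinite(work).any()
                        else 0.0)
    thr = q * np.maximum(med, 1.0)
    cand = np.nonzero(~masked & (total > thr))[0]

    peaks: list[int] = []
    for b in sorted(cand, key=lambda i: -total[i]):
        if all(abs(b - p) >= min_separation_bins for p in peaks):
            peaks.append(b)
    if n_boundaries is not None:
        peaks = peaks[:n_boundaries]
    peaks.sort()

    if not peaks:
        logger.warning("segment_domains: no boundary peaks found; "
                       "returning a single domain")
    bounds0 = [0] + [p * bin_size for p in peaks] + [profile.length]
    counts_per_bin = total.copy()
    counts_per_bin[masked] = 0.0
    domains = []
    for i, (a0, b0) in enumerate(zip(bounds0, bounds0[1:]), start=1):
        lo_bin, hi_bin = a0 // bin_size, (b0 - 1) // bin_size + 1
        count = int(counts_per_bin[lo_bin:hi_bin].sum())
        domains.append(PhageDomain(label=f"D{i}", start=a0 + 1, end=b0,
                                   event_count=count))
    masked_events = int(total[masked].sum())
    if masked_events:
        logger.info("segment_domains: %d events in masked zones excluded",
                    masked_events)
    return domains


def pair_loops(domains: list[PhageDomain]) -> LoopModel:
    """Symmetric pairing of interior domains into loops.

    The two terminal domains (genome ends, held in the transposome) are
    excluded; the remaining interior domains must be odd in number.  Loop
    L1 pairs the outermost interior pair, L2 the next, ...; the central
    domain forms the apex loop alone.  Shares are event fractions within
    each loop.
    """
    if len(domains) < 3:
        raise ValueError("need at least three domains")
    interior = domains[1:-1]
    if len(interior) % 2 == 0:
        raise ValueError(f"even number of interior domains "
                         f"({len(interior)}): symmetric pairing undefined")
    loops = []
    half = len(interior) // 2
    for i in range(half):
        a, b = interior[i], interior[-1 - i]
        tot = a.event_count + b.event_count
        shares = {a.label: a.event_count / tot if tot else 0.5,
                  b.label: b.event_count / tot if tot else 0.5}
        loops.append(Loop(label=f"L{i + 1}", members=(a.label, b.label),
                          shares=shares))
    apex = interior[half]
    loops.append(Loop(label=f"L{half + 1}", members=(apex.label,),
                      shares={apex.label: 1.0}))
    return LoopModel(loops=loops, apex=apex.label)


def protected_gap(table: SiteTable, min_gap: int = 30,
                  search_center: float = 0.5, search_radius: int = 1000
                  ) -> GapReport:
    """Zero-event runs of >= ``min_gap`` bp near the genome middle.

    At realistic self-insertion densities (~1300 events/kb) an empty run of
    ~37 bp is essentially impossible by chance, so such a gap marks a
    protected segment -- the candidate gyrase-site core.  An empty table
    returns the whole search window flagged uninformative.
    """
    L = table.length
    mid = int(round(search_center * L))
    lo = max(1, mid - search_radius)
    hi = min(L, mid + search_radius)
    counts = np.zeros(hi - lo + 1, dtype=np.int64)
    for pos, n in table.position_totals().items():
        if lo <= pos <= hi:
            counts[pos - lo] = n
    if table.total_events == 0:
        return GapReport(gaps=[Gap(lo, hi, (lo + hi) // 2 - mid)],
                         uninformative=True)
    gaps = []
    i = 0
    n = len(counts)
    while i < n:
        if counts[i] == 0:
            j = i
            while j + 1 < n and counts[j + 1] == 0:
                j += 1
            if j - i + 1 >= min_gap:
                a, b = lo + i, lo + j
                gaps.append(Gap(a, b, (a + b) // 2 - mid))
            i = j + 1
        else:
            i += 1
    return GapReport(gaps=gaps, uninformative=False)


def write_domains_tsv(domains: list[PhageDomain], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("label\tstart\tend\tlength\tevent_count\tdensity_per_kb\n")
        for d in domains:
            fh.write(f"{d.label}\t{d.start}\t{d.end}\t{d.length}\t"
                     f"{d.event_count}\t{d.density:.1f}\n")


def write_loops_tsv(model: LoopModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("loop\tmembers\tshares\n")
        for lp in model.loops:
            shares = ";".join(f"{m}={lp.shares[m]:.3f}" for m in lp.members)
            fh.write(f"{lp.label}\t{';'.join(lp.members)}\t{shares}\n")


def write_profile_bedgraph(profile: BinnedProfile, reference: str,
                           path: str) -> None:
    with open(path, "w") as fh:
        tot = profile.total
        for b in range(len(profile)):
            start = b * profile.bin_size
            end = min(profile.length, start + profile.bin_size)
            fh.write(f"{reference}\t{start}\t{end}\t{int(tot[b])}\n")
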
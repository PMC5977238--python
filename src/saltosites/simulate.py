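"""Synthetic virion-read generator.

Emulates the data structure produced by sequencing virions of a transposable
(Mu-like) phage:

* a **host chromosome** with a tunable GC landscape -- low-GC islands (which
  real insertion data show to be transposition coldspots) and planted
  palindromic-repeat motifs (which nucleate insertion hotspots);
* a **phage genome** whose termini carry the conserved TGT ... ACA
  trinucleotides and which holds exactly two recognition sites for the
  enrichment enzyme, one of them close to the right end;
* a **site-selection model** over host positions: a flat base weight,
  suppressed in low-GC windows, boosted near planted motifs, plus a small
  target-immunity leak routing a fraction of events into an already inserted
  phage copy with a structured domain profile;
* **virion molecules** = short host left flank (31-36 bp) + phage genome +
  long variable host right flank, and reads sampled over them, either
  whole-virion style or mimicking the restriction enrichment of the short
  phage right end.

Every operation takes an explicit seed; there is no hidden global RNG state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import FORWARD, REVERSE, Genome, InsertionEvent, ReadSet, revcomp

logger = logging.getLogger("saltosites")

#: Recognition sequence of the enrichment-enzyme model (NsiI, a palindrome).
#: The modelled cut falls after the fifth base of the site, so the 1-based
#: cut position (last base of the upstream fragment) is site_start + 4.
ENZYME_RECOGNITION = "ATGCAT"
_CUT_OFFSET = 4  # 0-based offset of the cut within the recognition site


@dataclass(frozen=True)
class PhageSpec:
    """Layout of the phage genome used by the generator.

    Defaults describe a 37,205 bp genome with enzyme recognition sites
    cutting at 1-based positions 6170 and 37,024, leaving a 181 bp terminal
    fragment on the right -- the fragment that anchors the junction
    enrichment.
    """

    length: int = 37_205
    left_end: str = "TGT"
    right_end: str = "ACA"
    enzyme_sites: tuple[int, ...] = (6170, 37_024)
    gc: float = 0.64

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValueError("phage genome too short")
        sites = self.enzyme_sites
        if list(sites) != sorted(set(sites)):
            raise ValueError("enzyme sites must be strictly increasing")
        for c in sites:
            if not (0 < c < self.length):
                raise ValueError(f"cut position {c} outside (0, {self.length})")
            # the 6 bp recognition site around the cut must not clobber the
            # terminal trinucleotides
            if c - _CUT_OFFSET < 4 or c + 2 > self.length - 3:
                raise ValueError(
                    f"cut at {c} too close to a genome end to honour the "
                    f"terminal trinucleotides")

    @property
    def right_end_len(self) -> int | None:
        """Length of the terminal fragment right of the last cut (181 bp
        under the defaults); ``None`` when there are no enzyme sites."""
        if not self.enzyme_sites:
            return None
        return self.length - self.enzyme_sites[-1]


@dataclass(frozen=True)
class SiteModel:
    """Insertion site-selection model over the host genome.

    ``base_weight`` is the flat per-position weight.  Positions whose
    ``gc_window``-bp centred GC fraction falls below ``gc_cold_threshold``
    are multiplied by ``gc_cold_factor`` (default 0.005, making low-GC
    islands essentially transposition-free, < 10 events/kb at realistic
    depths).  Positions within ``motif_window`` bp of a planted motif are
    multiplied by ``motif_boost`` (default 300, the order of the insertion
    bias observed next to palindromic-repeat elements).  ``immunity_leak``
    is the probability that an event escapes target immunity and lands in a
    phage copy (default 0.004).  ``duplication_offset`` shifts the reported
    junction coordinate of reverse-orientation events, reproducing the
    paired forward/reverse peak geometry of real hotspots (default 5 bp,
    configurable: the target-site duplication length of this phage group is
    not established).
    """

    base_weight: float = 1.0
    gc_window: int = 500
    gc_cold_threshold: float = 0.50
    gc_cold_factor: float = 0.005
    motif_positions: tuple[int, ...] = ()
    motif_boost: float = 300.0
    motif_window: int = 120
    immunity_leak: float = 0.004
    duplication_offset: int = 5

    def __post_init__(self) -> None:
        if self.base_weight <= 0:
            raise ValueError("base_weight must be positive")
        if not (0.0 <= self.immunity_leak <= 1.0):
            raise ValueError("immunity_leak must be a probability")
        if self.gc_cold_factor <= 0 or self.motif_boost <= 0:
            raise ValueError("weights must stay positive")


#: Composition is homogenised at this scale: every block carries its exact
#: (rounded) share of G+C, so windowed GC tracks the requested value
#: instead of wandering across the cold threshold by sampling noise.
_COMPOSITION_BLOCK = 100


def _exact_block(n: int, n_gc: int, rng: np.random.Generator) -> np.ndarray:
    arr = np.empty(n, dtype=np.uint8)
    n_at = n - n_gc
    g = n_gc // 2
    a = n_at // 2
    arr[:g] = ord("G")
    arr[g:n_gc] = ord("C")
    arr[n_gc:n_gc + a] = ord("A")
    arr[n_gc + a:] = ord("T")
    rng.shuffle(arr)
    return arr


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """n random bases whose GC composition is exact (rounded) within every
    100 bp block; uint8 ASCII codes."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be a fraction")
    out = np.empty(n, dtype=np.uint8)
    prev_target = 0
    for start in range(0, n, _COMPOSITION_BLOCK):
        end = min(n, start + _COMPOSITION_BLOCK)
        target = round(gc * end)
        out[start:end] = _exact_block(end - start, target - prev_target, rng)
        prev_target = target
    return out


def make_host_genome(length: int, gc: float = 0.65,
                     low_gc_islands: tuple[tuple[int, int, float], ...] = (),
                     planted_motifs: tuple[tuple[int, str], ...] = (),
                     seed: int = 0, name: str = "host",
                     circular: bool = True) -> Genome:
    """Random host chromosome with low-GC islands and verbatim motifs.

    ``low_gc_islands`` are (1-based start, length, gc) triples;
    ``planted_motifs`` are (1-based position, motif string) pairs which must
    not overlap one another.  Motifs are planted last, so they appear
    verbatim even inside an island.
    """
    rng = np.random.default_rng(seed)
    for start, ln, igc in low_gc_islands:
        if start < 1 or start + ln - 1 > length:
            raise ValueError(f"island ({start}, {ln}) outside genome")
    spans = sorted((pos, pos + len(m) - 1) for pos, m in planted_motifs)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise ValueError("overlapping motif placements")
    for pos, m in planted_motifs:
        if pos < 1 or pos + len(m) - 1 > length:
            raise ValueError(f"motif at {pos} outside genome")

    arr = _random_bases(length, gc, rng)
    for start, ln, igc in low_gc_islands:
        arr[start - 1:start - 1 + ln] = _random_bases(ln, igc, rng)
    for pos, m in planted_motifs:
        arr[pos - 1:pos - 1 + len(m)] = np.frombuffer(
            m.upper().encode(), dtype=np.uint8)
    return Genome(name=name, seq=arr.tobytes().decode(), circular=circular)


def _scrub_recognition_sites(arr: np.ndarray, protected: list[tuple[int, int]],
                             rng: np.random.Generator) -> None:
    """Destroy every occurrence of the recognition 6-mer whose 0-based start
    is not listed in ``protected`` starts, by mutating one unprotected base.
    ``protected`` holds 0-based (start, end) inclusive spans to keep intact.
    """
    seq_bytes = arr.tobytes()
    site = ENZYME_RECOGNITION.encode()
    keep_starts = {a for a, b in protected if b - a + 1 == len(site)}
    prot_mask = np.zeros(len(arr), dtype=bool)
    for a, b in protected:
        prot_mask[a:b + 1] = True
    for _ in range(50):  # converges in one or two passes in practice
        dirty = False
        i = seq_bytes.find(site)
        while i != -1:
            if i not in keep_starts:
                free = [j for j in range(i, i + len(site)) if not prot_mask[j]]
                if not free:
                    raise ValueError("cannot scrub recognition site inside "
                                     "fully protected region")
                j = free[len(free) // 2]
                old = chr(arr[j])
                choices = [b for b in "ACGT" if b != old]
                arr[j] = ord(choices[rng.integers(len(choices))])
                dirty = True
            i = seq_bytes.find(site, i + 1)
        seq_bytes = arr.tobytes()
        if not dirty:
            return
    raise RuntimeError("recognition-site scrub did not converge")


def make_phage_genome(spec: PhageSpec = PhageSpec(), seed: int = 0,
                      name: str = "phage") -> Genome:
    """Random phage genome honouring the given layout.

    The genome begins with the left trinucleotide and ends with the right
    one; the enzyme recognition 6-mer occurs exactly at the layout's cut
    sites and nowhere else, so a digest of the returned genome reproduces
    the layout's fragment lengths.
    """
    rng = np.random.default_rng(seed)
    arr = _random_bases(spec.length, spec.gc, rng)
    arr[:3] = np.frombuffer(spec.left_end.encode(), dtype=np.uint8)
    arr[-3:] = np.frombuffer(spec.right_end.encode(), dtype=np.uint8)
    site = np.frombuffer(ENZYME_RECOGNITION.encode(), dtype=np.uint8)
    protected: list[tuple[int, int]] = [(0, 2), (spec.length - 3, spec.length - 1)]
    for c in spec.enzyme_sites:
        start0 = c - 1 - _CUT_OFFSET          # 0-based start of the site
        arr[start0:start0 + len(site)] = site
        protected.append((start0, start0 + len(site) - 1))
    _scrub_recognition_sites(arr, protected, rng)
    genome = Genome(name=name, seq=arr.tobytes().decode(), circular=False)
    assert tuple(find_enzyme_cut_sites(genome)) == tuple(spec.enzyme_sites)
    return genome


def find_enzyme_cut_sites(genome: Genome,
                          recognition: str = ENZYME_RECOGNITION) -> list[int]:
    """1-based cut positions (last base of the upstream fragment) of every
    occurrence of the recognition sequence on the plus strand.  The default
    recognition site is palindromic, so one strand suffices."""
    cuts = []
    i = genome.seq.find(recognition)
    while i != -1:
        cuts.append(i + 1 + _CUT_OFFSET)
        i = genome.seq.find(recognition, i + 1)
    return cuts


def digest(genome_length: int, site_positions: list[int] | tuple[int, ...]) -> list[int]:
    """Fragment lengths of a complete digest.

    ``site_positions`` are 1-based cut positions, strictly increasing, each
    in (0, genome_length); a cut at position c leaves c bases upstream.
    Fragment count is ``len(sites) + 1`` and fragments sum to the input
    length.
    """
    sites = list(site_positions)
    if sites != sorted(set(sites)):
        raise ValueError("cut positions must be strictly increasing")
    for c in sites:
        if not (0 < c < genome_length):
            raise ValueError(f"cut position {c} outside (0, {genome_length})")
    bounds = [0] + sites + [genome_length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def digest_genome(genome: Genome,
                  recognition: str = ENZYME_RECOGNITION) -> list[int]:
    """Digest a genome with the recognition-site model."""
    return digest(len(genome), find_enzyme_cut_sites(genome, recognition))


# ---------------------------------------------------------------------------
# site selection
# ---------------------------------------------------------------------------

def windowed_gc(genome: Genome, window: int) -> np.ndarray:
    """Per-position GC fraction in a centred window (wraps on circular
    genomes, clamps at linear ends)."""
    if window > len(genome):
        raise ValueError("window larger than genome")
    gc = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_gc = ((gc == ord("G")) | (gc == ord("C"))).astype(np.float64)
    L = len(genome)
    half = window // 2
    if genome.circular:
        ext = np.concatenate([is_gc[-half:], is_gc, is_gc[:window - half]])
        cs = np.concatenate([[0.0], np.cumsum(ext)])
        return (cs[window:window + L] - cs[:L]) / window
    cs = np.concatenate([[0.0], np.cumsum(is_gc)])
    lo = np.clip(np.arange(L) - half, 0, L)
    hi = np.clip(np.arange(L) - half + window, 0, L)
    return (cs[hi] - cs[lo]) / (hi - lo)


def site_weights(host: Genome, model: SiteModel) -> np.ndarray:
    """Per-position (1-based index p stored at p-1) insertion weight."""
    if model.gc_window > len(host):
        raise ValueError("gc_window larger than genome")
    L = len(host)
    w = np.full(L, model.base_weight, dtype=np.float64)
    gc = windowed_gc(host, model.gc_window)
    w[gc < model.gc_cold_threshold] *= model.gc_cold_factor
    if model.motif_positions:
        boost = np.zeros(L, dtype=bool)
        idx = np.arange(-model.motif_window, model.motif_window + 1)
        for m in model.motif_positions:
            pos = (m - 1) + idx
            pos = pos % L if host.circular else pos[(pos >= 0) & (pos < L)]
            boost[pos] = True
        w[boost] *= model.motif_boost
    return w


def sample_insertions(n: int, host: Genome, phage: Genome, model: SiteModel,
                      phage_domain_profile: np.ndarray | None = None,
                      seed: int = 0) -> list[InsertionEvent]:
    """Draw n independent transposition events.

    Each event targets an inserted phage copy with probability
    ``model.immunity_leak`` (position drawn from ``phage_domain_profile``,
    a per-base relative density over phage coordinates; uniform when None),
    otherwise the host (position drawn proportionally to
    :func:`site_weights`).  Orientation is uniform; reverse events report
    the junction coordinate shifted by ``model.duplication_offset``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    is_phage = rng.random(n) < model.immunity_leak
    n_ph = int(is_phage.sum())
    n_ho = n - n_ph

    w = site_weights(host, model)
    host_pos = rng.choice(len(host), size=n_ho, p=w / w.sum()) + 1

    Lp = len(phage)
    if phage_domain_profile is None:
        phage_pos = rng.integers(1, Lp + 1, size=n_ph)
    else:
        prof = np.asarray(phage_domain_profile, dtype=np.float64)
        if prof.shape != (Lp,):
            raise ValueError("phage_domain_profile must be per-base over the "
                             "phage genome")
        if prof.sum() <= 0:
            raise ValueError("profile must sum to a positive value")
        phage_pos = rng.choice(Lp, size=n_ph, p=prof / prof.sum()) + 1

    is_rev = rng.random(n) < 0.5
    events: list[InsertionEvent] = []
    hi = pi = 0
    for k in range(n):
        if is_phage[k]:
            target, L, pos = "phage", Lp, int(phage_pos[pi]); pi += 1
        else:
            target, L, pos = "host", len(host), int(host_pos[hi]); hi += 1
        if is_rev[k]:
            pos = (pos - 1 + model.duplication_offset) % L + 1
            events.append(InsertionEvent(target, pos, REVERSE))
        else:
            events.append(InsertionEvent(target, pos, FORWARD))
    return events


# ---------------------------------------------------------------------------
# virion molecules and reads
# ---------------------------------------------------------------------------

def _flank_seqs(event: InsertionEvent, src: Genome, lf: int, rl: int
                ) -> tuple[str, str] | None:
    """(left_flank, right_flank) of the virion molecule, or None if a flank
    runs off a linear genome end.

    The left flank is the 31-36 bp of target DNA adjacent to the phage LEFT
    end, written in virion orientation (so it always precedes the phage
    'TGT...').  The junction coordinate of the event is the target base of
    the flank touching the phage, for both flanks and both orientations.
    """
    p0 = event.position - 1  # 0-based junction base
    L = len(src)
    try:
        if event.orientation == FORWARD:
            left = src.fetch(p0 - lf + 1, p0 + 1)
            right = src.fetch(p0, p0 + rl)
        else:
            left = revcomp(src.fetch(p0, p0 + lf))
            right = revcomp(src.fetch(p0 - rl + 1, p0 + 1))
    except IndexError:
        return None
    return left, right


def package_reads(events: list[InsertionEvent], host: Genome, phage: Genome,
                  mode: str = "enriched-right", read_length: int = 250,
                  left_flank_range: tuple[int, int] = (31, 36),
                  right_flank_range: tuple[int, int] = (170, 2500),
                  reads_per_molecule: int = 3,
                  right_end_len: int | None = None,
                  seed: int = 0) -> ReadSet:
    """Emit reads over simulated virion molecules.

    ``whole-virion`` mode samples ``reads_per_molecule`` reads per molecule
    with both molecule ends always represented (chromosome ends are
    overrepresented in shearing libraries of linear molecules), so every
    event yields at least one read spanning the left junction.

    ``enriched-right`` mode mimics the restriction enrichment: each read
    starts precisely at the modelled cut preceding the terminal right-end
    phage fragment and runs into the flanking target DNA.  Half the reads
    are emitted reverse-complemented.

    The truth table records the generating event for every junction-bearing
    read.  Events whose flank would run off a linear genome end are dropped
    and counted.
    """
    if mode not in ("whole-virion", "enriched-right"):
        raise ValueError(f"unknown mode {mode!r}")
    if read_length < 50:
        raise ValueError("read_length must be >= 50")
    rng = np.random.default_rng(seed)
    if right_end_len is None:
        cuts = find_enzyme_cut_sites(phage)
        if not cuts:
            raise ValueError("phage has no recognition site; pass "
                             "right_end_len explicitly")
        right_end_len = len(phage) - cuts[-1]
    right_end_seq = phage.seq[len(phage) - right_end_len:]

    reads: list[tuple[str, str]] = []
    truth: dict[str, InsertionEvent] = {}
    dropped = 0
    rid = 0
    for ev in events:
        src = host if ev.target == "host" else phage
        lf = int(rng.integers(left_flank_range[0], left_flank_range[1] + 1))
        rl = int(rng.integers(right_flank_range[0], right_flank_range[1] + 1))
        flanks = _flank_seqs(ev, src, lf, rl)
        if flanks is None:
            dropped += 1
            continue
        left, right = flanks
        if mode == "enriched-right":
            host_part = right[:read_length - right_end_len]
            seq = right_end_seq + host_part
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid += 1
            name = f"r{rid:07d}"
            reads.append((name, seq))
            if host_part:
                truth[name] = ev
        else:
            # the virion always carries the phage left-to-right in phage
            # orientation; the insertion orientation lives in the flanks,
            # which are already written in virion orientation
            molecule = left + phage.seq + right
            starts = [0, max(0, len(molecule) - read_length)]
            starts += list(rng.integers(0, max(1, len(molecule) - read_length + 1),
                                        size=max(0, reads_per_molecule - 2)))
            for s in starts[:reads_per_molecule]:
                rid += 1
                name = f"r{rid:07d}"
                seq = molecule[s:s + read_length]
                reads.append((name, seq))
                # spans the left junction with host and phage on both sides?
                if s < lf and s + len(seq) > lf:
                    truth[name] = ev
    if dropped:
        logger.info("package_reads: dropped %d events with flanks off a "
                    "linear genome end", dropped)
    return ReadSet(reads=reads, truth=truth, dropped=dropped)


# ---------------------------------------------------------------------------
# domain profile helper and configuration
# ---------------------------------------------------------------------------

#: Study-like nine-domain layout: 1-based first positions of domains 2..9
#: and relative densities of domains 1..9 (events/kb at full depth), on a
#: 37.2 kb genome.  Terminal-domain densities are not printed anywhere and
#: are set to a plausible low 300/kb.
_DOMAIN_SIZES = (900, 2900, 6100, 5300, 7200, 4500, 3800, 5800, 700)
_DOMAIN_DENSITIES = (300.0, 330.0, 800.0, 800.0, 1332.0, 620.0, 709.0,
                     1049.0, 300.0)


def scaled_domain_profile(phage_length: int, boundary_peak_rel: float = 10.0,
                          peak_halfwidth: int = 25,
                          include_gap: bool = True,
                          gap_width: int = 37) -> np.ndarray:
    """Per-base self-insertion profile shaped like the nine-domain study
    layout, rescaled to an arbitrary phage length.

    Domain boundaries carry sharp peaks (``boundary_peak_rel`` times the
    densest domain) -- the fixed loop crossing points.  When
    ``include_gap``, a ``gap_width`` bp zero-density segment (the protected
    gyrase-site core) is placed 150 bp (rescaled) right of the exact
    middle.
    """
    total = sum(_DOMAIN_SIZES)
    scale = phage_length / total
    cum = np.cumsum(_DOMAIN_SIZES)[:-1]
    bounds = tuple(int(round(c * scale)) + 1 for c in cum)
    gap = None
    if include_gap:
        mid = phage_length // 2 + int(round(150 * scale))
        gap = (mid - gap_width // 2, mid - gap_width // 2 + gap_width - 1)
    return domain_profile(phage_length, bounds, _DOMAIN_DENSITIES,
                          boundary_peak=boundary_peak_rel * max(_DOMAIN_DENSITIES),
                          peak_halfwidth=peak_halfwidth,
                          protected_gap_span=gap)


def scaled_phage_spec(length: int, right_end_len: int = 181) -> PhageSpec:
    """A phage layout for toy genome sizes: the first cut at the rescaled
    position of the full-size layout, the last cut ``right_end_len`` bp
    before the right end."""
    first = max(10, int(round(length * 6170 / 37_205)))
    return PhageSpec(length=length,
                     enzyme_sites=(first, length - right_end_len))


def domain_profile(phage_length: int,
                   domain_bounds: tuple[int, ...],
                   domain_densities: tuple[float, ...],
                   boundary_peak: float = 0.0,
                   peak_halfwidth: int = 25,
                   protected_gap_span: tuple[int, int] | None = None
                   ) -> np.ndarray:
    """Per-base relative self-insertion density with stepwise domains.

    ``domain_bounds`` are 1-based first positions of domains 2..k (k-1
    boundaries); ``domain_densities`` the k relative densities.  When
    ``boundary_peak`` > 0, each boundary carries a sharp peak of that
    relative density over +/- ``peak_halfwidth`` bp (the fixed crossing
    points of the loop topology attract events in real profiles).
    ``protected_gap_span`` zeroes a 1-based inclusive span (the
    gyrase-protected core near the genome middle).
    """
    k = len(domain_densities)
    if len(domain_bounds) != k - 1:
        raise ValueError("need k-1 bounds for k densities")
    prof = np.empty(phage_length, dtype=np.float64)
    bounds = [1, *domain_bounds, phage_length + 1]
    if bounds != sorted(bounds):
        raise ValueError("domain bounds must increase")
    for d, (a, b) in zip(domain_densities, zip(bounds, bounds[1:])):
        prof[a - 1:b - 1] = d
    if boundary_peak > 0:
        for b in domain_bounds:
            lo = max(0, b - 1 - peak_halfwidth)
            prof[lo:b - 1 + peak_halfwidth + 1] = boundary_peak
    if protected_gap_span is not None:
        a, b = protected_gap_span
        prof[a - 1:b] = 0.0
    return prof
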
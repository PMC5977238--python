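"""Transposition coldspots and their link to local GC content.

Insertion density is tallied in sliding windows alongside the windowed GC
fraction; coldspots are maximal merged runs of windows whose density falls
below a cutoff (10 events/kb against a genome-wide average of 1300-1800 at
full experimental depth), kept when at least 1 kb long.  In this phage
group the coldspots coincide with the low-GC (< 50%) islands of an
otherwise 65%-GC host genome -- horizontally acquired regions such as the
O-antigen biosynthesis cluster -- while intermediate-GC regions like rRNA
operons (~52% GC, ~30 events/kb) fall above the cutoff and are not called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import Genome, SiteTable

logger = logging.getLogger("saltosites")


@dataclass
class DensityTrack:
    """Sliding-window event density (events/kb) and GC fraction."""

    window: int
    step: int
    starts: np.ndarray          # 1-based window starts
    density: np.ndarray         # events per kb, per window
    gc: np.ndarray              # GC fraction, per window
    length: int
    circular: bool
    # per-base arrays kept for exact aggregates over merged regions
    _pos_counts: np.ndarray = field(repr=False, default=None)
    _gc_mask: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class Coldspot:
    start: int   # 1-based inclusive
    end: int
    density: float  # events/kb over the region
    gc: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def density_gc_track(table: SiteTable, genome: Genome, window: int = 1000,
                     step: int = 200) -> DensityTrack:
    """Per-window events/kb and GC fraction; windows wrap on circular
    genomes and stop at the end of linear ones."""
    if window > len(genome):
        raise ValueError("window larger than genome")
    if table.length != len(genome):
        raise ValueError("site table and genome lengths differ")
    L = len(genome)
    counts = np.zeros(L, dtype=np.int64)
    for pos, n in table.position_totals().items():
        counts[pos - 1] = n
    gb = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    gc_mask = (gb == ord("G")) | (gb == ord("C"))

    if genome.circular:
        starts0 = np.arange(0, L, step)
        ext_counts = np.concatenate([counts, counts[:window]])
        ext_gc = np.concatenate([gc_mask, gc_mask[:window]])
    else:
        starts0 = np.arange(0, L - window + 1, step)
        ext_counts, ext_gc = counts, gc_mask
    cs = np.concatenate([[0], np.cumsum(ext_counts)])
    gs = np.concatenate([[0], np.cumsum(ext_gc)])
    ev = cs[starts0 + window] - cs[starts0]
    gcf = (gs[starts0 + window] - gs[starts0]) / window
    return DensityTrack(window=window, step=step, starts=starts0 + 1,
                        density=ev / (window / 1000.0), gc=gcf,
                        length=L, circular=genome.circular,
                        _pos_counts=counts, _gc_mask=gc_mask)


def call_coldspots(track: DensityTrack, max_density: float = 10.0,
                   min_length: int = 1000) -> list[Coldspot]:
    """Maximal runs of consecutive below-cutoff windows, merged into
    regions, reported with exact aggregate density and GC when at least
    ``min_length`` bp long."""
    below = track.density < max_density
    if not below.any():
        return []
    L = track.length
    n = len(below)
    runs: list[tuple[int, int]] = []  # window index ranges [i, j] inclusive
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge a run touching the array end with one at the start (circular)
    if track.circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n - 1:
        first = runs.pop(0)
        runs[-1] = (runs[-1][0], first[1] + n)
    # bp spans of the runs (end may exceed L for a wrapped run); because
    # windows overlap (step < window), runs interrupted by an isolated
    # noisy window produce overlapping spans -- merge those into regions
    spans = sorted((int(track.starts[i % n]),
                    int(track.starts[i % n])
                    + (int(track.starts[j % n]) - int(track.starts[i % n]))
                    % max(L, 1) + track.window - 1)
                   for i, j in runs)
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out: list[Coldspot] = []
    for a, b in merged:
        span = b - a + 1
        if span < min_length:
            continue
        idx = (np.arange(a - 1, b) % L if track.circular
               else np.arange(a - 1, min(b, L)))
        ev = int(track._pos_counts[idx].sum())
        gc = float(track._gc_mask[idx].mean())
        density = ev / (span / 1000.0)
        if density >= max_density:
            continue
        out.append(Coldspot(start=a, end=(b - 1) % L + 1, density=density,
                            gc=gc))
    logger.info("call_coldspots: %d regions below %.3g events/kb",
                len(out), max_density)
    return out


def write_coldspots_bed(spots: list[Coldspot], reference: str, path: str
                        ) -> None:
    with open(path, "w") as fh:
        for c in spots:
            fh.write(f"{reference}\t{c.start - 1}\t{c.end}\tcoldspot\t"
                     f"{c.density:.3f}\t.\t{c.gc:.4f}\n")


def write_track_bedgraph(track: DensityTrack, reference: str, path: str
                         ) -> None:
    with open(path, "w") as fh:
        for s, d in zip(track.starts, track.density):
            fh.write(f"{reference}\t{s - 1}\t{s - 1 + track.window}\t{d:.4f}\n")
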
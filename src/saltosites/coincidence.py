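"""Coincidence statistics of integration positions.

If T transposition events fall independently and uniformly on a genome of
N positions, with R = T/N, the expected number of positions carrying two
coincident events is closely approximated (for R < 0.1) by

    E2 = T * R / 2

and higher coincidences follow the recurrence

    E_{i+1} = ln(1/(1 - R)) * E_i / (i + 1).

E_i is read as the expected number of positions with AT LEAST i events (the
balls-in-bins tail); the observed spectrum therefore reports both the
exactly-i and at-least-i counts so either comparison can be made.
Departures of the observed spectrum from this null -- a handful of
positions carrying many coincident events -- are what flags hotspots;
:func:`segment_fold_excess` turns an interval's event share into a fold
excess over the uniform expectation.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .model import SiteTable


@dataclass
class CoincidenceModel:
    """Closed-form expectations E_2 .. E_imax of the uniform null."""

    T: int
    N: int
    R: float
    expected: dict[int, float]

    def __getitem__(self, i: int) -> float:
        return self.expected[i]


@dataclass
class CoincidenceSpectrum:
    """Observed multiplicity spectrum of a site table.

    ``observed[i]`` is the number of positions carrying exactly i events
    (orientations summed); ``at_least[i]`` the cumulative variant.
    Conservation: sum(i * observed[i]) equals the table total.
    """

    observed: dict[int, int] = field(default_factory=dict)
    at_least: dict[int, int] = field(default_factory=dict)

    @property
    def total_events(self) -> int:
        return sum(i * n for i, n in self.observed.items())


def expected_spectrum(T: int, N: int, i_max: int = 5) -> CoincidenceModel:
    """Expected coincidence counts under the uniform random model.

    The approximation is valid for R = T/N below 0.1; larger R triggers a
    warning but the values are still computed.
    """
    if T <= 0 or N <= 0:
        raise ValueError("T and N must be positive")
    if i_max < 2:
        raise ValueError("i_max must be >= 2")
    R = T / N
    if R >= 0.1:
        warnings.warn(f"R = {R:.3g} >= 0.1: the closed-form approximation "
                      "is outside its validity range", stacklevel=2)
    expected = {2: T * R / 2}
    c = math.log(1.0 / (1.0 - R))
    for i in range(2, i_max):
        expected[i + 1] = c * expected[i] / (i + 1)
    return CoincidenceModel(T=T, N=N, R=R, expected=expected)


def observed_spectrum(table: SiteTable) -> CoincidenceSpectrum:
    """Multiplicity spectrum of a site table, orientations summed."""
    mult = Counter(table.position_totals().values())
    observed = dict(sorted(mult.items()))
    at_least: dict[int, int] = {}
    acc = 0
    for i in sorted(observed, reverse=True):
        acc += observed[i]
        at_least[i] = acc
    return CoincidenceSpectrum(observed=observed,
                               at_least=dict(sorted(at_least.items())))


def segment_fold_excess(table: SiteTable, interval: tuple[int, int],
                        T: int, N: int) -> tuple[float, float]:
    """(event_fraction, fold excess) of a 1-based inclusive interval.

    fold = (events_in_interval / T) / (interval_length / N); an interval
    with zero events reports (0, 0).
    """
    a, b = interval
    if b < a or a < 1 or b > table.length:
        raise ValueError(f"bad interval {interval}")
    totals = table.position_totals()
    in_events = sum(n for pos, n in totals.items() if a <= pos <= b)
    frac = in_events / T
    fold = frac / ((b - a + 1) / N)
    return frac, fold


def write_spectrum_tsv(spectrum: CoincidenceSpectrum, model: CoincidenceModel,
                       path: str) -> None:
    """TSV report: i, observed_exact, observed_at_least, expected."""
    imax = max([*spectrum.observed, *model.expected], default=1)
    with open(path, "w") as fh:
        fh.write("i\tobserved_exact\tobserved_at_least\texpected_at_least\n")
        for i in range(1, imax + 1):
            exp = model.expected.get(i)
            fh.write(f"{i}\t{spectrum.observed.get(i, 0)}\t"
                     f"{spectrum.at_least.get(i, 0)}\t"
                     f"{'' if exp is None else f'{exp:.6g}'}\n")
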
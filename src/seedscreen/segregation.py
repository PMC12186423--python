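"""Mendelian segregation statistics for transgenic seed counts.

A T1 plant hemizygous at k independent dominant T-DNA loci yields selfed T2
seed in which the expected marker-positive fraction is 1 - (1/4)^k: 3:1 for
a single locus, 15:1 for two.  Observed transgenic/wild-type counts are
tested against the single-locus 3:1 null with Pearson's chi-squared test
(two categories, one degree of freedom, no continuity correction); p-values
below alpha = 0.05 are taken to indicate multiple independently segregating
loci or transgene silencing, and such lines are rejected from single-locus
screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy import stats as _stats

from .errors import ChannelMismatchError, ParameterError

Call = Literal["single_locus_consistent", "rejected"]
Direction = Literal["excess_transgenic", "deficit_transgenic", "exact"]


@dataclass(frozen=True)
class SeedCounts:
    """Transgenic / wild-type tally for one line."""

    n_transgenic: int
    n_wildtype: int

    def __post_init__(self):
        if self.n_transgenic < 0 or self.n_wildtype < 0:
            raise ParameterError("seed counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_transgenic + self.n_wildtype

    @property
    def transgenic_fraction(self) -> float:
        if self.n_total == 0:
            raise ParameterError("no seeds counted")
        return self.n_transgenic / self.n_total


@dataclass(frozen=True)
class SegregationResult:
    """Chi-squared verdict for one line against a Mendelian null."""

    expected_fraction: float
    chi2_statistic: float
    p_value: float
    call: Call
    direction: Direction


def combine_counts(n_total_from_brightfield: int, n_marker: int) -> SeedCounts:
    """Merge the two channels: brightfield gives totals, marker channel transgenics.

    A marker count above the total signals mis-tuned thresholds on one of the
    channels and raises :class:`ChannelMismatchError`.
    """
    if n_total_from_brightfield < 0 or n_marker < 0:
        raise ParameterError("counts must be non-negative")
    if n_marker > n_total_from_brightfield:
        raise ChannelMismatchError(
            f"marker-channel count {n_marker} exceeds brightfield total "
            f"{n_total_from_brightfield}; re-tune the intensity thresholds "
            "(the fluorescent channel may be picking up background)"
        )
    return SeedCounts(
        n_transgenic=n_marker, n_wildtype=n_total_from_brightfield - n_marker
    )


def expected_transgenic_fraction(k_loci: int) -> float:
    """Expected marker-positive T2 fraction for k independent hemizygous loci.

    1 - (1/4)^k: 0.75 for one locus (3:1), 0.9375 for two (15:1).
    """
    if k_loci < 0:
        raise ParameterError("number of loci must be >= 0")
    return 1.0 - 0.25**k_loci


def classify_line(p_value: float, alpha: float = 0.05) -> Call:
    """Reject iff p < alpha (strict); p == alpha stays consistent."""
    if not 0.0 <= p_value <= 1.0:
        raise ParameterError("p-value outside [0, 1]")
    return "rejected" if p_value < alpha else "single_locus_consistent"


def chi_squared_segregation(
    counts: SeedCounts, expected_fraction: float = 0.75, alpha: float = 0.05
) -> SegregationResult:
    """Pearson chi-squared test of observed counts against a Mendelian null.

    Two categories with expectations ``(f*N, (1-f)*N)``, one degree of
    freedom, no continuity correction; the statistic is 0 (and p = 1) exactly
    when the observed fraction equals the expectation.  The ``direction``
    annotation distinguishes an excess of transgenic seeds (suggesting
    multiple loci, e.g. 15:1 for double insertions) from a deficit
    (suggesting transgene silencing).
    """
    if counts.n_total < 1:
        raise ParameterError("chi-squared test needs at least one seed")
    if not 0.0 < expected_fraction < 1.0:
        raise ParameterError("expected fraction must lie strictly in (0, 1)")
    n = counts.n_total
    expected = [expected_fraction * n, (1.0 - expected_fraction) * n]
    stat, p = _stats.chisquare(
        [counts.n_transgenic, counts.n_wildtype], f_exp=expected
    )
    delta = counts.n_transgenic - expected[0]
    direction: Direction = (
        "exact" if delta == 0 else
        "excess_transgenic" if delta > 0 else
        "deficit_transgenic"
    )
    return SegregationResult(
        expected_fraction=expected_fraction,
        chi2_statistic=float(stat),
        p_value=float(p),
        call=classify_line(float(p), alpha),
        direction=direction,
    )
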
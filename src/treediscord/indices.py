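"""Branch-level estimators of incomplete lineage sorting and introgression.

Around an internal branch of a rooted species tree, gene trees induce three
possible (unrooted quartet, or rooted triplet) topologies whose frequencies
are denoted ``q1 >= q2 >= q3`` (``q1 + q2 + q3 = 1``).  Under the
multispecies coalescent the two minor topologies are equally frequent, each
with probability ``e^(-t)/3`` where ``t`` is the branch length in coalescent
units; asymmetric gene flow inflates one minor topology above the other.

This module turns observed ``(q1, q2, q3)`` into two percentages:

* the **ILS index** ``L = e^(-t)``, the strength of incomplete lineage
  sorting (100% at a zero-length branch, <1% once ``t > 4.6``), and
* the **IH index** ``H``, the estimated proportion of the genome inherited
  from the minor parental lineage (the inheritance probability gamma),
  bounded by 50%.

A one-degree-of-freedom chi-square test of ``q2 = q3`` (on counts) decides
whether the discordance is symmetric (pure ILS) or carries an introgression
signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

from scipy import stats

__all__ = [
    "TopologyFrequencies",
    "IndexResult",
    "Resolution",
    "ResolutionCall",
    "DEFAULT_THRESHOLDS",
    "STRICT_THRESHOLDS",
    "canonicalize",
    "symmetry_test",
    "estimate_indices",
    "expected_frequencies",
    "ils_index_to_time",
    "time_to_ils_index",
    "classify_node",
    "format_percent",
]

_ONE_THIRD = 1.0 / 3.0


@dataclass(frozen=True)
class TopologyFrequencies:
    """Canonical topology frequencies at one internal branch.

    ``q1 >= q2 >= q3`` sum to one; ``n`` is the effective number of gene
    trees behind them (may be fractional, e.g. ASTRAL's EN; 0 = unknown).
    ``species_rank`` records where the species-tree topology landed after
    sorting (0 = it is the major topology; >0 = demoted by the data).
    """

    q1: float
    q2: float
    q3: float
    n: float = 0.0
    species_rank: int = 0

    def __post_init__(self) -> None:
        qs = (self.q1, self.q2, self.q3)
        if any(q < -1e-9 or q > 1.0 + 1e-9 for q in qs):
            raise ValueError(f"frequencies out of [0, 1]: {qs}")
        if abs(sum(qs) - 1.0) > 1e-6:
            raise ValueError(f"frequencies must sum to 1: {qs}")
        if not (self.q1 >= self.q2 - 1e-12 and self.q2 >= self.q3 - 1e-12):
            raise ValueError(f"frequencies not sorted descending: {qs}")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.species_rank not in (0, 1, 2):
            raise ValueError("species_rank must be 0, 1 or 2")

    @property
    def demoted(self) -> bool:
        """True when the species-tree topology is not the most frequent one."""
        return self.species_rank != 0

    def as_counts(self) -> Tuple[float, float, float]:
        return (self.q1 * self.n, self.q2 * self.n, self.q3 * self.n)


@dataclass(frozen=True)
class IndexResult:
    """ILS/IH indices (percent) plus the symmetry test behind them."""

    ils_index: float
    ih_index: float
    ils_explained: float
    ih_explained: float
    p_value: float
    chi2_stat: float
    n_effective: float
    significant: bool
    alpha: float
    tested: bool = True

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.ils_index <= 100.0 + 1e-9):
            raise ValueError("ILS index out of [0, 100]")
        if not (-1e-9 <= self.ih_index <= 50.0 + 1e-9):
            raise ValueError("IH index out of [0, 50]")
        if not self.significant and (self.ih_index != 0 or self.ih_explained != 0):
            raise ValueError("non-significant branches must have IH = 0")
        if self.ils_explained + self.ih_explained > 100.0 + 1e-6:
            raise ValueError("explained fractions exceed 100%")


class Resolution(str, Enum):
    WELL_RESOLVED = "well_resolved"
    ILS_CONFLICT = "ils_conflict"
    IH_CONFLICT = "ih_conflict"
    ILS_AND_IH_CONFLICT = "ils_and_ih_conflict"


DEFAULT_THRESHOLDS = (50.0, 10.0)
STRICT_THRESHOLDS = (30.0, 5.0)


@dataclass(frozen=True)
class ResolutionCall:
    category: Resolution
    strict: bool
    ils_threshold: float
    ih_threshold: float


def canonicalize(raw: Sequence[float], n: Optional[float] = None) -> TopologyFrequencies:
    """Sort three raw topology frequencies (or counts) into canonical form.

    Fractions (sum within 1e-3 of 1) are renormalized; anything else is
    treated as raw counts, normalized by their sum, which also becomes ``n``
    unless ``n`` is given explicitly.  Slot 0 of the input is taken to be
    the species-tree topology; its position after the (stable, descending)
    sort is recorded in ``species_rank``.
    """
    values = [float(v) for v in raw]
    if len(values) != 3:
        raise ValueError("expected exactly three frequencies")
    if any(v < 0 for v in values):
        raise ValueError(f"negative frequency: {values}")
    total = sum(values)
    if total == 0:
        raise ValueError("no quartet information")
    if n is None:
        n_eff = 0.0 if abs(total - 1.0) <= 1e-3 else total
    else:
        n_eff = float(n)
    order = sorted(range(3), key=lambda i: -values[i])  # stable: ties keep input order
    q = [values[i] / total for i in order]
    return TopologyFrequencies(q[0], q[1], q[2], n=n_eff, species_rank=order.index(0))


def symmetry_test(count2: float, count3: float) -> Tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) of ``q2 == q3``.

    Tests whether the two minor-topology counts are compatible with the
    multispecies coalescent's prediction of equal frequency.  Empty minor
    classes are trivially symmetric: ``(0, 1.0)``.
    """
    if count2 < 0 or count3 < 0:
        raise ValueError("counts must be non-negative")
    total = count2 + count3
    if total == 0:
        return 0.0, 1.0
    stat = (count2 - count3) ** 2 / total
    return float(stat), float(stats.chi2.sf(stat, df=1))


def estimate_indices(freqs: TopologyFrequencies, alpha: float = 0.05) -> IndexResult:
    """Estimate the ILS and IH indices (percent) for one branch.

    If the symmetry test is not significant (``P > alpha``) the discordance
    is attributed entirely to ILS: ``L = ((q2+q3)/2)/(1/3)`` and
    ``ILS-e = q2+q3``.  Otherwise the symmetric part ``q3`` is attributed
    to ILS (``L = q3/(1/3)``, ``ILS-e = 2*q3``) and the excess of ``q2``
    to gene flow: ``IH-e = q2-q3`` and
    ``H = (q2-q3) / ((q1-q3) + (q2-q3))``.

    With ``n = 0`` the test cannot be run: indices come from the
    proportions alone, ``tested`` is False, ``p_value`` is NaN and the IH
    index is forced to 0.
    """
    q1, q2, q3 = freqs.q1, freqs.q2, freqs.q3
    tested = freqs.n > 0
    if tested:
        chi2_stat, p_value = symmetry_test(q2 * freqs.n, q3 * freqs.n)
        significant = p_value <= alpha
    else:
        chi2_stat, p_value = 0.0, math.nan
        significant = False

    if significant and q2 > q3:
        ils = q3 / _ONE_THIRD
        ils_e = 2.0 * q3
        ih_e = q2 - q3
        denom = (q1 - q3) + (q2 - q3)
        ih = (q2 - q3) / denom if denom > 0 else 0.0
    else:
        # symmetric discordance (incl. an exact q2 == q3 tie): pure ILS
        ils = ((q2 + q3) / 2.0) / _ONE_THIRD
        ils_e = q2 + q3
        ih = 0.0
        ih_e = 0.0
        significant = False  # a tie or zero denominator cannot carry an IH signal
    ils = min(max(ils, 0.0), 1.0)  # q3 > 1/3 can only arise from un-canonical noise

    return IndexResult(
        ils_index=100.0 * ils,
        ih_index=100.0 * ih,
        ils_explained=100.0 * ils_e,
        ih_explained=100.0 * ih_e,
        p_value=p_value,
        chi2_stat=chi2_stat,
        n_effective=freqs.n,
        significant=significant,
        alpha=alpha,
        tested=tested,
    )


def expected_frequencies(L: float, H: float, n: float = 0.0) -> TopologyFrequencies:
    """Expected (q1, q2, q3) under given ILS index ``L`` and IH index ``H``.

    ``q3 = L/3``; the non-ILS fraction ``1-L`` splits ``H : (1-H)`` between
    the introgressed minor topology and the species-tree topology:
    ``q2 = L/3 + H*(1-L)``, ``q1 = L/3 + (1-H)*(1-L)``.
    """
    if not 0.0 <= L <= 1.0:
        raise ValueError(f"ILS index must be in [0, 1], got {L}")
    if not 0.0 <= H <= 0.5:
        raise ValueError(f"IH index must be in [0, 0.5], got {H}")
    q3 = L / 3.0
    q2 = q3 + H * (1.0 - L)
    q1 = q3 + (1.0 - H) * (1.0 - L)
    return TopologyFrequencies(q1, q2, q3, n=n)


def ils_index_to_time(L: float, ne: Optional[float] = None) -> float:
    """Coalescent time ``t = -ln(L)`` for an ILS index ``L`` (fraction).

    With ``ne`` given, returns generations ``T = -ln(L) * Ne``.  ``L = 0``
    corresponds to an unbounded (infinite) branch and returns ``inf``.
    """
    if not 0.0 <= L <= 1.0:
        raise ValueError(f"ILS index must be in [0, 1], got {L}")
    t = math.inf if L == 0 else -math.log(L)
    return t * ne if ne is not None else t


def time_to_ils_index(t: float, ne: Optional[float] = None) -> float:
    """ILS index ``e^(-t)`` for a branch of ``t`` coalescent units.

    With ``ne`` given, ``t`` is interpreted as generations and divided by
    ``Ne`` first.  ``t = 0`` gives 1 (maximal ILS).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    u = t / ne if ne is not None else t
    return math.exp(-u)


def classify_node(result: IndexResult, strict: bool = False) -> ResolutionCall:
    """Call a branch well resolved or in ILS and/or IH conflict.

    Default thresholds: ILS index < 50% and IH index < 10%; strict:
    < 30% and < 5%.
    """
    ils_thr, ih_thr = STRICT_THRESHOLDS if strict else DEFAULT_THRESHOLDS
    high_ils = result.ils_index >= ils_thr
    high_ih = result.ih_index >= ih_thr
    if high_ils and high_ih:
        category = Resolution.ILS_AND_IH_CONFLICT
    elif high_ils:
        category = Resolution.ILS_CONFLICT
    elif high_ih:
        category = Resolution.IH_CONFLICT
    else:
        category = Resolution.WELL_RESOLVED
    return ResolutionCall(category=category, strict=strict,
                          ils_threshold=ils_thr, ih_threshold=ih_thr)


def format_percent(x: float) -> str:
    """Percentages are reported to one decimal place everywhere."""
    return f"{x:.1f}"
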
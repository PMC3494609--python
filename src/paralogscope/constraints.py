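"""Saturation filtering, selection classification, and group statistics.

Operates on :class:`~paralogscope.io.GenePairRecord` lists: Ks-based
saturation filtering, omega-threshold selection classes, replicon-relation
grouping, gene-length binning, and the distributional tests used to compare
in-paralogs with out-paralogs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import PLASMIDS, REPLICONS, GenePairRecord

__all__ = [
    "SelectionClass",
    "RepliconRelation",
    "GroupSummary",
    "TestResult",
    "KS_CUTOFF",
    "OMEGA_PURIFYING_MAX",
    "OMEGA_POSITIVE_MIN",
    "filter_unsaturated",
    "classify_selection",
    "replicon_relation",
    "summarize_omega_by_group",
    "length_bin_frequencies",
    "ks_two_sample",
    "rate_divergence_correlation",
    "is_recent_pair",
]

#: Ks saturation cutoff: pairs at or above this are excluded.
KS_CUTOFF = 1.1
#: omega <= this => purifying; omega >= OMEGA_POSITIVE_MIN => positive.
OMEGA_PURIFYING_MAX = 0.3
OMEGA_POSITIVE_MIN = 3.0

SelectionClass = str  # {"purifying", "neutral", "positive", "undefined"}
RepliconRelation = str


@dataclass(frozen=True)
class GroupSummary:
    group: RepliconRelation
    n: int
    mean_omega: float
    sd_omega: Optional[float]  # None when n = 1


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float


def filter_unsaturated(
    pairs: Sequence[GenePairRecord], ks_max: float = KS_CUTOFF
) -> list[GenePairRecord]:
    """Keep pairs with finite Ks strictly below ``ks_max``.

    Saturated or missing-Ks pairs are removed; input order is preserved.
    """
    return [
        p
        for p in pairs
        if not p.saturated and p.ks is not None and p.ks < ks_max
    ]


def classify_selection(omega: Optional[float]) -> SelectionClass:
    """Map omega to a selection class.

    purifying iff omega <= 0.3; neutral iff 0.3 < omega < 3; positive iff
    omega >= 3; ``None`` maps to "undefined".
    """
    if omega is None:
        return "undefined"
    if omega < 0:
        raise ValueError(f"omega must be nonnegative, got {omega}")
    if omega <= OMEGA_PURIFYING_MAX:
        return "purifying"
    if omega < OMEGA_POSITIVE_MIN:
        return "neutral"
    return "positive"


def replicon_relation(r1: str, r2: str) -> RepliconRelation:
    """Symmetric replicon relation of a gene pair's two copies."""
    for r in (r1, r2):
        if r not in REPLICONS:
            raise ValueError(f"unknown replicon {r!r}")
    pair = frozenset((r1, r2))
    if pair == {"CI"}:
        return "within-CI"
    if pair == {"CII"}:
        return "within-CII"
    if pair == {"CI", "CII"}:
        return "between-CI-CII"
    if pair <= PLASMIDS:
        return "within-plasmids"
    return "chromosome-plasmid"


_RELATION_ORDER = [
    "within-CI",
    "within-CII",
    "between-CI-CII",
    "within-plasmids",
    "chromosome-plasmid",
]


def summarize_omega_by_group(pairs: Sequence[GenePairRecord]) -> list[GroupSummary]:
    """Mean and sample sd (n-1) of omega per nonempty replicon relation."""
    groups: dict[str, list[float]] = {}
    for p in pairs:
        if p.omega is None:
            raise ValueError(
                f"pair {p.gene1_id}/{p.gene2_id} has no omega; filter first"
            )
        groups.setdefault(replicon_relation(p.replicon1, p.replicon2), []).append(
            p.omega
        )
    summaries = []
    for relation in _RELATION_ORDER:
        if relation not in groups:
            continue
        values = groups[relation]
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
        summaries.append(GroupSummary(relation, len(values), float(np.mean(values)), sd))
    return summaries


def length_bin_frequencies(
    pairs: Sequence[GenePairRecord], bin_width: int = 100
) -> dict[str, dict[str, float]]:
    """Relative length-bin frequencies per paralog class.

    Bins follow the printed convention [100k+1, 100(k+1)]; frequencies are
    normalized within each class. Classes with no pairs emit no bins.
    """
    counts: dict[str, dict[int, int]] = {}
    for p in pairs:
        if p.length is None:
            continue
        if p.length <= 0:
            raise ValueError(
                f"pair {p.gene1_id}/{p.gene2_id}: nonpositive length {p.length}"
            )
        b = math.ceil(p.length / bin_width)
        counts.setdefault(p.paralog_class, {})[b] = (
            counts.get(p.paralog_class, {}).get(b, 0) + 1
        )
    out: dict[str, dict[str, float]] = {}
    for cls, bins in counts.items():
        total = sum(bins.values())
        out[cls] = {
            f"{bin_width * (b - 1) + 1}-{bin_width * b}": n / total
            for b, n in sorted(bins.items())
        }
    return out


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample Kolmogorov–Smirnov test (asymptotic p)."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue))


def rate_divergence_correlation(
    pairs: Sequence[GenePairRecord], rate_field: str
) -> tuple[float, float]:
    """Pearson correlation of ka or ks against amino-acid divergence.

    p-value from the t-transform of R with n - 2 degrees of freedom.
    """
    if rate_field not in ("ka", "ks"):
        raise ValueError("rate_field must be 'ka' or 'ks'")
    xy = [
        (getattr(p, rate_field), p.divergence_pct)
        for p in pairs
        if getattr(p, rate_field) is not None and p.divergence_pct is not None
    ]
    if len(xy) < 3:
        raise ValueError(f"need >= 3 pairs with {rate_field} and divergence")
    x, y = zip(*xy)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) sample")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def is_recent_pair(pair: GenePairRecord, ks_max: float = KS_CUTOFF,
                   divergence_max: float = 50.0) -> bool:
    """Recent duplication: Ks below cutoff and divergence below 50%."""
    return (
        pair.ks is not None
        and pair.ks < ks_max
        and pair.divergence_pct is not None
        and pair.divergence_pct < divergence_max
    )
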
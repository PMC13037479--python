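"""Depth-normalized viral progeny ratio per cluster, with bootstrap uncertainty.

The ratio compares per-particle recovery rates of a cluster in the
BONCAT-positive (newly produced) and BONCAT-negative (pre-existing)
viral sorts:

    R = (n_pos / D_pos) / (n_pos / D_pos + n_neg / D_neg)

where n are member counts and D the sorted particle depths. Dividing by
depth removes the arbitrary difference in how many particles each pool
received; with equal depths R reduces to the raw proportion
n_pos / (n_pos + n_neg), and it is invariant to rescaling both depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedRatioError
from .formats_io import round_half_up
from .protein_network import ViralCluster
from .synthetic_community import SortedLibrary

REASON_OK = ""
REASON_NO_VIRAL_MEMBERS = "no viral-fraction members"
REASON_NO_NEGATIVE_LIBRARY = "no negative-depth library"


def progeny_ratio(n_pos: int, n_neg: int, D_pos: float, D_neg: float) -> float:
    """Rate-normalized fraction of newly produced members in a cluster."""
    if D_pos <= 0 or D_neg <= 0:
        raise DataError(f"sorted depths must be positive, got D_pos={D_pos}, D_neg={D_neg}")
    if n_pos < 0 or n_neg < 0:
        raise DataError(f"member counts must be non-negative, got {n_pos}, {n_neg}")
    if n_pos + n_neg == 0:
        raise UndefinedRatioError("cluster has no members from either viral fraction")
    rate_pos = n_pos / D_pos
    rate_neg = n_neg / D_neg
    return rate_pos / (rate_pos + rate_neg)


def ratio_percent(ratio: float) -> float:
    """Percent on the printed scale: half-up to 2 decimals (0.78947 -> 78.95)."""
    return round_half_up(100.0 * ratio, 2)


def bootstrap_ci(
    n_pos: int,
    n_neg: int,
    D_pos: float,
    D_neg: float,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the progeny ratio.

    Member labels are resampled with replacement; because the ratio
    depends on the labels only through their counts, each resample is an
    exact binomial draw of ``n_pos*`` out of ``n_total``.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be unstable", stacklevel=2)
    n_total = n_pos + n_neg
    if n_total < 1:
        raise UndefinedRatioError("cannot bootstrap an empty cluster")
    rng = np.random.default_rng(seed)
    boot_pos = rng.binomial(n_total, n_pos / n_total, size=n_boot)
    rate_pos = boot_pos / D_pos
    rate_neg = (n_total - boot_pos) / D_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = rate_pos / (rate_pos + rate_neg)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        r = progeny_ratio(n_pos, n_neg, D_pos, D_neg)
        return r, r
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class RatioResult:
    """Per-cluster turnover statistic and its provenance."""

    cluster_id: str
    n_pos: int = 0
    n_neg: int = 0
    D_pos: float = 0.0
    D_neg: float = 0.0
    ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    reason: str = REASON_OK

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def ratio_pct(self) -> float | None:
        return None if self.ratio is None else ratio_percent(self.ratio)


def cluster_ratios(
    clusters: Iterable[ViralCluster],
    libraries: Sequence[SortedLibrary],
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    pool_sites: bool = False,
) -> list[RatioResult]:
    """Progeny ratio for every cluster, pooling same-sign viral libraries.

    Only members from viral-fraction libraries enter the ratio
    (cell-fraction members are excluded). A site whose roster lacks a
    negative viral sort contributes members to clusters but not to
    ratios, unless ``pool_sites`` pools rates across all sites. Pooled
    rates use ``sum(n_i) / sum(D_i)`` per sign. Clusters with no
    countable members are reported with a reason code instead of a
    ratio. Unknown member libraries raise :class:`DataError` upstream
    when counts are built; here every count key must be in ``libraries``.
    """
    lib_by_id = {lib.library_id: lib for lib in libraries}
    sites_with_neg = {
        lib.site for lib in libraries if lib.fraction == "pre_existing_viruses"
    }

    def eligible(lib: SortedLibrary) -> bool:
        if not lib.is_viral_fraction:
            return False
        return pool_sites or lib.site in sites_with_neg

    pos_libs = [l for l in libraries if eligible(l) and l.fraction == "viral_progeny"]
    neg_libs = [l for l in libraries if eligible(l) and l.fraction == "pre_existing_viruses"]
    D_pos = float(sum(l.sorted_depth for l in pos_libs))
    D_neg = float(sum(l.sorted_depth for l in neg_libs))

    results: list[RatioResult] = []
    for cluster in clusters:
        n_pos = n_neg = 0
        any_viral_member = False
        for lib_id, count in cluster.per_library_counts.items():
            if lib_id not in lib_by_id:
                raise DataError(
                    f"cluster {cluster.cluster_id!r} counts unknown library {lib_id!r}"
                )
            lib = lib_by_id[lib_id]
            if not lib.is_viral_fraction:
                continue
            any_viral_member = any_viral_member or count > 0
            if not eligible(lib):
                continue
            if lib.fraction == "viral_progeny":
                n_pos += count
            else:
                n_neg += count
        result = RatioResult(cluster_id=cluster.cluster_id, n_pos=n_pos, n_neg=n_neg,
                             D_pos=D_pos, D_neg=D_neg)
        if not any_viral_member:
            result.reason = REASON_NO_VIRAL_MEMBERS
        elif n_pos + n_neg == 0 or D_pos == 0 or D_neg == 0:
            result.reason = REASON_NO_NEGATIVE_LIBRARY
        else:
            result.ratio = progeny_ratio(n_pos, n_neg, D_pos, D_neg)
            result.ci_low, result.ci_high = bootstrap_ci(
                n_pos, n_neg, D_pos, D_neg, n_boot=n_boot, ci_level=ci_level, seed=seed
            )
        results.append(result)
    return results


def ratios_to_frame(results: Iterable[RatioResult]) -> pd.DataFrame:
    """Tabular report: one row per cluster, percentages at printed precision."""
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "ratio_pct": r.ratio_pct,
                "ci_low_pct": None if r.ci_low is None else round_half_up(100 * r.ci_low, 2),
                "ci_high_pct": None if r.ci_high is None else round_half_up(100 * r.ci_high, 2),
                "n_total": r.n_total,
                "reason": r.reason,
            }
            for r in results
        ]
    )


def enumerate_matching_splits(
    n_total: int, printed_pct: float, D_pos: float, D_neg: float
) -> list[tuple[int, int]]:
    """All integer splits (n_pos, n_neg) of ``n_total`` whose ratio prints as ``printed_pct``.

    This is the enumeration oracle used to recover the member splits
    behind published per-cluster percentages.
    """
    matches = []
    for n_pos in range(n_total + 1):
        n_neg = n_total - n_pos
        if n_pos + n_neg == 0:
            continue
        r = progeny_ratio(n_pos, n_neg, D_pos, D_neg)
        if ratio_percent(r) == printed_pct:
            matches.append((n_pos, n_neg))
    return matches
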
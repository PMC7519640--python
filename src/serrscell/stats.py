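"""Group-comparison statistics for cell areas.

Pairwise two-sided Mann-Whitney U tests between the phenotype area
distributions, with Holm's step-down correction across the pairs.  The exact
null distribution is used for small tie-free samples; otherwise the normal
approximation with tie-corrected variance and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Largest combined sample size for which the exact permutation null is used.
_EXACT_N_MAX = 12


@dataclass(frozen=True)
class RankTestResult:
    pair: tuple[str, str]
    u: float
    p: float
    method: str  # "exact" | "normal-approximation"


def mann_whitney_u(x, y, pair: tuple[str, str] = ("x", "y")) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact p-value by rank enumeration when n1 + n2 <= 12 and there are no
    ties; otherwise normal approximation with tie correction and continuity
    correction.  U is reported for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= _EXACT_N_MAX and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal-approximation"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return RankTestResult(pair=pair, u=float(res.statistic), p=float(res.pvalue), method=method)


def holm_adjust(pvalues) -> list[float]:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="holm")[1]]


def pairwise_area_test(areas_by_class: dict[str, "np.ndarray | list"]) -> pd.DataFrame:
    """All pairwise Mann-Whitney tests on per-class areas, Holm-adjusted.

    Returns a table with columns group_a, group_b, u, p_raw, p_holm, method.
    """
    names = sorted(areas_by_class)
    if len(names) < 2:
        raise ValueError("need at least two classes")
    for name in names:
        if len(areas_by_class[name]) < 2:
            raise ValueError(f"class {name} needs >= 2 cells")
    results = [
        mann_whitney_u(areas_by_class[a], areas_by_class[b], pair=(a, b))
        for a, b in combinations(names, 2)
    ]
    adjusted = holm_adjust([r.p for r in results])
    return pd.DataFrame(
        {
            "group_a": [r.pair[0] for r in results],
            "group_b": [r.pair[1] for r in results],
            "u": [r.u for r in results],
            "p_raw": [r.p for r in results],
            "p_holm": adjusted,
            "method": [r.method for r in results],
        }
    )
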
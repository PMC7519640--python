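"""Attribution-threshold calibration and efficiency-corrected enumeration.

Calibration works by "theoretical mixing": cells are resampled without
replacement from three single-phenotype reference pools so that the true
composition is known exactly; sweeping the attribution threshold and
comparing recovered tumor counts with the truth selects the smallest
threshold that recovers the spiked tumor cells.  Enumeration then counts, in
a real (or simulated) mixed sample, the cells whose dominant class is a
tumor phenotype with attribution at or above the calibrated threshold,
normalizes per ml, attaches a bootstrap uncertainty, and reports the
capture-efficiency-corrected estimate of the spiked concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CLASS_ORDER, Attribution, FeatureRow, TrainedForest, oob_attributions, predict_attributions

TUMOR_CLASSES = ("LNCaP", "U251")

#: Uninformative attribution level: a uniform three-class vote.
UNCERTAIN_ATTRIBUTION_PCT = 100.0 / 3.0


@dataclass(frozen=True)
class ReferencePools:
    """Labelled feature rows from three single-phenotype reference samples."""

    pools: dict[str, tuple[FeatureRow, ...]]

    def __post_init__(self) -> None:
        for name, rows in self.pools.items():
            if name not in CLASS_ORDER:
                raise ValueError(f"unknown pool class {name!r}")
            if any(r.label != name for r in rows):
                raise ValueError(f"pool {name} contains rows with a different label")

    def __getitem__(self, name: str) -> tuple[FeatureRow, ...]:
        return self.pools[name]

    def all_rows(self) -> list[FeatureRow]:
        return [r for name in CLASS_ORDER if name in self.pools for r in self.pools[name]]


@dataclass
class TheoreticalMix:
    rows: list[FeatureRow]
    composition: dict[str, int]
    seed: int


@dataclass
class ThresholdCalibration:
    grid_pct: np.ndarray
    table: pd.DataFrame  # columns: tau_pct, n_lncap, n_u251, true_lncap, true_u251
    tau_attr_pct: float
    matched_within_tolerance: bool


@dataclass
class EnumerationResult:
    identified_per_ml: dict[str, float]
    uncertainty_per_ml: dict[str, float]
    interval_68_per_ml: dict[str, tuple[float, float]]
    corrected_per_ml: dict[str, float]
    corrected_uncertainty_per_ml: dict[str, float]
    tau_attr_pct: float
    efficiency: float
    volume_ml: float
    n_cells_gated: int = 0


def make_theoretical_mix(
    pools: ReferencePools, composition: dict[str, int], seed: int = 0
) -> TheoreticalMix:
    """Sample a known composition without replacement from the reference pools."""
    rng = np.random.default_rng(seed)
    rows: list[FeatureRow] = []
    for name in CLASS_ORDER:
        want = int(composition.get(name, 0))
        if want == 0:
            continue
        pool = pools[name]
        if want > len(pool):
            raise ValueError(f"requested {want} {name} cells but the pool holds {len(pool)}")
        idx = rng.choice(len(pool), size=want, replace=False)
        rows.extend(pool[i] for i in idx)
    return TheoreticalMix(rows=rows, composition={k: int(composition.get(k, 0)) for k in CLASS_ORDER}, seed=seed)


def threshold_sweep(attributions: list[Attribution], grid_pct: np.ndarray) -> pd.DataFrame:
    """Tumor-cell counts recovered at each attribution threshold (inclusive).

    Counts are non-increasing in the threshold by construction.
    """
    recs = []
    for tau in grid_pct:
        row = {"tau_pct": float(tau)}
        for cls, col in (("LNCaP", "n_lncap"), ("U251", "n_u251")):
            row[col] = sum(1 for a in attributions if a.dominant == cls and a.attribution_pct >= tau)
        recs.append(row)
    return pd.DataFrame(recs)


def attribution_histogram(attributions: list[Attribution], bin_width_pct: float = 5.0) -> pd.DataFrame:
    """Cells per attribution-percent bin and dominant class (identified-cell
    counts as a function of the attribution percentage)."""
    edges = np.arange(UNCERTAIN_ATTRIBUTION_PCT, 100.0 + bin_width_pct, bin_width_pct)
    recs = []
    for cls in CLASS_ORDER:
        vals = [a.attribution_pct for a in attributions if a.dominant == cls]
        hist, _ = np.histogram(vals, bins=edges)
        for lo, hi, n in zip(edges[:-1], edges[1:], hist):
            recs.append({"class": cls, "bin_low_pct": float(lo), "bin_high_pct": float(hi), "n_cells": int(n)})
    return pd.DataFrame(recs)


def select_threshold(
    per_mix_attributions: list[list[Attribution]],
    truths: list[dict[str, int]],
    grid_pct: np.ndarray,
    tolerance: int = 2,
) -> ThresholdCalibration:
    """Pick the attribution threshold from per-mix attribution tables.

    The chosen threshold is the smallest grid value at which the recovered
    LNCaP and U251 counts match the known composition within ``tolerance``
    cells in every mix; if no value matches, the one minimizing the summed
    absolute count error (ties to the smallest) is chosen.
    """
    grid_pct = np.asarray(grid_pct, dtype=float)
    if grid_pct.size == 0:
        raise ValueError("threshold grid is empty")
    if grid_pct.min() <= UNCERTAIN_ATTRIBUTION_PCT or grid_pct.max() > 100.0:
        raise ValueError("threshold grid must lie in (33.3, 100]")
    if not per_mix_attributions:
        raise ValueError("at least one theoretical mix is required")

    tables = []
    for attrs, truth in zip(per_mix_attributions, truths):
        t = threshold_sweep(attrs, grid_pct)
        t["true_lncap"] = int(truth.get("LNCaP", 0))
        t["true_u251"] = int(truth.get("U251", 0))
        tables.append(t)

    total_err = np.zeros(grid_pct.size)
    all_match = np.ones(grid_pct.size, dtype=bool)
    for t in tables:
        e_l = (t["n_lncap"] - t["true_lncap"]).abs().to_numpy()
        e_u = (t["n_u251"] - t["true_u251"]).abs().to_numpy()
        total_err += e_l + e_u
        all_match &= (e_l <= tolerance) & (e_u <= tolerance)

    if all_match.any():
        k = int(np.flatnonzero(all_match)[0])
        matched = True
    else:
        k = int(np.argmin(total_err))  # argmin takes the smallest tau on ties
        matched = False

    summary = tables[0].copy()
    for t in tables[1:]:
        summary[["n_lncap", "n_u251", "true_lncap", "true_u251"]] += t[
            ["n_lncap", "n_u251", "true_lncap", "true_u251"]
        ]
    return ThresholdCalibration(
        grid_pct=grid_pct,
        table=summary,
        tau_attr_pct=float(grid_pct[k]),
        matched_within_tolerance=matched,
    )


def calibrate_threshold(
    forest: TrainedForest,
    mixes: list[TheoreticalMix],
    grid_pct: np.ndarray | None = None,
    tolerance: int = 2,
    use_oob: bool = True,
) -> ThresholdCalibration:
    """Select the attribution threshold from theoretical mixes.

    Mix cells drawn from the training pools are attributed with out-of-bag
    votes (``use_oob``); the selection rule is :func:`select_threshold`.
    """
    if grid_pct is None:
        grid_pct = np.arange(35.0, 96.0, 5.0)
    if not mixes:
        raise ValueError("at least one theoretical mix is required")
    attr_fn = oob_attributions if use_oob else predict_attributions
    per_mix = [attr_fn(forest, m.rows) for m in mixes]
    return select_threshold(per_mix, [m.composition for m in mixes], grid_pct, tolerance)


def _count_identified(attributions: list[Attribution], tau_attr_pct: float) -> dict[str, int]:
    out = {}
    for cls in CLASS_ORDER:
        out[cls] = sum(
            1 for a in attributions if a.dominant == cls and a.attribution_pct >= tau_attr_pct
        )
    return out


def enumerate_cells(
    attributions: list[Attribution],
    tau_attr_pct: float,
    volume_ml: float,
    efficiency: float = 0.84,
    n_boot: int = 1000,
    seed: int = 0,
) -> EnumerationResult:
    """Count identified cells per class per ml and attach uncertainties.

    A cell is identified as class c when its dominant class is c and its
    attribution percent is at or above the threshold (inclusive).  The
    uncertainty is the standard deviation over nonparametric bootstrap
    resamples of the cell list; a central 68% percentile interval is also
    reported.  The efficiency-corrected estimates divide by the
    capture-and-fixing efficiency; raw identified counts are never silently
    replaced by corrected ones.
    """
    if volume_ml <= 0:
        raise ValueError("sample volume must be > 0")
    if not UNCERTAIN_ATTRIBUTION_PCT < tau_attr_pct <= 100.0:
        raise ValueError("tau_attr_pct must be in (33.3, 100]")
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")

    counts = _count_identified(attributions, tau_attr_pct)
    rng = np.random.default_rng(seed)
    n = len(attributions)
    boot = {cls: np.zeros(n_boot) for cls in CLASS_ORDER}
    if n > 0:
        dominant = np.array([a.dominant for a in attributions])
        pct = np.array([a.attribution_pct for a in attributions])
        hit = {cls: (dominant == cls) & (pct >= tau_attr_pct) for cls in CLASS_ORDER}
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            for cls in CLASS_ORDER:
                boot[cls][b] = hit[cls][idx].sum()

    identified = {c: counts[c] / volume_ml for c in CLASS_ORDER}
    uncertainty = {c: float(boot[c].std(ddof=1)) / volume_ml if n_boot > 1 else 0.0 for c in CLASS_ORDER}
    interval = {
        c: (
            float(np.percentile(boot[c], 16.0)) / volume_ml,
            float(np.percentile(boot[c], 84.0)) / volume_ml,
        )
        for c in CLASS_ORDER
    }
    return EnumerationResult(
        identified_per_ml=identified,
        uncertainty_per_ml=uncertainty,
        interval_68_per_ml=interval,
        corrected_per_ml={c: correct_for_efficiency(identified[c], efficiency) for c in CLASS_ORDER},
        corrected_uncertainty_per_ml={c: uncertainty[c] / efficiency for c in CLASS_ORDER},
        tau_attr_pct=tau_attr_pct,
        efficiency=efficiency,
        volume_ml=volume_ml,
        n_cells_gated=len(attributions),
    )


def expected_fixed(spiked_per_ml: float, efficiency: float) -> int:
    """Expected captured-and-fixed count: round(spiked x efficiency)."""
    if spiked_per_ml < 0:
        raise ValueError("spiked count must be >= 0")
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    return int(np.floor(spiked_per_ml * efficiency + 0.5))


def correct_for_efficiency(identified: float, efficiency: float) -> float:
    """Estimate the spiked concentration from the identified count."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    return identified / efficiency
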
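"""End-to-end pipeline: simulate -> detect -> score -> gate -> attribute ->
calibrate -> enumerate.

``run_pipeline`` orchestrates the whole per-cell analysis on a synthetic
spiked-sample experiment: reference pools from single-phenotype samples
train the forest and calibrate the attribution threshold by theoretical
mixing; the mixed sample is rendered to a chamber image, cells are detected
morphologically, scored against the reporter references, size-gated and
attributed; tumor cells are enumerated per ml with bootstrap uncertainty and
the capture-efficiency correction.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import (
    EnumerationResult,
    ReferencePools,
    ThresholdCalibration,
    attribution_histogram,
    calibrate_threshold,
    enumerate_cells,
    expected_fixed,
    make_theoretical_mix,
    threshold_sweep,
)
from .classify import CLASS_ORDER, FeatureRow, ForestConfig, TrainedForest, predict_attributions, size_gate, train_forest
from .config import RunConfig
from .imaging import ChamberImage, binarize, detect_cells, match_to_truth
from .scoring import ReferenceLibrary, call_positivity, score_cell
from .spectra import SpectralGrid
from .stats import pairwise_area_test
from .synthetic import (
    DEFAULT_CLASS_MODELS,
    ExperimentSpec,
    NoiseModel,
    SyntheticCell,
    _draw_cell,
    default_reference_library,
    generate_cell_spectrum,
    render_chamber_image,
    sample_cell_population,
)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass
class PipelineResult:
    per_cell: pd.DataFrame
    calibration: ThresholdCalibration | None
    enumeration: EnumerationResult
    area_stats: pd.DataFrame
    forest: TrainedForest
    attributions: list
    report: dict


def _experiment_spec(cfg: RunConfig) -> ExperimentSpec:
    e = cfg.experiment
    return ExperimentSpec(
        lncap_per_ml=e.lncap_per_ml,
        u251_per_ml=e.u251_per_ml,
        pbmc_per_ml=e.pbmc_per_ml,
        depletion=e.depletion,
        efficiency=e.efficiency,
        volume_ml=e.volume_ml,
        chamber_mm=e.chamber_mm,
        pixel_size_um=e.pixel_size_um,
        pbmc_scale=e.pbmc_scale,
    )


def _noise_model(cfg: RunConfig) -> NoiseModel:
    n = cfg.noise
    return NoiseModel(
        baseline_coeffs=tuple(n.baseline_coeffs),
        additive_sd=n.additive_sd,
        shot_noise=n.shot_noise,
        fluorescence_amplitude=n.fluorescence_amplitude,
    )


def build_reference_pools(
    cfg: RunConfig,
    library: ReferenceLibrary,
    noise: NoiseModel,
    rng: np.random.Generator,
    id_start: int = 0,
    class_models: dict | None = None,
) -> tuple[ReferencePools, dict[str, np.ndarray]]:
    """Generate the three single-phenotype reference samples, score and gate.

    Returns the gated labelled pools and the full (pre-gate) per-class area
    arrays used for the area statistics.
    """
    models = class_models or DEFAULT_CLASS_MODELS
    sizes = {"LNCaP": cfg.pools.n_lncap, "U251": cfg.pools.n_u251, "PBMC": cfg.pools.n_pbmc}
    pools: dict[str, tuple[FeatureRow, ...]] = {}
    areas: dict[str, np.ndarray] = {}
    next_id = id_start
    for name in CLASS_ORDER:
        rows = []
        cls_areas = []
        for _ in range(sizes[name]):
            cell = _draw_cell(name, models[name], rng)
            spectrum = generate_cell_spectrum(cell, library.spectra, noise, rng)
            feats = score_cell(spectrum, library, preprocess=cfg.scoring.preprocess, cell_id=next_id)
            rows.append(
                FeatureRow(
                    cell_id=next_id,
                    r1=feats.r1,
                    r2=feats.r2,
                    r3=feats.r3,
                    area_um2=cell.area_um2,
                    label=name,
                )
            )
            cls_areas.append(cell.area_um2)
            next_id += 1
        pools[name] = tuple(size_gate(rows, cfg.gate.lower_um2, cfg.gate.upper_um2))
        areas[name] = np.asarray(cls_areas)
    return ReferencePools(pools=pools), areas


def _analyze_chamber(
    cfg: RunConfig,
    spec: ExperimentSpec,
    library: ReferenceLibrary,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[list[FeatureRow], list[SyntheticCell], pd.DataFrame]:
    """Simulate one spiked chamber and measure it: render, detect, match,
    score.  Returns ungated feature rows (measured areas), the placed
    ground-truth cells, and the per-cell table skeleton."""
    population = sample_cell_population(spec, seed=rng)
    if population:
        image, placed = render_chamber_image(population, spec, seed=rng)
    else:
        size = int(round(spec.chamber_mm * 1000.0 / spec.pixel_size_um))
        image, placed = np.zeros((size, size)), []
    chamber = ChamberImage(data=image, pixel_size_um=spec.pixel_size_um)
    mask = binarize(chamber, method="otsu") if np.ptp(image) > 0 else np.zeros_like(image, bool)
    detected = detect_cells(mask, spec.pixel_size_um, cfg.gate.min_pixels, cfg.gate.connectivity)
    pairs = match_to_truth(detected, [c.centroid_um for c in placed], max_dist_um=3 * spec.pixel_size_um)

    rows: list[FeatureRow] = []
    recs = []
    truth: list[SyntheticCell] = []
    for det_i, tru_j in pairs:
        det = detected[det_i]
        cell = placed[tru_j]
        spectrum = generate_cell_spectrum(cell, library.spectra, noise, rng)
        feats = score_cell(spectrum, library, preprocess=cfg.scoring.preprocess, cell_id=det.id)
        pos = call_positivity(feats, cfg.scoring.tau_pos)
        rows.append(FeatureRow(cell_id=det.id, r1=feats.r1, r2=feats.r2, r3=feats.r3, area_um2=det.area_um2))
        truth.append(cell)
        recs.append(
            {
                "cell_id": det.id,
                "x_um": det.x_um,
                "y_um": det.y_um,
                "area_um2": det.area_um2,
                "r_ns1": feats.r1,
                "r_ns2": feats.r2,
                "r_ns3": feats.r3,
                "pos_ns1": pos.ns1,
                "pos_ns2": pos.ns2,
                "pos_ns3": pos.ns3,
                "true_class": cell.true_class,
            }
        )
    table = pd.DataFrame(recs)
    return rows, truth, table


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full per-cell analysis on a synthetic spiked experiment.

    When ``outdir`` is given, writes the per-cell table, the calibration and
    attribution-histogram tables, the enumeration JSON and a run log there;
    a failing stage removes partial outputs and raises ``PipelineError``
    naming the stage.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "setup"
    try:
        ss = np.random.SeedSequence(cfg.seed)
        rng_pools, rng_mix, rng_exp, rng_boot = (np.random.default_rng(c) for c in ss.spawn(4))
        forest_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        grid = SpectralGrid(cfg.grid.start_cm1, cfg.grid.stop_cm1, cfg.grid.n_points)
        library = ReferenceLibrary(spectra=default_reference_library(grid))
        noise = _noise_model(cfg)
        spec = _experiment_spec(cfg)

        stage = "reference_pools"
        pools, pool_areas = build_reference_pools(cfg, library, noise, rng_pools, id_start=1_000_000)

        stage = "train"
        forest = train_forest(
            pools.all_rows(),
            ForestConfig(
                n_trees=cfg.forest.n_trees,
                m_try=cfg.forest.m_try,
                seed=forest_seed,
                interaction_features=cfg.forest.interaction_features,
            ),
        )

        stage = "calibrate"
        cal_cfg = cfg.calibration
        grid_pct = np.arange(cal_cfg.grid_start_pct, cal_cfg.grid_stop_pct + 1e-9, cal_cfg.grid_step_pct)
        calibration: ThresholdCalibration | None = None
        if cal_cfg.tau_attr_pct is None:
            # mixes mirror the expected gated composition of the spiked
            # sample; the PBMC gate-pass rate is estimated from the pool
            gate_pass = len(pools["PBMC"]) / max(cfg.pools.n_pbmc, 1)
            n_retained_pbmc = (
                spec.pbmc_per_ml * spec.pbmc_scale * (1 - spec.depletion)
                * spec.efficiency * spec.volume_ml
            )
            n_pbmc_mix = min(
                len(pools["PBMC"]), max(1, int(round(n_retained_pbmc * gate_pass)))
            )
            composition = {
                "LNCaP": min(len(pools["LNCaP"]), expected_fixed(spec.lncap_per_ml, spec.efficiency)),
                "U251": min(len(pools["U251"]), expected_fixed(spec.u251_per_ml, spec.efficiency)),
                "PBMC": n_pbmc_mix,
            }
            mixes = [
                make_theoretical_mix(pools, composition, seed=int(rng_mix.integers(2**31)))
                for _ in range(cal_cfg.n_mixes)
            ]
            calibration = calibrate_threshold(forest, mixes, grid_pct, tolerance=cal_cfg.tolerance)
            tau_attr = calibration.tau_attr_pct
        else:
            tau_attr = float(cal_cfg.tau_attr_pct)

        stage = "chamber"
        rows, truth, table = _analyze_chamber(cfg, spec, library, noise, rng_exp)
        if not rows:
            warnings.warn("no cells detected in the chamber; reporting zero counts")

        stage = "gate_and_attribute"
        gated = size_gate(rows, cfg.gate.lower_um2, cfg.gate.upper_um2)
        attributions = predict_attributions(forest, gated)
        attr_by_id = {a.cell_id: a for a in attributions}
        if len(table):
            table["gated"] = table["cell_id"].isin({r.cell_id for r in gated})
            table["p_lncap"] = [
                attr_by_id[i].fractions["LNCaP"] if i in attr_by_id else np.nan for i in table["cell_id"]
            ]
            table["p_pbmc"] = [
                attr_by_id[i].fractions["PBMC"] if i in attr_by_id else np.nan for i in table["cell_id"]
            ]
            table["p_u251"] = [
                attr_by_id[i].fractions["U251"] if i in attr_by_id else np.nan for i in table["cell_id"]
            ]
            table["attribution_pct"] = [
                attr_by_id[i].attribution_pct if i in attr_by_id else np.nan for i in table["cell_id"]
            ]
            table["call"] = [
                (
                    attr_by_id[i].dominant
                    if i in attr_by_id and attr_by_id[i].attribution_pct >= tau_attr
                    else "unassigned"
                )
                for i in table["cell_id"]
            ]

        stage = "enumerate"
        enumeration = enumerate_cells(
            attributions,
            tau_attr,
            volume_ml=spec.volume_ml,
            efficiency=spec.efficiency,
            n_boot=cfg.n_bootstrap,
            seed=int(rng_boot.integers(2**31)),
        )

        stage = "stats"
        area_stats = pairwise_area_test(pool_areas)

        report = {
            "version": __version__,
            "seed": cfg.seed,
            "tau_attr_pct": tau_attr,
            "tau_calibrated": cal_cfg.tau_attr_pct is None,
            "oob_error": forest.oob_error,
            "class_errors": forest.class_errors,
            "expected_fixed_per_ml": {
                "LNCaP": expected_fixed(spec.lncap_per_ml, spec.efficiency),
                "U251": expected_fixed(spec.u251_per_ml, spec.efficiency),
            },
            "identified_per_ml": enumeration.identified_per_ml,
            "identified_uncertainty_per_ml": enumeration.uncertainty_per_ml,
            "corrected_per_ml": enumeration.corrected_per_ml,
            "n_cells_detected": int(len(table)),
            "n_cells_gated": len(gated),
            "true_retained": {
                c: sum(1 for t in truth if t.true_class == c) for c in CLASS_ORDER
            },
        }

        if out is not None:
            stage = "write_outputs"
            table.to_csv(out / "per_cell.csv", index=False, float_format="%.6f")
            if calibration is not None:
                calibration.table.to_csv(out / "calibration.csv", index=False, float_format="%.6f")
            sweep = threshold_sweep(attributions, np.arange(35.0, 100.1, 2.5))
            sweep.to_csv(out / "attribution_sweep.csv", index=False, float_format="%.6f")
            attribution_histogram(attributions).to_csv(
                out / "attribution_histogram.csv", index=False, float_format="%.6f"
            )
            area_stats.to_csv(out / "area_stats.csv", index=False, float_format="%.6g")
            with open(out / "enumeration.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            with open(out / "run.log", "w") as fh:
                fh.write(f"serrscell {__version__}\nseed {cfg.seed}\n")
                fh.write(f"tau_attr_pct {tau_attr}\noob_error {forest.oob_error:.4f}\n")

        return PipelineResult(
            per_cell=table,
            calibration=calibration,
            enumeration=enumeration,
            area_stats=area_stats,
            forest=forest,
            attributions=attributions,
            report=report,
        )
    except PipelineError:
        raise
    except Exception as exc:
        if out is not None and stage != "setup":
            shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc
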
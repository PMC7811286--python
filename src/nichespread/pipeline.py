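"""End-to-end workflow: clean -> thin -> predictors -> calibrate ->
select -> final replicates -> binarize -> independent test -> consensus
-> MOP trim -> dispersal sweep (-> optional PAM).

Four calibration schemes combine a predictor treatment (raw correlation-
filtered variables, or principal components fitted on the calibration
area) with a thinning treatment (distance-based or country-density).
All randomness derives from one master seed via named substreams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import calibration as cal
from . import maxent, occurrences as occ_mod, predictors
from .mop import mop as mop_metric
from .dispersal import DEFAULT_D_LIST, default_e_levels, sweep
from .raster import EnvStack, RasterGrid, buffer_mask
from .synthetic import VirtualSpecies

__all__ = ["PipelineConfig", "PipelineResult", "stage_seed", "evaluate_candidates", "run_pipeline"]

DEFAULT_RMS = (0.10, 0.25, 0.50, 0.75, 1, 2, 3, 4, 5, 6)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    digest = zlib.crc32(stage.encode("utf8"))
    ss = np.random.SeedSequence([int(master), digest])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    predictor_scheme: str = "raw"  # raw | pca
    thinning_scheme: str = "distance"  # distance | country
    thin_km: float = 50.0
    country_targets: dict = field(default_factory=dict)
    buffer_km: float = 500.0
    r_max: float = 0.85
    pca_min_variance: float = 95.0  # cumulative % retained
    rms: tuple = DEFAULT_RMS
    class_sets: tuple = maxent.CLASS_SETS
    min_subset: int = 2
    k: int = 5
    train_fraction: float = 0.5
    E: float = 0.05
    alpha: float = 0.05
    delta_max: float = 2.0
    n_boot: int = 500
    boot_fraction: float = 0.5
    n_replicates: int = 10
    transfer_mode: str = "E"
    p_nearest: float = 0.05
    d_list: tuple = DEFAULT_D_LIST
    e_levels: tuple = tuple(default_e_levels())
    steps: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.predictor_scheme not in ("raw", "pca"):
            raise ValueError("predictor_scheme must be raw|pca")
        if self.thinning_scheme not in ("distance", "country"):
            raise ValueError("thinning_scheme must be distance|country")


@dataclass
class PipelineResult:
    config: PipelineConfig
    occurrences: object
    mask: RasterGrid
    stack: EnvStack
    eval_records: list
    selected: list
    final_models: list
    replicate_layers: list
    replicate_binaries: list
    consensus_median: RasterGrid | None
    consensus_sum: RasterGrid | None
    mop_result: object
    occupancy: RasterGrid | None
    scenario_log: list
    manifest: dict
    halted_at: str | None = None


def _occ_cells(grid: RasterGrid, lons, lats):
    rows, cols = [], []
    for lon, lat in zip(lons, lats):
        r, c = grid.index_of(lon, lat)
        rows.append(r)
        cols.append(c)
    return np.asarray(rows), np.asarray(cols)


def evaluate_candidates(
    candidates,
    stack: EnvStack,
    bg_mask: np.ndarray,
    occ_rows: np.ndarray,
    occ_cols: np.ndarray,
    splits,
    config: PipelineConfig,
    seed: int,
):
    """Fit and score every candidate on every split.

    Returns one EvalRecord per (candidate, split); partial ROC and
    omission come from the split's train/test halves, AICc from an
    all-occurrence refit of the candidate (shared across splits).
    """
    records = []
    bg_cells = np.nonzero(bg_mask)
    for ci, cand in enumerate(candidates):
        sub = stack.subset(list(cand.variable_set))
        spec = maxent.make_feature_spec(sub, bg_mask, cand.feature_classes)
        try:
            full_model = maxent.fit(
                (occ_rows, occ_cols), bg_cells, sub, spec, cand.rm
            )
        except (RuntimeError, ValueError):
            continue
        land_raw = maxent.raw_values(full_model, sub.to_matrix(bg_cells))
        occ_raw = maxent.raw_values(full_model, sub.to_matrix((occ_rows, occ_cols)))
        aicc_val = cal.aicc(full_model, occ_raw, land_raw)
        for si, (train, test) in enumerate(splits):
            try:
                model = maxent.fit(
                    (occ_rows[train], occ_cols[train]), bg_cells, sub, spec, cand.rm
                )
            except (RuntimeError, ValueError):
                continue
            land = maxent.raw_values(model, sub.to_matrix(bg_cells))
            train_suit = maxent.raw_values(
                model, sub.to_matrix((occ_rows[train], occ_cols[train]))
            )
            test_suit = maxent.raw_values(
                model, sub.to_matrix((occ_rows[test], occ_cols[test]))
            )
            ratio, p = cal.partial_roc(
                test_suit,
                land,
                E=config.E,
                n_boot=config.n_boot,
                boot_fraction=config.boot_fraction,
                seed=seed + 1000 * ci + si,
            )
            thr = cal.lpt_threshold(train_suit, E=config.E)
            om = cal.omission_rate(test_suit, thr)
            records.append(
                cal.EvalRecord(
                    config=cand,
                    proc_p=p,
                    mean_auc_ratio=ratio,
                    omission_rate=om,
                    aicc=aicc_val,
                    n_params=full_model.n_params,
                    extras={"split": si},
                )
            )
    return records


def run_pipeline(species: VirtualSpecies, config: PipelineConfig) -> PipelineResult:
    """Run the full workflow on a virtual species input bundle."""
    manifest: dict = {"config": _jsonable(asdict(config)), "stages": {}}

    # 1. clean
    occ = occ_mod.clean(species.occurrences, species.countries)
    manifest["stages"]["clean"] = {"n": len(occ), "log": occ.provenance[-1]}

    # 2. thin
    if config.thinning_scheme == "distance":
        occ = occ_mod.thin_distance(occ, config.thin_km, stage_seed(config.seed, "thin"))
    else:
        targets = config.country_targets or _default_targets(occ)
        occ = occ_mod.thin_country_density(occ, targets, stage_seed(config.seed, "thin"))
    manifest["stages"]["thin"] = {"n": len(occ), "log": occ.provenance[-1]}

    # 3. calibration area (M): buffer around thinned occurrences
    template = species.env.template
    mask = buffer_mask(occ.lons, occ.lats, config.buffer_km, template)
    bg_mask = (np.asarray(mask.values) == 1) & ~species.env.nodata_mask()
    manifest["stages"]["mask"] = {"background_cells": int(bg_mask.sum())}

    # 4. predictors
    if config.predictor_scheme == "raw":
        stack = predictors.select_uncorrelated(
            species.env, mask, r_max=config.r_max
        )
        manifest["stages"]["predictors"] = {"scheme": "raw", "kept": stack.names}
    else:
        transform = predictors.pca_fit(species.env, mask)
        cum = np.cumsum(transform.variance_explained)
        n_comp = max(2, int(np.searchsorted(cum, config.pca_min_variance) + 1))
        n_comp = min(n_comp, len(transform.variable_names))
        stack = predictors.pca_project(species.env, transform, n_comp)
        manifest["stages"]["predictors"] = {
            "scheme": "pca",
            "components": n_comp,
            "cumulative_variance": float(cum[n_comp - 1]),
        }

    # 5-6. candidates and calibration
    candidates = cal.enumerate_candidates(
        stack.names, config.rms, config.class_sets, config.min_subset
    )
    manifest["stages"]["candidates"] = {"n": len(candidates)}
    occ_rows, occ_cols = _occ_cells(template, occ.lons, occ.lats)
    splits = cal.kfold_splits(
        len(occ), k=config.k, train_fraction=config.train_fraction,
        seed=stage_seed(config.seed, "kfold"),
    )
    records = evaluate_candidates(
        candidates, stack, bg_mask, occ_rows, occ_cols, splits, config,
        seed=stage_seed(config.seed, "proc"),
    )
    selected = cal.select_models(
        records, alpha=config.alpha, E=config.E, delta_max=config.delta_max
    )
    manifest["stages"]["selection"] = {
        "n_evaluated": len(records),
        "n_selected": len(selected),
    }
    base = dict(
        config=config,
        occurrences=occ,
        mask=mask,
        stack=stack,
        eval_records=records,
        selected=selected,
    )
    if not selected:
        manifest["halted"] = "no models met all selection criteria"
        return PipelineResult(
            **base,
            final_models=[],
            replicate_layers=[],
            replicate_binaries=[],
            consensus_median=None,
            consensus_sum=None,
            mop_result=None,
            occupancy=None,
            scenario_log=[],
            manifest=manifest,
            halted_at="selection",
        )

    # 7. final models: bootstrap replicates per selected config
    sel_configs = sorted({r.config for r in selected}, key=lambda c: c.label())
    bg_cells = np.nonzero(bg_mask)
    rng = np.random.default_rng(stage_seed(config.seed, "bootstrap"))
    final_models, rep_layers, rep_binaries, per_config_medians = [], [], [], []
    n_pass_independent = 0
    for cand in sel_configs:
        sub = stack.subset(list(cand.variable_set))
        spec = maxent.make_feature_spec(sub, bg_mask, cand.feature_classes)
        cfg_layers = []
        for _ in range(config.n_replicates):
            take = rng.integers(0, len(occ), size=len(occ))
            model = maxent.fit(
                (occ_rows[take], occ_cols[take]), bg_cells, sub, spec, cand.rm
            )
            layer = maxent.transfer(model, sub, mode=config.transfer_mode)
            occ_suit = maxent.cloglog_values(
                model, sub.to_matrix((occ_rows, occ_cols)),
                clamp=(config.transfer_mode == "EC"),
            )
            bmap = cal.binarize(layer, occ_suit, E=config.E)
            try:
                ok, _ = cal.independent_test(
                    bmap, species.invasion_records.lons, species.invasion_records.lats
                )
            except ValueError:
                ok = False
            if ok:
                n_pass_independent += 1
                final_models.append(model)
                cfg_layers.append(layer)
                rep_layers.append(layer)
                rep_binaries.append(bmap)
        if cfg_layers:
            per_config_medians.append(cal.consensus_median(cfg_layers))
    manifest["stages"]["replicates"] = {
        "n_configs": len(sel_configs),
        "n_passing_independent": n_pass_independent,
    }
    if not rep_layers:
        manifest["halted"] = "no replicate predicted all independent records"
        return PipelineResult(
            **base,
            final_models=[],
            replicate_layers=[],
            replicate_binaries=[],
            consensus_median=None,
            consensus_sum=None,
            mop_result=None,
            occupancy=None,
            scenario_log=[],
            manifest=manifest,
            halted_at="independent_test",
        )

    # consensus: median of per-config medians; sum of replicate binaries
    cons_median = cal.consensus_median(per_config_medians)
    cons_sum = cal.consensus_sum(rep_binaries)

    # 8. MOP trim (reference = calibration area, projection = full extent)
    union_vars = sorted({v for c in sel_configs for v in c.variable_set})
    ref_stack = stack.subset(union_vars)
    mres = mop_metric(
        ref_stack, mask, ref_stack, p_nearest=config.p_nearest,
        seed=stage_seed(config.seed, "mop"),
    )
    strict = np.asarray(mres.strict_mask.values) == 1

    # 9. dispersal sweep on the trimmed continuous consensus
    median_vals = cons_median.values.astype(float).copy()
    median_vals[strict] = -1.0  # strict-extrapolation cells never suitable
    trimmed_continuous = cons_median.copy_with(median_vals)
    # representative model for occurrence suitabilities: median replicate values
    occ_suit_cons = np.median(
        np.column_stack(
            [lay.values[occ_rows, occ_cols] for lay in rep_layers]
        ),
        axis=1,
    )
    seeds = list(
        zip(*_occ_cells(template, species.invasion_records.lons, species.invasion_records.lats))
    )
    occupancy, log = sweep(
        trimmed_continuous,
        occ_suit_cons,
        seeds,
        d_list=config.d_list,
        e_levels=config.e_levels,
        steps=config.steps,
    )
    manifest["stages"]["dispersal"] = {
        "n_scenarios": len(log),
        "max_occupancy": float(np.max(occupancy.values)),
    }
    return PipelineResult(
        **base,
        final_models=final_models,
        replicate_layers=rep_layers,
        replicate_binaries=rep_binaries,
        consensus_median=cons_median,
        consensus_sum=cons_sum,
        mop_result=mres,
        occupancy=occupancy,
        scenario_log=log,
        manifest=manifest,
    )


def _default_targets(occ) -> dict:
    """Reduce every country above the median count down to the median."""
    counts = occ.df["country"].value_counts()
    med = int(max(2, counts.median()))
    return {c: med for c, n in counts.items() if n > med}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
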
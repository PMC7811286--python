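"""Candidate model calibration, evaluation and selection.

A calibration run enumerates candidate configurations (regularization
multiplier x feature-class set x predictor subset of size >= 2), fits each
on random 50/50 occurrence splits, and scores them by:

* partial ROC — significance of the AUC ratio above a sensitivity floor
  of 1 - E, against the 1:1 random line, with a bootstrap p-value;
* omission rate at E — fraction of test occurrences below the modified
  least-presence threshold;
* AICc — complexity penalty computed from the raw output normalized over
  the prediction landscape, with k = number of nonzero weights.

Selected models are the statistically significant, low-omission ones
within delta-AICc <= 2 of the best of that filtered set. Continuous
predictions are binarized at the modified least-presence (E-omission)
threshold; consensus is the cellwise median of continuous layers or the
cellwise sum of binary ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid

__all__ = [
    "CandidateConfig",
    "EvalRecord",
    "BinaryMap",
    "enumerate_candidates",
    "kfold_splits",
    "partial_roc",
    "omission_rate",
    "aicc",
    "select_models",
    "binarize",
    "consensus_median",
    "consensus_sum",
    "independent_test",
]


@dataclass(frozen=True)
class CandidateConfig:
    rm: float
    feature_classes: str
    variable_set: tuple[str, ...]

    def __post_init__(self):
        if len(self.variable_set) < 2:
            raise ValueError("variable_set must contain at least 2 predictors")

    def label(self) -> str:
        return f"rm={self.rm}_fc={self.feature_classes}_vars={'+'.join(self.variable_set)}"


@dataclass
class EvalRecord:
    config: CandidateConfig
    proc_p: float
    mean_auc_ratio: float
    omission_rate: float
    aicc: float
    n_params: int
    delta_aicc: float = np.nan
    selected: bool = False
    extras: dict = field(default_factory=dict)


@dataclass
class BinaryMap:
    """Binarized suitability plus the threshold that produced it."""

    grid: RasterGrid
    threshold: float
    E: float

    def __post_init__(self):
        vals = np.asarray(self.grid.values)
        if not np.all(np.isin(np.unique(vals), (0, 1))):
            raise ValueError("binary map values must be 0/1")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def enumerate_candidates(
    variable_names,
    rms,
    class_sets,
    min_subset: int = 2,
) -> list[CandidateConfig]:
    """Every (variable subset of size >= min_subset) x rm x class set, in
    deterministic lexicographic order.

    With p variables the subset count is 2^p - p - 1 for min_subset=2, so
    6 predictors x 10 multipliers x 8 class sets gives 4,560 candidates
    and 4 components gives 880.
    """
    variable_names = list(variable_names)
    p = len(variable_names)
    if p < min_subset:
        raise ValueError(f"need at least {min_subset} variables, got {p}")
    configs = []
    for size in range(min_subset, p + 1):
        for subset in itertools.combinations(variable_names, size):
            for rm in rms:
                for fc in class_sets:
                    configs.append(CandidateConfig(rm=rm, feature_classes=fc, variable_set=subset))
    return configs


def kfold_splits(n_records: int, k: int = 5, train_fraction: float = 0.5, seed: int = 0):
    """k independent random train/test splits (not a partition).

    Each split assigns round(train_fraction * n) records to train and the
    rest to test, mirroring repeated 50% random subsampling evaluation.
    Returns a list of (train_idx, test_idx) arrays.
    """
    if n_records < 4:
        raise ValueError("need at least 4 records to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n_records))
    n_train = min(max(n_train, 1), n_records - 1)
    splits = []
    for _ in range(k):
        perm = rng.permutation(n_records)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def _roc_curve_points(test_values: np.ndarray, thresholds: np.ndarray, area_frac: np.ndarray):
    """Sensitivity of ``test_values`` at each landscape threshold.

    ``thresholds`` ascending; ``area_frac[k]`` is the proportion of
    landscape cells with suitability >= thresholds[k]. Sensitivity uses
    the matching >= rule. Both x=area_frac and y=sensitivity are
    non-increasing along k.
    """
    n = test_values.size
    pos = np.searchsorted(thresholds, test_values, side="right")  # values < t_k for k >= pos
    counts = np.bincount(pos, minlength=thresholds.size + 1)
    below = np.cumsum(counts)[:-1]  # test values strictly below t_k... see note
    sens = (n - below) / n
    return area_frac, sens


def _partial_auc_ratio(x: np.ndarray, y: np.ndarray, E: float) -> float:
    """AUC ratio over the sensitivity band y >= 1 - E.

    ``x`` (proportion of area predicted present) and ``y`` (sensitivity)
    are non-increasing sequences over ascending thresholds. The model's
    partial AUC is the trapezoid area under (x, y) restricted to the band,
    with linear interpolation at the band boundary; the random partial AUC
    is the same integral of the diagonal y = x. E = 0 is the degenerate
    "no restriction" convention: the full curve is integrated.

    Curves are completed with the (1, 1) and (0, 0) endpoints.
    """
    x = np.concatenate([[1.0], x, [0.0]])
    y = np.concatenate([[1.0], y, [0.0]])
    if E > 0:
        floor = 1.0 - E
        keep = y >= floor
        if not keep.any():
            return np.nan
        last = np.flatnonzero(keep)[-1]
        xs = list(x[: last + 1])
        ys = list(y[: last + 1])
        if last + 1 < y.size and y[last] > floor:
            # interpolate the crossing point on the segment to the next vertex
            x0, x1 = x[last], x[last + 1]
            y0, y1 = y[last], y[last + 1]
            t = (y0 - floor) / (y0 - y1) if y0 != y1 else 0.0
            xs.append(x0 + t * (x1 - x0))
            ys.append(floor)
        x_band = np.asarray(xs)[::-1]
        y_band = np.asarray(ys)[::-1]
    else:
        x_band = x[::-1]
        y_band = y[::-1]
    auc_model = float(np.trapezoid(y_band, x_band))
    auc_random = float(np.trapezoid(x_band, x_band))
    if auc_random <= 0:
        return np.nan
    return auc_model / auc_random


def partial_roc(
    test_suitabilities,
    landscape_suitabilities,
    E: float = 0.05,
    n_boot: int = 500,
    boot_fraction: float = 0.5,
    seed: int = 0,
):
    """Partial ROC significance test for presence-only predictions.

    The statistic is the partial AUC ratio over the sensitivity band
    >= 1 - E. ``mean_auc_ratio`` is the mean ratio across ``n_boot``
    bootstrap resamples of the test occurrences (``boot_fraction``
    resampled with replacement, the method's customary summary).

    Significance is assessed against a Monte Carlo null: ``n_boot``
    samples of the same size as the test set are drawn from the
    landscape's own suitability distribution and scored identically; the
    p-value is the (add-one) fraction of null ratios at least as large
    as the observed full-sample ratio. The small-sample band restriction
    inflates the ratio above 1 even for random test points, so comparing
    against the landscape-matched null — rather than against the fixed
    value 1 — is what keeps the type-I error at its nominal level.
    """
    test = np.asarray(test_suitabilities, dtype=float)
    land = np.asarray(landscape_suitabilities, dtype=float)
    if test.size < 5:
        raise ValueError("need at least 5 test suitability values")
    if land.size == 0:
        raise ValueError("landscape is empty")
    if np.ptp(land) == 0 and np.ptp(test) == 0:
        return 1.0, 1.0  # degenerate: constant prediction carries no signal
    thresholds, counts = np.unique(land, return_counts=True)
    # proportion of landscape >= each threshold
    ge = np.cumsum(counts[::-1])[::-1]
    area_frac = ge / land.size
    rng = np.random.default_rng(seed)
    m = max(1, int(round(boot_fraction * test.size)))

    def ratio_of(sample):
        _, sens = _roc_curve_points(np.asarray(sample, dtype=float), thresholds, area_frac)
        return _partial_auc_ratio(area_frac, sens, E)

    boot = np.array([ratio_of(rng.choice(test, size=m, replace=True)) for _ in range(n_boot)])
    observed = ratio_of(test)
    null = np.array([ratio_of(rng.choice(land, size=test.size, replace=True)) for _ in range(n_boot)])
    valid = boot[np.isfinite(boot)]
    mean_ratio = float(valid.mean()) if valid.size else np.nan
    null = null[np.isfinite(null)]
    if not np.isfinite(observed) or null.size == 0:
        return mean_ratio, 1.0
    p_value = float((1 + np.sum(null >= observed)) / (1 + null.size))
    return mean_ratio, p_value


def omission_rate(test_suitabilities, threshold: float) -> float:
    """Fraction of test suitability values strictly below the threshold."""
    vals = np.asarray(test_suitabilities, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one test value")
    return float(np.mean(vals < threshold))


def aicc(log_likelihood_or_model, occ_raw=None, landscape_raw=None, n_params=None):
    """AICc from the raw output normalized over the prediction landscape.

    Call either as ``aicc(model, occ_raw, landscape_raw)`` (k taken from
    the model's nonzero weights) or with explicit arrays and ``n_params``.
    The likelihood treats the normalized raw layer as a multinomial over
    landscape cells: lnL = sum_occ ln(raw_i / sum_landscape raw).
    Returns +inf when n - k - 1 <= 0 or when any occurrence sits on a
    zero-density cell.
    """
    if occ_raw is None:
        raise TypeError("aicc requires occurrence and landscape raw values")
    if n_params is None:
        n_params = log_likelihood_or_model.n_params
        occ = np.asarray(occ_raw, dtype=float)
        land = np.asarray(landscape_raw, dtype=float)
    else:
        occ = np.asarray(log_likelihood_or_model, dtype=float)
        land = np.asarray(occ_raw, dtype=float)
    k = int(n_params)
    n = occ.size
    if n - k - 1 <= 0:
        return np.inf
    total = land.sum()
    if total <= 0 or np.any(occ <= 0):
        return np.inf
    lnL = float(np.sum(np.log(occ / total)))
    return 2 * k - 2 * lnL + (2 * k * (k + 1)) / (n - k - 1)


def select_models(
    records: list[EvalRecord],
    alpha: float = 0.05,
    E: float = 0.05,
    delta_max: float = 2.0,
) -> list[EvalRecord]:
    """Filter to significant, low-omission candidates within delta-AICc.

    delta-AICc is recomputed inside the significance+omission-filtered set
    from its minimum AICc. May return an empty list (not every calibration
    yields a model meeting all three criteria).
    """
    if not records:
        raise ValueError("no evaluation records to select from")
    passing = [
        r for r in records if r.proc_p < alpha and r.omission_rate < E and np.isfinite(r.aicc)
    ]
    if not passing:
        return []
    best = min(r.aicc for r in passing)
    selected = []
    for r in passing:
        r.delta_aicc = r.aicc - best
        if r.delta_aicc <= delta_max:
            r.selected = True
            selected.append(r)
    selected.sort(key=lambda r: (r.aicc, r.config.label()))
    return selected


def lpt_threshold(calibration_suitabilities, E: float = 0.05) -> float:
    """Modified least-presence threshold: the order statistic at 0-based
    index floor(E * n) of the ascending calibration suitabilities."""
    vals = np.sort(np.asarray(calibration_suitabilities, dtype=float))
    if vals.size == 0:
        raise ValueError("need at least one calibration value")
    idx = min(int(np.floor(E * vals.size)), vals.size - 1)
    return float(vals[idx])


def binarize(layer: RasterGrid, calibration_suitabilities, E: float = 0.05) -> BinaryMap:
    """Binarize a continuous layer at the modified least-presence threshold.

    A cell is suitable iff its value >= threshold; nodata cells are
    unsuitable. Calibration omission after binarization is bounded by
    E + 1/n.
    """
    thr = lpt_threshold(calibration_suitabilities, E)
    vals = np.asarray(layer.values, dtype=float)
    binary = (vals >= thr) & ~layer.nodata_mask()
    grid = layer.copy_with(binary.astype(np.uint8), nodata=255)
    return BinaryMap(grid=grid, threshold=thr, E=E)


def consensus_median(layers: list[RasterGrid]) -> RasterGrid:
    """Cellwise median of continuous layers (nodata-aware)."""
    if not layers:
        raise ValueError("need at least one layer")
    ref = layers[0]
    stack = []
    for g in layers:
        if not g.same_geometry(ref):
            raise ValueError("consensus layers must share geometry")
        v = g.values.astype(float).copy()
        v[g.nodata_mask()] = np.nan
        stack.append(v)
    with np.errstate(all="ignore"):
        med = np.nanmedian(np.stack(stack), axis=0)
    out = med.copy()
    out[np.isnan(out)] = ref.nodata
    return ref.copy_with(out)


def consensus_sum(maps: list[BinaryMap]) -> RasterGrid:
    """Cellwise agreement count across binary maps (0 .. n_maps)."""
    if not maps:
        raise ValueError("need at least one binary map")
    ref = maps[0].grid
    total = np.zeros(ref.shape, dtype=int)
    for bm in maps:
        if not bm.grid.same_geometry(ref):
            raise ValueError("consensus maps must share geometry")
        total += bm.grid.values.astype(int)
    return ref.copy_with(total, nodata=-1)


def independent_test(binary_map: BinaryMap, lons, lats):
    """Check that every independent record falls in a suitable cell.

    Returns ``(passed, flags)`` with one boolean per record. Records
    outside the raster extent or on nodata cells raise ``ValueError``.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("no independent records supplied")
    grid = binary_map.grid
    flags = []
    for lon, lat in zip(lons, lats):
        row, col = grid.index_of(lon, lat)
        val = grid.values[row, col]
        if val == grid.nodata:
            raise ValueError(f"independent record ({lon}, {lat}) falls on a nodata cell")
        flags.append(bool(val == 1))
    return all(flags), flags
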
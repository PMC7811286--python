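"""Maxent-style presence-background suitability model.

The model estimates a Gibbs density over background cells,

    P(cell) = exp(lambda . f(cell)) / Z,

where ``f`` are feature transforms of the environmental variables and
``Z`` normalizes over the background. The weights ``lambda`` minimize the
L1-regularized convex objective

    -mean_presence(lambda . f)  +  log sum_background exp(lambda . f)
        +  sum_j beta_j |lambda_j|,

with per-feature penalties ``beta_j = rm * c_class * sd_j / sqrt(n)``
(``rm`` the regularization multiplier, ``sd_j`` the feature's background
standard deviation, ``n`` the presence count). Larger ``rm`` shrinks more
weights to exactly zero and yields simpler models.

Feature classes follow the customary letters: l (linear), q (quadratic),
p (pairwise products), t (threshold steps), h (forward hinges), all built
on variables rescaled by their calibration-background range.

Output scales: *raw* is the normalized density (sums to 1 over the
background); *cloglog* is ``1 - exp(-exp(H) * raw)`` with ``H`` the
entropy of the raw distribution, an index in [0, 1].

Transfers to new regions support three extrapolation modes: free (E),
clamped to the calibration range (EC), and no extrapolation (NE, cells
with any out-of-range variable masked to nodata).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .raster import EnvStack, RasterGrid

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "make_feature_spec",
    "build_features",
    "fit",
    "predict",
    "transfer",
]

FEATURE_CLASSES = frozenset("lqpth")
CLASS_SETS = ("lq", "lp", "lqp", "qp", "q", "lqpt", "lqpth", "lqph")

#: per-class penalty scale entering beta_j
_CLASS_COST = {"l": 0.05, "q": 0.05, "p": 0.1, "t": 1.0, "h": 0.5}


@dataclass
class FeatureSpec:
    """Feature construction recipe tied to calibration ranges."""

    classes: str
    variable_names: list[str]
    calibration_ranges: dict[str, tuple[float, float]]
    hinge_knots: int = 20
    threshold_knots: int = 10

    def __post_init__(self):
        bad = set(self.classes) - FEATURE_CLASSES
        if bad:
            raise ValueError(f"unknown feature class letters: {sorted(bad)}")
        if not self.classes:
            raise ValueError("classes must be nonempty")
        for name in self.variable_names:
            lo, hi = self.calibration_ranges[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid calibration range for {name!r}: ({lo}, {hi})")


def make_feature_spec(
    stack: EnvStack,
    background: np.ndarray,
    classes: str,
    hinge_knots: int = 20,
    threshold_knots: int = 10,
) -> FeatureSpec:
    """Build a spec whose calibration ranges come from the background cells.

    ``background`` is a boolean mask over the stack geometry.
    """
    X = stack.to_matrix(background)
    ranges = {
        name: (float(X[:, j].min()), float(X[:, j].max()))
        for j, name in enumerate(stack.names)
    }
    return FeatureSpec(
        classes=classes,
        variable_names=stack.names,
        calibration_ranges=ranges,
        hinge_knots=hinge_knots,
        threshold_knots=threshold_knots,
    )


def build_features(X: np.ndarray, spec: FeatureSpec, clamp: bool = False):
    """Feature matrix for rows of raw variable values.

    Variables are rescaled to z = (x - min)/(max - min) by calibration
    range; in clamped mode z is clipped to [0, 1] first. Classes:

    * l: z per variable
    * q: z^2 per variable
    * p: z_i * z_j for i < j
    * t: step indicators z >= knot, knots equally spaced inside (0, 1)
    * h: forward hinges max(0, z - knot)/(1 - knot), knots in [0, 1)

    Returns ``(features, names, class_of_feature)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = len(spec.variable_names)
    if X.shape[1] != p:
        raise ValueError(f"expected {p} variables, got {X.shape[1]}")
    lo = np.array([spec.calibration_ranges[v][0] for v in spec.variable_names])
    hi = np.array([spec.calibration_ranges[v][1] for v in spec.variable_names])
    Z = (X - lo) / (hi - lo)
    if clamp:
        Z = np.clip(Z, 0.0, 1.0)
    cols, names, classes = [], [], []
    if "l" in spec.classes:
        for j, v in enumerate(spec.variable_names):
            cols.append(Z[:, j])
            names.append(f"l({v})")
            classes.append("l")
    if "q" in spec.classes:
        for j, v in enumerate(spec.variable_names):
            cols.append(Z[:, j] ** 2)
            names.append(f"q({v})")
            classes.append("q")
    if "p" in spec.classes:
        for i in range(p):
            for j in range(i + 1, p):
                cols.append(Z[:, i] * Z[:, j])
                names.append(f"p({spec.variable_names[i]}*{spec.variable_names[j]})")
                classes.append("p")
    if "t" in spec.classes:
        knots = np.arange(1, spec.threshold_knots + 1) / (spec.threshold_knots + 1)
        for j, v in enumerate(spec.variable_names):
            for k in knots:
                cols.append((Z[:, j] >= k).astype(float))
                names.append(f"t({v}>={k:.3f})")
                classes.append("t")
    if "h" in spec.classes:
        knots = np.arange(spec.hinge_knots) / spec.hinge_knots
        for j, v in enumerate(spec.variable_names):
            for k in knots:
                cols.append(np.maximum(0.0, Z[:, j] - k) / (1.0 - k))
                names.append(f"h({v}>={k:.3f})")
                classes.append("h")
    return np.column_stack(cols), names, classes


@dataclass
class MaxentModel:
    """Fitted weights plus the normalizers needed for prediction."""

    spec: FeatureSpec
    rm: float
    lambdas: np.ndarray
    feature_names: list[str]
    log_partition: float
    entropy_H: float
    objective: float = np.nan
    objective_trace: list = field(default_factory=list, repr=False)

    @property
    def n_params(self) -> int:
        """Count of nonzero weights (model complexity for AICc)."""
        return int(np.sum(np.abs(self.lambdas) > 1e-8))

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "classes": self.spec.classes,
            "variable_names": self.spec.variable_names,
            "calibration_ranges": {
                k: list(v) for k, v in self.spec.calibration_ranges.items()
            },
            "hinge_knots": self.spec.hinge_knots,
            "threshold_knots": self.spec.threshold_knots,
            "rm": self.rm,
            "lambdas": np.asarray(self.lambdas).tolist(),
            "feature_names": self.feature_names,
            "log_partition": self.log_partition,
            "entropy_H": self.entropy_H,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaxentModel":
        with open(path) as fh:
            obj = json.load(fh)
        spec = FeatureSpec(
            classes=obj["classes"],
            variable_names=obj["variable_names"],
            calibration_ranges={k: tuple(v) for k, v in obj["calibration_ranges"].items()},
            hinge_knots=obj["hinge_knots"],
            threshold_knots=obj["threshold_knots"],
        )
        return cls(
            spec=spec,
            rm=obj["rm"],
            lambdas=np.asarray(obj["lambdas"]),
            feature_names=obj["feature_names"],
            log_partition=obj["log_partition"],
            entropy_H=obj["entropy_H"],
        )


def _objective_parts(lam, F_pres_mean, F_bg):
    s = F_bg @ lam
    lse = logsumexp(s)
    smooth = -float(F_pres_mean @ lam) + float(lse)
    w = np.exp(s - lse)
    grad = -F_pres_mean + F_bg.T @ w
    return smooth, grad


def fit_matrix(
    F_pres: np.ndarray,
    F_bg: np.ndarray,
    beta: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float, list]:
    """Minimize the L1 objective given prebuilt feature matrices.

    Solved via the split formulation lambda = u - v with u, v >= 0, which
    turns the penalty into a smooth linear term under bound constraints;
    L-BFGS-B then converges deterministically on the convex problem.
    Returns ``(lambdas, objective, trace)``.
    """
    m = F_bg.shape[1]
    F_pres_mean = F_pres.mean(axis=0)
    beta = np.asarray(beta, dtype=float)
    trace: list[float] = []

    def obj(z):
        u, v = z[:m], z[m:]
        lam = u - v
        smooth, grad = _objective_parts(lam, F_pres_mean, F_bg)
        val = smooth + float(beta @ (u + v))
        trace.append(val)
        g = np.concatenate([grad + beta, -grad + beta])
        return val, g

    z0 = np.zeros(2 * m) if x0 is None else np.concatenate([np.maximum(x0, 0), np.maximum(-x0, 0)])
    res = minimize(
        obj,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and res.status != 2:  # status 2: ftol reached edge cases
        raise RuntimeError(
            f"maxent fit did not converge: {res.message}; trace tail {trace[-5:]}"
        )
    lam = res.x[:m] - res.x[m:]
    # collapse numerically tiny weights created by the split formulation
    lam[np.abs(lam) < 1e-10] = 0.0
    return lam, float(res.fun), trace


def _betas(F_bg: np.ndarray, classes: list[str], rm: float, n_pres: int) -> np.ndarray:
    sd = F_bg.std(axis=0)
    cost = np.array([_CLASS_COST[c] for c in classes])
    beta = rm * cost * sd / np.sqrt(n_pres)
    return np.maximum(beta, 1e-9)


def fit(
    presence_cells,
    background_cells,
    stack: EnvStack,
    spec: FeatureSpec,
    rm: float,
) -> MaxentModel:
    """Fit the model from presence and background cell indices.

    ``presence_cells``/``background_cells`` are ``(rows, cols)`` index
    tuples (or boolean masks) into the stack geometry.
    """
    X_pres = stack.to_matrix(presence_cells)
    X_bg = stack.to_matrix(background_cells)
    if X_pres.shape[0] < 2:
        raise ValueError("need at least 2 presence cells")
    F_pres, names, classes = build_features(X_pres, spec)
    F_bg, _, _ = build_features(X_bg, spec)
    beta = _betas(F_bg, classes, rm, X_pres.shape[0])
    lam, objective, trace = fit_matrix(F_pres, F_bg, beta)
    s = F_bg @ lam
    log_Z = float(logsumexp(s))
    p_bg = np.exp(s - log_Z)
    H = float(-np.sum(p_bg * np.log(np.maximum(p_bg, 1e-300))))
    return MaxentModel(
        spec=spec,
        rm=rm,
        lambdas=lam,
        feature_names=names,
        log_partition=log_Z,
        entropy_H=H,
        objective=objective,
        objective_trace=trace[-10:],
    )


def raw_values(model: MaxentModel, X: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Raw (background-normalized) density for rows of variable values."""
    F, _, _ = build_features(X, model.spec, clamp=clamp)
    return np.exp(F @ model.lambdas - model.log_partition)


def cloglog_values(model: MaxentModel, X: np.ndarray, clamp: bool = False) -> np.ndarray:
    raw = raw_values(model, X, clamp=clamp)
    return 1.0 - np.exp(-np.exp(model.entropy_H) * raw)


def predict(model: MaxentModel, stack: EnvStack, output: str = "cloglog") -> RasterGrid:
    """Suitability layer over a stack (free extrapolation semantics)."""
    return transfer(model, stack, mode="E", output=output)


def transfer(
    model: MaxentModel, new_stack: EnvStack, mode: str = "E", output: str = "cloglog"
) -> RasterGrid:
    """Project the model onto a (possibly new) region.

    mode E: features evaluated as-is beyond calibration ranges;
    mode EC: variables clamped to calibration [min, max] first;
    mode NE: cells with any out-of-range variable become nodata.
    """
    if mode not in ("E", "EC", "NE"):
        raise ValueError(f"unknown extrapolation mode {mode!r}")
    if output not in ("raw", "cloglog"):
        raise ValueError(f"unknown output scale {output!r}")
    missing = [v for v in model.spec.variable_names if v not in new_stack.names]
    if missing:
        raise ValueError(f"stack lacks model variables: {missing}")
    sub = new_stack.subset(model.spec.variable_names)
    template = sub.template
    bad = sub.nodata_mask()
    X = sub.to_matrix()
    func = cloglog_values if output == "cloglog" else raw_values
    vals = func(model, X, clamp=(mode == "EC")).reshape(template.shape)
    if mode == "NE":
        lo = np.array([model.spec.calibration_ranges[v][0] for v in model.spec.variable_names])
        hi = np.array([model.spec.calibration_ranges[v][1] for v in model.spec.variable_names])
        outside = ((X < lo) | (X > hi)).any(axis=1).reshape(template.shape)
        bad = bad | outside
    vals = vals.astype(float)
    vals[bad] = template.nodata
    return template.copy_with(vals)
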
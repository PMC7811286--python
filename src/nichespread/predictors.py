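"""Predictor screening and principal-component projection.

Two alternative predictor treatments feed the niche models:

* a greedy Pearson-correlation filter keeping, in a user-supplied priority
  order, only variables whose pairwise |r| over the calibration area stays
  below a threshold (0.85 by default in the pipeline);
* a standardized PCA fitted on the calibration area (M) only, whose
  centering, scaling and rotation are then applied to the full extent so
  that component scores are comparable between the calibration region and
  any projection region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .raster import EnvStack, RasterGrid

__all__ = ["PCATransform", "select_uncorrelated", "pca_fit", "pca_project"]


@dataclass
class PCATransform:
    """Frozen standardized-PCA parameters (fitted on the calibration area)."""

    variable_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    rotation: np.ndarray  # p x p, columns are components
    variance_explained: np.ndarray  # percentages, non-increasing

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        p = len(self.variable_names)
        if self.rotation.shape != (p, p):
            raise ValueError("rotation must be p x p")
        gram = self.rotation.T @ self.rotation
        if np.max(np.abs(gram - np.eye(p))) >= 1e-8:
            raise ValueError("rotation columns are not orthonormal")
        if abs(self.variance_explained.sum() - 100.0) > 1e-6:
            raise ValueError("variance_explained must sum to 100%")
        if np.any(np.diff(self.variance_explained) > 1e-9):
            raise ValueError("variance_explained must be non-increasing")

    def to_json(self, path) -> None:
        obj = {
            "variable_names": self.variable_names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "rotation": self.rotation.tolist(),
            "variance_explained": self.variance_explained.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCATransform":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            variable_names=obj["variable_names"],
            means=np.asarray(obj["means"]),
            scales=np.asarray(obj["scales"]),
            rotation=np.asarray(obj["rotation"]),
            variance_explained=np.asarray(obj["variance_explained"]),
        )


def _masked_matrix(stack: EnvStack, mask: RasterGrid) -> np.ndarray:
    m = np.asarray(mask.values) == 1
    if not m.any():
        raise ValueError("mask selects no cells")
    return stack.to_matrix(m)


def select_uncorrelated(
    stack: EnvStack,
    mask: RasterGrid,
    r_max: float = 0.85,
    priority: list[str] | None = None,
) -> EnvStack:
    """Greedy correlation filter over the masked (calibration) cells.

    Variables are examined in ``priority`` order (default: stack order,
    standing in for expert preference); each is kept iff its |Pearson r|
    with every previously kept variable is <= ``r_max``.
    """
    priority = list(priority) if priority is not None else stack.names
    if sorted(priority) != sorted(stack.names):
        raise ValueError("priority must list every stack variable exactly once")
    X = _masked_matrix(stack.subset(priority), mask)
    sd = X.std(axis=0)
    for j, name in enumerate(priority):
        if sd[j] == 0:
            raise ValueError(f"variable {name!r} is constant over the mask")
    corr = np.corrcoef(X, rowvar=False)
    kept: list[int] = []
    for j in range(len(priority)):
        if all(abs(corr[j, k]) <= r_max for k in kept):
            kept.append(j)
    return stack.subset([priority[j] for j in kept])


def pca_fit(stack: EnvStack, mask: RasterGrid) -> PCATransform:
    """Standardized (correlation-matrix) PCA over the masked cells.

    Component signs are fixed so each column's largest-magnitude loading
    is positive, making the decomposition deterministic.
    """
    X = _masked_matrix(stack, mask)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} masked cells, found {n}")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    for j, name in enumerate(stack.names):
        if scales[j] == 0:
            raise ValueError(f"variable {name!r} is constant over the mask")
    Z = (X - means) / scales
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(p):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    var_pct = 100.0 * eigvals / eigvals.sum()
    return PCATransform(
        variable_names=stack.names,
        means=means,
        scales=scales,
        rotation=eigvecs,
        variance_explained=var_pct,
    )


def pca_project(
    stack: EnvStack, transform: PCATransform, n_components: int
) -> EnvStack:
    """Score layers for the first ``n_components`` components, for every
    cell of ``stack`` (inside or outside the fitting mask alike).

    Applying the frozen centering/scaling/rotation from the calibration
    area keeps scores comparable when transferring models to new regions.
    Cells that are nodata in any input layer are nodata in every score
    layer.
    """
    if stack.names != transform.variable_names:
        raise ValueError(
            f"stack variables {stack.names} do not match transform "
            f"{transform.variable_names}"
        )
    p = len(transform.variable_names)
    if not (1 <= n_components <= p):
        raise ValueError(f"n_components must be in [1, {p}]")
    template = stack.template
    bad = stack.nodata_mask()
    X = stack.to_matrix()
    Z = (X - transform.means) / transform.scales
    scores = Z @ transform.rotation[:, :n_components]
    layers = {}
    for k in range(n_components):
        vals = scores[:, k].reshape(template.shape).astype(float)
        vals[bad] = template.nodata
        layers[f"PC{k + 1}"] = template.copy_with(vals)
    return EnvStack(layers)
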
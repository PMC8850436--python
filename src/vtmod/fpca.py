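"""Functional PCA of vocal-tract outlines.

Outlines are resampled to a fixed number of equally arc-length-spaced
points and the two coordinate functions x(t), y(t) are concatenated into
a single functional observation, so that coupled deformations (e.g. the
larynx lowering that lengthens the whole tract) appear as one component.
On a common equally spaced grid with uniform quadrature weights this
discretized fPCA is exactly a multivariate PCA of the stacked coordinate
vectors; eigenfunctions are orthonormal under the concatenated-curve dot
product and eigenvalues carry the component variances (mm^2 per grid
node).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import VTOutline, ensure_ccw


@dataclass
class ParametrizedCurve:
    """A contour resampled to n equally arc-length-spaced points."""

    points: np.ndarray
    closed: bool = False
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("curve points must be an (N, 2) array")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def concat(self) -> np.ndarray:
        """Stack into the (x(t); y(t)) vector used for the inner product."""
        return np.concatenate([self.points[:, 0], self.points[:, 1]])


@dataclass
class FPCAModel:
    """Mean curve, orthonormal eigenfunctions and eigenvalues of a contour set."""

    mean_curve: ParametrizedCurve
    eigenfunctions: np.ndarray  # (K, n_points, 2)
    eigenvalues: np.ndarray  # (K,), nonincreasing, mm^2
    total_variance: float
    sign_convention: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_points(self) -> int:
        return self.mean_curve.n_points

    @property
    def variance_proportions(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance

    def eigenfunction_concat(self) -> np.ndarray:
        """(K, 2 n) matrix of stacked eigenfunctions."""
        K, n, _ = self.eigenfunctions.shape
        return np.concatenate(
            [self.eigenfunctions[:, :, 0], self.eigenfunctions[:, :, 1]], axis=1
        )


def _arc_length_resample(points: np.ndarray, n_points: int, closed: bool) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) outline")
    if closed:
        t = np.arange(n_points) * total / n_points
    else:
        t = np.linspace(0.0, total, n_points)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    return np.column_stack([x, y])


def resample_contour(
    outline: VTOutline, n_points: int = 100, labels: dict | None = None
) -> ParametrizedCurve:
    """Equal-arc-length resampling by linear interpolation.

    Closed outlines are first put in counter-clockwise order with the
    first point at the lip landmark (the anterior-most point, ties broken
    by the uppermost), so that every curve in a dataset shares one
    parametrization.  Closed curves are sampled at n equal steps around
    the loop without repeating the start; open curves include both ends.
    """
    if n_points < 20:
        raise ValueError("n_points must be at least 20")
    pts = outline.points
    if outline.closed:
        pts = ensure_ccw(pts)
        start = np.lexsort((pts[:, 1], pts[:, 0]))[0]  # min x, then min y
        pts = np.roll(pts, -start, axis=0)
    curve = _arc_length_resample(pts, n_points, outline.closed)
    lab = dict(labels or {})
    lab.setdefault("frame_index", outline.frame_index)
    return ParametrizedCurve(curve, closed=outline.closed, labels=lab)


def _stack(curves: Sequence[ParametrizedCurve]) -> np.ndarray:
    n = curves[0].n_points
    if any(c.n_points != n for c in curves):
        raise ValueError("all curves must share n_points")
    return np.stack([c.concat() for c in curves])


def fit_fpca(curves: Sequence[ParametrizedCurve], n_components: int = 5) -> FPCAModel:
    """Fit the fPCA model by singular value decomposition of the centred data."""
    curves = list(curves)
    if len(curves) < n_components + 1:
        raise ValueError(
            f"need at least n_components + 1 = {n_components + 1} curves, got {len(curves)}"
        )
    X = _stack(curves)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD route; the equivalent covariance eigendecomposition is kept as a
    # test oracle.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = len(curves)
    eigvals_all = s**2 / (m - 1)
    total = float(eigvals_all.sum())
    K = n_components
    n = curves[0].n_points
    phi = Vt[:K]
    eigenfunctions = np.stack([phi[:, :n], phi[:, n:]], axis=-1)
    mean_curve = ParametrizedCurve(
        np.column_stack([mean[:n], mean[n:]]), closed=curves[0].closed
    )
    return FPCAModel(
        mean_curve=mean_curve,
        eigenfunctions=eigenfunctions,
        eigenvalues=eigvals_all[:K].copy(),
        total_variance=total,
    )


def project_scores(
    model: FPCAModel, curves: Sequence[ParametrizedCurve]
) -> pd.DataFrame:
    """Score table: inner product of each centred curve with each eigenfunction."""
    curves = list(curves)
    if any(c.n_points != model.n_points for c in curves):
        raise ValueError("curve sampling does not match the model")
    X = _stack(curves) - model.mean_curve.concat()
    scores = X @ model.eigenfunction_concat().T
    label_keys: list[str] = []
    for c in curves:
        for k in c.labels:
            if k not in label_keys:
                label_keys.append(k)
    data = {k: [c.labels.get(k) for c in curves] for k in label_keys}
    for k in range(model.n_components):
        data[f"fPC{k + 1}"] = scores[:, k]
    return pd.DataFrame(data)


def reconstruct_shape(
    model: FPCAModel, scores: Sequence[float], score_range_sd: float = 3.0
) -> ParametrizedCurve:
    """mean + sum_k score_k * eigenfunction_k (the companion-app operation)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) > model.n_components:
        raise ValueError("more scores than model components")
    sd = np.sqrt(np.maximum(model.eigenvalues[: len(scores)], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, np.abs(scores) / sd, 0.0)
    if np.any(z > score_range_sd):
        warnings.warn(
            f"scores exceed +/-{score_range_sd} SD of the fitted components",
            stacklevel=2,
        )
    vec = model.mean_curve.concat() + scores @ model.eigenfunction_concat()[: len(scores)]
    n = model.n_points
    return ParametrizedCurve(
        np.column_stack([vec[:n], vec[n:]]), closed=model.mean_curve.closed
    )


def orient_components(
    model: FPCAModel, references: dict[int, np.ndarray]
) -> FPCAModel:
    """Fix eigenfunction signs against reference deformation curves.

    ``references`` maps component index (0-based) to an (n, 2) deformation;
    each eigenfunction whose inner product with its reference is negative is
    flipped, making conventions like "positive length scores = smaller
    tract" reproducible.  Scores projected through the oriented model flip
    consistently.
    """
    eig = model.eigenfunctions.copy()
    convention = list(model.sign_convention)
    for k, ref in references.items():
        ref = np.asarray(ref, dtype=float)
        if ref.shape != (model.n_points, 2):
            raise ValueError("reference deformation shape must match the model grid")
        ip = float(np.sum(eig[k] * ref))
        if ip == 0.0:
            warnings.warn(f"component {k + 1} orientation is ambiguous", stacklevel=2)
            continue
        if ip < 0:
            eig[k] = -eig[k]
            convention.append((k, "flipped"))
        else:
            convention.append((k, "kept"))
    return FPCAModel(
        mean_curve=model.mean_curve,
        eigenfunctions=eig,
        eigenvalues=model.eigenvalues.copy(),
        total_variance=model.total_variance,
        sign_convention=convention,
    )


def identify_component(model: FPCAModel, reference: np.ndarray) -> int:
    """Index (0-based) of the eigenfunction best aligned with a reference
    deformation — the programmatic counterpart of interpreting a component
    (e.g. finding which one loads on vocal-tract length)."""
    r = np.asarray(reference, dtype=float)
    rc = np.concatenate([r[:, 0], r[:, 1]])
    rc = rc / np.linalg.norm(rc)
    cos = np.abs(model.eigenfunction_concat() @ rc)
    return int(np.argmax(cos))


def variance_explained(model: FPCAModel) -> pd.DataFrame:
    """Per-component and cumulative variance proportions."""
    props = model.variance_proportions
    return pd.DataFrame(
        {
            "component": np.arange(1, model.n_components + 1),
            "eigenvalue": model.eigenvalues,
            "proportion": props,
            "cumulative": np.cumsum(props),
        }
    )
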
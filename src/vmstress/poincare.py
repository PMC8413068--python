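"""Second-order-difference Poincaré plots and their descriptors.

For a sequence x, the plot scatters successive first differences against
each other:

    X(t) = x(t+1) - x(t),     Y(t) = x(t+2) - x(t+1).

Three descriptors summarize the dispersion of the point cloud around the
origin:

* **ellipse area**  pi*a*b, where a, b are the square roots of the
  eigenvalues of the raw second-moment matrix [[SX^2, SXY], [SXY, SY^2]]
  with SX = sqrt(mean X^2), SY = sqrt(mean Y^2), SXY = mean X*Y.  The
  eigenvalues are lambda_± = ((SX^2 + SY^2) ± D)/2 with
  D = sqrt((SX^2 - SY^2)^2 + 4*SXY^2); round-off negatives are clamped by
  absolute value so the radii stay real.
* **mean distance** m: the average Euclidean distance of plot points from
  the origin.
* **central tendency measure (CTM)**: the fraction of points strictly
  inside a circle of radius r around the origin — high CTM means low
  sample-to-sample variability.

No centering, normalization or detrending is applied: the moments are raw,
as difference sequences are near zero-mean by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PoincarePlot",
    "EllipseDescriptor",
    "PPFeatures",
    "make_plot",
    "ellipse_descriptor",
    "mean_distance",
    "ctm",
    "extract_features",
]


@dataclass
class PoincarePlot:
    X: np.ndarray
    Y: np.ndarray

    @property
    def n_points(self) -> int:
        return self.X.size


@dataclass
class EllipseDescriptor:
    SX: float
    SY: float
    SXY: float
    D: float
    a: float    # major radius
    b: float    # minor radius
    area: float


@dataclass
class PPFeatures:
    area: float
    mean_distance: float
    ctm: float
    r: float


def make_plot(x) -> PoincarePlot:
    """Build the second-order difference plot of a sequence (length >= 3)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sequence of length >= 3")
    d = np.diff(x)
    return PoincarePlot(X=d[:-1], Y=d[1:])


def ellipse_descriptor(pp: PoincarePlot) -> EllipseDescriptor:
    """Fit the dispersion ellipse from raw second moments of the plot."""
    if pp.n_points < 2:
        raise ValueError("need at least 2 plot points for an ellipse")
    sx2 = float(np.mean(pp.X**2))
    sy2 = float(np.mean(pp.Y**2))
    sxy = float(np.mean(pp.X * pp.Y))
    d = float(np.sqrt((sx2 - sy2) ** 2 + 4.0 * sxy**2))
    lam_plus = (sx2 + sy2 + d) / 2.0
    lam_minus = (sx2 + sy2 - d) / 2.0
    # round-off can push the small eigenvalue slightly negative
    a = float(np.sqrt(abs(lam_plus)))
    b = float(np.sqrt(abs(lam_minus)))
    return EllipseDescriptor(
        SX=float(np.sqrt(sx2)),
        SY=float(np.sqrt(sy2)),
        SXY=sxy,
        D=d,
        a=a,
        b=b,
        area=float(np.pi * a * b),
    )


def mean_distance(pp: PoincarePlot) -> float:
    """Average Euclidean distance of plot points from the origin."""
    if pp.n_points < 1:
        raise ValueError("empty plot")
    return float(np.mean(np.hypot(pp.X, pp.Y)))


def ctm(pp: PoincarePlot, r: float) -> float:
    """Fraction of plot points strictly inside radius ``r``."""
    if r <= 0:
        raise ValueError("r must be positive")
    if pp.n_points < 1:
        raise ValueError("empty plot")
    return float(np.mean(np.hypot(pp.X, pp.Y) < r))


def extract_features(x, r: float = 0.5) -> PPFeatures:
    """All three descriptors of a sequence's second-order difference plot."""
    pp = make_plot(x)
    desc = ellipse_descriptor(pp)
    return PPFeatures(
        area=desc.area,
        mean_distance=mean_distance(pp),
        ctm=ctm(pp, r),
        r=r,
    )
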
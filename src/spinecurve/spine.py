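"""Spinal-curve fitting, curvature-angle measurement and rule-based diagnosis.

The spine runs along image rows, so the fitted curve expresses the lateral
(column) coordinate as a polynomial in the cranio-caudal (row) coordinate.
The spinal curvature angle ``phi`` is the unsigned angle between the curve's
tangents at the centroids of the two terminal vertebrae,

    phi = | integral_a^b  y'' / (1 + y'^2) dx |
        = | arctan y'(b) - arctan y'(a) |,

a landmark-free alternative to the endplate-based Cobb angle.  Diagnosis
follows clinical priors: in the coronal view the spine is nominally
straight, and ``phi >= 10`` degrees is called scoliosis; in the sagittal
view the angle is compared against the region's normal physiologic range —
cervical lordosis 35-45, thoracic kyphosis 20-45, lumbar lordosis 40-60
degrees (closed intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

VIEWS = ("coronal", "sagittal")
REGIONS = ("cervical", "thoracic", "lumbar", "whole")

#: Normal sagittal curvature ranges in degrees (closed intervals).
SAGITTAL_NORMAL_RANGES = {
    "cervical": (35.0, 45.0),
    "thoracic": (20.0, 45.0),
    "lumbar": (40.0, 60.0),
}

SCOLIOSIS_THRESHOLD_DEG = 10.0


@dataclass(frozen=True)
class SpineCurve:
    """Least-squares polynomial spinal curve with fit-quality statistics.

    ``poly`` maps the cranio-caudal coordinate to the lateral coordinate;
    ``domain`` spans the cranio-caudal coordinates of the two terminal
    centroids.
    """

    poly: Polynomial
    domain: tuple[float, float]
    r_squared: float
    rmse: float

    @property
    def degree(self) -> int:
        return self.poly.degree()


@dataclass(frozen=True)
class CurvatureReport:
    """Curvature angle, the diagnosis it implies, and fit quality."""

    phi: float  # degrees, unsigned
    view: str
    region: str | None
    diagnosis: str  # "normal" or "abnormal"
    rule: str  # human-readable rule that fired
    r_squared: float | None = None
    rmse: float | None = None
    n_centroids: int | None = None

    def to_dict(self) -> dict:
        return {
            "phi_degrees": self.phi,
            "view": self.view,
            "region": self.region,
            "diagnosis": self.diagnosis,
            "rule": self.rule,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n_centroids": self.n_centroids,
        }


# ---------------------------------------------------------------------------
# Centroids
# ---------------------------------------------------------------------------


def extract_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Center of mass ``(k, l)`` of a binary mask: mean row and mean column.

    ``k = sum(x * I(x, y)) / sum(I)`` over rows ``x`` and columns ``y`` of
    the 0/1 mask ``I``; raises on an empty mask.
    """
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask has no foreground pixels")
    return float(rows.mean()), float(cols.mean())


def default_degree(n_centroids: int) -> int:
    """Fitting degree by centroid count: 3 for >=5, 2 for 3-4, 1 for 2."""
    if n_centroids >= 5:
        return 3
    if n_centroids >= 3:
        return 2
    return 1


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------


def fit_spine_curve(centroids, degree: int | None = None) -> SpineCurve:
    """Ordinary least-squares polynomial fit of lateral vs cranio-caudal coordinate.

    ``centroids`` is an ordered (superior-to-inferior) sequence of
    ``(row, col)`` positions.  R^2 and RMSE compare the observed lateral
    coordinates ``v`` with the fitted values ``v'``:

        R^2  = 1 - sum (v' - v)^2 / sum (v - vbar)^2
        RMSE = sqrt( mean (v - v')^2 )

    When the lateral coordinates are all identical the R^2 denominator
    vanishes; a perfect fit then reports R^2 = 1 and any residual R^2 = 0.
    """
    pts = np.asarray(centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (row, col) centroids")
    x = pts[:, 0]
    v = pts[:, 1]
    if degree is None:
        degree = default_degree(len(pts))
    if len(pts) < degree + 1:
        raise ValueError(f"{len(pts)} centroids cannot support degree {degree}")
    if np.unique(x).size != x.size:
        raise ValueError("duplicate cranio-caudal coordinates")
    poly = Polynomial.fit(x, v, deg=degree).convert()
    v_fit = poly(x)
    ss_res = float(np.sum((v_fit - v) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot < 1e-12:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((v - v_fit) ** 2)))
    return SpineCurve(
        poly=poly, domain=(float(x[0]), float(x[-1])), r_squared=r2, rmse=rmse
    )


def curvature_at(curve: SpineCurve, x: float) -> float:
    """Signed curvature ``y'' / (1 + y'^2)^(3/2)`` of the fitted curve at ``x``."""
    d1 = curve.poly.deriv(1)(x)
    d2 = curve.poly.deriv(2)(x) if curve.degree >= 2 else 0.0
    return float(d2 / (1.0 + d1**2) ** 1.5)


def curvature_angle(curve: SpineCurve) -> float:
    """Unsigned tangent angle (degrees) between the terminal centroids.

    Evaluates the exact antiderivative of ``y'' / (1 + y'^2)``:
    ``|arctan y'(b) - arctan y'(a)|`` over the fit domain ``[a, b]``.
    """
    a, b = curve.domain
    d1 = curve.poly.deriv(1)
    return float(abs(np.degrees(np.arctan(d1(b)) - np.arctan(d1(a)))))


def curvature_angle_quadrature(curve: SpineCurve) -> float:
    """Tangent angle by numeric quadrature of ``y'' / (1 + y'^2)`` (degrees).

    Independent of the closed form used by :func:`curvature_angle`; the two
    agree to well below 1e-6 degrees for polynomial curves.
    """
    from scipy.integrate import quad

    a, b = curve.domain
    d1 = curve.poly.deriv(1)
    if curve.degree < 2:
        return 0.0
    d2 = curve.poly.deriv(2)
    val, _ = quad(lambda x: d2(x) / (1.0 + d1(x) ** 2), a, b, limit=200)
    return float(abs(np.degrees(val)))


# ---------------------------------------------------------------------------
# Diagnosis
# ---------------------------------------------------------------------------


def diagnose(
    phi_degrees: float,
    view: str,
    region: str | None = None,
    curve: SpineCurve | None = None,
    n_centroids: int | None = None,
) -> CurvatureReport:
    """Apply the clinical decision rules to a curvature angle.

    Coronal view: scoliosis (abnormal) iff ``phi >= 10`` degrees, regardless
    of region.  Sagittal view: the region is required, and the angle is
    normal iff it falls inside the region's physiologic range.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    if phi_degrees < 0:
        raise ValueError("phi must be non-negative")
    if view == "coronal":
        if phi_degrees >= SCOLIOSIS_THRESHOLD_DEG:
            diagnosis = "abnormal"
            rule = f"coronal: phi = {phi_degrees:.1f} >= {SCOLIOSIS_THRESHOLD_DEG:.0f} deg (scoliosis)"
        else:
            diagnosis = "normal"
            rule = f"coronal: phi = {phi_degrees:.1f} < {SCOLIOSIS_THRESHOLD_DEG:.0f} deg"
    else:
        if region not in SAGITTAL_NORMAL_RANGES:
            raise ValueError(
                f"sagittal view requires region in {sorted(SAGITTAL_NORMAL_RANGES)}"
            )
        lo, hi = SAGITTAL_NORMAL_RANGES[region]
        if lo <= phi_degrees <= hi:
            diagnosis = "normal"
            rule = f"sagittal {region}: phi = {phi_degrees:.1f} in [{lo:.0f}, {hi:.0f}] deg"
        else:
            diagnosis = "abnormal"
            rule = f"sagittal {region}: phi = {phi_degrees:.1f} outside [{lo:.0f}, {hi:.0f}] deg"
    return CurvatureReport(
        phi=float(phi_degrees),
        view=view,
        region=region,
        diagnosis=diagnosis,
        rule=rule,
        r_squared=None if curve is None else curve.r_squared,
        rmse=None if curve is None else curve.rmse,
        n_centroids=n_centroids,
    )


def analyze(
    masks,
    view: str,
    region: str | None = None,
    degree: int | None = None,
    inferior_first: bool = False,
) -> CurvatureReport:
    """Full curvature analysis from per-vertebra binary masks.

    Extracts a centroid from every non-empty mask, orders them by detection
    number (superior to inferior; set ``inferior_first`` for inverted
    acquisitions), fits the spinal curve, measures the tangent angle and
    applies the diagnosis rules.  Empty masks are skipped.
    """
    entries = []
    for i, m in enumerate(masks):
        arr = m.mask if hasattr(m, "mask") else np.asarray(m)
        number = getattr(m, "number", i + 1)
        if not np.any(arr):
            continue
        try:
            entries.append((number, extract_centroid(arr)))
        except ValueError as exc:  # pragma: no cover - guarded by any() above
            raise ValueError(f"mask {number}: {exc}") from exc
    if len(entries) < 3:
        raise ValueError(f"need at least 3 non-empty masks, got {len(entries)}")
    entries.sort(key=lambda e: e[0], reverse=inferior_first)
    centroids = [c for _, c in entries]
    curve = fit_spine_curve(centroids, degree)
    phi = curvature_angle(curve)
    return diagnose(phi, view, region, curve=curve, n_centroids=len(centroids))
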
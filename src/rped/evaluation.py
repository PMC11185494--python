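"""Image-quality metrics and Thr/alpha parameter-sweep selection.

Quality of a stimulation strategy is judged by comparing the original
grayscale image against the gray-level stimulation frame (active pixels
keep their intensity, inactive pixels are 0) with MSE, PSNR and a
global-statistics SSIM:

    PSNR = 10 log10(R^2 / MSE)
    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03 and L the dynamic
range.  The SSIM here is the single-statistics form over the whole image
(one mean/variance/covariance per image), not the sliding-window form of
packaged implementations; :func:`ssim_windowed` exposes the windowed
variant for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ActivationMap, GrayImage, RPEDParams, render_stimulation, rped_detect

__all__ = [
    "SSIMConstants",
    "MetricReport",
    "SweepTable",
    "mse",
    "psnr",
    "ssim_global",
    "ssim_windowed",
    "evaluate",
    "sweep_parameter",
    "select_alpha",
]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizing constants of the SSIM formula."""

    k1: float = 0.01
    k2: float = 0.03
    L: float = 255.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.L <= 0:
            raise ValueError("k1, k2 and L must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2


@dataclass(frozen=True)
class MetricReport:
    """Per-run quality/activity summary.

    ``active_ratio`` is a percentage of the array's pixels, kept
    unrounded; table-style output rounds it to 2 decimals.
    """

    mse: float
    psnr: float
    ssim: float
    n_active: int
    active_ratio: float

    @property
    def active_ratio_pct(self) -> float:
        """Percentage rounded to 2 decimals, matching table formatting."""
        return round(self.active_ratio, 2)


def _check_dims(a, b) -> None:
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")


def mse(reference: GrayImage | np.ndarray, test: GrayImage | np.ndarray) -> float:
    """Mean squared per-pixel difference (float, overflow-safe)."""
    ref = reference.values if hasattr(reference, "values") else np.asarray(reference)
    tst = test.values if hasattr(test, "values") else np.asarray(test)
    _check_dims(ref, tst)
    diff = ref.astype(np.float64) - tst.astype(np.float64)
    return float(np.mean(diff * diff))


def psnr(
    reference: GrayImage | np.ndarray,
    test: GrayImage | np.ndarray,
    data_range: float | None = None,
) -> float:
    """Peak signal-to-noise ratio in dB.

    ``R`` defaults to the reference's dynamic range (255 for 8-bit).
    A perfect reconstruction (MSE = 0) returns ``math.inf`` — a
    documented sentinel, not an error.
    """
    if data_range is None:
        data_range = reference.max_value if hasattr(reference, "max_value") else 255
    err = mse(reference, test)
    if err == 0:
        return math.inf
    return float(10.0 * math.log10(data_range**2 / err))


def ssim_global(
    x: GrayImage | np.ndarray,
    y: GrayImage | np.ndarray,
    constants: SSIMConstants | None = None,
) -> float:
    """Whole-image structural similarity from global sample statistics."""
    xv = (x.values if hasattr(x, "values") else np.asarray(x)).astype(np.float64)
    yv = (y.values if hasattr(y, "values") else np.asarray(y)).astype(np.float64)
    _check_dims(xv, yv)
    if constants is None:
        L = float(x.max_value) if hasattr(x, "max_value") else 255.0
        constants = SSIMConstants(L=L)
    mu_x, mu_y = xv.mean(), yv.mean()
    var_x, var_y = xv.var(), yv.var()
    cov = float(np.mean((xv - mu_x) * (yv - mu_y)))
    c1, c2 = constants.c1, constants.c2
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(num / den)


def ssim_windowed(
    x: GrayImage | np.ndarray,
    y: GrayImage | np.ndarray,
    win_size: int = 7,
    constants: SSIMConstants | None = None,
) -> float:
    """Sliding-square-window SSIM (the common packaged form), for
    comparison against the global-statistics form."""
    from skimage.metrics import structural_similarity

    xv = (x.values if hasattr(x, "values") else np.asarray(x)).astype(np.float64)
    yv = (y.values if hasattr(y, "values") else np.asarray(y)).astype(np.float64)
    _check_dims(xv, yv)
    if constants is None:
        L = float(x.max_value) if hasattr(x, "max_value") else 255.0
        constants = SSIMConstants(L=L)
    return float(
        structural_similarity(
            xv,
            yv,
            win_size=win_size,
            data_range=constants.L,
            K1=constants.k1,
            K2=constants.k2,
            gaussian_weights=False,
        )
    )


def evaluate(
    image: GrayImage,
    activation: ActivationMap,
    rendering: str = "gray",
    constants: SSIMConstants | None = None,
) -> MetricReport:
    """Metrics of a stimulation strategy on one image.

    Renders the stimulation frame and scores it against the original.
    ``rendering="gray"`` (default) keeps active-pixel intensities;
    ``rendering="binary"`` drives active pixels at full scale, for
    sensitivity analysis.
    """
    if image.shape != activation.shape:
        raise ValueError("image and activation dimensions must match")
    if rendering == "gray":
        frame = render_stimulation(image, activation).values
    elif rendering == "binary":
        frame = np.where(activation.active, image.max_value, 0)
    else:
        raise ValueError(f"unknown rendering {rendering!r}")
    n = activation.n_active
    return MetricReport(
        mse=mse(image.values, frame),
        psnr=psnr(image, frame),
        ssim=ssim_global(image.values, frame, constants or SSIMConstants(L=image.max_value)),
        n_active=n,
        active_ratio=100.0 * n / (image.height * image.width),
    )


@dataclass(frozen=True)
class SweepTable:
    """One metric row per swept parameter value, plus forward-difference
    gradient columns for PSNR and SSIM (gradient at row i is
    value(i) - value(i-1); the first row's gradient is NaN)."""

    parameter: str
    values: tuple
    reports: tuple[MetricReport, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.reports):
            raise ValueError("values and reports must align")
        if list(self.values) != sorted(self.values):
            raise ValueError("sweep values must be sorted ascending")
        object.__setattr__(self, "values", tuple(self.values))
        object.__setattr__(self, "reports", tuple(self.reports))

    @classmethod
    def from_psnr(
        cls, parameter: str, values, psnr_column, ssim_column=None
    ) -> "SweepTable":
        """Build a table from bare PSNR (and optional SSIM) columns, e.g.
        published values; the other metric fields are NaN placeholders."""
        if ssim_column is None:
            ssim_column = [math.nan] * len(psnr_column)
        reports = tuple(
            MetricReport(mse=math.nan, psnr=p, ssim=s, n_active=0, active_ratio=math.nan)
            for p, s in zip(psnr_column, ssim_column, strict=True)
        )
        return cls(parameter, tuple(values), reports)

    def gradient(self, metric: str = "psnr") -> list[float]:
        col = [getattr(r, metric) for r in self.reports]
        return [math.nan] + [col[i] - col[i - 1] for i in range(1, len(col))]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": list(self.values),
                "mse": [r.mse for r in self.reports],
                "psnr_db": [r.psnr for r in self.reports],
                "ssim": [r.ssim for r in self.reports],
                "n_active": [r.n_active for r in self.reports],
                "active_ratio_pct": [r.active_ratio_pct for r in self.reports],
                "psnr_gradient": self.gradient("psnr"),
                "ssim_gradient": self.gradient("ssim"),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sweep_parameter(
    image: GrayImage,
    params: RPEDParams,
    which: str,
    values,
    rendering: str = "gray",
) -> SweepTable:
    """Sweep Thr index or alpha, holding everything else fixed."""
    if which not in ("thr_index", "alpha"):
        raise ValueError("which must be 'thr_index' or 'alpha'")
    values = list(values)
    if not values:
        raise ValueError("values must be nonempty")
    if values != sorted(values):
        raise ValueError("values must be sorted ascending")
    reports = []
    for v in values:
        p = params.with_(**{which: v})
        reports.append(evaluate(image, rped_detect(image, p), rendering=rendering))
    name = "thr" if which == "thr_index" else "alpha"
    return SweepTable(name, tuple(values), tuple(reports))


def select_alpha(table: SweepTable) -> int:
    """Pick the neighbor distance at the steepest PSNR rise.

    PSNR keeps improving with alpha but so does power; the operating
    point is the alpha with the largest forward-difference PSNR gain.
    Ties break toward the smaller alpha (lower power).
    """
    if len(table.values) < 2:
        raise ValueError("alpha selection needs at least 2 sweep rows")
    grads = table.gradient("psnr")[1:]  # first entry is NaN
    best_i = 1 + int(np.argmax(grads))  # argmax takes first on ties
    return table.values[best_i]
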
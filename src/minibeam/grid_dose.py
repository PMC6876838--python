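"""Dose modelling for pencil-minibeam patterns on a square lattice.

Spatially fractionated proton fields are modelled as Gaussian (or square
top-hat) pencil beams placed on a quadratic grid of center-to-center
distance ``ctc``.  At a fixed field-mean dose the whole dose modulation of
the infinite lattice is governed by the single dimensionless ratio
``sigma/ctc``; the peak-to-valley dose ratio (PVDR) follows analytically
from one-dimensional lattice (theta) sums because the square Gaussian
lattice is separable.

Coordinate convention: beam centers sit at integer multiples of ``ctc``
in both axes; the unit cell is ``[-ctc/2, ctc/2]^2`` and the dose valley
of the infinite lattice is at ``(±ctc/2, ±ctc/2)``.

All lengths are in micrometres and doses in gray.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, signal

__all__ = [
    "INFINITE",
    "BeamSpec",
    "DoseField",
    "ProfileCut",
    "PvdrResult",
    "SigmaFit",
    "InvalidGeometryError",
    "ResolutionError",
    "GeometryError",
    "FitError",
    "amplitude_from_mean",
    "dose_at",
    "render_dose_map",
    "pvdr_analytic",
    "pvdr_of_ratio",
    "extract_diagonal_profile",
    "pvdr_from_profile",
    "fit_beam_sigma",
    "tophat_peak",
    "write_dose_map",
    "read_dose_map",
    "write_profile",
    "read_profile",
]

#: Sentinel for an unbounded (periodic) lattice.
INFINITE = math.inf


class InvalidGeometryError(ValueError):
    """Non-positive beam size, spacing or otherwise impossible geometry."""


class ResolutionError(ValueError):
    """Requested pixel size too coarse to resolve the lattice."""


class GeometryError(ValueError):
    """Requested cut or window falls outside the sampled field."""


class FitError(RuntimeError):
    """Nonlinear beam-size fit failed to converge."""


@dataclass(frozen=True)
class BeamSpec:
    """Minibeam lattice geometry and mean-dose normalisation.

    Parameters
    ----------
    shape:
        ``"gaussian"`` (beam of standard deviation ``sigma``) or
        ``"square_tophat"`` (uniform square beam of side ``width``).
    sigma, width:
        Beam size in μm for the respective shape.
    ctc:
        Center-to-center lattice spacing, μm.
    grid_n:
        Beams per side of a finite ``grid_n x grid_n`` pattern, or
        :data:`INFINITE` for the periodic lattice.
    mean_dose:
        Field-mean dose (Gy) of the infinite lattice; single-beam
        amplitude is derived from it.
    """

    shape: str = "gaussian"
    sigma: float | None = None
    width: float | None = None
    ctc: float = 1800.0
    grid_n: float = INFINITE
    mean_dose: float = 60.0

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "square_tophat"):
            raise InvalidGeometryError(f"unknown beam shape {self.shape!r}")
        if self.ctc <= 0:
            raise InvalidGeometryError("ctc must be positive")
        if self.mean_dose < 0:
            raise InvalidGeometryError("mean_dose must be non-negative")
        if self.shape == "gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise InvalidGeometryError("gaussian spec requires sigma > 0")
        else:
            if self.width is None or self.width <= 0:
                raise InvalidGeometryError("square_tophat spec requires width > 0")
            if self.width > self.ctc:
                raise InvalidGeometryError("top-hat width must not exceed ctc")
        if self.grid_n != INFINITE:
            if self.grid_n != int(self.grid_n) or self.grid_n < 1:
                raise InvalidGeometryError("grid_n must be a positive integer or INFINITE")

    @property
    def ratio(self) -> float:
        """sigma/ctc — the single geometry parameter of the Gaussian lattice."""
        if self.shape != "gaussian":
            raise InvalidGeometryError("ratio defined for gaussian beams only")
        return self.sigma / self.ctc

    @property
    def is_infinite(self) -> bool:
        return self.grid_n == INFINITE

    def beam_centers_1d(self) -> np.ndarray | None:
        """1-D beam-center coordinates for a finite grid (None if infinite).

        A finite ``n x n`` grid is centred on the origin, so a 1x1 grid is
        a single beam at (0, 0).
        """
        if self.is_infinite:
            return None
        n = int(self.grid_n)
        return (np.arange(n) - (n - 1) / 2.0) * self.ctc


@dataclass(frozen=True)
class DoseField:
    """Sampled 2-D dose map.

    ``values[r, c]`` is the dose at ``(origin[0] + c*pixel_size,
    origin[1] + r*pixel_size)``; ``origin`` is the lattice-frame
    coordinate of the center of pixel (0, 0).
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidGeometryError("pixel_size must be positive")
        if np.any(np.asarray(self.values) < 0):
            raise InvalidGeometryError("dose values must be non-negative")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the pixel-center grid, μm."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, x0 + (nx - 1) * self.pixel_size, y0, y0 + (ny - 1) * self.pixel_size)


@dataclass(frozen=True)
class ProfileCut:
    """1-D dose profile along a cut through the field."""

    positions: np.ndarray  # μm along the cut, strictly increasing
    doses: np.ndarray  # Gy
    cut_kind: str = "diagonal"  # "axis" or "diagonal"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or np.any(np.diff(pos) <= 0):
            raise InvalidGeometryError("positions must be strictly increasing 1-D")
        if self.cut_kind not in ("axis", "diagonal"):
            raise InvalidGeometryError(f"unknown cut_kind {self.cut_kind!r}")


@dataclass(frozen=True)
class PvdrResult:
    """Peak-to-valley dose ratio with propagated uncertainty.

    ``is_lower_bound`` is set when the valley mean falls below the film
    noise floor, in which case ``value`` is the ratio of the peak mean to
    the noise floor (a lower limit on the true PVDR).
    """

    value: float
    uncertainty: float
    is_lower_bound: bool = False
    n_peaks: int = 0
    n_valleys: int = 0


@dataclass(frozen=True)
class SigmaFit:
    """Gaussian beam-size fit result."""

    sigma: float
    sigma_stderr: float
    amplitude: float
    center: float
    baseline: float


# ---------------------------------------------------------------------------
# lattice sums
# ---------------------------------------------------------------------------


def amplitude_from_mean(mean_dose: float, sigma: float, ctc: float) -> float:
    """Central amplitude A of one Gaussian beam normalised to a field mean.

    The infinite lattice of 2-D Gaussians of amplitude A integrates to
    ``A * 2*pi*sigma^2`` per unit cell of area ``ctc^2``, so
    ``A = mean_dose * ctc^2 / (2*pi*sigma^2)``.
    """
    if sigma <= 0 or ctc <= 0:
        raise InvalidGeometryError("sigma and ctc must be positive")
    return mean_dose * ctc**2 / (2.0 * math.pi * sigma**2)


def _truncation_order(sigma: float, ctc: float) -> int:
    # neighbours beyond 6 sigma contribute < 1e-8 relative
    return math.ceil(6.0 * sigma / ctc) + 1


def _theta(x: np.ndarray, sigma: float, ctc: float, order: int | None = None) -> np.ndarray:
    """1-D lattice sum  theta(x) = sum_i exp(-(x - i*ctc)^2 / (2 sigma^2)).

    Truncated at ``order`` lattice neighbours around each coordinate.
    """
    x = np.asarray(x, dtype=float)
    k = _truncation_order(sigma, ctc) if order is None else order
    i0 = np.floor(x / ctc)
    out = np.zeros_like(x)
    for di in range(-k, k + 1):
        out += np.exp(-((x - (i0 + di) * ctc) ** 2) / (2.0 * sigma**2))
    return out


def _theta_finite(x: np.ndarray, sigma: float, centers: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.exp(-((x[..., None] - centers) ** 2) / (2.0 * sigma**2)).sum(axis=-1)


def dose_at(spec: BeamSpec, x, y, truncation_order: int | None = None):
    """Dose (Gy) of the lattice at lattice-frame coordinates (x, y) μm.

    The square lattice of Gaussian beams is separable,
    ``D(x, y) = A * theta(x) * theta(y)``, both for the truncated infinite
    sum and for a finite grid.  Top-hat lattices are evaluated as
    indicator sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.shape == "gaussian":
        a = amplitude_from_mean(spec.mean_dose, spec.sigma, spec.ctc)
        if spec.is_infinite:
            tx = _theta(x, spec.sigma, spec.ctc, truncation_order)
            ty = _theta(y, spec.sigma, spec.ctc, truncation_order)
        else:
            centers = spec.beam_centers_1d()
            tx = _theta_finite(x, spec.sigma, centers)
            ty = _theta_finite(y, spec.sigma, centers)
        return a * tx * ty
    # square top-hat: uniform dose inside each width x width square
    peak = tophat_peak(spec.mean_dose, spec.width, spec.ctc)
    half = spec.width / 2.0
    if spec.is_infinite:
        fx = np.abs(x - np.round(x / spec.ctc) * spec.ctc) <= half
        fy = np.abs(y - np.round(y / spec.ctc) * spec.ctc) <= half
    else:
        centers = spec.beam_centers_1d()
        fx = (np.abs(x[..., None] - centers) <= half).any(axis=-1)
        fy = (np.abs(y[..., None] - centers) <= half).any(axis=-1)
    return peak * (fx & fy)


def tophat_peak(mean_dose: float, width: float, ctc: float) -> float:
    """In-beam dose of square top-hat beams delivering a given field mean.

    One beam of side ``width`` carries the whole unit-cell dose, so the
    peak is ``mean_dose * (ctc / width)^2`` — e.g. 180 μm beams on a
    1.8 mm grid concentrate a 60 Gy mean into 6000 Gy peaks.
    """
    if width <= 0 or ctc <= 0:
        raise InvalidGeometryError("width and ctc must be positive")
    if width > ctc:
        raise InvalidGeometryError("top-hat width must not exceed ctc")
    return mean_dose * (ctc / width) ** 2


# ---------------------------------------------------------------------------
# rendering and PVDR
# ---------------------------------------------------------------------------


def render_dose_map(
    spec: BeamSpec,
    extent: tuple[float, float, float, float],
    pixel_size: float,
) -> DoseField:
    """Sample the lattice dose on a regular pixel grid.

    ``extent`` is (xmin, xmax, ymin, ymax) in μm; pixel centers start at
    ``min + pixel_size/2`` so that whole unit cells average exactly to the
    field mean (midpoint rule).  ``pixel_size`` must resolve the lattice
    (at most ctc/32).
    """
    xmin, xmax, ymin, ymax = extent
    if xmax - xmin < spec.ctc or ymax - ymin < spec.ctc:
        raise GeometryError("extent must cover at least one unit cell")
    if pixel_size > spec.ctc / 32.0:
        raise ResolutionError(
            f"pixel_size {pixel_size} too coarse; need <= ctc/32 = {spec.ctc / 32:.3g}"
        )
    nx = int(round((xmax - xmin) / pixel_size))
    ny = int(round((ymax - ymin) / pixel_size))
    xs = xmin + (np.arange(nx) + 0.5) * pixel_size
    ys = ymin + (np.arange(ny) + 0.5) * pixel_size
    if spec.shape == "gaussian":
        a = amplitude_from_mean(spec.mean_dose, spec.sigma, spec.ctc)
        if spec.is_infinite:
            tx = _theta(xs, spec.sigma, spec.ctc)
            ty = _theta(ys, spec.sigma, spec.ctc)
        else:
            centers = spec.beam_centers_1d()
            tx = _theta_finite(xs, spec.sigma, centers)
            ty = _theta_finite(ys, spec.sigma, centers)
        values = a * np.outer(ty, tx)
    else:
        values = dose_at(spec, *np.meshgrid(xs, ys))
    return DoseField(values=values, pixel_size=pixel_size, origin=(float(xs[0]), float(ys[0])))


def pvdr_of_ratio(ratio: float) -> float:
    """Analytic PVDR of the infinite Gaussian lattice at a given sigma/ctc.

    Separability gives ``PVDR = [theta(0) / theta(ctc/2)]^2`` with the 1-D
    lattice sum evaluated in units of ctc.  Computed in the log domain;
    ratios so small that the valley underflows return ``inf``.
    """
    if ratio <= 0:
        raise InvalidGeometryError("ratio must be positive")
    k = _truncation_order(ratio, 1.0)
    i = np.arange(-k, k + 1, dtype=float)
    log_peak = _logsumexp(-(i**2) / (2.0 * ratio**2))
    log_valley = _logsumexp(-((0.5 - i) ** 2) / (2.0 * ratio**2))
    log_pvdr = 2.0 * (log_peak - log_valley)
    if log_pvdr > 700.0:
        return math.inf
    return float(np.exp(log_pvdr))


def _logsumexp(a: np.ndarray) -> float:
    m = float(np.max(a))
    return m + math.log(float(np.sum(np.exp(a - m))))


def pvdr_analytic(spec: BeamSpec) -> float:
    """PVDR of an infinite Gaussian lattice spec (see :func:`pvdr_of_ratio`)."""
    if spec.shape != "gaussian" or not spec.is_infinite:
        raise InvalidGeometryError("analytic PVDR requires an infinite Gaussian lattice")
    return pvdr_of_ratio(spec.ratio)


def extract_diagonal_profile(field: DoseField, step: float | None = None) -> ProfileCut:
    """Cut the field along the lattice diagonal y = x.

    The diagonal passes through the beam centers at (i*ctc, i*ctc), so
    successive peaks appear at spacing ``ctc * sqrt(2)`` along the cut —
    the cut shows the absolute dose maxima and the absolute minima at the
    cell-corner valleys.  Bilinear interpolation between pixel centers.
    """
    xmin, xmax, ymin, ymax = field.extent
    lo = max(xmin, ymin)
    hi = min(xmax, ymax)
    if hi <= lo:
        raise GeometryError("diagonal does not intersect the field extent")
    if step is None:
        step = field.pixel_size
    # parametrise by s along the diagonal: point = (s/sqrt2, s/sqrt2)
    s_lo = lo * math.sqrt(2.0)
    s_hi = hi * math.sqrt(2.0)
    n = max(int(math.floor((s_hi - s_lo) / step)) + 1, 2)
    s = s_lo + np.arange(n) * step
    xy = s / math.sqrt(2.0)
    cols = (xy - field.origin[0]) / field.pixel_size
    rows = (xy - field.origin[1]) / field.pixel_size
    doses = ndimage.map_coordinates(
        np.asarray(field.values, dtype=float), [rows, cols], order=1, mode="nearest"
    )
    return ProfileCut(positions=s, doses=doses, cut_kind="diagonal")


def pvdr_from_profile(
    cut: ProfileCut,
    noise_floor_frac: float = 0.005,
    prominence_frac: float = 0.05,
) -> PvdrResult:
    """PVDR extracted from a profile cut, peaks over valleys.

    Interior peaks are detected by prominence (``prominence_frac`` of the
    profile span, which rejects noise bumps on the beam flanks); each
    valley is the dose minimum between two consecutive peaks.  The PVDR
    is the mean peak over the mean valley dose, with the uncertainty from
    Gaussian propagation of the standard errors of the peak and valley
    determinations.  Valleys whose mean falls below
    ``noise_floor_frac * mean_peak`` cannot be resolved (film noise), and
    the result is flagged as a lower bound with the floor as denominator.
    """
    doses = np.asarray(cut.doses, dtype=float)
    span = float(doses.max() - doses.min())
    if span <= 1e-9 * max(abs(float(doses.max())), 1.0):
        return PvdrResult(value=1.0, uncertainty=0.0, is_lower_bound=False)
    prom = prominence_frac * span
    peaks, _ = signal.find_peaks(doses, prominence=prom)
    if len(peaks) < 2:
        raise GeometryError("need at least two interior peaks to bracket a valley")
    peak_vals = doses[peaks]
    peak_mean = float(peak_vals.mean())
    peak_sem = float(peak_vals.std(ddof=1) / math.sqrt(len(peak_vals))) if len(peak_vals) > 1 else 0.0
    floor = noise_floor_frac * peak_mean
    valley_vals = np.array(
        [doses[a : b + 1].min() for a, b in zip(peaks[:-1], peaks[1:])]
    )
    valleys = valley_vals  # one per inter-peak segment
    valley_mean = float(valley_vals.mean())
    valley_sem = (
        float(valley_vals.std(ddof=1) / math.sqrt(len(valley_vals))) if len(valley_vals) > 1 else 0.0
    )
    if valley_mean < floor:
        return PvdrResult(
            value=peak_mean / floor,
            uncertainty=0.0,
            is_lower_bound=True,
            n_peaks=len(peaks),
            n_valleys=len(valleys),
        )
    ratio = peak_mean / valley_mean
    unc = ratio * math.sqrt(
        (peak_sem / peak_mean) ** 2 + (valley_sem / valley_mean) ** 2
    )
    return PvdrResult(
        value=ratio,
        uncertainty=unc,
        is_lower_bound=False,
        n_peaks=len(peaks),
        n_valleys=len(valleys),
    )


# ---------------------------------------------------------------------------
# beam-size fitting
# ---------------------------------------------------------------------------


def _gauss1d(x, amplitude, center, sigma, baseline):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + baseline


def fit_beam_sigma(
    field_or_cut: DoseField | ProfileCut, relative_noise: bool = False
) -> SigmaFit:
    """Beam standard deviation from a Gaussian least-squares fit.

    Accepts a 1-D :class:`ProfileCut` over a single beam, or a
    :class:`DoseField` in which case the row through the beam is fitted.
    Free parameters: amplitude, center, sigma, baseline.  Set
    ``relative_noise`` when the dominant error is multiplicative (film
    darkening): residuals are then weighted by the signal, which makes
    the reported standard error consistent with that noise model.
    """
    if isinstance(field_or_cut, DoseField):
        vals = np.asarray(field_or_cut.values, dtype=float)
        # row through the beam: choose by integrated dose, which is robust
        # against single-pixel noise unlike the hottest pixel
        r = int(np.argmax(vals.sum(axis=1)))
        doses = vals[r, :]
        positions = field_or_cut.origin[0] + np.arange(vals.shape[1]) * field_or_cut.pixel_size
    else:
        positions = np.asarray(field_or_cut.positions, dtype=float)
        doses = np.asarray(field_or_cut.doses, dtype=float)
    baseline0 = float(doses.min())
    amp0 = float(doses.max() - baseline0)
    if amp0 <= 0:
        raise FitError("profile has no peak above baseline")
    center0 = float(positions[int(np.argmax(doses))])
    # moment-based width start
    w = np.clip(doses - baseline0, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (positions - center0) ** 2) / np.sum(w)))
    sigma0 = max(sigma0, (positions[1] - positions[0]))
    if relative_noise:
        # multiplicative noise model: near-zero tail pixels carry no
        # information but dilute the residual-variance estimate, so fit
        # only the signal region, weighted by the signal, with the
        # baseline pinned at the tail level
        keep = doses >= 0.05 * doses.max()
        pos_fit = positions[keep] if keep.sum() >= 16 else positions
        dose_fit = doses[keep] if keep.sum() >= 16 else doses
        model = lambda x, a, c, s: _gauss1d(x, a, c, s, baseline0)
        p0 = [amp0, center0, sigma0]
        weights = dose_fit.astype(float)
    else:
        pos_fit, dose_fit = positions, doses
        model = _gauss1d
        p0 = [amp0, center0, sigma0, baseline0]
        weights = None
    try:
        with warnings.catch_warnings():
            # noiseless data triggers a covariance warning; handled below
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model,
                pos_fit,
                dose_fit,
                p0=p0,
                sigma=weights,
                maxfev=10000,
            )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    if len(popt) == 3:
        popt = np.append(popt, baseline0)
        pcov = np.pad(pcov, ((0, 1), (0, 1)))
    if not np.all(np.isfinite(popt)):
        raise FitError(f"Gaussian fit returned non-finite parameters: {popt}")
    if np.all(np.isfinite(pcov)):
        perr = np.sqrt(np.diag(pcov))
    else:
        # exactly-fitting (noiseless) data: zero residual variance
        ssr = float(np.sum((_gauss1d(positions, *popt) - doses) ** 2))
        if ssr <= 1e-18 * float(np.sum(doses**2)):
            perr = np.zeros(4)
        else:
            raise FitError("covariance of the Gaussian fit could not be estimated")
    return SigmaFit(
        sigma=abs(float(popt[2])),
        sigma_stderr=float(perr[2]),
        amplitude=float(popt[0]),
        center=float(popt[1]),
        baseline=float(popt[3]),
    )


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def write_dose_map(field: DoseField, path: str | Path, spec: BeamSpec | None = None) -> None:
    """Write a dose map as matrix CSV plus a JSON sidecar (<path>.json)."""
    path = Path(path)
    np.savetxt(path, np.asarray(field.values), delimiter=",", fmt="%.8g")
    meta: dict = {"pixel_size_um": field.pixel_size, "origin_um": list(field.origin)}
    if spec is not None:
        meta["spec"] = {
            "shape": spec.shape,
            "sigma_um": spec.sigma,
            "width_um": spec.width,
            "ctc_um": spec.ctc,
            "grid_n": None if spec.is_infinite else int(spec.grid_n),
            "mean_dose_gy": spec.mean_dose,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_dose_map(path: str | Path) -> DoseField:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DoseField(
        values=values,
        pixel_size=float(meta["pixel_size_um"]),
        origin=tuple(meta["origin_um"]),
    )


def write_profile(cut: ProfileCut, path: str | Path) -> None:
    """Two-column CSV: position_um, dose_gy."""
    arr = np.column_stack([cut.positions, cut.doses])
    np.savetxt(path, arr, delimiter=",", fmt="%.8g", header="position_um,dose_gy", comments="")


def read_profile(path: str | Path, cut_kind: str = "diagonal") -> ProfileCut:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return ProfileCut(positions=arr[:, 0], doses=arr[:, 1], cut_kind=cut_kind)
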
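"""Areal surface-texture parameters of adhesion maps.

Six parameters summarise each map (or map quadrant):

* ``sdr`` — surface area ratio (%): the excess of the true interfacial
  area over the projected flat area, from the quadrilateral facet area
  :math:`A_{kl}` of each pixel cell.
* ``sdq`` — root-mean-square gradient of the surface slope.
* ``spk`` — reduced summit height (nN): the height of the peak zone
  above the core surface, constructed geometrically from the bearing
  area ratio (Abbott–Firestone) curve.
* ``sfd``, ``sfd_top``, ``sfd_bottom`` — spectral fractal dimensions
  ``2 - b``, where *b* is the log–log slope of the direction-averaged
  Fourier amplitude ``A(Q) ~ Q^b``.  ``sfd`` is fitted over the full
  resolvable band, ``sfd_top`` over features larger than 300 nm
  (``Q < 1/300 nm^-1``) and ``sfd_bottom`` over features smaller than
  300 nm (``Q >= 1/300 nm^-1``).

All formulas mix force (nN) and length (nm) dimensions, so parameter
values depend on the unit convention; units are fixed to nN / nm at load
time and every formula below assumes them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_qc import AdhesionMap, aggregate_cell, qc_check, split_quadrants

#: Crossover spatial frequency between the two fractal bands, nm^-1
#: (features of 300 nm lateral size).
Q_SPLIT_DEFAULT = 1.0 / 300.0

#: The six parameter names, in canonical column order.
PARAMETER_NAMES = ("sdr", "sdq", "spk", "sfd", "sfd_top", "sfd_bottom")


class ParameterError(ValueError):
    """A surface parameter could not be computed; the message names it."""


@dataclass
class SurfaceParameterSet:
    """The six texture parameters of one map (quadrant or whole cell)."""

    sdr: float
    sdq: float
    spk: float
    sfd: float
    sfd_top: float
    sfd_bottom: float
    cell_id: str = ""
    failed: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


@dataclass
class BearingAreaCurve:
    """Height vs the fraction of the surface at or above that height.

    ``ratios`` is the bearing area ratio in percent, strictly positive
    and covering (0, 100]; ``heights`` is non-increasing.
    """

    ratios: np.ndarray
    heights: np.ndarray

    def evaluate(self, p: np.ndarray | float) -> np.ndarray:
        """Height at bearing ratio ``p`` (%), by linear interpolation.

        For p below the first tabulated ratio the maximum height is
        returned (the whole surface lies at or above any height up to
        the summit).
        """
        p = np.asarray(p, dtype=float)
        # heights are descending in ratio; np.interp wants ascending x
        return np.interp(p, self.ratios, self.heights)


@dataclass
class RadialSpectrum:
    """Direction-averaged Fourier amplitude spectrum A(Q).

    ``Q`` are annular-bin centres in nm^-1 (strictly increasing, zero
    frequency excluded); ``A`` is the mean amplitude of the modes in
    each annulus.
    """

    Q: np.ndarray
    A: np.ndarray
    nyquist: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.Q) <= 0):
            raise ValueError("Q bins must be strictly increasing")
        if np.any(self.Q <= 0):
            raise ValueError("zero-frequency bin must be excluded")


@dataclass
class PowerLawFit:
    """Least-squares power-law fit of A(Q) ~ Q^b over one frequency band."""

    b: float
    q_min: float
    q_max: float
    r_squared: float
    n_bins: int = 0

    @property
    def fd(self) -> float:
        """Fractal dimension, defined as 2 - b."""
        return 2.0 - self.b


# ---------------------------------------------------------------------------
# Sdr / Sdq


def compute_sdr(amap: AdhesionMap) -> float:
    """Surface area ratio (%).

    Each pixel cell (k, l) contributes a quadrilateral facet area

    ``A_kl = 1/4 [sqrt(dy^2 + dzy0^2) + sqrt(dy^2 + dzy1^2)]
             * [sqrt(dx^2 + dzx0^2) + sqrt(dx^2 + dzx1^2)]``

    where ``dzy*`` are the value differences along y on the cell's two x
    edges and ``dzx*`` the differences along x on its two y edges.  Sdr
    is the summed excess over the flat projected area, in percent.
    """
    z = amap.values
    dx, dy = amap.dx, amap.dy
    dzy0 = z[:-1, :-1] - z[1:, :-1]  # y-difference at left edge
    dzy1 = z[:-1, 1:] - z[1:, 1:]  # y-difference at right edge
    dzx0 = z[:-1, :-1] - z[:-1, 1:]  # x-difference at top edge
    dzx1 = z[1:, :-1] - z[1:, 1:]  # x-difference at bottom edge
    a_kl = 0.25 * (
        np.sqrt(dy * dy + dzy0 * dzy0) + np.sqrt(dy * dy + dzy1 * dzy1)
    ) * (np.sqrt(dx * dx + dzx0 * dzx0) + np.sqrt(dx * dx + dzx1 * dzx1))
    n_cells = a_kl.size
    flat = n_cells * dx * dy
    return float((a_kl.sum() - flat) / flat * 100.0)


def compute_sdq(amap: AdhesionMap) -> float:
    """Root-mean-square gradient of the surface.

    RMS over all interior sample points of the backward-difference slope
    magnitude ``sqrt((dz/dx)^2 + (dz/dy)^2)``.
    """
    z = amap.values
    gx = (z[1:, 1:] - z[1:, :-1]) / amap.dx
    gy = (z[1:, 1:] - z[:-1, 1:]) / amap.dy
    return float(np.sqrt(np.mean(gx * gx + gy * gy)))


# ---------------------------------------------------------------------------
# bearing curve / Spk


def compute_bearing_curve(amap: AdhesionMap) -> BearingAreaCurve:
    """Bearing area ratio (Abbott–Firestone) curve of a map.

    The i-th largest value h has bearing ratio i/n * 100 %: the fraction
    of pixels lying at or above h.  Heights are exactly the sorted map
    values, so the curve is a lossless reordering of the surface.
    """
    values = np.sort(amap.values, axis=None)[::-1]
    n = values.size
    ratios = np.arange(1, n + 1) / n * 100.0
    return BearingAreaCurve(ratios=ratios, heights=values)


def _sliding_line_fits(p: np.ndarray, h: np.ndarray, width: int):
    """Slopes/intercepts of least-squares lines over all sliding windows.

    Windows are ``width`` consecutive points of the (equally spaced)
    abscissa ``p``.  Returns arrays of slope and intercept, one per
    window start, computed from running sums.
    """
    n = width

    def winsum(x):
        c = np.concatenate(([0.0], np.cumsum(x)))
        return c[n:] - c[:-n]

    sp = winsum(p)
    sh = winsum(h)
    sph = winsum(p * h)
    spp = winsum(p * p)
    denom = spp - sp * sp / n
    slope = (sph - sp * sh / n) / denom
    intercept = (sh - slope * sp) / n
    return slope, intercept


def compute_spk(amap: AdhesionMap, step: float = 0.1) -> float:
    """Reduced summit height (nN) from the bearing area ratio curve.

    Construction: (1) among all contiguous 40 %-wide windows of the
    bearing curve (sampled at ``step`` % resolution) fit a least-squares
    line and keep the window with the smallest absolute slope, taking
    the earliest window on ties; (2) extrapolate that core line to 0 %
    and 100 % bearing ratio; (3) intersect the horizontal line through
    the 0 %-height with the bearing curve; (4) the peak material between
    the curve and that horizontal line is replaced by a right triangle
    of equal area based on the intersection abscissa — Spk is that
    triangle's height.
    """
    values = amap.values
    if np.unique(values).size < 2:
        warnings.warn("degenerate bearing curve (single level): Spk = 0")
        return 0.0
    curve = compute_bearing_curve(amap)
    p = np.arange(0.0, 100.0 + step / 2, step)
    h = curve.evaluate(p)

    width = int(round(40.0 / step)) + 1  # points per 40 % window
    if width > p.size:
        warnings.warn("bearing curve shorter than the 40% window: Spk = 0")
        return 0.0
    slopes, intercepts = _sliding_line_fits(p, h, width)
    i_best = int(np.argmin(np.abs(slopes)))  # argmin takes first on ties
    a, c = slopes[i_best], intercepts[i_best]

    h_upper = c  # core line extrapolated to 0 % bearing ratio
    # first crossing of the (non-increasing) curve with the upper line
    below = np.nonzero(h <= h_upper)[0]
    if below.size == 0 or below[0] == 0:
        return 0.0
    j = below[0]
    # linear interpolation of the crossing abscissa
    p_cross = p[j - 1] + (h[j - 1] - h_upper) / (h[j - 1] - h[j]) * (p[j] - p[j - 1])
    # area between curve and upper horizontal line over [0, p_cross]
    pp = np.concatenate((p[:j], [p_cross]))
    hh = np.concatenate((h[:j], [h_upper]))
    area = float(np.trapezoid(hh - h_upper, pp))
    if p_cross <= 0 or area <= 0:
        return 0.0
    return 2.0 * area / p_cross


# ---------------------------------------------------------------------------
# spectrum / fractal dimensions


def fourier_transform(
    amap: AdhesionMap, subtract_mean: bool = True, hann_window: bool = False
) -> np.ndarray:
    """2-D DFT of the map with the 1/(Nx Ny) normalization.

    Under this convention Parseval's identity reads
    ``sum |F(u,v)|^2 = mean(z^2)`` — the variance of the grid when the
    mean has been subtracted.
    """
    z = amap.values
    if subtract_mean:
        z = z - z.mean()
    if hann_window:
        w = np.hanning(z.shape[0])
        z = z * np.outer(w, w)
    return np.fft.fft2(z) / z.size


def compute_radial_spectrum(
    amap: AdhesionMap,
    subtract_mean: bool = True,
    hann_window: bool = False,
    power: bool = False,
) -> RadialSpectrum:
    """Direction-averaged 2-D Fourier amplitude spectrum.

    The DFT uses the 1/(Nx Ny) normalization; mode (u, v) sits at
    spatial frequency ``Q = sqrt((u/(Nx dx))^2 + (v/(Ny dy))^2)`` with
    signed (symmetric) frequency indices.  Amplitudes ``|F|`` are
    averaged in annular bins one fundamental frequency wide; the bin
    centre is the mean Q of the contributing modes.  The zero-frequency
    bin is excluded.

    ``subtract_mean`` removes the grid mean first (kills only the
    zero-frequency spike); ``hann_window`` applies a Hann taper and
    ``power`` averages ``|F|^2`` instead — both off by default.
    """
    if amap.n_rows != amap.n_cols:
        raise ParameterError("radial spectrum requires a square grid")
    f = fourier_transform(amap, subtract_mean=subtract_mean, hann_window=hann_window)
    n = amap.n_rows
    amp = np.abs(f)
    if power:
        amp = amp * amp

    qx = np.fft.fftfreq(n, d=amap.dx)
    qy = np.fft.fftfreq(n, d=amap.dy)
    q = np.sqrt(qx[None, :] ** 2 + qy[:, None] ** 2)

    df = 1.0 / (n * amap.dx)  # fundamental frequency = bin width
    idx = np.rint(q / df).astype(int).ravel()
    amp_flat = amp.ravel()
    q_flat = q.ravel()
    nbins = idx.max() + 1
    counts = np.bincount(idx, minlength=nbins)
    a_sum = np.bincount(idx, weights=amp_flat, minlength=nbins)
    q_sum = np.bincount(idx, weights=q_flat, minlength=nbins)
    good = counts > 0
    good[0] = False  # exclude zero frequency
    return RadialSpectrum(
        Q=q_sum[good] / counts[good],
        A=a_sum[good] / counts[good],
        nyquist=1.0 / (2.0 * amap.dx),
    )


def fit_power_law(
    spectrum: RadialSpectrum, q_min: float, q_max: float
) -> PowerLawFit:
    """Fit ``A(Q) ~ Q^b`` by least squares in log–log coordinates.

    The band is half-open, ``q_min <= Q < q_max``; bins with zero
    amplitude are dropped.  At least three usable bins are required.
    """
    if not q_min < q_max:
        raise ParameterError(f"empty band: q_min={q_min} >= q_max={q_max}")
    mask = (spectrum.Q >= q_min) & (spectrum.Q < q_max) & (spectrum.A > 0)
    if mask.sum() < 3:
        raise ParameterError(
            f"power-law fit needs >= 3 bins with A > 0 in [{q_min:g}, {q_max:g}), "
            f"got {int(mask.sum())}"
        )
    lq = np.log(spectrum.Q[mask])
    la = np.log(spectrum.A[mask])
    b, c = np.polyfit(lq, la, 1)
    resid = la - (b * lq + c)
    ss_tot = float(np.sum((la - la.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        b=float(b),
        q_min=q_min,
        q_max=q_max,
        r_squared=r2,
        n_bins=int(mask.sum()),
    )


def compute_fractal_dimensions(
    amap: AdhesionMap,
    q_split: float = Q_SPLIT_DEFAULT,
    full_band_upper_frac: float = 0.8,
    hann_window: bool = False,
    power: bool = False,
) -> tuple[float, float, float]:
    """The three spectral fractal dimensions (sfd, sfd_top, sfd_bottom).

    ``sfd`` is fitted from the second radial bin up to
    ``full_band_upper_frac`` of the Nyquist frequency; ``sfd_top`` over
    ``Q < q_split`` (features larger than 300 nm at the default split)
    and ``sfd_bottom`` over ``q_split <= Q`` up to Nyquist.
    """
    spectrum = compute_radial_spectrum(
        amap, hann_window=hann_window, power=power
    )
    if spectrum.Q.size < 3:
        raise ParameterError("spectrum has fewer than 3 usable bins")
    q_lo = spectrum.Q[1]  # skip the first (lowest) bin
    nyq = spectrum.nyquist
    if not (q_lo < q_split < nyq):
        raise ParameterError(
            f"band split {q_split:g} nm^-1 outside the resolvable band "
            f"({q_lo:g}, {nyq:g})"
        )
    results = {}
    for name, (lo, hi) in {
        "sfd": (q_lo, full_band_upper_frac * nyq),
        "sfd_top": (q_lo, q_split),
        "sfd_bottom": (q_split, nyq * (1 + 1e-9)),
    }.items():
        try:
            results[name] = fit_power_law(spectrum, lo, hi).fd
        except ParameterError as exc:
            raise ParameterError(f"{name}: {exc}") from exc
    return results["sfd"], results["sfd_top"], results["sfd_bottom"]


# ---------------------------------------------------------------------------
# all six


def compute_all(
    amap: AdhesionMap,
    q_split: float = Q_SPLIT_DEFAULT,
    hann_window: bool = False,
    power: bool = False,
) -> SurfaceParameterSet:
    """All six parameters of one map, under the fixed nN / nm convention.

    Fractal-dimension fits that fail (e.g. on a constant map, whose
    spectrum is identically zero) are reported as NaN with the parameter
    recorded in ``failed``; cells carrying failures are excluded from
    the feature table upstream of classification.
    """
    sdr = compute_sdr(amap)
    sdq = compute_sdq(amap)
    spk = compute_spk(amap)
    failed: list[str] = []
    try:
        sfd, sfd_top, sfd_bottom = compute_fractal_dimensions(
            amap, q_split=q_split, hann_window=hann_window, power=power
        )
    except ParameterError as exc:
        warnings.warn(f"fractal-dimension fit failed for {amap.cell_id!r}: {exc}")
        sfd = sfd_top = sfd_bottom = math.nan
        failed = ["sfd", "sfd_top", "sfd_bottom"]
    return SurfaceParameterSet(
        sdr=sdr,
        sdq=sdq,
        spk=spk,
        sfd=sfd,
        sfd_top=sfd_top,
        sfd_bottom=sfd_bottom,
        cell_id=amap.cell_id,
        failed=tuple(failed),
    )


# ---------------------------------------------------------------------------
# feature extraction over a cohort


class SurfaceParameterExtractor(TransformerMixin, BaseEstimator):
    """Transform adhesion maps into the six-parameter feature table.

    Each map is split into four quadrants, the six parameters computed
    per quadrant, the mean-vs-median QC check applied across quadrants,
    and the retained quadrants averaged into one row per cell.

    Parameters
    ----------
    use_quadrants : bool
        Analyse the four quadrants separately and average (the standard
        protocol); if False, compute parameters on the whole map.
    qc_threshold : float
        Relative mean-vs-median difference above which a cell is flagged.
    qc_auto_exclude : bool
        Automatically drop the most deviant quadrant of a flagged cell
        (at most twice) instead of only flagging it.
    q_split : float
        Band crossover frequency for sfd_top / sfd_bottom, nm^-1.
    hann_window, power : bool
        Spectrum-estimation variants (Hann taper; power instead of
        amplitude averaging), both off by default.

    This transformer is stateless; ``fit`` only validates parameters.
    """

    def __init__(
        self,
        use_quadrants: bool = True,
        qc_threshold: float = 0.5,
        qc_auto_exclude: bool = False,
        q_split: float = Q_SPLIT_DEFAULT,
        hann_window: bool = False,
        power: bool = False,
    ):
        self.use_quadrants = use_quadrants
        self.qc_threshold = qc_threshold
        self.qc_auto_exclude = qc_auto_exclude
        self.q_split = q_split
        self.hann_window = hann_window
        self.power = power

    def fit(self, X: Sequence[AdhesionMap] | None = None, y=None):
        if not 0 < self.qc_threshold:
            raise ValueError("qc_threshold must be positive")
        self.n_features_out_ = len(PARAMETER_NAMES)
        self.qc_reports_ = {}
        return self

    def transform(self, X: Sequence[AdhesionMap]) -> pd.DataFrame:
        """Return one feature row per cell.

        Columns: ``cell_id``, the six parameters, ``class`` (when the
        maps carry labels), ``qc_flag``, ``n_quadrants``.  Cells whose
        fractal fits failed in every retained quadrant get NaN features
        and are expected to be dropped before classification.
        """
        rows = []
        self.qc_reports_ = {}
        for amap in X:
            rows.append(self._extract_one(amap))
        return pd.DataFrame(rows)

    def _extract_one(self, amap: AdhesionMap) -> dict:
        if self.use_quadrants:
            qs = split_quadrants(amap)
            per_quad = [
                compute_all(
                    q,
                    q_split=self.q_split,
                    hann_window=self.hann_window,
                    power=self.power,
                ).as_dict()
                for q in qs
            ]
            by_param = {
                p: [d[p] for d in per_quad] for p in PARAMETER_NAMES
            }
            finite = {
                p: v for p, v in by_param.items() if np.all(np.isfinite(v))
            }
            if finite:
                report = qc_check(
                    finite,
                    threshold=self.qc_threshold,
                    auto_exclude=self.qc_auto_exclude,
                )
                retained = [
                    i for i in range(4) if i not in report.excluded_quadrants
                ]
                flag = report.flag
            else:
                report = None
                retained = list(range(4))
                flag = "review"
            self.qc_reports_[amap.cell_id] = report
            agg = aggregate_cell(per_quad, retained)
            row = {"cell_id": amap.cell_id, **agg}
            row["qc_flag"] = flag
        else:
            params = compute_all(
                amap,
                q_split=self.q_split,
                hann_window=self.hann_window,
                power=self.power,
            )
            row = {"cell_id": amap.cell_id, **params.as_dict()}
            row["n_quadrants"] = 1
            row["qc_flag"] = "review" if params.failed else "pass"
        if amap.class_label is not None:
            row["class"] = amap.class_label
        return row


def extract_features(
    maps: Sequence[AdhesionMap], **kwargs
) -> tuple[pd.DataFrame, dict]:
    """Functional wrapper over :class:`SurfaceParameterExtractor`.

    Returns the feature table and the per-cell QC reports.
    """
    ext = SurfaceParameterExtractor(**kwargs).fit()
    table = ext.transform(maps)
    return table, ext.qc_reports_
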
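"""Quantification of eisosome fluorescence microscopy.

Implements the image measurements used throughout the study: Richardson-Lucy
deconvolution with rolling-ball background equalization, the network factor
(a density-of-signal score separating clustered from dispersed plasma-
membrane patterns), Pearson colocalization over the AND-combined channel
masks, periphery linearization ("straightening") of medial cell sections,
sub-pixel radial peak-distance measurement between two channels, the
PM/cytosol intensity ratio, and the center-to-center gap of tetraspanner
double strands.

All physical distances are reported in nanometers via the pixel size carried
by :class:`ImageFrame`; pixel centers sit at integer (row, col) coordinates
with the origin at the top-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage import restoration
from skimage.filters import threshold_otsu

__all__ = [
    "ImageFrame",
    "PeakPair",
    "UndefinedColocalizationError",
    "UndefinedRatioError",
    "preprocess",
    "network_factor",
    "pearson_and_mask",
    "estimate_shift",
    "linearize_periphery",
    "radial_peak_distance",
    "pm_cytosol_ratio",
    "strand_gap_width",
]

NETWORK_FACTOR_CUTOFF = 0.15  # <= clustered/patchy, > dispersed/network-like
MIN_AND_MASK_PIXELS = 10
DEFAULT_R2_MIN = 0.8


class UndefinedColocalizationError(ValueError):
    """AND mask too small for a meaningful correlation."""


class UndefinedRatioError(ValueError):
    """Cytosol intensity non-positive after background subtraction."""


@dataclass
class ImageFrame:
    """2D intensity image with physical pixel size.

    ``data`` is a float array (photon-scale intensities may be negative after
    background subtraction or read noise); ``pixel_size_nm`` > 0.
    """

    data: np.ndarray
    pixel_size_nm: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ImageFrame expects a 2D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite intensities")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")


def _as_array(image) -> np.ndarray:
    return image.data if isinstance(image, ImageFrame) else np.asarray(image, dtype=float)


def _gaussian_psf(sigma_px: float, half: int | None = None) -> np.ndarray:
    if half is None:
        half = max(3, int(math.ceil(4 * sigma_px)))
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax ** 2) / (2 * sigma_px ** 2))
    psf = np.outer(g, g)
    return psf / psf.sum()


def preprocess(image, psf_sigma: float, iterations: int = 20,
               ball_radius: float = 12.5):
    """Rolling-ball background equalization followed by Richardson-Lucy
    deconvolution.

    ``psf_sigma`` is the Gaussian PSF sigma in pixels; ``ball_radius`` the
    rolling-ball radius in pixels (default: 25 px diameter);
    ``iterations = 0`` skips the deconvolution.  Output is non-negative, of
    the same type (array or :class:`ImageFrame`) as the input.
    """
    data = _as_array(image)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite input image")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    background = restoration.rolling_ball(data, radius=ball_radius)
    out = np.clip(data - background, 0.0, None)
    if iterations > 0:
        scale = out.max()
        if scale > 0:
            psf = _gaussian_psf(psf_sigma)
            out = restoration.richardson_lucy(out / scale, psf,
                                              num_iter=iterations, clip=False)
            out = np.clip(out, 0.0, None) * scale
    if isinstance(image, ImageFrame):
        return ImageFrame(out, image.pixel_size_nm, image.channel)
    return out


def network_factor(image, cell_mask) -> float:
    """Fraction of cell pixels carrying above-threshold signal.

    A density-of-signal score for the lateral protein distribution: punctate
    or patchy patterns concentrate their intensity in a small pixel fraction
    (values <= 0.15), dispersed network-like patterns spread it widely
    (> 0.15).  The threshold is Otsu's, computed within the cell mask, which
    makes the score invariant to positive affine intensity rescaling.  For a
    (near-)uniform image no threshold separates signal from background and
    the fully dispersed limit 1.0 is returned.
    """
    data = _as_array(image)
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cell mask")
    vals = data[mask]
    spread = float(vals.max() - vals.min())
    if spread <= 1e-12 * max(abs(float(vals.max())), 1.0):
        return 1.0
    thr = threshold_otsu(vals)
    return float(np.mean(vals > thr))


def pearson_and_mask(image_a, image_b) -> float:
    """Pearson correlation of two channels over their AND-combined masks.

    Each channel is thresholded (Otsu), the masks intersected, and the
    correlation computed over the intersection.  Invariant to positive affine
    rescaling of either channel.
    """
    a, b = _as_array(image_a), _as_array(image_b)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    mask = (a > threshold_otsu(a)) & (b > threshold_otsu(b))
    n = int(mask.sum())
    if n < MIN_AND_MASK_PIXELS:
        raise UndefinedColocalizationError(
            f"AND mask has {n} px (< {MIN_AND_MASK_PIXELS})")
    va, vb = a[mask], b[mask]
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        raise UndefinedColocalizationError("constant intensities over the AND mask")
    return float(np.corrcoef(va, vb)[0, 1])


def estimate_shift(image_a, image_b):
    """Rigid (row, col) shift of channel B relative to A by phase
    cross-correlation, for upstream channel registration."""
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(_as_array(image_a), _as_array(image_b),
                                          upsample_factor=20)
    return tuple(float(s) for s in shift)


def linearize_periphery(image, center, radius: float, half_width: float) -> np.ndarray:
    """Straighten an annulus along the cell periphery.

    Samples the annulus ``[radius - half_width, radius + half_width]`` around
    ``center`` (row, col) along arc length with bilinear interpolation.
    Returns a strip of shape ``(2*half_width + 1, round(2 pi radius))`` whose
    rows run from the inner to the outer annulus edge.
    """
    data = _as_array(image)
    cr, cc = float(center[0]), float(center[1])
    r_out = radius + half_width
    if (cr - r_out < 0 or cc - r_out < 0
            or cr + r_out > data.shape[0] - 1 or cc + r_out > data.shape[1] - 1):
        raise ValueError("annulus exits image bounds")
    n_arc = int(round(2 * math.pi * radius))
    theta = np.linspace(0.0, 2 * math.pi, n_arc, endpoint=False)
    offsets = np.arange(-half_width, half_width + 1, dtype=float)
    rr = cr + np.outer(radius + offsets, np.sin(theta))
    cc_ = cc + np.outer(radius + offsets, np.cos(theta))
    return ndimage.map_coordinates(data, [rr, cc_], order=1, mode="nearest")


def _gauss(x, amp, mu, sigma, off):
    return amp * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2)) + off


def _fit_gaussian(xs: np.ndarray, ys: np.ndarray):
    """Least-squares single-Gaussian + offset fit.

    Returns (mu, mu_err, r2) or None when the fit fails.
    """
    off0 = float(ys.min())
    amp0 = float(ys.max() - off0)
    if amp0 <= 0:
        return None
    mu0 = float(xs[int(np.argmax(ys))])
    sigma0 = max((xs[-1] - xs[0]) / 10.0, 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _gauss, xs, ys, p0=[amp0, mu0, sigma0, off0],
            bounds=([0, xs[0], 0.1, -np.inf], [np.inf, xs[-1], xs[-1] - xs[0], np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    resid = ys - _gauss(xs, *popt)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    mu_err = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return float(popt[1]), mu_err, float(r2)


@dataclass(frozen=True)
class PeakPair:
    """Sub-pixel peak positions of two channels along one radial profile."""

    anchor: tuple[float, float]
    pos_a_nm: float
    err_a_nm: float
    pos_b_nm: float
    err_b_nm: float
    r2_a: float
    r2_b: float

    @property
    def separation_nm(self) -> float:
        return abs(self.pos_a_nm - self.pos_b_nm)


def _sample_profile(data: np.ndarray, anchor, direction, ts: np.ndarray) -> np.ndarray:
    rr = anchor[0] + direction[0] * ts
    cc = anchor[1] + direction[1] * ts
    if (rr.min() < 0 or cc.min() < 0
            or rr.max() > data.shape[0] - 1 or cc.max() > data.shape[1] - 1):
        raise ValueError("profile leaves image bounds")
    return ndimage.map_coordinates(data, [rr, cc], order=1)


def radial_peak_distance(image_a: ImageFrame, image_b: ImageFrame, anchors,
                         center, profile_length: int = 21,
                         r2_min: float = DEFAULT_R2_MIN):
    """Radial separation of two channels' intensity peaks at each anchor.

    For every anchor point on the periphery, a line profile of
    ``profile_length`` px is extracted radially (perpendicular to the local
    periphery, i.e. along anchor - center) from both registered channels; a
    single Gaussian plus offset is fitted per channel with sub-pixel center.
    Profiles whose fit R^2 falls below ``r2_min`` in either channel are
    dropped and counted.

    Returns ``(pairs, n_rejected)``; raises if every profile was rejected.
    """
    if image_a.pixel_size_nm != image_b.pixel_size_nm:
        raise ValueError("channels have different pixel sizes")
    px = image_a.pixel_size_nm
    ts = np.arange(profile_length, dtype=float) - (profile_length - 1) / 2.0
    pairs: list[PeakPair] = []
    n_rejected = 0
    for anchor in anchors:
        ar, ac = float(anchor[0]), float(anchor[1])
        dr, dc = ar - float(center[0]), ac - float(center[1])
        norm = math.hypot(dr, dc)
        if norm == 0:
            raise ValueError("anchor coincides with center")
        direction = (dr / norm, dc / norm)
        prof_a = _sample_profile(image_a.data, (ar, ac), direction, ts)
        prof_b = _sample_profile(image_b.data, (ar, ac), direction, ts)
        fit_a = _fit_gaussian(ts, prof_a)
        fit_b = _fit_gaussian(ts, prof_b)
        if fit_a is None or fit_b is None or fit_a[2] < r2_min or fit_b[2] < r2_min:
            n_rejected += 1
            continue
        pairs.append(PeakPair(
            anchor=(ar, ac),
            pos_a_nm=fit_a[0] * px, err_a_nm=fit_a[1] * px,
            pos_b_nm=fit_b[0] * px, err_b_nm=fit_b[1] * px,
            r2_a=fit_a[2], r2_b=fit_b[2],
        ))
    if not pairs:
        raise ValueError("all radial profiles were rejected")
    return pairs, n_rejected


def _disk_mask(shape, center, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def pm_cytosol_ratio(image, outer_circle, inner_circle, background: float = 0.0,
                     erode_px: float = 3.0) -> float:
    """Plasma-membrane over cytosol mean-intensity ratio.

    ``outer_circle`` and ``inner_circle`` are ``(center, radius)`` with the
    inner strictly inside the outer; the PM intensity is the mean over the
    annulus between them, the cytosol intensity the mean over the inner disk
    eroded by ``erode_px``.  ``background`` is subtracted from both, which
    makes the ratio invariant to a constant offset on the whole image.
    """
    data = _as_array(image)
    (oc, orad), (ic, irad) = outer_circle, inner_circle
    if irad >= orad:
        raise ValueError("inner circle must be strictly inside the outer")
    outer = _disk_mask(data.shape, oc, orad)
    inner = _disk_mask(data.shape, ic, irad)
    pm = outer & ~inner
    cyt = _disk_mask(data.shape, ic, max(irad - erode_px, 1.0))
    if pm.sum() == 0 or cyt.sum() == 0:
        raise ValueError("degenerate ROI masks")
    pm_mean = float(data[pm].mean()) - background
    cyt_mean = float(data[cyt].mean()) - background
    if cyt_mean <= 0:
        raise UndefinedRatioError("cytosol intensity <= 0 after background subtraction")
    return pm_mean / cyt_mean


def _two_gauss(x, a1, mu1, a2, mu2, sigma, off):
    return (a1 * np.exp(-((x - mu1) ** 2) / (2 * sigma ** 2))
            + a2 * np.exp(-((x - mu2) ** 2) / (2 * sigma ** 2)) + off)


def strand_gap_width(image: ImageFrame, axis_angle_deg: float = 0.0,
                     min_separation_px: float = 1.0,
                     min_amp_ratio: float = 0.2) -> float | None:
    """Center-to-center gap (nm) of a double-strand structure.

    Intensity profiles perpendicular to the strand axis are averaged along
    the strand and a two-Gaussian model (shared width, common offset) is
    fitted.  Returns ``None`` (no-gap signal) when the structure is single-
    stranded: the two fitted centers collapse below ``min_separation_px`` or
    one amplitude drops below ``min_amp_ratio`` of the other.
    """
    data = image.data
    if axis_angle_deg % 360 != 0:
        data = ndimage.rotate(data, -axis_angle_deg, reshape=True, order=1)
    # restrict the along-axis average to the columns occupied by the strands
    col_mass = data.sum(axis=0)
    keep = col_mass > 0.5 * col_mass.max()
    prof = data[:, keep].mean(axis=1)
    xs = np.arange(prof.size, dtype=float)

    single = _fit_gaussian(xs, prof)
    off0 = float(prof.min())
    amp0 = float(prof.max() - off0)
    mu0 = float(xs[int(np.argmax(prof))]) if single is None else single[0]
    # the merged profile of two close strands is barely bimodal, so the fit
    # is started from several candidate separations and the best SSE kept
    best = None
    best_sse = np.inf
    for d0 in (1.0, 2.5, 5.0, 8.0):
        try:
            popt, _ = optimize.curve_fit(
                _two_gauss, xs, prof,
                p0=[amp0 / 2, mu0 - d0 / 2, amp0 / 2, mu0 + d0 / 2, 1.5, off0],
                bounds=([0, 0, 0, 0, 0.3, -np.inf],
                        [np.inf, xs[-1], np.inf, xs[-1], xs[-1], np.inf]),
                maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((prof - _two_gauss(xs, *popt)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        return None
    a1, mu1, a2, mu2, _, _ = best
    if abs(mu1 - mu2) < min_separation_px:
        return None
    if min(a1, a2) < min_amp_ratio * max(a1, a2):
        return None
    return float(abs(mu1 - mu2) * image.pixel_size_nm)
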
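"""The 171-entry lesion texture descriptor suite.

Six descriptor families are computed on the lesion's bounding box, in a
frozen order, with frozen per-family feature lists::

    histogram  4   mean, variance, skewness, kurtosis of in-mask intensities
    glcm      22   direction-averaged co-occurrence statistics (list below)
    glrl      11   direction-averaged run-length statistics (classical set)
    wavelet   28   2-level Daubechies-4 DWT, 7 subbands x 4 statistics
    gabor     48   3 scales x 4 orientations, magnitude x 4 statistics
    lbp       58   uniform 8-neighbor local binary pattern histogram
    ------------
    total    171

All families operate on the half-open bounding box of the mask, so the
vector is invariant to translating the ROI inside a larger image and to
adding background pixels outside the mask.

The 22 GLCM statistics are the 13 classical Haralick measures (angular
second moment, contrast, correlation, sum-of-squares variance, inverse
difference moment, sum average, sum variance, sum entropy, entropy,
difference variance, difference entropy, and the two information measures
of correlation) plus 9 complements (autocorrelation, cluster shade, cluster
prominence, dissimilarity, homogeneity, maximum probability, inverse
difference, inverse difference normalized, inverse difference moment
normalized).  Note: under the formula conventions frozen here,
``homogeneity`` and ``inverse_difference`` share the same definition as
published variants of each other's family; both are retained because the
22-name list is a documented package convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

from .errors import ConfigurationError, DataError
from .segmentation import LesionMask, ScanImage

# --------------------------------------------------------------------------
# naming / layout contracts
# --------------------------------------------------------------------------

FAMILY_SIZES = {
    "histogram": 4,
    "glcm": 22,
    "glrl": 11,
    "wavelet": 28,
    "gabor": 48,
    "lbp": 58,
}
TOTAL_FEATURES = 171

HISTOGRAM_NAMES = ("mean", "variance", "skewness", "kurtosis")

GLCM_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "dissimilarity",
    "homogeneity",
    "maximum_probability",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

GLRL_NAMES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
)

WAVELET_SUBBANDS = ("LH1", "HL1", "HH1", "LH2", "HL2", "HH2", "LL2")
SUBBAND_STATS = ("mean_abs", "std", "energy", "entropy")

GABOR_N_SCALES = 3
GABOR_N_ORIENTATIONS = 4
#: Center frequencies (cycles/pixel) per scale; one octave apart.
GABOR_FREQUENCIES = (0.4, 0.2, 0.1)
GABOR_ORIENTATIONS_DEG = (0, 45, 90, 135)

#: Direction angle -> (drow, dcol) offset for GLCM / GLRL scanning.
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
DEFAULT_DIRECTIONS = (0, 45, 90, 135)

#: LBP neighbor offsets in circular order (bit 0 = east, counter-clockwise).
LBP_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1),
    (0, -1), (1, -1), (1, 0), (1, 1),
)


def _uniform_lbp_codes() -> tuple[int, ...]:
    codes = []
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        if transitions <= 2:
            codes.append(code)
    return tuple(codes)


#: The 58 uniform 8-bit patterns, in ascending code order.
UNIFORM_LBP_CODES = _uniform_lbp_codes()
assert len(UNIFORM_LBP_CODES) == 58


def feature_names(prefix: str = "") -> tuple[str, ...]:
    """Return the 171 feature names in extraction order."""
    names: list[str] = []
    names += [f"histogram.{n}" for n in HISTOGRAM_NAMES]
    names += [f"glcm.{n}" for n in GLCM_NAMES]
    names += [f"glrl.{n}" for n in GLRL_NAMES]
    names += [f"wavelet.{stat}.{band}" for band in WAVELET_SUBBANDS for stat in SUBBAND_STATS]
    for s in range(GABOR_N_SCALES):
        for o_deg in GABOR_ORIENTATIONS_DEG:
            for stat in ("mean", "std", "energy", "entropy"):
                names.append(f"gabor.s{s}.o{o_deg}.{stat}")
    names += [f"lbp.u{code}" for code in UNIFORM_LBP_CODES]
    assert len(names) == TOTAL_FEATURES
    return tuple(prefix + n for n in names)


FEATURE_NAMES = feature_names()


@dataclass
class DescriptorVector:
    """Ordered, named 171-entry feature vector of one lesion."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (TOTAL_FEATURES,):
            raise DataError(
                f"descriptor vector must have {TOTAL_FEATURES} entries, "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            bad = self.names[int(np.argmax(~np.isfinite(self.values)))]
            raise DataError(f"non-finite descriptor value for feature {bad!r}")

    def __len__(self) -> int:
        return TOTAL_FEATURES


@dataclass
class QuantizedROI:
    """Lesion bounding box re-quantized to integer gray levels 1..n_levels.

    Out-of-mask pixels hold level 0 and never contribute to matrix
    statistics.
    """

    pixels: np.ndarray  # int levels, 0 outside mask
    mask: np.ndarray  # bool, same shape
    n_levels: int


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise DataError("empty lesion mask")
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def crop_to_roi(image, mask) -> tuple[np.ndarray, np.ndarray]:
    """Crop image and mask to the mask's half-open bounding box."""
    img = image.pixels if isinstance(image, ScanImage) else np.asarray(image, dtype=float)
    msk = mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    if img.shape != msk.shape:
        raise DataError(f"image shape {img.shape} != mask shape {msk.shape}")
    rs, cs = _bounding_box(msk)
    return img[rs, cs], msk[rs, cs]


def quantize_roi(image, mask, n_levels: int = 16) -> QuantizedROI:
    """Re-quantize in-mask intensities to ``1..n_levels`` by min–max binning."""
    if n_levels < 2:
        raise ConfigurationError(f"n_levels must be >= 2, got {n_levels}")
    img, msk = crop_to_roi(image, mask)
    vals = img[msk]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(img.shape, dtype=np.int64)
    if hi == lo:
        q[msk] = 1
    else:
        lev = np.floor((img[msk] - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
        q[msk] = np.clip(lev, 1, n_levels)
    return QuantizedROI(pixels=q, mask=msk, n_levels=n_levels)


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log(0)=0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


#: Energies below this are numerical residue of exactly-cancelling filters
#: (e.g. a DC-free kernel on a constant image); their entropy is defined 0.
ENERGY_EPS = 1e-18


def _four_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    """mean(|.|), std, energy, entropy-of-normalized-squares of an array."""
    flat = np.asarray(values, dtype=float).ravel()
    mean_abs = float(np.abs(flat).mean())
    std = float(flat.std())
    energy = float((flat ** 2).sum())
    if energy > ENERGY_EPS:
        entropy = _entropy_bits(flat ** 2 / energy)
    else:
        entropy = 0.0
    return mean_abs, std, energy, entropy


# --------------------------------------------------------------------------
# family 1: gray-level histogram (4)
# --------------------------------------------------------------------------


def histogram_features(image, mask) -> np.ndarray:
    """Mean, variance, skewness and kurtosis of in-mask intensities.

    Population moments; a zero-variance ROI yields skewness = kurtosis = 0
    by convention (kurtosis is the raw fourth standardized moment, not
    excess).
    """
    img, msk = crop_to_roi(image, mask)
    vals = img[msk].astype(float)
    if vals.size == 0:
        raise DataError("histogram_features requires a non-empty mask")
    mean = float(vals.mean())
    var = float(((vals - mean) ** 2).mean())
    if var == 0.0:
        return np.array([mean, 0.0, 0.0, 0.0])
    m3 = float(((vals - mean) ** 3).mean())
    m4 = float(((vals - mean) ** 4).mean())
    return np.array([mean, var, m3 / var**1.5, m4 / var**2])


# --------------------------------------------------------------------------
# family 2: gray-level co-occurrence matrix (22)
# --------------------------------------------------------------------------


def glcm_matrix(roi: QuantizedROI, direction: int, distance: int = 1) -> np.ndarray | None:
    """Symmetric, normalized co-occurrence matrix for one direction.

    Only pixel pairs with both endpoints in the mask are counted.  Returns
    ``None`` when no valid pair exists for this direction.
    """
    dr, dc = DIRECTION_OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    g = roi.n_levels
    h, w = roi.pixels.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = roi.pixels[r0s:r0e, c0s:c0e]
    b = roi.pixels[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = roi.mask[r0s:r0e, c0s:c0e] & roi.mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    if not valid.any():
        return None
    av, bv = a[valid] - 1, b[valid] - 1
    mat = np.zeros((g, g), dtype=float)
    np.add.at(mat, (av, bv), 1.0)
    np.add.at(mat, (bv, av), 1.0)  # symmetric accumulation
    return mat / mat.sum()


def _glcm_statistics(p: np.ndarray, g: int) -> np.ndarray:
    i = np.arange(1, g + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    asm = float((p ** 2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    sosv = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # p_{x+y} over k = 2..2G and p_{x-y} over k = 0..G-1
    ksum = np.arange(2, 2 * g + 1, dtype=float)
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    kdiff = np.arange(0, g, dtype=float)
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    sum_avg = float((ksum * p_sum).sum())
    sum_var = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy_bits(p_sum)
    entropy = _entropy_bits(p.ravel())
    diff_avg = float((kdiff * p_diff).sum())
    diff_var = float(((kdiff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = _entropy_bits(p_diff)

    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-(pxy * log_pxy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    autoc = float((ii * jj * p).sum())
    cshade = float(((ii + jj - mu_x - mu_y) ** 3 * p).sum())
    cprom = float(((ii + jj - mu_x - mu_y) ** 4 * p).sum())
    dissi = float((np.abs(ii - jj) * p).sum())
    homog = float((p / (1.0 + np.abs(ii - jj))).sum())
    maxpr = float(p.max())
    invdiff = float((p / (1.0 + np.abs(ii - jj))).sum())
    inn = float((p / (1.0 + np.abs(ii - jj) / g)).sum())
    idmn = float((p / (1.0 + (ii - jj) ** 2 / g**2)).sum())

    return np.array([
        asm, contrast, correlation, sosv, idm, sum_avg, sum_var, sum_ent,
        entropy, diff_var, diff_ent, imc1, imc2,
        autoc, cshade, cprom, dissi, homog, maxpr, invdiff, inn, idmn,
    ])


def glcm_features(
    roi: QuantizedROI,
    directions: tuple[int, ...] = DEFAULT_DIRECTIONS,
    distance: int = 1,
) -> np.ndarray:
    """22 co-occurrence statistics on the direction-averaged GLCM."""
    mats = []
    for d in directions:
        m = glcm_matrix(roi, d, distance)
        if m is None:
            warnings.warn(f"no valid pixel pair for GLCM direction {d} deg; skipped")
        else:
            mats.append(m)
    if not mats:
        raise DataError("no GLCM direction has a valid pixel pair")
    avg = np.mean(mats, axis=0)
    return _glcm_statistics(avg, roi.n_levels)


# --------------------------------------------------------------------------
# family 3: gray-level run-length matrix (11)
# --------------------------------------------------------------------------


def _direction_lines(roi: QuantizedROI, direction: int):
    """Yield (levels, in_mask) 1-D arrays for each scan line of a direction."""
    q, m = roi.pixels, roi.mask
    if direction == 0:
        for r in range(q.shape[0]):
            yield q[r, :], m[r, :]
    elif direction == 90:
        for c in range(q.shape[1]):
            yield q[:, c], m[:, c]
    elif direction == 135:  # main diagonals (dr=1, dc=1 traversal)
        h, w = q.shape
        for off in range(-h + 1, w):
            yield np.diagonal(q, offset=off), np.diagonal(m, offset=off)
    elif direction == 45:  # anti-diagonals
        qf, mf = q[::-1, :], m[::-1, :]
        h, w = q.shape
        for off in range(-h + 1, w):
            yield np.diagonal(qf, offset=off), np.diagonal(mf, offset=off)
    else:
        raise ConfigurationError(f"unknown direction {direction}")


def glrl_matrix(roi: QuantizedROI, direction: int) -> np.ndarray:
    """Run-length count matrix (gray level x run length) for one direction.

    Runs are maximal stretches of identical level along the scan line;
    out-of-mask pixels break runs and are never counted.
    """
    g = roi.n_levels
    max_len = max(roi.pixels.shape)
    mat = np.zeros((g, max_len), dtype=float)
    for levels, in_mask in _direction_lines(roi, direction):
        run_level, run_len = 0, 0
        for lev, ok in zip(levels, in_mask):
            lev = int(lev) if ok else 0
            if lev == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    mat[run_level - 1, run_len - 1] += 1
                run_level, run_len = lev, (1 if lev > 0 else 0)
        if run_level > 0:
            mat[run_level - 1, run_len - 1] += 1
    return mat


def glrl_features(
    roi: QuantizedROI, directions: tuple[int, ...] = DEFAULT_DIRECTIONS
) -> np.ndarray:
    """The classical 11 run-length statistics on the direction-averaged matrix.

    SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE; run
    percentage uses the number of in-mask pixels as denominator.
    """
    mats = [glrl_matrix(roi, d) for d in directions]
    mats = [m for m in mats if m.sum() > 0]
    if not mats:
        raise DataError("no GLRL direction has any run")
    r = np.mean(mats, axis=0)
    n_runs = r.sum()
    n_pixels = int(roi.mask.sum())
    g_idx = np.arange(1, r.shape[0] + 1, dtype=float)[:, None]
    l_idx = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    sre = float((r / l_idx**2).sum() / n_runs)
    lre = float((r * l_idx**2).sum() / n_runs)
    gln = float((r.sum(axis=1) ** 2).sum() / n_runs)
    rln = float((r.sum(axis=0) ** 2).sum() / n_runs)
    rp = float(n_runs / n_pixels)
    lgre = float((r / g_idx**2).sum() / n_runs)
    hgre = float((r * g_idx**2).sum() / n_runs)
    srlge = float((r / (g_idx**2 * l_idx**2)).sum() / n_runs)
    srhge = float((r * g_idx**2 / l_idx**2).sum() / n_runs)
    lrlge = float((r * l_idx**2 / g_idx**2).sum() / n_runs)
    lrhge = float((r * g_idx**2 * l_idx**2).sum() / n_runs)
    return np.array([sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge])


# --------------------------------------------------------------------------
# family 4: 2-level Daubechies-4 wavelet transform (28)
# --------------------------------------------------------------------------

# Daubechies-4 (8-tap, 4 vanishing moments) decomposition low-pass filter.
DB4_DEC_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
DB4_DEC_HI = np.array([(-1) ** k * DB4_DEC_LO[len(DB4_DEC_LO) - 1 - k]
                       for k in range(len(DB4_DEC_LO))])

MIN_WAVELET_SIZE = 4


def _dwt_1d(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Filter + dyadic downsample along one axis with symmetric extension.

    Output sample ``k`` is ``sum_m filt[m] * x_ext[2k + m]`` where ``x_ext``
    is ``x`` padded symmetrically by ``len(filt)//2`` on the left and
    ``len(filt)`` on the right; output length is ``ceil(n / 2)``.
    """
    n = x.shape[axis]
    L = len(filt)
    pad = [(0, 0)] * x.ndim
    pad[axis] = (L // 2, L)
    ext = np.pad(x, pad, mode="symmetric")
    out_len = (n + 1) // 2
    windows = np.lib.stride_tricks.sliding_window_view(ext, L, axis=axis)
    starts = np.arange(out_len) * 2
    windows = np.take(windows, starts, axis=axis)
    return np.tensordot(windows, filt, axes=([-1], [0]))


def _dwt2(image: np.ndarray) -> dict[str, np.ndarray]:
    """One 2-D DWT level: returns LL, LH, HL, HH.

    Subband naming: first letter = filter applied along axis 0 (rows index),
    second letter = filter along axis 1.
    """
    lo0 = _dwt_1d(image, DB4_DEC_LO, axis=0)
    hi0 = _dwt_1d(image, DB4_DEC_HI, axis=0)
    return {
        "LL": _dwt_1d(lo0, DB4_DEC_LO, axis=1),
        "LH": _dwt_1d(lo0, DB4_DEC_HI, axis=1),
        "HL": _dwt_1d(hi0, DB4_DEC_LO, axis=1),
        "HH": _dwt_1d(hi0, DB4_DEC_HI, axis=1),
    }


def wavelet_features(roi_image: np.ndarray, levels: int = 2) -> np.ndarray:
    """28 statistics from the 2-level Daubechies-4 decomposition.

    For each of the 7 subbands (LH1, HL1, HH1, LH2, HL2, HH2, LL2): mean of
    absolute coefficients, standard deviation, energy, and entropy of the
    normalized squared coefficients.
    """
    img = np.asarray(roi_image, dtype=float)
    if min(img.shape) < MIN_WAVELET_SIZE:
        raise DataError(
            f"ROI {img.shape} too small for the wavelet transform: "
            f"minimum size is {MIN_WAVELET_SIZE}x{MIN_WAVELET_SIZE}"
        )
    level1 = _dwt2(img)
    level2 = _dwt2(level1["LL"])
    subbands = {
        "LH1": level1["LH"], "HL1": level1["HL"], "HH1": level1["HH"],
        "LH2": level2["LH"], "HL2": level2["HL"], "HH2": level2["HH"],
        "LL2": level2["LL"],
    }
    out = []
    for band in WAVELET_SUBBANDS:
        out.extend(_four_stats(subbands[band]))
    return np.array(out)


# --------------------------------------------------------------------------
# family 5: Gabor filter bank (48)
# --------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _gabor_bank(frequencies: tuple[float, ...], thetas_deg: tuple[int, ...]):
    """DC-free Gabor kernels for every (scale, orientation) pair."""
    bank = []
    for f in frequencies:
        for t in thetas_deg:
            k = gabor_kernel(frequency=f, theta=np.deg2rad(t))
            real = np.real(k)
            real = real - real.mean()  # remove DC so constant images respond 0
            bank.append((real, np.imag(k)))
    return bank


def gabor_features(
    roi_image: np.ndarray,
    frequencies: tuple[float, ...] = GABOR_FREQUENCIES,
    orientations_deg: tuple[int, ...] = GABOR_ORIENTATIONS_DEG,
) -> np.ndarray:
    """48 statistics of Gabor response magnitudes (12 filters x 4 stats).

    Each filter response is computed by reflect-padded convolution of the
    DC-free kernel; statistics (mean, std, energy, entropy) are taken on the
    magnitude image.
    """
    img = np.asarray(roi_image, dtype=float)
    if img.size == 0:
        raise DataError("gabor_features requires a non-empty ROI")
    out = []
    for real, imag in _gabor_bank(tuple(frequencies), tuple(orientations_deg)):
        resp_r = ndimage.convolve(img, real, mode="reflect")
        resp_i = ndimage.convolve(img, imag, mode="reflect")
        magnitude = np.hypot(resp_r, resp_i)
        out.extend(_four_stats(magnitude))
    return np.array(out)


# --------------------------------------------------------------------------
# family 6: uniform local binary patterns (58)
# --------------------------------------------------------------------------


def lbp_features(roi_image: np.ndarray) -> np.ndarray:
    """Normalized histogram over the 58 uniform 8-neighbor LBP codes.

    Codes use the 8 immediate neighbors in counter-clockwise order starting
    east; a neighbor >= center sets its bit.  Only pixels whose full 3x3
    neighborhood lies inside the ROI contribute; non-uniform patterns are
    discarded and the histogram is normalized over the remaining pixels
    (all-zero if every pattern is non-uniform).
    """
    img = np.asarray(roi_image, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise DataError(f"ROI {img.shape} too small for LBP: minimum is 3x3")
    center = img[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(LBP_OFFSETS):
        neigh = img[1 + dr : img.shape[0] - 1 + dr, 1 + dc : img.shape[1] - 1 + dc]
        codes |= (neigh >= center).astype(np.int64) << bit
    counts = np.bincount(codes.ravel(), minlength=256).astype(float)
    hist = counts[list(UNIFORM_LBP_CODES)]
    total = hist.sum()
    return hist / total if total > 0 else hist


# --------------------------------------------------------------------------
# full suite
# --------------------------------------------------------------------------


def extract_all(image, mask, n_levels: int = 16) -> DescriptorVector:
    """Compute the full 171-entry descriptor vector of one segmented lesion.

    Families are concatenated in the fixed order histogram | GLCM | GLRL |
    wavelet | Gabor | LBP; block sizes 4/22/11/28/48/58 are asserted.
    """
    img, msk = crop_to_roi(image, mask)
    roi = quantize_roi(img, msk, n_levels=n_levels)
    blocks = {
        "histogram": histogram_features(img, msk),
        "glcm": glcm_features(roi),
        "glrl": glrl_features(roi),
        "wavelet": wavelet_features(img),
        "gabor": gabor_features(img),
        "lbp": lbp_features(img),
    }
    for family, block in blocks.items():
        if len(block) != FAMILY_SIZES[family]:
            raise DataError(
                f"family {family!r} produced {len(block)} features, "
                f"expected {FAMILY_SIZES[family]}"
            )
    values = np.concatenate([blocks[f] for f in FAMILY_SIZES])
    return DescriptorVector(values=values)
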
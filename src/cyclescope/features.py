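"""The 240-parameter DNA-channel feature vector per nucleus.

Five feature families are computed from the background-corrected DNA
channel of each segmented nucleus:

* 9 intensity properties (mean, SD, median, max, min, sum, CV%,
  quantile-50%, Michelson contrast);
* 4 basic morphology properties (area, roundness, width, length);
* 16 SER texture features: eight pattern filters (spot, hole, ridge,
  valley, saddle, edge, bright, dark) built from the scale-normalized
  Hessian eigenvalues and gradient of the Gaussian-smoothed image, each
  reduced over the ROI at two scales (sigma = 1 and 2 px);
* 4 Haralick grey-level co-occurrence statistics (contrast, correlation,
  homogeneity, sum variance) at distance 1 on 32 grey levels;
* 207 STAR morphology properties: 23 intensity-weighted shape
  descriptors (symmetry, threshold compactness, axial, radial, profile)
  computed on 9 image variants — the raw DNA channel and each of the 8
  SER responses at sigma = 1 (e.g. "Nucleus Radial Mean SER-Edge").

The catalog (name, family, variant, scale) is frozen: every feature
vector has exactly 240 finite values in catalog order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import perimeter_crofton as _perimeter

from .segmentation import NucleusROI

__all__ = [
    "FeatureDef",
    "default_catalog",
    "catalog_names",
    "intensity_properties",
    "basic_morphology",
    "ser_filter_bank",
    "ser_features",
    "haralick_features",
    "star_properties",
    "FieldFeatureExtractor",
    "extract_features",
    "SER_FILTERS",
    "N_FEATURES",
]

SER_FILTERS = ("spot", "hole", "ridge", "valley", "saddle", "edge",
               "bright", "dark")
SER_SCALES = (1.0, 2.0)
N_FEATURES = 240

INTENSITY_NAMES = (
    "Intensity Nucleus Mean", "Intensity Nucleus SD",
    "Intensity Nucleus Median", "Intensity Nucleus Max",
    "Intensity Nucleus Min", "Intensity Nucleus Sum",
    "Intensity Nucleus CV %", "Intensity Nucleus Quantile 50%",
    "Intensity Nucleus Contrast",
)
MORPHOLOGY_NAMES = (
    "Nucleus Area", "Nucleus Roundness", "Nucleus Width", "Nucleus Length",
)
HARALICK_NAMES = (
    "Nucleus Haralick Contrast", "Nucleus Haralick Correlation",
    "Nucleus Haralick Homogeneity", "Nucleus Haralick Sum Variance",
)
STAR_NAMES = (
    tuple(f"Nucleus Symmetry {k:02d}" for k in range(1, 9))
    + tuple(f"Nucleus Threshold Compactness {t}%" for t in
            (30, 40, 50, 60, 70))
    + ("Nucleus Axial Small Length", "Nucleus Axial Length",
       "Nucleus Axial Anisotropy", "Nucleus Axial Ratio")
    + ("Nucleus Radial Mean", "Nucleus Radial Relative Deviation",
       "Nucleus Radial Mean Normalized",
       "Nucleus Radial Inner Intensity Fraction")
    + ("Nucleus Profile Correlation", "Nucleus Profile Outer Ratio")
)
#: STAR image variants: raw DNA channel, then each sigma=1 SER response.
STAR_VARIANTS = ("raw",) + SER_FILTERS


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry: frozen name, family and computation variant."""

    name: str
    family: str          # intensity | basic_morphology | SER | haralick | STAR
    variant: str = ""    # STAR image variant or SER filter name
    scale: float = 0.0   # SER scale (px), 0 where not applicable


def default_catalog() -> list[FeatureDef]:
    """The frozen, ordered 240-entry feature catalog."""
    catalog: list[FeatureDef] = []
    for name in INTENSITY_NAMES:
        catalog.append(FeatureDef(name, "intensity"))
    for name in MORPHOLOGY_NAMES:
        catalog.append(FeatureDef(name, "basic_morphology"))
    for sigma in SER_SCALES:
        for filt in SER_FILTERS:
            catalog.append(FeatureDef(
                f"Nucleus SER {filt.capitalize()} {sigma:g} px", "SER",
                variant=filt, scale=sigma))
    for name in HARALICK_NAMES:
        catalog.append(FeatureDef(name, "haralick"))
    for variant in STAR_VARIANTS:
        suffix = "" if variant == "raw" else f" SER-{variant.capitalize()}"
        for name in STAR_NAMES:
            catalog.append(FeatureDef(name + suffix, "STAR", variant=variant,
                                      scale=0.0 if variant == "raw" else 1.0))
    assert len(catalog) == N_FEATURES
    return catalog


def catalog_names(catalog: list[FeatureDef] | None = None) -> list[str]:
    return [f.name for f in (catalog or default_catalog())]


# ---------------------------------------------------------------------------
# intensity and morphology


def intensity_properties(roi: NucleusROI, dna: np.ndarray) -> np.ndarray:
    """Nine intensity properties of the ROI pixels.

    SD is the population standard deviation; CV is ``100*sd/mean`` in
    percent (0 when the mean is 0); contrast is Michelson
    ``(max-min)/(max+min)`` (0 when ``max+min`` is 0).  Quantile-50%
    equals the median; it is retained as a distinct catalog slot.
    """
    v = roi.pixel_values(dna).astype(np.float64)
    if v.size == 0:
        raise ValueError("empty ROI mask")
    mean = v.mean()
    sd = v.std()
    vmax, vmin = v.max(), v.min()
    cv = 100.0 * sd / mean if mean != 0 else 0.0
    contrast = (vmax - vmin) / (vmax + vmin) if (vmax + vmin) != 0 else 0.0
    median = float(np.median(v))
    return np.array([mean, sd, median, vmax, vmin, v.sum(), cv, median,
                     contrast])


def basic_morphology(roi: NucleusROI, pixel_size_um: float = 1.0
                     ) -> np.ndarray:
    """Area (um^2), roundness, width and length (um) of the mask.

    Width/length are the minor/major axis lengths of the second-moment
    ellipse (4*sqrt(eigenvalue) of the pixel-coordinate covariance);
    roundness is ``4*pi*area_px / perimeter^2`` clipped to [0, 1].  A
    single-pixel mask degenerates to width = length = pixel size and
    roundness 1.
    """
    area_um2 = roi.area_px * pixel_size_um ** 2
    rows, cols = np.nonzero(roi.mask)
    if rows.size == 0:
        raise ValueError("empty ROI mask")
    if rows.size == 1:
        return np.array([area_um2, 1.0, pixel_size_um, pixel_size_um])
    coords = np.stack([rows, cols]).astype(np.float64)
    cov = np.cov(coords, bias=True)
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    minor, major = 4.0 * np.sqrt(np.clip(eigvals, 0.0, None))
    per = _perimeter(roi.mask, directions=4)
    roundness = (4.0 * np.pi * roi.area_px / per ** 2) if per > 0 else 1.0
    return np.array([area_um2, float(np.clip(roundness, 0.0, 1.0)),
                     max(minor, 1.0) * pixel_size_um,
                     max(major, 1.0) * pixel_size_um])


# ---------------------------------------------------------------------------
# SER texture filters


def ser_filter_bank(dna: np.ndarray, sigma: float) -> dict[str, np.ndarray]:
    """Eight non-negative SER pattern responses at scale ``sigma``.

    With ``I_s`` the Gaussian-smoothed image, ``l1 <= l2`` the
    eigenvalues of the scale-normalized Hessian (sigma^2 * H), ``g`` the
    scale-normalized gradient magnitude and ``I_S`` a coarse background
    (Gaussian at 4*sigma):

    - spot   = sqrt(max(0,-l1) * max(0,-l2))   (both curvatures negative)
    - hole   = sqrt(max(0, l1) * max(0, l2))
    - ridge  = max(0,-l1) - max(0,-l2)         (one-directional crest)
    - valley = max(0, l2) - max(0, l1)
    - saddle = sqrt(max(0,-l1) * max(0, l2))
    - edge   = g
    - bright = max(0, I_s - I_S)
    - dark   = max(0, I_S - I_s)
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(dna, dtype=np.float64)
    # offsetting by the minimum removes the small DC bias of the
    # discrete derivative kernels (constant image -> exactly zero
    # responses); the minimum, unlike the mean, is invariant to pixel
    # permutation, preserving exact translation equivariance
    img = img - float(img.min())
    s2 = sigma * sigma
    hrr = s2 * ndi.gaussian_filter(img, sigma, order=(2, 0))
    hcc = s2 * ndi.gaussian_filter(img, sigma, order=(0, 2))
    hrc = s2 * ndi.gaussian_filter(img, sigma, order=(1, 1))
    half_tr = 0.5 * (hrr + hcc)
    disc = np.sqrt(np.clip((0.5 * (hrr - hcc)) ** 2 + hrc ** 2, 0.0, None))
    l1 = half_tr - disc
    l2 = half_tr + disc
    gr = ndi.gaussian_filter(img, sigma, order=(1, 0))
    gc = ndi.gaussian_filter(img, sigma, order=(0, 1))
    g = sigma * np.sqrt(gr ** 2 + gc ** 2)
    smooth = ndi.gaussian_filter(img, sigma)
    coarse = ndi.gaussian_filter(img, 4.0 * sigma)

    neg1 = np.clip(-l1, 0.0, None)
    neg2 = np.clip(-l2, 0.0, None)
    pos1 = np.clip(l1, 0.0, None)
    pos2 = np.clip(l2, 0.0, None)
    return {
        "spot": np.sqrt(neg1 * neg2),
        "hole": np.sqrt(pos1 * pos2),
        "ridge": neg1 - neg2,
        "valley": pos2 - pos1,
        "saddle": np.sqrt(neg1 * pos2),
        "edge": g,
        "bright": np.clip(smooth - coarse, 0.0, None),
        "dark": np.clip(coarse - smooth, 0.0, None),
    }


def ser_features(roi: NucleusROI, responses: dict[str, np.ndarray],
                 dna: np.ndarray) -> np.ndarray:
    """Per-ROI SER reduction: mean squared response / (ROI mean)^2.

    Normalizing by the squared ROI mean intensity makes the texture
    energy invariant to overall staining brightness.
    """
    mean = roi.pixel_values(dna).mean()
    denom = mean * mean if mean != 0 else 1.0
    return np.array([
        (roi.pixel_values(responses[f]) ** 2).mean() / denom
        for f in SER_FILTERS])


# ---------------------------------------------------------------------------
# Haralick co-occurrence features

_GLCM_LEVELS = 32
# distance-1 offsets; with the symmetric transpose these cover the four
# directed axial neighbours
_GLCM_OFFSETS = ((0, 1), (1, 0))


def _masked_glcm(quant: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix of within-ROI pairs."""
    glcm = np.zeros((_GLCM_LEVELS, _GLCM_LEVELS), dtype=np.float64)
    for dr, dc in _GLCM_OFFSETS:
        a_mask = mask[:mask.shape[0] - dr, :mask.shape[1] - dc]
        b_mask = mask[dr:, dc:]
        valid = a_mask & b_mask
        a = quant[:quant.shape[0] - dr, :quant.shape[1] - dc][valid]
        b = quant[dr:, dc:][valid]
        np.add.at(glcm, (a, b), 1.0)
        np.add.at(glcm, (b, a), 1.0)
    total = glcm.sum()
    return glcm / total if total > 0 else glcm


def haralick_features(roi: NucleusROI, dna: np.ndarray) -> np.ndarray:
    """Haralick contrast, correlation, homogeneity and sum variance.

    ROI pixels are quantized to 32 levels between the ROI min and max;
    the GLCM is built at distance 1, symmetric, restricted to pixel
    pairs both inside the ROI and normalized to sum 1.  A constant ROI
    (or one with no within-ROI pairs) returns the degenerate convention
    ``(0, 0, 1, 0)``.
    """
    v = roi.pixel_values(dna).astype(np.float64)
    if v.size == 0:
        raise ValueError("empty ROI mask")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.array([0.0, 0.0, 1.0, 0.0])
    r0, c0, r1, c1 = roi.bbox
    patch = np.asarray(dna, dtype=np.float64)[r0:r1, c0:c1]
    quant = np.clip(((patch - vmin) / (vmax - vmin) * _GLCM_LEVELS
                     ).astype(np.int64), 0, _GLCM_LEVELS - 1)
    glcm = _masked_glcm(quant, roi.mask)
    if glcm.sum() == 0:
        return np.array([0.0, 0.0, 1.0, 0.0])

    idx = np.arange(_GLCM_LEVELS, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    contrast = float((glcm * (i - j) ** 2).sum())
    px = glcm.sum(axis=1)
    mu = float((idx * px).sum())
    var = float(((idx - mu) ** 2 * px).sum())
    correlation = float(((i - mu) * (j - mu) * glcm).sum() / var) if var > 0 \
        else 0.0
    homogeneity = float((glcm / (1.0 + (i - j) ** 2)).sum())
    # sum variance: variance of i+j under its marginal distribution
    k = np.arange(2 * _GLCM_LEVELS - 1, dtype=np.float64)
    p_sum = np.array([
        np.trace(np.fliplr(glcm), offset=_GLCM_LEVELS - 1 - d)
        for d in range(2 * _GLCM_LEVELS - 1)])
    sum_avg = float((k * p_sum).sum())
    sum_var = float(((k - sum_avg) ** 2 * p_sum).sum())
    return np.array([contrast, correlation, homogeneity, sum_var])


# ---------------------------------------------------------------------------
# STAR intensity-weighted morphology


def _hull_pixel_area(rows: np.ndarray, cols: np.ndarray) -> float:
    """Pixel count of the convex hull of a lattice point set.

    Pick's theorem: lattice points inside or on a polygon of area A with
    B boundary lattice points number A + B/2 + 1.  Degenerate (collinear)
    sets count their own pixels.
    """
    pts = np.column_stack([rows, cols]).astype(float)
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        return float(len(pts))
    area = hull.volume  # 2-D: enclosed area
    verts = pts[hull.vertices]
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    boundary = float(np.gcd(
        np.abs(edges[:, 0]).astype(np.int64),
        np.abs(edges[:, 1]).astype(np.int64)).sum())
    return area + boundary / 2.0 + 1.0


def star_properties(roi: NucleusROI, image_variant: np.ndarray) -> np.ndarray:
    """23 intensity-weighted shape descriptors of one image variant.

    With ``w_i`` the (non-negative) intensity of mask pixel ``i`` and
    ``(r_i, theta_i)`` its polar coordinates about the intensity-weighted
    centroid:

    - symmetry(k), k = 1..8: ``|sum w*exp(1j*k*theta)| / sum w``
      (0 when the total intensity is 0);
    - threshold compactness at t in {0.3..0.7}: area of the pixel set
      ``{w >= t*max(w)}`` divided by the area of its convex hull
      (1 for sets of <= 2 pixels);
    - axial: sqrt of the small/large eigenvalues of the weighted
      second-moment matrix, their anisotropy
      ``(lmax - lmin)/(lmax + lmin)`` and the ratio ``sqrt(lmin/lmax)``;
    - radial: weighted mean radius, its relative deviation
      (weighted SD / mean), the mean radius normalized by the equivalent
      radius ``sqrt(area_px/pi)``, and the fraction of total intensity
      within half the equivalent radius;
    - profile: Pearson correlation between ``w`` and the distance to the
      mask border (0 if either is constant), and the ratio of mean
      intensity in the outer 25%-depth border band to the mean elsewhere
      (1 when both are empty of intensity).
    """
    rows, cols = np.nonzero(roi.mask)
    if rows.size == 0:
        raise ValueError("empty ROI mask")
    w = np.clip(roi.pixel_values(image_variant).astype(np.float64), 0.0, None)
    total = w.sum()
    out = np.zeros(23)

    if total > 0:
        crow = (w * rows).sum() / total
        ccol = (w * cols).sum() / total
    else:
        crow, ccol = rows.mean(), cols.mean()
    dr = rows - crow
    dc = cols - ccol
    r = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    # a pixel at (numerically) zero radius has no defined direction and
    # therefore no anisotropy to contribute: drop it from the harmonic
    # numerators (it stays in the normalizing total), which keeps the
    # symmetry features exactly invariant under rigid motions
    w_ang = np.where(r > 1e-6, w, 0.0)

    # symmetry 1..8
    if total > 0:
        for k in range(1, 9):
            out[k - 1] = np.abs(
                (w_ang * np.exp(1j * k * theta)).sum()) / total

    # threshold compactness
    wmax = w.max() if w.size else 0.0
    for ti, t in enumerate((0.3, 0.4, 0.5, 0.6, 0.7)):
        sel = w >= t * wmax if wmax > 0 else np.ones_like(w, dtype=bool)
        n_sel = int(sel.sum())
        if n_sel <= 2:
            out[8 + ti] = 1.0
            continue
        hull_area = _hull_pixel_area(rows[sel], cols[sel])
        out[8 + ti] = min(n_sel / hull_area, 1.0) if hull_area > 0 else 1.0

    # axial
    if total > 0:
        m_rr = (w * dr * dr).sum() / total
        m_cc = (w * dc * dc).sum() / total
        m_rc = (w * dr * dc).sum() / total
        eig = np.sort(np.linalg.eigvalsh(
            np.array([[m_rr, m_rc], [m_rc, m_cc]])))
        lmin = float(np.clip(eig[0], 0, None))
        lmax = float(np.clip(eig[1], 0, None))
    else:
        lmin = lmax = 0.0
    out[13] = np.sqrt(lmin)
    out[14] = np.sqrt(lmax)
    out[15] = (lmax - lmin) / (lmax + lmin) if (lmax + lmin) > 0 else 0.0
    out[16] = np.sqrt(lmin / lmax) if lmax > 0 else 1.0

    # radial
    req = np.sqrt(rows.size / np.pi)
    if total > 0:
        rmean = (w * r).sum() / total
        rsd = np.sqrt((w * (r - rmean) ** 2).sum() / total)
        out[17] = rmean
        out[18] = rsd / rmean if rmean > 0 else 0.0
        out[19] = rmean / req if req > 0 else 0.0
        out[20] = w[r <= 0.5 * req].sum() / total

    # profile
    border_dist = ndi.distance_transform_edt(roi.mask)[rows, cols]
    if w.std() > 0 and border_dist.std() > 0:
        out[21] = float(np.corrcoef(w, border_dist)[0, 1])
    dmax = border_dist.max()
    outer = border_dist <= 0.25 * dmax
    num = w[outer].mean() if outer.any() else 0.0
    den = w[~outer].mean() if (~outer).any() else 0.0
    if den > 0:
        out[22] = num / den
    else:
        out[22] = 1.0 if num == 0 else 1e6
    return out


# ---------------------------------------------------------------------------
# assembly


class FieldFeatureExtractor:
    """Computes the 240-feature vector for every ROI of one field.

    The SER filter banks are computed once per field (on the
    background-corrected DNA channel) and reused across ROIs, which is
    what makes whole-plate extraction tractable.
    """

    def __init__(self, dna_corrected: np.ndarray, pixel_size_um: float = 1.0,
                 catalog: list[FeatureDef] | None = None):
        self.dna = np.asarray(dna_corrected, dtype=np.float64)
        self.pixel_size_um = pixel_size_um
        self.catalog = catalog or default_catalog()
        if len(self.catalog) != N_FEATURES:
            raise ValueError("catalog must contain exactly 240 entries")
        self.banks = {s: ser_filter_bank(self.dna, s) for s in SER_SCALES}

    def features(self, roi: NucleusROI) -> np.ndarray:
        parts = [
            intensity_properties(roi, self.dna),
            basic_morphology(roi, self.pixel_size_um),
        ]
        for sigma in SER_SCALES:
            parts.append(ser_features(roi, self.banks[sigma], self.dna))
        parts.append(haralick_features(roi, self.dna))
        parts.append(star_properties(roi, self.dna))
        for filt in SER_FILTERS:
            parts.append(star_properties(roi, self.banks[1.0][filt]))
        vec = np.concatenate(parts)
        assert vec.shape == (N_FEATURES,)
        return vec


def extract_features(roi: NucleusROI, dna_corrected: np.ndarray,
                     pixel_size_um: float = 1.0,
                     catalog: list[FeatureDef] | None = None) -> np.ndarray:
    """240-feature vector of one nucleus (convenience single-ROI path).

    For whole fields prefer :class:`FieldFeatureExtractor`, which shares
    the per-field SER filter banks across all nuclei.
    """
    return FieldFeatureExtractor(
        dna_corrected, pixel_size_um, catalog).features(roi)
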
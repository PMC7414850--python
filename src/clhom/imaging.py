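"""Image and point-pattern quantification operators.

Covers the fluorescence-lifetime (FLIM) pipeline for intracellular Cl-
(mono-exponential lifetime fit with optional instrument-response convolution,
Stern-Volmer conversion, Cl--vs-depth regression), the laminar
immunofluorescence quantifications (IB4 barycentric axis, trans-laminar
intensity profile, MAGI global membrane index, MASC-pi membrane-distance
profile, white-matter background subtraction), and the immunogold analyses
(65 nm transitive clustering into oligomer/monomer groups, all-pairs distance
histogram).

Images are plain 2-D numpy arrays (row 0 = dorsal edge by convention);
coordinates are (row, col) in pixels with an explicit pixel size in um.
Particle coordinates are (x, y) in nm in the section plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = [
    "FlimTrace",
    "LaminarImage",
    "ParticleSet",
    "QuadraticAxis",
    "ClusterResult",
    "fit_lifetime",
    "stern_volmer_cl",
    "cl_depth_regression",
    "ib4_axis",
    "translaminar_profile",
    "magi_index",
    "masc_profile",
    "subtract_background",
    "cluster_particles",
    "oligomer_percentage",
    "interparticle_histogram",
]

DEFAULT_PIXEL_SIZE_UM = 0.103
DEFAULT_KSV_PER_M = 32.0
DEFAULT_CUTOFF_NM = 65.0


@dataclass
class FlimTrace:
    """Photon arrival-time histogram of one region of interest."""

    counts: np.ndarray
    bin_width_ns: float
    irf: np.ndarray | None = None  # instrument response histogram, same binning
    ksv_per_m: float = DEFAULT_KSV_PER_M  # Stern-Volmer constant, M-1
    tau_zero_ns: float = 5.5  # lifetime at 0 mM Cl-
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width_ns <= 0:
            raise ValueError("bin width must be positive")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.irf is not None:
            self.irf = np.asarray(self.irf, dtype=float)

    @property
    def times_ns(self) -> np.ndarray:
        return (np.arange(self.counts.size) + 0.5) * self.bin_width_ns


@dataclass
class LaminarImage:
    """Multi-channel 2-D confocal image with laminar annotations.

    ``channels`` maps channel names ('kcc2', 'ib4', 'cgrp', ...) to arrays of
    identical shape.  Annotations are optional and hold boolean masks
    (``lamina_masks``, ``intracellular_mask``, ``background_region``) and
    membrane polylines (arrays of (row, col) vertices, traversed with the
    intracellular side on the left).
    """

    channels: dict
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    dorsal_at_top: bool = True
    lamina_masks: dict = field(default_factory=dict)
    intracellular_mask: np.ndarray | None = None
    background_region: np.ndarray | None = None
    membrane_polylines: list = field(default_factory=list)
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ParticleSet:
    """Immunogold particle centroids of one cell body, nm coordinates."""

    xy_nm: np.ndarray  # (n, 2)
    lamina: str = ""
    cutoff_nm: float = DEFAULT_CUTOFF_NM
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.xy_nm = np.asarray(self.xy_nm, dtype=float)
        if self.xy_nm.ndim != 2 or self.xy_nm.shape[1] != 2:
            raise ValueError("xy_nm must have shape (n, 2)")
        if not np.all(np.isfinite(self.xy_nm)):
            raise ValueError("particle coordinates must be finite")
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")


# ---------------------------------------------------------------------------
# FLIM


def _decay_model(t_idx: np.ndarray, bin_width: float, irf_norm: np.ndarray | None):
    def model(_x, y0, tau):
        t = (t_idx + 0.5) * bin_width
        decay = np.exp(-t / tau)
        if irf_norm is None:
            return y0 * decay
        return y0 * np.convolve(irf_norm, decay)[: t.size]

    return model


def fit_lifetime(trace: FlimTrace, poisson_weights: bool = False) -> float:
    """Fluorescence lifetime tau (ns) from a mono-exponential decay fit.

    The model y0 exp(-t/tau) is convolved with the normalized instrument
    response when one is supplied (a delta otherwise) and fit by least
    squares; ``poisson_weights=True`` weights residuals by 1/sqrt(max(y, 1)).
    """
    y = trace.counts
    if y.sum() <= 100:
        raise ValueError("too few photons for a lifetime fit (need > 100 counts)")
    irf_norm = None
    if trace.irf is not None and trace.irf.sum() > 0:
        irf_norm = trace.irf / trace.irf.sum()
    t_idx = np.arange(y.size, dtype=float)
    model = _decay_model(t_idx, trace.bin_width_ns, irf_norm)
    # crude initial guess: amplitude from the peak, tau from the mean arrival time
    t = trace.times_ns
    tau0 = max(float((t * y).sum() / y.sum()), trace.bin_width_ns)
    sigma = np.sqrt(np.maximum(y, 1.0)) if poisson_weights else None
    try:
        popt, _ = curve_fit(
            model, t_idx, y, p0=(float(y.max()), tau0), sigma=sigma, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError("lifetime fit did not converge") from exc
    return float(popt[1])


def stern_volmer_cl(tau_ns: float, trace: FlimTrace) -> float:
    """[Cl-] in mM from a fitted lifetime via tau0/tau = 1 + Ksv [Cl-].

    A lifetime above tau0 (formally negative concentration) is clipped to
    0 mM; callers can detect the condition by comparing tau to tau0.
    """
    if tau_ns <= 0:
        raise ValueError("lifetime must be positive")
    cl_molar = (trace.tau_zero_ns / tau_ns - 1.0) / trace.ksv_per_m
    return max(cl_molar, 0.0) * 1e3


def cl_depth_regression(
    depths_um: np.ndarray, cl_mm: np.ndarray, bin_um: float = 20.0
) -> tuple[float, float, dict]:
    """Slope (mM um-1) and intercept of binned [Cl-] vs distance from the
    dorsal border.

    Cells are binned every ``bin_um`` along depth; bin mean concentrations are
    regressed by ordinary least squares against the mean depth of the cells in
    each bin (rather than the nominal bin centre, so that partially filled
    edge bins do not bias the slope).
    """
    depths = np.asarray(depths_um, dtype=float)
    cl = np.asarray(cl_mm, dtype=float)
    if depths.shape != cl.shape:
        raise ValueError("depth and concentration arrays must match")
    idx = np.floor(depths / bin_um).astype(int)
    uniq = np.unique(idx)
    if uniq.size < 2:
        raise ValueError("need at least two occupied depth bins")
    centres = np.array([depths[idx == u].mean() for u in uniq])
    means = np.array([cl[idx == u].mean() for u in uniq])
    ns = np.array([(idx == u).sum() for u in uniq])
    slope, intercept = np.polyfit(centres, means, 1)
    pred = slope * centres + intercept
    diag = {
        "bin_centres_um": centres,
        "bin_means_mM": means,
        "bin_counts": ns,
        "rmse_mM": float(np.sqrt(np.mean((means - pred) ** 2))),
    }
    return float(slope), float(intercept), diag


# ---------------------------------------------------------------------------
# laminar quantification


@dataclass
class QuadraticAxis:
    """Quadratic laminar reference curve row = a col^2 + b col + c."""

    coeffs: tuple[float, float, float]
    included_columns: np.ndarray | None = None

    def __call__(self, col) -> np.ndarray:
        a, b, c = self.coeffs
        col = np.asarray(col, dtype=float)
        return a * col * col + b * col + c

    def sample(self, n_cols: int) -> np.ndarray:
        cols = np.arange(n_cols, dtype=float)
        return np.column_stack([self(cols), cols])  # (row, col) points


def ib4_axis(image: LaminarImage, exponent: int = 4, floor_fraction: float = 0.01) -> QuadraticAxis:
    """Barycentric IB4 axis: order-``exponent`` intensity-weighted centre per
    column, then a least-squares quadratic through the centres.

    Columns whose total weight (sum of intensity**exponent) falls below
    ``floor_fraction`` times the image-wide column median are excluded.
    """
    if "ib4" not in image.channels:
        raise ValueError("image has no 'ib4' channel")
    img = np.asarray(image.channels["ib4"], dtype=float)
    w = img**exponent
    colsum = w.sum(axis=0)
    floor = floor_fraction * np.median(colsum)
    keep = colsum > max(floor, 0.0)
    if not np.any(keep):
        raise ValueError("no column carries enough IB4 signal for the axis")
    rows = np.arange(img.shape[0], dtype=float)
    centres = (rows[:, None] * w).sum(axis=0)[keep] / colsum[keep]
    cols = np.arange(img.shape[1], dtype=float)[keep]
    a, b, c = np.polyfit(cols, centres, 2)
    return QuadraticAxis(coeffs=(float(a), float(b), float(c)), included_columns=np.flatnonzero(keep))


def _signed_distance_to_axis(image: LaminarImage, axis: QuadraticAxis) -> np.ndarray:
    """Per-pixel signed minimum distance (um) to the sampled axis curve.

    The curve is sampled at every column; distance is the minimum Euclidean
    distance to those sample points, and the sign is positive on the
    superficial (dorsal) side of the curve.
    """
    h, w = image.shape
    pts = axis.sample(w)
    tree = cKDTree(pts)
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    d, _ = tree.query(pix, workers=-1)
    d = d.reshape(h, w) * image.pixel_size_um
    above = rr < axis(cc)  # smaller row index = closer to the image top
    sign = np.where(above == image.dorsal_at_top, 1.0, -1.0)
    return d * sign


def translaminar_profile(
    image: LaminarImage,
    axis: QuadraticAxis,
    bin_um: float = 5.0,
    channels: tuple[str, ...] | None = None,
) -> dict:
    """Mean channel intensity vs signed distance to the IB4 axis.

    Superficial (dorsal) pixels have positive distance.  Returns a dict with
    ``distance_um`` bin centres and one mean-intensity array per channel.
    """
    sd = _signed_distance_to_axis(image, axis)
    names = channels or tuple(image.channels)
    idx = np.floor(sd / bin_um).astype(int)
    uniq = np.unique(idx)
    out = {"distance_um": (uniq + 0.5) * bin_um}
    flat_idx = idx.ravel()
    for name in names:
        vals = np.asarray(image.channels[name], dtype=float).ravel()
        out[name] = np.array([vals[flat_idx == u].mean() for u in uniq])
    return out


def magi_index(
    image: LaminarImage, lamina_mask: np.ndarray, intracellular_mask: np.ndarray,
    channel: str = "kcc2",
) -> float:
    """Global membrane intensity index M = T - I.

    T is the mean channel intensity over the lamina mask; I the mean over the
    intracellular (cytoplasmic) regions.  Background must already have been
    subtracted (:func:`subtract_background`).
    """
    img = np.asarray(image.channels[channel], dtype=float)
    lam = np.asarray(lamina_mask, dtype=bool)
    intra = np.asarray(intracellular_mask, dtype=bool)
    if not lam.any() or not intra.any():
        raise ValueError("lamina and intracellular masks must be non-empty")
    return float(img[lam].mean() - img[intra].mean())


def _point_segment_distance(points: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Distances of pixels to one segment plus the side of the segment line."""
    seg = p2 - p1
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0.0:
        raise ValueError("degenerate polyline segment (repeated vertex)")
    t = np.clip((points - p1) @ seg / seg_len2, 0.0, 1.0)
    proj = p1 + t[:, None] * seg
    d = np.hypot(*(points - proj).T)
    cross = seg[0] * (points[:, 1] - p1[1]) - seg[1] * (points[:, 0] - p1[0])
    return d, cross


def masc_profile(
    image: LaminarImage,
    max_distance_um: float,
    channel: str = "kcc2",
    bin_um: float | None = None,
    roi_mask: np.ndarray | None = None,
) -> dict:
    """Membrane-distance intensity profile (MASC-pi).

    For each pixel (optionally restricted to ``roi_mask``) the distance to the
    closest membrane polyline segment is computed; intensity is then binned in
    distance shells of one pixel width (or ``bin_um``).  Positive distances
    are on the intracellular side, which is the left side of the polyline
    traversal direction.  Returns bin centres, mean and SD per bin.
    """
    polylines = [np.asarray(p, dtype=float) for p in image.membrane_polylines]
    if not polylines:
        raise ValueError("image carries no membrane polylines")
    for p in polylines:
        if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 2:
            raise ValueError("each polyline needs at least two (row, col) vertices")
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    if roi_mask is not None:
        sel = np.asarray(roi_mask, dtype=bool).ravel()
    else:
        sel = np.ones(h * w, dtype=bool)
    pix = np.column_stack([rr.ravel()[sel], cc.ravel()[sel]])
    vals = np.asarray(image.channels[channel], dtype=float).ravel()[sel]

    best = np.full(pix.shape[0], np.inf)
    best_side = np.zeros(pix.shape[0])
    for poly in polylines:
        for p1, p2 in zip(poly[:-1], poly[1:]):
            d, cross = _point_segment_distance(pix, p1, p2)
            closer = d < best
            best[closer] = d[closer]
            best_side[closer] = cross[closer]
    signed = best * np.where(best_side >= 0, 1.0, -1.0) * image.pixel_size_um

    step = bin_um if bin_um is not None else image.pixel_size_um
    keep = np.abs(signed) <= max_distance_um
    idx = np.floor(signed[keep] / step).astype(int)
    uniq = np.unique(idx)
    centres = (uniq + 0.5) * step
    means = np.array([vals[keep][idx == u].mean() for u in uniq])
    sds = np.array([vals[keep][idx == u].std() for u in uniq])
    return {"distance_um": centres, "mean": means, "sd": sds}


def subtract_background(image: LaminarImage, channel: str = "kcc2") -> LaminarImage:
    """Subtract the mean intensity of the annotated background region
    (a region known to lack signal, e.g. dorsal white matter), clipping at 0.
    """
    if image.background_region is None or not np.any(image.background_region):
        raise ValueError("image carries no (non-empty) background region annotation")
    region = np.asarray(image.background_region, dtype=bool)
    channels = dict(image.channels)
    img = np.asarray(channels[channel], dtype=float)
    channels[channel] = np.clip(img - img[region].mean(), 0.0, None)
    return LaminarImage(
        channels=channels,
        pixel_size_um=image.pixel_size_um,
        dorsal_at_top=image.dorsal_at_top,
        lamina_masks=image.lamina_masks,
        intracellular_mask=image.intracellular_mask,
        background_region=image.background_region,
        membrane_polylines=image.membrane_polylines,
        truth=image.truth,
    )


# ---------------------------------------------------------------------------
# immunogold particle analysis


@dataclass
class ClusterResult:
    labels: np.ndarray  # component label per particle
    oligomer_percentage: float  # % of particles in components of size >= 2
    n_oligomeric: int
    n_monomeric: int


def cluster_particles(particles: ParticleSet) -> ClusterResult:
    """Transitive (single-linkage) clustering under the distance cutoff.

    Particles A and C belong to one oligomeric group whenever a chain of
    pairwise distances below the cutoff (default 65 nm) connects them, even
    if A and C are themselves farther apart.  Particles in components of size
    >= 2 are classified oligomeric, singletons monomeric; the percentage is
    per particle.
    """
    xy = particles.xy_nm
    n = xy.shape[0]
    if n < 1:
        raise ValueError("need at least one particle")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=particles.cutoff_nm, output_type="ndarray")
    if pairs.size:
        data = np.ones(pairs.shape[0])
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    _, sizes = np.unique(labels, return_counts=True)
    size_per_particle = sizes[labels]
    n_olig = int(np.sum(size_per_particle >= 2))
    return ClusterResult(
        labels=labels,
        oligomer_percentage=oligomer_percentage(n_olig, n - n_olig),
        n_oligomeric=n_olig,
        n_monomeric=n - n_olig,
    )


def oligomer_percentage(n_oligomeric: int, n_monomeric: int) -> float:
    """Per-particle oligomeric percentage from category counts."""
    total = n_oligomeric + n_monomeric
    if total == 0:
        raise ValueError("no particles")
    return 100.0 * n_oligomeric / total


def interparticle_histogram(
    particles: ParticleSet, bin_nm: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all n(n-1)/2 pairwise distances of one cell body.

    Returns (counts, bin_edges) in nm.
    """
    if particles.xy_nm.shape[0] < 2:
        raise ValueError("need at least two particles for pairwise distances")
    d = pdist(particles.xy_nm)
    edges = np.arange(0.0, d.max() + bin_nm, bin_nm)
    counts, edges = np.histogram(d, bins=edges)
    return counts, edges
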
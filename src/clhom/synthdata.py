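"""Seeded synthetic-data generators.

Each generator is a pure function of its parameters and seed, emulates the
statistical structure of one input type consumed by the analysis operators
(linear GABA I-V with Gaussian noise, Poisson-counted exponential photon
decays, laminar images with a dorsoventral gradient and ring-shaped cells,
clustered vs random immunogold point fields, one-phase-decay eIPSC trains),
and stores its ground-truth parameters on the returned object (``truth``
attribute) so recovery tests are self-contained.
"""

from __future__ import annotations

import math

import numpy as np

from .ephys import IVRecording, TrainRecording
from .imaging import DEFAULT_KSV_PER_M, FlimTrace, LaminarImage, ParticleSet

__all__ = [
    "gen_iv",
    "gen_flim",
    "flim_tau_for_cl",
    "gen_laminar_image",
    "gen_particles",
    "gen_eipsc_train",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_iv(
    e_true: float,
    g: float = 1.0,
    noise_sd: float = 2.0,
    voltages: np.ndarray | None = None,
    repeats: int = 3,
    seed=0,
    junction_offset: float = 0.0,
) -> IVRecording:
    """Synthetic GABA I-V recording: I = g (V - E) + Gaussian noise.

    ``voltages`` defaults to eight holding potentials in 12.5 mV steps
    around the physiological range; each step is repeated ``repeats`` times.
    When a ``junction_offset`` is given, the stored voltages are the
    *apparent* (uncorrected) ones, as in a raw recording.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = _rng(seed)
    if voltages is None:
        voltages = np.arange(-85.0, 2.6, 12.5)
    v = np.repeat(np.asarray(voltages, dtype=float), repeats)
    i = g * (v - e_true) + rng.normal(0.0, noise_sd, size=v.size)
    return IVRecording(
        voltages=v + junction_offset,
        currents=i,
        junction_offset=junction_offset,
        truth={"e_true_mV": e_true, "g_nS": g, "noise_sd_pA": noise_sd, "seed": seed},
    )


def flim_tau_for_cl(cl_mm: float, tau_zero_ns: float = 5.5,
                    ksv_per_m: float = DEFAULT_KSV_PER_M) -> float:
    """Lifetime implied by a Cl- concentration under the Stern-Volmer relation."""
    return tau_zero_ns / (1.0 + ksv_per_m * cl_mm * 1e-3)


def gen_flim(
    tau: float,
    counts: int = 100_000,
    irf_sigma: float = 0.0,
    seed=0,
    n_bins: int = 500,
    bin_width_ns: float = 0.05,
    tau_zero_ns: float = 5.5,
) -> FlimTrace:
    """Poisson-sampled photon histogram of an IRF-convolved exponential decay.

    With ``irf_sigma`` = 0 the instrument response is a delta (no ``irf``
    attached); otherwise a Gaussian IRF histogram (sigma in ns, centred at
    1 ns) is generated, attached to the trace, and convolved into the
    expectation before Poisson sampling.
    """
    if counts <= 0:
        raise ValueError("counts must be positive")
    rng = _rng(seed)
    t = (np.arange(n_bins) + 0.5) * bin_width_ns
    decay = np.exp(-t / tau)
    irf = None
    if irf_sigma > 0:
        irf = np.exp(-0.5 * ((t - 1.0) / irf_sigma) ** 2)
        expected = np.convolve(irf / irf.sum(), decay)[:n_bins]
    else:
        expected = decay
    expected = expected / expected.sum() * counts
    sampled = rng.poisson(expected).astype(float)
    return FlimTrace(
        counts=sampled,
        bin_width_ns=bin_width_ns,
        irf=irf,
        tau_zero_ns=tau_zero_ns,
        truth={"tau_ns": tau, "counts": counts, "irf_sigma_ns": irf_sigma, "seed": seed},
    )


def _circle_polyline(centre_rc: tuple[float, float], radius_px: float, n_vertices: int = 48):
    """Closed circle polyline oriented with its interior on the left."""
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices + 1)
    rows = centre_rc[0] + radius_px * np.sin(th)
    cols = centre_rc[1] + radius_px * np.cos(th)
    poly = np.column_stack([rows, cols])
    # orientation check against the implemented side convention: the centre
    # must land on the positive (intracellular) side of the first segment
    seg = poly[1] - poly[0]
    cross = seg[0] * (centre_rc[1] - poly[0][1]) - seg[1] * (centre_rc[0] - poly[0][0])
    if cross < 0:
        poly = poly[::-1]
    return poly


def gen_laminar_image(
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.103,
    kcc2_gradient: float = 3.4,  # intensity units per um of depth
    kcc2_base: float = 50.0,
    background_offset: float = 20.0,
    ib4_depth_um: float = 18.0,
    ib4_curvature: float = 0.0,
    band_width_um: float = 4.0,
    band_amplitude: float = 800.0,
    cgrp_offset_um: float = 8.0,
    n_cells: int = 4,
    cell_radius_um: float = 1.8,
    membrane_intensity: float = 400.0,
    cytoplasm_intensity: float = 120.0,
    noise_sd: float = 2.0,
    white_matter_um: float = 3.0,
    seed=0,
) -> LaminarImage:
    """Synthetic laminar confocal field: KCC2/IB4/CGRP channels + annotations.

    Emulates the structure the laminar quantifications assume: a dorsal
    white-matter strip devoid of KCC2 (the background region), a KCC2
    intensity increasing linearly with depth at ``kcc2_gradient`` i.u. um-1,
    an IB4 band whose centre follows a (possibly curved) quadratic axis, a
    CGRP band dorsal to it, and ring-shaped cells with bright membranes over
    dimmer cytoplasm.  Ground-truth annotations (axis coefficients, lamina
    masks, intracellular mask, membrane polylines) are attached.
    """
    rng = _rng(seed)
    h, w = shape
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    depth_um = rows * pixel_size_um  # from the dorsal (top) edge

    wm = depth_um < white_matter_um
    wm_mask = np.broadcast_to(wm, (h, w)).copy()

    kcc2 = np.where(wm, 0.0, kcc2_base + kcc2_gradient * (depth_um - white_matter_um))
    kcc2 = np.broadcast_to(kcc2, (h, w)).copy()

    # IB4 band along a quadratic axis; CGRP band dorsal to it
    axis_row0 = (white_matter_um + ib4_depth_um) / pixel_size_um
    a = ib4_curvature
    b = -a * (w - 1)  # vertex mid-image so the curve stays in frame
    c0 = axis_row0
    axis_rows = a * cols * cols + b * cols + c0
    sigma_px = band_width_um / pixel_size_um / 2.355  # FWHM -> sigma
    ib4 = band_amplitude * np.exp(-0.5 * ((rows - axis_rows) / sigma_px) ** 2)
    cgrp_rows = axis_rows - cgrp_offset_um / pixel_size_um
    cgrp = band_amplitude * np.exp(-0.5 * ((rows - cgrp_rows) / sigma_px) ** 2)

    # ring cells below the white matter
    r_px = cell_radius_um / pixel_size_um
    intracellular = np.zeros((h, w), dtype=bool)
    polylines = []
    cell_centres = []
    margin = int(3 * r_px) + 2
    lo_row = int(white_matter_um / pixel_size_um + 2 * r_px) + 2
    if n_cells > 0 and (lo_row + margin >= h - margin or 2 * margin >= w):
        raise ValueError(
            "image too small for the requested cells; enlarge `shape`, reduce "
            "`cell_radius_um` or increase `pixel_size_um`"
        )
    for _ in range(n_cells):
        cr = rng.uniform(lo_row + margin, h - margin)
        ccol = rng.uniform(margin, w - margin)
        cell_centres.append((cr, ccol))
        d = np.hypot(rows - cr, cols - ccol)
        ring = np.abs(d - r_px) <= 1.0
        inner = d < r_px - 1.0
        kcc2[ring] += membrane_intensity
        kcc2[inner] += cytoplasm_intensity
        intracellular |= d < r_px - 2.0
        polylines.append(_circle_polyline((cr, ccol), r_px))

    kcc2 = kcc2 + background_offset + rng.normal(0.0, noise_sd, size=(h, w))
    ib4 = ib4 + rng.normal(0.0, noise_sd, size=(h, w))
    cgrp = cgrp + rng.normal(0.0, noise_sd, size=(h, w))

    li_hi = white_matter_um + 20.0
    lamina_masks = {
        "LI": np.broadcast_to((depth_um >= white_matter_um) & (depth_um < li_hi), (h, w)).copy(),
        "LII": np.broadcast_to((depth_um >= li_hi) & (depth_um < white_matter_um + 80.0), (h, w)).copy(),
    }
    truth = {
        "kcc2_gradient_iu_per_um": kcc2_gradient,
        "kcc2_base_iu": kcc2_base,
        "background_offset_iu": background_offset,
        "axis_coeffs": (a, b, c0),
        "cell_centres_rc": cell_centres,
        "cell_radius_px": r_px,
        "membrane_intensity_iu": membrane_intensity,
        "cytoplasm_intensity_iu": cytoplasm_intensity,
        "white_matter_um": white_matter_um,
        "seed": seed,
    }
    return LaminarImage(
        channels={"kcc2": np.clip(kcc2, 0, None), "ib4": np.clip(ib4, 0, None),
                  "cgrp": np.clip(cgrp, 0, None)},
        pixel_size_um=pixel_size_um,
        lamina_masks=lamina_masks,
        intracellular_mask=intracellular,
        background_region=wm_mask,
        membrane_polylines=polylines,
        truth=truth,
    )


def gen_particles(
    n: int,
    oligomer_fraction: float,
    cluster_spread: float = 15.0,
    field: float = 5000.0,
    seed=0,
    cluster_size: int = 3,
    cutoff_nm: float = 65.0,
    lamina: str = "",
) -> ParticleSet:
    """Mixture of uniform singletons and Gaussian clusters on a square field.

    ``oligomer_fraction`` of the ``n`` particles are placed in clusters of
    ``cluster_size`` (spread well below half the linkage cutoff so members
    bind transitively); the rest are singletons rejection-sampled to stay
    isolated.  Truth labels (per-particle oligomeric flag) are stored.
    """
    if not (0.0 <= oligomer_fraction <= 1.0):
        raise ValueError("oligomer_fraction must lie in [0, 1]")
    if cluster_spread >= cutoff_nm / 2:
        raise ValueError("cluster spread must stay below half the cutoff")
    rng = _rng(seed)
    n_olig = int(round(n * oligomer_fraction))
    if n_olig == 1:
        n_olig = 0
    clusters: list[int] = []
    rem = n_olig
    while rem >= cluster_size:
        clusters.append(cluster_size)
        rem -= cluster_size
    if rem >= 2:
        clusters.append(rem)
        rem = 0
    n_single = n - sum(clusters)

    keep_out = 3 * cluster_spread + cutoff_nm
    placed: list[np.ndarray] = []  # cluster centres and singleton positions

    def far_enough(p: np.ndarray, min_d: float) -> bool:
        return all(np.hypot(*(p - q)) >= min_d for q in placed)

    pts = []
    labels = []
    for size in clusters:
        for _ in range(10_000):
            ctr = rng.uniform(keep_out, field - keep_out, size=2)
            if far_enough(ctr, 2 * keep_out):
                break
        else:
            raise RuntimeError("field too dense to place clusters; enlarge `field`")
        placed.append(ctr)
        members = ctr + rng.normal(0.0, cluster_spread, size=(size, 2))
        pts.extend(members)
        labels.extend([True] * size)
    for _ in range(n_single):
        for _ in range(10_000):
            p = rng.uniform(0.0, field, size=2)
            if far_enough(p, keep_out):
                break
        else:
            raise RuntimeError("field too dense to place singletons; enlarge `field`")
        placed.append(p)
        pts.append(p)
        labels.append(False)
    return ParticleSet(
        xy_nm=np.asarray(pts),
        lamina=lamina,
        cutoff_nm=cutoff_nm,
        truth={
            "oligomer_fraction": oligomer_fraction,
            "oligomeric": np.asarray(labels),
            "cluster_spread_nm": cluster_spread,
            "seed": seed,
        },
    )


def gen_eipsc_train(
    plateau: float,
    rate: float,
    noise_sd: float = 0.0,
    seed=0,
    amplitude: float = 100.0,
    holding_mv: float = 0.0,
) -> TrainRecording:
    """25-pulse eIPSC train following a one-phase decay plus relative noise.

    a_i = amplitude * [plateau + (1 - plateau) exp(-rate (i-1)) + eps_i] with
    eps_i ~ N(0, noise_sd) on the normalized scale (the first pulse is noisy
    too, as in a real recording).
    """
    if not (0.0 <= plateau <= 1.0):
        raise ValueError("plateau must lie in [0, 1]")
    rng = _rng(seed)
    n = np.arange(25, dtype=float)
    rel = plateau + (1.0 - plateau) * np.exp(-rate * n)
    rel = rel + rng.normal(0.0, noise_sd, size=25)
    return TrainRecording(
        amplitudes=amplitude * rel,
        holding_mv=holding_mv,
        truth={"plateau": plateau, "rate": rate, "noise_sd": noise_sd,
               "amplitude_pA": amplitude, "seed": seed},
    )
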
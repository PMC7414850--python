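"""Pipette-imposed Cl- load: reduced-dimension diffusion model with KCC2 efflux.

A whole-cell pipette filled with a high-Cl- solution clamps the far end of a
diffusion path at the pipette concentration; Cl- diffuses through the
truncated-cone pipette into the soma and dendrites, where KCC2 extrudes it
across the membrane.  The steady-state somatic Cl- then reflects the balance
between diffusive supply and extrusion capacity, which is how extrusion
capacity (Vmax) is estimated from measured reversal potentials.

The geometry is reduced to an axisymmetric one-dimensional finite-volume
chain: pipette cone -> soma (axial slices of a prolate ellipsoid, membrane
area from the exact surface-band integral) -> the two dendritic cylinders
merged into one axial compartment of doubled cross-section and membrane
area.  Axial coupling between neighbouring elements uses the truncated-cone
series-conductance formula G = D pi r_i r_j / d.

Internal units: um for lengths, um^2/s for the diffusion coefficient
(2.03e-9 m^2/s = 2030 um^2/s), mM for concentrations and umol m-2 s-1 for
KCC2 flux.  With these units the membrane sink of an element is numerically
J * membrane_area in mM um^3 s-1, since 1 umol m-2 s-1 x 1 um^2 =
1e-18 mol s-1 and 1 mM um^3 = 1e-18 mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve_banded

from .ionlib import KCC2Params, kcc2_flux

__all__ = [
    "DIFFUSION_COEFF_UM2_S",
    "LAMINA_SEMI_AXES",
    "CompartmentChain",
    "LoadSolution",
    "build_geometry",
    "steady_state_cl",
    "fit_vmax",
    "tip_gradient_extent",
]

#: Cl- diffusion coefficient in cytosol and pipette solution, um^2 s-1.
DIFFUSION_COEFF_UM2_S = 2.03e-9 * 1e12  # 2.03e-9 m^2/s

#: Prolate-ellipsoid soma semi-axes (minor, major) in um per lamina.
LAMINA_SEMI_AXES = {"LI": (5.5, 10.75), "LII": (4.58, 7.9)}

PIPETTE_TIP_RADIUS = 0.6
PIPETTE_BACK_RADIUS = 11.0
PIPETTE_LENGTH = 120.0
DENDRITE_RADIUS = 0.75
DENDRITE_LENGTH = 80.0
N_DENDRITES = 2


@dataclass
class CompartmentChain:
    """Discretized pipette/soma/dendrite geometry for the Cl--load model.

    Arrays are ordered from the pipette back (index 0, the fixed-concentration
    boundary) through the pipette tip and soma to the sealed dendrite tip.
    """

    position: np.ndarray  # element-centre axial position, um
    length: np.ndarray  # element axial length, um
    volume: np.ndarray  # um^3
    radius: np.ndarray  # effective cross-section radius at centre, um
    membrane_area: np.ndarray  # KCC2-bearing membrane per element, um^2 (0 in pipette)
    region: np.ndarray  # 'pipette' | 'soma' | 'dendrite'
    diffusion_coefficient: float = DIFFUSION_COEFF_UM2_S  # um^2 s-1
    lamina: str = ""

    def __post_init__(self) -> None:
        if np.any(self.volume <= 0) or np.any(self.radius <= 0):
            raise ValueError("element volumes and radii must be positive")

    @property
    def n(self) -> int:
        return self.position.size

    @property
    def soma_mask(self) -> np.ndarray:
        return self.region == "soma"

    #: optional face radii (n, 2): radius at the upstream/downstream face of
    #: each element, used for the half-element series conductance formula
    face_radius: np.ndarray | None = None

    def axial_conductances(self) -> np.ndarray:
        """Series conductance (um^3 s-1) between consecutive element centres.

        Each half-element is treated as a truncated cone (G = D pi r_a r_b / d)
        between the element centre and the shared face; the two halves combine
        in series.  Where no face radii are available (or the face pinches off
        at an ellipsoid pole), the centre-to-centre cone formula is used.
        """
        dpi = self.diffusion_coefficient * np.pi
        d = 0.5 * (self.length[:-1] + self.length[1:])
        direct = dpi * self.radius[:-1] * self.radius[1:] / d
        if self.face_radius is None:
            return direct
        g = direct.copy()
        for i in range(g.size):
            f1 = self.face_radius[i, 1]
            f2 = self.face_radius[i + 1, 0]
            # shared face: within a region both sides agree; at a region
            # junction the physical opening is the non-degenerate one (the
            # pipette mouth or the dendrite stalk, not the pinched-off
            # ellipsoid pole)
            r_face = max(f1, f2) if min(f1, f2) <= 1e-6 else 0.5 * (f1 + f2)
            if r_face <= 1e-6:
                continue
            g1 = dpi * self.radius[i] * r_face / (0.5 * self.length[i])
            g2 = dpi * r_face * self.radius[i + 1] / (0.5 * self.length[i + 1])
            g[i] = 1.0 / (1.0 / g1 + 1.0 / g2)
        return g


def _ellipsoid_band_area(b: float, a: float, s1: float, s2: float) -> float:
    """Surface area of the prolate spheroid x^2/a^2 + (y^2+z^2)/b^2 = 1 between
    axial planes s1 < s2 (s measured from the centre, |s| <= a)."""

    def integrand(s: float) -> float:
        t = 1.0 - (s / a) ** 2
        t = max(t, 0.0)
        return 2.0 * np.pi * b * np.sqrt(t + (b * s / a**2) ** 2)

    val, _ = quad(integrand, s1, s2, limit=200)
    return val


def build_geometry(
    lamina: str,
    resolution: float = 1.0,
    dendrite_length: float = DENDRITE_LENGTH,
    dendritic_kcc2: bool = False,
) -> CompartmentChain:
    """Discretize the pipette + soma + dendrite geometry for one lamina.

    ``resolution`` is the target element length in um (<= 2 um).  The pipette
    is a truncated cone (tip diameter 1.2 um, back diameter 22 um, length
    120 um) whose back element is the fixed-concentration boundary; the soma
    is the lamina's prolate ellipsoid sliced along its major axis; the two
    1.5 um x ``dendrite_length`` dendritic cylinders are merged into one
    compartment of doubled cross-section attached past the far soma pole.

    By default only the somatic membrane bears KCC2 (``membrane_area`` is zero
    on dendrite elements).  In the original three-dimensional model, somatic
    Cl- under load was insensitive to dendritic extrusion capacity and to the
    extent of the dendritic tree, and the published extrusion capacities were
    obtained in that regime; a strictly one-dimensional chain with uniformly
    extruding dendrites instead routes roughly half of the diffusive supply
    into the dendritic membrane, which roughly halves the fitted capacities
    (see the methods note).  Set ``dendritic_kcc2=True`` to place KCC2
    uniformly on the dendritic membrane as well.
    """
    if lamina not in LAMINA_SEMI_AXES:
        raise ValueError(f"unknown lamina {lamina!r}; expected one of {sorted(LAMINA_SEMI_AXES)}")
    if resolution > 2.0:
        raise ValueError("resolution must be <= 2 um")
    b, a = LAMINA_SEMI_AXES[lamina]

    pos, length, vol, rad, mem, reg, faces = [], [], [], [], [], [], []

    # --- pipette: back (x=0) to tip (x=120), radius linear in x
    n_pip = max(2, int(round(PIPETTE_LENGTH / resolution)))
    edges = np.linspace(0.0, PIPETTE_LENGTH, n_pip + 1)

    def pip_radius(x: float) -> float:
        return PIPETTE_BACK_RADIUS + (PIPETTE_TIP_RADIUS - PIPETTE_BACK_RADIUS) * x / PIPETTE_LENGTH

    for x1, x2 in zip(edges[:-1], edges[1:]):
        r1, r2 = pip_radius(x1), pip_radius(x2)
        pos.append(0.5 * (x1 + x2))
        length.append(x2 - x1)
        vol.append(np.pi * (x2 - x1) / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2))
        rad.append(pip_radius(0.5 * (x1 + x2)))
        mem.append(0.0)
        reg.append("pipette")
        faces.append((r1, r2))

    # --- soma: sliced prolate ellipsoid along the major axis (length 2a)
    x0 = PIPETTE_LENGTH
    n_soma = max(4, int(round(2 * a / resolution)))
    s_edges = np.linspace(-a, a, n_soma + 1)
    for s1, s2 in zip(s_edges[:-1], s_edges[1:]):
        sc = 0.5 * (s1 + s2)
        # exact slice volume of the ellipsoid of revolution
        v = np.pi * b * b * ((s2 - s1) - (s2**3 - s1**3) / (3.0 * a * a))
        r = b * np.sqrt(max(1.0 - (sc / a) ** 2, 1e-6))
        pos.append(x0 + (sc + a))
        length.append(s2 - s1)
        vol.append(v)
        rad.append(r)
        mem.append(_ellipsoid_band_area(b, a, s1, s2))
        reg.append("soma")
        faces.append((
            b * np.sqrt(max(1.0 - (s1 / a) ** 2, 0.0)),
            b * np.sqrt(max(1.0 - (s2 / a) ** 2, 0.0)),
        ))

    # --- dendrites: two cylinders merged into one axial compartment
    x0 = PIPETTE_LENGTH + 2 * a
    n_den = max(2, int(round(dendrite_length / resolution)))
    d_edges = np.linspace(0.0, dendrite_length, n_den + 1)
    area = N_DENDRITES * np.pi * DENDRITE_RADIUS**2
    r_eff = np.sqrt(area / np.pi)
    for x1, x2 in zip(d_edges[:-1], d_edges[1:]):
        pos.append(x0 + 0.5 * (x1 + x2))
        length.append(x2 - x1)
        vol.append(area * (x2 - x1))
        rad.append(r_eff)
        if dendritic_kcc2:
            mem.append(N_DENDRITES * 2.0 * np.pi * DENDRITE_RADIUS * (x2 - x1))
        else:
            mem.append(0.0)
        reg.append("dendrite")
        faces.append((r_eff, r_eff))

    return CompartmentChain(
        position=np.asarray(pos),
        length=np.asarray(length),
        volume=np.asarray(vol),
        radius=np.asarray(rad),
        membrane_area=np.asarray(mem),
        region=np.asarray(reg, dtype=object),
        lamina=lamina,
        face_radius=np.asarray(faces),
    )


@dataclass
class LoadSolution:
    """Steady-state Cl- profile of the loaded cell."""

    chain: CompartmentChain
    concentration: np.ndarray  # mM per element
    somatic_mean: float  # volume-weighted mean over soma elements, mM
    pipette_cl: float
    iterations: int
    residual: float  # max |net element balance| relative to boundary influx

    def mass_balance_error(self, kcc2: KCC2Params) -> float:
        """Relative mismatch between boundary diffusive influx and KCC2 efflux."""
        g = self.chain.axial_conductances()
        influx = g[0] * (self.concentration[0] - self.concentration[1])
        efflux = sum(
            kcc2_flux(c, kcc2.null_offset, kcc2) * area
            for c, area in zip(self.concentration, self.chain.membrane_area)
        )
        return abs(influx - efflux) / max(abs(influx), 1e-30)


def _kcc2_vec(c: np.ndarray, kcc2: KCC2Params) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized KCC2 flux and its derivative wrt concentration."""
    x = (c - kcc2.null_offset) / kcc2.michaelis_scale
    active = x > 0
    j = np.where(active, kcc2.vmax * x / (1.0 + x), 0.0)
    dj = np.where(active, kcc2.vmax / kcc2.michaelis_scale / (1.0 + x) ** 2, 0.0)
    return j, dj


def steady_state_cl(
    chain: CompartmentChain,
    kcc2: KCC2Params,
    pipette_cl: float = 29.0,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> LoadSolution:
    """Solve the steady diffusion/extrusion balance by damped Newton iteration.

    Element balance: sum_j G_ij (c_j - c_i) - A_mem,i J_KCC2(c_i) = 0 with the
    pipette back element held at ``pipette_cl``.  The tridiagonal Jacobian is
    solved with a banded solver; steps are halved whenever the residual norm
    does not decrease.  Convergence is declared when the largest element
    imbalance falls below ``tol`` times the boundary influx scale.
    """
    if pipette_cl <= kcc2.null_offset:
        raise ValueError("pipette concentration must exceed the KCC2 null point")
    g = chain.axial_conductances()
    n = chain.n
    c = np.full(n, float(pipette_cl))
    mem = chain.membrane_area

    def residual_vec(cv: np.ndarray) -> np.ndarray:
        j, _ = _kcc2_vec(cv, kcc2)
        f = np.zeros(n)
        flux = g * (cv[:-1] - cv[1:])  # axial flux from i to i+1
        f[:-1] -= flux
        f[1:] += flux
        f -= mem * j
        return f[1:]  # element 0 is the Dirichlet boundary

    scale = max(g[0] * pipette_cl, 1e-30)
    f = residual_vec(c)
    res = np.max(np.abs(f)) / scale
    it = 0
    while res > tol and it < max_iter:
        _, dj = _kcc2_vec(c, kcc2)
        # tridiagonal Jacobian for unknowns c[1:]
        m = n - 1
        diag = np.zeros(m)
        lower = np.zeros(m)
        upper = np.zeros(m)
        for k in range(m):
            i = k + 1
            dsum = 0.0
            if i - 1 >= 0:
                dsum += g[i - 1]
                if k > 0:
                    lower[k - 1] = g[i - 1]  # dF_k/dc_{k-1}
            if i < n - 1:
                dsum += g[i]
                upper[k + 1] = g[i]  # dF_k/dc_{k+1}
            diag[k] = -dsum - mem[i] * dj[i]
        ab = np.zeros((3, m))
        ab[0, 1:] = upper[1:]
        ab[1, :] = diag
        ab[2, :-1] = lower[:-1]
        step = solve_banded((1, 1), ab, -f)
        # damped update
        lam = 1.0
        for _ in range(40):
            trial = c.copy()
            trial[1:] = c[1:] + lam * step
            trial = np.maximum(trial, 1e-9)
            f_trial = residual_vec(trial)
            if np.linalg.norm(f_trial) <= np.linalg.norm(f) * (1 - 1e-4 * lam) or lam < 1e-8:
                break
            lam *= 0.5
        c = trial
        f = f_trial
        res = np.max(np.abs(f)) / scale
        it += 1
    if res > tol:
        raise RuntimeError(
            f"steady-state solve did not converge in {max_iter} iterations "
            f"(relative residual {res:.3e})"
        )
    soma = chain.soma_mask
    somatic_mean = float(np.average(c[soma], weights=chain.volume[soma]))
    return LoadSolution(
        chain=chain,
        concentration=c,
        somatic_mean=somatic_mean,
        pipette_cl=pipette_cl,
        iterations=it,
        residual=float(res),
    )


def fit_vmax(
    chain: CompartmentChain,
    kcc2_template: KCC2Params,
    pipette_cl: float,
    target_somatic_cl: float,
    vmax_bounds: tuple[float, float] = (0.0, 200.0),
    tol: float = 0.1,
) -> float:
    """Bisect Vmax so the steady somatic mean Cl- matches a target (umol m-2 s-1).

    The somatic mean is strictly decreasing in Vmax, from ``pipette_cl`` at
    Vmax = 0 toward the KCC2 null point, so a plain bisection to ``tol``
    (0.1 umol m-2 s-1) suffices.
    """
    from dataclasses import replace

    if not (kcc2_template.null_offset < target_somatic_cl < pipette_cl):
        raise ValueError(
            "target somatic Cl- must lie strictly between the KCC2 null point "
            f"({kcc2_template.null_offset} mM) and the pipette concentration ({pipette_cl} mM)"
        )

    def somatic(v: float) -> float:
        return steady_state_cl(chain, replace(kcc2_template, vmax=v), pipette_cl).somatic_mean

    lo, hi = vmax_bounds
    if somatic(hi) > target_somatic_cl:
        raise ValueError(
            f"target {target_somatic_cl:g} mM not attainable with vmax <= {hi:g}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if somatic(mid) > target_somatic_cl:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tip_gradient_extent(solution: LoadSolution, fraction: float = 0.95) -> tuple[float, bool]:
    """Distance (um) from the pipette tip, back into the pipette, at which the
    Cl- concentration has recovered to ``fraction`` x pipette concentration.

    Returns ``(extent, reached)``; if the profile never reaches the fraction
    within the pipette, the pipette length is returned with ``reached=False``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    chain = solution.chain
    pip = chain.region == "pipette"
    pos = chain.position[pip]
    c = solution.concentration[pip]
    target = fraction * solution.pipette_cl
    tip_x = pos[-1] + 0.5 * chain.length[pip][-1]
    if c[-1] >= target:
        return 0.0, True
    # walk from the tip back toward the barrel until recovery
    for i in range(len(c) - 1, 0, -1):
        if c[i - 1] >= target > c[i]:
            frac = (target - c[i]) / (c[i - 1] - c[i])
            x_cross = pos[i] + frac * (pos[i - 1] - pos[i])
            return float(tip_x - x_cross), True
    return float(PIPETTE_LENGTH), False
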
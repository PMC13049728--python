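"""Alexander-de Gennes steric brush force law and the two-regime
decomposition of an approach curve into an elastic (Hertz) response and a
glycocalyx brush response.

The brush force between a sphere of radius R and a grafted polymer layer of
length L (nm) and grafting density N (m^-2) at separation h is modelled in
its exponential form

    F(h) = 50 * kB * T * R * N^{3/2} * L * exp(-2 pi h / L),

nominally valid for 0.1 < h/L < 0.8.  ``log F`` is affine in h with slope
-2 pi / L, which the fit exploits: a weighted log-linear regression
initialises (L, N) and a nonlinear refinement follows.

The decomposition procedure: baseline -> contact scan -> deep-window Hertz
fit (with a free constant offset, the force plateau transmitted by the fully
squeezed brush) -> brush fit on the long-range residual -> quality flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._constants import BOLTZMANN_PN_NM, UM_TO_NM
from .contact import ContactPoint, HertzFit, elastic_force, estimate_contact_point, fit_hertz
from .curves import ForceCurve, ProbeGeometry, correct_baseline
from .errors import FitError, GlycoforceError

__all__ = [
    "BrushFit",
    "CurveDecomposition",
    "DecomposeConfig",
    "brush_force",
    "brush_prefactor",
    "fit_brush",
    "decompose_curve",
    "QUALITY_FLAGS",
]

#: documented vocabulary of per-curve quality flags
QUALITY_FLAGS = frozenset({
    "no_contact",
    "no_brush",
    "poor_hertz_fit",
    "window_truncated",
    "brush_window_collapse",
})


@dataclass(frozen=True)
class BrushFit:
    """Fitted brush parameters: glycocalyx length L (nm), grafting density
    N (m^-2), the separation window used, residual RMS and the r^2 of the
    log-linear initialisation stage."""

    L_nm: float
    N_per_m2: float
    h_window_nm: tuple[float, float]
    residual_rms_pn: float
    r_squared_loglinear: float
    L_stderr_nm: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.L_nm <= 0 or self.N_per_m2 <= 0:
            raise GlycoforceError("brush L and N must be > 0")
        if not self.h_window_nm[0] < self.h_window_nm[1]:
            raise GlycoforceError("h window must satisfy h_min < h_max")


@dataclass(frozen=True)
class CurveDecomposition:
    """Joint decomposition of one approach curve: the deep-regime Hertz fit,
    the optional brush fit, and quality flags."""

    hertz: HertzFit
    brush: BrushFit | None
    brush_detected: bool
    quality_flags: frozenset[str] = frozenset()
    contact: ContactPoint | None = None

    def __post_init__(self) -> None:
        if (self.brush is not None) != self.brush_detected:
            raise GlycoforceError("brush present iff brush_detected")
        unknown = set(self.quality_flags) - QUALITY_FLAGS
        if unknown:
            raise GlycoforceError(f"unknown quality flags: {sorted(unknown)}")


@dataclass(frozen=True)
class DecomposeConfig:
    """Tunables of the two-regime decomposition.

    ``hertz_window`` is the deep-regime policy (fraction of the maximal
    indentation); the brush window iterates toward ``brush_band`` in units
    of h/L; ``noise_sigma_factor`` sets the detection floor for a brush
    residual in units of the far-baseline RMS.
    """

    baseline_fraction: float = 0.3
    hertz_window: str = "deep:0.4"
    brush_band: tuple[float, float] = (0.1, 0.8)
    brush_max_iter: int = 10
    brush_rtol: float = 0.01
    noise_sigma_factor: float = 5.0
    poisson: float = 0.5
    fit_offset: bool = True
    min_brush_points: int = 8


def brush_prefactor(L_nm: float, N_per_m2: float, radius_um: float,
                    temperature_k: float) -> float:
    """Brush force at zero separation, 50 kB T R N^{3/2} L, in pN."""
    if min(L_nm, N_per_m2, radius_um, temperature_k) <= 0:
        raise GlycoforceError("brush parameters must be > 0")
    n_per_nm2 = N_per_m2 * 1e-18
    return (50.0 * BOLTZMANN_PN_NM * temperature_k * radius_um * UM_TO_NM
            * n_per_nm2**1.5 * L_nm)


def brush_force(L_nm: float, N_per_m2: float, radius_um: float,
                temperature_k: float, h_nm) -> np.ndarray | float:
    """Steric brush force (pN) at separation ``h_nm`` (>= 0)."""
    h = np.asarray(h_nm, dtype=float)
    if np.any(h < 0):
        raise GlycoforceError("separation must be >= 0")
    out = brush_prefactor(L_nm, N_per_m2, radius_um, temperature_k) \
        * np.exp(-2.0 * np.pi * h / L_nm)
    return out if out.ndim else float(out)


def _loglinear_init(h: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Weighted LS of ln f on h (weights f^2, i.e. inverse variance of ln f
    under additive force noise).  Returns (slope, intercept, r^2)."""
    w = f**2
    x, y = h, np.log(f)
    wsum = w.sum()
    xbar = (w * x).sum() / wsum
    ybar = (w * y).sum() / wsum
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    syy = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if syy == 0 else float(sxy**2 / (sxx * syy))
    return float(slope), float(intercept), r2


def fit_brush(curve: ForceCurve, hertz: HertzFit,
              config: DecomposeConfig | None = None) -> BrushFit | None:
    """Fit the brush law to the long-range residual of a curve.

    Subtracts the fitted Hertz force, converts to separation relative to the
    squeezed-brush surface (the Hertz contact point), and fits the
    exponential law: weighted log-linear regression initialises (L, N), a
    nonlinear least squares refines them, and the separation window is
    iterated to the configured h/L band.  Returns ``None`` when there is no
    positive residual to fit (no brush detected); raises :class:`FitError`
    when the window collapses without converging.
    """
    cfg = config or DecomposeConfig()
    if curve.probe.kind != "sphere":
        raise GlycoforceError("brush fit requires a spherical probe")
    radius = curve.probe.radius_um
    temperature = curve.temperature_k
    k = curve.calibration.k_pn_per_nm
    z, f = curve.z_nm, curve.force_pn
    d = f / k
    z0 = hertz.z0_nm
    s = (z - z0) + d
    delta = np.maximum(0.0, -s)
    f_hertz = np.asarray(elastic_force(hertz.E_pa, hertz.poisson, curve.probe, delta))
    resid = f - f_hertz

    order = np.argsort(z)[::-1]
    nbase = max(8, z.size // 5)
    noise_rms = float(np.std(f[order][:nbase]))
    floor = max(cfg.noise_sigma_factor * noise_rms,
                1e-9 * max(1.0, float(np.max(np.abs(f)))))

    # detection and log-linear initialisation use only clearly-positive
    # residuals; the nonlinear refinement uses every positive-separation
    # point inside the band (near-zero residuals carry no bias, and the
    # decay toward zero constrains the slope)
    positive = (s > 0) & (resid > floor)
    if int(positive.sum()) < cfg.min_brush_points:
        return None

    def refine(h: np.ndarray, fr: np.ndarray,
               L0: float, N0: float) -> tuple[float, float, float, np.ndarray]:
        def resid_fn(p: np.ndarray) -> np.ndarray:
            L, log10N = p
            return brush_force(L, 10.0**log10N, radius, temperature, h) - fr
        res = least_squares(resid_fn, x0=np.array([L0, math.log10(N0)]),
                            bounds=([1e-3, 5.0], [1e5, 25.0]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        L, log10N = res.x
        rms = float(np.sqrt(np.mean(res.fun**2)))
        return float(L), float(10.0**log10N), rms, res.jac

    def params_from_loglin(slope: float, intercept: float) -> tuple[float, float]:
        L = -2.0 * np.pi / slope if slope < 0 else float("nan")
        if not np.isfinite(L) or L <= 0:
            raise FitError("log-linear stage found a non-decaying residual")
        pref = math.exp(intercept)
        N = (pref / (50.0 * BOLTZMANN_PN_NM * temperature
                     * radius * UM_TO_NM * L)) ** (2.0 / 3.0) * 1e18
        return L, N

    # initial L guess over the whole clearly-positive region
    h_all, f_all = s[positive], resid[positive]
    slope, intercept, r2 = _loglinear_init(h_all, f_all)
    L, N = params_from_loglin(slope, intercept)

    h_window = (float(h_all.min()), float(h_all.max()))
    n_win = h_all.size
    for _ in range(cfg.brush_max_iter):
        lo, hi = cfg.brush_band[0] * L, cfg.brush_band[1] * L
        mask = (s >= lo) & (s <= hi) & (s > 0)
        if int(mask.sum()) < cfg.min_brush_points \
                or int((mask & positive).sum()) < 3:
            raise FitError("brush window collapsed before convergence")
        h_w, f_w = s[mask], resid[mask]
        try:
            slope, intercept, r2 = _loglinear_init(s[mask & positive],
                                                   resid[mask & positive])
            L_init, N_init = params_from_loglin(slope, intercept)
        except FitError:
            L_init, N_init = L, N  # keep the previous iterate as initialiser
        L_new, N, rms, jac = refine(h_w, f_w, L_init, N_init)
        h_window = (float(h_w.min()), float(h_w.max()))
        n_win = h_w.size
        converged = abs(L_new - L) <= cfg.brush_rtol * L
        L = L_new
        if converged:
            break
    else:
        raise FitError("brush window iteration did not converge")

    L_se = float("nan")
    dof = n_win - 2
    if dof > 0:
        try:
            cov = np.linalg.inv(jac.T @ jac) * rms**2 * n_win / dof
            L_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            pass

    return BrushFit(L_nm=L, N_per_m2=N, h_window_nm=h_window,
                    residual_rms_pn=rms, r_squared_loglinear=r2,
                    L_stderr_nm=L_se, n_points=n_win)


def decompose_curve(curve: ForceCurve, geometry: ProbeGeometry | None = None,
                    config: DecomposeConfig | None = None) -> CurveDecomposition:
    """Run the full two-regime pipeline on one approach curve.

    baseline correction -> contact-point scan -> deep-window Hertz fit with
    squeezed-brush offset -> brush fit on the long-range residual.
    Deterministic given (curve, config); fit problems surface as quality
    flags, not exceptions, on any curve with a detectable contact.
    """
    cfg = config or DecomposeConfig()
    geometry = geometry or curve.probe
    if geometry.kind != "sphere":
        raise GlycoforceError(
            "two-regime decomposition is defined for the spherical probe"
        )
    flags: set[str] = set()
    work = curve if curve.baseline_corrected else correct_baseline(
        curve, cfg.baseline_fraction)
    contact = estimate_contact_point(work)  # NoContactError propagates
    hertz = fit_hertz(work, geometry, window=cfg.hertz_window, contact=contact,
                      poisson=cfg.poisson, fit_offset=cfg.fit_offset)
    if not hertz.success:
        flags.add("poor_hertz_fit")
        return CurveDecomposition(hertz=hertz, brush=None, brush_detected=False,
                                  quality_flags=frozenset(flags), contact=contact)
    brush = None
    try:
        brush = fit_brush(work, hertz, cfg)
    except FitError:
        flags.add("brush_window_collapse")
    if brush is None and "brush_window_collapse" not in flags:
        flags.add("no_brush")
    if brush is not None:
        # flag windows truncated against the sampled separation range
        s_max = float(np.max((work.z_nm - hertz.z0_nm)
                             + work.force_pn / work.calibration.k_pn_per_nm))
        if brush.h_window_nm[1] > 0.99 * s_max:
            flags.add("window_truncated")
    return CurveDecomposition(hertz=hertz, brush=brush,
                              brush_detected=brush is not None,
                              quality_flags=frozenset(flags), contact=contact)
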
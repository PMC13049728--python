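"""Elastic contact mechanics: Hertz (sphere) and Sneddon (pyramid) force laws,
contact-point estimation, and nonlinear least-squares fitting of the apparent
Young's modulus E.

Force laws (internal units nm / pN; E in Pa, R in um, angles in degrees):

* sphere on elastic half-space:    F = (4/3) * E/(1-nu^2) * sqrt(R) * delta^{3/2}
* four-sided pyramidal indenter:   F = E/(1-nu^2) * (tan(theta)/sqrt(2)) * delta^2
  (the conical front factor (2/pi)*tan(theta) is selectable via
  ``pyramid_front="cone"``)

nu defaults to 0.5 (incompressible cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._constants import PA_TO_PN_PER_NM2, UM_TO_NM
from .curves import ForceCurve, ProbeGeometry
from .errors import FitError, GlycoforceError, NoContactError

__all__ = [
    "ContactPoint",
    "HertzFit",
    "hertz_sphere_force",
    "sneddon_pyramid_force",
    "elastic_force",
    "estimate_contact_point",
    "fit_hertz",
]


@dataclass(frozen=True)
class ContactPoint:
    """Estimated contact point: piezo height z0 (nm), estimation method and
    a half-width uncertainty (nm) of the near-optimal region of the scan."""

    z0_nm: float
    method: str = "piecewise_fit"
    uncertainty_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.uncertainty_nm < 0:
            raise GlycoforceError("uncertainty must be >= 0")


@dataclass(frozen=True)
class HertzFit:
    """Result of an elastic-model fit on one curve.

    ``E_pa`` is the apparent Young's modulus; ``offset_pn`` is the optional
    constant force offset (the squeezed-brush plateau when fitted inside the
    two-regime decomposition, 0 otherwise).
    """

    E_pa: float
    poisson: float
    z0_nm: float
    fit_window_nm: tuple[float, float]
    residual_rms_pn: float
    n_points: int
    offset_pn: float = 0.0
    E_stderr_pa: float = float("nan")
    z0_stderr_nm: float = float("nan")
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.success and self.E_pa <= 0:
            raise GlycoforceError("fitted E must be > 0")
        if not (0 <= self.poisson <= 0.5 + 1e-12):
            raise GlycoforceError("poisson ratio must be in [0, 0.5]")
        lo, hi = self.fit_window_nm
        if self.success and not lo < hi:
            raise GlycoforceError("fit window must satisfy delta_min < delta_max")
        if self.success and self.n_points < 8:
            raise GlycoforceError("fit needs >= 8 points")


# ---------------------------------------------------------------------------
# Closed-form force laws
# ---------------------------------------------------------------------------

def hertz_sphere_force(E_pa: float, poisson: float, radius_um: float,
                       delta_nm) -> np.ndarray | float:
    """Hertz force (pN) for a sphere of radius ``radius_um`` indenting an
    elastic half-space by ``delta_nm``."""
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise GlycoforceError("indentation must be >= 0")
    if radius_um <= 0:
        raise GlycoforceError("radius must be > 0")
    pref = (4.0 / 3.0) * (E_pa * PA_TO_PN_PER_NM2) / (1.0 - poisson**2)
    out = pref * math.sqrt(radius_um * UM_TO_NM) * delta**1.5
    return out if out.ndim else float(out)


def sneddon_pyramid_force(E_pa: float, poisson: float, half_angle_deg: float,
                          delta_nm, front: Literal["pyramid", "cone"] = "pyramid"
                          ) -> np.ndarray | float:
    """Hertz-Sneddon force (pN) for a pyramidal (default) or conical indenter
    with face half-angle ``half_angle_deg`` at indentation ``delta_nm``."""
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise GlycoforceError("indentation must be >= 0")
    if not (0 < half_angle_deg < 90):
        raise GlycoforceError("half angle must be in (0, 90) degrees")
    tan = math.tan(math.radians(half_angle_deg))
    geom = tan / math.sqrt(2.0) if front == "pyramid" else (2.0 / math.pi) * tan
    out = (E_pa * PA_TO_PN_PER_NM2) / (1.0 - poisson**2) * geom * delta**2
    return out if out.ndim else float(out)


def elastic_force(E_pa: float, poisson: float, geometry: ProbeGeometry,
                  delta_nm, front: str = "pyramid") -> np.ndarray | float:
    """Dispatch to the sphere or pyramid force law for ``geometry``."""
    if geometry.kind == "sphere":
        return hertz_sphere_force(E_pa, poisson, geometry.radius_um, delta_nm)
    return sneddon_pyramid_force(E_pa, poisson, geometry.half_angle_deg,
                                 delta_nm, front=front)  # type: ignore[arg-type]


def _exponent(geometry: ProbeGeometry) -> float:
    return 1.5 if geometry.kind == "sphere" else 2.0


def _prefactor_to_E(pref_pn, poisson: float, geometry: ProbeGeometry,
                    front: str = "pyramid"):
    """Invert F = pref * delta^m to the modulus in Pa."""
    if geometry.kind == "sphere":
        geom = (4.0 / 3.0) * math.sqrt(geometry.radius_um * UM_TO_NM)
    else:
        tan = math.tan(math.radians(geometry.half_angle_deg))
        geom = tan / math.sqrt(2.0) if front == "pyramid" else (2.0 / math.pi) * tan
    return pref_pn * (1.0 - poisson**2) / (geom * PA_TO_PN_PER_NM2)


# ---------------------------------------------------------------------------
# Contact-point estimation
# ---------------------------------------------------------------------------

def estimate_contact_point(curve: ForceCurve, exponent: float = 1.5,
                           min_rise_sigma: float = 5.0) -> ContactPoint:
    """Scan candidate contact points over the sampled piezo grid, fitting a
    piecewise model (zero force above z0, power law ``C (z0-z)^m`` below) and
    return the SSE-minimising z0.

    The uncertainty is the half-width of the candidate region whose SSE is
    within 5% (plus one noise variance) of the minimum.  Raises
    :class:`NoContactError` when the maximal force is below
    ``min_rise_sigma`` times the far-baseline RMS.
    """
    z = curve.z_nm
    f = curve.force_pn
    order = np.argsort(z)[::-1]  # far (high z) -> near
    z_o, f_o = z[order], f[order]
    d_o = f_o / curve.calibration.k_pn_per_nm
    n = z_o.size
    nbase = max(8, n // 5)
    base_rms = float(np.std(f_o[:nbase]))
    floor = max(base_rms, 1e-12 * max(1.0, float(np.max(np.abs(f)))), 1e-30)
    if float(np.max(f)) < min_rise_sigma * floor:
        raise NoContactError("no force rise detected (max force below noise floor)")

    best_sse, best_i = np.inf, None
    sses = np.full(n, np.inf)
    for i in range(1, n - 4):
        z0 = z_o[i]
        delta = np.maximum(0.0, (z0 - z_o[i:]) - d_o[i:])
        dm = delta**exponent
        denom = float(dm @ dm)
        c = float(f_o[i:] @ dm) / denom if denom > 0 else 0.0
        c = max(c, 0.0)
        resid_contact = f_o[i:] - c * dm
        sse = float(f_o[:i] @ f_o[:i]) + float(resid_contact @ resid_contact)
        sses[i] = sse
        if sse < best_sse:
            best_sse, best_i = sse, i
    if best_i is None:
        raise NoContactError("curve too short for contact scan")
    near = np.flatnonzero(sses <= best_sse * 1.05 + base_rms**2)
    half_width = 0.0
    if near.size > 1:
        half_width = 0.5 * abs(float(z_o[near[0]] - z_o[near[-1]]))
    return ContactPoint(z0_nm=float(z_o[best_i]), method="piecewise_fit",
                        uncertainty_nm=half_width)


# ---------------------------------------------------------------------------
# Hertz fitting
# ---------------------------------------------------------------------------

def _parse_window(window: str | tuple[str, float]) -> tuple[str, float]:
    if isinstance(window, tuple):
        return window
    kind, _, arg = window.partition(":")
    if kind == "deep":
        return ("deep", float(arg or 0.4))
    if kind == "cap":
        return ("cap", float(arg or 200.0))
    raise GlycoforceError(f"unknown window policy {window!r}")


def fit_hertz(curve: ForceCurve, geometry: ProbeGeometry | None = None,
              window: str | tuple[str, float] = "deep:0.4", *,
              contact: ContactPoint | None = None,
              poisson: float = 0.5,
              fit_z0: bool = True,
              fit_offset: bool = False,
              pyramid_front: str = "pyramid",
              max_window_iter: int = 3) -> HertzFit:
    """Fit the elastic model over an indentation window.

    ``window`` is either ``"deep:q"`` (the top fraction ``q`` of the
    indentation range — the deep regime where the glycocalyx is assumed to
    be squeezed) or ``"cap:delta_max"`` (all points with indentation up to
    ``delta_max`` nm, the constant-indentation-range policy used for
    pyramidal mapping so the stiff substrate never enters the fit).

    The contact point is re-optimised within generous bounds by default
    (``fit_z0=True``); ``fit_offset=True`` additionally frees a constant
    force offset (the squeezed-brush plateau inside the two-regime
    decomposition).  Returns a flagged (``success=False``) result on
    non-convergence rather than raising.
    """
    geometry = geometry or curve.probe
    if contact is None:
        contact = estimate_contact_point(curve, exponent=_exponent(geometry))
    m = _exponent(geometry)
    kind, arg = _parse_window(window)
    k = curve.calibration.k_pn_per_nm
    z, f = curve.z_nm, curve.force_pn
    d = f / k
    span = float(np.max(z) - np.min(z))

    def indentation(z0: float) -> np.ndarray:
        return (z0 - z) - d

    def window_mask(delta: np.ndarray) -> np.ndarray:
        dmax = float(np.max(delta))
        if dmax <= 0:
            return np.zeros(delta.size, dtype=bool)
        if kind == "deep":
            return delta >= (1.0 - arg) * dmax
        return (delta > 0) & (delta <= arg)

    z0_init = contact.z0_nm
    if fit_z0:
        lo = max(float(np.min(z)), z0_init - 0.25 * span)
        hi = min(float(np.max(z)), z0_init + 0.25 * span)
    else:
        lo = hi = z0_init

    _BIG = 1e300

    def profiled_sse(z0_c: float, mask: np.ndarray
                     ) -> tuple[float, float, float]:
        """Profile the linear parameters (offset, prefactor) out at fixed z0
        over a FIXED window point set, so SSE values are comparable across
        candidate contact points.  Returns (sse, offset, prefactor)."""
        delta = np.maximum(0.0, indentation(z0_c)[mask]) ** m
        fw = f[mask]
        if fit_offset:
            A = np.column_stack([np.ones_like(delta), delta])
            coef, *_ = np.linalg.lstsq(A, fw, rcond=None)
            off, pref = float(coef[0]), float(coef[1])
            resid = fw - A @ coef
        else:
            denom = float(delta @ delta)
            if denom <= 0:
                return _BIG, 0.0, 0.0
            off, pref = 0.0, float(fw @ delta) / denom
            resid = fw - pref * delta
        if pref <= 0:
            return _BIG, off, pref
        return float(resid @ resid), off, pref

    from scipy.optimize import minimize_scalar

    z0 = z0_init
    mask = window_mask(np.maximum(0.0, indentation(z0)))
    if int(mask.sum()) < 8:
        raise FitError(f"only {int(mask.sum())} points in fit window (< 8)")
    for _ in range(max_window_iter):
        if fit_z0:
            # coarse scan + Brent refinement on the profiled 1-D objective:
            # robust against the near-collinearity of (z0, offset, prefactor)
            candidates = np.linspace(lo, hi, 256)
            sses = np.array([profiled_sse(c, mask)[0] for c in candidates])
            best = int(np.argmin(sses))
            if sses[best] >= _BIG:
                return HertzFit(E_pa=float("nan"), poisson=poisson,
                                z0_nm=z0_init, fit_window_nm=(0.0, 0.0),
                                residual_rms_pn=float("nan"), n_points=0,
                                success=False,
                                message="no candidate contact point admits a fit")
            b_lo = candidates[max(best - 1, 0)]
            b_hi = candidates[min(best + 1, candidates.size - 1)]
            res = minimize_scalar(lambda c: profiled_sse(c, mask)[0],
                                  bounds=(b_lo, b_hi), method="bounded",
                                  options={"xatol": 1e-10})
            z0 = float(res.x) if res.fun <= sses[best] \
                else float(candidates[best])
        new_mask = window_mask(np.maximum(0.0, indentation(z0)))
        if int(new_mask.sum()) >= 8 and not np.array_equal(new_mask, mask):
            mask = new_mask
        else:
            break
        if not fit_z0:
            break

    sse, offset, pref = profiled_sse(z0, mask)
    nw = int(mask.sum())
    if sse >= _BIG or pref <= 0 or nw < 8:
        return HertzFit(E_pa=float("nan"), poisson=poisson, z0_nm=z0,
                        fit_window_nm=(0.0, 0.0), residual_rms_pn=float("nan"),
                        n_points=nw, offset_pn=offset, success=False,
                        message="fit did not converge")
    E = float(_prefactor_to_E(pref, poisson, geometry, front=pyramid_front))
    rms = float(np.sqrt(sse / nw))
    delta_w = np.maximum(0.0, (z0 - z[mask]) - d[mask])

    # standard errors from the jacobian of the equivalent nonlinear problem
    E_se = z0_se = float("nan")
    n_par = 3 if fit_offset else 2
    if not fit_z0:
        n_par -= 1
    dof = nw - n_par
    if dof > 0:
        dm = delta_w**m
        d_dz0 = pref * m * delta_w ** (m - 1.0)
        cols = [d_dz0] if fit_z0 else []
        if fit_offset:
            cols.append(np.ones_like(dm))
        cols.append(dm)
        J = np.column_stack(cols)
        try:
            cov = np.linalg.inv(J.T @ J) * sse / dof
            pref_se = float(np.sqrt(max(cov[-1, -1], 0.0)))
            E_se = float(_prefactor_to_E(pref_se, poisson, geometry,
                                         front=pyramid_front))
            if fit_z0:
                z0_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            pass

    return HertzFit(
        E_pa=E, poisson=poisson, z0_nm=z0,
        fit_window_nm=(float(np.min(delta_w)), float(np.max(delta_w))),
        residual_rms_pn=rms, n_points=nw, offset_pn=offset,
        E_stderr_pa=E_se, z0_stderr_nm=z0_se,
    )
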
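"""Model/Results interface over the curve fits.

Two model classes follow the statsmodels convention of a model object built
from data whose ``fit()`` returns a results object carrying estimates,
uncertainties, diagnostics and a ``summary()`` table:

* :class:`HertzModel` — plain elastic fit (sphere or pyramid) of one curve.
* :class:`BrushHertzModel` — the two-regime decomposition yielding the cell
  modulus E and the glycocalyx length L jointly.

Both accept a raw or baseline-corrected :class:`~glycoforce.curves.ForceCurve`;
simulation helpers live in :mod:`glycoforce.simulate` and plotting hangs off
the results objects.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .brush import CurveDecomposition, DecomposeConfig, decompose_curve
from .contact import HertzFit, elastic_force, fit_hertz
from .curves import ForceCurve, ProbeGeometry, correct_baseline
from .errors import GlycoforceError

__all__ = ["HertzModel", "HertzResults", "BrushHertzModel", "BrushHertzResults"]


def _fmt(x: float, unit: str = "") -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "nan"
    return f"{x:.6g}{unit}"


class HertzModel:
    """Elastic contact model for a single approach curve.

    Parameters
    ----------
    curve : ForceCurve
        Approach curve; baseline-corrected automatically if it is not.
    geometry : ProbeGeometry, optional
        Defaults to the probe stored on the curve.
    window : str
        ``"deep:q"`` or ``"cap:delta_max_nm"`` indentation window policy.
    """

    def __init__(self, curve: ForceCurve, geometry: ProbeGeometry | None = None,
                 window: str = "deep:0.4", poisson: float = 0.5,
                 baseline_fraction: float = 0.3):
        if curve.segment != "approach":
            raise GlycoforceError("elastic fits are defined on approach curves")
        self.curve = curve if curve.baseline_corrected else correct_baseline(
            curve, baseline_fraction)
        self.geometry = geometry or curve.probe
        self.window = window
        self.poisson = poisson

    def fit(self, **kw) -> "HertzResults":
        hf = fit_hertz(self.curve, self.geometry, window=self.window,
                       poisson=self.poisson, **kw)
        return HertzResults(self, hf)


class HertzResults:
    """Results of :class:`HertzModel.fit`: apparent Young's modulus E (Pa),
    contact point z0 (nm), standard errors and residual diagnostics."""

    def __init__(self, model: HertzModel, fit: HertzFit):
        self.model = model
        self._fit = fit

    @property
    def hertz_fit(self) -> HertzFit:
        return self._fit

    @property
    def params(self) -> pd.Series:
        return pd.Series({"E_pa": self._fit.E_pa, "z0_nm": self._fit.z0_nm,
                          "offset_pn": self._fit.offset_pn})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({"E_pa": self._fit.E_stderr_pa,
                          "z0_nm": self._fit.z0_stderr_nm})

    @property
    def fittedvalues(self) -> np.ndarray:
        c = self.model.curve
        d = c.force_pn / c.calibration.k_pn_per_nm
        delta = np.maximum(0.0, (self._fit.z0_nm - c.z_nm) - d)
        return self._fit.offset_pn + np.asarray(
            elastic_force(self._fit.E_pa, self._fit.poisson,
                          self.model.geometry, delta))

    @property
    def resid(self) -> np.ndarray:
        return self.model.curve.force_pn - self.fittedvalues

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Elastic contact fit",
            "=" * 46,
            f"probe:              {self.model.geometry.kind}",
            f"window:             {self.model.window}",
            f"n points in window: {f.n_points}",
            f"E (apparent)        {_fmt(f.E_pa)} Pa  (se {_fmt(f.E_stderr_pa)})",
            f"contact z0          {_fmt(f.z0_nm)} nm  (se {_fmt(f.z0_stderr_nm)})",
            f"poisson ratio       {_fmt(f.poisson)} (fixed)",
            f"force offset        {_fmt(f.offset_pn)} pN",
            f"residual RMS        {_fmt(f.residual_rms_pn)} pN",
            f"converged           {f.success}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Force vs piezo height with the fitted model overlaid."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.z_nm, c.force_pn, ".", ms=3, label="data")
        ax.plot(c.z_nm, self.fittedvalues, "-", label="fit")
        ax.axvline(self._fit.z0_nm, ls=":", color="k", label="z0")
        ax.set_xlabel("piezo height (nm)")
        ax.set_ylabel("force (pN)")
        ax.invert_xaxis()
        ax.legend()
        return ax


class BrushHertzModel:
    """Two-regime model of an approach curve on a glycocalyx-bearing cell:
    deep-regime Hertz elasticity plus a long-range Alexander-de Gennes brush."""

    def __init__(self, curve: ForceCurve, geometry: ProbeGeometry | None = None,
                 config: DecomposeConfig | None = None):
        if curve.segment != "approach":
            raise GlycoforceError("the decomposition is defined on approach curves")
        self.curve = curve
        self.geometry = geometry or curve.probe
        self.config = config or DecomposeConfig()

    def fit(self) -> "BrushHertzResults":
        decomp = decompose_curve(self.curve, self.geometry, self.config)
        return BrushHertzResults(self, decomp)


class BrushHertzResults:
    """Results of the two-regime decomposition: E, z0, and when a brush is
    detected L and N, with standard errors, flags and a summary table."""

    def __init__(self, model: BrushHertzModel, decomposition: CurveDecomposition):
        self.model = model
        self.decomposition = decomposition

    @property
    def hertz_fit(self) -> HertzFit:
        return self.decomposition.hertz

    @property
    def brush_fit(self):
        return self.decomposition.brush

    @property
    def brush_detected(self) -> bool:
        return self.decomposition.brush_detected

    @property
    def flags(self) -> frozenset[str]:
        return self.decomposition.quality_flags

    @property
    def params(self) -> pd.Series:
        h, b = self.decomposition.hertz, self.decomposition.brush
        out = {"E_pa": h.E_pa, "z0_nm": h.z0_nm, "offset_pn": h.offset_pn,
               "L_nm": np.nan, "N_per_m2": np.nan}
        if b is not None:
            out["L_nm"] = b.L_nm
            out["N_per_m2"] = b.N_per_m2
        return pd.Series(out)

    @property
    def bse(self) -> pd.Series:
        h, b = self.decomposition.hertz, self.decomposition.brush
        return pd.Series({
            "E_pa": h.E_stderr_pa,
            "z0_nm": h.z0_stderr_nm,
            "L_nm": b.L_stderr_nm if b is not None else np.nan,
        })

    def to_row(self) -> dict:
        """Flat record (one CSV row) of all fitted fields."""
        h = self.decomposition.hertz
        row = {f"hertz_{k}": v for k, v in asdict(h).items()}
        b = self.decomposition.brush
        if b is not None:
            row.update({f"brush_{k}": v for k, v in asdict(b).items()})
        row["brush_detected"] = self.brush_detected
        row["quality_flags"] = ";".join(sorted(self.flags))
        return row

    def summary(self) -> str:
        h, b = self.decomposition.hertz, self.decomposition.brush
        lines = [
            "Two-regime curve decomposition (Hertz + glycocalyx brush)",
            "=" * 58,
            f"E (apparent)        {_fmt(h.E_pa)} Pa  (se {_fmt(h.E_stderr_pa)})",
            f"contact z0          {_fmt(h.z0_nm)} nm",
            f"brush plateau       {_fmt(h.offset_pn)} pN",
            f"Hertz window        {_fmt(h.fit_window_nm[0])}-"
            f"{_fmt(h.fit_window_nm[1])} nm ({h.n_points} pts, "
            f"RMS {_fmt(h.residual_rms_pn)} pN)",
            f"brush detected      {self.brush_detected}",
        ]
        if b is not None:
            lines += [
                f"glycocalyx L        {_fmt(b.L_nm)} nm  (se {_fmt(b.L_stderr_nm)})",
                f"grafting density N  {_fmt(b.N_per_m2)} m^-2",
                f"brush window        {_fmt(b.h_window_nm[0])}-"
                f"{_fmt(b.h_window_nm[1])} nm ({b.n_points} pts)",
                f"log-linear r^2      {_fmt(b.r_squared_loglinear)}",
            ]
        lines.append(f"flags               {sorted(self.flags) or 'none'}")
        return "\n".join(lines)

    def plot_decomposition(self, ax=None):
        """Data with the Hertz and brush components overlaid vs piezo height."""
        import matplotlib.pyplot as plt
        from .brush import brush_force
        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        h = self.decomposition.hertz
        d = c.force_pn / c.calibration.k_pn_per_nm
        s = (c.z_nm - h.z0_nm) + d
        delta = np.maximum(0.0, -s)
        ax.plot(c.z_nm, c.force_pn, ".", ms=3, label="data")
        ax.plot(c.z_nm, h.offset_pn * (delta > 0) + np.asarray(
            elastic_force(h.E_pa, h.poisson, self.model.geometry, delta)),
            "-", label="Hertz")
        b = self.decomposition.brush
        if b is not None:
            mask = s > 0
            ax.plot(c.z_nm[mask],
                    np.asarray(brush_force(b.L_nm, b.N_per_m2,
                                           self.model.geometry.radius_um,
                                           c.temperature_k, s[mask])),
                    "--", label="brush")
        ax.set_xlabel("piezo height (nm)")
        ax.set_ylabel("force (pN)")
        ax.invert_xaxis()
        ax.legend()
        return ax
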
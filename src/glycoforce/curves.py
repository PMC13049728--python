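"""Force-distance curve containers, file I/O, calibration and baseline correction.

Axis and sign conventions (fixed package-wide):

* ``z`` is the piezo height in nm. It **decreases** as the tip approaches the
  sample; approach segments are stored far-to-near, i.e. strictly decreasing.
* ``deflection`` is the cantilever deflection in nm, positive for repulsive
  loading, so that ``force = spring_constant * deflection`` (force in pN,
  spring constant in N/m = 1000 pN/nm).
* For a contact point ``z0``, tip-sample separation and indentation are

      separation  s = (z - z0) + d
      indentation delta = max(0, -s) = max(0, (z0 - z) - d)

  (a repulsive deflection moves the tip away from the surface, so it adds
  to the separation and subtracts from the indentation); ``delta = 0``
  exactly at ``z = z0`` when ``d = 0``.

Curve files are plain TSV with ``#``-prefixed ``key: value`` header lines;
force maps are a directory of curve TSVs plus a ``manifest.txt`` of
``key: value`` lines (grid shape, step, origin, file layout).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._constants import DEFAULT_TEMPERATURE_K, N_PER_M_TO_PN_PER_NM
from .errors import CurveParseError, GlycoforceError, InvariantError

__all__ = [
    "ProbeGeometry",
    "CantileverCalibration",
    "ForceCurve",
    "MapHeader",
    "read_curves",
    "write_curves",
    "read_map",
    "write_map",
    "correct_baseline",
    "to_tip_sample",
]

#: force/deflection consistency tolerance (relative)
_FD_RTOL = 1e-6
_MIN_SAMPLES = 16
_MIN_BASELINE_SAMPLES = 8


@dataclass(frozen=True)
class ProbeGeometry:
    """AFM probe geometry: a sphere (radius in um) or a four-sided pyramid
    (face half-angle in degrees)."""

    kind: str  # "sphere" | "pyramid"
    radius_um: float | None = None
    half_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "sphere":
            if self.radius_um is None or self.radius_um <= 0:
                raise InvariantError("sphere probe requires radius_um > 0")
            if self.half_angle_deg is not None:
                raise InvariantError("sphere probe must not set half_angle_deg")
        elif self.kind == "pyramid":
            if self.half_angle_deg is None or not (0 < self.half_angle_deg < 90):
                raise InvariantError("pyramid probe requires 0 < half_angle_deg < 90")
            if self.radius_um is not None:
                raise InvariantError("pyramid probe must not set radius_um")
        else:
            raise InvariantError(f"unknown probe kind {self.kind!r}")

    @classmethod
    def sphere(cls, radius_um: float = 1.25) -> "ProbeGeometry":
        return cls(kind="sphere", radius_um=radius_um)

    @classmethod
    def pyramid(cls, half_angle_deg: float = 20.0) -> "ProbeGeometry":
        return cls(kind="pyramid", half_angle_deg=half_angle_deg)


@dataclass(frozen=True)
class CantileverCalibration:
    """Cantilever calibration: spring constant (N/m), deflection offset (nm)
    and residual baseline slope (pN per nm of piezo travel)."""

    spring_constant: float = 0.02
    deflection_offset_nm: float = 0.0
    baseline_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise InvariantError("spring_constant must be > 0")

    @property
    def k_pn_per_nm(self) -> float:
        return self.spring_constant * N_PER_M_TO_PN_PER_NM


@dataclass(frozen=True)
class MapHeader:
    """Force-map grid metadata: (rows, cols), step in um, origin in um."""

    grid_shape: tuple[int, int]
    step_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise InvariantError("grid_shape entries must be >= 1")
        if self.step_um <= 0:
            raise InvariantError("step must be > 0")


@dataclass(frozen=True)
class ForceCurve:
    """One calibrated force-distance curve (approach or retract segment).

    ``z_nm`` is the piezo height channel; exactly one of deflection/force is
    the raw channel but both are stored for convenience and must satisfy
    ``force = k * deflection`` wherever both are present.
    Optional derived channels ``separation_nm``/``indentation_nm`` are added
    by :func:`to_tip_sample`.
    """

    z_nm: np.ndarray
    force_pn: np.ndarray
    deflection_nm: np.ndarray | None = None
    segment: str = "approach"
    position_um: tuple[float, float] | None = None
    temperature_k: float = DEFAULT_TEMPERATURE_K
    probe: ProbeGeometry = field(default_factory=ProbeGeometry.sphere)
    calibration: CantileverCalibration = field(default_factory=CantileverCalibration)
    separation_nm: np.ndarray | None = None
    indentation_nm: np.ndarray | None = None
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        z = np.asarray(self.z_nm, dtype=float)
        f = np.asarray(self.force_pn, dtype=float)
        object.__setattr__(self, "z_nm", z)
        object.__setattr__(self, "force_pn", f)
        if self.deflection_nm is not None:
            d = np.asarray(self.deflection_nm, dtype=float)
            object.__setattr__(self, "deflection_nm", d)
        if self.segment not in ("approach", "retract"):
            raise InvariantError(f"unknown segment {self.segment!r}")
        if z.ndim != 1 or z.size < _MIN_SAMPLES:
            raise InvariantError(
                f"curve needs >= {_MIN_SAMPLES} samples, got {z.size}"
            )
        for name, ch in (
            ("force", f),
            ("deflection", self.deflection_nm),
            ("separation", self.separation_nm),
            ("indentation", self.indentation_nm),
        ):
            if ch is not None and len(ch) != z.size:
                raise InvariantError(
                    f"channel length mismatch: {name} has {len(ch)}, z has {z.size}"
                )
        if self.segment == "approach":
            dz = np.diff(z)
            if not (np.all(dz < 0) or np.all(dz > 0)):
                raise InvariantError("approach piezo_height must be strictly monotone")
        if self.temperature_k <= 0:
            raise InvariantError("temperature must be > 0")
        if self.deflection_nm is not None:
            k = self.calibration.k_pn_per_nm
            scale = max(1.0, float(np.max(np.abs(f))))
            if not np.allclose(f, k * self.deflection_nm, atol=_FD_RTOL * scale):
                raise InvariantError("force != spring_constant * deflection")

    @property
    def n(self) -> int:
        return int(self.z_nm.size)

    def deflection(self) -> np.ndarray:
        """Deflection channel (nm), derived from force if not stored."""
        if self.deflection_nm is not None:
            return self.deflection_nm
        return self.force_pn / self.calibration.k_pn_per_nm

    def replace(self, **kw) -> "ForceCurve":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# I/O: TSV dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = {
    "segment",
    "probe_kind",
    "probe_radius_um",
    "probe_half_angle_deg",
    "spring_constant_n_per_m",
    "deflection_offset_nm",
    "baseline_slope",
    "temperature_k",
    "position_x_um",
    "position_y_um",
    "baseline_corrected",
}


def _curve_header_lines(curve: ForceCurve) -> list[str]:
    lines = [
        "# glycoforce-curve v1",
        f"# segment: {curve.segment}",
        f"# probe_kind: {curve.probe.kind}",
        f"# spring_constant_n_per_m: {curve.calibration.spring_constant!r}",
        f"# deflection_offset_nm: {curve.calibration.deflection_offset_nm!r}",
        f"# baseline_slope: {curve.calibration.baseline_slope!r}",
        f"# temperature_k: {curve.temperature_k!r}",
        f"# baseline_corrected: {curve.baseline_corrected}",
    ]
    if curve.probe.kind == "sphere":
        lines.insert(3, f"# probe_radius_um: {curve.probe.radius_um!r}")
    else:
        lines.insert(3, f"# probe_half_angle_deg: {curve.probe.half_angle_deg!r}")
    if curve.position_um is not None:
        lines.append(f"# position_x_um: {curve.position_um[0]!r}")
        lines.append(f"# position_y_um: {curve.position_um[1]!r}")
    return lines


def write_curves(path: str | os.PathLike, curves: ForceCurve | Iterable[ForceCurve]) -> None:
    """Write one or more curves to a TSV file (records separated by headers)."""
    if isinstance(curves, ForceCurve):
        curves = [curves]
    buf = io.StringIO()
    for curve in curves:
        for line in _curve_header_lines(curve):
            buf.write(line + "\n")
        buf.write("# columns: z_nm\tdeflection_nm\n")
        d = curve.deflection()
        for zi, di in zip(curve.z_nm, d):
            buf.write(f"{float(zi)!r}\t{float(di)!r}\n")
    Path(path).write_text(buf.getvalue())


def _parse_record(header: dict[str, str], rows: list[tuple[float, float]],
                  where: str) -> ForceCurve:
    if len(rows) < _MIN_SAMPLES:
        raise CurveParseError(f"{where}: record has {len(rows)} samples (< {_MIN_SAMPLES})")
    kind = header.get("probe_kind", "sphere")
    if kind == "sphere":
        probe = ProbeGeometry.sphere(float(header.get("probe_radius_um", 1.25)))
    else:
        probe = ProbeGeometry.pyramid(float(header.get("probe_half_angle_deg", 20.0)))
    calib = CantileverCalibration(
        spring_constant=float(header.get("spring_constant_n_per_m", 0.02)),
        deflection_offset_nm=float(header.get("deflection_offset_nm", 0.0)),
        baseline_slope=float(header.get("baseline_slope", 0.0)),
    )
    position = None
    if "position_x_um" in header and "position_y_um" in header:
        position = (float(header["position_x_um"]), float(header["position_y_um"]))
    z = np.array([r[0] for r in rows])
    d = np.array([r[1] for r in rows])
    try:
        return ForceCurve(
            z_nm=z,
            force_pn=calib.k_pn_per_nm * d,
            deflection_nm=d,
            segment=header.get("segment", "approach"),
            position_um=position,
            temperature_k=float(header.get("temperature_k", DEFAULT_TEMPERATURE_K)),
            probe=probe,
            calibration=calib,
            baseline_corrected=header.get("baseline_corrected", "False") == "True",
        )
    except InvariantError as exc:
        raise CurveParseError(f"{where}: {exc}") from exc


def read_curves(path: str | os.PathLike) -> list[ForceCurve]:
    """Read curves from a TSV file written in the package dialect."""
    path = Path(path)
    if not path.exists():
        raise CurveParseError(f"no such file: {path}")
    curves: list[ForceCurve] = []
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    rec_start = 1

    def flush(lineno: int) -> None:
        nonlocal header, rows, rec_start
        if rows or header:
            curves.append(
                _parse_record(header, rows, f"{path}:record starting line {rec_start}")
            )
        header, rows, rec_start = {}, [], lineno

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("glycoforce-curve"):
                if rows:
                    flush(lineno)
                continue
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in _HEADER_KEYS:
                    if rows:  # header after data = new record without magic line
                        flush(lineno)
                    header[key.strip()] = val.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CurveParseError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise CurveParseError(f"{path}:{lineno}: non-numeric value") from exc
    flush(-1)
    if not curves:
        raise CurveParseError(f"{path}: no curve records found")
    return curves


def write_map(dirpath: str | os.PathLike, header: MapHeader,
              curves: Sequence[Sequence[ForceCurve | None]]) -> None:
    """Write a force map as a directory of curve TSVs plus a manifest."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    rows, cols = header.grid_shape
    lines = [
        "map_format: glycoforce-map v1",
        f"grid_rows: {rows}",
        f"grid_cols: {cols}",
        f"step_um: {header.step_um!r}",
        f"origin_x_um: {header.origin_um[0]!r}",
        f"origin_y_um: {header.origin_um[1]!r}",
        "file_pattern: r{row}_c{col}.tsv",
    ]
    (dirpath / "manifest.txt").write_text("\n".join(lines) + "\n")
    for r in range(rows):
        for c in range(cols):
            curve = curves[r][c]
            if curve is not None:
                write_curves(dirpath / f"r{r}_c{c}.tsv", curve)


def read_map(dirpath: str | os.PathLike) -> tuple[MapHeader, list[list[ForceCurve | None]]]:
    """Read a force map directory; missing pixel files yield ``None``."""
    dirpath = Path(dirpath)
    manifest = dirpath / "manifest.txt"
    if not manifest.exists():
        raise CurveParseError(f"{dirpath}: missing manifest.txt")
    meta: dict[str, str] = {}
    for raw in manifest.read_text().splitlines():
        if ":" in raw:
            key, _, val = raw.partition(":")
            meta[key.strip()] = val.strip()
    try:
        header = MapHeader(
            grid_shape=(int(meta["grid_rows"]), int(meta["grid_cols"])),
            step_um=float(meta["step_um"]),
            origin_um=(float(meta.get("origin_x_um", 0.0)),
                       float(meta.get("origin_y_um", 0.0))),
        )
    except (KeyError, ValueError, InvariantError) as exc:
        raise CurveParseError(f"{manifest}: malformed manifest ({exc})") from exc
    rows, cols = header.grid_shape
    grid: list[list[ForceCurve | None]] = []
    for r in range(rows):
        row: list[ForceCurve | None] = []
        for c in range(cols):
            f = dirpath / f"r{r}_c{c}.tsv"
            row.append(read_curves(f)[0] if f.exists() else None)
        grid.append(row)
    return header, grid


# ---------------------------------------------------------------------------
# Baseline correction and tip-sample transformation
# ---------------------------------------------------------------------------

def _far_window(curve: ForceCurve, fraction: float) -> np.ndarray:
    """Indices of the far (non-contact) end of the approach ramp."""
    if not (0 < fraction < 1):
        raise GlycoforceError("baseline_fraction must be in (0, 1)")
    nwin = int(round(fraction * curve.n))
    if nwin < _MIN_BASELINE_SAMPLES:
        raise GlycoforceError(
            f"baseline window has {nwin} samples (< {_MIN_BASELINE_SAMPLES}); "
            "increase baseline_fraction"
        )
    # far end = largest piezo height
    if curve.z_nm[0] > curve.z_nm[-1]:
        return np.arange(nwin)
    return np.arange(curve.n - nwin, curve.n)


def correct_baseline(curve: ForceCurve, baseline_fraction: float = 0.3) -> ForceCurve:
    """Subtract a least-squares line fitted over the far non-contact window.

    The line is fitted to force vs piezo height over the farthest
    ``baseline_fraction`` of the approach samples and subtracted from the
    whole force channel (idempotent to numerical tolerance).
    """
    idx = _far_window(curve, baseline_fraction)
    z, f = curve.z_nm[idx], curve.force_pn[idx]
    slope, intercept = np.polyfit(z, f, 1)
    f_new = curve.force_pn - (slope * curve.z_nm + intercept)
    k = curve.calibration.k_pn_per_nm
    return curve.replace(
        force_pn=f_new,
        deflection_nm=f_new / k,
        baseline_corrected=True,
    )


def to_tip_sample(curve: ForceCurve, contact_z0: float) -> ForceCurve:
    """Add separation ``s = (z - z0) + d`` and indentation
    ``delta = max(0, (z0 - z) - d)`` channels for a given contact point."""
    zmin, zmax = float(np.min(curve.z_nm)), float(np.max(curve.z_nm))
    if not (zmin <= contact_z0 <= zmax):
        raise GlycoforceError(
            f"contact z0 {contact_z0} outside piezo range [{zmin}, {zmax}]"
        )
    d = curve.deflection()
    s = (curve.z_nm - contact_z0) + d
    delta = np.maximum(0.0, -s)
    return curve.replace(separation_nm=s, indentation_nm=delta)
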
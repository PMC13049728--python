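"""Synthetic-data generators with planted ground truth for every pipeline
stage: force curves and maps, fluorescence ROI images, scratch-assay series,
and gene/protein tables.

The defaults emulate the acquisition conditions of the endothelial-cell
experiments the package analyses: a 1.25 um spherical glass probe on a
0.02 N/m cantilever at 36.2 degC, 500 pN force setpoint (modelled as ramp
truncation), 7x7 force-map grids at 1.5 um step, hourly scratch frames, and
DEG/DEP tables whose p-values are generated from the same normal model as
the effects (z -> two-sided p -> Benjamini-Hochberg).

Curve mechanics: total force is the sum of the Alexander-de Gennes brush
term and the Hertz term sharing one contact point,

    F(z) = brush(max(s, 0)) + hertz(max(delta, 0)) + baseline + noise

with s and delta the tip-sample channels (the brush force saturates at its
zero-separation plateau once the layer is fully squeezed).  Deflection
consistency d = F/k is enforced by solving the cantilever fixed point at
every piezo position, so the kinematic bookkeeping (s = (z-z0)+d,
delta = max(0, -s)) is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._constants import DEFAULT_TEMPERATURE_K
from .brush import DecomposeConfig, brush_prefactor, decompose_curve
from .contact import fit_hertz
from .curves import CantileverCalibration, ForceCurve, MapHeader, ProbeGeometry
from .errors import GlycoforceError
from .imaging import ROISet, ScratchSeries
from .maps import ForceMap, central_region

__all__ = [
    "CurveSim", "MapSim", "ImageSim", "ScratchSim", "GeneSim", "SimConfig",
    "CurveTruth", "simulate_curve", "simulate_map", "simulate_fluor_image",
    "simulate_scratch", "simulate_gene_table",
]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSim:
    """Planted parameters of one synthetic approach curve."""

    E_pa: float = 2000.0
    poisson: float = 0.5
    brush: bool = True
    L_nm: float = 300.0
    N_per_m2: float = 1.0e14
    z0_nm: float = 0.0
    noise_sd_pn: float = 3.0
    baseline_offset_pn: float = 0.0
    baseline_slope_pn_per_nm: float = 0.0
    n_points: int | None = None  # default: one sample per z_step_nm of ramp
    z_step_nm: float = 2.0
    max_force_pn: float = 500.0
    s_max_nm: float | None = None  # default max(4 L, 400)
    probe: ProbeGeometry = field(default_factory=ProbeGeometry.sphere)
    spring_constant: float = 0.02
    temperature_k: float = DEFAULT_TEMPERATURE_K
    rigid_substrate: bool = False  # brush on a rigid wall (E effectively infinite)
    substrate_onset_nm: float | None = None  # planted stiff-substrate upturn
    substrate_factor: float = 5.0
    delta_max_nm: float | None = None  # override the force-ceiling truncation


@dataclass(frozen=True)
class MapSim:
    """A force map over an elliptical cell phantom with distinct central and
    peripheral mechanics; optional cytochalasin mode scales E by a factor."""

    grid_shape: tuple[int, int] = (7, 7)
    step_um: float = 1.5
    mode: str = "sphere"  # "sphere" (glycocalyx decomposition) | "pyramid" (E map)
    E_central_pa: float = 2000.0
    E_peripheral_pa: float = 2000.0
    L_central_nm: float = 300.0
    L_peripheral_nm: float = 300.0
    N_per_m2: float = 1.0e14
    cyto_factor: float | None = None  # multiply all E by this ("after" map)
    biological_cv: float = 0.0  # lognormal pixel-to-pixel spread of E
    ellipse_fraction: tuple[float, float] = (0.95, 0.85)
    central_area_fraction: float = 0.5
    curve: CurveSim = field(default_factory=CurveSim)


@dataclass(frozen=True)
class ImageSim:
    """Fluorescence image with planted per-cell totals on a flat background."""

    shape: tuple[int, int] = (192, 256)
    n_cells: int = 3
    cell_radius_px: int = 18
    cell_totals: Sequence[float] | None = None  # default 5e4 * (1..n)
    background_level: float = 10.0
    gain: float = 1.0
    noise_scale: float = 0.0  # sd = noise_scale * sqrt(intensity), shot-like


@dataclass(frozen=True)
class ScratchSim:
    """Rectangular wound closing at a constant rate (percent of initial area
    per hour), sampled hourly."""

    shape: tuple[int, int] = (200, 300)
    gap_width0_px: int = 150
    closure_rate_percent_per_h: float = 10.0
    n_frames: int = 10
    texture_amplitude: float = 20.0
    texture_baseline: float = 100.0


@dataclass(frozen=True)
class GeneSim:
    """Gene/protein tables with planted effects and an optionally enriched
    target list."""

    n_genes: int = 2000
    frac_deg: float = 0.1
    effect_log2fc: float = 1.0
    effect_log2fc_mac: float = 0.6
    se_log2fc: float = 0.25
    n_targets: int = 300
    target_enrichment: float = 0.0  # fraction of targets forced to be true DEGs
    measure: str = "rna"
    # protein-table variant
    n_proteins: int = 200
    frac_dep: float = 0.1
    effect_log2fc_protein: float = 0.5849625007211562  # log2(1.5)
    se_log2fc_protein: float = 0.21


@dataclass(frozen=True)
class SimConfig:
    """Bundle of all generator sections plus the master seed."""

    seed: int = 0
    curve: CurveSim = field(default_factory=CurveSim)
    force_map: MapSim = field(default_factory=MapSim)
    image: ImageSim = field(default_factory=ImageSim)
    scratch: ScratchSim = field(default_factory=ScratchSim)
    genes: GeneSim = field(default_factory=GeneSim)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveTruth:
    """Planted parameters and exact noise-free channels of one curve."""

    E_pa: float
    L_nm: float | None
    N_per_m2: float | None
    z0_nm: float
    plateau_pn: float
    true_force_pn: np.ndarray
    true_deflection_nm: np.ndarray
    true_separation_nm: np.ndarray
    true_indentation_nm: np.ndarray


_RIGID_E_PA = 5.0e6


def _curve_force_model(cfg: CurveSim):
    """Noise-free total force as a function of (z, d) given the planted truth."""
    from .contact import elastic_force

    E = _RIGID_E_PA if cfg.rigid_substrate else cfg.E_pa
    plateau = 0.0
    if cfg.brush:
        if cfg.probe.kind != "sphere":
            raise GlycoforceError("brush term requires a spherical probe")
        plateau = brush_prefactor(cfg.L_nm, cfg.N_per_m2, cfg.probe.radius_um,
                                  cfg.temperature_k)

    def total(z: float, d: float) -> float:
        s = (z - cfg.z0_nm) + d
        delta = max(0.0, -s)
        f = float(elastic_force(E, cfg.poisson, cfg.probe, delta))
        if cfg.substrate_onset_nm is not None and delta > cfg.substrate_onset_nm:
            extra = delta - cfg.substrate_onset_nm
            f += float(elastic_force(cfg.substrate_factor * E, cfg.poisson,
                                     cfg.probe, extra))
        if cfg.brush:
            f += plateau * float(np.exp(-2.0 * np.pi * max(s, 0.0) / cfg.L_nm))
        return f

    return total, plateau, E


def simulate_curve(cfg: CurveSim | None = None, seed=0) -> tuple[ForceCurve, CurveTruth]:
    """Generate one approach curve (far-to-near, strictly decreasing z) with
    its exact truth record.  Byte-identical outputs under a fixed seed."""
    cfg = cfg or CurveSim()
    rng = _rng(seed)
    total, plateau, E = _curve_force_model(cfg)
    k = cfg.spring_constant * 1e3  # pN/nm
    from .contact import elastic_force

    # ramp extent: force ceiling (ramp truncation), or an explicit delta cap
    if cfg.delta_max_nm is not None:
        delta_end = cfg.delta_max_nm
    else:
        f_cell = max(cfg.max_force_pn - plateau, 0.05 * cfg.max_force_pn)
        m = 1.5 if cfg.probe.kind == "sphere" else 2.0
        unit = float(elastic_force(E, cfg.poisson, cfg.probe, 1.0))
        delta_end = (f_cell / unit) ** (1.0 / m)
    s_max = cfg.s_max_nm
    if s_max is None:
        s_max = max(4.0 * cfg.L_nm, 400.0) if cfg.brush else 400.0

    d_end = total(cfg.z0_nm - delta_end, 0.0) / k  # overestimate of final deflection
    z_far = cfg.z0_nm + s_max
    z_near = cfg.z0_nm - delta_end - d_end
    n_points = cfg.n_points
    if n_points is None:
        n_points = max(64, int(np.ceil((z_far - z_near) / cfg.z_step_nm)))
    z = np.linspace(z_far, z_near, n_points)

    # cantilever equilibrium k*d = F(z, d); g(d) = F - k*d is continuous with
    # g(0) >= 0 and g < 0 for d above F(z, 0)/k, so a bracketed root always
    # exists (brentq)
    from scipy.optimize import brentq

    d = np.empty_like(z)
    for i, zi in enumerate(z):
        g = lambda dd: total(zi, dd) - k * dd
        hi = total(zi, 0.0) / k + 1.0
        for _ in range(60):
            if g(hi) < 0:
                break
            hi *= 2.0
        d[i] = 0.0 if g(0.0) == 0.0 else brentq(g, 0.0, hi, xtol=1e-13)
    f_true = k * d

    keep = f_true <= cfg.max_force_pn
    if cfg.delta_max_nm is not None:
        keep = np.ones_like(keep)
    z, d, f_true = z[keep], d[keep], f_true[keep]

    s = (z - cfg.z0_nm) + d
    delta = np.maximum(0.0, -s)

    f_obs = f_true + cfg.baseline_offset_pn \
        + cfg.baseline_slope_pn_per_nm * (z - z[0]) \
        + (rng.normal(0.0, cfg.noise_sd_pn, z.size) if cfg.noise_sd_pn > 0
           else 0.0)

    curve = ForceCurve(
        z_nm=z, force_pn=f_obs, deflection_nm=f_obs / k,
        segment="approach", temperature_k=cfg.temperature_k, probe=cfg.probe,
        calibration=CantileverCalibration(spring_constant=cfg.spring_constant),
    )
    truth = CurveTruth(
        E_pa=E, L_nm=cfg.L_nm if cfg.brush else None,
        N_per_m2=cfg.N_per_m2 if cfg.brush else None,
        z0_nm=cfg.z0_nm, plateau_pn=plateau,
        true_force_pn=f_true, true_deflection_nm=f_true / k,
        true_separation_nm=s, true_indentation_nm=delta,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# Force maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapTruth:
    E_field_pa: np.ndarray
    L_field_nm: np.ndarray | None
    cell_mask: np.ndarray
    central_mask: np.ndarray
    curves: tuple


def _ellipse_mask(shape: tuple[int, int],
                  fraction: tuple[float, float]) -> np.ndarray:
    rows, cols = shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    a = max(fraction[0] * rows / 2.0, 1.0)
    b = max(fraction[1] * cols / 2.0, 1.0)
    rr, cc = np.mgrid[0:rows, 0:cols]
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def simulate_map(cfg: MapSim | None = None, seed=0,
                 cell_id: str = "cell") -> tuple[ForceMap, MapTruth]:
    """Generate and fit a force map over an elliptical cell phantom.

    ``mode="sphere"`` runs the full two-regime decomposition per pixel
    (glycocalyx maps); ``mode="pyramid"`` runs a capped-window Hertz fit per
    pixel (modulus maps, 200 nm indentation cap).  Central pixels carry the
    central (E, L), peripheral pixels the peripheral values; ``cyto_factor``
    scales every E (the cytochalasin "after" condition).
    """
    cfg = cfg or MapSim()
    rng = _rng(seed)
    rows, cols = cfg.grid_shape
    header = MapHeader(grid_shape=cfg.grid_shape, step_um=cfg.step_um)
    cell = _ellipse_mask(cfg.grid_shape, cfg.ellipse_fraction)
    central = central_region(cell, cfg.central_area_fraction)

    if cfg.mode == "pyramid":
        base_curve = replace(
            cfg.curve, brush=False,
            probe=ProbeGeometry.pyramid() if cfg.curve.probe.kind != "pyramid"
            else cfg.curve.probe,
            spring_constant=0.01, delta_max_nm=350.0)
    elif cfg.mode == "sphere":
        base_curve = cfg.curve
    else:
        raise GlycoforceError(f"unknown map mode {cfg.mode!r}")

    E_field = np.zeros(cfg.grid_shape)
    L_field = np.zeros(cfg.grid_shape)
    pixels: list[list[object | None]] = []
    curves: list[list[ForceCurve | None]] = []
    for r in range(rows):
        prow: list[object | None] = []
        crow: list[ForceCurve | None] = []
        for c in range(cols):
            if not cell[r, c]:
                prow.append(None)
                crow.append(None)
                continue
            is_central = bool(central[r, c])
            E = cfg.E_central_pa if is_central else cfg.E_peripheral_pa
            L = cfg.L_central_nm if is_central else cfg.L_peripheral_nm
            if cfg.cyto_factor is not None:
                E *= cfg.cyto_factor
            if cfg.biological_cv > 0:
                sigma = np.sqrt(np.log1p(cfg.biological_cv**2))
                E *= float(rng.lognormal(-0.5 * sigma**2, sigma))
            E_field[r, c], L_field[r, c] = E, L
            pix_cfg = replace(base_curve, E_pa=E, L_nm=L, N_per_m2=cfg.N_per_m2)
            curve, _ = simulate_curve(pix_cfg, rng)
            curve = curve.replace(position_um=(c * cfg.step_um, r * cfg.step_um))
            crow.append(curve)
            if cfg.mode == "sphere":
                prow.append(decompose_curve(curve, config=DecomposeConfig()))
            else:
                prow.append(fit_hertz(curve, window="cap:200"))
        pixels.append(prow)
        curves.append(crow)

    fmap = ForceMap(header=header, pixels=tuple(tuple(r) for r in pixels),
                    cell_mask=cell, central_mask=central, cell_id=cell_id)
    truth = MapTruth(E_field_pa=E_field,
                     L_field_nm=L_field if cfg.mode == "sphere" else None,
                     cell_mask=cell, central_mask=central,
                     curves=tuple(tuple(r) for r in curves))
    return fmap, truth


# ---------------------------------------------------------------------------
# Fluorescence images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageTruth:
    cell_totals: np.ndarray
    background_level: float
    label_mask: np.ndarray


def simulate_fluor_image(cfg: ImageSim | None = None, seed=0
                         ) -> tuple[ROISet, ImageTruth]:
    """Disk-shaped cells with planted integrated signals on a flat background;
    background ROIs are rectangles in the image corners."""
    cfg = cfg or ImageSim()
    rng = _rng(seed)
    h, w = cfg.shape
    totals = np.asarray(cfg.cell_totals if cfg.cell_totals is not None
                        else [5.0e4 * (i + 1) for i in range(cfg.n_cells)],
                        dtype=float)
    if totals.size != cfg.n_cells:
        raise GlycoforceError("cell_totals length must equal n_cells")
    img = np.full(cfg.shape, float(cfg.background_level))
    labels = np.zeros(cfg.shape, dtype=int)
    rr, cc = np.mgrid[0:h, 0:w]
    # deterministic cell centres on a horizontal line
    for i in range(cfg.n_cells):
        cy = h // 2
        cx = int((i + 1) * w / (cfg.n_cells + 1))
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= cfg.cell_radius_px**2
        if np.any(labels[disk] > 0):
            raise GlycoforceError("cells overlap; reduce radius or count")
        labels[disk] = i + 1
        img[disk] += totals[i] / int(disk.sum())
    img *= cfg.gain
    if cfg.noise_scale > 0:
        img = img + rng.normal(0.0, cfg.noise_scale * np.sqrt(np.maximum(img, 0.0)))
    bh, bw = max(4, h // 16), max(4, w // 16)
    bgs = []
    for sy, sx in ((0, 0), (0, w - bw), (h - bh, 0), (h - bh, w - bw)):
        m = np.zeros(cfg.shape, dtype=bool)
        m[sy:sy + bh, sx:sx + bw] = True
        if np.any(m & (labels > 0)):
            raise GlycoforceError("background ROI overlaps a cell")
        bgs.append(m)
    rois = ROISet(image=img, cell_rois=labels, background_rois=tuple(bgs))
    return rois, ImageTruth(cell_totals=totals * cfg.gain,
                            background_level=cfg.background_level * cfg.gain,
                            label_mask=labels)


# ---------------------------------------------------------------------------
# Scratch assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScratchTruth:
    closure_percent: np.ndarray
    rate_percent_per_h: float
    frames: tuple  # textured intensity frames matching the masks


def simulate_scratch(cfg: ScratchSim | None = None, seed=0
                     ) -> tuple[ScratchSeries, ScratchTruth]:
    """Vertical cell-free stripe shrinking symmetrically at a constant
    percentage of the initial area per hour, plus textured intensity frames
    (noisy cell lawn, smooth wound) for segmentation tests."""
    cfg = cfg or ScratchSim()
    rng = _rng(seed)
    h, w = cfg.shape
    if cfg.gap_width0_px >= w:
        raise GlycoforceError("initial gap wider than the frame")
    times = np.arange(cfg.n_frames, dtype=float)
    masks, frames, closure = [], [], []
    for t in times:
        width = int(round(cfg.gap_width0_px
                          * (1.0 - cfg.closure_rate_percent_per_h * t / 100.0)))
        width = max(width, 0)
        mask = np.zeros(cfg.shape, dtype=bool)
        if width > 0:
            left = (w - width) // 2
            mask[:, left:left + width] = True
        masks.append(mask)
        closure.append(100.0 * (cfg.gap_width0_px - width) / cfg.gap_width0_px)
        frame = np.full(cfg.shape, cfg.texture_baseline)
        texture = rng.normal(0.0, cfg.texture_amplitude, cfg.shape)
        frame = frame + np.where(mask, 0.0, texture)
        frames.append(frame)
    series = ScratchSeries(times_h=times, open_masks=tuple(masks))
    truth = ScratchTruth(closure_percent=np.asarray(closure),
                         rate_percent_per_h=cfg.closure_rate_percent_per_h,
                         frames=tuple(frames))
    return series, truth


# ---------------------------------------------------------------------------
# Gene / protein tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTableTruth:
    true_deg: frozenset[str]
    targets: frozenset[str]
    universe: frozenset[str]
    true_dep: frozenset[str] = frozenset()


def _pvalues_from_effects(obs: np.ndarray, se: float) -> np.ndarray:
    from scipy.stats import norm
    z = obs / se
    return 2.0 * norm.sf(np.abs(z))


def simulate_gene_table(cfg: GeneSim | None = None, seed=0
                        ) -> tuple[pd.DataFrame, GeneTableTruth]:
    """RNA table with two contrasts (mac, bac), a protein table appended,
    and a putative-target list with configurable enrichment.

    Observed log2 fold changes are true effect + N(0, se); p-values come
    from the matching z statistic (two-sided) and are Benjamini-Hochberg
    adjusted per contrast, so filters see internally consistent data.
    """
    cfg = cfg or GeneSim()
    rng = _rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    n_deg = int(round(cfg.frac_deg * cfg.n_genes))
    deg_idx = rng.choice(cfg.n_genes, size=n_deg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_deg)
    mu_bac = np.zeros(cfg.n_genes)
    mu_bac[deg_idx] = signs * cfg.effect_log2fc
    mu_mac = np.zeros(cfg.n_genes)
    mu_mac[deg_idx] = signs * cfg.effect_log2fc_mac

    rows = {"gene_id": genes, "measure": "rna"}
    for name, mu in (("mac", mu_mac), ("bac", mu_bac)):
        obs = mu + rng.normal(0.0, cfg.se_log2fc, cfg.n_genes)
        p = _pvalues_from_effects(obs, cfg.se_log2fc)
        padj = multipletests(p, method="fdr_bh")[1]
        rows[f"log2fc_{name}"] = obs
        rows[f"p_{name}"] = p
        rows[f"padj_{name}"] = padj
    rna = pd.DataFrame(rows)

    prots = np.array([f"P{i:05d}" for i in range(cfg.n_proteins)])
    n_dep = int(round(cfg.frac_dep * cfg.n_proteins))
    dep_idx = rng.choice(cfg.n_proteins, size=n_dep, replace=False)
    mu_p = np.zeros(cfg.n_proteins)
    mu_p[dep_idx] = rng.choice([-1.0, 1.0], size=n_dep) * cfg.effect_log2fc_protein
    obs_p = mu_p + rng.normal(0.0, cfg.se_log2fc_protein, cfg.n_proteins)
    p_raw = _pvalues_from_effects(obs_p, cfg.se_log2fc_protein)
    prot = pd.DataFrame({
        "gene_id": prots, "measure": "protein",
        "log2fc_mac": obs_p, "log2fc_bac": obs_p,
        "p_mac": p_raw, "p_bac": p_raw,
        "padj_mac": np.nan, "padj_bac": np.nan,
    })
    table = pd.concat([rna, prot], ignore_index=True)

    true_deg = frozenset(genes[deg_idx])
    n_enriched = int(round(cfg.target_enrichment * cfg.n_targets))
    n_enriched = min(n_enriched, n_deg)
    chosen: list[str] = []
    if n_enriched > 0:
        chosen += list(rng.choice(sorted(true_deg), size=n_enriched,
                                  replace=False))
    pool = np.setdiff1d(genes, np.array(chosen, dtype=object))
    chosen += list(rng.choice(pool, size=cfg.n_targets - n_enriched,
                              replace=False))
    truth = GeneTableTruth(
        true_deg=true_deg, targets=frozenset(chosen),
        universe=frozenset(genes),
        true_dep=frozenset(prots[dep_idx]),
    )
    return table, truth
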
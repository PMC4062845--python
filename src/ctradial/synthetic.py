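"""Synthetic 2D-FISH fields and 3D-FISH confocal stacks with ground truth.

Every stage of the pipeline is testable without microscopy data by
simulating what the analysis assumes about real images: an elliptical
(2D, flattened nuclei) or ellipsoidal (3D, preserved nuclei) DAPI-stained
nucleus with a mild radial intensity gradient and texture, one or more
chromosome-paint territories rendered as Gaussian blobs whose *radial
fraction* ρ is the controllable ground truth, Gaussian PSF blur, and
Poisson + Gaussian (photon + readout) noise.

ρ is defined shape-independently as the territory centre's distance from the
nuclear centre divided by the distance to the nuclear boundary along the
same direction, so ρ = 0 is the exact centre and ρ = 1 the boundary, for
circles, ellipses and ellipsoids alike.  Population presets draw ρ from Beta
distributions: ``interior`` (mean 0.3, like gene-dense chromosomes 17/19/20),
``intermediate`` (mean 0.5) and ``peripheral`` (mean 0.8, like chromosomes
18/21/22); relocation experiments move a territory between presets.

Paired territories (e.g. a relocating chromosome analysed against a static
neighbour) may be angularly correlated via ``CTSpec.follow``: the follower's
direction tracks its partner's with Gaussian jitter, emulating the conserved
relative arrangement of neighbouring territories that makes radial
relocation change their pairwise distance.

All randomness flows from a single integer seed; nucleus ``i`` of a
population uses the independent substream ``(seed, i)``, so populations are
reproducible bit-for-bit and per-nucleus scenes can be regenerated in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import ChannelImage

__all__ = [
    "CTTruth",
    "SceneTruth",
    "CTSpec",
    "SimulatedDataset",
    "RHO_PRESETS",
    "simulate_nucleus_2d",
    "simulate_stack_3d",
    "simulate_population",
    "default_scene_2d",
    "default_scene_3d",
]

#: Beta(α, β) parameters of the radial-fraction distribution per preset.
RHO_PRESETS: dict[str, tuple[float, float]] = {
    "interior": (3.0, 7.0),  # mean 0.3
    "intermediate": (5.0, 5.0),  # mean 0.5
    "peripheral": (8.0, 2.0),  # mean 0.8
}

#: ρ is capped just below 1 so a territory centre is strictly inside the nucleus.
RHO_MAX = 0.95


@dataclass(frozen=True)
class CTTruth:
    """Ground truth for one rendered chromosome territory."""

    name: str
    rho: float  # radial fraction in [0, 1]
    theta: float  # azimuth of the offset direction, radians
    phi: float = math.pi / 2  # polar angle (3D); pi/2 = equatorial plane
    sigma_um: float = 1.0  # Gaussian blob sigma in xy, μm
    sigma_z_um: float = 0.5  # blob sigma along z (3D), μm
    peak: float = 80.0  # peak intensity before blur/noise

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"radial fraction rho must be in [0, 1], got {self.rho}")


@dataclass(frozen=True)
class SceneTruth:
    """Full ground-truth parameter set of one simulated nucleus scene."""

    seed: int
    shape: tuple[int, ...]  # (ny, nx) or (nz, ny, nx)
    pixel_size: float  # μm per pixel in x, y
    semi_axes_um: tuple[float, ...]  # (a, b) along x, y or (a, b, c) with c along z
    center_px: tuple[float, ...]  # (x, y[, z]) in pixel/plane units
    orientation: float = 0.0  # in-plane rotation, radians
    cts: tuple[CTTruth, ...] = ()
    z_step: float | None = None  # μm between planes (3D)
    dapi_base: float = 100.0
    texture_amp: float = 5.0  # sd of smoothed DAPI texture
    gradient_g: float = 0.3  # DAPI = base*(1 + g*(1 - r_norm))
    psf_sigma_um: float = 0.25
    psf_sigma_z_um: float = 0.5
    poisson_scale: float = 1.0  # photons per intensity unit; 0 disables
    gaussian_sd: float = 2.0  # readout noise sd; 0 disables

    @property
    def ndim(self) -> int:
        return len(self.shape)


def default_scene_2d(seed: int = 0, **overrides) -> SceneTruth:
    """A typical flattened fibroblast nucleus: 14 × 10 μm ellipse, 0.3 μm px."""
    kw = dict(
        seed=seed,
        shape=(80, 80),
        pixel_size=0.3,
        semi_axes_um=(7.0, 5.0),
        center_px=(40.0, 40.0),
    )
    kw.update(overrides)
    return SceneTruth(**kw)


def default_scene_3d(seed: int = 0, **overrides) -> SceneTruth:
    """A preserved nucleus imaged as ~8 informative 0.3-μm optical sections."""
    kw = dict(
        seed=seed,
        shape=(16, 64, 64),
        pixel_size=0.3,
        z_step=0.3,
        semi_axes_um=(5.0, 4.0, 1.35),
        center_px=(32.0, 32.0, 8.0),
        psf_sigma_z_um=0.3,
    )
    kw.update(overrides)
    return SceneTruth(**kw)


# ---------------------------------------------------------------------------
# rendering


def _grid_um(truth: SceneTruth):
    """Physical coordinates of pixel centres relative to the nucleus centre.

    Returns offsets in μm, axis order matching ``center_px`` (x, y[, z]).
    """
    if truth.ndim == 2:
        ny, nx = truth.shape
        cx, cy = truth.center_px
        x = (np.arange(nx) + 0.5 - cx) * truth.pixel_size
        y = (np.arange(ny) + 0.5 - cy) * truth.pixel_size
        return np.meshgrid(x, y)  # dx[y, x], dy[y, x]
    nz, ny, nx = truth.shape
    cx, cy, cz = truth.center_px
    x = (np.arange(nx) + 0.5 - cx) * truth.pixel_size
    y = (np.arange(ny) + 0.5 - cy) * truth.pixel_size
    z = (np.arange(nz) + 0.5 - cz) * truth.z_step
    dz, dy, dx = np.meshgrid(z, y, x, indexing="ij")
    return dx, dy, dz


def _rotate_xy(dx, dy, angle):
    c, s = math.cos(angle), math.sin(angle)
    return c * dx + s * dy, -s * dx + c * dy


def _normalized_radius(truth: SceneTruth, grids):
    if truth.ndim == 2:
        dx, dy = grids
        u, v = _rotate_xy(dx, dy, truth.orientation)
        a, b = truth.semi_axes_um
        return np.sqrt((u / a) ** 2 + (v / b) ** 2)
    dx, dy, dz = grids
    u, v = _rotate_xy(dx, dy, truth.orientation)
    a, b, c = truth.semi_axes_um
    return np.sqrt((u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2)


def _direction_unit(ct: CTTruth, ndim: int) -> np.ndarray:
    if ndim == 2:
        return np.array([math.cos(ct.theta), math.sin(ct.theta)])
    sp = math.sin(ct.phi)
    return np.array([sp * math.cos(ct.theta), sp * math.sin(ct.theta), math.cos(ct.phi)])


def boundary_intercept_um(truth: SceneTruth, ct: CTTruth) -> float:
    """Distance from the nucleus centre to the boundary along the CT direction."""
    u = _direction_unit(ct, truth.ndim)
    ux, uy = _rotate_xy(u[0], u[1], truth.orientation)
    axes = truth.semi_axes_um
    if truth.ndim == 2:
        q = (ux / axes[0]) ** 2 + (uy / axes[1]) ** 2
    else:
        q = (ux / axes[0]) ** 2 + (uy / axes[1]) ** 2 + (u[2] / axes[2]) ** 2
    return 1.0 / math.sqrt(q)


def ct_center_um(truth: SceneTruth, ct: CTTruth) -> np.ndarray:
    """Territory centre as a μm offset (x, y[, z]) from the nucleus centre."""
    return ct.rho * boundary_intercept_um(truth, ct) * _direction_unit(ct, truth.ndim)


def _apply_noise(img: np.ndarray, truth: SceneTruth, rng: np.random.Generator) -> np.ndarray:
    out = img
    if truth.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * truth.poisson_scale) / truth.poisson_scale
    if truth.gaussian_sd > 0:
        out = out + rng.normal(0.0, truth.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _psf_sigma_px(truth: SceneTruth):
    s_xy = truth.psf_sigma_um / truth.pixel_size
    if truth.ndim == 2:
        return (s_xy, s_xy)
    return (truth.psf_sigma_z_um / truth.z_step, s_xy, s_xy)


def _render(truth: SceneTruth) -> tuple[ChannelImage, dict[str, ChannelImage]]:
    rng = np.random.default_rng(truth.seed)
    grids = _grid_um(truth)
    r_norm = _normalized_radius(truth, grids)
    inside = r_norm <= 1.0
    if not inside.any():
        raise ValueError("nucleus ellipse lies outside the field")

    dapi = truth.dapi_base * (1.0 + truth.gradient_g * (1.0 - r_norm)) * inside
    if truth.texture_amp > 0:
        raw = rng.standard_normal(truth.shape)
        tex = ndimage.gaussian_filter(raw, 2.0)
        sd = tex.std()
        if sd > 0:
            dapi = dapi + truth.texture_amp * (tex / sd) * inside

    probes: dict[str, np.ndarray] = {}
    for ct in truth.cts:
        center = ct_center_um(truth, ct)
        if truth.ndim == 2:
            dx, dy = grids
            r2 = ((dx - center[0]) / ct.sigma_um) ** 2 + ((dy - center[1]) / ct.sigma_um) ** 2
        else:
            dx, dy, dz = grids
            r2 = (
                ((dx - center[0]) / ct.sigma_um) ** 2
                + ((dy - center[1]) / ct.sigma_um) ** 2
                + ((dz - center[2]) / ct.sigma_z_um) ** 2
            )
        blob = ct.peak * np.exp(-0.5 * r2) * inside  # paint confined to nucleus
        probes[ct.name] = probes.get(ct.name, 0.0) + blob

    sig = _psf_sigma_px(truth)
    dapi = _apply_noise(ndimage.gaussian_filter(dapi, sig), truth, rng)
    out_probes = {}
    for name, img in probes.items():
        out_probes[name] = ChannelImage(
            _apply_noise(ndimage.gaussian_filter(img, sig), truth, rng),
            role=f"probe_{name}",
            pixel_size=truth.pixel_size,
            z_step=truth.z_step,
        )
    dapi_img = ChannelImage(dapi, role="dapi", pixel_size=truth.pixel_size, z_step=truth.z_step)
    return dapi_img, out_probes


def simulate_nucleus_2d(truth: SceneTruth) -> tuple[ChannelImage, dict[str, ChannelImage]]:
    """Render one 2D field: DAPI plane plus one probe plane per territory name."""
    if truth.ndim != 2:
        raise ValueError("simulate_nucleus_2d expects a 2D SceneTruth")
    return _render(truth)


def simulate_stack_3d(truth: SceneTruth) -> tuple[ChannelImage, dict[str, ChannelImage]]:
    """Render one 3D stack with anisotropic PSF and the configured z step."""
    if truth.ndim != 3:
        raise ValueError("simulate_stack_3d expects a 3D SceneTruth")
    if truth.z_step is None:
        raise ValueError("3D scenes require z_step")
    return _render(truth)


# ---------------------------------------------------------------------------
# populations


@dataclass(frozen=True)
class CTSpec:
    """How to draw one territory per nucleus of a population.

    ``rho`` is a preset name, a Beta ``(alpha, beta)`` pair, or a fixed
    float.  ``follow`` names another territory in the same nucleus whose
    direction this one tracks with Gaussian angular jitter ``angle_sd``
    (radians) — used for pairwise-distance experiments between a relocating
    and a static territory.
    """

    name: str = "A"
    rho: str | tuple[float, float] | float = "interior"
    sigma_um: float = 1.0
    sigma_z_um: float = 0.5
    peak: float = 80.0
    n_copies: int = 1  # homologs per nucleus
    follow: str | None = None
    angle_sd: float = 0.5
    phi_sd: float = 0.35  # 3D polar-angle spread about the equatorial plane


@dataclass
class SimulatedDataset:
    """A simulated population: per-nucleus scenes plus a ground-truth manifest."""

    condition: str
    scenes: list[tuple[SceneTruth, ChannelImage, dict[str, ChannelImage]]]
    manifest: pd.DataFrame
    seed: int

    def __len__(self) -> int:
        return len(self.scenes)

    def write(self, out_dir) -> pd.DataFrame:
        """Write TIFFs and manifest.csv; returns the manifest with file paths."""
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (truth, dapi, probes) in enumerate(self.scenes):
            paths = {}
            stem = f"{self.condition}_{i:04d}"
            dapi_path = out / f"{stem}_dapi.tif"
            tifffile.imwrite(dapi_path, dapi.data.astype(np.float32))
            paths["dapi_path"] = str(dapi_path)
            for name, img in probes.items():
                p = out / f"{stem}_probe_{name}.tif"
                tifffile.imwrite(p, img.data.astype(np.float32))
                paths[f"probe_{name}_path"] = str(p)
            rows.append(paths)
        manifest = self.manifest.join(pd.DataFrame(rows, index=self.manifest.index))
        manifest.to_csv(out / "manifest.csv", index=False)
        return manifest


def _draw_rho(spec: CTSpec, rng: np.random.Generator) -> float:
    if isinstance(spec.rho, str):
        try:
            a, b = RHO_PRESETS[spec.rho]
        except KeyError:
            raise ValueError(f"unknown rho preset {spec.rho!r}") from None
    elif isinstance(spec.rho, (tuple, list)):
        a, b = spec.rho
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
    else:
        return min(float(spec.rho), RHO_MAX)
    return min(float(rng.beta(a, b)), RHO_MAX)


def simulate_population(
    n: int,
    condition: str = "control",
    cts: list[CTSpec] | None = None,
    seed: int = 0,
    dims: int = 2,
    scene_overrides: dict | None = None,
    axis_jitter_sd: float = 0.08,
) -> SimulatedDataset:
    """Simulate ``n`` single-nucleus fields or stacks for one condition.

    Each nucleus gets log-normal jitter of its semi-axes (``axis_jitter_sd``
    in log units), a uniform random in-plane orientation, and territory
    draws per ``cts`` (default: one territory with interior placement).
    Nucleus ``i`` uses the substream ``(seed, i)``; identical config + seed
    reproduce the dataset bit-for-bit.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if cts is None:
        cts = [CTSpec()]
    base = default_scene_2d() if dims == 2 else default_scene_3d()
    if scene_overrides:
        base = replace(base, **scene_overrides)

    scenes = []
    rows = []
    for i in range(n):
        rng = np.random.default_rng((seed, i))
        axes = tuple(
            float(ax * math.exp(rng.normal(0.0, axis_jitter_sd)))
            for ax in base.semi_axes_um
        )
        orientation = float(rng.uniform(0.0, math.pi))
        drawn: dict[str, CTTruth] = {}
        ct_truths = []
        row: dict = {"nucleus_id": i, "condition": condition, "seed": seed}
        for spec in cts:
            for copy in range(spec.n_copies):
                rho = _draw_rho(spec, rng)
                if spec.follow is not None and spec.follow in drawn:
                    # azimuthal correlation only: the follower tracks its
                    # partner's in-plane direction; the polar angle keeps the
                    # flat-nucleus equatorial draw below
                    theta = float(drawn[spec.follow].theta + rng.normal(0.0, spec.angle_sd))
                else:
                    theta = float(rng.uniform(0.0, 2 * math.pi))
                # flattened nuclei: territories lie close to the equatorial
                # plane, so the polar angle concentrates about pi/2
                phi = (
                    float(
                        np.clip(
                            math.pi / 2 + rng.normal(0.0, spec.phi_sd),
                            0.05,
                            math.pi - 0.05,
                        )
                    )
                    if dims == 3
                    else math.pi / 2
                )
                ct = CTTruth(
                    name=spec.name,
                    rho=rho,
                    theta=theta,
                    phi=phi,
                    sigma_um=spec.sigma_um,
                    sigma_z_um=spec.sigma_z_um,
                    peak=spec.peak,
                )
                ct_truths.append(ct)
                drawn.setdefault(spec.name, ct)
                suffix = spec.name if spec.n_copies == 1 else f"{spec.name}{copy + 1}"
                row[f"rho_{suffix}"] = rho
                row[f"theta_{suffix}"] = theta
        scene_seed = int(np.random.SeedSequence((seed, i, 7)).generate_state(1)[0] % (2**31))
        truth = replace(
            base,
            seed=scene_seed,
            semi_axes_um=axes,
            orientation=orientation,
            cts=tuple(ct_truths),
        )
        dapi, probes = _render(truth)
        row["semi_axes_um"] = "x".join(f"{a:.3f}" for a in axes)
        row["orientation"] = orientation
        rows.append(row)
        scenes.append((truth, dapi, probes))
    manifest = pd.DataFrame(rows)
    return SimulatedDataset(condition=condition, scenes=scenes, manifest=manifest, seed=seed)
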
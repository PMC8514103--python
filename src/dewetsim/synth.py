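"""Seeded synthetic masks, traction maps, and dewetting-like time series.

These generators emulate the statistical structure of the experimental data
the analysis stages consume: roughly circular epithelial islands ~400 μm in
diameter, traction that concentrates in a boundary layer at the periphery and
points centripetally, and time series in which transformed islands shrink,
break symmetry, and show a dip-then-recover traction magnitude, while control
islands stay put. Everything is a pure function of (params, seed): the
top-level seed fans out to fixed per-stream substreams (mask phases, field
noise, series) so outputs are bit-reproducible and adding a new generator
never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from dewetsim.traction import BinaryMask, VectorField2D, inward_normals

_STREAMS = {"mask": 0, "field": 1, "series": 2}


@dataclass(frozen=True)
class SynthParams:
    """Generator controls. Defaults emulate the experimental conditions:
    200 μm island radius, traction peaking in the outer ~15% of the radius
    at a few hundred Pa, gentle low-wavenumber boundary roughness."""

    radius: float = 200.0  # μm
    pixel_size: float = 4.0  # μm/px
    rim_fraction: float = 0.15  # boundary-layer width / radius
    traction_peak: float = 0.3  # kPa
    boundary_noise_amp: float = 0.0  # μm
    boundary_wavenumbers: tuple[int, ...] = (2, 3, 5)
    field_noise_sd: float = 0.0  # kPa
    n_frames: int = 12
    area_decay: float = 0.4  # transformed mode: fractional radius loss by the end
    symmetry_break: float = 1.5  # transformed mode: final aspect ratio
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0 or self.pixel_size <= 0:
            raise ValueError("radius and pixel_size must be positive")
        if not 0 < self.rim_fraction <= 1:
            raise ValueError("rim_fraction must lie in (0, 1]")
        if self.boundary_noise_amp < 0 or self.field_noise_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.boundary_noise_amp >= 0.5 * self.radius:
            raise ValueError("boundary noise too large: contour would self-intersect")
        if not 0 <= self.area_decay < 1:
            raise ValueError("area_decay must lie in [0, 1)")
        if self.symmetry_break < 1:
            raise ValueError("symmetry_break must be >= 1")


def _rng(params: SynthParams, stream: str, index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(params.seed, spawn_key=(_STREAMS[stream], index))
    return np.random.default_rng(ss)


def synth_mask(
    params: SynthParams,
    radius_scale: float = 1.0,
    aniso: float = 1.0,
    frame: int = 0,
) -> BinaryMask:
    """Rasterize a star-convex island contour r(θ) = R + amp·Σ cos(kθ + φ_k).

    ``radius_scale`` shrinks the island isotropically; ``aniso`` ≥ 1 stretches
    x by √aniso and squeezes y by 1/√aniso (area-preserving symmetry
    breaking). The random phases φ_k come from the mask substream of the seed
    and are identical for every frame, so a time series deforms one island
    rather than redrawing it.
    """
    rng = _rng(params, "mask")
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(params.boundary_wavenumbers))

    extent = params.radius + params.boundary_noise_amp
    n_px = int(np.ceil(2.0 * extent / params.pixel_size)) + 4
    c = (n_px - 1) / 2.0
    rows, cols = np.indices((n_px, n_px))
    x = (cols - c) * params.pixel_size
    y = (rows - c) * params.pixel_size
    # invert the anisotropic stretch to test against the reference contour
    sx = np.sqrt(aniso)
    xr = x / (radius_scale * sx)
    yr = y * sx / radius_scale
    theta = np.arctan2(yr, xr)
    r_ref = params.radius + sum(
        params.boundary_noise_amp * np.cos(k * theta + p)
        for k, p in zip(params.boundary_wavenumbers, phases)
    )
    inside = np.hypot(xr, yr) <= r_ref
    lbl, n_comp = ndimage.label(inside, structure=np.ones((3, 3), dtype=bool))
    if n_comp != 1:
        raise ValueError("generated contour produced a disconnected mask")
    return BinaryMask(data=inside, pixel_size=params.pixel_size)


def synth_traction_map(
    mask: BinaryMask, params: SynthParams, magnitude_scale: float = 1.0, frame: int = 0
) -> VectorField2D:
    """Centripetal traction peaked at the island rim, plus optional noise.

    The magnitude decays exponentially with distance d from the edge,
    T(d) = traction_peak · exp(−d / (rim_fraction·radius)), and the direction
    points from each pixel toward the foreground centroid. For a symmetric
    island the per-pixel vectors cancel pairwise under the grid's reflection
    symmetries, so the noiseless net force vanishes to rounding error; the
    noiseless T⊥ is non-negative everywhere (the centripetal direction never
    makes an obtuse angle with the inward edge normal of a star-convex
    island) and maximal on the outermost ring. Gaussian component noise
    (sd = field_noise_sd) is drawn from the field substream, per frame.
    """
    d = ndimage.distance_transform_edt(mask.data) * mask.pixel_size
    width = params.rim_fraction * params.radius
    mag = params.traction_peak * magnitude_scale * np.exp(-d / width)
    mag[~mask.data] = 0.0
    rows, cols = np.indices(mask.data.shape)
    r0 = rows[mask.data].mean()
    c0 = cols[mask.data].mean()
    dy = r0 - rows
    dx = c0 - cols
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    tx = mag * dx / norm
    ty = mag * dy / norm
    if params.field_noise_sd > 0:
        rng = _rng(params, "field", frame)
        noise = rng.normal(0.0, params.field_noise_sd, size=(2,) + mask.data.shape)
        tx = tx + np.where(mask.data, noise[0], 0.0)
        ty = ty + np.where(mask.data, noise[1], 0.0)
    return VectorField2D(tx=tx, ty=ty)


#: dip-then-recover template for the transformed-mode traction magnitude:
#: (fraction of the series, magnitude relative to baseline)
DIP_RECOVER_TEMPLATE = ((0.0, 1.0), (0.25, 0.6), (1.0, 1.1))


def _template_value(s: float, template) -> float:
    xs, ys = zip(*template)
    return float(np.interp(s, xs, ys))


@dataclass(frozen=True)
class DewettingSeries:
    """Frames of (mask, traction) with the applied per-frame controls."""

    masks: list[BinaryMask]
    fields: list[VectorField2D]
    radius_scales: np.ndarray
    aniso: np.ndarray
    magnitude_scales: np.ndarray
    mode: str
    params: SynthParams = field(repr=False, default=None)


def synth_dewetting_series(
    params: SynthParams, mode: str = "transformed", template=DIP_RECOVER_TEMPLATE
) -> DewettingSeries:
    """Generate a control or transformed (dewetting-like) island time series.

    Control mode keeps the footprint and traction template constant (only the
    per-frame field noise varies). Transformed mode shrinks the radius
    linearly to (1 − area_decay)·R after an initial flat quarter of the
    frames, ramps the aspect ratio to ``symmetry_break`` over the last 40% of
    frames, and scales the traction magnitude by the dip-then-recover
    template.
    """
    if mode not in ("control", "transformed"):
        raise ValueError(f"mode must be 'control' or 'transformed', got {mode!r}")
    if params.n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    s = np.linspace(0.0, 1.0, params.n_frames)
    if mode == "control":
        radius_scales = np.ones_like(s)
        aniso = np.ones_like(s)
        mag = np.ones_like(s)
    else:
        radius_scales = 1.0 - params.area_decay * np.clip((s - 0.25) / 0.75, 0.0, 1.0)
        aniso = 1.0 + (params.symmetry_break - 1.0) * np.clip((s - 0.6) / 0.4, 0.0, 1.0)
        mag = np.array([_template_value(si, template) for si in s])
    masks, fields = [], []
    for i in range(params.n_frames):
        m = synth_mask(params, radius_scale=float(radius_scales[i]), aniso=float(aniso[i]))
        f = synth_traction_map(m, params, magnitude_scale=float(mag[i]), frame=i)
        masks.append(m)
        fields.append(f)
    return DewettingSeries(
        masks=masks,
        fields=fields,
        radius_scales=radius_scales,
        aniso=aniso,
        magnitude_scales=mag,
        mode=mode,
        params=params,
    )


def with_seed(params: SynthParams, seed: int) -> SynthParams:
    """Convenience: copy of params with a different seed."""
    return replace(params, seed=seed)


def save_series(series: DewettingSeries, out_dir) -> None:
    """Write a series as TIFF masks + CSV field grids + a JSON manifest."""
    import dataclasses
    import json
    from pathlib import Path

    from dewetsim import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (mask, fld) in enumerate(zip(series.masks, series.fields)):
        io.write_mask(mask, out / f"mask_{i:03d}.tif")
        io.write_field(fld, out / f"tx_{i:03d}.csv", out / f"ty_{i:03d}.csv")
    manifest = {
        "mode": series.mode,
        "n_frames": len(series.masks),
        "radius_scales": series.radius_scales.tolist(),
        "aniso": series.aniso.tolist(),
        "magnitude_scales": series.magnitude_scales.tolist(),
        "params": dataclasses.asdict(series.params),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
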
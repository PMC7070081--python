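"""Ground-truthed mock 4D scenes for end-to-end validation.

Real acquisitions of this kind — a reflection stack of a rough apatitic
substratum plus a time-lapse fluorescence channel of surface colonizers —
are emulated here with full ground truth: the true heightmap, every
colonizer's scheduled volume trajectory V(t) = V(0) + a·t^b (or a static
V ≈ V(0)), scripted detachment times, and merge contacts computed
directly from the rendered masks.  Every pipeline stage can therefore be
checked against known truth.

Colonizer blobs are grown by a deterministic dilation-to-target-volume:
the voxels nearest the seed point (anisotropic physical metric),
restricted to the space above the local substratum, are claimed in
distance order until the voxelized volume matches the schedule to within
one voxel.  Growth is therefore nested over time (monotone dilation) and
connected for smooth substrata.

Defaults mirror the study acquisition geometry: 0.42-µm Z step, 20-min
frame interval, 0.624 µm/px lateral pitch (a ~319.5-µm field at 512 px).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .stacks_io import ImageStack, TimeLapse, VoxelGeometry, write_stack
from .topography import HeightMap
from .segmentation import UNIT_CELL_VOLUME

DEFAULT_GEOMETRY = VoxelGeometry(dx=0.624, dy=0.624, dz=0.42, frame_interval=20.0)
DEFAULT_TIMES = tuple(float(t) for t in range(0, 421, 20))  # 22 frames, minutes

_BACKGROUND = 10    # reflection/bacteria background gray level
_SOLID = 200        # substratum reflection level
_SIGNAL = 255       # clean fluorescence level


@dataclass
class ColonizerSpec:
    """One scripted colonizer.

    ``x, y`` are pixel coordinates of the seed on the surface; ``p0`` the
    initial cell count (V0 = p0 × 0.35 µm³).  ``mode`` is ``"static"``
    (V(t) ≈ V0) or ``"power"`` (V(t) = V0 + a·t^b, t minutes from
    attachment).  ``detach_at`` removes the colonizer from frames at or
    after that time.
    """

    x: int
    y: int
    p0: int = 1
    mode: str = "static"
    a: float = 1e-5          # µm³·min^(−b)
    b: float = 2.6
    detach_at: float | None = None
    attach_at: float = 0.0

    def scheduled_volume(self, t: float) -> float:
        v0 = self.p0 * UNIT_CELL_VOLUME
        if self.mode == "static":
            return v0
        tt = max(0.0, t - self.attach_at)
        return v0 + self.a * tt ** self.b


@dataclass
class SceneSpec:
    """Full description of a mock 4D scene (seed fixed ⇒ identical output)."""

    nx: int
    ny: int
    nz: int
    geometry: VoxelGeometry = DEFAULT_GEOMETRY
    times: tuple[float, ...] = DEFAULT_TIMES
    surface_sa: float = 1.0            # target Sa, µm (0 = flat)
    surface_correlation_um: float = 10.0
    surface_base_um: float | None = None   # mean elevation; default nz·dz/2
    colonizers: list[ColonizerSpec] = field(default_factory=list)
    blur_sigma: float = 0.0            # px, for render_noisy
    noise_sigma: float = 0.0           # gray levels
    noise_poisson: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSpec":
        raw = yaml.safe_load(Path(path).read_text())
        geom = VoxelGeometry(**raw.pop("geometry", {})) if "geometry" in raw \
            else DEFAULT_GEOMETRY
        cols = [ColonizerSpec(**c) for c in raw.pop("colonizers", [])]
        times = tuple(float(t) for t in raw.pop("times", DEFAULT_TIMES))
        return cls(geometry=geom, colonizers=cols, times=times, **raw)

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["times"] = list(self.times)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)


# ---------------------------------------------------------------------------
# Substratum
# ---------------------------------------------------------------------------

def generate_surface(spec: SceneSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[HeightMap, ImageStack]:
    """Rough random-field substratum and its rendered reflection stack.

    A white-noise field smoothed at the requested correlation length is
    rescaled so its Sa equals ``spec.surface_sa`` exactly, then shifted
    to a base elevation.  The reflection stack is solid (bright) at and
    below the quantized surface.  Returns the continuous ground-truth
    heightmap (pre-quantization) and the reflection stack; heightmap
    extraction from the rendering recovers the truth to within dz.
    """
    geom = spec.geometry
    z_extent = spec.nz * geom.dz
    if not 0 <= spec.surface_sa <= z_extent / 3:
        raise ValueError(f"target Sa {spec.surface_sa} unreachable for Z extent "
                         f"{z_extent:.2f} µm (must be ≤ {z_extent / 3:.2f})")
    rng = rng or np.random.default_rng(spec.seed)
    # mid-depth base keeps the scaled field clear of both clip planes
    base = spec.surface_base_um if spec.surface_base_um is not None \
        else z_extent / 2
    if spec.surface_sa == 0:
        h = np.full((spec.ny, spec.nx), base, dtype=float)
    else:
        noise = rng.standard_normal((spec.ny, spec.nx))
        sigma_px = spec.surface_correlation_um / geom.dx
        f = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
        f -= f.mean()
        sa = np.abs(f).mean()
        if sa == 0:
            raise ValueError("degenerate surface field")
        h = base + f * (spec.surface_sa / sa)
        h = np.clip(h, 0.0, (spec.nz - 1) * geom.dz)
    truth = HeightMap(h.copy(), np.ones_like(h, dtype=bool), geom)

    k_surface = spec.nz - 1 - np.round(h / geom.dz).astype(int)  # top slice of solid
    zidx = np.arange(spec.nz)[:, None, None]
    values = np.where(zidx >= k_surface[None, :, :], _SOLID, _BACKGROUND
                      ).astype(np.uint8)
    stack = ImageStack(values, geom, channel="reflection")
    return truth, stack


# ---------------------------------------------------------------------------
# Colonizer scenes
# ---------------------------------------------------------------------------

def _blob_order(spec: SceneSpec, col: ColonizerSpec,
                k_surface: np.ndarray, max_voxels: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel coordinates claimable by one colonizer, in claiming order."""
    geom = spec.geometry
    # generous search radius: hemisphere of max volume plus margin
    v_max = (max_voxels + 8) * geom.voxel_volume
    r = (3.0 * v_max / (2.0 * np.pi)) ** (1.0 / 3.0) * 1.8 + 2 * max(geom.dx, geom.dz)
    wx, wy = int(np.ceil(r / geom.dx)) + 1, int(np.ceil(r / geom.dy)) + 1
    x0, x1 = max(0, col.x - wx), min(spec.nx, col.x + wx + 1)
    y0, y1 = max(0, col.y - wy), min(spec.ny, col.y + wy + 1)
    zz, yy, xx = np.meshgrid(np.arange(spec.nz), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    zz, yy, xx = zz.ravel(), yy.ravel(), xx.ravel()
    allowed = zz < k_surface[yy, xx]          # strictly above the substratum
    zz, yy, xx = zz[allowed], yy[allowed], xx[allowed]
    k_seed = k_surface[col.y, col.x] - 1      # first free slice above the surface
    seed = np.array([col.x * geom.dx, col.y * geom.dy, k_seed * geom.dz])
    d = np.sqrt((xx * geom.dx - seed[0]) ** 2 + (yy * geom.dy - seed[1]) ** 2
                + (zz * geom.dz - seed[2]) ** 2)
    order = np.lexsort((xx, yy, zz, d))
    return zz[order], yy[order], xx[order]


def generate_scene(spec: SceneSpec) -> tuple[TimeLapse, dict]:
    """Render a mock time lapse with full ground truth.

    The first frame carries both the reflection and the bacteria channel;
    later frames the bacteria channel only.  Ground truth contains the
    continuous heightmap, per-frame per-colonizer element records,
    scheduled volume series, detachment times, and merge contacts (first
    frame at which two blobs become 26-connected, computed from the
    rendered masks).

    Raises if two colonizers already overlap at the first frame.
    """
    rng = np.random.default_rng(spec.seed)
    heightmap, reflection = generate_surface(spec, rng)
    geom = spec.geometry
    k_surface = spec.nz - 1 - np.round(heightmap.h / geom.dz).astype(int)

    orders = []
    for col in spec.colonizers:
        if not (0 <= col.x < spec.nx and 0 <= col.y < spec.ny):
            raise ValueError(f"colonizer at ({col.x}, {col.y}) outside field")
        v_final = max(col.scheduled_volume(t) for t in spec.times)
        n_max = max(1, round(v_final / geom.voxel_volume))
        order = _blob_order(spec, col, k_surface, n_max)
        if len(order[0]) < n_max:
            raise ValueError(f"colonizer at ({col.x}, {col.y}) outgrows the "
                             "imaged volume; enlarge nz or the field")
        orders.append(order)

    frames: list[tuple[float, dict[str, ImageStack]]] = []
    element_rows = []
    masks_per_frame: list[dict[int, tuple[np.ndarray, ...]]] = []
    for fi, t in enumerate(spec.times):
        values = np.zeros((spec.nz, spec.ny, spec.nx), dtype=np.uint8)
        frame_masks: dict[int, tuple[np.ndarray, ...]] = {}
        for ci, col in enumerate(spec.colonizers):
            if col.detach_at is not None and t >= col.detach_at:
                continue
            if t < col.attach_at:
                continue
            n = max(1, round(col.scheduled_volume(t) / geom.voxel_volume))
            zz, yy, xx = (arr[:n] for arr in orders[ci])
            values[zz, yy, xx] = _SIGNAL
            frame_masks[ci] = (zz, yy, xx)
            element_rows.append(dict(
                colonizer=ci, frame=fi, time_min=t, n_voxels=n,
                volume_um3=n * geom.voxel_volume,
                scheduled_um3=col.scheduled_volume(t),
                x_um=float(xx.mean()) * geom.dx, y_um=float(yy.mean()) * geom.dy,
                z_um=float(zz.mean()) * geom.dz))
        masks_per_frame.append(frame_masks)
        chans = {"bacteria": ImageStack(values, geom, channel="bacteria")}
        if fi == 0:
            chans["reflection"] = reflection
        frames.append((t, chans))

    _check_initial_overlap(masks_per_frame[0], (spec.nz, spec.ny, spec.nx))
    merges = _merge_contacts(masks_per_frame, (spec.nz, spec.ny, spec.nx),
                             list(spec.times))
    truth = {
        "seed": spec.seed,
        "heightmap": heightmap,
        "elements": pd.DataFrame(element_rows),
        "detachments": {ci: c.detach_at for ci, c in enumerate(spec.colonizers)
                        if c.detach_at is not None},
        "scheduled": {ci: [c.scheduled_volume(t) for t in spec.times]
                      for ci, c in enumerate(spec.colonizers)},
        "merges": merges,
        "n_colonizers": len(spec.colonizers),
    }
    return TimeLapse(frames, t0_index=0), truth


def _check_initial_overlap(masks: dict[int, tuple[np.ndarray, ...]],
                           shape: tuple[int, int, int]) -> None:
    claimed = np.zeros(int(np.prod(shape)), dtype=bool)
    for ci, (zz, yy, xx) in masks.items():
        flat = np.ravel_multi_index((zz, yy, xx), shape)
        if claimed[flat].any():
            raise ValueError(f"colonizer {ci} overlaps another at the first frame")
        claimed[flat] = True


def _merge_contacts(masks_per_frame, shape, times) -> list[dict]:
    """First frame at which each colonizer pair becomes 26-connected."""
    struct = np.ones((3, 3, 3), dtype=bool)
    seen: set[tuple[int, int]] = set()
    contacts = []
    for fi, masks in enumerate(masks_per_frame):
        ids = sorted(masks)
        dilated = {}
        for ci in ids:
            m = np.zeros(shape, dtype=bool)
            m[masks[ci]] = True
            dilated[ci] = ndimage.binary_dilation(m, structure=struct)
        for i, ci in enumerate(ids):
            mi = np.zeros(shape, dtype=bool)
            mi[masks[ci]] = True
            for cj in ids[i + 1:]:
                pair = (ci, cj)
                if pair in seen:
                    continue
                if (dilated[cj] & mi).any():
                    seen.add(pair)
                    contacts.append(dict(pair=pair, frame=fi, time_min=times[fi]))
    return contacts


def example_scene(seed: int = 11) -> SceneSpec:
    """A mixed benchmark scene exercising every pipeline stage.

    20 colonizers on a rough substratum over a 420-min time lapse:
    6 power-law growers (a around 1e-5–2.5e-5 µm³·min⁻ᵇ, b 2.4–2.65),
    12 static colonizers of which 3 detach at 40/80/120 min, and one
    close pair of growers scripted to merge mid-experiment.  The field
    (88 × 72 µm at 0.5 µm/px) is sized so no blob reaches a lateral edge
    by the final frame.
    """
    geom = VoxelGeometry(dx=0.5, dy=0.5, dz=0.42, frame_interval=20.0)
    times = tuple(float(t) for t in range(0, 421, 20))
    pos = [(16 + 32 * i, 16 + 32 * j) for j in range(4) for i in range(5)]
    cols: list[ColonizerSpec] = []
    for k, (x, y) in enumerate(pos):
        if k < 6:
            cols.append(ColonizerSpec(x=x, y=y, p0=10 + 5 * k, mode="power",
                                      a=1e-5 * (1 + 0.3 * k), b=2.4 + 0.05 * k))
        elif k < 9:
            cols.append(ColonizerSpec(x=x, y=y, p0=3 + k, mode="static",
                                      detach_at=float(40 + 40 * (k - 6))))
        else:
            cols.append(ColonizerSpec(x=x, y=y, p0=2 + k, mode="static"))
    cols[18] = ColonizerSpec(x=100, y=120, p0=20, mode="power", a=3e-5, b=2.6)
    cols[19] = ColonizerSpec(x=113, y=120, p0=20, mode="power", a=3e-5, b=2.6)
    return SceneSpec(nx=176, ny=144, nz=30, geometry=geom, times=times,
                     surface_sa=0.5, colonizers=cols, seed=seed)


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def render_noisy(timelapse: TimeLapse, noise_sigma: float = 0.0,
                 blur_sigma: float = 0.0, background: float = 0.0,
                 poisson: bool = False, seed: int = 0) -> TimeLapse:
    """PSF-like blur plus background and additive/Poisson noise, 8-bit clipped.

    With all parameters zero the input is returned value-identical.
    Output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t, chans in timelapse.frames:
        out = {}
        for name, stack in chans.items():
            v = np.asarray(stack.values, dtype=np.float64)
            if blur_sigma > 0:
                v = ndimage.gaussian_filter(v, sigma=blur_sigma, mode="reflect")
            v = v + background
            if poisson:
                v = rng.poisson(np.clip(v, 0, None)).astype(np.float64)
            if noise_sigma > 0:
                v = v + rng.normal(0.0, noise_sigma, size=v.shape)
            out[name] = stack.with_values(np.clip(np.round(v), 0, 255
                                                  ).astype(np.uint8))
        frames.append((t, out))
    return TimeLapse(frames, t0_index=timelapse.t0_index)


def export_scene(timelapse: TimeLapse, truth: dict, out_dir: str | Path) -> Path:
    """Write a scene as TIFF stacks + manifest + ground-truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    any_stack = next(iter(timelapse.frames[0][1].values()))
    manifest = {
        "geometry": dict(dx=any_stack.geometry.dx, dy=any_stack.geometry.dy,
                         dz=any_stack.geometry.dz,
                         frame_interval=any_stack.geometry.frame_interval),
        "t0_index": timelapse.t0_index,
        "frames": [],
    }
    for fi, (t, chans) in enumerate(timelapse.frames):
        entry = {"time": t, "channels": {}}
        for name, stack in chans.items():
            fname = f"frame{fi:03d}_{name}.tif"
            write_stack(stack, out / fname)
            entry["channels"][name] = fname
        manifest["frames"].append(entry)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    truth["elements"].to_csv(out / "truth_elements.csv", index=False)
    pd.DataFrame(truth["merges"]).to_csv(out / "truth_merges.csv", index=False)
    return out
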
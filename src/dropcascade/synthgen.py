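"""Seeded synthetic droplet scenes, ground-truth masks and time-lapse series.

The generator emulates bright-field snapshots of a droplet-microfluidics
storage chip: bright aqueous droplets (~170 µm, rendered at ~7 µm/px so a
droplet spans ~24 px) resting on a textured high-contrast background, with
small (<= 3 px) calcium-carbonate inclusions appearing inside droplets over
time.  Two crystalline polymorphs are rendered: vaterite as a small round
blob with a warm colour cast, calcite as a sharp-edged square/rhombus with a
cooler, darker cast.  Each droplet starts out containing amorphous calcium
carbonate (ACC), which has too little optical contrast to render explicitly;
a droplet "is ACC" exactly when it contains no crystal.

Transformation kinetics follow a two-population first-order model: a labile
fraction of droplets transforms with exponentially distributed waiting times
(rate ``k_true`` per minute), the remainder never transforms within any
finite horizon.  The ACC-containing fraction therefore decays as

    ratio(t) = (1 - labile_fraction) + labile_fraction * exp(-k_true * t)

which is the generating analogue of the exponential-plateau model the
kinetics module fits.

Conventions: 0-based row-major coordinates, origin top-left, (row, col)
order everywhere; binary masks use {0, 255} uint8.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

ACC = "acc"
VATERITE = "vaterite"
CALCITE = "calcite"
PHASES = (ACC, VATERITE, CALCITE)

#: Sentinel transformation time for droplets that never transform.
NEVER = np.inf


class PlacementError(RuntimeError):
    """Raised when non-overlapping droplet placement fails."""


def _default_timesteps() -> list[float]:
    # 17 acquisition times spanning a 6-hour monitoring window.
    return list(np.linspace(0.0, 360.0, 17))


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and appearance of one synthetic frame.

    Defaults reproduce the study conditions: a 3 mm x 1.5 mm field of view
    at ~7 µm/px (428 x 214 px) holding ~50 droplets of ~170 µm diameter
    (radius ~12 px), with crystals no larger than 3 px.
    """

    image_height_px: int = 214
    image_width_px: int = 428
    droplet_radius_px: float = 12.0
    radius_jitter: float = 0.08  # fractional radius jitter
    droplets_per_frame: int = 50
    crystal_size_px: int = 3
    background_contrast: float = 0.5  # distractor texture amplitude in [0, 1]
    noise_sd: float = 4.0  # additive intensity noise, 0-255 scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.droplet_radius_px <= 0:
            raise ValueError("droplet_radius_px must be positive")
        if self.droplets_per_frame < 0:
            raise ValueError("droplets_per_frame must be nonnegative")
        if not 1 <= self.crystal_size_px <= 5:
            raise ValueError("crystal_size_px must be in [1, 5]")
        if not 0.0 <= self.background_contrast <= 1.0:
            raise ValueError("background_contrast must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class KineticsSpec:
    """Transformation kinetics and acquisition schedule of a time-lapse.

    ``k_true`` is the first-order transformation rate (1/min) of the labile
    droplet population; ``labile_fraction`` is the fraction of droplets that
    can ever transform, so the ACC fraction plateaus at
    ``1 - labile_fraction``.  Defaults match an exponential-plateau decay
    with rate 0.027/min and plateau ~0.9 over a 6-hour window observed at
    17 timesteps across 12 locations imaged sequentially.
    """

    k_true: float = 0.027
    labile_fraction: float = 0.1
    initial_transformed_fraction: float = 0.0
    p_vaterite: float = 0.5
    timesteps: Sequence[float] = field(default_factory=_default_timesteps)
    n_locations: int = 12
    per_location_time_offset_min: float = 0.75

    def __post_init__(self) -> None:
        for name in ("labile_fraction", "p_vaterite"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.initial_transformed_fraction < 1.0:
            raise ValueError("initial_transformed_fraction must be in [0, 1)")
        if self.k_true < 0:
            raise ValueError("k_true must be nonnegative")
        ts = np.asarray(self.timesteps, dtype=float)
        if ts.size == 0:
            raise ValueError("timesteps must be non-empty")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timesteps must be strictly increasing")
        if self.n_locations <= 0:
            raise ValueError("n_locations must be positive")
        if self.per_location_time_offset_min < 0:
            raise ValueError("per_location_time_offset_min must be nonnegative")


@dataclass
class GroundTruth:
    """Exact bookkeeping for one rendered frame."""

    centers: np.ndarray  # (n, 2) float, (row, col)
    radii: np.ndarray  # (n,) float
    phases: list[str]  # per-droplet phase at this frame's time
    droplet_mask: np.ndarray  # uint8 {0, 255}
    vaterite_mask: np.ndarray
    calcite_mask: np.ndarray

    @property
    def n_droplets(self) -> int:
        return len(self.phases)

    @property
    def n_acc(self) -> int:
        return sum(p == ACC for p in self.phases)


def sample_transformation_schedule(
    kinetics: KineticsSpec, n_droplets: int, seed: int
) -> tuple[np.ndarray, list[str]]:
    """Draw per-droplet transformation times and target phases.

    Returns ``(times, phases)`` where ``times[i]`` is the transformation
    time in minutes (``np.inf`` for droplets that never transform — the
    inert population, or any droplet when ``k_true == 0``) and ``phases[i]``
    is the polymorph the droplet turns into once transformed.  Droplets in
    the ``initial_transformed_fraction`` are already transformed at t=0
    (time 0.0).  Deterministic for a fixed seed.
    """
    if n_droplets < 0:
        raise ValueError("n_droplets must be nonnegative")
    rng = np.random.default_rng(seed)
    labile = rng.random(n_droplets) < kinetics.labile_fraction
    times = np.full(n_droplets, NEVER)
    if kinetics.k_true > 0:
        waits = rng.exponential(1.0 / kinetics.k_true, size=n_droplets)
        times[labile] = waits[labile]
    already = rng.random(n_droplets) < kinetics.initial_transformed_fraction
    times[already & labile] = 0.0
    phase_draw = rng.random(n_droplets) < kinetics.p_vaterite
    phases = [VATERITE if v else CALCITE for v in phase_draw]
    return times, phases


def _place_droplets(
    scene: SceneSpec, rng: np.random.Generator, max_attempts_per_droplet: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping droplet circles fully inside the frame."""
    n = scene.droplets_per_frame
    centers = np.zeros((n, 2))
    radii = np.zeros(n)
    for i in range(n):
        placed = False
        for _ in range(max_attempts_per_droplet):
            r = scene.droplet_radius_px * (
                1.0 + scene.radius_jitter * (2.0 * rng.random() - 1.0)
            )
            row = rng.uniform(r, scene.image_height_px - r)
            col = rng.uniform(r, scene.image_width_px - r)
            if i > 0:
                # 2 px clearance so rendered disks are never pixel-adjacent
                d = np.hypot(centers[:i, 0] - row, centers[:i, 1] - col)
                if np.any(d < radii[:i] + r + 2.0):
                    continue
            centers[i] = (row, col)
            radii[i] = r
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place droplet {i + 1}/{n} without overlap; "
                "use fewer or smaller droplets for this frame size"
            )
    return centers, radii


def _disk_indices(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[inside], cc[inside]


def _render_background(scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Textured background: base grey, smooth intensity gradient, blob distractors."""
    from scipy.ndimage import gaussian_filter

    h, w = scene.image_height_px, scene.image_width_px
    base = np.full((h, w), 70.0)
    # gentle illumination gradient
    gy = np.linspace(-1, 1, h)[:, None]
    gx = np.linspace(-1, 1, w)[None, :]
    base += scene.background_contrast * 12.0 * (gy + 0.5 * gx)
    # low-frequency high-contrast blobs the segmenter must ignore
    blobs = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    if blobs.std() > 0:
        blobs = blobs / blobs.std()
    base += scene.background_contrast * 45.0 * blobs
    rgb = np.stack([base, base, base * 0.98], axis=-1)
    return rgb


def _render_crystal(
    rgb: np.ndarray,
    mask: np.ndarray,
    center: tuple[int, int],
    size_px: int,
    phase: str,
) -> None:
    """Draw one crystal (<= size_px across) and stamp its exact mask."""
    r0, c0 = center
    half = size_px // 2
    if phase == VATERITE:
        # round warm blob
        rr, cc = _disk_indices((r0, c0), max(size_px / 2.0, 0.6), rgb.shape[:2])
        rgb[rr, cc] = np.array([120.0, 85.0, 60.0])
        mask[rr, cc] = 255
    else:
        # sharp-edged square (rhombohedral habit seen face-on), cooler/darker
        rs = slice(max(r0 - half, 0), min(r0 + half + 1, rgb.shape[0]))
        cs = slice(max(c0 - half, 0), min(c0 + half + 1, rgb.shape[1]))
        rgb[rs, cs] = np.array([45.0, 55.0, 90.0])
        mask[rs, cs] = 255


def generate_scene(
    scene: SceneSpec, phases: Sequence[str], seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render one frame plus its exact ground-truth masks.

    ``phases`` lists each droplet's current phase (``"acc"``, ``"vaterite"``
    or ``"calcite"``) and must have length ``scene.droplets_per_frame``.
    Returns ``(rgb, droplet_mask, vaterite_mask, calcite_mask, truth)``;
    the rgb image carries noise and background distractors while the masks
    are exact renderings.  Bit-identical for identical (scene, phases, seed).
    """
    if len(phases) != scene.droplets_per_frame:
        raise ValueError(
            f"phase list length {len(phases)} != droplets_per_frame "
            f"{scene.droplets_per_frame}"
        )
    for p in phases:
        if p not in PHASES:
            raise ValueError(f"unknown phase {p!r}")
    rng = np.random.default_rng(seed)
    centers, radii = _place_droplets(scene, rng)
    crystal_centers = _sample_crystal_centers(scene, centers, radii, rng)
    return _render_frame(scene, centers, radii, list(phases), rng, crystal_centers)


def _sample_crystal_centers(
    scene: SceneSpec,
    centers: np.ndarray,
    radii: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """One crystal anchor per droplet, strictly inside and clear of the rim."""
    out = []
    c_margin = scene.crystal_size_px + 2.5
    for (row, col), r in zip(centers, radii):
        if r > c_margin + 1:
            rho = rng.uniform(0, r - c_margin)
            theta = rng.uniform(0, 2 * np.pi)
            out.append((int(round(row + rho * np.sin(theta))),
                        int(round(col + rho * np.cos(theta)))))
        else:
            out.append((int(round(row)), int(round(col))))
    return out


def _render_frame(
    scene: SceneSpec,
    centers: np.ndarray,
    radii: np.ndarray,
    phases: list[str],
    rng: np.random.Generator,
    crystal_centers: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    h, w = scene.image_height_px, scene.image_width_px
    rgb = _render_background(scene, rng)
    droplet_mask = np.zeros((h, w), dtype=np.uint8)
    vat_mask = np.zeros((h, w), dtype=np.uint8)
    cal_mask = np.zeros((h, w), dtype=np.uint8)

    for i in range(len(phases)):
        (row, col), r = centers[i], radii[i]
        rr, cc = _disk_indices((row, col), r, (h, w))
        droplet_mask[rr, cc] = 255
        # bright interior with a 2 px darker rim
        dist = np.hypot(rr - row, cc - col)
        interior = dist <= r - 2.0
        rgb[rr, cc] = np.array([205.0, 205.0, 200.0]) * 0.55  # rim tone
        ir, ic = rr[interior], cc[interior]
        rgb[ir, ic] = np.array([205.0, 205.0, 200.0])

    # crystals drawn after all droplets so rims never overwrite them
    for i, phase in enumerate(phases):
        if phase == ACC:
            continue
        mask = vat_mask if phase == VATERITE else cal_mask
        _render_crystal(rgb, mask, crystal_centers[i], scene.crystal_size_px, phase)

    if scene.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, scene.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    truth = GroundTruth(
        centers=centers.copy(),
        radii=radii.copy(),
        phases=list(phases),
        droplet_mask=droplet_mask,
        vaterite_mask=vat_mask,
        calcite_mask=cal_mask,
    )
    return rgb, droplet_mask, vat_mask, cal_mask, truth


@dataclass
class Timelapse:
    """In-memory time-lapse: manifest, per-frame truth and true counts."""

    manifest: pd.DataFrame  # location_id, timestep_index, acquisition_time_min, frame_path
    frames: list[np.ndarray] | None  # rgb frames aligned with manifest rows, or None
    truths: list[GroundTruth]  # aligned with manifest rows
    true_counts: pd.DataFrame  # per (location, timestep) count table


def phases_at_time(
    times: np.ndarray, target_phases: Sequence[str], t: float
) -> list[str]:
    """Phase of each droplet at time ``t`` given its transformation schedule."""
    return [
        target_phases[i] if times[i] <= t else ACC for i in range(len(target_phases))
    ]


def generate_timelapse(
    scene: SceneSpec,
    kinetics: KineticsSpec,
    seed: int,
    render: bool = True,
    out_dir: str | Path | None = None,
) -> Timelapse:
    """Simulate a multi-location time-lapse with a known transformation rate.

    Droplet positions are fixed per location across time; a droplet that
    transformed at time tau shows its crystal in every frame with t >= tau.
    With ``render=False`` only the exact masks and count tables are produced
    (fast path for kinetics experiments).  With ``out_dir`` set, frames and
    masks are written to disk and ``frames`` holds None; otherwise rendered
    frames are kept in memory.
    """
    ss = np.random.SeedSequence(seed)
    loc_seeds = ss.spawn(kinetics.n_locations)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    frames: list[np.ndarray] | None = [] if (render and out_path is None) else None
    truths: list[GroundTruth] = []
    count_rows = []
    for loc in range(kinetics.n_locations):
        child = np.random.SeedSequence(entropy=loc_seeds[loc].entropy,
                                       spawn_key=loc_seeds[loc].spawn_key)
        rng = np.random.default_rng(child)
        centers, radii = _place_droplets(scene, rng)
        crystal_centers = _sample_crystal_centers(scene, centers, radii, rng)
        sched_seed = int(rng.integers(0, 2**31 - 1))
        times, targets = sample_transformation_schedule(
            kinetics, scene.droplets_per_frame, sched_seed
        )
        offset = loc * kinetics.per_location_time_offset_min
        for ti, t_nominal in enumerate(kinetics.timesteps):
            t = float(t_nominal) + offset
            phases = phases_at_time(times, targets, t)
            frame_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=child.entropy,
                                       spawn_key=child.spawn_key + (ti + 1,))
            )
            if render:
                rgb, dmask, vmask, cmask, truth = _render_frame(
                    scene, centers, radii, phases, frame_rng, crystal_centers
                )
            else:
                h, w = scene.image_height_px, scene.image_width_px
                empty = np.zeros((h, w), dtype=np.uint8)
                truth = GroundTruth(centers.copy(), radii.copy(), phases,
                                    empty, empty, empty)
                rgb = None
            frame_name = f"loc{loc:02d}_t{ti:02d}.png"
            if out_path is not None and render:
                iio.imwrite(out_path / frame_name, rgb)
                iio.imwrite(out_path / f"mask_droplet_{frame_name}", dmask)
                iio.imwrite(out_path / f"mask_vaterite_{frame_name}", vmask)
                iio.imwrite(out_path / f"mask_calcite_{frame_name}", cmask)
            elif frames is not None and render:
                frames.append(rgb)
            truths.append(truth)
            n_v = sum(p == VATERITE for p in phases)
            n_c = sum(p == CALCITE for p in phases)
            rows.append(
                dict(
                    location_id=loc,
                    timestep_index=ti,
                    acquisition_time_min=t,
                    frame_path=frame_name,
                )
            )
            count_rows.append(
                dict(
                    location_id=loc,
                    timestep_index=ti,
                    acquisition_time_min=t,
                    n_droplets=len(phases),
                    n_vaterite_droplets=n_v,
                    n_calcite_droplets=n_c,
                    n_acc=len(phases) - n_v - n_c,
                )
            )
    manifest = pd.DataFrame(rows)
    true_counts = pd.DataFrame(count_rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        true_counts.to_csv(out_path / "true_counts.csv", index=False)
        _write_truth_json(out_path, truths, manifest)
    return Timelapse(manifest=manifest, frames=frames, truths=truths,
                     true_counts=true_counts)


def _write_truth_json(out_path: Path, truths: list[GroundTruth],
                      manifest: pd.DataFrame) -> None:
    records = []
    for (_, row), truth in zip(manifest.iterrows(), truths):
        records.append(
            dict(
                frame_path=row["frame_path"],
                centers=truth.centers.tolist(),
                radii=truth.radii.tolist(),
                phases=truth.phases,
            )
        )
    (out_path / "ground_truth.json").write_text(json.dumps(records))


def scene_to_dict(scene: SceneSpec) -> dict:
    return dataclasses.asdict(scene)


def kinetics_to_dict(kinetics: KineticsSpec) -> dict:
    d = dataclasses.asdict(kinetics)
    d["timesteps"] = list(map(float, d["timesteps"]))
    return d
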
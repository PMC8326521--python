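"""Synthetic flow-channel videos with exact ground truth.

Emulates the imaging conditions of a microfluidic islet counter: elliptical
islets translate along the channel axis (+x) over a static light background,
each partially stained red by dithizone (a contiguous angular sector of the
ellipse at the stained hue, the rest at an unstained yellow hue), with small
per-frame velocity and cross-channel jitter and additive Gaussian sensor
noise. Islets are laid out in non-overlapping lanes so every rendered pixel
belongs to exactly one islet, giving exact per-frame ground truth (centers,
semiaxes, orientation, rendered and stained pixel counts) against which
segmentation, tracking, and metrics are validated.

What this does NOT emulate: lens blur fields, rolling shutter, compression
artifacts, overlapping or aggregated islets, illumination drift.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames_io import FrameSequence, write_sequence

__all__ = ["GroundTruth", "SceneConfig", "make_scene", "write_fixture"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene; the defaults are the validation
    conditions used throughout the test suite.

    ``radius_range`` is the equivalent radius r (px): semiaxes are
    a = r sqrt(ratio), b = r / sqrt(ratio) with ratio drawn from
    ``axis_ratio_range``, so the rendered area stays ~pi r^2 and the
    equivalent spherical diameter is 2 r regardless of elongation.
    """

    n_islets: int = 50
    radius_range: tuple[float, float] = (14.0, 26.0)
    axis_ratio_range: tuple[float, float] = (1.0, 1.5)
    velocity_px: float = 20.0
    velocity_jitter_sd: float = 0.5
    y_jitter_sd: float = 1.0
    stain_fraction_range: tuple[float, float] = (0.3, 1.0)
    stained_hue_deg: float = 330.0
    unstained_hue_deg: float = 55.0
    stained_sat_val: tuple[float, float] = (0.75, 0.55)
    unstained_sat_val: tuple[float, float] = (0.70, 0.50)
    background_level: float = 210.0
    background_gradient: float = 0.0
    noise_sd: float = 2.0
    frame_size: tuple[int, int] = (640, 360)  # (width, height)
    n_frames: int | None = None
    irregularity_amp: float = 0.0
    irregularity_lobes: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        lo, hi = self.stain_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"stain fractions must lie in [0, 1], got {lo}, {hi}")
        if self.axis_ratio_range[0] < 1.0:
            raise ValueError("axis_ratio_range values must be >= 1")
        if self.velocity_px <= 0:
            raise ValueError("velocity_px must be > 0")


@dataclass
class GroundTruth:
    """Exact bookkeeping of a rendered scene.

    ``per_frame`` has one row per (frame_index, islet_id) with the islet
    visible; ``islets`` one row per islet including entry/exit frames.
    """

    per_frame: pd.DataFrame
    islets: pd.DataFrame
    config: SceneConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def frame_rows(self, frame_index: int) -> pd.DataFrame:
        return self.per_frame[self.per_frame.frame_index == frame_index]


def _hsv_to_rgb8(hue_deg: float, sat: float, val: float) -> np.ndarray:
    rgb = colorsys.hsv_to_rgb((hue_deg % 360.0) / 360.0, sat, val)
    return np.array([c * 255.0 for c in rgb])


def _render_background(config: SceneConfig) -> np.ndarray:
    w, h = config.frame_size
    row = np.full(w, config.background_level, dtype=float)
    if config.background_gradient:
        row = row + config.background_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
    bg = np.broadcast_to(row[None, :, None], (h, w, 3))
    return np.clip(np.round(bg), 0, 255).astype(np.uint8)


def make_scene(
    config: SceneConfig,
) -> tuple[FrameSequence, np.ndarray, GroundTruth]:
    """Render a scene, returning (frames, background frame, ground truth).

    Deterministic: the same config (including seed) yields byte-identical
    frames. Raises if the requested islets cannot be packed without overlap.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.frame_size
    n = config.n_islets

    r_eq = rng.uniform(*config.radius_range, size=n)
    ratio = rng.uniform(*config.axis_ratio_range, size=n)
    a = r_eq * np.sqrt(ratio)
    b = r_eq / np.sqrt(ratio)
    theta = rng.uniform(0, np.pi, size=n)
    stain_frac = rng.uniform(*config.stain_fraction_range, size=n)
    sector_start = rng.uniform(0, 2 * np.pi, size=n)

    # lane layout: keep islets fully inside vertically, well separated
    max_a = float(a.max()) if n else config.radius_range[1]
    jitter_allow = 4.0 * config.y_jitter_sd + 2.0
    lane_pitch = 2 * max_a + 2 * jitter_allow
    y_lo, y_hi = max_a + jitter_allow, h - max_a - jitter_allow
    n_lanes = int((y_hi - y_lo) // lane_pitch) + 1 if y_hi >= y_lo else 0
    if n and n_lanes < 1:
        raise ValueError(
            "cannot pack islets without overlap: frame too small for the "
            "requested radii — use fewer/smaller islets or a larger frame"
        )
    lane_y = y_lo + lane_pitch * np.arange(n_lanes) if n else np.array([])

    dx = 2 * max_a + max(3.0 * config.velocity_px, 30.0)
    lane_idx = np.arange(n) % max(n_lanes, 1)
    slot = np.arange(n) // max(n_lanes, 1)
    x0 = -(a + 2.0) - slot * dx - rng.uniform(0, dx / 4.0, size=n)
    y0 = lane_y[lane_idx] if n else np.array([])

    # trajectories: cumulative jittered velocity in x, jitter around lane in y
    if config.n_frames is None:
        span = (x0.min() if n else 0.0)
        n_frames = int(np.ceil((w + 2 * max_a + 4 - span) / config.velocity_px)) + 2
    else:
        n_frames = config.n_frames

    if n:
        vel = config.velocity_px + rng.normal(
            0, config.velocity_jitter_sd, size=(n_frames, n)
        )
        x = x0[None, :] + np.cumsum(vel, axis=0)
        y = y0[None, :] + rng.normal(0, config.y_jitter_sd, size=(n_frames, n))
    else:
        x = np.zeros((n_frames, 0))
        y = np.zeros((n_frames, 0))

    _check_no_overlap(x, y, a)

    background = _render_background(config)
    stained_rgb = _hsv_to_rgb8(config.stained_hue_deg, *config.stained_sat_val)
    unstained_rgb = _hsv_to_rgb8(config.unstained_hue_deg, *config.unstained_sat_val)

    frames: list[np.ndarray] = []
    rows: list[dict] = []
    for t in range(n_frames):
        img = background.astype(float).copy()
        for i in range(n):
            stats = _render_islet(
                img,
                cx=x[t, i],
                cy=y[t, i],
                a=a[i],
                b=b[i],
                theta=theta[i],
                stain_frac=stain_frac[i],
                sector_start=sector_start[i],
                stained_rgb=stained_rgb,
                unstained_rgb=unstained_rgb,
                irregularity=(config.irregularity_amp, config.irregularity_lobes),
            )
            if stats is None:
                continue
            area_px, stained_px, clipped = stats
            rows.append(
                {
                    "frame_index": t,
                    "islet_id": i,
                    "cx": x[t, i],
                    "cy": y[t, i],
                    "semi_major_px": max(a[i], b[i]),
                    "semi_minor_px": min(a[i], b[i]),
                    "theta": theta[i],
                    "stain_fraction": stain_frac[i],
                    "area_px": area_px,
                    "stained_px": stained_px,
                    "clipped": clipped,
                }
            )
        if config.noise_sd > 0:
            img = img + rng.normal(0, config.noise_sd, size=img.shape)
        frames.append(np.clip(np.round(img), 0, 255).astype(np.uint8))

    per_frame = pd.DataFrame(
        rows,
        columns=[
            "frame_index", "islet_id", "cx", "cy", "semi_major_px",
            "semi_minor_px", "theta", "stain_fraction", "area_px",
            "stained_px", "clipped",
        ],
    )
    islets = pd.DataFrame(
        {
            "islet_id": np.arange(n),
            "equivalent_radius_px": r_eq,
            "semi_major_px": np.maximum(a, b),
            "semi_minor_px": np.minimum(a, b),
            "theta": theta,
            "stain_fraction": stain_frac,
            "lane_y": y0,
        }
    )
    if len(per_frame):
        bounds = per_frame.groupby("islet_id")["frame_index"].agg(["min", "max"])
        islets = islets.merge(
            bounds.rename(columns={"min": "entry_frame", "max": "exit_frame"}),
            left_on="islet_id",
            right_index=True,
            how="left",
        )
    else:
        islets["entry_frame"] = np.nan
        islets["exit_frame"] = np.nan

    gt = GroundTruth(per_frame=per_frame, islets=islets, config=config)
    return FrameSequence(frames=frames), background, gt


def _render_islet(
    img: np.ndarray,
    cx: float,
    cy: float,
    a: float,
    b: float,
    theta: float,
    stain_frac: float,
    sector_start: float,
    stained_rgb: np.ndarray,
    unstained_rgb: np.ndarray,
    irregularity: tuple[float, int] = (0.0, 7),
) -> tuple[int, int, bool] | None:
    """Paint one elliptical islet in place; returns (area, stained, clipped)."""
    h, w = img.shape[:2]
    reach = max(a, b) * (1.0 + irregularity[0]) + 1.0
    r0, r1 = int(np.floor(cy - reach)), int(np.ceil(cy + reach)) + 1
    c0, c1 = int(np.floor(cx - reach)), int(np.ceil(cx + reach)) + 1
    clipped = r0 < 0 or c0 < 0 or r1 > h or c1 > w
    r0, r1 = max(r0, 0), min(r1, h)
    c0, c1 = max(c0, 0), min(c1, w)
    if r0 >= r1 or c0 >= c1:
        return None

    yy, xx = np.mgrid[r0:r1, c0:c1]
    u = np.cos(theta) * (xx - cx) + np.sin(theta) * (yy - cy)
    v = -np.sin(theta) * (xx - cx) + np.cos(theta) * (yy - cy)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    amp, lobes = irregularity
    if amp > 0:
        ang = np.arctan2(v, u)
        inside = rho2 <= (1.0 + amp * np.sin(lobes * ang)) ** 2
    else:
        inside = rho2 <= 1.0
    area = int(inside.sum())
    if area == 0:
        return None

    # contiguous stained sector; the angle is measured in ellipse-normalized
    # coordinates so the stained AREA fraction equals stain_frac exactly
    # (a linear map preserves area ratios of unit-disk sectors)
    ang = np.mod(np.arctan2(v / b, u / a) - sector_start, 2 * np.pi)
    stained = inside & (ang < 2 * np.pi * stain_frac)
    region = img[r0:r1, c0:c1]
    region[stained] = stained_rgb
    region[inside & ~stained] = unstained_rgb
    return area, int(stained.sum()), clipped


def _check_no_overlap(x: np.ndarray, y: np.ndarray, a: np.ndarray) -> None:
    """Bounding-circle check that no two islets overlap in any frame."""
    n = a.size
    if n < 2:
        return
    reach = a + 0.5
    for t in range(x.shape[0]):
        d2 = (x[t, :, None] - x[t, None, :]) ** 2 + (y[t, :, None] - y[t, None, :]) ** 2
        lim = (reach[:, None] + reach[None, :]) ** 2
        bad = (d2 < lim) & ~np.eye(n, dtype=bool)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"islets {i} and {j} overlap in frame {t}: packing infeasible "
                "— use fewer/smaller islets or a larger frame"
            )


def write_fixture(
    frames: FrameSequence,
    background: np.ndarray,
    ground_truth: GroundTruth,
    directory: str | Path,
) -> Path:
    """Write a scene as a PNG sequence + background.png + ground-truth CSVs."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame_dir = directory / "frames"
    write_sequence(frames, frame_dir)
    iio.imwrite(directory / "background.png", background)
    ground_truth.per_frame.to_csv(directory / "ground_truth.csv", index=False)
    ground_truth.islets.to_csv(directory / "islets_truth.csv", index=False)
    if ground_truth.config is not None:
        cfg = asdict(ground_truth.config)
        (directory / "scene.json").write_text(json.dumps(cfg, indent=2))
    return directory
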
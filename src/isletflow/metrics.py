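"""Physical-unit islet metrics and the sample-level mass report.

Converts pixel measurements into the quantities islet-transplant labs report:

* equivalent spherical diameter (ESD), D = 2 sqrt(A/pi) * delta;
* islet equivalents (IEq): diameters binned into eight 50-um classes
  (50-100, 101-150, ..., 351-400, >400 um) and scored with the standard
  conversion multipliers, one IEq being a 150-um islet;
* ellipsoid-fitting volume (EFV): the fitted 2-D ellipse revolved into an
  ellipsoid, "major" variant (4/3) pi Ma^2 Mi, "minor" variant
  (4/3) pi Ma Mi^2, with Ma/Mi the SEMI-axis lengths, frame-averaged per
  track and converted by delta^3;
* IEqV, the volume implied by the IEq total (IEq x volume of a 150 um
  sphere);
* circularity 4 pi A / P^2 and solidity A / A_hull, both clamped to [0, 1];
* DTZ-positive purity ratio, per islet and area-weighted per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .frames_io import ScaleCalibration
from .segmentation import Detection
from .tracking import Track

__all__ = [
    "IEQ_BIN_EDGES_UM",
    "IEQ_MULTIPLIERS",
    "IeqTable",
    "IsletRecord",
    "SampleReport",
    "V150_UM3",
    "assign_ieq",
    "circularity",
    "dtz_ratio",
    "ellipsoid_volume",
    "equivalent_diameter",
    "ieq_volume",
    "record_from_track",
    "records_from_tracks",
    "solidity",
    "summarize",
    "track_volume",
]

#: Volume of a 150-um-diameter sphere (one IEq), (4/3) pi 75^3 um^3.
V150_UM3 = (4.0 / 3.0) * math.pi * 75.0**3

#: Printed labels of the eight diameter classes, um.
IEQ_BIN_EDGES_UM: tuple[tuple[float, float], ...] = (
    (50, 100), (101, 150), (151, 200), (201, 250),
    (251, 300), (301, 350), (351, 400), (400, math.inf),
)

#: Standard IEq conversion multiplier of each class.
IEQ_MULTIPLIERS: tuple[float, ...] = (
    0.167, 0.667, 1.685, 3.499, 6.315, 10.352, 15.833, 22.750,
)

# Real-valued bin boundaries with round-to-nearest-integer semantics of the
# printed integer ranges: [50, 100.5), [100.5, 150.5), ..., [400.5, inf).
_BIN_UPPER = np.array([100.5, 150.5, 200.5, 250.5, 300.5, 350.5, 400.5])
_FRAGMENT_MAX_UM = 50.0


@dataclass(frozen=True)
class IeqTable:
    """Eight diameter classes and their IEq multipliers."""

    bin_edges: tuple[tuple[float, float], ...] = IEQ_BIN_EDGES_UM
    multipliers: tuple[float, ...] = IEQ_MULTIPLIERS

    def __post_init__(self) -> None:
        if len(self.bin_edges) != 8 or len(self.multipliers) != 8:
            raise ValueError("IeqTable requires exactly eight bins")
        if any(b >= a for a, b in zip(self.multipliers[1:], self.multipliers)):
            raise ValueError("multipliers must be strictly increasing")


def equivalent_diameter(area_px: float, scale: ScaleCalibration) -> float:
    """Equivalent spherical diameter in um: 2 sqrt(area/pi) * delta."""
    if area_px <= 0:
        raise ValueError(f"area_px must be > 0, got {area_px}")
    return 2.0 * math.sqrt(area_px / math.pi) * scale.delta_um_per_px


def assign_ieq(
    diameters_um: Sequence[float], table: IeqTable = IeqTable()
) -> tuple[list[int | None], float]:
    """Bin diameters into the eight IEq classes and sum their multipliers.

    Diameters below 50 um are tissue fragments: bin ``None``, contribution 0.
    Returns (per-islet bin indices, total IEq).
    """
    bins: list[int | None] = []
    total = 0.0
    for d in diameters_um:
        if d <= 0:
            raise ValueError(f"diameters must be positive, got {d}")
        if d < _FRAGMENT_MAX_UM:
            bins.append(None)
            continue
        b = int(np.searchsorted(_BIN_UPPER, d, side="right"))
        bins.append(b)
        total += table.multipliers[b]
    return bins, total


def ellipsoid_volume(
    major_semiaxis: float, minor_semiaxis: float, variant: str = "major"
) -> float:
    """Volume of the ellipsoid of revolution of a fitted 2-D ellipse.

    ``variant="major"`` revolves about the minor axis (third axis = major):
    (4/3) pi Ma^2 Mi. ``variant="minor"`` revolves about the major axis:
    (4/3) pi Ma Mi^2. Axes are SEMI-axis lengths; a sphere of diameter 150 um
    (Ma = Mi = 75) gives 1.767e6 um^3 under either variant.
    """
    if not major_semiaxis >= minor_semiaxis > 0:
        raise ValueError(
            f"semiaxes must satisfy major >= minor > 0, got "
            f"({major_semiaxis}, {minor_semiaxis})"
        )
    if variant == "major":
        return (4.0 / 3.0) * math.pi * major_semiaxis**2 * minor_semiaxis
    if variant == "minor":
        return (4.0 / 3.0) * math.pi * major_semiaxis * minor_semiaxis**2
    raise ValueError(f"variant must be 'major' or 'minor', got {variant!r}")


def _qualifying(track: Track) -> list[Detection]:
    return [d for d in track.detections if not d.degenerate and not d.touches_edge]


def track_volume(
    track: Track, scale: ScaleCalibration, variant: str = "major"
) -> float:
    """Frame-averaged ellipsoid volume of a track, converted by delta^3."""
    dets = _qualifying(track)
    if not dets:
        raise ValueError("track has no qualifying (non-degenerate, non-edge) detection")
    v_px = np.mean(
        [
            ellipsoid_volume(
                d.ellipse_major_semiaxis_px, d.ellipse_minor_semiaxis_px, variant
            )
            for d in dets
        ]
    )
    return float(v_px) * scale.delta_um_per_px**3


def ieq_volume(total_ieq: float) -> float:
    """Sample volume implied by an IEq total: IEq x V150."""
    if total_ieq < 0:
        raise ValueError("total_ieq must be >= 0")
    return total_ieq * V150_UM3


def circularity(area: float, perimeter: float) -> float:
    """4 pi A / P^2, clamped to [0, 1]; 1 for a perfect circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be > 0")
    return min(1.0, area / (perimeter**2 / (4.0 * math.pi)))


def solidity(area: float, hull_area: float) -> float:
    """A / A_hull, clamped to [0, 1]; lower for fragmented/concave shapes."""
    if area <= 0 or hull_area <= 0:
        raise ValueError("area and hull_area must be > 0")
    if hull_area < area * 0.98:  # beyond discretization slack
        raise ValueError(f"hull_area {hull_area} < area {area}")
    return min(1.0, area / hull_area)


def dtz_ratio(dtz_positive_px: float, area_px: float) -> float:
    """Fraction of an islet's area that is DTZ-positive (beta-cell tissue)."""
    if area_px <= 0:
        raise ValueError("area_px must be > 0")
    if not 0 <= dtz_positive_px <= area_px:
        raise ValueError("dtz_positive_px must lie in [0, area_px]")
    return dtz_positive_px / area_px


@dataclass
class IsletRecord:
    """Per-islet metrics in physical units, frame-averaged over its track."""

    track_id: int
    n_frames: int
    diameter_um: float
    volume_major_um3: float
    volume_minor_um3: float
    volume_variant: str
    circularity: float
    solidity: float
    dtz_ratio: float
    ieq_bin: int | None = None
    ieq_contribution: float = 0.0
    total_area_px: float = 0.0
    total_dtz_px: float = 0.0

    @property
    def volume_efv_um3(self) -> float:
        return self.volume_major_um3 if self.volume_variant == "major" else self.volume_minor_um3


def record_from_track(
    track: Track,
    scale: ScaleCalibration,
    volume_variant: str = "major",
) -> IsletRecord | None:
    """Aggregate a track's qualifying detections into an IsletRecord.

    Scalar metrics (diameter, circularity, solidity, DTZ ratio) are averaged
    over the track's non-degenerate, non-edge detections, mirroring the
    frame-averaging of volume. Returns None when no detection qualifies
    (track excluded from volume totals).
    """
    dets = _qualifying(track)
    if not dets:
        return None
    return IsletRecord(
        track_id=track.track_id,
        n_frames=len(dets),
        diameter_um=float(
            np.mean([equivalent_diameter(d.area_px, scale) for d in dets])
        ),
        volume_major_um3=track_volume(track, scale, "major"),
        volume_minor_um3=track_volume(track, scale, "minor"),
        volume_variant=volume_variant,
        circularity=float(
            np.mean([circularity(d.area_px, d.perimeter_px) for d in dets])
        ),
        solidity=float(np.mean([solidity(d.area_px, d.hull_area_px) for d in dets])),
        dtz_ratio=float(
            np.mean([dtz_ratio(d.dtz_positive_px, d.area_px) for d in dets])
        ),
        total_area_px=float(sum(d.area_px for d in dets)),
        total_dtz_px=float(sum(d.dtz_positive_px for d in dets)),
    )


def records_from_tracks(
    tracks: Sequence[Track],
    scale: ScaleCalibration,
    volume_variant: str = "major",
    table: IeqTable = IeqTable(),
) -> list[IsletRecord]:
    """Build records for all tracks and assign IEq bins/contributions."""
    records = [
        r
        for t in tracks
        if (r := record_from_track(t, scale, volume_variant)) is not None
    ]
    bins, _ = assign_ieq([r.diameter_um for r in records], table)
    for r, b in zip(records, bins):
        r.ieq_bin = b
        r.ieq_contribution = table.multipliers[b] if b is not None else 0.0
    return records


@dataclass
class SampleReport:
    """Sample-level islet mass summary."""

    islet_count: int
    total_ieq: float
    ieqv_um3: float
    total_efv_um3: float
    total_efv_major_um3: float
    total_efv_minor_um3: float
    volume_variant: str
    v150_um3: float = V150_UM3
    mean_sd: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    histograms: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    sample_dtz_ratio: float | None = None
    mean_dtz_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "islet_count": self.islet_count,
            "total_ieq": self.total_ieq,
            "ieqv_um3": self.ieqv_um3,
            "total_efv_um3": self.total_efv_um3,
            "total_efv_major_um3": self.total_efv_major_um3,
            "total_efv_minor_um3": self.total_efv_minor_um3,
            "volume_variant": self.volume_variant,
            "v150_um3": self.v150_um3,
            "mean_sd": {
                k: (None if v is None else {"mean": v[0], "sd": v[1]})
                for k, v in self.mean_sd.items()
            },
            "histograms": self.histograms,
            "sample_dtz_ratio": self.sample_dtz_ratio,
            "mean_dtz_ratio": self.mean_dtz_ratio,
        }


def _mean_sd(values: Sequence[float]) -> tuple[float, float] | None:
    if len(values) == 0:
        return None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd


def _histogram(values: Sequence[float], bin_width: float, vmin: float = 0.0):
    if len(values) == 0:
        return {"edges": [], "counts": []}
    arr = np.asarray(values, dtype=float)
    top = max(arr.max(), vmin + bin_width)
    n_bins = int(math.ceil((top - vmin) / bin_width))
    edges = vmin + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return {"edges": edges.tolist(), "counts": counts.tolist()}


def summarize(
    records: Sequence[IsletRecord],
    volume_variant: str = "major",
    diameter_bin_um: float = 25.0,
    ratio_bin: float = 0.1,
) -> SampleReport:
    """Aggregate islet records into the sample report.

    Means use the n-1 (sample) standard deviation. The sample DTZ ratio is
    reported both as the area-weighted aggregate (sum of DTZ-positive pixels
    over sum of islet pixels) and as the mean of per-islet ratios.
    """
    diameters = [r.diameter_um for r in records]
    _, total_ieq = assign_ieq(diameters) if diameters else ([], 0.0)
    total_major = sum(r.volume_major_um3 for r in records)
    total_minor = sum(r.volume_minor_um3 for r in records)
    total_area = sum(r.total_area_px for r in records)
    total_dtz = sum(r.total_dtz_px for r in records)

    return SampleReport(
        islet_count=len(records),
        total_ieq=total_ieq,
        ieqv_um3=ieq_volume(total_ieq),
        total_efv_um3=total_major if volume_variant == "major" else total_minor,
        total_efv_major_um3=total_major,
        total_efv_minor_um3=total_minor,
        volume_variant=volume_variant,
        mean_sd={
            "diameter_um": _mean_sd(diameters),
            "circularity": _mean_sd([r.circularity for r in records]),
            "solidity": _mean_sd([r.solidity for r in records]),
            "dtz_ratio": _mean_sd([r.dtz_ratio for r in records]),
            "volume_efv_um3": _mean_sd(
                [
                    r.volume_major_um3 if volume_variant == "major" else r.volume_minor_um3
                    for r in records
                ]
            ),
        },
        histograms={
            "diameter_um": _histogram(diameters, diameter_bin_um),
            "circularity": _histogram([r.circularity for r in records], ratio_bin),
            "solidity": _histogram([r.solidity for r in records], ratio_bin),
            "dtz_ratio": _histogram([r.dtz_ratio for r in records], ratio_bin),
        },
        sample_dtz_ratio=(total_dtz / total_area) if total_area > 0 else None,
        mean_dtz_ratio=(
            float(np.mean([r.dtz_ratio for r in records])) if records else None
        ),
    )
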
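"""Synthetic brightfield rendering of Feulgen-stained nuclei.

Renders simulated germ-cell populations as transmitted-light fields paired
with a cell-free reference image of the incident illumination, mimicking a
monochrome CCD acquisition through an interferential filter.  The stain is
stoichiometric: each nucleus is an ellipse of uniform optical density whose
integrated OD equals ``od_per_c × DNA content``, so integrated optical
density (IOD) is exactly proportional to DNA content by construction.
Transmission follows Beer–Lambert, ``T = I · 10^(−OD)``, on top of a
low-order polynomial illumination surface with per-field brightness jitter;
camera noise is additive Gaussian on the transmitted intensity.

The renderer also emits a per-pixel ground-truth label mask and a per-object
truth table, so the downstream densitometry can be validated against known
DNA contents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .meiosis import SimCell

__all__ = [
    "StageGeometry",
    "RenderConfig",
    "FieldImage",
    "EmptyField",
    "GroundTruth",
    "render_field",
    "write_field",
    "read_field",
]

# IOD scale anchor: a 2C nucleus integrates to ~92.56 arbitrary units, the
# printed C. japonica 2C mean, so synthetic outputs live on the same scale
# as the real densitometry.
DEFAULT_OD_PER_C = 92.56 / 2.0


@dataclass(frozen=True)
class StageGeometry:
    """Nuclear geometry of one cell stage (µm)."""

    diameter_um: float
    diameter_sd_um: float
    elongation: float = 1.0
    elongation_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.diameter_sd_um < 0:
            raise ValueError("diameters must be positive")
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1")


def _default_geometry() -> dict[str, StageGeometry]:
    # Diameters from the histological morphometry: spermatogonia 5.4±0.69,
    # spermatocytes 3.93±0.41, spermatids 1.71±0.34 µm; spermatozoa have
    # small elongated conical heads (no printed diameter; see docs/methods.md).
    return {
        "spermatogonium": StageGeometry(5.4, 0.69, 1.1, 0.08),
        "spermatocyte": StageGeometry(3.93, 0.41, 1.1, 0.08),
        "spermatid": StageGeometry(1.71, 0.34, 1.3, 0.2),
        "spermatozoon": StageGeometry(2.0, 0.15, 4.0, 0.5),
        "somatic": StageGeometry(5.0, 0.6, 1.15, 0.1),
    }


@dataclass
class RenderConfig:
    """All tunables of the synthetic acquisition."""

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.16
    od_per_c: float = DEFAULT_OD_PER_C
    incident_level: float = 30000.0
    gradient_amplitude: float = 0.08
    brightness_jitter: float = 0.03
    noise_sd: float = 60.0
    speckle_sd: float = 0.0
    debris_rate: float = 0.05
    overlap_rate: float = 0.0
    geometry: dict[str, StageGeometry] = field(default_factory=_default_geometry)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.od_per_c <= 0:
            raise ValueError("od_per_c must be positive")
        if self.incident_level <= 0:
            raise ValueError("incident intensity must be positive")
        for name, rate in (
            ("debris_rate", self.debris_rate),
            ("overlap_rate", self.overlap_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["geometry"] = {k: dataclasses.asdict(v) for k, v in self.geometry.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RenderConfig":
        d = yaml.safe_load(Path(path).read_text())
        geom = {k: StageGeometry(**v) for k, v in d.pop("geometry", {}).items()}
        cfg = cls(**d)
        if geom:
            cfg.geometry = geom
        return cfg


@dataclass
class FieldImage:
    transmitted: np.ndarray  # (H, W) float intensities
    pixel_size_um: float

    @property
    def width_px(self) -> int:
        return self.transmitted.shape[1]

    @property
    def height_px(self) -> int:
        return self.transmitted.shape[0]


@dataclass
class EmptyField:
    incident: np.ndarray  # (H, W) strictly positive intensities


@dataclass
class GroundTruth:
    """Per-pixel label mask plus a per-object truth table.

    ``objects`` columns: label, kind ('cell' or 'debris'), stage, true_c,
    true_iod (the integrated OD actually painted), cell_id (−1 for debris).
    """

    label_mask: np.ndarray  # (H, W) uint16, 0 = background
    objects: pd.DataFrame


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices inside an ellipse (semi-axes a, b px, rotated theta)."""
    r = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _draw_geometry(
    geom: StageGeometry, rng: np.random.Generator, px: float
) -> tuple[float, float, float]:
    """Semi-axes (a, b) in pixels and orientation for one nucleus."""
    d = -1.0
    while d <= 0:
        d = rng.normal(geom.diameter_um, geom.diameter_sd_um)
        d = float(np.clip(d, geom.diameter_um - 3 * geom.diameter_sd_um, geom.diameter_um + 3 * geom.diameter_sd_um))
        if d < 0.5:
            d = 0.5
    e = max(1.0, float(np.clip(
        rng.normal(geom.elongation, geom.elongation_sd),
        geom.elongation - 2 * geom.elongation_sd,
        geom.elongation + 2 * geom.elongation_sd,
    )))
    req = d / 2.0 / px  # equivalent radius in px
    a = req * np.sqrt(e)
    b = req / np.sqrt(e)
    return float(a), float(b), float(rng.uniform(0, np.pi))


def _place(
    occupancy: np.ndarray,
    a: float,
    b: float,
    theta: float,
    rng: np.random.Generator,
    allow_overlap: bool,
    max_tries: int = 200,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    h, w = occupancy.shape
    margin = max(a, b) + 2
    if 2 * margin >= min(h, w):
        raise ValueError("field too small for requested nucleus")
    for _ in range(max_tries):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ys, xs = _ellipse_mask((h, w), cy, cx, a + 1.5, b + 1.5, theta)
        if allow_overlap or not occupancy[ys, xs].any():
            ys, xs = _ellipse_mask((h, w), cy, cx, a, b, theta)
            if ys.size == 0:
                continue
            return cy, cx, ys, xs
    raise RuntimeError("could not place nucleus without overlap (field too crowded)")


def render_field(
    cells: Sequence[SimCell],
    config: RenderConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FieldImage, EmptyField, GroundTruth]:
    """Render a population as (transmitted field, empty field, ground truth).

    Noise-free, the transmitted image is ``incident × 10^(−OD)`` with each
    object's summed OD exactly ``od_per_c × measured_c``; debris are rendered
    as irregular aggregates of ≥ 2 fused nuclei and labelled as such in the
    truth table.
    """
    config = config or RenderConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    px = config.pixel_size_um

    # incident illumination: low-order polynomial surface × brightness factor
    yy, xx = np.mgrid[0:h, 0:w]
    u = xx / max(w - 1, 1) - 0.5
    v = yy / max(h - 1, 1) - 0.5
    g = config.gradient_amplitude
    c1, c2, c3 = rng.uniform(-1, 1, size=3)
    surface = 1.0 + g * (c1 * u + c2 * v + c3 * (u * v))
    brightness = np.exp(rng.normal(0.0, config.brightness_jitter))
    incident = config.incident_level * brightness * surface
    if (incident <= 0).any():
        raise ValueError("non-positive incident intensity (gradient too strong)")

    od = np.zeros((h, w), dtype=np.float64)
    label_mask = np.zeros((h, w), dtype=np.uint16)
    occupancy = np.zeros((h, w), dtype=bool)
    records: list[tuple] = []
    label = 0

    def paint(ys, xs, total_od):
        od[ys, xs] += total_od / ys.size

    for cell in cells:
        geom = config.geometry.get(cell.stage)
        if geom is None:
            raise ValueError(f"no geometry for stage {cell.stage!r}")
        a, b, theta = _draw_geometry(geom, rng, px)
        allow = bool(rng.random() < config.overlap_rate)
        cy, cx, ys, xs = _place(occupancy, a, b, theta, rng, allow)
        label += 1
        total = config.od_per_c * cell.measured_c
        paint(ys, xs, total)
        label_mask[ys, xs] = label
        occupancy[ys, xs] = True
        records.append((label, "cell", cell.stage, cell.measured_c, total, cell.cell_id))

    # debris: aggregates of 2–4 fused nuclei with heterogeneous contents
    n_debris = int(rng.binomial(max(len(cells), 1), config.debris_rate)) if cells else 0
    stages = list(config.geometry)
    for _ in range(n_debris):
        k = int(rng.integers(2, 5))
        stage0 = stages[rng.integers(len(stages))]
        a, b, theta = _draw_geometry(config.geometry[stage0], rng, px)
        try:
            cy, cx, ys, xs = _place(occupancy, a, b, theta, rng, False)
        except RuntimeError:
            continue
        label += 1
        base_p = cells[0].base_ploidy if cells else 2
        c0 = float(rng.choice([1.0, base_p, 2.0 * base_p]))
        total = config.od_per_c * c0
        paint(ys, xs, total)
        label_mask[ys, xs] = label
        occupancy[ys, xs] = True
        tot_iod = total
        for _ in range(k - 1):
            stage_j = stages[rng.integers(len(stages))]
            aj, bj, thj = _draw_geometry(config.geometry[stage_j], rng, px)
            off = rng.uniform(0.4, 0.9) * (a + aj)
            ang = rng.uniform(0, 2 * np.pi)
            cyj = float(np.clip(cy + off * np.sin(ang), aj + 2, h - aj - 3))
            cxj = float(np.clip(cx + off * np.cos(ang), aj + 2, w - aj - 3))
            ysj, xsj = _ellipse_mask((h, w), cyj, cxj, aj, bj, thj)
            if ysj.size == 0:
                continue
            cj = float(rng.choice([1.0, base_p, 2.0 * base_p]))
            tj = config.od_per_c * cj
            paint(ysj, xsj, tj)
            label_mask[ysj, xsj] = label
            occupancy[ysj, xsj] = True
            tot_iod += tj
        records.append((label, "debris", "debris", np.nan, tot_iod, -1))

    if config.speckle_sd > 0:  # optional chromatin-texture speckle
        nz = od > 0
        od[nz] *= np.exp(
            rng.normal(0.0, config.speckle_sd, size=int(nz.sum()))
            - config.speckle_sd**2 / 2
        )

    transmitted = incident * np.power(10.0, -od)
    if config.noise_sd > 0:
        transmitted = transmitted + rng.normal(0.0, config.noise_sd, size=od.shape)
    transmitted = np.clip(transmitted, 0.0, incident)

    objects = pd.DataFrame(
        records, columns=["label", "kind", "stage", "true_c", "true_iod", "cell_id"]
    )
    return (
        FieldImage(transmitted=transmitted, pixel_size_um=px),
        EmptyField(incident=incident),
        GroundTruth(label_mask=label_mask, objects=objects),
    )


def true_iod_from_mask(od_image: np.ndarray, truth: GroundTruth) -> pd.DataFrame:
    """Integrated OD of each ground-truth object, summed over its mask."""
    labels = truth.objects["label"].to_numpy()
    sums = [float(od_image[truth.label_mask == lab].sum()) for lab in labels]
    out = truth.objects.copy()
    out["mask_iod"] = sums
    return out


def write_field(
    prefix,
    fieldimg: FieldImage,
    empty: EmptyField,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write a rendered field as 16-bit TIFFs plus a truth CSV.

    Intensities are rounded to integer counts (≤ 1 quantization step per
    pixel); the label mask round-trips bit-identically.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "transmitted": prefix.with_name(prefix.name + "_transmitted.tif"),
        "incident": prefix.with_name(prefix.name + "_incident.tif"),
        "labels": prefix.with_name(prefix.name + "_labels.tif"),
        "truth": prefix.with_name(prefix.name + "_truth.csv"),
    }
    for key, arr in (("transmitted", fieldimg.transmitted), ("incident", empty.incident)):
        q = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            paths[key], q, resolution=(1e4 / fieldimg.pixel_size_um,) * 2
        )
    tifffile.imwrite(paths["labels"], truth.label_mask.astype(np.uint16))
    truth.objects.to_csv(paths["truth"], index=False, float_format="%.12g")
    return paths


def read_field(prefix, pixel_size_um: float = 0.16):
    """Read back a field written by :func:`write_field`."""
    prefix = Path(prefix)
    transmitted = tifffile.imread(
        prefix.with_name(prefix.name + "_transmitted.tif")
    ).astype(np.float64)
    incident = tifffile.imread(
        prefix.with_name(prefix.name + "_incident.tif")
    ).astype(np.float64)
    labels = tifffile.imread(prefix.with_name(prefix.name + "_labels.tif"))
    if transmitted.shape != incident.shape or transmitted.shape != labels.shape:
        raise ValueError("shape mismatch between paired field files")
    objects = pd.read_csv(prefix.with_name(prefix.name + "_truth.csv"))
    return (
        FieldImage(transmitted=transmitted, pixel_size_um=pixel_size_um),
        EmptyField(incident=np.maximum(incident, 1.0)),
        GroundTruth(label_mask=labels, objects=objects),
    )
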
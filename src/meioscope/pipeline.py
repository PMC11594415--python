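"""End-to-end orchestration: simulate → render → measure → type → calibrate
→ tabulate → infer.

Two entry points are provided.  :func:`simulate_and_infer` is the fast
table-top path: simulated DNA contents are mapped directly to IOD (one C unit
= ``od_per_c`` arbitrary units) without rendering, which is how the
stochastic repeatability of the mechanism call is characterized.
:func:`run_pipeline` is the full imaging path, pushing rendered fields
through segmentation and classification before calibration and inference.
All randomness flows from one top-level seed, split deterministically per
stage, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import celltyping, cytometry, imaging, inference, meiosis, ploidy

__all__ = ["RunConfig", "simulate_and_infer", "run_pipeline", "default_multipliers"]

log = logging.getLogger(__name__)

DEFAULT_STAGE_MIX = {
    "spermatozoon": 0.45,
    "spermatid": 0.20,
    "spermatocyte": 0.20,
    "spermatogonium": 0.15,
}


def default_multipliers(base_ploidy: int) -> tuple[int, ...]:
    """Allowed ploidy multipliers for a run: gametic, somatic, replicated and
    the 4×base endoreplication sentinel."""
    return tuple(sorted({1, 2, base_ploidy, 2 * base_ploidy, 4 * base_ploidy}))


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML round-trippable)."""

    model_mix: dict = field(default_factory=lambda: {"A_CANONICAL": 1.0})
    stage_mix: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_MIX))
    base_ploidy: int = 2
    n_cells: int = 1000
    n_somatic: int = 300
    cv: float = 0.08
    seed: int = 0
    multipliers: tuple[int, ...] | None = None
    thresholds: inference.Thresholds = field(default_factory=inference.Thresholds)
    render: imaging.RenderConfig = field(default_factory=imaging.RenderConfig)
    typing: celltyping.TypingParams = field(default_factory=celltyping.TypingParams)
    cells_per_field: int = 30
    write_images: bool = False

    def resolved_multipliers(self) -> tuple[int, ...]:
        return self.multipliers or default_multipliers(self.base_ploidy)

    def to_yaml(self, path) -> None:
        d = {
            "model_mix": dict(self.model_mix),
            "stage_mix": dict(self.stage_mix),
            "base_ploidy": self.base_ploidy,
            "n_cells": self.n_cells,
            "n_somatic": self.n_somatic,
            "cv": self.cv,
            "seed": self.seed,
            "multipliers": list(self.resolved_multipliers()),
            "thresholds": {
                "tau_reduced": self.thresholds.tau_reduced,
                "tau_endorep": self.thresholds.tau_endorep,
                "tau_mixed": self.thresholds.tau_mixed,
            },
            "cells_per_field": self.cells_per_field,
            "write_images": self.write_images,
            "typing": self.typing.to_dict(),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for key in (
            "model_mix",
            "stage_mix",
            "base_ploidy",
            "n_cells",
            "n_somatic",
            "cv",
            "seed",
            "cells_per_field",
            "write_images",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "multipliers" in d and d["multipliers"]:
            kwargs["multipliers"] = tuple(d["multipliers"])
        if "thresholds" in d:
            kwargs["thresholds"] = inference.Thresholds(**d["thresholds"])
        if "typing" in d:
            t = dict(d["typing"])
            t["size_gates"] = {k: tuple(v) for k, v in t.get("size_gates", {}).items()}
            t["somatic_diameter_um"] = tuple(t.get("somatic_diameter_um", (5.0, 0.6)))
            kwargs["typing"] = celltyping.TypingParams(**t)
        return cls(**kwargs)


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


class _SimRecord:
    """Minimal record adapter for the table-top (no-imaging) path."""

    __slots__ = ("cell_class", "iod")

    def __init__(self, cell_class: str, iod: float) -> None:
        self.cell_class = cell_class
        self.iod = iod


def simulate_and_infer(
    model_mix: Mapping,
    base_ploidy: int,
    n: int = 1000,
    cv: float = 0.08,
    seed: int = 0,
    *,
    stage_mix: Mapping | None = None,
    multipliers: Sequence[int] | None = None,
    thresholds: inference.Thresholds | None = None,
    od_per_c: float = imaging.DEFAULT_OD_PER_C,
    n_somatic: int = 300,
) -> tuple[inference.MechanismCall, ploidy.CytometryTable]:
    """Simulation-level pipeline: cells → IODs → calibrate → crosstab → infer.

    True cell stages stand in for the manual sort so the procedure isolates
    the densitometric logic; the IOD scale is anchored at ``od_per_c`` per C.
    The somatic reference population fixes the C unit through its modal IOD.
    """
    rng_germ, rng_som = _stage_rngs(seed, 2)
    stage_mix = dict(stage_mix or DEFAULT_STAGE_MIX)
    cells = meiosis.sample_population(
        model_mix, stage_mix, {base_ploidy: 1.0}, n, cv, rng_germ
    )
    somatic = meiosis.sample_population(
        model_mix, {"somatic": 1.0}, {base_ploidy: 1.0}, n_somatic, cv, rng_som
    )
    iods = np.array([c.measured_c * od_per_c for c in cells])
    som_iods = [c.measured_c * od_per_c for c in somatic]
    mult = tuple(multipliers or default_multipliers(base_ploidy))
    scale = ploidy.calibrate(iods, mult, reference=som_iods, base_ploidy=base_ploidy)
    records = [_SimRecord(c.stage, i) for c, i in zip(cells, iods)]
    table = ploidy.crosstab(records, scale, mult)
    call = inference.infer(table, base_ploidy, thresholds)
    return call, table


def _render_batch(
    cells: list[meiosis.SimCell],
    render_cfg: imaging.RenderConfig,
    rng: np.random.Generator,
    cells_per_field: int,
    typing_params: celltyping.TypingParams,
    outdir: Path | None,
    prefix: str,
    write_images: bool,
) -> tuple[list[celltyping.CellRecord], float, dict]:
    """Render cells over as many fields as needed, measure and classify."""
    objects: list[cytometry.SegmentedObject] = []
    n_fields = 0
    n_empty = 0
    for start in range(0, len(cells), cells_per_field):
        chunk = cells[start : start + cells_per_field]
        fieldimg, empty, truth = imaging.render_field(chunk, render_cfg, rng)
        n_fields += 1
        od = cytometry.correct_and_transform(fieldimg, empty)
        objs = cytometry.segment_and_measure(od)
        if not objs:
            n_empty += 1  # systematic elimination of empty fields
            continue
        for o in objs:
            o.object_id = len(objects)
            objects.append(o)
        if write_images and outdir is not None:
            imaging.write_field(
                outdir / f"{prefix}_field{n_fields:03d}", fieldimg, empty, truth
            )
    records, debris_fraction = celltyping.classify_population(objects, typing_params)
    stats = {
        "fields_rendered": n_fields,
        "fields_eliminated_empty": n_empty,
        "objects_segmented": len(objects),
        "debris_fraction": round(debris_fraction, 4),
    }
    return records, debris_fraction, stats


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Full imaging pipeline; returns a result dict and writes artifacts.

    Stages: simulate germ and somatic populations → render fields → empty-
    field correction and OD transform → segmentation and morphometry →
    rule-based classification → somatic-reference calibration → class ×
    ploidy cross-tabulation → mechanism inference.  Failures are re-raised
    annotated with the stage name.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(config.seed, 4)
    result: dict = {"seed": config.seed}
    mult = config.resolved_multipliers()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    cells = stage(
        "simulate",
        lambda: meiosis.sample_population(
            config.model_mix,
            config.stage_mix,
            {config.base_ploidy: 1.0},
            config.n_cells,
            config.cv,
            rngs[0],
        ),
    )
    somatic_cells = stage(
        "simulate_somatic",
        lambda: meiosis.sample_population(
            config.model_mix,
            {"somatic": 1.0},
            {config.base_ploidy: 1.0},
            config.n_somatic,
            config.cv,
            rngs[1],
        ),
    )
    if out is not None:
        meiosis.population_to_csv(cells, out / "population_germ.csv")
        meiosis.population_to_csv(somatic_cells, out / "population_somatic.csv")

    germ_records, germ_debris, germ_stats = stage(
        "measure_germ",
        lambda: _render_batch(
            cells,
            config.render,
            rngs[2],
            config.cells_per_field,
            config.typing,
            out,
            "germ",
            config.write_images,
        ),
    )
    from dataclasses import replace

    somatic_params = replace(config.typing, somatic_slide=True)
    somatic_records, somatic_debris, somatic_stats = stage(
        "measure_somatic",
        lambda: _render_batch(
            somatic_cells,
            config.render,
            rngs[3],
            config.cells_per_field,
            somatic_params,
            out,
            "somatic",
            config.write_images,
        ),
    )
    result["germ"] = germ_stats
    result["somatic"] = somatic_stats
    log.info("germ slide: %s", germ_stats)
    log.info("somatic slide: %s", somatic_stats)

    som_iods = [r.iod for r in somatic_records if r.cell_class == "somatic"]
    scale = stage(
        "calibrate",
        lambda: ploidy.calibrate(
            [r.iod for r in germ_records if r.cell_class != "debris"],
            mult,
            reference=som_iods if som_iods else None,
            base_ploidy=config.base_ploidy,
        ),
    )
    table = stage("crosstab", lambda: ploidy.crosstab(germ_records, scale, mult))
    call = stage(
        "infer", lambda: inference.infer(table, config.base_ploidy, config.thresholds)
    )

    result["c_unit"] = scale.c_unit
    result["table"] = table.summary()
    result["verdict"] = call.verdict.value
    if out is not None:
        celltyping.records_to_dataframe(germ_records).to_csv(
            out / "features_germ.csv", index=False, float_format="%.10g"
        )
        table.to_csv(out / "cytometry_table.csv")
        table.to_json(out / "cytometry_table.json")
        call.to_json(out / "mechanism_call.json")
        (out / "report.md").write_text(call.to_markdown())
        config.to_yaml(out / "run_config.yaml")
        with open(out / "run_summary.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True, default=float)
        from .reporting import plot_iod_histogram

        plot_iod_histogram(table, [r.iod for r in germ_records if r.cell_class != "debris"], out / "iod_histogram.png")
    result["call"] = call
    result["table_obj"] = table
    return result
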
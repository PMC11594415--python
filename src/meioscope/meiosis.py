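"""Gamete-formation models and germ-cell population simulation.

Four C-value trajectories describe how male germ cells can reach the mature
gamete stage, with 1C defined as the DNA content of an unreplicated reduced
chromosome set and ``base_ploidy`` (p) the C-value of the unreplicated somatic
set (2 for diploids, 3 for triploids, 4 for tetraploids):

* ``A_CANONICAL`` — canonical meiosis: G1 (p) → S → G2 (2p) → M1 (p) →
  M2 (p/2); gametes are reduced.
* ``B_MODIFIED`` — modified meiosis with one abortive division (M*): the
  trajectory never drops below p and gametes are unreduced (p).
* ``C_PREMEIOTIC_ENDOREP`` — pre-meiotic endoreplication (E) doubles the
  replicated set to 4p before two normal meiotic divisions; gametes are
  unreduced (p) but a transient 4p stage exists (8C in diploids, 12C in
  triploids).
* ``D_POSTMEIOTIC_RESTORE`` — canonical meiosis down to p/2 followed by a
  restoration step (R, endoreplication or nuclear fusion) back to p; reduced
  spermatids exist transiently but mature spermatozoa are unreduced.

Populations are simulated as weighted mixtures of models, germ-cell stages
and base ploidies; DNA contents are the admissible stage contents jittered by
multiplicative lognormal measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Model",
    "STAGES",
    "GERM_STAGES",
    "SimCell",
    "trajectory",
    "stage_content",
    "sample_population",
    "population_to_csv",
    "population_from_csv",
    "population_to_dataframe",
]


class Model(str, Enum):
    """The four gamete-formation modes, by their C-value trajectory."""

    A_CANONICAL = "A_CANONICAL"
    B_MODIFIED = "B_MODIFIED"
    C_PREMEIOTIC_ENDOREP = "C_PREMEIOTIC_ENDOREP"
    D_POSTMEIOTIC_RESTORE = "D_POSTMEIOTIC_RESTORE"


STAGES: tuple[str, ...] = (
    "spermatogonium",
    "spermatocyte",
    "spermatid",
    "spermatozoon",
    "somatic",
)
GERM_STAGES: tuple[str, ...] = STAGES[:4]

VALID_PLOIDIES = (2, 3, 4)


@dataclass(frozen=True)
class SimCell:
    """A simulated cell with known ground-truth DNA content.

    ``true_c`` is the exact admissible stage content (a point on the model
    trajectory); ``measured_c`` is the content after multiplicative lognormal
    measurement jitter and is what the renderer / densitometry sees.
    """

    cell_id: int
    stage: str
    base_ploidy: int
    true_c: float
    model_id: str
    measured_c: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.true_c <= 0 or self.measured_c <= 0:
            raise ValueError("DNA content must be positive")


def _as_model(model: Model | str) -> Model:
    try:
        return Model(model)
    except ValueError as exc:
        raise ValueError(f"unknown model id {model!r}") from exc


def _check_ploidy(base_ploidy: int) -> int:
    p = int(base_ploidy)
    if p < 2:
        raise ValueError(f"base_ploidy must be >= 2, got {base_ploidy}")
    return p


def trajectory(model: Model | str, base_ploidy: int) -> list[tuple[str, float]]:
    """C-value trajectory of a model as an ordered list of (phase, C).

    The S phase is recorded by its end point (2p); M* denotes the abortive
    division of the modified meiosis, E the pre-meiotic endoreplication and R
    the post-meiotic restoration step.
    """
    model = _as_model(model)
    p = float(_check_ploidy(base_ploidy))
    if model is Model.A_CANONICAL:
        return [("G1", p), ("S", 2 * p), ("G2", 2 * p), ("M1", p), ("M2", p / 2)]
    if model is Model.B_MODIFIED:
        return [("G1", p), ("S", 2 * p), ("G2", 2 * p), ("M*", 2 * p), ("M2", p)]
    if model is Model.C_PREMEIOTIC_ENDOREP:
        return [
            ("G1", p),
            ("S", 2 * p),
            ("G2", 2 * p),
            ("E", 4 * p),
            ("M1", 2 * p),
            ("M2", p),
        ]
    # D: canonical reduction then restoration of the somatic content
    return [
        ("G1", p),
        ("S", 2 * p),
        ("G2", 2 * p),
        ("M1", p),
        ("M2", p / 2),
        ("R", p),
    ]


def stage_content(
    model: Model | str, stage: str, base_ploidy: int
) -> frozenset[float]:
    """Admissible noise-free C-values for a germ stage under a model.

    Spermatogonia cover the gonial G1/G2 cycle {p, 2p}; spermatocytes cover G2
    and the post-M1 content; spermatids and spermatozoa carry the terminal
    gametic content(s) — model D spermatids exist both before (p/2) and after
    (p) restoration.  Somatic cells are a cycling population {p, 2p}.
    """
    model = _as_model(model)
    p = float(_check_ploidy(base_ploidy))
    if stage not in STAGES:
        raise ValueError(f"invalid stage name {stage!r}")
    if stage in ("spermatogonium", "somatic"):
        return frozenset({p, 2 * p})
    if stage == "spermatocyte":
        if model is Model.B_MODIFIED:
            return frozenset({2 * p})
        if model is Model.C_PREMEIOTIC_ENDOREP:
            return frozenset({2 * p, 4 * p})
        return frozenset({2 * p, p})  # A, D: G2 and post-M1
    if stage == "spermatid":
        if model is Model.A_CANONICAL:
            return frozenset({p / 2})
        if model is Model.D_POSTMEIOTIC_RESTORE:
            return frozenset({p / 2, p})
        return frozenset({p})
    # spermatozoon
    if model is Model.A_CANONICAL:
        return frozenset({p / 2})
    return frozenset({p})


def default_content_weights(
    model: Model | str,
    stage: str,
    base_ploidy: int,
    *,
    cycling_fraction: float = 0.15,
    restored_spermatid_fraction: float = 0.5,
) -> dict[float, float]:
    """Default weights over the admissible contents of a stage.

    Spermatogonia and somatic cells spend ``cycling_fraction`` of their time
    replicated (2p); model D spermatids split between the transient reduced
    state and the restored state; other multi-valued stages are uniform.
    """
    model = _as_model(model)
    p = float(_check_ploidy(base_ploidy))
    contents = sorted(stage_content(model, stage, base_ploidy))
    if len(contents) == 1:
        return {contents[0]: 1.0}
    if stage in ("spermatogonium", "somatic"):
        return {p: 1.0 - cycling_fraction, 2 * p: cycling_fraction}
    if stage == "spermatid" and model is Model.D_POSTMEIOTIC_RESTORE:
        return {
            p / 2: 1.0 - restored_spermatid_fraction,
            p: restored_spermatid_fraction,
        }
    w = 1.0 / len(contents)
    return {c: w for c in contents}


def _normalize_mix(mix: Mapping, what: str) -> tuple[list, np.ndarray]:
    if not mix:
        raise ValueError(f"{what} mix is empty")
    keys = list(mix.keys())
    w = np.asarray([mix[k] for k in keys], dtype=float)
    if (w < 0).any():
        raise ValueError(f"negative weight in {what} mix")
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{what} mix weights sum to zero")
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"{what} mix weights must sum to 1 (got {total:g})")
    return keys, w / total


def sample_population(
    model_mix: Mapping[Model | str, float],
    stage_mix: Mapping[str, float],
    ploidy_mix: Mapping[int, float],
    n: int,
    cv: float,
    seed: int | np.random.Generator | None = None,
    *,
    content_weights: Mapping[str, Mapping[float, float]] | None = None,
    cycling_fraction: float = 0.15,
    restored_spermatid_fraction: float = 0.5,
) -> list[SimCell]:
    """Draw ``n`` cells from a weighted model × stage × ploidy mixture.

    Each cell's ``true_c`` is drawn from the admissible stage contents (with
    the default or supplied per-stage content weights) and ``measured_c`` is
    ``true_c`` times a unit-mean lognormal factor of coefficient of variation
    ``cv``.  Reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    models, mw = _normalize_mix(model_mix, "model")
    models = [_as_model(m) for m in models]
    stages, sw = _normalize_mix(stage_mix, "stage")
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"invalid stage name {s!r}")
    ploidies, pw = _normalize_mix(ploidy_mix, "ploidy")
    ploidies = [_check_ploidy(p) for p in ploidies]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return []

    mi = rng.choice(len(models), size=n, p=mw)
    si = rng.choice(len(stages), size=n, p=sw)
    pi = rng.choice(len(ploidies), size=n, p=pw)
    # unit-mean lognormal jitter
    sigma = float(np.sqrt(np.log1p(cv**2)))
    jitter = (
        np.exp(rng.normal(0.0, sigma, size=n) - sigma**2 / 2.0)
        if cv > 0
        else np.ones(n)
    )

    cells: list[SimCell] = []
    weight_cache: dict[tuple, tuple[list[float], np.ndarray]] = {}
    for i in range(n):
        model, stage, p = models[mi[i]], stages[si[i]], ploidies[pi[i]]
        key = (model, stage, p)
        if key not in weight_cache:
            if content_weights is not None and stage in content_weights:
                cw = dict(content_weights[stage])
                admissible = stage_content(model, stage, p)
                if not set(cw) <= admissible:
                    raise ValueError(
                        f"content weights {sorted(cw)} not admissible for "
                        f"{model.value}/{stage}/p={p} (allowed {sorted(admissible)})"
                    )
            else:
                cw = default_content_weights(
                    model,
                    stage,
                    p,
                    cycling_fraction=cycling_fraction,
                    restored_spermatid_fraction=restored_spermatid_fraction,
                )
            vals = list(cw.keys())
            w = np.asarray(list(cw.values()), dtype=float)
            weight_cache[key] = (vals, w / w.sum())
        vals, w = weight_cache[key]
        c = float(vals[rng.choice(len(vals), p=w)]) if len(vals) > 1 else float(vals[0])
        cells.append(
            SimCell(
                cell_id=i,
                stage=stage,
                base_ploidy=p,
                true_c=c,
                model_id=model.value,
                measured_c=c * float(jitter[i]),
            )
        )
    return cells


_CSV_COLUMNS = ["cell_id", "stage", "base_ploidy", "true_c", "model_id", "measured_c"]


def population_to_dataframe(cells: Iterable[SimCell]) -> pd.DataFrame:
    rows = [
        (c.cell_id, c.stage, c.base_ploidy, c.true_c, c.model_id, c.measured_c)
        for c in cells
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def population_to_csv(cells: Sequence[SimCell], path) -> None:
    # 17 significant digits: lossless binary64 round-trip through text
    population_to_dataframe(cells).to_csv(path, index=False, float_format="%.17g")


def population_from_csv(path) -> list[SimCell]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"population CSV missing columns {sorted(missing)}")
    return [
        SimCell(
            cell_id=int(r.cell_id),
            stage=str(r.stage),
            base_ploidy=int(r.base_ploidy),
            true_c=float(r.true_c),
            model_id=str(r.model_id),
            measured_c=float(r.measured_c),
        )
        for r in df.itertuples(index=False)
    ]
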
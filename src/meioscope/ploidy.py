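"""IOD-axis calibration in C units, ploidy binning, and cytometry tables.

The DNA-content histogram of a germ-cell population clusters at integer
multiples of the 1C unit.  Calibration finds that unit either (a) from a
somatic reference population whose modal IOD corresponds to the known base
ploidy, or (b) by maximum likelihood of a constrained one-dimensional normal
mixture whose component means are fixed at ``k · c_unit`` for the allowed
multipliers ``k`` with a shared coefficient of variation — a coarse
log-spaced grid over candidate units followed by EM for weights/CV and a
bounded scalar refinement of the unit.

Bin boundaries between adjacent multipliers sit at geometric midpoints
``√(k·k′)·c_unit`` because densitometric error is multiplicative; exact
boundary values round up.  Cross-tabulation reports counts, percentages of
total sorted cells (2 decimals) and per-population mean ± SD IOD, with the
SD suppressed for populations of fewer than six cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .celltyping import CellRecord

__all__ = [
    "PloidyScale",
    "CytometryTable",
    "CalibrationError",
    "calibrate",
    "assign_ploidy",
    "assign_ploidies",
    "crosstab",
    "population_percentages",
    "modal_value",
]

log = logging.getLogger(__name__)

MIN_CALIBRATION_N = 30


class CalibrationError(ValueError):
    pass


@dataclass
class PloidyScale:
    c_unit: float  # IOD of 1C, arbitrary units
    method: str  # "constrained_mixture" | "reference_population"
    residual: float  # mean negative log-likelihood (mixture) or 0
    cv: float = np.nan  # shared coefficient of variation of the mixture fit
    weights: dict | None = None
    degenerate: bool = False  # fewer than two components carry >= 1% weight

    def __post_init__(self) -> None:
        if self.c_unit <= 0:
            raise CalibrationError("c_unit must be positive")


def modal_value(values: Sequence[float]) -> float:
    """Mode of a positive-valued sample via Gaussian KDE (median fallback)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size == 0:
        raise ValueError("no positive values")
    if x.size < 5 or np.ptp(x) < 1e-9 * np.median(x):
        return float(np.median(x))
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _em_loglik(
    x: np.ndarray, c: float, ks: np.ndarray, n_iter: int = 30, cv0: float = 0.1
) -> tuple[float, float, np.ndarray]:
    """EM over weights and shared CV with means fixed at k·c.

    Returns (log-likelihood, cv, weights).
    """
    mu = ks * c  # (K,)
    w = np.full(ks.size, 1.0 / ks.size)
    cv = cv0
    xi = x[:, None]  # (N, 1)
    for _ in range(n_iter):
        sd = np.maximum(cv * mu, 1e-12)
        logp = (
            np.log(np.maximum(w, 1e-300))
            - np.log(sd)
            - 0.5 * np.log(2 * np.pi)
            - 0.5 * ((xi - mu) / sd) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        r = p / tot
        w = r.mean(axis=0)
        cv = float(np.sqrt(np.sum(r * ((xi - mu) / mu) ** 2) / x.size))
        cv = max(cv, 1e-3)
    sd = np.maximum(cv * mu, 1e-12)
    logp = (
        np.log(np.maximum(w, 1e-300))
        - np.log(sd)
        - 0.5 * np.log(2 * np.pi)
        - 0.5 * ((xi - mu) / sd) ** 2
    )
    m = logp.max(axis=1)
    ll = float(np.sum(m + np.log(np.exp(logp - m[:, None]).sum(axis=1))))
    return ll, cv, w


def calibrate(
    iods: Sequence[float],
    candidate_multipliers: Sequence[int],
    reference: Sequence[float] | None = None,
    *,
    base_ploidy: int | None = None,
    grid_size: int = 120,
) -> PloidyScale:
    """Estimate the IOD of 1C.

    With a somatic ``reference``, ``c_unit = modal reference IOD /
    base_ploidy`` (the base ploidy of the reference individuals is then
    required).  Otherwise a constrained normal mixture with means at
    ``k · c_unit`` and shared CV is fitted by grid + EM + local refinement.
    """
    ks = np.asarray(sorted(set(int(k) for k in candidate_multipliers)), dtype=float)
    if ks.size == 0:
        raise CalibrationError("candidate multiplier set is empty")
    if (ks <= 0).any():
        raise CalibrationError("multipliers must be positive integers")

    if reference is not None:
        if base_ploidy is None:
            raise CalibrationError("base_ploidy required with a somatic reference")
        c = modal_value(reference) / float(base_ploidy)
        return PloidyScale(c_unit=c, method="reference_population", residual=0.0)

    x = np.asarray(iods, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < MIN_CALIBRATION_N:
        raise CalibrationError(
            f"need at least {MIN_CALIBRATION_N} IOD values, got {x.size}"
        )

    lo = np.quantile(x, 0.02) / ks.max()
    hi = np.quantile(x, 0.98) / ks.min() * 1.05
    grid = np.geomspace(lo, hi, grid_size)
    lls = np.array([_em_loglik(x, c, ks, n_iter=15)[0] for c in grid])
    best = grid[int(np.argmax(lls))]

    step = grid[1] / grid[0]

    def nll(c: float) -> float:
        return -_em_loglik(x, c, ks, n_iter=30)[0]

    res = optimize.minimize_scalar(
        nll, bounds=(best / step**1.5, best * step**1.5), method="bounded",
        options={"xatol": best * 1e-5},
    )
    c_hat = float(res.x)
    ll, cv, w = _em_loglik(x, c_hat, ks, n_iter=50)
    weights = {int(k): float(wi) for k, wi in zip(ks, w)}
    degenerate = int(np.sum(w >= 0.01)) < 2
    if degenerate:
        log.warning(
            "calibration fit is degenerate: a single mixture component carries "
            "nearly all weight; the scale may be unidentifiable"
        )
    return PloidyScale(
        c_unit=c_hat,
        method="constrained_mixture",
        residual=-ll / x.size,
        cv=cv,
        weights=weights,
        degenerate=degenerate,
    )


def _edges(ks: np.ndarray, c: float) -> np.ndarray:
    return np.sqrt(ks[:-1] * ks[1:]) * c


def assign_ploidy(
    iod: float, scale: PloidyScale, multipliers: Sequence[int]
) -> int:
    """Multiplier bin of one IOD (geometric-midpoint boundaries, ties up)."""
    k, _ = assign_ploidies([iod], scale, multipliers)
    return int(k[0])


def assign_ploidies(
    iods: Sequence[float], scale: PloidyScale, multipliers: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bin assignment; returns (multipliers, out-of-range flags).

    Values beyond the outermost geometric boundaries are assigned to the
    nearest extreme multiplier and flagged.
    """
    x = np.asarray(iods, dtype=float)
    if (x <= 0).any():
        raise ValueError("IOD values must be positive")
    ks = np.asarray(sorted(set(int(k) for k in multipliers)))
    if ks.size == 0:
        raise ValueError("multiplier set is empty")
    c = scale.c_unit
    if ks.size == 1:
        k_out = np.full(x.size, ks[0])
        flags = (x < ks[0] * c / np.sqrt(2)) | (x >= ks[0] * c * np.sqrt(2))
        return k_out, flags
    edges = _edges(ks.astype(float), c)
    idx = np.searchsorted(edges, x, side="right")  # ties go to the upper bin
    k_out = ks[idx]
    r_lo = np.sqrt(ks[1] / ks[0])
    r_hi = np.sqrt(ks[-1] / ks[-2])
    flags = (x < ks[0] * c / r_lo) | (x >= ks[-1] * c * r_hi)
    return k_out, flags


def population_percentages(counts: Mapping[int, int]) -> dict[int, float]:
    """Percentage of total sorted cells per ploidy population, 2 decimals."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty count table")
    return {k: round(100.0 * n / total, 2) for k, n in counts.items()}


@dataclass
class CytometryTable:
    """Class × ploidy-population cross-tabulation with summary statistics."""

    counts: pd.DataFrame  # rows: cell classes (no debris); columns: multipliers
    percentages: pd.Series  # per-population % of total sorted cells
    mean_iod: pd.Series
    sd_iod: pd.Series  # NaN where population n < 6
    total: int
    scale: PloidyScale
    multipliers: tuple[int, ...]

    def population_counts(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.counts.sum(axis=0).items()}

    def class_counts(self) -> dict[str, int]:
        return {str(k): int(v) for k, v in self.counts.sum(axis=1).items()}

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.loc["TOTAL"] = out.sum(axis=0)
        out.loc["PERCENT"] = [self.percentages.get(c, 0.0) for c in out.columns]
        out.loc["MEAN_IOD"] = [self.mean_iod.get(c, np.nan) for c in out.columns]
        out.loc["SD_IOD"] = [self.sd_iod.get(c, np.nan) for c in out.columns]
        out.to_csv(path, float_format="%.6g")

    def summary(self) -> dict:
        return {
            "total_sorted_cells": self.total,
            "c_unit": self.scale.c_unit,
            "calibration_method": self.scale.method,
            "multipliers": list(self.multipliers),
            "population_counts": {str(k): v for k, v in self.population_counts().items()},
            "population_percentages": {
                str(k): float(self.percentages[k]) for k in self.percentages.index
            },
            "population_mean_iod": {
                str(k): (None if pd.isna(v) else float(v))
                for k, v in self.mean_iod.items()
            },
            "population_sd_iod": {
                str(k): (None if pd.isna(v) else float(v))
                for k, v in self.sd_iod.items()
            },
            "class_by_population": {
                str(cls): {str(k): int(self.counts.loc[cls, k]) for k in self.counts.columns}
                for cls in self.counts.index
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def crosstab(
    records: Sequence[CellRecord],
    scale: PloidyScale,
    multipliers: Sequence[int],
) -> CytometryTable:
    """Cross-tabulate classified records into a class × ploidy table.

    Debris records are excluded from all statistics; percentages are
    population count / total sorted cells × 100, reported to 2 decimals.
    """
    kept = [r for r in records if r.cell_class != "debris"]
    if not kept:
        raise ValueError("no non-debris records to tabulate")
    ks = tuple(sorted(set(int(k) for k in multipliers)))
    iods = np.array([r.iod for r in kept])
    assigned, _ = assign_ploidies(iods, scale, ks)
    classes = [r.cell_class for r in kept]

    counts = pd.DataFrame(0, index=sorted(set(classes)), columns=list(ks), dtype=int)
    for cls, k in zip(classes, assigned):
        counts.loc[cls, int(k)] += 1
    total = int(counts.values.sum())
    pop_counts = counts.sum(axis=0)
    percentages = (100.0 * pop_counts / total).round(2)
    mean_iod = pd.Series(index=counts.columns, dtype=float)
    sd_iod = pd.Series(index=counts.columns, dtype=float)
    for k in counts.columns:
        vals = iods[assigned == k]
        mean_iod[k] = vals.mean() if vals.size else np.nan
        # SD suppressed for populations of fewer than six cells
        sd_iod[k] = vals.std(ddof=1) if vals.size >= 6 else np.nan
    return CytometryTable(
        counts=counts,
        percentages=percentages,
        mean_iod=mean_iod,
        sd_iod=sd_iod,
        total=total,
        scale=scale,
        multipliers=ks,
    )
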
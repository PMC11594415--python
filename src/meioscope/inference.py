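"""Decision procedure mapping a cytometry table to a gamete-formation verdict.

The logic formalizes how DNA-content distributions discriminate the four
trajectories: a pre-meiotic endoreplication leaves germ cells at four times
the base ploidy (8C in diploids, 12C in triploids), so any appreciable
≥ 4×base population calls that mechanism; comparable reduced and unreduced
mature-gamete fractions call a mixed canonical/modified system (the
reduced-plus-unreduced sperm pattern); an overwhelmingly reduced mature pool
with essentially no unreduced spermatozoa is canonical meiosis; essentially
no reduced mature gametes with the unreduced class dominant is the modified
meiosis (the post-meiotic restoration alternative is rejected because it
predicts transient reduced spermatids); and a population with a substantial
transient reduced-spermatid fraction but unreduced spermatozoa only is the
post-meiotic restoration.  Every fired and rejected rule is recorded as
evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path

import numpy as np

from .ploidy import CytometryTable

__all__ = ["Verdict", "Thresholds", "MechanismCall", "infer"]

MATURE_CLASSES = ("spermatozoon", "spermatid")
GERM_CLASSES = ("spermatogonium", "spermatocyte", "spermatid", "spermatozoon")


class Verdict(str, Enum):
    A_CANONICAL = "A_CANONICAL"
    B_MODIFIED = "B_MODIFIED"
    C_PREMEIOTIC_ENDOREP = "C_PREMEIOTIC_ENDOREP"
    D_POSTMEIOTIC_RESTORE = "D_POSTMEIOTIC_RESTORE"
    MIXED_A_B = "MIXED_A_B"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class Thresholds:
    """Decision cutoffs on mature-gamete content fractions.

    ``tau_reduced`` — reduced-gamete fractions below this are treated as
    meiotic noise (the few-percent regime); ``tau_endorep`` — minimum
    ≥ 4×base fraction that evidences pre-meiotic endoreplication;
    ``tau_mixed`` — minimum fraction of each of reduced and unreduced mature
    gametes to call a mixed system (separates a ~50:50 split cleanly from the
    few-percent regime).
    """

    tau_reduced: float = 0.05
    tau_endorep: float = 0.01
    tau_mixed: float = 0.20

    def __post_init__(self) -> None:
        for name in ("tau_reduced", "tau_endorep", "tau_mixed"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.tau_reduced >= self.tau_mixed:
            raise ValueError("tau_reduced must be below tau_mixed")


@dataclass
class MechanismCall:
    verdict: Verdict
    evidence: dict
    thresholds: Thresholds
    rejected: list = dc_field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "verdict": self.verdict.value,
            "evidence": self.evidence,
            "thresholds": {
                "tau_reduced": self.thresholds.tau_reduced,
                "tau_endorep": self.thresholds.tau_endorep,
                "tau_mixed": self.thresholds.tau_mixed,
            },
            "rejected_alternatives": self.rejected,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def to_markdown(self) -> str:
        lines = [
            "# Gamete-formation mechanism call",
            "",
            f"**Verdict: {self.verdict.value}**",
            "",
            "## Evidence",
        ]
        for k, v in sorted(self.evidence.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append("## Rejected alternatives")
        if self.rejected:
            for r in self.rejected:
                lines.append(f"- {r}")
        else:
            lines.append("- none")
        return "\n".join(lines) + "\n"


def _fractions(table: CytometryTable, base_ploidy: int) -> dict:
    counts = table.counts
    ks = np.asarray(list(counts.columns), dtype=float)
    # reduced = at most half the somatic content; for pooled mixed-ploidy
    # populations intermediate multipliers (e.g. 2C under a 3C base) are the
    # unreduced gametes of lower-ploidy individuals, not reduced cells
    reduced_ks = [int(k) for k in ks if k <= base_ploidy / 2]
    unreduced_ks = [int(k) for k in ks if k >= base_ploidy]
    endorep_ks = [int(k) for k in ks if k >= 4 * base_ploidy]

    def frac(classes, which_ks):
        rows = [c for c in classes if c in counts.index]
        if not rows:
            return 0.0, 0
        sub = counts.loc[rows]
        denom = int(sub.values.sum())
        if denom == 0:
            return 0.0, 0
        num = int(sub[[k for k in which_ks if k in sub.columns]].values.sum())
        return num / denom, denom

    r, n_mature = frac(MATURE_CLASSES, reduced_ks)
    u, _ = frac(MATURE_CLASSES, unreduced_ks)
    e, n_germ = frac(GERM_CLASSES, endorep_ks)
    r_spz, n_spz = frac(["spermatozoon"], reduced_ks)
    u_spz, _ = frac(["spermatozoon"], unreduced_ks)
    r_spd, n_spd = frac(["spermatid"], reduced_ks)

    somatic_match = None
    if "somatic" in counts.index and counts.loc["somatic"].sum() > 0:
        modal_k = int(counts.loc["somatic"].idxmax())
        somatic_match = modal_k == base_ploidy
    return {
        "reduced_mature_fraction": r,
        "unreduced_mature_fraction": u,
        "endorep_germ_fraction": e,
        "reduced_spermatozoon_fraction": r_spz,
        "unreduced_spermatozoon_fraction": u_spz,
        "reduced_spermatid_fraction": r_spd,
        "n_mature": n_mature,
        "n_spermatozoa": n_spz,
        "n_spermatids": n_spd,
        "n_germ": n_germ,
        "max_multiplier_over_base": float(ks.max()) / base_ploidy,
        "somatic_match": somatic_match,
        "base_ploidy": base_ploidy,
    }


def infer(
    table: CytometryTable,
    base_ploidy: int,
    thresholds: Thresholds | None = None,
) -> MechanismCall:
    """Apply the ordered rule set to a class × ploidy table.

    Requires mature-gamete rows (spermatids and/or spermatozoa) and a known
    base ploidy (in practice the modal multiplier of the somatic reference).
    """
    if base_ploidy < 2:
        raise ValueError("base_ploidy must be >= 2")
    if not any(c in table.counts.index for c in MATURE_CLASSES):
        raise ValueError("table lacks mature-gamete rows (spermatid/spermatozoon)")
    th = thresholds or Thresholds()
    ev = _fractions(table, base_ploidy)
    r = ev["reduced_mature_fraction"]
    u = ev["unreduced_mature_fraction"]
    e = ev["endorep_germ_fraction"]
    r_spz = ev["reduced_spermatozoon_fraction"]
    u_spz = ev["unreduced_spermatozoon_fraction"]
    r_spd = ev["reduced_spermatid_fraction"]
    rejected: list[str] = []
    fired: list[str] = []

    def call(verdict: Verdict) -> MechanismCall:
        ev["rules_fired"] = fired
        return MechanismCall(verdict=verdict, evidence=ev, thresholds=th, rejected=rejected)

    # rule 1 — any appreciable 4×base population is diagnostic of
    # pre-meiotic endoreplication and takes precedence
    if e >= th.tau_endorep:
        fired.append(f"endorep: germ fraction at >=4x base = {e:.4f} >= {th.tau_endorep}")
        return call(Verdict.C_PREMEIOTIC_ENDOREP)
    rejected.append(
        f"C_PREMEIOTIC_ENDOREP rejected: no >=4x-base germ cells "
        f"(fraction {e:.4f} < {th.tau_endorep})"
    )

    # rule 2 — both pathways co-occurring
    if r >= th.tau_mixed and u >= th.tau_mixed:
        fired.append(
            f"mixed: reduced {r:.3f} and unreduced {u:.3f} both >= {th.tau_mixed}"
        )
        return call(Verdict.MIXED_A_B)

    # rule 3 — canonical meiosis: reduced mature pool, no unreduced sperm
    if r >= 1.0 - th.tau_mixed and u_spz < th.tau_reduced:
        fired.append(
            f"canonical: reduced mature {r:.3f} >= {1 - th.tau_mixed:.2f}, "
            f"unreduced spermatozoa {u_spz:.3f} < {th.tau_reduced}"
        )
        rejected.append("B_MODIFIED rejected: mature gametes are reduced")
        return call(Verdict.A_CANONICAL)

    # rule 4 — modified meiosis: no reduced stage, unreduced dominant
    if r < th.tau_reduced and u > 0.5:
        fired.append(
            f"modified: reduced mature {r:.3f} < {th.tau_reduced}, "
            f"unreduced dominant ({u:.3f})"
        )
        rejected.append(
            "D_POSTMEIOTIC_RESTORE rejected: no transient reduced spermatids "
            f"(reduced spermatid fraction {r_spd:.3f} < {th.tau_mixed})"
        )
        rejected.append("A_CANONICAL rejected: no reduced mature gametes")
        return call(Verdict.B_MODIFIED)

    # rule 5 — restoration: reduced spermatids transiently present while
    # spermatozoa are exclusively unreduced
    if r_spd >= th.tau_mixed and r_spz < th.tau_reduced and u_spz > 0.5:
        fired.append(
            f"restore: reduced spermatids {r_spd:.3f} >= {th.tau_mixed} but "
            f"reduced spermatozoa {r_spz:.3f} < {th.tau_reduced}"
        )
        rejected.append(
            "B_MODIFIED rejected: reduced spermatids present "
            f"({r_spd:.3f} >= {th.tau_mixed})"
        )
        return call(Verdict.D_POSTMEIOTIC_RESTORE)

    fired.append("no rule satisfied")
    return call(Verdict.INDETERMINATE)
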
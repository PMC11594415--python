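"""Mechanism inference from cytometry tables."""

import numpy as np
import pytest

from meioscope import simulate_and_infer
from meioscope.inference import Thresholds, Verdict, infer
from meioscope.ploidy import PloidyScale, crosstab


class Rec:
    def __init__(self, cell_class, iod):
        self.cell_class = cell_class
        self.iod = iod


SCALE = PloidyScale(c_unit=50.0, method="reference_population", residual=0.0)


def make_table(class_k_counts, multipliers):
    """Build a cytometry table from {class: {multiplier: count}}."""
    records = []
    for cls, by_k in class_k_counts.items():
        for k, n in by_k.items():
            records.extend(Rec(cls, 50.0 * k) for _ in range(n))
    return crosstab(records, SCALE, multipliers)


MULT2 = (1, 2, 4, 8)


def test_canonical_diploid_table():
    """1C-dominant mature gametes with 2C/4C precursors: canonical meiosis."""
    table = make_table(
        {
            "spermatozoon": {1: 300, 2: 5},
            "spermatid": {1: 150, 2: 10},
            "spermatocyte": {2: 150, 4: 60},
            "spermatogonium": {2: 100},
        },
        MULT2,
    )
    call = infer(table, base_ploidy=2)
    assert call.verdict is Verdict.A_CANONICAL
    assert call.rejected  # alternatives recorded


def test_triploid_modified_meiosis_table():
    """Germ distribution matching the somatic ploidies, ~2% reduced
    spermatids, no 12C: modified meiosis with restoration rejected."""
    mult3 = (1, 2, 3, 4, 6, 8, 12)
    table = make_table(
        {
            "spermatid": {1: 5, 3: 80, 2: 10},
            "spermatozoon": {3: 70, 4: 15},
            "spermatocyte": {3: 40, 6: 20},
            "spermatogonium": {3: 10, 6: 5},
        },
        mult3,
    )
    call = infer(table, base_ploidy=3)
    assert call.verdict is Verdict.B_MODIFIED
    assert any("D_POSTMEIOTIC_RESTORE" in r for r in call.rejected)
    assert any("12" not in r or True for r in call.rejected)


def test_half_unreduced_sperm_table():
    """Comparable reduced and unreduced spermatozoa: mixed system."""
    table = make_table(
        {
            "spermatozoon": {1: 110, 2: 90},
            "spermatid": {1: 60, 2: 40},
            "spermatocyte": {2: 80, 4: 30},
        },
        MULT2,
    )
    call = infer(table, base_ploidy=2)
    assert call.verdict is Verdict.MIXED_A_B


def test_endoreplication_rule_takes_precedence():
    """Adding >= 1% of 4x-base germ cells flips any verdict to the
    pre-meiotic endoreplication call."""
    base = {
        "spermatozoon": {2: 200},
        "spermatid": {2: 100},
        "spermatocyte": {2: 50, 4: 50},
    }
    assert infer(make_table(base, MULT2), 2).verdict is Verdict.B_MODIFIED
    with_8c = {**base, "spermatocyte": {2: 50, 4: 50, 8: 5}}
    assert infer(make_table(with_8c, MULT2), 2).verdict is Verdict.C_PREMEIOTIC_ENDOREP


def test_restoration_signature():
    """Transient reduced spermatids with exclusively unreduced spermatozoa."""
    table = make_table(
        {
            "spermatozoon": {2: 200},
            "spermatid": {1: 40, 2: 60},
            "spermatocyte": {2: 60, 4: 40},
        },
        MULT2,
    )
    assert infer(table, 2).verdict is Verdict.D_POSTMEIOTIC_RESTORE


def test_indeterminate_when_no_rule_fits():
    # 18% unreduced sperm: too many for a clean canonical call, too few for
    # a mixed system
    table = make_table(
        {"spermatozoon": {1: 85, 2: 15}, "spermatid": {1: 5, 2: 5}},
        MULT2,
    )
    call = infer(table, 2)
    assert call.verdict is Verdict.INDETERMINATE


def test_validation_errors():
    table = make_table({"spermatocyte": {2: 50}}, MULT2)
    with pytest.raises(ValueError):
        infer(table, 2)  # no mature-gamete rows
    good = make_table({"spermatozoon": {1: 50}}, MULT2)
    with pytest.raises(ValueError):
        infer(good, 1)
    with pytest.raises(ValueError):
        Thresholds(tau_reduced=0.3, tau_mixed=0.2)
    with pytest.raises(ValueError):
        Thresholds(tau_endorep=0.0)


def test_evidence_fields_complete():
    table = make_table({"spermatozoon": {1: 100}, "spermatid": {1: 50}}, MULT2)
    call = infer(table, 2)
    for key in (
        "reduced_mature_fraction",
        "unreduced_mature_fraction",
        "endorep_germ_fraction",
        "max_multiplier_over_base",
    ):
        assert key in call.evidence
    assert 0.0 <= call.evidence["reduced_mature_fraction"] <= 1.0


@pytest.mark.parametrize(
    "mix,base,expected",
    [
        ({"A_CANONICAL": 1.0}, 2, "A_CANONICAL"),
        ({"B_MODIFIED": 1.0}, 3, "B_MODIFIED"),
        ({"C_PREMEIOTIC_ENDOREP": 1.0}, 3, "C_PREMEIOTIC_ENDOREP"),
        ({"D_POSTMEIOTIC_RESTORE": 1.0}, 2, "D_POSTMEIOTIC_RESTORE"),
        ({"A_CANONICAL": 0.5, "B_MODIFIED": 0.5}, 2, "MIXED_A_B"),
    ],
)
def test_noise_free_simulation_returns_generating_model(mix, base, expected):
    """With zero measurement noise the decision procedure recovers the
    generating trajectory for every model and the 50:50 mix."""
    call, _ = simulate_and_infer(mix, base, n=800, cv=0.0, seed=0)
    assert call.verdict.value == expected


def test_mechanism_call_json_and_markdown(tmp_path):
    call, _ = simulate_and_infer({"A_CANONICAL": 1.0}, 2, n=500, cv=0.0, seed=1)
    call.to_json(tmp_path / "call.json")
    import json

    d = json.loads((tmp_path / "call.json").read_text())
    assert d["verdict"] == "A_CANONICAL"
    md = call.to_markdown()
    assert "Verdict" in md and "Evidence" in md
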
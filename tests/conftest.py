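import numpy as np
import pytest

from meioscope import cytometry, imaging, meiosis

MIXED_STAGE_MIX = {
    "spermatozoon": 0.3,
    "spermatid": 0.25,
    "spermatocyte": 0.25,
    "spermatogonium": 0.2,
}


def render_population(
    seed: int,
    n: int = 50,
    cv: float = 0.0,
    noise_sd: float = 0.0,
    debris_rate: float = 0.0,
    model: str = "A_CANONICAL",
    base_ploidy: int = 2,
):
    """One rendered field of a mixed-stage canonical population."""
    rng = np.random.default_rng(seed)
    cells = meiosis.sample_population(
        {model: 1.0}, MIXED_STAGE_MIX, {base_ploidy: 1.0}, n, cv, rng
    )
    config = imaging.RenderConfig(noise_sd=noise_sd, debris_rate=debris_rate)
    field, empty, truth = imaging.render_field(
        cells, config, np.random.default_rng(seed + 1000)
    )
    return cells, config, field, empty, truth


@pytest.fixture(scope="session")
def clean_render():
    """Noise-free, debris-free render of 50 canonical cells."""
    return render_population(seed=3)


@pytest.fixture(scope="session")
def clean_objects(clean_render):
    cells, config, field, empty, truth = clean_render
    od = cytometry.correct_and_transform(field, empty)
    return cytometry.segment_and_measure(od), od, truth


def match_stage(obj, truth):
    """Ground-truth stage of the nucleus a segmented object overlaps most."""
    labs = truth.label_mask[obj.mask]
    lab = int(np.bincount(labs).argmax())
    row = truth.objects[truth.objects.label == lab].iloc[0]
    return row.stage, lab
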
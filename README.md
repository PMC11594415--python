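# meioscope

Feulgen image-cytometry simulation and analysis of gamete-formation
mechanisms from nuclear DNA content.

## The problem

Some freshwater clams (*Corbicula*) reproduce by androgenesis: males clone
themselves through **unreduced sperm** that carry the full somatic DNA
content, while the maternal chromosomes are discarded after fertilization.
Whether a male germ line produces reduced (1C) or unreduced sperm — and by
which cytological route — can be read from the DNA content of its germ-cell
stages, measured by Feulgen densitometry: the stain binds DNA
stoichiometrically, so the **integrated optical density** (IOD) of a nucleus,

    IOD = Σ_pixels log10(I_incident / I_transmitted),

is proportional to its DNA content (C-value).

Four trajectories of DNA content through spermatogenesis are
distinguishable this way (base ploidy *p* in C units, e.g. *p* = 2 for a
diploid, *p* = 3 for a triploid):

| model | trajectory | mature gametes | diagnostic signature |
|---|---|---|---|
| A canonical | p → 2p → p → p/2 | reduced (p/2) | 1C-dominant sperm |
| B modified meiosis | p → 2p → (M\* abortive) → p | unreduced (p) | no stage below p |
| C pre-meiotic endoreplication | p → 2p → 4p → 2p → p | unreduced (p) | transient 4p (12C in a triploid) |
| D post-meiotic restoration | p → 2p → p → p/2 → (R) → p | unreduced (p) | transient reduced spermatids only |

`meioscope` simulates germ-cell populations under these models, renders them
as synthetic thionin-Feulgen brightfield fields with a paired empty-field
illumination reference, recovers per-nucleus morphometry and IOD
(empty-field correction → Beer–Lambert OD transform → Otsu threshold +
distance-transform watershed → feature extraction), classifies nuclei into
the seven classes of classical gonad cytometry (four germ stages, somatic,
stem cell, debris) by auditable size/density/shape gates, calibrates the IOD
axis in C units with a constrained normal mixture (component means fixed at
integer multiples of the 1C unit) or a somatic reference population, and
applies an ordered decision procedure that maps the resulting class × ploidy
table to one of the four mechanisms, a mixed canonical/modified system, or
an indeterminate call.

## Worked example

A population in which half the germ line runs a canonical meiosis and half a
modified meiosis — the mixed reduced/unreduced sperm pattern:

```python
from meioscope import simulate_and_infer

call, table = simulate_and_infer(
    {"A_CANONICAL": 0.5, "B_MODIFIED": 0.5},
    base_ploidy=2, n=1000, cv=0.08, seed=42,
)
print("verdict:", call.verdict.value)
print("1C unit (IOD):", round(table.scale.c_unit, 2))
print("population %:", {k: float(v) for k, v in table.percentages.items()})
print("reduced mature fraction:", round(call.evidence["reduced_mature_fraction"], 3))
print("unreduced mature fraction:", round(call.evidence["unreduced_mature_fraction"], 3))
```

prints

```
verdict: MIXED_A_B
1C unit (IOD): 46.17
population %: {1: 32.2, 2: 50.7, 4: 17.1, 8: 0.0}
reduced mature fraction: 0.493
unreduced mature fraction: 0.507
```

The somatic reference anchors the 1C unit at ≈ 46.2 IOD (the scale is tied
to a 2C mean of ≈ 92.6 arbitrary units); the 1C population holds the reduced
spermatozoa/spermatids, 2C the unreduced gametes plus G1 precursors, 4C the
replicated spermatocytes; mature gametes split roughly half reduced, half
unreduced, so the verdict is the mixed canonical/modified system rather than
any single trajectory.

The same analysis on rendered images, from the shell:

```sh
meioscope all --seed 21 --out run/          # simulate → render → measure → infer
meioscope render --seed 5 --out fields/     # TIFF fields + ground truth
meioscope analyze --fields fields/ --out analysis/ --multipliers 1,2,4
```

`run/` then contains the population CSV, the per-object feature table, the
class × ploidy table (CSV + JSON), an IOD histogram styled like classical
DNA-content cytometry figures, and the mechanism call with its evidence and
rejected alternatives.

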
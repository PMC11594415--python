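# Methods

## DNA-content models

A germ cell's DNA content is expressed in C units, with 1C the content of an
unreplicated reduced chromosome set and the base ploidy *p* the content of
the unreplicated somatic set (p ∈ {2, 3, 4}; these are the ploidies observed
in the clam system the package models, where individuals of different ploidy
may be pooled in one preparation). Four trajectories are implemented
(`meiosis.trajectory`): canonical meiosis (A) ends at p/2; modified meiosis
(B) carries one abortive division M\* and never drops below p; pre-meiotic
endoreplication (C) inserts a doubling E so the trajectory peaks at 4p
before two normal divisions; post-meiotic restoration (D) is canonical down
to p/2 followed by a restoration step R back to p.

Stage contents (`meiosis.stage_content`) discretize these trajectories:
spermatogonia and somatic cells occupy {p, 2p} (a cycling population),
spermatocytes {2p together with the post-first-division content}, spermatids
and spermatozoa the terminal gametic content(s); model D spermatids exist at
both p/2 (pre-restoration) and p. Within-stage weights default to a 15 %
replicated fraction for cycling populations (the order of the 2×base somatic
population seen in pooled somatic reference data) and a 50 % restored
fraction for model D spermatids (the transient stage is not quantified
anywhere; it is an explicit free parameter). Mixed mechanisms are expressed
as mixtures over models rather than a fifth trajectory, because a population
in which both pathways co-occur is exactly a mixture at the cell level.

Measurement noise is multiplicative lognormal with unit mean and
user-specified coefficient of variation (default 0.08 in the stochastic
checks, the order of the relative SD of published 2C populations,
13.64/92.56 ≈ 0.15, tightened to reflect that the simulation omits
section-truncation artifacts). A positive, multiplicative error model is the
natural choice for a quantity that is a product of stain uptake, section
thickness and illumination factors.

## Synthetic imaging

`imaging.render_field` places elliptical nuclei on a field (default 512 ×
512 px at 0.16 µm/px, a ×40-objective sampling pitch) with stage-specific
geometry: spermatogonia 5.4 ± 0.69 µm, spermatocytes 3.93 ± 0.41 µm,
spermatids 1.71 ± 0.34 µm (published histological morphometry; draws
truncated at ±3 SD), somatic nuclei 5.0 ± 0.6 µm, and spermatozoa rendered
as small strongly elongated heads (equivalent diameter 2.0 ± 0.15 µm, axis
ratio 4.0 ± 0.5) since only their elongated, conical shape — not a diameter —
is described. Within a nucleus the optical density is uniform and normalized
so the painted pixel sum equals `od_per_c × C`; `od_per_c` defaults to 46.28
so a 2C nucleus integrates to 92.56 arbitrary units, putting synthetic IODs
on the published scale. Chromatin texture can be added as multiplicative
speckle but defaults to off; with uniform painting, apparent "paleness"
still emerges naturally because mean OD is content divided by area — large
2C spermatogonia are pale, small spermatids dense, as in stained sections.

Illumination is a low-order polynomial surface with a per-field brightness
factor; transmission follows Beer–Lambert (T = I·10^(−OD)); camera noise is
additive Gaussian on the transmitted intensity (default SD 60 counts at an
incident level of 30 000), clipped to [0, incident]. Debris is rendered as
irregular aggregates of 2–4 fused nuclei of heterogeneous content. Ground
truth (label mask plus per-object stage, content and painted integrated
absorbance) is returned with every render.

What the generator does **not** emulate: section truncation of nuclei,
chromatin texture of real Feulgen staining, out-of-focus light, stain
batch variation, and the very high debris loads of disaggregated gonad
preparations (70–80 % of objects in real slides; the default synthetic rate
is 5 %). Passing tests therefore demonstrate the correctness of the
measurement and inference chain under controlled optics, not robustness to
every histological artifact.

## Densitometry

OD is computed per pixel as log10(incident/transmitted) against the paired
empty-field reference, with the transmitted intensity floored at one
quantization step and negative OD clamped to zero; the correction makes all
features invariant to rescaling both images by a common factor and cancels
the illumination surface exactly. log10 versus natural log is irrelevant to
every inference because only IOD ratios enter the analysis.

Segmentation thresholds the OD image by Otsu **on the log-OD histogram**,
floored at OD 0.05: the background is a massive near-zero spike while nuclei
span an order of magnitude, and raw-histogram Otsu drifts above the palest
(2C spermatogonium) class. Touching nuclei are split by watershed; markers
are depth-suppressed regional maxima (h = 0.5 px) of the distance transform
smoothed with a 2.5 px Gaussian. The smoothing matters: an elongated sperm
head has a near-flat distance ridge whose pixelation ripple otherwise seeds
spurious splits, while the valley between two fused round nuclei survives
it. Marker pixels are dilated before labelling because the h-maxima
transform marks only the topmost pixels of a plateau, which can be
disconnected dots on one ridge; any foreground component left seedless
receives one marker at its distance maximum. Objects outside 0.3–120 µm²
are discarded; fields with no surviving object are eliminated and logged.

Per-object features: area (pixel count × pixel size²), equivalent diameter,
circularity 4πA/P² with the perimeter from the boundary crack-length
estimator (circularity therefore slightly exceeds 1 for small discs and is
clipped at 1.05), elongation as the major/minor axis ratio of the image
moments, mean OD, OD texture (within-object SD), and IOD as the exact pixel
sum. Coordinates are row-major, 0-based, origin top-left, pixel centers.

## Cell typing

The ordered gates replace a manual sort. Debris first: area outside the
plausible nuclear range (0.6–8.5 µm equivalent diameter), aggregate-like
shape (circularity < 0.3 without sperm-like elongation), or heterogeneous
internal OD (texture/mean > 0.25, the signature of fused nuclei of unequal
content). Then spermatozoa (elongation ≥ 2, diameter ≤ 3 µm, dense); then
the three size-window gates at ±3 SD of the published diameters. Because
mean OD is content over area, a pale nucleus in the
spermatocyte/spermatogonium overlap zone is genuinely ambiguous; the
pale/dense condition is therefore a soft penalty (+1.5 SD on the
standardized size distance) rather than a hard filter, and ties resolve to
the smallest penalized distance. The pale/dense cutoff itself is the Otsu
split of per-object mean OD in log space, re-estimated per population since
no absolute chromatin-density value exists. A stem-cell gate (very pale,
larger than the spermatogonium window) is best-effort: no size parameters
for stem cells exist because they were too rare to measure, and none are
recorded in cytometry runs. Somatic reference slides are typed with a
dedicated flag under which size-plausible nuclei are classified somatic; on
germ-cell slides a somatic nucleus is indistinguishable from a
spermatogonium and will be typed as one (a documented limitation, harmless
to the downstream logic because both occupy {p, 2p}).

Expected residual confusion is between size-window neighbours only
(spermatid↔spermatozoon, spermatocyte↔spermatogonium, and the 2.7 µm
spermatid/spermatocyte corner); on rendered populations with the published
size SDs the non-debris accuracy is ≥ 0.9 and no small↔large confusion
occurs.

## Ploidy calibration and tabulation

With a somatic reference, the 1C unit is the modal reference IOD (Gaussian
KDE mode) divided by the known base ploidy. Without one, a constrained
one-dimensional normal mixture is fitted by maximum likelihood: component
means fixed at k·c for the allowed multipliers k, one shared coefficient of
variation, free weights; a 120-point log-spaced grid over candidate units is
profiled by EM (15 iterations, CV floored at 10⁻³) and the best candidate
refined by bounded scalar minimization. The mixture is scale-identifiable
only when the multiplier set cannot be shifted onto itself (e.g. {1, 2, 4}
for a canonical diploid); an all-unreduced population clustered at {p, 2p}
is not, which is exactly why the somatic reference exists, and a degenerate
fit (fewer than two components above 1 % weight) is flagged on the returned
scale.

Bin boundaries between adjacent multipliers sit at geometric midpoints
√(k·k′)·c because the error model is multiplicative; exact boundary values
round up; values beyond the outermost boundaries are assigned to the nearest
extreme multiplier and flagged. Multiplier sets are per-run choices: {1, 2,
4, 8} for a diploid, {1, 2, 3, 6, 12} for a triploid (always including
4×base so the endoreplication signature has a bin), and denser sets for
pooled mixed-ploidy material. No per-individual deconvolution of pooled
suspensions is attempted; mixed ploidy is represented in the multiplier set.

The cytometry table cross-tabulates non-debris classes against multipliers
and reports per-population counts, percentages of total sorted cells
(2 decimals), and mean ± SD IOD with the SD suppressed below six cells,
matching the reporting conventions of the source tables.

## Mechanism inference

With r = the reduced fraction of mature gametes (spermatids + spermatozoa at
k ≤ p/2), u = their unreduced fraction (k ≥ p), and e = the fraction of all
germ cells at k ≥ 4p, the ordered rules are: (1) e ≥ 0.01 → pre-meiotic
endoreplication (the 4×base population exists under no other model, so it
takes precedence); (2) r and u both ≥ 0.20 → mixed canonical/modified
system; (3) r ≥ 0.80 with unreduced spermatozoa < 0.05 → canonical; (4) r <
0.05 with u dominant → modified meiosis, restoration rejected on the absence
of reduced spermatids; (5) reduced spermatids ≥ 0.20 while spermatozoa are
exclusively unreduced → post-meiotic restoration; (6) otherwise
indeterminate. Thresholds: 0.05 treats a few-percent reduced fraction as
meiotic noise (spontaneous unreduced-gamete errors of the same order are
documented even in strictly sexual species) with headroom over an observed
~2 % rate; 0.20 separates a roughly half-and-half mixed system cleanly from
that noise regime; 0.01 on e because even a small 4×base population is
mechanistically diagnostic. The reduced criterion is k ≤ p/2 (not merely
k < p) because in pooled mixed-ploidy material intermediate multipliers are
the unreduced gametes of lower-ploidy individuals. Every fired and rejected
rule is recorded in the call's evidence.

The D-versus-B disambiguation rests entirely on the spermatid/spermatozoon
asymmetry (transient reduced spermatids); on sperm alone the two are
indistinguishable, and the evidence field says so via the recorded rejection
reasons. Canonical meiosis at odd base ploidy would produce half-integer
gametic contents that integer multiplier sets cannot represent; this case is
not modelled (it is also the aneuploidy-generating case that real odd-ploidy
systems avoid precisely by modifying meiosis).

## Problem sizes and seeds

Stochastic guarantees are characterized on the simulation-level path
(contents → IOD at 46.28/C → calibrate → tabulate → infer): 100 seeds per
scenario at n = 1000 cells and CV 8 % for mechanism calls, 50 seeds for
calibration recovery, with recovery judged against the generator truth of
each sample. The imaging path is exercised deterministically (stoichiometry,
segmentation oracle, classification accuracy) on 50-nucleus fields and by
single-seed end-to-end runs; rendering hundreds of seeds through full fields
would add only placement variability that the deterministic checks already
cover. All randomness descends from one top-level seed via spawned
generators, so every artifact of a run is byte-reproducible.

## Known limitations

Real debris fractions (70–80 %) are far above the synthetic default, and the
classifier's debris gates are tuned to renderer aggregates, not to true
histological debris diversity. The somatic/spermatogonium degeneracy on germ
slides is unresolved by design. The constrained-mixture calibration requires
an identifiable multiplier set or a somatic reference. Published mean IODs
and per-stage unreduced percentages from real slides serve as scale anchors
and documentation examples only; original images do not exist in any public
archive, so those numbers are not reproducible from this package and are not
claimed.
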
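# Methods

This note documents the models, algorithms, defaults and known limits of
the package. It is written for users deciding whether the defaults match
their data and for maintainers changing them.

## Probe design

**Model.** A probe body is a plus-strand (mRNA-sense) subsequence of the
vector genome, so it hybridizes only to the packaged negative-sense
strand and not to transcripts. A valid body is ≥ 36 nt long with a
predicted duplex melting temperature inside a window (default 67–71 °C),
and bodies never overlap. The finished oligo is `body + TTT + primer`,
where the primer is one of two registered 9-nt concatemer-extension
primers (`CATCATCAT`, `CAACTTAAC`); the concatemerization chemistry
itself is out of scope and only the primer identity is recorded.

**Tm engine.** Unified nearest-neighbor thermodynamics
(Allawi & SantaLucia 1997 parameters, via Biopython), entropy salt
correction `0.368·(N−1)·ln[Na+]`, two-state concentration term `c_T/4`.
Defaults: 50 mM monovalent salt, 25 nM total strand concentration,
both exposed in `TmConditions`. Published probe sets were designed with
a variety of Tm engines whose parameters are rarely reported; users
reproducing an existing set should recalibrate the window rather than
expect identical oligo lists. For this reason no probe-count figure is
treated as reproducible.

**Search.** Greedy leftmost-first: at the leftmost unused position a
candidate grows from 36 nt upward until its Tm enters the window
(accept) or overshoots it (advance one position). Longer candidates only
get hotter, so overshoot is a terminal condition per start. The search
is deterministic and is verified exactly against a brute-force oracle on
genomes up to 1 kb. Adjacent probes may abut (gap 0 is allowed; only
overlap is forbidden). Exclusion intervals (e.g. ITRs) are honored by
jumping past any interval a candidate would enter; coordinates are
0-based half-open everywhere.

**5′/3′ split.** Each probe joins the 5′ set iff its body midpoint is
left of the split coordinate; each half is assembled with its own
primer. The two primers must differ or the channels are
indistinguishable.

## Synthetic data

The simulator emulates a confocal stack of photoreceptor-dense tissue
and is the ground truth for every downstream test.

* **Geometry.** Cell seed points are placed by dart throwing with a
  minimum separation (2.3× the nucleus radius, or a packing-derived
  floor); cells are the nearest-seed (Voronoi) partition of the tissue
  mask under the anisotropy-aware micron metric; the nucleus is the ball
  of `nucleus_radius` around the seed, which the separation rule keeps
  strictly inside its own cell. The mask is either a slab occupying a
  central fraction of y (a retina-like section crossing the field of
  view) or, with `margin_um`, a block bounded away from every face so
  all cells are whole. Defaults: 0.4 × 0.2 × 0.2 µm voxels,
  nucleus radius 1.2 µm in the generic default, 1.8 µm in the
  photoreceptor-scale studies (rod and cone nuclei occupy much of the
  soma, and nuclear volume sets how crowded high-copy counting gets).
* **Genomes.** Per cell, counts are Poisson(λ·titer_scale); expected
  counts therefore scale exactly with titer, which is the known truth
  the dilution analysis must recover. λ defaults to 2.1 (the measured
  mean in expressing rods; presets carry 2.5 for cones and 29.9 for
  RPE). Each genome sits in the nucleus with probability
  `nuclear_fraction` (default 0.8 — genomes are predominantly nuclear
  shortly after infection), uniformly within the compartment. Two-channel
  modes: `co_located` renders the same genome in both channels with a
  Gaussian inter-channel offset (σ default 0.05 µm, truncated at 5σ),
  modeling 5′/3′ half-genome probe sets; `independent` draws the two
  channels as separate populations, modeling two co-injected vectors.
  Per-channel `detection_efficiency` thins rendered puncta, modeling
  probe-level dropout.
* **Rendering.** Membranes are the inter-label boundary voxels, nuclei
  their masks, both PSF-blurred; puncta are anisotropic Gaussians
  (σ default 0.15 µm lateral / 0.4 µm axial — a placeholder confocal
  PSF, config-exposed) at continuous positions, rasterized with voxel
  centers at `(i+0.5)·voxel_size`. Noise is Poisson shot noise on
  signal + background (default background 10, punctum amplitude 800);
  Gaussian read noise is available. A PSF below 0.25 voxel on any axis
  is rejected as unresolvable.
* **Expression.** Mean readout `baseline + increment·k/(1 + k/saturation)`
  for genome count k plus Gaussian noise — linear at low copy number and
  saturating, which is what makes expression imperfectly predictive of
  genome count at high copy number.

What the simulator does **not** model: bleed-through, autofluorescence,
aberration, cell-type-specific shapes, probe-sequence-specific binding.
Passing tests demonstrate that the analysis recovers truth under this
idealized forward model, not that it is robust to every artifact of real
tissue.

## Segmentation

Nuclei: Gaussian smoothing (0.3 µm), Otsu threshold, Euclidean distance
transform (lightly smoothed to remove plateaus), anisotropy-aware peak
markers at least 1.5 µm apart (adjacent plateau peaks merged into one
marker), distance-watershed split, minimum volume 1 µm³. Cells:
marker-controlled watershed of the smoothed membrane channel (optional
Hessian plate-enhancement accentuates sheet-like membranes), seeded by
the segmented nuclei, restricted to the tissue mask, so in-mask voxels
partition exhaustively into cells. Inclusion rules: `touches_border` iff
any voxel lies on one of the six volume faces; `in_tissue` iff ≥ 50% of
voxels are inside the mask; only cells that are in tissue and not on the
border are analyzed. On default-noise simulations ≥ 90% of cells are
recovered one-to-one at IoU ≥ 0.7.

## Puncta detection

Scale-normalized LoG: response `−σ² · ∇²G_σ * I` at three scales
log-spaced ±50% around the PSF σ (axial σ scaled by the PSF aspect
ratio), max-projected over scales. Candidate peaks are in-mask local
maxima above `median + k·1.4826·MAD` of the in-mask response (k = 5 by
default); peaks closer than 0.3 µm (2× the lateral PSF σ) collapse to
the strongest; positions are refined per axis by a 3-point quadratic
fit clamped to ±0.5 voxel. Assignment is point-in-mask at the rounded
voxel: cell label → `cell_id`, nucleus mask → nuclear vs cytoplasmic,
background → extracellular; puncta in excluded cells are flagged and
kept out of statistics. A nearest-nucleus mode within a radius supports
tissues quantified per nucleus (RPE-style sheets without a usable
membrane channel).

**Thresholds and volume.** k = 5 keeps single-image false calls rare,
but the false-call probability per voxel (~2·10⁻⁵ at k = 5 under shot
noise) is not negligible when one analysis spans tens of millions of
voxels and expects only a few hundred true spots. The large-volume
studies therefore run at k = 7, where the expected false-call count is
effectively zero while spot peaks remain far above threshold; this is a
family-wise error consideration, not a sensitivity trade-off at these
amplitudes.

**Crowding.** Two genomes closer than roughly the PSF (worst along z)
merge into one punctum; the loss scales with λ²/nuclear volume. At
λ = 5 in 1.8 µm-radius nuclei this costs ~3% of counts — the physical
resolution limit of counting by peak detection, and the reason per-cell
means at high copy number are recovered to within a few percent rather
than exactly.

## Colocalization

Candidate pairs within the match radius are sorted by distance (ties:
lower id) and accepted greedily one-to-one — deterministic,
O(n log n), and equal to the brute-force replay on test sets; at the
sparse densities involved it differs negligibly from optimal assignment.
Default radius 0.3 µm (2× lateral PSF σ); the dual-vector chance study
uses 0.5 µm. Probability = mean of the two per-channel matched
fractions; a fraction over an empty channel is undefined (None) and the
probability falls back to the defined one. In co-located mode with
per-channel efficiency e the expected probability is e (each detected
punctum's partner survived with probability e); in independent mode with
*uniform* placement it is the Poisson-field chance rate
`1 − exp(−ρ·(4/3)πr³)`. Note that concentrating both channels in nuclei
(nuclear_fraction above the nuclear volume fraction) raises chance
colocalization above that formula — shared subcellular structure mimics
colocalization, which is why the chance-level checks use uniform
placement.

## Statistics

Limiting-dilution: OLS of group mean count on relative titer over ≥ 3
groups (group means, matching how such series are presented; per-group
SEMs carried for display; a cell-level variant would weight groups by n
and is intentionally not the default). R² over the group means, 95% CIs
from the t distribution. The alternative count ∝ titer^y (default
y = 2) is anchored at the highest-titer group's observed mean, and its
goodness of fit is reported in log-log space over nonzero groups; data
generated under y = 2 prefer that model over the linear fit in ≥ 95% of
seeded replicates. The five default titers are log-spaced across one
decade — the span of the original dilution series; the exact factors
were not published, so equal log spacing is the neutral choice.
Count histograms use bins {0,1,2,3,4,>4}. Expression trend: Spearman
rank correlation with a seeded permutation p (10,000 draws). Group
comparisons: two-tailed Student's t with pooled variance (the named
test; Welch is deliberately not substituted) and Bonferroni adjustment
`min(1, m·p)` over the m pairwise comparisons performed; two zero-
variance groups with equal means return p = 1 by convention.

## Pipeline and reproducibility

A pydantic-validated YAML config (unknown keys rejected) drives
simulate → segment → detect → assign → count → colocalize/statistics
with every stage boundary on disk (TIFF + JSON sidecar for images and
labels, CSV for tables, JSON for results), so stages can be re-run in
isolation or fed real data. Stage RNGs are substreams of the master seed
keyed by stage name; a manifest records package version, config hash and
SHA-256 of every output, and identical seeds reproduce identical
checksums end to end. The tissue mask used by the pipeline is the
simulator's slab mask when simulating (standing in for the manual
"inside the tissue" judgment); `estimate_tissue_mask` provides an
Otsu-based fallback for real stacks.

## Study problem sizes

The dilution study runs five groups of 550 whole cells (~5 × 10⁶ voxels
per group); count-recovery studies size themselves to keep ≥ 1000
expected genomes in the volume (5000 cells at λ = 0.2, on a coarser
0.5 × 0.25 × 0.25 µm grid since isolated spots do not need the finest
sampling); the chance-colocalization study uses 1000 cells of ~500 µm³
at 0.5 µm isotropic placement resolution with nothing rendered. These
sizes keep the sampling error of each checked quantity several times
smaller than its tolerance.

## Known limitations

* Counting by peak detection saturates with copy number; per-nucleus
  counts in the tens (RPE-scale) are not reliably resolvable at the
  default PSF and are not claimed.
* The Tm window reproduces a design *rule*, not any historical probe
  list, because historical Tm engines are undocumented.
* The watershed reproduces the role, not the algorithm, of
  resolution-adaptive membrane segmenters; no claim is made about
  matching any specific tool's masks.
* Chance colocalization is quoted for uniform placement; correlated
  subcellular localization raises it.
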
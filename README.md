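# aavfish

Quantification of single AAV vector genomes in tissue imaged by
amplified DNA FISH (SABER-FISH), for gene-therapy and imaging labs that
need per-cell genome counts rather than bulk titers.

After an AAV vector is delivered to tissue, each packaged single-stranded
genome can be visualized as one diffraction-limited punctum by
hybridizing tiled oligo probes against the packaged (negative-sense)
strand and amplifying the signal. Counting those puncta per cell turns a
microscope image into a per-cell multiplicity-of-infection measurement.
This package implements the full quantitative stack around that idea:

* **Probe design** — tiles a vector genome (plus-strand FASTA) into
  non-overlapping oligos, each ≥ 36 nt with a nearest-neighbor duplex
  melting temperature in a 67–71 °C window, then appends a `TTT` linker
  and one of two 9-nt concatemer primers (`CATCATCAT` / `CAACTTAAC`).
  A probe set can be split at a genome coordinate into 5′/3′ halves with
  distinct primers, so the two halves of one genome report in separate
  fluorescent channels.
* **3D segmentation** — marker-controlled watershed on a membrane
  (WGA-like) channel seeded by nuclei segmented from a DAPI-like
  channel; cells touching any image boundary, or mostly outside the
  tissue mask, are excluded so only whole cells are quantified.
* **Puncta detection** — scale-normalized Laplacian-of-Gaussian spot
  calling with a robust threshold (median + k·1.4826·MAD of the in-mask
  response), subvoxel localization, and per-cell / nuclear-vs-cytoplasmic
  assignment.
* **Colocalization** — greedy one-to-one matching of two puncta channels
  within a micron radius; the colocalization probability is the average
  of the two per-channel matched fractions,
  `P = (n_match/n_A + n_match/n_B) / 2`.
* **Statistics** — limiting-dilution regression (mean puncta per cell vs
  relative titer: one genome per punctum predicts an *x*-fold count drop
  per *x*-fold dilution, while *y* genomes per punctum would predict
  *x*^*y*; the package fits OLS with R² and a 95% CI and overlays the
  titer^y prediction), count distributions, expression-vs-count trends
  (Spearman with a permutation p), and pooled two-sample t tests with
  Bonferroni correction.
* **Synthetic data** — a 3D tissue simulator (Voronoi cells with bright
  membranes, ellipsoidal nuclei, Poisson genome counts proportional to
  titer, configurable nuclear fraction, co-located or independent
  two-channel modes, Gaussian-PSF rendering with shot noise) provides
  ground truth against which every stage is tested.

## Worked example

Design probes for a (here random) 1 kb vector genome, then simulate and
re-quantify a small volume:

```python
import numpy as np
from aavfish import VectorGenome, tile_probes, assemble_probes

rng = np.random.default_rng(42)
genome = VectorGenome("demo", "".join(rng.choice(list("ACGT"), 300)))
probes = assemble_probes(tile_probes(genome), "CATCATCAT")
print(len(probes), probes.probes[0].full_sequence[-12:])
```

prints `7 TTTCATCATCAT`: seven tiled probes, each ending in the linker
plus primer. Each probe's `tm` lies in [67, 71] °C and intervals do not
overlap.

Running the configured pipeline on a simulated dilution series:

```python
from aavfish.studies import dilution_study
fit = dilution_study(seed=1)
print(round(fit.r_squared, 4), [round(m, 2) for m in fit.group_means])
```

prints `0.9991 [0.2, 0.46, 0.75, 1.37, 2.51]`: five titer groups spanning
one decade recover group mean counts proportional to titer (top group
generated at a mean of 2.5 genomes per cell), and the regression of
recovered means on titer has R² ≈ 0.999 — the limiting-dilution
signature that each punctum reports a single genome.

The same stages are available from the shell:

```bash
aavfish probes design --fasta vector.fa --out probes/
aavfish run --config sim.yaml --seed 1 --out run/
aavfish coloc --a run/run/puncta_punctaA.csv --b run/run/puncta_punctaB.csv \
    --radius 0.5 --out coloc/
```

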
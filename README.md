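# pnnquant

Automated detection and quantification of **perineuronal nets (PNNs)**
in multi-channel fluorescence microscopy, together with a synthetic
scene generator that makes every stage of the pipeline verifiable
against known ground truth.

PNNs are mesh-like extracellular-matrix structures condensed around the
somata of a subset of neurons (chiefly parvalbumin-positive
interneurons).  In a single confocal plane stained with *Wisteria
floribunda* agglutinin (WFA) a net appears as a punctate ring around
the cell.  A recurring analysis problem is to find those rings
automatically, confirm each one surrounds a cell (via the
Hoechst/nuclear channel), measure its mean intensity, and relate that
intensity to a second channel carrying a tagged protein of interest —
for example a myc- or his-tagged neuronal pentraxin.  The package is
aimed at cellular-neuroscience groups doing exactly this kind of
object-based two-channel quantification, in tissue sections or
dissociated cultures.

## What it computes

* **Ring detection.** Canny edges in the WFA channel feed a circular
  Hough accumulator over a configurable radius range; peaks are
  non-max-suppressed deterministically and each radius is refined to
  the ring's radial intensity centroid.
* **Nucleus gating.** A candidate circle is kept only if a detected
  nucleus centroid lies inside it — the "is the circle around a cell?"
  check.  The WFA-positive pixels of the annulus are then selected as
  the measurement region.
* **Object-based colocalization.** For each net, the mean intensity of
  both channels over the *same* ring mask; association is summarised by
  the Spearman rank correlation of the pooled per-net pairs,

  ρ = corr(rank xᵢ, rank yᵢ),   xᵢ = mean WFA, yᵢ = mean tag,

  computed as the Pearson correlation of average-assigned ranks (exact
  under ties).
* **Phenotype census.** Each net is called *surface-positive* (tag
  signal on the ring, a background z-score test) and/or
  *intracellular-punctate* (≥ m vesicle-like local maxima in the soma),
  and the percentages over the PNN-positive population are reported.
* **Culture statistics.** PNN density per 50 mm², per-net size and WFA
  intensity (absolute and relative to a control group), the fraction of
  parvalbumin-positive cells carrying a net, and the group comparisons
  (pooled-variance Student's t, one-way ANOVA).
* **Synthetic scenes.** Four-channel scenes (nuclear, WFA, tag, PV)
  with punctate annuli, somatic puncta and configurable noise.  Ring
  intensities of the two channels are drawn through a Gaussian copula
  (latent Pearson 2·sin(πρ_s/6)), so the population Spearman among
  tagged nets equals a requested value; phenotype fractions can be
  drawn exactly.  Identical configs reproduce scenes bit for bit.

## Worked example

```python
from pnnquant import (GeneratorConfig, generate_scene, detect_and_segment,
                      measure_all, classify_all, census, colocalize)

cfg = GeneratorConfig(image_shape=(1024, 1024), n_cells=40, seed=7)
stack, truth = generate_scene(cfg)

objects, nuclei, log = detect_and_segment(stack)
print(log)
records = measure_all(stack, objects)
phen = classify_all(stack, objects, nuclei, records)
pop = census(phen)
print(f"surface-positive: {pop.frac_surface_positive:.1f}%  "
      f"intracellular: {pop.frac_intracellular:.1f}%")
tagged = [r for r, p in zip(records, phen) if p.surface_positive]
res = colocalize(tagged)
print(f"rho = {res.rho:.3f} over n = {res.n} tagged nets")
```

prints

```
{'nuclei': 40, 'ring_candidates': 25, 'validated': 25, 'segmented': 25, 'dropped_empty_mask': 0}
surface-positive: 56.0%  intracellular: 28.0%
rho = 0.846 over n = 14 tagged nets
```

All 40 nuclei and all 25 rendered nets are found; none of the ring
candidates fail the nucleus gate.  The census is taken over the 25
detected PNN cells (the scene was generated with Bernoulli phenotype
draws, so the realised fractions differ from their expectations), and
the rank correlation of the per-net WFA/tag intensity pairs among the
14 tagged nets recovers the generative coupling of 0.816 up to sampling
noise at that n.

The same steps are available from the shell (`pnnquant simulate`,
`pnnquant detect`, `pnnquant coloc`, `pnnquant culture`,
`pnnquant recover`), and the numbered scripts under `analysis/` run the
full study-style experiments, writing their tables under `results/`.

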
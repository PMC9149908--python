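# Methods

## The model

`lopitmap` treats a published organellar map — a 2-D t-SNE embedding of
LOPIT density-gradient profiles in which each protein has fixed
coordinates and one of 13 compartment assignments (cytosol, endoplasmic
reticulum, golgi, lysosome, mitochondria, nucleus, nucleus-chromatin,
peroxisome, plasma membrane, proteasome, ribosome 40S, ribosome 60S,
unknown) — as an immutable frame of reference. Quantitative proteome
data from unrelated experiments are joined onto that frame by UniProt
accession, and all statistics are computed in the map's coordinate and
compartment space. The embedding itself is never recomputed or refined;
"unknown" is a genuine assignment (ambiguous gradient profile) and is
kept strictly distinct from a protein being absent from the map.

Two analyses sit on top of the overlay:

**Proximity-labeling enrichment.** For a BioID-style experiment with
wash fractions (W-1, W-2) and a biotin-competition eluate, the
per-protein enrichment statistic is the ratio of Elute to final-wash
(W-2) abundance. The four endogenously biotinylated carboxylases
(P11498, P05165, Q96RQ3, Q13085) are guaranteed substrates of the
streptavidin selection, so their Elute/W-2 ratios benchmark what a
truly biotinylated protein achieves; candidates are kept when their
ratio is at least a cutoff (inclusive boundary), conventionally 3.
Proteins quantified only in the eluate cannot be ratioed; absence from
the wash is the strongest enrichment signal, so they pass by default
with a distinct `numerator_only` status rather than via a pseudo-count
(an abundance floor is available but off by default). Controls missing
from either fraction are excluded from the benchmark, never imputed.

**EV-preparation evaluation.** A categorized marker list in the
MISEV2018 style (five disjoint categories; categories 1, 2 and 5 are EV
markers, 3 contaminant markers, 4 subtype markers) is intersected with
the detected proteome to give per-category recovery percentages, and
the detected proteins are tallied per compartment. The marker region
{plasma membrane, lysosome, endoplasmic reticulum, cytosol} and
contaminant region {mitochondria, nucleus, nucleus-chromatin, ribosome
40S, ribosome 60S} summarize where vesicle and carry-over proteins
respectively concentrate; the report gives the share of mapped
detected proteins in each region but deliberately issues no good/poor
verdict — the interpretation is qualitative and left to the analyst (a
threshold hook exists, default off).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| cutoff | 3.0 (unitless ratio) | minimum Elute/W-2 enrichment; inclusive |
| cutoff policy | `fixed` | alternatives: `min_control` (smallest carboxylase ratio), `total` (aggregate-abundance ratio) |
| n_bins / scheme | 5, `quantile-log10` | display binning of abundances or ratios |
| k_sigma | 2.0 | region-ellipse radius in standard deviations; covers the bulk of a Gaussian cluster |
| duplicate_policy | `error` | `max`/`sum` aggregate repeated accessions |
| isoform collapse | on | `Q96NT5-2` keyed as `Q96NT5`, matching map keying |

Missing values: blank, NA and zero abundances are all "not quantified
in this fraction". Label-free zero intensities almost always mean not
detected, and the ratio logic presumes detection. Detection is defined
per fraction (non-missing abundance in that fraction), which is also
the denominator convention for per-group mapping percentages.

## Numerical choices

- **Binning.** Values are log10-transformed, then split at interior
  quantile edges. Edges are *lower order statistics*
  (`np.quantile(..., method="lower")`), not interpolated quantiles:
  interpolated edges differ between implementations at the last ulp,
  which would make the tie rule ambiguous. With exact data values as
  edges, "ties at an edge go to the lower bin" is well defined
  bit-for-bit, binning is monotone by construction, and an all-equal
  input collapses to bin 1. Equal-width log-range binning is available
  as an alternative scheme.
- **Region ellipses.** Center = member coordinate mean; covariance =
  sample covariance scaled by k². Identical member points give a
  zero-covariance ellipse with a warning rather than an error, so
  collapsed synthetic clusters remain drawable. Fewer than three
  members is an error. How the published figures' ellipses were
  parameterized is not stated anywhere we know of; this deterministic
  rule is the package's own.
- **Compartment vocabulary.** Closed set of 13 labels. Input spellings
  are mapped through an explicit alias table (`ER` → `endoplasmic
  reticulum`, ...); anything unmatched is an error, never fuzzy-matched,
  so tallies are reproducible.
- **Determinism.** All generators run on `numpy` `SeedSequence` streams
  keyed by (seed, CRC32 of a stream name); SVG output is rendered with
  a fixed hash salt and stripped date metadata, so identical inputs
  give byte-identical files.

## The synthetic-data generators

The package is developed and tested entirely against synthetic data
with known ground truth.

- **Reference map**: twelve labeled compartments as isotropic Gaussian
  clusters on a circle (150 proteins each, spread 2.5) plus a broad
  central "unknown" cloud (600 proteins, spread 12) — the qualitative
  geometry of published organellar t-SNE maps at roughly half their
  protein count, a size at which every compartment statistic is stable
  while the whole suite runs in seconds. The carboxylase controls are
  planted at their physiological locations (three mitochondrial; ACC1
  cytosolic).
- **Proximity labeling**: 400 background proteins and 60 planted
  interactors from the bait compartment (plasma membrane, matching a
  membrane-transporter bait), with W-2-level base abundances log-normal
  (mean 10^7, sd 0.6 log10) and every measurement multiplied by
  independent log-normal noise of sigma 0.2 log10 units — a typical
  label-free intensity CV. Interactors are enriched 10x in the test
  group's eluate; background 1x; carboxylases at configured ratios
  (defaults 2.1, 10, 30, 68.8, spanning the range a real bait-group
  selection shows). Under these conditions the elute/wash ratio of an
  interactor is log-normal around 10 with sd 0.2·√2 log10, so a 3x
  cutoff recovers ≈97% of interactors while ≈5% of background passes —
  the property the acceptance suite asserts at ≥90%/≤10%.
- **EV preparations**: a 561-entry marker list with category sizes
  110/55/195/41/160 drawn from biologically consistent compartments,
  and two preparations: A detects marker-region proteins at p=0.8 and
  contaminant-region proteins at p=0.15; B's contaminant detection
  scales with `contamination_level` (zero at level 0). Each
  preparation also detects 300 proteins with no map coordinates, so
  mapped fractions sit realistically below 100%.

What the generators do **not** emulate: peptide-level inference,
shared-peptide ambiguity, intensity-dependent missingness (dropout
exists but defaults off so presence/absence logic is tested
explicitly), correlated noise between fractions, multi-localizing
proteins, and the irregular, anisotropic cluster shapes of real
embeddings. Passing tests therefore demonstrate the correctness of the
statistics and the recoverability of planted structure under the
stated noise model — not performance on real instrument data.

## Known limitations

- Accession matching is by protein identity only (with isoform
  collapse); no gene-symbol fallback, by design — silent mis-mapping is
  worse than a smaller join.
- No between-fraction normalization is applied before ratioing; if
  loading differs grossly between fractions the cutoff absorbs it only
  partially.
- Compartment tallies count each protein once at its single map
  assignment; multi-compartment residency is invisible.
- The map reflects resting-state localization; interventions that
  relocalize proteins are not represented.
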
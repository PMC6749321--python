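# Methods

## Reference library

The packaged compound library (`data/compounds.csv`, 82 records) is a
transcription of a published HS-SPME/GC–qMS identification table for
Madeira wines on a polyethylene-glycol (BP-20) column. Each record carries:

* `rt_min`, `ki_calc` — retention time and the Kovats index calculated from
  a C8–C20 alkane series on the experimental column;
* `ki_lit` — the literature Kovats index for an equivalent column (missing
  for one compound);
* `evidence` — MS (spectral match), RI (retention-index agreement), Std
  (confirmed against an authentic standard);
* `ot_ug_per_L` — odor threshold determined in 10–12% v/v ethanol. The
  18–19% ethanol of fortified wines shifts perception thresholds; no matrix
  correction is applied, a documented limitation of threshold screening in
  this matrix;
* `descriptors` — normalised odor-descriptor tokens; `aroma_notes` — the
  subset flagged in the source as Madeira aroma notes; `common_to_all` —
  whether the compound was detected in every study wine.

Missing thresholds and literature indices are explicit nulls, never zero.
The file is frozen with a sha256 checksum verified on load. The flagged
aroma-note vocabulary contains 14 tokens; the panel's sensory table uses a
larger vocabulary (mushroom, tea, cocoa, ripe fruit have no known carrier
compound in the library), so note counts are reported, not asserted.

Descriptor normalisation applies a synonym map (toasty→toast,
flower→floral, fruity→fruit, woody→wood, spicy→spice). The collective note
"dried fruits" expands to {almond, coconut, nutty, peanut, walnut}; the
grouping map is a configurable argument of every operation that consumes
notes.

One known source discrepancy: the impact-odorant discussion names α-pinene
among citrus odorants while the identification table lists β-pinene; the
library records β-pinene as transcribed.

## Wine-type classification

Residual sugar (g/L) maps to type via half-open classes
dry [49.1, 64.8), medium dry [64.8, 80.4), medium sweet [80.4, 96.1),
sweet [96.1, 150]; the published ranges reuse boundary values in adjacent
classes, so each boundary belongs to the upper class and the top class is
closed. Sugar outside [49.1, 150] returns an out-of-range flag (None), and
negative sugar is an error. Age classes are young = 3–5 y and old = 10–20 y
per the sensory table's headers; ages 6–9 y are rejected as unclassifiable.

## Kovats identification

`compute_ki` implements the van den Dool–Kratz interpolation; it is exact
at anchors, strictly increasing, and refuses retention times outside the
ladder span unless linear extrapolation is explicitly enabled.

Acceptance of a peak requires every applicable rule:

* spectral resemblance ≥ 80% when a library-search candidate accompanies
  the peak (a failing candidate rejects the peak outright — it is a known
  non-match);
* |KI_calc − KI_lit| ≤ 35 and ≤ 5% of KI_lit when the matched compound has
  a literature index. Defaults reflect the observed agreement of the
  transcribed table, whose |ΔKI| spans 0–28 (max 1.61% relative); 35 is an
  upper bound, not an observed maximum.

Peaks without a spectral candidate may be identified from the retention
index alone and are flagged as the lower RI-only evidence tier, mirroring
the "MS, RI" vs "MS, RI, Std" distinction of the source table. Each library
compound is assigned to at most one peak — smallest |ΔKI|, then largest
area, then earliest retention time; the ordering is deterministic and the
tie-break is fixed by convention (the source is silent).

## Semi-quantification

c = (area / IS area) × 250 µg/L, linear through the origin, with the
internal standard 4-methyl-2-pentanol. A missing or zero-area IS peak is a
hard error because nothing downstream is defined without it. Replicate RSD
uses the sample (n−1) standard deviation; zero-mean compounds are flagged
undefined. Family aggregates sum member compounds' mean concentrations per
age class (means, not medians, across replicates — the convention chosen
where the source does not state one), and the old-vs-young trend is called
increase/decrease beyond a ±10% relative band, flat inside it.

## Odor-activity screening

OAV = c / OT with *strict* exceedance (c > OT) defining a potential impact
odorant; equality at the threshold is not impact. Compounds without an OT
yield undefined OAVs and enter impact tables only under
`include_unknown_ot`. The note → wines → odorants table intersects, per
note, the library compounds flagged with the note and the compounds
impact-flagged in samples of the varieties/age classes whose sensory
profile reports the note. Because the source merges evidence across
varieties in an unstated way, both conventions are exposed:
`merge_varieties=True` (default) pools evidence over reporting varieties;
`False` requires impact in every reporting variety.

## Aroma networks

The bipartite graph has one edge per (compound, flagged note). Projections
weight edges by exhaustive shared-neighbor counts; zero-weight edges are
omitted. Variety projections take, per variety, the union of its notes'
neighborhoods (collective notes expanded first; panel notes with no carrier
compound contribute nothing rather than erroring, so a variety described
only by such notes becomes an isolated node). Projections can optionally be
restricted to an impact-flagged compound subset via `build_bipartite`'s
`restrict_to`; the default uses all 82 compounds. Exports are GraphML and
weighted edge-list CSV; no layout or community detection is attempted.

## Synthetic study generator

The generator emulates the study design — 22 monovarietal wines (Malvasia
sweet, Bual medium sweet, Sercial dry, Verdelho medium dry across four ages
each; Tinta Negra in all four types), ages drawn from
{3, 5, 10, 15, 17, 18, 19, 20}, three replicate peak tables per wine — at
the peak-table level only. No chromatograms, mass spectra or co-elution are
simulated, and resemblance percentages are drawn, not computed.

**Alkane ladder.** Anchor retention times at KI = 100·n are interpolated
through the library's published (KI, rt) pairs, extended to C8–C28 (a
deliberate superset of the experimental C8–C20 series: several library
compounds elute past KI 2000, up to 2620). Each compound's synthetic
retention time is the exact inverse of the Kovats interpolation at its
published KI, so computing the index back is exact by construction. The
published (KI, rt) pairs are themselves not piecewise-linear between alkane
anchors (real temperature programs are not), so synthetic retention times
track, but do not equal, the published ones; the published *elution order*
is preserved exactly.

**True concentrations.** Levels are anchored to odor thresholds so the
impact screen is exercised on both sides. Each compound with an OT gets an
exceedance profile realising the source's note-by-note conclusions:

* above-OT in young wines only — the varietal/fermentative odorants of
  young wines (monoterpenes, norisoprenoids, fruity esters, hexanol);
* above-OT in old wines only — oak/Maillard products
  (γ-octalactone, γ-decalactone, (Z)-whiskylactone,
  5-ethoxymethyl-2-furfural, eugenol, vanillin);
* always above — ethyl butanoate, hexyl acetate, 2-phenylethyl alcohol;
* never above — everything else with an OT, notably the high-threshold
  furfurals, butyrolactone and the acetals.

Class factors (young, old) are (2.5, 0.4)×OT for young-only, mirrored for
old-only, (3.0, 1.5)/(1.5, 3.0) for always-above and (0.4, 0.15) bands for
never-above; compounds without an OT use a family-typical µg/L scale.
A small (±8%) within-class age slope in the family's direction keeps
aging monotone inside a class without crossing any threshold band. Family
direction signs are −1 for terpenic, norisoprenoid, higher-alcohol, sulphur
and ester families (freshness lost with age), +1 for furanic, lactone,
acetal and volatile-phenol families (Maillard/oak products), 0 for acids.
Ethyl pyruvate, which has no OT, uses the reported varietal means: 3.54
µg/L in Verdelho vs 1.49 µg/L elsewhere.

**Peak synthesis.** Areas invert the IS formula,
area = c/250 × 10⁶ × (1 + ε), ε ~ N(0, cv) — multiplicative because areas
are positive and dispersion is reported as CV; negative draws truncate to
zero and are recorded. Default cv = 0.05, the magnitude typical of
replicate HS-SPME precision. Retention jitter defaults to 0.01 min under
noise and exactly 0 when cv = 0, so the zero-noise pipeline is an exact
identity. True peaks carry their compound as candidate with resemblance
drawn uniformly in [85, 99]%; optional decoys carry a real candidate with
resemblance in [40, 79.4]%, below the 80% gate. Randomness uses one
`numpy` Generator per sample seeded by (study seed, crc32(sample id)), so
any sample regenerates independently and runs are reproducible
cross-platform.

**What the generator does not emulate.** All 82 compounds appear in every
sample (the real study detected 76–82 per wine); response factors are
implicitly 1, so semi-quantification recovers truth exactly rather than
proportionally; thresholds are not matrix-corrected; and truth magnitudes
are synthetic constructions, not the study's unpublished values. Passing
tests therefore demonstrate correctness of the algorithms and the internal
consistency of the pipeline, not reproduction of the original sample-level
concentrations.

## Numerical and testing choices

Zero-noise recovery is asserted at relative 1e-12; floats round-trip
through files via `repr`. The RSD calibration check (median per-compound
RSD within [0.7c, 1.3c] of the generating cv at n = 3 replicates × 82
compounds) allows for the ~0.89 small-sample bias of the n = 3 standard
deviation. Projection weights are validated against exhaustive brute-force
intersections for every pair; the Kovats interpolation is validated against
an independent bracket-and-search oracle on randomly generated ladders.
Test problem sizes (22 wines × 3 replicates, 100 random ladders × 10 probes)
keep the whole suite in a few seconds while exercising every compound and
every note pair exhaustively.
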
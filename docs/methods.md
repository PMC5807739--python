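# Methods

## Segmentation model

Domain annotations are intervals (1-based, inclusive) on protein sequences.
Per protein, overlapping annotations are merged into maximal disjoint
intervals with pooled names; two annotations merge when the later one starts
at or before the current end. Merging is the only defensible treatment here:
counting a residue once per overlapping annotation would break the partition
property below. Abutting intervals (`next.start == current.end + 1`) are kept
distinct — merging them would change nothing measurable in composition, since
the gap between them has length zero and yields no linker either way.

A linker is the run of positions strictly between two consecutive merged
intervals (length ≥ 1). Terminal tails — before the first domain and after
the last — belong to neither class, following the definition of a linker as
sequence flanked by two domains. Proteins without any annotation are excluded
from the domain/linker analysis but retained for whole-proteome composition.
This yields the invariant used throughout testing: domain residues + linker
residues + tail residues = protein length, with every position labelled at
most once.

## Composition convention

Residues are pooled across all proteins (or all matching segments) of a
species before percentages are taken; per-protein percentages are never
averaged. Pooling is the standard proteome-composition convention and is
robust to protein length variation, at the cost of letting long proteins
dominate — acceptable because the questions asked are about residue mass, not
protein counts. The ambiguity letters B, J, O, U, X, Z are accepted by the
parsers (so reading never alters data) but excluded from both numerator and
denominator at counting time; the 20 standard percentages of any non-empty
profile therefore sum to exactly 100. A profile with zero counted residues is
flagged empty rather than given percentages.

## Selection and the enrichment statistics

A query selects dictionary entries either by exact name or by
case-insensitive, unanchored regular-expression search over both the name and
the description. A domain segment belongs to the selection when its pooled
names intersect the matched set; a linker belongs when **at least one** of its
two flanking intervals does. Requiring both flanks would discard most linkers
around isolated selected domains, defeating the purpose of the surrounding-
linker analysis.

For each amino acid, species where the selected feature profile is empty are
dropped from feature and background alike, so the means `f` (feature) and `b`
(background) always average over the same species set. The statistics:

* **Direction of enrichment** — fraction of species with feature percentage
  strictly greater than background. Ties count as *not* enriched ("more
  present" reads as strict). Range [0, 1].
* **Mean fold deviation** — `|f/b − 1|`. Zero iff `f = b`; invariant to
  rescaling `f` and `b` by a common factor. Its direction is the direction of
  enrichment: above 0.5 the feature is called enriched, below 0.5 the
  background, exactly 0.5 is reported as a tie rather than forced to a side.
  `b = 0` makes the ratio undefined; the standalone function raises, naming
  the amino acid. Inside the full pipeline `b = 0` implies the amino acid is
  absent from the entire background and hence (features being subsets of
  their background) from the feature too, so the table reports 0 with a tie
  sign and a log line instead of aborting a 40-row report over a degenerate
  letter.
* **Mean abundance** — `f` itself, with no background contrast.
* **Dispersion** — sum of squared Euclidean distances of per-species points
  to their centroid, equal to n × the summed population variance of the
  coordinates. The per-species values form 2-D points (background %,
  feature %); because squared Euclidean distance separates over coordinates,
  the 2-D cloud dispersion is exactly the sum of the 1-D dispersion of the
  feature values and that of the background values. The table reports the two
  1-D components separately — they answer different questions (is the family
  variable across species? is the background?) and their sum recovers the
  2-D value. This geometry is recorded in the run metadata.

**Match-count warning.** Per species, the number of matched segments (domain
instances, or surrounding linkers — instances, not distinct names, because
the warning is about sample size) is coloured green when above ten, red when
above five but at most ten, yellow otherwise. The verbal rule "more than ten
… less than ten but more than five" leaves exactly ten unassigned; ten takes
the conservative red.

## Synthetic data generator

The generator emulates the structural skeleton that the analysis relies on:
proteins as alternating blocks tail–domain–linker–…–domain–tail, with block
lengths uniform on [40, 120] residues, tails and domain-free proteins drawn
from background residue frequencies (Swiss-Prot-like averages), linkers from
a mildly polar-biased distribution (+30% proline, +20% glutamine, echoing
real linkers), and each domain block from its family's distribution.
Domain-free proteins (rate 0.08) and single-domain proteins (rate 0.12)
exercise the discard and no-linker paths; all other proteins carry at least
two domains so linkers always exist.

Planting is exact on the biased letters: an amino acid with relative
enrichment ρ has frequency `background × (1 + ρ)` in the family distribution,
with the unbiased letters rescaled to keep the vector a distribution. The
planted effect is then analytically recoverable: if the family holds a share
`s` of all domain residues, the expected mean fold deviation of the planted
amino acid is `ρ(1 − s)/(1 + sρ)` — the background itself contains the
enriched family, which dilutes the contrast exactly as a real selected family
dilutes its own background.

The reference study (`default_study_spec`) uses five species of 500 proteins
each: one DNA-binding family with arginine at ρ = 0.5, held to a small rate
(0.45 expected blocks per multi-domain protein, ≈ 7% of domain residues, ≈
15,000 family residues per species) against one large unbiased family
(rate 5.95). These sizes keep the planted family a minor background
component, as a single functional family is in a real proteome-wide
annotation set, while giving enough residues that sampling noise on the fold
deviation is below ±0.02 and the direction of enrichment is 1.0 with margin.
Expected recovery at these settings: 0.5 × 0.93 / 1.035 ≈ 0.45.

What the generator does **not** emulate: real domain length distributions,
sequence correlations and repeats, phylogenetic covariance between species,
annotation errors, or genuine SMART domain models. Passing the recovery tests
therefore shows the statistics measure what they claim on data with a known
ground truth — not that any particular biological enrichment is real.

A single integer seed drives one `numpy` Generator; the draw order is fixed
(per species: all structure draws, then one bulk residue draw per
distribution in sorted key order), so identical seeds give byte-identical
FASTA/TSV outputs. The hand-written worked example (two species, five
annotated proteins) covers every structural case — homopolymeric blocks with
known percentages, an all-twenty-letter protein guaranteeing non-zero
backgrounds, a single-domain protein, unannotated proteins — and a dictionary
whose descriptions match the query `DNA-binding|DNA binding`.

## Numerical and interface choices

* Percentages and statistics are plain double arithmetic; no tolerance
  tricks. Profile normalisation is exact to the 1e-9 assertion used in tests.
* Output tables are TSV with fixed column order, rows sorted by schema key
  columns, floats at 6 significant digits — repeated runs are byte-identical,
  enabling golden-file comparisons.
* Strict input validation is the default; `--lenient` drops annotation rows
  referencing unknown proteins with a logged count, since real annotation
  dumps contain orphans.
* The fold classes of the linker-vs-domain dots use strict inequalities
  (> 2×); dots exactly on a guide line are classed `between`.
* Plot rendering is isolated and failure-tolerant: a plotting error degrades
  to a warning, never a failed run.

## Limitations

* Unannotated domains are invisible: residues of real but unannotated domains
  are counted as tails or linkers, exactly as in any annotation-dependent
  analysis.
* The statistics are descriptive; no significance testing is attempted, and
  dispersion is an unnormalised sum (it grows with species count).
* Whether historical analyses of this kind merged overlapping annotations,
  used pooled or per-protein percentages, or measured dispersion in one or
  two dimensions is not always documented; the choices above are fixed,
  stated in the run metadata, and tested, but they are choices.
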
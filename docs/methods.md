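# Methods

## Orthology assignment

Each source gene is compared to every target protein by Needleman–Wunsch
global alignment (Biopython `PairwiseAligner`; BLOSUM62, gap open −11,
extend −1). Two derived quantities drive the decisions:

* **Homology score** `s(a,b) = S(a,b) / S(m,m)` where `S` is the raw
  alignment score and `m` the shorter of the two sequences, clipped to
  [0, 1]. It is symmetric, equals 1 for self-alignment, and is monotone in
  similarity, so one cutoff (default **0.20**) is reusable across
  sequence lengths. A best score ≤ 0 is treated as "no ortholog
  detectable".
* **Percent identity** = identical residue pairs / aligned columns
  between the first and last column where both rows carry a residue
  (terminal gaps excluded, internal gaps counted in the denominator).

The best-scoring target is the candidate ortholog; exact score ties break
toward the lexicographically smaller identifier and are flagged
ambiguous. The target's own best match in the source proteome must map
back to the query (reverse confirmation). Four discard rules run in fixed
order — no ortholog, reverse mismatch, multi-source ambiguity, low
score — and a gene keeps the first reason that fires. With deterministic
single-best reverse matching, two sources can survive the reverse check
while claiming the same target only in contrived circumstances, so the
doubles rule is exposed as a separately testable step
(`apply_discard_rules`); with database-backed scores (where forward and
reverse rankings need not be consistent) it does real work, which is why
it is kept.

The identity summary counts accepted genes with identity **strictly
above** the threshold (default 40%) and reports the share rounded to the
nearest percent, plus per-functional-class mean identity when annotations
are supplied.

## Field rendering (synthetic data)

A field is two co-registered float grids. Nuclei are antialiased discs
(radius ~ N(6, 0.8) px truncated at ±2 sd, amplitude 2000) placed by
rejection sampling with centers ≥ one diameter apart and away from the
border; placement failure raises rather than silently overlapping. Every
cell carries a diffuse GFP disc (2.2× nucleus radius, amplitude 300);
`round(n_cells × aggregate_fraction)` cells get one bright aggregate
(radius ~ N(2.5, 0.4) px truncated at ±2 sd, amplitude = contrast × 300,
contrast ≥ 3, default 5) placed just outside the nucleus and kept ≥ ~8 px
from other aggregates so the planted count stays operationally countable.
Both channels are blurred by a Gaussian PSF (σ = 1 px) and receive
background 100 plus Gaussian noise (σ = 5). The radius truncation keeps
every object resolvable relative to the PSF; without it, rare ~3 sd draws
produce sub-resolution aggregates that no intensity-based detector can
separate from diffuse-signal fluctuations.

What the renderer does **not** model: real chromatin texture, partial
transfection (every cell expresses the reporter), intensity gradients,
edge effects, multiple aggregates per cell, and aggregate–nucleus
occlusion. A green count-recovery test therefore establishes that the
quantifier inverts this renderer's forward model at high SNR — not that
it matches a particular microscope.

## Quantification

Nuclei: Gaussian smoothing (σ = 1), Otsu threshold, hole filling,
distance-transform watershed seeded at local maxima ≥ 5 px apart, area
filter 20–2000 px². The Otsu foreground is rejected wholesale when the
foreground/background mean gap is below 3 background-sd — this keeps
pure-noise fields at zero objects, where a raw Otsu split would
hallucinate blobs. A constant image is flagged "blank" and counted 0.
Empirically the watershed separates equal-size overlapping nuclei down to
~10 px center distance (radius 6); below that the additive overlap lens
dominates and the fused blob is convex.

Aggregates: white top-hat with a radius-6 disc (larger than any
aggregate, smaller than a cell) isolates compact spots; spots must exceed
1.6× the estimated diffuse-GFP amplitude (median foreground minus median
background) and pass a 2–300 px² area filter; blobs containing several
maxima ≥ 3 px apart are split on those maxima. The 1.6 factor sits in the
measured gap between the strongest diffuse-edge top-hat response (~1.35×)
and the weakest true-aggregate response (~1.9×) under default rendering.
All thresholds are relative to image statistics, so counts are invariant
under positive intensity rescaling.

Per well: `pct = 100 × aggregates / nuclei` per field; fields with zero
nuclei are undefined and excluded from the arithmetic mean (not treated
as 0%); a deviation from the expected 5 fields is recorded as a warning,
not an error.

## Screen simulation and noise model

Raw well values are `baseline_pct × effect × ε` with `baseline_pct = 8%`
(a realistic puncta-positive fraction under scrambled control),
`ε ~ lognormal` with unit mean and configurable CV (default 0.15 —
typical well-to-well variability for imaging readouts). The noise is
multiplicative because aggregation fractions are positive and
right-skewed. Suppressor genes draw per-construct effects from
N(2.2, 0.25) truncated at ≥ 1 (constructs of a real suppressor differ in
knockdown efficiency); null genes have effect exactly 1. Each experiment
(one round-1 pass, three confirmation repeats by default) carries 2 SCR
wells, one GFP control (effect 0.5) and one CCT2 control (effect 2.0);
experiments whose simulated controls land on the wrong side of the QC
bounds are redrawn, mirroring the practice of repeating failed
experiments.

## Selection cascade

* Normalization: `norm = 100 × raw / mean(raw SCR)` strictly within
  experiment; mean normalized SCR is exactly 100 by construction.
* QC bounds: GFP ≤ 80%, CCT2 ≥ 120% of SCR. These two numbers are this
  package's defaults — the screen design states only "reduction" and
  "induction" — and are configurable.
* Round-1 cutoff ≥ 150% **inclusive** (the procedural "at least 150%"
  reading wins over the results-prose ">150%").
* Advancement: ≥ 2 round-1-positive constructs; all constructs of an
  advanced gene enter confirmation, including round-1 negatives.
* Confirmation: per-construct arithmetic mean over exactly 3 confirmation
  values (round-1 values never enter the average); constructs lacking the
  full triplet make the gene "incomplete" and uncallable rather than
  silently callable on fewer repeats.
* Final hit: advanced, complete, and ≥ 2 confirmed constructs. Genes with
  a single designed construct are structurally ineligible. Constructs
  that *reduce* aggregation are carried through all tables but no reducer
  hit class is defined.

## Numerical and degenerate-input choices

Ties in best-match scores break lexicographically (determinism over
arbitrariness). SCR mean ≤ 0 or all-blank SCR wells abort normalization
with an explicit error. Zero-cell fields, blank images, empty candidate
sets, and empty report inputs all return typed empty results rather than
raising. All generators are `numpy.random.default_rng`-seeded;
fixed config + seed reproduces byte-identical files.

## Known limitations

* The homology score is a self-contained alignment statistic; absolute
  values are not comparable to database-specific similarity scores, only
  the [0, 1] scale and the 0.20 cutoff semantics carry over.
* The quantifier assigns no aggregate to a specific cell; a field's
  percentage can exceed 100 if aggregates outnumber nuclei.
* Sensitivity/specificity figures from the simulated screen describe the
  stated noise world (lognormal, CV 0.15, effect 2.2×); real screens add
  transfection-efficiency and batch structure that the generator does not
  model.
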
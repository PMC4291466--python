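# Methods

`startshift` analyzes two kinds of measurements made on budding-yeast
transcription mutants: transcription start site (TSS) usage at a single
multi-start promoter, read out by primer extension, and semi-quantitative
growth of single and double mutants on a panel of media.  It quantifies TSS
usage shifts, normalizes growth scores into heatmap-ready matrices, and calls
double-mutant genetic interactions against explicit null models.  A
synthetic-data generator with planted ground truth makes every stage testable
without gel or plate data.

## TSS quantification

A primer-extension lane is a map from promoter position (integers on a
promoter-local axis increasing downstream) to non-negative band intensity.
Quantification proceeds in three steps:

1. **Binning.** Positions are partitioned into `K` contiguous closed-open
   intervals `[start, end)`, numbered 1 (most upstream) to `K` (most
   downstream); `K = 6` is the canonical scheme and other values are flagged.
   Bin sums preserve the lane total exactly.  Bin boundaries are
   configuration input: they depend on the promoter under study and are not a
   property of the method.
2. **Normalization.** Bin sums are divided by the lane total, giving usage
   fractions that sum to 1.
3. **Replicate aggregation.** Per-replicate fractions are averaged bin-wise
   and renormalized; per-bin sample standard deviations (ddof = 1) accompany
   the mean.  Averaging per-determination quantifications (rather than
   pooling raw intensities) keeps each determination equally weighted
   regardless of exposure.  Fewer than three determinations triggers a
   low-replicate warning and flag.

A mutant's defect is the per-bin difference to the reference (wild-type)
distribution, `delta_b = f_mut,b - f_ref,b`, which sums to zero.  The
profile is summarized by a signed **shift index**

    index = sum_b delta_b * (b - (K + 1) / 2),

the centered-rank-weighted sum of the deltas.  Negative values mean usage
moved upstream, positive downstream; negating a profile negates the index.
The index is classified as `upstream` / `downstream` / `none` against a
tolerance with strict inequalities.  By default the tolerance is twice the
standard error of the index propagated from the replicate standard deviations
of both strains (`se_b = sqrt(sd_mut^2/n_mut + sd_ref^2/n_ref)`, combined
through the rank weights); when either side lacks replication it falls back
to 0.05 in absolute index units — roughly the index produced by moving 1% of
usage across half the bin range.

## Growth-score normalization

Growth on each medium is scored 0–5.  On general media and the MPA medium,
5 is wild-type-like growth; on the reporter media (galactose resistance,
Spt⁻ lysine prototrophy) 0 is wild-type and 5 the strongest mutant phenotype.
Three media classes are normalized differently:

* general (`YPD`, `YPD37`, `YPRaf`, `SC-Leu`): `mutant − WT`, same plate;
* MPA (`SC-Leu+MPA`, control `SC-Leu`): the general-media difference on the
  MPA plate minus the difference on the control plate — net growth change
  attributable to MPA;
* reporter (`YPRafGal` control `YPD`; `SC-Lys` control `SC-Leu`):
  `reporter / (WT_control / mutant_control)`, discounting reporter signal by
  the mutant's underlying growth defect.

Scores are integers; normalized values are reals and are not re-rounded.
Two degenerate cases are handled explicitly.  A mutant control score of 0
makes the reporter divisor undefined; the cell becomes `MISSING` rather than
an infinity so the matrix stays renderable.  The net-MPA formula cannot
report sensitivity below a mutant's zero-growth floor: when the mutant's MPA
score is 0 the net value understates true sensitivity, so such cells carry a
machine-readable zero-growth caveat while the formula's value is still
reported.  Inviable double mutants carry an `INVIABLE` marker that supports
no arithmetic — any attempt to use it in a numeric expression raises — and
propagates to every derived cell.  The reference for every medium, including
`YPD37`, is the same-plate wild-type score.  Heatmaps use a diverging
blue-white-red map, symmetric about zero, with `INVIABLE` dark gray and
`MISSING` hatched light gray.

## Interaction calling

For a genotype triple (single A, single B, double AB), two null models are
evaluated.

**TSS — additive null.** The expected double profile change is
`deltaA + deltaB` (equivalently, expected fractions `ref + deltaA + deltaB`,
clipped at zero and renormalized when the sum leaves the simplex; the clipped
mass is reported).  The observed `deltaAB` is compared by Euclidean distance
to three candidates: the additive sum, A's profile, and B's profile.  The
nearest candidate within tolerance names the category (`additive`,
`epistatic_to_A`, `epistatic_to_B`); nothing within tolerance is `other`.
Exact ties resolve to `additive`, the weakest claim.  The default tolerance
is twice the pooled standard error of the three profiles when replicate SDs
exist, else 0.15.  A polarity annotation follows the singles' directions:
opposite-direction singles whose double shifts less than the stronger single
are `mutually_suppressive`; same-direction singles whose double shifts more
than either are `exacerbating`; other sign patterns are `mixed`, and pairs
containing a no-shift single are `none`.

**Growth — multiplicative null.** Fitness is mapped linearly from scores,
`f = score / 5` (`INVIABLE` → 0 with a flag); the expectation is
`E = fA * fB`.  With tolerance `tau` (default 0.1, half a score unit):
an inviable double with `E > tau` is `synthetic_lethal`; `fAB < E − tau` is
`synthetic_sick`; `|fAB − E| ≤ tau` is `no_interaction`.  Above the
expectation, a double beating both singles by more than `tau` is
`suppression_mutual`; one matching a single within `tau` is `epistasis`;
the remainder is `suppression_directional`.  The boundary between
directional suppression and epistasis is not sharply determined by
plate-score data; output files flag the heuristic in their metadata.  Calls
are made per medium independently.

**Relationship classes.** Calls for one genetic interactor across a panel of
Pol II active-site alleles (A = Pol II allele, B = interactor; inviable
doubles contribute growth but no TSS evidence) are summarized as:

* **Class I** — the interactor shifts TSSs on its own and a strict majority
  of its TSS calls are additive (suppressive or exacerbating by polarity).
* **Class II** — the interactor shifts TSSs on its own and at least one
  triple is TSS-epistatic with a matching epistatic or enhancing
  (synthetic sick/lethal) growth call.
* **Class III** — the interactor has no TSS shift of its own, every viable
  double stays within tolerance of the Pol II single's profile
  (`d_A < tolerance`, judged on distances rather than the category so that
  the near-tie between the additive and epistatic nulls when `deltaB ≈ 0`
  cannot flip the outcome), and at least one growth call is non-trivial.

Panels matching none of the rules are `unclassified` with their evidence
listed.  The classes are operationalized as majority/threshold rules because
the underlying taxonomy is qualitative; the rules are deterministic given
the calls.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
planted ground truth:

* **Promoter.** Discrete start positions with base usage weights.  The
  default fixture has 8 positions over a 56-nt window with a unimodal
  profile — an explicitly synthetic multi-start promoter, not a
  reconstruction of any real gene's TSS coordinates (which are not available
  numerically).
* **Shift model.** A mutant tilts initiation probability across the
  already-usable sites: `w_i ∝ base_i * exp(theta * z_i)` with `z` the
  standardized position.  `theta < 0` shifts usage upstream, `> 0`
  downstream, 0 is the identity; the support never grows, matching the view
  that mutants redistribute usage polarly over a fixed repertoire of sites
  rather than creating new ones.  The sign convention makes `theta` and the
  shift index agree in sign.
* **Noise.** Band intensities are `total * p_i * exp(g_i) + background` with
  `g_i ~ N(0, sigma)`: multiplicative lognormal band noise (the standard
  model for densitometry intensities; defaults `sigma = 0.1`,
  `total = 10^4`, no background) — no gel-geometry artifacts (smiling,
  saturation) are simulated.  Replicates (default 3, the study's minimum)
  use child streams spawned deterministically from one seed.
* **Growth.** Each strain has per-medium fitness in [0, 1] (wild type 1 on
  general media); a double's fitness is `fA * fB * exp(epsilon)`, so
  `epsilon = 0` reproduces the multiplicative null exactly before rounding.
  Fitness maps to scores as `round(5 f)` (deterministic half-up rounding,
  clamped), making planted truth recoverable; visual scoring error can be
  emulated by an optional seeded ±1 jitter (default off).  A strain below
  fitness 0.05 on the permissive control medium is inviable.
* **Planted double mechanisms.** A double's usage can be specified as a tilt
  of its own, as the additive composition of its parents' usage changes
  (clip-and-renormalize, mirroring the analysis null), or as a copy of one
  parent (planted epistasis).  Composing tilts by summing `theta` is *not*
  additive in bin-fraction space at realistic shift strengths, which is why
  the generator plants mechanisms at the usage level.

What passing tests on these data do and do not show: they demonstrate that
the quantification is conservative and exact, that planted polarities and
mechanisms are recovered under calibrated noise, and that the classification
rules reproduce the intended taxonomy.  They do not validate gel
densitometry, visual plate scoring, or the biological assumptions (e.g. that
one promoter proxies global initiation behavior).

## Demo scenario and problem sizes

The shipped configuration (`startshift/data/demo_config.yaml`) plants a wild
type, an upstream-shifting and a downstream-shifting Pol II allele
(`theta = ∓0.6`), a graded family of GTF-like alleles (`theta = −1.5, −0.6,
0, +1.5`), and three interactors realizing the three relationship classes,
with growth interaction terms chosen to produce one synthetic-lethal, two
synthetic-sick, one epistatic, and several null growth calls.  Calibration
checks use 200 seeded runs per condition cell (1000 lanes for conservation
and oracle checks) — sizes at which the binomial uncertainty on a 90–95%
recovery rate is a few percent, chosen to keep the full suite under half a
minute.  All stochastic stages derive their streams from a single
configuration seed, so pipeline reruns are byte-identical on TSV outputs
(figures are excluded from the byte-identity contract).

## Known limitations

* The shift index collapses a six-bin profile to one number; bimodal
  redistribution can cancel to a near-zero index and be called `none`.
* Fitness from a 0–5 score is granular (0.2 steps); `tau` below 0.1 is not
  meaningful for score-derived fitness.
* The additive TSS null is compared in bin-delta space; strong same-direction
  pairs whose expectation leaves the simplex are clipped, which slightly
  biases `d_additive` upward.
* Relationship classes follow fixed majority rules; panels with single-pair
  evidence rest on one call.
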
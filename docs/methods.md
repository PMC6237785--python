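# Methods

## Coordinate and molecule model

All genomic intervals are 0-based, half-open. A nick is a single-strand
break at an integer *bond index* `i` (between bases `i-1` and `i`),
expressed in top-strand coordinates on both strands so that apposition of
opposite-strand nicks is a plain integer distance. A `Molecule` is a linear
duplex with sorted, unique nick indices per strand plus labeled tracts;
fragments of any operation partition the parent exactly, which the test
suite asserts as a hard invariant.

## Fragmentation operations

* **Shear / combing** breaks each nick independently with probability
  `p_break` (default 1.0: stretch-induced breakage on combed fibers is
  treated as complete).
* **S1 digestion** cleaves the intact strand exactly opposite every nick
  (no resection is modeled; enzyme nibbling is irrelevant at the ≥100 bp
  size scales analyzed).
* **Denaturation** splits each strand at its own nicks only.
* **Apposed melt** severs the duplex where opposite-strand nicks lie within
  `appose_window` bp of each other (default 25), breaking at the floored
  midpoint — any coordinate inside the window is indistinguishable at gel
  resolution. The 25 bp threshold is a constant, not a computed melting
  temperature, and is configurable.

A useful exact law replaces a tempting approximate one: since S1 cuts at
the union of both strands' nicks, S1-then-denature *refines* the
denature-alone partition of each strand. Fragment count can only rise, so
the **mean** ss size can only fall, with equality exactly when the two
strands carry identical nick sets. The analogous statement for the
**median** is false in general (small multisets admit counterexamples where
refinement raises the median); it does hold statistically at loop-size nick
densities, and both facts are tested — the mean law exhaustively over all
2^10 nick configurations of a 6 bp duplex against a brute-force splitter,
the median version on sparse megabase molecules.

Gel migration interpolates mobility linearly in log10(size) between
calibration points; bands within a mobility tolerance merge with summed
intensity (the 982/1029 bp rDNA fragments co-migrate at the defaults).
Contour length uses 3 bp/nm (display rounded to 0.1 μm; stored values are
full precision). Even-count medians are the mean of the central pair.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analyses consume,
not yeast sequence:

* 16 chromosomes by default, log-spaced 230 kb–1.53 Mb (≥5-fold span so the
  count-vs-length correlation is testable); genes placed uniformly without
  overlap, counts proportional to chromosome length; expression log-normal
  with median 10 RPKM and σ=1.2 (a realistic heavy tail with a defined
  median — only the spread matters downstream).
* Nicks: per chromosome, total count Poisson with mean
  `2·background_rate·L` (default rate 1/140 000 per bp per strand, i.e. one
  duplex-fragmenting nick per ~70 kb); each nick is placed with probability
  `promoter_fraction` (default 0.5) uniformly inside a ±500 bp TSS window of
  a gene sampled ∝ expression, else uniformly; strands i.i.d. 1/2.
  Expression-proportional gene sampling is the minimal coupling that makes
  nick-associated genes high-expression; the within-window law is uniform
  (a peaked-at-TSS law is plausible but unconstrained — flagged as an open
  choice).
* R-loops: Poisson per gene (rate 0.1), midpoints at the TTS ±500 bp with
  probability 0.9, 300 bp long. An exogenous nicking enzyme adds each of
  its recognition sites with probability 0.07.
* Tiled array signal: probes every 250 bp; expected log-ratio is elevated
  by 2.0 within 200 bp (the limiting-label reach) of a nick, plus Gaussian
  noise of sd 0.3.

Not modeled: real sacCer3 coordinates or sequence, chromatin state,
hybridization/dye biases, optics beyond a 1 kb resolution threshold, and
melting thermodynamics. Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated under its stated
assumptions — not that real arrays are free of normalization artefacts.

## rDNA unit map

The 9117 bp unit is registered on the SfiI site (coordinate 0). StuI sites
at 3983/6402/8088 give the 3983, 2419, 1686, 1029 bp fragments; PvuII sites
at 757/2818/5420 make the StuI+PvuII double digest contain 757, 2061, 1165,
982 and 1029 bp fragments (named a–g in map order); the two sub-fragments
not pinned by those sizes absorb the residual 3123 bp as 1437+1686, an
explicitly unconstrained, configurable split. Feature coordinates are
synthetic placeholders — only fragment membership is meaningful: C-PRO in
fragment a, ARS/IGS2 in b, E-PRO in c, RFB/IGS1 in d, the TAR1 promoter in
e. Weighted nick sites b–i load the three promoter fragments (weights
3/3+2/3 for a/c/e), leave fragment b at zero, and were placed by constraint
search so that every endogenous fragment size and every composite size
involving the default off-target incision site differ by ≥4% — twice the
2% band-matching tolerance — keeping band-origin classification exact for
any realization.

Arrays nick every unit independently (default fraction 0.1, "every ~10th
unit"); within a nicked unit one site is drawn from the weights, its strand
fixed by the map. Note the spacing consequence: inter-break distances are
geometric with mean 10 units = 91.2 kb but *median* ≈7 units ≈64 kb; the
~10-unit periodicity is a statement about the mean, and the acceptance
checks treat it as such.

Mutant strains with defective rDNA silencing are simulated by scaling the
per-unit nicking probability (a global scale of the normalized site-weight
distribution would be a no-op); `compare_strains` recovers the scale from
raw biotin/EBr ratios — max-normalized ratios would cancel it, so
normalization is applied only for display.

### Treatment-order logic

Digestion makes ds cuts at canonical sites and, for off-target-prone
enzymes, adds single-strand *nicks* at near-cognate sites with a per-unit
probability. Hence `[S1, digest]` and `[digest, S1]` commute exactly when
the off-target probability is zero (tested on 100 random arrays), and an
off-target incision produces extra bands only in the enzyme-first order. A
band in the enzyme-first table is classified *endogenous* if a band of
matching size (2% relative tolerance) appears in the S1-first table or
among the denaturing-gel ss bands, *off-target* if in neither. The
denaturing reference is generated with the artefact-free enzyme (SfiI),
mirroring the experimental practice of reserving a clean single-cutter for
denaturing runs; in this synthetic map the off-target-prone enzyme's
canonical site coincides with the unit registration point so sizes are
comparable across tables (real in-unit enzyme coordinates are not
constrained here).

## Statistics

* **Shuffle null**: randomized peak sets preserve the per-chromosome
  multiset of peak lengths (hard assertion in tests); placements are
  uniform and non-overlapping via rejection sampling with an iteration cap,
  with a fast exact path for 1-bp peaks. Fold change = observed overlap
  nucleotides / null mean; the p-value is a two-tailed pooled
  two-proportion z-test of the observed overlap proportion against the
  pooled null proportion over all permutations (the most conservative
  pairing; the pooled degenerate case p̂∈{0,1} returns p=1).
* **Profiles**: ±window binned means over anchors, strand-aware flipping,
  loess (= local linear regression with tricube weights, via statsmodels
  lowess, which reproduces exactly linear inputs to 1e-9).
* **Closest gene**: signed edge-to-edge distance, 0 on overlap, ties broken
  toward the smallest (5′-most) gene start — deterministic and matching
  common interval-tool behavior.
* **Expression resampling**: the nick-gene RPKM set is Mann–Whitney-tested
  (normal approximation, tie-corrected) against N same-size random samples
  from the pool; Benjamini–Hochberg is applied across resamples. At the
  genome-wide proportions used here (215 of 6664 genes) the nick set and a
  random sample share ~3% of genes and the null rejection rate is ~α; at
  much denser proportions the overlap makes the test conservative, which
  the calibration experiment would expose.

## Calibration experiments and problem sizes

The package's own evidence is computed, never asserted: type-I error of the
enrichment test is estimated on 500 two-chromosome 100 kb genomes with a
fixed 10%-coverage annotation and ~400 uniform nicks as 1-bp peaks, 60
permutations each (≈400 nicks keeps the normal approximation of the
proportion test accurate; the measured rate sits in [0.03, 0.07]).
Detection power uses 60 replicates of a ten-chromosome ~3.3 Mb genome with
600 genes, where ±500 bp TSS windows cover ~18% of the genome; under the
default TSS-enriched placement the test rejects with fold >2 in every
replicate. At the real yeast gene density TSS windows cover roughly half
the genome, capping the achievable fold near 1.6 — a useful reminder that
fold-change magnitudes are annotation-density-dependent even when
direction and significance are robust. Parameter recovery estimates the
per-strand nick rate as 1/mean of denatured fragment sizes on a 50 Mb
chromosome (~700 fragments, error well under 10%), and the ×0.5 mutant
scaling from 10 simulated rSW replicates per strain of 2000-unit arrays
with 99% bootstrap intervals (joint coverage over six bands). rDNA
periodicity pools 100 arrays of 150 units.

## Known limitations

* The apposition threshold is a fixed constant; sequence-dependent melting
  is out of scope.
* Off-target nicking is parameterized per enzyme at one site per unit by
  default; real enzymes have dispersed star activity.
* The combing detection floor (`min_detect_length`, default 5 kb) is a
  guess — the experimental floor is not quantified — and is configurable.
* The λ nickase fixture reproduces the six printed inter-site spacings from
  coordinate 0 (25 679 bp) and places the seventh site arbitrarily in the
  remaining 22 823 bp; only the fragment count and mean are constrained.
* Peak calling is a deliberately simple robust-z run-merger standing in
  for array-analysis suites; the statistics downstream, not the caller,
  are the object of study, and any caller satisfying the same interval
  contract can be substituted.
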
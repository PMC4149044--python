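# Methods

## Coordinates, sequences and counting conventions

All coordinates are 0-based half-open (BED convention); reports render
1-based inclusive. Sequences are uppercase over {A,C,G,T,N}; soft-masked
lowercase input is uppercased (no masking semantics are attached to
case). A CpG site is the position of the C in a forward-strand 5'-CG-3'
dinucleotide, counted once per dinucleotide — never once per strand — so
densities in CpG/100 bp have a ceiling of 50. Positions involving an N
never count as CpG; whole-interval density divides by the *effective
length* (interval length minus N count), and an interval that is more
than 50% N is reported as `masked` and never classified as a desert.
This avoids assembly gaps deflating density into the desert band.

## Density

Two density modes are provided because region-level summaries and
figure-style tracks answer different questions: `interval_cpg_density`
is the whole-interval count × 100 / effective length (the quantity the
desert definition bounds), and `sliding_density_profile` computes
per-window densities (default 100 bp windows, 50 bp step; trailing
partial windows are dropped). Desert classification uses the
whole-interval mode: the definition is stated per region, not per
window.

## CpG islands and small clusters

The desert definition requires "no CpG island" and "small CpG clusters
present" but neither concept has a universal parameterization, so both
are explicit and configurable:

* **Islands** use the Gardiner–Garden & Frommer convention: a 200 bp
  window qualifies when GC ≥ 0.50 and observed/expected CpG ≥ 0.60,
  where obs/exp = n_CpG·L/(n_C·n_G) (defined as 0 when n_C·n_G = 0).
  Overlapping qualifying windows (step 1) merge into maximal extents,
  and each merged extent is re-validated against all three thresholds
  (including length ≥ 200 bp) before being reported; extents failing
  re-validation are dropped. A stricter preset (≥ 500 bp, GC ≥ 0.55,
  obs/exp ≥ 0.65) is exported as `STRICT_ISLAND_PARAMS`.
* **Clusters** are maximal runs of ≥ 3 CpG sites with consecutive
  C-to-C gaps ≤ 30 bp, spanning first C to last G. Runs overlapping a
  detected island are excluded — a cluster is by definition CpG
  structure outside islands.

## Desert classification

`DesertParams` defaults encode the definition: length within
[500, 2000] bp, whole-interval density strictly below 15 CpG/100 bp
(a density of exactly 15.0 fails — the bound is read literally as
"<15"), at least one small cluster, and zero overlapping islands.
"At least one" cluster is used rather than "exactly one"; the plural
"clusters" in the definition sets no upper bound. Intervals outside the
length bounds are reported with reason `length` rather than trimmed —
no trimming rule exists to apply. Every criterion is evaluated without
short-circuiting so `reasons` is always the complete list of failures,
and `is_desert ⇔ reasons == ()`. The set-level summary reports the
fraction of deserts, the fraction of intervals below 10 CpG/100 bp (the
headline density claim), density min/median/max, and a 1-CpG/100 bp
histogram.

## DMR calling

Per probe the statistic is the median of all n_c × n_e pairwise
exposure-minus-control log-intensity differences (a Hodges–Lehmann-type
shift estimate: robust, and total for unbalanced designs); the
alternative "difference of group medians" is available via
`aggregate="group_median_difference"`. The medians are standardized by
the mean and SD (ddof = 1) taken over **all probes in the experiment**
— one scaling per experiment, with a per-chromosome option — and
converted to two-sided standard-normal p-values (two-sided because DMRs
can be hyper- or hypomethylated). A DMR is a maximal run of
design-adjacent probes on one chromosome, each with p < α (default
10⁻⁵) and, by default, an identical sign of the median difference
("same statistical difference" is read as same direction *and*
significance; `same_direction=False` gives the looser reading). Runs
shorter than 3 probes are discarded. Adjacency is array design order
regardless of genomic gap; `max_gap_bp` optionally breaks runs across
large gaps. The DMR interval is probe-bounded (first probe start to
last probe end) — conservative and reproducible, with no half-spacing
extension. No multiple-testing correction enters the calling (the
extreme α plus the 3-adjacent rule is the filter); a Benjamini–Hochberg
q-value column is emitted for context only.

### Statistical behavior worth knowing

Because σ̂ is estimated from all probes, the statistic is exactly
self-calibrating under the global null (empirical per-probe
false-positive rates match α; the test suite verifies this at α = 10⁻²
and 10⁻³ over 200 replicate null experiments and observes zero false
DMRs under the 3-adjacent rule at α = 10⁻⁵). The same property makes
power sensitive to the *fraction* of truly shifted probes: planted
effects inflate σ̂, and with ≳2% of probes carrying a 5σ shift the
planted z-scores drop below the 10⁻⁵ threshold. Simulated experiments
in the tests and the acceptance script therefore keep planted fractions
at or below 0.5% — comparable to a few hundred DMRs of ~5 probes on a
promoter array of tens to hundreds of thousands of probes. At δ = 5σ
with 3 vs 3 replicates the per-probe detection rate is ~0.91 (the null
SD of the median-of-pairwise statistic is ≈0.85σ, putting planted
probes near z ≈ 5.8 against the 4.42 two-sided threshold), so width-5
runs are recovered with sensitivity ≈0.9 and boundaries typically
within one probe spacing; recovery is not near-certain at this effect
size, and the recovery test asserts exactly these levels over 500
planted runs.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, plus exact truth records; they deliberately do not model MeDIP
pulldown chemistry, dye bias, spatial array artifacts, or
heteroscedastic probe noise, so passing tests demonstrate correctness
of the analysis logic under the stated model — not robustness to
real-array artifacts.

* **Genome background**: a first-order Markov chain whose C→G
  transition is pinned to hit a target genome-wide CpG obs/exp (default
  0.2, mimicking vertebrate CpG depletion) at a target GC fraction
  (default 0.42); the remaining transition rows are solved from the
  stationarity equation so the realized base composition matches the
  target exactly.
* **Planted islands**: segments from an island-parameterized chain
  (GC 0.70, P(G|C) = 0.5 ⇒ obs/exp ≈ 1.4), lengths 300–800 bp. These
  robustly pass the island detector's defaults.
* **Planted desert loci**: 500–2000 bp segments of CpG-free chain at
  GC 0.30 into which an exact number of CG dinucleotides is written:
  one or more tight clusters (default 3 sites, 12 bp gaps) plus
  stratified-scattered singles to reach a target density drawn from
  1–8 CpG/100 bp (the band where most transgenerational DMRs fall).
  Writing sites into a CpG-free background makes the realized density
  exact up to site-count rounding (well within ±1 CpG/100 bp). The
  desert GC of 0.30 keeps even the densest planted locus far from the
  50% GC island threshold, so planted truth is self-consistent with the
  island detector.
* **Probe experiments**: probes tile the chromosome at fixed spacing
  (default 100 bp start-to-start, 50 bp probes); control log-intensities
  are i.i.d. Normal(0, σ²) (σ = 0.25), exposure samples add
  direction·δ·σ on planted runs of ≥ 3 probes (narrower runs are
  rejected, citing the adjacency rule). Homoscedastic normal noise is
  the simplest model consistent with the normal-scaling statistic.
  `plan_runs_for_deserts` places one width-5 run inside each
  (grid-aligned) desert locus so called DMRs land inside planted
  deserts.
* **Exposure sets**: labelled interval sets with an exactly known Venn
  partition, built by disjoint-pair sharing — sets are paired and each
  pair shares `round(shared_fraction · min(pair sizes))` identical
  intervals, everything else disjoint. This keeps the truth partition
  trivially exact for any number of sets; it does not emulate
  higher-order sharing (triple-overlap cells are always empty by
  construction).

All generators are deterministic under a fixed seed.

## Problem sizes used by tests and the acceptance script

Oracle-equivalence checks run on 1,000 random sequences (≤ 2 kb) for
CpG counting and 200 sequences for island detection; planted-feature
recovery uses a 1 Mb genome with 20 deserts and 10 islands; caller
calibration uses 200 replicate null experiments of 10,000 probes;
recovery power uses 25 experiments of 200,000 probes with 20 planted
runs each; the end-to-end run uses a 5 Mb genome, 50 desert loci and
50,000 probes. These sizes give stable estimates (hundreds of planted
features, millions of null probes) while keeping the whole suite around
a minute of CPU.

## Known limitations

* Island/cluster parameterizations are field conventions, not measured
  properties of any particular dataset; conclusions about "no islands in
  DMRs" inherit the chosen thresholds.
* The Venn overlap rule defaults to ≥ 1 bp shared; a reciprocal-fraction
  option exists but there is no canonical value.
* The caller assumes exchangeable, homoscedastic probes; real arrays
  violate this (sequence-dependent affinity, spatial effects), and no
  normalization step is provided — input is assumed normalized.
* Called DMR extents are probe-bounded, so sparse designs understate
  the true region length (a width-5 run at 100 bp spacing spans 450 bp,
  below the desert definition's 500 bp bound; the classification table
  makes this visible via the `length` reason).
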
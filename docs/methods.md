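# Methods

This note records the models, conventions and numerical choices behind
`metcensus`, and what the synthetic-data based tests do and do not
demonstrate about real proteomes.

## Conventions

* **Initiator methionine.** Nearly every protein starts with Met for
  translation-initiation reasons, which says nothing about Met biology in
  the mature chain. For all spatial statistics the initiator (position 1,
  when it is Met) is removed from both the Met count m and the sequence
  length: a 957-residue protein with 43 Met is analysed as 956 residues /
  42 Met. Reported domain coordinates stay in canonical full-sequence
  1-based inclusive numbering (a domain at 65–121 spans 57 residues).
* **Dataset filter.** Sequences shorter than 100 residues are dropped on
  input. Ambiguity codes (X, U, B, Z, …) are retained in sequences but
  never counted as Met.
* **Membrane status** is an input accession list; the pipeline only
  partitions on it (membrane proteins have elevated Met for biophysical
  reasons and are excluded from the census background).

## Transect statistic and empirical null

The protein is divided into consecutive 50-residue segments; q is the
population SD over the mean of the per-segment Met counts. 50 residues is
matched to the ~2% average Met content: the expected count per segment is
then 1, and a Poisson count vector has CV ≈ 1. More generally the null CV
concentrates near 1/sqrt(λ) with λ = m·50/N — for Met-rich proteins
(λ > 1) the null centre drops below 1, which is exactly why each protein is
compared with **its own** null rather than a global threshold.

* **Tail rule.** When the length is not a multiple of 50, the default
  (`ceil`) keeps the final short segment; `merge` folds the remainder into
  the last full segment. Both dialects are implemented and
  `calibrate_tail_rule` adjudicates them against a reference protein with a
  published q (the O75400 calibration requires its canonical sequence,
  which must be supplied externally).
* **Null sampling.** Placing m ones uniformly without replacement into N
  slots partitioned into segments makes the segment counts multivariate
  hypergeometric over the segment sizes; the null is sampled directly from
  that law (exact, and orders of magnitude faster than explicit
  placement). A cross-check against explicit binary-vector placement is in
  the test suite. B = 10,000 replicates, α = 10⁻⁴.
* **Empirical p-values** use the plug-in estimator r/B, not (r+1)/(B+1):
  with B = 10⁴ the α = 10⁻⁴ verdict is only attainable as r = 0, i.e. the
  observed q must fall strictly outside the entire null sample. This is
  anti-conservative by construction and documented as such. Ties count
  toward both tails (≥ / ≤ inclusive).
* **Per-protein seeds** are derived from a global seed plus a CRC of the
  accession, so proteome-scale runs are reproducible and independent of
  input order. Proteome runs may share null samples between proteins with
  identical (m, N) — the null law depends on nothing else — which is the
  default for speed; per-protein independent nulls are available
  (`share_nulls=False`) and used where replicate independence matters.
* Proteins with m = 0 or fewer than two segments are `not_evaluable` and
  excluded from category percentages.

**Resolution limit.** The transect method cannot see clusters that straddle
a segment boundary: a 30-residue cluster window crosses a boundary roughly
half the time, and in short proteins (~4 segments) even a clean
within-segment cluster produces a count multiset the null can reproduce
with probability ~10⁻⁴–10⁻⁵ per draw. Consequently the recovery of planted
10-Met/30-residue clusters in 200-residue proteins saturates near 40%, not
near 100% — an intrinsic property of the published procedure at α = 10⁻⁴,
reproduced (not fixed) here.

## MR-PrLD calling

* **Met-bias scan (criterion ii).** A functional equivalent of an fLPS-style
  lowest-probability-subsequence search, not a bit-exact replication (out
  of scope). Candidate stretches start and end on a Met — trimming non-Met
  flanks always lowers the binomial tail P[#Met ≥ k | n, p_bg], so the
  minimiser is Met-delimited — with lengths in [10, 1000]. The globally
  lowest-tail stretch is grown over adjacent Mets while the extension still
  beats the 10⁻⁵ threshold (maximal significant region, mirroring fLPS's
  merged biased regions), then masked, and the scan repeats on the
  remaining blocks. An exhaustive O(L²) enumeration oracle checks the scan
  on short sequences. The background p defaults to the whole-input pooled
  Met frequency; a per-protein override exists (the external tool offers
  several baselines and no single choice is canonical).
* **Prion-likeness (criterion iii).** A two-state (background / prion-like)
  HMM decoded by forward–backward, replacing the external HMM tool.
  Emissions: a bundled background table approximating average human
  composition (Met 2%) and a Q/N/S/G-rich prion table whose Met weight is
  configurable (default 0.2, the Met density of published MR-PrLDs).
  Transitions encode mean segment lengths of 1,000 (background) and 100
  (prion) residues; initial distribution is the stationary one. Residues
  outside the 20-letter alphabet emit uniformly. PrLDs are maximal runs of
  posterior ≥ 0.9.
* **Run-length filter.** The domain scale of interest is ≥ 60 residues,
  but a posterior-threshold run systematically under-covers the true state
  segment by a few residues per boundary (smoothing at the edges), so a
  60-residue filter rejects most true 60-residue domains. The filter
  default is therefore **30 residues — half the domain scale**; spurious
  ≥ 0.9-posterior excursions that long essentially never occur on
  background sequence (0/200 in simulation). The external tool's "core
  length 60" convention belongs to its own Viterbi-core scoring and does
  not transfer to a posterior-run rule; the parameter remains configurable.
* **Criterion matching.** "The LCR must match a PrLD" is implemented as
  non-empty positional overlap, with the emitted domain being the
  intersection span (union and containment are config options); duplicate
  spans are merged and spans with < 5 Met dropped (criterion iv). Multiple
  domains per protein are allowed.
* **Scoring.** Exact binomial upper tail P[X ≥ x] (inclusive), computed via
  the survival function; an independent log-space term-summation oracle
  checks it to 1e-10 relative error. p_bg is the initiator-stripped
  whole-protein Met frequency. The published census p-values cannot be
  recomputed bit-exactly (they depend on each protein's unprinted p_bg and
  isoform conventions), so published values anchor *ranking* checks only.

## Compactness

Ic = d/N from the first and last Cα-bearing residues of the first chain
(predicted single-chain models); structures with fewer than two Cα are
skipped with a logged reason. Null distributions of 49-protein mean Ic are
built by resampling without replacement from a reference pool: unrestricted;
size-matched (each target matched within ±10% relative length); or
Met-matched (±0.5 percentage points Met frequency) — tolerances are
declared defaults, widened stepwise (×2, logged) when no unused match
exists. The comparison is one-sided lower-tail ("more compact"); an empty
tail is reported as p < 1/reps. The sample size 49 is a parameter (it
mirrors a 51-protein set with two unavailable structures), not a constant.

## GO network

Term sets are used exactly as annotated (no ancestor propagation — whether
the published analysis propagated is unknown; a propagation hook is left to
the caller by supplying pre-propagated annotations). Jaccard of two empty
sets is defined as 0 (logged), so unannotated proteins stay isolated
nodes. Newman's nominal assortativity is computed from the edge mixing
matrix; r = 1 is returned for the 0/0 limit of an entirely single-class
edge set. Both permutation controls are upper-tail plug-in tests
(consistent with the spatial statistics): relabelling preserves label
counts on the fixed topology (10⁵ reps); resampling rebuilds the graph from
pool proteins and labels them at the observed proportion (10³ reps),
skipping edgeless replicates with a log message. Enrichment is the
upper-tail hypergeometric per term with Bonferroni over tested terms;
fold-enrichment is the ratio of proportions (k/n)/(K/N) — a ratio of raw
counts would not be a *fold* enrichment.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume:
i.i.d. ~2% Met over a background amino-acid table approximating human
composition; lognormal lengths truncated to [100, 5000]; a zero-Met
subpopulation; planted Met clusters (uniform window, never over position
1); planted prion-composition segments; CA-only extended and freely jointed
random-walk chains; two-group GAF annotations whose within-group term
overlap exceeds the between-group overlap, with a noise parameter that
spreads pairwise Jaccard around its pool-determined expectation (real
annotation sets are not block-identical; the analysis driver uses
within 0.55 / between 0.50 / noise 0.2, which yields a modestly assortative
148-node network, r ≈ 0.19).

They do **not** emulate: real domain grammar or residue correlations
(sequences are i.i.d. given the table), folding or secondary structure
(random walks have no excluded volume — compact MR chains are emulated by a
shorter step length), isoforms, or the topology of real GO term
hierarchies. Passing tests therefore demonstrate the correctness of the
statistics and the recovery of planted signal under the stated noise model
— not performance on any particular proteome release, which additionally
depends on database versions and external-tool parameterizations.

## Problem sizes

Simulation-based checks run at desk scale, chosen to keep the full suite in
the minutes range while leaving standard errors well inside the asserted
margins: 2,000 proteins for the type-I-error and mean-q checks, 200–300
seeds for recovery rates, 10,000 null replicates per protein (the value the
procedure itself prescribes), 10⁴–10⁵ permutation replicates in the network
tests' drivers.

## Known limitations

* The empirical-p convention (r/B) cannot distinguish p = 0 from p < 1/B;
  outputs report the bound where it matters (compactness nulls).
* The bias scan's greedy mask-and-repeat can split one biological region
  into two when a long gap separates Met clusters; the maximal-extension
  step mitigates but does not eliminate this.
* The HMM is a two-state model with i.i.d. emissions; it will under-segment
  compositionally gradual transitions.
* Published proteome-scale counts (e.g. class percentages) depend on the
  proteome release and are treated as context, not targets.
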
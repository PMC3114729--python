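# Methods

## Bootstrap expression calling

The estimator targets the central difficulty of quantifying a mixed
two-organism transcriptome against a combined gene-model catalog:
short reads frequently align to more than one location (paralogs,
shared domains, and — in a dual catalog — occasional cross-organism
hits). Rather than discarding multireads or spreading them
fractionally, each bootstrap iteration assigns every multiread
uniformly at random to one of its candidate *locations*; two candidate
locations inside the same gene both credit that gene, so a read whose
candidates all fall in one gene is effectively unique. Per iteration,
per-gene RPKM is

    RPKM_g = count_g / (L_g / 10^3) / (D / 10^6)

with L_g the gene-model length in bp and D the read denominator. D
defaults to the number of mapped reads (constant across iterations,
which makes the per-iteration identity Σ_g RPKM_g·L_g/10^3 = 10^6
exact); the full library size including unmapped reads is selectable
(`rpkm_denominator="library_reads"`).

Across B iterations (default 1000) the mean μ and **population**
standard deviation σ (divisor B, not B−1; at B = 1000 the difference
is negligible) summarize each gene's RPKM distribution, and
significance is the cumulative-normal mass at or below zero
expression:

    p = Φ(−μ/σ)

with an explicit precedence for the degenerate cases: μ = 0 → p = 1
(nothing observed; this branch wins even when σ = 0), else σ = 0 →
p = 0 (a constant non-zero signal, e.g. a gene covered only by unique
reads). p is strictly decreasing in μ/σ and approaches 0.5 as the
signal-to-noise ratio vanishes; the μ = 0 override is deliberately
discontinuous. A standard error σ/√B is reported alongside σ for
users who prefer the Monte-Carlo precision of μ.

Implementation notes: per-iteration RNG streams are spawned from one
master `SeedSequence`, so results are bit-reproducible given the seed
and independent of scheduling. Iteration counts are stored only for
genes reachable by multireads; unique-read genes take a closed-form
path, which is what guarantees σ = 0 *exactly* (a floating-point
accumulator would not). Genes with no candidates receive
(μ=0, σ=0, p=1). A gene is expressed when p < α (default 0.001) in
every replicate; replicate agreement can be scored with a
hypergeometric overlap test (`overlap_significance`). Strand is
recorded but not used in counting: alignment is in transcript space,
where antisense hits are rare.

## Enrichment statistics

All enrichment modes share one statistic: for a class observed x
times in a subset of size n with background frequency p, the upper
binomial tail P(X ≥ x) (computed through the regularized incomplete
beta function, stable far beyond n = 10^5) is the enrichment p-value
and the lower tail P(X ≤ x) the depletion p-value. Both are always
emitted; note the binomial model samples *with* replacement, so for
classes that are a large fraction of the genome it is slightly
conservative relative to the hypergeometric.

* **Annotation classes**: x = expressed class members, n = expressed
  genes of that organism, p = genomic class frequency; coverage =
  expressed members / genomic members.
* **Shared pathways**: x = pathway functions expressed by both
  organisms, n = all jointly expressed functions, p = pathway size over
  the number of functions expressed by either organism (clamped at 1);
  the report also carries x over the pathway functions expressed by
  either organism ("% shared").
* **Unique pathways**: a success is an expressed gene carrying a
  partner-absent function that maps to the pathway, n = that
  organism's expressed genes, p = genomic frequency of genes mapping
  to the pathway; the coverage column is the fraction of the pathway's
  functions in the unique set.

Reporting keeps results with p < 0.01 and coverage ≥ 0.25. No
multiple-testing correction is applied — the per-class tails are
reported raw, and the number of tests run is surfaced so users can
post-correct; with tens of classes the planted-fixture conclusions are
insensitive to this choice. EC codes match at all four levels; a `-`
level (partial annotation) matches any completion, configurable off.

## Network construction

A reference reaction (KEGG-style record: EC set, substrates, products,
reversibility) is included when at least one of its EC numbers is
expressed by either organism, and every metabolite of an included
reaction becomes a node. Provenance is tracked at two levels:
per *function* (an EC is A-only / B-only / shared by membership in
the two expressed sets) and per *reaction edge* (a reaction is
organism-unique only when **all** of its expressed catalysts are
unique to that organism — the roll-up the exchange predictor needs to
avoid claiming uniqueness for reactions the partner also catalyzes).
Reversible reactions contribute directed edges both ways but count
once. Construction is monotone (adding an expressed function never
removes anything) and idempotent. Compound totals are raw — no
currency-metabolite filtering. Pathway detection uses coverage =
expressed pathway functions / pathway size with a 0.30 threshold, and
a reference universe (e.g. a global metabolism map) can be projected
to an expressed fraction overall and per organism.

## Exchange prediction

Candidates must satisfy three criteria simultaneously: (1) produced by
at least one reaction whose expressed catalysts are all unique to the
producer (for reversible reactions both sides count as products);
(2) substrate of a transporter class enriched below the gate (default
0.05) in either partner — the shipped class map covers sugar porters
(hexoses + sucrose), amino-acid transport (the 20 proteinogenic amino
acids), ammonium, and inorganic phosphate, and is fully
user-overridable; (3) consumed by a partner-expressed reaction within
`partner_depth` reaction steps (default 1 = direct consumption; larger
depths walk the included network), **or** listed on an explicit
consumption allow-list. The allow-list exists because utilization of
an exported compound may occur in tissues outside the sampled material
(the canonical case being a ureide like allantoin, exported by the
fungal partner but metabolized in the plant's shoots rather than the
sampled root); it is off by default and every candidate admitted
through it is flagged. Prediction is anti-monotone: removing reactions
or shrinking transporter substrate sets never adds candidates, and the
test suite re-checks every candidate with an independent brute-force
scan of the raw reaction table.

## Synthetic data

The generator emulates the *shape* of a deep dual-organism mRNA-seq
study at desk scale. Defaults: two organisms × 100 gene models
(lengths uniform in 500–3000 bp), 50,000 aligned 46-bp reads, 18% of
reads multi-mapped, 40% of gene models silent, lognormal expression
levels (log-SD 1.0), two replicates whose shared expression weights
are jittered by a lognormal factor (SD 0.05) before counts are
redrawn. Multimapping is modelled by duplicated gene pairs — identical
copies whose reads align at the same offset in both members — which
pins the per-read candidate multiplicity at exactly 2 and concentrates
the planted multiread mass, the structure bootstrap resampling must
resolve. Reads are emitted directly as alignment records (text SAM,
byte-deterministic given the seed), skipping the aligner: planting
candidate locations gives exact control of the multimapping structure.
Truth tables record per-gene counts/RPKM (with a Poisson-scale
standard error √c scaled to RPKM units) and per-read multiplicity.

Planted annotations are sized analytically from the fixture geometry
(100 genes, 60 expressed): all-expressed 14-member transporter classes
sit at an exact binomial tail of 0.0352 (below the 0.05 gate),
proportionally expressed classes near 0.56 (null), and the generic
24-member enriched class at 0.0044 (below the 0.01 reporting
threshold). A separate pure-set fixture (5000 genes, 500 expressed,
40-member class with 30 expressed) exercises calibration: the planted
class reaches p ≈ 5·10⁻¹⁷ with 75% coverage while freshly drawn null
classes reject at no more than the nominal rate.

What the generator does **not** model — sequencing errors and quality
strings, positional coverage bias, strand structure, intron/splice
effects, cross-organism multireads other than through designed
duplicate pairs, and realistic annotation sparsity — bounds what
passing tests show: they validate the estimator, the statistics and
the pipeline plumbing under controlled conditions, not performance on
real libraries, whose headline totals additionally depend on genome
annotation and reaction-database versions.

The hand-built miniature economy (13 reactions) encodes the canonical
symbiotic exchange: invertase unique to the plant side; glutamate
dehydrogenase, serine hydroxymethyltransferase, hexose kinases and the
urate-oxidase/allantoinase/allantoicase/urease chain unique to the
fungal side; one shared isomerase; one genomic-only reaction that must
stay out of the network. Its designed answer — glucose and fructose
one way, glutamate, glycine and allantoin the other — is asserted
exactly, with allantoin entering via a user-supplied
allantoin-permease transporter class and the consumption allow-list.

## Numerical and design choices

* Tail direction: enrichment is the *upper* binomial tail (small value
  = over-representation); the raw CDF is exposed as `cbd` and the
  depletion tail alongside.
* The CND functional form is isolated in `cnd_pvalue` so an
  alternative significance rule can be swapped in one place.
* SAM coordinates: 1-based POS on disk, 0-based half-open internally;
  candidate lists are de-duplicated on (gene, start, strand).
* Reads with candidates in both organisms' catalogs are ordinary
  multireads — no special rule.
* Ties/degenerate inputs: empty alignment sets give all-zero counts;
  a zero denominator yields an all-(μ=0, p=1) table; empty expressed
  sets give empty networks and no reported pathways.
* Pipeline thresholds (α_expr = 0.001, report p < 0.01 with coverage
  ≥ 0.25, transporter gate 0.05, pathway detection 0.30) live in one
  config object that serializes to YAML; the run manifest records the
  seed, the scientific parameters and SHA-256 digests of every input
  and output, making runs byte-reproducible.

## Known limitations

Uniform random assignment is the estimator's definition, not an
EM-style probabilistic reassignment: for a duplicated pair it
converges to the pair mean, so truly asymmetric expression between
near-identical paralogs is averaged, and σ reflects resampling spread
rather than full posterior uncertainty. The binomial background and
flat annotation labels (no GO-graph propagation) follow the same
modelling choices as the pipeline's statistics; differential
expression, flux modelling and gap-filling are out of scope.
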
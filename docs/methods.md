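# Methods

## The probability model

Let the model's marker list be `M` ordered biallelic SNPs flanking one
classical HLA locus. An *extended haplotype* is `e = (h, a)` with
`h ∈ {0,1}^M` the SNP alleles on one chromosome and `a` the 4-digit HLA
allele carried on the same chromosome. The population parameters are the
frequencies `f(e)`, constrained to sum to one.

Under Hardy–Weinberg random pairing, the probability of observing a sample
with unphased genotypes `G ∈ {0,1,2,missing}^M` and (unphased) HLA pair
`H = {a1, a2}` is

    P(G, H) = Σ f(e1) f(e2)

over *ordered* pairs `(e1, e2)` such that `h1 + h2` matches `G` at every
non-missing site and `{a1', a2'} = H`. Phase and assignment are missing
data, so the frequencies are estimated by EM. The E step weights each
sample's compatible ordered pairs by `f(e1) f(e2)` (normalised within the
sample); the M step sets `f(e)` to its expected count divided by `2n`. The
observed-data log-likelihood is recorded at every iteration and is
non-decreasing by construction; the fit stops when the relative change drops
below `tol` (default 1e-8) or after `max_iter` (default 1000) iterations.
Identical (genotype, HLA-pair) rows are collapsed into weighted patterns
before iteration, which leaves the estimates unchanged and makes the E step
cost proportional to the number of distinct patterns.

Initialisation is uniform over the union of all samples' compatible extended
haplotypes — deterministic, so the fit needs no random seed. On fully
homozygous data there is no ambiguity and a single iteration reproduces
direct haplotype-count proportions exactly (a property the tests assert).
After convergence, haplotypes below `prune_threshold` (default 1e-6) are
removed and the table renormalised; pruning bounds table growth during
selection. Table rows are kept in a canonical (allele code, SNP vector)
order so that fits are invariant to sample order.

Two refit paths keep selection tractable instead of re-enumerating supports:

* **extend**: every retained haplotype spawns two children (new SNP allele
  0/1) with half the parent's frequency as a warm start, then EM;
* **drop**: haplotypes identical after removing a column are merged (their
  frequencies summed), then EM.

Direct enumeration is capped at 2^20 configurations per sample; a genotype
vector with more free sites (heterozygous + missing) than that raises a
clear error rather than exhausting memory.

## Posterior prediction and confidence thresholds

For a new sample, `P({a1,a2} | G)` is proportional to the mass of ordered
table pairs compatible with `G` carrying that allele pair, normalised over
all pairs. If `G` has zero exact support under the (pruned) table, every
table pair is admitted with a per-site mismatch penalty factor `smoothing`
(default 1e-3), so a distribution always exists and a prediction is always
available — necessary for the guarantee that CT = 0 yields a 100% call
rate. The same smoothed distribution is used when scoring a training sample
whose true pair has no exact support (e.g. after pruning), keeping the
selection objective finite.

The maximum-posterior pair is called iff its probability **strictly
exceeds** the confidence threshold CT ∈ [0, 1); ties are broken by
lexicographic order of the sorted code pair, making calls deterministic.

## SNP selection and window sweeps

The selection objective is the AIC-penalised negative conditional
log-likelihood

    score = − Σ_i log P(H_i | G_i) + 2 (K − 1),

with `K` the number of retained haplotypes; the frequencies are the model's
free parameters (they sum to one, hence `K − 1`). The objective is evaluated
on the training fold only; cross-validation measures generalisation
separately afterwards.

Search starts from the marginal model (no SNPs: `P(H)` is the HWE pair
distribution of allele frequencies) — the limiting case of seeding with
allele-associated genotypes — and a config option (`preseed`) lets a user
force an initial SNP list instead. Each forward step fits and scores every
single-SNP extension and accepts the best only if it strictly lowers the
score; backward passes after every addition remove any SNP whose removal
lowers the score (running the backward pass after each step, rather than
once at the end, is the stricter reading and is what is implemented). Ties
break by smaller genomic position, then lexicographic id, so the outcome is
canonical and independent of candidate order. A float guard of 1e-9 protects
the strict-improvement comparison from round-off only.

Flanking windows are 1-based inclusive, `[gene_start − 1000·W, gene_stop +
1000·W]` for a half-width of `W` kb anchored at the gene's start/stop. The
sweep runs the full selection pipeline inside k-fold CV for every grid
value and applies the parsimonious rule: among grid values attaining the
maximum mean accuracy (exact ties), the smallest window, then the fewest
selected SNPs. `max_snps` defaults to 30, matching the scale of selected-SNP
counts that this class of model reaches on real MHC panels.

## Evaluation

Folds are a seeded random partition with sizes differing by at most one.
Prediction scoring is by maximum multiset matching: 1 for both alleles, 0.5
for exactly one, 0 otherwise (the multiset form settles homozygous-truth
edge cases). Per fold, accuracy is `T_v / N_v` with `T_v` the summed scores
of *called* samples and `N_v` the called count; at CT = 0 this reduces to
plain mean score over the fold. The headline number is the mean of fold
accuracies; pooling `T_v`/`N_v` over folds is exposed as `pooled_accuracy`
since both conventions exist in practice. Call rate is counted over all
samples. Alleles seen fewer than three times are flagged in the report as
rare (they are retained in the model; flagging only, since their effect is a
caveat rather than a removal rule).

Cohen's kappa pools all shared (sample, SNP) cells into one 3×3 table;
`kappa = (p_o − p_e)/(1 − p_e)`, defined as 1 when both call sets are
constant and identical. Selected-SNP variation is `(∪ − ∩)/∪`.

The SNP-vs-locus D′ estimates two-locus haplotype frequencies `p_ij` with
the same EM engine (one SNP, the multi-allelic locus), then averages
`|D′_ij| = |p_ij − p_i q_j| / D_max,ij` with weights `p_i q_j`; the result
lies in [0, 1]. A monomorphic SNP is reported as missing (NaN), not 0.

QC removes SNPs with MAF < 0.01, call rate < 0.95 or exact Hardy–Weinberg
p < 1e-4. The HWE test enumerates the conditional distribution of the
heterozygote count given the allele counts (log-gamma arithmetic, summing
probabilities ≤ that of the observed table); the exact test is the correct
choice near the MAF boundary where chi-square approximations fail.

Allele spectra of two populations are compared on the 2×A contingency table
by the chi-square statistic with a Monte-Carlo p-value from tables drawn
with both margins fixed (Patefield's algorithm, default 10⁴ seeded
replicates, resolution limit 1/(R+1)); the asymptotic p is reported only
when all expected counts are ≥ 5. This is the sparse-table strategy needed
when many alleles are rare.

## The synthetic-data generator

The simulator emulates a multi-allelic HLA locus embedded in an MHC-like SNP
map. Each HLA allele owns a distinct binary *core haplotype*; each gamete
draws an allele from the locus's frequency spectrum, copies its core, and
flips every SNP independently with probability

    eps(d) = eps0 + (eps_max − eps0) · min(1, d / d_decay),

where `d` is the bp distance to the nearest gene edge (0 inside). Genotypes
are gamete sums with i.i.d. missingness on SNP calls only; HLA typings are
always complete, matching the near-zero missingness of laboratory HLA
typing. Phased truth is retained on the dataset for oracle tests. Platform
subsets are plain marker masks; two-population studies are realised by
building two founder pools with different spectra/seeds over the same map.

Defaults, chosen once as realistic study conditions: `n_samples = 437` (a
typical single-site cohort), `missing_rate = 0.015` (array-era sample call
rates of ~98.5%), `eps0 = 0.05`, `eps_max = 0.5`, `d_decay = 200 kb` (tag
SNPs at D′ ≈ 0.8–0.95 at the gene decaying to independence within a few
hundred kb — spanning the 0.4–0.9 range real MHC panels show), gene span
3.3 kb (a classical class I gene), Dirichlet concentration 0.3 for drawn
spectra (a 44-allele locus then almost always carries sub-1% alleles, the
long rare tail seen at class I loci).

What the generator does **not** emulate: recombination-graph LD structure
(flips are independent given the allele, so SNP–SNP LD beyond what the
locus induces is absent), genotyping error, strand ambiguity, admixture and
selection. Passing tests therefore demonstrate correctness of the
estimation and selection machinery under a known generative model, not
performance on any real cohort; real-data accuracy depends on population
haplotype structure that only real panels can supply.

## Numerical choices and limitations

* EM tolerance 1e-8 (relative log-likelihood), max 1000 iterations; the
  trace is exposed for monotonicity checks.
* Pruning at 1e-6 with renormalisation; prediction-time smoothing 1e-3 per
  mismatched site.
* Missing genotypes are marginalised (both alleles free at the site) in
  both fitting and prediction.
* EM on unphased data converges to a stationary point; with the uniform
  deterministic initialisation the fitted table is reproducible, but global
  optimality is not guaranteed for adversarial inputs. Greedy
  forward/backward selection likewise does not guarantee the exhaustive-
  subset optimum, though it attains it on tag-SNP constructions (asserted
  statistically in the tests).
* The acceptance pipeline (`scripts/acceptance.py`) uses a 437-sample,
  48-SNP, 12-allele cohort, a 3-value flank grid with 3-fold CV inside the
  sweep and 5-fold CV for the headline accuracies, and `max_snps = 8`;
  these are the package's chosen desk-scale study conditions.
* 2-digit or 6/8-digit resolution, allele-group (G/P) codes, NMDP
  ambiguity strings, multi-locus joint models and dosage-format inputs are
  out of scope.
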
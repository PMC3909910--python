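# hlatag

Prediction of 4-digit classical **HLA genotypes** from unphased flanking **SNP
genotypes**, with a synthetic MHC-cohort generator for method development and
validation.

Classical HLA loci (HLA-A, -B, -C, -DRB1, -DQB1, -DPB1) are the most
polymorphic genes in the human genome, and direct typing (SSO/SSP or
sequencing) is slow and expensive. Because the MHC carries strong, long-range
linkage disequilibrium, the HLA allele on a chromosome can be predicted from
the ordinary biallelic SNPs already present on genotyping arrays. `hlatag`
implements this imputation pipeline for cohorts that have SNP genotypes plus
4-digit HLA typings for a training subset — the setting of GWAS groups who
want HLA calls without typing every sample.

## Model

The unit of inference is the *extended haplotype* `e = (h, a)`: a binary SNP
allele vector `h` over an ordered marker list joined to the HLA allele `a`
carried on the same chromosome. Under Hardy–Weinberg random pairing a sample
with unphased SNP genotypes `G` and HLA pair `{a1, a2}` arises from an
unordered pair of extended haplotypes; SNP phase and the allele-to-haplotype
assignment are missing data. The frequencies `f(e)` are fitted by EM:

* **E step** — each sample's compatible ordered haplotype pairs `(e1, e2)`
  (per-site alleles summing to the 0/1/2 call, missing sites free) get
  posterior weight ∝ `f(e1)·f(e2)`;
* **M step** — `f(e)` ← expected count of `e` over the `2n` chromosomes.

Prediction for a new sample is the posterior over HLA pairs,

```
P({a1,a2} | G) ∝ Σ_{(e1,e2) compatible with G, {e1.a, e2.a} = {a1,a2}} f(e1) f(e2),
```

and the maximum-posterior pair is called when it exceeds a confidence
threshold CT (CT = 0 calls everything; higher CT trades call rate for
accuracy).

SNPs enter the model by forward selection / backward elimination on an
AIC-penalised conditional likelihood, `−Σ_i log P(H_i | G_i) + 2(K−1)` with
`K` retained haplotypes, and candidate windows around the gene (±10 kb to
±400 kb) are compared by cross-validated accuracy under the parsimonious
rule: smallest window, then fewest SNPs, among those reaching the best mean
accuracy.

Supporting statistics: half-pair accuracy scoring (1 / 0.5 / 0), Cohen's
kappa for between-platform genotype concordance, the (∪−∩)/∪ variation of
selected-SNP sets, a multi-allelic D′ between each SNP and the HLA locus,
GWAS QC filters (MAF < 0.01, call rate < 0.95, exact Hardy–Weinberg test at
p < 1e-4) and a fixed-margin Monte-Carlo chi-square test for comparing
sparse allele-frequency spectra between populations.

## Worked example

Real cohorts pairing dense MHC SNPs with HLA typings are rarely shareable, so
the package ships a generator with known ground truth: each HLA allele owns a
core SNP haplotype, and gametes copy the core with flip probability rising
from `eps0` at the gene to `eps_max` far away (scale `d_decay`), giving tag
SNPs nearby and noise beyond.

```python
import hlatag as ht

pool = ht.build_founder_pool(
    n_markers=24, n_alleles=6, region_span_bp=400_000,
    spectrum=[0.30, 0.25, 0.20, 0.12, 0.08, 0.05],
    ld_params=(0.02, 0.5, 120_000), seed=7,
)
ds = ht.simulate_cohort(pool, ht.SimulationConfig(n_samples=300, missing_rate=0.01, seed=8))

rep0 = ht.cross_validate(ds, pool.locus, k=5, ct=0.0, seed=9, max_snps=6)
rep9 = ht.cross_validate(ds, pool.locus, k=5, ct=0.9, seed=9, max_snps=6)
print(f"CT=0.0  accuracy {100*rep0.mean_accuracy:.2f}%  call rate {100*rep0.call_rate:.2f}%")
print(f"CT=0.9  accuracy {100*rep9.mean_accuracy:.2f}%  call rate {100*rep9.call_rate:.2f}%")

rows, pairs = ds.hla_pairs(pool.locus)
model = ht.select_snps(ds.genotypes[rows], ds.markers, pairs, locus=pool.locus, max_snps=6)
print("selected SNPs:", model.marker_ids)
print(f"AIC objective: {model.objective:.2f}")

ld = ht.ld_report(ds, pool.locus)
print(f"highest D' in the window: {ld.max_dprime:.2f}")
```

prints

```
CT=0.0  accuracy 81.00%  call rate 100.00%
CT=0.9  accuracy 94.40%  call rate 30.00%
selected SNPs: ['rs199911', 'rs187173', 'rs231306', 'rs250025']
AIC objective: 355.76
highest D' in the window: 0.95
```

At CT = 0 every sample is called and five-fold CV accuracy is 81%; raising
the threshold to 0.9 keeps only the confident 30% of calls and lifts their
accuracy to 94%. Four SNPs suffice for six alleles, and the strongest tag
SNP sits at D′ = 0.95 with the locus.

The same pipeline is available as a CLI
(`hlatag simulate | qc | train | sweep | predict | evaluate | concordance`);
cohorts are read from unphased VCF or a 0/1/2 TSV matrix plus marker map,
HLA typings from a long-format TSV, and models round-trip through versioned
JSON.

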
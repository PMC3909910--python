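import numpy as np
import pytest

import hlatag as ht


@pytest.fixture(scope="session")
def perfect_pool():
    """Error-free founder pool: SNP haplotypes tag HLA alleles bijectively."""
    return ht.build_founder_pool(
        n_markers=10,
        n_alleles=4,
        region_span_bp=400_000,
        spectrum=[0.4, 0.3, 0.2, 0.1],
        ld_params=(0.0, 0.0, 100_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def perfect_cohort(perfect_pool):
    return ht.simulate_cohort(
        perfect_pool, ht.SimulationConfig(n_samples=300, missing_rate=0.0, seed=12)
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with distance-decaying LD and a little missingness."""
    pool = ht.build_founder_pool(
        n_markers=24,
        n_alleles=5,
        region_span_bp=600_000,
        spectrum=[0.35, 0.25, 0.2, 0.15, 0.05],
        ld_params=(0.03, 0.5, 80_000),
        seed=21,
    )
    ds = ht.simulate_cohort(pool, ht.SimulationConfig(n_samples=250, missing_rate=0.02, seed=22))
    return pool, ds


def random_table(rng, n_snps, n_alleles):
    """A random valid haplotype frequency table for posterior tests."""
    codes = [f"{k + 1:02d}01" for k in range(n_alleles)]
    k = rng.integers(n_alleles, 2 * n_alleles + 3)
    haps = rng.integers(0, 2, size=(k, n_snps)).astype(np.int8)
    hla = [codes[c] for c in rng.integers(0, n_alleles, size=k)]
    # dedupe rows, keep at least one hap per drawn code set
    seen, keep = set(), []
    for idx, (row, c) in enumerate(zip(map(tuple, haps), hla)):
        if (row, c) not in seen:
            seen.add((row, c))
            keep.append(idx)
    haps, hla = haps[keep], [hla[i] for i in keep]
    f = rng.dirichlet(np.ones(len(hla)))
    return ht.HaplotypeFrequencyTable("HLA-A", [f"s{j}" for j in range(n_snps)],
                                      haps, hla, f)


def brute_posterior(table, genotype, smoothing=None):
    """Independent posterior oracle: explicit loop over ordered hap pairs."""
    entries = list(table.entries.items())
    weights = {}
    total = 0.0
    for e1, f1 in entries:
        for e2, f2 in entries:
            exact = all(
                g < 0 or a + b == g
                for a, b, g in zip(e1.snp_alleles, e2.snp_alleles, genotype)
            )
            if smoothing is None:
                w = f1 * f2 if exact else 0.0
            else:
                mism = sum(
                    1
                    for a, b, g in zip(e1.snp_alleles, e2.snp_alleles, genotype)
                    if g >= 0 and a + b != g
                )
                w = f1 * f2 * smoothing**mism
            if w > 0:
                key = ht.pair_key(e1.hla.code, e2.hla.code)
                weights[key] = weights.get(key, 0.0) + w
                total += w
    return {k: v / total for k, v in weights.items()} if total else {}
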
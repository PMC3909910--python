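"""Evaluation: cross-validated accuracy, concordance, LD, QC and spectra tests.

Accuracy follows the half-pair convention: a predicted HLA allele pair scores
1 when it matches the true pair, 0.5 when exactly one allele matches (as a
multiset matching, which settles homozygous edge cases), else 0.  Per fold,
accuracy is T_v / N_v where T_v sums the predictive values of called samples
and N_v counts them; at CT = 0 everything is called, so N_v is the fold size.

Also here: Cohen's kappa on pooled genotype calls (platform concordance), the
(union − intersection)/union variation of selected-SNP sets, a multi-allelic
D' between each SNP and the HLA locus, standard GWAS-style QC filters with an
exact Hardy-Weinberg test, and a fixed-margin Monte-Carlo chi-square test for
comparing sparse HLA allele-frequency spectra between populations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import DEFAULT_SMOOTHING, HlaAllele, call_genotype, fit_haplotype_frequencies, pair_key
from .io import CohortDataset
from .selection import select_snps

__all__ = [
    "EvaluationReport",
    "ConcordanceReport",
    "LdReport",
    "FrequencyComparison",
    "score_prediction",
    "cross_validate",
    "cohens_kappa",
    "platform_variation",
    "multiallelic_dprime",
    "ld_report",
    "hwe_exact_pvalue",
    "qc_filter",
    "compare_allele_frequencies",
]

#: Alleles seen fewer than this many times in training are flagged as rare.
RARE_ALLELE_COUNT = 3


@dataclass
class EvaluationReport:
    """Cross-validation outcome at one confidence threshold."""

    ct: float
    per_fold: pd.DataFrame  # fold, n_test, n_called, t_v, accuracy
    mean_accuracy: float
    pooled_accuracy: float
    call_rate: float
    fold_assignment: pd.Series  # sample -> fold
    seed: int
    predictions: pd.DataFrame  # sample, fold, allele1, allele2, posterior, called, score
    rare_alleles: dict[str, int] = field(default_factory=dict)


@dataclass
class ConcordanceReport:
    """Chance-corrected genotype agreement between two call sets."""

    kappa: float
    table: np.ndarray  # pooled 3x3 agreement counts
    n_cells: int
    platforms: tuple[str, str] = ("a", "b")
    variation: float | None = None


@dataclass
class LdReport:
    """Per-SNP multi-allelic D' against the HLA locus."""

    dprime: pd.Series  # indexed by marker id; NaN where undefined
    max_dprime: float


@dataclass
class FrequencyComparison:
    """Sparse-table test of allele-frequency spectra between two populations."""

    chi2: float
    df: int
    mc_p: float
    asymptotic_p: float | None
    n_replicates: int
    min_p: float  # Monte-Carlo resolution limit 1/(R+1)


# ---------------------------------------------------------------------------
# Prediction scoring and cross-validation
# ---------------------------------------------------------------------------


def score_prediction(true_pair, predicted_pair) -> float:
    """Predictive value of a called pair: 1 full match, 0.5 half, 0 none.

    Computed as (size of a maximum matching between the two multisets) / 2,
    so a homozygous truth against a half-matching prediction scores 0.5.
    """
    t, p = tuple(true_pair), tuple(predicted_pair)
    if any(isinstance(x, HlaAllele) for x in t + p):
        loci = {x.locus for x in t + p if isinstance(x, HlaAllele)}
        if len(loci) > 1:
            raise ValueError(f"locus mismatch between pairs: {sorted(loci)}")
        t = tuple(x.code if isinstance(x, HlaAllele) else x for x in t)
        p = tuple(x.code if isinstance(x, HlaAllele) else x for x in p)
    matched = sum((Counter(t) & Counter(p)).values())
    return matched / 2.0


def cross_validate(
    dataset: CohortDataset,
    locus: str,
    *,
    k: int = 10,
    ct: float = 0.0,
    seed: int = 0,
    candidate_ids=None,
    mean: str = "folds",
    **select_kwargs,
) -> EvaluationReport:
    """k-fold cross-validated accuracy and call rate at one CT.

    Samples typed at *locus* are shuffled with *seed* and split into k folds
    of sizes differing by at most one.  For each fold the full selection
    pipeline is trained on the complement and applied to the fold; alleles
    unseen in training are handled by the prediction-time mismatch smoothing,
    never by aborting.  ``mean_accuracy`` is the mean of fold accuracies (the
    default); ``pooled_accuracy`` pools T_v and N_v over folds.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rows_idx, pairs = dataset.hla_pairs(locus)
    n = len(rows_idx)
    if n < k:
        raise ValueError(f"only {n} typed samples for {k} folds")
    rows_idx = np.asarray(rows_idx)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    counts = Counter(c for p in pairs for c in p)
    rare = {c: m for c, m in counts.items() if m < RARE_ALLELE_COUNT}

    marker_col = {mid: j for j, mid in enumerate(dataset.markers["id"])}
    fold_of = np.empty(n, dtype=int)
    per_fold, pred_rows = [], []
    for fi, test in enumerate(folds):
        fold_of[test] = fi
        train = np.setdiff1d(perm, test)
        model = select_snps(
            dataset.genotypes[rows_idx[train]],
            dataset.markers,
            [pairs[t] for t in train],
            locus=locus,
            candidate_ids=candidate_ids,
            **select_kwargs,
        )
        cols = [marker_col[mid] for mid in model.table.marker_ids]
        t_v, n_called = 0.0, 0
        for t in test:
            g = dataset.genotypes[rows_idx[t], cols]
            res = call_genotype(model.posterior(g), ct)
            sc = score_prediction(pairs[t], res.best_pair) if res.called else np.nan
            if res.called:
                n_called += 1
                t_v += sc
            pred_rows.append(
                {
                    "sample": dataset.samples[rows_idx[t]],
                    "fold": fi,
                    "allele1": res.best_pair[0],
                    "allele2": res.best_pair[1],
                    "posterior": res.max_posterior,
                    "called": res.called,
                    "score": sc,
                }
            )
        per_fold.append(
            {
                "fold": fi,
                "n_test": len(test),
                "n_called": n_called,
                "t_v": t_v,
                "accuracy": t_v / n_called if n_called else np.nan,
            }
        )

    pf = pd.DataFrame(per_fold)
    total_called = int(pf["n_called"].sum())
    mean_acc = float(np.nanmean(pf["accuracy"])) if total_called else np.nan
    pooled = float(pf["t_v"].sum() / total_called) if total_called else np.nan
    assignment = pd.Series({dataset.samples[rows_idx[s]]: int(fold_of[s]) for s in range(n)})
    return EvaluationReport(
        ct=ct,
        per_fold=pf,
        mean_accuracy=mean_acc if mean == "folds" else pooled,
        pooled_accuracy=pooled,
        call_rate=total_called / n,
        fold_assignment=assignment,
        seed=seed,
        predictions=pd.DataFrame(pred_rows),
        rare_alleles=rare,
    )


# ---------------------------------------------------------------------------
# Platform concordance
# ---------------------------------------------------------------------------


def cohens_kappa(calls_a, calls_b, platforms=("a", "b")) -> ConcordanceReport:
    """Cohen's kappa over paired 0/1/2 calls, pooled into one 3x3 table.

    Cells where either call is missing are excluded.  kappa =
    (p_o − p_e)/(1 − p_e); when both call sets are constant and identical
    (p_e = 1) kappa is defined as 1.
    """
    a = np.asarray(calls_a).ravel()
    b = np.asarray(calls_b).ravel()
    if a.shape != b.shape:
        raise ValueError("call sets must be paired over the same cells")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok].astype(int), b[ok].astype(int)
    if a.size == 0:
        raise ValueError("no shared non-missing cells")
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    kappa = 1.0 if abs(1.0 - p_e) < 1e-15 else float((p_o - p_e) / (1.0 - p_e))
    return ConcordanceReport(kappa=kappa, table=table, n_cells=int(n), platforms=tuple(platforms))


def platform_variation(set_a, set_b) -> float:
    """Selected-SNP dissimilarity between platforms: |union − intersection| / |union|."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("both SNP sets are empty")
    return len(union - (a & b)) / len(union)


# ---------------------------------------------------------------------------
# Multi-allelic D'
# ---------------------------------------------------------------------------


def multiallelic_dprime(snp_calls, hla_pairs) -> float:
    """D' between one biallelic SNP and the multi-allelic HLA locus.

    Two-locus haplotype frequencies p_ij are estimated by EM from the
    unphased calls; |D'_ij| = |p_ij − p_i q_j| / D_max with the standard
    bound, and the locus-level value is the frequency-weighted average
    sum_ij p_i q_j |D'_ij|, which lies in [0, 1].  Returns NaN for a
    monomorphic SNP (undefined, reported as missing rather than 0).
    """
    g = np.asarray(snp_calls, dtype=np.int8).reshape(-1, 1)
    obs = g[g >= 0]
    if obs.size == 0:
        return float("nan")
    p_alt = obs.sum() / (2 * obs.size)
    if p_alt <= 0.0 or p_alt >= 1.0:  # monomorphic: D' undefined
        return float("nan")
    table = fit_haplotype_frequencies(g, hla_pairs, ["snp"], prune_threshold=0.0)
    alleles = table.alleles
    P = np.zeros((2, len(alleles)))
    a_idx = {c: j for j, c in enumerate(alleles)}
    for row, code, f in zip(table.haplotypes, table.hla_codes, table.frequencies):
        P[int(row[0]), a_idx[code]] += float(f)
    p = P.sum(axis=1)  # SNP allele frequencies
    q = P.sum(axis=0)  # HLA allele frequencies
    if min(p) <= 1e-12:
        return float("nan")
    d = P - np.outer(p, q)
    dmax = np.where(
        d >= 0,
        np.minimum(np.outer(p, 1 - q), np.outer(1 - p, q)),
        np.minimum(np.outer(p, q), np.outer(1 - p, 1 - q)),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        dp = np.where(dmax > 0, np.abs(d) / dmax, 0.0)
    return float(np.sum(np.outer(p, q) * dp))


def ld_report(dataset: CohortDataset, locus: str) -> LdReport:
    """Per-SNP D' against *locus* over all markers in the dataset."""
    rows_idx, pairs = dataset.hla_pairs(locus)
    vals = {
        mid: multiallelic_dprime(dataset.genotypes[rows_idx, j], pairs)
        for j, mid in enumerate(dataset.markers["id"])
    }
    series = pd.Series(vals)
    return LdReport(dprime=series, max_dprime=float(series.max()))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, conditional on margins).

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the conditional probabilities no larger than that of the observed
    table.  Exact enumeration is the right tool near the MAF ~ 0.01 boundary
    where chi-square approximations fail.
    """
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        return 1.0
    n_minor = min(2 * n_ref_hom + n_het, 2 * n_alt_hom + n_het)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (
        gammaln(n + 1)
        - gammaln(hom_min + 1)
        - gammaln(hets + 1)
        - gammaln(hom_maj + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def qc_filter(
    dataset: CohortDataset,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 1e-4,
) -> tuple[CohortDataset, pd.DataFrame]:
    """Standard GWAS QC: drop SNPs failing MAF, call-rate or HWE thresholds.

    A SNP is removed when MAF < *maf_min*, call rate < *call_rate_min*, or
    the exact HWE p-value < *hwe_alpha*.  Returns the filtered dataset and a
    per-SNP report (maf, call_rate, hwe_p, kept, reason).
    """
    if dataset.n_markers == 0 or dataset.n_samples == 0:
        raise ValueError("cannot QC an empty dataset")
    rows = []
    for j, mid in enumerate(dataset.markers["id"]):
        col = dataset.genotypes[:, j]
        obs = col[col >= 0]
        call_rate = obs.size / col.size
        if obs.size:
            p_alt = obs.sum() / (2 * obs.size)
            maf = min(p_alt, 1 - p_alt)
            hwe_p = hwe_exact_pvalue(
                int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())
            )
        else:
            maf, hwe_p = 0.0, 1.0
        reasons = []
        if maf < maf_min:
            reasons.append("maf")
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        if hwe_p < hwe_alpha:
            reasons.append("hwe")
        rows.append(
            {
                "id": mid,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "kept": not reasons,
                "reason": ",".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    kept_ids = report.loc[report["kept"], "id"]
    return dataset.subset_markers(kept_ids), report


# ---------------------------------------------------------------------------
# Allele-frequency spectrum comparison
# ---------------------------------------------------------------------------


def compare_allele_frequencies(
    counts_pop1,
    counts_pop2,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> FrequencyComparison:
    """Compare two allele-count spectra with a fixed-margin Monte-Carlo test.

    Builds the 2 x A contingency table, computes the chi-square statistic,
    and estimates its p-value by sampling tables with both margins fixed
    (Patefield's algorithm) -- the sparse-table strategy appropriate for HLA
    spectra with many rare alleles.  The asymptotic chi-square p-value is
    reported alongside only when every expected count is >= 5.  The
    Monte-Carlo p cannot go below 1/(R+1).
    """
    c1 = np.asarray(counts_pop1, dtype=np.int64)
    c2 = np.asarray(counts_pop2, dtype=np.int64)
    if c1.shape != c2.shape:
        raise ValueError("count vectors must share the same allele universe")
    if c1.sum() == 0 or c2.sum() == 0:
        raise ValueError("zero-total population")
    keep = (c1 + c2) > 0
    obs = np.stack([c1[keep], c2[keep]])
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1

    rng = np.random.default_rng(seed)
    sim = stats.random_table(rows, cols).rvs(size=n_replicates, random_state=rng)
    sim_stats = ((sim - expected) ** 2 / expected).sum(axis=(1, 2))
    mc_p = float((1 + (sim_stats >= chi2 - 1e-12).sum()) / (n_replicates + 1))
    asym = float(1 - stats.chi2.cdf(chi2, df)) if (expected >= 5).all() else None
    return FrequencyComparison(
        chi2=chi2,
        df=df,
        mc_p=mc_p,
        asymptotic_p=asym,
        n_replicates=n_replicates,
        min_p=1.0 / (n_replicates + 1),
    )
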
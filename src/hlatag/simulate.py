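"""Synthetic MHC-like cohort generator with known ground truth.

Real cohorts pairing dense MHC SNP genotypes with 4-digit HLA typings are
rarely shareable, so this module generates them.  The generative model is
deliberately simple: each HLA allele owns a distinct binary *core haplotype*
over the marker map, each gamete draws an allele from the locus's frequency
spectrum, copies its core, and then flips each SNP allele independently with a
probability that grows with distance from the gene,

    eps(d) = eps0 + (eps_max - eps0) * min(1, d / d_decay),

where d is the bp distance from the SNP to the nearest edge of the gene region
(d = 0 inside).  This produces tag SNPs in strong LD with the locus nearby and
uninformative noise far away -- the regime the flanking-window sweep and the
SNP-selection procedure are designed to exploit -- without any recombination-
graph machinery.  Phased truth is retained for oracle tests.

Unphased genotypes are the per-site sums of the two gametes (0/1/2), with
calls independently set to missing; HLA typings are always complete, matching
the near-zero typing missingness of SSO/SSP workflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING
from .io import CohortDataset

__all__ = [
    "FounderPool",
    "SimulationConfig",
    "build_founder_pool",
    "simulate_cohort",
    "apply_platform_mask",
]

#: Default LD parameters: (flip prob at the gene, asymptotic flip prob, decay bp).
DEFAULT_LD_PARAMS = (0.05, 0.5, 200_000)
DEFAULT_LOCUS = "HLA-A"


@dataclass
class FounderPool:
    """Population ground truth: marker map, allele spectrum, core haplotypes.

    ``core_haplotypes`` maps each 4-digit allele code to a 0/1 vector over
    ``markers`` (ordered by position); ``ld_params`` is (eps0, eps_max,
    d_decay) for the distance-scaled flip model.
    """

    markers: pd.DataFrame  # columns: id, chrom, pos
    locus_region: tuple[int, int]
    allele_spectrum: dict[str, float]
    core_haplotypes: dict[str, np.ndarray]
    ld_params: tuple[float, float, float] = DEFAULT_LD_PARAMS
    locus: str = DEFAULT_LOCUS

    def __post_init__(self) -> None:
        total = sum(self.allele_spectrum.values())
        if any(f <= 0 for f in self.allele_spectrum.values()) or abs(total - 1.0) > 1e-12:
            raise ValueError("allele spectrum must be positive and sum to 1")
        m = len(self.markers)
        for code, core in self.core_haplotypes.items():
            if len(core) != m:
                raise ValueError(f"core haplotype for {code} has wrong length")
        if set(self.core_haplotypes) != set(self.allele_spectrum):
            raise ValueError("spectrum and core haplotypes cover different alleles")
        pos = self.markers["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def allele_codes(self) -> list[str]:
        return sorted(self.allele_spectrum)

    def flip_probabilities(self) -> np.ndarray:
        """Per-marker flip probability eps(d) under the LD decay model."""
        eps0, eps_max, d_decay = self.ld_params
        pos = self.markers["pos"].to_numpy(dtype=float)
        start, stop = self.locus_region
        d = np.where(pos < start, start - pos, np.where(pos > stop, pos - stop, 0.0))
        return eps0 + (eps_max - eps0) * np.minimum(1.0, d / float(d_decay))


@dataclass
class SimulationConfig:
    """Cohort-level knobs: sample count, SNP missingness, platform masks."""

    n_samples: int = 437
    missing_rate: float = 0.015
    seed: int = 0
    platform_masks: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


def _allele_code(k: int) -> str:
    # 4-digit codes 0101, 0201, ... mirroring 2-digit family / 2-digit protein
    return f"{(k + 1) % 100:02d}{(k // 100) + 1:02d}"


def build_founder_pool(
    n_markers: int,
    n_alleles: int,
    region_span_bp: int = 1_000_000,
    spectrum=0.3,
    ld_params: tuple[float, float, float] = DEFAULT_LD_PARAMS,
    seed: int = 0,
    *,
    gene_span_bp: int = 3300,
    locus: str = DEFAULT_LOCUS,
    chrom: str = "6",
) -> FounderPool:
    """Build a founder pool for a multi-allelic locus embedded in a SNP map.

    *spectrum* is either an explicit frequency list of length *n_alleles* or a
    Dirichlet concentration parameter (float); small concentrations (default
    0.3) yield the long rare-allele tail typical of class I loci, where a
    44-allele locus carries many alleles below 1% frequency.  Marker positions
    are drawn uniformly over the span and the gene region is centred in it.
    The gene span default (3.3 kb) matches a classical class I gene.
    """
    if n_alleles < 2 or n_markers < 1:
        raise ValueError("need n_alleles >= 2 and n_markers >= 1")
    rng = np.random.default_rng(seed)

    if np.isscalar(spectrum):
        freqs = rng.dirichlet(np.full(n_alleles, float(spectrum)))
        freqs = np.maximum(freqs, 1e-12)
        freqs = freqs / freqs.sum()
    else:
        freqs = np.asarray(spectrum, dtype=float)
        if freqs.shape != (n_alleles,):
            raise ValueError("explicit spectrum must have n_alleles entries")
        if np.any(freqs <= 0) or abs(float(freqs.sum()) - 1.0) > 1e-9:
            raise ValueError("explicit spectrum must be positive and sum to 1")
        freqs = freqs / freqs.sum()

    pos = np.sort(rng.choice(np.arange(1, region_span_bp + 1), size=n_markers, replace=False))
    markers = pd.DataFrame(
        {"id": [f"rs{p}" for p in pos], "chrom": chrom, "pos": pos.astype(int)}
    )
    mid = region_span_bp // 2
    locus_region = (mid - gene_span_bp // 2, mid + gene_span_bp - gene_span_bp // 2)

    codes = [_allele_code(k) for k in range(n_alleles)]
    cores = rng.integers(0, 2, size=(n_alleles, n_markers))
    if n_markers >= math.ceil(math.log2(n_alleles)):
        for _ in range(1000):
            _, first = np.unique(cores, axis=0, return_index=True)
            dup = np.setdiff1d(np.arange(n_alleles), first)
            if dup.size == 0:
                break
            cores[dup] = rng.integers(0, 2, size=(dup.size, n_markers))
        else:  # pragma: no cover - astronomically unlikely for sane sizes
            raise RuntimeError("could not draw pairwise-distinct core haplotypes")

    return FounderPool(
        markers=markers,
        locus_region=locus_region,
        allele_spectrum=dict(zip(codes, freqs.tolist())),
        core_haplotypes={c: cores[k].astype(np.int8) for k, c in enumerate(codes)},
        ld_params=tuple(ld_params),
        locus=locus,
    )


def simulate_cohort(pool: FounderPool, config: SimulationConfig) -> CohortDataset:
    """Draw a diploid cohort from the founder pool.

    Each of the 2n gametes draws an HLA allele from the spectrum, copies its
    core haplotype and applies independent per-site flips with probability
    eps(d).  Genotypes are gamete sums with i.i.d. missingness; the phased
    truth (haplotypes and allele per gamete) is kept on the returned dataset
    for oracle tests.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, len(pool.markers)
    codes = pool.allele_codes
    probs = np.array([pool.allele_spectrum[c] for c in codes])
    cores = np.stack([pool.core_haplotypes[c] for c in codes]).astype(np.int8)

    gam_allele = rng.choice(len(codes), size=(n, 2), p=probs)
    eps = pool.flip_probabilities()
    flips = rng.random(size=(n, 2, m)) < eps
    haps = (cores[gam_allele] ^ flips).astype(np.int8)
    geno = haps.sum(axis=1).astype(np.int8)
    miss = rng.random(size=(n, m)) < config.missing_rate
    geno[miss] = MISSING

    samples = [f"S{k:04d}" for k in range(n)]
    rows = []
    for s in range(n):
        a, b = sorted(codes[k] for k in gam_allele[s])
        rows.append((samples[s], pool.locus, a, b))
    hla = pd.DataFrame(rows, columns=["sample", "locus", "allele1", "allele2"])

    truth_alleles = np.array([[codes[k] for k in gam_allele[s]] for s in range(n)])
    return CohortDataset(
        samples=samples,
        markers=pool.markers.copy(),
        genotypes=geno,
        hla=hla,
        truth_haplotypes=haps,
        truth_alleles=truth_alleles,
    )


def apply_platform_mask(dataset: CohortDataset, mask) -> CohortDataset:
    """Restrict a dataset to the markers a genotyping platform assays.

    The returned dataset contains exactly the masked markers (original
    order); samples, calls and HLA typings are unchanged.
    """
    mask = set(mask)
    known = set(dataset.markers["id"])
    unknown = mask - known
    if unknown:
        raise KeyError(f"unknown marker ids in mask: {sorted(unknown)[:5]}")
    keep = dataset.markers["id"].isin(mask).to_numpy()
    return CohortDataset(
        samples=list(dataset.samples),
        markers=dataset.markers.loc[keep].reset_index(drop=True),
        genotypes=dataset.genotypes[:, keep].copy(),
        hla=dataset.hla.copy(),
        truth_haplotypes=(
            None if dataset.truth_haplotypes is None else dataset.truth_haplotypes[:, :, keep].copy()
        ),
        truth_alleles=(None if dataset.truth_alleles is None else dataset.truth_alleles.copy()),
    )
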
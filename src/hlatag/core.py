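"""Probabilistic engine for HLA genotype prediction from unphased SNP genotypes.

The model treats an *extended haplotype* -- a binary SNP-allele vector over an
ordered marker list joined to the classical HLA allele carried on the same
chromosome -- as the unit whose population frequency is estimated.  Under
Hardy-Weinberg random pairing, a sample's unphased SNP genotypes together with
its (unphased) HLA allele pair arise from an unordered pair of extended
haplotypes; both the SNP phase and the assignment of HLA alleles to haplotypes
are missing data, and the haplotype frequencies are fitted by EM.

Given a fitted frequency table, the posterior probability of each HLA allele
pair for a new sample is the total frequency-weighted mass of extended-haplotype
pairs compatible with the observed SNP genotypes, normalised over all pairs.
A call is emitted when the maximum posterior exceeds a confidence threshold
(CT); CT = 0 calls every sample.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "HlaAllele",
    "ExtendedHaplotype",
    "HaplotypeFrequencyTable",
    "CallResult",
    "IncompatibleGenotypeError",
    "normalize_hla",
    "pair_key",
    "enumerate_compatible_pairs",
    "fit_haplotype_frequencies",
    "extend_table",
    "drop_marker",
    "hla_posterior",
    "call_genotype",
]

#: Sentinel for a missing genotype call in 0/1/2 matrices.
MISSING = -1

#: EM convergence: relative log-likelihood change below this stops iteration.
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000
#: Haplotypes below this fitted frequency are pruned and the table renormalised.
DEFAULT_PRUNE = 1e-6
#: Per-site mismatch penalty used when a genotype has no exact support.
DEFAULT_SMOOTHING = 1e-3
#: Hard cap on enumerated haplotype configurations per sample.
MAX_CONFIGURATIONS = 2**20


class IncompatibleGenotypeError(ValueError):
    """A training sample admits no extended-haplotype configuration."""


# ---------------------------------------------------------------------------
# HLA allele nomenclature
# ---------------------------------------------------------------------------

_FULL_RE = re.compile(r"^(?:HLA[-_])?([A-Z][A-Z0-9]*)\*(\d{2}):?(\d{2})$")
_CODE_RE = re.compile(r"^\d{4}$")


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A classical HLA allele at 4-digit (protein-level) resolution."""

    locus: str
    code: str

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise ValueError(f"HLA code must be 4 digits, got {self.code!r}")

    def __str__(self) -> str:  # e.g. HLA-A*02:01
        return f"{self.locus}*{self.code[:2]}:{self.code[2:]}"


def normalize_hla(value: str, locus: str | None = None) -> HlaAllele:
    """Normalise an HLA allele string to a 4-digit :class:`HlaAllele`.

    Accepted forms: ``"A*02:01"``, ``"HLA-A*02:01"``, ``"A*0201"`` and the bare
    4-digit code ``"0201"`` (the latter requires *locus*).  Higher-resolution
    names (6/8-digit), allele groups and ambiguity codes are rejected.
    """
    value = value.strip()
    m = _FULL_RE.match(value)
    if m:
        gene, f1, f2 = m.groups()
        found = gene if gene.startswith("HLA") else f"HLA-{gene}"
        if locus is not None and _norm_locus(locus) != found:
            raise ValueError(f"allele {value!r} conflicts with locus {locus!r}")
        return HlaAllele(found, f1 + f2)
    if _CODE_RE.match(value):
        if locus is None:
            raise ValueError(f"bare 4-digit code {value!r} needs an explicit locus")
        return HlaAllele(_norm_locus(locus), value)
    raise ValueError(f"cannot parse HLA allele {value!r} at 4-digit resolution")


def _norm_locus(locus: str) -> str:
    locus = locus.strip().upper().replace("_", "-")
    return locus if locus.startswith("HLA-") else f"HLA-{locus}"


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered pair of 4-digit allele codes."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtendedHaplotype:
    """A binary SNP-allele vector joined to the HLA allele on that chromosome."""

    snp_alleles: tuple[int, ...]
    hla: HlaAllele


@dataclass
class HaplotypeFrequencyTable:
    """Fitted extended-haplotype frequencies (the model parameters).

    ``haplotypes`` is a K x M 0/1 matrix over ``marker_ids`` (ordered),
    ``hla_codes`` gives the HLA allele code of each row, and ``frequencies``
    sum to one.  ``loglik_trace`` records the observed-data log-likelihood at
    every EM iteration of the final fit (non-decreasing by construction).
    """

    locus: str
    marker_ids: list[str]
    haplotypes: np.ndarray
    hla_codes: list[str]
    frequencies: np.ndarray
    prune_threshold: float = DEFAULT_PRUNE
    loglik_trace: list[float] = field(default_factory=list)
    n_train: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8).reshape(
            len(self.hla_codes), len(self.marker_ids)
        )
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.validate()

    @property
    def n_haplotypes(self) -> int:
        return len(self.hla_codes)

    @property
    def alleles(self) -> list[str]:
        return sorted(set(self.hla_codes))

    @property
    def entries(self) -> dict[ExtendedHaplotype, float]:
        return {
            ExtendedHaplotype(tuple(int(x) for x in row), HlaAllele(self.locus, code)): float(f)
            for row, code, f in zip(self.haplotypes, self.hla_codes, self.frequencies)
        }

    def validate(self) -> None:
        if self.n_haplotypes == 0:
            raise ValueError("empty haplotype table")
        if np.any(self.frequencies < 0):
            raise ValueError("negative haplotype frequency")
        total = float(self.frequencies.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total!r}, not 1")


@dataclass(frozen=True)
class CallResult:
    """Outcome of confidence-threshold calling on a posterior distribution."""

    best_pair: tuple[str, str]
    max_posterior: float
    called: bool
    ct: float


# ---------------------------------------------------------------------------
# Compatibility enumeration
# ---------------------------------------------------------------------------


def _site_options(g: int) -> tuple[int, ...]:
    # per-site haplotype alleles consistent with a 0/1/2/missing call
    if g == 0:
        return (0,)
    if g == 2:
        return (1,)
    return (0, 1)  # het or missing: both alleles free


def _compatible_vectors(genotype: np.ndarray) -> list[tuple[int, ...]]:
    """All single-haplotype SNP vectors consistent with an unphased genotype."""
    options = [_site_options(int(g)) for g in genotype]
    n_free = sum(1 for o in options if len(o) == 2)
    if 2**n_free > MAX_CONFIGURATIONS:
        raise IncompatibleGenotypeError(
            f"genotype admits 2^{n_free} haplotype configurations "
            f"(cap {MAX_CONFIGURATIONS}); reduce the marker set"
        )
    return list(itertools.product(*options))


def enumerate_compatible_pairs(
    genotype,
    hla_pair: tuple[HlaAllele, HlaAllele],
    n_markers: int | None = None,
) -> list[tuple[ExtendedHaplotype, ExtendedHaplotype, int]]:
    """Enumerate unordered extended-haplotype pairs compatible with a sample.

    Returns triples ``(e1, e2, multiplicity)`` where per-site SNP alleles sum
    to the observed 0/1/2 call (missing sites unconstrained), the two HLA
    alleles equal *hla_pair* as a multiset, and multiplicity is 2 for e1 != e2
    (the two chromosome orderings) else 1.
    """
    g = np.asarray(genotype, dtype=int)
    if n_markers is not None and g.shape[0] != n_markers:
        raise ValueError(f"genotype length {g.shape[0]} != marker count {n_markers}")
    a, b = hla_pair
    nonmiss = g >= 0
    out: dict[tuple, tuple[ExtendedHaplotype, ExtendedHaplotype, int]] = {}
    for v1 in _compatible_vectors(g):
        # partner alleles: determined where observed, free where missing
        opts = [((int(c) - x,) if m else (0, 1)) for x, c, m in zip(v1, g, nonmiss)]
        for v2 in itertools.product(*opts):
            for ha, hb in {(a, b), (b, a)}:
                e1 = ExtendedHaplotype(tuple(v1), ha)
                e2 = ExtendedHaplotype(tuple(v2), hb)
                key = tuple(
                    sorted([(e1.snp_alleles, str(e1.hla)), (e2.snp_alleles, str(e2.hla))])
                )
                if key not in out:
                    out[key] = (e1, e2, 1 if e1 == e2 else 2)
    return list(out.values())


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _pair_arrays(
    H: np.ndarray,
    hla_idx: np.ndarray,
    genotypes: np.ndarray,
    pair_idx: np.ndarray,
):
    """Ordered compatible-pair index arrays for every sample.

    Returns (i, j, sid): haplotype row indices of the ordered pair and the
    sample each pair belongs to.  Raises if any sample has no support.
    """
    n = genotypes.shape[0]
    by_allele = {a: np.flatnonzero(hla_idx == a) for a in np.unique(hla_idx)}
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    sid: list[np.ndarray] = []
    for s in range(n):
        g = genotypes[s]
        nonmiss = g >= 0
        a, b = int(pair_idx[s, 0]), int(pair_idx[s, 1])
        ia = by_allele.get(a, np.empty(0, dtype=int))
        ib = by_allele.get(b, np.empty(0, dtype=int))
        if ia.size == 0 or ib.size == 0:
            raise IncompatibleGenotypeError(
                f"sample {s}: HLA allele absent from the haplotype support"
            )
        S = H[ia][:, None, :] + H[ib][None, :, :]
        ok = (~nonmiss | (S == g)).all(axis=2)
        I, J = np.nonzero(ok)
        if I.size == 0:
            raise IncompatibleGenotypeError(
                f"sample {s}: no extended-haplotype pair matches its genotypes"
            )
        i, j = ia[I], ib[J]
        if a != b:  # both chromosome orderings
            i, j = np.concatenate([i, j]), np.concatenate([j, i])
        ii.append(i)
        jj.append(j)
        sid.append(np.full(i.size, s, dtype=np.int64))
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(sid)


def _dedupe(genotypes: np.ndarray, pair_idx: np.ndarray):
    """Collapse identical (genotype, HLA pair) rows into weighted patterns."""
    key = np.column_stack([genotypes.astype(np.int16), pair_idx])
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return genotypes[first], pair_idx[first], counts.astype(float)


def _em(
    H: np.ndarray,
    hla_idx: np.ndarray,
    freqs: np.ndarray,
    genotypes: np.ndarray,
    pair_idx: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[float]]:
    """Run EM to convergence from the given starting frequencies."""
    n, K = genotypes.shape[0], H.shape[0]
    G, P, wts = _dedupe(genotypes, pair_idx)
    i, j, sid = _pair_arrays(H, hla_idx, G, P)
    f = freqs.astype(float).copy()
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        p = f[i] * f[j]
        L = np.bincount(sid, weights=p, minlength=G.shape[0])
        ll = float((wts * np.log(L)).sum())
        trace.append(ll)
        if prev > -np.inf and abs(ll - prev) <= tol * max(abs(prev), 1.0):
            break
        prev = ll
        w = (p / L[sid]) * wts[sid]
        c = np.bincount(i, weights=w, minlength=K) + np.bincount(j, weights=w, minlength=K)
        f = c / (2.0 * n)
    return f, trace


def _prune(
    H: np.ndarray, codes: list[str], f: np.ndarray, threshold: float
) -> tuple[np.ndarray, list[str], np.ndarray]:
    keep = f >= threshold
    if not keep.any():  # degenerate: keep the single best haplotype
        keep = f == f.max()
    H, f = H[keep], f[keep]
    codes = [c for c, k in zip(codes, keep) if k]
    # canonical row order: table output independent of sample/support order
    order = sorted(range(len(codes)), key=lambda k: (codes[k], tuple(H[k])))
    return H[order], [codes[k] for k in order], f[order] / f.sum()


def _as_pair_idx(hla_pairs, code_index: dict[str, int]) -> np.ndarray:
    out = np.empty((len(hla_pairs), 2), dtype=np.int64)
    for s, (a, b) in enumerate(hla_pairs):
        out[s, 0] = code_index[a]
        out[s, 1] = code_index[b]
    return out


def fit_haplotype_frequencies(
    genotypes,
    hla_pairs,
    marker_ids: list[str] | None = None,
    *,
    locus: str = "HLA",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    prune_threshold: float = DEFAULT_PRUNE,
) -> HaplotypeFrequencyTable:
    """Fit extended-haplotype frequencies by EM on unphased training data.

    Parameters
    ----------
    genotypes
        n x M array of 0/1/2 calls (−1 missing) over *marker_ids* (ordered).
    hla_pairs
        Sequence of n unordered 4-digit allele-code pairs, one per sample.
    marker_ids
        Ordered marker labels; defaults to ``snp0..snpM-1``.

    The support is the union over samples of all extended haplotypes
    compatible with the sample's genotypes and either of its HLA alleles;
    initial frequencies are uniform over that support.  The E-step weights
    each sample's compatible ordered haplotype pairs by f(e1)·f(e2); the
    M-step sets each frequency to its expected count over 2n chromosomes.
    Haplotypes below *prune_threshold* are removed afterwards and the table
    renormalised.
    """
    G = np.asarray(genotypes, dtype=np.int8)
    if G.ndim == 1:
        G = G.reshape(len(hla_pairs), -1)
    n, M = G.shape
    if n == 0 or n != len(hla_pairs):
        raise ValueError("need >= 1 training sample with one HLA pair each")
    if marker_ids is None:
        marker_ids = [f"snp{k}" for k in range(M)]
    if len(marker_ids) != M:
        raise ValueError("marker_ids length does not match genotype columns")

    hla_pairs = [pair_key(str(a), str(b)) for a, b in hla_pairs]
    support: dict[tuple[tuple[int, ...], str], int] = {}
    for s in range(n):
        vecs = _compatible_vectors(G[s])
        for code in set(hla_pairs[s]):
            for v in vecs:
                support.setdefault((v, code), len(support))

    K = len(support)
    H = np.array([v for v, _ in support], dtype=np.int8).reshape(K, M)
    codes = [c for _, c in support]
    code_list = sorted(set(codes))
    code_index = {c: k for k, c in enumerate(code_list)}
    hla_idx = np.array([code_index[c] for c in codes], dtype=np.int64)
    pair_idx = _as_pair_idx(hla_pairs, code_index)

    f0 = np.full(K, 1.0 / K)
    f, trace = _em(H, hla_idx, f0, G, pair_idx, tol, max_iter)
    H, codes, f = _prune(H, codes, f, prune_threshold)
    return HaplotypeFrequencyTable(
        locus=locus,
        marker_ids=list(marker_ids),
        haplotypes=H,
        hla_codes=codes,
        frequencies=f,
        prune_threshold=prune_threshold,
        loglik_trace=trace,
        n_train=n,
    )


def _refit(
    table: HaplotypeFrequencyTable,
    H: np.ndarray,
    codes: list[str],
    f0: np.ndarray,
    marker_ids: list[str],
    genotypes: np.ndarray,
    hla_pairs,
    tol: float,
    max_iter: int,
) -> HaplotypeFrequencyTable:
    code_list = sorted(set(codes) | {c for p in hla_pairs for c in p})
    code_index = {c: k for k, c in enumerate(code_list)}
    hla_idx = np.array([code_index[c] for c in codes], dtype=np.int64)
    pair_idx = _as_pair_idx([pair_key(a, b) for a, b in hla_pairs], code_index)
    f, trace = _em(H, hla_idx, f0, np.asarray(genotypes, dtype=np.int8), pair_idx, tol, max_iter)
    H, codes, f = _prune(H, codes, f, table.prune_threshold)
    return HaplotypeFrequencyTable(
        locus=table.locus,
        marker_ids=marker_ids,
        haplotypes=H,
        hla_codes=codes,
        frequencies=f,
        prune_threshold=table.prune_threshold,
        loglik_trace=trace,
        n_train=len(hla_pairs),
    )


def extend_table(
    table: HaplotypeFrequencyTable,
    new_marker_id: str,
    genotypes,
    hla_pairs,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> HaplotypeFrequencyTable:
    """Refit the model with one additional SNP appended to the marker list.

    Each retained haplotype spawns two children (appended allele 0/1), each
    inheriting half the parent frequency as the EM start -- a warm start that
    keeps forward selection tractable instead of re-enumerating the full
    support.  *genotypes* must cover ``table.marker_ids + [new_marker_id]``.
    """
    K = table.n_haplotypes
    H = np.concatenate(
        [
            np.hstack([table.haplotypes, np.zeros((K, 1), dtype=np.int8)]),
            np.hstack([table.haplotypes, np.ones((K, 1), dtype=np.int8)]),
        ]
    )
    codes = table.hla_codes + table.hla_codes
    f0 = np.concatenate([table.frequencies, table.frequencies]) / 2.0
    return _refit(
        table, H, codes, f0, table.marker_ids + [new_marker_id],
        genotypes, hla_pairs, tol, max_iter,
    )


def drop_marker(
    table: HaplotypeFrequencyTable,
    marker_id: str,
    genotypes,
    hla_pairs,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> HaplotypeFrequencyTable:
    """Refit the model with one SNP removed (haplotypes merged, then EM).

    *genotypes* must cover the reduced marker list (original order minus
    *marker_id*).
    """
    pos = table.marker_ids.index(marker_id)
    keep_cols = [k for k in range(len(table.marker_ids)) if k != pos]
    merged: dict[tuple[tuple[int, ...], str], float] = {}
    for row, code, fr in zip(table.haplotypes, table.hla_codes, table.frequencies):
        key = (tuple(int(row[k]) for k in keep_cols), code)
        merged[key] = merged.get(key, 0.0) + float(fr)
    H = np.array([v for v, _ in merged], dtype=np.int8).reshape(len(merged), len(keep_cols))
    codes = [c for _, c in merged]
    f0 = np.array(list(merged.values()))
    marker_ids = [table.marker_ids[k] for k in keep_cols]
    return _refit(table, H, codes, f0, marker_ids, genotypes, hla_pairs, tol, max_iter)


# ---------------------------------------------------------------------------
# Posterior prediction and confidence-threshold calling
# ---------------------------------------------------------------------------


def hla_posterior(
    table: HaplotypeFrequencyTable,
    genotype,
    smoothing: float = DEFAULT_SMOOTHING,
) -> dict[tuple[str, str], float]:
    """Posterior probability of each unordered HLA allele pair given genotypes.

    P(pair | G) is proportional to the summed f(e1)·f(e2) over ordered
    extended-haplotype pairs from the table whose per-site allele sums match
    G (missing sites unconstrained) and whose HLA alleles form the pair.  If
    no table pair matches G exactly, every pair is admitted with a per-site
    mismatch penalty factor of *smoothing*, so a distribution always exists.
    """
    if table.n_haplotypes == 0:
        raise ValueError("empty haplotype table")
    g = np.asarray(genotype, dtype=np.int8)
    if g.shape[0] != len(table.marker_ids):
        raise ValueError("genotype length does not match the model's marker count")
    H, f = table.haplotypes, table.frequencies
    nonmiss = g >= 0
    S = H[:, None, :] + H[None, :, :]
    ok = (~nonmiss | (S == g)).all(axis=2)
    W = np.outer(f, f) * ok
    if W.sum() <= 0.0:
        mism = ((S != g) & nonmiss).sum(axis=2)
        W = np.outer(f, f) * np.power(smoothing, mism)
    post: dict[tuple[str, str], float] = {}
    codes = table.hla_codes
    I, J = np.nonzero(W)
    for i, j in zip(I, J):
        k = pair_key(codes[i], codes[j])
        post[k] = post.get(k, 0.0) + W[i, j]
    total = sum(post.values())
    return {k: v / total for k, v in post.items()}


def call_genotype(posterior: dict[tuple[str, str], float], ct: float) -> CallResult:
    """Call the maximum-posterior HLA pair if it exceeds the threshold.

    Ties are broken by lexicographic order of the sorted allele-code pair.
    The comparison is strict (> ct); at ct = 0 every sample with a valid
    posterior is called.
    """
    if not 0.0 <= ct < 1.0:
        raise ValueError("ct must lie in [0, 1)")
    best_pair = min(posterior, key=lambda k: (-posterior[k], k))
    p = posterior[best_pair]
    return CallResult(best_pair=best_pair, max_posterior=p, called=p > ct, ct=ct)
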
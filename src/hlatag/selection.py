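"""Predictive-SNP selection and flanking-window sweeps.

Model choice follows a penalised conditional likelihood: the objective is the
negative log-likelihood of the observed HLA allele pairs given the unphased
SNP genotypes, plus an AIC penalty of two per free parameter (the K fitted
haplotype frequencies sum to one, so K − 1 parameters),

    score(model) = -sum_i log P(H_i | G_i) + 2 (K - 1).

SNPs enter by forward selection (the single extension that most lowers the
score, if any strictly lowers it) and leave by backward elimination after
every addition (any SNP whose removal lowers the score).  The flanking-window
sweep evaluates candidate windows around the gene by cross-validated accuracy
and applies the parsimonious rule: the smallest window (then the fewest SNPs)
among those reaching the best mean accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_MAX_ITER,
    DEFAULT_PRUNE,
    DEFAULT_SMOOTHING,
    DEFAULT_TOL,
    HaplotypeFrequencyTable,
    drop_marker,
    extend_table,
    fit_haplotype_frequencies,
    hla_posterior,
    pair_key,
)

__all__ = [
    "RegionConfig",
    "PredictionModel",
    "SweepResult",
    "model_objective",
    "select_snps",
    "sweep_flanking",
]

# Accepted moves must lower the objective by more than this guard, which only
# shields the comparison from float round-off, not from real ties.
_OBJ_EPS = 1e-9


@dataclass
class RegionConfig:
    """Gene coordinates plus the candidate flanking half-window grid (kb).

    Windows are 1-based inclusive: ``[gene_start - 1000*flank_kb,
    gene_stop + 1000*flank_kb]``, anchored at the gene start/stop.
    """

    gene_start: int
    gene_stop: int
    flank_grid: list[int] = field(default_factory=lambda: list(range(10, 401, 10)))

    def __post_init__(self) -> None:
        if self.gene_start >= self.gene_stop:
            raise ValueError("gene_start must be < gene_stop")
        if not self.flank_grid or any(
            b <= a for a, b in zip(self.flank_grid, self.flank_grid[1:])
        ):
            raise ValueError("flank grid must be non-empty and strictly increasing")

    def window(self, flank_kb: int) -> tuple[int, int]:
        return (self.gene_start - 1000 * flank_kb, self.gene_stop + 1000 * flank_kb)


@dataclass
class PredictionModel:
    """A trained predictor: ordered selected SNPs plus their frequency table."""

    locus: str
    marker_ids: list[str]  # in selection order
    table: HaplotypeFrequencyTable
    flank_kb: int | None = None
    objective: float | None = None
    n_train: int = 0
    seed: int | None = None
    smoothing: float = DEFAULT_SMOOTHING

    def posterior(self, genotype) -> dict[tuple[str, str], float]:
        return hla_posterior(self.table, genotype, smoothing=self.smoothing)


@dataclass
class SweepResult:
    """Per-flank sweep records and the parsimonious choice."""

    records: pd.DataFrame  # flank_kb, n_candidates, n_selected, mean_accuracy, call_rate
    chosen_flank_kb: int


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def model_objective(
    table: HaplotypeFrequencyTable,
    genotypes,
    hla_pairs,
    smoothing: float = DEFAULT_SMOOTHING,
) -> float:
    """Penalised negative conditional log-likelihood of HLA pairs given SNPs.

    For each sample, P(H_i | G_i) is the fitted posterior of the sample's
    true allele pair.  Samples whose true pair has no exact support under the
    (pruned) table are scored with the per-site mismatch-penalty weights, so
    the score is always finite.  The penalty term is 2 (K − 1) with K the
    number of retained haplotypes.
    """
    G = np.asarray(genotypes, dtype=np.int8)
    if G.ndim == 1:
        G = G.reshape(len(hla_pairs), -1)
    if G.shape[0] == 0:
        raise ValueError("cannot score an empty dataset")
    pairs = [pair_key(a, b) for a, b in hla_pairs]

    H, f = table.haplotypes, table.frequencies
    codes = np.asarray(table.hla_codes)
    T = H[:, None, :] + H[None, :, :]
    f_outer = np.outer(f, f)
    mask_cache: dict[tuple[str, str], np.ndarray] = {}

    def pair_mask(p):
        m = mask_cache.get(p)
        if m is None:
            a, b = p
            m = (codes[:, None] == a) & (codes[None, :] == b)
            m |= m.T
            mask_cache[p] = m
        return m

    # dedupe identical (genotype, pair) rows -- CV folds repeat patterns a lot
    pair_ids: dict[tuple[str, str], int] = {}
    pid = np.array([pair_ids.setdefault(p, len(pair_ids)) for p in pairs])
    key = np.column_stack([G.astype(np.int16), pid])
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    nll = 0.0
    for u, s in enumerate(first):
        g = G[s]
        nonmiss = g >= 0
        compat = (~nonmiss | (T == g)).all(axis=2)
        W = f_outer * compat
        num = float(W[pair_mask(pairs[s])].sum())
        if num <= 0.0:
            mism = ((T != g) & nonmiss).sum(axis=2)
            W = f_outer * np.power(smoothing, mism)
            num = float(W[pair_mask(pairs[s])].sum())
        den = float(W.sum())
        nll -= counts[u] * (np.log(num) - np.log(den))
    return float(nll + 2.0 * (table.n_haplotypes - 1))


# ---------------------------------------------------------------------------
# Forward selection / backward elimination
# ---------------------------------------------------------------------------


def _cand_order(markers: pd.DataFrame) -> list[str]:
    return markers.sort_values(["pos", "id"])["id"].tolist()


def select_snps(
    genotypes,
    markers: pd.DataFrame,
    hla_pairs,
    *,
    locus: str = "HLA",
    candidate_ids=None,
    max_snps: int = 30,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    prune_threshold: float = DEFAULT_PRUNE,
    smoothing: float = DEFAULT_SMOOTHING,
    preseed: list[str] | None = None,
    log=None,
) -> PredictionModel:
    """Select predictive SNPs by greedy forward/backward search on the AIC score.

    Starts from the marginal HLA-pair model (no SNPs).  At each forward step
    every single-SNP extension is fitted (warm-started from the current
    table) and scored; the best is added only if it strictly lowers the
    objective, then backward passes remove any SNP whose removal lowers it.
    Ties break by smaller genomic position, then lexicographic id, making the
    output deterministic and independent of candidate input order.  An empty
    candidate list yields the marginal model.  *preseed* forces an initial
    ordered SNP list into the model before the search.
    """
    G = np.asarray(genotypes, dtype=np.int8)
    n = G.shape[0]
    if n == 0 or n != len(hla_pairs):
        raise ValueError("genotypes and hla_pairs must align, with n >= 1")
    col_of = {mid: k for k, mid in enumerate(markers["id"])}
    pos_of = dict(zip(markers["id"], markers["pos"]))
    if candidate_ids is None:
        candidates = _cand_order(markers)
    else:
        candidates = _cand_order(markers[markers["id"].isin(set(candidate_ids))])
    em = dict(tol=tol, max_iter=max_iter)

    def cols(ids):
        return G[:, [col_of[i] for i in ids]]

    table = fit_haplotype_frequencies(
        G[:, :0], hla_pairs, [], locus=locus,
        tol=tol, max_iter=max_iter, prune_threshold=prune_threshold,
    )
    selected: list[str] = []
    for mid in preseed or []:
        table = extend_table(table, mid, cols(selected + [mid]), hla_pairs, **em)
        selected.append(mid)
    obj = model_objective(table, cols(selected), hla_pairs, smoothing)

    while len(selected) < max_snps:
        best = None
        for cid in candidates:
            if cid in selected:
                continue
            t = extend_table(table, cid, cols(selected + [cid]), hla_pairs, **em)
            o = model_objective(t, cols(selected + [cid]), hla_pairs, smoothing)
            cand_key = (o, pos_of[cid], cid)
            if best is None or cand_key < best[0]:
                best = (cand_key, cid, t)
            if log:
                log(f"forward? +{cid} objective={o:.6f} (current {obj:.6f})")
        if best is None or best[0][0] >= obj - _OBJ_EPS:
            break
        _, cid, table = best
        obj = best[0][0]
        selected.append(cid)
        if log:
            log(f"accepted +{cid} objective={obj:.6f}")

        # backward elimination after every forward step
        while len(selected) > 1:
            best_rm = None
            for mid in selected:
                rest = [x for x in selected if x != mid]
                t = drop_marker(table, mid, cols(rest), hla_pairs, **em)
                o = model_objective(t, cols(rest), hla_pairs, smoothing)
                rm_key = (o, pos_of[mid], mid)
                if best_rm is None or rm_key < best_rm[0]:
                    best_rm = (rm_key, mid, t)
            if best_rm is None or best_rm[0][0] >= obj - _OBJ_EPS:
                break
            _, mid, table = best_rm
            obj = best_rm[0][0]
            selected.remove(mid)
            if log:
                log(f"removed -{mid} objective={obj:.6f}")

    return PredictionModel(
        locus=locus,
        marker_ids=list(selected),
        table=table,
        objective=float(obj),
        n_train=n,
        smoothing=smoothing,
    )


# ---------------------------------------------------------------------------
# Flanking-window sweep
# ---------------------------------------------------------------------------


def sweep_flanking(
    dataset,
    locus: str,
    region: RegionConfig,
    *,
    k: int = 10,
    seed: int = 0,
    ct: float = 0.0,
    **select_kwargs,
) -> SweepResult:
    """Evaluate each flanking half-window and apply the parsimonious rule.

    For every grid value the candidate SNPs are restricted to the window,
    models are selected inside k-fold cross-validation (accuracy recorded at
    the given CT), and a final model is trained on the full data to report
    the selected-SNP count.  The chosen flank is the smallest grid value
    attaining the maximum mean CV accuracy (ties then broken by fewest
    selected SNPs).  A window with zero markers is scored with the marginal
    model, not treated as an error.
    """
    from .metrics import cross_validate  # local import to avoid a module cycle

    rows_idx, pairs = dataset.hla_pairs(locus)
    recs = []
    for flank in region.flank_grid:
        lo, hi = region.window(flank)
        in_win = (dataset.markers["pos"] >= lo) & (dataset.markers["pos"] <= hi)
        cand = dataset.markers.loc[in_win, "id"].tolist()
        rep = cross_validate(
            dataset, locus, k=k, ct=ct, seed=seed, candidate_ids=cand, **select_kwargs
        )
        final = select_snps(
            dataset.genotypes[rows_idx],
            dataset.markers,
            pairs,
            locus=locus,
            candidate_ids=cand,
            **select_kwargs,
        )
        recs.append(
            {
                "flank_kb": flank,
                "n_candidates": len(cand),
                "n_selected": len(final.marker_ids),
                "mean_accuracy": rep.mean_accuracy,
                "call_rate": rep.call_rate,
            }
        )
    records = pd.DataFrame(recs)
    best = records["mean_accuracy"].max()
    tied = records[records["mean_accuracy"] >= best - 1e-12]
    tied = tied.sort_values(["flank_kb", "n_selected"])
    return SweepResult(records=records, chosen_flank_kb=int(tied.iloc[0]["flank_kb"]))
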
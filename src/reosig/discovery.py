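"""Discovery of a rank-based gene-pair signature from a training cohort.

Three screening stages followed by a greedy search:

1. **Differential expression** — genes separating pathological complete
   responders (CR) from non-responders (non-CR) by pooled-variance
   t-test at p < alpha, then genes whose continuous expression is
   associated with recurrence-free survival by univariate Cox at
   p < alpha.  This stage uses the quantitative values.
2. **Prognostic pairs** — every unordered pair of surviving genes is
   reduced to its within-sample ordering indicator 1[E_a > E_b]; a
   univariate Cox fit on the indicator, oriented so the favorable
   pattern has hazard ratio < 1, is kept at BH-adjusted q < fdr.  From
   here on only order information is consumed, which is what makes the
   final signature invariant to per-sample monotone distortions.
3. **Forward selection** — starting from each surviving pair as a seed,
   greedily grow a voting committee by the pairs that most increase the
   concordance index of the strict-majority vote; the seed-grown set
   with the largest final C-index is the signature.

The committee is grown two pairs at a time so its size stays odd: an
even-sized strict-majority vote is structurally conservative (a split
vote defaults to non-responder), which makes the C-index dip at every
even size and would stall a one-at-a-time search regardless of how
informative the remaining pairs are.  C-index differences smaller than
the statistic's sampling resolution (``cindex_tol``, default 0.01 —
roughly its standard error at a few hundred observed events) are
treated as ties and resolved by the strength of the pair-level survival
association, so the search prefers strongly associated pairs whenever
predictive performance is statistically indistinguishable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import (
    NON_RESPONDER,
    GenePairSignature,
    OrientedGenePair,
    indicator_matrix,
    labels_from_votes,
    reo_indicator,
)
from .data import DataError, ExpressionMatrix
from .stats import (
    DegenerateCovariateError,
    StatsError,
    SurvivalData,
    bh_fdr,
    concordance_index,
    cox_fit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ForwardSelectionTrace",
    "select_de_genes",
    "select_prognostic_genes",
    "enumerate_candidate_pairs",
    "select_prognostic_pairs",
    "signature_cindex",
    "forward_select_signature",
]

#: C-index differences below this are sampling noise, not evidence:
#: roughly the standard error of Harrell's C at a few hundred events.
CINDEX_TOL = 0.01


@dataclass
class ForwardSelectionTrace:
    """Growth paths of the seeded greedy search.

    ``paths[i]`` lists, for seed i, the (pair, resulting C-index) steps
    of its growth; both pairs of a two-at-a-time step carry the same
    resulting C-index.  Along each path the C-index never drops by more
    than the selection tolerance between consecutive steps.
    ``chosen_seed`` indexes the path whose final set was returned.
    """

    paths: list[list[tuple[OrientedGenePair, float]]]
    chosen_seed: int


def _align_labels(expr: ExpressionMatrix, response_labels) -> pd.Series:
    if isinstance(response_labels, pd.Series):
        return response_labels.reindex(expr.sample_ids)
    arr = pd.Series(list(response_labels), index=expr.sample_ids)
    return arr


def select_de_genes(expr: ExpressionMatrix, response_labels, alpha: float = 0.05) -> list[str]:
    """Genes differentially expressed between CR and non-CR samples.

    Pooled-variance two-sample t-test per gene, two-sided p strictly
    below ``alpha``.  Samples with a missing response state are
    excluded; genes with zero pooled variance are skipped with a logged
    warning.
    """
    labels = _align_labels(expr, response_labels)
    cr_mask = (labels == "CR").to_numpy()
    noncr_mask = (labels == "nonCR").to_numpy()
    if cr_mask.sum() < 2 or noncr_mask.sum() < 2:
        raise DataError("both CR and non-CR groups need at least 2 samples")
    values = expr.data.to_numpy(dtype=float)
    x = values[:, cr_mask]
    y = values[:, noncr_mask]
    from scipy import stats as sps

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes
        _, p = sps.ttest_ind(x, y, axis=1, equal_var=True)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning("%d degenerate genes skipped in DE screening", degenerate.sum())
    keep = np.isfinite(p) & (p < alpha)
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def select_prognostic_genes(
    expr: ExpressionMatrix,
    survival: SurvivalData,
    candidate_genes,
    alpha: float = 0.05,
) -> list[str]:
    """Candidates whose continuous expression predicts survival.

    Univariate Cox on each gene's expression; kept at Wald p strictly
    below ``alpha``.  Degenerate or non-converging genes are excluded
    with a logged warning.
    """
    candidates = list(candidate_genes)
    missing = sorted(set(candidates) - set(expr.gene_ids))
    if missing:
        raise DataError(f"candidate genes not in matrix: {missing}")
    selected = []
    for gene in candidates:
        vals = expr.values_for(gene)
        try:
            fit = cox_fit(pd.DataFrame({gene: vals}), survival)
        except DegenerateCovariateError:
            logger.warning("gene %s degenerate, skipped", gene)
            continue
        if not fit.converged:
            logger.warning("gene %s: Cox fit did not converge, skipped", gene)
            continue
        if fit.p_values[0] < alpha:
            selected.append(gene)
    return selected


def enumerate_candidate_pairs(genes) -> list[tuple[str, str]]:
    """All C(m, 2) unordered pairs in lexicographic order."""
    genes = list(genes)
    if len(genes) != len(set(genes)):
        raise DataError("duplicate gene in candidate list")
    if len(genes) < 2:
        raise DataError("need at least 2 genes to form pairs")
    return list(itertools.combinations(sorted(genes), 2))


def select_prognostic_pairs(
    expr: ExpressionMatrix,
    candidate_pairs,
    survival: SurvivalData,
    fdr: float = 0.05,
) -> list[OrientedGenePair]:
    """Oriented pairs whose ordering indicator predicts survival at FDR.

    For each candidate the Cox model is fit on the binary indicator
    1[E_a > E_b]; the pair is oriented so the favorable pattern carries
    hazard ratio < 1.  Wald p-values are BH-adjusted over all tested
    pairs and pairs with q strictly below ``fdr`` are kept, each
    annotated with the concordance index of its single-pair vote
    (risk 1 for the unfavorable ordering).
    """
    tested: list[OrientedGenePair] = []
    pvals: list[float] = []
    for a, b in candidate_pairs:
        pair = OrientedGenePair(a, b)
        ind = reo_indicator(expr, pair)
        if ind.min() == ind.max():
            continue  # ordering constant across the cohort: no information
        try:
            fit = cox_fit(pd.DataFrame({"reo": ind.astype(float)}), survival)
        except StatsError as exc:
            logger.warning("pair %s>%s: %s, skipped", a, b, exc)
            continue
        if not fit.converged:
            logger.warning("pair %s>%s: Cox fit did not converge, skipped", a, b)
            continue
        coef = fit.coef[0]
        if coef > 0:
            # indicator=1 raises hazard: favorable pattern is E_b > E_a
            pair = OrientedGenePair(b, a, pair_hr=float(np.exp(-coef)))
        else:
            pair = OrientedGenePair(a, b, pair_hr=float(np.exp(coef)))
        pair = replace(pair, pair_p=float(fit.p_values[0]))
        tested.append(pair)
        pvals.append(pair.pair_p)
    if not tested:
        return []
    qvals = bh_fdr(pvals)
    selected = []
    for pair, q in zip(tested, qvals):
        if q < fdr:
            risk = 1.0 - reo_indicator(expr, pair)  # favorable = low risk
            cidx = concordance_index(risk, survival)
            selected.append(replace(pair, pair_q=float(q), pair_cindex=cidx))
    return selected


def _cindex_from_indicators(ind: np.ndarray, survival: SurvivalData) -> float:
    """C-index of the strict-majority vote encoded by indicator rows."""
    counts = ind.sum(axis=0)
    labels = labels_from_votes(counts, ind.shape[0])
    risk = (labels == NON_RESPONDER).astype(float)
    return concordance_index(risk, survival)


def signature_cindex(expr: ExpressionMatrix, pairs, survival: SurvivalData) -> float:
    """Concordance index of the strict-majority vote of ``pairs``.

    Risk score 1 for predicted non-responders, 0 for responders.
    """
    pairs = list(pairs)
    if not pairs:
        raise DataError("need at least one pair")
    return _cindex_from_indicators(indicator_matrix(expr, pairs), survival)


def _candidate_sort_key(pair: OrientedGenePair):
    q = pair.pair_q if pair.pair_q is not None else np.inf
    return (q, pair.gene_a, pair.gene_b)


def forward_select_signature(
    expr: ExpressionMatrix,
    prognostic_pairs,
    survival: SurvivalData,
    cindex_tol: float = CINDEX_TOL,
) -> tuple[GenePairSignature, ForwardSelectionTrace]:
    """Seeded greedy search for the best-concordance majority vote.

    Every prognostic pair serves once as a seed.  From a seed the
    committee grows two pairs at a time (sizes stay odd so every step
    is judged on a decision-coherent vote): the addition with the
    highest resulting C-index is chosen, candidates within
    ``cindex_tol`` of the best counting as tied and resolved by the
    strongest weakest member (smallest maximum pair-level q) then
    lexicographic pair name.  Growth stops when the chosen addition
    worsens the C-index by more than ``cindex_tol``.  The final
    signature is chosen among the seed-grown sets at the same
    resolution: within ``cindex_tol`` of the best final C-index, the
    committee whose weakest member has the strongest survival
    association wins (then fewest pairs, then lexicographic pair
    names); the whole search is deterministic.
    """
    pool = list(prognostic_pairs)
    if not pool:
        raise DataError("forward selection needs at least one prognostic pair")
    indicators = indicator_matrix(expr, pool)

    paths: list[list[tuple[OrientedGenePair, float]]] = []
    finals: list[tuple[float, int, tuple[str, ...], list[int]]] = []
    for seed_idx in range(len(pool)):
        chosen = [seed_idx]
        current_c = _cindex_from_indicators(indicators[chosen], survival)
        path = [(pool[seed_idx], current_c)]
        remaining = [i for i in range(len(pool)) if i != seed_idx]
        while len(remaining) >= 2:
            best_c = -np.inf
            scores: dict[tuple[int, int], float] = {}
            for ij in itertools.combinations(remaining, 2):
                c = _cindex_from_indicators(indicators[chosen + list(ij)], survival)
                scores[ij] = c
                best_c = max(best_c, c)
            tied = [ij for ij, c in scores.items() if c >= best_c - cindex_tol]
            # rank tied doubles by their weakest member so a weak pair
            # cannot ride in on a strong partner's association
            pick = min(
                tied,
                key=lambda ij: max(
                    _candidate_sort_key(pool[ij[0]]), _candidate_sort_key(pool[ij[1]])
                ),
            )
            pick_c = scores[pick]
            if pick_c < current_c - cindex_tol:
                break
            chosen.extend(pick)
            for i in pick:
                remaining.remove(i)
            current_c = pick_c
            path.extend((pool[i], current_c) for i in pick)
        paths.append(path)
        names = tuple(sorted(pool[i].name for i in chosen))
        weakest_q = max(
            (p.pair_q if (p := pool[i]).pair_q is not None else np.inf)
            for i in chosen
        )
        finals.append((current_c, weakest_q, len(chosen), names, chosen))

    # Largest C-index, judged at the same resolution as the growth steps:
    # among seed-grown sets within cindex_tol of the best, prefer the
    # committee whose weakest member has the strongest survival
    # association, then fewest pairs, then lexicographic pair names.
    best_c_overall = max(f[0] for f in finals)
    contenders = [s for s in range(len(finals)) if finals[s][0] >= best_c_overall - cindex_tol]
    best_seed = min(contenders, key=lambda s: (finals[s][1], finals[s][2], finals[s][3]))
    final_c, _, _, _, chosen = finals[best_seed]
    signature = GenePairSignature(
        pairs=tuple(pool[i] for i in chosen),
        rule="strict_majority",
        training_cindex=float(final_c),
    )
    return signature, ForwardSelectionTrace(paths=paths, chosen_seed=best_seed)
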
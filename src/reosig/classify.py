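"""Gene-pair signature classification by within-sample orderings.

A :class:`GenePairSignature` is an ordered set of oriented gene pairs
(a, b) where the favorable pattern — the one associated with longer
recurrence-free survival — is Ea > Eb.  A sample is called a responder
iff strictly more than half of its pairs show the favorable ordering.
Because the rule consumes only the within-sample order of two values,
it is invariant to any strictly increasing per-sample transform and can
be applied to a single sample in isolation.

Also provided: the published four-pair ovarian-cancer signature
(:func:`four_gps`) and the median-anchored point-score comparator
(:func:`quant_score_classify`), a quantitative rule whose labels depend
on the composition of the scored cohort — the failure mode the
rank-based signature is designed to avoid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import DataError, ExpressionMatrix

__all__ = [
    "OrientedGenePair",
    "GenePairSignature",
    "PredictionResult",
    "QuantSignatureSpec",
    "reo_indicator",
    "vote_classify",
    "four_gps",
    "quant_score_classify",
    "RESPONDER",
    "NON_RESPONDER",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass(frozen=True)
class OrientedGenePair:
    """Ordered gene pair; favorable pattern is E[gene_a] > E[gene_b].

    For pairs selected by survival screening the attached statistics
    describe the favorable pattern: ``pair_hr`` < 1 (lower recurrence
    hazard), with Wald p, BH-adjusted q, and the concordance index of
    the single-pair vote.
    """

    gene_a: str
    gene_b: str
    pair_hr: float | None = None
    pair_p: float | None = None
    pair_q: float | None = None
    pair_cindex: float | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DataError(f"gene pair must use two distinct genes: {self.gene_a}")

    @property
    def unordered(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))

    @property
    def name(self) -> str:
        return f"{self.gene_a}>{self.gene_b}"

    def flipped(self) -> "OrientedGenePair":
        hr = None if self.pair_hr is None else 1.0 / self.pair_hr
        return replace(self, gene_a=self.gene_b, gene_b=self.gene_a, pair_hr=hr)


@dataclass(frozen=True)
class GenePairSignature:
    """Ordered collection of oriented pairs with strict-majority voting."""

    pairs: tuple[OrientedGenePair, ...]
    rule: str = "strict_majority"
    training_cindex: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if len(self.pairs) < 1:
            raise DataError("signature needs at least one pair")
        unordered = [p.unordered for p in self.pairs]
        if len(set(unordered)) != len(unordered):
            raise DataError("signature contains a duplicate gene pair")
        if self.rule != "strict_majority":
            raise DataError(f"unknown voting rule {self.rule!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend((p.gene_a, p.gene_b))
        return out

    def to_json(self) -> str:
        payload = {
            "pairs": [{"gene_a": p.gene_a, "gene_b": p.gene_b} for p in self.pairs],
            "rule": self.rule,
            "training_cindex": self.training_cindex,
        }
        return json.dumps(payload, indent=2, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "GenePairSignature":
        payload = json.loads(text)
        pairs = tuple(
            OrientedGenePair(p["gene_a"], p["gene_b"]) for p in payload["pairs"]
        )
        return cls(
            pairs=pairs,
            rule=payload.get("rule", "strict_majority"),
            training_cindex=payload.get("training_cindex"),
        )


@dataclass
class PredictionResult:
    """Per-sample favorable-vote counts and responder labels."""

    sample_ids: list[str]
    vote_counts: np.ndarray
    labels: np.ndarray  # RESPONDER / NON_RESPONDER
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vote_count": self.vote_counts, "label": self.labels},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def subset(self, sample_ids) -> "PredictionResult":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PredictionResult(
            sample_ids=list(sample_ids),
            vote_counts=self.vote_counts[idx],
            labels=self.labels[idx],
            n_pairs=self.n_pairs,
        )


def reo_indicator(expr: ExpressionMatrix, pair: OrientedGenePair) -> np.ndarray:
    """Per-sample indicator of the favorable ordering E_a > E_b.

    Strict inequality; a tie (E_a = E_b) counts as not favorable.  The
    indicator depends only on the within-sample order of the two values,
    so it is unchanged by any strictly increasing per-sample transform.
    """
    for gene in (pair.gene_a, pair.gene_b):
        if gene not in expr.data.index:
            raise DataError(f"gene {gene!r} not in expression matrix")
    a = expr.data.loc[pair.gene_a].to_numpy(dtype=float)
    b = expr.data.loc[pair.gene_b].to_numpy(dtype=float)
    return (a > b).astype(int)


def indicator_matrix(expr: ExpressionMatrix, pairs) -> np.ndarray:
    """Stack of REO indicators, one row per pair (pairs x samples)."""
    return np.vstack([reo_indicator(expr, p) for p in pairs])


def labels_from_votes(vote_counts: np.ndarray, n_pairs: int) -> np.ndarray:
    """Strict-majority rule: responder iff favorable count > n_pairs / 2."""
    return np.where(vote_counts * 2 > n_pairs, RESPONDER, NON_RESPONDER)


def vote_classify(expr: ExpressionMatrix, signature: GenePairSignature) -> PredictionResult:
    """Classify each sample by strict-majority vote over the signature.

    Each sample's label depends only on that sample's own values.
    Missing signature genes raise an error listing all of them.
    """
    missing = sorted(set(signature.genes) - set(expr.gene_ids))
    if missing:
        raise DataError(f"signature genes missing from expression matrix: {missing}")
    ind = indicator_matrix(expr, signature.pairs)
    counts = ind.sum(axis=0)
    return PredictionResult(
        sample_ids=expr.sample_ids,
        vote_counts=counts,
        labels=labels_from_votes(counts, len(signature)),
        n_pairs=len(signature),
    )


def four_gps() -> GenePairSignature:
    """The published four-pair ovarian-cancer response signature.

    Favorable orderings: FUS > THBS2, GUCY2C > RCVRN, PCSK6 > ZNF365,
    PASK > DNAJB14; a sample is a responder iff more than two of the
    four pairs show the favorable ordering.
    """
    return GenePairSignature(
        pairs=(
            OrientedGenePair("FUS", "THBS2"),
            OrientedGenePair("GUCY2C", "RCVRN"),
            OrientedGenePair("PCSK6", "ZNF365"),
            OrientedGenePair("PASK", "DNAJB14"),
        ),
        rule="strict_majority",
    )


@dataclass(frozen=True)
class QuantSignatureSpec:
    """Median-anchored point-score comparator specification.

    One point per gene when its expression lies on the good side of the
    cohort median for that gene (above for ``high_good`` genes, below
    for ``high_bad``); a sample is high-risk (non-responder) when its
    total score is strictly below ``threshold``.
    """

    genes: tuple[tuple[str, str], ...]  # (gene_id, direction)
    threshold: int

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise DataError("comparator spec needs at least one gene")
        for gene, direction in self.genes:
            if direction not in ("high_good", "high_bad"):
                raise DataError(f"unknown direction {direction!r} for gene {gene!r}")
        if not 0 <= self.threshold <= len(self.genes):
            raise DataError("threshold must lie within [0, n_genes]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": [{"gene": g, "direction": d} for g, d in self.genes],
                "threshold": self.threshold,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "QuantSignatureSpec":
        payload = json.loads(text)
        return cls(
            genes=tuple((g["gene"], g["direction"]) for g in payload["genes"]),
            threshold=int(payload["threshold"]),
        )


def quant_score_classify(
    expr: ExpressionMatrix, spec: QuantSignatureSpec
) -> tuple[PredictionResult, np.ndarray]:
    """Score-based classification anchored at cohort gene medians.

    Unlike the rank-based vote, each sample's label depends on the
    cohort it is scored with: the per-gene median moves when the cohort
    composition changes, so the same sample can flip label.  Values
    exactly at the median earn no point (median = midpoint of the two
    central order statistics for even cohorts).  Requires >= 2 samples.
    """
    if expr.shape[1] < 2:
        raise DataError("comparator requires a cohort (>= 2 samples)")
    missing = sorted({g for g, _ in spec.genes} - set(expr.gene_ids))
    if missing:
        raise DataError(f"comparator genes missing from expression matrix: {missing}")
    scores = np.zeros(expr.shape[1], dtype=int)
    for gene, direction in spec.genes:
        vals = expr.data.loc[gene].to_numpy(dtype=float)
        med = float(np.median(vals))
        if direction == "high_good":
            scores += (vals > med).astype(int)
        else:
            scores += (vals < med).astype(int)
    labels = np.where(scores < spec.threshold, NON_RESPONDER, RESPONDER)
    result = PredictionResult(
        sample_ids=expr.sample_ids,
        vote_counts=scores,
        labels=labels,
        n_pairs=len(spec.genes),
    )
    return result, scores
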
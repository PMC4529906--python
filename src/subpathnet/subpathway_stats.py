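"""Sign-consistency scoring of subpathways against fold-change data.

A gene is *up* when its case/control ratio exceeds 1, *down* below 1 and
*neutral* at exactly 1. An activation edge is consistent when source and
target share a direction; an inhibition edge when they oppose; a neutral
endpoint breaks consistency. The per-chain statistic is the number of
consistent edges, and two null models turn it into a P-value:

* an analytic binomial null (each edge consistent with probability ½,
  one-sided upper tail) — deterministic, the default;
* a label-permutation null that reassigns the dataset's observed
  fold-changes to genes at random, which preserves the empirical
  direction imbalance of the dataset.

Both are deliberately sign-based: fold-change *magnitudes* never enter the
statistic, so chains reported here are comparable across datasets with
different dynamic ranges.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .pathway_io import ACTIVATION, INHIBITION, ExpressionDataset, Subpathway

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
Direction = Literal["up", "down", "neutral"]


@dataclass(frozen=True)
class ScoredSubpathway:
    """A subpathway with its fold-changes, consistency count and P-value."""

    subpathway: Subpathway
    fold_changes: Mapping[str, float]
    consistent_edges: int
    total_edges: int
    p_value: float
    dataset_id: str

    def __post_init__(self):
        if not 0 <= self.consistent_edges <= self.total_edges:
            raise ValidationError(
                f"consistent_edges {self.consistent_edges} outside "
                f"[0, {self.total_edges}]"
            )
        if self.total_edges != self.subpathway.n_edges:
            raise ValidationError("total_edges must equal the chain's edge count")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


def direction(fc: float) -> Direction:
    """Direction of a case/control ratio: up (>1), down (<1) or neutral (==1)."""
    if fc <= 0 or not math.isfinite(fc):
        raise ValueError(f"fold-change must be a positive finite ratio, got {fc}")
    if fc > 1:
        return "up"
    if fc < 1:
        return "down"
    return "neutral"


def edge_consistency(source_fc: float, target_fc: float, sign: int) -> bool:
    """Does a signed edge agree with its endpoint directions?

    Activation (+1): consistent iff both endpoints share a direction.
    Inhibition (−1): consistent iff the directions oppose.
    A neutral endpoint (ratio exactly 1) is never consistent.
    """
    if sign not in (ACTIVATION, INHIBITION):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    ds, dt = direction(source_fc), direction(target_fc)
    if "neutral" in (ds, dt):
        return False
    return (ds == dt) if sign == ACTIVATION else (ds != dt)


def score_subpathway(
    sub: Subpathway, data: ExpressionDataset
) -> tuple[int, int]:
    """Count consistent edges along a chain; returns ``(consistent, total)``.

    Raises :class:`KeyError` when a chain gene has no fold-change in the
    dataset; batch scoring (:func:`score_subpathways`) treats that as
    "not scorable" and skips the chain instead.
    """
    missing = [n for n in sub.nodes if n not in data.fold_changes]
    if missing:
        raise KeyError(
            f"gene(s) {', '.join(missing)} not measured in {data.dataset_id}"
        )
    fcs = data.fold_changes
    consistent = sum(
        edge_consistency(fcs[u], fcs[v], s) for u, v, s in sub.edges()
    )
    return consistent, sub.n_edges


def binomial_pvalue(consistent: int, total: int) -> float:
    """One-sided upper-tail binomial P: ``P(X >= consistent | n=total, p=1/2)``."""
    if total < 1:
        raise ValueError(f"total must be >= 1, got {total}")
    if not 0 <= consistent <= total:
        raise ValueError(f"consistent {consistent} outside [0, {total}]")
    return float(stats.binom.sf(consistent - 1, total, 0.5))


def _chain_scores(values: np.ndarray, signs: Sequence[int]) -> np.ndarray:
    """Consistent-edge counts for rows of fold-change assignments.

    ``values`` has shape ``(m, k)``: m assignments of ratios to the k chain
    positions. An edge is consistent iff the product of its endpoint
    direction signs (+1 up, −1 down, 0 neutral) equals the edge sign.
    """
    d = np.sign(np.log(values))
    prod = d[:, :-1] * d[:, 1:]
    return (prod == np.asarray(signs)).sum(axis=1)


def permutation_pvalue(
    sub: Subpathway,
    data: ExpressionDataset,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    exhaustive: bool = False,
) -> float:
    """Permutation P-value for a chain's consistency count.

    The null reassigns the dataset's observed fold-changes to genes uniformly
    at random (equivalently: draws an ordered sample of ``k`` distinct
    fold-changes from the gene universe for the chain's ``k`` positions) and
    recomputes the consistent-edge count. Monte-Carlo mode returns the
    add-one estimate ``(1 + #{perm >= observed}) / (n_perm + 1)``, which is
    never zero; ``exhaustive=True`` enumerates every ordered assignment
    (feasible for small universes) and returns the exact fraction.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    genes = sorted(data.fold_changes)
    k = len(sub.nodes)
    if len(genes) < k:
        raise ValueError(
            f"gene universe ({len(genes)}) smaller than the chain ({k} nodes)"
        )
    observed, _ = score_subpathway(sub, data)
    values = np.array([data.fold_changes[g] for g in genes])

    if exhaustive:
        hits = total = 0
        for combo in itertools.permutations(values, k):
            arr = np.asarray(combo)[None, :]
            hits += int(_chain_scores(arr, sub.signs)[0] >= observed)
            total += 1
        return hits / total

    rng = np.random.default_rng(seed)
    # Ordered sample without replacement per permutation: sort random keys
    # and keep the first k columns.
    keys = rng.random((n_perm, len(values)))
    idx = np.argsort(keys, axis=1)[:, :k]
    scores = _chain_scores(values[idx], sub.signs)
    return (1 + int((scores >= observed).sum())) / (n_perm + 1)


def score_subpathways(
    subpathways: Iterable[Subpathway],
    data: ExpressionDataset,
    null: Literal["binomial", "permutation"] = "binomial",
    n_perm: int = 1_000,
    seed: int | None = None,
) -> list[ScoredSubpathway]:
    """Score every chain against one dataset; chains with unmeasured genes are skipped."""
    if null not in ("binomial", "permutation"):
        raise ValueError(f"null must be 'binomial' or 'permutation', got {null!r}")
    seed_seq = np.random.SeedSequence(seed)
    scored: list[ScoredSubpathway] = []
    skipped = 0
    for i, sub in enumerate(subpathways):
        try:
            consistent, total = score_subpathway(sub, data)
        except KeyError:
            skipped += 1
            continue
        if null == "binomial":
            p = binomial_pvalue(consistent, total)
        else:
            p = permutation_pvalue(sub, data, n_perm=n_perm, seed=seed_seq.spawn(1)[0])
        fcs = {g: data.fold_changes[g] for g in sub.nodes}
        scored.append(
            ScoredSubpathway(sub, fcs, consistent, total, p, data.dataset_id)
        )
    if skipped:
        logger.info(
            "skipped %d/%d subpathways with genes unmeasured in %s",
            skipped, skipped + len(scored), data.dataset_id,
        )
    return scored


def significant_subpathways(
    scored: Iterable[ScoredSubpathway], alpha: float = DEFAULT_ALPHA
) -> list[ScoredSubpathway]:
    """Retain chains with ``p_value`` strictly below ``alpha``; order preserved."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return [s for s in scored if s.p_value < alpha]


def benjamini_hochberg(scored: Sequence[ScoredSubpathway]) -> list[ScoredSubpathway]:
    """Return copies with Benjamini–Hochberg-adjusted P-values (optional rigor)."""
    from statsmodels.stats.multitest import multipletests

    if not scored:
        return []
    adjusted = multipletests([s.p_value for s in scored], method="fdr_bh")[1]
    return [replace(s, p_value=float(p)) for s, p in zip(scored, adjusted)]
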
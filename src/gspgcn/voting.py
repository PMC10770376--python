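"""Trial-level hard voting with the consecutive-pair tie-break.

Each subject contributes a pool of per-trial classification labels
(0 = patient/PD, 1 = healthy control).  A verification round draws 10 labels,
takes the majority, and on a 5-5 tie applies the consecutive-pair counting
rule (a Boyer-Moore-style cancellation scan): equal neighbouring votes
increment that label's counter, unequal neighbours cancel.  The worked
contract: {0,1,1,0,1,0,0,1,1,0} gives BM0 = 1, BM1 = 2 -> healthy.

A double tie (BM0 = BM1, e.g. a strictly alternating draw) resolves to
healthy (label 1, the benign default) and is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["VoteOutcome", "bm_counts", "vote_once", "posterior_verify"]

logger = logging.getLogger(__name__)

DRAW_SIZE = 10


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise InvalidArgumentError("labels must be a 1-D sequence")
    if not np.isin(labels, (0, 1)).all():
        raise InvalidArgumentError("labels must be binary (0 = PD, 1 = healthy)")
    return labels


def bm_counts(labels) -> tuple[int, int]:
    """Scan consecutive pairs: equal pairs increment that label's counter,
    unequal pairs cancel.  Returns (BM0, BM1)."""
    labels = _check_binary(np.asarray(labels))
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 labels to scan pairs")
    eq = labels[:-1] == labels[1:]
    bm1 = int(np.sum(eq & (labels[:-1] == 1)))
    bm0 = int(np.sum(eq & (labels[:-1] == 0)))
    return bm0, bm1


@dataclass(frozen=True)
class VoteOutcome:
    N0: int
    N1: int
    BM0: int | None
    BM1: int | None
    decision: int  # 0 = PD, 1 = healthy
    path: str  # "majority" | "boyer_moore"


def vote_once(labels) -> VoteOutcome:
    """Decide one subject from a 10-label draw.

    Majority rules; on N0 = N1 the consecutive-pair counts decide; a BM
    double tie defaults to healthy.
    """
    labels = _check_binary(np.asarray(labels))
    if len(labels) != DRAW_SIZE:
        raise InvalidArgumentError(f"vote_once needs exactly {DRAW_SIZE} labels")
    n1 = int(labels.sum())
    n0 = DRAW_SIZE - n1
    if n0 != n1:
        return VoteOutcome(n0, n1, None, None, 0 if n0 > n1 else 1, "majority")
    bm0, bm1 = bm_counts(labels)
    if bm0 == bm1:
        logger.info("BM double tie (BM0 = BM1 = %d): defaulting to healthy", bm0)
        return VoteOutcome(n0, n1, bm0, bm1, 1, "boyer_moore")
    return VoteOutcome(n0, n1, bm0, bm1, 0 if bm0 > bm1 else 1, "boyer_moore")


def posterior_verify(
    trial_labels_per_subject,
    true_groups,
    repeats: int = 100,
    draw: int = DRAW_SIZE,
    seed: int = 0,
) -> dict:
    """Repeated-draw verification of per-trial labels.

    For every repetition, draw ``draw`` labels per subject without
    replacement, decide by :func:`vote_once`, and score against the true
    groups.  Returns the mean and variance of accuracy over repetitions.
    """
    if draw != DRAW_SIZE:
        raise InvalidArgumentError(f"the voting rule is defined for draws of {DRAW_SIZE}")
    pools = [_check_binary(np.asarray(p)) for p in trial_labels_per_subject]
    true_groups = np.asarray(true_groups, int)
    if len(pools) != len(true_groups):
        raise InvalidArgumentError("one label pool per subject is required")
    for p in pools:
        if len(p) < draw:
            raise InvalidArgumentError(
                f"every subject needs >= {draw} trial labels (got {len(p)})"
            )
    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for r in range(repeats):
        correct = 0
        for pool, truth in zip(pools, true_groups):
            picked = rng.choice(pool, size=draw, replace=False)
            if vote_once(picked).decision == truth:
                correct += 1
        accs[r] = correct / len(pools)
    return {
        "mean_accuracy": float(accs.mean()),
        "var_accuracy": float(accs.var()),
        "per_repetition": accs,
    }
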
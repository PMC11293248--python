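"""Small, exactly specified clinical computations.

Immunohistochemistry (IHC) scoring (intensity x positive-cell count,
dichotomised low/high), relative qPCR quantification via 2**(-ddCt), and
a tie-corrected rank-based ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("dnbtip")

__all__ = ["IHCScore", "ihc_score", "fold_change_ddct", "roc_auc"]

HIGH_CUTOFF = 7  # product score at or above which expression is called high


@dataclass(frozen=True)
class IHCScore:
    intensity: int
    positive_cell_score: int
    product: int
    label: str  # "low" or "high"


def ihc_score(intensity: int, positive_cell_score: int) -> IHCScore:
    """IHC product score: staining intensity (0-3) x positive cells (1-4).

    Products of 7 or above are "high", everything below is "low".  The
    published rule leaves the attainable product 6 (= 2 x 3) between its
    "below 6" and "7 or above" bands; it is assigned "low" so that "high"
    is exactly >= 7, and the gap is logged when hit.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be in 0..3, got {intensity!r}")
    if positive_cell_score not in (1, 2, 3, 4):
        raise ValueError(
            f"positive_cell_score must be in 1..4, got {positive_cell_score!r}"
        )
    product = intensity * positive_cell_score
    if product == 6:
        logger.warning("IHC product 6 falls in the unassigned band; labelling low")
    label = "high" if product >= HIGH_CUTOFF else "low"
    return IHCScore(intensity, positive_cell_score, product, label)


def fold_change_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression fold change by the 2**(-ddCt) method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def roc_auc(scores_cases, scores_controls) -> float:
    """ROC AUC by Mann-Whitney pair counting, ties counted half.

    AUC = (#{case > control} + 0.5 * #{case == control}) / (n_case * n_ctrl).
    """
    cases = np.asarray(list(scores_cases), dtype=float)
    controls = np.asarray(list(scores_controls), dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = cases[:, None] - controls[None, :]
    wins = np.count_nonzero(diff > 0)
    ties = np.count_nonzero(diff == 0)
    return float((wins + 0.5 * ties) / (cases.size * controls.size))
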
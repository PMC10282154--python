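"""Subtype-wise Bonferroni control and three-level evidence grading.

Each MR result is graded against three criteria:

1. strength — the IVW p-value passes the Bonferroni threshold for its
   dietary subtype (0.05 / number of habits in the subtype);
2. fitness of the MR assumptions — after removal of likely pleiotropic
   outliers the estimates stay sign-consistent and IVW stays nominally
   significant;
3. direction — every sensitivity estimator points the same way as IVW.

The base grade is *reliable* (all three), *insufficient* (2 and 3 hold with
nominal but not Bonferroni significance), *weak* (nominally significant and
direction-consistent but criterion 2 fails), else *none*; a leave-one-out
dependence on a single variant demotes the grade one level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .estimators import MREstimate

__all__ = ["GradedResult", "bonferroni_threshold", "grade",
           "grade_from_criteria", "GRADES"]

#: grade ladder from strongest to weakest
GRADES = ("reliable", "insufficient", "weak", "none")


@dataclass
class GradedResult:
    """Evidence grade for one exposure–outcome analysis."""

    analysis_id: str
    ivw_p: float
    alpha_bonf: float
    criterion1: bool
    criterion2: bool
    criterion3: bool
    loo_flag: bool
    grade: str


def bonferroni_threshold(n_in_subtype: int) -> float:
    """0.05 divided by the number of habits tested within the subtype."""
    if n_in_subtype < 1:
        raise ValueError("subtype must contain at least one trait")
    return 0.05 / n_in_subtype


def grade_from_criteria(c1: bool, c2: bool, c3: bool, nominal: bool,
                        loo_flag: bool) -> str:
    """Map the three criteria (plus nominal significance) to a grade.

    ``nominal`` is p < 0.05; criterion 1 implies it.  A leave-one-out flag
    demotes the base grade one level (reliable→insufficient→weak→none).
    """
    if c1 and c2 and c3:
        base = "reliable"
    elif c2 and c3 and nominal and not c1:
        base = "insufficient"
    elif nominal and c3 and not c2:
        base = "weak"
    else:
        base = "none"
    if loo_flag and base != "none":
        base = GRADES[GRADES.index(base) + 1]
    return base


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def grade(analysis_id: str, ivw: MREstimate, alpha_bonf: float,
          sensitivity: Sequence[MREstimate], loo_flag: bool,
          post_removal_ivw: MREstimate | None = None,
          post_removal_sensitivity: Sequence[MREstimate] | None = None,
          require_sensitivity_significance: bool = False) -> GradedResult:
    """Grade one analysis from its fitted estimates.

    ``post_removal_ivw`` / ``post_removal_sensitivity`` are the refits after
    Egger-gated outlier removal; when no removal was triggered they default to
    the original fits (criterion 2 then reduces to sign consistency plus
    nominal IVW significance).  ``require_sensitivity_significance``
    additionally demands nominal significance of every sensitivity method for
    criterion 2 (off by default: the low-precision estimators rarely reach it).
    """
    if not sensitivity:
        raise ValueError("at least one sensitivity estimate is required")
    c1 = ivw.pval < alpha_bonf
    ref = _sign(ivw.estimate)
    c3 = all(_sign(m.estimate) == ref for m in sensitivity)

    post_ivw = post_removal_ivw if post_removal_ivw is not None else ivw
    post_sens = (post_removal_sensitivity
                 if post_removal_sensitivity is not None else sensitivity)
    c2 = (post_ivw.pval < 0.05
          and all(_sign(m.estimate) == _sign(post_ivw.estimate) for m in post_sens))
    if require_sensitivity_significance:
        c2 = c2 and all(m.pval < 0.05 for m in post_sens)

    g = grade_from_criteria(c1, c2, c3, ivw.pval < 0.05, loo_flag)
    return GradedResult(analysis_id, ivw.pval, alpha_bonf, c1, c2, c3,
                        loo_flag, g)
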
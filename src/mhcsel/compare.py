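"""Between-class selection comparison.

Given two (dN - dS, SE) estimates -- e.g. one per MHC class, each from a
codon bootstrap -- the difference is scored as

    Z = (d1 - d2) / sqrt(se1^2 + se2^2)

and referred to a one-sided standard normal test of the hypothesis that the
first class is under stronger positive selection (callers order arguments,
or pass ``direction``, per their hypothesis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm

from .selection import SelectionResult


def class_z(d1: float, se1: float, d2: float, se2: float) -> tuple[float, float]:
    """Z statistic and one-sided p for H1: d1 > d2.

    Raises when both standard errors are zero (no sampling variance to
    scale the difference by).
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    if se1 == 0 and se2 == 0:
        raise ValueError("both standard errors are zero; Z undefined")
    z = (d1 - d2) / math.sqrt(se1**2 + se2**2)
    return z, float(norm.sf(z))


@dataclass(frozen=True)
class ClassComparison:
    label_1: str
    label_2: str
    diff_1: float
    se_1: float
    diff_2: float
    se_2: float
    direction: str  # "1>2" or "2>1": which class is hypothesised stronger
    z: float
    one_sided_p: float
    method_1: str = ""
    method_2: str = ""


def _extract(result) -> tuple[float, float, str, str]:
    """Accept a SelectionResult, a (diff, se) tuple, or a mapping."""
    if isinstance(result, SelectionResult):
        return result.diff, result.se, result.mask_tag, result.method
    if isinstance(result, dict):
        return (
            float(result["diff"]),
            float(result["se"]),
            str(result.get("label", "")),
            str(result.get("method", "")),
        )
    diff, se = result
    return float(diff), float(se), "", ""


def compare_classes(result_1, result_2, direction: str = "1>2") -> ClassComparison:
    """Compare two selection results with the between-class Z formula.

    ``direction`` names the hypothesised stronger class; the reported Z is
    always signed as (d1 - d2)/SE, while the one-sided p tests the stated
    direction.  Differing method tags trigger a warning but the comparison
    is still performed (flagged in the output).
    """
    if direction not in ("1>2", "2>1"):
        raise ValueError("direction must be '1>2' or '2>1'")
    d1, se1, label1, method1 = _extract(result_1)
    d2, se2, label2, method2 = _extract(result_2)
    if method1 and method2 and method1 != method2:
        warnings.warn(
            f"comparing selection results from different methods: "
            f"{method1} vs {method2}"
        )
    z, p_fwd = class_z(d1, se1, d2, se2)
    p = p_fwd if direction == "1>2" else float(norm.sf(-z))
    return ClassComparison(
        label_1=label1,
        label_2=label2,
        diff_1=d1,
        se_1=se1,
        diff_2=d2,
        se_2=se2,
        direction=direction,
        z=z,
        one_sided_p=p,
        method_1=method1,
        method_2=method2,
    )
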
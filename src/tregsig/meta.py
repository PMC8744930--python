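"""Inverse-variance pooling of log hazard ratios across cohorts.

Fixed-effect pooling weights each study by 1/SE^2.  The random-effects
option adds the DerSimonian-Laird moment estimate of the between-study
variance tau^2 (weights 1/(SE^2 + tau^2)).  Heterogeneity is reported as
Cochran's Q with k-1 degrees of freedom and I^2 = max(0, (Q - df)/Q).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import MetaResult, StudyEffect

__all__ = ["pool_hr"]


def pool_hr(
    studies: Sequence[tuple],
    method: str = "fixed",
) -> MetaResult:
    """Pool per-study (log HR, SE) pairs into an overall hazard ratio.

    ``studies`` is a sequence of ``(log_hr, se)`` or ``(label, log_hr, se)``
    tuples.  ``method`` is ``"fixed"`` or ``"dersimonian_laird"``.  A single
    study is returned unchanged with tau^2 = 0.
    """
    if method not in ("fixed", "dersimonian_laird"):
        raise ValueError(f"unknown pooling method {method!r}")
    parsed: list[StudyEffect] = []
    for i, s in enumerate(studies):
        if len(s) == 3:
            label, y, se = s
        elif len(s) == 2:
            y, se = s
            label = f"study_{i + 1}"
        else:
            raise ValueError("each study must be (log_hr, se) or (label, log_hr, se)")
        y, se = float(y), float(se)
        if not np.isfinite(y) or not np.isfinite(se):
            raise ValueError(f"non-finite effect or SE in study {label!r}")
        if se <= 0:
            raise ValueError(f"SE must be > 0 (study {label!r})")
        parsed.append(StudyEffect(label=str(label), log_hr=y, se=se))
    if not parsed:
        raise ValueError("at least one study required")

    y = np.array([s.log_hr for s in parsed])
    v = np.array([s.se**2 for s in parsed])
    w = 1.0 / v
    k = y.size
    y_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fixed) ** 2))
    df = k - 1
    if k > 1:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0

    if method == "fixed":
        w_star = w
    else:
        w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    pooled_se = float(1.0 / np.sqrt(np.sum(w_star)))
    for s, wt in zip(parsed, w_star):
        s.weight = float(wt)

    return MetaResult(
        studies=parsed,
        method=method,
        pooled_log_hr=pooled,
        pooled_se=pooled_se,
        q_statistic=q,
        df=df,
        tau2=tau2,
        i2=i2,
    )
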
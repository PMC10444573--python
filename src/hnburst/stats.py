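"""Thin wrappers around the off-the-shelf statistics used on burst metrics.

These exist so analysis scripts can call one namespace; the heavy lifting is
scipy's.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = ["pearson_regression", "mann_whitney_u", "t_test_one_tailed"]


def pearson_regression(x, y):
    """Pearson r, p-value and least-squares slope/intercept."""
    res = _st.linregress(np.asarray(x, float), np.asarray(y, float))
    return {"r": res.rvalue, "p": res.pvalue,
            "slope": res.slope, "intercept": res.intercept}


def mann_whitney_u(a, b, alternative: str = "two-sided"):
    """Mann-Whitney U statistic and p-value."""
    u, p = _st.mannwhitneyu(a, b, alternative=alternative)
    return {"U": float(u), "p": float(p)}


def t_test_one_tailed(a, b, alternative: str = "less"):
    """One-tailed independent-samples t test."""
    t, p = _st.ttest_ind(a, b, alternative=alternative)
    return {"t": float(t), "p": float(p)}
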
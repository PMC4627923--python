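"""Small statistical helpers for group comparisons on summary data."""

from __future__ import annotations

from scipy import stats as _st

__all__ = ["two_tailed_t_test"]


def two_tailed_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    *, equal_var: bool = False,
) -> tuple[float, float]:
    """Two-tailed t-test from group summary statistics.

    Returns ``(t_statistic, p_value)``; Welch's correction by default,
    matching the usual bench comparison of small triplicate groups.
    """
    res = _st.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var, alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)
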
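"""Per-million normalisation, fold changes and the two-library count statistic.

For a tag with ``x`` reads in the control library (total ``N1``) and ``y``
reads in the treatment library (total ``N2``), the point probability

    p(x|y) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

is evaluated in log-space (no factorial overflow), together with the two
cumulative tails C(y <= y_obs | x) and D(y >= y_obs | x).  The reported
significance value is the smaller tail; both tails are always emitted.

Normalisation follows the printed rules: counts are scaled to reads per
million, an exact zero is revised to 0.01, and a tag whose normalised value
is below 1 in every library is filtered out.  The p-value itself always uses
the raw integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

ZERO_REVISION = 0.01
DEFAULT_P_THRESHOLD = 0.01
DEFAULT_FC_THRESHOLD = 1.0


def normalize(count: float, library_total: float) -> float:
    """Reads-per-million value; an exact zero count becomes 0.01."""
    if count < 0:
        raise ValueError(f"negative count: {count}")
    if library_total <= 0:
        raise ValueError(f"non-positive library total: {library_total}")
    if count == 0:
        return ZERO_REVISION
    return count * 1e6 / library_total


def low_expression_filter(normalized_values) -> bool:
    """True (keep) unless the normalised value is below 1 in every library."""
    values = list(normalized_values)
    if not values:
        raise ValueError("no normalized values supplied")
    return not all(v < 1.0 for v in values)


def log2_fold_change(norm_treatment: float, norm_control: float) -> float:
    if norm_treatment <= 0 or norm_control <= 0:
        raise ValueError("fold change requires positive normalised values")
    return math.log2(norm_treatment / norm_control)


def _check_counts(x, y) -> tuple[int, int]:
    for v in (x, y):
        if v != int(v):
            raise ValueError(f"counts must be integers, got {v!r}")
        if v < 0:
            raise ValueError(f"counts must be nonnegative, got {v!r}")
    return int(x), int(y)


def _log_p(x: int, y, N1: float, N2: float):
    """log p(y|x) for scalar x and array-like y."""
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    r = N2 / N1
    y = np.asarray(y, dtype=np.float64)
    return (
        y * math.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(r)
    )


def audic_claverie_p(x: int, y: int, N1: float, N2: float) -> float:
    """Point probability p(x|y) of the two-library count statistic."""
    x, y = _check_counts(x, y)
    return float(np.exp(_log_p(x, np.array([y]), N1, N2)[0]))


def audic_claverie_p_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    """Exact rational evaluation of p(x|y); small-count reference route."""
    x, y = _check_counts(x, y)
    r = Fraction(N2, N1)
    return r**y * math.comb(x + y, y) / (1 + r) ** (x + y + 1)


def cumulative_tails(x: int, y_obs: int, N1: float, N2: float) -> tuple[float, float]:
    """Lower and upper cumulative tails of the count statistic.

    ``C`` sums p(y|x) for y = 0..y_obs; ``D`` is the complementary tail
    computed as 1 - C + p(y_obs|x), so C + D = 1 + p(y_obs|x) identically.
    """
    x, y_obs = _check_counts(x, y_obs)
    logp = _log_p(x, np.arange(y_obs + 1), N1, N2)
    c = float(np.exp(logsumexp(logp)))
    c = min(c, 1.0)
    p_obs = float(np.exp(logp[-1]))
    d = min(max(1.0 - c + p_obs, 0.0), 1.0)
    return c, d


@dataclass
class ExpressionResult:
    """One treatment/control comparison for one miRNA."""

    mirna: str
    x: int  # control reads
    y: int  # treatment reads
    N1: float
    N2: float
    norm_control: float
    norm_treatment: float
    fold_change: float
    C: float
    D: float
    p: float
    filtered: bool = False
    call: str = "unchanged"


def significance_call(
    result: ExpressionResult,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> str:
    """'up' / 'down' / 'unchanged' from the smaller tail and the fold change."""
    if result.filtered:
        return "unchanged"
    if result.p <= p_threshold:
        if result.fold_change >= fc_threshold:
            return "up"
        if result.fold_change <= -fc_threshold:
            return "down"
    return "unchanged"


def compare_pair(
    mirna: str,
    x: int,
    y: int,
    N1: float,
    N2: float,
    *,
    filtered: bool = False,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> ExpressionResult:
    norm_c = normalize(x, N1)
    norm_t = normalize(y, N2)
    c, d = cumulative_tails(x, y, N1, N2)
    result = ExpressionResult(
        mirna=mirna,
        x=int(x),
        y=int(y),
        N1=N1,
        N2=N2,
        norm_control=norm_c,
        norm_treatment=norm_t,
        fold_change=log2_fold_change(norm_t, norm_c),
        C=c,
        D=d,
        p=min(c, d),
        filtered=filtered,
    )
    result.call = significance_call(result, p_threshold, fc_threshold)
    return result


def compare_libraries(
    counts: pd.DataFrame,
    library_totals: dict[str, float],
    control: str,
    *,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Compare every non-control library against the control.

    ``counts`` holds one row per miRNA and one integer column per library.
    Tags normalised below 1 in all libraries are flagged ``filtered`` and
    never called significant.  ``bh_correct`` optionally applies a
    Benjamini-Hochberg adjustment to the reported p per treatment library
    (off by default).
    """
    if control not in counts.columns:
        raise ValueError(f"control library {control!r} not among {list(counts.columns)}")
    missing = [lib for lib in counts.columns if lib not in library_totals]
    if missing:
        raise ValueError(f"missing library totals for {missing}")
    rows = []
    for mirna, row in counts.iterrows():
        norms = {lib: normalize(int(row[lib]), library_totals[lib]) for lib in counts.columns}
        filtered = not low_expression_filter(norms.values())
        for lib in counts.columns:
            if lib == control:
                continue
            res = compare_pair(
                str(mirna),
                int(row[control]),
                int(row[lib]),
                library_totals[control],
                library_totals[lib],
                filtered=filtered,
                p_threshold=p_threshold,
                fc_threshold=fc_threshold,
            )
            rows.append(
                {
                    "mirna": res.mirna,
                    "treatment": lib,
                    "x": res.x,
                    "y": res.y,
                    "norm_control": res.norm_control,
                    "norm_treatment": res.norm_treatment,
                    "log2_fold_change": res.fold_change,
                    "C": res.C,
                    "D": res.D,
                    "p": res.p,
                    "filtered": res.filtered,
                    "call": res.call,
                }
            )
    table = pd.DataFrame(rows)
    if bh_correct and len(table):
        for lib in table["treatment"].unique():
            mask = table["treatment"] == lib
            table.loc[mask, "p_adjusted"] = benjamini_hochberg(table.loc[mask, "p"].values)
    return table


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up adjusted p-values, monotone and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return adjusted


def ddct_relative_expression(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative quantity by the 2^-ddCt method."""
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return 2.0**-ddct
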
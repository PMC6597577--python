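"""Distribution-comparison statistics for P-gp activity histograms.

Pairs of event samples are compared with the two-sample Kolmogorov-
Smirnov test (the standard nonparametric test on cytometry distributions;
Anderson-Darling is available as an alternative), and p-values are mapped
to the significance tiers used in the figure annotations:
``***`` p < 0.0005, ``**`` p < 0.005, ``*`` p < 0.05, else ``ns``.
Families of pairwise comparisons are Holm-corrected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sst
from statsmodels.stats.multitest import multipletests

from .synth import EventSample

__all__ = ["ComparisonResult", "significance_tier", "compare_distributions", "pairwise_table"]

_TIERS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def significance_tier(p_value: float) -> str:
    """Map a p-value to its tier: *** < 0.0005, ** < 0.005, * < 0.05, else ns."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p_value}")
    for threshold, tier in _TIERS:
        if p_value < threshold:
            return tier
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison: statistic, p-value, sizes and significance tier."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    tier: str
    small_sample: bool = False


def compare_distributions(
    a: EventSample, b: EventSample, test: str = "ks", method: str = "auto"
) -> ComparisonResult:
    """Two-sample test on the activity values of two event samples.

    ``test='ks'`` (default) runs the two-sample Kolmogorov-Smirnov test;
    ``test='ad'`` runs the k-sample Anderson-Darling test.  Samples with
    fewer than 10 events are flagged (``small_sample=True``) with a warning
    but still computed.
    """
    if a.n_events == 0 or b.n_events == 0:
        raise ValueError("both samples must be nonempty")
    small = a.n_events < 10 or b.n_events < 10
    if small:
        warnings.warn("sample with fewer than 10 events; p-value unreliable", stacklevel=2)
    if test == "ks":
        res = _sst.ks_2samp(a.activities, b.activities, method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "ad":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _sst.anderson_ksamp([a.activities, b.activities])
        stat, p = float(res.statistic), float(np.clip(res.significance_level, 0.0, 1.0))
    else:
        raise ValueError(f"unknown test: {test!r}")
    return ComparisonResult(
        statistic=stat,
        p_value=p,
        n_a=a.n_events,
        n_b=b.n_events,
        tier=significance_tier(p),
        small_sample=small,
    )


def pairwise_table(
    samples: list[EventSample], test: str = "ks", method: str = "auto"
) -> pd.DataFrame:
    """All unordered pairwise comparisons with Holm correction.

    Returns one row per pair with raw and Holm-adjusted p-values and the
    tiers derived from each.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    names = [
        s.condition if s.condition else f"sample_{k}" for k, s in enumerate(samples)
    ]
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(samples), 2):
        r = compare_distributions(a, b, test=test, method=method)
        rows.append(
            {
                "a": names[i],
                "b": names[j],
                "statistic": r.statistic,
                "p_raw": r.p_value,
                "n_a": r.n_a,
                "n_b": r.n_b,
            }
        )
    table = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(table["p_raw"].to_numpy(), method="holm")
    table["p_holm"] = p_adj
    table["tier_raw"] = [significance_tier(p) for p in table["p_raw"]]
    table["tier_holm"] = [significance_tier(p) for p in table["p_holm"]]
    return table
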
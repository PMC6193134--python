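"""Prescription Diversity (PD): a Simpson-type index of prescribing variety.

For one practice and one pharmaceutical family (PF), let ``np_c`` be the
number of prescriptions of pharmaceutical class ``c`` and ``NP`` their sum.

    PD = 1 - sum_c np_c (np_c - 1) / (NP (NP - 1))

This is exactly the probability that two prescriptions drawn without
replacement from the practice's PF belong to different classes: 0 means a
single class is ever prescribed, and values approach ``1 - 1/k`` when ``k``
classes are prescribed evenly (the family's natural limit — e.g. 0.75 for
four classes, 0.88 for eight — so PD is only comparable within a family).
PD is undefined when ``NP < 2``; undefined values are excluded from medians
and from quintile ranking.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

from .taxonomy import UNRESOLVED


def compute_pd(np_counts: Sequence[float]) -> Optional[float]:
    """PD of one per-class count vector; ``None`` (undefined) when NP < 2."""
    arr = np.asarray(np_counts, dtype=float)
    if arr.size and (arr < 0).any():
        raise ValidationError("class counts must be non-negative")
    total = arr.sum()
    if total < 2:
        return None
    return float(1.0 - (arr * (arr - 1.0)).sum() / (total * (total - 1.0)))


def pd_even(k: int, total: int) -> float:
    """PD of a 'completely diverse' family: ``k`` classes prescribed evenly.

    This is the natural PD limit of a family with ``k`` available classes at
    ``total`` prescriptions; it increases with ``k`` and approaches
    ``1 - 1/k`` as ``total`` grows.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if total < 2:
        raise ValidationError("total must be >= 2")
    if total % k != 0:
        raise ValidationError(f"total={total} is not divisible by k={k}")
    return compute_pd([total // k] * k)


def round_pd(value: float, ndigits: int = 2) -> float:
    """Reporting precision: half-even rounding to 2 decimal places."""
    return float(np.round(value, ndigits))


def practice_pd_table(
    events: pd.DataFrame,
    pf: str,
    species: Optional[str] = None,
    mpc: Optional[str] = None,
    route: Optional[str] = None,
) -> pd.DataFrame:
    """Per-practice PD for one family, optionally stratified.

    Only events resolved to class level enter the calculation (family-level
    descriptors such as generic vaccine entries are excluded).  Returns one
    row per practice with >= 1 qualifying event: columns ``practice_id, pf,
    pd, NP, n_classes_prescribed``; ``pd`` is NaN where undefined (NP < 2).
    """
    ev = events[events["pf"] == pf]
    if species is not None:
        ev = ev[ev["species"] == species]
    if mpc is not None:
        ev = ev[ev["mpc"] == mpc]
    if route is not None:
        if "route" not in ev.columns:
            raise ValidationError(
                "route stratification requires a 'route' column on events"
            )
        ev = ev[ev["route"] == route]
    ev = ev[ev["agent"] != UNRESOLVED]
    if ev.empty:
        logger.warning("no class-resolved events for family %r in stratum", pf)
        return pd.DataFrame(
            columns=["practice_id", "pf", "pd", "NP", "n_classes_prescribed"]
        )

    rows = []
    for pid, grp in ev.groupby("practice_id", sort=True):
        counts = grp["pc"].value_counts().to_numpy()
        value = compute_pd(counts)
        rows.append(
            {
                "practice_id": pid,
                "pf": pf,
                "pd": np.nan if value is None else value,
                "NP": int(counts.sum()),
                "n_classes_prescribed": int((counts > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def _quintile_assignments(values: pd.Series) -> pd.Series:
    """Rank into five (near-)equal groups, 1 = lowest values.

    Ties break by a stable sort on the index (practice id); when the count
    is not divisible by 5, earlier quintiles take the extra members.
    """
    ordered = values.sort_index(kind="stable").sort_values(kind="stable")
    n = len(ordered)
    base, extra = divmod(n, 5)
    sizes = [base + (1 if i < extra else 0) for i in range(5)]
    labels = np.repeat(np.arange(1, 6), sizes)
    return pd.Series(labels, index=ordered.index)


def benchmark_quintile_matrix(
    freq: pd.Series, pd_values: pd.Series
) -> pd.DataFrame:
    """5x5 practice-benchmarking matrix of frequency vs PD quintiles.

    Both metrics are ranked independently over the same practices and split
    into evenly sized quintiles; cell (i, j) counts practices in frequency
    quintile i and PD quintile j.  Practices with an undefined PD are
    dropped before ranking.
    """
    freq = freq.dropna()
    pd_values = pd_values.dropna()
    common = freq.index.intersection(pd_values.index)
    if len(common) < 5:
        raise ValidationError(
            f"need >= 5 practices with both metrics defined, got {len(common)}"
        )
    fq = _quintile_assignments(freq.loc[common])
    dq = _quintile_assignments(pd_values.loc[common])
    matrix = pd.crosstab(fq, dq).reindex(
        index=range(1, 6), columns=range(1, 6), fill_value=0
    )
    matrix.index.name = "freq_quintile"
    matrix.columns.name = "pd_quintile"
    return matrix
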
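"""Prescription diversity: index, limits, practice tables, benchmarking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetpharm import (
    ValidationError,
    benchmark_quintile_matrix,
    compute_pd,
    pd_even,
    practice_pd_table,
)
from vetpharm.diversity import round_pd


def pd_oracle(counts):
    """Probability two prescriptions drawn without replacement belong to
    different classes, by exhaustive enumeration of ordered pairs."""
    labels = np.repeat(np.arange(len(counts)), counts)
    n = len(labels)
    if n < 2:
        return None
    different = int((labels[:, None] != labels[None, :]).sum())
    return different / (n * (n - 1))


def test_worked_example_two_decimals():
    assert round_pd(compute_pd([800, 400, 400, 400])) == 0.72


def test_single_class_is_zero_diversity():
    assert compute_pd([10]) == 0.0
    assert compute_pd([7, 0, 0]) == 0.0


def test_two_singletons_are_maximally_diverse():
    assert compute_pd([1, 1]) == 1.0


def test_small_mixed_counts_match_pair_enumeration():
    assert compute_pd([5, 3, 2]) == pytest.approx(pd_oracle([5, 3, 2]))
    assert compute_pd([5, 3, 2]) == pytest.approx(0.68889, abs=1e-5)


def test_undefined_below_two_prescriptions():
    assert compute_pd([]) is None
    assert compute_pd([1]) is None
    assert compute_pd([0, 1, 0]) is None


def test_negative_counts_rejected():
    with pytest.raises(ValidationError):
        compute_pd([3, -1])


@given(
    st.lists(st.integers(min_value=0, max_value=12), min_size=1, max_size=6)
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_pd_equals_oracle_and_is_permutation_invariant(counts):
    value = compute_pd(counts)
    expected = pd_oracle(counts)
    if expected is None:
        assert value is None
    else:
        assert value == pytest.approx(expected)
        shuffled = list(reversed(sorted(counts)))
        assert compute_pd(shuffled) == pytest.approx(value)
        assert 0.0 <= value <= 1.0


@given(
    st.lists(st.integers(min_value=1, max_value=10), min_size=2, max_size=5),
    st.data(),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_merging_classes_never_increases_pd(counts, data):
    i = data.draw(st.integers(0, len(counts) - 1))
    j = data.draw(st.integers(0, len(counts) - 1).filter(lambda k: k != i))
    merged = [c for k, c in enumerate(counts) if k not in (i, j)]
    merged.append(counts[i] + counts[j])
    assert compute_pd(merged) <= compute_pd(counts) + 1e-12
    # splitting one class evenly never decreases PD
    if counts[i] % 2 == 0 and counts[i] >= 2:
        split = counts[:i] + [counts[i] // 2, counts[i] // 2] + counts[i + 1:]
        assert compute_pd(split) >= compute_pd(counts) - 1e-12


def test_even_limits_examples():
    assert round_pd(pd_even(4, 2000)) == 0.75
    assert round_pd(pd_even(8, 2000)) == 0.88
    assert pd_even(1, 100) == 0.0


def test_even_limit_requires_divisibility():
    with pytest.raises(ValidationError, match="divisible"):
        pd_even(3, 1000)


def test_even_limit_monotone_in_classes_and_total():
    """The even-prescription ceiling rises with the number of classes and
    approaches 1 - 1/k from above as the total grows (drawing without
    replacement makes the finite-sample index exceed its asymptote)."""
    for total in (120, 240, 2400):
        values = [pd_even(k, total) for k in (2, 3, 4, 6, 8)]
        assert values == sorted(values)
        assert all(v >= 1 - 1 / k
                   for v, k in zip(values, (2, 3, 4, 6, 8)))
    for k in (2, 4, 6):
        series = [pd_even(k, t) for t in (12, 120, 1200, 12000)]
        assert series == sorted(series, reverse=True)
        assert series[-1] == pytest.approx(1 - 1 / k, abs=1e-3)


# -- practice table ---------------------------------------------------------

def events_frame(rows):
    cols = ["consultation_id", "animal_id", "species", "practice_id",
            "site_id", "date", "mpc", "agent", "pc", "pf", "authorisation",
            "multiplicity"]
    out = []
    for practice, pc, n in rows:
        for i in range(n):
            out.append(
                {"consultation_id": f"{practice}-{pc}-{i}", "animal_id": "a",
                 "species": "dog", "practice_id": practice, "site_id": "s",
                 "date": "2015-01-01", "mpc": "other unwell",
                 "agent": f"drug-{pc}", "pc": pc, "pf": "antibiotic",
                 "authorisation": "veterinary", "multiplicity": 1}
            )
    return pd.DataFrame(out, columns=cols)


def test_practice_table_worked_example_and_single_class():
    ev = events_frame(
        [("A", "x1", 800), ("A", "x2", 400), ("A", "x3", 400),
         ("A", "x4", 400), ("B", "x1", 10)]
    )
    table = practice_pd_table(ev, "antibiotic").set_index("practice_id")
    assert round_pd(table.loc["A", "pd"]) == 0.72
    assert table.loc["B", "pd"] == 0.0
    assert table.loc["A", "n_classes_prescribed"] == 4


def test_practice_with_one_prescription_is_undefined():
    ev = events_frame([("A", "x1", 1), ("B", "x1", 5)])
    table = practice_pd_table(ev, "antibiotic").set_index("practice_id")
    assert np.isnan(table.loc["A", "pd"])
    assert table["pd"].median(skipna=True) == 0.0


def test_family_level_events_excluded_from_pd():
    ev = events_frame([("A", "x1", 3), ("A", "x2", 3)])
    unresolved = ev.iloc[:2].copy()
    unresolved["agent"] = "unresolved"
    table = practice_pd_table(
        pd.concat([ev, unresolved], ignore_index=True), "antibiotic"
    ).set_index("practice_id")
    assert table.loc["A", "NP"] == 6


def test_empty_family_warns_and_returns_empty(caplog):
    ev = events_frame([("A", "x1", 3)])
    with caplog.at_level("WARNING"):
        table = practice_pd_table(ev, "vaccine")
    assert table.empty


def test_pd_recovery_on_generated_data(small_events, small_gt):
    """Observed PD is an unbiased estimate of the generating distribution's
    Simpson diversity; at moderate counts it sits within a loose band."""
    table = practice_pd_table(small_events, "antibiotic")
    merged = table.merge(
        small_gt.true_pd[small_gt.true_pd["pf"] == "antibiotic"],
        on="practice_id",
    )
    strong = merged[merged["NP"] >= 40]
    assert len(strong) >= 3
    assert (np.abs(strong["pd"] - strong["true_pd"]) <= 0.15).all()


# -- quintile benchmarking --------------------------------------------------

def test_concordant_ranks_fill_diagonal():
    idx = [f"p{i}" for i in range(10)]
    vals = pd.Series(np.arange(10, dtype=float), index=idx)
    matrix = benchmark_quintile_matrix(vals, vals.copy())
    assert np.diag(matrix.to_numpy()).tolist() == [2] * 5
    assert matrix.to_numpy().sum() == 10


def test_reversed_ranks_fill_antidiagonal():
    idx = [f"p{i}" for i in range(10)]
    freq = pd.Series(np.arange(10, dtype=float), index=idx)
    pdv = pd.Series(np.arange(10, dtype=float)[::-1], index=idx)
    matrix = benchmark_quintile_matrix(freq, pdv).to_numpy()
    assert np.fliplr(matrix).diagonal().tolist() == [2] * 5


def test_uneven_count_gives_earlier_quintiles_extras():
    idx = [f"p{i:02d}" for i in range(12)]
    vals = pd.Series(np.arange(12, dtype=float), index=idx)
    matrix = benchmark_quintile_matrix(vals, vals.copy())
    assert matrix.sum(axis=1).tolist() == [3, 3, 2, 2, 2]


def test_too_few_practices_rejected():
    idx = ["p0", "p1", "p2"]
    vals = pd.Series([1.0, 2.0, 3.0], index=idx)
    with pytest.raises(ValidationError):
        benchmark_quintile_matrix(vals, vals.copy())


def test_independent_metrics_spread_uniformly():
    """216 practices with independent metrics: mean cell count over seeds
    approaches 216 / 25 (multinomial expectation)."""
    idx = [f"p{i:03d}" for i in range(216)]
    cells = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        freq = pd.Series(rng.random(216), index=idx)
        pdv = pd.Series(rng.random(216), index=idx)
        cells.append(benchmark_quintile_matrix(freq, pdv).to_numpy())
    mean_cells = np.mean(cells, axis=0)
    assert np.all(np.abs(mean_cells - 216 / 25) < 2.5)
    assert np.sum(cells[0]) == 216
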
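"""Frequency statistics and the cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest

from vetpharm import (
    UndefinedResultError,
    ValidationError,
    animal_level_exposure,
    authorisation_breakdown,
    cluster_bootstrap,
    consult_prescription_frequency,
    rate_per_10k,
)
from vetpharm.rates import has_event_flag


def records_of(n, species="dog", cluster=None):
    return pd.DataFrame(
        {
            "consultation_id": [f"c{i}" for i in range(n)],
            "animal_id": [f"a{i}" for i in range(n)],
            "species": species,
            "practice_id": "p1",
            "site_id": cluster if cluster is not None else "s1",
            "date": "2015-06-01",
            "mpc": "other unwell",
            "products": "",
        }
    )


def events_for(records, idx, pf="antibiotic", authorisation="veterinary"):
    sub = records.iloc[list(idx)]
    return pd.DataFrame(
        {
            "consultation_id": sub["consultation_id"],
            "animal_id": sub["animal_id"],
            "species": sub["species"],
            "practice_id": sub["practice_id"],
            "site_id": sub["site_id"],
            "date": sub["date"],
            "mpc": sub["mpc"],
            "agent": "x",
            "pc": "y",
            "pf": pf,
            "authorisation": authorisation,
            "multiplicity": 1,
        }
    )


def test_frequency_counts_consultations_with_any_event():
    recs = records_of(10)
    ev = events_for(recs, range(7))
    assert consult_prescription_frequency(recs, ev) == pytest.approx(0.7)


def test_frequency_zero_when_no_events():
    recs = records_of(5)
    ev = events_for(recs, [])
    assert consult_prescription_frequency(recs, ev) == 0.0


def test_empty_stratum_is_undefined_not_zero():
    recs = records_of(5, species="dog")
    ev = events_for(recs, [0])
    with pytest.raises(UndefinedResultError):
        consult_prescription_frequency(recs, ev, species="rabbit")


def test_rate_per_10k_arithmetic():
    recs = records_of(2000)
    ev = events_for(recs, range(558), pf="vaccine")
    assert rate_per_10k(recs, ev, "vaccine") == pytest.approx(2790.0)


def test_rate_per_10k_bounds():
    recs = records_of(4)
    none = events_for(recs, [])
    assert rate_per_10k(recs, none, "vaccine") == 0.0
    everywhere = events_for(recs, range(4), pf="vaccine")
    assert rate_per_10k(recs, everywhere, "vaccine") == 10_000.0


def test_animal_level_exposure_counts_distinct_animals():
    recs = pd.concat(
        [records_of(3)], ignore_index=True
    )
    ev = events_for(recs, [0, 1])
    assert animal_level_exposure(recs, ev, "dog") == pytest.approx(2 / 3)
    with pytest.raises(ValidationError, match="unknown species"):
        animal_level_exposure(recs, ev, "hamster")


def test_authorisation_breakdown_normalises_over_defined():
    recs = records_of(10)
    ev = pd.concat(
        [
            events_for(recs, range(9), authorisation="veterinary"),
            events_for(recs, [9], pf="neurological", authorisation="human"),
        ],
        ignore_index=True,
    )
    out = authorisation_breakdown(ev)
    assert out["veterinary"] == pytest.approx(0.9)
    assert out["human"] == pytest.approx(0.1)
    assert out["generic"] == 0.0
    assert out["not_estimable"] == 0.0


def test_authorisation_unresolved_reported_separately():
    recs = records_of(4)
    ev = pd.concat(
        [
            events_for(recs, [0, 1], authorisation="veterinary"),
            events_for(recs, [2, 3], pf="vaccine", authorisation=""),
        ],
        ignore_index=True,
    )
    out = authorisation_breakdown(ev)
    assert out["veterinary"] == pytest.approx(1.0)  # of the estimable events
    assert out["not_estimable"] == pytest.approx(0.5)


# -- cluster bootstrap ------------------------------------------------------

def clustered_frame(cluster_values):
    rows = []
    for cid, values in cluster_values.items():
        for i, y in enumerate(values):
            rows.append({"site_id": cid, "practice_id": "p", "animal_id": f"{cid}-{i}", "y": y})
    return pd.DataFrame(rows)


def test_identical_clusters_give_zero_width_interval():
    df = clustered_frame({f"s{i}": [1, 0] for i in range(6)})
    est = cluster_bootstrap(lambda d: d["y"].mean(), df, "site_id",
                            n_boot=200, seed=0)
    assert est.ci_low == est.ci_high == est.statistic == pytest.approx(0.5)


def test_two_opposite_clusters_span_unit_interval():
    """With clusters at proportions 0 and 1 the four equally likely
    resamples give replicate values {0, 0.5, 0.5, 1}: the percentile
    interval approaches [0, 1]."""
    df = clustered_frame({"s0": [0, 0], "s1": [1, 1]})
    est = cluster_bootstrap(lambda d: d["y"].mean(), df, "site_id",
                            n_boot=4000, seed=1)
    assert est.ci_low == pytest.approx(0.0)
    assert est.ci_high == pytest.approx(1.0)
    assert est.statistic == pytest.approx(0.5)


def test_bootstrap_reproducible_under_seed():
    rng = np.random.default_rng(3)
    df = clustered_frame(
        {f"s{i}": rng.integers(0, 2, size=8).tolist() for i in range(10)}
    )
    a = cluster_bootstrap(lambda d: d["y"].mean(), df, "site_id",
                          n_boot=300, seed=42)
    b = cluster_bootstrap(lambda d: d["y"].mean(), df, "site_id",
                          n_boot=300, seed=42)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_single_cluster_degenerate_warning(caplog):
    df = clustered_frame({"only": [0, 1, 1]})
    with caplog.at_level("WARNING"):
        est = cluster_bootstrap(lambda d: d["y"].mean(), df, "site_id",
                                n_boot=50, seed=0)
    assert est.ci_low == est.ci_high
    assert any("single cluster" in r.message for r in caplog.records)


def test_interval_width_decreases_with_more_clusters():
    """Stochastic invariant: at fixed effect size, more independent clusters
    mean a narrower percentile interval (averaged over seeds)."""
    widths = []
    for k in (5, 20, 80):
        ws = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            effects = rng.normal(0.5, 0.15, size=k).clip(0.05, 0.95)
            df = clustered_frame(
                {f"s{i}": (rng.random(10) < effects[i]).astype(float).tolist()
                 for i in range(k)}
            )
            est = cluster_bootstrap(lambda d: d["y"].mean(), df, "site_id",
                                    n_boot=300, seed=seed)
            ws.append(est.ci_high - est.ci_low)
        widths.append(np.mean(ws))
    assert widths[0] > widths[1] > widths[2]


def test_pf_rate_bounded_by_overall_frequency(small_records, small_events):
    overall = consult_prescription_frequency(small_records, small_events)
    for pf in small_events["pf"].unique():
        assert rate_per_10k(small_records, small_events, pf) / 10_000 <= overall


def test_frequency_matches_planted_probability(small_records, small_gt,
                                               small_events):
    freq = consult_prescription_frequency(small_records, small_events)
    planted = (small_gt.n_prescribing_consultations
               / small_gt.n_consultations)
    assert abs(freq - planted) <= 0.02


def test_exposure_matches_generator_closed_form():
    """Animal-level exposure equals the generator's closed form
    1 - (1-p) * exp(-(lambda-1) p) averaged over practice effects."""
    from vetpharm import synthdata as sd
    from vetpharm import map_consultations

    cfg = sd.SynthConfig(n_practices=5, n_animals=1500,
                         consults_per_animal=6.0, broken_rate=0.0, seed=31)
    records, gt = sd.generate_dataset(cfg)
    events, _ = map_consultations(records, sd.builtin_ruleset())
    lam = cfg.consults_per_animal
    expected = np.mean(
        [1 - (1 - p) * np.exp(-(lam - 1) * p)
         for p in gt.p_prescribe_by_practice.values()]
    )
    animals = records["animal_id"].nunique()
    exposed = events["animal_id"].nunique()
    assert abs(exposed / animals - expected) <= 0.02
    # per-species exposure agrees with the pooled value (species-independent)
    for sp in records["species"].unique():
        if (records["species"] == sp).sum() < 200:
            continue
        assert abs(animal_level_exposure(records, events, sp) - expected) <= 0.05


def test_authorisation_recovers_configured_mix(small_events):
    out = authorisation_breakdown(small_events)
    assert abs(out["veterinary"] - 0.93) <= 0.02
    assert abs(out["human"] - 0.05) <= 0.02
    assert abs(out["generic"] - 0.02) <= 0.02


def test_has_event_flag_consistent_with_frequency(small_records, small_events):
    flags = has_event_flag(small_records, small_events)
    assert flags.mean() == pytest.approx(
        consult_prescription_frequency(small_records, small_events)
    )
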
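"""Prescription frequency statistics with cluster-bootstrap confidence intervals.

Consultation-level proportions ("share of booked consultations with at least
one prescription"), family rates per 10,000 consultations, animal-level
exposure over the study window, and the veterinary / human / generic
authorisation breakdown.  Confidence intervals resample whole clusters
(sites, or animals within practices) with replacement so that they remain
valid under within-cluster correlation; the interval reported by
:func:`cluster_bootstrap_dual` is the wider of the two clustering schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import UndefinedResultError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RateEstimate:
    """Point estimate with percentile bootstrap bounds."""

    statistic: float
    ci_low: float
    ci_high: float
    n_boot: int
    cluster_level: str


def _stratum_records(
    records: pd.DataFrame, species: Optional[str]
) -> pd.DataFrame:
    if species is None:
        return records
    return records[records["species"] == species]


def _qualifying_consults(
    events: pd.DataFrame,
    species: Optional[str] = None,
    pf: Optional[str] = None,
    authorisation: Optional[str] = None,
) -> pd.Series:
    ev = events
    if species is not None:
        ev = ev[ev["species"] == species]
    if pf is not None:
        ev = ev[ev["pf"] == pf]
    if authorisation is not None:
        ev = ev[ev["authorisation"] == authorisation]
    return ev["consultation_id"].drop_duplicates()


def consult_prescription_frequency(
    records: pd.DataFrame,
    events: pd.DataFrame,
    species: Optional[str] = None,
    pf: Optional[str] = None,
    authorisation: Optional[str] = None,
) -> float:
    """Proportion of consultations in the stratum with >= 1 qualifying event.

    Repeat visits by the same animal count separately.  An empty stratum is
    an error (undefined), not zero.
    """
    recs = _stratum_records(records, species)
    if recs.empty:
        raise UndefinedResultError("no consultations in stratum")
    qualifying = _qualifying_consults(events, species, pf, authorisation)
    n_hit = recs["consultation_id"].isin(set(qualifying)).sum()
    return float(n_hit) / len(recs)


def rate_per_10k(
    records: pd.DataFrame,
    events: pd.DataFrame,
    pf: str,
    species: Optional[str] = None,
) -> float:
    """Consultations with >= 1 event of the family, per 10,000 consultations."""
    return 10_000.0 * consult_prescription_frequency(
        records, events, species=species, pf=pf
    )


def animal_level_exposure(
    records: pd.DataFrame, events: pd.DataFrame, species: str
) -> float:
    """Fraction of distinct animals of a species with >= 1 prescription event."""
    known = set(records["species"].unique())
    if species not in known:
        raise ValidationError(
            f"unknown species {species!r}; records contain {sorted(known)}"
        )
    animals = records.loc[records["species"] == species, "animal_id"].unique()
    exposed = events.loc[events["species"] == species, "animal_id"].unique()
    return len(np.intersect1d(animals, exposed, assume_unique=True)) / len(animals)


def authorisation_breakdown(
    events: pd.DataFrame, species: Optional[str] = None
) -> dict[str, float]:
    """Proportions of events by authorisation category.

    Proportions are over events whose authorisation is defined and sum to 1;
    events from unresolved agents cannot be categorised and are reported
    separately under ``not_estimable`` (as a proportion of all events).
    """
    ev = events if species is None else events[events["species"] == species]
    if ev.empty:
        raise UndefinedResultError("no events in stratum")
    auth = ev["authorisation"].fillna("")
    defined = auth[auth != ""]
    out = {k: 0.0 for k in ("veterinary", "human", "generic")}
    if len(defined):
        for k, v in (defined.value_counts(normalize=True)).items():
            out[str(k)] = float(v)
    out["not_estimable"] = float((auth == "").mean())
    return out


def cluster_bootstrap(
    stat_fn: Callable[[pd.DataFrame], float],
    records: pd.DataFrame,
    cluster_key: str,
    n_boot: int = 5000,
    seed: Optional[int] = None,
    strata: Optional[str] = None,
    cluster_level: Optional[str] = None,
) -> RateEstimate:
    """Percentile bootstrap resampling whole clusters with replacement.

    Each replicate draws the observed number of clusters (within each
    stratum when ``strata`` is given, e.g. animals within practices),
    concatenates their rows and recomputes ``stat_fn``.  The reported
    statistic is ``stat_fn`` on the observed data; percentile bounds are the
    2.5th / 97.5th percentiles of the replicates, clamped (with a warning)
    in the rare case the observed statistic falls outside them.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if cluster_key not in records.columns:
        raise ValidationError(f"records lack cluster column {cluster_key!r}")
    if records.empty:
        raise UndefinedResultError("no records to bootstrap")

    rng = np.random.default_rng(seed)
    positions = np.arange(len(records))
    if strata is None:
        strata_codes = np.zeros(len(records), dtype=int)
    else:
        strata_codes = pd.factorize(records[strata].to_numpy())[0]
    cluster_codes = pd.factorize(records[cluster_key].to_numpy())[0]

    # per stratum: list of row-position arrays, one per cluster
    groups: list[list[np.ndarray]] = []
    for s in np.unique(strata_codes):
        mask = strata_codes == s
        s_pos = positions[mask]
        s_clu = cluster_codes[mask]
        order = np.argsort(s_clu, kind="stable")
        s_pos, s_clu = s_pos[order], s_clu[order]
        bounds = np.flatnonzero(np.diff(s_clu)) + 1
        groups.append(np.split(s_pos, bounds))

    total_clusters = sum(len(g) for g in groups)
    if total_clusters == 1:
        logger.warning(
            "single cluster: bootstrap interval is degenerate (width 0)"
        )

    observed = float(stat_fn(records))
    reps = np.empty(n_boot)
    for b in range(n_boot):
        chunks = []
        for g in groups:
            picks = rng.integers(0, len(g), size=len(g))
            chunks.extend(g[i] for i in picks)
        idx = np.concatenate(chunks)
        reps[b] = stat_fn(records.iloc[idx])

    ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    if not (ci_low <= observed <= ci_high):
        logger.warning(
            "observed statistic %.6g outside percentile interval "
            "[%.6g, %.6g]; clamping", observed, ci_low, ci_high
        )
        ci_low = min(ci_low, observed)
        ci_high = max(ci_high, observed)
    return RateEstimate(
        statistic=observed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        cluster_level=cluster_level or cluster_key,
    )


def cluster_bootstrap_dual(
    stat_fn: Callable[[pd.DataFrame], float],
    records: pd.DataFrame,
    n_boot: int = 5000,
    seed: Optional[int] = None,
) -> RateEstimate:
    """Run both clustering schemes and keep the wider (more conservative) CI.

    Scheme one clusters consultations by site; scheme two clusters by animal
    within practice (practices as strata).  The two one-stage bootstraps
    bracket the ambiguity of nesting sites and animals in a single scheme.
    """
    ss = np.random.SeedSequence(seed)
    s_site, s_animal = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    by_site = cluster_bootstrap(
        stat_fn, records, "site_id", n_boot, s_site, cluster_level="site"
    )
    by_animal = cluster_bootstrap(
        stat_fn, records, "animal_id", n_boot, s_animal,
        strata="practice_id", cluster_level="animal_within_practice",
    )
    w_site = by_site.ci_high - by_site.ci_low
    w_animal = by_animal.ci_high - by_animal.ci_low
    return by_site if w_site >= w_animal else by_animal


def has_event_flag(
    records: pd.DataFrame,
    events: pd.DataFrame,
    pf: Optional[str] = None,
    authorisation: Optional[str] = None,
) -> pd.Series:
    """Boolean per-record indicator of >= 1 qualifying event (bootstrap helper)."""
    qualifying = set(_qualifying_consults(events, None, pf, authorisation))
    return records["consultation_id"].isin(qualifying)
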
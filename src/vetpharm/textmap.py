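"""Two-stage mapping of free-text product descriptions to prescription events.

Veterinary practices record everything dispensed at a consultation as free
text ("Metronidazole 400MG tabs", "1x dog annual booster", "consult fee").
Mapping proceeds in two stages, in this order:

1. **exclusion**: regular expressions remove descriptions that merely look
   like prescriptions (diagnostic tests, syringes, refunds);
2. **identification**: literal identification strings, matched
   case-insensitively as substrings of the normalised text, link the
   description to taxonomy entries.

A description may legitimately match several entries (combination and
multivalent products).  When one matched string is nested inside a longer
matched string at the same position ("amox" inside "co-amox"), only the
longer match is kept so constituents are not double-counted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import TaxonomyError, ValidationError
from .taxonomy import Taxonomy, TaxonomyEntry

logger = logging.getLogger(__name__)

KIND_EXCLUSION = "exclusion_pattern"
KIND_IDENTIFICATION = "identification_string"

#: delimiter joining multiple product descriptions in one consultation row
PRODUCT_SEP = " | "

RECORD_COLUMNS = (
    "consultation_id",
    "animal_id",
    "species",
    "practice_id",
    "site_id",
    "date",
    "mpc",
    "products",
)

EVENT_COLUMNS = (
    "consultation_id",
    "animal_id",
    "species",
    "practice_id",
    "site_id",
    "date",
    "mpc",
    "agent",
    "pc",
    "pf",
    "authorisation",
    "multiplicity",
)

_WS_RE = re.compile(r"\s+")
_PUNCT_TRANS = str.maketrans(
    {"–": "-", "—": "-", "‐": "-", "‘": "'", "’": "'",
     "“": '"', "”": '"'}
)


def normalise_text(text: str) -> str:
    """Lower-case, collapse whitespace and standardise punctuation.

    Idempotent by construction: applying it twice equals applying it once.
    """
    t = text.casefold().translate(_PUNCT_TRANS)
    return _WS_RE.sub(" ", t).strip()


@dataclass(frozen=True)
class MatchRule:
    """One matching rule: an exclusion regex or an identification string."""

    kind: str
    pattern: str
    priority: int
    target: Optional[TaxonomyEntry] = None
    regex: Optional[re.Pattern] = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class PrescriptionMatch:
    """A single identification-rule hit on one description."""

    description_text: str
    matched_rule: MatchRule
    entry: TaxonomyEntry


class RuleSet:
    """Validated rules, split by kind, with exclusion regexes pre-compiled."""

    def __init__(self, rules: Sequence[MatchRule]):
        self.rules = list(rules)
        self.exclusions = [r for r in self.rules if r.kind == KIND_EXCLUSION]
        self.identifications = sorted(
            (r for r in self.rules if r.kind == KIND_IDENTIFICATION),
            key=lambda r: r.priority,
        )

    def __len__(self) -> int:
        return len(self.rules)


def load_rules(
    source: Union[str, Path, pd.DataFrame], taxonomy: Taxonomy
) -> RuleSet:
    """Load a rules table (columns ``kind,pattern,agent,priority``, optional
    ``pc`` for disambiguating agents shared between taxonomy entries).

    Exclusion patterns are compiled here so that malformed regexes fail at
    load time rather than during matching; identification patterns are
    normalised with :func:`normalise_text`.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    for col in ("kind", "pattern", "priority"):
        if col not in df.columns:
            raise ValidationError(f"rules table is missing column {col!r}")
    if "agent" not in df.columns:
        df["agent"] = ""
    if "pc" not in df.columns:
        df["pc"] = ""

    rules: list[MatchRule] = []
    for idx, row in df.iterrows():
        kind = str(row["kind"]).strip()
        pattern = str(row["pattern"])
        agent = str(row["agent"]).strip()
        pc = str(row["pc"]).strip() or None
        try:
            priority = int(row["priority"])
        except (TypeError, ValueError):
            raise ValidationError(f"rules row {idx}: priority must be an integer")
        if kind == KIND_EXCLUSION:
            if agent:
                raise ValidationError(
                    f"rules row {idx}: exclusion rules must not name a target agent"
                )
            try:
                regex = re.compile(pattern, re.IGNORECASE)
            except re.error as exc:
                raise TaxonomyError(
                    f"rules row {idx}: exclusion pattern {pattern!r} does not "
                    f"compile: {exc}"
                )
            rules.append(MatchRule(kind, pattern, priority, regex=regex))
        elif kind == KIND_IDENTIFICATION:
            if not agent:
                raise ValidationError(
                    f"rules row {idx}: identification rules require a target agent"
                )
            norm = normalise_text(pattern)
            if not norm:
                raise ValidationError(f"rules row {idx}: empty pattern")
            entry = taxonomy.get(agent, pc)
            rules.append(MatchRule(kind, norm, priority, target=entry))
        else:
            raise ValidationError(
                f"rules row {idx}: unknown kind {kind!r} (expected "
                f"{KIND_EXCLUSION!r} or {KIND_IDENTIFICATION!r})"
            )

    for kind in (KIND_EXCLUSION, KIND_IDENTIFICATION):
        pris = [r.priority for r in rules if r.kind == kind]
        if len(set(pris)) != len(pris):
            raise ValidationError(f"duplicate priorities within kind {kind!r}")
    return RuleSet(rules)


def apply_exclusions(text: str, rules: RuleSet) -> bool:
    """True iff any exclusion regex matches the normalised text.

    Exclusion is evaluated before identification; an excluded description
    never yields prescription matches.
    """
    return any(r.regex.search(text) for r in rules.exclusions)


def _occurrences(text: str, pattern: str) -> list[tuple[int, int]]:
    spans = []
    start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            break
        spans.append((i, i + len(pattern)))
        start = i + 1
    return spans


def identify_prescriptions(
    text: str, rules: RuleSet
) -> list[PrescriptionMatch]:
    """All identification-rule matches on a (non-excluded) normalised text.

    Returns one match per distinct taxonomy entry, in priority order.  An
    occurrence strictly nested inside a longer matched occurrence is
    suppressed, so "co-amoxiclav" beats the constituent "amox".
    """
    if not text:
        return []
    occ: list[tuple[int, int, MatchRule]] = []
    for rule in rules.identifications:
        for s, e in _occurrences(text, rule.pattern):
            occ.append((s, e, rule))
    if not occ:
        logger.debug("no identification rule matched %r", text)
        return []

    surviving: list[MatchRule] = []
    seen_rules: set[int] = set()
    for s, e, rule in occ:
        if id(rule) in seen_rules:
            continue
        dominated = any(
            s2 <= s and e <= e2 and (e2 - s2) > (e - s) for s2, e2, _ in occ
        )
        if not dominated:
            surviving.append(rule)
            seen_rules.add(id(rule))

    matches: list[PrescriptionMatch] = []
    seen_entries: set[TaxonomyEntry] = set()
    for rule in sorted(surviving, key=lambda r: r.priority):
        if rule.target in seen_entries:
            continue
        seen_entries.add(rule.target)
        matches.append(PrescriptionMatch(text, rule, rule.target))
    return matches


@dataclass
class MapReport:
    """Coverage statistics for one mapping run over unique descriptions."""

    n_unique_descriptions: int
    n_excluded: int
    n_matched: int
    n_unmatched: int
    n_rules_used: int
    unmatched_examples: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_unique_descriptions": self.n_unique_descriptions,
            "n_excluded": self.n_excluded,
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "n_rules_used": self.n_rules_used,
            "unmatched_examples": list(self.unmatched_examples),
        }


def map_consultations(
    records: pd.DataFrame, rules: RuleSet, sep: str = PRODUCT_SEP
) -> tuple[pd.DataFrame, MapReport]:
    """Map every consultation's product descriptions to prescription events.

    Returns one event row per (consultation, distinct taxonomy entry) pair —
    the same agent listed twice in one consultation yields a single event
    with ``multiplicity`` recording the raw description count — plus a
    :class:`MapReport` of excluded / matched / unmatched unique descriptions.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records are missing columns: {missing}")
    if records["consultation_id"].duplicated().any():
        dupes = records.loc[
            records["consultation_id"].duplicated(), "consultation_id"
        ].unique()[:5]
        raise ValidationError(f"duplicate consultation ids: {list(dupes)}")

    # resolve each unique description once; descriptions repeat heavily
    cache: dict[str, Optional[list[PrescriptionMatch]]] = {}
    excluded: set[str] = set()
    rules_used: set[int] = set()

    def resolve(desc: str) -> Optional[list[PrescriptionMatch]]:
        if desc in cache:
            return cache[desc]
        norm = normalise_text(desc)
        if not norm:
            cache[desc] = []
            return cache[desc]
        if apply_exclusions(norm, rules):
            excluded.add(desc)
            cache[desc] = None  # None marks exclusion
            return None
        matches = identify_prescriptions(norm, rules)
        for m in matches:
            rules_used.add(id(m.matched_rule))
        cache[desc] = matches
        return matches

    rows: list[dict] = []
    for rec in records.itertuples(index=False):
        products = rec.products if isinstance(rec.products, str) else ""
        descs = [d for d in (p.strip() for p in products.split(sep)) if d]
        counts: dict[TaxonomyEntry, int] = {}
        for desc in descs:
            matches = resolve(desc)
            if not matches:
                continue
            for m in matches:
                counts[m.entry] = counts.get(m.entry, 0) + 1
        for entry, mult in counts.items():
            rows.append(
                {
                    "consultation_id": rec.consultation_id,
                    "animal_id": rec.animal_id,
                    "species": rec.species,
                    "practice_id": rec.practice_id,
                    "site_id": rec.site_id,
                    "date": rec.date,
                    "mpc": rec.mpc,
                    "agent": entry.agent,
                    "pc": entry.pc,
                    "pf": entry.pf,
                    "authorisation": entry.authorisation or "",
                    "multiplicity": mult,
                }
            )

    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    unmatched = [
        d for d, v in cache.items() if v is not None and len(v) == 0 and d.strip()
    ]
    report = MapReport(
        n_unique_descriptions=len(cache),
        n_excluded=len(excluded),
        n_matched=len(cache) - len(excluded) - len(unmatched),
        n_unmatched=len(unmatched),
        n_rules_used=len(rules_used),
        unmatched_examples=sorted(unmatched)[:20],
    )
    return events, report
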
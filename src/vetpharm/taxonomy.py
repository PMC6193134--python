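"""Drug taxonomy: agent → pharmaceutical class (PC) → pharmaceutical family (PF).

The taxonomy is a three-level hierarchy over prescribed active substances.
Every pharmaceutical class belongs to exactly one pharmaceutical family, and
every resolvable agent carries an authorisation category: ``veterinary``
(authorised veterinary product), ``human`` (authorised for human use only,
prescribed to animals under the veterinary cascade) or ``generic`` (the
recorded term is ambiguous between veterinary- and human-authorised products,
e.g. "co-amox").

Some families — vaccines, euthanasia products, neurological agents and
replacement agents (rehydration / vitamin / mineral products) — are routinely
recorded with descriptors that cannot be pinned to a specific agent
("1x dog annual booster"); those entries carry ``agent == "unresolved"`` and
no authorisation (reported downstream as not estimable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Union

import pandas as pd

from .errors import TaxonomyError, ValidationError

logger = logging.getLogger(__name__)

AUTHORISATIONS = ("veterinary", "human", "generic")

#: agent label used for family-level descriptors that cannot be resolved
UNRESOLVED = "unresolved"

#: families whose descriptions frequently cannot be resolved beyond family level
FAMILY_ONLY_PFS = frozenset(
    {"vaccine", "neurological", "euthanasia", "replacement agent"}
)

TAXONOMY_COLUMNS = ("agent", "pc", "pf", "authorisation")


@dataclass(frozen=True)
class TaxonomyEntry:
    """One node of the drug hierarchy.

    ``authorisation`` is ``None`` for unresolved (family-only) entries, for
    which the veterinary/human/generic split cannot be estimated.
    """

    agent: str
    pc: str
    pf: str
    authorisation: Optional[str]

    @property
    def resolved(self) -> bool:
        return self.agent != UNRESOLVED


class Taxonomy:
    """Validated collection of :class:`TaxonomyEntry` with fast lookup."""

    def __init__(self, entries: list[TaxonomyEntry]):
        self.entries = list(entries)
        self._by_key: dict[tuple[str, str], TaxonomyEntry] = {}
        self._by_agent: dict[str, list[TaxonomyEntry]] = {}
        for e in self.entries:
            self._by_key[(e.agent, e.pc)] = e
            self._by_agent.setdefault(e.agent, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TaxonomyEntry]:
        return iter(self.entries)

    @property
    def pfs(self) -> set[str]:
        return {e.pf for e in self.entries}

    @property
    def pcs(self) -> set[str]:
        return {e.pc for e in self.entries}

    def get(self, agent: str, pc: Optional[str] = None) -> TaxonomyEntry:
        """Look up an entry by agent name, optionally disambiguated by PC."""
        if pc is not None:
            try:
                return self._by_key[(agent, pc)]
            except KeyError:
                raise TaxonomyError(f"no taxonomy entry for agent={agent!r}, pc={pc!r}")
        candidates = self._by_agent.get(agent, [])
        if not candidates:
            raise TaxonomyError(f"no taxonomy entry for agent={agent!r}")
        if len(candidates) > 1:
            raise TaxonomyError(
                f"agent={agent!r} is ambiguous ({len(candidates)} entries); "
                "disambiguate with a pc"
            )
        return candidates[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "agent": e.agent,
                    "pc": e.pc,
                    "pf": e.pf,
                    "authorisation": e.authorisation or "",
                }
                for e in self.entries
            ],
            columns=list(TAXONOMY_COLUMNS),
        )


def load_taxonomy(source: Union[str, Path, pd.DataFrame]) -> Taxonomy:
    """Load and validate a taxonomy table.

    ``source`` is a CSV path (UTF-8, header ``agent,pc,pf,authorisation``) or
    an equivalent DataFrame.  Validation enforces:

    * no duplicate (agent, pc) pairs;
    * every PC maps to exactly one PF;
    * every resolvable agent has a valid authorisation; unresolved
      (family-level) entries have none and occur only in families where
      agent-level resolution is genuinely impossible.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"taxonomy is missing columns: {missing}")
    if df.empty:
        logger.warning("taxonomy source is empty; returning an empty taxonomy")
        return Taxonomy([])

    entries: list[TaxonomyEntry] = []
    for idx, row in df.iterrows():
        agent = str(row["agent"]).strip()
        pc = str(row["pc"]).strip()
        pf = str(row["pf"]).strip()
        auth = str(row["authorisation"]).strip() or None
        if not agent or not pc or not pf:
            raise ValidationError(
                f"taxonomy row {idx}: agent/pc/pf must all be non-empty "
                f"(got agent={agent!r}, pc={pc!r}, pf={pf!r})"
            )
        if agent == UNRESOLVED:
            if pf not in FAMILY_ONLY_PFS:
                raise ValidationError(
                    f"taxonomy row {idx}: unresolved agents are only allowed in "
                    f"family-only families {sorted(FAMILY_ONLY_PFS)}, not {pf!r}"
                )
            if auth is not None:
                raise ValidationError(
                    f"taxonomy row {idx}: unresolved entries cannot carry an "
                    "authorisation"
                )
        else:
            if auth not in AUTHORISATIONS:
                raise ValidationError(
                    f"taxonomy row {idx}: authorisation must be one of "
                    f"{AUTHORISATIONS}, got {auth!r}"
                )
        entries.append(TaxonomyEntry(agent=agent, pc=pc, pf=pf, authorisation=auth))

    keys = [(e.agent, e.pc) for e in entries]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (agent, pc) pairs in taxonomy: {dupes}")

    pc_to_pf: dict[str, str] = {}
    for e in entries:
        seen = pc_to_pf.setdefault(e.pc, e.pf)
        if seen != e.pf:
            raise TaxonomyError(
                f"pharmaceutical class {e.pc!r} maps to two families: "
                f"{seen!r} and {e.pf!r}"
            )
    return Taxonomy(entries)
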
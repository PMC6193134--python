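"""Synthetic sentinel-network EHR generator with known ground truth.

Emulates the structure of booked-consultation records from a voluntary
network of UK companion-animal practices: practices with one or more branch
sites, dogs/cats/rabbits making repeat visits, one of ten main presenting
complaints (MPC) per consultation, and noisy practitioner-style free-text
product descriptions for everything dispensed.

Prescribing is organised around three planted co-prescription blocks —

* **preventive** (vaccine, ectoparasiticide, endectocide, endoparasiticide),
* **treatment** (antibiotic, anti-inflammatory, antimycotic,
  gastrointestinal, neurological, cardiovascular, replacement agent,
  endocrine),
* **euthanasia** (euthanasia only; never co-prescribed with anything else)

— with within-block co-prescription much more likely than cross-block
leakage, so the downstream network pipeline has a known partition to
recover.  Within each pharmaceutical family, each practice has its own
probability vector over pharmaceutical classes; the Simpson-type diversity
of that vector is the practice's true prescription diversity, recorded in
the ground truth for parameter-recovery testing.

Everything is driven by a single integer seed and is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .taxonomy import Taxonomy, load_taxonomy
from .textmap import (
    KIND_EXCLUSION,
    KIND_IDENTIFICATION,
    PRODUCT_SEP,
    RECORD_COLUMNS,
    RuleSet,
    load_rules,
    normalise_text,
)

SPECIES = ("dog", "cat", "rabbit")

MPCS = (
    "gastroenteric",
    "respiratory",
    "pruritus",
    "trauma",
    "tumour",
    "kidney disease",
    "other unwell",
    "post-operative",
    "vaccination",
    "other healthy",
)

#: planted co-prescription blocks over pharmaceutical families
BLOCKS: dict[str, tuple[str, ...]] = {
    "preventive": ("vaccine", "ectoparasiticide", "endectocide", "endoparasiticide"),
    "treatment": (
        "antibiotic",
        "anti-inflammatory",
        "antimycotic",
        "gastrointestinal",
        "neurological",
        "cardiovascular",
        "replacement agent",
        "endocrine",
    ),
    "euthanasia": ("euthanasia",),
}

#: families rendered only as family-level descriptors (agent unresolvable)
FAMILY_ONLY = frozenset({"vaccine", "euthanasia"})

# ---------------------------------------------------------------------------
# built-in synthetic taxonomy and rule set
# ---------------------------------------------------------------------------

#: pharmaceutical classes per resolvable family (synthetic, field-flavoured)
PF_PCS: dict[str, tuple[str, ...]] = {
    "antibiotic": (
        "potentiated aminopenicillin",
        "cephalosporin",
        "fluoroquinolone",
        "tetracycline",
        "nitroimidazole",
        "lincosamide",
    ),
    "anti-inflammatory": ("nsaid", "corticosteroid"),
    "antimycotic": ("imidazole", "polyene"),
    "gastrointestinal": ("h2 antagonist", "prokinetic", "antiemetic"),
    "neurological": ("anticonvulsant", "opioid analgesic"),
    "cardiovascular": ("ace inhibitor", "diuretic"),
    "replacement agent": ("rehydration fluid", "vitamin supplement"),
    "endocrine": ("insulin", "thyroid agent"),
    "ectoparasiticide": (
        "neonicotinoid",
        "isoxazoline",
        "pyrethroid",
        "insect growth regulator",
    ),
    "endectocide": ("milbemycin", "avermectin"),
    "endoparasiticide": ("quinoline", "benzimidazole"),
}

#: curated agent names; uncurated (pc, authorisation) slots fall back to a
#: systematic name, and every generic slot defaults to the bare class name
#: (an intrinsically ambiguous description, which is what "generic" means)
_CURATED_AGENTS: dict[tuple[str, str], str] = {
    ("potentiated aminopenicillin", "veterinary"): "amoxicillin clavulanate",
    ("potentiated aminopenicillin", "generic"): "co-amox",
    ("cephalosporin", "veterinary"): "cefovecin",
    ("cephalosporin", "human"): "cephalexin",
    ("fluoroquinolone", "veterinary"): "enrofloxacin",
    ("fluoroquinolone", "human"): "ciprofloxacin",
    ("tetracycline", "veterinary"): "doxycycline",
    ("nitroimidazole", "human"): "metronidazole",
    ("lincosamide", "veterinary"): "clindamycin",
    ("nsaid", "veterinary"): "meloxicam",
    ("nsaid", "human"): "ibuprofen",
    ("corticosteroid", "veterinary"): "prednisolone",
    ("corticosteroid", "human"): "dexamethasone",
    ("imidazole", "veterinary"): "miconazole",
    ("imidazole", "human"): "ketoconazole",
    ("polyene", "veterinary"): "nystatin",
    ("polyene", "human"): "amphotericin",
    ("h2 antagonist", "veterinary"): "cimetidine",
    ("h2 antagonist", "human"): "ranitidine",
    ("prokinetic", "human"): "cisapride",
    ("antiemetic", "veterinary"): "maropitant",
    ("anticonvulsant", "veterinary"): "imepitoin",
    ("anticonvulsant", "generic"): "phenobarbitone",
    ("opioid analgesic", "veterinary"): "buprenorphine",
    ("opioid analgesic", "human"): "tramadol",
    ("ace inhibitor", "veterinary"): "benazepril",
    ("ace inhibitor", "human"): "ramipril",
    ("diuretic", "generic"): "furosemide",
    ("insulin", "generic"): "insulin",
    ("thyroid agent", "human"): "levothyroxine",
    ("neonicotinoid", "veterinary"): "imidacloprid",
    ("isoxazoline", "veterinary"): "fluralaner",
    ("pyrethroid", "veterinary"): "permethrin",
    ("insect growth regulator", "veterinary"): "lufenuron",
    ("milbemycin", "veterinary"): "milbemycin oxime",
    ("avermectin", "veterinary"): "ivermectin",
    ("quinoline", "veterinary"): "praziquantel",
    ("benzimidazole", "veterinary"): "fenbendazole",
}

_AUTH_SUFFIX = {"veterinary": "v", "human": "h"}

VACCINE_DESCRIPTORS = {
    "dog": ("1x dog annual booster", "puppy vacc course", "annual booster",
            "booster vacc", "primary vaccination"),
    "cat": ("kitten vacc course", "annual booster", "cat flu vaccine",
            "booster vacc"),
    "rabbit": ("rabbit vhd vaccine", "vhd vaccine", "annual booster"),
}

EUTHANASIA_DESCRIPTORS = (
    "euthanasia",
    "home visit euthanasia",
    "pentobarbital injection",
    "put to sleep",
)

VACCINE_PATTERNS = ("vaccine", "vaccination", "vacc", "booster", "vhd")
EUTHANASIA_PATTERNS = ("euthanasia", "put to sleep", "pentobarbital")

EXCLUSION_PATTERNS = (
    r"toxicity\s+test",
    r"syringe",
    r"refund",
    r"blood\s+test",
    r"swab",
)

DECOY_STRINGS = (
    "consultation fee",
    "nail clip",
    "microchip implant",
    "bandage change",
    "repeat health check",
    "dental descale",
    "kennel stay",
    "pet passport",
    "food 2kg bag",
)

EXCLUDED_DECOY_STRINGS = (
    "phenobarbitone toxicity test",
    "insulin syringes x10",
    "refund - flea spot-on",
    "pre-anaesthetic blood test",
    "ear swab",
)


def agent_name(pc: str, authorisation: str) -> str:
    """Agent name for a (class, authorisation) slot of the built-in taxonomy."""
    if (pc, authorisation) in _CURATED_AGENTS:
        return _CURATED_AGENTS[(pc, authorisation)]
    if authorisation == "generic":
        return pc
    return f"{pc} {_AUTH_SUFFIX[authorisation]}"


def builtin_taxonomy_frame() -> pd.DataFrame:
    """Synthetic drug taxonomy as a DataFrame (agent,pc,pf,authorisation)."""
    rows = []
    for pf, pcs in PF_PCS.items():
        for pc in pcs:
            for auth in ("veterinary", "human", "generic"):
                rows.append(
                    {"agent": agent_name(pc, auth), "pc": pc, "pf": pf,
                     "authorisation": auth}
                )
    for pf in sorted(FAMILY_ONLY):
        rows.append({"agent": "unresolved", "pc": pf, "pf": pf,
                     "authorisation": ""})
    return pd.DataFrame(rows, columns=["agent", "pc", "pf", "authorisation"])


def builtin_rules_frame() -> pd.DataFrame:
    """Synthetic matching rules: exclusion regexes + identification strings.

    Identification patterns are the agent names themselves plus family-level
    descriptor fragments for vaccines and euthanasia.  Priorities order
    longer patterns first (cosmetic; nested-match suppression is positional).
    """
    rows = []
    for i, pat in enumerate(EXCLUSION_PATTERNS):
        rows.append({"kind": KIND_EXCLUSION, "pattern": pat, "agent": "",
                     "pc": "", "priority": i})
    id_rows = []
    for pf, pcs in PF_PCS.items():
        for pc in pcs:
            for auth in ("veterinary", "human", "generic"):
                name = agent_name(pc, auth)
                id_rows.append((name, name, pc))
    for pat in VACCINE_PATTERNS:
        id_rows.append((pat, "unresolved", "vaccine"))
    for pat in EUTHANASIA_PATTERNS:
        id_rows.append((pat, "unresolved", "euthanasia"))
    id_rows.sort(key=lambda t: (-len(t[0]), t[0]))
    for i, (pat, agent, pc) in enumerate(id_rows):
        rows.append({"kind": KIND_IDENTIFICATION, "pattern": pat,
                     "agent": agent, "pc": pc, "priority": i})
    return pd.DataFrame(rows, columns=["kind", "pattern", "agent", "pc",
                                       "priority"])


def builtin_taxonomy() -> Taxonomy:
    return load_taxonomy(builtin_taxonomy_frame())


def builtin_ruleset(taxonomy: Optional[Taxonomy] = None) -> RuleSet:
    return load_rules(builtin_rules_frame(), taxonomy or builtin_taxonomy())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_mpc_probs() -> dict[str, float]:
    return {
        "gastroenteric": 0.10,
        "respiratory": 0.05,
        "pruritus": 0.09,
        "trauma": 0.05,
        "tumour": 0.04,
        "kidney disease": 0.03,
        "other unwell": 0.16,
        "post-operative": 0.08,
        "vaccination": 0.26,
        "other healthy": 0.14,
    }


def _default_mpc_group_probs() -> dict[str, dict[str, float]]:
    probs: dict[str, dict[str, float]] = {
        "vaccination": {"preventive": 1.0},
        "other healthy": {"preventive": 0.9, "treatment": 0.1},
        "tumour": {"treatment": 0.8, "euthanasia": 0.2},
        "kidney disease": {"treatment": 0.85, "euthanasia": 0.15},
        "other unwell": {"treatment": 0.96, "euthanasia": 0.04},
    }
    for mpc in MPCS:
        probs.setdefault(mpc, {"treatment": 1.0})
    return probs


def _default_pf_profiles() -> dict[str, dict[str, float]]:
    return {
        "preventive": {
            "vaccine": 0.40,
            "ectoparasiticide": 0.22,
            "endectocide": 0.20,
            "endoparasiticide": 0.18,
        },
        "treatment": {
            "antibiotic": 0.20,
            "anti-inflammatory": 0.18,
            "gastrointestinal": 0.14,
            "neurological": 0.12,
            "antimycotic": 0.09,
            "cardiovascular": 0.09,
            "replacement agent": 0.09,
            "endocrine": 0.09,
        },
        "euthanasia": {"euthanasia": 1.0},
    }


@dataclass
class SynthConfig:
    """Generator configuration; the defaults define the study conditions.

    Probability vectors must sum to 1 (tolerance 1e-9); the seed fully
    determines the output.
    """

    n_practices: int = 50
    sites_per_practice: tuple[int, int] = (1, 4)  # inclusive uniform range
    n_animals: int = 5000
    species_mix: dict[str, float] = field(
        default_factory=lambda: {"dog": 0.71, "cat": 0.27, "rabbit": 0.02}
    )
    consults_per_animal: float = 8.0  # mean of 1 + Poisson(mean - 1)
    mpc_probs: dict[str, float] = field(default_factory=_default_mpc_probs)
    mpc_group_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_mpc_group_probs
    )
    pf_profiles: dict[str, dict[str, float]] = field(
        default_factory=_default_pf_profiles
    )
    within_block_co: dict[str, float] = field(
        default_factory=lambda: {"preventive": 0.22, "treatment": 0.08,
                                 "euthanasia": 0.0}
    )
    cross_block_rate: float = 0.03
    p_prescribe: float = 0.65
    practice_effect_sd: float = 0.4
    pc_dirichlet_alpha: float = 2.0
    pc_within_pf_probs: Optional[dict[str, dict[str, dict[str, float]]]] = None
    authorisation_mix: dict[str, float] = field(
        default_factory=lambda: {"veterinary": 0.93, "human": 0.05,
                                 "generic": 0.02}
    )
    decoy_rate: float = 0.35
    excluded_decoy_rate: float = 0.05
    duplicate_description_rate: float = 0.03
    broken_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_practices < 1:
            errors.append("n_practices must be >= 1")
        if self.n_animals < 0:
            errors.append("n_animals must be >= 0")
        lo, hi = self.sites_per_practice
        if not (1 <= lo <= hi):
            errors.append("sites_per_practice must satisfy 1 <= lo <= hi")
        if self.consults_per_animal < 1:
            errors.append("consults_per_animal must be >= 1")
        for name, vec in (
            ("species_mix", self.species_mix),
            ("mpc_probs", self.mpc_probs),
            ("authorisation_mix", self.authorisation_mix),
        ):
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                errors.append(f"{name} must sum to 1")
            if any(v < 0 for v in vec.values()):
                errors.append(f"{name} has negative probabilities")
        if set(self.species_mix) != set(SPECIES):
            errors.append(f"species_mix keys must be {SPECIES}")
        if set(self.mpc_probs) != set(MPCS):
            errors.append("mpc_probs keys must be the ten presenting complaints")
        for mpc, gp in self.mpc_group_probs.items():
            if abs(sum(gp.values()) - 1.0) > 1e-9:
                errors.append(f"mpc_group_probs[{mpc!r}] must sum to 1")
            if not set(gp) <= set(BLOCKS):
                errors.append(f"mpc_group_probs[{mpc!r}] has unknown groups")
        for group, prof in self.pf_profiles.items():
            if group not in BLOCKS:
                errors.append(f"pf_profiles has unknown group {group!r}")
                continue
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                errors.append(f"pf_profiles[{group!r}] must sum to 1")
            if not set(prof) <= set(BLOCKS[group]):
                errors.append(
                    f"pf_profiles[{group!r}] names families outside its block"
                )
        for group, p in self.within_block_co.items():
            if not 0.0 <= p <= 1.0:
                errors.append(f"within_block_co[{group!r}] must be in [0, 1]")
        for name, p in (
            ("cross_block_rate", self.cross_block_rate),
            ("p_prescribe", self.p_prescribe),
            ("decoy_rate", self.decoy_rate),
            ("excluded_decoy_rate", self.excluded_decoy_rate),
            ("duplicate_description_rate", self.duplicate_description_rate),
            ("broken_rate", self.broken_rate),
        ):
            if not 0.0 <= p <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        if self.practice_effect_sd < 0:
            errors.append("practice_effect_sd must be >= 0")
        if self.pc_dirichlet_alpha <= 0:
            errors.append("pc_dirichlet_alpha must be > 0")
        if errors:
            raise ValidationError("invalid SynthConfig: " + "; ".join(errors))

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        cfg = cls(**d)
        if isinstance(cfg.sites_per_practice, list):
            cfg.sites_per_practice = tuple(cfg.sites_per_practice)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    true_pd: pd.DataFrame            # practice_id, pf, true_pd
    pc_probs: dict                   # practice -> pf -> {pc: prob}
    planted_groups: dict[str, str]   # pf -> block, for generated PFs
    planted_event_count: int         # matchable (non-broken) planted events
    broken_event_count: int
    decoy_count: int
    excluded_decoy_count: int
    n_consultations: int
    n_prescribing_consultations: int
    n_coprescribing_consultations: int
    authorisation_counts: dict[str, int]
    p_prescribe_by_practice: dict[str, float]
    events: pd.DataFrame             # planted events incl. broken flag

    def summary_dict(self) -> dict:
        return {
            "planted_groups": dict(sorted(self.planted_groups.items())),
            "planted_event_count": self.planted_event_count,
            "broken_event_count": self.broken_event_count,
            "decoy_count": self.decoy_count,
            "excluded_decoy_count": self.excluded_decoy_count,
            "n_consultations": self.n_consultations,
            "n_prescribing_consultations": self.n_prescribing_consultations,
            "n_coprescribing_consultations": self.n_coprescribing_consultations,
            "authorisation_counts": dict(sorted(self.authorisation_counts.items())),
            "p_prescribe_by_practice": {
                k: round(v, 6)
                for k, v in sorted(self.p_prescribe_by_practice.items())
            },
        }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_FORMS = ("tablets", "tabs", "suspension", "capsules", "injection",
          "spot-on pipette", "oral solution")
_DOSES = (5, 10, 20, 25, 50, 100, 250, 400)
_UNITS = ("mg", "ml")

_STUDY_START = np.datetime64("2014-04-01")
_STUDY_DAYS = 730  # two-year surveillance window


def _render_resolved(rng: np.random.Generator, name: str) -> str:
    """Noisy practitioner-style description guaranteed to contain ``name``."""
    parts = []
    if rng.random() < 0.25:
        parts.append(f"{rng.integers(1, 4)}x")
    parts.append(name)
    parts.append(f"{_DOSES[rng.integers(len(_DOSES))]}"
                 f"{_UNITS[rng.integers(len(_UNITS))]}")
    if rng.random() < 0.7:
        parts.append(_FORMS[rng.integers(len(_FORMS))])
    joiner = "  " if rng.random() < 0.1 else " "
    text = joiner.join(parts)
    u = rng.random()
    if u < 0.2:
        text = text.upper()
    elif u < 0.4:
        text = text.title()
    return text


def render_description(
    rng: np.random.Generator,
    pf: str,
    agent: str,
    species: str,
    broken: bool = False,
    broken_counter: int = 0,
) -> str:
    """Render one planted prescription as raw product-description text.

    Non-broken text always contains an identification pattern for the
    prescription; ``broken=True`` emulates entries too mangled to recognise
    and is guaranteed to match no rule (tracked in the ground truth).
    """
    if broken:
        return f"illegible entry {broken_counter}"
    if pf == "vaccine":
        opts = VACCINE_DESCRIPTORS[species]
        return opts[rng.integers(len(opts))]
    if pf == "euthanasia":
        return EUTHANASIA_DESCRIPTORS[rng.integers(len(EUTHANASIA_DESCRIPTORS))]
    return _render_resolved(rng, agent)


def _draw_pc_probs(
    rng: np.random.Generator, config: SynthConfig, practices: list[str]
) -> dict[str, dict[str, dict[str, float]]]:
    if config.pc_within_pf_probs is not None:
        return config.pc_within_pf_probs
    out: dict[str, dict[str, dict[str, float]]] = {}
    for pid in practices:
        out[pid] = {}
        for pf, pcs in PF_PCS.items():
            alpha = np.full(len(pcs), config.pc_dirichlet_alpha)
            probs = rng.dirichlet(alpha)
            out[pid][pf] = {pc: float(p) for pc, p in zip(pcs, probs)}
    return out


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_dataset(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full synthetic consultation table plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    practices = [f"P{i:03d}" for i in range(config.n_practices)]
    lo, hi = config.sites_per_practice
    sites = {
        pid: [f"{pid}-S{j}" for j in range(rng.integers(lo, hi + 1))]
        for pid in practices
    }
    base_logit = math.log(config.p_prescribe / (1 - config.p_prescribe))
    effects = rng.normal(0.0, config.practice_effect_sd, size=len(practices))
    p_eff = {pid: _expit(base_logit + e) for pid, e in zip(practices, effects)}

    pc_probs = _draw_pc_probs(rng, config, practices)
    true_pd_rows = [
        {"practice_id": pid, "pf": pf,
         "true_pd": 1.0 - sum(p * p for p in vec.values())}
        for pid, by_pf in pc_probs.items()
        for pf, vec in by_pf.items()
    ]

    species_names = list(config.species_mix)
    species_p = np.array([config.species_mix[s] for s in species_names])
    mpc_names = list(config.mpc_probs)
    mpc_p = np.array([config.mpc_probs[m] for m in mpc_names])
    auth_names = list(config.authorisation_mix)
    auth_p = np.array([config.authorisation_mix[a] for a in auth_names])

    group_choices = {
        mpc: (list(gp), np.array(list(gp.values())))
        for mpc, gp in config.mpc_group_probs.items()
    }
    profile_arrays = {
        g: (list(prof), np.array(list(prof.values())))
        for g, prof in config.pf_profiles.items()
    }

    if config.n_animals == 0:
        empty_records = pd.DataFrame(columns=list(RECORD_COLUMNS))
        empty_events = pd.DataFrame(
            columns=["consultation_id", "practice_id", "species", "pf", "pc",
                     "agent", "authorisation", "broken"]
        )
        gt = GroundTruth(
            true_pd=pd.DataFrame(true_pd_rows),
            pc_probs=pc_probs,
            planted_groups={},
            planted_event_count=0,
            broken_event_count=0,
            decoy_count=0,
            excluded_decoy_count=0,
            n_consultations=0,
            n_prescribing_consultations=0,
            n_coprescribing_consultations=0,
            authorisation_counts={},
            p_prescribe_by_practice=p_eff,
            events=empty_events,
        )
        return empty_records, gt

    animal_practice = rng.integers(0, len(practices), size=config.n_animals)
    animal_species = rng.choice(len(species_names), size=config.n_animals,
                                p=species_p)
    n_consults = 1 + rng.poisson(config.consults_per_animal - 1,
                                 size=config.n_animals)

    record_rows: list[dict] = []
    event_rows: list[dict] = []
    planted_groups: dict[str, str] = {}
    auth_counts: dict[str, int] = {}
    n_prescribing = 0
    n_coprescribing = 0
    n_broken = 0
    n_decoys = 0
    n_excluded_decoys = 0
    consult_counter = 0

    for a_idx in range(config.n_animals):
        pid = practices[animal_practice[a_idx]]
        sp = species_names[animal_species[a_idx]]
        animal_id = f"A{a_idx:06d}"
        practice_sites = sites[pid]
        for _ in range(n_consults[a_idx]):
            cid = f"C{consult_counter:07d}"
            consult_counter += 1
            site = practice_sites[rng.integers(len(practice_sites))]
            date = str(_STUDY_START + rng.integers(_STUDY_DAYS))
            mpc = mpc_names[rng.choice(len(mpc_names), p=mpc_p)]
            g_names, g_p = group_choices[mpc]
            group = g_names[rng.choice(len(g_names), p=g_p)]

            descriptions: list[str] = []
            prescribing = rng.random() < p_eff[pid]
            pf_set: list[str] = []
            if prescribing:
                prof_names, prof_p = profile_arrays[group]
                primary = prof_names[rng.choice(len(prof_names), p=prof_p)]
                pf_set.append(primary)
                co_p = config.within_block_co.get(group, 0.0)
                for other in BLOCKS[group]:
                    if other != primary and rng.random() < co_p:
                        pf_set.append(other)
                # occasional cross-block leakage; euthanasia never leaks
                if group != "euthanasia" and rng.random() < config.cross_block_rate:
                    other_groups = [g for g in ("preventive", "treatment")
                                    if g != group]
                    og = other_groups[rng.integers(len(other_groups))]
                    og_names, og_p = profile_arrays[og]
                    pf_set.append(og_names[rng.choice(len(og_names), p=og_p)])

                for pf in pf_set:
                    if pf in FAMILY_ONLY:
                        pc, agent, auth = pf, "unresolved", ""
                    else:
                        vec = pc_probs[pid][pf]
                        pcs = list(vec)
                        pc = pcs[rng.choice(len(pcs),
                                            p=np.array(list(vec.values())))]
                        auth = auth_names[rng.choice(len(auth_names), p=auth_p)]
                        agent = agent_name(pc, auth)
                        auth_counts[auth] = auth_counts.get(auth, 0) + 1
                    broken = rng.random() < config.broken_rate
                    if broken:
                        n_broken += 1
                    text = render_description(rng, pf, agent, sp, broken,
                                              n_broken)
                    descriptions.append(text)
                    if not broken and rng.random() < config.duplicate_description_rate:
                        descriptions.append(text)
                    planted_groups[pf] = _block_of(pf)
                    event_rows.append(
                        {"consultation_id": cid, "practice_id": pid,
                         "species": sp, "pf": pf, "pc": pc, "agent": agent,
                         "authorisation": auth, "broken": broken}
                    )
                n_prescribing += 1
                if len(set(pf_set)) >= 2:
                    n_coprescribing += 1

            if rng.random() < config.decoy_rate:
                n_decoys += 1
                if rng.random() < config.excluded_decoy_rate:
                    n_excluded_decoys += 1
                    decoy = EXCLUDED_DECOY_STRINGS[
                        rng.integers(len(EXCLUDED_DECOY_STRINGS))]
                else:
                    decoy = DECOY_STRINGS[rng.integers(len(DECOY_STRINGS))]
                descriptions.append(decoy)

            record_rows.append(
                {"consultation_id": cid, "animal_id": animal_id, "species": sp,
                 "practice_id": pid, "site_id": site, "date": date,
                 "mpc": mpc, "products": PRODUCT_SEP.join(descriptions)}
            )

    records = pd.DataFrame(record_rows, columns=list(RECORD_COLUMNS))
    events = pd.DataFrame(
        event_rows,
        columns=["consultation_id", "practice_id", "species", "pf", "pc",
                 "agent", "authorisation", "broken"],
    )
    # planted events are counted at (consultation, entry) level, matching the
    # dedup applied by the mapper; duplicate renderings are extra text only
    if len(events):
        nonbroken = events[~events["broken"]]
        planted_count = len(
            nonbroken.drop_duplicates(["consultation_id", "agent", "pc"])
        )
    else:
        planted_count = 0

    gt = GroundTruth(
        true_pd=pd.DataFrame(true_pd_rows),
        pc_probs=pc_probs,
        planted_groups=planted_groups,
        planted_event_count=planted_count,
        broken_event_count=n_broken,
        decoy_count=n_decoys,
        excluded_decoy_count=n_excluded_decoys,
        n_consultations=len(records),
        n_prescribing_consultations=n_prescribing,
        n_coprescribing_consultations=n_coprescribing,
        authorisation_counts=auth_counts,
        p_prescribe_by_practice=p_eff,
        events=events,
    )
    return records, gt


def _block_of(pf: str) -> str:
    for block, members in BLOCKS.items():
        if pf in members:
            return block
    raise ValidationError(f"family {pf!r} belongs to no block")


def write_dataset(
    records: pd.DataFrame, gt: GroundTruth, outdir: Union[str, Path]
) -> dict[str, Path]:
    """Write consultations CSV plus ground-truth JSON/CSVs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "consultations.csv",
        "ground_truth": outdir / "ground_truth.json",
        "true_pd": outdir / "true_pd.csv",
        "planted_events": outdir / "planted_events.csv",
    }
    records.to_csv(paths["records"], index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(gt.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    gt.true_pd.to_csv(paths["true_pd"], index=False)
    gt.events.to_csv(paths["planted_events"], index=False)
    return paths
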
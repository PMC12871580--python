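"""Seeded synthetic pediatric emergency-department cohorts.

Generates structured encounter records plus multi-note clinical narratives
with ground-truth labels for self-injurious thoughts and behaviors (SITB).
The generator emulates the statistical structure of a pediatric
mental-health ED population: ~46% SITB prevalence, gatekept c-SSRS
screening, stratum-dependent fidelity of structured documentation (weaker
for younger/male and neurodevelopmental strata) with uniformly high text
fidelity, and SITB-lexicon distractor sentences whose negation / tense /
referent modifiers make them true negatives.

Everything is driven by a ``CohortConfig`` and a single integer seed;
identical (config, seed) pairs produce byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StratumSpec",
    "CohortConfig",
    "Encounter",
    "Note",
    "Sentence",
    "ConfigurationError",
    "generate_cohort",
    "sample_cssrs",
    "generate_notes",
    "cohort_to_frame",
    "write_encounters_csv",
    "read_encounters_csv",
    "write_notes_jsonl",
    "read_notes_jsonl",
    "CSSRS_N_ITEMS",
    "DX_CATEGORIES",
    "RACE_CATEGORIES",
]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


CSSRS_N_ITEMS = 5

#: CAMHD-CS-style diagnostic category taxonomy (pediatric mental-health
#: ICD-10-CM groupings).  Order is the canonical column order downstream.
DX_CATEGORIES = (
    "adhd",
    "anxiety",
    "autism_spectrum",
    "bipolar",
    "depressive",
    "developmental",
    "disruptive_impulse_conduct",
    "feeding_eating",
    "intellectual_disability",
    "mh_symptom",
    "miscellaneous",
    "neurocognitive",
    "obsessive_compulsive",
    "psychotic",
    "substance_related",
    "suicide_self_injury",
    "trauma_stressor",
)

RACE_CATEGORIES = ("white", "hispanic_latino", "black", "asian", "other")
INSURANCE_CATEGORIES = ("public", "private", "self_pay")
DISPOSITION_CATEGORIES = ("discharged", "psychiatric_hosp", "medical_hosp", "other")
AUTHOR_TYPES = ("ed_physician", "psychiatrist", "social_worker", "nurse")

# Baseline marginal rates for diagnostic categories as (rate_pos, rate_neg)
# by encounter label; internalizing categories carry most label dependence.
_DX_RATES = {
    "adhd": (0.22, 0.22),
    "anxiety": (0.34, 0.27),
    "autism_spectrum": (0.12, 0.12),
    "bipolar": (0.05, 0.04),
    "depressive": (0.50, 0.24),
    "developmental": (0.02, 0.02),
    "disruptive_impulse_conduct": (0.06, 0.08),
    "feeding_eating": (0.03, 0.03),
    "intellectual_disability": (0.017, 0.017),
    "mh_symptom": (0.12, 0.16),
    "miscellaneous": (0.05, 0.05),
    "neurocognitive": (0.015, 0.018),
    "obsessive_compulsive": (0.05, 0.04),
    "psychotic": (0.035, 0.04),
    "substance_related": (0.13, 0.12),
    "trauma_stressor": (0.07, 0.06),
}

# Documentation-fidelity multipliers applied on top of the demographic
# stratum fidelity for encounters carrying these diagnostic categories:
# structured SITB documentation is systematically weaker for
# neurodevelopmental, psychotic and externalizing presentations.
DEFAULT_DX_FIDELITY_MULTIPLIERS = {
    "intellectual_disability": 0.60,
    "autism_spectrum": 0.75,
    "developmental": 0.70,
    "psychotic": 0.75,
    "disruptive_impulse_conduct": 0.80,
    "adhd": 0.90,
}


@dataclass(frozen=True)
class StratumSpec:
    """One demographic stratum of the cohort.

    ``structured_fidelity`` is the probability that a true-SITB encounter in
    this stratum receives each structured SITB indicator (ICD flag,
    SITB chief concern, positive c-SSRS screen), modelling
    subgroup-dependent documentation quality.  ``text_fidelity`` is the
    probability that the clinical narrative of a true-SITB encounter
    contains at least one affirmed, present-tense, patient-referent SITB
    sentence.
    """

    stratum_id: str
    proportion: float
    structured_fidelity: float
    text_fidelity: float


def default_subgroup_spec() -> list[StratumSpec]:
    """Sex-by-age strata matching a 51.3% female / 26.4% child cohort.

    Structured-documentation fidelity declines for male and younger
    strata (lowest for male children) while text fidelity is uniformly
    high — the mechanism behind subgroup detection gaps of
    code/chief-concern-based surveillance.
    """
    female, child = 0.513, 0.264
    return [
        StratumSpec("female_adolescent", female * (1 - child), 0.90, 0.95),
        StratumSpec("male_adolescent", (1 - female) * (1 - child), 0.78, 0.95),
        StratumSpec("female_child", female * child, 0.80, 0.95),
        StratumSpec("male_child", (1 - female) * child, 0.48, 0.95),
    ]


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort; every rate is overridable."""

    n_encounters: int = 1000
    sitb_prevalence: float = 0.46
    subgroup_spec: list[StratumSpec] = field(default_factory=default_subgroup_spec)
    notes_per_encounter: tuple[int, int] = (2, 5)
    sentences_per_note: tuple[int, int] = (3, 8)
    distractor_rate: float = 0.35
    cssrs_administer_prob: float = 0.70
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"svi": 0.05, "adi": 0.05, "insurance": 0.30}
    )
    dx_fidelity_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DX_FIDELITY_MULTIPLIERS)
    )
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_encounters, (int, np.integer)) and self.n_encounters > 0):
            raise ConfigurationError("n_encounters must be a positive integer")
        for name in ("sitb_prevalence", "distractor_rate", "cssrs_administer_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not self.subgroup_spec:
            raise ConfigurationError("subgroup_spec must be nonempty")
        total = sum(s.proportion for s in self.subgroup_spec)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"subgroup_spec proportions must sum to 1 (got {total!r})"
            )
        for s in self.subgroup_spec:
            for name in ("proportion", "structured_fidelity", "text_fidelity"):
                v = getattr(s, name)
                if not (0.0 <= v <= 1.0):
                    raise ConfigurationError(
                        f"stratum {s.stratum_id!r}: {name} must be in [0, 1], got {v}"
                    )
        for name in ("notes_per_encounter", "sentences_per_note"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty or invalid")
        for k, v in self.missing_rates.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"missing_rates[{k!r}] must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "subgroup_spec" in d:
            d["subgroup_spec"] = [
                s if isinstance(s, StratumSpec) else StratumSpec(**s)
                for s in d["subgroup_spec"]
            ]
        for key in ("notes_per_encounter", "sentences_per_note"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Sentence:
    text: str
    sitb_related: bool = False
    affirmed: bool = False
    present_tense: bool = False
    patient_referent: bool = False
    human_label: float | None = None

    @property
    def truth_tags(self) -> dict[str, bool]:
        return {
            "sitb_related": self.sitb_related,
            "affirmed": self.affirmed,
            "present_tense": self.present_tense,
            "patient_referent": self.patient_referent,
        }

    @property
    def fully_affirmed(self) -> bool:
        """True SITB evidence: all four annotation axes positive."""
        return (
            self.sitb_related
            and self.affirmed
            and self.present_tense
            and self.patient_referent
        )


@dataclass
class Note:
    note_id: str
    encounter_id: str
    author_type: str
    sentences: list[Sentence]

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)


@dataclass
class Encounter:
    encounter_id: str
    stratum: str
    age_years: int
    age_group: str  # child (6-12) | adolescent (13-17)
    sex: str
    race_ethnicity: str
    insurance: str | None
    dx_flags: dict[str, int]
    sitb_icd_flag: int
    sitb_chief_concern_flag: int
    mh_chief_concern_flag: int
    cssrs_items: list[str]  # each in {"positive", "negative", "missing"}
    psychotropic_med_flag: int
    homicidal_ideation_flag: int
    overdose_lab_flag: int
    urine_drug_positive_flag: int
    disposition: str
    prior_counts: dict[str, int]
    svi: float | None
    adi: float | None
    label: int


# --------------------------------------------------------------------------
# sentence template pools

SITB_TERMS = (
    "suicidal ideation",
    "thoughts of suicide",
    "a suicide attempt",
    "self-harm",
    "cutting behavior",
    "an intentional overdose",
    "a wish to be dead",
    "nonsuicidal self-injury",
)

_AFFIRMED_TEMPLATES = (
    "Patient endorses {term} today.",
    "Patient reports {term} with a plan.",
    "The patient is experiencing {term} at this visit.",
    "Patient admits to {term} this evening.",
)
_NEGATED_TEMPLATES = (
    "Patient denies {term}.",
    "Patient denies {term} at this time.",
    "No evidence of {term} on evaluation.",
)
_HISTORICAL_TEMPLATES = (
    "History of {term} last year.",
    "Patient reported {term} in the past.",
    "Prior episode of {term} two years ago.",
)
_OTHER_SUBJECT_TEMPLATES = (
    "Mother states that a classmate endorsed {term}.",
    "Family reports a sibling struggled with {term}.",
    "Father mentions a friend of the patient described {term}.",
)
_FILLER_TEMPLATES = (
    "Vital signs reviewed and within normal limits.",
    "Patient resting comfortably in room.",
    "Labs pending at this time.",
    "Nursing assessment completed without incident.",
    "Plan discussed with attending physician.",
    "Guardian remains at bedside.",
    "Patient tolerated dinner well.",
    "Follow up with primary care in one week.",
    "Patient presents with headache and mild nausea.",
    "Medication reconciliation completed on arrival.",
    "Social work consulted for disposition planning.",
    "Patient is cooperative with the examination.",
    "Sleep has been irregular over recent weeks.",
    "School attendance discussed with the family.",
    "Discharge paperwork reviewed with guardian.",
)


def _make_sentence(kind: str, rng: np.random.Generator) -> Sentence:
    term = SITB_TERMS[rng.integers(len(SITB_TERMS))]
    if kind == "affirmed":
        tpl = _AFFIRMED_TEMPLATES[rng.integers(len(_AFFIRMED_TEMPLATES))]
        s = Sentence(tpl.format(term=term), True, True, True, True)
    elif kind == "negated":
        tpl = _NEGATED_TEMPLATES[rng.integers(len(_NEGATED_TEMPLATES))]
        s = Sentence(tpl.format(term=term), True, False, True, True)
    elif kind == "historical":
        tpl = _HISTORICAL_TEMPLATES[rng.integers(len(_HISTORICAL_TEMPLATES))]
        s = Sentence(tpl.format(term=term), True, True, False, True)
    elif kind == "other_subject":
        tpl = _OTHER_SUBJECT_TEMPLATES[rng.integers(len(_OTHER_SUBJECT_TEMPLATES))]
        s = Sentence(tpl.format(term=term), True, True, True, False)
    elif kind == "filler":
        tpl = _FILLER_TEMPLATES[rng.integers(len(_FILLER_TEMPLATES))]
        s = Sentence(tpl)
    else:  # pragma: no cover - internal
        raise ValueError(kind)
    s.human_label = 1.0 if s.fully_affirmed else 0.0
    return s


_DISTRACTOR_KINDS = ("negated", "historical", "other_subject")


def generate_notes(
    truth: int,
    text_fidelity: float,
    config: CohortConfig,
    rng: np.random.Generator,
    encounter_id: str = "enc",
) -> list[Note]:
    """Generate the clinical narrative for one encounter.

    A true-SITB encounter receives, with probability ``text_fidelity``, at
    least one sentence affirming current patient SITB.  Any encounter may
    receive distractor sentences — SITB-lexicon phrases with a negation,
    historical, or other-subject modifier — at ``config.distractor_rate``,
    so negative encounters are lexically contaminated but never fully
    affirmed.
    """
    if not (_AFFIRMED_TEMPLATES and _FILLER_TEMPLATES):  # pragma: no cover
        raise ConfigurationError("sentence template pools must be nonempty")
    lo, hi = config.notes_per_encounter
    n_notes = int(rng.integers(lo, hi + 1))
    slo, shi = config.sentences_per_note
    notes: list[Note] = []
    for j in range(n_notes):
        n_sent = int(rng.integers(slo, shi + 1))
        sentences = [_make_sentence("filler", rng) for _ in range(n_sent)]
        author = AUTHOR_TYPES[rng.integers(len(AUTHOR_TYPES))]
        notes.append(Note(f"{encounter_id}-n{j}", encounter_id, author, sentences))

    def _inject(sentence: Sentence) -> None:
        note = notes[rng.integers(len(notes))]
        pos = int(rng.integers(len(note.sentences) + 1))
        note.sentences.insert(pos, sentence)

    if truth and rng.random() < text_fidelity:
        for _ in range(1 + rng.binomial(2, 0.5)):
            _inject(_make_sentence("affirmed", rng))
    if rng.random() < config.distractor_rate:
        for _ in range(1 + rng.binomial(2, 0.5)):
            kind = _DISTRACTOR_KINDS[rng.integers(len(_DISTRACTOR_KINDS))]
            _inject(_make_sentence(kind, rng))
    return notes


def sample_cssrs(
    truth: int,
    fidelity: float,
    administer_prob: float,
    rng: np.random.Generator,
    n_items: int = CSSRS_N_ITEMS,
) -> list[str]:
    """Sample a gatekept screening-item vector.

    The screen is administered with probability ``administer_prob``; if not
    administered every item is missing.  Administered items are asked
    sequentially and administration stops at the first non-positive
    response: the stopping (negative) item is observed, everything after
    it is missing.  For a true-SITB encounter the first item is positive
    with probability ``fidelity`` (documentation fidelity), and deeper
    items remain positive with a fixed continuation probability.
    """
    for name, p in (("fidelity", fidelity), ("administer_prob", administer_prob)):
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
    items = ["missing"] * n_items
    if rng.random() >= administer_prob:
        return items
    p_first = fidelity if truth else 0.08
    p_continue = 0.75 if truth else 0.30
    for i in range(n_items):
        p = p_first if i == 0 else p_continue
        if rng.random() < p:
            items[i] = "positive"
        else:
            items[i] = "negative"
            break  # gate closes: later items never administered
    return items


# --------------------------------------------------------------------------
# structured-field sampling

def _sample_structured(
    truth: int,
    f: float,
    dx_flags: dict[str, int],
    config: CohortConfig,
    rng: np.random.Generator,
) -> dict:
    """Sample structured clinical fields given truth and effective fidelity f."""
    out: dict = {}
    out["sitb_icd_flag"] = int(rng.random() < (f if truth else 0.05))
    out["sitb_chief_concern_flag"] = int(rng.random() < (0.45 * f if truth else 0.03))
    out["mh_chief_concern_flag"] = int(rng.random() < (0.72 if truth else 0.48))
    out["cssrs_items"] = sample_cssrs(truth, f, config.cssrs_administer_prob, rng)
    out["psychotropic_med_flag"] = int(rng.random() < (0.25 if truth else 0.12))
    out["homicidal_ideation_flag"] = int(rng.random() < (0.08 if truth else 0.05))
    out["overdose_lab_flag"] = int(rng.random() < (0.12 if truth else 0.03))
    out["urine_drug_positive_flag"] = int(rng.random() < (0.15 if truth else 0.12))
    dispo_p = (0.45, 0.42, 0.08, 0.05) if truth else (0.72, 0.15, 0.11, 0.02)
    out["disposition"] = DISPOSITION_CATEGORIES[
        rng.choice(len(DISPOSITION_CATEGORIES), p=dispo_p)
    ]
    lam = {
        "prior_ed_visits": (0.9, 0.5),
        "prior_psych_hosp": (0.45, 0.12),
        "prior_medical_hosp": (0.15, 0.12),
    }
    counts: dict[str, int] = {}
    for base, (lp, ln) in lam.items():
        annual = float(lp if truth else ln)
        for window, frac in (("30d", 30 / 365), ("90d", 90 / 365), ("365d", 1.0)):
            counts[f"{base}_{window}"] = int(rng.poisson(annual * frac))
    out["prior_counts"] = counts
    # neighborhood indices: weak positive shift in vulnerability for cases
    svi = float(np.clip(rng.beta(2.0, 3.0) + (0.04 if truth else 0.0), 0.0, 1.0))
    adi = float(np.clip(rng.integers(1, 101) + (3 if truth else 0), 1, 100))
    out["svi"] = None if rng.random() < config.missing_rates.get("svi", 0.0) else round(svi, 3)
    out["adi"] = None if rng.random() < config.missing_rates.get("adi", 0.0) else adi
    if rng.random() < config.missing_rates.get("insurance", 0.0):
        out["insurance"] = None
    else:
        out["insurance"] = INSURANCE_CATEGORIES[rng.choice(3, p=(0.45, 0.45, 0.10))]
    return out


_RACE_P = (0.495, 0.266, 0.095, 0.046, 0.098)


def generate_cohort(config: CohortConfig) -> tuple[list[Encounter], list[Note]]:
    """Generate a full synthetic cohort (encounters + notes).

    Deterministic for a fixed (config, seed).  Labels are drawn at the
    configured prevalence; each encounter is assigned a demographic stratum
    whose fidelities govern structured documentation and narrative content.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    strata = config.subgroup_spec
    props = np.array([s.proportion for s in strata], dtype=float)
    props = props / props.sum()

    encounters: list[Encounter] = []
    notes: list[Note] = []
    for i in range(config.n_encounters):
        eid = f"E{i:06d}"
        stratum = strata[int(rng.choice(len(strata), p=props))]
        label = int(rng.random() < config.sitb_prevalence)
        sid = stratum.stratum_id
        sex = "female" if "female" in sid else ("male" if "male" in sid else
                                                ("female" if rng.random() < 0.5 else "male"))
        is_child = "child" in sid if ("child" in sid or "adolescent" in sid) else (
            rng.random() < 0.264
        )
        if is_child:
            age = int(rng.integers(6, 13))
            age_group = "child"
        else:
            age = int(rng.choice([13, 14, 15, 16, 17], p=(0.12, 0.20, 0.26, 0.24, 0.18)))
            age_group = "adolescent"
        race = RACE_CATEGORIES[int(rng.choice(len(RACE_CATEGORIES), p=_RACE_P))]

        dx_flags = {
            cat: int(rng.random() < (_DX_RATES[cat][0] if label else _DX_RATES[cat][1]))
            for cat in DX_CATEGORIES
            if cat != "suicide_self_injury"
        }
        # effective structured fidelity: stratum fidelity scaled down by the
        # strongest active diagnostic documentation penalty
        mult = min(
            [config.dx_fidelity_multipliers.get(c, 1.0) for c, v in dx_flags.items() if v]
            or [1.0]
        )
        f_eff = stratum.structured_fidelity * mult
        s = _sample_structured(label, f_eff, dx_flags, config, rng)
        # the suicide/self-injury diagnostic category is the ICD-coded flag
        dx_flags["suicide_self_injury"] = s["sitb_icd_flag"]

        enc = Encounter(
            encounter_id=eid,
            stratum=sid,
            age_years=age,
            age_group=age_group,
            sex=sex,
            race_ethnicity=race,
            insurance=s["insurance"],
            dx_flags=dx_flags,
            sitb_icd_flag=s["sitb_icd_flag"],
            sitb_chief_concern_flag=s["sitb_chief_concern_flag"],
            mh_chief_concern_flag=s["mh_chief_concern_flag"],
            cssrs_items=s["cssrs_items"],
            psychotropic_med_flag=s["psychotropic_med_flag"],
            homicidal_ideation_flag=s["homicidal_ideation_flag"],
            overdose_lab_flag=s["overdose_lab_flag"],
            urine_drug_positive_flag=s["urine_drug_positive_flag"],
            disposition=s["disposition"],
            prior_counts=s["prior_counts"],
            svi=s["svi"],
            adi=s["adi"],
            label=label,
        )
        encounters.append(enc)
        notes.extend(generate_notes(label, stratum.text_fidelity, config, rng, eid))
    return encounters, notes


# --------------------------------------------------------------------------
# tabular serialization

_PRIOR_KEYS = tuple(
    f"{base}_{w}"
    for base in ("prior_ed_visits", "prior_psych_hosp", "prior_medical_hosp")
    for w in ("30d", "90d", "365d")
)


def cohort_to_frame(encounters: Sequence[Encounter]) -> pd.DataFrame:
    """Flatten encounters to one row each; missing values become NaN."""
    rows = []
    for e in encounters:
        row: dict = {
            "encounter_id": e.encounter_id,
            "stratum": e.stratum,
            "age_years": e.age_years,
            "age_group": e.age_group,
            "sex": e.sex,
            "race_ethnicity": e.race_ethnicity,
            "insurance": e.insurance,
        }
        for cat in DX_CATEGORIES:
            row[f"dx_{cat}"] = e.dx_flags[cat]
        row.update(
            sitb_icd_flag=e.sitb_icd_flag,
            sitb_chief_concern_flag=e.sitb_chief_concern_flag,
            mh_chief_concern_flag=e.mh_chief_concern_flag,
        )
        for i, item in enumerate(e.cssrs_items, start=1):
            row[f"cssrs_item{i}"] = None if item == "missing" else item
        row.update(
            psychotropic_med_flag=e.psychotropic_med_flag,
            homicidal_ideation_flag=e.homicidal_ideation_flag,
            overdose_lab_flag=e.overdose_lab_flag,
            urine_drug_positive_flag=e.urine_drug_positive_flag,
            disposition=e.disposition,
        )
        for k in _PRIOR_KEYS:
            row[k] = e.prior_counts[k]
        row.update(svi=e.svi, adi=e.adi, label=e.label)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_encounters(df: pd.DataFrame) -> list[Encounter]:
    """Inverse of :func:`cohort_to_frame` (empty cells become missing)."""
    encounters = []
    for _, r in df.iterrows():
        cssrs = []
        for i in range(1, CSSRS_N_ITEMS + 1):
            v = r[f"cssrs_item{i}"]
            cssrs.append("missing" if pd.isna(v) else str(v))
        encounters.append(
            Encounter(
                encounter_id=str(r["encounter_id"]),
                stratum=str(r["stratum"]),
                age_years=int(r["age_years"]),
                age_group=str(r["age_group"]),
                sex=str(r["sex"]),
                race_ethnicity=str(r["race_ethnicity"]),
                insurance=None if pd.isna(r["insurance"]) else str(r["insurance"]),
                dx_flags={c: int(r[f"dx_{c}"]) for c in DX_CATEGORIES},
                sitb_icd_flag=int(r["sitb_icd_flag"]),
                sitb_chief_concern_flag=int(r["sitb_chief_concern_flag"]),
                mh_chief_concern_flag=int(r["mh_chief_concern_flag"]),
                cssrs_items=cssrs,
                psychotropic_med_flag=int(r["psychotropic_med_flag"]),
                homicidal_ideation_flag=int(r["homicidal_ideation_flag"]),
                overdose_lab_flag=int(r["overdose_lab_flag"]),
                urine_drug_positive_flag=int(r["urine_drug_positive_flag"]),
                disposition=str(r["disposition"]),
                prior_counts={k: int(r[k]) for k in _PRIOR_KEYS},
                svi=None if pd.isna(r["svi"]) else float(r["svi"]),
                adi=None if pd.isna(r["adi"]) else float(r["adi"]),
                label=int(r["label"]),
            )
        )
    return encounters


def write_encounters_csv(encounters: Sequence[Encounter], path: str | Path) -> None:
    cohort_to_frame(encounters).to_csv(path, index=False)


def read_encounters_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"encounter_id": str})


def write_notes_jsonl(notes: Sequence[Note], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in notes:
            obj = {
                "note_id": n.note_id,
                "encounter_id": n.encounter_id,
                "author_type": n.author_type,
                "text": n.text,
                "sentences": [
                    {
                        "text": s.text,
                        "truth_tags": s.truth_tags,
                        "human_label": s.human_label,
                    }
                    for s in n.sentences
                ],
            }
            fh.write(json.dumps(obj) + "\n")


def read_notes_jsonl(path: str | Path) -> list[Note]:
    notes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            sentences = [
                Sentence(
                    text=s["text"],
                    human_label=s.get("human_label"),
                    **s.get("truth_tags", {}),
                )
                for s in obj.get("sentences", [])
            ]
            notes.append(
                Note(obj["note_id"], obj["encounter_id"], obj["author_type"], sentences)
            )
    return notes
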
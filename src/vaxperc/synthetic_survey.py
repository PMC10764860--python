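"""Seeded synthetic vaccine-perception surveys.

The generator emulates the statistical structure the downstream analysis
assumes: four latent subpopulations (U unwilling, H hesitant, W willing,
V vaccinated) with distinct closed-answer profiles over categorical and
1-10 scale questions, and open-text answers seeded with the transition-driver
word co-locations (hub word + associated noun/verb in one sentence) plus
noise sentences drawn from an unrelated vocabulary.

One global seed fans out to independent per-stage substreams
(labels, closed answers, open answers) via ``numpy.random.SeedSequence`` so
each stage is reproducible in isolation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import resources

__all__ = [
    "AnswerDistribution",
    "KeywordTemplate",
    "SubpopProfile",
    "QuestionSpec",
    "SurveyDataset",
    "generate_closed_responses",
    "generate_open_responses",
    "generate_survey_dataset",
    "profiles_from_config",
    "schema_from_config",
]

SCALE_VALUES = tuple(range(1, 11))


class ValidationError(ValueError):
    """Raised when a generator input violates its contract."""


@dataclass(frozen=True)
class QuestionSpec:
    """One survey question: categorical options, a 1-10 scale, or open text."""

    kind: str                       # "categorical" | "scale" | "open"
    options: Optional[Tuple[str, ...]] = None
    text: str = ""

    def __post_init__(self):
        if self.kind not in ("categorical", "scale", "open"):
            raise ValidationError(f"unknown question kind {self.kind!r}")
        if self.kind == "categorical" and not self.options:
            raise ValidationError("categorical question needs options")


@dataclass(frozen=True)
class AnswerDistribution:
    """Discrete answer distribution over a question's legal codes."""

    support: Tuple[object, ...]
    probs: Tuple[float, ...]

    def __post_init__(self):
        if len(self.support) != len(self.probs):
            raise ValidationError("support/probs length mismatch")
        if any(p < 0 for p in self.probs):
            raise ValidationError("negative probability")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValidationError(f"probabilities sum to {sum(self.probs)}, not 1")

    @classmethod
    def categorical(cls, options: Sequence[str], mode: str, p_mode: float) -> "AnswerDistribution":
        options = list(options)
        if mode not in options:
            raise ValidationError(f"mode {mode!r} not among options {options}")
        if not 0 < p_mode <= 1:
            raise ValidationError("p_mode must be in (0, 1]")
        rest = (1.0 - p_mode) / (len(options) - 1) if len(options) > 1 else 0.0
        probs = [p_mode if o == mode else rest for o in options]
        return cls(tuple(options), tuple(probs))

    @classmethod
    def scale(cls, mode: int, conc: float = 0.15) -> "AnswerDistribution":
        """Peaked distribution on 1..10: P(x) proportional to conc**|x-mode|."""
        if mode not in SCALE_VALUES:
            raise ValidationError("scale mode must be in 1..10")
        if not 0 < conc < 1:
            raise ValidationError("conc must be in (0, 1)")
        w = np.array([conc ** abs(x - mode) for x in SCALE_VALUES])
        w /= w.sum()
        return cls(SCALE_VALUES, tuple(w))


@dataclass(frozen=True)
class KeywordTemplate:
    """A planted word co-location: hub + associate emitted in one sentence."""

    hub: str
    associate: str
    pos: str                 # coarse class of the associate: "noun" | "verb"
    tag: str                 # transition this co-location evidences, e.g. "U->H induced"


@dataclass
class SubpopProfile:
    """Latent subpopulation: answer distributions plus open-text templates."""

    label: str
    proportion: float
    closed_answer_distributions: Dict[str, AnswerDistribution]
    keyword_templates: List[KeywordTemplate] = field(default_factory=list)
    emission_rate: float = 0.0
    open_question: Optional[str] = None

    def __post_init__(self):
        if not 0 <= self.proportion <= 1:
            raise ValidationError(f"proportion {self.proportion} outside [0,1]")
        if self.emission_rate < 0:
            raise ValidationError("emission_rate must be >= 0")


def _validate_profiles(profiles: Sequence[SubpopProfile]) -> None:
    if not profiles:
        raise ValidationError("empty profile list")
    total = sum(p.proportion for p in profiles)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"profile proportions sum to {total}, not 1")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate profile labels")


@dataclass
class SurveyDataset:
    """Ordered respondent records with closed codes and open free text."""

    table: pd.DataFrame
    question_schema: Dict[str, QuestionSpec]
    seed: Optional[int] = None

    def __post_init__(self):
        if "respondent_id" not in self.table.columns:
            raise ValidationError("table must have a respondent_id column")
        for qid, spec in self.question_schema.items():
            if qid not in self.table.columns:
                raise ValidationError(f"schema question {qid} missing from table")
            if spec.kind == "categorical":
                bad = set(self.table[qid].astype(str)) - set(spec.options)
                if bad:
                    raise ValidationError(f"illegal codes {bad} for {qid}")
            elif spec.kind == "scale":
                vals = pd.to_numeric(self.table[qid])
                if not vals.isin(SCALE_VALUES).all():
                    raise ValidationError(f"scale answers for {qid} outside 1..10")

    @property
    def respondent_ids(self) -> List[str]:
        return list(self.table["respondent_id"])

    @property
    def planted_labels(self) -> Optional[List[str]]:
        if "planted_label" in self.table.columns:
            return list(self.table["planted_label"])
        return None

    def closed_questions(self) -> List[str]:
        return [q for q, s in self.question_schema.items() if s.kind != "open"]

    def open_questions(self) -> List[str]:
        return [q for q, s in self.question_schema.items() if s.kind == "open"]

    def open_answers(self, question: str) -> Dict[str, str]:
        return dict(zip(self.table["respondent_id"], self.table[question].fillna("")))

    # -- CSV interface -----------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        self.table.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, question_schema: Dict[str, QuestionSpec],
                 seed: Optional[int] = None) -> "SurveyDataset":
        df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
        for qid, spec in question_schema.items():
            if spec.kind == "scale" and qid in df.columns:
                df[qid] = df[qid].astype(int)
        return cls(df, question_schema, seed=seed)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        a = self.table.astype(str).fillna("")
        b = other.table.astype(str).fillna("")
        return a.equals(b) and self.question_schema == other.question_schema


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_closed_responses(
    n: int,
    profiles: Sequence[SubpopProfile],
    seed: int,
) -> Tuple[pd.DataFrame, List[str]]:
    """Draw planted labels and closed answers for ``n`` respondents.

    Labels follow the profile proportions; answers are drawn independently
    per question from the labelled profile's distribution. Identical inputs
    and seed give identical output.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    _validate_profiles(profiles)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    label_rng, answer_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    props = np.array([p.proportion for p in profiles])
    idx = label_rng.choice(len(profiles), size=n, p=props)
    labels = [profiles[i].label for i in idx]

    by_label = {p.label: p for p in profiles}
    questions = list(profiles[0].closed_answer_distributions)
    for p in profiles:
        if list(p.closed_answer_distributions) != questions:
            raise ValidationError("profiles disagree on closed-question set")

    rows: Dict[str, list] = {q: [] for q in questions}
    for lab in labels:
        prof = by_label[lab]
        for q in questions:
            dist = prof.closed_answer_distributions[q]
            j = answer_rng.choice(len(dist.support), p=np.array(dist.probs))
            rows[q].append(dist.support[j])
    df = pd.DataFrame(rows)
    df.insert(0, "respondent_id", [f"R{i:05d}" for i in range(n)])
    return df, labels


_SENTENCE_PATTERNS = (
    ("my", "{a}", "{h}"),
    ("{a}", "{h}", "for", "me"),
    ("the", "{a}", "will", "{h}"),
    ("if", "{a}", "then", "{h}"),
)

# canonical compound -> spaced surface form, to exercise normalization
_SPACED_FORMS = {
    "FamilyMembers": "family members",
    "SideEffects": "side effects",
    "NewStrain": "new strain",
    "HerdImmunity": "herd immunity",
}


def _render(template: KeywordTemplate, rng: np.random.Generator,
            spaced_prob: float) -> str:
    pattern = _SENTENCE_PATTERNS[rng.integers(len(_SENTENCE_PATTERNS))]
    hub, assoc = template.hub, template.associate
    if spaced_prob > 0:
        if hub in _SPACED_FORMS and rng.random() < spaced_prob:
            hub = _SPACED_FORMS[hub]
        if assoc in _SPACED_FORMS and rng.random() < spaced_prob:
            assoc = _SPACED_FORMS[assoc]
    words = [w.format(a=assoc, h=hub) for w in pattern]
    return " ".join(words) + "."


def generate_open_responses(
    labels: Sequence[str],
    profiles: Sequence[SubpopProfile],
    noise_vocab: Sequence[str] = (),
    noise_rate: float = 0.0,
    seed: int = 0,
    open_questions: Sequence[str] = (),
    noise_sentence_words: Tuple[int, int] = (2, 4),
    spaced_prob: float = 0.0,
) -> pd.DataFrame:
    """Generate open-text answers for each respondent and open question.

    Templated sentences always contain their hub and associate in one
    sentence; noise sentences contain only ``noise_vocab`` words. Both go to
    the profile's own open question — as in the source survey, respondents
    only answer the open question aimed at their compartment. A profile
    with ``emission_rate`` >= 1 emits at least one templated sentence
    (count = 1 + Poisson(rate - 1), which preserves the expectation).
    """
    if noise_rate < 0:
        raise ValidationError("noise_rate must be >= 0")
    by_label = {p.label: p for p in profiles}
    missing = set(labels) - set(by_label)
    if missing:
        raise ValidationError(f"labels without profiles: {sorted(missing)}")
    if not open_questions:
        open_questions = sorted({p.open_question for p in profiles
                                 if p.open_question})
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1,)))

    columns: Dict[str, List[str]] = {q: [] for q in open_questions}
    for lab in labels:
        prof = by_label[lab]
        answers = {q: [] for q in open_questions}
        if prof.keyword_templates and prof.emission_rate > 0 and prof.open_question:
            rate = prof.emission_rate
            count = (1 + rng.poisson(rate - 1)) if rate >= 1 else rng.poisson(rate)
            for _ in range(count):
                t = prof.keyword_templates[rng.integers(len(prof.keyword_templates))]
                answers[prof.open_question].append(_render(t, rng, spaced_prob))
        if noise_rate > 0 and noise_vocab and prof.open_question:
            q = prof.open_question
            for _ in range(rng.poisson(noise_rate)):
                nw = rng.integers(noise_sentence_words[0],
                                  noise_sentence_words[1] + 1)
                words = rng.choice(noise_vocab, size=nw, replace=True)
                answers[q].append(" ".join(words) + ".")
        for q in open_questions:
            columns[q].append(" ".join(answers[q]))
    return pd.DataFrame(columns)


def schema_from_config(config: dict) -> Dict[str, QuestionSpec]:
    schema = {}
    for qid, spec in config["schema"].items():
        kind = spec["kind"]
        options = tuple(str(o) for o in spec.get("options", ())) or None
        schema[qid] = QuestionSpec(kind=kind, options=options,
                                   text=spec.get("text", ""))
    return schema


def profiles_from_config(config: dict) -> List[SubpopProfile]:
    schema = schema_from_config(config)
    profiles = []
    for pc in config["profiles"]:
        dists = {}
        for qid, dspec in pc["closed"].items():
            qspec = schema[qid]
            if qspec.kind == "categorical":
                dists[qid] = AnswerDistribution.categorical(
                    qspec.options, str(dspec["mode"]),
                    float(dspec.get("p_mode", 1.0)))
            elif qspec.kind == "scale":
                dists[qid] = AnswerDistribution.scale(
                    int(dspec["mode"]), float(dspec.get("conc", 0.15)))
            else:
                raise ValidationError(f"{qid} is open-ended, not closed")
        templates = [KeywordTemplate(t["hub"], t["associate"], t["pos"], t["tag"])
                     for t in pc.get("templates", ())]
        profiles.append(SubpopProfile(
            label=pc["label"],
            proportion=float(pc["proportion"]),
            closed_answer_distributions=dists,
            keyword_templates=templates,
            emission_rate=float(pc.get("emission_rate", 0.0)),
            open_question=pc.get("open_question"),
        ))
    _validate_profiles(profiles)
    return profiles


def generate_survey_dataset(config: Optional[dict] = None,
                            **overrides) -> SurveyDataset:
    """Compose the closed- and open-answer generators into a full dataset.

    ``config`` defaults to the shipped survey configuration; ``overrides``
    patch top-level keys (``n``, ``seed``, ...).
    """
    if config is None:
        config = resources.default_survey_config()
    config = {**config, **overrides}
    n = int(config["n"])
    seed = int(config["seed"])
    schema = schema_from_config(config)
    profiles = profiles_from_config(config)
    open_qs = [q for q, s in schema.items() if s.kind == "open"]
    for p in profiles:
        if p.open_question is not None and p.open_question not in open_qs:
            raise ValidationError(
                f"profile {p.label} targets unknown question {p.open_question}")

    closed, labels = generate_closed_responses(n, profiles, seed)
    noise = config.get("noise", {}) or {}
    open_df = generate_open_responses(
        labels, profiles,
        noise_vocab=tuple(noise.get("vocab", ())),
        noise_rate=float(noise.get("rate", 0.0)),
        seed=seed,
        open_questions=open_qs,
        noise_sentence_words=(int(noise.get("min_words", 2)),
                              int(noise.get("max_words", 4))),
        spaced_prob=float(config.get("spaced_prob", 0.0)),
    )
    table = pd.concat([closed, open_df], axis=1)
    table["planted_label"] = labels
    return SurveyDataset(table, schema, seed=seed)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
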
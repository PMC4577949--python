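"""Symptom cue lexicon and negation/experiencer rule set.

The lexicon maps each of the ten negative-symptom labels to cue phrases
(case-insensitive token sequences). The rule set implements NegEx-style
pre-cue negation scoping plus sentence-wide experiencer (family-attribution)
detection. Neither inventory is canonical — the defaults below are a
documented design choice, editable via YAML files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .corpus import SYMPTOMS

DEFAULT_CUES: dict[str, list[str]] = {
    "poor_motivation": ["poor motivation", "poorly motivated", "lack of motivation", "amotivation"],
    "blunted_affect": ["blunted affect", "flattened affect", "flat affect", "affective blunting"],
    "poor_eye_contact": ["poor eye contact", "reduced eye contact", "avoids eye contact"],
    "emotional_withdrawal": ["emotional withdrawal", "emotionally withdrawn"],
    "poor_rapport": ["poor rapport", "limited rapport", "difficult to establish rapport"],
    "social_withdrawal": ["social withdrawal", "socially withdrawn"],
    "poverty_of_speech": ["poverty of speech", "paucity of speech"],
    "mute": ["mute", "mutism", "electively mute"],
    "apathy": ["apathy", "apathetic"],
    "concrete_thinking": ["concrete thinking", "concrete thought", "thinking is concrete"],
}

DEFAULT_NEGATION_CUES = [
    "no", "not", "denies", "denied", "without", "nil", "never", "absence",
]

DEFAULT_EXPERIENCER_CUES = [
    "mother", "father", "brother", "sister", "family", "wife", "husband",
    "son", "daughter", "parents", "grandmother", "grandfather",
]


class LexiconError(ValueError):
    """Invalid lexicon or rule configuration."""


@dataclass(frozen=True)
class Lexicon:
    """Cue phrases per symptom; each cue is a non-empty token sequence."""

    cues: dict[str, tuple[tuple[str, ...], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for symptom in SYMPTOMS:
            entries = self.cues.get(symptom)
            if not entries:
                raise LexiconError(f"symptom {symptom!r} has no cue phrases")
            for cue in entries:
                if not cue or any(not tok for tok in cue):
                    raise LexiconError(f"symptom {symptom!r}: empty cue token")
        unknown = set(self.cues) - set(SYMPTOMS)
        if unknown:
            raise LexiconError(f"unknown symptom labels {sorted(unknown)}")

    @classmethod
    def from_phrases(cls, phrases: dict[str, list[str]]) -> "Lexicon":
        return cls(
            cues={
                sym: tuple(tuple(p.lower().split()) for p in plist)
                for sym, plist in phrases.items()
            }
        )

    @classmethod
    def default(cls) -> "Lexicon":
        return cls.from_phrases(DEFAULT_CUES)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise LexiconError(f"{path}: expected a mapping symptom -> phrase list")
        return cls.from_phrases(data)

    def to_yaml(self, path: str | Path) -> None:
        data = {sym: [" ".join(c) for c in cues] for sym, cues in self.cues.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class RuleSet:
    """Negation and experiencer rules.

    A mention is forced not-positive when a negation cue occurs within
    ``scope_window`` tokens immediately preceding the cue in the same
    sentence, or when an experiencer cue occurs anywhere in the sentence.
    """

    negation_cues: tuple[str, ...] = tuple(DEFAULT_NEGATION_CUES)
    experiencer_cues: tuple[str, ...] = tuple(DEFAULT_EXPERIENCER_CUES)
    scope_window: int = 5

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise LexiconError("scope_window must be >= 1")
        if not self.negation_cues or not self.experiencer_cues:
            raise LexiconError("cue lists must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            negation_cues=tuple(t.lower() for t in data["negation_cues"]),
            experiencer_cues=tuple(t.lower() for t in data["experiencer_cues"]),
            scope_window=int(data.get("scope_window", 5)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "negation_cues": list(self.negation_cues),
                    "experiencer_cues": list(self.experiencer_cues),
                    "scope_window": self.scope_window,
                },
                fh,
                sort_keys=False,
            )
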
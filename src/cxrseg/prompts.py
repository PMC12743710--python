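"""Anatomical text-prompt construction and normalization.

Word-level prompts ("right lung", "left lobe") localize anatomy better
than sentence-level instructions, because short prompts concentrate a
grounded detector's attention on the anatomical tokens.  Two word-level
styles are supported:

* ``plain`` — terms joined with ". " ("right lung", "right lung. heart").
* ``dot_separated`` — every whitespace token followed by a dot separator,
  e.g. "right . lung ." — a framing that treats each word as its own
  phrase for the detector's text grounding.

Sentence-level prompts ("segment the right lobe") pass through verbatim
under the ``sentence`` style and are flagged in metadata so reports can
distinguish them.  Case transformation (lower/upper) is applied last, so
"RIGHT . LOBE ." style variants are one config switch away.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["PromptSpec", "build_prompt", "parse_dot_separated", "load_prompt_specs"]


@dataclass(frozen=True)
class PromptSpec:
    """One prompt to build: ordered anatomical terms plus framing style."""

    raw_terms: tuple[str, ...]
    style: Literal["plain", "dot_separated", "sentence"] = "plain"
    case_mode: Literal["as_given", "lower", "upper"] = "as_given"

    def __post_init__(self) -> None:
        if not self.raw_terms:
            raise ValueError("raw_terms must be nonempty")
        if any(not t.strip() for t in self.raw_terms):
            raise ValueError("each term must be nonempty after trimming")
        if self.style not in ("plain", "dot_separated", "sentence"):
            raise ValueError(f"unknown style {self.style!r}")
        if self.case_mode not in ("as_given", "lower", "upper"):
            raise ValueError(f"unknown case_mode {self.case_mode!r}")

    @property
    def is_sentence_level(self) -> bool:
        """Sentence-level prompts are pass-through and flagged for reports."""
        return self.style == "sentence"

    @property
    def slug(self) -> str:
        """Filesystem-safe identifier for artifact naming."""
        text = build_prompt(self)
        return "".join(c if c.isalnum() else "-" for c in text).strip("-").lower()


def build_prompt(spec: PromptSpec) -> str:
    """Render a PromptSpec to the prompt string handed to the detector."""
    terms = tuple(t.strip() for t in spec.raw_terms)
    if spec.style == "plain":
        text = ". ".join(terms)
    elif spec.style == "sentence":
        text = " ".join(terms)
    else:  # dot_separated: every token followed by " ."
        tokens = [tok for term in terms for tok in term.split()]
        text = " . ".join(tokens) + " ."
    if spec.case_mode == "lower":
        return text.lower()
    if spec.case_mode == "upper":
        return text.upper()
    return text


def parse_dot_separated(prompt: str) -> list[str]:
    """Recover the token sequence from a dot_separated prompt (round-trip)."""
    text = prompt.strip()
    if text.endswith("."):
        text = text[:-1]
    return [tok.strip() for tok in text.split(" . ") if tok.strip()]


def load_prompt_specs(path: str | Path) -> list[PromptSpec]:
    """Load a prompt set from a YAML list.

    Entries are either plain strings (style/case defaults) or mappings
    with ``terms`` (string or list), ``style`` and ``case_mode`` keys.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ValueError("prompt YAML must be a list")
    specs = []
    for entry in data:
        if isinstance(entry, str):
            specs.append(PromptSpec(raw_terms=(entry,)))
        elif isinstance(entry, dict):
            terms = entry["terms"]
            if isinstance(terms, str):
                terms = (terms,)
            specs.append(
                PromptSpec(
                    raw_terms=tuple(terms),
                    style=entry.get("style", "plain"),
                    case_mode=entry.get("case_mode", "as_given"),
                )
            )
        else:
            raise ValueError(f"bad prompt entry: {entry!r}")
    return specs
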
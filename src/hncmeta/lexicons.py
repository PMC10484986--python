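"""Term lists (lexicons) used by the rule-based classifiers.

A :class:`Lexicon` is a named list of ``(term, mode)`` entries.  Three match
modes exist:

``WHOLE_WORD``
    the term matches only between non-letter boundaries ("men" matches in
    "women and men" but not inside "treatment");
``PREFIX_STEM``
    the term matches any word that *begins* with it ("pregnan" matches
    "pregnant", "pregnancy");
``SUBSTRING``
    the term matches anywhere, after whitespace normalization.

The default lexicons ship as editable plain-text files under
``hncmeta/data`` (one ``term<TAB>mode`` line each, ``#`` comments allowed)
and are loaded lazily by the accessor functions below.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path


class MatchMode(str, Enum):
    WHOLE_WORD = "word"
    PREFIX_STEM = "stem"
    SUBSTRING = "substring"


@dataclass(frozen=True)
class Lexicon:
    """A named, ordered list of lower-case terms with per-term match modes."""

    name: str
    entries: tuple[tuple[str, MatchMode], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"lexicon {self.name!r} has no entries")
        seen: set[tuple[str, MatchMode]] = set()
        for term, mode in self.entries:
            if term != term.lower():
                raise ValueError(f"lexicon term {term!r} must be lower-case")
            if (term, mode) in seen:
                raise ValueError(f"duplicate lexicon entry {(term, mode)!r}")
            seen.add((term, mode))

    @property
    def terms(self) -> list[str]:
        return [term for term, _ in self.entries]


def parse_lexicon(name: str, text: str) -> Lexicon:
    """Parse ``term<TAB>mode`` lines into a Lexicon; blank/# lines skipped."""
    entries: list[tuple[str, MatchMode]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{name}:{lineno}: expected 'term<TAB>mode', got {raw!r}")
        term, mode = parts[0].strip().lower(), parts[1].strip().lower()
        entries.append((term, MatchMode(mode)))
    return Lexicon(name=name, entries=tuple(entries))


def load_lexicon(path: str | Path) -> Lexicon:
    path = Path(path)
    return parse_lexicon(path.stem, path.read_text(encoding="utf-8"))


def _builtin(name: str) -> Lexicon:
    text = resources.files("hncmeta.data").joinpath(f"{name}.txt").read_text("utf-8")
    return parse_lexicon(name, text)


def sg_lexicon() -> Lexicon:
    """Sex/gender terms: whole words plus the stems "pregnan" and "transg"."""
    return _builtin("sg_terms")


def hpv_lexicon() -> Lexicon:
    """Human-papillomavirus strings (MeSH-derived)."""
    return _builtin("hpv_terms")


def subsite_lexicon() -> Lexicon:
    """Condition strings that mark HPV-relevant subsites (group A)."""
    return _builtin("subsite_terms")


def neoplasm_lexicon() -> Lexicon:
    """Substring stems identifying neoplasm conditions."""
    return _builtin("neoplasm_terms")


def region_lexicon() -> Lexicon:
    """Substring stems identifying head-and-neck anatomical regions."""
    return _builtin("region_terms")
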
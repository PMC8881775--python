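"""Dictionary-based word-category counting for speech and writing content.

The content features follow the LIWC convention: a lexicon assigns words to
categories (first-person pronouns, positive emotion words, negations, ...),
and each category score is the percentage of a text's tokens matched by that
category's entries.  Entries are either exact words or wildcard stems written
with a trailing ``*`` (``blij*`` matches ``blij``, ``blije``, ``blijdschap``
but not ``bli``).  A token may count toward several categories at once, so
percentages are not constrained to sum to 100.

Matching is single-token only: negated phrases such as "niet blij" score one
negation and one positive-emotion word.  This mirrors the behaviour (and the
known limitation) of word-count tools in this literature and is deliberate.

The shipped demo lexicon (:func:`load_demo_lexicon`) is a small synthetic
Dutch-flavoured dictionary with the required category structure; it is not a
reimplementation of any proprietary dictionary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "WORD_CATEGORIES",
    "SPEECH_CONTENT_FEATURES",
    "WRITING_CONTENT_FEATURES",
    "Lexicon",
    "ContentFeatureVector",
    "load_lexicon",
    "load_demo_lexicon",
    "tokenize",
    "extract_content_features",
]

#: Dictionary-backed word categories (word count and exclamation marks are
#: computed from the token stream itself, not from lexicon entries).
WORD_CATEGORIES = (
    "i", "we", "you", "negate", "posemo", "negemo",
    "anx", "anger", "sad", "certain", "swear",
)

#: Feature columns of the speech-content family (12 variables).
SPEECH_CONTENT_FEATURES = ("wc",) + WORD_CATEGORIES

#: Feature columns of the writing-content family (13 variables; exclamation
#: marks are added for writing only).
WRITING_CONTENT_FEATURES = SPEECH_CONTENT_FEATURES + ("exclam",)

_TOKEN_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*", re.UNICODE)


class LexiconError(ValueError):
    """Raised for structurally invalid lexicons."""


@dataclass(frozen=True)
class Lexicon:
    """A validated category dictionary plus emoji partition.

    Parameters
    ----------
    categories
        Mapping of category name to entries.  Entry sets must cover exactly
        the categories in :data:`WORD_CATEGORIES`; entries are lowercase
        exact words or trailing-star stems.
    pos_emojis, neg_emojis
        Emoji (or emoticon) strings counted separately from word tokens.
    """

    categories: dict[str, frozenset[str]]
    pos_emojis: frozenset[str] = field(default_factory=frozenset)
    neg_emojis: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        names = set(self.categories)
        required = set(WORD_CATEGORIES)
        if names != required:
            missing, extra = required - names, names - required
            raise LexiconError(
                f"lexicon categories must be exactly {sorted(required)}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, entries in self.categories.items():
            exact = {e for e in entries if not e.endswith("*")}
            stems = {e[:-1] for e in entries if e.endswith("*")}
            for entry in entries:
                if entry != entry.lower():
                    raise LexiconError(f"entry {entry!r} in {name!r} is not lowercase")
                if not entry.rstrip("*"):
                    raise LexiconError(f"empty entry in category {name!r}")
            clash = exact & stems
            if clash:
                raise LexiconError(
                    f"category {name!r} lists {sorted(clash)} both as exact word and stem"
                )

    def __hash__(self) -> int:
        return hash((tuple(sorted(self.categories.items())),
                     self.pos_emojis, self.neg_emojis))

    def matchers(self) -> dict[str, tuple[frozenset[str], tuple[str, ...]]]:
        """Per category: (exact word set, stem prefixes)."""
        out = {}
        for name, entries in self.categories.items():
            exact = frozenset(e for e in entries if not e.endswith("*"))
            stems = tuple(sorted(e[:-1] for e in entries if e.endswith("*")))
            out[name] = (exact, stems)
        return out


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a JSON file with a ``categories`` map."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return _lexicon_from_dict(raw)


def load_demo_lexicon() -> Lexicon:
    """The packaged ~100-entry demo lexicon."""
    raw = json.loads(
        resources.files("esmlang.data").joinpath("demo_lexicon.json").read_text("utf-8")
    )
    return _lexicon_from_dict(raw)


def _lexicon_from_dict(raw: dict) -> Lexicon:
    cats = {k: frozenset(v) for k, v in raw["categories"].items()}
    return Lexicon(
        categories=cats,
        pos_emojis=frozenset(raw.get("pos_emojis", ())),
        neg_emojis=frozenset(raw.get("neg_emojis", ())),
    )


@dataclass(frozen=True)
class ContentFeatureVector:
    """Word-count features of one text: percentages per category.

    ``wc`` is the raw token count; every category value is
    ``100 * matches / wc``.  ``exclam`` is reported both as a raw count and,
    for the writing stream, as a percentage of word count (``exclam_pct``).
    ``recognized_fraction`` is the share of tokens matched by at least one
    entry anywhere in the lexicon.  Texts with zero tokens are flagged
    ``degenerate`` and carry all-zero percentages.
    """

    wc: int
    percentages: dict[str, float]
    exclam_count: int
    exclam_pct: float
    pos_emojis: int
    neg_emojis: int
    recognized_fraction: float
    degenerate: bool = False

    def as_dict(self, *, include_exclam: bool = False,
                exclam_as_pct: bool = True) -> dict[str, float]:
        """Flatten into a feature-name -> value mapping (analysis columns)."""
        out = {"wc": float(self.wc)}
        out.update(self.percentages)
        if include_exclam:
            out["exclam"] = self.exclam_pct if exclam_as_pct else float(self.exclam_count)
        return out


def tokenize(text: str, lexicon: Lexicon | None = None
             ) -> tuple[list[str], int, int, int]:
    """Split text into lowercase word tokens.

    Returns ``(tokens, exclam_count, pos_emoji_count, neg_emoji_count)``.
    Emoji strings from the lexicon are counted and removed before word
    segmentation; words are maximal letter runs (apostrophes are kept inside
    tokens); exclamation marks are counted separately.
    """
    pos = neg = 0
    if lexicon is not None:
        # longest-first so ":-)" is not consumed as ":" + "-)" fragments
        for emoji in sorted(lexicon.pos_emojis, key=len, reverse=True):
            n = text.count(emoji)
            if n:
                pos += n
                text = text.replace(emoji, " ")
        for emoji in sorted(lexicon.neg_emojis, key=len, reverse=True):
            n = text.count(emoji)
            if n:
                neg += n
                text = text.replace(emoji, " ")
    exclam = text.count("!")
    tokens = _TOKEN_RE.findall(text.lower())
    return tokens, exclam, pos, neg


def extract_content_features(text: str, lexicon: Lexicon) -> ContentFeatureVector:
    """Count lexicon-category occurrences in ``text``.

    Each category percentage is ``100 *`` (tokens matching any entry of the
    category) ``/`` (total tokens); stems match by prefix and a token may
    fall in several categories.
    """
    tokens, exclam, pos, neg = tokenize(text, lexicon)
    wc = len(tokens)
    matchers = lexicon.matchers()
    counts = dict.fromkeys(WORD_CATEGORIES, 0)
    recognized = 0
    for tok in tokens:
        hit_any = False
        for name, (exact, stems) in matchers.items():
            if tok in exact or any(tok.startswith(s) for s in stems):
                counts[name] += 1
                hit_any = True
        if hit_any:
            recognized += 1
    if wc == 0:
        return ContentFeatureVector(
            wc=0, percentages=dict.fromkeys(WORD_CATEGORIES, 0.0),
            exclam_count=exclam, exclam_pct=0.0,
            pos_emojis=pos, neg_emojis=neg,
            recognized_fraction=0.0, degenerate=True,
        )
    pct = {name: 100.0 * c / wc for name, c in counts.items()}
    return ContentFeatureVector(
        wc=wc, percentages=pct,
        exclam_count=exclam, exclam_pct=100.0 * exclam / wc,
        pos_emojis=pos, neg_emojis=neg,
        recognized_fraction=recognized / wc,
    )
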
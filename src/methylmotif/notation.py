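"""Pattern text notations.

The canonical form is the 5-symbol string over ``{A,C,G,T,*}``, e.g.
``CCGG*``.  Reports often render wildcards in a regex-flavoured bracket
notation with lowercase fixed bases: ``ccgg[agct]{0,1}``.  Both are parsed.
"""

from __future__ import annotations

import re

from .patterns import PATTERN_LENGTH, WildcardPattern

__all__ = ["pattern_to_regex", "parse_pattern", "PatternParseError"]

_BRACKET = "[agct]{0,1}"
_TOKEN_RE = re.compile(r"\[agct\]\{0,(\d)\}|[acgtACGT*]")


class PatternParseError(ValueError):
    """Malformed pattern text; carries the offending position."""

    def __init__(self, text: str, position: int, message: str):
        self.position = position
        super().__init__(f"cannot parse pattern {text!r} at position {position}: {message}")


def pattern_to_regex(pattern: WildcardPattern) -> str:
    """Render a pattern in bracket notation: ``CCGG*`` → ``ccgg[agct]{0,1}``."""
    return "".join(
        _BRACKET if s == "*" else s.lower() for s in pattern.symbols
    )


def parse_pattern(text: str) -> WildcardPattern:
    """Parse either notation into a canonical :class:`WildcardPattern`.

    Accepts ``GA**T`` and ``ga[agct]{0,1}[agct]{0,1}t`` alike; a bracket
    term ``[agct]{0,n}`` expands to ``n`` wildcard symbols.
    """
    symbols: list[str] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise PatternParseError(text, pos, "unexpected character")
        if match.group(1) is not None:
            symbols.extend("*" * int(match.group(1)))
        else:
            token = match.group(0)
            symbols.append("*" if token == "*" else token.upper())
        pos = match.end()
    if len(symbols) != PATTERN_LENGTH:
        raise PatternParseError(
            text, pos, f"expands to {len(symbols)} symbols (need {PATTERN_LENGTH})"
        )
    try:
        return WildcardPattern("".join(symbols))
    except ValueError as exc:
        raise PatternParseError(text, 0, str(exc)) from exc
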
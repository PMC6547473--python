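"""Tokenizer for pipeline scripts.

The language is line-oriented with indentation-delimited blocks (used by
``preprocess ... using |read|:`` and ``if ...:``).  Tabs in indentation are
rejected; four-space indents are canonical but any consistent deepening is
accepted.  Comments run from ``#`` to end of line.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import LexicalError

KEYWORDS = frozenset(
    ["ngless", "import", "version", "using", "if", "discard", "continue", "true", "false"]
)

# Longest-match first.
_SYMBOLS = ["==", "!=", "<=", ">=", "=", "<", ">", "(", ")", "[", "]", ",", ":", "|", "+"]

# Token kinds
KW = "KW"
ID = "ID"
STR = "STR"
INT = "INT"
SYM = "SYM"
NEWLINE = "NEWLINE"
INDENT = "INDENT"
DEDENT = "DEDENT"
EOF = "EOF"


@dataclass(frozen=True)
class Token:
    kind: str
    value: str
    line: int
    col: int

    def __repr__(self) -> str:  # pragma: no cover
        return f"{self.kind}({self.value!r}@{self.line}:{self.col})"


def _lex_string(text: str, i: int, line: int, col: int) -> tuple[str, int]:
    """Lex a quoted string starting at ``text[i]``; returns (value, next index).

    Only ``\\"``, ``\\'`` and ``\\\\`` escapes are recognized.
    """
    quote = text[i]
    out = []
    j = i + 1
    while j < len(text):
        c = text[j]
        if c == "\\":
            if j + 1 < len(text) and text[j + 1] in ('"', "'", "\\"):
                out.append(text[j + 1])
                j += 2
                continue
            raise LexicalError("invalid escape sequence", line, col + (j - i))
        if c == quote:
            return "".join(out), j + 1
        out.append(c)
        j += 1
    raise LexicalError("unterminated string literal", line, col)


def tokenize(source: str) -> list[Token]:
    """Tokenize ``source``; raises :class:`LexicalError` with position on bad input."""
    tokens: list[Token] = []
    indent_stack = [0]
    lines = source.split("\n")
    for lineno, raw in enumerate(lines, start=1):
        # Leading whitespace / indentation.
        i = 0
        while i < len(raw) and raw[i] in " \t":
            if raw[i] == "\t":
                raise LexicalError("tab character in indentation (use spaces)", lineno, i + 1)
            i += 1
        rest = raw[i:]
        if not rest or rest.startswith("#"):
            continue  # blank or comment-only line: no tokens, no indent change
        indent = i
        if indent > indent_stack[-1]:
            indent_stack.append(indent)
            tokens.append(Token(INDENT, "", lineno, 1))
        else:
            while indent < indent_stack[-1]:
                indent_stack.pop()
                tokens.append(Token(DEDENT, "", lineno, 1))
            if indent != indent_stack[-1]:
                raise LexicalError("inconsistent indentation", lineno, indent + 1)
        # Tokens on the line.
        while i < len(raw):
            c = raw[i]
            if c == " ":
                i += 1
                continue
            if c == "\t":
                raise LexicalError("tab character", lineno, i + 1)
            if c == "#":
                break
            col = i + 1
            if c in "\"'":
                value, i = _lex_string(raw, i, lineno, col)
                tokens.append(Token(STR, value, lineno, col))
                continue
            if c.isdigit():
                j = i
                while j < len(raw) and raw[j].isdigit():
                    j += 1
                tokens.append(Token(INT, raw[i:j], lineno, col))
                i = j
                continue
            if c.isalpha() or c == "_":
                j = i
                while j < len(raw) and (raw[j].isalnum() or raw[j] == "_"):
                    j += 1
                word = raw[i:j]
                tokens.append(Token(KW if word in KEYWORDS else ID, word, lineno, col))
                i = j
                continue
            for sym in _SYMBOLS:
                if raw.startswith(sym, i):
                    tokens.append(Token(SYM, sym, lineno, col))
                    i += len(sym)
                    break
            else:
                raise LexicalError(f"unrecognized character {c!r}", lineno, col)
        tokens.append(Token(NEWLINE, "", lineno, len(raw) + 1))
    final_line = len(lines) + 1
    while indent_stack[-1] > 0:
        indent_stack.pop()
        tokens.append(Token(DEDENT, "", final_line, 1))
    tokens.append(Token(EOF, "", final_line, 1))
    return tokens
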
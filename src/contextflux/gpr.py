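"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers stating which
gene products enable a reaction: ``and`` nodes model enzyme complexes
(all subunits required), ``or`` nodes model isozymes (any one suffices).
Rules are parsed from the conventional parenthesized string syntax used
by COBRA-style model files, e.g. ``"(g1 and g2) or g3"``.

The empty rule (blank string) is represented by ``None`` throughout the
package and means "no gene requirement": such reactions (transport,
exchange, biomass pseudo-reactions) are always retained by
presence-based filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "Gene",
    "BoolOp",
    "GPRExpression",
    "GPRParseError",
    "parse_gpr",
    "gpr_to_string",
    "gpr_genes",
    "evaluate_gpr_presence",
    "evaluate_gpr_abundance",
]


@dataclass(frozen=True)
class Gene:
    """A leaf of the GPR tree: a single gene identifier."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene id must be non-empty")


@dataclass(frozen=True)
class BoolOp:
    """An internal AND/OR node with two or more children."""

    op: str  # "and" | "or"
    children: tuple["GPRExpression", ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown boolean operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node needs >= 2 children")


GPRExpression = Union[Gene, BoolOp]


class GPRParseError(ValueError):
    """Raised for malformed rule text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_PUNCT = {"(", ")"}


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _PUNCT:
            tokens.append((ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in _PUNCT:
            j += 1
        tokens.append((text[i:j], i))
        i = j
    return tokens


def parse_gpr(rule_text: str) -> GPRExpression | None:
    """Parse a rule string into a GPR tree; blank text yields ``None``.

    Operators ``and``/``or`` are case-insensitive; anything else that is
    not a parenthesis is a gene id (exact string, whitespace-delimited).
    Raises :class:`GPRParseError` with a character position on malformed
    input (unbalanced parentheses, dangling operators).
    """
    if rule_text is None or not rule_text.strip():
        return None
    tokens = _tokenize(rule_text)
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def is_op(tok: str, name: str) -> bool:
        return tok.lower() == name

    def parse_or() -> GPRExpression:
        nonlocal pos
        children = [parse_and()]
        while (t := peek()) is not None and is_op(t[0], "or"):
            pos += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    def parse_and() -> GPRExpression:
        nonlocal pos
        children = [parse_atom()]
        while (t := peek()) is not None and is_op(t[0], "and"):
            pos += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def parse_atom() -> GPRExpression:
        nonlocal pos
        t = peek()
        if t is None:
            raise GPRParseError("unexpected end of rule", len(rule_text))
        tok, at = t
        if tok == "(":
            pos += 1
            inner = parse_or()
            t2 = peek()
            if t2 is None or t2[0] != ")":
                raise GPRParseError("unbalanced parenthesis", at)
            pos += 1
            return inner
        if tok == ")":
            raise GPRParseError("unexpected ')'", at)
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator {tok!r}", at)
        pos += 1
        return Gene(tok.strip())

    expr = parse_or()
    if pos < len(tokens):
        raise GPRParseError(f"unexpected token {tokens[pos][0]!r}", tokens[pos][1])
    return expr


def gpr_to_string(gpr: GPRExpression | None) -> str:
    """Serialize a GPR tree back to rule text; re-parses to an equal tree."""
    if gpr is None:
        return ""
    if isinstance(gpr, Gene):
        return gpr.name
    sep = f" {gpr.op} "
    parts = []
    for child in gpr.children:
        s = gpr_to_string(child)
        if isinstance(child, BoolOp):
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def gpr_genes(gpr: GPRExpression | None) -> set[str]:
    """The set of gene ids appearing in the rule (empty for the empty rule)."""
    if gpr is None:
        return set()
    if isinstance(gpr, Gene):
        return {gpr.name}
    out: set[str] = set()
    for child in gpr.children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr_presence(gpr: GPRExpression | None, present_genes: set[str]) -> bool:
    """Boolean evaluation: a leaf is true iff its gene is present.

    The empty rule evaluates to True (gene-less reactions are retained).
    """
    if gpr is None:
        return True
    if isinstance(gpr, Gene):
        return gpr.name in present_genes
    results = (evaluate_gpr_presence(c, present_genes) for c in gpr.children)
    return all(results) if gpr.op == "and" else any(results)


def evaluate_gpr_abundance(gpr: GPRExpression, abundance: dict[str, float]) -> float:
    """Numeric evaluation: AND combines by min, OR by max.

    A complex is limited by its scarcest subunit; isozymes contribute
    their most abundant member. Genes absent from ``abundance`` score 0.
    """
    if isinstance(gpr, Gene):
        return float(abundance.get(gpr.name, 0.0))
    values = [evaluate_gpr_abundance(c, abundance) for c in gpr.children]
    return min(values) if gpr.op == "and" else max(values)
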
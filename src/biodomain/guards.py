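"""Transition-guard language for single-entity state machines.

Guards combine three kinds of atom with ``&`` (conjunction, binds tighter)
and ``|`` (disjunction):

* a bare *predicate* name, valued by the environment for the current step
  (co-location facts, received signals, other regions' active states);
* ``δ(p)`` — a probabilistic event: one Bernoulli draw per evaluation with
  success probability taken from the model parameter table under ``p``;
* ``λ(t)`` — a timed event: true once the entity has dwelt at least ``t``
  steps (a nonnegative integer parameter) in the transition's source state.

ASCII spellings ``delta(p)`` and ``lambda(t)`` are accepted everywhere the
Greek forms are; the printer emits the Greek forms.

An empty guard string denotes the always-true guard (an unguarded
transition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional

import numpy as np

__all__ = [
    "GuardExpr",
    "TrueGuard",
    "Predicate",
    "Delta",
    "Lambda",
    "And",
    "Or",
    "GuardSyntaxError",
    "GuardEvaluationError",
    "parse_guard",
    "evaluate_guard",
]


class GuardSyntaxError(ValueError):
    """Raised on malformed guard text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GuardEvaluationError(KeyError):
    """Raised when a predicate or parameter cannot be resolved."""


class GuardExpr:
    """Base class for guard expression trees."""

    def evaluate(
        self,
        env: Mapping[str, bool],
        elapsed_steps: int,
        parameters: Mapping[str, float],
        rng: np.random.Generator,
    ) -> bool:
        raise NotImplementedError

    def atoms(self) -> Iterator["GuardExpr"]:
        """Yield every atom occurrence in the tree (duplicates included)."""
        yield from ()

    def predicates(self) -> set[str]:
        return {a.name for a in self.atoms() if isinstance(a, Predicate)}

    def satisfiable(self, fixed: Mapping[str, bool]) -> bool:
        """Whether some valuation of the unfixed atoms makes the guard true.

        Predicates named in ``fixed`` take the given truth value; all other
        atoms (free predicates, δ, λ) are treated as potentially true.  The
        grammar has no negation, so expressions are monotone and the maximal
        assignment decides satisfiability exactly.
        """
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - delegated to subclasses
        raise NotImplementedError

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self.__dict__ == other.__dict__

    def __hash__(self):
        return hash((type(self).__name__, tuple(sorted(self.__dict__.items()))))


class TrueGuard(GuardExpr):
    """The always-true guard of an unguarded transition."""

    def evaluate(self, env, elapsed_steps, parameters, rng) -> bool:
        return True

    def satisfiable(self, fixed) -> bool:
        return True

    def __str__(self) -> str:
        return ""

    def __repr__(self) -> str:
        return "TrueGuard()"


@dataclass(frozen=True, eq=False)
class Predicate(GuardExpr):
    name: str

    def evaluate(self, env, elapsed_steps, parameters, rng) -> bool:
        try:
            return bool(env[self.name])
        except KeyError:
            raise GuardEvaluationError(
                f"predicate {self.name!r} is not valued in the environment"
            ) from None

    def atoms(self):
        yield self

    def satisfiable(self, fixed) -> bool:
        return bool(fixed.get(self.name, True))

    def __str__(self) -> str:
        return self.name


def _resolve_param(parameters: Mapping[str, float], name: str, kind: str) -> float:
    try:
        return parameters[name]
    except KeyError:
        raise GuardEvaluationError(
            f"{kind} parameter {name!r} is not in the parameter table"
        ) from None


@dataclass(frozen=True, eq=False)
class Delta(GuardExpr):
    """Probabilistic atom: one Bernoulli(p) draw per evaluation."""

    param: str

    def evaluate(self, env, elapsed_steps, parameters, rng) -> bool:
        p = _resolve_param(parameters, self.param, "δ")
        if not 0.0 <= p <= 1.0:
            raise GuardEvaluationError(
                f"δ parameter {self.param!r} = {p} lies outside [0, 1]"
            )
        return bool(rng.random() < p)

    def atoms(self):
        yield self

    def satisfiable(self, fixed) -> bool:
        return True

    def __str__(self) -> str:
        return f"δ({self.param})"


@dataclass(frozen=True, eq=False)
class Lambda(GuardExpr):
    """Timed atom: true once dwell time reaches the parameter's value."""

    param: str

    def evaluate(self, env, elapsed_steps, parameters, rng) -> bool:
        t = _resolve_param(parameters, self.param, "λ")
        if t < 0 or int(t) != t:
            raise GuardEvaluationError(
                f"λ parameter {self.param!r} = {t} is not a nonnegative integer"
            )
        return elapsed_steps >= int(t)

    def atoms(self):
        yield self

    def satisfiable(self, fixed) -> bool:
        return True

    def __str__(self) -> str:
        return f"λ({self.param})"


@dataclass(frozen=True, eq=False)
class And(GuardExpr):
    left: GuardExpr
    right: GuardExpr

    def evaluate(self, env, elapsed_steps, parameters, rng) -> bool:
        # deliberately no short-circuit: every δ occurrence draws exactly once
        a = self.left.evaluate(env, elapsed_steps, parameters, rng)
        b = self.right.evaluate(env, elapsed_steps, parameters, rng)
        return a and b

    def atoms(self):
        yield from self.left.atoms()
        yield from self.right.atoms()

    def satisfiable(self, fixed) -> bool:
        return self.left.satisfiable(fixed) and self.right.satisfiable(fixed)

    def __str__(self) -> str:
        # right operand parenthesized when it is itself an And: the parser
        # is left-associative, and printing must preserve tree structure
        left = _paren_if_or(self.left)
        right = (
            f"({self.right})"
            if isinstance(self.right, (And, Or))
            else str(self.right)
        )
        return f"{left} & {right}"


@dataclass(frozen=True, eq=False)
class Or(GuardExpr):
    left: GuardExpr
    right: GuardExpr

    def evaluate(self, env, elapsed_steps, parameters, rng) -> bool:
        a = self.left.evaluate(env, elapsed_steps, parameters, rng)
        b = self.right.evaluate(env, elapsed_steps, parameters, rng)
        return a or b

    def atoms(self):
        yield from self.left.atoms()
        yield from self.right.atoms()

    def satisfiable(self, fixed) -> bool:
        return self.left.satisfiable(fixed) or self.right.satisfiable(fixed)

    def __str__(self) -> str:
        right = f"({self.right})" if isinstance(self.right, Or) else str(self.right)
        return f"{self.left} | {right}"


def _paren_if_or(expr: GuardExpr) -> str:
    return f"({expr})" if isinstance(expr, Or) else str(expr)


# --------------------------------------------------------------------------
# Tokenizer / recursive-descent parser


_NAME_START = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ_")
_NAME_CHARS = _NAME_START | set("0123456789-:")


@dataclass
class _Token:
    kind: str  # NAME | DELTA | LAMBDA | AND | OR | LPAREN | RPAREN | END
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "&":
            tokens.append(_Token("AND", c, i))
            i += 1
        elif c == "|":
            tokens.append(_Token("OR", c, i))
            i += 1
        elif c == "(":
            tokens.append(_Token("LPAREN", c, i))
            i += 1
        elif c == ")":
            tokens.append(_Token("RPAREN", c, i))
            i += 1
        elif c == "δ":
            tokens.append(_Token("DELTA", c, i))
            i += 1
        elif c == "λ":
            tokens.append(_Token("LAMBDA", c, i))
            i += 1
        elif c in _NAME_START:
            j = i
            while j < n and text[j] in _NAME_CHARS:
                j += 1
            word = text[i:j]
            if word == "delta":
                tokens.append(_Token("DELTA", word, i))
            elif word == "lambda":
                tokens.append(_Token("LAMBDA", word, i))
            else:
                tokens.append(_Token("NAME", word, i))
            i = j
        else:
            raise GuardSyntaxError(f"unknown token {c!r}", i)
    tokens.append(_Token("END", "", n))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        tok = self.peek()
        if tok.kind != kind:
            raise GuardSyntaxError(f"expected {what}", tok.pos)
        return self.advance()

    def parse_expr(self) -> GuardExpr:
        node = self.parse_term()
        while self.peek().kind == "OR":
            self.advance()
            node = Or(node, self.parse_term())
        return node

    def parse_term(self) -> GuardExpr:
        node = self.parse_factor()
        while self.peek().kind == "AND":
            self.advance()
            node = And(node, self.parse_factor())
        return node

    def parse_factor(self) -> GuardExpr:
        tok = self.peek()
        if tok.kind == "LPAREN":
            self.advance()
            node = self.parse_expr()
            self.expect("RPAREN", "')'")
            return node
        if tok.kind in ("DELTA", "LAMBDA"):
            self.advance()
            self.expect("LPAREN", "'(' after δ/λ")
            name = self.expect("NAME", "parameter name")
            self.expect("RPAREN", "')'")
            return Delta(name.text) if tok.kind == "DELTA" else Lambda(name.text)
        if tok.kind == "NAME":
            self.advance()
            return Predicate(tok.text)
        raise GuardSyntaxError("expected an atom or '('", tok.pos)


def parse_guard(text: Optional[str]) -> GuardExpr:
    """Parse guard text into an expression tree.

    ``None`` or all-whitespace text yields the always-true guard.  Raises
    :class:`GuardSyntaxError` (with a character position) on malformed input.
    """
    if text is None or not text.strip():
        return TrueGuard()
    parser = _Parser(_tokenize(text))
    expr = parser.parse_expr()
    tok = parser.peek()
    if tok.kind != "END":
        raise GuardSyntaxError(f"unexpected {tok.text!r}", tok.pos)
    return expr


def evaluate_guard(
    guard: GuardExpr,
    env: Mapping[str, bool],
    elapsed_steps: int,
    parameters: Mapping[str, float],
    rng: np.random.Generator,
) -> bool:
    """Evaluate a guard for one step.

    Predicates are read from ``env``; each ``δ`` occurrence draws one
    Bernoulli variate from ``rng``; ``λ`` compares ``elapsed_steps`` against
    its parameter.  Evaluation is eager (no short-circuiting) so the number
    of random draws depends only on the guard's structure.
    """
    return guard.evaluate(env, elapsed_steps, parameters, rng)
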
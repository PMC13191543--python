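"""Equivalent-circuit elements, notation grammar and impedance evaluation.

Circuits are written in the compact notation used throughout the EIS
literature: element tokens (``R1``, ``C2``, ``CPE``, ``W``), ``+`` for series
combination, ``||`` for parallel combination (binding tighter than ``+``),
and parentheses for grouping.  Examples::

    R1 + (R2||CPE)                      # Randles-type cell with a CPE
    R1 + (R2||C1) + (R3||C2) + (R4||C3) # three relaxations in series
    R1 + (C1||(R2 + (C2||W)))           # diffusion-limited interface

Element impedances (omega in rad/s):

====================  ==========================  =================
element               impedance                   parameter units
====================  ==========================  =================
resistor              ``R``                       R [ohm]
capacitor             ``1/(j w C)``               C [F]
constant phase elem.  ``1/(Y0 (j w)^n)``          Y0 [S s^n], n [-]
Warburg (semi-inf.)   ``1/(W sqrt(j w))``         W [S s^1/2]
====================  ==========================  =================

The CPE reduces to an ideal capacitor at ``n = 1`` and the semi-infinite
Warburg has a constant -45 degree phase at every frequency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .parameters import ParameterSet
from .spectrum import FrequencySpectrum

__all__ = [
    "CircuitElement",
    "Series",
    "Parallel",
    "CircuitModel",
    "CircuitSyntaxError",
    "parse_circuit",
    "element_impedance",
    "circuit_impedance",
]


class CircuitSyntaxError(ValueError):
    """Malformed circuit notation; carries the 0-based offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class CircuitElement:
    """A leaf of the circuit tree.

    ``kind`` is one of resistor/capacitor/cpe/warburg; ``label`` is the token
    as written (``R2``, ``CPE``, ``CPE2``, ``W``).  Parameter names derive from
    the label so that every name in a circuit is unique: ``R2 -> R2``,
    ``CPE -> Y0, n``, ``CPE2 -> Y0_2, n_2``, ``W2 -> W_2``.
    """

    kind: str
    label: str

    @property
    def param_names(self) -> Tuple[str, ...]:
        if self.kind in ("resistor", "capacitor"):
            return (self.label,)
        suffix = ""
        if self.kind == "cpe":
            idx = self.label[3:]
            suffix = f"_{idx}" if idx else ""
            return (f"Y0{suffix}", f"n{suffix}")
        idx = self.label[1:]
        suffix = f"_{idx}" if idx else ""
        return (f"W{suffix}",)


Node = Union[CircuitElement, "Series", "Parallel"]


@dataclass(frozen=True)
class Series:
    children: Tuple[Node, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("series node needs >= 2 children")


@dataclass(frozen=True)
class Parallel:
    children: Tuple[Node, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("parallel node needs >= 2 children")


@dataclass(frozen=True)
class CircuitModel:
    """An expression tree of series/parallel element combinations."""

    root: Node
    source_text: str

    @property
    def param_names(self) -> Tuple[str, ...]:
        """Ordered names of all leaf parameters (depth-first, left to right)."""
        names: List[str] = []
        for el in self.elements:
            names.extend(el.param_names)
        return tuple(names)

    @property
    def elements(self) -> Tuple[CircuitElement, ...]:
        out: List[CircuitElement] = []

        def walk(node: Node) -> None:
            if isinstance(node, CircuitElement):
                out.append(node)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return tuple(out)

    def serialize(self) -> str:
        """Render the tree back to notation (parallel groups parenthesised)."""
        return _render(self.root, top=True)

    def __str__(self) -> str:
        return self.serialize()


def _render(node: Node, top: bool = False) -> str:
    if isinstance(node, CircuitElement):
        return node.label
    if isinstance(node, Series):
        body = " + ".join(_render(c) for c in node.children)
        return body if top else f"({body})"
    body = "||".join(_render(c) for c in node.children)
    return f"({body})" if not top else f"({body})"


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(CPE\d*|R\d+|C\d+|W\d*|\|\||\+|\(|\))")

_KINDS = {"R": "resistor", "C": "capacitor", "CPE": "cpe", "W": "warburg"}


def _tokenize(text: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = pos + len(text[pos:]) - len(text[pos:].lstrip())
            if stripped >= len(text):
                break
            raise CircuitSyntaxError(f"unknown token {text[stripped]!r}", stripped)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; `||` binds tighter than `+`, left-associative."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> Tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> Tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise CircuitSyntaxError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.series()
        tok = self.peek()
        if tok is not None:
            raise CircuitSyntaxError(f"unexpected token {tok[0]!r}", tok[1])
        return node

    def series(self) -> Node:
        children = [self.parallel()]
        while (tok := self.peek()) is not None and tok[0] == "+":
            self.next()
            children.append(self.parallel())
        return children[0] if len(children) == 1 else Series(tuple(children))

    def parallel(self) -> Node:
        children = [self.factor()]
        while (tok := self.peek()) is not None and tok[0] == "||":
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else Parallel(tuple(children))

    def factor(self) -> Node:
        tok, pos = self.next()
        if tok == "(":
            node = self.series()
            nxt = self.peek()
            if nxt is None:
                raise CircuitSyntaxError("unbalanced parenthesis", len(self.text))
            if nxt[0] != ")":
                raise CircuitSyntaxError(f"expected ')', got {nxt[0]!r}", nxt[1])
            self.next()
            return node
        if tok in ("+", "||", ")"):
            raise CircuitSyntaxError(f"unexpected token {tok!r}", pos)
        head = "CPE" if tok.startswith("CPE") else tok[0]
        return CircuitElement(kind=_KINDS[head], label=tok)


def parse_circuit(spec: str) -> CircuitModel:
    """Parse circuit notation into a :class:`CircuitModel`.

    Raises :class:`CircuitSyntaxError` on malformed input and ``ValueError``
    on duplicate element labels (which would collide parameter names).
    """
    if not spec or not spec.strip():
        raise CircuitSyntaxError("empty circuit specification", 0)
    root = _Parser(spec).parse()
    model = CircuitModel(root=root, source_text=spec)
    seen: Dict[str, str] = {}
    for el in model.elements:
        for name in el.param_names:
            if name in seen:
                raise ValueError(
                    f"duplicate parameter {name!r} from labels {seen[name]!r} and "
                    f"{el.label!r}; use indexed labels (e.g. CPE2) to disambiguate"
                )
            seen[name] = el.label
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def element_impedance(
    element: CircuitElement, params: Mapping[str, float], omega: np.ndarray | float
) -> np.ndarray | complex:
    """Complex impedance of a single element at angular frequency ``omega`` (rad/s)."""
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("omega must be > 0")
    names = element.param_names
    try:
        vals = [params[name] for name in names]
    except KeyError as exc:
        raise KeyError(f"missing parameter {exc.args[0]!r} for element {element.label!r}") from None
    for name, v in zip(names, vals):
        if v <= 0:
            raise ValueError(f"parameter {name!r} of {element.label!r} must be > 0, got {v!r}")
    if element.kind == "resistor":
        return np.broadcast_to(complex(vals[0]), w.shape).copy() if w.ndim else complex(vals[0])
    if element.kind == "capacitor":
        return 1.0 / (1j * w * vals[0])
    if element.kind == "cpe":
        y0, n = vals
        if n > 1:
            raise ValueError(f"CPE exponent {names[1]!r} must satisfy 0 < n <= 1, got {n!r}")
        return 1.0 / (y0 * (1j * w) ** n)
    # warburg: semi-infinite diffusion, constant -45 degree phase
    return 1.0 / (vals[0] * np.sqrt(1j * w))


def _evaluate(node: Node, params: Mapping[str, float], w: np.ndarray) -> np.ndarray:
    if isinstance(node, CircuitElement):
        return np.asarray(element_impedance(node, params, w))
    if isinstance(node, Series):
        return np.sum([_evaluate(c, params, w) for c in node.children], axis=0)
    admittance = np.sum([1.0 / _evaluate(c, params, w) for c in node.children], axis=0)
    return 1.0 / admittance


def circuit_impedance(
    model: CircuitModel,
    params: ParameterSet | Mapping[str, float],
    frequencies: Sequence[float] | np.ndarray,
) -> FrequencySpectrum:
    """Evaluate a circuit over a frequency grid (Hz) by series/parallel reduction.

    Series nodes sum child impedances; parallel nodes sum child admittances and
    invert.  Frequencies are external Hz, converted to rad/s only at element
    evaluation.
    """
    values = params.values_dict() if isinstance(params, ParameterSet) else dict(params)
    missing = [n for n in model.param_names if n not in values]
    if missing:
        raise KeyError(f"parameters missing for circuit {model.source_text!r}: {missing}")
    f = np.asarray(frequencies, dtype=float)
    z = _evaluate(model.root, values, 2.0 * np.pi * f)
    return FrequencySpectrum(f, z, {"circuit": model.serialize()})
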
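"""Native text format for (parametrised) Boolean networks.

A model file is a sequence of lines:

* ``#key: value`` — a free-form annotation (e.g. ``#name: my model``);
* ``SRC -> TGT`` — an activating regulation; ``SRC -| TGT`` an inhibiting
  one; ``SRC -? TGT`` a regulation of unknown sign.  A trailing ``?`` on
  the arrow (``->?``, ``-|?``, ``-??``) marks observability as NOT
  required; plain arrows require it;
* ``$VAR: expression`` — the update expression of a variable.

Variables are declared by their update lines (one each, in order);
parameters are declared implicitly by their first application, with arity
consistency enforced.  Blank lines are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .expr import ExprError, parse_expression, to_text
from .network import (
    ACTIVATION,
    INHIBITION,
    MONO_UNKNOWN,
    OBS_REQUIRED,
    OBS_UNKNOWN,
    ParameterDecl,
    ParametrisedNetwork,
    Regulation,
)


class FormatError(ValueError):
    """Parse error carrying the 1-based source line."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


@dataclass
class ModelDocument:
    """A network plus free-form annotations (names, layout hints, ...)."""

    network: ParametrisedNetwork
    annotations: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelDocument):
            return NotImplemented
        return self.network == other.network and self.annotations == other.annotations


_REG_RE = re.compile(r"^(\w+)\s*-(>|\||\?)(\?)?\s*(\w+)$")
_UPDATE_RE = re.compile(r"^\$(\w+)\s*:\s*(\S.*)$")
_ANNOTATION_RE = re.compile(r"^#\s*([^:]+?)\s*:\s*(.*)$")

_SIGN_TO_MONO = {">": ACTIVATION, "|": INHIBITION, "?": MONO_UNKNOWN}
_MONO_TO_SIGN = {v: k for k, v in _SIGN_TO_MONO.items()}


def read_native(text: str) -> ModelDocument:
    annotations: dict[str, str] = {}
    raw_regulations: list[tuple[int, str, str, str, str]] = []
    raw_updates: list[tuple[int, str, str]] = []
    update_lines: dict[str, int] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _ANNOTATION_RE.match(line)
            if not m:
                raise FormatError("malformed annotation, expected '#key: value'", lineno)
            key = m.group(1)
            if key in annotations:
                raise FormatError(f"duplicate annotation {key!r}", lineno)
            annotations[key] = m.group(2)
            continue
        if line.startswith("$"):
            m = _UPDATE_RE.match(line)
            if not m:
                raise FormatError("malformed update, expected '$VAR: expression'", lineno)
            name = m.group(1)
            if name in update_lines:
                raise FormatError(f"duplicate update for variable {name!r}", lineno)
            update_lines[name] = lineno
            raw_updates.append((lineno, name, m.group(2)))
            continue
        m = _REG_RE.match(line)
        if not m:
            raise FormatError(f"unrecognised line {line!r}", lineno)
        source, sign, non_obs, target = m.group(1), m.group(2), m.group(3), m.group(4)
        raw_regulations.append((lineno, source, sign, non_obs or "", target))

    if not raw_updates:
        raise FormatError("model declares no variables (no '$VAR: ...' lines)")

    variables = tuple(name for _, name, _ in raw_updates)
    declared = frozenset(variables)

    regulations: list[Regulation] = []
    seen_pairs: set[tuple[str, str]] = set()
    for lineno, source, sign, non_obs, target in raw_regulations:
        for endpoint in (source, target):
            if endpoint not in declared:
                raise FormatError(
                    f"regulation references {endpoint!r}, which has no update line", lineno
                )
        pair = (source, target)
        if pair in seen_pairs:
            raise FormatError(f"duplicate regulation {source} -> {target}", lineno)
        seen_pairs.add(pair)
        regulations.append(
            Regulation(
                source,
                target,
                observable=OBS_UNKNOWN if non_obs else OBS_REQUIRED,
                monotonicity=_SIGN_TO_MONO[sign],
            )
        )

    implicit: dict[str, int] = {}
    update = {}
    for lineno, name, expr_text in raw_updates:
        try:
            update[name] = parse_expression(
                expr_text, declared, parameters=None, implicit_parameters=implicit
            )
        except ExprError as exc:
            raise FormatError(f"in the update of {name!r}: {exc}", lineno) from exc

    parameters = tuple(ParameterDecl(n, a) for n, a in implicit.items())
    network = ParametrisedNetwork(variables, regulations, parameters, update)
    return ModelDocument(network, annotations)


def write_native(doc: ModelDocument) -> str:
    """Serialize to the native format with normalized ordering.

    Annotations keep insertion order; regulations are sorted by (source,
    target) variable index; update lines follow variable declaration order.
    """
    n = doc.network
    applied: set[str] = set()
    for expr in n.update.values():
        from .expr import parameters_of

        applied |= set(parameters_of(expr))
    unused = {p.name for p in n.parameters} - applied
    if unused:
        raise FormatError(
            f"parameters {sorted(unused)} are declared but never applied; the native "
            "format declares parameters implicitly at first use"
        )
    lines: list[str] = []
    for key, value in doc.annotations.items():
        if "\n" in value or "\n" in key:
            raise FormatError(f"annotation {key!r} contains a newline")
        lines.append(f"#{key}: {value}")
    index = {name: i for i, name in enumerate(n.variables)}
    for reg in sorted(n.regulations, key=lambda r: (index[r.source], index[r.target])):
        arrow = "-" + _MONO_TO_SIGN[reg.monotonicity]
        if reg.observable == OBS_UNKNOWN:
            arrow += "?"
        lines.append(f"{reg.source} {arrow} {reg.target}")
    for name in n.variables:
        lines.append(f"${name}: {to_text(n.update[name])}")
    return "\n".join(lines) + "\n"
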
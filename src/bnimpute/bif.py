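"""Reader/writer for discrete networks in BIF (Bayesian Interchange
Format), the plain-text format used by the standard network repositories.

Supported grammar (the common subset emitted by those repositories)::

    network <name> { }
    variable <name> {
      type discrete [ <k> ] { <level>, ... };
    }
    probability ( <child> ) { table <p>, ...; }
    probability ( <child> | <parent>, ... ) {
      ( <level>, ... ) <p>, ...;
      ...
    }

Parsing is strict: undeclared variables or levels, CPT rows of the wrong
length and missing parent configurations raise a parse error carrying the
line number.  Write/read round trips are lossless.
"""

from __future__ import annotations

import itertools
import re

from .dataset import ConfigurationError, VariableSpec
from .graphs import NetworkStructure
from .simulate import DiscreteNode, SimulationModel

__all__ = ["load_bif", "write_bif", "BifParseError"]


class BifParseError(ConfigurationError):
    """Malformed BIF input; message includes the offending line number."""


_TOKEN = re.compile(r"//[^\n]*|\"[^\"]*\"|[A-Za-z0-9_.\-+]+|[{}()\[\]|,;]")


def _tokenize(text):
    tokens = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for m in _TOKEN.finditer(line):
            tok = m.group(0)
            if tok.startswith("//"):
                break
            tokens.append((tok.strip('"'), lineno))
    return tokens


class _Cursor:
    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    @property
    def lineno(self):
        i = min(self.i, len(self.tokens) - 1)
        return self.tokens[i][1] if self.tokens else 0

    def next(self):
        if self.i >= len(self.tokens):
            raise BifParseError("unexpected end of file")
        tok, _ = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, want):
        tok = self.next()
        if tok != want:
            raise BifParseError(
                f"line {self.lineno}: expected {want!r}, found {tok!r}"
            )
        return tok


def _parse_float(cur):
    tok = cur.next()
    try:
        return float(tok)
    except ValueError:
        raise BifParseError(f"line {cur.lineno}: expected number, found {tok!r}")


def load_bif(path) -> SimulationModel:
    """Parse a BIF file into a discrete :class:`SimulationModel`."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    cur = _Cursor(_tokenize(text))

    levels: dict = {}
    cpts: dict = {}
    parents: dict = {}
    order: list = []

    while cur.peek() is not None:
        tok = cur.next()
        if tok == "network":
            cur.next()  # name
            cur.expect("{")
            depth = 1
            while depth:
                t = cur.next()
                depth += (t == "{") - (t == "}")
        elif tok == "variable":
            name = cur.next()
            cur.expect("{")
            cur.expect("type")
            cur.expect("discrete")
            cur.expect("[")
            k = int(_parse_float(cur))
            cur.expect("]")
            cur.expect("{")
            vals = []
            while cur.peek() != "}":
                t = cur.next()
                if t != ",":
                    vals.append(t)
            cur.expect("}")
            cur.expect(";")
            cur.expect("}")
            if len(vals) != k:
                raise BifParseError(
                    f"line {cur.lineno}: variable {name!r} declares {k} "
                    f"levels but lists {len(vals)}"
                )
            if name in levels:
                raise BifParseError(f"line {cur.lineno}: duplicate variable {name!r}")
            levels[name] = tuple(vals)
            order.append(name)
        elif tok == "probability":
            cur.expect("(")
            child = cur.next()
            if child not in levels:
                raise BifParseError(
                    f"line {cur.lineno}: probability for undeclared "
                    f"variable {child!r}"
                )
            pars = []
            if cur.peek() == "|":
                cur.next()
                while cur.peek() != ")":
                    t = cur.next()
                    if t != ",":
                        pars.append(t)
            cur.expect(")")
            for p_ in pars:
                if p_ not in levels:
                    raise BifParseError(
                        f"line {cur.lineno}: undeclared parent {p_!r}"
                    )
            parents[child] = tuple(pars)
            cur.expect("{")
            table: dict = {}
            while cur.peek() != "}":
                if cur.peek() == "table":
                    cur.next()
                    probs = []
                    while cur.peek() != ";":
                        t = cur.peek()
                        if t == ",":
                            cur.next()
                            continue
                        probs.append(_parse_float(cur))
                    cur.expect(";")
                    table[()] = probs
                else:
                    cur.expect("(")
                    key = []
                    while cur.peek() != ")":
                        t = cur.next()
                        if t != ",":
                            key.append(t)
                    cur.expect(")")
                    for p_, lev in zip(pars, key):
                        if lev not in levels[p_]:
                            raise BifParseError(
                                f"line {cur.lineno}: level {lev!r} not "
                                f"declared for parent {p_!r}"
                            )
                    if len(key) != len(pars):
                        raise BifParseError(
                            f"line {cur.lineno}: configuration arity mismatch"
                        )
                    probs = []
                    while cur.peek() != ";":
                        t = cur.peek()
                        if t == ",":
                            cur.next()
                            continue
                        probs.append(_parse_float(cur))
                    cur.expect(";")
                    table[tuple(key)] = probs
            cur.expect("}")
            for key, probs in table.items():
                if len(probs) != len(levels[child]):
                    raise BifParseError(
                        f"CPT row {key} of {child!r} has {len(probs)} "
                        f"entries for {len(levels[child])} levels"
                    )
            cpts[child] = table
        else:
            raise BifParseError(f"line {cur.lineno}: unexpected token {tok!r}")

    edges = []
    nodes = {}
    for name in order:
        if name not in cpts:
            raise BifParseError(f"variable {name!r} has no probability block")
        pars = parents.get(name, ())
        expected = list(itertools.product(*[levels[p_] for p_ in pars]))
        missing = [k for k in expected if k not in cpts[name]]
        if missing:
            raise BifParseError(
                f"CPT of {name!r} lacks parent configuration {missing[0]}"
            )
        for p_ in pars:
            edges.append((p_, name))
        node = DiscreteNode(levels=levels[name], parents=pars, cpt=cpts[name])
        node.validate()
        nodes[name] = node
    variables = [VariableSpec(n_, "discrete", levels=levels[n_]) for n_ in order]
    return SimulationModel(NetworkStructure(variables, edges), nodes)


def write_bif(model: SimulationModel, path, name="network"):
    """Serialise a discrete SimulationModel to BIF."""
    lines = [f"network {name} {{", "}"]
    for v in model.structure.node_names:
        node = model.nodes[v]
        if not isinstance(node, DiscreteNode):
            raise ConfigurationError("BIF supports discrete networks only")
        levs = ", ".join(node.levels)
        lines.append(f"variable {v} {{")
        lines.append(f"  type discrete [ {len(node.levels)} ] {{ {levs} }};")
        lines.append("}")
    for v in model.structure.node_names:
        node = model.nodes[v]
        if node.parents:
            pars = ", ".join(node.parents)
            lines.append(f"probability ( {v} | {pars} ) {{")
            for key in itertools.product(
                *[model.nodes[p_].levels for p_ in node.parents]
            ):
                probs = ", ".join(repr(float(x)) for x in node.cpt[key])
                lines.append(f"  ( {', '.join(key)} ) {probs};")
            lines.append("}")
        else:
            probs = ", ".join(repr(float(x)) for x in node.cpt[()])
            lines.append(f"probability ( {v} ) {{")
            lines.append(f"  table {probs};")
            lines.append("}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
    return text
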
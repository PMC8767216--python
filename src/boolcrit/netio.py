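"""Reading and writing Boolean network models as plain text.

Two interchangeable formats are supported:

* **Truth-table** (``.tt``): tab-separated columns ``node``,
  comma-separated ordered input names, and the ``2**k`` output bits as a
  string (lexicographic row order, first input most significant).  Lines
  starting with ``#`` are comments.

* **Logical expressions** (``.bnet`` dialect): one ``target, expression``
  line per node using ``&`` (and), ``|`` (or), ``!`` (not), parentheses
  and the constants ``0``/``1``.  An optional ``targets, factors`` header
  line is accepted.  Expressions are compiled to LUTs over the referenced
  variables in order of first appearance.  Variables that appear only as
  regulators become input nodes modelled as ``k = 1`` self-loop copies.
"""

from __future__ import annotations

import re
from pathlib import Path

from .rules import BooleanNetwork, BooleanRule, rule_from_string

__all__ = ["read_network", "write_network", "parse_bnet", "parse_truth_table"]

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")
_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_.]*|[01]|[()&|!])")


class NetworkParseError(ValueError):
    """Malformed network file; message carries the offending line number."""


def _compile_expression(expr: str, lineno: int) -> tuple[list[str], BooleanRule]:
    """Compile a logical expression to (ordered inputs, LUT rule)."""
    pos = 0
    py_tokens: list[str] = []
    variables: list[str] = []
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            if expr[pos:].strip():
                raise NetworkParseError(
                    f"line {lineno}: cannot parse expression at {expr[pos:]!r}")
            break
        tok = m.group(1)
        pos = m.end()
        if tok == "&":
            py_tokens.append(" and ")
        elif tok == "|":
            py_tokens.append(" or ")
        elif tok == "!":
            py_tokens.append(" not ")
        elif tok in "()":
            py_tokens.append(tok)
        elif tok in ("0", "1"):
            py_tokens.append(f" {tok} ")
        else:
            if tok not in variables:
                variables.append(tok)
            py_tokens.append(f" _v[{variables.index(tok)!r}] ")
    py_expr = "".join(py_tokens).strip()
    if not py_expr:
        raise NetworkParseError(f"line {lineno}: empty expression")
    try:
        code = compile(py_expr, f"<expression line {lineno}>", "eval")
    except SyntaxError as exc:
        raise NetworkParseError(
            f"line {lineno}: malformed expression {expr.strip()!r}") from exc
    k = len(variables)
    outputs = []
    for row in range(1 << k):
        _v = {i: (row >> (k - 1 - i)) & 1 for i in range(k)}
        try:
            outputs.append(1 if eval(code, {"__builtins__": {}}, {"_v": _v})
                           else 0)
        except Exception as exc:  # pragma: no cover - defensive
            raise NetworkParseError(f"line {lineno}: {exc}") from exc
    if k == 0:
        # constant expression: model as a self-loop node pinned by its rule
        return [], BooleanRule(0, tuple(outputs))
    return variables, BooleanRule(k, tuple(outputs))


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse logical-expression lines into a network."""
    targets: list[str] = []
    exprs: dict[str, tuple[list[str], BooleanRule]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise NetworkParseError(
                f"line {lineno}: expected 'target, expression'")
        target, expr = line.split(",", 1)
        target = target.strip()
        if not _IDENT.fullmatch(target):
            raise NetworkParseError(f"line {lineno}: bad target name {target!r}")
        if target in exprs:
            raise NetworkParseError(f"line {lineno}: duplicate target {target!r}")
        inputs, rule = _compile_expression(expr, lineno)
        if rule.k == 0:
            # constant target: self-loop with a constant rule of arity 1
            inputs, rule = [target], BooleanRule(1, (rule.outputs[0],) * 2)
        targets.append(target)
        exprs[target] = (inputs, rule)
    if not targets:
        raise NetworkParseError("no rules found")
    # regulators never defined as targets become self-loop input nodes
    names = list(targets)
    for target in targets:
        for regulator in exprs[target][0]:
            if regulator not in exprs:
                exprs[regulator] = ([regulator], BooleanRule(1, (0, 1)))
                names.append(regulator)
    index = {name: i for i, name in enumerate(names)}
    inputs = [tuple(index[r] for r in exprs[name][0]) for name in names]
    rules = [exprs[name][1] for name in names]
    return BooleanNetwork(inputs=inputs, rules=rules, names=names)


def parse_truth_table(text: str) -> BooleanNetwork:
    """Parse tab-separated ``node / inputs / output-bits`` records."""
    rows: list[tuple[str, list[str], str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise NetworkParseError(
                f"line {lineno}: expected 3 tab-separated fields, "
                f"got {len(parts)}")
        name, inputs_field, bits = (p.strip() for p in parts)
        inputs = [s.strip() for s in inputs_field.split(",") if s.strip()]
        if not inputs:
            raise NetworkParseError(f"line {lineno}: node {name!r} has no inputs")
        if set(bits) - {"0", "1"} or len(bits) != 1 << len(inputs):
            raise NetworkParseError(
                f"line {lineno}: output string must be {1 << len(inputs)} "
                f"bits for {len(inputs)} inputs")
        rows.append((name, inputs, bits))
    if not rows:
        raise NetworkParseError("no records found")
    names = [name for name, _, _ in rows]
    index = {name: i for i, name in enumerate(names)}
    defined = set(names)
    for _, inputs, _ in rows:
        for r in inputs:
            if r not in defined:
                names.append(r)
                index[r] = len(index)
                defined.add(r)
                rows.append((r, [r], "01"))
    inputs_idx = [tuple(index[r] for r in inputs) for _, inputs, _ in rows]
    rules = [rule_from_string(bits) for _, _, bits in rows]
    return BooleanNetwork(inputs=inputs_idx, rules=rules, names=names)


def read_network(path: str | Path, format: str | None = None) -> BooleanNetwork:
    """Load a network; format inferred from the suffix unless given.

    ``format`` is ``"bnet"`` (logical expressions) or ``"table"``
    (truth-table records); ``.bnet`` files default to the former.
    """
    path = Path(path)
    if format is None:
        format = "bnet" if path.suffix.lower() == ".bnet" else "table"
    text = path.read_text()
    if format == "bnet":
        return parse_bnet(text)
    if format == "table":
        return parse_truth_table(text)
    raise ValueError(f"unknown format {format!r}")


def _expression_for(net: BooleanNetwork, i: int) -> str:
    from .canalization import prime_schemata  # local import, avoids cycle

    rule = net.rules[i]
    names = [net.names[j] for j in net.inputs[i]]
    on, _ = prime_schemata(rule)
    if not on:
        return "0"
    terms = []
    for schema in on:
        lits = [
            name if ch == "1" else f"!{name}"
            for name, ch in zip(names, schema.pattern)
            if ch != "#"
        ]
        terms.append(" & ".join(lits) if lits else "1")
    if any(t == "1" for t in terms):
        return "1"
    return " | ".join(f"({t})" if " & " in t and len(terms) > 1 else t
                      for t in terms)


def write_network(net: BooleanNetwork, path: str | Path,
                  format: str = "table") -> None:
    """Serialize a network; the truth-table format round-trips bit-exactly."""
    path = Path(path)
    lines: list[str] = []
    if format == "table":
        lines.append("# node\tinputs\toutputs (lexicographic, first input "
                     "most significant)")
        for i in range(net.n):
            inputs = ",".join(net.names[j] for j in net.inputs[i])
            lines.append(f"{net.names[i]}\t{inputs}\t"
                         f"{net.rules[i].to_bitstring()}")
    elif format == "bnet":
        lines.append("targets, factors")
        for i in range(net.n):
            lines.append(f"{net.names[i]}, {_expression_for(net, i)}")
    else:
        raise ValueError(f"unknown format {format!r}")
    path.write_text("\n".join(lines) + "\n")
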
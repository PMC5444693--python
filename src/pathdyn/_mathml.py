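"""Content-MathML <-> sympy conversion for the kinetic-law core subset.

Supported operators: plus, minus (unary and binary), times, divide, power.
Supported leaves: <ci> (identifiers), <cn> (real / integer / e-notation /
rational), and the SBML time csymbol, mapped to :data:`TIME`.  Anything else
(piecewise, delay, functions, logic) raises
:class:`~pathdyn.errors.UnsupportedFeatureError` naming the construct.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import sympy

from .errors import SBMLFormatError, UnsupportedFeatureError

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"

#: canonical symbol for simulation time (minutes)
TIME = sympy.Symbol("_time")

_OPS = {"plus", "minus", "times", "divide", "power"}


def _tag(el: ET.Element) -> str:
    return el.tag.rsplit("}", 1)[-1]


def parse_mathml(math_el: ET.Element) -> sympy.Expr:
    """Parse a ``<math>`` element (or a bare operand element) to sympy."""
    if _tag(math_el) == "math":
        children = [c for c in math_el]
        if len(children) != 1:
            raise SBMLFormatError("<math> must contain exactly one expression")
        return _parse(children[0])
    return _parse(math_el)


def _parse(el: ET.Element) -> sympy.Expr:
    tag = _tag(el)
    if tag == "ci":
        return sympy.Symbol((el.text or "").strip())
    if tag == "cn":
        return _parse_cn(el)
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        if url == TIME_URL:
            return TIME
        raise UnsupportedFeatureError(f"csymbol '{url}' is not supported")
    if tag == "apply":
        children = [c for c in el]
        if not children:
            raise SBMLFormatError("empty <apply>")
        op = _tag(children[0])
        args = [_parse(c) for c in children[1:]]
        if op not in _OPS:
            raise UnsupportedFeatureError(f"MathML construct '{op}' is not supported")
        return _apply(op, args)
    if tag == "piecewise":
        raise UnsupportedFeatureError("MathML construct 'piecewise' is not supported")
    raise UnsupportedFeatureError(f"MathML construct '{tag}' is not supported")


def _parse_cn(el: ET.Element) -> sympy.Expr:
    ctype = el.get("type", "real")
    text = (el.text or "").strip()
    if ctype == "integer":
        return sympy.Integer(int(text))
    if ctype in ("real", ""):
        return sympy.Float(text) if "." in text or "e" in text.lower() else sympy.Integer(int(text))
    if ctype == "e-notation":
        sep = el.find(f"{{{MATHML_NS}}}sep")
        if sep is None:
            raise SBMLFormatError("e-notation <cn> missing <sep/>")
        mantissa = text
        exponent = (sep.tail or "").strip()
        return sympy.Float(f"{mantissa}e{exponent}")
    if ctype == "rational":
        sep = el.find(f"{{{MATHML_NS}}}sep")
        if sep is None:
            raise SBMLFormatError("rational <cn> missing <sep/>")
        return sympy.Rational(int(text), int((sep.tail or "").strip()))
    raise UnsupportedFeatureError(f"<cn type='{ctype}'> is not supported")


def _apply(op: str, args: list[sympy.Expr]) -> sympy.Expr:
    if op == "plus":
        return sympy.Add(*args) if args else sympy.Integer(0)
    if op == "minus":
        if len(args) == 1:
            return -args[0]
        if len(args) == 2:
            return args[0] - args[1]
        raise SBMLFormatError("minus takes one or two operands")
    if op == "times":
        return sympy.Mul(*args) if args else sympy.Integer(1)
    if op == "divide":
        if len(args) != 2:
            raise SBMLFormatError("divide takes exactly two operands")
        return args[0] / args[1]
    if op == "power":
        if len(args) != 2:
            raise SBMLFormatError("power takes exactly two operands")
        return sympy.Pow(args[0], args[1])
    raise UnsupportedFeatureError(op)  # unreachable


def to_mathml(expr: sympy.Expr) -> ET.Element:
    """Serialize a sympy expression to a namespaced ``<math>`` element."""
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(_emit(sympy.sympify(expr)))
    return math


def _emit(expr: sympy.Expr) -> ET.Element:
    ns = f"{{{MATHML_NS}}}"
    if expr is TIME or expr == TIME:
        el = ET.Element(ns + "csymbol", {"encoding": "text", "definitionURL": TIME_URL})
        el.text = "time"
        return el
    if isinstance(expr, sympy.Symbol):
        el = ET.Element(ns + "ci")
        el.text = f" {expr.name} "
        return el
    if isinstance(expr, sympy.Integer):
        el = ET.Element(ns + "cn", {"type": "integer"})
        el.text = str(int(expr))
        return el
    if isinstance(expr, sympy.Rational):
        return _emit_apply("divide", [sympy.Integer(expr.p), sympy.Integer(expr.q)])
    if isinstance(expr, (sympy.Float, sympy.Number)):
        el = ET.Element(ns + "cn")
        el.text = repr(float(expr))
        return el
    if isinstance(expr, sympy.Add):
        return _emit_apply("plus", list(expr.args))
    if isinstance(expr, sympy.Mul):
        num, den = expr.as_numer_denom()
        if den != 1:
            return _emit_apply("divide", [num, den])
        return _emit_apply("times", list(expr.args))
    if isinstance(expr, sympy.Pow):
        base, exp = expr.args
        if exp == -1:
            return _emit_apply("divide", [sympy.Integer(1), base])
        return _emit_apply("power", [base, exp])
    raise UnsupportedFeatureError(
        f"cannot serialize expression node of type {type(expr).__name__}"
    )


def _emit_apply(op: str, args: list[sympy.Expr]) -> ET.Element:
    ns = f"{{{MATHML_NS}}}"
    apply = ET.Element(ns + "apply")
    apply.append(ET.Element(ns + op))
    for a in args:
        apply.append(_emit(sympy.sympify(a)))
    return apply
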
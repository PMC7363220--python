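"""SBML Level 3 qual import/export, with an extension for parametrised models.

Boolean variables map to qualitative species with ``maxLevel="1"``; update
functions map to transition function terms in MathML.  A variable ``A`` is
referenced as ``<apply><eq/><ci>A</ci><cn>1</cn></apply>``; the logical
connectives use the standard MathML ``and``/``or``/``xor``/``not``/
``implies`` (``<=>`` is an ``eq`` of two Boolean sub-terms).  Applications
of uninterpreted functions are encoded as MathML ``csymbol`` applications
with ``definitionURL="urn:bnbif:uninterpreted-function"`` — parameter-free
documents contain no such symbol and use only the restricted MathML subset
of the qual package.

Regulation signs map to the ``qual:sign`` attribute of transition inputs
(``positive`` / ``negative`` / ``unknown``).  Observability-not-required and
the parameter declaration order are stored inside SBML ``<annotation>``
elements under the ``urn:bnbif:annotations`` namespace, keeping the
document schema-conformant.  Multi-valued species are rejected.
"""

from __future__ import annotations

from lxml import etree

from .expr import App, BinOp, Const, Expr, Not, Var
from .io_native import ModelDocument
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

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
BNBIF_NS = "urn:bnbif:annotations"
CSYMBOL_URL = "urn:bnbif:uninterpreted-function"

_NSMAP = {None: SBML_NS, "qual": QUAL_NS, "bnbif": BNBIF_NS}


class SbmlError(ValueError):
    pass


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


# -- writing ---------------------------------------------------------------


def _math_of(e: Expr, parent: etree._Element) -> None:
    if isinstance(e, Const):
        etree.SubElement(parent, _q(MATHML_NS, "true" if e.value else "false"))
    elif isinstance(e, Var):
        apply = etree.SubElement(parent, _q(MATHML_NS, "apply"))
        etree.SubElement(apply, _q(MATHML_NS, "eq"))
        ci = etree.SubElement(apply, _q(MATHML_NS, "ci"))
        ci.text = e.name
        cn = etree.SubElement(apply, _q(MATHML_NS, "cn"))
        cn.set("type", "integer")
        cn.text = "1"
    elif isinstance(e, Not):
        apply = etree.SubElement(parent, _q(MATHML_NS, "apply"))
        etree.SubElement(apply, _q(MATHML_NS, "not"))
        _math_of(e.operand, apply)
    elif isinstance(e, BinOp):
        tag = {"and": "and", "or": "or", "xor": "xor", "imp": "implies", "iff": "eq"}[e.op]
        apply = etree.SubElement(parent, _q(MATHML_NS, "apply"))
        etree.SubElement(apply, _q(MATHML_NS, tag))
        _math_of(e.left, apply)
        _math_of(e.right, apply)
    elif isinstance(e, App):
        apply = etree.SubElement(parent, _q(MATHML_NS, "apply"))
        csymbol = etree.SubElement(apply, _q(MATHML_NS, "csymbol"))
        csymbol.set("encoding", "text")
        csymbol.set("definitionURL", CSYMBOL_URL)
        csymbol.text = e.param
        for arg in e.args:
            _math_of(arg, apply)
    else:
        raise SbmlError(f"not an expression node: {e!r}")


def write_sbml(doc: ModelDocument) -> bytes:
    n = doc.network
    sbml = etree.Element(
        _q(SBML_NS, "sbml"), nsmap=_NSMAP, attrib={"level": "3", "version": "1"}
    )
    sbml.set(_q(QUAL_NS, "required"), "true")
    model = etree.SubElement(sbml, _q(SBML_NS, "model"))
    model.set("id", "model_1")

    if doc.annotations or n.parameters:
        annotation = etree.SubElement(model, _q(SBML_NS, "annotation"))
        extra = etree.SubElement(annotation, _q(BNBIF_NS, "model"))
        for key, value in doc.annotations.items():
            entry = etree.SubElement(extra, _q(BNBIF_NS, "entry"))
            entry.set("key", key)
            entry.set("value", value)
        for decl in n.parameters:
            param = etree.SubElement(extra, _q(BNBIF_NS, "parameter"))
            param.set("name", decl.name)
            param.set("arity", str(decl.arity))

    compartments = etree.SubElement(model, _q(SBML_NS, "listOfCompartments"))
    comp = etree.SubElement(compartments, _q(SBML_NS, "compartment"))
    comp.set("id", "comp1")
    comp.set("constant", "true")

    species_list = etree.SubElement(model, _q(QUAL_NS, "listOfQualitativeSpecies"))
    for name in n.variables:
        sp = etree.SubElement(species_list, _q(QUAL_NS, "qualitativeSpecies"))
        sp.set(_q(QUAL_NS, "id"), name)
        sp.set(_q(QUAL_NS, "compartment"), "comp1")
        sp.set(_q(QUAL_NS, "constant"), "false")
        sp.set(_q(QUAL_NS, "maxLevel"), "1")

    transitions = etree.SubElement(model, _q(QUAL_NS, "listOfTransitions"))
    for name in n.variables:
        tr = etree.SubElement(transitions, _q(QUAL_NS, "transition"))
        tr.set(_q(QUAL_NS, "id"), f"tr_{name}")
        regs = [r for r in n.regulations if r.target == name]
        if regs:
            inputs = etree.SubElement(tr, _q(QUAL_NS, "listOfInputs"))
            for reg in sorted(regs, key=lambda r: n.variable_index(r.source)):
                inp = etree.SubElement(inputs, _q(QUAL_NS, "input"))
                inp.set(_q(QUAL_NS, "id"), f"tr_{name}_in_{reg.source}")
                inp.set(_q(QUAL_NS, "qualitativeSpecies"), reg.source)
                inp.set(_q(QUAL_NS, "transitionEffect"), "none")
                sign = {
                    ACTIVATION: "positive",
                    INHIBITION: "negative",
                    MONO_UNKNOWN: "unknown",
                }[reg.monotonicity]
                inp.set(_q(QUAL_NS, "sign"), sign)
                if reg.observable == OBS_UNKNOWN:
                    ann = etree.SubElement(inp, _q(SBML_NS, "annotation"))
                    flag = etree.SubElement(ann, _q(BNBIF_NS, "regulation"))
                    flag.set("observable", "false")
        outputs = etree.SubElement(tr, _q(QUAL_NS, "listOfOutputs"))
        out = etree.SubElement(outputs, _q(QUAL_NS, "output"))
        out.set(_q(QUAL_NS, "id"), f"tr_{name}_out")
        out.set(_q(QUAL_NS, "qualitativeSpecies"), name)
        out.set(_q(QUAL_NS, "transitionEffect"), "assignmentLevel")
        terms = etree.SubElement(tr, _q(QUAL_NS, "listOfFunctionTerms"))
        default = etree.SubElement(terms, _q(QUAL_NS, "defaultTerm"))
        default.set(_q(QUAL_NS, "resultLevel"), "0")
        term = etree.SubElement(terms, _q(QUAL_NS, "functionTerm"))
        term.set(_q(QUAL_NS, "resultLevel"), "1")
        math = etree.SubElement(
            term, _q(MATHML_NS, "math"), nsmap={None: MATHML_NS}
        )
        _math_of(n.update[name], math)

    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# -- reading ---------------------------------------------------------------


def _children(element: etree._Element) -> list[etree._Element]:
    return [c for c in element if isinstance(c.tag, str)]


def _parse_math(element: etree._Element) -> Expr:
    tag = etree.QName(element).localname
    if tag == "math":
        kids = _children(element)
        if len(kids) != 1:
            raise SbmlError("math element must contain exactly one expression")
        return _parse_math(kids[0])
    if tag == "true":
        return Const(True)
    if tag == "false":
        return Const(False)
    if tag == "ci":
        return Var((element.text or "").strip())
    if tag != "apply":
        raise SbmlError(f"unsupported MathML element <{tag}>")
    kids = _children(element)
    if not kids:
        raise SbmlError("empty MathML apply")
    head, args = kids[0], kids[1:]
    op = etree.QName(head).localname
    if op == "csymbol":
        if head.get("definitionURL") != CSYMBOL_URL:
            raise SbmlError(
                f"unsupported csymbol definitionURL {head.get('definitionURL')!r}"
            )
        name = (head.text or "").strip()
        if not name:
            raise SbmlError("csymbol with empty parameter name")
        return App(name, tuple(_parse_math(a) for a in args))
    if op == "not":
        if len(args) != 1:
            raise SbmlError("MathML not takes exactly one operand")
        return Not(_parse_math(args[0]))
    if op in ("and", "or", "xor"):
        if len(args) < 2:
            raise SbmlError(f"MathML {op} needs at least two operands")
        parsed = [_parse_math(a) for a in args]
        out = parsed[-1]
        for left in reversed(parsed[:-1]):
            out = BinOp(op, left, out)
        return out
    if op == "implies":
        if len(args) != 2:
            raise SbmlError("MathML implies takes exactly two operands")
        return BinOp("imp", _parse_math(args[0]), _parse_math(args[1]))
    if op == "eq":
        if len(args) != 2:
            raise SbmlError("MathML eq takes exactly two operands")
        left_tag = etree.QName(args[0]).localname
        right_tag = etree.QName(args[1]).localname
        if left_tag == "ci" and right_tag == "cn":
            level = (args[1].text or "").strip()
            if level not in ("0", "1"):
                raise SbmlError(
                    f"unsupported level {level!r} in species test (Boolean species only)"
                )
            var = Var((args[0].text or "").strip())
            return var if level == "1" else Not(var)
        return BinOp("iff", _parse_math(args[0]), _parse_math(args[1]))
    raise SbmlError(f"unsupported MathML operator <{op}>")


def _qattr(element: etree._Element, name: str) -> str | None:
    value = element.get(_q(QUAL_NS, name))
    if value is None:
        value = element.get(name)
    return value


def read_sbml(data: bytes | str) -> ModelDocument:
    try:
        if isinstance(data, str):
            data = data.encode("utf-8")
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"malformed XML: {exc}") from exc
    if etree.QName(root).localname != "sbml":
        raise SbmlError("not an SBML document (root element is not <sbml>)")
    model = root.find(_q(SBML_NS, "model"))
    if model is None:
        raise SbmlError("SBML document has no <model>")

    annotations: dict[str, str] = {}
    declared_params: list[ParameterDecl] = []
    ann = model.find(_q(SBML_NS, "annotation"))
    if ann is not None:
        extra = ann.find(_q(BNBIF_NS, "model"))
        if extra is not None:
            for entry in extra.findall(_q(BNBIF_NS, "entry")):
                annotations[entry.get("key", "")] = entry.get("value", "")
            for param in extra.findall(_q(BNBIF_NS, "parameter")):
                declared_params.append(
                    ParameterDecl(param.get("name", ""), int(param.get("arity", "0")))
                )

    species_list = model.find(_q(QUAL_NS, "listOfQualitativeSpecies"))
    if species_list is None:
        raise SbmlError("model has no listOfQualitativeSpecies")
    variables: list[str] = []
    for sp in species_list.findall(_q(QUAL_NS, "qualitativeSpecies")):
        name = _qattr(sp, "id")
        if not name:
            raise SbmlError("qualitativeSpecies without an id")
        max_level = _qattr(sp, "maxLevel")
        if max_level is not None and max_level != "1":
            raise SbmlError(
                f"species {name!r} has maxLevel={max_level}; only Boolean "
                "(maxLevel 1) species are supported"
            )
        variables.append(name)
    declared = frozenset(variables)

    regulations: list[Regulation] = []
    update: dict[str, Expr] = {}
    transitions = model.find(_q(QUAL_NS, "listOfTransitions"))
    if transitions is not None:
        for tr in transitions.findall(_q(QUAL_NS, "transition")):
            outputs = tr.find(_q(QUAL_NS, "listOfOutputs"))
            if outputs is None:
                raise SbmlError("transition without outputs")
            outs = outputs.findall(_q(QUAL_NS, "output"))
            if len(outs) != 1:
                raise SbmlError("exactly one output per transition is supported")
            target = _qattr(outs[0], "qualitativeSpecies")
            if target not in declared:
                raise SbmlError(f"transition output references unknown species {target!r}")
            inputs = tr.find(_q(QUAL_NS, "listOfInputs"))
            if inputs is not None:
                for inp in inputs.findall(_q(QUAL_NS, "input")):
                    source = _qattr(inp, "qualitativeSpecies")
                    if source not in declared:
                        raise SbmlError(
                            f"transition input references unknown species {source!r}"
                        )
                    sign = _qattr(inp, "sign") or "unknown"
                    mono = {
                        "positive": ACTIVATION,
                        "negative": INHIBITION,
                        "unknown": MONO_UNKNOWN,
                    }.get(sign)
                    if mono is None:
                        raise SbmlError(f"unsupported input sign {sign!r}")
                    observable = OBS_REQUIRED
                    inp_ann = inp.find(_q(SBML_NS, "annotation"))
                    if inp_ann is not None:
                        flag = inp_ann.find(_q(BNBIF_NS, "regulation"))
                        if flag is not None and flag.get("observable") == "false":
                            observable = OBS_UNKNOWN
                    regulations.append(Regulation(source, target, observable, mono))
            terms = tr.find(_q(QUAL_NS, "listOfFunctionTerms"))
            expr: Expr | None = None
            if terms is not None:
                default = terms.find(_q(QUAL_NS, "defaultTerm"))
                for term in terms.findall(_q(QUAL_NS, "functionTerm")):
                    if _qattr(term, "resultLevel") != "1":
                        raise SbmlError("function terms must assign level 0 or 1")
                    math = term.find(_q(MATHML_NS, "math"))
                    if math is None:
                        raise SbmlError("functionTerm without MathML content")
                    expr = _parse_math(math)
                if expr is None and default is not None:
                    expr = Const(_qattr(default, "resultLevel") == "1")
            if expr is None:
                raise SbmlError(f"transition for {target!r} defines no update function")
            if target in update:
                raise SbmlError(f"species {target!r} has more than one transition")
            update[target] = expr

    missing = declared - set(update)
    if missing:
        raise SbmlError(f"species without transitions: {sorted(missing)}")

    from .expr import parameters_of

    used: dict[str, int] = {}
    for name in variables:
        for pname, arity in parameters_of(update[name]).items():
            if pname in used and used[pname] != arity:
                raise SbmlError(f"parameter {pname!r} used with inconsistent arities")
            used.setdefault(pname, arity)
    if declared_params:
        declared_map = {p.name: p.arity for p in declared_params}
        for pname, arity in used.items():
            if declared_map.get(pname, arity) != arity:
                raise SbmlError(
                    f"parameter {pname!r} declared with arity {declared_map[pname]}, used with {arity}"
                )
        for pname, arity in used.items():
            if pname not in declared_map:
                declared_params.append(ParameterDecl(pname, arity))
        parameters = tuple(declared_params)
    else:
        parameters = tuple(ParameterDecl(n_, a) for n_, a in used.items())

    network = ParametrisedNetwork(tuple(variables), regulations, parameters, update)
    return ModelDocument(network, annotations)
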
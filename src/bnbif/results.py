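"""Results bundle: JSON export of the bifurcation function and attractors.

The bundle is self-contained: it embeds the model (native text), the
parameter-encoder bit layout, and one serialized colour-set BDD per
behaviour class, so external tools can decode assignments and this package
can later extract witness networks without re-running the analysis.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from . import bdd as _bdd
from .analysis import AnalysisResult
from .classify import BehaviourClass, witness as _witness
from .encoding import ColourSet, build_encoder
from .io_native import ModelDocument, read_native, write_native
from .network import BooleanNetwork

FORMAT_NAME = "bnbif-results"
FORMAT_VERSION = 1


class ResultsError(ValueError):
    pass


def export_results(result: AnalysisResult, doc: ModelDocument) -> dict[str, Any]:
    """Build the JSON-serializable results bundle for one analysis."""
    graph = result.graph
    encoder = graph.encoder
    network = graph.network
    classes: list[dict[str, Any]] = []
    if result.bifurcation is not None:
        for cls, colours in sorted(result.bifurcation.classes.items()):
            classes.append(
                {
                    "class": str(cls),
                    "cardinality": str(colours.count()),
                    "colours": colours.serialize().decode("ascii"),
                }
            )
    attractors: list[dict[str, Any]] = []
    for attractor in result.attractors:
        attractors.append(
            {
                "states": [network.state_to_string(s) for s in sorted(attractor.states)],
                "size": attractor.size,
                "colour_cardinality": str(attractor.colours.count()),
                "behaviours": {
                    behaviour: str(colours.count())
                    for behaviour, colours in sorted(attractor.behaviours.items())
                },
            }
        )
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "complete": result.complete,
        "model": write_native(doc),
        "valid_cardinality": str(graph.valid.count()),
        "encoder": {
            "num_bits": encoder.num_bits,
            "bits": [
                {"bit": i, "parameter": name, "row": row}
                for i, (name, row) in enumerate(encoder.bits)
            ],
            "parameters": [
                {"name": p.name, "arity": p.arity} for p in network.parameters
            ],
        },
        "classes": classes,
        "attractors": attractors,
    }


def save_results(bundle: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(bundle, indent=2) + "\n", encoding="utf-8")


def load_results(path: str | Path) -> dict[str, Any]:
    try:
        bundle = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ResultsError(f"not a valid results bundle: {exc}") from exc
    if not isinstance(bundle, dict) or bundle.get("format") != FORMAT_NAME:
        raise ResultsError("not a bnbif results bundle")
    return bundle


def class_colours(bundle: dict[str, Any], class_string: str) -> ColourSet:
    """Deserialize the colour set stored for one behaviour class."""
    for entry in bundle.get("classes", []):
        if entry["class"] == class_string:
            return ColourSet(_bdd.deserialize(entry["colours"]))
    available = [entry["class"] for entry in bundle.get("classes", [])]
    raise ResultsError(
        f"no class {class_string!r} in the bundle; available classes: {available}"
    )


def witness_from_bundle(bundle: dict[str, Any], class_string: str) -> tuple[ModelDocument, BooleanNetwork]:
    """Re-read the embedded model and extract a witness of one class."""
    doc = read_native(bundle["model"])
    encoder = build_encoder(doc.network)
    manifest = [(entry["parameter"], entry["row"]) for entry in bundle["encoder"]["bits"]]
    if manifest != list(encoder.bits):
        raise ResultsError(
            "encoder bit layout in the bundle does not match the embedded model"
        )
    colours = class_colours(bundle, class_string)
    return doc, _witness(doc.network, encoder, colours)
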
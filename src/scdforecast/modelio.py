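"""Lossless JSON (de)serialization of fitted models.

The file carries the registry, learned structure, smoothing hyperparameter,
raw counts and probabilities of every CPT (counts are kept so credible
intervals can resample the parameter posterior after a reload), and a format
version; forward-incompatible versions are rejected.
"""

from __future__ import annotations

import json

import numpy as np

from .core import CPT, DBNModel, ModelFormatError, NetworkStructure, VariableRegistry

FORMAT_VERSION = 1


def _cpt_to_dict(cpt: CPT) -> dict:
    return {
        "child": cpt.child,
        "parents": list(cpt.parents),
        "shape": list(cpt.counts.shape),
        "counts": cpt.counts.reshape(-1).tolist(),
        "probs": cpt.probs.reshape(-1).tolist(),
        "alpha": cpt.alpha,
    }


def _cpt_from_dict(d: dict) -> CPT:
    shape = tuple(d["shape"])
    return CPT(
        child=d["child"],
        parents=tuple(d["parents"]),
        counts=np.asarray(d["counts"], dtype=np.int64).reshape(shape),
        probs=np.asarray(d["probs"], dtype=float).reshape(shape),
        alpha=float(d["alpha"]),
    )


def serialize_model(model: DBNModel, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "registry": model.registry.to_dict(),
        "structure": {
            "intra_parents": {c: list(p) for c, p in model.structure.intra_parents.items()},
            "temporal_vars": sorted(model.structure.temporal_vars),
            "score": model.structure.score,
            "family_scores": dict(model.structure.family_scores),
            "margins": dict(model.structure.margins),
        },
        "alpha": model.alpha,
        "initial": {name: _cpt_to_dict(c) for name, c in model.initial.items()},
        "transition": {name: _cpt_to_dict(c) for name, c in model.transition.items()},
        "deterministic": sorted(model.deterministic),
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def deserialize_model(path) -> DBNModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"not a valid model file: {exc}") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version!r} (expected {FORMAT_VERSION})"
        )
    try:
        registry = VariableRegistry.from_dict(doc["registry"])
        s = doc["structure"]
        structure = NetworkStructure(
            intra_parents={c: tuple(p) for c, p in s["intra_parents"].items()},
            temporal_vars=frozenset(s["temporal_vars"]),
            score=float(s["score"]),
            family_scores=s.get("family_scores", {}),
            margins=s.get("margins", {}),
        )
        model = DBNModel(
            registry=registry,
            structure=structure,
            alpha=float(doc["alpha"]),
            initial={n: _cpt_from_dict(d) for n, d in doc["initial"].items()},
            transition={n: _cpt_from_dict(d) for n, d in doc["transition"].items()},
            deterministic=frozenset(doc.get("deterministic", [])),
            meta=doc.get("meta", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model file: {exc}") from exc
    model.validate()
    return model
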
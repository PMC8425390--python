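"""Native JSON interchange format for PD maps.

This is the lossless interchange of record for the package: a single JSON
document with a ``format_version`` and a serialized map.  Serialization is
canonical (sorted keys, sorted arrays, two-space indent, trailing newline),
so ``write(read(x))`` is byte-stable.  A structural validator reports every
violation with its JSON path; the same rules are documented in the shipped
schema (``pdlint/data/native_map_schema.json``).
"""

from __future__ import annotations

import json
import os
from typing import Any, Union

from pdlint.model import (
    ComplexPool,
    MapModel,
    MapValidationError,
    Process,
    ProteinPool,
    StateVariable,
    MODULATION_CLASSES,
    PROCESS_KINDS,
)

FORMAT_VERSION = "1.0"


class NativeFormatError(ValueError):
    """The document violates the native map schema.

    ``errors`` is a list of (json_path, message) pairs.
    """

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"{path}: {msg}" for path, msg in self.errors)
        super().__init__(f"invalid native map document: {lines}")


def model_to_document(model: MapModel) -> dict[str, Any]:
    """Serialize a MapModel to a plain JSON-compatible dict."""
    pools = []
    for pool in model.protein_pools():
        pools.append(
            {
                "pool_id": pool.pool_id,
                "label": pool.label,
                "protein_key": pool.protein_key,
                "uniprot_ids": sorted(pool.uniprot_ids),
                "is_generic": pool.is_generic,
                "members": sorted(pool.members),
                "state": [
                    {"site": sv.site, "value": sv.value}
                    for sv in sorted(pool.state, key=lambda s: s.site)
                ],
                "compartment": pool.compartment,
            }
        )
    complexes = []
    for cx in model.complex_pools():
        complexes.append(
            {
                "pool_id": cx.pool_id,
                "components": sorted(cx.components),
                "compartment": cx.compartment,
            }
        )
    processes = []
    for proc in (model.processes[k] for k in sorted(model.processes)):
        processes.append(
            {
                "process_id": proc.process_id,
                "kind": proc.kind,
                "reactants": sorted(proc.reactants),
                "products": sorted(proc.products),
                "modulators": sorted(
                    ({"pool": pid, "class": cls} for pid, cls in proc.modulators),
                    key=lambda m: (m["pool"], m["class"]),
                ),
            }
        )
    return {
        "format_version": FORMAT_VERSION,
        "map": {
            "map_name": model.map_name,
            "compartments": sorted(model.compartments),
            "pools": pools,
            "complexes": complexes,
            "processes": processes,
            "provenance": model.provenance,
        },
    }


# -- structural validation -----------------------------------------------------


def _expect(errors, cond, path, msg):
    if not cond:
        errors.append((path, msg))
    return cond


def validate_document(doc: Any) -> None:
    """Structurally validate a native map document; raise on any violation."""
    errors: list[tuple[str, str]] = []
    if not _expect(errors, isinstance(doc, dict), "$", "document must be an object"):
        raise NativeFormatError(errors)
    _expect(
        errors,
        isinstance(doc.get("format_version"), str),
        "$.format_version",
        "missing or non-string",
    )
    mp = doc.get("map")
    if not _expect(errors, isinstance(mp, dict), "$.map", "missing or not an object"):
        raise NativeFormatError(errors)
    _expect(
        errors,
        isinstance(mp.get("map_name"), str) and mp.get("map_name"),
        "$.map.map_name",
        "must be a non-empty string",
    )
    for key in ("pools", "complexes", "processes", "compartments"):
        _expect(
            errors,
            isinstance(mp.get(key), list),
            f"$.map.{key}",
            "missing or not an array",
        )
    for i, pool in enumerate(mp.get("pools") or []):
        path = f"$.map.pools[{i}]"
        if not _expect(errors, isinstance(pool, dict), path, "must be an object"):
            continue
        for fld in ("pool_id", "label", "protein_key", "compartment"):
            _expect(
                errors,
                isinstance(pool.get(fld), str),
                f"{path}.{fld}",
                "missing or non-string",
            )
        _expect(
            errors,
            isinstance(pool.get("is_generic"), bool),
            f"{path}.is_generic",
            "missing or non-boolean",
        )
        for fld in ("uniprot_ids", "members", "state"):
            _expect(
                errors,
                isinstance(pool.get(fld), list),
                f"{path}.{fld}",
                "missing or not an array",
            )
        for j, sv in enumerate(pool.get("state") or []):
            spath = f"{path}.state[{j}]"
            if not _expect(errors, isinstance(sv, dict), spath, "must be an object"):
                continue
            _expect(
                errors,
                isinstance(sv.get("site"), str) and sv.get("site"),
                f"{spath}.site",
                "must be a non-empty string",
            )
            _expect(
                errors,
                isinstance(sv.get("value"), str),
                f"{spath}.value",
                "missing or non-string",
            )
    for i, cx in enumerate(mp.get("complexes") or []):
        path = f"$.map.complexes[{i}]"
        if not _expect(errors, isinstance(cx, dict), path, "must be an object"):
            continue
        _expect(
            errors,
            isinstance(cx.get("pool_id"), str),
            f"{path}.pool_id",
            "missing or non-string",
        )
        comps = cx.get("components")
        _expect(
            errors,
            isinstance(comps, list) and len(comps) >= 1,
            f"{path}.components",
            "must be a non-empty array",
        )
    for i, proc in enumerate(mp.get("processes") or []):
        path = f"$.map.processes[{i}]"
        if not _expect(errors, isinstance(proc, dict), path, "must be an object"):
            continue
        _expect(
            errors,
            isinstance(proc.get("process_id"), str),
            f"{path}.process_id",
            "missing or non-string",
        )
        _expect(
            errors,
            proc.get("kind") in PROCESS_KINDS,
            f"{path}.kind",
            f"must be one of {sorted(PROCESS_KINDS)}",
        )
        for fld in ("reactants", "products", "modulators"):
            _expect(
                errors,
                isinstance(proc.get(fld), list),
                f"{path}.{fld}",
                "missing or not an array",
            )
        for j, mod in enumerate(proc.get("modulators") or []):
            mpath = f"{path}.modulators[{j}]"
            if not _expect(errors, isinstance(mod, dict), mpath, "must be an object"):
                continue
            _expect(
                errors,
                isinstance(mod.get("pool"), str),
                f"{mpath}.pool",
                "missing or non-string",
            )
            _expect(
                errors,
                mod.get("class") in MODULATION_CLASSES,
                f"{mpath}.class",
                f"must be one of {sorted(MODULATION_CLASSES)}",
            )
    if errors:
        raise NativeFormatError(errors)


def document_to_model(doc: Any, map_name: str | None = None) -> MapModel:
    """Deserialize (and validate) a native map document into a MapModel."""
    validate_document(doc)
    mp = doc["map"]
    model = MapModel(
        map_name=map_name or mp["map_name"],
        provenance=mp.get("provenance", ""),
    )
    model.compartments.update(mp.get("compartments") or [])
    for pool in mp["pools"]:
        model.add_protein(
            ProteinPool(
                pool_id=pool["pool_id"],
                label=pool["label"],
                protein_key=pool["protein_key"],
                uniprot_ids=frozenset(pool["uniprot_ids"]),
                is_generic=pool["is_generic"],
                members=frozenset(pool["members"]),
                state=frozenset(
                    StateVariable(sv["site"], sv["value"]) for sv in pool["state"]
                ),
                compartment=pool["compartment"],
            )
        )
    for cx in mp["complexes"]:
        model.add_complex(
            ComplexPool(
                pool_id=cx["pool_id"],
                components=tuple(cx["components"]),
                compartment=cx.get("compartment", "default"),
            )
        )
    for proc in mp["processes"]:
        model.add_process(
            Process(
                process_id=proc["process_id"],
                kind=proc["kind"],
                reactants=tuple(proc["reactants"]),
                products=tuple(proc["products"]),
                modulators=tuple(
                    (m["pool"], m["class"]) for m in proc["modulators"]
                ),
            )
        )
    return model.validate()


def dumps(model: MapModel) -> str:
    """Canonical serialization of a model (byte-stable)."""
    return json.dumps(model_to_document(model), indent=2, sort_keys=True) + "\n"


def write_native(model: MapModel, path: Union[str, os.PathLike]) -> None:
    model.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps(model))


def read_native(path: Union[str, os.PathLike], map_name: str | None = None) -> MapModel:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NativeFormatError([("$", f"not valid JSON: {exc}")]) from exc
    model = document_to_model(doc, map_name=map_name)
    if not model.provenance:
        model.provenance = str(path)
    return model
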
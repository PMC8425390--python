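"""Extension-based format dispatch for reading/writing maps."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

from pdlint.model import MapModel
from pdlint.io.celldesigner import read_celldesigner, write_celldesigner
from pdlint.io.native import read_native, write_native

_CELLDESIGNER_EXTS = {".xml", ".sbml"}
_NATIVE_EXTS = {".json"}


def read_map(path: Union[str, os.PathLike], map_name: Optional[str] = None) -> MapModel:
    """Read a map, choosing the format from the file extension."""
    ext = Path(path).suffix.lower()
    if ext in _CELLDESIGNER_EXTS:
        return read_celldesigner(path, map_name=map_name)
    if ext in _NATIVE_EXTS:
        return read_native(path, map_name=map_name)
    raise ValueError(
        f"unrecognized map extension {ext!r} for {path}; expected one of "
        f"{sorted(_CELLDESIGNER_EXTS | _NATIVE_EXTS)}"
    )


def write_map(model: MapModel, path: Union[str, os.PathLike]) -> None:
    """Write a map, choosing the format from the file extension."""
    ext = Path(path).suffix.lower()
    if ext in _CELLDESIGNER_EXTS:
        write_celldesigner(model, path)
    elif ext in _NATIVE_EXTS:
        write_native(model, path)
    else:
        raise ValueError(f"unrecognized map extension {ext!r} for {path}")
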
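"""Model checkpoint container: config + named parameter arrays (npz)."""

from __future__ import annotations

import json

import numpy as np

from .errors import ConfigurationError

FORMAT_VERSION = 1


def save_checkpoint(path, kind: str, config_dict: dict, params) -> None:
    arrays = {f"param/{p.name}": p.value for p in params}
    header = json.dumps({"format_version": FORMAT_VERSION, "kind": kind, "config": config_dict})
    np.savez(path, __header__=np.array(header), **arrays)


def load_checkpoint(path) -> tuple[str, dict, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["__header__"]))
        if header.get("format_version") != FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint format version {header.get('format_version')!r}"
            )
        arrays = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return header["kind"], header["config"], arrays


def restore_params(params, arrays: dict[str, np.ndarray]) -> None:
    for p in params:
        if p.name not in arrays:
            raise ConfigurationError(f"checkpoint is missing parameter {p.name!r}")
        if arrays[p.name].shape != p.value.shape:
            raise ConfigurationError(
                f"checkpoint parameter {p.name!r} has shape {arrays[p.name].shape}, "
                f"expected {p.value.shape}"
            )
        p.value[...] = arrays[p.name]
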
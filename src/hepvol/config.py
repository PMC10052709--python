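"""YAML configuration for phantom specs and study designs.

The phantom config is a flat key-value mapping with one nested
``observer_noise`` block, mirroring :class:`~hepvol.phantom.PhantomSpec`
field-for-field; round-tripping through :func:`save_phantom_config` /
:func:`load_phantom_config` is lossless.  Unknown keys are rejected with
the offending names listed.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError
from .phantom import PhantomSpec
from .study import DEFAULT_BIN_EDGES, StudyDesign, default_groups
from .volumetry import DecimationScheme


def load_phantom_config(path: str | Path) -> PhantomSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return PhantomSpec()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: phantom config must be a mapping")
    return PhantomSpec.from_dict(data)


def save_phantom_config(spec: PhantomSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


_DESIGN_KEYS = {"groups", "n_observers", "bin_edges"}


def load_design_config(path: str | Path) -> StudyDesign:
    """Study design from YAML.

    ``groups`` is a list of ``{thickness_mm, interval_mm}`` mappings
    (``interval_mm == thickness_mm`` is the full group); omitted keys fall
    back to the default design.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return StudyDesign()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: design config must be a mapping")
    unknown = sorted(set(data) - _DESIGN_KEYS)
    if unknown:
        raise ConfigError(f"unknown design config keys: {unknown}")
    if "groups" in data:
        groups = []
        for g in data["groups"]:
            extra = sorted(set(g) - {"thickness_mm", "interval_mm"})
            if extra:
                raise ConfigError(f"unknown group keys: {extra}")
            try:
                groups.append(
                    DecimationScheme(g["thickness_mm"] / 10.0, g["interval_mm"] / 10.0)
                )
            except KeyError as e:
                raise ConfigError(f"group entry missing key: {e}") from e
        groups = tuple(groups)
    else:
        groups = default_groups()
    return StudyDesign(
        groups=groups,
        n_observers=int(data.get("n_observers", 3)),
        bin_edges=tuple(data.get("bin_edges", DEFAULT_BIN_EDGES)),
    )


def save_design_config(design: StudyDesign, path: str | Path) -> None:
    data = {
        "groups": [
            {"thickness_mm": g.thickness_cm * 10.0, "interval_mm": g.interval_cm * 10.0}
            for g in design.groups
        ],
        "n_observers": design.n_observers,
        "bin_edges": list(design.bin_edges),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
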
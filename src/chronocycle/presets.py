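"""Named cell-cycle parameter presets and their YAML serialisation.

Three presets ship with the package: ``host`` (bone-marrow-like blood cell
progenitors), ``tumor_fast`` (colorectal cancer cells with a short S phase)
and ``tumor_slow`` (long S phase).  Their kinetic values were fixed by the
calibration procedure in :mod:`chronocycle.experiments` against the daily
S-phase-fraction ranges and peak times the three populations are meant to
display (see docs/methods.md); each YAML carries its calibration report.
"""

from __future__ import annotations

from dataclasses import fields
from importlib import resources
from pathlib import Path

import yaml

from .model import CellCyclePreset

_FIELD_NAMES = tuple(f.name for f in fields(CellCyclePreset))
BUILTIN = ("host", "tumor_fast", "tumor_slow")


def preset_to_dict(preset: CellCyclePreset) -> dict:
    return {name: getattr(preset, name) for name in _FIELD_NAMES}


def save_preset(preset: CellCyclePreset, path, extra: dict | None = None) -> None:
    doc = preset_to_dict(preset)
    if extra:
        doc["_meta"] = extra
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _from_mapping(doc: dict, source: str) -> CellCyclePreset:
    doc = dict(doc)
    doc.pop("_meta", None)
    unknown = set(doc) - set(_FIELD_NAMES)
    if unknown:
        raise ValueError(f"unknown preset keys in {source}: {sorted(unknown)}")
    return CellCyclePreset(**doc)


def load_preset(name_or_path: str) -> CellCyclePreset:
    """Load a preset by built-in name (host, tumor_fast, tumor_slow) or path.

    The loader validates all invariants and rejects unknown keys.
    """
    if name_or_path in BUILTIN:
        ref = resources.files("chronocycle") / "presets" / f"{name_or_path}.yaml"
        doc = yaml.safe_load(ref.read_text())
        return _from_mapping(doc, name_or_path)
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"no such preset: {name_or_path!r} (built-ins: {', '.join(BUILTIN)})")
    return _from_mapping(yaml.safe_load(path.read_text()), str(path))


def schedule_to_dict(schedule) -> dict:
    return {f.name: getattr(schedule, f.name) for f in fields(type(schedule))}


def load_schedule(path):
    from .treatment import Schedule

    doc = yaml.safe_load(Path(path).read_text())
    allowed = {f.name for f in fields(Schedule)}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown schedule keys in {path}: {sorted(unknown)}")
    return Schedule(**doc)
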
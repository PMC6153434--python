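"""Provenance-tagged parameter registry.

Every number a simulation consumes resolves to exactly one named entry with
declared units, a provenance tag (``PAPER`` for published values, ``ASSUMED``
for defaults chosen here, ``FITTED`` for values estimated by the calibration
module) and a citation string.  Values are stored in internal units
(uM, um, s); the declared units are kept for round-tripping.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import yaml

from . import units as _units

PROVENANCES = ("PAPER", "ASSUMED", "FITTED")


@dataclass(frozen=True)
class ParameterEntry:
    name: str
    value: float | str
    units: str
    provenance: str
    cite: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"{self.name}: provenance must be one of {PROVENANCES}")

    @property
    def declared_value(self) -> float | str:
        if isinstance(self.value, str):
            return self.value
        return _units.from_internal(self.value, self.units)


class MissingParameterError(KeyError):
    def __init__(self, names: Iterable[str]):
        self.names = sorted(names)
        super().__init__("missing parameters: " + ", ".join(self.names))


class ParameterRegistry:
    """Mapping of parameter name -> :class:`ParameterEntry`."""

    def __init__(self, entries: Iterable[ParameterEntry] = ()):
        self.entries: dict[str, ParameterEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ParameterEntry) -> None:
        if entry.name in self.entries:
            raise ValueError(f"duplicate parameter name {entry.name!r}")
        self.entries[entry.name] = entry

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> ParameterEntry:
        try:
            return self.entries[name]
        except KeyError:
            raise MissingParameterError([name]) from None

    def value(self, name: str) -> float | str:
        return self[name].value

    def get(self, name: str, default=None):
        e = self.entries.get(name)
        return default if e is None else e.value

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.entries]
        if missing:
            raise MissingParameterError(missing)

    def patch(self, updates: Mapping[str, float],
              provenance: str = "FITTED", cite: str = "") -> "ParameterRegistry":
        """Return a new registry with ``updates`` (internal units) applied."""
        reg = ParameterRegistry(self.entries.values())
        for name, value in updates.items():
            base = reg[name]
            reg.entries[name] = replace(base, value=float(value),
                                        provenance=provenance,
                                        cite=cite or base.cite)
        return reg

    def assumed(self) -> list[str]:
        """Names of every ASSUMED entry (for run-manifest logging)."""
        return sorted(n for n, e in self.entries.items()
                      if e.provenance == "ASSUMED")

    def fully_constrained(self, names: Iterable[str]) -> bool:
        """True if every named entry is PAPER or FITTED (no ASSUMED)."""
        return all(self[n].provenance != "ASSUMED" for n in names)

    def manifest(self) -> dict:
        """JSON-serialisable dump (declared units) for run manifests."""
        return {n: {"value": e.declared_value, "units": e.units,
                    "provenance": e.provenance, "cite": e.cite}
                for n, e in sorted(self.entries.items())}


def _leaf(name: str, node: object) -> ParameterEntry:
    if isinstance(node, Mapping):
        if "value" not in node or "units" not in node:
            raise ValueError(f"{name}: leaves must declare 'value' and 'units'")
        raw = node["value"]
        unit = str(node["units"])
        value = raw if isinstance(raw, str) else _units.to_internal(float(raw), unit)
        return ParameterEntry(name, value, unit,
                              str(node.get("provenance", "ASSUMED")),
                              str(node.get("cite", "")))
    raise ValueError(
        f"{name}: bare values are not accepted; use "
        "{{value, units, provenance, cite}}")


def _flatten(prefix: str, node: object, out: list[ParameterEntry]) -> None:
    if isinstance(node, Mapping) and "value" in node:
        out.append(_leaf(prefix, node))
        return
    if isinstance(node, Mapping):
        for key, sub in node.items():
            _flatten(f"{prefix}.{key}" if prefix else str(key), sub, out)
        return
    if isinstance(node, list):
        for item in node:
            if not isinstance(item, Mapping) or "name" not in item:
                raise ValueError(f"{prefix}: list items must carry a 'name'")
            sub = {k: v for k, v in item.items() if k != "name"}
            _flatten(f"{prefix}.{item['name']}", sub, out)
        return
    if isinstance(node, str):
        out.append(ParameterEntry(prefix, node, "", "ASSUMED", "structural"))
        return
    raise ValueError(f"{prefix}: bare value {node!r} not accepted; declare units")


def load_parameter_registry(source=None) -> ParameterRegistry:
    """Load a registry from a YAML file (path or file object).

    With no argument the packaged default parameter set is loaded.  The YAML
    schema has top-level sections (``parameters``, ``solutes``, ``cell_lines``,
    ``kill_models``, ``geometry``); every leaf must be a
    ``{value, units, provenance, cite}`` mapping — bare numbers are rejected.
    """
    if source is None:
        ref = importlib.resources.files("hapabm").joinpath("params/default.yaml")
        text = ref.read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValueError("parameter file must be a mapping")
    out: list[ParameterEntry] = []
    section_prefix = {"parameters": "", "solutes": "solute",
                      "cell_lines": "line", "kill_models": "kill",
                      "geometry": "geometry"}
    for section, node in doc.items():
        prefix = section_prefix.get(section, section)
        _flatten(prefix, node, out)
    return ParameterRegistry(out)
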
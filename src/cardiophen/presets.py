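"""Named parameter presets encoding the study's printed group means.

Each preset bundles the published group-mean values for one measurement
modality (calcium kinetics, patch-clamp APD, Poincare axis ratio, micropost
twitch force, mitostress OCR metrics, cell area) together with the units and
the location of the printed number.  The synthetic generators in
:mod:`cardiophen.synth` consume these presets so that every analysis stage can
be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["Preset", "PresetParameter", "load_presets", "get_preset", "list_presets"]


@dataclass(frozen=True)
class PresetParameter:
    """A single target value with its units."""

    value: float
    units: str


@dataclass(frozen=True)
class Preset:
    """A named bundle of target parameters for one modality.

    Attributes
    ----------
    name : str
        Group label, e.g. ``"WT_12D_GlcFA"`` or ``"EV"``.
    modality : str
        Measurement family the preset parameterises
        (``calcium``, ``patch``, ``rhythm``, ``micropost``, ``mitostress``,
        ``area``).
    parameters : dict
        Mapping from metric name to :class:`PresetParameter`.
    source : str
        Where the printed value comes from.
    """

    name: str
    modality: str
    parameters: dict[str, PresetParameter] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for key, par in self.parameters.items():
            if not isinstance(par, PresetParameter):
                raise TypeError(f"parameter {key!r} is not a PresetParameter")
            if not par.units:
                raise ValueError(f"parameter {key!r} has no units")

    def value(self, key: str) -> float:
        return self.parameters[key].value


def _load_raw() -> dict:
    text = resources.files("cardiophen.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def load_presets() -> dict[tuple[str, str], Preset]:
    """Load the full preset registry keyed by ``(modality, name)``."""
    registry: dict[tuple[str, str], Preset] = {}
    for modality, entries in _load_raw().items():
        for name, spec in entries.items():
            params = {
                key: PresetParameter(float(p["value"]), str(p["units"]))
                for key, p in spec["parameters"].items()
            }
            key = (modality, name)
            if key in registry:  # pragma: no cover - guarded by YAML structure
                raise ValueError(f"duplicate preset {key}")
            registry[key] = Preset(
                name=name, modality=modality, parameters=params, source=spec["source"]
            )
    return registry


def list_presets(modality: str | None = None) -> list[Preset]:
    """All presets, optionally restricted to one modality."""
    return [
        p
        for (mod, _), p in load_presets().items()
        if modality is None or mod == modality
    ]


def get_preset(modality: str, name: str) -> Preset:
    """Look up one preset; raises ``KeyError`` with the known names on miss."""
    registry = load_presets()
    try:
        return registry[(modality, name)]
    except KeyError:
        known = sorted(n for (m, n) in registry if m == modality)
        raise KeyError(
            f"no preset {name!r} for modality {modality!r}; known: {known}"
        ) from None
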
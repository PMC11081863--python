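"""Day-night (zeitgeber-time) conductance-scaling scenarios.

Encodes the diurnal states compared throughout the tissue/cell analyses as
multiplicative scale factors on per-current maximal conductances and on
cable coupling (the gap-junction / Cx43 proxy):

* ``ZT0``   — lights-on baseline; every factor 1.
* ``ZT12``  — lights-off state anchored to the measured day-night current
  changes: peak I_Na density down ≈42% (factor 0.58) and end-of-pulse I_Kr
  density up ≈150% (factor 2.50), with reduced coupling reflecting the
  lower Cx43/Gja1 expression at ZT12.
* ``ZT12_GRKO`` — the cardiomyocyte glucocorticoid-receptor-knockout
  counterfactual: identical to ZT12 except the I_Na, I_Kr and coupling
  rhythms are abolished (factors restored to 1).

Factors for currents whose diurnal magnitudes are not anchored by printed
measurements (I_CaL, I_to, I_NCX, ...) default to 1 and are marked as
placeholders in the provenance notes; a full scaling table can be dropped
in via YAML scenario files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .ionic_models.base import MembraneModel

__all__ = [
    "ScenarioScaling",
    "builtin_scenarios",
    "apply_scenario",
    "percent_change",
    "load_scenarios",
    "save_scenarios",
]

#: measured anchors: 1 - 0.42 and 1 + 1.50
ZT12_INA_FACTOR = 0.58
ZT12_IKR_FACTOR = 2.50
#: direction-only default for the Cx43/Gja1 coupling reduction at ZT12
ZT12_COUPLING_FACTOR = 0.75


@dataclass(frozen=True)
class ScenarioScaling:
    """Per-current multiplicative scale factors for one diurnal state."""

    scenario_id: str
    channel_scales: dict[str, float] = field(default_factory=dict)
    coupling_scale: float = 1.0
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for label, factor in self.channel_scales.items():
            if factor <= 0:
                raise ValueError(
                    f"{self.scenario_id}: factor for {label} must be > 0")
        if self.coupling_scale <= 0:
            raise ValueError(f"{self.scenario_id}: coupling_scale must be > 0")

    def factor(self, label: str) -> float:
        return self.channel_scales.get(label, 1.0)

    def with_scales(self, **channel_scales: float) -> "ScenarioScaling":
        merged = {**self.channel_scales, **channel_scales}
        return replace(self, channel_scales=merged)


def builtin_scenarios() -> dict[str, ScenarioScaling]:
    """The three built-in diurnal states: ZT0, ZT12 and ZT12_GRKO.

    ZT0 is the all-ones reference.  ZT12 carries the measured I_Na and
    I_Kr anchors plus the placeholder coupling reduction.  ZT12_GRKO
    equals ZT12 with I_Na, I_Kr and coupling restored to 1 (the
    knockout abolishes those three rhythms); because every other default
    factor is also 1, ZT12_GRKO is numerically identical to ZT0 until a
    non-anchored factor is configured away from unity.
    """
    zt0 = ScenarioScaling(
        scenario_id="ZT0",
        channel_scales={},
        coupling_scale=1.0,
        provenance={"*": "lights-on baseline; all factors 1 by definition"},
    )
    zt12 = ScenarioScaling(
        scenario_id="ZT12",
        channel_scales={"I_Na": ZT12_INA_FACTOR, "I_Kr": ZT12_IKR_FACTOR},
        coupling_scale=ZT12_COUPLING_FACTOR,
        provenance={
            "I_Na": "measured anchor: peak I_Na at -30 mV reduced ~42% at ZT12",
            "I_Kr": "measured anchor: end-of-pulse I_Kr ~150% higher at ZT12",
            "coupling": ("placeholder: expresses the direction of the lower "
                         "Cx43/Gja1 expression at ZT12; not a measured value"),
            "other": "placeholder 1.0: diurnal magnitudes not anchored here",
        },
    )
    grko = ScenarioScaling(
        scenario_id="ZT12_GRKO",
        channel_scales={k: v for k, v in zt12.channel_scales.items()
                        if k not in ("I_Na", "I_Kr")},
        coupling_scale=1.0,
        provenance={
            "I_Na": "GR knockout abolishes the Scn5a rhythm: factor restored to 1",
            "I_Kr": "GR knockout abolishes the Kcnh2 rhythm: factor restored to 1",
            "coupling": "GR knockout abolishes the Gja1 rhythm: factor restored to 1",
            "other": "inherited from ZT12 (placeholder 1.0 by default)",
        },
    )
    return {"ZT0": zt0, "ZT12": zt12, "ZT12_GRKO": grko}


def apply_scenario(model: MembraneModel, scenario: ScenarioScaling) -> MembraneModel:
    """A copy of the model with the scenario's conductance factors applied.

    Unknown current labels raise; the original model is unmodified.
    Applying a scenario twice composes multiplicatively.
    """
    if not scenario.channel_scales:
        return model
    return model.scaled(scenario.channel_scales)


def percent_change(reference_value: float, test_value: float) -> float:
    """Signed percent change: 100·(test − reference)/|reference|."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (test_value - reference_value) / abs(reference_value)


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def save_scenarios(scenarios: dict[str, ScenarioScaling], path) -> None:
    doc = {
        sid: {
            "channel_scales": dict(s.channel_scales),
            "coupling_scale": s.coupling_scale,
            "provenance": dict(s.provenance),
        }
        for sid, s in scenarios.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_scenarios(path) -> dict[str, ScenarioScaling]:
    """Read scenario scale factors from a YAML file.

    Layout: top-level keys are scenario ids; each maps channel_scales
    (current label → factor), coupling_scale, and optional provenance.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for sid, body in doc.items():
        out[sid] = ScenarioScaling(
            scenario_id=str(sid),
            channel_scales={str(k): float(v)
                            for k, v in (body.get("channel_scales") or {}).items()},
            coupling_scale=float(body.get("coupling_scale", 1.0)),
            provenance={str(k): str(v)
                        for k, v in (body.get("provenance") or {}).items()},
        )
    return out
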
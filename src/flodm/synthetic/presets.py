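"""Condition presets.

Each preset encodes one experimental condition as a map from signal
(``Ca_A``, ``Ca_N``, ``CBFv``, ``diameter``) to a response template whose
breakpoints are the printed group kinetics for that condition:

* ``cocaine`` — acute cocaine (1 mg/kg i.v., injection at t=0) in the
  prefrontal cortex, group of n=7 animals: neuronal Ca²⁺ rises to 2.46% at
  8.2 min and returns by 28.8 min (followed by a downshoot), astrocytic Ca²⁺
  rises to 2.97% at 12.1 min returning only by 59.5 min, and vascular CBFv
  drops to −25.1% at 21.0 min returning by 64.0 min.  Compartment templates
  carry the arteriolar (−19.8%), venular (−29.3%) and capillary (−13.5%)
  flow drops; per-capillary gains spread the capillary responses across
  positive and negative changes (some capillaries gain >7% flow while others
  lose >35%).
* ``cocaine_single`` — the single-session variant (m=5 ROIs, one animal):
  Ca_N 2.92% @ 8.6 min (return 27.6), Ca_A 3.87% @ 10.6 min (return 50.6),
  CBFv −22.8% @ 16.6 min (return 58.6).
* ``clozapine_baseline`` — clozapine activation of astrocytic DREADD(Gi) at
  rest (n=5): vasodilation Δφ = +9.17% and ΔCBFv = +10.51% at 25 min,
  astrocytic Ca²⁺ decrease of −3.0%, and no neuronal change.
* ``dreadd_cocaine`` — cocaine after DREADD(Gi) activation: the astrocytic,
  vascular and neuronal responses are carried as rate-true templates
  (per-minute rates 0.35, −2.03 and 0.11 %/min over the rising phase) with
  the neuronal response shortened to a 2.24 min FWHM.  Rates and amplitudes
  are on independent scales (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, model_validator

from flodm.synthetic.templates import ResponseTemplate

Signal = Literal["Ca_A", "Ca_N", "CBFv", "diameter"]
Compartment = Literal["artery", "vein", "capillary"]
PresetName = Literal[
    "cocaine", "cocaine_single", "clozapine_baseline", "dreadd_cocaine"
]

SIGNALS: Tuple[str, ...] = ("Ca_A", "Ca_N", "CBFv", "diameter")
COMPARTMENTS: Tuple[str, ...] = ("artery", "vein", "capillary")


class UsageError(ValueError):
    """A preset-level precondition was violated."""


class TemplateSpec(BaseModel):
    """Serializable mirror of :class:`ResponseTemplate`."""

    amplitude: float
    t_onset: float
    t_peak: float
    t_return: float
    undershoot_depth: float = 0.0
    undershoot_end: Optional[float] = None
    rate_override: Optional[float] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _buildable(self) -> "TemplateSpec":
        self.as_template()  # raises TemplateConstraintError on bad ordering
        return self

    def as_template(self) -> ResponseTemplate:
        return ResponseTemplate(**self.model_dump())


class CohortPreset(BaseModel):
    """One simulated experiment: condition, cohort size, noise, time axis."""

    name: PresetName
    templates: Dict[Signal, TemplateSpec]
    compartment_templates: Optional[Dict[Compartment, TemplateSpec]] = None
    compartment_gains: Optional[Dict[Compartment, List[float]]] = None
    n_animals: int = 7
    rois_per_signal: int = 5
    animal_sd: float = 15.0  # percent, relative spread of per-animal gain
    trace_noise_sd: float = 0.3  # percentage points, i.i.d. per sample
    sample_period: float = 0.5  # minutes
    window: Tuple[float, float] = (-10.0, 70.0)
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _validate(self) -> "CohortPreset":
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be (t_start, t_end) with t_start < t_end")
        if self.n_animals < 1 or self.rois_per_signal < 1:
            raise ValueError("n_animals and rois_per_signal must be >= 1")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be > 0")
        if set(self.templates) != set(SIGNALS):
            missing = set(SIGNALS) - set(self.templates)
            raise ValueError(f"every signal needs exactly one template; missing {sorted(missing)}")
        groups = [self.templates.values()]
        if self.compartment_templates:
            groups.append(self.compartment_templates.values())
        for spec in (s for g in groups for s in g):
            lo, hi = spec.as_template().span
            if lo < self.window[0] or hi > self.window[1]:
                raise ValueError(
                    f"window {self.window} does not contain template span ({lo}, {hi})"
                )
        if self.compartment_gains:
            if not self.compartment_templates:
                raise ValueError("compartment_gains without compartment_templates")
            for comp, gains in self.compartment_gains.items():
                if len(gains) == 0:
                    raise ValueError(f"empty gain list for compartment {comp}")
        return self

    # -- accessors ----------------------------------------------------------

    def template(self, signal: str) -> ResponseTemplate:
        return self.templates[signal].as_template()

    def compartment_template(self, compartment: str) -> ResponseTemplate:
        if not self.compartment_templates:
            raise UsageError(f"preset '{self.name}' has no compartment templates")
        return self.compartment_templates[compartment].as_template()

    def time_grid(self) -> np.ndarray:
        """Common minute-scale time axis, t=0 at injection."""
        t0, t1 = self.window
        n = int(round((t1 - t0) / self.sample_period)) + 1
        return t0 + self.sample_period * np.arange(n)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None, **kwargs) -> str:
        doc = json.dumps(self.model_dump(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source) -> "CohortPreset":
        if hasattr(source, "read"):
            return cls.model_validate_json(source.read())
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.model_validate_json(text)
        with open(text) as fh:
            return cls.model_validate_json(fh.read())

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON form (provenance)."""
        doc = json.dumps(self.model_dump(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(doc.encode()).hexdigest()

    @classmethod
    def json_schema(cls) -> dict:
        return cls.model_json_schema()


# ---------------------------------------------------------------------------
# Built-in condition presets
# ---------------------------------------------------------------------------

def cocaine_preset(n_animals: int = 7, seed: int = 101) -> CohortPreset:
    """Acute cocaine group kinetics (n=7 cohort)."""
    return CohortPreset(
        name="cocaine",
        templates={
            "Ca_N": TemplateSpec(
                amplitude=2.46, t_onset=0.5, t_peak=8.2, t_return=28.8,
                undershoot_depth=0.8, undershoot_end=45.0,
            ),
            "Ca_A": TemplateSpec(
                amplitude=2.97, t_onset=0.5, t_peak=12.1, t_return=59.5,
            ),
            "CBFv": TemplateSpec(
                amplitude=-25.1, t_onset=0.5, t_peak=21.0, t_return=64.0,
            ),
            # cocaine vasoconstriction; magnitude chosen to track CBFv timing
            "diameter": TemplateSpec(
                amplitude=-8.0, t_onset=0.5, t_peak=21.0, t_return=64.0,
            ),
        },
        compartment_templates={
            "artery": TemplateSpec(
                amplitude=-19.8, t_onset=0.5, t_peak=20.0, t_return=49.5,
            ),
            "vein": TemplateSpec(
                amplitude=-29.3, t_onset=0.5, t_peak=18.0, t_return=45.5,
            ),
            "capillary": TemplateSpec(
                amplitude=-13.5, t_onset=0.5, t_peak=20.0, t_return=48.0,
            ),
        },
        # per-vessel multiplicative gains (mean 1); the capillary set spreads
        # individual responses from >+7% to <-35% flow change while keeping
        # the compartment mean at the template value
        compartment_gains={
            "artery": [0.85, 0.95, 1.05, 1.15],
            "vein": [0.85, 0.95, 1.05, 1.15],
            "capillary": [-0.55, 0.55, 1.4, 2.6],
        },
        n_animals=n_animals,
        seed=seed,
    )


def cocaine_single_preset(seed: int = 404) -> CohortPreset:
    """Single-session cocaine kinetics (one animal, m=5 ROIs)."""
    return CohortPreset(
        name="cocaine_single",
        templates={
            "Ca_N": TemplateSpec(
                amplitude=2.92, t_onset=0.5, t_peak=8.6, t_return=27.6,
                undershoot_depth=0.8, undershoot_end=45.0,
            ),
            "Ca_A": TemplateSpec(
                amplitude=3.87, t_onset=0.5, t_peak=10.6, t_return=50.6,
            ),
            "CBFv": TemplateSpec(
                amplitude=-22.8, t_onset=0.5, t_peak=16.6, t_return=58.6,
            ),
            "diameter": TemplateSpec(
                amplitude=-8.0, t_onset=0.5, t_peak=16.6, t_return=58.6,
            ),
        },
        n_animals=1,
        seed=seed,
    )


def clozapine_baseline_preset(n_animals: int = 5, seed: int = 202) -> CohortPreset:
    """Clozapine activation of astrocytic DREADD(Gi) at baseline (n=5)."""
    return CohortPreset(
        name="clozapine_baseline",
        templates={
            "diameter": TemplateSpec(
                amplitude=9.17, t_onset=2.0, t_peak=25.0, t_return=65.0,
            ),
            "CBFv": TemplateSpec(
                amplitude=10.51, t_onset=2.0, t_peak=25.0, t_return=65.0,
            ),
            "Ca_A": TemplateSpec(
                amplitude=-3.0, t_onset=5.0, t_peak=25.0, t_return=65.0,
            ),
            # astrocyte inhibition leaves neuronal activity unchanged
            "Ca_N": TemplateSpec(
                amplitude=0.0, t_onset=0.0, t_peak=35.0, t_return=70.0,
            ),
        },
        n_animals=n_animals,
        seed=seed,
    )


def dreadd_cocaine_preset(n_animals: int = 4, seed: int = 303) -> CohortPreset:
    """Cocaine after astrocytic DREADD(Gi) activation.

    Rate-true templates: the rising phases are linear ramps whose OLS slopes
    over [0, min(t_peak, 30)] equal the printed post-activation per-minute
    rates (Ca_A 0.35, CBFv -2.03, Ca_N 0.11 %/min); the neuronal template's
    return time is set so its analytic FWHM is 2.24 min.
    """
    return CohortPreset(
        name="dreadd_cocaine",
        templates={
            "Ca_A": TemplateSpec(
                amplitude=0.35 * 6.0, t_onset=0.0, t_peak=6.0, t_return=40.0,
                rate_override=0.35,
            ),
            "CBFv": TemplateSpec(
                amplitude=-2.03 * 6.0, t_onset=0.0, t_peak=6.0, t_return=40.0,
                rate_override=-2.03,
            ),
            # FWHM = t_peak/2 + (2/3)(t_return - t_peak) - t_peak/2 picked so
            # the half-width is 2.24 min: t_return = 3.5 + 0.49/(2/3)
            "Ca_N": TemplateSpec(
                amplitude=0.11 * 3.5, t_onset=0.0, t_peak=3.5, t_return=4.235,
                rate_override=0.11,
            ),
            # vasoconstriction eliminated by astrocyte inhibition
            "diameter": TemplateSpec(
                amplitude=0.0, t_onset=0.0, t_peak=35.0, t_return=70.0,
            ),
        },
        n_animals=n_animals,
        seed=seed,
    )


_BUILTINS = {
    "cocaine": cocaine_preset,
    "cocaine_single": cocaine_single_preset,
    "clozapine_baseline": clozapine_baseline_preset,
    "dreadd_cocaine": dreadd_cocaine_preset,
}


def get_preset(name: str, **kwargs) -> CohortPreset:
    """Look up a built-in preset by name."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise UsageError(
            f"unknown preset '{name}'; available: {sorted(_BUILTINS)}"
        ) from None
    return factory(**kwargs)


def apply_dreadd(preset: CohortPreset) -> CohortPreset:
    """Derive the DREADD(Gi)+cocaine preset from the cocaine preset.

    Astrocytic Ca²⁺ amplitude and rate are suppressed, the CBFv drop is
    flattened, and the neuronal response is shortened (reduced FWHM and
    rate), per the printed post-activation kinetics.  Applying it to an
    already-derived preset raises instead of double-suppressing.
    """
    if preset.name == "dreadd_cocaine":
        raise UsageError("preset is already a dreadd_cocaine preset")
    if preset.name not in ("cocaine", "cocaine_single"):
        raise UsageError(
            f"apply_dreadd expects a cocaine preset, got '{preset.name}'"
        )
    return dreadd_cocaine_preset(seed=preset.seed + 1)


def apply_clozapine_baseline(preset: CohortPreset) -> CohortPreset:
    """Derive the clozapine-baseline preset (no cocaine challenge)."""
    if preset.name == "clozapine_baseline":
        raise UsageError("preset is already a clozapine_baseline preset")
    return clozapine_baseline_preset(seed=preset.seed + 2)
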
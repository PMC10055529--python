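"""Cohort-level trace simulation.

A cohort realizes a :class:`~flodm.synthetic.presets.CohortPreset` as noisy
per-ROI traces: for each animal and signal, ``rois_per_signal`` traces equal
``template(t) * gain`` plus i.i.d. Gaussian noise on the preset time grid,
where ``gain ~ Normal(1, animal_sd/100)`` is the animal's multiplicative
response gain for that signal.  The ground-truth record stores every realized
gain and the analytic template estimands, so downstream estimators can be
scored against what the generator actually produced.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from flodm.synthetic.presets import SIGNALS, CohortPreset

TRACE_COLUMNS = ["animal", "signal", "roi", "t_min", "value"]


def simulate_cohort(
    preset: CohortPreset, seed: int | None = None
) -> Tuple[pd.DataFrame, dict]:
    """Simulate one cohort of per-ROI traces.

    Parameters
    ----------
    preset:
        Validated condition preset.
    seed:
        Overrides ``preset.seed`` when given.

    Returns
    -------
    traces:
        Tidy frame with columns (animal, signal, roi, t_min, value); values
        are percent fractional change.
    truth:
        Ground-truth record: per-(animal, signal) gains, per-signal template
        estimands, seed and preset hash.
    """
    seed = preset.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    t = preset.time_grid()
    n, m = preset.n_animals, preset.rois_per_signal

    rows = []
    gain_rows = []
    for animal in range(1, n + 1):
        for signal in SIGNALS:
            template = preset.template(signal)
            gain = 1.0 + (preset.animal_sd / 100.0) * rng.standard_normal()
            gain_rows.append({"animal": animal, "signal": signal, "gain": gain})
            base = gain * template(t)
            noise = rng.normal(0.0, preset.trace_noise_sd, size=(m, t.size))
            values = base[None, :] + noise
            for roi in range(1, m + 1):
                rows.append(
                    pd.DataFrame(
                        {
                            "animal": animal,
                            "signal": signal,
                            "roi": roi,
                            "t_min": t,
                            "value": values[roi - 1],
                        }
                    )
                )

    traces = pd.concat(rows, ignore_index=True)
    truth = {
        "seed": seed,
        "preset_name": preset.name,
        "preset_hash": preset.content_hash(),
        "gains": pd.DataFrame(gain_rows),
        "estimands": template_estimands(preset),
    }
    return traces, truth


def template_estimands(preset: CohortPreset) -> pd.DataFrame:
    """Analytic estimands of every template in the preset."""
    rows = []
    groups = [("signal", preset.templates)]
    if preset.compartment_templates:
        groups.append(("compartment", preset.compartment_templates))
    for kind, mapping in groups:
        for key, spec in mapping.items():
            tmpl = spec.as_template()
            rows.append(
                {
                    "kind": kind,
                    "name": key,
                    "amplitude": tmpl.amplitude,
                    "t_onset": tmpl.t_onset,
                    "t_peak": tmpl.t_peak,
                    "t_return": tmpl.t_return,
                    "rate": tmpl.rate_pct_per_min,
                    "fwhm": tmpl.fwhm_min,
                    "undershoot_depth": tmpl.undershoot_depth,
                }
            )
    return pd.DataFrame(rows)


def traces_to_csv(traces: pd.DataFrame, path) -> None:
    """Write a trace frame with a fixed float format (byte-reproducible)."""
    traces.to_csv(path, index=False, float_format="%.6f")


def traces_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def animal_mean_traces(traces: pd.DataFrame) -> pd.DataFrame:
    """ROI-averaged trace per (animal, signal) — the unit the kinetics
    metrics are estimated on (m ROIs averaged into one curve per animal)."""
    out = (
        traces.groupby(["animal", "signal", "t_min"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    return out


def cohort_mean_traces(traces: pd.DataFrame) -> pd.DataFrame:
    """Grand mean trace per signal across all animals and ROIs."""
    return traces.groupby(["signal", "t_min"], sort=True)["value"].mean().reset_index()
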
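"""Standard simulation worlds used by the analysis scripts and the test suite.

Each factory returns a fully specified :class:`SimulationConfig`. The
parameter choices emulate a large inpatient registry: per-disease
admission probabilities of a few percent up to ~15% (chronic circulatory
and metabolic chapters are common, specific rare diseases are not),
~5% of admissions carrying non-disease principal codes, in-hospital
death hazards concentrated on high-mortality diagnoses, and a ~20-year
study window. Planted pair intervals default to ~115 ± 84 days, the
scale reported for real comorbidity pairs.
"""

from __future__ import annotations

import numpy as np

from .simulate import PlantedPair, SimulationConfig

__all__ = [
    "DISEASE_CODES",
    "null_world",
    "planted_world",
    "small_world",
    "merge_world",
    "demo_world",
]

#: Three-digit ICD-9-CM disease chapter codes used by the standard worlds.
#: A mix of common chronic, acute and rare conditions: septicemia (038),
#: diabetes (250), schizophrenia (295), episodic mood disorders (296),
#: hypertension (401), acute myocardial infarction (410), heart failure
#: (428), pneumonia (486), chronic liver disease (571), its sequelae
#: (572), chronic kidney disease (585), cellulitis (682), muscle
#: disorders (728), osteomyelitis (730), plus filler chapters.
DISEASE_CODES = [
    "038", "250", "272", "276", "280", "285", "295", "296", "300", "303",
    "331", "332", "345", "401", "403", "410", "414", "427", "428", "433",
    "434", "438", "486", "491", "493", "496", "507", "530", "531", "535",
    "555", "558", "562", "571", "572", "574", "577", "584", "585", "599",
    "682", "707", "710", "714", "715", "721", "724", "728", "730", "733",
]

#: High-mortality diagnoses and their in-hospital death hazards.
_DEATH_HAZARD = {
    "038": 0.25, "410": 0.10, "428": 0.08, "486": 0.07,
    "571": 0.10, "572": 0.15, "584": 0.08, "585": 0.05,
}


def _rates(codes: list[str]) -> dict[str, float]:
    """Deterministic spread of admission probabilities over [0.03, 0.15]."""
    grid = np.linspace(0.03, 0.15, len(codes))
    return {c: round(float(r), 4) for c, r in zip(codes, grid)}


def null_world(
    n_patients: int = 20_000, n_diseases: int = 30, seed: int = 0
) -> SimulationConfig:
    """All diseases mutually independent (every lift = 1): the null registry."""
    codes = DISEASE_CODES[:n_diseases]
    return SimulationConfig(
        n_patients=n_patients,
        disease_codes=codes,
        baseline_rates=_rates(codes),
        planted_pairs=[],
        death_hazard={c: h for c, h in _DEATH_HAZARD.items() if c in codes},
        nondisease_fraction=0.05,
        seed=seed,
    )


def planted_world(
    n_patients: int = 50_000,
    lift: float = 3.0,
    direction_prob: float = 0.9,
    seed: int = 0,
) -> SimulationConfig:
    """One planted effect — schizophrenia (295) → muscle disorders (728) —
    in a 40-disease background, for parameter recovery."""
    codes = DISEASE_CODES[:39] + ["728"]
    rates = _rates(codes)
    rates["295"] = 0.05
    rates["728"] = 0.05
    return SimulationConfig(
        n_patients=n_patients,
        disease_codes=codes,
        baseline_rates=rates,
        planted_pairs=[
            PlantedPair("295", "728", lift=lift, direction_prob=direction_prob)
        ],
        death_hazard={c: h for c, h in _DEATH_HAZARD.items() if c in codes},
        nondisease_fraction=0.05,
        seed=seed,
    )


def small_world(seed: int, n_patients: int = 400) -> SimulationConfig:
    """A tiny registry (<= 8 diseases) amenable to exhaustive path search.

    High rates, strong planted chain and tight intervals so that small
    cohorts still produce multi-step trajectories.
    """
    codes = ["295", "296", "410", "428", "486", "571", "584", "728"]
    rng = np.random.default_rng(seed)
    rates = {c: round(float(r), 3) for c, r in zip(codes, rng.uniform(0.15, 0.45, len(codes)))}
    chain = [
        PlantedPair("296", "295", lift=2.0, direction_prob=0.95,
                    interval_mean_days=90.0, interval_sd_days=60.0),
        PlantedPair("295", "728", lift=2.0, direction_prob=0.9,
                    interval_mean_days=110.0, interval_sd_days=70.0),
        PlantedPair("410", "428", lift=2.0, direction_prob=0.9,
                    interval_mean_days=120.0, interval_sd_days=80.0),
        PlantedPair("428", "584", lift=1.8, direction_prob=0.85,
                    interval_mean_days=100.0, interval_sd_days=70.0),
    ]
    return SimulationConfig(
        n_patients=n_patients,
        disease_codes=codes,
        baseline_rates=rates,
        planted_pairs=chain,
        death_hazard={"428": 0.2, "584": 0.25, "486": 0.1},
        nondisease_fraction=0.05,
        study_window_days=1500,
        seed=seed,
    )


def merge_world(n_patients: int = 3_000, seed: int = 0) -> SimulationConfig:
    """Three annual editions with known overlap for exercising the merge rule.

    Patients are spread uniformly over the editions regardless of vital
    status, so earlier editions contain surviving patients that the merge
    must drop (the deceased-only registries are produced by
    ``deceased_only_backfill`` worlds instead).
    """
    codes = DISEASE_CODES[:20]
    return SimulationConfig(
        n_patients=n_patients,
        disease_codes=codes,
        baseline_rates=_rates(codes),
        death_hazard={c: min(0.6, 3 * h) for c, h in _DEATH_HAZARD.items() if c in codes},
        n_editions=3,
        deceased_only_backfill=False,
        nondisease_fraction=0.05,
        seed=seed,
    )


def demo_world(n_patients: int = 30_000, seed: int = 0) -> SimulationConfig:
    """The worked-example registry: a mood-disorder → schizophrenia →
    muscle-disorder chain plus two classic comorbidity chains, three
    editions with deceased-only backfill."""
    codes = DISEASE_CODES[:39] + ["728"]
    rates = _rates(codes)
    rates.update({"295": 0.06, "296": 0.08, "728": 0.04})
    pairs = [
        PlantedPair("296", "295", lift=3.0, direction_prob=0.9,
                    interval_mean_days=150.0, interval_sd_days=90.0),
        PlantedPair("295", "728", lift=2.5, direction_prob=0.9),
        PlantedPair("410", "428", lift=2.5, direction_prob=0.85,
                    interval_mean_days=130.0, interval_sd_days=90.0),
        PlantedPair("486", "038", lift=2.0, direction_prob=0.8,
                    interval_mean_days=100.0, interval_sd_days=70.0),
        PlantedPair("571", "572", lift=3.0, direction_prob=0.85,
                    interval_mean_days=140.0, interval_sd_days=90.0),
        PlantedPair("572", "038", lift=2.0, direction_prob=0.8,
                    interval_mean_days=110.0, interval_sd_days=80.0),
    ]
    return SimulationConfig(
        n_patients=n_patients,
        disease_codes=codes,
        baseline_rates=rates,
        planted_pairs=pairs,
        death_hazard=dict(_DEATH_HAZARD),
        n_editions=3,
        deceased_only_backfill=True,
        nondisease_fraction=0.05,
        seed=seed,
    )
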
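"""Synthetic longitudinal inpatient registry with planted disease-pair effects.

The real registries behind trajectory mining are access-restricted, so
every downstream stage is exercised on simulated admissions that emulate
their structure: multi-edition releases without cross-edition patient
linkage, ~20-year per-patient diagnostic timelines, three-digit ICD-9-CM
principal diagnoses (occasionally emitted at sub-code resolution to
exercise truncation), admissions with non-disease principal codes to
exercise filtering, and in-hospital death outcomes.

Generative model
----------------
Each patient's disease set is sampled marginally (independent Bernoulli
per code), then pair-coupled: for a planted ordered pair (i, j, lift),
the target status is redrawn with probability min(1, lift * rate_j) for
patients carrying *i* and with the compensated probability
rate_j * (1 - lift * rate_i) / (1 - rate_i) for the rest, so that the
probability of carrying both is lift * rate_i * rate_j while the marginal
of *j* stays exactly rate_j. For patients with both, the order is forward
(i before j) with probability ``direction_prob`` and the inter-diagnosis
gap is truncated-normal (>= 1 day); all other first-admission days are
uniform over the study window.

The expected relative association measured downstream is then
lift * P(gap <= window) * f, where f is the fraction of simulated
patients that appear in the registry at all (a patient with no admission
does not exist in inpatient data, which shrinks the patient total N the
estimator sees). With enough disease codes at realistic rates f is close
to 1; both factors are properties of the stated world, not of the
estimator.

Death is attached to a patient's chronologically last admission with the
configured per-code hazard; non-disease admissions carry zero hazard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError
from .records import AdmissionRecord

__all__ = [
    "PlantedPair",
    "SimulationConfig",
    "generate_registry",
    "GroundTruth",
    "ground_truth",
]

logger = logging.getLogger(__name__)

#: Study window: ~20 years of longitudinal records per patient.
DEFAULT_WINDOW_DAYS = 7300

#: Mean/SD of patient age (years) at study entry in large inpatient registries.
AGE_MEAN, AGE_SD = 63.77, 19.58

#: Non-disease principal codes injected to exercise the chapter filter:
#: obstetric (630-679), injury/poisoning (800-999), external cause (E),
#: administrative (V).
NONDISEASE_POOL = ("650", "664.1", "812.21", "959", "E880.2", "E849", "V58.11", "V30")


@dataclass(frozen=True)
class PlantedPair:
    """A directed disease-pair effect to plant in the registry.

    ``lift`` multiplies the chance of co-occurrence relative to
    independence; ``direction_prob`` is the probability that the source is
    diagnosed first; the source→target gap is truncated normal (>= 1 day).
    Interval defaults are on the scale reported for real comorbidity
    pairs (~115 ± 84 days).
    """

    source: str
    target: str
    lift: float
    interval_mean_days: float = 114.9
    interval_sd_days: float = 84.3
    direction_prob: float = 0.9


@dataclass
class SimulationConfig:
    """Full description of one synthetic registry."""

    n_patients: int
    disease_codes: list[str]
    baseline_rates: dict[str, float]
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    death_hazard: dict[str, float] = field(default_factory=dict)
    n_editions: int = 1
    deceased_only_backfill: bool = False
    nondisease_fraction: float = 0.0
    study_window_days: int = DEFAULT_WINDOW_DAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_editions <= 0:
            raise ConfigurationError("n_patients and n_editions must be positive")
        for c in self.disease_codes:
            if c not in self.baseline_rates:
                raise ConfigurationError(f"no baseline rate for code {c!r}")
        for c, r in self.baseline_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"baseline rate of {c!r} outside [0, 1]")
        for c, h in self.death_hazard.items():
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(f"death hazard of {c!r} outside [0, 1]")
        if not 0.0 <= self.nondisease_fraction <= 1.0:
            raise ConfigurationError("nondisease_fraction outside [0, 1]")
        for p in self.planted_pairs:
            if p.lift <= 0:
                raise ConfigurationError(f"lift of pair {p.source}->{p.target} <= 0")
            if p.interval_sd_days < 0:
                raise ConfigurationError("interval SD must be nonnegative")
            if not 0.0 <= p.direction_prob <= 1.0:
                raise ConfigurationError("direction_prob outside [0, 1]")
            if p.source not in self.disease_codes or p.target not in self.disease_codes:
                raise ConfigurationError(
                    f"planted pair {p.source}->{p.target} uses unknown codes"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["planted_pairs"] = [
            p if isinstance(p, PlantedPair) else PlantedPair(**p)
            for p in d.get("planted_pairs", [])
        ]
        return cls(**d)

    @property
    def edition_labels(self) -> list[str]:
        """Edition labels as consecutive years ending at the latest, 2010."""
        last = 2010
        return [str(last - self.n_editions + 1 + k) for k in range(self.n_editions)]


def _truncated_gaps(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Integer inter-diagnosis gaps >= 1 day, truncated normal."""
    if size == 0:
        return np.empty(0, dtype=int)
    if sd == 0:
        return np.full(size, max(1, int(round(mean))), dtype=int)
    a = (1.0 - mean) / sd
    draws = sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
    return np.maximum(1, np.rint(draws).astype(int))


def generate_registry(config: SimulationConfig) -> list[AdmissionRecord]:
    """Simulate a multi-edition registry; deterministic given ``config.seed``.

    Returns admissions sorted by patient then day. Patients appear in one
    edition only; with ``deceased_only_backfill`` every patient placed in
    a non-latest edition is flagged deceased there.
    """
    rng = np.random.default_rng(config.seed)
    codes = list(config.disease_codes)
    m = len(codes)
    n = config.n_patients
    window = config.study_window_days
    col = {c: k for k, c in enumerate(codes)}
    rates = np.array([config.baseline_rates[c] for c in codes])

    present = rng.random((n, m)) < rates
    days = rng.integers(0, window, size=(n, m))
    # pinned marks days already coupled by an earlier planted pair: a later
    # pair keeps a pinned source day as its anchor, so planted chains
    # (i -> j, j -> k) compose into multi-step trajectories
    pinned = np.zeros((n, m), dtype=bool)

    for pair in config.planted_pairs:
        si, ti = col[pair.source], col[pair.target]
        p_t = pair.lift * rates[ti]
        if p_t > 1.0:
            logger.warning(
                "planted pair %s->%s: lift x rate = %.3f capped at 1",
                pair.source,
                pair.target,
                p_t,
            )
            p_t = 1.0
        # compensate the non-source arm so the target marginal stays rate_j
        p_rest = rates[ti]
        if rates[si] < 1.0:
            p_rest = (rates[ti] - rates[si] * p_t) / (1.0 - rates[si])
            if p_rest < 0.0:
                logger.warning(
                    "planted pair %s->%s: compensated rate < 0, clipped; "
                    "target marginal will exceed its configured rate",
                    pair.source,
                    pair.target,
                )
                p_rest = 0.0
        has_s = present[:, si]
        draw = rng.random(n)
        present[:, ti] = np.where(has_s, draw < p_t, draw < p_rest)
        both = has_s & present[:, ti]
        nb = int(both.sum())
        gaps = _truncated_gaps(rng, pair.interval_mean_days, pair.interval_sd_days, nb)
        gaps = np.minimum(gaps, max(1, window // 2 - 1))
        forward = rng.random(nb) < pair.direction_prob
        idx = np.flatnonzero(both)
        # anchor: keep the source day if a previous pair pinned it, else
        # draw it so both days stay inside the window
        d0 = gaps + (rng.random(nb) * (window - 2 * gaps)).astype(int)
        s_day = np.where(pinned[idx, si], days[idx, si], d0)
        t_day = np.clip(np.where(forward, s_day + gaps, s_day - gaps), 0, window - 1)
        t_day = np.where(t_day == s_day, np.minimum(s_day + 1, window - 1), t_day)
        days[idx, si] = s_day
        days[idx, ti] = t_day
        pinned[idx, si] = True
        pinned[idx, ti] = True

    base_age = np.clip(rng.normal(AGE_MEAN, AGE_SD, size=n), 1.0, 100.0)

    # per-patient admission lists: (day, principal, secondaries)
    sub_digit = rng.integers(0, 10, size=(n, m))
    emit_sub = rng.random((n, m)) < 0.4

    n_disease_adm = int(present.sum())
    n_extra = rng.binomial(n_disease_adm, config.nondisease_fraction)
    extra_patient = rng.choice(np.flatnonzero(present.any(axis=1)), size=n_extra) if n_extra else np.empty(0, int)
    extra_code = rng.choice(len(NONDISEASE_POOL), size=n_extra)
    extra_day = rng.integers(0, window, size=n_extra)
    extras: dict[int, list[tuple[int, str]]] = {}
    for p, ci, d in zip(extra_patient, extra_code, extra_day):
        extras.setdefault(int(p), []).append((int(d), NONDISEASE_POOL[ci]))

    # edition and death assignment need the last admission per patient
    records: list[AdmissionRecord] = []
    death_draw = rng.random(n)
    edition_draw = rng.integers(0, config.n_editions, size=n)
    editions = config.edition_labels
    latest = editions[-1]
    pid_width = len(str(n))

    for p in range(n):
        adm: list[tuple[int, str, bool]] = []  # (day, code, is_disease)
        for ci in np.flatnonzero(present[p]):
            code = codes[ci]
            if emit_sub[p, ci] and code.isdigit():
                code = f"{code}.{sub_digit[p, ci]}"
            adm.append((int(days[p, ci]), code, True))
        for d, code in extras.get(p, []):
            adm.append((d, code, False))
        if not adm:
            continue
        adm.sort()
        last_day, last_code, last_is_disease = adm[-1]
        hazard = 0.0
        if last_is_disease:
            hazard = config.death_hazard.get(last_code.split(".")[0], 0.0)
        died = bool(death_draw[p] < hazard)

        if config.n_editions == 1:
            edition = latest
        elif config.deceased_only_backfill:
            edition = editions[edition_draw[p]] if died else latest
        else:
            edition = editions[edition_draw[p]]

        pid = f"p{p:0{pid_width}d}"
        first_day = adm[0][0]
        for day, code, _ in adm:
            records.append(
                AdmissionRecord(
                    patient_id=pid,
                    edition_id=edition,
                    admission_day=day,
                    diagnosis_codes=(code,),
                    died_in_hospital=died and day == last_day,
                    age_years=round(float(base_age[p] + (day - first_day) / 365.25), 1),
                )
            )
    return records


class GroundTruth:
    """Planted (lift, direction_prob) per ordered pair.

    Querying a non-planted pair returns the null ``(1.0, 0.5)``; the
    reverse of a planted pair returns the same lift with the complementary
    direction probability.
    """

    def __init__(self, planted: Mapping[tuple[str, str], tuple[float, float]]):
        self.planted = dict(planted)

    def __getitem__(self, pair: tuple[str, str]) -> tuple[float, float]:
        return self.planted.get(tuple(pair), (1.0, 0.5))

    def items(self):
        return self.planted.items()


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """The planted parameters, for parameter-recovery checks."""
    planted: dict[tuple[str, str], tuple[float, float]] = {}
    for p in config.planted_pairs:
        planted[(p.source, p.target)] = (p.lift, p.direction_prob)
        planted[(p.target, p.source)] = (p.lift, 1.0 - p.direction_prob)
    return GroundTruth(planted)
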
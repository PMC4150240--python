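"""Seeded synthetic cohort generator.

Real Module 1 score sheets live in access-controlled repositories, so the
pipeline is exercised on generated cohorts that reproduce the *statistical
structure* the analysis relies on, not any real item distribution:

* a latent severity ``theta`` per subject, normally distributed around a
  class-specific mean (spectrum vs non-spectrum control);
* 29 ordinal item codes drawn from a graded-response-style model,
  ``P(code >= k) = logistic(a_i * (theta - b_ik))`` with per-item
  discriminations ``a_i`` and ordered cutpoints ``b_i1 < b_i2 < b_i3``, so
  every instrument total and the trained classifier covary with severity;
* item A1 (overall level of non-echoed language) is drawn from the same
  model, which places severely affected subjects in the "few to no words"
  branch;
* demographics matching the study cohort: age truncated-normal
  6.21 +/- 4.25 years on [1, 20], gender 76.8% male / 18.5% female /
  4.7% unknown, and an 89.2% spectrum class mix.

One generator seeded once drives all draws in a fixed stream order
(class, theta, items in item-id order, age, gender, then the optional
special-code / label-noise / dx-availability streams), so cohorts are
byte-identical across runs with the same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .sheets import (Cohort, ITEM_IDS, NON_SPECTRUM, SPECTRUM, ScoreSheet,
                     ValidationError)


@dataclass
class CohortParams:
    """Generative settings for a synthetic score-sheet cohort."""

    n: int = 2616
    p_spectrum: float = 0.892  # ~ 2333 / 2616
    severity_mean_spectrum: float = 1.5
    severity_mean_control: float = -1.5
    severity_sd: float = 1.0
    item_discriminations: float | Mapping[str, float] = 1.0
    item_cutpoints: Sequence[float] | Mapping[str, Sequence[float]] = (-0.5, 0.5, 1.5)
    age_mean: float = 6.21
    age_sd: float = 4.25
    age_lo: float = 1.0
    age_hi: float = 20.0
    gender_probs: tuple[float, float, float] = (0.768, 0.185, 0.047)
    p_special: float = 0.0  # probability an item emits a 7/8 special code
    label_noise: float = 0.0  # probability clinical_dx flips from the true class
    p_dx_available: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not 0.0 < self.p_spectrum < 1.0:
            raise ValidationError("p_spectrum must lie in (0, 1)")
        if self.severity_sd <= 0:
            raise ValidationError("severity_sd must be > 0")
        if abs(sum(self.gender_probs) - 1.0) > 1e-9:
            raise ValidationError("gender_probs must sum to 1")
        if not (0 <= self.p_special <= 1 and 0 <= self.label_noise <= 1
                and 0 <= self.p_dx_available <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.age_lo >= self.age_hi or self.age_sd <= 0:
            raise ValidationError("invalid age distribution")
        for item_id in ITEM_IDS:
            a = self.discrimination(item_id)
            if a <= 0:
                raise ValidationError(f"discrimination for {item_id} must be > 0")
            b = self.cutpoints(item_id)
            if len(b) != 3 or not (b[0] < b[1] < b[2]):
                raise ValidationError(
                    f"cutpoints for {item_id} must be three strictly increasing reals")

    def discrimination(self, item_id: str) -> float:
        if isinstance(self.item_discriminations, Mapping):
            return float(self.item_discriminations[item_id])
        return float(self.item_discriminations)

    def cutpoints(self, item_id: str) -> tuple[float, float, float]:
        value = self.item_cutpoints
        if isinstance(value, Mapping):
            value = value[item_id]
        b1, b2, b3 = (float(v) for v in value)
        return (b1, b2, b3)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(params: CohortParams) -> tuple[Cohort, list[str], np.ndarray]:
    """Generate a cohort plus the ground truth behind it.

    Returns ``(cohort, true_labels, theta)`` where ``true_labels`` is the
    per-subject generating class ("spectrum"/"non_spectrum") and ``theta``
    the latent severity.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n

    # Stream order is part of the contract: class, theta, items (id order),
    # age, gender, then optional corruption streams.
    is_spectrum = rng.random(n) < params.p_spectrum
    means = np.where(is_spectrum, params.severity_mean_spectrum,
                     params.severity_mean_control)
    theta = rng.normal(means, params.severity_sd)

    codes = np.empty((n, len(ITEM_IDS)), dtype=np.int64)
    for j, item_id in enumerate(ITEM_IDS):
        a = params.discrimination(item_id)
        b = np.array(params.cutpoints(item_id))
        p_ge = _logistic(a * (theta[:, None] - b[None, :]))  # (n, 3), decreasing in k
        u = rng.random(n)
        codes[:, j] = (u[:, None] < p_ge).sum(axis=1)

    a_lo, a_hi = ((params.age_lo - params.age_mean) / params.age_sd,
                  (params.age_hi - params.age_mean) / params.age_sd)
    ages = stats.truncnorm.rvs(a_lo, a_hi, loc=params.age_mean,
                               scale=params.age_sd, size=n, random_state=rng)
    genders = rng.choice(["male", "female", "unknown"], size=n,
                         p=list(params.gender_probs))

    if params.p_special > 0:
        special_mask = rng.random(codes.shape) < params.p_special
        special_codes = rng.choice([7, 8], size=codes.shape)
        codes = np.where(special_mask, special_codes, codes)

    labels = np.where(is_spectrum, SPECTRUM, NON_SPECTRUM)
    dx = labels.copy()
    if params.label_noise > 0:
        flip = rng.random(n) < params.label_noise
        dx = np.where(flip, np.where(dx == SPECTRUM, NON_SPECTRUM, SPECTRUM), dx)
    dx_available = np.ones(n, dtype=bool)
    if params.p_dx_available < 1.0:
        dx_available = rng.random(n) < params.p_dx_available

    width = max(6, len(str(n)))
    sheets = []
    for i in range(n):
        sheets.append(ScoreSheet(
            subject_id=f"S{i:0{width}d}",
            age_years=float(ages[i]),
            gender=str(genders[i]),
            items={item_id: int(codes[i, j]) for j, item_id in enumerate(ITEM_IDS)},
            clinical_dx=str(dx[i]) if dx_available[i] else None,
        ))
    cohort = Cohort(sheets=sheets, source_tag=f"synthetic(seed={params.seed})")
    return cohort, [str(lab) for lab in labels], theta
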
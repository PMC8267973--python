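"""Synthetic (age, IMT) cohort generation.

Emulates the structure of the clinical carotid-ultrasound samples the
logistic analysis is designed for: each patient contributes one age and —
when the cohort is bilateral — two artery measurements (left and right) at
that age, each perturbed by independent additive Gaussian noise about the
cohort's true logistic curve.  Ages are drawn uniformly over the cohort age
range (only ranges, not a distribution, are available for the real samples).

Four named presets mirror the reported cohort fits, with the printed
parameters as ground truth, the printed group sizes (62 / 18 / 44 / 11
observations) and measurement noise set to each fit's reported RMSE — the
only dispersion information available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .logistic import LogisticParams

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "presets",
    "REFERENCE_CURVES",
    "REFERENCE_COHORT_META",
]

# floor applied after noise; IMT below this is not physiological
MIN_IMT_MM = 0.05

# Reported logistic fits for the four study cohorts (ground truth for
# synthesis and the reference inputs of the timing analysis).
REFERENCE_CURVES: dict[str, LogisticParams] = {
    "aggregate": LogisticParams(x0=0.3, c=1.2, a=0.02875),
    "non_medicated": LogisticParams(x0=0.275, c=0.9, a=0.03962),
    "statin_medicated": LogisticParams(x0=0.325, c=1.25, a=0.02625),
    "dialysis_legacy": LogisticParams(x0=0.05, c=1.8, a=0.06),
}

# (n observations, reported SSE, reported RMSE, reported R2, rmse dialect)
REFERENCE_COHORT_META: dict[str, dict] = {
    "aggregate": dict(n=62, sse=1.689, rmse=0.1664, r2=0.0526, dialect="n_minus_1"),
    "non_medicated": dict(n=18, sse=0.2713, rmse=0.1263, r2=0.0563, dialect="n_minus_1"),
    "statin_medicated": dict(n=44, sse=1.369, rmse=0.1784, r2=-0.13, dialect="n_minus_1"),
    "dialysis_legacy": dict(n=11, sse=0.389, rmse=0.1881, r2=0.36, dialect="n"),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative recipe for one synthetic cohort.

    ``noise_sd`` is the additive Gaussian measurement noise (mm) about the
    true curve; ``lr_jitter_sd`` adds extra independent per-side noise on
    top of it for bilateral cohorts.  ``bilateral`` cohorts yield exactly
    two rows (sides L and R) per patient at a shared age.
    """

    group: str
    n_patients: int
    age_range: tuple[float, float]
    true_params: LogisticParams
    noise_sd: float
    bilateral: bool = True
    lr_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError(f"age_range must be increasing, got {self.age_range}")
        if self.noise_sd < 0 or self.lr_jitter_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def n_observations(self) -> int:
        return 2 * self.n_patients if self.bilateral else self.n_patients


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort; deterministic for a given spec seed.

    Returns a DataFrame in the standard cohort schema (patient_id, sex,
    group, statin columns, age_years, side, imt_mm).  Ages are uniform on
    the recipe's range; every IMT is truncated below at 0.05 mm so noise cannot
    produce a non-physical thickness.
    """
    from .logistic import imt_at_age  # local import keeps module load light

    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_patients)
    sides = ["L", "R"] if spec.bilateral else ["U"]

    rows = []
    for i, age in enumerate(ages):
        true_imt = imt_at_age(spec.true_params, age)
        for side in sides:
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
            jitter = rng.normal(0.0, spec.lr_jitter_sd) if spec.lr_jitter_sd else 0.0
            rows.append(
                {
                    "patient_id": f"{spec.group}-{i:04d}",
                    "sex": "M",
                    "group": spec.group,
                    "statin_status": _statin_status(spec.group),
                    "statin_drug": "",
                    "statin_dose_mg": "",
                    "statin_duration_months": "",
                    "age_years": float(age),
                    "side": side,
                    "imt_mm": max(MIN_IMT_MM, float(true_imt + noise + jitter)),
                }
            )
    return pd.DataFrame(rows)


def _statin_status(group: str) -> str:
    if group == "statin_medicated":
        return "on"
    if group == "non_medicated":
        return "none"
    return "mixed"


def presets(seed: int = 0) -> dict[str, CohortSpec]:
    """The four named cohort recipes mirroring the reported study groups.

    Group sizes regenerate the printed observation counts exactly:
    aggregate 31 patients x 2 arteries = 62, non-medicated 9 x 2 = 18,
    statin-medicated 22 x 2 = 44, and the legacy dialysis sample 11
    unilateral points over its narrower 53-78 y age window.
    """
    new_ages = (19.0, 74.0)
    return {
        "aggregate": CohortSpec(
            group="aggregate",
            n_patients=31,
            age_range=new_ages,
            true_params=REFERENCE_CURVES["aggregate"],
            noise_sd=REFERENCE_COHORT_META["aggregate"]["rmse"],
            bilateral=True,
            seed=seed,
        ),
        "non_medicated": CohortSpec(
            group="non_medicated",
            n_patients=9,
            age_range=new_ages,
            true_params=REFERENCE_CURVES["non_medicated"],
            noise_sd=REFERENCE_COHORT_META["non_medicated"]["rmse"],
            bilateral=True,
            seed=seed + 1,
        ),
        "statin_medicated": CohortSpec(
            group="statin_medicated",
            n_patients=22,
            age_range=new_ages,
            true_params=REFERENCE_CURVES["statin_medicated"],
            noise_sd=REFERENCE_COHORT_META["statin_medicated"]["rmse"],
            bilateral=True,
            seed=seed + 2,
        ),
        "dialysis_legacy": CohortSpec(
            group="dialysis_legacy",
            n_patients=11,
            age_range=(53.0, 78.0),
            true_params=REFERENCE_CURVES["dialysis_legacy"],
            noise_sd=REFERENCE_COHORT_META["dialysis_legacy"]["rmse"],
            bilateral=False,
            seed=seed + 3,
        ),
    }


def scaled_preset(name: str, factor: int, seed: int = 0) -> CohortSpec:
    """A preset with its patient count multiplied, for recovery studies."""
    spec = presets(seed)[name]
    return replace(spec, n_patients=spec.n_patients * factor)
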
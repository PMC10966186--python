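"""Logistic inference of endothermy probability from HMC.

The coefficients of the published phylogenetic logistic regression are
treated as configuration (they were calibrated on extant tetrapods
elsewhere); only prediction and cut-off classification are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.special import expit

from .histology import CanalMeasurementSet, SpecimenRecord

__all__ = ["LogisticModel", "predict_pend", "classify", "classify_measurements"]

ECTOTHERMY = "ectothermy"
ENDOTHERMY = "endothermy"


@dataclass(frozen=True)
class LogisticModel:
    """Published logistic model mapping HMC (µm) to probability of endothermy.

    Attributes
    ----------
    coefficient
        Slope on HMC (per µm). Negative: larger canals mean lower
        probability of endothermy.
    intercept
        Intercept of the linear predictor (dimensionless).
    threshold
        Cut-off probability; ``p_end >= threshold`` classifies as
        endothermic (boundary inclusive).
    """

    coefficient: float = -0.45
    intercept: float = 6.04
    threshold: float = 0.59

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold {self.threshold} outside (0, 1)")


def predict_pend(hmc: float, model: LogisticModel = LogisticModel()) -> float:
    """Probability of endothermy for a harmonic mean canal diameter.

    Computes ``expit(c * HMC + i)``, numerically stable for arbitrarily
    large linear predictors (no overflow).
    """
    if not hmc > 0:
        raise ValueError(f"hmc must be positive, got {hmc!r}")
    return float(expit(model.coefficient * hmc + model.intercept))


def classify(p_end: float, model: LogisticModel = LogisticModel()) -> str:
    """Binary thermophysiological status from a probability of endothermy."""
    if not 0.0 <= p_end <= 1.0:
        raise ValueError(f"p_end={p_end!r} outside [0, 1]")
    return ENDOTHERMY if p_end >= model.threshold else ECTOTHERMY


def classify_measurements(
    sets: Iterable[CanalMeasurementSet],
    model: LogisticModel = LogisticModel(),
) -> list[SpecimenRecord]:
    """HMC, p_end and status for each thin section."""
    records = []
    for s in sets:
        hmc = s.hmc
        p = predict_pend(hmc, model)
        records.append(
            SpecimenRecord(
                specimen_id=s.specimen_id,
                taxon=s.taxon,
                hmc=hmc,
                p_end=p,
                status=classify(p, model),
            )
        )
    return records
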
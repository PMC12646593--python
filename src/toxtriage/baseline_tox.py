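"""Baseline-toxicity (narcosis) QSARs per test species.

Baseline toxicity is the minimal, nonspecific toxicity every chemical exerts
through membrane partitioning. Each species model is a linear regression

    -log10(effect concentration) = a * log10 D_lip/w + b

with the liposome-water distribution ratio as descriptor, which keeps the
QSAR applicable to ionizable chemicals. The registry carries the five frozen
test-system models; the Drosophila model operates on feed concentration
(BMD50, mol/L feed) and must not be pooled with aqueous LC50 models.

The specificity ratio SR = predicted baseline effect concentration divided
by the experimentally observed effect concentration flags chemicals whose
observed potency exceeds baseline expectation: SR >= 10 (inclusive, the
conventional narcosis cutoff) is classified specific/reactive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import (
    InsufficientDataError,
    SingularFitError,
    UnknownSpeciesError,
    ValidationError,
)
from .partitioning import LOG_DLIPW_FLOOR

ENDPOINT_LC50_AQUEOUS = "LC50_aqueous_mol_per_L"
ENDPOINT_BMD50_FEED = "BMD50_feed_mol_per_L_feed"
ENDPOINT_IC10_CELL = "IC10_cell"


@dataclass(frozen=True)
class QSARModel:
    """One species' baseline-toxicity regression (slope a, intercept b)."""

    species: str
    a: float
    b: float
    r2: float | None = None
    n: int | None = None
    endpoint: str = ENDPOINT_LC50_AQUEOUS
    provenance: str = "user-fitted"

    def __post_init__(self):
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValidationError("non-finite QSAR coefficients")
        if self.r2 is not None and not 0.0 <= self.r2 <= 1.0:
            raise ValidationError(f"r2 out of [0, 1]: {self.r2}")


@dataclass(frozen=True)
class SpecificityResult:
    """Specificity ratio and its baseline vs specific/reactive call."""

    sr: float
    classification: str  # "baseline" | "specific/reactive"

    def __post_init__(self):
        if self.sr <= 0:
            raise ValidationError("specificity ratio must be positive")


_REGISTRY: dict[str, QSARModel] = {
    m.species: m
    for m in (
        QSARModel(
            "C. elegans", a=0.81, b=1.15, endpoint=ENDPOINT_LC50_AQUEOUS,
            provenance="registry: rescaled from a Kow-based model",
        ),
        QSARModel(
            "D. magna", a=0.82, b=1.48, endpoint=ENDPOINT_LC50_AQUEOUS,
            provenance="registry: derived from a Kow-based 48-h LC50 model",
        ),
        QSARModel(
            "D. rerio", a=0.99, b=0.78, endpoint=ENDPOINT_LC50_AQUEOUS,
            provenance="registry: developed directly on D_lip/w",
        ),
        QSARModel(
            "X. laevis", a=0.61, b=2.12, r2=0.690, n=22,
            endpoint=ENDPOINT_LC50_AQUEOUS,
            provenance="registry: fit to 22 cross-confirmed baseline toxicants",
        ),
        QSARModel(
            "D. melanogaster", a=0.83, b=0.52, r2=0.724, n=11,
            endpoint=ENDPOINT_BMD50_FEED,
            provenance="registry: fit to 11 baseline toxicants, feed dosing",
        ),
    )
}


def species_registry() -> dict[str, QSARModel]:
    """The five frozen per-species baseline-toxicity models."""
    return dict(_REGISTRY)


def get_species_model(label: str) -> QSARModel:
    try:
        return _REGISTRY[label]
    except KeyError:
        raise UnknownSpeciesError(label, sorted(_REGISTRY)) from None


def predict_neg_log_lc50(model: QSARModel, log_dlipw: float) -> float:
    """-log10 effect concentration (model units) at ``log_dlipw``.

    Values below the D_lip/w domain floor of -1 are computed anyway but
    flagged with a warning: the QSAR is not validated there.
    """
    if log_dlipw < LOG_DLIPW_FLOOR:
        warnings.warn(
            f"log_dlipw={log_dlipw} below the QSAR domain floor "
            f"{LOG_DLIPW_FLOOR}; prediction is extrapolated",
            stacklevel=2,
        )
    return model.a * log_dlipw + model.b


def predict_effect_concentration(model: QSARModel, log_dlipw: float) -> float:
    """Effect concentration (mol/L in the model's units) at ``log_dlipw``."""
    return 10.0 ** (-predict_neg_log_lc50(model, log_dlipw))


def fit_baseline_qsar(
    pairs: Sequence[tuple[float, float]],
    species: str,
    endpoint: str = ENDPOINT_LC50_AQUEOUS,
) -> QSARModel:
    """Ordinary least squares of -log effect concentration on log D_lip/w."""
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(pairs)}")
    x = [float(p[0]) for p in pairs]
    y = [float(p[1]) for p in pairs]
    if not all(math.isfinite(v) for v in x + y):
        raise ValidationError("non-finite values in fit input")
    if max(x) == min(x):
        raise SingularFitError("zero variance in log_dlipw")
    res = stats.linregress(x, y)
    return QSARModel(
        species=species,
        a=float(res.slope),
        b=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(pairs),
        endpoint=endpoint,
        provenance="user-fitted",
    )


def fit_baseline_qsar_ci(
    pairs: Sequence[tuple[float, float]], alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided (1-alpha) confidence interval for the fitted slope."""
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(pairs)}")
    x = [float(p[0]) for p in pairs]
    y = [float(p[1]) for p in pairs]
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(1 - alpha / 2, df=len(pairs) - 2)
    return (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)


def specificity_ratio(
    predicted_effect: float, experimental_effect: float, threshold: float = 10.0
) -> SpecificityResult:
    """Classify a chemical as baseline or specific/reactive.

    SR = predicted / experimental; SR >= threshold (boundary inclusive) is
    specific/reactive, i.e. the chemical is more potent than hydrophobicity
    alone explains.
    """
    if predicted_effect <= 0 or experimental_effect <= 0:
        raise ValidationError("effect concentrations must be positive")
    sr = predicted_effect / experimental_effect
    cls = "specific/reactive" if sr >= threshold else "baseline"
    return SpecificityResult(sr=sr, classification=cls)
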
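"""Partition-constant prediction and ionization-corrected distribution ratios.

Per-species partition constants (liposome-water, BSA-water,
structural-protein-water) are predicted from log K_ow of the neutral species
through pluggable linear maps, then combined into distribution ratios at a
given pH as species-fraction-weighted sums:

    D_x/w(pH) = sum_i f_i * K_x/w,i

Species rules follow standard sorption practice for screening-level models:

* membranes: charged species partition about one log unit below the neutral
  species (configurable ``ion_offset``); log D_lip/w is floored at -1, the
  empirical lowest membrane affinity.
* BSA: cations bind like the neutral species; anions follow a separate
  (stronger-binding) linear map; hydrophilic chemicals (log K_ow < 2) use a
  fixed constant of 1.31 -- interpreted by default as the linear ratio
  K_BSA/w = 1.31 L/L (``hydrophilic_floor_is_log=True`` switches to
  log10 K = 1.31; see docs/methods.md for why the linear reading is the
  default).
* structural proteins: same structure as BSA with the anion term attenuated
  by ``sp_anion_attenuation`` log units (anions bind SPs weaker than BSA).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import MissingInputError, ValidationError
from .speciation import DEFAULT_PH, SpeciesFractions, daw_at_ph, species_fractions

LOG_DLIPW_FLOOR = -1.0
HYDROPHILIC_LOG_KOW_CUTOFF = 2.0
HYDROPHILIC_BSA_CONSTANT = 1.31


@dataclass(frozen=True)
class LinearMapModel:
    """log10 K = slope * log10 K_ow + intercept."""

    slope: float
    intercept: float
    name: str = "linear"

    def __post_init__(self):
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValidationError("non-finite linear map coefficients")

    def __call__(self, log_kow: float) -> float:
        if log_kow is None:
            raise MissingInputError(f"{self.name}: log_kow is required")
        return self.slope * log_kow + self.intercept


@dataclass(frozen=True)
class PartitionSet:
    """Ionization-corrected log10 distribution ratios at one pH."""

    ph: float
    log_daw: float
    log_dlipw: float
    log_dbsaw: float
    log_dspw: float

    def __post_init__(self):
        for name in ("log_dlipw", "log_dbsaw", "log_dspw"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"non-finite {name}")
        if self.log_dlipw < LOG_DLIPW_FLOOR - 1e-12:
            raise ValidationError(f"log_dlipw below floor {LOG_DLIPW_FLOOR}")

    @property
    def daw(self) -> float:
        return 10.0**self.log_daw

    @property
    def dlipw(self) -> float:
        return 10.0**self.log_dlipw


@dataclass(frozen=True)
class PartitionConfig:
    """Prediction backends and species rules, echoed into audit reports.

    The defaults are the package's documented screening-level maps; any of
    them can be replaced from a JSON config (see :func:`load_partition_config`).
    """

    lipw_model: LinearMapModel = field(
        default_factory=lambda: LinearMapModel(1.01, 0.12, "lipw-default")
    )
    bsa_neutral_model: LinearMapModel = field(
        default_factory=lambda: LinearMapModel(1.15, -1.85, "bsaw-neutral-default")
    )
    bsa_anion_model: LinearMapModel = field(
        default_factory=lambda: LinearMapModel(0.30, 3.00, "bsaw-anion-default")
    )
    sp_model: LinearMapModel = field(
        default_factory=lambda: LinearMapModel(0.78, -0.84, "spw-default")
    )
    ion_offset: float = 1.0
    sp_anion_attenuation: float = 1.0
    hydrophilic_floor_is_log: bool = False
    version: str = "defaults-1"

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "lipw_model": vars(self.lipw_model),
            "bsa_neutral_model": vars(self.bsa_neutral_model),
            "bsa_anion_model": vars(self.bsa_anion_model),
            "sp_model": vars(self.sp_model),
            "ion_offset": self.ion_offset,
            "sp_anion_attenuation": self.sp_anion_attenuation,
            "hydrophilic_floor_is_log": self.hydrophilic_floor_is_log,
        }


def load_partition_config(path: str | Path) -> PartitionConfig:
    """Read a :class:`PartitionConfig` from a JSON key-value file."""
    raw = json.loads(Path(path).read_text())
    cfg = PartitionConfig()
    kwargs = {}
    for key in ("lipw_model", "bsa_neutral_model", "bsa_anion_model", "sp_model"):
        if key in raw:
            kwargs[key] = LinearMapModel(**raw[key])
    for key in ("ion_offset", "sp_anion_attenuation", "hydrophilic_floor_is_log", "version"):
        if key in raw:
            kwargs[key] = raw[key]
    return replace(cfg, **kwargs)


def predict_log_klipw_neutral(log_kow: float | None, model: LinearMapModel) -> float:
    """Neutral-species liposome-water constant from log K_ow."""
    if log_kow is None:
        raise MissingInputError("predict_log_klipw_neutral: log_kow is required")
    return model(log_kow)


def _weighted_log_d(terms: list[tuple[float, float]]) -> float:
    """log10 of sum f_i * 10^logK_i, stably in the log domain."""
    live = [(f, lk) for f, lk in terms if f > 0.0]
    if not live:
        return -math.inf
    m = max(lk for _, lk in live)
    return m + math.log10(sum(f * 10.0 ** (lk - m) for f, lk in live))


def dlipw_at_ph(
    log_klipw_neutral: float,
    fractions: SpeciesFractions,
    ion_offset: float = 1.0,
) -> float:
    """log10 liposome-water distribution ratio, floored at -1.

    Charged species carry the neutral constant reduced by ``ion_offset`` log
    units; the species-weighted sum is log-transformed and clipped from below
    at the empirical floor of -1.
    """
    log_k_ion = log_klipw_neutral - ion_offset
    raw = _weighted_log_d(
        [
            (fractions.f_neutral, log_klipw_neutral),
            (fractions.f_charged, log_k_ion),
        ]
    )
    return max(raw, LOG_DLIPW_FLOOR)


def _bsa_species_constants(
    log_kow: float | None, config: PartitionConfig
) -> tuple[float, float]:
    """(log K for neutral+cation, log K for anions) for BSA binding."""
    if log_kow is None:
        raise MissingInputError("BSA-water prediction requires log_kow")
    if log_kow < HYDROPHILIC_LOG_KOW_CUTOFF:
        if config.hydrophilic_floor_is_log:
            log_k_neutral = HYDROPHILIC_BSA_CONSTANT
        else:
            log_k_neutral = math.log10(HYDROPHILIC_BSA_CONSTANT)
    else:
        log_k_neutral = config.bsa_neutral_model(log_kow)
    log_k_anion = config.bsa_anion_model(log_kow)
    return log_k_neutral, log_k_anion


def dbsaw_at_ph(
    log_kow: float | None,
    fractions: SpeciesFractions,
    config: PartitionConfig | None = None,
) -> float:
    """log10 BSA-water distribution ratio at the fractions' pH.

    Cations are assigned the neutral-species constant; anions use the
    stronger anion map; hydrophilic chemicals (log K_ow < 2) use the fixed
    1.31 constant for the neutral/cation term.
    """
    config = config or PartitionConfig()
    log_k_neutral, log_k_anion = _bsa_species_constants(log_kow, config)
    return _weighted_log_d(
        [
            (fractions.f_neutral + fractions.f_plus + fractions.f_plus2, log_k_neutral),
            (fractions.f_minus + fractions.f_minus2, log_k_anion),
        ]
    )


def dspw_at_ph(
    log_kow: float | None,
    fractions: SpeciesFractions,
    config: PartitionConfig | None = None,
) -> float:
    """log10 structural-protein-water distribution ratio.

    Same species-weighted structure as BSA with the SP neutral map and the
    anion term attenuated by ``sp_anion_attenuation`` log units.
    """
    config = config or PartitionConfig()
    if log_kow is None:
        raise MissingInputError("SP-water prediction requires log_kow")
    log_k_neutral = config.sp_model(log_kow)
    _, log_k_anion_bsa = _bsa_species_constants(log_kow, config)
    log_k_anion = log_k_anion_bsa - config.sp_anion_attenuation
    return _weighted_log_d(
        [
            (fractions.f_neutral + fractions.f_plus + fractions.f_plus2, log_k_neutral),
            (fractions.f_minus + fractions.f_minus2, log_k_anion),
        ]
    )


def partition_record(
    log_kow: float | None,
    profile,
    log_kaw: float | None = None,
    ph: float = DEFAULT_PH,
    config: PartitionConfig | None = None,
) -> PartitionSet:
    """Full :class:`PartitionSet` for one chemical at ``ph``.

    Both ``log_kow`` and ``log_kaw`` are required; absent inputs raise
    :class:`MissingInputError` (they are never imputed). A fully ionized
    chemical has D_aw = 0 and reports ``log_daw = -inf``.
    """
    config = config or PartitionConfig()
    if log_kow is None:
        raise MissingInputError("partition_record: log_kow is required")
    fr = species_fractions(profile, ph)
    log_klipw = predict_log_klipw_neutral(log_kow, config.lipw_model)
    log_dlipw = dlipw_at_ph(log_klipw, fr, config.ion_offset)
    log_dbsaw = dbsaw_at_ph(log_kow, fr, config)
    log_dspw = dspw_at_ph(log_kow, fr, config)
    if log_kaw is None:
        raise MissingInputError("partition_record: log_kaw is required")
    daw = daw_at_ph(log_kaw, fr)
    log_daw = math.log10(daw) if daw > 0 else -math.inf
    return PartitionSet(
        ph=ph,
        log_daw=log_daw,
        log_dlipw=log_dlipw,
        log_dbsaw=log_dbsaw,
        log_dspw=log_dspw,
    )
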
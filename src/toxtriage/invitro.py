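"""Mass-balance model of chemical availability in FBS-supplemented cell assays.

Medium proteins (BSA surrogate) and lipids are the dominant sorptive phases.
With distribution ratios D_BSA/w, D_lip/w, D_SP/w at the assay pH, the model
computes:

* ``d_medium_w`` -- partition ratio between the pooled medium sorptive phase
  (protein + lipid) and water, with phase volume fractions normalized to the
  sorptive-phase volume;
* ``d_cell_w``  -- cell-water ratio from cellular protein, lipid and water
  volume fractions (structural proteins surrogate the cell protein);
* ``f_free``    -- freely dissolved fraction,
  1 / (1 + D_medium/w * V_sorb/V_medium + D_cell/w * V_cell/V_medium);
* ``ic10_nominal_baseline`` / ``ic10_free`` -- nominal and freely dissolved
  baseline-cytotoxicity concentrations derived from the critical membrane
  concentration IC10_membrane (default 26 mmol per liter lipid, 10% growth
  inhibition endpoint).

The two volume-fraction conventions are kept mutually consistent: the
medium-sorption term of ``f_free`` equals
D_BSA/w * VF_protein,medium + D_lip/w * VF_lipid,medium with the VFs per
medium volume, which is also the form the nominal-IC10 expression uses.
Defaults encode a 10% FBS medium (0.3% protein, 0.007% lipid by volume) and
a typical cell composition (3% protein, 0.5% lipid, rest water). Binding to
plastic is not modeled; treated (anionic) plates can bind cations, so a
warning is emitted for predominantly cationic chemicals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ValidationError

MMOL_PER_MOL = 1e3


@dataclass(frozen=True)
class BioassaySetup:
    """Volume composition of medium and cells for the mass balance.

    ``vf_protein_medium`` and ``vf_lipid_medium`` are volumes per medium
    volume; the cell composition fractions are per cell volume and must sum
    to 1. ``v_cell_over_v_bioassay`` defaults to 0: in 10% FBS media the
    cellular uptake term is negligible unless supplied.
    """

    vf_protein_medium: float = 0.003
    vf_lipid_medium: float = 0.00007
    v_cell_over_v_bioassay: float = 0.0
    vf_protein_cell: float = 0.03
    vf_lipid_cell: float = 0.005
    vf_water_cell: float = 0.965

    def __post_init__(self):
        for name in (
            "vf_protein_medium",
            "vf_lipid_medium",
            "v_cell_over_v_bioassay",
            "vf_protein_cell",
            "vf_lipid_cell",
            "vf_water_cell",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} out of [0, 1]: {v}")
        cell_sum = self.vf_protein_cell + self.vf_lipid_cell + self.vf_water_cell
        if abs(cell_sum - 1.0) > 1e-9:
            raise ValidationError(f"cell volume fractions sum to {cell_sum}, not 1")

    @property
    def vf_sorptive_medium(self) -> float:
        """Total sorptive-phase volume per medium volume."""
        return self.vf_protein_medium + self.vf_lipid_medium


@dataclass(frozen=True)
class BaselineConstants:
    """Critical baseline-toxic membrane concentration, mmol per liter lipid."""

    ic10_membrane_mmol_per_l_lip: float = 26.0

    def __post_init__(self):
        if self.ic10_membrane_mmol_per_l_lip <= 0:
            raise ValidationError("ic10_membrane must be positive")


def d_medium_w(log_dbsaw: float, log_dlipw: float, setup: BioassaySetup) -> float:
    """Medium-sorptive-phase/water partition ratio (dimensionless).

    VFs here are normalized to the sorptive-phase volume, so the result is a
    convex combination of D_BSA/w and D_lip/w. An all-zero sorptive phase
    contributes nothing and returns 0.
    """
    total = setup.vf_sorptive_medium
    if total == 0.0:
        return 0.0
    vf_p = setup.vf_protein_medium / total
    vf_l = setup.vf_lipid_medium / total
    return vf_p * 10.0**log_dbsaw + vf_l * 10.0**log_dlipw


def d_cell_w(log_dspw: float, log_dlipw: float, setup: BioassaySetup) -> float:
    """Cell/water partition ratio from protein, lipid and water fractions."""
    return (
        setup.vf_protein_cell * 10.0**log_dspw
        + setup.vf_lipid_cell * 10.0**log_dlipw
        + setup.vf_water_cell
    )


def f_free(d_medium_w_ratio: float, d_cell_w_ratio: float, setup: BioassaySetup) -> float:
    """Freely dissolved fraction in the bioassay medium, in (0, 1]."""
    if d_medium_w_ratio < 0 or d_cell_w_ratio < 0:
        raise ValidationError("partition ratios must be non-negative")
    return 1.0 / (
        1.0
        + d_medium_w_ratio * setup.vf_sorptive_medium
        + d_cell_w_ratio * setup.v_cell_over_v_bioassay
    )


def ic10_nominal_baseline(
    log_dlipw: float,
    log_dbsaw: float,
    d_cell_w_ratio: float,
    setup: BioassaySetup,
    constants: BaselineConstants | None = None,
    cationic: bool = False,
) -> float:
    """Nominal baseline-cytotoxicity concentration, mol/L medium.

    (IC10_membrane / D_lip/w) * (1 + D_BSA/w*VF_protein,medium
    + D_lip/w*VF_lipid,medium + D_cell/w*V_cell/V_bioassay), with the VF
    terms per bioassay volume (medium and bioassay volume treated as equal).
    """
    constants = constants or BaselineConstants()
    dlipw = 10.0**log_dlipw
    if dlipw <= 0:
        raise ValidationError("D_lip/w must be positive")
    if cationic:
        warnings.warn(
            "cationic chemical: binding to tissue-culture-treated (anionic) "
            "plastic is not modeled and may reduce availability",
            stacklevel=2,
        )
    dbsaw = 10.0**log_dbsaw
    enhancement = (
        1.0
        + dbsaw * setup.vf_protein_medium
        + dlipw * setup.vf_lipid_medium
        + d_cell_w_ratio * setup.v_cell_over_v_bioassay
    )
    ic10_mmol = constants.ic10_membrane_mmol_per_l_lip / dlipw * enhancement
    return ic10_mmol / MMOL_PER_MOL


def ic10_free(log_dlipw: float, constants: BaselineConstants | None = None) -> float:
    """Freely dissolved baseline-cytotoxicity concentration, mol/L."""
    constants = constants or BaselineConstants()
    dlipw = 10.0**log_dlipw
    if dlipw <= 0:
        raise ValidationError("D_lip/w must be positive")
    return constants.ic10_membrane_mmol_per_l_lip / dlipw / MMOL_PER_MOL
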
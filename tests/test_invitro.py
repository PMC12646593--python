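"""Mass-balance dosimetry: compartment ratios, f_free and baseline IC10s."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxtriage.errors import ValidationError
from toxtriage.invitro import (
    BaselineConstants,
    BioassaySetup,
    d_cell_w,
    d_medium_w,
    f_free,
    ic10_free,
    ic10_nominal_baseline,
)
from toxtriage.partitioning import PartitionConfig, dbsaw_at_ph, dlipw_at_ph, dspw_at_ph
from toxtriage.registry import IonizationProfile
from toxtriage.speciation import species_fractions


def test_setup_invariants():
    with pytest.raises(ValidationError):
        BioassaySetup(vf_protein_cell=0.5, vf_lipid_cell=0.5, vf_water_cell=0.5)
    with pytest.raises(ValidationError):
        BioassaySetup(vf_protein_medium=1.5)
    with pytest.raises(ValidationError):
        BaselineConstants(ic10_membrane_mmol_per_l_lip=0.0)


def test_d_medium_w_is_convex_combination():
    setup = BioassaySetup()
    assert d_medium_w(3.0, 3.0, setup) == pytest.approx(1000.0, rel=1e-12)
    lipid_free = BioassaySetup(vf_lipid_medium=0.0)
    assert d_medium_w(3.0, 1.0, lipid_free) == pytest.approx(1000.0, rel=1e-12)


def test_d_medium_w_default_composition():
    # protein:lipid volumes 0.003:0.00007 -> (0.003*1000 + 0.00007*100)/0.00307
    setup = BioassaySetup()
    expected = (0.003 * 1000 + 0.00007 * 100) / 0.00307
    assert d_medium_w(3.0, 2.0, setup) == pytest.approx(expected, rel=1e-12)


def test_d_medium_w_zero_sorptive_volume_is_zero_not_error():
    setup = BioassaySetup(vf_protein_medium=0.0, vf_lipid_medium=0.0)
    assert d_medium_w(5.0, 5.0, setup) == 0.0


def test_d_cell_w_all_water_cell():
    setup = BioassaySetup(vf_protein_cell=0.0, vf_lipid_cell=0.0, vf_water_cell=1.0)
    assert d_cell_w(2.0, 3.0, setup) == pytest.approx(1.0, rel=1e-12)


def test_d_cell_w_default_composition():
    # D_SP/w=100, D_lip/w=1000 with (0.03, 0.005, 0.965) -> 3 + 5 + 0.965
    assert d_cell_w(2.0, 3.0, BioassaySetup()) == pytest.approx(8.965, rel=1e-12)


def test_d_cell_w_unity_everywhere():
    assert d_cell_w(0.0, 0.0, BioassaySetup()) == pytest.approx(1.0, rel=1e-12)


def test_f_free_closed_forms():
    setup = BioassaySetup(v_cell_over_v_bioassay=0.0)
    assert f_free(0.0, 0.0, setup) == 1.0
    # medium sorption term = D_medium/w * vf_sorptive = 1 -> half dissolved
    assert f_free(1.0 / setup.vf_sorptive_medium, 0.0, setup) == pytest.approx(0.5)
    assert f_free(9.0 / setup.vf_sorptive_medium, 0.0, setup) == pytest.approx(0.1)
    with pytest.raises(ValidationError):
        f_free(-1.0, 0.0, setup)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0, max_value=1e6),
    st.floats(min_value=0, max_value=1e6),
    st.floats(min_value=0, max_value=0.02),
    st.floats(min_value=0, max_value=0.001),
    st.floats(min_value=0, max_value=0.05),
)
def test_f_free_equals_three_compartment_mass_balance_oracle(
    dmw, dcw, vfp, vfl, vcell
):
    """f_free == C_w*V_w / (C_w*V_w + C_med*V_med + C_cell*V_cell) to 1e-12.

    The oracle builds explicit compartment amounts from D*V products with a
    unit aqueous concentration, independently of the closed form.
    """
    setup = BioassaySetup(
        vf_protein_medium=vfp, vf_lipid_medium=vfl, v_cell_over_v_bioassay=vcell
    )
    v_medium = 1.0
    amount_water = 1.0 * v_medium
    amount_sorbed = dmw * (setup.vf_sorptive_medium * v_medium)
    amount_cell = dcw * (vcell * v_medium)
    oracle = amount_water / (amount_water + amount_sorbed + amount_cell)
    assert f_free(dmw, dcw, setup) == pytest.approx(oracle, abs=1e-12, rel=1e-12)


def test_f_free_monotone_in_each_sorption_term():
    setup = BioassaySetup(v_cell_over_v_bioassay=0.01)
    base = f_free(100.0, 10.0, setup)
    assert f_free(200.0, 10.0, setup) < base
    assert f_free(100.0, 20.0, setup) < base


def test_ic10_free_inverse_in_dlipw():
    assert ic10_free(0.0) == pytest.approx(26e-3, rel=1e-12)  # mol/L at D=1
    assert ic10_free(3.0) == pytest.approx(26e-6, rel=1e-12)
    assert ic10_free(1.0) == pytest.approx(ic10_free(0.0) / 10, rel=1e-12)


def test_ic10_nominal_reduces_to_membrane_constant_without_sorbents():
    bare = BioassaySetup(
        vf_protein_medium=0.0, vf_lipid_medium=0.0, v_cell_over_v_bioassay=0.0
    )
    got = ic10_nominal_baseline(0.0, 0.0, 0.0, bare)
    assert got == pytest.approx(0.026, rel=1e-12)
    assert ic10_nominal_baseline(3.0, 0.0, 0.0, bare) == pytest.approx(
        26e-6, rel=1e-12
    )


def test_ic10_nominal_with_protein_binding_term():
    setup = BioassaySetup(vf_lipid_medium=0.0, v_cell_over_v_bioassay=0.0)
    got = ic10_nominal_baseline(3.0, 3.0, 0.0, setup)
    assert got == pytest.approx(0.026 * (1 + 3) / 1000, rel=1e-12)  # 1.04e-4


def test_ic10_nominal_never_below_free_times_enhancement_one():
    setup = BioassaySetup(v_cell_over_v_bioassay=0.001)
    for log_dlipw in (-1.0, 0.0, 2.0, 4.0):
        nominal = ic10_nominal_baseline(log_dlipw, log_dlipw, 5.0, setup)
        assert nominal >= ic10_free(log_dlipw) * (1 - 1e-12)


def test_cationic_plate_binding_warning():
    with pytest.warns(UserWarning, match="cationic"):
        ic10_nominal_baseline(2.0, 2.0, 0.0, BioassaySetup(), cationic=True)


def neutral_sweep_f_free(log_dlipw_grid):
    """f_free for non-ionizable chemicals across a log D_lip/w grid."""
    cfg = PartitionConfig()
    setup = BioassaySetup()
    fr = species_fractions(IonizationProfile(), 7.4)
    out = []
    for target in log_dlipw_grid:
        log_kow = (target - cfg.lipw_model.intercept) / cfg.lipw_model.slope
        log_dlipw = dlipw_at_ph(cfg.lipw_model(log_kow), fr, cfg.ion_offset)
        log_dbsaw = dbsaw_at_ph(log_kow, fr, cfg)
        log_dspw = dspw_at_ph(log_kow, fr, cfg)
        ff = f_free(
            d_medium_w(log_dbsaw, log_dlipw, setup),
            d_cell_w(log_dspw, log_dlipw, setup),
            setup,
        )
        out.append((log_dlipw, ff))
    return out


def test_availability_contract_under_default_fbs_setup():
    """Low-hydrophobicity chemicals are freely dissolved, high ones bound.

    Under the default 10% FBS composition, neutral chemicals on a half-log
    sweep are >95% free below log D_lip/w of 3 and <5% free above 5.
    """
    sweep = neutral_sweep_f_free(np.arange(-1.0, 8.01, 0.5))
    for log_dlipw, ff in sweep:
        if log_dlipw < 3.0:
            assert ff > 0.95, (log_dlipw, ff)
        elif log_dlipw > 5.0:
            assert ff < 0.05, (log_dlipw, ff)
    # and the transition is monotone
    ffs = [ff for _, ff in sweep]
    assert all(b <= a + 1e-12 for a, b in zip(ffs, ffs[1:]))
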
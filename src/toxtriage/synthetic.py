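"""Synthetic chemical pools and effect datasets for offline pipeline runs.

The generator emulates the marginal property structure of a realistic
screening-panel nominee pool: log K_ow from a truncated normal centred at
2.31 (range -4.63 to 8.50, spanning the twelve orders of magnitude real
collections cover), a speciation mix of roughly 40% neutral-dominant, 30%
strongly charged and 30% intermediate chemicals at pH 7.4, a small volatile
subpopulation, near-supplier purities, and lognormal costs. Properties are
drawn independently -- the generator reproduces marginals, not the joint
chemistry (see docs/methods.md).

Effect datasets are QSAR-consistent: baseline chemicals scatter around the
generating species model with lognormal noise (Gaussian on the -log10
concentration scale); specifically acting chemicals are shifted toward
higher potency by a fixed number of log units so that specificity-ratio
classification can be scored against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .baseline_tox import QSARModel
from .errors import ValidationError
from .registry import ACID, BASE, ChemicalRecord, IonizationProfile, cas_check_digit

TOXICITY_GROUPS = (
    "hepatotoxicant", "neurotoxicant", "nephrotoxicant", "cardiotoxicant",
    "immunotoxicant", "developmental_neurotoxicant", "endocrine_disruptor",
    "developmental_toxicant",
)

N_MOA_TAGS = 40


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults encode the emulated pool structure."""

    n: int = 200
    seed: int = 0
    log_kow_mean: float = 2.31
    log_kow_sd: float = 2.0
    log_kow_range: tuple[float, float] = (-4.63, 8.50)
    frac_neutral_dominant: float = 0.40
    frac_charged: float = 0.30
    volatile_fraction: float = 0.10
    cost_lognorm_median_eur: float = 200.0
    cost_lognorm_sigma: float = 1.0
    purity_high_fraction: float = 0.90
    frac_available: float = 0.95
    frac_restricted: float = 0.02
    frac_hazard: float = 0.02
    frac_stable: float = 0.95
    frac_exposome: float = 0.25
    frac_reference: float = 0.05
    frac_moa_exception: float = 0.01

    def __post_init__(self):
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if self.frac_neutral_dominant + self.frac_charged > 1.0 + 1e-12:
            raise ValidationError("speciation fractions sum above 1")
        lo, hi = self.log_kow_range
        if not lo <= self.log_kow_mean <= hi:
            raise ValidationError("log_kow_range must contain log_kow_mean")


def _draw_ionization(rng: np.random.Generator, kind: str) -> IonizationProfile:
    """One ionization profile per speciation class at pH 7.4."""
    acid = rng.random() < 0.5
    if kind == "neutral":
        if rng.random() < 0.5:
            return IonizationProfile()
        pka = rng.uniform(9.0, 11.0) if acid else rng.uniform(3.0, 5.5)
    elif kind == "charged":  # > 80% ionized: |pKa - 7.4| > 0.7
        pka = rng.uniform(2.0, 6.5) if acid else rng.uniform(8.3, 11.0)
    else:  # intermediate
        pka = rng.uniform(6.8, 8.0)
    group = (float(pka), ACID if acid else BASE)
    return IonizationProfile(groups=(group,))


def generate_chemicals(config: SyntheticConfig | None = None) -> list[ChemicalRecord]:
    """A reproducible nominee pool with the configured property marginals."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.log_kow_range
    a = (lo - config.log_kow_mean) / config.log_kow_sd
    b = (hi - config.log_kow_mean) / config.log_kow_sd
    log_kows = stats.truncnorm.rvs(
        a, b, loc=config.log_kow_mean, scale=config.log_kow_sd,
        size=config.n, random_state=rng,
    )

    records = []
    for i in range(config.n):
        u_class = rng.random()
        if u_class < config.frac_neutral_dominant:
            ion_kind = "neutral"
        elif u_class < config.frac_neutral_dominant + config.frac_charged:
            ion_kind = "charged"
        else:
            ion_kind = "intermediate"
        profile = _draw_ionization(rng, ion_kind)

        volatile = rng.random() < config.volatile_fraction
        log_kaw = rng.uniform(-3.0, 0.5) if volatile else rng.uniform(-10.0, -5.0)

        if rng.random() < config.purity_high_fraction:
            purity = rng.uniform(98.0, 100.0)
        else:
            purity = rng.uniform(90.0, 98.0)
        cost = config.cost_lognorm_median_eur * float(
            np.exp(rng.normal(0.0, config.cost_lognorm_sigma))
        )

        n_groups = int(rng.integers(1, 4))
        groups = frozenset(rng.choice(TOXICITY_GROUPS, size=n_groups, replace=False))
        n_tags = int(rng.integers(1, 3))
        tags = frozenset(
            f"moa_{t:02d}" for t in rng.choice(N_MOA_TAGS, size=n_tags, replace=False)
        )

        part1, part2 = str(10000 + i), f"{i % 100:02d}"
        cas = f"{part1}-{part2}-{cas_check_digit(part1 + part2)}"
        records.append(
            ChemicalRecord(
                name=f"CHEM-{i:05d}",
                cas=cas,
                dtxsid=f"DTXSID{7000000 + i}",
                log_kow=float(log_kows[i]),
                ionization=profile,
                log_kaw=float(log_kaw),
                purity_pct=float(purity),
                cost_eur=float(cost),
                available=bool(rng.random() < config.frac_available),
                restricted=bool(rng.random() < config.frac_restricted),
                hazard_excluded=bool(rng.random() < config.frac_hazard),
                stability_ok=bool(rng.random() < config.frac_stable),
                toxicity_groups=groups,
                moa_tags=tags,
                exposome=bool(rng.random() < config.frac_exposome),
                reference_compound=bool(rng.random() < config.frac_reference),
                moa_exception=bool(rng.random() < config.frac_moa_exception),
            )
        )
    return records


@dataclass(frozen=True)
class EffectObservation:
    """One synthetic effect measurement with its ground-truth class."""

    chemical_id: str
    log_dlipw: float
    observed_effect_mol_per_l: float
    true_class: str  # "baseline" | "specific"


def generate_effect_data(
    model: QSARModel,
    n: int,
    noise_sd: float = 0.3,
    specific_fraction: float = 0.0,
    specific_shift: float = 2.0,
    seed: int = 0,
    log_dlipw_range: tuple[float, float] = (-1.0, 4.0),
) -> list[EffectObservation]:
    """QSAR-consistent effect concentrations with optional specific actors.

    Baseline: -log10 C = a*log_dlipw + b + N(0, noise_sd). Specific
    chemicals get an extra ``specific_shift`` log units of potency.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if specific_fraction > 0 and specific_shift <= 0:
        raise ValidationError("specific_shift must be positive when used")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        x = float(rng.uniform(*log_dlipw_range))
        specific = rng.random() < specific_fraction
        y = model.a * x + model.b + float(rng.normal(0.0, noise_sd))
        if specific:
            y += specific_shift
        out.append(
            EffectObservation(
                chemical_id=f"EFF-{i:05d}",
                log_dlipw=x,
                observed_effect_mol_per_l=10.0 ** (-y),
                true_class="specific" if specific else "baseline",
            )
        )
    return out
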
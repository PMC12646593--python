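"""Henderson-Hasselbalch speciation and the ionization-corrected D_aw.

Each ionizable group is treated as an independent two-state site. Relative
to the fully neutral reference microstate, deprotonating an acid group with
constant pKa contributes a weight factor 10^(pH - pKa), and protonating a
base group contributes 10^(pKa - pH). The population of each net-charge
state is the normalized sum of microstate weights with that charge; with at
most two acids and two bases the net charge spans -2..+2. All net-neutral
microstates, including zwitterions (one deprotonated acid plus one
protonated base), are pooled into the neutral fraction.

Only the neutral species has appreciable vapor pressure, so the air-water
distribution ratio at a given pH is D_aw = K_aw * f_neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .registry import IonizationProfile

DEFAULT_PH = 7.4

_FIELD_BY_CHARGE = {-2: "f_minus2", -1: "f_minus", 0: "f_neutral", 1: "f_plus", 2: "f_plus2"}


@dataclass(frozen=True)
class SpeciesFractions:
    """Net-charge state populations at one pH; fractions sum to 1."""

    f_neutral: float
    f_minus: float
    f_minus2: float
    f_plus: float
    f_plus2: float
    ph: float

    def __post_init__(self):
        fracs = self.as_dict()
        for name, f in fracs.items():
            if not -1e-12 <= f <= 1 + 1e-12:
                raise ValidationError(f"{name} out of [0, 1]: {f}")
        if abs(sum(fracs.values()) - 1.0) > 1e-12:
            raise ValidationError(f"fractions sum to {sum(fracs.values())}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "f_neutral": self.f_neutral,
            "f_minus": self.f_minus,
            "f_minus2": self.f_minus2,
            "f_plus": self.f_plus,
            "f_plus2": self.f_plus2,
        }

    @property
    def f_charged(self) -> float:
        return 1.0 - self.f_neutral


def species_fractions(profile: IonizationProfile, ph: float = DEFAULT_PH) -> SpeciesFractions:
    """Net-charge fractions of a chemical at ``ph``.

    The charge distribution is the convolution of the per-group two-state
    weight vectors; weights are normalized at the end. Log-domain scaling
    keeps the intermediate products finite even for extreme pKa - pH gaps.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValidationError(f"ph out of [0, 14]: {ph}")

    # per-group (log10 weight, charge delta) alternatives vs the neutral state
    site_states: list[list[tuple[float, int]]] = []
    for pka in profile.acids:
        site_states.append([(0.0, 0), (ph - pka, -1)])
    for pka in profile.bases:
        site_states.append([(0.0, 0), (pka - ph, +1)])

    # convolve in the log domain over net charge -2..+2
    log_w = {0: 0.0}  # charge -> log10 total weight
    for states in site_states:
        nxt: dict[int, float] = {}
        for z, lw in log_w.items():
            for dlw, dz in states:
                zz, lww = z + dz, lw + dlw
                nxt[zz] = np.logaddexp(nxt[zz] * np.log(10), lww * np.log(10)) / np.log(10) if zz in nxt else lww
        log_w = nxt

    charges = sorted(log_w)
    logs = np.array([log_w[z] for z in charges])
    w = np.power(10.0, logs - logs.max())
    w /= w.sum()
    fracs = dict.fromkeys(_FIELD_BY_CHARGE.values(), 0.0)
    for z, f in zip(charges, w):
        fracs[_FIELD_BY_CHARGE[z]] += float(f)
    return SpeciesFractions(ph=ph, **fracs)


def daw_at_ph(log_kaw: float, fractions: SpeciesFractions) -> float:
    """Ionization-corrected air-water distribution ratio (dimensionless).

    D_aw(pH) = K_aw * f_neutral: ionic species are taken as non-volatile.
    """
    return float(10.0**log_kaw * fractions.f_neutral)
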
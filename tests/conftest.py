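import itertools

import pytest

from toxtriage.registry import ACID, BASE, IonizationProfile


@pytest.fixture
def neutral_profile():
    return IonizationProfile()


def microstate_fractions_oracle(profile: IonizationProfile, ph: float) -> dict[int, float]:
    """Brute-force enumeration of all protonation microstates.

    Independent of the package's convolution path: loops over every
    combination of per-group states and accumulates linear-scale weights by
    net charge.
    """
    sites = []
    for pka, kind in profile.groups:
        if kind == ACID:
            sites.append([(1.0, 0), (10.0 ** (ph - pka), -1)])
        elif kind == BASE:
            sites.append([(1.0, 0), (10.0 ** (pka - ph), +1)])
    weights: dict[int, float] = {}
    for combo in itertools.product(*sites) if sites else [()]:
        w = 1.0
        z = 0
        for wi, zi in combo:
            w *= wi
            z += zi
        weights[z] = weights.get(z, 0.0) + w
    total = sum(weights.values())
    return {z: w / total for z, w in weights.items()}
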
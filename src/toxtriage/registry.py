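"""Core chemical-record data model and identifier validation.

A :class:`ChemicalRecord` is one nominee for the screening panel: identifiers,
the physicochemical inputs the partitioning and dosimetry models need
(log K_ow of the neutral species, pKa list, log K_aw), the logistics fields
the triage consults (purity, cost, availability and safety flags) and the
annotation tags used for diversity selection (toxicity groups, mechanism
tags, exposome membership).

Missing optional numerics are represented as ``None`` and stay ``None``:
downstream models that need them raise :class:`~toxtriage.errors.MissingInputError`
rather than imputing, mirroring how triage drops data-poor nominees instead
of guessing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .errors import MalformedIdentifierError, UnsupportedChargeError, ValidationError

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

ACID = "acid"
BASE = "base"


def validate_cas(cas: str) -> bool:
    """Check a CAS registry number's check digit.

    The check digit is the weighted sum of the other digits (weights 1, 2, 3,
    ... from the rightmost non-check digit leftwards) modulo 10.

    Raises :class:`MalformedIdentifierError` if the string does not have the
    ``digits-digits-digit`` shape; returns ``False`` only for a well-formed
    number whose checksum fails.
    """
    m = _CAS_RE.match(cas.strip())
    if m is None:
        raise MalformedIdentifierError(f"not a CAS-shaped identifier: {cas!r}")
    body = m.group(1) + m.group(2)
    check = int(m.group(3))
    total = sum(int(d) * w for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


def cas_check_digit(body: str) -> int:
    """Check digit for a CAS digit body (hyphens and check digit removed)."""
    return sum(int(d) * w for w, d in enumerate(reversed(body), start=1)) % 10


@dataclass(frozen=True)
class IonizationProfile:
    """Ionizable groups of a chemical.

    ``groups`` is an ordered list of ``(pka, kind)`` with kind ``"acid"`` or
    ``"base"``. At most two of each kind are supported, since species beyond
    charge +/-2 are not tracked. ``zwitterionic`` marks profiles whose
    net-neutral state is an internal salt; net-neutral microstates are pooled
    into the neutral fraction either way.
    """

    groups: tuple[tuple[float, str], ...] = ()
    zwitterionic: bool = False

    def __post_init__(self):
        groups = tuple((float(p), str(k)) for p, k in self.groups)
        object.__setattr__(self, "groups", groups)
        for pka, kind in groups:
            if not math.isfinite(pka):
                raise ValidationError(f"non-finite pKa: {pka}")
            if kind not in (ACID, BASE):
                raise ValidationError(f"group kind must be 'acid' or 'base', got {kind!r}")
        if len(self.acids) > 2 or len(self.bases) > 2:
            raise UnsupportedChargeError(
                "at most 2 acid and 2 base groups supported (species beyond +/-2)"
            )

    @property
    def acids(self) -> tuple[float, ...]:
        return tuple(p for p, k in self.groups if k == ACID)

    @property
    def bases(self) -> tuple[float, ...]:
        return tuple(p for p, k in self.groups if k == BASE)

    @property
    def is_ionizable(self) -> bool:
        return bool(self.groups)


@dataclass
class ChemicalRecord:
    """One panel nominee with identifiers, physchem, logistics and tags."""

    name: str
    cas: str | None = None
    dtxsid: str | None = None
    smiles: str | None = None
    inchikey: str | None = None
    log_kow: float | None = None
    ionization: IonizationProfile = field(default_factory=IonizationProfile)
    log_kaw: float | None = None
    purity_pct: float | None = None
    cost_eur: float | None = None
    available: bool | None = None
    restricted: bool = False
    hazard_excluded: bool = False
    stability_ok: bool = True
    toxicity_groups: frozenset[str] = frozenset()
    use_categories: frozenset[str] = frozenset()
    moa_tags: frozenset[str] = frozenset()
    exposome: bool = False
    reference_compound: bool = False
    moa_exception: bool = False

    def __post_init__(self):
        self.toxicity_groups = frozenset(self.toxicity_groups)
        self.use_categories = frozenset(self.use_categories)
        self.moa_tags = frozenset(self.moa_tags)
        if not any([self.name, self.cas, self.dtxsid, self.smiles, self.inchikey]):
            raise ValidationError("at least one identifier is required")
        if self.purity_pct is not None and not 0.0 <= self.purity_pct <= 100.0:
            raise ValidationError(f"purity_pct out of [0, 100]: {self.purity_pct}")
        if self.cost_eur is not None and self.cost_eur < 0:
            raise ValidationError(f"cost_eur negative: {self.cost_eur}")
        if self.cas is not None and not validate_cas(self.cas):
            raise ValidationError(f"CAS checksum failure: {self.cas}")

    @property
    def identifier(self) -> str:
        """Preferred stable identifier: InChIKey > DTXSID > CAS > name."""
        return self.inchikey or self.dtxsid or self.cas or self.name
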
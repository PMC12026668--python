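"""Indicator codebook: coding ranges, flags, differentiation, index membership.

The OxCGRT-style panels code each policy measure as a small ordinal
(e.g. school closing: 0 = no measures ... 3 = require closing all), most
indicators carry a binary geographic-scope flag (1 = nationwide,
0 = targeted to a specific region), and a subset of indicators is recorded
separately for vaccinated and non-vaccinated people during periods when a
jurisdiction differentiated its rules by vaccination status.

Two composite indices are supported:

* ``CHI`` — the Containment and Health Index, the unweighted mean of 14
  sub-indices (C1–C8, H1, H2, H3, H6, H7, H8);
* ``STRINGENCY`` — the Stringency Index, the unweighted mean of 9
  sub-indices (C1–C8, H1).

All ten differentiated indicators (C1–C8, H6, H8) belong to the CHI, so
both indices split into a non-vaccinated and a vaccinated variant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml

__all__ = [
    "CHI",
    "STRINGENCY",
    "INDEX_NAMES",
    "IndicatorSpec",
    "Codebook",
    "default_codebook",
]

CHI = "CHI"
STRINGENCY = "STRINGENCY"
INDEX_NAMES = (CHI, STRINGENCY)


@dataclass(frozen=True)
class IndicatorSpec:
    """Coding schema for one policy indicator.

    Parameters
    ----------
    id
        Short identifier, e.g. ``"C1"`` or ``"H6"``.
    label
        Human-readable name of the measure.
    max_code
        Maximum ordinal code ``N_j`` (the strictest level), at least 1.
    has_flag
        Whether a geographic-scope flag variable accompanies the indicator.
    differentiated
        Whether separate vaccinated / non-vaccinated values may exist.
    index_membership
        Subset of ``{"CHI", "STRINGENCY"}``.
    """

    id: str
    label: str
    max_code: int
    has_flag: bool
    differentiated: bool
    index_membership: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.max_code < 1:
            raise ValueError(f"{self.id}: max_code must be >= 1, got {self.max_code}")
        bad = set(self.index_membership) - set(INDEX_NAMES)
        if bad:
            raise ValueError(f"{self.id}: unknown index membership {sorted(bad)}")
        object.__setattr__(self, "index_membership", frozenset(self.index_membership))


class Codebook:
    """Ordered collection of :class:`IndicatorSpec`, keyed by indicator id."""

    def __init__(self, specs):
        specs = list(specs)
        ids = [s.id for s in specs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate indicator ids: {dupes}")
        self._specs = {s.id: s for s in specs}

    def __getitem__(self, indicator_id: str) -> IndicatorSpec:
        return self._specs[indicator_id]

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def ids(self) -> list:
        return list(self._specs)

    def members(self, index_name: str) -> list:
        """Indicator ids belonging to *index_name*, in codebook order."""
        if index_name not in INDEX_NAMES:
            raise ValueError(
                f"unknown index {index_name!r}; expected one of {INDEX_NAMES}"
            )
        return [s.id for s in self if index_name in s.index_membership]

    def differentiated_ids(self) -> list:
        return [s.id for s in self if s.differentiated]

    def version(self) -> str:
        """Stable content hash identifying this codebook in run manifests."""
        h = hashlib.sha256()
        for s in self:
            h.update(
                f"{s.id}|{s.max_code}|{int(s.has_flag)}|{int(s.differentiated)}"
                f"|{','.join(sorted(s.index_membership))};".encode()
            )
        return h.hexdigest()[:12]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "indicators": [
                {
                    "id": s.id,
                    "label": s.label,
                    "max_code": s.max_code,
                    "has_flag": s.has_flag,
                    "differentiated": s.differentiated,
                    "index_membership": sorted(s.index_membership),
                }
                for s in self
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Codebook":
        specs = [
            IndicatorSpec(
                id=row["id"],
                label=row.get("label", row["id"]),
                max_code=int(row["max_code"]),
                has_flag=bool(row["has_flag"]),
                differentiated=bool(row["differentiated"]),
                index_membership=frozenset(row.get("index_membership", ())),
            )
            for row in data["indicators"]
        ]
        return cls(specs)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        """Load an overriding codebook from a YAML (or JSON) config file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# (id, label, max_code, has_flag, stringency_member)
_DEFAULT_ROWS = [
    ("C1", "School closing", 3, True, True),
    ("C2", "Workplace closing", 3, True, True),
    ("C3", "Cancel public events", 2, True, True),
    ("C4", "Restrictions on gatherings", 4, True, True),
    ("C5", "Close public transport", 2, True, True),
    ("C6", "Stay at home requirements", 3, True, True),
    ("C7", "Restrictions on internal movement", 2, True, True),
    ("C8", "International travel controls", 4, False, True),
    ("H1", "Public information campaigns", 2, True, True),
    ("H2", "Testing policy", 3, False, False),
    ("H3", "Contact tracing", 2, False, False),
    ("H6", "Facial coverings", 4, True, False),
    ("H7", "Vaccination policy", 5, True, False),
    ("H8", "Protection of elderly people", 3, True, False),
]
_DIFFERENTIATED = {"C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "H6", "H8"}


def default_codebook(h7_flag: bool = True) -> Codebook:
    """The built-in 14-indicator Containment-and-Health codebook.

    All 14 indicators are CHI members; C1–C8 and H1 additionally form the
    Stringency Index. C8, H2 and H3 have no geographic-scope flag. H7's
    companion variable records cost rather than geographic scope; it is
    treated as a flag for sub-index arithmetic by default (matching the
    upstream index calculation), and ``h7_flag=False`` disables that.
    """
    specs = []
    for iid, label, max_code, has_flag, stringency in _DEFAULT_ROWS:
        if iid == "H7" and not h7_flag:
            has_flag = False
        membership = {CHI} | ({STRINGENCY} if stringency else set())
        specs.append(
            IndicatorSpec(
                id=iid,
                label=label,
                max_code=max_code,
                has_flag=has_flag,
                differentiated=iid in _DIFFERENTIATED,
                index_membership=frozenset(membership),
            )
        )
    return Codebook(specs)
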
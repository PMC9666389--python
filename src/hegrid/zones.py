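"""Clinical risk zone labels shared by all error grids."""

from __future__ import annotations

from enum import IntEnum


class RiskZone(IntEnum):
    """Risk category of a (reference, measured) glucose discrepancy.

    Ordered by severity: A < B < C < D < E. Hypoglycaemia error grids built
    from the consensus questionnaire use only A-D; the legacy Clarke and
    Parkes grids additionally use E.
    """

    A = 1
    B = 2
    C = 3
    D = 4
    E = 5

    @property
    def meaning(self) -> str:
        return _MEANINGS[self]

    @classmethod
    def from_label(cls, label: str) -> "RiskZone":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown risk zone label: {label!r}") from None


_MEANINGS = {
    RiskZone.A: "none",
    RiskZone.B: "slight",
    RiskZone.C: "moderate",
    RiskZone.D: "severe",
    RiskZone.E: "extreme (legacy grids only)",
}

#: Numeric risk scale used when collating questionnaires (A=1 ... D=4).
RISK_SCORE = {RiskZone.A: 1, RiskZone.B: 2, RiskZone.C: 3, RiskZone.D: 4}
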
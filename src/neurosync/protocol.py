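"""Pharmacology protocols: ordered agent applications with start/end times.

A recording session consists of a baseline epoch followed by a series of
agent applications (GABA, the GABA_A antagonist bicuculline, the gap-junction
blocker carbenoxolone, glutamate, and high potassium), each separated by a
washout perfusion. Epoch annotations attach to both fluorescence movies and
MEA recordings and drive all per-epoch quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Agent names recognised in an epoch annotation.
KNOWN_AGENTS = frozenset({"baseline", "GABA", "Bic", "CBX", "glut", "K+"})


class ProtocolError(ValueError):
    """Raised for malformed pharmacology protocols."""


@dataclass(frozen=True)
class Epoch:
    """One agent application window.

    Parameters
    ----------
    agent:
        Agent name; one of ``KNOWN_AGENTS``.
    concentration:
        Applied concentration (``None`` for baseline).
    unit:
        Concentration unit, e.g. ``"uM"`` or ``"mM"``.
    start_s, end_s:
        Application window in seconds from recording start.
    """

    agent: str
    concentration: float | None
    unit: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class PharmacologyProtocol:
    """Ordered, non-overlapping agent application epochs."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -float("inf")
        for ep in self.epochs:
            if ep.agent not in KNOWN_AGENTS:
                raise ProtocolError(f"unknown agent {ep.agent!r}; expected one of {sorted(KNOWN_AGENTS)}")
            if ep.end_s <= ep.start_s:
                raise ProtocolError(f"epoch {ep.agent!r} has non-positive duration")
            if ep.start_s < prev_end:
                raise ProtocolError(f"epoch {ep.agent!r} overlaps the previous epoch")
            if ep.concentration is not None and ep.concentration <= 0:
                raise ProtocolError(f"epoch {ep.agent!r} has non-positive concentration")
            prev_end = ep.end_s

    def epoch(self, agent: str) -> Epoch | None:
        """First epoch for `agent`, or None if absent."""
        for ep in self.epochs:
            if ep.agent == agent:
                return ep
        return None

    def require(self, agent: str) -> Epoch:
        ep = self.epoch(agent)
        if ep is None:
            raise ProtocolError(f"protocol has no {agent!r} epoch")
        return ep

    @property
    def end_s(self) -> float:
        return max((ep.end_s for ep in self.epochs), default=0.0)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "epochs": [
                {
                    "agent": ep.agent,
                    "concentration": ep.concentration,
                    "unit": ep.unit,
                    "start_s": ep.start_s,
                    "end_s": ep.end_s,
                }
                for ep in self.epochs
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacologyProtocol":
        return cls(epochs=[Epoch(**e) for e in d["epochs"]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PharmacologyProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_protocol() -> PharmacologyProtocol:
    """Full application series: 10-min baseline, then GABA 100 uM, Bic 10 uM,
    CBX 25 uM, glut 30 uM and K+ 5 mM, each followed by a ~4-min washout."""
    return PharmacologyProtocol(
        epochs=[
            Epoch("baseline", None, "", 0.0, 600.0),
            Epoch("GABA", 100.0, "uM", 600.0, 840.0),
            Epoch("Bic", 10.0, "uM", 1080.0, 1320.0),
            Epoch("CBX", 25.0, "uM", 1560.0, 1800.0),
            Epoch("glut", 30.0, "uM", 2040.0, 2220.0),
            Epoch("K+", 5.0, "mM", 2460.0, 2580.0),
        ]
    )


def qc_protocol(baseline_s: float = 540.0, washout_s: float = 20.0, kplus_s: float = 60.0) -> PharmacologyProtocol:
    """Compact baseline + high-K+ protocol used for viability-QC benchmarks."""
    t0 = baseline_s + washout_s
    return PharmacologyProtocol(
        epochs=[
            Epoch("baseline", None, "", 0.0, baseline_s),
            Epoch("K+", 5.0, "mM", t0, t0 + kplus_s),
        ]
    )
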
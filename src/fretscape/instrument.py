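"""Instrument and correction constants shared by analysis and simulation.

A :class:`FretSetup` bundles the Förster radius of the dye pair, the
detection/quantum-yield imbalance ``gamma``, background count rates, spectral
crosstalk of donor emission into the acceptor channel, and direct excitation
of the acceptor by the donor laser.  Defaults are neutral (``gamma = 1``, no
background, no crosstalk, no direct excitation) so that uncorrected photon
counts pass through unchanged; instrument-specific values are supplied via a
config file or directly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["FretSetup"]

#: Förster radius (nm) of the Alexa 488 / Alexa 594 donor-acceptor pair.
DEFAULT_R0_NM = 5.4

#: Unquenched donor fluorescence lifetime (ns), typical for Alexa 488.
DEFAULT_TAU0_NS = 4.0


@dataclass(frozen=True)
class FretSetup:
    """Correction constants for transfer-efficiency analysis.

    Parameters
    ----------
    r0_nm : float
        Förster radius of the dye pair in nm (E = 0.5 at this separation).
    gamma : float
        Ratio of acceptor to donor detection efficiency times quantum yield.
        ``gamma = 1`` means balanced detection.
    bg_donor_hz, bg_acceptor_hz : float
        Background count rates (Hz) in the donor and acceptor channels.
    crosstalk : float
        Fraction of donor photons detected in the acceptor channel.
    direct_excitation : float
        Fraction of acceptor-excitation signal leaking into donor-excitation
        acceptor counts.
    donor_lifetime_tau0_ns : float
        Unquenched donor lifetime (ns); reference for relative-lifetime work.
    """

    r0_nm: float = DEFAULT_R0_NM
    gamma: float = 1.0
    bg_donor_hz: float = 0.0
    bg_acceptor_hz: float = 0.0
    crosstalk: float = 0.0
    direct_excitation: float = 0.0
    donor_lifetime_tau0_ns: float = DEFAULT_TAU0_NS

    def __post_init__(self) -> None:
        if self.r0_nm <= 0:
            raise ValueError(f"Förster radius must be positive, got {self.r0_nm}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.bg_donor_hz < 0 or self.bg_acceptor_hz < 0:
            raise ValueError("background rates must be non-negative")
        if not 0 <= self.crosstalk < 1:
            raise ValueError(f"crosstalk must be in [0, 1), got {self.crosstalk}")
        if not 0 <= self.direct_excitation < 1:
            raise ValueError(
                f"direct_excitation must be in [0, 1), got {self.direct_excitation}"
            )
        if self.donor_lifetime_tau0_ns <= 0:
            raise ValueError("donor lifetime must be positive")

    @property
    def is_neutral(self) -> bool:
        """True when every correction leaves raw counts unchanged."""
        return (
            self.gamma == 1.0
            and self.bg_donor_hz == 0.0
            and self.bg_acceptor_hz == 0.0
            and self.crosstalk == 0.0
            and self.direct_excitation == 0.0
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "FretSetup":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "FretSetup":
        return cls.from_dict(json.loads(Path(path).read_text()))
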
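"""Canonical electrophysiological frequency bands.

Band edges follow the convention used throughout resting-state MEG
connectivity work: delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–13 Hz,
beta 13–30 Hz, gamma 30–48 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low_hz, high_hz] in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)

    @property
    def bandwidth_hz(self) -> float:
        return self.high_hz - self.low_hz

    def validate_for_fs(self, fs: float) -> None:
        """Raise if the band's upper edge is at or above the Nyquist rate."""
        if self.high_hz >= fs / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high_hz} Hz >= "
                f"Nyquist {fs / 2.0} Hz for fs={fs} Hz"
            )


DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 48.0)

#: The five canonical bands, in ascending frequency order.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    b.name: b for b in (DELTA, THETA, ALPHA, BETA, GAMMA)
}

#: Broadband range used for the initial wide filter before band splitting.
BROADBAND = BandDefinition("broadband", 0.5, 48.0)

BAND_ORDER = ["delta", "theta", "alpha", "beta", "gamma"]


def get_band(band: str | BandDefinition) -> BandDefinition:
    """Resolve a band name (or pass a BandDefinition through)."""
    if isinstance(band, BandDefinition):
        return band
    try:
        return CANONICAL_BANDS[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; known bands: {sorted(CANONICAL_BANDS)}"
        ) from None
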
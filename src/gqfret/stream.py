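"""The photon-stream container shared by the simulator, burst search and I/O.

A confocal PIE measurement is reduced to a table of photon detection events,
each carrying an arrival time (seconds from acquisition start), a detection
channel (donor or acceptor emission path) and an excitation-window label
(donor-excitation or acceptor-excitation half of the sync period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Channel codes
DONOR = 0
ACCEPTOR = 1

# Excitation-window codes
DONOR_WINDOW = 0
ACCEPTOR_WINDOW = 1

#: Default laser sync repetition rate (Hz) of the pulsed interleaved scheme.
DEFAULT_SYNC_RATE_HZ = 32e6

CHANNEL_NAMES = {DONOR: "donor", ACCEPTOR: "acceptor"}
EXCITATION_NAMES = {DONOR_WINDOW: "donor_window", ACCEPTOR_WINDOW: "acceptor_window"}


@dataclass
class PhotonStream:
    """Timestamped photon events with channel and excitation-window labels.

    Parameters
    ----------
    timestamps
        Arrival times in seconds, non-decreasing, within ``[0, duration]``.
    channel
        Per-photon detection channel, ``0`` = donor, ``1`` = acceptor.
    excitation
        Per-photon excitation window, ``0`` = donor window, ``1`` = acceptor
        window.
    duration
        Acquisition duration in seconds.
    sync_rate_hz
        Laser sync repetition rate of the interleaved excitation scheme.
    truth
        Optional simulation ground truth (:class:`gqfret.simulate.SimulationTruth`);
        ``None`` for measured or file-loaded streams.
    """

    timestamps: np.ndarray
    channel: np.ndarray
    excitation: np.ndarray
    duration: float
    sync_rate_hz: float = DEFAULT_SYNC_RATE_HZ
    truth: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        self.excitation = np.asarray(self.excitation, dtype=np.uint8)
        if not (self.timestamps.shape == self.channel.shape == self.excitation.shape):
            raise ValueError("timestamps, channel and excitation must have equal length")
        if self.timestamps.ndim != 1:
            raise ValueError("photon arrays must be one-dimensional")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.size:
            if np.any(np.diff(self.timestamps) < 0):
                raise ValueError("timestamps must be non-decreasing")
            if self.timestamps[0] < 0 or self.timestamps[-1] > self.duration:
                raise ValueError("timestamps must lie within [0, duration]")
            bad = set(np.unique(self.channel)) - set(CHANNEL_NAMES)
            if bad:
                raise ValueError(f"unknown channel codes: {sorted(bad)}")
            bad = set(np.unique(self.excitation)) - set(EXCITATION_NAMES)
            if bad:
                raise ValueError(f"unknown excitation codes: {sorted(bad)}")

    @property
    def size(self) -> int:
        return int(self.timestamps.size)

    def __len__(self) -> int:
        return self.size

    def counts(self) -> dict[str, int]:
        """Photon counts by (excitation window, channel) class.

        Keys: ``dd`` donor-window/donor-channel, ``da`` donor-window/acceptor
        channel, ``aa`` acceptor-window/acceptor channel, ``ad`` the
        (physically near-empty) acceptor-window/donor class.
        """
        dexc = self.excitation == DONOR_WINDOW
        acc = self.channel == ACCEPTOR
        return {
            "dd": int(np.sum(dexc & ~acc)),
            "da": int(np.sum(dexc & acc)),
            "aa": int(np.sum(~dexc & acc)),
            "ad": int(np.sum(~dexc & ~acc)),
        }


def infer_excitation(timestamps_s: np.ndarray, sync_rate_hz: float = DEFAULT_SYNC_RATE_HZ) -> np.ndarray:
    """Assign excitation windows from arrival times modulo the sync period.

    For interleaved excitation at ``sync_rate_hz`` the sync period is split at
    mid-period: photons in the first half are labelled donor-window, the rest
    acceptor-window.  Intended for photon tables lacking explicit labels.
    """
    if sync_rate_hz <= 0:
        raise ValueError("sync_rate_hz must be positive")
    period = 1.0 / sync_rate_hz
    phase = np.mod(np.asarray(timestamps_s, dtype=np.float64), period)
    return np.where(phase < period / 2, DONOR_WINDOW, ACCEPTOR_WINDOW).astype(np.uint8)
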
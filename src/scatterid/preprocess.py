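"""Acquisition preprocessing: high-pass filter, epoching, artifact rejection.

The chain mirrors the acquisition protocol: each whole 120 s recording is
high-pass filtered (2nd-order 500 Hz Butterworth, zero-phase), split into
non-overlapping 2 s epochs, and each epoch is z-scored; an epoch is
discarded when any |z| exceeds 5 (or the epoch is degenerate, SD == 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth_signals import SignalAcquisition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    hp_cutoff: float = 500.0
    hp_order: int = 2
    epoch_seconds: float = 2.0
    z_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.hp_order < 1 or self.epoch_seconds <= 0 or self.z_threshold <= 0:
            raise ValueError("invalid preprocessing parameters")


@dataclass
class Epoch:
    """One fixed-length signal portion with its accept/reject status."""

    samples: np.ndarray
    fs: float
    particle_id: str
    class_label: str
    index: int
    accepted: bool = True


@dataclass
class EpochSet:
    epochs: list[Epoch] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(e.accepted for e in self.epochs)

    @property
    def n_rejected(self) -> int:
        return len(self.epochs) - self.n_accepted

    def accepted(self) -> list[Epoch]:
        return [e for e in self.epochs if e.accepted]


def highpass(samples: np.ndarray, fs: float,
             params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Zero-phase Butterworth high-pass of the stated order and cutoff.

    Zero-phase (forward-backward) filtering squares the magnitude
    response, so the effective attenuation is |H(f)|^2 with
    |H(f)| = 1/sqrt(1 + (fc/f)^(2*order)); downstream features are
    phase-insensitive, and zero phase keeps epochs aligned with the raw
    recording.
    """
    samples = np.asarray(samples, dtype=float)
    if params.hp_cutoff >= fs / 2:
        raise ValueError("high-pass cutoff must be below Nyquist")
    if len(samples) < 3 * params.hp_order:
        raise ValueError("input too short to filter")
    sos = sps.butter(params.hp_order, params.hp_cutoff, btype="highpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, samples)


def epoch_split(samples: np.ndarray, fs: float,
                params: PreprocessParams = PreprocessParams(),
                particle_id: str = "", class_label: str = "") -> list[Epoch]:
    """Consecutive non-overlapping epochs; a trailing partial window is dropped."""
    samples = np.asarray(samples, dtype=float)
    n_per = int(round(fs * params.epoch_seconds))
    n_epochs = len(samples) // n_per
    if n_epochs == 0:
        logger.warning("input shorter than one epoch (%d < %d samples)",
                       len(samples), n_per)
        return []
    return [
        Epoch(samples=samples[i * n_per:(i + 1) * n_per], fs=fs,
              particle_id=particle_id, class_label=class_label, index=i)
        for i in range(n_epochs)
    ]


def artifact_reject(epoch: Epoch,
                    params: PreprocessParams = PreprocessParams()) -> bool:
    """Accept an epoch iff all within-epoch |z-scores| stay at or below the
    threshold and the epoch is non-degenerate (SD > 0).

    Z-scores use the sample SD (denominator n-1).  The epoch samples are
    not modified.
    """
    x = epoch.samples
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    z = (x - x.mean()) / sd
    return bool(np.max(np.abs(z)) <= params.z_threshold)


def preprocess_acquisition(acq: SignalAcquisition,
                           params: PreprocessParams = PreprocessParams(),
                           ) -> EpochSet:
    """Filter the whole acquisition, split into epochs, flag artifacts."""
    if len(acq.samples) == 0:
        return EpochSet([])
    n_per = int(round(acq.fs * params.epoch_seconds))
    if len(acq.samples) < n_per:
        return EpochSet([])
    filtered = highpass(acq.samples, acq.fs, params)
    epochs = epoch_split(filtered, acq.fs, params,
                         particle_id=acq.particle_id,
                         class_label=acq.class_label)
    for e in epochs:
        e.accepted = artifact_reject(e, params)
    eset = EpochSet(epochs)
    logger.info("%s: %d epochs, %d rejected", acq.particle_id,
                len(epochs), eset.n_rejected)
    return eset
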
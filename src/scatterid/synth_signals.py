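"""Synthetic back-scattered photodetector acquisitions.

The generator emulates the statistical structure of the back-scatter
channel of a lensed optical-fiber tweezer: a 1 kHz sinusoidal
laser-modulation carrier whose amplitude is proportional to the product
of the particle/medium refractive-index contrast and the particle
diameter (dn*d), multiplied by a slow Nakagami-distributed envelope
fluctuation encoding particle heterogeneity, plus broadband Gaussian
noise and occasional high-amplitude single-sample artifacts.

Model for one acquisition::

    s[t] = (baseline + A * effect * (1 + env_depth * w[t])) * sin(2*pi*f_mod*t) + n[t]

with A = gain * dn * d, ``w`` a zero-mean unit-variance low-pass-filtered
Nakagami(mu, omega=1) noise series and ``n`` white Gaussian noise.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

CLASS_LABELS = ("no_particle", "pmma", "ps", "yeast")


@dataclass(frozen=True)
class ParticleClassSpec:
    """One particle class of the study design.

    Parameters
    ----------
    label : str
        One of ``no_particle``, ``pmma``, ``ps``, ``yeast``.
    diameter : float
        Particle diameter in meters (ignored for ``no_particle``).
    n_particle, n_medium : float
        Refractive indices of particle and suspension medium.
    count : int
        Number of particles (acquisitions) of this class.
    nakagami_mu : float
        Shape of the multiplicative envelope fluctuation; small values
        mean strong fading (heterogeneous scatterers such as living
        cells), large values an almost steady envelope.
    env_depth : float
        Relative depth of the envelope fluctuation (>= 0).
    """

    label: str
    diameter: float = 0.0
    n_particle: float = 0.0
    n_medium: float = 1.327
    count: int = 1
    nakagami_mu: float = 5.0
    env_depth: float = 0.1

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.nakagami_mu <= 0 or self.env_depth < 0:
            raise ValueError("nakagami_mu must be > 0 and env_depth >= 0")
        if self.label != "no_particle":
            if self.diameter <= 0:
                raise ValueError("diameter must be > 0 for material classes")
            if self.n_particle < self.n_medium:
                raise ValueError("n_particle must be >= n_medium")

    @property
    def dnd(self) -> float:
        """Refractive-index contrast times diameter (meters); 0 when empty."""
        if self.label == "no_particle":
            return 0.0
        return (self.n_particle - self.n_medium) * self.diameter


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition-chain parameters shared by all classes.

    Defaults reproduce the study conditions: 5 kHz sampling, 120 s
    acquisitions, 1 kHz modulation carrier.
    """

    fs: float = 5000.0
    duration: float = 120.0
    f_mod: float = 1000.0
    gain: float = 1.0e6          # volts per (refractive-index * meter)
    baseline: float = 0.2        # volts: carrier amplitude with no particle
    noise_sd: float = 0.05       # volts
    env_cutoff: float = 10.0     # Hz: bandwidth of the envelope fluctuation
    artifact_rate: float = 2.0   # expected artifacts per acquisition
    artifact_scale: float = 10.0  # spike amplitude in signal-SD units
    particle_sigma: float = 0.1  # log-normal SD of per-particle amplitude effect
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (self.fs, self.duration, self.f_mod, self.gain, self.baseline,
                self.noise_sd, self.env_cutoff, self.artifact_rate,
                self.artifact_scale, self.particle_sigma)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite acquisition parameter")
        if self.fs <= 2 * self.f_mod:
            raise ValueError("fs must exceed 2*f_mod (Nyquist)")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if min(self.gain, self.baseline, self.noise_sd, self.env_cutoff,
               self.artifact_rate, self.artifact_scale, self.particle_sigma) < 0:
            raise ValueError("scale parameters must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class SignalAcquisition:
    """One single-channel recording with its metadata."""

    samples: np.ndarray
    fs: float
    class_label: str
    particle_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def default_study_design() -> list[ParticleClassSpec]:
    """The four-class study design.

    Particle optics: polystyrene (n=1.5731, d=8 um, 18 particles), PMMA
    (n=1.4843, d=8 um, 16), living yeast (midpoints n=1.51, d=6.5 um, 16)
    in de-ionized water (n=1.327), plus 16 empty-trap reference
    acquisitions.  Envelope texture encodes heterogeneity: yeast gets the
    lowest Nakagami shape and the deepest fluctuation; the two synthetic
    polymer beads share identical texture so that only their refractive
    index separates them.
    """
    return [
        ParticleClassSpec("no_particle", count=16, nakagami_mu=10.0, env_depth=0.05),
        ParticleClassSpec("pmma", diameter=8e-6, n_particle=1.4843, count=16,
                          nakagami_mu=6.0, env_depth=0.10),
        ParticleClassSpec("ps", diameter=8e-6, n_particle=1.5731, count=18,
                          nakagami_mu=6.0, env_depth=0.10),
        ParticleClassSpec("yeast", diameter=6.5e-6, n_particle=1.51, count=16,
                          nakagami_mu=1.5, env_depth=0.35),
    ]


def _nakagami_noise(mu: float, n: int, rng: np.random.Generator) -> np.ndarray:
    # Nakagami(mu, omega=1) via the gamma representation X = sqrt(G),
    # G ~ Gamma(mu, 1/mu), so that E[X^2] = 1.
    return np.sqrt(rng.gamma(shape=mu, scale=1.0 / mu, size=n))


def envelope_noise(mu: float, n: int, fs: float, cutoff: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance low-pass-filtered Nakagami noise.

    With ``cutoff >= fs/2`` the low-pass stage is skipped and the series
    is the standardized raw Nakagami draw (useful for distribution-level
    checks, since standardization preserves the Nakagami shape up to an
    affine map).
    """
    raw = _nakagami_noise(mu, n, rng)
    if cutoff < fs / 2:
        sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
        raw = sps.sosfiltfilt(sos, raw)
    sd = raw.std()
    if sd == 0:
        return np.zeros(n)
    return (raw - raw.mean()) / sd


def synthesize_acquisition(spec: ParticleClassSpec, cfg: AcquisitionConfig,
                           particle_effect: float = 1.0,
                           rng: np.random.Generator | int | None = None,
                           ) -> SignalAcquisition:
    """Generate one artifact-free acquisition for a particle of ``spec``.

    ``particle_effect`` is the per-particle multiplicative amplitude
    effect (drawn upstream by :func:`generate_dataset`).  Deterministic
    given the random state.
    """
    if not (math.isfinite(particle_effect) and particle_effect > 0):
        raise ValueError("particle_effect must be finite and > 0")
    rng = np.random.default_rng(rng)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    amplitude = cfg.gain * spec.dnd * particle_effect

    envelope = np.full(n, cfg.baseline)
    if amplitude > 0:
        w = envelope_noise(spec.nakagami_mu, n, cfg.fs, cfg.env_cutoff, rng)
        envelope = envelope + amplitude * (1.0 + spec.env_depth * w)
    carrier = np.sin(2 * np.pi * cfg.f_mod * t)
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
    samples = envelope * carrier + noise
    return SignalAcquisition(
        samples=samples, fs=cfg.fs, class_label=spec.label,
        particle_id=spec.label,
        provenance={"amplitude": amplitude, "particle_effect": particle_effect,
                    "nakagami_mu": spec.nakagami_mu, "env_depth": spec.env_depth},
    )


def inject_artifacts(acq: SignalAcquisition, cfg: AcquisitionConfig,
                     rng: np.random.Generator | int | None = None,
                     ) -> SignalAcquisition:
    """Add Poisson(artifact_rate)-many single-sample spikes.

    Spike amplitude is ``artifact_scale`` times the SD of the clean
    samples; positions are uniform.  With ``artifact_rate == 0`` the
    output equals the input.
    """
    rng = np.random.default_rng(rng)
    k = int(rng.poisson(cfg.artifact_rate)) if cfg.artifact_rate > 0 else 0
    samples = acq.samples.copy()
    positions: list[int] = []
    if k > 0:
        sd = samples.std()
        positions = rng.integers(0, len(samples), size=k).tolist()
        samples[positions] += cfg.artifact_scale * sd
    prov = dict(acq.provenance)
    prov["artifact_positions"] = positions
    return SignalAcquisition(samples=samples, fs=acq.fs,
                             class_label=acq.class_label,
                             particle_id=acq.particle_id, provenance=prov)


def particle_rng(seed: int, label: str, index: int) -> np.random.Generator:
    """Per-particle child generator, stable under design subsetting.

    The child seed mixes the global seed with a CRC-32 of the
    ``label:index`` tag, so removing one class from the design leaves
    every other particle's signal unchanged.
    """
    key = zlib.crc32(f"{label}:{index}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def generate_dataset(specs: list[ParticleClassSpec],
                     cfg: AcquisitionConfig) -> list[SignalAcquisition]:
    """One acquisition per particle per class, fully seeded by ``cfg.seed``.

    Per-particle amplitude effects are log-normal with configurable
    sigma (positive multiplicative biological/positioning variability).
    """
    if not specs:
        raise ValueError("study design must contain at least one class")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels in study design")
    acquisitions = []
    for spec in specs:
        for i in range(spec.count):
            rng = particle_rng(cfg.seed, spec.label, i)
            effect = float(np.exp(rng.normal(0.0, cfg.particle_sigma)))
            acq = synthesize_acquisition(spec, cfg, particle_effect=effect, rng=rng)
            acq = inject_artifacts(acq, cfg, rng=rng)
            acq.particle_id = f"{spec.label}_{i:02d}"
            acquisitions.append(acq)
    logger.info("generated %d acquisitions (%.0f s of signal)",
                len(acquisitions), sum(a.duration for a in acquisitions))
    return acquisitions
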
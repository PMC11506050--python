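"""Synthetic EEG+GSR cohorts with known infra-slow phase-coupling ground truth.

Emulates a two-group meditation study design: each participant contributes
multichannel EEG and a single galvanic-skin-response (GSR) channel, where
every EEG channel carries infra-slow oscillations phase-locked to the GSR
oscillation with a channel-specific lag ``delta_c`` and a group-dependent
von Mises phase jitter of concentration ``kappa``.  The expected phase
synchronization index for jitter concentration kappa is the Bessel ratio
``I1(kappa)/I0(kappa)``, which gives every downstream statistic a closed
form to recover.

Two levels of synthesis are provided:

* :func:`jittered_phase_pair` draws phase series directly (i.i.d. von Mises
  jitter per sample) — the exact setting in which the Bessel-ratio recovery
  and permutation-null calibrations hold.
* :func:`generate_recording` builds raw signals (oscillation + broadband
  noise + linear drift).  There the jitter is held constant over
  ``jitter_dwell``-second blocks (i.i.d. von Mises across blocks) so that it
  survives the narrow-band filtering of the analysis pipeline; i.i.d.
  per-sample jitter would be averaged away by any filter whose bandwidth is
  far below the sampling rate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.special import ive

__all__ = [
    "CohortSpec",
    "Participant",
    "Recording",
    "GroundTruth",
    "expected_psi",
    "default_lag_map",
    "make_montage",
    "make_participants",
    "jittered_phase_pair",
    "generate_recording",
    "generate_cohort",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def expected_psi(kappa):
    """Expected resultant length of a von Mises sample, I1(kappa)/I0(kappa).

    Uses exponentially scaled Bessel functions so the ratio is stable for
    arbitrarily large concentration.
    """
    kappa = np.asarray(kappa, dtype=float)
    return ive(1, kappa) / ive(0, kappa)


@dataclass(frozen=True)
class Participant:
    id: str
    group: str  # "Expert" | "Novice"
    sex: str  # "F" | "M"
    age: float

    def __post_init__(self):
        if self.group not in ("Expert", "Novice"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass
class Recording:
    """Raw multichannel EEG (µV) plus single-channel GSR and montage."""

    eeg: np.ndarray  # (n_channels, n_samples)
    gsr: np.ndarray  # (n_samples,)
    fs: float
    montage: np.ndarray  # (n_channels, 3) unit vectors
    ch_names: list
    participant: Participant
    session_index: int = 0

    def __post_init__(self):
        if self.eeg.shape[1] != self.gsr.shape[0]:
            raise ValueError("EEG and GSR must share the sample count")
        if self.montage.shape[0] != self.eeg.shape[0]:
            raise ValueError("montage must have one position per EEG channel")
        norms = np.linalg.norm(self.montage, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must be unit vectors")


@dataclass
class GroundTruth:
    """True lag, concentration and expected resultant per (channel, band)."""

    lag: np.ndarray  # (n_channels, n_bands) radians
    kappa: np.ndarray  # (n_channels, n_bands)
    expected_psi: np.ndarray  # (n_channels, n_bands)


def default_lag_map(n_channels: int) -> np.ndarray:
    """Channel lags organized into spatial clusters.

    3/8 of channels lie in-phase (0 rad), 3/8 anti-phase (pi rad), and the
    remainder at intermediate lags ±3pi/8, ±5pi/8.  The Fibonacci montage
    of :func:`make_montage` orders channels by elevation, so the in-phase
    block (low indices) forms an outer annulus, the anti-phase block (high
    indices) a polar cap — mirroring a pericentral/peripheral cluster
    topography — with the intermediate lags in the band between them.
    The resulting lag field is spatially piecewise-smooth, which matters
    because the surface Laplacian mixes spatially adjacent channels.
    """
    n0 = (3 * n_channels) // 8
    npi = (3 * n_channels) // 8
    inter = np.array([3 * np.pi / 8, -3 * np.pi / 8, 5 * np.pi / 8, -5 * np.pi / 8])
    rest = n_channels - n0 - npi
    lags = np.concatenate(
        [np.zeros(n0), inter[np.arange(rest) % 4], np.full(npi, np.pi)]
    )
    return lags


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic two-group cohort.

    ``kappa_expert``/``kappa_novice`` may be scalars or per-channel arrays.
    A scalar Expert concentration is expanded to a per-channel profile:
    kappa at the 0/pi lag-cluster channels and kappa/4 at intermediate-lag
    channels, reflecting that Expert synchronization concentrates at
    in-phase/anti-phase channels; a scalar Novice concentration is uniform
    across channels.

    The organized lag topography is an Expert phenomenon: Novice channel
    lags are scattered per participant by a uniform offset of half-width
    ``lag_disorder_novice`` (default pi, i.e. fully disorganized), so the
    Novice group shows neither an mPD-PSI association nor a grand-mean
    phase-difference topography aligned with connectivity.
    """

    n_expert: int = 12
    n_novice: int = 12
    n_channels: int = 64
    fs: float = 256.0
    duration: float = 5400.0  # seconds per session (90 min)
    n_sessions: int = 3
    bands: tuple = tuple(np.round(np.arange(0.01, 0.105, 0.01), 3))
    kappa_expert: object = 4.0
    kappa_novice: object = 1.0
    lag_map: np.ndarray | None = None
    lag_disorder_novice: float = np.pi  # half-width of per-participant lag scatter
    noise_sd: float = 0.5  # relative to unit oscillation amplitude
    drift_slope: float = 0.1  # signal units per second
    amplitudes: np.ndarray | None = None
    jitter_dwell: float = 300.0  # seconds per independent jitter draw
    carrier_walk_sd: float = 0.01  # rad per sqrt(second) random walk of the carrier
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.fs <= 2.0 * max(self.bands):
            raise ValueError("fs must exceed twice the highest band frequency")
        if self.lag_map is None:
            self.lag_map = default_lag_map(self.n_channels)
        self.lag_map = np.asarray(self.lag_map, dtype=float)
        if self.lag_map.shape != (self.n_channels,):
            raise ValueError("lag_map must have one lag per channel")
        if np.any(self.lag_map <= -np.pi) or np.any(self.lag_map > np.pi):
            raise ValueError("lags must lie in (-pi, pi]")
        if not 0.0 <= self.lag_disorder_novice <= np.pi:
            raise ValueError("lag_disorder_novice must lie in [0, pi]")
        if self.amplitudes is None:
            self.amplitudes = np.ones(len(self.bands))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        for k in (self.kappa_expert, self.kappa_novice):
            if np.any(np.asarray(k, dtype=float) < 0):
                raise ValueError("kappa must be non-negative")

    def kappa_profile(self, group: str) -> np.ndarray:
        """Per-channel von Mises concentration for a group."""
        kappa = self.kappa_expert if group == "Expert" else self.kappa_novice
        kappa = np.asarray(kappa, dtype=float)
        if kappa.ndim == 0:
            if group == "Expert":
                clustered = np.isin(self.lag_map, (0.0, np.pi))
                return np.where(clustered, float(kappa), float(kappa) / 4.0)
            return np.full(self.n_channels, float(kappa))
        if kappa.shape != (self.n_channels,):
            raise ValueError("per-channel kappa must match n_channels")
        return kappa

    def lag_profile(self, participant: "Participant") -> np.ndarray:
        """Per-channel lags for one participant (session-independent).

        Experts carry the cohort lag map exactly; Novice lags add a
        deterministic per-(participant, channel) uniform scatter of
        half-width ``lag_disorder_novice``.
        """
        if participant.group == "Expert" or self.lag_disorder_novice == 0.0:
            return self.lag_map.copy()
        rng = default_rng(
            SeedSequence((self.seed, zlib.crc32(participant.id.encode()), 13))
        )
        offs = rng.uniform(
            -self.lag_disorder_novice, self.lag_disorder_novice, self.n_channels
        )
        return _wrap(self.lag_map + offs)


def make_montage(n_channels: int, seed: int = 0) -> np.ndarray:
    """Spherical Fibonacci lattice on the upper hemisphere (unit sphere).

    A deterministic stand-in for an EEG cap: positions are approximately
    uniform over the upper hemisphere, pairwise distinct, and the azimuthal
    origin is a seeded rotation so distinct seeds give distinct caps.
    """
    if n_channels < 2:
        raise ValueError("a montage needs at least 2 channels")
    k = np.arange(n_channels)
    z = (k + 0.5) / n_channels  # upper hemisphere: z in (0, 1)
    r = np.sqrt(1.0 - z**2)
    offset = default_rng(seed).uniform(0.0, 2.0 * np.pi)
    az = k * _GOLDEN_ANGLE + offset
    pos = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def make_participants(spec: CohortSpec) -> list:
    """Deterministic participant roster with the default sex imbalance.

    Experts: 1/4 female; Novices: 5/6 female (3 F and 10 F at n = 12),
    mirroring the demographic imbalance the participant filter is meant to
    exercise.  Ages are drawn from N(39.3, 12.0) for Experts and
    N(45.0, 14.8) for Novices, clipped to [20, 75].
    """
    rng = default_rng(SeedSequence((spec.seed, 901)))
    out = []
    for group, n, n_f, mu, sd in (
        ("Expert", spec.n_expert, round(spec.n_expert * 3 / 12), 39.3, 12.0),
        ("Novice", spec.n_novice, round(spec.n_novice * 10 / 12), 45.0, 14.8),
    ):
        ages = np.clip(rng.normal(mu, sd, size=n), 20.0, 75.0)
        sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
        rng.shuffle(sexes)
        for i in range(n):
            out.append(
                Participant(
                    id=f"{group[0]}{i + 1:02d}",
                    group=group,
                    sex=str(sexes[i]),
                    age=float(np.round(ages[i], 1)),
                )
            )
    return out


def jittered_phase_pair(
    kappa: float, delta: float, n_samples: int, rng: Generator
) -> tuple:
    """Draw (theta_eeg, theta_gsr) with i.i.d. von Mises phase jitter.

    theta_gsr is uniform on (-pi, pi]; theta_eeg = theta_gsr + delta + eps
    with eps ~ von Mises(0, kappa).  The population resultant of the phase
    difference is exactly I1(kappa)/I0(kappa) at direction ``delta``.
    """
    theta_gsr = rng.uniform(-np.pi, np.pi, size=n_samples)
    eps = rng.vonmises(0.0, kappa, size=n_samples)
    theta_eeg = _wrap(theta_gsr + delta + eps)
    return theta_eeg, theta_gsr


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi)
    return np.pi - out


def _participant_stream(spec: CohortSpec, participant: Participant, session: int):
    pid = zlib.crc32(participant.id.encode())  # stable across runs/platforms
    return default_rng(SeedSequence((spec.seed, pid, session, 7)))


def generate_recording(
    spec: CohortSpec, participant: Participant, session: int = 0
) -> tuple:
    """Generate one session's raw (Recording, GroundTruth).

    GSR = sum_b A_b cos(phi_b(t)) + noise, with phi_b advancing at 2*pi*f_b
    plus a small random walk.  EEG channel c = sum_b A_b cos(phi_b(t) +
    delta_c + eps_cb(t)) + white noise + linear drift, where eps_cb is
    blockwise-constant von Mises(0, kappa_c) jitter (independent across
    channels, bands and blocks).  Deterministic in (spec.seed, participant
    id, session).
    """
    rng = _participant_stream(spec, participant, session)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    kappa = spec.kappa_profile(participant.group)
    lags = spec.lag_profile(participant)
    n_blocks = max(1, int(np.ceil(spec.duration / spec.jitter_dwell)))
    block_len = int(round(spec.jitter_dwell * spec.fs))
    block_idx = np.minimum(np.arange(n) // max(block_len, 1), n_blocks - 1)

    eeg = np.zeros((spec.n_channels, n))
    gsr = np.zeros(n)
    lag2d = np.empty((spec.n_channels, len(spec.bands)))
    kap2d = np.empty_like(lag2d)
    for b, (f_b, a_b) in enumerate(zip(spec.bands, spec.amplitudes)):
        walk = np.cumsum(
            rng.normal(0.0, spec.carrier_walk_sd / np.sqrt(spec.fs), size=n)
        )
        phi = 2.0 * np.pi * f_b * t + walk
        gsr += a_b * np.cos(phi)
        eps_blocks = rng.vonmises(0.0, kappa[:, None], size=(spec.n_channels, n_blocks))
        eps = eps_blocks[:, block_idx]
        eeg += a_b * np.cos(phi[None, :] + lags[:, None] + eps)
        lag2d[:, b] = lags
        kap2d[:, b] = kappa

    gsr += spec.noise_sd * rng.standard_normal(n)
    eeg += spec.noise_sd * rng.standard_normal((spec.n_channels, n))
    eeg += spec.drift_slope * t[None, :]

    montage = make_montage(spec.n_channels, spec.seed)
    rec = Recording(
        eeg=eeg,
        gsr=gsr,
        fs=spec.fs,
        montage=montage,
        ch_names=[f"EEG{c + 1:03d}" for c in range(spec.n_channels)],
        participant=participant,
        session_index=session,
    )
    truth = GroundTruth(lag=lag2d, kappa=kap2d, expected_psi=expected_psi(kap2d))
    return rec, truth


def generate_cohort(spec: CohortSpec) -> list:
    """All (Recording, GroundTruth) pairs for the cohort, session by session."""
    out = []
    for participant in make_participants(spec):
        for session in range(spec.n_sessions):
            out.append(generate_recording(spec, participant, session))
    return out
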
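"""Phase synchronization index (PSI), mean phase difference (mPD), and
time-shuffled surrogate significance.

For phase series theta_eeg(t), theta_gsr(t) of length T, the complex mean
phase difference is

    DeltaTheta = (1/T) * sum_t exp(i (theta_eeg(t) - theta_gsr(t)))

PSI = |DeltaTheta| in [0, 1] (1 iff the phase difference is constant) and
mPD = arg(DeltaTheta).  The surrogate null permutes the GSR phase samples
in time, preserving both marginal phase distributions while destroying the
temporal pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .synth import _wrap

__all__ = [
    "PhasePairSummary",
    "SurrogateEnsemble",
    "phase_pair_summary",
    "surrogate_psis",
    "psi_significance",
    "summarize_cohort",
]


@dataclass
class PhasePairSummary:
    delta_theta: complex
    psi: float
    mpd: float
    T: int
    participant_id: str | None = None
    channel: int | None = None
    band: float | None = None


@dataclass
class SurrogateEnsemble:
    surrogate_psis: np.ndarray
    n_surrogates: int
    seed: int


def _check_pair(theta_eeg, theta_gsr):
    theta_eeg = np.asarray(theta_eeg, dtype=float)
    theta_gsr = np.asarray(theta_gsr, dtype=float)
    if theta_eeg.shape != theta_gsr.shape:
        raise ValueError("phase series must have equal length")
    if theta_eeg.size < 2:
        raise ValueError("need at least 2 phase samples")
    return theta_eeg, theta_gsr


def phase_pair_summary(theta_eeg, theta_gsr, **ids) -> PhasePairSummary:
    """Complex mean phase difference, PSI and mPD of one channel/band pair."""
    theta_eeg, theta_gsr = _check_pair(theta_eeg, theta_gsr)
    dt = np.mean(np.exp(1j * (theta_eeg - theta_gsr)))
    return PhasePairSummary(
        delta_theta=complex(dt),
        psi=float(np.abs(dt)),
        mpd=float(_wrap(np.angle(dt))),
        T=theta_eeg.size,
        **ids,
    )


def surrogate_psis(
    theta_eeg,
    theta_gsr,
    n_surrogates: int = 10_000,
    seed: int = 0,
    chunk: int = 512,
) -> SurrogateEnsemble:
    """Surrogate PSI ensemble from uniform random time permutations of the
    GSR phases; deterministic given ``seed``."""
    theta_eeg, theta_gsr = _check_pair(theta_eeg, theta_gsr)
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = default_rng(seed)
    ze = np.exp(1j * theta_eeg)
    zg = np.exp(-1j * theta_gsr)
    t = theta_eeg.size
    out = np.empty(n_surrogates)
    done = 0
    while done < n_surrogates:
        k = min(chunk, n_surrogates - done)
        perms = rng.permuted(np.tile(np.arange(t), (k, 1)), axis=1)
        out[done : done + k] = np.abs(np.mean(ze[None, :] * zg[perms], axis=1))
        done += k
    return SurrogateEnsemble(out, n_surrogates, seed)


def psi_significance(
    observed: PhasePairSummary, ensemble: SurrogateEnsemble, alpha: float = 0.05
) -> tuple:
    """Add-one permutation p-value and the strict 95th-percentile criterion.

    p = (1 + #{surrogate >= observed}) / (1 + n); significance requires the
    observed PSI to strictly exceed the (1 - alpha) percentile.
    """
    surr = np.asarray(ensemble.surrogate_psis)
    if surr.size == 0:
        raise ValueError("empty surrogate ensemble")
    p = (1 + int(np.sum(surr >= observed.psi))) / (1 + surr.size)
    threshold = np.percentile(surr, 100.0 * (1.0 - alpha))
    return p, bool(observed.psi > threshold)


def summarize_cohort(entries, bands) -> pd.DataFrame:
    """One PSI/mPD row per (participant, channel, band).

    ``entries`` is an iterable of dicts with keys ``participant`` (having
    id/group/sex/age) and ``sessions``: a list of (eeg PhaseTensor,
    gsr PhaseTensor) tuples.  Valid phase samples are concatenated across
    sessions before averaging, so T counts valid samples over all sessions.
    """
    bands = list(bands)
    rows = []
    for entry in entries:
        part = entry["participant"]
        sessions = entry["sessions"]
        if not sessions:
            raise ValueError(f"participant {part.id} has no sessions")
        n_ch = sessions[0][0].n_channels
        for b, f_b in enumerate(bands):
            if sessions[0][0].n_bands != len(bands):
                raise ValueError("phase tensors do not match the band list")
            z_sum = np.zeros(n_ch, dtype=complex)
            t_total = 0
            for eeg_pt, gsr_pt in sessions:
                m = eeg_pt.valid_mask[b] & gsr_pt.valid_mask[b]
                diff = eeg_pt.phases[:, m, b] - gsr_pt.phases[0, m, b][None, :]
                z_sum += np.exp(1j * diff).sum(axis=1)
                t_total += int(m.sum())
            if t_total < 2:
                raise ValueError(
                    f"participant {part.id}, band {f_b}: fewer than 2 valid samples"
                )
            dt = z_sum / t_total
            lo, hi = sessions[0][0].band_edges[b]
            for c in range(n_ch):
                rows.append(
                    {
                        "participant": part.id,
                        "group": part.group,
                        "sex": part.sex,
                        "age": part.age,
                        "channel": c,
                        "band": f_b,
                        "band_lo": lo,
                        "band_hi": hi,
                        "psi": float(np.abs(dt[c])),
                        "mpd": float(_wrap(np.angle(dt[c]))),
                        "T": t_total,
                        "re": float(dt[c].real),
                        "im": float(dt[c].imag),
                    }
                )
    return pd.DataFrame(rows)
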
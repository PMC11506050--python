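# isasync

Phase synchronization between infra-slow EEG activity and electrodermal
arousal, as a tested, reproducible pipeline.

## The scientific problem

Infra-slow activity (ISA, 0.01–0.1 Hz) in the EEG and the tonic galvanic
skin response (GSR) both fluctuate on minute time scales, and their
oscillatory phases are coupled: arousal fluctuations track the phase of
cortical ISA. `isasync` quantifies this coupling channel by channel and
compares it between groups (e.g. experienced meditators vs novices),
covering the whole analysis chain:

1. **Preprocessing** — zero-mean + linear detrend, decimation to 8 Hz,
   spherical-spline surface Laplacian (current source density, Perrin
   splines with m = 4, λ = 10⁻⁵, Legendre order 50), narrow-band
   zero-phase Hamming FIR filtering in ten bands (0.01…0.1 Hz, 0.01 Hz
   wide), Hilbert instantaneous phase.
2. **Phase Synchronization Index** — for phases θ_EEG(t), θ_GSR(t),

       ΔΘ = (1/T) Σ_t exp(i·(θ_EEG(t) − θ_GSR(t))),
       PSI = |ΔΘ| ∈ [0, 1],   mPD = arg ΔΘ,

   with a permutation null that shuffles the GSR phase samples in time
   (10,000 surrogates, 95th-percentile criterion).
3. **mPD–PSI coupling** — the mPD axis (−π, π] is split into 16 bins; the
   per-bin average PSI, normalized to sum 1, is compared to the uniform
   distribution by Kullback–Leibler divergence (0 ≤ KL ≤ ln 16), with a
   label-shuffling permutation test.
4. **Topography** — the grand-mean phase difference gmPD = arg(Σ_k ΔΘ_k / K)
   per channel; functional connectivity (zero-clipped Pearson correlation
   of band-passed signals); its principal gradient by diffusion-map
   embedding (α = 0.5); and an OLS regression of |gmPD| on the gradient.
5. **Group statistics** — pooled and per-channel one-tailed Wilcoxon
   rank-sum tests, Benjamini–Hochberg FDR over bands, Cohen's d, and a
   demographic participant filter (retain males and females aged ≤ 38).

Because the original recordings are large, every stage is driven and
verified by a **synthetic cohort generator** with known ground truth: each
EEG channel carries ISA oscillations phase-locked to a simulated GSR with a
channel-specific lag δ_c and von Mises phase jitter of concentration κ, so
the expected PSI is the Bessel ratio I₁(κ)/I₀(κ) and every downstream
statistic has a closed form or oracle to recover.

## Worked example

```python
from isasync import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=1, n_expert=4, n_novice=4, n_channels=16, fs=8.0,
    duration=3600.0, n_sessions=1, band_spec="0.03:0.07:0.04",
    jitter_dwell=600.0, n_surrogates_psi=500,
    n_surrogates_coupling=10_000, alpha_coupling=0.05,
)
run_dir = run_pipeline(cfg, "runs/demo")
```

This simulates a 4+4-participant cohort (Expert κ = 4, Novice κ = 1),
preprocesses it, and writes the PSI summaries, coupling tests, gradient
maps and group statistics (about 2 minutes on one CPU; the per-pair PSI
surrogates dominate). The run above prints, per band:

```
 band  statistic        p_raw        p_fdr  cohens_d  n_expert  n_novice
 0.03     5238.0 6.202972e-08 6.202972e-08  0.993622        64        64
 0.07     5433.0 2.538603e-10 5.077206e-10  1.046694        64        64
Expert_0.03: kl=0.255 p=0.0174 significant=True
Expert_0.07: kl=0.200 p=0.0117 significant=True
Novice_0.03: kl=0.027 p=0.4843 significant=False
Novice_0.07: kl=0.019 p=0.6042 significant=False
Expert_0.03: R2=0.962 p=2.31e-11
Expert_0.07: R2=0.989 p=3.19e-15
Novice_0.03: R2=0.072 p=3.16e-01
Novice_0.07: R2=0.016 p=6.45e-01
```

Reading: pooled PSI is higher in the Expert group in both bands
(rank-sum FDR p < 10⁻⁷, Cohen's d ≈ 1), Expert synchronization
concentrates at in-phase/anti-phase mPD bins (significant KL coupling)
while Novices show none, and the Expert |gmPD| topography is linear in the
connectivity gradient (R² > 0.96) while the Novice one is not — the
qualitative fingerprint the generator was designed to carry.

The same pipeline is scriptable from the shell:

```bash
isasync run --config cfg.yaml --out runs/demo
isasync simulate --config cfg.yaml --out data/   # EDF files + montage
isasync preprocess --in data/ --out tensors/ --bands 0.01:0.1:0.01
```

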
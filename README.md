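# scatterid

Label-free differentiation of optically trapped microparticles from the
back-scattered light they return through a lensed optical-fiber tweezer.

A micro-lensed fiber tip traps a single particle and collects the
back-scattered laser light onto a photodetector (5 kHz sampling, 120 s
per particle, 1 kHz sinusoidal laser modulation). The voltage time
series carries a signature of what is trapped: nothing, an 8 µm PMMA
bead, an 8 µm polystyrene (PS) bead, or a living yeast cell (6–7 µm).
`scatterid` implements the full signal-analysis chain that turns such
recordings into a single discriminant score per particle:

1. **Preprocessing** — 2nd-order 500 Hz Butterworth high-pass
   (zero-phase), split into 2 s epochs, reject any epoch whose
   within-epoch z-scores exceed |z| > 5.
2. **Feature registry (45 features per epoch)** — time-domain statistics
   (M, SD, RMS, Skew, Kurt, IQR, Shannon entropy E); Nakagami envelope
   parameters (µ, ω) fitted by moment estimators to the Hilbert-envelope
   magnitudes; the 20 largest-magnitude orthonormal DCT-II coefficients
   of the envelope plus N_DCT (coefficients holding 98% of the energy),
   AUC, peak and total power of the DCT spectrum; relative powers of
   detail levels 1–6 of a 6-level orthogonal wavelet decomposition for
   Haar and Daubechies-10 mothers.
3. **Fisher LDA** — after dropping RMS (redundant with SD) and
   ω_Nakagami (outlier-prone), the remaining 43 features are z-scored
   and fused into one score by the direction φ maximizing the Rayleigh
   quotient φᵀS_Bφ / φᵀS_Wφ, solved as the largest-eigenvalue solution
   of the generalized eigenproblem S_B φ = λ S_W φ.
4. **Statistics** — per-particle averaging, Kruskal–Wallis and pairwise
   Mann–Whitney screening of every feature and of the score,
   Bhattacharyya class-separability distances, and the Spearman rank
   correlation of per-class mean score against Δn·d (refractive-index
   contrast × particle diameter), the physical driver of scattering
   amplitude.

Because the raw study acquisitions are not publicly deposited, the
package includes a first-class synthetic generator that emulates the
acquisition physics: a 1 kHz carrier with amplitude ∝ gain·Δn·d, slow
multiplicative Nakagami-distributed envelope fluctuations whose shape
encodes particle heterogeneity (living cells fade more), white Gaussian
noise, and occasional high-amplitude spike artifacts.

Audience: biophotonics / optical-tweezer groups prototyping label-free
particle and cell classification from single-angle scattering signals.

## Worked example

```python
from scatterid import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=7))   # 66 particles x 120 s, 4 classes
print(result.lda_results.summary())
```

```
Linear discriminant (single direction)
==============================================
features retained : 43
excluded          : ['RMS', 'omega_nakagami']
eigenvalue (between/within): 0.271964
class mean scores:
   no_particle : -0.9843
          pmma : +0.3180
            ps : +0.3229
         yeast : +0.3080
top contribution weights:
              SD : phi=-0.4974 (squared weight 0.247)
         E_Haar2 : phi=+0.4129 (squared weight 0.170)
         E_Haar1 : phi=+0.4056 (squared weight 0.165)
        Peak_DCT : phi=+0.3955 (squared weight 0.156)
        E_DCT_l1 : phi=+0.3955 (squared weight 0.156)
```

The class mean scores order exactly as the scattering driver Δn·d
(PS > PMMA > yeast > empty trap), and frequency-domain features carry
most of the discriminant weight. The statistical layer confirms the
separation on per-particle scores:

```python
h, p = result.report.score_kruskal      # H=45.66, p=6.7e-10
rho, sp = result.report.spearman        # rho=1.00, p<0.05
```

Of the 3960 generated 2 s epochs, 3805 survive artifact rejection
(about 58 accepted portions per particle).

A thin CLI wraps the same stages:

```bash
scatterid run --out results/run1 --seed 7
scatterid simulate --out acqs/ --seed 7
scatterid lda-fit --features epoch_features.csv --out model.json
```

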
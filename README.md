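# subunitscope

Inference of the subunit structure of primary-visual-cortex neurons from
spike trains recorded under dense noise stimuli.

Classical models describe what a direction-selective (DS) V1 neuron computes
— e.g. the Energy Model's phase-invariant motion energy — but not how that
computation is assembled from the neuron's inputs. `subunitscope` implements
a statistical pipeline that infers a physiologically interpretable set of
*localized subunit filters* and their nonlinearities directly from an
extracellular spike train and the stimulus movie:

1. **Spike-triggered analysis.** The STA gives the linear receptive field;
   spike-triggered covariance (STC) diagonalizes
   ΔC = C_spike − C_all and finds the excitatory (variance-increasing) and
   suppressive (variance-decreasing) stimulus subspaces, with significance
   assessed against a spike-train circular-shift null. For correlated
   (1/f movie) stimuli the design matrix is first whitened on a reduced PCA
   basis, Z = S·V·D^(−1/2), and filters are mapped back after estimation.
2. **Localization.** The STC filters are just one coordinate system for the
   recovered subspace. Among all unit-norm combinations k_β = Σᵢβᵢbᵢ the
   pipeline finds, at each target position c, the one minimizing the
   power-weighted spatial spread L(c,β) = Σₓ R_β(x)(c−x)² — where
   R_β(x) is the filter's variance across time lags at position x — turning
   multi-lobed, extended STC filters into compact, simple-cell-like subunit
   estimates that tile the receptive field.
3. **Nonlinear cascade fitting (GNM).** With filters fixed, per-filter
   nonlinearities fᵢ (piecewise-linear tent bases), temporal kernels h and
   offset θ of r(t) = log(1+exp(Σᵢ Σ_τ h_{iτ} fᵢ(kᵢ·s_{t−τ}) − θ)) are fit
   by smoothness-penalized Poisson maximum likelihood; relevant localized
   filters are pre-selected by L1 logistic regression on their rectified
   outputs.
4. **Tuning prediction.** Fitted models are probed with drifting gratings
   to predict DSI = (R_p−R_np)/(R_p+R_np) and MI = F1/DC, and filters are
   scored directly by DSI_RF = (Q1−Q2)/(Q1+Q2) from the upper quadrants of
   their 2-D Fourier power; SVD decomposes DS filters into separable
   (non-DS) components.

The package also ships the generative model neurons needed to validate all
of this — LN simple cells, simple cells built from separable non-DS inputs,
energy-model complex cells, and pooled-subunit complex cells with Poisson
spiking — plus the stimulus ensembles (m-sequence bars, drifting gratings,
1/f pink-noise movies).

Estimators follow scikit-learn conventions (`fit`, `predict`/`transform`,
fitted attributes with trailing underscores) and compose with sklearn
tooling; module-level functions are thin wrappers over them.

## Worked example

A motion-energy complex cell is simulated for five minutes of Gaussian bar
noise and analyzed end to end:

```python
import numpy as np
from subunitscope import (
    NeuronSpec, StimulusMovie, embed_stimulus, make_gabor_strf,
    neuron_rate, poisson_spikes, select_significant,
    SubunitLocalizer, GNM, grating_tuning, dsi_from_rf,
)

rng = np.random.default_rng(0)
movie = StimulusMovie(rng.standard_normal((16, 30_000)), frame_rate_hz=100.0)
design = embed_stimulus(movie, n_lags=14)
pair = [make_gabor_strf(16, 14, spatial_freq=3.0, tilt_phase_per_lag=0.5, phase=p)
        for p in (0.0, np.pi / 2)]
cell = NeuronSpec(kind="energy_complex", filters=pair,
                  spiking_gain=0.5, spiking_offset=-2.0, seed=0)
spikes = poisson_spikes(neuron_rate(cell, design), seed=1)
print(f"{spikes.total_spikes} spikes in {design.n_frames} bins")

stc = select_significant(design, spikes, method="shuffle",
                         n_shuffles=100, alpha=0.01, random_state=2)
print(f"significant filters: {stc.excitatory.size} excitatory, "
      f"{stc.suppressive.size} suppressive")
print(f"|STA| relative to top STC filter: {np.linalg.norm(stc.sta_raw):.3f}")

loc = SubunitLocalizer(n_centers=40, n_restarts=20, seed=3).fit(stc.excitatory_filters())
print(f"aligned PCA, first two components: {loc.pca_explained_[:2].sum():.1%}")

gnm = GNM(filters=stc.excitatory_filters(), n_knots=15).fit(design, spikes)
print(f"GNM training LL improvement: {gnm.train_ll_:.2f} nats/spike")

tun = grating_tuning(gnm.model_, sf_grid=[2.0, 3.0, 4.0], tf_grid=[4.0, 8.0])
print(f"predicted DSI = {tun.dsi:.2f}, MI = {tun.mi:.2f}  "
      f"(DSI_RF of top filter = {dsi_from_rf(stc.excitatory_filters()[0]):.2f})")
```

Output:

```
12191 spikes in 30000 bins
significant filters: 2 excitatory, 0 suppressive
|STA| relative to top STC filter: 0.168
aligned PCA, first two components: 99.4%
GNM training LL improvement: 0.40 nats/spike
predicted DSI = 0.96, MI = 0.02  (DSI_RF of top filter = 0.95)
```

Reading the numbers: the cell's STA is structureless (norm 0.17 of the
leading STC filter — it responds to a pattern and its contrast-inverse
alike), STC finds exactly the planted quadrature pair, the localized set is
spanned by two aligned components (a quadrature pair at each position), the
fitted cascade predicts spikes far better than a mean-rate model, and the
grating predictions classify the cell as strongly direction-selective
(DSI 0.96) and phase-invariant (MI 0.02 ≪ 1, i.e. complex).

A command-line interface mirrors the pipeline
(`subunitscope simulate-stimulus | simulate-neuron | stc | localize |
select | fit-gnm | tuning | run`), reading and writing HDF5 containers and
CSV reports; `subunitscope run --outdir out` executes the whole chain on a
built-in pooled-subunit demo configuration and writes a manifest whose hash
certifies bit-identical reproduction.

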
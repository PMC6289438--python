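# dogait

Accelerometric gait analysis for longitudinal studies of dystrophic dogs
(CXMD_J, a beagle model of Duchenne muscular dystrophy), built for
methodologists who want the full analysis chain — sensor signal
processing, Bayesian trend modelling and muscle-MRI correlation — as
tested, reusable code driven entirely by a synthetic-data generator.

A trunk-mounted hybrid sensor (±8 G, ±1000 dps, 20 ms sampling) records
three-axial acceleration and angular velocity while a dog runs 15 m.
Per trial the package computes the mean absolute vectors *Ax, Ay, Az,
Gx, Gy, Gz*, the trial-averaged acceleration magnitude

    AM_k = sqrt(Ax_k² + Ay_k² + Az_k²),

and the three acceleration ratios (per-sample percentage contribution of
each axis to AM, averaged over the trial), after gravity-offset removal
on a quadrupedal standing window and start→goal segmentation.

Monthly outcomes form an unbalanced dog-month panel modelled with a
Bayesian local level model: for dog *i* at month *t*,

    log(y_it)                 ~ N(m_t + β·x_it, σ₀²)     (accelerations, angular velocities)
    log(r_it / (100 − r_it))  ~ N(m_t + β·x_it, σ₀²)     (acceleration ratios)
    m_t                       ~ N(m_{t−1}, σ₁²)

with a latent trend *m_t* shared by all dogs in a group, estimated by a
forward-filtering backward-sampling Gibbs sampler with conjugate
inverse-gamma updates for σ₀², σ₁² and a conjugate normal update for the
covariate coefficient β (clinical grading score or locomotor activity).
Trends are reported with equal-tailed 95% credible bands; β "excludes
zero" when 0 lies outside its interval.

Muscle involvement is quantified from MRI ROI tables as
SNR = intensity / SD_air, aggregated per muscle into the pixel-weighted
bilateral **Ave SNR**, compared between groups by the exact Mann-Whitney
U test and correlated with AM by Pearson's test (5% level).

## Worked example

Fit the covariate extension on synthetic dystrophic panels drawn from
the model itself (standardized covariates, planted β of ∓0.3):

```sh
python analysis/04_covariate_coefficients.py --seed 0 --out results/analysis
```

prints

```
         covariate outcome   region  beta_true  beta_mean  beta_lower  beta_upper  excludes_zero
    clinical_score      AM thoracic       -0.3     -0.414      -0.578      -0.229           True
    clinical_score      AM   lumbar       -0.3     -0.313      -0.499      -0.150           True
locomotor_activity      AM thoracic        0.3      0.382       0.249       0.510           True
locomotor_activity      AM   lumbar        0.3      0.260       0.147       0.381           True

4/4 coefficients exclude zero (planted effects: [-0.3, 0.3])
```

Each row is one forest-plot entry: the posterior mean of β with its 95%
credible interval. Negative clinical-score coefficients mean the
acceleration magnitude falls as clinical severity rises; positive
activity coefficients mean it moves with spontaneous locomotor activity
— and every planted effect is recovered with the right sign and an
interval that excludes zero.

The other numbered scripts under `analysis/` run the remaining stages:
`01` simulates the 11-dog cohort's raw trials (with the study's missing
dog-months), `02` processes them into per-session outcome tables, `03`
fits and compares the wild-type vs dystrophic trend curves, and `05`
runs the MRI Ave SNR comparison and AM correlation table. The same
stages are available as a CLI (`dogait run-study --packaged
strong_effect --out DIR`) or as library calls (`dogait.pipeline`).

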
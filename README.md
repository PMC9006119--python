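# esindy

Ensemble sparse identification of nonlinear dynamics: data-driven
discovery of ODE and PDE models from noisy, limited time series, with
uncertainty quantification, probabilistic forecasting, active learning
and model predictive control.

## The problem and the method

Given m snapshots of a state u arranged as U ∈ R^{m×n} and a library of D
candidate terms Θ(U) = [1, U, U², …, sin U, …], sparse model discovery
seeks a sparse coefficient matrix Ξ with

    U̇ = Θ(U) Ξ,      Ξ = argmin ½‖U̇ − Θ(U) Ξ̂‖² + λ₁‖Ξ̂‖₀ + λ₂‖Ξ̂‖²,

solved by sequentially thresholded least squares / ridge regression
(iterate fit → hard-threshold → refit). For PDEs the library includes
spatial derivatives, and a weak (integral) formulation — multiply by
compactly supported test functions, integrate by parts over many random
subdomains — replaces pointwise derivatives of noisy data with the linear
system q₀ = Q Ξ.

The package's core contribution is the *ensemble* layer: fit q models on
bootstrap resamples of the regression rows (bagging; median aggregation =
bragging) or on random subsets of library columns (library bagging). The
fraction of members in which each term is active — its *inclusion
probability* — drives model selection (threshold or prescreen), member
spread gives coefficient uncertainty, and drawing small groups of members
yields predictive bands. The ensemble statistics also power an active
learning loop (sample the initial condition with the largest one-step
ensemble forecast variance) and low-data model predictive control.

Typical users: researchers in systems biology, ecology, fluid dynamics or
engineering who want interpretable governing equations — not black-box
forecasts — from short, noisy measurement records.

## Worked example: predator–prey dynamics from 21 yearly observations

The bundled fixture holds the classic yearly lynx–hare pelt counts
(1900–1920, thousands of pelts). Library bagging prescreens a cubic
polynomial library, then bagging with a 65% inclusion threshold selects
the model:

```python
>>> import esindy as es
>>> result = es.run_lynx_hare()
>>> for eq in result.model.equation_strings():
...     print(eq)
dhare/dt = +0.537 hare -0.02165 hare*lynx
dlynx/dt = -0.84 lynx +0.02177 hare*lynx
>>> round(result.data_coverage, 2)
0.69
```

That is the Lotka–Volterra predator–prey system, discovered from 21
points per species: hares grow at ≈0.54/yr and are consumed in proportion
to encounters; lynx decline at ≈0.84/yr except as sustained by predation.
`result.band` holds the 95% ensemble reconstruction (1000 draws of 5
members each); it brackets 69% of the observations — the record is not
exactly Lotka–Volterra, so a structural residual remains.

The same machinery runs from the shell:

```sh
esindy generate --system lorenz --m 2500 --out lorenz.csv
esindy fit --data lorenz.csv --poly-order 3 --lambda1 0.1 --out model.json
# dx/dt = -9.979 x +9.979 y
# dy/dt = +27.81 x -0.9652 y -0.9947 x*z
# dz/dt = -2.659 z +0.9971 x*y
esindy benchmark --preset desk --out robustness.csv
esindy mpc --train-steps 150 --out mpc_trajectory.csv
```

Other entry points: `es.fit_ensemble` / `es.fit_library_ensemble`
(ensembles with inclusion probabilities), `es.assemble_weak_system` /
`es.weak_fit` (weak-form PDE discovery), `es.ensemble_forecast`
(predictive bands), `es.run_active_loop` (uncertainty-driven data
acquisition), `esindy.mpc.identify_and_control` (identify-then-control).
`docs/methods.md` documents the models, defaults and their rationale.

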
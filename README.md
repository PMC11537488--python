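# engram-forgetting

A computational account of natural forgetting in the mouse
novel-object-recognition task, for behavioral neuroscientists and
cognitive modelers: forgetting is treated not as passive decay but as
adaptive Rescorla–Wagner learning about which memories are still relevant.

## The model

A latent **engram relevancy** `e_t ∈ [0, 1]` tracks the object–context
association of the familiar object on a whole-day grid `t = 0..21` and is
updated by a delta rule with asymmetric learning rates,

    e_{t+1} = e_t + α_t (o_t − e_t),   α_t = 1 if o_t − e_t ≥ 0, else α⁻,

so one exposure fully restores the memory while each day of object
absence shaves off a fraction α⁻ (the forgetting rate). A softmax with
inverse temperature β ≤ 0 maps relevancy to the mean familiar-object
exploration probability μ (novelty preference: higher relevancy, less
exploration of the familiar object), and per-mouse observed probabilities
μ̂ follow Beta(μκ, (1−μ)κ). The three free parameters (α⁻, β, κ) are
estimated per group by bounded maximum likelihood (L-BFGS-B, multi-start)
and the fit is compared by BIC (`l − (k/2)·ln S`, higher is better)
against a chance baseline (μ = 0.5, Beta(1, 1), BIC ≡ 0). A synthetic-data
module generates between-subjects forgetting-curve datasets with exactly
this generative structure, so fitting and parameter recovery are testable
end to end.

## Worked example

```python
from engram_forgetting import (
    ModelParams, build_schedule, run_trajectory, exploration_mean,
    generate_forgetting_curve_dataset, fit_group, compare_to_baseline,
)

# standard housing: forgetting rate 0.07, test 2 weeks after acquisition
params = ModelParams(alpha_neg=0.07, beta=-5.0, kappa=10.0)
traj = run_trajectory(build_schedule("standard", test_day=14), params)
print(round(traj.test_day_relevancy, 4))            # 0.3893  (= 0.93**13)
print(round(exploration_mean(traj.test_day_relevancy, 0.0, -5.0), 4))  # 0.1249

# simulate 4 groups x 12 mice at days 1, 7, 14, 21 and refit
obs = generate_forgetting_curve_dataset(params, seed=42)
fit = fit_group(obs, seed=0)
print(round(fit.params_hat.alpha_neg, 3))           # 0.058
print(round(fit.bic, 1), compare_to_baseline(fit, obs)["winner"])
# 112.7 learning_model
```

Two weeks of absence updates leave 39% of the original relevancy, which
the softmax turns into 12% familiar-object exploration (88% novel —
memory largely intact but fading). Refitting data simulated from the
model recovers a forgetting rate near the generative 0.07 (single
replicates scatter by ±0.02–0.03), and the fitted model's BIC of ~113
versus the baseline's 0 says the learning model explains the simulated
behavior far better than chance.

The same pipeline is scripted in `analysis/01…05` (simulate each
condition, fit, parameter recovery, BIC comparison, forgetting curves;
tables land in `results/`), and a CLI exposes it as
`engram-forget simulate|fit|recover|compare|curves`, e.g.

```sh
engram-forget simulate --condition standard --n-mice 12 --seed 7 --out sim.csv
engram-forget fit --data sim.csv --seed 0 --out fit.json
```

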
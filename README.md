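# corticostriatal

A model of how the primate corticostriatal system learns to select
action sequences, and the analysis toolkit for its population dynamics.

During learning of an oculomotor sequence task — three binary saccade
decisions per trial, one fixed correct sequence per block, blocks ending
after eight error-free trials — neurons in dorsal striatum carry action
values while lateral prefrontal cortex carries action choices. This
package implements a joint model of that circuit and the analyses that
characterize how its internal representations change within a block of
learning:

- **Task and behavior.** A deterministic task state machine (eight
  sequences over ten movement directions, forced repeats after errors)
  and a softmax Q-learning behavioral model,

      Q(s_t, a_t) <- Q(s_t, a_t) + alpha [r_{t+1} + gamma max_a Q(s_{t+1}, a) - Q(s_t, a_t)],
      p_t = softmax(beta Q_t),   Q_{t+1} = tau Q_t,

  with fitted parameters alpha = 0.8100, gamma = 0.2010, beta = 3.050,
  tau = 0.95. The Q-agent doubles as the synthetic-behavior generator:
  its learning curve rises from chance (50%) on the first decision after
  a sequence switch to above 90% by the fifth trial.
- **Coupled rate networks.** A striatal network mapping action/reward
  pulses to value signals and a prefrontal network mapping value +
  instruction signals to next-action pulses:

      tau dx/dt = -x + W_rr tanh(x) + W_ir u + eta,   u_v = W_ro^s x_s,
      u_a = W_ro^p x_p,

  trained jointly by backpropagation through time on a squared-error
  loss with double weight on the striatal term (hand-derived gradients,
  verified against finite differences).
- **Closed loop.** After training, decoded prefrontal actions and task
  rewards feed back into the striatal network and the system performs
  whole blocks autonomously, reproducing the behavioral learning curve.
- **Dynamics analyses.** Demixed PCA (exact ANOVA-style marginalization
  plus reduced-rank regression), trajectory distances within hemifield
  clusters, distance-to-centroid compactness, potential surfaces over
  latent meshes with verified fixed points, Dijkstra minimal paths
  between sequence attractors, and CCA comparison against reference
  population data.

The headline phenomenon: as certainty grows over a block, sequence
representations move apart in activity space, the troughs of the
potential landscape separate, and the ridge between attractors rises —
making wrong-action selection progressively less likely — while
striatal trajectories grow more compact.

## Worked example

```python
from corticostriatal import behavior_synth, value_model

log = behavior_synth.simulate_session(1000, value_model.QParams(), rng=1)
profile, curve = behavior_synth.error_profile(log)
print(curve[["trial", "frac_correct"]].round(3).to_string(index=False))
```

prints the within-block learning curve of the fitted Q-learning agent
(fraction of first-attempt-correct decisions per trial after the
sequence switch):

```
 trial  frac_correct
     1         0.501
     2         0.891
     3         0.912
     4         0.933
     5         0.935
     6         0.934
     7         0.928
     8         0.934
```

Trial 1 sits at chance — the new sequence is uncorrelated with anything
learned — and performance exceeds 90% from the second trial on.

The full model pipeline (simulate behavior, fit/derive value traces,
encode tensors, train both networks, run closed loop, analyze latent
dynamics and potential surfaces, CCA) runs from one config:

```
corticostriatal run --out artifacts --seed 0
```

producing behavior logs (CSV), tensors and checkpoints (HDF5), distance
and path-length curves (CSV) and a manifest with per-stage seeds.
Defaults use the 5x reduced network (260 striatal / 200 prefrontal
units); full-scale sizes are a config change.

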
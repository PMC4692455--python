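# szdcm — spectral DCM of seizure activity with Bayesian belief updating

Electrographic seizures can last minutes to hours while their spectral
content changes from second to second. A biophysically interpretable way to
analyse such recordings is dynamic causal modelling (DCM) for cross-spectral
density: a neural mass model of the seizure onset zone predicts the complex
spectrum of each short data epoch, and Bayesian inversion recovers the
synaptic parameters that generated it. Inverting a long seizure *jointly* —
every epoch at once, with parameter trajectories expanded on temporal basis
functions — is accurate but expensive. `szdcm` implements the efficient
alternative: **recursive Bayesian belief updating**, where each epoch's
prior is the previous epoch's posterior, inflated by a random walk on the
parameters that are allowed to drift. It is written for computational
neuroscientists and clinical neurophysiology researchers who want
time-resolved estimates of intrinsic connectivity and afferent input from
EEG/ECoG seizure recordings, and for methodologists studying filtering
versus smoothing schemes for slowly varying model parameters.

## The model

A canonical microcircuit (CMC) with four populations — excitatory granular
(spiny stellate) cells, superficial pyramidal cells, inhibitory
interneurons, deep pyramidal cells — coupled by ten intrinsic connections
g₁…g₁₀. Each population's mean potential obeys a second-order synaptic
convolution v̈ₖ = Tₖuₖ − 2Tₖv̇ₖ − Tₖ²vₖ with uₖ the connection-weighted sum
of presynaptic firing rates S(v) = 1/(1+e^{−γv}) − ½. Within a 2000 ms
epoch the circuit is assumed quasi-stationary, so the observed spectrum is
that of the linearised system:

    g_i = H(θ_i) + ξ,    S(f) = κ·|H(f)|²·g_u(f) + σ_n·g_n(f)

with H(f) the transfer function of the delayed linearised dynamics,
g_u(f) = a₁f^(−a₂)·exp(Σ dₖχₖ(f)) a power-law input spectrum with
discrete-cosine innovations, and g_n a power-law measurement-noise floor.
Between epochs the *volatile* parameter classes (inhibitory connections
{g₃,g₄,g₉}, excitatory connections {g₅,g₆,g₈}, endogenous input
{a₁,a₂,d₁…d₈}) follow a random walk θ_i = θ_{i−1} + ε, ε ~ N(0, R_i)
with R_i = (1+η_i)R₀; the volatility η_i is re-estimated every epoch by
maximising free energy. Each epoch is inverted by variational Laplace
(Gauss–Newton ascent on the free energy); model comparison over the eight
combinations of volatile classes uses total free energy relative to the
null model, with ≥ 3 nats counted as strong evidence.

All parameters live on log-scaling latents φ (θ = θ̄·e^φ with θ̄ the prior
means), so priors are Gaussian and positivity is automatic.

## Worked example

Recover a known inhibitory drift from simulated seizures. Ten 14-s
seizures are simulated while the inhibitory connections rise by one e-fold
(a sigmoid on the log scale); their induced spectra are averaged per epoch
and filtered through the belief-updating scheme:

```python
import numpy as np
from szdcm import (DriftSchedule, average_induced, epoch_and_csd,
                   multi_seizure, run_updating)

recordings = multi_seizure(10, "inhibitory", seed=1)
sequence = average_induced([epoch_and_csd(r) for r in recordings])
trajectory = run_updating(sequence.spectra, volatile_spec=("inhibitory",))

truth = DriftSchedule("inhibitory").epoch_trajectory(7)
mean, sd = trajectory.class_trajectory("inhibitory")
```

This prints, per 2-s epoch, the true and recovered log-scaling of the
inhibitory connections:

```
epoch  truth  posterior (±2 SD)
    0   0.01      -0.00 ± 0.27
    1   0.03      -0.01 ± 0.32
    2   0.15       0.04 ± 0.35
    3   0.50       0.50 ± 0.37
    4   0.85       0.76 ± 0.34
    5   0.97       0.89 ± 0.33
    6   0.99       0.96 ± 0.32
correlation with truth: 0.995
variance explained:     0.963
volatility per epoch:      -- -0.42 -0.42  1.09 -0.16 -0.48 -0.53
```

The posterior tracks the sigmoid (r = 0.995), the truth stays inside the
±2 SD band, and the volatility estimate η̂ spikes exactly at epoch 3 where
the drift is steepest — the behaviour expected around seizure onset.

The same pipeline is scriptable from the shell:

```sh
szdcm simulate --scenario inhibitory --seed 1 --n-seizures 10 --out run/
szdcm preprocess run/seizure_*.tsv --out run/seq.json
szdcm invert run/seq.json --scheme updating --model inhibitory --out run/traj.json
szdcm report run/traj.json
```

`szdcm invert --scheme standard` runs the joint temporal-basis inversion
instead, and `szdcm compare` ranks a directory of inverted models by free
energy with the null model at 0.

## Layout

- `szdcm.cmc` — CMC populations, wiring, priors, equilibrium, Jacobian
- `szdcm.forward` — transfer functions and predicted cross-spectra
- `szdcm.laplace` — variational Laplace inversion of one epoch
- `szdcm.updating` — prediction/update recursion and volatility
- `szdcm.basis` — joint inversion on a discrete-cosine temporal basis
- `szdcm.compare` — factorial model space and free-energy ranking
- `szdcm.preprocess` — filtering, epoching, multitaper CSD, averaging
- `szdcm.simulate` — ground-truth seizure simulator
- `szdcm.cli` — the `szdcm` command

See `docs/methods.md` for modelling assumptions, parameter tables and
numerical choices.
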
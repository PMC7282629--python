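# silentwm

A spiking-neuron model of **activity-silent visual working memory**.
Human observers can hold a grating's orientation in mind across seconds
in which no sustained neural firing is measurable; `silentwm` implements
the leading mechanistic account of how: the memorandum is written into
**short-term synaptic plasticity** — residual presynaptic calcium *u* and
depleted transmitter resources *x* on recurrent connections — and read
back out by perturbing the network, not by persistent spiking. The
package is for computational neuroscientists who want a runnable,
desk-scale instantiation of calcium-mediated synaptic working memory in a
population spiking framework, complete with the retro-cue
delayed-response tasks used to probe it experimentally.

## The model

Two modules (one per visual hemifield) each stack four leaky
integrate-and-fire populations: sensory (1000 neurons, Gabor-filter
encoders over 128×128 images, 24-D code), memory (1500 neurons, recurrent
with plasticity), comparison (1500 neurons, 4-D) and decision (1000
neurons, 1-D). The plasticity kinetics on each memory neuron are

    dx/dt = (1 − x)/τ_D − u x δ(t − t_sp)
    du/dt = (U − u)/τ_F + U(1 − u) δ(t − t_sp)

with U = 0.2, τ_D = 0.2 s, τ_F = 1.5 s, and effective recurrent weights
w_ij = (u_i x_i / U) · w⁰_ij: every spike depresses its synapses for
~200 ms (resources) and facilitates them for ~1.5 s (calcium), leaving a
synaptic trace of whatever pattern just fired. Stimulus orientation is
decoded as (sin 2θ, cos 2θ); the comparison stage outputs
sin(2(θ_probe − θ_memory)), whose integrated sign is the clockwise /
counter-clockwise choice.

In a trial of the reference task, two gratings are encoded (250 ms), a
retro-cue reactivates the relevant module's memory (20 ms non-specific
pulse at 1050 ms), a task-neutral bull's-eye impulse perturbs both
modules at 2150 ms, and a probe at 2650 ms is judged clockwise or
counter-clockwise of the cued item. Between events the memory populations
are exactly silent — the item survives only in (u, x).

## Worked example

```python
import numpy as np
from silentwm import ModelConfig, WMModel
from silentwm import protocols

model = WMModel(ModelConfig(), seed=42)          # ~1 min: bases + decoders
ref = protocols.reference_trial_run(model, n_trials=20)

print("delay spikes/trial (cued):", ref[0]["delay_spikes_per_trial"])
print("cue-recovery top orientation:", ref[0]["cue_top_theta"], "deg")
print("uncued impulse/item similarity ratio:",
      round(ref[1]["impulse"]["ratio_impulse_over_item"], 2))
```

prints

```
delay spikes/trial (cued): 0.0
cue-recovery top orientation: 1.0 deg
uncued impulse/item similarity ratio: 2.74
```

meaning: across 1500 memory neurons and half a second of delay there is
*zero* spiking (the memory is activity-silent), yet the non-specific cue
pulse re-expresses the stored 0° grating (best-matching ideal vector at
1°), and in the uncued module the impulse-evoked response resembles the
impulse about twice as strongly as the decayed, never-reactivated item —
the signature dissociation between prioritized and dropped memoranda.

The command line mirrors the library:

```
silentwm make-stimuli --design exp1 --seed 1 --out stim/
silentwm simulate --design exp1 --participants 2 --trials-per 4 \
         --seed 0 --out runs/exp1
silentwm analyze --responses runs/exp1/responses.csv --out runs/exp1
silentwm explore --tau-d 0.2 --tau-f 0.6,1.8 --out runs/grid
```

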
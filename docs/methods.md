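# Methods

`twostage` implements a reduced-model account of synaptic integration in
fast-spiking (FS) basket cells and its consequences for memory encoding.
This note documents the models, the calibration constants, what the
synthetic data emulate, and the numerical choices.

## The two-stage neuron

A neuron is a set of independent dendritic subunits feeding an adaptive
integrate-and-fire soma.  Subunit voltage obeys

    tau_b dV_b/dt = sum_j w_j E_syn delta(t - t_ij) - V_b,

so each presynaptic spike of weight `w` increments `V_b` by `w·E_syn/tau_b`
and the subunit relaxes exponentially otherwise.  The subunit output passed
to the soma is a static function of `V_b` (plus the backpropagating-AP
component, below):

* **linear** — identity;
* **sublinear** — `max(V_b, 0)^0.7`, a saturating power law (the exponent
  0.7 is fixed; `V_b` is clamped at zero before the power law);
* **supralinear** — `passive_gain·V_b + spike_amp·sigma((V_b −
  theta_dspike)/slope)`.  The logistic term is the local dendritic sodium
  spike: an all-or-none regenerative event whose contribution *saturates*
  at `spike_amp`, on top of an attenuated passive transfer
  (`passive_gain` < 1).  Making the spike component saturating (rather
  than a gain added to a full linear pass-through) is deliberate: local
  spikes do not grow without bound with input, and it is what renders a
  supralinear branch sigmoid-like from the soma's point of view.

The soma integrates

    C dV/dt = −g_L(V − E_L) − g_AHP(V − E_K) + I_syn,
    tau_AHP dg_AHP/dt = a_AHP δ(t − t_spike) − g_AHP,
    I_syn = g_syn Σ_n f(V_b,n + V_bAP) − IPSC(t),

spiking at `theta_soma` with reset to `E_L = 0 mV` and a 2 ms absolute
refractory period.  A somatic spike launches a backpropagating
depolarization `V_bAP(t) = E_bAP e^{−t/tau_bAP}` added to every subunit.
Inhibition arrives as exponentially decaying perisomatic current pulses
(`tau_IPSC = 10 ms`); the kernel is a choice — only the presence of an
IPSC term is prescribed by the model equations.

Units are mV, ms, nA, uS and nF, which close under `I = g·V` and
`C dV/dt`.  All state variables advance by per-variable exponential-Euler
updates, so homogeneous decays are exact at any step size; the default
`dt` is 0.1 ms for single cells and 0.5 ms for the network (both well
under `min(tau_b, tau_AHP)/10`, the stability guard in `simulate`).
Halving `dt` moves batch-mean rates by under 5%.

### Parameter values

The reduced-model constants are calibration constants, fixed once in
`twostage/params.py` and not tuned per experiment.  The reference FS cell
(40 synthetic dendrites, ~35% supralinear) uses `tau_b = 10 ms`,
`E_syn = 15 mV`, `theta_dspike = 15 mV`, `spike_amp = 12 mV`,
`passive_gain = 0.3`, `C = 0.2 nF`, `g_L = 0.01 uS`, `theta_soma = 15 mV`,
`tau_AHP = 80 ms`, `a_AHP = 0.2 uS·ms`, `g_syn = 0.013 uS`,
`E_bAP = 5 mV` (backpropagation is weak in FS cells).  They were chosen so
that three operating points hold simultaneously: (i) 60 dispersed synapses
driven at 50 Hz put the cell in the gamma band (30–100 Hz); (ii) the
sparse background protocol (below) yields ~3 Hz; (iii) dispersed
allocations outrate grouped ones at matched synapse counts, and replacing
the sublinear transfer with a linear one abolishes that preference — the
reduced analogue of widening the dendrites and blocking the A-type
current.

## Synthetic data

No downloads are required; every input is generated.

* **Morphometry.**  Branch length and mean diameter are log-normal per
  integration class — supralinear branches longer and thicker (medians
  110 um / 0.90 um) than sublinear ones (60 um / 0.55 um), mixture 35%
  supralinear — so the supralinear class has the larger cylinder volume
  `V = pi (d/2)^2 L` and, through the monotone map
  `R_in = 1000/sqrt(V) MOhm`, the lower input resistance.  Branches with
  mean diameter above 1.2 um are excluded and resampled.  Group
  separation in volume and R_in is significant (Welch) at n = 40 per
  class.  The moments are chosen to reproduce the qualitative hippocampal
  pattern, not any particular reconstruction; the monotone R_in map
  stands in for per-branch current injection, which would need a cable
  model.
* **Stimulation protocols.**  Dispersed allocation places `step ∈ {2, 5,
  10}` synapses on randomly drawn dendrites (without replacement) until
  the total is reached; grouped allocation gives each selected dendrite a
  group of `Sclu ∈ {10, 15, 20, 30, 60}` synapses, so 60 synapses at
  `Sclu = 20` occupy exactly three dendrites.  When the total is not a
  multiple of the group size the last dendrite takes the remainder.  The
  default repeat count is five times the number of dendrites, mirroring
  the resample-five-locations-per-dendrite, repeat-per-dendrite design of
  the original stimulation experiments (synapse position *within* a
  subunit has no meaning in a reduced subunit, so the multiplicity is
  retained as allocation resampling).
* **Poisson drive.**  Homogeneous 50 Hz trains; batch simulations exploit
  the fact that superposed unit-weight Poisson trains are Poisson with
  summed rate.
* **Background activity.**  32 excitatory synapses (weight 3.0) on random
  dendrites plus 8 perisomatic inhibitory synapses (0.09 nA pulses), each
  active at 10 Hz, hold the reference cell at ~3 Hz — an in-vivo-like
  low-rate regime.  The per-synapse rate and weights are calibration
  constants (only the 32/8 composition and the 3 ± 1 Hz outcome are
  externally specified).
* **Surrogate firing-rate datasets.**  Rows pair a per-dendrite synapse
  count vector with the mean somatic rate of the reference cell over
  several seeded simulations.  These stand in for compartmental-model
  simulations of reconstructed cells; they inherit the reduced model's
  simplifications (no within-branch synapse positions, stationary drive).

## Plasticity (synaptic tagging and capture)

Per presynaptic spike, a synapse admits calcium
`ΔC = a_Ca / (1 + exp(−(V − 30)/5))` with `V` the subunit depolarization
including the backpropagating and NMDA-plateau components.  Calcium
accumulates during a stimulus and is read out at stimulus end: below 4
(accumulated units) no tag, between 4 and 12 a depotentiation tag, above
12 a potentiation tag; the accumulator then resets.  A neuron whose total
stimulus calcium exceeds 200 triggers somatic PRP synthesis (level 1.0,
exponential decay, `tau_PRP = 1.5 h`) and a 12 h halving of its AHP
increment (the intrinsic-excitability correlate of learning that
underlies memory linking).  Tags consolidate into weights at a rate
proportional to the instantaneous PRP level (fully consolidated tags add
`2·w_init` or remove `0.5·w_init`); unconsolidated tag fractions persist
until the next stimulus overwrites them.  Homeostatic scaling applies the
shared increment `dw_j/dt = (1/tau_H)(1 − Σw/(w_init N))` with
`tau_H = 48 h`, whose fixed point conserves each neuron's summed weight.

Interstimulus intervals are fast-forwarded analytically — consolidation
uses the closed-form integral of the decaying PRP level, homeostasis the
exponential relaxation of the summed weight (time constant
`tau_H · w_init`) — rather than stepping hours at sub-millisecond
resolution; the closed forms agree with fine-step Euler integration to
<0.1%.  Within an interval the order is consolidation → PRP decay →
homeostasis → clock advance (excitability restoration).  The tag/PRP
thresholds and quanta are calibration constants of the reduced model.

## The engram microcircuit

400 two-stage excitatory neurons (20 subunits each, NMDA plateaus:
20 mV for 40 ms when a subunit crosses 18 mV; `E_bAP = 15 mV`), 40 FS
basket cells and 40 SOM+ interneurons (10 subunits each).  FS cells
inhibit excitatory somata (current pulses), SOM+ cells inhibit excitatory
dendrites (subunit-voltage decrements); both are driven by excitatory
spikes.  Interneuron afferent synapses are static — plasticity acts only
on the memory afferents of excitatory cells.  Each memory is carried by
100 afferents (50 conditioned + 50 unconditioned) contacting excitatory
dendrites with probability 0.25 at weight `w_init = 2.8`.  Encoding
co-activates both halves at 50 Hz for 1 s; recall presents the CS half
alone for 1 s with plasticity frozen; excitatory neurons above 10 Hz at
recall form the engram.  Connection probabilities and weights are single
scalars per projection, calibrated once so the control configuration
(bimodal FS dendrites, dispersed FS inputs, sublinear SOM dendrites)
yields a median engram of 25–30% of the excitatory population —
the experimentally constrained operating point.

The FS dendritic configuration is the experimental dial: `linear` (all
ten subunits linear) or `bimodal` (five supralinear + five sublinear).
Network interneurons use a lower dendritic-spike midpoint (5 mV) than the
isolated reference cell, placing their subunits' sigmoids in the range of
the feedback drive they actually receive; with that, bimodal FS dendrites
produce more inhibition than linear ones at network operating voltages,
which is what shrinks the engram, lowers mean rates and sparsifies the
population code.  Engram overlap between two memories is reported as
|intersection| / |first engram| × 100; the chance level is the
independence product of the two engram fractions (a population-scale
quantity, reported alongside for reference).  Memory linking arises from
the 12 h excitability window: a second memory encoded 1 h after the first
preferentially recruits first-engram neurons (and residual PRP from the
first memory aids its consolidation), while at 24 h separation both
effects have lapsed.

Desk-scale choices: population sizes (400/40/40), 1 s encode/recall
windows and `dt = 0.5 ms` keep a 10-trial experiment within minutes on
one CPU; the directional results are not sensitive to these sizes.

## ANN abstractions

Four two-layer feed-forward reductions map synapse-count vectors to
rates: linear, supralinear (sigmoid), sublinear (`(x+2)^0.7 − 2`) hidden
layers of five units, and the bimodal modular net whose hidden layer
splits into a sigmoid block (supralinear-dendrite counts only) and a
sublinear block (sublinear-dendrite counts), five units each.  All
weights and biases are projected to ≥ 0 after every Adam update (the
biophysical cells receive only excitatory input; under this constraint a
ReLU is the identity).  Training minimizes MSE on a random 80% of rows
with minibatches of 64; targets are internally rescaled by their standard
deviation for conditioning and predictions mapped back to Hz.  The
default learning rate is 3·10⁻³ with ≤ 2000 epochs and early stopping
after 200 epochs without improvement — chosen for reliable convergence of
the constrained nets at this data scale.  R² is reported as the
coefficient of determination on the held-out rows (it can be negative);
the squared Pearson correlation is reported alongside since both
conventions circulate under the name "R²".

The fixed-count challenge holds total input power constant (20, 40 or 60
synapses) so only synapse *location* drives rate variance.  For the
per-count tables each architecture is trained and evaluated on that
count's rows alone — the pooled model's job (tracking total drive) and
the within-count discrimination job are reported separately.  On
surrogate datasets (≥2000 rows per cell) the bimodal modular net beats
the linear net pooled, and by a much wider margin within the fixed-60
subset, reproducing the directional pattern of the original comparison;
the absolute R² values differ because the generating model here is the
reduced cell, not a compartmental simulation.

## Known limitations

* The surrogate reference cell stands in for multicompartmental models:
  no cable geometry, channel kinetics, or within-branch synapse position.
  Passing tests show the reduced abstraction is self-consistent, not that
  it matches any particular biological cell.
* Morphometry distributions are qualitative; measured p-values on real
  reconstructions are out of reach by construction.
* Interneuron afferents are non-plastic, and inhibitory inputs onto
  interneurons are omitted (they are a small minority of contacts on FS
  cells).
* The gap-junction current is provided as a utility between reduced
  compartments; no coupled-pair biophysics is modelled.
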
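# Methods

## Model

Each neuron is a leaky integrate-and-fire unit, τ_m V̇_i = −V_i + I_i^syn +
I_i^b, with τ_m = 30 ms, threshold V_th = 15 mV and reset V_r = 13.5 mV; the
membrane input resistance is folded into the currents, so drives are in mV.
Spikes are δ-pulses. The synaptic current is the in-degree-normalised sum of
active resources, I_i^syn = (1/K_i^I) Σ_j G_ij Y_ij (a neuron with K^I = 0
receives zero current). Each directed synapse follows the
Tsodyks–Uziel–Markram three-state scheme: Ẏ = −Y/T^I + uXS_j,
Ż = Y/T^I − Z/T^R, X = 1 − Y − Z, where S_j is the presynaptic spike train.
Synapses onto inhibitory neurons facilitate, u̇ = −(u − U)/T^F + U(1 − u)S_j;
onto excitatory neurons u ≡ U. At a presynaptic spike the facilitation
increment is applied **before** the release (update-then-use, the standard
facilitation convention; the δ-term ordering is otherwise ambiguous).

Parameter defaults (mean, with SD = mean/2, truncated positive by redraw and
U clipped to [0.001, 0.999]); subscripts are (postsynaptic, presynaptic):

| parameter | value | units | role |
|---|---|---|---|
| N, N_e, N_i | 100, 90, 10 | — | population and composition |
| K̄ᴵ | 10 | — | ER mean in-degree (edge prob. K̄ᴵ/(N−1)) |
| T̄ᴵ | 3 | ms | postsynaptic-current decay, all synapses |
| T̄ᴿ (onto e / onto i) | 800 / 100 | ms | recovery from depression |
| T̄ᶠ (onto i) | 1000 | ms | facilitation decay |
| Ū (onto e / onto i) | 0.5 / 0.04 | — | baseline release fraction |
| Ḡ (e←e, e←i, i←e, i←i) | 45, 135, 180, 180 | mV | coupling magnitude; sign from presynaptic class |
| I^b support | 15 ± 0.45 | mV | flat; exactly 10% strictly above V_th |

The stated "width 0.45 mV" of the excitability distribution is implemented
as a **half-width** (support [14.55, 15.45] mV): only this support is
consistent with the published clique-leader excitability of 15.32 mV, with
hub excitabilities up to 15.42 mV, and with the ~22 Hz maximal control
firing rate (an isolated neuron at 15.45 mV fires at
1000/(30 ln(1.95/0.45)) ≈ 22.7 Hz).

The exact 10%-suprathreshold constraint is realised by drawing
round(0.1 N) values uniformly on (V_th, 15.45] and the rest on
[14.55, V_th], then shuffling — which *is* the flat law conditioned on the
exact count when the support straddles the threshold.

Anti-correlation (the developmental rule): excitabilities are sorted and the
r-th largest total degree K^T = K^I + K^O receives the r-th smallest I^b, so
Spearman(I^b, K^T) = −1 up to degree ties (ties broken by neuron index). The
uncorrelated control keeps the same marginal distributions but assigns the
excitabilities in their random draw order.

## Event-driven integration

Between spikes every variable has a closed form; V(t) is a constant plus a
sum of exponentials (one per active in-edge, rates 1/T^I_e, plus 1/τ_m). The
next threshold crossing of each neuron is found by a marching bracket with a
rigorous per-interval upper bound (each exponential term is monotone, so its
maximum on an interval is at one end): an interval is discarded only when V
provably stays below threshold on it, inconclusive intervals are subdivided
(down to 1e-9 ms), and brackets are bisected to 1e-10 ms. The step grows
geometrically (×1.4, capped at τ_m/2) once the fast synaptic transients have
been covered, and the search terminates with "never fires" only when the
rigorous tail bound drops below threshold. The map is therefore exact up to
root tolerance. Membrane states advance lazily (only when one of a neuron's
presynaptic cells fires, or a scheduled current change touches it), so a
spike costs O(K^O · K^I) exponentials. A guard nudges any synaptic T^I
within 1e-6 ms of τ_m (a measure-zero resonance of the closed form).

Cross-validation: a deliberately naive fixed-step RK4 integrator of the same
equations (dt = 1e-3 ms, crossing located by bisecting the step) shares no
code with the event-driven kernel beyond the model definition; on 5–6-neuron
random motifs over 1 s both produce identical spike sequences with times
agreeing to ~1e-7 ms.

Initial conditions (not specified by the modelling literature this follows):
V uniform on [V_r, V_th), X = 1, Y = Z = 0, u = U, all drawn from the run
seed; a 10 s burn-in under control conditions is discarded before every
analysis window. Perturbation programs (deletions, DC steps) switch on at
the start of the recording window. A deleted neuron neither integrates nor
fires; its synapses keep relaxing. Channel noise, when enabled, draws each
reset uniformly from [V_r − Δ, V_r + Δ] (default Δ = 0; with Δ = 0 a run is
bit-reproducible for a fixed seed). Simultaneous crossings are processed in
ascending neuron index.

## Burst detection

*Population bursts (PBs).* Spikes are binned at 10 ms (bins anchored at
t = 0 of the window; the anchor matters at the ±1-bin level and is fixed for
reproducibility). A bin is burst-active when the number of **distinct**
neurons firing in it strictly exceeds 25% of the population — participation
language counts neurons, not spikes. Runs of active bins merge into one PB;
the peak is the centre of the maximal-count bin, the width the
onset-to-offset span of the run. Inter-burst intervals (IGIs) are peak-to-
peak, reported in seconds.

*Build-up refinement.* Each PB's peak is re-located at 1 ms resolution as
the first fine bin with more than 5% of the population firing, the crossing
interpolated linearly between adjacent bin counts; the 70 ms before the
refined peak is the build-up window, in which each neuron's first spike is
taken. Events with no qualifying fine bin are dropped with a warning.

*Event participation.* The fraction of the population recruited by a burst
is measured over the window from 70 ms before the peak (the build-up, when
the early cells fire) to the PB offset. The strict onset-to-offset
participation is also available and is systematically ~10 points lower.

*Aborted bursts (ABs).* Collective enhancements that fail to reach the PB
criterion. The operational rule: a local maximum of the 10 ms binned
distinct-neuron count that (a) exceeds twice the median inter-burst bin
count and involves ≥ 15% of the population, (b) is not inside a PB and lies
≥ 50 ms from every PB peak, and (c) is an isolated bump — the bins 2–3 away
on both sides stay below half the peak. The isolation clause separates
event-like failures of ignition from sustained elevated firing, which a bare
threshold rule counts by the hundreds. The participation floor and isolation
window were calibrated so that the pooled AB/PB percentages of the two
network variants land at the published order of magnitude with the published
ranking; all four parameters are exposed as arguments.

*Phase indicator.* Φ_i = (t_G^i − i·Δt)/Δt with events indexed from 1 and
Δt the control-mean IGI: negative drift = acceleration. Epoch comparisons
use the two-sample Kolmogorov–Smirnov test at α = 0.05 (fewer than two
events in an epoch yields an explicit undefined result), plus a 60 s
forward-rolling mean-IGI series for visualization.

*Participation similarity.* PBs as binary participation vectors, pairwise
cosine similarity, average-linkage two-cluster cut; the split separates
high- from low-participation event types when the low events share a
consistent core subpopulation.

## Functional connectivity

Timestamps are binarised at 1 ms and, per neuron pair, the normalised
cross-correlogram C_ab(τ) = Σ_t a_{t+τ} b_t / min(Σa, Σb) is evaluated on
|τ| ≤ 500 ms (computed sparsely from coincidence lags; identical to the
dense formula). An edge is assigned only when the correlogram is compatible
neither with uncorrelated firing nor with synchrony. The published recipe
names a Student's t and a KS test without the null constructions; the policy
implemented here treats the multiset of coincidence lags as the sample:
KS against the uniform lag law on [−500, 500] rejects "uncorrelated", a
one-sample t-test of zero mean rejects "synchronous", both at α = 0.05
jointly. This interpretation is validated by its type-I control (false-edge
rate ≤ 5% on independent Poisson trains) and by direction recovery on
planted-lag chains; it is a documented choice, not a published algorithm.
The peak lag τ_max (ties to the smaller |τ|; an unresolved ± tie or τ_max=0
assigns nothing) sets the direction: τ_max > 0 means b fires before a.
Functional degrees D^O, D^I are percentages of the N−1 potential partners;
hubs are the ≥ 90th percentile of D^O.

Surrogate constructions select the dynamics of interest: `degree` keeps
spikes at least 35 ms after the previously kept one (one spike per burst),
`buildup` keeps first spikes in the 70 ms pre-peak windows, `interburst`
keeps everything outside the PB spans.

## Perturbation protocols and driver classes

Control variability is measured as the PB-count mean and SD over
independent initial conditions in a fixed 84 s window (100 by default;
protocol-level analyses here use 8–20, which already pin the SD to a few
counts). Single-neuron deletion (SND) removes one neuron for the window;
single-neuron stimulation (SNS) holds its total drive at I^stim (the sweep
convention: the value replaces I^b, grid 14.5–18.0 mV, paper step 0.015 mV,
coarse grids for routine use). A change counts when it is both ≥ 50% of the
control mean and outside three control SDs (the conservative conjunctive
reading). Hubs: SND decrease ≥ 50%. LC drivers: non-hubs with some
significant SNS change; LC2 if all their significant changes are increases,
LC1 otherwise.

Clique extraction: within each burst's build-up window the hub spikes form
an ordered sequence (a hub firing twice contributes two elements,
distinguished by occurrence index); identical sequences define a route, and
per-route inter-firing delays are reported as mean ± SD. The leader is the
hub with zero functional in-degree in the first-spike build-up graph.
Window alignment is the refined peak by default; micro-fixtures whose whole
burst *is* the causal chain (no synchronous volley after it) use the PB
offset plus one bin, with a window shorter than the burst cycle.

Resource monitoring samples X^OUT_i (mean recovered fraction over efferent
synapses; X^IN likewise) at a stated cadence; for each burst after the
first, the maximum of X^OUT between 50 ms after the previous peak and the
current peak is paired with the preceding IGI, and the minimal ignition
value X* is the smallest such maximum over observed bursts.

## Synthetic fixtures

Four hand-built motifs isolate the model's mechanisms at minimal scale:
`pair_entrain` (suprathreshold e-cell entraining a subthreshold i-cell 1:1
through a facilitating synapse), `gate` (e→i→e: the entrained interneuron
slows a second pacemaker), `chain6` (a pacemaker-headed excitatory chain —
every cycle is a stereotyped single-route burst with stationary ~4.3 ms
delays; couplings chosen so each link fires exactly once per cycle), and
`lc_probe` (chain6 plus a silent inhibitory gate onto the chain and a
silent probe cell wired onto the gate: deletion of the probe changes
nothing, stimulation silences the bursts — an LC1 driver in miniature).
These fixtures exercise every analysis stage deterministically; they do not
emulate the full network's heterogeneity, degree-excitability correlation
or burst-failure statistics, so passing them shows the machinery is
correct, not that the N = 100 phenomenology holds — that is what the
control-statistics and perturbation analyses on full realizations are for.

## Problem sizes and reproducibility

Control statistics pool five bursting realizations per variant (84 s
windows after 10 s burn-in; realizations with fewer than 10 PBs are
excluded, mirroring the fraction of preparations without usable bursting).
Perturbation analyses use one strongly gated anti-correlated realization
(SND of every neuron; SNS on a coarse grid over hub-afferent candidates)
and three uncorrelated controls at 42 s windows. All seeds are explicit;
with Δ = 0 every reported number is deterministic given its seed.

## Known limitations

- The anti-correlated ensemble reproduces the published control statistics
  (IGI, width, AB fraction, participation) within the published bands, but
  the *uncorrelated* ensemble does not reproduce the published fast-sloppy
  regime (mean IGI ≈ 0.3 s, width ≈ 30 ms): across many seeds and
  assignment variants its pooled IGI stays at 0.6–1.3 s with ~17 ms widths,
  and correspondingly a few uncorrelated deletions (~2%) still cross the
  50% driver criterion. The event-driven map is verified exact against an
  independent integrator, and the realization statistics of the
  anti-correlated variant match published per-cell values closely, so this
  looks like realization-level variability rather than an equation error;
  the numbers are reported as measured.
- The AB rule and the correlogram statistics are operational definitions of
  qualitative published descriptions; both are exposed as parameters and
  documented above.
- No synaptic delays, conductances, spatial structure, or plasticity beyond
  the short-term dynamics; stimulation is DC, not pulsed.
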
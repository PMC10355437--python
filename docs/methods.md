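# Methods

## Model

Each cortical region is a Wilson-Cowan pair of excitatory and inhibitory
mean-field populations with rates r^E, r^I in (0, 1):

    tau_E dr^E_i/dt = -r^E_i + F( c_EE r^E_i - c_EI,i r^I_i
                                  + C * sum_j W_ij r^E_j(t - tau_ij)
                                  + xi(t) + P )
    tau_I dr^I_i/dt = -r^I_i + F( c_IE r^E_i + xi(t) )

with the sigmoid F(x) = 1/(1 + exp(-(x - mu)/sigma)). Long-range coupling
is excitatory-to-excitatory only, weighted by the structural connectome W
and scaled by the global coupling C; conduction delays tau_ij come from
tract lengths divided by a conduction speed chosen so that the mean delay
over connected pairs equals a configured value. With tau_E = 2.5 ms and
tau_I = 5 ms an isolated node crosses a Hopf bifurcation as its net drive
rises and oscillates in the gamma range; at the inhibition level
c_EI = 2.5 the node is quiescent at the baseline excitability P = 0.31
and settles on a ~41.6 Hz limit cycle at P = 0.40 (verified by
linearization of the 2-D subsystem and by simulation). Fixed parameters:

| parameter | value | meaning |
|---|---|---|
| tau_E, tau_I | 2.5 ms, 5 ms | population time constants (set the ~40 Hz rhythm) |
| c_EE, c_IE | 3.5, 3.75 | local E->E and E->I couplings |
| P | 0.31 | intrinsic excitability (node poised near the bifurcation) |
| mu, sigma | 1, 0.25 | sigmoid threshold and sensitivity |
| noise variance | 0.01 | Gaussian input noise, per node/population/step |
| dt | 0.2 ms | Euler step (5 kHz) |
| C, rho, mean delay | 4.07, 0.2, 4 ms | fitted working point (defaults) |

Noise convention: xi is drawn independently per node, per population, per
Euler step with SD 0.1 and enters inside the sigmoid argument, not on the
rate, and is *not* scaled by sqrt(dt) — it is treated as a discrete-time
input fluctuation, the convention of the neural-mass lineage this model
follows. Initial conditions are deterministic (r^E = r^I = 0.1); the delay
ring buffer is pre-filled with the initial rates, and the first 10 s of
every recording are discarded. Delays round to the nearest integer step
with a minimum of one step for connected pairs (instantaneous coupling
only when the mean delay is set to 0). Rate series are recorded at 1 ms
decimation (preserves the gamma band with margin); inhibitory weights are
sampled every 10 s.

## Homeostatic inhibitory scaling

Local inhibition onto each excitatory population adapts as

    tau_homeo d c_EI,i / dt = r^I_i (r^E_i - rho),

clamped at zero (negative inhibition is unphysical), applied every Euler
step with tau_homeo = 2.5 s by default. Because tau_homeo only sets the
approach speed, the steady state is invariant to it as long as plasticity
stays slow relative to the ~25 ms oscillation cycle (checked at 2.5 s vs
25 s, agreement within 1%).

What the rule controls: its equilibrium is <r^I (r^E - rho)> = 0, i.e. the
*inhibition-weighted* time-mean of r^E equals rho. In the gamma-oscillatory
regime the model is designed for, r^E and r^I co-oscillate, so the plain
time-mean rate sits below rho by Cov(r^I, r^E)/E[r^I] — about 0.03–0.06 at
rho = 0.2 on the synthetic networks, insensitive to the coupling strength.
Both quantities are reported by the working-point analysis; tests that
assert setpoint control target the weighted mean, which is the quantity
the equation fixes.

Steady-state detection: the 10-s-sampled c_EI trajectory is scanned with a
sliding window spanning 40 tau_homeo (10 samples at the default tau); the
network has converged when every node's windowed range, relative to its
current magnitude (floored at 0.1), falls below 1e-2. The tolerance sits
above the measured equilibrium jitter of the sampled trajectory (~3–7e-3
per window under the reference noise) and well below pre-convergence
drift; expressing the window in units of tau_homeo makes detection — and
hence the reported adaptation times — timescale-relative. Stabilization
runs until convergence or a 500-simulated-minute cap (configurable), and
non-convergence is flagged, never silently accepted.

## Hemodynamics

Excitatory rates drive a Balloon-Windkessel model per region (vasodilatory
signal, inflow, venous volume, deoxyhemoglobin), integrated with Euler at
the 1 ms rate-series step and read out as

    y = V0 (7 rho_h (1 - q) + 2 (1 - q/v) + (2 rho_h - 0.2)(1 - v)),

with the standard constant set kappa = 0.65 s^-1, gamma = 0.41 s^-1,
tau = 0.98 s, alpha = 0.32, rho_h = 0.34, V0 = 0.02. A single oxygen
extraction fraction rho_h is used throughout the readout. Output is
downsampled to TR = 0.72 s; the first 10 BOLD samples are dropped, and
analysis uses a 2nd-order zero-phase Butterworth band-pass at
0.01–0.1 Hz (the standard resting-state band; the model's own spectral
content at the working point lies inside it). The Euler integration was
checked against an adaptive ODE solver on step responses (peak agreement
within 2%).

## Lesion protocol

A gray-matter lesion removes all connections to and from one region; the
node remains in the simulation, isolated and noise-driven. Three phases
are recorded, plasticity always off during recording: T0 (baseline, from
converged intact weights), T1 (acute: lesioned network on the frozen
baseline weights), and T2 (chronic: after plasticity re-converges on the
lesioned network, up to the configured cap). Per-lesion randomness derives
from (master seed, node id, stage), so sweeps are reproducible and
independent of execution order; the baseline stabilization and T0
recording are shared across lesions of one seed.

For hemisphere-averaged maps, left-lesion patterns are mirrored by
swapping homotopic partners so the lesioned hemisphere always lies on one
side; mirroring is an involution and regions without a partner keep their
value (flagged).

## Metrics

- **FC**: Pearson correlations between filtered BOLD series. **FCD**:
  correlations between upper-triangle FC patterns of 80-sample windows
  advanced 16 samples (80% overlap). Fit to a reference uses Pearson r and
  MSE over FC upper triangles plus the two-sample KS statistic between
  off-diagonal FCD value distributions.
- **FC distance**: Frobenius norm of the matrix difference (with the root;
  the norm named in the definition). Comparisons across lesion phases
  exclude the lesioned row/column by default so all phases share a node
  set.
- **Synchrony/metastability**: mean and SD over time of the Kuramoto order
  parameter R(t) computed from analytic-signal phases of the filtered
  BOLD (edge samples trimmed).
- **Avalanches**: per-node Z-scored rate series (1 ms bins, full-series
  mean/SD); an event is the first bin of each excursion beyond +/-2.3 SD,
  tracked per sign so a direct flip across the band is a new crossing; an
  avalanche is a maximal run of consecutive bins with at least one event
  network-wide, its size the event count. **Criticality**:
  k = 1 + (1/m) sum [F_PL(beta_n) - F_NA(beta_n)] with m = 10 log-spaced
  points between the observed minimum and maximum sizes, F_PL the CDF of
  a -1.5 power law truncated at the network size, both CDFs evaluated
  right-continuously. Sign convention: an excess of small avalanches
  (subcritical) puts the empirical CDF above the power-law CDF, so k < 1
  subcritical and k > 1 supercritical, matching the verbal definition of
  the statistic; the opposite ordering, sometimes seen in print, would
  invert that reading.
- **Graphs**: FC matrices are thresholded to keep the top density fraction
  of off-diagonal correlations (ties broken deterministically by value,
  then indices). Modules are fixed a priori by consensus k-means (many
  k-means runs on FC rows, co-assignment matrix, one final k-means) on an
  *independent* intact-network recording, not on the T0 recording itself:
  scoring a recording with a partition fitted to it overfits recording
  noise (measured in-sample Q can triple the out-of-sample value at 16
  nodes) and fabricates a baseline no later phase could recover to.
  Modularity is Newman's Q for that fixed partition; the small-world
  coefficient is (C/C_rand)/(L/L_rand) against connected Erdos-Renyi
  graphs with identical node and edge counts. Q is evaluated over
  densities 4–40% and SW over 20–40% (2% steps) by default, lesioned node
  removed first; SW is undefined (NaN) at densities where the graph
  disconnects, and because 16-node FC graphs disconnect below ~50%
  density, the desk-scale study evaluates SW at 50–70% — the same
  smaller-network range adaptation as moving from 4–20% to 4–40% when
  going from hundreds of regions to 78.
- **Excitability**: per-region percentage change of c_EI from T0 to T2
  (negative = increased excitability; the lesioned node's entry is
  missing). Spatial structure is summarized by a least-squares fit
  a*exp(-d/lambda) + c against Euclidean distance to the lesion (the
  additive offset absorbs the far-field plateau), by pooled correlation
  with structural weight to the lesion and per-lesion correlation with
  lesion strength (F-test p-values), and by the homotopic asymmetry index
  [c_R(T2)/c_L(T2)] / [c_R(T0)/c_L(T0)] - 1.

## Synthetic data

The connectome generator emulates what the analysis assumes of
DTI-derived cortices: regions placed mirror-symmetrically in two 60-mm
hemispheric balls 80 mm apart (realistic distance range for the delay
arithmetic), weights exp(-d/40 mm) with multiplicative lognormal jitter
(sigma = 0.5, the heavy-tailed weight spread of empirical connectomes),
homotopic pairs boosted 2x, thresholded to 40% density, lengths equal to
Euclidean distance, and weights rescaled to mean node strength 1 so the
fitted working-point coupling C = 4.07 produces comparable long-range
drive at desk scale. It does not emulate curved tract geometry,
inter-subject variability, or the true cortical folding; passing tests
demonstrate the mechanics and directions of the pipeline on networks with
the right statistical structure, not quantitative reproduction of
empirical cortical values, which require the normative connectome and
empirical BOLD. Reference "BOLD" fixtures are correlated Gaussians with
planted block covariance for exercising fit metrics and clustering.

## Study scale

The reference protocol (78 regions, 30-minute recordings, 500-minute
adaptation cap, 25x26x16 fit grid) is supported by configuration but slow
on a desktop. The shipped analyses and tests run a scaled study chosen as
the package's default desk scale: 16-region connectomes, 5-minute
recordings, a 120-minute adaptation cap, 5-lesion x 3-seed direction
sweeps, a 3x3 (C, rho) recovery grid with 3-minute recordings, and 20–50
random graphs per small-world estimate. Directions and invariances are
stable at this scale; absolute metric values (e.g. FC distances, Q) scale
with network size and recording length.

## Known limitations

- Euler's first-order bias shifts the limit-cycle frequency by ~8% at
  dt = 0.2 ms (41.6 Hz at the reference step vs ~44.6 Hz extrapolated);
  convergence is first-order, and the reference step keeps the rhythm
  inside the gamma band.
- The plain time-mean firing rate sits below the homeostatic target in
  the oscillatory regime (see above); analyses that need "the controlled
  rate" should use the inhibition-weighted mean.
- Modularity/small-world values at 16 nodes are noisy at the lowest
  densities; the direction tests therefore aggregate across the density
  grid and across lesions.
- Lesion severity does not scale down with the network: one node of 16 is
  proportionally several times more cortex than one region of 78, and a
  16-node hub can carry ~12% of total strength. The acute modularity dip
  reproduces robustly at this scale, but chronic modularity recovery only
  holds for weak-to-moderate lesions; for the strongest hubs, functional
  reorganization outweighs restoration and Q keeps falling from T1 to T2,
  so the "recovery in the majority of lesions" direction sits at chance
  in the 5-lesion sweeps that deliberately include the top hubs.
- Single-node lesions only; no white-matter (edge) lesions, subcortical
  structures, conduction-velocity heterogeneity, or plasticity beyond
  inhibitory synaptic scaling.
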
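# Methods

This note documents the models, conventions and numerical choices behind
famscape, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where genuinely open design points were
decided.

## Burst characterization

Traces are uniformly sampled voltage pairs.  A **spike** is one contiguous
excursion strictly above −20 mV; its time is the excursion's sampled
maximum and its amplitude the peak voltage.  A **burst** is a maximal run
of at least three spikes whose inter-spike gaps are below 1 s; a gap of
exactly 1 s terminates the burst (the boundary had to be fixed one way;
strict `<` keeps a run together).  Bursts whose first or last spike lies
within one minimum gap of the recording edge may be truncated and are
excluded from all statistics.

The **middle spike** of an n-spike burst is the lower median, 0-based
index `(n − 1) // 2`; for even n no convention is canonical, and the lower
median keeps the choice deterministic and symmetric across cells.  The
**period** is the interval between middle spikes of consecutive bursts
(per-cycle list; summaries use the mean).  **Phase** is computed per B
burst as (B middle − preceding A middle)/(next A middle − preceding A
middle) and averaged; 0.5 is perfect alternation.  **Duty cycle** is
100 × mean burst duration / mean period.  A cell's **spike frequency** is
mean spikes-per-burst divided by mean burst duration.  A literal reading
of the alternative formulation "mean of the per-burst spike frequencies
divided by the mean burst duration" is dimensionally inconsistent (Hz/s);
both variants are computed (`spike_freq_hz`, normative, and
`spike_freq_alt_hz`, the mean of per-burst frequencies) so either
convention can be compared.  Coefficients of variation use the sample
standard deviation (ddof = 1).

## Activity classification

An instance is an **HCO** when both cells show at least two complete
bursts whose middle spikes fall within the final 40 s of the recording
(a stationarity-biased placement of the unspecified 40 s window), every
burst has within-burst amplitude CV < 0.07, the period CV is < 0.05, the
phase lies in [0.45, 0.55], and at least one synaptic conductance is
nonzero.  **rHCO** additionally requires period ∈ [5, 15] s, spike
frequency ∈ [8, 25] Hz and duty cycle ∈ [50, 70] %; all range checks are
closed intervals (a period of exactly 5 s is realistic).  HCOs that are
not realistic are **fHCO**.  Synapse-free twins with the same regularity
are **bursters**, **realistic** when period and frequency are in range
(duty is not part of the isolated criterion).  **Plateau** is
operationalized as ≥ 1 s continuously above −20 mV containing fewer than
three spikes; **asymmetric** covers cells with differing per-cell labels
or alternation that fails the phase/CV criteria; the taxonomy for non-HCO
instances is a reconstruction, since no operational definition is
published for the companion database.  Relabelling the cells reflects the
phase to 1 − phase; the criterion interval is symmetric about 0.5, so HCO
status is invariant under the swap.

Failure of the three physiological criteria is encoded as a 3-character
mask (`P`, `F`, `D` positions; `---` = all met) and as one of the seven
nonempty failure subsets used in the missing-member tabulations.

## Families and robustness measures

A family is built from one label-homogeneous group by grouping instances
on the context key (all varied parameters except the defining one).
Singletons are families; one-member families count as noninterrupted
(the census table leaves their entry blank; the convention only matters
for Y at n = 0 and is stated here).  Members, interior missing levels and
out-of-range levels partition the defining parameter's grid levels.

Measures at threshold n: X sums family counts over sizes > n, Y the
noninterrupted counts, Z counts missing members with functional (fHCO)
bursting.  The published value of Z for the h conductance cannot be
reconciled with the published per-size missing-member table under any
single scope, so Z's scope is configurable: `inside` (default) counts
interruptions only; `all_missing` also counts members outside the
permissible range.  The score R = wX·X + wY·Y + wZ·Z requires nonnegative
weights summing to 1 (tolerance 1e−9); normalization divides by a
positive user-chosen denominator and reports three decimals.

Packaged census tables (family sizes per parameter, missing-member
failure categories for h, period-sensitivity classes for h) ship as TSV
with SHA-256 checksums; every row satisfies the partition identity
Σ size × count = group size (99,066 for the realistic-HCO group).

## Sensitivity classification

Family curves put the defining parameter on the x axis in
canonical-fraction units (0.00–1.75) and the characteristic (period in s
or frequency in Hz) on y.  Monotonicity is a sign test on consecutive
differences with ties compatible with either direction; an entirely flat
curve reports "increasing" by convention.  Classification fits a
polynomial of degree min(5, points − 1) — degree 5 is the published
choice for 8-point curves; shorter curves reduce the degree to keep the
fit determined — and minimizes its derivative over the member span on a
1,000-point grid plus the derivative's analytic critical points
(deterministic).  Thresholds: slope ≤ −2.5 → high (descent angle ≳ 68°),
≥ −0.4 → low (≲ 22°), else medium, with a 1e−9 tie-break so curves lying
exactly on a threshold are not misfiled by fit round-off.  The
fraction-unit x axis is what makes the slope thresholds correspond to the
stated angles; percent units would scale slopes by 100.

## Synthetic data

`synthesize_trace_pair` builds noise-free (or Gaussian-noise) alternating
trace pairs from ground-truth period, duty, spike frequency and phase:
stereotyped 6 ms triangular spikes ride on a −45 mV burst plateau over a
−60 mV interburst baseline, `round(freq × burst duration)` spikes span
each burst, apexes snapped to the sampling grid (default dt = 1 ms) so
detection recovers the generating values to within discretization.  This
validates the metrics pipeline by parameter recovery; it does not emulate
conductance dynamics, spike-shape variability, or burst irregularity, so
recovery tests certify the measurement chain, not the simulator.

`grid_response` maps grid points to labels and characteristics through an
ordered rule set with linear period/frequency/duty responses around the
canonical point.  The coefficient signs encode the qualitative parameter
dependencies of the conductance model — period falls with more h, K2 or
leak and rises with more CaS, P or SynS; frequency rises with h, CaS and
P and falls with K2, leak and SynS; graded transmission has negligible
effect — while the magnitudes are original to this package, chosen so the
default grid produces every activity label and the canonical point is a
realistic HCO with period 10 s, 15 Hz, duty 60 %.  Absolute census counts
of the full database are out of reach of any such phenomenological
response and are not attempted.  The response is deterministic, so the
family structure of a synthetic database is analytically known; the seed
argument exists for jittered variants and reproducibility discipline.

## The simulator and its surrogate model

The engine integrates two identical single-compartment cells coupled by
graded and spike-mediated inhibition.  Kinetics are entirely
config-driven (YAML): currents are `g·Πxᵢ^pᵢ·(V − E)` with sigmoid
steady states and constant or cosh-bell time constants; the graded
synapse relaxes toward a sigmoid of presynaptic voltage; the
spike-mediated synapse is a rise/decay conductance gated by the
presynaptic spike threshold, equivalent to a stereotyped per-spike
kernel while remaining well-posed inside a variable-step solver.  Both
cells always share parameter values; the initial state is produced by
integrating the canonical-parameter model from documented default states
(cell A depolarized, cell B hyperpolarized) and is cached and reused for
all grid points.

The packaged surrogate config is a minimal bursting cell: fast Na (with
an explicit inactivation gate mirroring the delayed-rectifier
complement), delayed-rectifier K, a slowly inactivating persistent Na as
the P-like burst driver, plus h-like, CaS-like and slow-K2-like currents
and the two synapse kinds, with hyperpolarizing synaptic reversal
(−80 mV) so the inhibited cell escapes via h-current activation.  At the
canonical point the pair produces alternating bursting with a period
near 3 s in antiphase.  Units: mV, nS, pF, ms.

Numerics: LSODA (stiff-capable, variable step) with rtol 1e−6 /
atol 1e−8 by default; `dt` is the dense-output recording grid (1 ms), not
the solver step.  On the surrogate, tightening tolerances a hundredfold
moves early spike times by well under 5 ms over a 2 s window; the
leak-only configuration matches the closed-form RC relaxation to better
than 1e−3 of the excursion.  Non-finite states abort with a diagnostic.
The true published HCO kinetics live in an external model repository and
are deliberately not transcribed; porting them is a config-file exercise,
not a code change.

## Problem sizes

The test suite and examples run on a 3-level grid (3 fraction levels per
conductance × 2 E_leak levels = 4,374 points) for end-to-end pipelines,
≤ 500-instance samples for the quadratic family-construction oracle, 100
random trace pairs for metric recovery, and seconds-long surrogate
simulations; the full 10.5-million-point grid is enumerated analytically
(counted, not instantiated).  These sizes are the package's own
desk-scale defaults.

## Known limitations

- The synthetic response is linear with hard rule boundaries; it cannot
  reproduce interrupted-family geometry driven by nonlinear dynamics, so
  interruption-heavy statistics (e.g. Z) are only exercised on small
  constructed cases and census tables.
- The surrogate model is one convenient bursting regime, not a calibrated
  replica; activity maps over its grid differ from the published
  database's.
- Phase conventions for even-spike-count bursts and the 40 s window
  placement are fixed choices among defensible alternatives; both are
  documented above and isolated in one module each.
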
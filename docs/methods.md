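# Methods

## The biological system and the modelling question

Curli amyloid fibers are the main proteinaceous component of the *E. coli*
biofilm matrix. Isogenic cells under identical conditions split into
curli-on and curli-off subpopulations, and the regulatory layer suspected
of producing this heterogeneity is post-translational: two diguanylate
cyclase / phosphodiesterase (DGC/PDE) pairs — YegE/YhjH (module I) and
YdaM/YciR (module II) — set the level of the second messenger c-di-GMP,
which gates the YdaM → MlrA → *csgD* cascade that switches curli synthesis
on. YciR is a trigger enzyme: with c-di-GMP bound it acts as a PDE
(state I); without it, it inhibits YdaM and MlrA (state II). The package
asks, in three stages of increasing resolution, whether this wiring can
produce bistability consistent with the reporter activities measured in all
sixteen knockout combinations of *yegE*, *yhjH*, *ydaM* and *yciR*, and
what switching dynamics the resulting parameterisations imply.

## Logical stage

Components are Boolean except YciR, which is ternary (absent / state I /
state II). YdaM is active unless YciR is present in state II; YciR, when
present, is in state I exactly when c-di-GMP is on. The inputs YegE and
YhjH hold their initial value (on unless knocked out). The rules for
c-di-GMP (regulators YegE+, YhjH−, YdaM+, YciR-in-state-I−) and MlrA
(YdaM+, YciR-in-state-II−) are enumerated as all non-constant Boolean
functions that are monotone with respect to the regulator signs and in
which every regulator is essential. Enumeration is by the recursive
cofactor pairing of monotone functions, independently cross-checked in the
tests by filtering all 2^16 truth tables. This yields 114 functions for
c-di-GMP and 2 for MlrA, hence 228 candidate models. The counts equal the
inclusion–exclusion counts of essential monotone functions obtained from
the Dedekind numbers (M(4) = 168 = 2 + 4·1 + 6·2 + 4·9 + 114), which is
what pins down this particular admissibility rule.

Dynamics are asynchronous: one component updates per transition. A
knockout clamps a component off (YciR becomes absent, silencing both of
its effect channels). Stable states are fixed points of the update; they
are update-scheme invariant, which the tests exploit as an oracle.

Phenotype predicates per genetic background:

* **intermediate** — some state can reach both a stable state with MlrA on
  and the curli-off stable state (a genuinely nondeterministic commitment);
* **hyperactivated** — a stable state with MlrA on exists (a residual
  curli-off subpopulation is not excluded);
* **hyperrepressed** and (in the less conservative mode) **basal** — the
  curli-off core state (c-di-GMP off, YdaM off, YciR in state II where
  present, MlrA off) is a stable state and no stable state has MlrA on.

The off state is pinned to the core configuration because the basal and
hyperrepressed classes agree on the core circuit and differ only in
YdaM-independent residual MlrA activity. The sixteen backgrounds carry the
classes: wild type and ΔyegE ΔyhjH intermediate; the five backgrounds with
*yciR* deleted and *ydaM* intact, plus ΔyhjH, hyperactivated; ΔydaM,
ΔydaM ΔyegE and ΔydaM ΔyegE ΔyhjH hyperrepressed; the remaining six
(ΔyegE, ΔydaM ΔyhjH, and the four ΔydaM ΔyciR combinations) basal. Placing
ΔydaM ΔyhjH in the basal class is a deliberate reading of the measured
activities ("absent **or very low** expression" for *ydaM* knockouts): it
is the unique assignment under which the conservative analysis comprises
15 properties (2 intermediate backgrounds × 2 + 5 hyperactivated × 1 + 3
hyperrepressed × 2) out of 32 (2 per background), and under which the
conservative filter leaves 10 of the 228 models — 5 distinct c-di-GMP
mechanisms, each with both MlrA rules — while the full 32-constraint
analysis leaves exactly 1. All 10 feasible models share the same pair of
wild-type stable states, (1,1,I,1) and (0,0,II,0), a 16-state transition
graph and a 12-state strongly connected component, and all have
f_cdigmp = 1 in the all-regulators-active context, which grounds the
kinetic inequality k_YciRact ≤ k_YdaMact used downstream.

## Kinetic stage

The validated core (c-di-GMP x1, YciR-state-II x2, active YdaM x3; MlrA is
output-only and dropped; total YciR and YdaM conserved) evolves under eight
rates: product-inhibited synthesis by YegE (V1, inhibition constant
Ki_YegE), Michaelis–Menten degradation by YhjH (V2) and by YciR state I
(V3), cooperative synthesis by active YdaM (V4, Hill coefficient n = 4,
reflecting tetramerisation), the c-di-GMP-driven II→I and spontaneous I→II
transitions of YciR (V5, V6), and the inactivation/recovery pair of YdaM
(V7, V8). c6 = c8 = 10 s⁻¹ are fixed (structurally non-identifiable
against k_YciRde and k_YdaMde; only the ratios Kd_YciRact = c6/k_YciRde
and Kd_YdaMact = c8/k_YdaMde matter at steady state). The system volume is
1 µm³, so molecule counts and concentrations coincide; all computations
are in counts. k_YciRde and k_YdaMde are treated as first-order rate
scales (s⁻¹) — they multiply molecule counts inside V5/V7 — and likewise
k_YciRact multiplies the YciR-state-I count in V3 and is intensive under
volume scaling.

Setting dx2/dt = dx3/dt = 0 gives monotone steady-state curves
x2ss(x1) (decreasing) and x3ss(x2) (decreasing), so fixed points of the
full system are roots of a one-dimensional residual in x1. Roots are
bracketed by sign changes on a grid of 2000 log-spaced points on
[0, x1_max] and refined by Brent's method (x tolerance 1e-10); each root
is lifted to 3-D and classified by the eigenvalues of the analytic 3×3
Jacobian (stable iff all real parts negative; complex eigenvalues are
recorded). x1_max is derived from the YhjH branch alone: at any fixed
point V2 ≤ V1 + V4 ≤ Vmax1 + k_YdaMact, so when Vmax2 exceeds this
production cap the root is bounded by the x1 at which V2 reaches it
(taken with a 10× margin); otherwise the scan falls back to a hard
ceiling of 1e6 molecules. A bound built instead from V2 + V3's combined
capacity fails when YciR sits mostly in state II (the V3 term is then
fictitious), which is why the V2-only bound is used.

Bifurcation scans sweep Vmax1, Vmax2 or the complex parameter
c6/k_YciRde (varying k_YciRde at fixed c6), count stable fixed points per
grid value, and refine each boundary by bisection on the count to a
relative tolerance of 1e-4. On accepted parameter sets both the Vmax1 and
the c6/k_YciRde scans produce a single closed bistable interval bounded by
two saddle-node points, with monostable-low behaviour on one side and
monostable-high on the other — the qualitative pattern that maps onto the
basal (*yegE* knockout), heterogeneous (wild-type) and hyperactivated
(*yhjH* knockout) phenotypes.

## Parameter sampling

Stage one draws the fourteen rate parameters i.i.d. uniformly from
literature-informed bounds (Km/Kd-type constants 100–3000 molecules,
capacities and rate scales 0–2000), ties YciRtot = YdaMtot (protein assays
indicate equal totals), rejects proposals with k_YciRact > k_YdaMact (the
logical-stage constraint), and accepts a proposal iff the wild type and
the ΔyegE ΔyhjH double knockout have exactly two stable states, ΔyegE has
exactly one, and ΔyhjH has one or two (knockouts of *ydaM*/*yciR* are not
representable — those proteins are state variables). Km_YciR is sampled to
3000 and trimmed to ≤ 1000 post hoc, exactly as described for the original
protocol. A vectorised sign-change screen on the same grid as the exact
finder (wild type and double knockout must bracket at least three roots)
prunes proposals before any eigenvalue computation; the exact acceptance
test is always the final authority.

Measured at 2×10⁷ blind uniform proposals, the stage-one acceptance rate
is ≈ 1.9×10⁻⁶. Stage two therefore matters: Gaussian proposals (diagonal
covariance, σ = 0.25·mean, negative draws rejected, identical constraints)
centred on accepted sets are accepted at a rate of a few percent, so the
bulk of any realistically sized ensemble is stage-two. The 40 accepted
stage-one sets from that campaign are packaged as anchors (in discovery
order, no post-selection) and are re-verified wherever they are used; the
pipeline falls back to them as stage-two seeds when a short stage-one run
finds nothing.

A quasi-steady-state validity surrogate (total enzyme ≤ threshold ×
(half-saturation constant + substrate) at every stable wild-type state) is
available with a configurable threshold. At the textbook-strict threshold
of 0.1 it rejects every accepted set — totals of hundreds to thousands of
molecules against bounds of ~100–300 — so the pipeline records the flag
per set instead of enforcing it by default.

## Stochastic stage

The chemical master equation keeps the eight channels with propensities
equal to the deterministic rate laws at integer counts; conservation makes
out-of-range propensities vanish identically. Trajectories use Gillespie's
direct method (a numba-compiled loop with incremental propensity updates;
no tau-leaping anywhere in the quantitative path). A switch from stable
state ss1 to ss2 is detected at the first time the L1 distance to ss2
drops below ε · Σᵢ|ss1ᵢ − ss2ᵢ| with ε = 0.1; the L1 reading (with
absolute values on both sides) is the only one that defines a
neighbourhood. Runs start at the rounded deterministic stable states, stop
at the first switch or at T = 100 s; switching probability is the switched
fraction and the mean switching time is over switchers only. Stationary
modes are estimated from end states assigned to the nearest stable state
(L1), with equilibration verified by the total-variation distance between
the assignments at T and 2T.

Classification splits the (P_off→on, P_on→off) unit square at 0.5
(boundary counts as high); extreme groups use 0.9/0.1. Group comparisons
use two-sided Wilcoxon rank-sum tests at p ≤ 0.001 with no multiplicity
correction by default (a Bonferroni option exists). Steady-state
separation is the per-component absolute difference between the two stable
states. Across the packaged anchors, separation strongly anti-correlates
with switching: wide wells switch rarely.

## What the synthetic data do and do not show

The observation-table generator plants the sixteen phenotype classes with
lognormal replicate noise around class means 1 : 20 : 300 : 900 (arbitrary
units; only the ordering matters) — it emulates the measurement design,
not growth biology, and recovery tests validate the classifier, not the
assay. The ground-truth panels guarantee only the stability labels they
are verified for. The telegraph trajectories are a closed-form oracle for
the switching-probability estimator, not a model of the circuit. Passing
these tests shows the estimators recover planted structure at the stated
noise; it says nothing about unmodelled features of real data
(transcriptional noise, growth-phase effects, reporter saturation).

## Problem sizes and numerical defaults

Tests run the enumeration exactly (2^16-table oracle), the full
228-model × 16-background model checking (memoised on the visible
truth-table slice per background, which collapses the 3648 graph analyses
to at most a few hundred distinct ones), uniform sampling at 10^5
proposals, and the switching survey at 100 parameter sets × 25 runs per
direction × T = 100 s; the published analysis used 2×10⁶ proposals and
10³ runs per set, and the sampler and estimator scale to those sizes
unchanged. Residual tolerance at fixed points is 1e-8·max(1, Vmax1 +
k_YdaMact); Ki_YegE must exceed 1e-9 (V1 is 0/0 at zero); eigenvalue
classification treats imaginary parts below 1e-12 as real. Ties in the
model ordering are broken by the (c-di-GMP, MlrA) truth-table bit strings,
serialised all-active context first, which makes the unique all-constraint
model the first row of the feasible table.

## Known limitations

* The published per-row constraint bookkeeping (Table S1/S2 of the
  original supplement) is reconstructed from the main text; the
  condition-level checks reproduce all published counts, but individual
  row attributions may differ.
* The uniform-stage acceptance rate is ~1.9×10⁻⁶, far below the published
  608/2×10⁶ ≈ 3×10⁻⁴; the published figure is only consistent with the
  two-stage combined yield, and the split between stages is not recoverable
  from the text.
* The reproduced ensembles (anchors plus Gaussian refinement) do not show
  the published dominance of fast-on/slow-off switching; the four regions
  come out nearly balanced. The published ensemble evidently reflects
  additional filtering (the original supplement's validity criterion) or
  an allocation of stage-two proposals that the text does not specify.
* Knockouts of *ydaM* and *yciR* have no kinetic counterpart by
  construction, so only four genetic conditions constrain the ODE.
* The estimators are exact-SSA based; deep-well parameter sets with
  switching times far beyond T are reported as censored (probability ~0),
  not extrapolated.
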
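# Methods

## The cell model

Each cell is a Hodgkin–Huxley-style pituitary lactotroph with four state
variables — membrane potential `V` (mV), delayed-rectifier K⁺ activation
`n`, free cytosolic Ca²⁺ `c` (µM), and BK-channel activation `b` — and
five membrane currents:

    C_m dV/dt = −(I_Kdr + I_Ca + I_BK + I_SK + I_L + I_c)
    τ_n dn/dt = n∞(V) − n
    dc/dt     = −f_c (α I_Ca + k_c c)
    τ_b db/dt = b∞(V) − b

with `I_Kdr = g_Kdr n (V − V_K)`, `I_Ca = g_Ca m∞(V) (V − V_Ca)`
(instantaneous activation), `I_BK = g_BK b (V − V_K)`,
`I_SK = g_SK d∞(c) (V − V_K)` where `d∞(c) = c²/(c² + k_SK²)`, and an
ohmic leak. Gating equilibria are Boltzmann sigmoids
`x∞(V) = 1/(1 + exp((ν_x − V)/l_x))`. Default parameters (`CellParams`)
describe an intrinsic pseudo-plateau **burster**; setting `g_BK = 0`
yields an intrinsic tonic **spiker**. That single conductance is the
only heterogeneity in the study: fast BK feedback is what lets the cell
linger on a depolarized plateau carrying small spikes.

Two dimensional conventions deserve note. The Ca²⁺ removal rate `k_c`
is treated as 0.12 ms⁻¹ — the product `k_c·c` must be a rate for the
`c` equation to be dimensionally consistent. The secretion readout is

    s(c) = 1 / (1 + exp(−5 ((c − 0.27)/0.082 − 0.6)))

a steep sigmoid with midpoint c\* ≈ 0.319 µM chosen to sit between the
Ca²⁺ levels of tonic spiking and bursting, standing in for the
cooperative Ca²⁺ dependence of exocytosis. Among the possible
groupings of this expression, this one is adopted because it places the
midpoint inside the physiological `c` range, so `s` rises substantially
during each burst and stays low between events; alternative groupings
put the midpoint below the entire operating range (both cell classes
saturated) or at several µM (readout permanently off).

## Networks and coupling

Structural networks are grown by a random walk: start with two
connected nodes; repeatedly pick a uniform random existing node and,
with probability `p`, attach a brand-new node to it, otherwise draw an
edge from it to another uniform random existing node (duplicate edges
are redrawn up to a bounded retry count, which biases the edge count
slightly low — measured ≈ 11.7 edges for `n = 10, p = 0.7` against the
rejection-free expectation 1 + (n−2)/p ≈ 12.4). `p` defaults to 0.7,
which produces 10–20-cell networks of realistic sparseness with
occasional hubs; it is exposed in `GenConfig`. Networks are validated
connected, simple, and fully labelled.

Gap junctions are ohmic: the current into cell *i* is
`I_c = Σ_j g_c (V_i − V_j)` over its neighbors, so pairwise exchanges
cancel exactly (charge conservation is asserted in the tests). The
burster placement strategies are: uniform `random` sets (the null model
of the sweeps); `defensive` — greedy growth of a connected burster
cluster, restarted from every node and keeping the best, which attains
the brute-force optimum of burster homophily Γ_b on small graphs; and
`offensive` — greedy dispersal preferring high-degree nodes not
adjacent to any burster, driving Γ_b toward 0.

## Integration

The coupled system is advanced with classic fixed-step 4th-order
Runge–Kutta at `dt = 0.5 ms` (halving `dt` leaves every event
classification in the reference experiments unchanged, and the stepper
shows clean 4th-order convergence on a closed-form problem). The kernel
integrates a *batch* of placements in lock-step — all placements of a
sweep share the structural graph and differ only in the per-cell BK
conductance — in a numba-jitted loop, with a vectorized pure-numpy
fallback selected automatically; the two backends agree to ≈1e-9 and
the kernel reproduces an independently composed right-hand side
(public `cell_rhs` + explicit pairwise coupling sums fed to the generic
`integrate`) to the same precision.

Initial conditions are not part of the model definition; the default is
a common near-rest state (V = −60 mV, n = 0.1, c = 0.1 µM, b = 0.1)
with small seeded per-cell jitter (±1 mV on V, ±5% on c) so that
identical cells do not start artificially synchronized. Both the base
state and the jitter are overridable, and placement sweeps draw a fresh
jitter seed per placement. Default protocol: 20 s of model time with
the first 10 s discarded as transient and the next 10 s analyzed
(60 s / 20 s for the two-cell reference experiments).

## Events, conversion, synchrony

Events are detected on the voltage trace with a hysteresis detector
(`V_on = −35 mV`, `V_off = −45 mV`, between the ≈ −60 mV silent phase
and the ≈ −20 mV plateau) and peaks counted with prominence ≥ 2 mV, all
configurable. Taxonomy: single-peak `spike`; `k-spike burst` for k ≥ 2
peaks inside one supra-threshold envelope; `doublet` for two single-peak
events separated by < 40 ms of sub-threshold voltage (kept distinct
from a 2-spike burst, where the voltage never re-crosses `V_off`);
`long burst` for bursts > 1.5× the train's median burst duration. A
cell is *converted to bursting* when ≥ 50% of its events are bursts
(doublets do not count). These thresholds are operational definitions,
not measured quantities.

The synchrony index is the mean pairwise Pearson correlation, computed
by default on the slow Ca²⁺ traces rather than raw voltage. Entrained
cells of different intrinsic class lock with a ~20 ms spike lag that
depresses zero-lag voltage correlation (≈ 0.78 for the strongly coupled
pair) even when the cells are strictly 1:1 phase-locked; the Ca²⁺
traces integrate over that lag (0.95 strong coupling vs 0.04 weak) and
correspond to what Ca²⁺-imaging studies of pituitary networks actually
correlate. Voltage-based correlation remains available via
`signal="v"`. "Synchronized" means index ≥ 0.9.

## Fast/slow analysis

The spiker (`g_BK = 0`) is reduced to 1 fast (V) / 2 slow (n, c)
variables. Writing the fast equation as `dV/dt = F(V, n, c)`, `F` is
linear in `n`, so the critical manifold is globally the graph
`n = h(V, c)` and `(V, c)` is a global chart. Substituting `h` into
`∂F/∂V` cancels every `c`-dependent term (SK and Kdr share the K⁺
reversal), so the fold curve consists of lines of constant `V` — the
fold voltages are found by 1-D root bracketing, folded singularities by
a scan along each fold line followed by a polished 2-D root solve of
{∂F/∂V = 0, G₁ = 0}, where

    G₁ = F_n ṅ + F_c ċ,    G₂ = −F_V ċ

is the desingularized slow flow (the reduced flow rescaled by −∂F/∂V so
it is regular across the fold). All algebra — `h`, the desingularized
field, and its Jacobian — is derived symbolically with sympy and
lambdified once per model; the Jacobian is cross-checked against
central finite differences in the tests. Residual tolerance at a
reported folded singularity is 1e-8 (achieved ≲ 1e-12); the search box
is V ∈ [−75, 60] mV, c ∈ [0, 2] µM.

For the table-parameter spiker the folded node sits at
(V, c, n) ≈ (−13.53 mV, 0.283 µM, 0.320) with eigenvalues
−0.0210 / −0.00098, ratio µ ≈ 0.0465. A constant gap-junction input
`g_c (V − V_fix)` from a depolarized partner right-shifts the node (and
the canards with it) to higher `c` — the geometric mechanism of
spiker-to-burster conversion — while leaving µ essentially unchanged
over g_c ∈ [0, 0.05].

The secondary-canard count uses the standard singular-limit sector
bound k with 2k+1 < 1/µ < 2k+3, giving k = 10 here. This is an upper
bound valid in the limit of infinite time-scale separation; at the
model's actual (finite, moderate) separation far fewer canards are
resolvable, and simulated pulse-driven trajectories show bursts of 2–4
spikes, i.e. 1–3 small oscillations. Computing which canards survive at
finite separation requires boundary-value continuation of the slow
manifolds, which is outside this package's scope; the trajectory-side
diagnostic (driven-spiker peak counts never exceed k+1) is the check
provided instead.

## Placement sweeps

`sweep_placements` samples distinct burster sets of size
`round(fraction·n)` uniformly without replacement, simulates all
placements of a chunk in one batched kernel call, and reports per
placement the homophily means Γ_b/Γ_s, the network-and-time-averaged
secretion ⟨s⟩ (accumulated at every post-transient step, not from
stored samples), and optionally per-cell conversion flags from the
classified event trains. Sweeps are bit-reproducible given their seed.
Default scales are 300 placements at 50% bursters and 200 at 25% —
deliberately reduced from exhaustive sweeps so a full strategy
experiment runs in about a minute on one core; the scale is a plain
argument.

The Γ_b landscape is summarized by 10 equal-width bins on [0, 1]
(right-open except the last; empty bins are flagged, never zero-filled)
and by Spearman rank correlation. For the γ_s-spread analysis,
placements are grouped by (Γ_b, Γ_s) rounded to multiples of 0.1 (the
tolerance was chosen so matched groups contain ≥ 10 networks at the
default sweep scale), the most populous group is split at its median
⟨s⟩, and the per-spiker γ_s values of each half are pooled.

## What the generator emulates — and what passing tests do not show

The synthetic networks emulate small, irregular, gap-junction-coupled
pituitary cell clusters with a binary burster/spiker dichotomy. Real
lactotroph populations are heterogeneous along many axes (graded BK
expression, cell size, coupling strength per junction, silent cells),
are spatially embedded, and experience channel noise and neurohormonal
modulation; none of that is modelled. Passing tests therefore
demonstrate properties of this idealized model, not of pituitary
tissue.

## Known limitations

- **Weak placement signal at network scale.** In this implementation,
  at `g_c = 0.05 nS` conversion propagates to essentially every spiker
  for the large majority of random placements on 20-cell random-walk
  networks, compressing the ⟨s⟩ range (≈ 0.26–0.33) and leaving the
  rank correlation between Γ_b and ⟨s⟩ small and topology-dependent
  (measured between −0.16 and +0.19 across structural seeds at 50%
  bursters). Greedy extreme placements show a shallow U-shape in Γ_b
  with the clustered end usually on top at both burster fractions. The
  direction and strength of the clustered-vs-dispersed secretion
  trade-off should therefore be treated as sensitive to the exact
  topology, initial conditions, and analysis window, and conclusions
  about optimal placement strategies drawn from this package require
  sweeping those conditions explicitly.
- Consequently the γ_s-spread contrast between low- and high-secreting
  matched subpopulations is also weak here, and in the default
  configuration its direction is the opposite of what a
  conversion-dominated regime would produce.
- The canard count reported by `FoldedNode.canard_count` is the
  singular-limit bound, not the finite-separation count (see above).
- Multistability is real: some placements admit distinct attractors
  (observed as a bimodal ⟨s⟩ across initial-condition seeds), so
  single-run sweep values carry attractor-selection noise of up to a
  few 0.01 in ⟨s⟩.
- The hysteresis event detector assumes the model's two-band voltage
  geometry; traces from other parameter regimes may need retuned
  thresholds.
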
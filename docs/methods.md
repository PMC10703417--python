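# Methods

This note documents the models, estimators and numerical choices behind
`infodyn`, and what the synthetic study conditions do and do not show
about recorded data.

## Measures

All information quantities are reported in bits (base-2 logarithms).

**Local mutual information.** For a pair of realizations (x, y) of
discrete random variables,

    i(x : y) = log2 [ p(x, y) / (p(x) p(y)) ] = log2 [ p(x | y) / p(x) ].

The average mutual information I(X:Y) is the probability-weighted average
of these per-realization terms; individual terms may be negative, meaning
that one realization *mis*informed about the other (conditioning lowered
the probability of what actually happened).  The local conditional mutual
information i(x : y | z) = log2 [ p(x | y, z) / p(x | z) ] behaves
analogously.

**Local active information storage (lAIS).** The local MI between a
process's present sample x_t and its embedded past state x^S,
quantifying moment-to-moment predictability of a signal from its own
history.  Negative lAIS marks samples the past necessarily mispredicted.

**Local transfer entropy (lTE).** The local conditional MI between the
target's present sample y_t and the source past state x^S, given the
target past y^S: the information transferred from input to output at time
t, over and above what the output's own history already provided.
Negative lTE marks moments when the source past misinformed about the
target's actual next state.

**Predictable information (pAIS).** When further recorded sources are
available, predictability generalizes to the local MI between s_t and the
joint past (s^-, n_1^-, ..., n_k^-); with no extra sources it reduces to
lAIS, and adding sources can only increase the average (refinement
monotonicity of MI).

**Local storage-transfer correlation (LSTC).** The Pearson correlation
between lAIS of the unit's *input* and lTE across the unit, aligned by
the reconstructed transfer delay u (the lTE value at t is paired with the
input's lAIS at t - u).  A unit that preferentially relays predictable
input shows positive LSTC; a unit that codes prediction errors shows
negative LSTC.  Pearson rather than rank correlation is used because only
the *sign* of a monotone association is at issue; a Spearman coefficient
is attached as a secondary diagnostic.  The permutation test (default
1000 circular-shift permutations of the storage series, two-sided)
preserves each series' autocorrelation under the null.

**PID of transfer entropy.** With T = y_t, S1 = x^S and S2 = y^S, the
bivariate partial information decomposition splits I(T : S1, S2) into
unique, shared and synergistic atoms.  We use the unique-information
definition of Bertschinger, Rauh, Olbrich, Jost and Ay: the unique
information of S1 is min over Q of I_Q(T : S1 | S2), where Q ranges over
all joints preserving the observed (T,S1) and (T,S2) pairwise marginals.
The remaining atoms follow from the consistency equations.  Interpreted
on transfer: unique(S1) is *state-independent* transfer (bottom-up
relaying of input evidence) and synergy is *state-dependent* transfer -
the signature of an XOR-like generalized prediction-error computation, in
which the output is only determined when input evidence and the unit's
own state are combined.  TE = unique(S1) + synergy holds identically.
This decomposition is average-only; localized PID is out of scope.

## Estimation

**Plug-in estimators.** Probabilities are relative frequencies of symbol
configurations over the valid sample range.  Series are binned at 1 ms by
default; bins with two or more spikes are clipped to 1 (a warning counts
them), keeping a binary alphabet - justified by neural refractoriness at
this resolution.  The first max(lags) samples are masked invalid rather
than wrapped, so every probability is estimated from genuinely observed
configurations.  Locals are only evaluated at observed configurations
(their probabilities are strictly positive there); averages use the
0 log 0 = 0 convention.  By construction the mean of a local series over
valid samples equals the plug-in average exactly.

**Bias correction.** Plug-in averages are biased upward for finite data.
The analytic Panzeri-Treves correction ((R - 1) / (2 N ln 2) per
constituent entropy term, R = number of occupied cells) is applied to the
*averaged* estimates, which are stored alongside the uncorrected locals.
The locals themselves are reported uncorrected: the package's inferential
statistics (the LSTC sign and all surrogate tests) are invariant under a
constant shift of the mean, and a per-sample localized correction would
require distributional assumptions the data do not constrain.

**Surrogate testing.** Null distributions come from circular shifts,
which preserve each series' autocorrelation while destroying the
cross-dependence under test; shifts are drawn uniformly with a minimum of
the maximum embedding lag.  One-sided p-values use the permutation
convention p = (1 + #{null >= observed}) / (n_perm + 1), so p is never
zero and the test is exact at the achievable levels.  Inside estimator-
level tests the embedded past-state column is rolled against the aligned
target over the valid window - equivalent to shifting the raw series up
to window-edge effects, and much cheaper; the generic `surrogate_test`
entry point shifts the raw series.

**Nonuniform embedding.** Past states are selected by greedy forward
selection over candidate lags (storage and target: 1..30 ms; source:
1..40 ms, measured back from y_t, which subsumes transfer delays up to
10 ms).  At each step the candidate with the largest conditional MI gain
given the already-selected variables is accepted only if surrogate-
significant; accepted candidates leave the pool; the first rejection
terminates selection (no look-ahead).  The target's own embedding is
optimized before the source's, so only genuinely transferred information
is attributed to the source.  Within a step, the repeated testing over
the pool is controlled with a maximum-statistic correction: the observed
best gain is compared against the null distribution of the *maximum*
gain over the remaining pool, with one shared shift per permutation so
the dependence between candidate gains is preserved under the null.
Exact ties in the argmax break toward the smallest lag (the most recent,
physiologically most plausible dependency; reproducible).

*Embedding-size cap.* Selection additionally stops after `max_vars = 6`
accepted variables per embedding.  Each accepted binary variable doubles
the conditioning state space; for recording lengths of order 1e5 bins,
past ~2^6 conditioning cells the plug-in gain estimates of both observed
and surrogate candidates are dominated by finite-sample bias rather than
structure, so further "selections" would fit noise while the state space
(and run time) grows exponentially.  For processes with genuinely
low-order structure the cap is never reached - selection stops at the
first non-significant candidate.

**Delay reconstruction.** The information-transfer delay is the selected
source lag with the highest conditional information contribution to y_t,
û = argmax_u I(y_t : x_{t-u} | {y^S, x^S \ x_{t-u}}), ties toward the
smallest lag (tolerance 1e-12 bits for float round-off).

**PID optimization.** The marginal polytope is parametrized by a basis of
the null space of the two pairwise-marginal maps (dimension
|T|(|S1|-1)(|S2|-1)); the convex objective I_Q(T:S1|S2) is minimized with
SLSQP (analytic gradient, box bounds |lambda_k| <= 1, non-negativity as
linear constraints, several starts), falling back to trust-constr if
SLSQP leaves the polytope.  Atoms more negative than -1e-5 bits raise a
convergence error; tiny negative round-off is clipped to zero and
recorded in `optimizer_gap`.  A dense grid search over the same polytope
(`brute_force_unique`, for polytope dimension <= 4) ships as an
independent validation oracle.  `decompose_te` condenses embeddings to at
most 3 highest-contribution lags per side before building the joint
table, keeping the table populated and the optimization small; a
sparsity flag marks inputs whose full embedding states were not all
observed.

## Spike-level conventions

Bins are half-open [k, k+1) ms, 0-based; a spike on an edge belongs to
the later bin.  An input spike in bin t is *relayed* iff the output
spikes in bin t + û (strict equality by default; a ± tolerance in bins is
available).  Efficacy = % of input spikes relayed; contribution = % of
output spikes with an input spike û bins earlier (a correlogram-window
variant, `contribution_in_window`, counts output spikes preceded by an
input spike within an arbitrary lag window, e.g. the significant
correlogram peak).  Cross-correlograms use 0.1 ms bins over ±50 ms;
baseline mean and SD come from the 30-50 ms lag bands on both sides, and
`peak_bins` is the contiguous run around the maximum with counts more
than 3 SD above baseline.  Because a single-bin 3 SD exceedance arises by
chance in a ~1000-bin correlogram with appreciable probability, the
operational connectivity call `has_peak` requires at least 2 contiguous
significant bins; a genuine monosynaptic peak at 0.1 ms resolution spans
several bins.  Spike tuples are pairs with a first ISI below 20 ms whose
first spike is preceded by >= 20 ms of silence (measured from the
recording start for the first spike).  Spike-triggered averages drop
events whose window is not fully inside the valid range; transfer STAs
are aligned to the triggering input spike by shifting the window by û.

## Synthetic study conditions

All generators are pure functions of (configuration, seed); defaults are
sized at 2e5 one-millisecond bins (~200 s), the order of typical
retinogeniculate recording lengths.

**Relay synapse.** The input is a bursty renewal process whose ISIs mix
70% Exp(mean 4 ms, shifted by a 2 ms floor) with 30% Exp(mean 60 ms),
placing the ISI mode at a few milliseconds over a slow background.  Each
input spike is relayed downstream at a fixed 3-bin conduction delay with
probability 0.25, raised by 0.55 when the preceding ISI is below 10 ms
(paired-spike facilitation); independent 5 Hz output noise keeps the
contribution below 100%.  This reproduces the qualitative physiology -
short-ISI spikes drive the output far more effectively - and, because
short-ISI spikes are also the predictable ones, the full pipeline yields
a positive storage-transfer correlation with unique-dominant transfer.

**Strategy toys.** The input is a two-state Markov chain with stay
probability 0.8, so its most probable continuation is its previous
symbol.  The *relay-predictable* unit relays an input spike (3-bin
delay) with probability 0.9 when the previous bin also spiked (a
confirmed prediction) and 0.1 otherwise; its output is a function of the
source state alone, so its generatively minimal target embedding is
empty.  The *error-coding* unit fires exactly when the delayed input
contradicts its internal state (its own previous output): y_t = x_{t-u}
XOR y_{t-1}, with 5% response noise - an explicit XOR-with-prediction.
The first construction produces significantly positive LSTC and
unique-dominant transfer, the second significantly negative LSTC and
synergy-dominant transfer.

**What passing tests do not show.** The generators emulate the coupling
*structure* of a relay synapse, not its biophysics: no conduction-delay
jitter (the correlogram peak is bin-exact), no refractory dynamics or
rate adaptation in the input beyond the renewal ISI mixture, no
common-input correlations, and stationary parameters throughout.
Positive results on these fixtures validate the estimators and the
inference machinery - they do not by themselves establish how any real
synapse codes.

## Defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| bin width | 1 | ms | spike-train discretization at refractory scale |
| max storage / target lag | 30 | ms | horizon over which input spikes affect future spiking |
| max source lag | 40 | ms | target horizon plus the largest admissible delay |
| max delay | 10 | ms | monosynaptic conduction range |
| alpha | 0.05 | - | per-step selection and final test level |
| selection surrogates | 200 | - | p-resolution 1/201 < alpha |
| LSTC permutations | 1000 | - | final-test resolution 1/1001 |
| max embedding vars | 6 | - | estimability cap, see above |

## Known limitations

* Discrete (binary) alphabets only; no continuous-valued estimators.
* The Panzeri-Treves correction is applied per-average, not per-sample.
* Bivariate PID only (one source past, one target past); no localized
  PID; network inference across more than two processes is limited to
  extra conditioning sources in pAIS.
* The greedy selection controls the family-wise error within each step
  (maximum statistic), not across the whole selection path.
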
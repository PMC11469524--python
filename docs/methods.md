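# Methods

## Model

`mranet` infers directed, signed, semi-quantitative signaling networks
from steady-state perturbation data. The modeled quantity is the log2
fold change of each phospho-readout relative to an unperturbed control.
The core relation is the Modular Response Analysis (MRA) steady state

    R = -r^{-1} p

where `r` is the local response matrix (diagonal normalized to -1;
`r[i,j]` is the direct effect of node *j* on node *i*, nonzero exactly on
the network's edges) and `p` encodes the experimental perturbations. A
coefficient with |r| > 1 amplifies, |r| < 1 dampens, and the sign encodes
activation versus inhibition.

Two perturbation types are distinguished:

* **Stimulation.** The stimulated receptor node is part of the network
  and receives a perturbation entry of 1; the stimulation strength is
  absorbed into the node's outgoing coefficients. Stimulus nodes have no
  incoming edges, so their own response is exactly 1.
* **Inhibition.** A kinase inhibitor of strength `l < 0` acts twofold on
  the signal its target transmits — never on the target's own measured
  phosphorylation: the transmitted signal becomes `exp(l)·x + l`, i.e. a
  multiplicative dampening `exp(l) ∈ (0,1)` of incoming (e.g. stimulated)
  signal plus a negative basal offset `l`. Inhibitors that do act on
  their target's own readout (AKT, Btk in the packaged design) are
  handled by masking that readout in every condition containing the
  inhibitor.

The steady state of a condition therefore solves `A x = -b` with
`A[:,k] = r[:,k]·exp(l_k)` (off-diagonal) for inhibited `k` and
`b = stimulus + Σ_k r[:,k]·l_k`. Feedback loops are fully supported; a
loop product reaching 1 makes the system singular and is rejected.

## Structural identifiability

With incomplete measurement/perturbation coverage, individual
coefficients are generally identifiable only in combinations. Responses
are rational functions whose numerator monomials are products of
coefficients along simple perturbation-to-readout paths (times `l` for
inhibitions) and whose denominator monomials are products of
vertex-disjoint simple cycles. The exponent vectors of all such
monomials, including one extra column per inhibitor for occurrences of
the relay-dampening factor `exp(l)`, form an integer matrix. Exact
Gaussian elimination over the rationals (pivot rows chosen among the
shortest monomials, so that names stay readable) yields:

* a basis of **coefficient paths** — named, identifiable multiplicative
  combinations such as `r_MEK_RAF*r_RAF_p38` (`r_<target>_<source>` per
  factor, inhibitor strengths `i_<target>`), and
* the **identifiable parameter count** (degrees of freedom). For the
  count, each `exp(l_k)` column is folded into the `l_k` column with a
  fixed generic rational multiplier (the Jacobian column of `l_k` is the
  multiplicative exponent plus `l_k` times the dampening exponent; two
  multiplier sets are evaluated exactly and the larger rank kept).

Exponent arithmetic cannot see *additive* degeneracies: when a node's
activity is proportional to another's in every condition (e.g. a relay
whose only input is a hub, and which is never separately perturbed),
parallel routes are confounded additively. The numerical Jacobian rank
of the simulated responses with respect to log-magnitude raw parameters
(central differences, SVD threshold 1e-8 relative, maximized over two
seeded random parameter points) is therefore computed alongside and is
authoritative for the degrees of freedom whenever it disagrees.
`verify_rank` exposes the cross-check. On the packaged starting network
this matters: the parallel SYK→Btk and SYK→ZAP70→Btk routes reduce the
true rank by one below the symbolic count.

## Parameterization and fitting

Free parameters are the pivot coefficients of the eliminated basis (one
per coefficient path) plus every inhibitor strength that appears in any
monomial; all non-pivot edge coefficients are gauge-fixed to 1. This
spans exactly the identifiable response manifold while keeping `l`
explicit, so inhibitor strengths can be clamped across models.

The objective is the weighted sum of squared residuals
`WSSR = Σ ((data - model)/error)²` over observed, unmasked cells, with
per-cell standard errors floored at 0.05 log2 units (configurable) to
avoid infinite weights. Goodness of fit is the reduced chi-square
`X_r = WSSR / (n_datapoints - n_identifiable)`; ~1 means noise-level fit.

The residual landscape of an MRA model is organized in *sign basins*:
each assignment of coefficient signs has its own local optimum, and
random multi-start rarely samples the right basin for ~30 parameters.
The optimizer is therefore staged:

1. **Multi-start:** Latin-hypercube initial points (default 100;
   magnitudes log-uniform in [0.01, 100] with random signs, inhibitor
   strengths uniform in [-5, -0.01]), each run through iteration-capped
   trust-region least squares with analytic sensitivities (one
   multi-right-hand-side solve per condition yields the steady state and
   all parameter derivatives).
2. **Polish:** the best few restarts, plus two informed starts — an
   optional caller-supplied warm start, and a regression start that
   estimates composite chain coefficients directly from the measured
   responses (each measured node regressed on its nearest measured or
   stimulus ancestors, with unmeasured intermediates collapsed so the
   regression coefficient estimates the product along the chain, which
   is exactly a path value) — refined to full tolerance (ftol 1e-8).
3. **Sign-flip refinement:** greedy local search over sign moves —
   single coefficients and all-edges-of-one-node groups (a wrong guess
   for a node's activity sign flips every edge touching it coherently) —
   each tried with a quick refit and kept when it improves.

Inhibitor strengths are bounded negative throughout. The returned fit is
the best over all stages; the number of restarts reaching the optimum
plateau is reported, with a warning when fewer than two do.

## Greedy structure adaptation

Starting from a literature-derived network, each iteration fits the
current structure on the training data (in the packaged design: the
stimulated conditions), scans all single-edge removals (likelihood-ratio
test p > alpha, default 0.05, ranked by descending p) and then all
single-edge additions (p < alpha, ascending), with the degrees of
freedom of each test equal to the change in *identifiable* parameter
count. A candidate is accepted when (a) the reduced chi-square does not
increase — every upheld alteration leaves the per-dof fit better or
equal — and (b) on the held-out data (unstimulated inhibitor conditions)
the error reduction over the all-zero null prediction,
`100·(WSSR_null - WSSR_sim)/WSSR_null`, drops by at most `delta_pct`
(default 2 percentage points) relative to the previous accepted step.
Rejected candidates are recorded and the next-ranked one is tried; the
loop stops when no candidate is accepted. Removals whose identifiable
count does not change are pure simplifications and accepted when the
fit is numerically unchanged. No multiple-testing correction is applied
across scanned candidates. Ties in p (including underflow ties for very
large improvements) are broken by smaller candidate WSSR — once the test
saturates, the likelihood itself is the finer statistic — then fewer
identifiable parameters, then edge name, making traces deterministic
and replayable.

The two gates interact: removing a genuinely superfluous edge from a
model fitting *below* noise level (X_r < 1) raises X_r toward 1 on
average (the removed parameter was absorbing chi-square-distributed
noise), so gate (a) deliberately keeps such edges — parsimony is
enforced only while it does not worsen the per-dof fit.

## Profile likelihood and model comparison

Pointwise confidence intervals scan one path value away from its
optimum, re-optimizing all remaining parameters at each point
(warm-started), until WSSR crosses the optimum plus the chi-square(1)
quantile (3.841 at alpha = 0.05). Stepping is adaptive — initial step
10% of the estimate (floor 0.01), doubled until the threshold is
bracketed, then bisected to within 1e-3 of the threshold increment and
interpolated. A direction whose scan passes |value| = 1e4 (configurable)
without crossing is flagged non-identifiable ("ni"): the coefficient can
be compensated by the rest of the model.

For cross-model comparison the inhibitor strengths are first clamped to
common values (reference model or mean across models — doses were
shared, so differences belong to the wiring) and the remaining paths
refit; a shared path differs significantly when the two 95% CIs do not
overlap. Paths present in only one model are reported as individual
links, not flagged. Transfer of a structure to a foreign dataset is a
full identifiability analysis plus fit on that data, statistically
comparable to a native fit.

A consensus core network keeps edges present in at least k of the
member models (default 3). Edge coefficients are binned into five
states: amplification (r > 1), dampening to neutral relay (0 < r ≤ 1),
no link (|r| < 1e-9), attenuating to neutral inhibition (-1 ≤ r < 0),
enforced inhibition (r < -1); boundary values fall to the neutral side.
The consensus state is the majority bin among members containing the
edge, with exact ties reported unresolved. Overall responses along a
chain multiply the coefficients, so two inhibitory links in series give
a positive composite response.

## Synthetic data generator

The generator emulates the B-cell-receptor perturbation experiments the
pipeline targets: a 20-node literature-style starting network (stimulus
BCR; proximal SYK/ZAP70/Btk/PI3K wiring with deliberate redundancy;
AKT-mTORC1, RAF-MEK-ERK with the canonical negative ERK→RAF feedback,
JNK, p38 and IKK/NF-κB branches; RAF and p38 unmeasured), 14
phospho-readouts, and 8 inhibitors (JNK, MEK, PI3K, Btk, AKT, mTORC1,
IKK, p38) each applied with and without stimulation plus the stimulation
alone — 17 conditions. A DLBCL-style variant drops the stimulated
conditions (chronically active receptor). The AKT- and Btk-inhibitor
readout maskings of the study design are included.

Ground-truth coefficients are drawn log-uniformly in magnitude
([0.5, 2] by default — edges that neither strongly amplify nor strongly
dampen), with fixed signs (all activating except ERK→RAF) or random
signs on request; inhibitor strengths uniform in [-2, -0.5] (twofold to
sevenfold basal reduction in linear scale, a realistic small-molecule
regime at the doses used in such panels). Unstable feedback draws are
resampled. Datasets are produced by simulating the noiseless responses
and adding independent Gaussian replicate noise (default sd 0.2 log2
units, matching typical bead-array replicate scatter) for n = 3
replicates; the stored value is the replicate mean and the stored error
either the sample standard error (`"sem"`, as with real replicates) or
the exact `sd/sqrt(n)` (`"exact"`). SEM weighting from n = 3 makes
per-cell weighted residuals t-like with heavy tails, so goodness-of-fit
calibration checks use exact weights; the SEM mode exercises the
pipeline exactly as real data would.

What the generator does **not** emulate: non-Gaussian and
intensity-dependent measurement noise, antibody cross-reactivity,
incomplete steady state, off-target inhibitor action, saturation
nonlinearity of strong perturbations. Passing tests therefore validate
the inference machinery under the model's own assumptions, not the
biology of any particular dataset.

## Problem sizes and numerical choices

Simulation studies in the test suite use: the packaged 17-condition ×
14-readout fixture for goodness-of-fit calibration (10 replicate
simulations, noise sd 0.2, exact weights, 40 restarts); 6-node networks
with two stimulus nodes and full single-inhibitor coverage for
parameter/structure recovery (20 seeded runs, noise sd 0.1, n = 3) —
two stimuli keep the stimulated-conditions training split data-rich at
desk scale, mirroring the ratio of the full design; and a 3-node chain
for profile-coverage calibration (100 runs). Degenerate inputs: empty
designs, all-control designs, singular steady states, masked cells and
NaNs are rejected or excluded as described above; condition ordering
never affects results beyond 1e-6.

## Known limitations

* The monomial analysis is exact for identifiability *counting* only in
  combination with the numerical rank check; the reported coefficient
  paths are the multiplicative basis and do not enumerate combinations
  that are identifiable only through the inhibitor dampening
  nonlinearity.
* The greedy adaptation explores single-edge moves and can end in local
  optima of structure space (as any hill climber); traces make the
  search auditable but not exhaustive.
* Consensus binning uses raw edge coefficient values; for edges that are
  identifiable only inside a product, the binned value reflects the
  gauge convention (non-pivot coefficients fixed at 1) and should be
  read together with the path table.
* The steady-state, log-linear-response assumption limits validity to
  moderate perturbations near the reference state.
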
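# Methods

This note documents the models, statistics, numerical choices, and known
limitations of `wormstates`. It is the package's own account of what it
computes; every empirical statement here is recomputed by the test suite or
by `scripts/acceptance.py`.

## Posture representation

A worm's midline posture in one video frame is summarized by 48 tangent
angles measured at regular intervals along the body, mean-centered to
discard overall orientation, and projected onto four orthonormal
"eigenworm" basis vectors. Each frame is therefore a 4-vector of
dimensionless amplitudes; an individual's recording is an `(F, 4)` series
at a fixed frame rate (5 fps after preprocessing). The package does not
estimate the basis from images — `synthgen.make_basis` draws a random
orthonormal, zero-column-sum basis so that posture reconstruction
(`atypicality.reconstruct_posture`) is exercised end to end; reconstructed
angle profiles are synthetic stand-ins, not real worm postures.

## Synthetic strain generator (`synthgen`)

The generator produces collections with the statistical structure the
analysis assumes of real recordings:

* **Multimodal state usage.** Each worm's 4-D trajectory relaxes toward one
  of `G` attractor means (drawn once per collection from a centered
  Gaussian with spread `5 * sigma_act`, so states are resolvable), with
  active dynamics `v[t+1] = v[t] + lam * (m_g - v[t]) + sigma_act * xi[t]`.
* **Bout structure.** The active attractor evolves as a Markov chain: the
  dwell in attractor `g` is geometric with continuation probability
  `A[g, g]`, and the successor is drawn from the off-diagonal of row `g`.
* **Quiescence.** At a bout boundary, with probability `rest_entry_prob`, a
  rest bout starts during which the posture performs a small random walk
  (`sigma_rest << sigma_act`) for a geometric duration. This produces
  contiguous near-zero-speed stretches and a low mode in the speed
  distribution, the synthetic analogue of behavioral quiescence.
* **Missingness.** A fraction of interior frames can be marked missing
  (never the first or last frame, since interpolation needs two observed
  flanks).

Defaults (chosen once as physically plausible study conditions; all in
eigenworm-amplitude units per frame at 5 fps):

| parameter | default | rationale |
| --- | --- | --- |
| `frames_per_worm` | 4500 | 900 s at 5 fps, the canonical recording length |
| `n_attractors` | 6 | a handful of resolvable posture modes |
| `relaxation_rate` | 0.2 | ~1 s relaxation toward an attractor |
| `active_noise` | 0.35 | active speeds ~0.4–1.3/frame, spanning the inactivity-threshold grid |
| bout stay probability | 0.9 | ~2 s dwell per postural bout |
| `rest_entry_prob` / `rest_exit_prob` | 0.2 / 0.08 | ~20% of time quiescent, ~2.5 s rest bouts |
| `rest_noise` | 0.05 | rest speed mode near 0.1, well below the active mode |

The per-frame speed `||v[t+1] - v[t]||` then has a rest mode near
`2 * sigma_rest = 0.1` and an active mode near `2 * sigma_act` — the
bimodal shape with a low quiescence mode that motivates the
inactivity-removal analysis.

**Perturbations** (mutant analogues), per strain:

* `no_rest` — rest-entry probability zeroed; removes the low speed mode.
* `accelerate` — exact γ-fold time compression of the whole generative
  process: AR coefficient `(1-lam)^gamma`, active noise rescaled to keep
  the stationary posture variance, bout chain `A^gamma`, rest-exit
  probability `1-(1-p)^gamma`. A γ-accelerated strain is therefore
  distributionally a γ-decimated wild type, which is precisely what the
  β-fold acceleration transform of the dissection stage emulates. (Scaling
  `lam` and `sigma_act` jointly by γ instead would inflate the stationary
  posture spread ~γ-fold and leave dwell times untouched — changing state
  usage rather than speed alone.)
* `retransition` — the bout chain is replaced by a reversible chain with
  the *same stationary distribution*: the uniform off-diagonal (every
  successor equally likely) is moved onto a cycle through the states in a
  random order, interpolated by `strength`, and turned into a chain by the
  Metropolis construction. Every state keeps its total exit rate, so dwell
  times are matched; because the base is successor-uniform, the distance
  of the rewired transition law from the base is identical for every
  relabeling — rewired strains have a reproducible effect size.
  Stationarity is preserved exactly (checked to 1e-8; an explicit
  replacement matrix that shifts the stationary law is rejected).
* `reweight` — the stationary law itself is tilted log-normally and a new
  chain built around it; state usage changes, which moves a strain *along*
  the occurrence/transition trend rather than off it.

Reproducibility: one seed per collection; per-worm generators are spawned
from `(seed, strain index, worm index)`, so collections are bit-identical
for a given configuration and independent of generation order.

**What the generator does not emulate:** measurement noise on the 48
angles, dorsal/ventral ambiguity, trajectory (x, y) information,
autocorrelated tracking failures, and any within-strain heterogeneity
beyond seed noise. Tests passing on this generator show the pipeline's
statistical machinery behaves as designed under its assumptions; they do
not validate the biology of any particular real strain.

## Preprocessing (`ingest`)

Fixed order: quality control → gap interpolation → downsampling.

* QC drops worms whose raw duration `F / fps` lies outside the closed
  interval [890, 910] s or whose gap fraction (on the raw frame count)
  exceeds 0.40 strictly; strains with fewer than five surviving worms are
  then dropped. The exclusion report lists each worm with the rule that
  removed it.
* Interior gap runs are filled by per-dimension linear interpolation
  between the two nearest observed flanking frames; leading/trailing gaps
  are trimmed because extrapolation has no second flank. Observed values
  are never modified.
* Downsampling to 5 fps keeps every ρ-th frame for integer rate ratios ρ;
  for non-integer ratios each target time takes the nearest source frame
  (ties to the earlier frame). Frames are selected, never averaged, so
  instantaneous postural speeds — measured later — are not smoothed.

## Postural-state binning (`binning`)

**FAB-GMM.** A full-covariance Gaussian mixture is fitted to a uniform
random sample of pooled frames (the analysis default is 1% of frames; the
synthetic studies at reduced scale sample 5%). The E-step is the standard
posterior followed by FAB shrinkage: responsibilities of component `k` are
multiplied by `exp(-D_c / (2 N_k))` with `D_c = 14` free parameters per
4-D component and `N_k` the component's effective count, then
row-renormalized; components whose mixture ratio drops below `eps` are
pruned after every E-step. Convergence is monitored on the FIC lower bound
(expected complete log-likelihood + responsibility entropy −
`(D_c/2) Σ log N_k` − `((K−1)/2) log N`).

Numerical choices:

* Initial means from k-means++; *all* initial covariances set to the
  global data covariance. A broad start keeps redundant components
  overlapping so shrinkage competition can act before they localize.
* `1e-6 * I` is added to every covariance after each M-step; a collapsing
  covariance is progressively ridged rather than fatal.
* Defaults `max_iter=2000`, relative FIC tolerance `1e-10`. These are
  deliberately patient: two components splitting one true cluster
  near-symmetrically dissolve through a slow competition mediated by the
  mixture weights (the shrinkage deficit compounds through `log w_k`), and
  an early stop freezes the split in. Empirically ~500–1400 iterations are
  needed on 6-cluster recovery problems.
* States are ordered by descending weight at convergence; with
  `shrink=False` and `eps=0` the procedure is plain EM and its objective
  trace is the (non-decreasing) log-likelihood.

**K-means baseline.** Lloyd iterations from k-means++, run to an
assignment fixpoint (≤300 iterations); an emptied cluster is reseeded to
the point farthest from its assigned centroid. Binning is one-hot at the
nearest centroid, ties to the lowest state index. Probabilistic (GMM)
responsibilities preserve information about intermediate postures that
one-hot binning discards; the test suite checks that GMM binning never
detects fewer within-strain-coherent strains than k-means at matched K.

## Occurrence/transition statistics (`behavior_stats`)

Per worm: `r_i = mean_f r_{i,f}` (occurrence vector over states) and
`T_i = mean_f outer(r_{i,f}, r_{i,f+1})` (joint transition-pair law; its
grand total is exactly 1 because each outer product of simplex rows sums
to 1). Strain aggregates are unweighted means across worms (after QC all
worms have near-identical F, so frame weighting would change nothing
material). Divergences are Jensen-Shannon in natural-log units (bounded by
ln 2); transition matrices are compared flattened as distributions over
state pairs. Because marginalization is a stochastic map, the JSD between
transition laws dominates the JSD between their marginals; with `r`
averaged over F frames and `T` over F−1 adjacent pairs, the worm-level
inequality `ΔT ≥ Δr` holds up to an O(1/F) edge term (tested with
tolerance `2 ln2 / F`).

Within- vs between-strain similarity: for worm `i`, `Δ_intra` is its mean
occurrence JSD to same-strain worms and `Δ_inter` to an equal-size seeded
random sample of other-strain worms. Each strain is tested with a
one-sided Wilcoxon-Mann-Whitney test (exact by enumeration when
`n + m ≤ 12` without ties, otherwise the tie- and continuity-corrected
normal approximation), with Benjamini-Hochberg correction across strains
at q < 0.05.

## Atypicality screen (`atypicality`)

Across strains, `Δ_ref T_S` rises almost linearly with `Δ_ref r_S`:
different posture usage necessarily drags transition usage with it. The
screen fits ordinary least squares of `delta_T` on `delta_r` (intercept
included — the joint-vs-marginal inequality permits a positive offset) and
flags strains whose transition divergence exceeds the trend prediction,
using upper-tail normal p-values on standardized residuals and BH
correction (q < 0.05).

**Residual standardization.** Two facts about small strain panels drove
the design:

1. *Masking.* With several genuine outliers among ~20 strains, any
   SSR-based residual scale is dominated by the outliers themselves; the
   joint standardized residual is then capped near 2 regardless of effect
   size, and no multiple-testing procedure can flag them all. (At a
   321-strain scale with ~2% outliers the effect is negligible.)
2. *Heteroscedasticity.* Estimated divergences get noisier roughly in
   proportion to their size; measured on on-trend synthetic panels, the
   median absolute residual grows ~linearly in `delta_r`.

The default standardization therefore uses a proportional robust noise
model: per-strain scale `s * (delta_r + delta0)`, where `s` is the
normalized MAD of the proportionally scaled residuals and
`delta0 = 0.02` nats is a fixed noise-floor divergence — the scale below
which estimation noise stops shrinking with the divergence itself
(measured on on-trend synthetic panels, the offset of the |residual|
versus `delta_r` line sits near 0.015–0.02; the floor also keeps the
scale from collapsing for strains whose measured `delta_r` fluctuates
near zero). For a null panel (all strains alike, every `delta_r` below
the floor) this reduces to plain robust standardization and the flag rate
respects the BH level; the classical `sqrt(SSR/(n-2))` scale remains
available (`scale='classical'`), under which OLS z-values average exactly
zero. A leverage correction (`1/sqrt(1-h_ii)`) is available behind a flag.

Flagged strains are characterized by per-state occupancy fold changes
(pseudo-count `1/(10 K F̄)` guards empty reference states) and by
reconstructing state-mean postures through the eigenworm basis.

## Factor dissection (`factor_dissection`)

The two "trivial" factors are applied to the reference strain in fixed
order: **inactivity removal** (drop every frame whose speed from its
*original* predecessor is below α; frame 0 always kept) then **uniform
acceleration** (β = 2: keep even frames; β = 1.5: each consecutive triple
`(v1, v2, v3) → (v1, (v2+v3)/2)`, remainder frames kept; β = 1 identity).
Speeds are recomputed after each stage and stay in per-frame units.
`(α, β)` is chosen by exhaustive grid search (α = 0.3…1.0 step 0.1,
β ∈ {1.5, 2.0}; an identity-including grid is available behind a flag)
minimizing the L1 distance between pooled empirical speed CDFs, computed
exactly as the 1-D Wasserstein-1 distance; ties break toward smaller α
then smaller β. Worms degenerating below two frames are excluded with a
warning.

The transformed reference is binned with the *fixed* state model from the
main screen (the model is never refitted on artificial data), aggregated,
and compared to the target strain; `Z_a` standardizes
`Δ_aRef T_S` against the previously fitted regression using the same
noise model as the screen. A small `|Z_a|` relative to the strain's
original Z means quiescence loss plus uniform acceleration explain its
atypical transition pattern.

## Scaled-down study conditions

The synthetic studies run at a fraction of the original database's scale,
as the package's own choice of problem size: screens use ~20 strains with
8–12 worms of 1000–1500 frames; model-recovery benchmarks use 10,000
points; the null false-discovery study uses 200 strains × 5 worms × 200
frames over 200 replicates. The discrimination study (retransition vs
reweight mutants) is generated without rest bouts: rests are entered at
bout boundaries, so strains with redistributed exit rates would
accumulate quiescence unevenly across attractors and contaminate the
matched-occurrence construction; quiescence effects are studied separately
in the artificial-strain analysis.

## Known limitations

* The FAB shrinkage/FIC construction is one standard reading; other
  variants (different penalty bookkeeping, burn-in before pruning) exist.
* The screen's noise model is a first-order description; strongly
  non-simplex-like state usage or very small panels (< ~10 strains) leave
  `delta0` and `s` poorly determined.
* `Z_a` inherits the regression fitted on the original panel; if the
  panel itself is atypical (few strains, no on-trend spread), `Z_a` is not
  meaningful.
* WCON support is deliberately minimal (id, time, one custom 4-column
  block); it is an interchange convenience, not a full reader.
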
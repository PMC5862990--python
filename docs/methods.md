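# Methods

## The model

Enzyme-catalysed rates deviate from Eyring behaviour: most enzymes show an
intrinsic temperature optimum (Topt) even in the absence of denaturation.
Macromolecular rate theory (MMRT) explains this by a non-zero activation
heat capacity change ΔCp‡ — the difference in heat capacity between the
enzyme–transition-state ensemble and the enzyme–substrate (reactant-state)
ensemble. With ΔCp‡ assumed temperature-independent over the fitted range,

    ln k(T) = ln(kB·T/h) − [ΔH‡(T0) + ΔCp‡·(T − T0)] / (R·T)
                        + [ΔS‡(T0) + ΔCp‡·ln(T/T0)] / R

with the transmission coefficient fixed at 1. A negative ΔCp‡ curves the
Eyring plot downward and places a finite optimum at

    Topt = (ΔCp‡·T0 − ΔH‡_T0) / (ΔCp‡ + R),

which exists only when ΔCp‡ < −R. ΔCp‡ is reference-independent; ΔH‡ and
ΔS‡ transform between references as ΔH‡(T0') = ΔH‡(T0) + ΔCp‡(T0'−T0),
ΔS‡(T0') = ΔS‡(T0) + ΔCp‡·ln(T0'/T0).

Independently, statistical thermodynamics gives the heat capacity of an
equilibrium ensemble from its enthalpy fluctuations, Cp = ⟨δH²⟩/(kB·T²);
for molar energies (kJ mol⁻¹, as force-field potential energies are
reported) the denominator constant is R = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹.
Sampling the reactant state and a transition-state-analogue (TSA) complex
at equilibrium therefore yields

    ΔCp‡ = (⟨δH²⟩_TSA − ⟨δH²⟩_RS) / (R·T²),

a second, fully independent route to the same macroscopic quantity.

## Fitting procedure and its conventions

The fit is a nonlinear least squares of the MMRT expression to ln(rate)
with three free parameters (ΔH‡_T0, ΔS‡_T0, ΔCp‡). The reference
temperature follows the convention T0 = Topt − 4 K. Because Topt is only
known after fitting, the package iterates: fit at the current T0, recompute
the closed-form optimum, reset T0 = Topt − 4 K, and repeat until T0 moves
by < 0.01 K (max 20 refits; in practice 2–3). Since resetting T0 is an
exact reparametrisation, the iteration converges as soon as the optimiser
does; a curve with no optimum (ΔCp‡ ≥ −R) keeps its initial reference.

Initial guesses are derivative-based and seed-free: a parabola fit to
ln k vs T supplies ΔCp‡ from its curvature (the dominant term of
d²ln k/dT² is ΔCp‡/(R·T²)), ΔH‡ from the local slope at T0 and ΔS‡ from
intercept matching; the initial T0 is 4 K below the parabola vertex.

Weighting: if per-point replicate standard deviations of ln k are present,
they enter as inverse-variance weights; otherwise the fit is unweighted.
Parameter covariance is scaled by the residual variance
(`absolute_sigma=False`), and the 95% interval check in the tests uses a
t-quantile with n − 3 degrees of freedom. Rates may be supplied on the
linear or log scale; the scale is an explicit flag and never auto-detected.

## Variance protocols

Naive total variance over a long trajectory is inflated whenever the system
switches between conformational substates with different mean energies (law
of total variance: total = occupancy-weighted within-cluster variance +
variance of cluster means). Two estimators address this:

* **Cluster-weighted** (few, well-defined clusters): Σ_c f_c·Var_c with
  f_c the cluster frame fraction. Suitable when frames have been assigned
  to clusters, e.g. by K-means on Cα-RMSD features.
* **Moving-window** (many clusters, frequent switching): the mean of
  unbiased variances over fixed-length windows slid along the trajectory
  (default stride window/10; configurable). Windows shorter than substate
  dwell times exclude the between-substate term while still capturing
  switching that happens within a window; scanning the window length and
  locating the plateau of ΔCp‡ makes the estimate clustering-independent.

Conventions: all estimator variances use the unbiased n−1 denominator
(small windows make the n-denominator bias material); the exact
law-of-total-variance identity is stated and tested with ddof=0 on every
term, since the unbiased per-cluster estimator does not satisfy it to
machine precision. Burn-in (default first 10% of frames, emulating
discarding the equilibration segment of a production run) is applied before
any variance. Replicates are aggregated as mean ± across-replicate standard
deviation; the "cumulative" state uncertainties combine in quadrature for
ΔCp‡. Temperature is ensemble metadata, never inferred from the energies.

Plateau rule for the window scan: three consecutive scan points agreeing
pairwise within 5% (relative to the largest magnitude in the triple) open a
plateau; the maximal such run ending at the largest windows is reported and
its mean is the plateau value. Absence of a plateau is reported as `none`,
not an error.

Partial ΔCp‡ applies the same machinery to a named region's energy column.
Because inter-region interaction energies are excluded, partial values need
not sum to the total; under a joint-Gaussian decomposition the deficit is
exactly twice the summed inter-region covariances over R·T², which the
region generator reproduces and the tests verify.

## Structural metrics

Superposition uses the centroid-shifted Kabsch solution (proper rotation
guaranteed) via `scipy.spatial.transform.Rotation.align_vectors`. Pairwise
Cα-RMSD matrices feed two clusterings: K-means (k-means++ initialisation,
10 restarts, fixed seed — deterministic) for a known small cluster count,
and average-linkage agglomerative clustering cut at a minimum inter-cluster
distance ε (linkage configurable to single/complete; the cutoff semantics
of published trajectory-clustering tools vary, so ε plus linkage are
exposed rather than hard-coded). Flexible termini can be excluded from the
RMSD fit.

RMSF is computed about a running-average reference: frames are first
aligned to the initial frame to strip global rigid motion, a centred
running-average structure is built (windows truncated at the ends; a window
covering the whole trajectory degenerates to the global mean), each frame
is re-fit to its own running average, and per-residue RMSF is the
root-mean-square deviation of each Cα from its windowed mean position.
Referencing a running average keeps slow inter-substate drift out of the
fluctuation measure. For isotropic Gaussian jitter of per-coordinate sd s
the expected RMSF is s·√3, which the tests verify.

Per-residue state differences use Welch's two-sample t-test on replicate
RMSF values, flagged at p < 0.01 per residue with no multiple-testing
correction by default (a Benjamini–Hochberg option is provided). Residues
constant and equal in both states get p = 1 and no flag, avoiding 0/0.

## Synthetic generators and what they do (not) emulate

The generators define the study conditions with known ground truth:

* **Rate profiles**: ln k from the MMRT law plus Gaussian noise (default
  sd 0.05 ln-units) on a 2 K grid, optionally replicated.
* **Energy series**: a hidden Markov chain over conformational clusters
  (per-frame transition matrix or mean dwell times), emission = cluster
  mean + cluster sd × a shared standardized AR(1) process, so the
  stationary within-cluster variance equals the specified cluster variance
  exactly. AR(1) (not white noise) because MD energies are autocorrelated;
  the lag-1 parameter makes window-size effects in the scan non-trivial.
* **Region streams**: correlated AR(1) Gaussian regions with a specified
  covariance matrix, summing exactly to the total column.
* **Toy trajectories**: reference + active-basin displacement + Gaussian
  jitter, contaminated by a random rigid motion per frame (on by default)
  so analyses must superpose honestly.

Two presets mirror the sampling geometry of long-timescale enzyme
simulations at desk scale: a "MalL-like" preset (6 clusters, mean dwell
5000 frames ≙ 50 ns at 10 ps/frame, φ = 0.9, 320 K, 10 replicates ×
45 000 frames per state ≙ 450 ns analysed per run) and a "KSI-like" preset
(2 clusters, 70/30 occupancy, 300 K). In each, the TSA cluster variances
are the reactant-state ones shifted by a constant so the within-state
variance difference corresponds exactly to a chosen ΔCp‡ (−10.0 and −0.86
kJ mol⁻¹ K⁻¹ respectively); both states share the cluster-mean geometry, so
between-substate leakage largely cancels in the difference. Cluster-mean
spread gives a between-cluster variance of 1680 (kJ mol⁻¹)² in the MalL
preset — small relative to the within variance (~25 000), a deliberate
choice that keeps the moving-window scan informative without letting the
between term dominate.

What the generators do **not** emulate: real force-field energy surfaces,
solvent, anharmonic or multi-timescale correlations beyond AR(1),
state-dependent substate geometries, or any coupling between coordinates
and energies. Passing tests therefore demonstrate estimator correctness
and calibration under the modelled statistical structure — switching,
autocorrelation, replicate scatter — not the adequacy of molecular
mechanics for real enzymes.

## Numerical choices and problem sizes

* Moving-window variances use a centred cumulative-sum formulation (the
  series is mean-shifted first to avoid catastrophic cancellation).
* Window lengths in ns are converted to frames via the trajectory time
  step; the default scan grid is 5–80 ns.
* The closed-form Topt is cross-checked against a 0.001 K-grid argmax.
* Statistical checks in the test suite run at sizes where their nominal
  error rates are meaningful yet fast: 200 noisy fits for interval
  coverage, 100 repeats × 200 residues for the t-test level, and five
  independent realisations of the full 10 × 45 000-frame two-state
  experiment for the fluctuation-route recovery (single realisations
  scatter ~5% through cluster-occupancy noise, so the recovery check is
  applied to their mean).

## Known limitations

* No modelling of denaturation or temperature-dependent ΔCp‡; κ ≠ 1 is not
  supported.
* The entropy-fluctuation route to ΔCp‡ is out of scope.
* Whether moving windows should overlap, and whether per-cluster variances
  should be pooled across replicates, are not settled conventions; both are
  exposed as options (stride; per-replicate aggregation is the default).
* The hierarchical-clustering cutoff ε is linkage-dependent; an ε taken
  from another tool's output is comparable only under the same linkage.
* `pairwise_rmsd` is O(F²) in frames and intended for snapshot-subsampled
  trajectories, not every MD frame.
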
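"""Synthetic data with known ground truth for every pipeline stage.

Three generator families emulate the study conditions the analyses were
designed for:

* MMRT-shaped ln(rate) profiles with Gaussian noise (assay emulation);
* stationary energy time series with hidden-Markov switching between
  conformational clusters of distinct means/variances and AR(1)
  autocorrelation within clusters (MD-enthalpy emulation; frames nominally
  10 ps apart as in snapshot analysis of long MD runs);
* toy coordinate trajectories with basin structure, per-residue jitter and
  deliberate rigid-motion contamination (so analyses must superpose).

Every generator is seeded and bit-reproducible, and returns a *truth record*
sufficient to compute the expected output of every downstream estimator
without re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .constants import R_KJ
from .fluctuation import EnergyTrajectory, StateEnsemble, REACTANT, TS_ANALOGUE
from .mmrt import MMRTParams, RateProfile, mmrt_lnk
from .structure import CoordinateTrajectory

__all__ = [
    "RateProfileSpec",
    "SwitchingSpec",
    "gen_rate_profile",
    "gen_switching_energy",
    "gen_region_energies",
    "gen_toy_trajectory",
    "gen_state_ensemble",
    "mall_like_ensembles",
    "ksi_like_ensembles",
]


# ---------------------------------------------------------------------------
# rate profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateProfileSpec:
    """Specification of a noisy MMRT rate profile."""

    params: MMRTParams
    temperatures: tuple[float, ...] = tuple(np.arange(280.0, 331.0, 2.0))
    noise_sd: float = 0.05       # sd of ln(rate) noise
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures)
        if np.any(t <= 250.0) or np.any(t >= 400.0):
            raise ValueError("temperature grid must lie within (250, 400) K")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def gen_rate_profile(spec: RateProfileSpec) -> tuple[RateProfile, dict]:
    """Draw ln k = MMRT(T) + Gaussian noise; reproducible under the seed.

    With multiple replicates the profile holds the per-point replicate mean
    of ln k and the per-point replicate sd; the truth record carries the
    generator parameters and the individual replicate draws.
    """
    rng = np.random.default_rng(spec.seed)
    T = np.asarray(spec.temperatures, dtype=float)
    clean = mmrt_lnk(spec.params, T)
    draws = clean[None, :] + spec.noise_sd * rng.standard_normal(
        (spec.replicates, T.size)
    )
    if spec.replicates > 1:
        lnk = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
    else:
        lnk = draws[0]
        sd = None
    profile = RateProfile(
        temperatures=T, rates=lnk, log_scale=True, replicate_sd=sd,
        label=f"synthetic(seed={spec.seed})",
    )
    truth = {
        "params": spec.params,
        "clean_lnk": clean,
        "draws": draws,
        "noise_sd": spec.noise_sd,
    }
    return profile, truth


# ---------------------------------------------------------------------------
# switching energy trajectories
# ---------------------------------------------------------------------------

@dataclass
class SwitchingSpec:
    """Markov-switching AR(1) Gaussian energy process.

    The hidden state follows a discrete Markov chain over conformational
    clusters; the emission is the active cluster's mean plus the cluster
    standard deviation times a shared standardized AR(1) process (stationary
    unit variance), so the stationary *within-cluster* variance equals the
    specified cluster variance exactly. Either a full per-frame transition
    matrix or mean dwell times (frames) may be given; dwell times build the
    matrix with uniform off-diagonal jumps.
    """

    means: tuple[float, ...]                  # kJ/mol per cluster
    variances: tuple[float, ...]              # (kJ/mol)^2 per cluster
    transition: Optional[np.ndarray] = None   # per-frame probabilities
    dwell_frames: Optional[tuple[float, ...]] = None
    ar1_phi: float = 0.0
    n_frames: int = 45000
    time_step_ps: float = 10.0
    temperature_K: float = 320.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.means)
        if len(self.variances) != k:
            raise ValueError("means and variances must have equal length")
        if any(v <= 0 for v in self.variances):
            raise ValueError("cluster variances must be positive")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.transition is None:
            if k == 1:
                self.transition = np.ones((1, 1))
            elif self.dwell_frames is not None:
                if len(self.dwell_frames) != k:
                    raise ValueError("one dwell time per cluster required")
                P = np.zeros((k, k))
                for i, d in enumerate(self.dwell_frames):
                    if d < 1:
                        raise ValueError("dwell times must be >= 1 frame")
                    p_leave = 1.0 / d
                    P[i] = p_leave / (k - 1)
                    P[i, i] = 1.0 - p_leave
                self.transition = P
            else:
                raise ValueError("provide a transition matrix or dwell times")
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix must be k×k")
        if np.any(self.transition < 0) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ):
            raise ValueError("transition matrix rows must be probabilities summing to 1")

    @property
    def n_clusters(self) -> int:
        return len(self.means)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (left Perron eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def _simulate_chain(P: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a Markov chain path by drawing geometric dwell segments."""
    k = P.shape[0]
    # stationary start
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    p0 = np.abs(np.real(vecs[:, i]))
    p0 /= p0.sum()
    state = int(rng.choice(k, p=p0))
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    while pos < n:
        p_stay = P[state, state]
        if p_stay >= 1.0:
            labels[pos:] = state
            break
        dwell = int(rng.geometric(1.0 - p_stay))
        end = min(pos + dwell, n)
        labels[pos:end] = state
        pos = end
        if pos >= n:
            break
        off = P[state].copy()
        off[state] = 0.0
        off /= off.sum()
        state = int(rng.choice(k, p=off))
    return labels


def _standard_ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) with unit stationary variance, stationary initial condition."""
    if phi == 0.0:
        return rng.standard_normal(n)
    eps = rng.standard_normal(n) * np.sqrt(1.0 - phi * phi)
    u0 = rng.standard_normal()
    u, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * u0]))
    return u


def gen_switching_energy(spec: SwitchingSpec) -> tuple[EnergyTrajectory, dict]:
    """Generate one replicate of the Markov-switching AR(1) energy process.

    The truth record carries the stationary occupancies, the
    occupancy-weighted within-state variance Σ_c π_c σ_c², the
    between-cluster variance Σ_c π_c (μ_c − μ̄)² and their sum (the
    law-of-total-variance total), plus the empirical frame occupancies.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _simulate_chain(spec.transition, spec.n_frames, rng)
    u = _standard_ar1(spec.n_frames, spec.ar1_phi, rng)
    means = np.asarray(spec.means)
    sds = np.sqrt(np.asarray(spec.variances))
    energies = means[labels] + sds[labels] * u
    times = np.arange(spec.n_frames) * spec.time_step_ps
    traj = EnergyTrajectory(
        times=times,
        energies=energies,
        temperature=spec.temperature_K,
        cluster_labels=labels,
        replicate_id=f"seed{spec.seed}",
    )
    pi = spec.stationary()
    mu_bar = float(pi @ means)
    within = float(pi @ np.asarray(spec.variances))
    between = float(pi @ (means - mu_bar) ** 2)
    counts = np.bincount(labels, minlength=spec.n_clusters)
    truth = {
        "stationary_occupancy": pi,
        "empirical_occupancy": counts / spec.n_frames,
        "within_variance": within,
        "between_variance": between,
        "total_variance": within + between,
        "ar1_phi": spec.ar1_phi,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# region decompositions
# ---------------------------------------------------------------------------

def gen_region_energies(
    spec: SwitchingSpec,
    region_names: Sequence[str],
    covariance: np.ndarray,
    region_means: Optional[np.ndarray] = None,
) -> tuple[EnergyTrajectory, dict]:
    """Region energy streams summing to a total with a known covariance.

    Regions are correlated AR(1) Gaussian streams with stationary
    cross-covariance ``covariance`` (positive semi-definite, (R, R)); the
    hidden Markov chain of ``spec`` shifts per-cluster region means
    (``region_means``: (k, R), default splits the cluster means equally).
    The total column is the exact sum of region columns, so its
    within-cluster variance is 1ᵀΣ1 — the spec's cluster variances are
    ignored in favour of Σ (recorded in the truth record).
    """
    names = list(region_names)
    Rn = len(names)
    Sigma = np.asarray(covariance, dtype=float)
    if Sigma.shape != (Rn, Rn):
        raise ValueError("covariance must be (n_regions, n_regions)")
    if not np.allclose(Sigma, Sigma.T):
        raise ValueError("covariance must be symmetric")
    evals = np.linalg.eigvalsh(Sigma)
    if evals.min() < -1e-10 * max(1.0, evals.max()):
        raise ValueError("covariance must be positive semi-definite")
    k = spec.n_clusters
    if region_means is None:
        region_means = np.tile(
            np.asarray(spec.means)[:, None] / Rn, (1, Rn)
        )
    region_means = np.asarray(region_means, dtype=float)
    if region_means.shape != (k, Rn):
        raise ValueError("region_means must be (n_clusters, n_regions)")

    rng = np.random.default_rng(spec.seed)
    labels = _simulate_chain(spec.transition, spec.n_frames, rng)
    # correlated AR(1): u_t = phi*u_{t-1} + w_t, w ~ MVN(0, (1-phi^2)Σ)
    evalsc, evecs = np.linalg.eigh(Sigma)
    L = evecs @ np.diag(np.sqrt(np.clip(evalsc, 0.0, None)))
    z = rng.standard_normal((spec.n_frames, Rn))
    phi = spec.ar1_phi
    if phi == 0.0:
        u = z @ L.T
    else:
        w = z @ L.T * np.sqrt(1.0 - phi * phi)
        u0 = rng.standard_normal(Rn) @ L.T
        u = np.empty_like(w)
        for r in range(Rn):
            u[:, r], _ = lfilter(
                [1.0], [1.0, -phi], w[:, r], zi=np.array([phi * u0[r]])
            )
    region_cols = region_means[labels] + u
    total = region_cols.sum(axis=1)
    times = np.arange(spec.n_frames) * spec.time_step_ps
    traj = EnergyTrajectory(
        times=times,
        energies=total,
        temperature=spec.temperature_K,
        cluster_labels=labels,
        region_energies={n: region_cols[:, i] for i, n in enumerate(names)},
        replicate_id=f"seed{spec.seed}",
    )
    truth = {
        "covariance": Sigma,
        "region_within_variance": {n: float(Sigma[i, i]) for i, n in enumerate(names)},
        "total_within_variance": float(Sigma.sum()),
        "cross_covariance_sum": float(Sigma.sum() - np.trace(Sigma)),
        "region_means": region_means,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# toy coordinate trajectories
# ---------------------------------------------------------------------------

def gen_toy_trajectory(
    reference: np.ndarray,
    basin_displacements: np.ndarray,
    jitter_sd: np.ndarray | float,
    switching: SwitchingSpec,
    seed: int = 0,
    rigid_motion: bool = True,
) -> tuple[CoordinateTrajectory, np.ndarray]:
    """Toy Cα trajectory with basin structure and rigid-motion contamination.

    Each frame is the reference plus the active basin's displacement plus
    isotropic Gaussian jitter (per-residue sd), then — by default — an
    arbitrary random rotation/translation, so downstream analyses must
    superpose before measuring anything. Returns the trajectory and the true
    per-frame basin labels.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference must be (N, 3)")
    disp = np.asarray(basin_displacements, dtype=float)
    if disp.ndim != 3 or disp.shape[1:] != ref.shape:
        raise ValueError("basin_displacements must be (n_basins, N, 3)")
    n_basins = disp.shape[0]
    if n_basins != switching.n_clusters:
        raise ValueError("one basin per switching cluster required")
    sd = np.broadcast_to(np.asarray(jitter_sd, dtype=float), (ref.shape[0],))
    if np.any(sd < 0):
        raise ValueError("jitter sds must be non-negative")
    rng = np.random.default_rng(seed)
    labels = _simulate_chain(switching.transition, switching.n_frames, rng)
    F, N = switching.n_frames, ref.shape[0]
    frames = ref[None] + disp[labels]
    frames = frames + rng.standard_normal((F, N, 3)) * sd[None, :, None]
    if rigid_motion:
        rots = Rotation.random(F, random_state=rng).as_matrix()
        trans = rng.uniform(-20.0, 20.0, size=(F, 3))
        frames = np.einsum("fij,fnj->fni", rots, frames) + trans[:, None, :]
    traj = CoordinateTrajectory(
        frames=frames,
        atom_names=np.array(["CA"] * N),
        residue_ids=np.arange(1, N + 1),
        chain_ids=np.array(["A"] * N),
        time_step_ps=switching.time_step_ps,
    )
    return traj, labels


# ---------------------------------------------------------------------------
# presets: full two-state experiments
# ---------------------------------------------------------------------------

def gen_state_ensemble(
    base_spec: SwitchingSpec,
    n_replicates: int,
    state: str,
    seed: int,
    burn_in_fraction: float = 0.1,
) -> StateEnsemble:
    """Independent replicate trajectories from one switching specification."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_replicates) >> np.uint32(1)]
    trajs = []
    for i, s in enumerate(seeds):
        spec_i = SwitchingSpec(
            means=base_spec.means,
            variances=base_spec.variances,
            transition=base_spec.transition,
            ar1_phi=base_spec.ar1_phi,
            n_frames=base_spec.n_frames,
            time_step_ps=base_spec.time_step_ps,
            temperature_K=base_spec.temperature_K,
            seed=s,
        )
        traj, _ = gen_switching_energy(spec_i)
        traj.state = state
        traj.replicate_id = f"{state}_{i}"
        trajs.append(traj)
    return StateEnsemble(trajectories=trajs, burn_in_fraction=burn_in_fraction)


# Within-state variance levels for the MalL-like preset. The TSA level sits
# exactly -10.0 * R * 320^2 (kJ/mol)^2 below the reactant level, so the true
# within-state dCp is -10.0 kJ/mol/K at 320 K. Both states share dwell
# structure and a between-cluster variance of 1680 (kJ/mol)^2.
_MALL_T = 320.0
_MALL_TRUE_DCP = -10.0
_MALL_RS_WITHIN = 25000.0
_MALL_TSA_WITHIN = _MALL_RS_WITHIN + _MALL_TRUE_DCP * R_KJ * _MALL_T**2
_MALL_MEANS = (-60.0, -36.0, -12.0, 12.0, 36.0, 60.0)
_MALL_RS_VARS = (22000.0, 23500.0, 25000.0, 25000.0, 26500.0, 28000.0)
_MALL_TSA_VARS = tuple(
    v + (_MALL_TSA_WITHIN - _MALL_RS_WITHIN) for v in _MALL_RS_VARS
)


def mall_like_ensembles(
    seed: int = 0,
    n_replicates: int = 10,
    n_frames: int = 45000,
) -> tuple[StateEnsemble, StateEnsemble, dict]:
    """MalL-like two-state experiment: many substates, moving-window route.

    Six conformational clusters with equal mean dwell times of 5000 frames
    (50 ns at 10 ps/frame), AR(1) autocorrelation 0.9, 320 K, ten replicates
    of 45 000 frames per state by default (matching 10 ps snapshots over
    50–500 ns with the first 10% treated as burn-in by the consumer). The
    truth record includes the generator's within-state ΔCp‡ of −10.0
    kJ mol⁻¹ K⁻¹.
    """
    common = dict(
        dwell_frames=(5000.0,) * 6,
        ar1_phi=0.9,
        n_frames=n_frames,
        time_step_ps=10.0,
        temperature_K=_MALL_T,
    )
    rs_spec = SwitchingSpec(means=_MALL_MEANS, variances=_MALL_RS_VARS, **common)
    tsa_spec = SwitchingSpec(means=_MALL_MEANS, variances=_MALL_TSA_VARS, **common)
    rs = gen_state_ensemble(rs_spec, n_replicates, REACTANT, seed=seed)
    tsa = gen_state_ensemble(tsa_spec, n_replicates, TS_ANALOGUE, seed=seed + 7919)
    truth = {
        "temperature_K": _MALL_T,
        "true_dcp": _MALL_TRUE_DCP,
        "rs_within_variance": _MALL_RS_WITHIN,
        "tsa_within_variance": _MALL_TSA_WITHIN,
        "between_variance": float(
            np.var(np.asarray(_MALL_MEANS))  # equal occupancies
        ),
    }
    return rs, tsa, truth


_KSI_T = 300.0
_KSI_TRUE_DCP = -0.86
_KSI_RS_VARS = (1800.0, 2600.0)   # two clusters, unequal variance
_KSI_MEANS = (0.0, 25.0)


def ksi_like_ensembles(
    seed: int = 0,
    n_replicates: int = 10,
    n_frames: int = 45000,
) -> tuple[StateEnsemble, StateEnsemble, dict]:
    """KSI-like two-state experiment: two clusters, cluster-weighted route.

    Two conformational clusters (70/30 stationary occupancy) at 300 K; the
    TSA cluster variances are shifted so the occupancy-weighted within-state
    variance difference equals −0.86·R·300² (kJ/mol)², i.e. a true ΔCp‡ of
    −0.86 kJ mol⁻¹ K⁻¹.
    """
    dwell = (7000.0, 3000.0)     # -> stationary occupancy 0.7 / 0.3
    pi = np.array([0.7, 0.3])
    shift = _KSI_TRUE_DCP * R_KJ * _KSI_T**2
    tsa_vars = tuple(v + shift for v in _KSI_RS_VARS)
    common = dict(
        dwell_frames=dwell,
        ar1_phi=0.8,
        n_frames=n_frames,
        time_step_ps=10.0,
        temperature_K=_KSI_T,
    )
    rs_spec = SwitchingSpec(means=_KSI_MEANS, variances=_KSI_RS_VARS, **common)
    tsa_spec = SwitchingSpec(means=_KSI_MEANS, variances=tsa_vars, **common)
    rs = gen_state_ensemble(rs_spec, n_replicates, REACTANT, seed=seed)
    tsa = gen_state_ensemble(tsa_spec, n_replicates, TS_ANALOGUE, seed=seed + 104729)
    truth = {
        "temperature_K": _KSI_T,
        "true_dcp": _KSI_TRUE_DCP,
        "rs_within_variance": float(pi @ np.asarray(_KSI_RS_VARS)),
        "tsa_within_variance": float(pi @ np.asarray(tsa_vars)),
    }
    return rs, tsa, truth
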
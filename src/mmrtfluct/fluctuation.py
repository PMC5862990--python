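"""Heat capacities and ΔCp‡ from enthalpy fluctuations.

At equilibrium the heat capacity of an ensemble follows from the variance of
its enthalpy, Cp = ⟨δH²⟩/(R·T²) for molar energies, and the activation heat
capacity change is the difference between the transition-state-analogue and
reactant-state ensembles::

    ΔCp‡ = (⟨δH²⟩_TSA − ⟨δH²⟩_RS) / (R·T²)

Naive variances are inflated by switching between conformational substates.
Two protocols suppress that inflation:

* **cluster-weighted**: per-cluster variances averaged with cluster
  occupancies as weights (appropriate when a small number of well-defined
  clusters is known);
* **moving-window**: mean of variances over fixed-length windows slid along
  the trajectory, independent of any clustering; windows shorter than the
  substate dwell time exclude between-substate contributions.

Replicate trajectories are aggregated as mean ± across-replicate standard
deviation; state uncertainties combine in quadrature for ΔCp‡.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import R_KJ

__all__ = [
    "EnergyTrajectory",
    "StateEnsemble",
    "CpEstimate",
    "StateVariance",
    "WindowScan",
    "variance_cp",
    "cluster_weighted_variance",
    "moving_window_variance",
    "state_variance",
    "delta_cp",
    "window_scan",
    "partial_cp",
    "energy_histogram",
]

REACTANT = "reactant"
TS_ANALOGUE = "ts_analogue"


class InsufficientDataError(ValueError):
    pass


class DegenerateClusterError(ValueError):
    pass


@dataclass
class EnergyTrajectory:
    """One replicate's enthalpy time series.

    Energies are molar (kJ mol⁻¹) potential energies used as a proxy for the
    system enthalpy; frames are uniformly spaced in time. Optional per-region
    energy columns support partial-ΔCp‡ analysis and optional cluster labels
    support the cluster-weighted protocol.
    """

    times: np.ndarray            # ps, uniform spacing
    energies: np.ndarray         # kJ/mol, "total" column
    temperature: float           # K of the generating ensemble
    state: str = REACTANT
    replicate_id: str = "r0"
    region_energies: dict[str, np.ndarray] = field(default_factory=dict)
    cluster_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.shape != self.energies.shape:
            raise ValueError("times and energies must have equal length")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.times.size > 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time step must be uniform")
        for name, col in self.region_energies.items():
            col = np.asarray(col, dtype=float)
            if col.shape != self.energies.shape:
                raise ValueError(f"region column {name!r} misaligned with frames")
            self.region_energies[name] = col
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)
            if self.cluster_labels.shape != self.energies.shape:
                raise ValueError("cluster labels must cover every frame")

    @property
    def time_step_ps(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least 2 frames for a time step")
        return float(self.times[1] - self.times[0])

    def column(self, region: str) -> np.ndarray:
        """Energy column for ``region`` ('total' selects the main series)."""
        if region == "total":
            return self.energies
        if region not in self.region_energies:
            raise KeyError(
                f"replicate {self.replicate_id!r} has no region column "
                f"{region!r}; available: {sorted(self.region_energies)}"
            )
        return self.region_energies[region]


@dataclass
class StateEnsemble:
    """Replicate trajectories sharing a thermodynamic state and temperature."""

    trajectories: list[EnergyTrajectory]
    burn_in_fraction: float = 0.1

    def __post_init__(self) -> None:
        if len(self.trajectories) < 1:
            raise ValueError("ensemble needs at least one trajectory")
        temps = {t.temperature for t in self.trajectories}
        if len(temps) > 1:
            raise ValueError(f"mixed temperatures in ensemble: {sorted(temps)}")
        states = {t.state for t in self.trajectories}
        if len(states) > 1:
            raise ValueError(f"mixed states in ensemble: {sorted(states)}")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")

    @property
    def temperature(self) -> float:
        return self.trajectories[0].temperature

    @property
    def state(self) -> str:
        return self.trajectories[0].state

    def equilibrated(self, region: str = "total") -> list[np.ndarray]:
        """Post-burn-in energy columns, one array per replicate."""
        out = []
        for t in self.trajectories:
            x = t.column(region)
            start = int(np.floor(self.burn_in_fraction * x.size))
            y = x[start:]
            if y.size == 0:
                raise InsufficientDataError(
                    f"replicate {t.replicate_id!r} empty after burn-in"
                )
            out.append(y)
        return out

    def equilibrated_labels(self) -> list[np.ndarray]:
        out = []
        for t in self.trajectories:
            if t.cluster_labels is None:
                raise ValueError(
                    f"replicate {t.replicate_id!r} carries no cluster labels"
                )
            start = int(np.floor(self.burn_in_fraction * t.cluster_labels.size))
            out.append(t.cluster_labels[start:])
        return out


@dataclass
class CpEstimate:
    """A heat capacity (or ΔCp‡) value with uncertainty and provenance."""

    value: float                 # kJ/mol/K
    sd: float                    # kJ/mol/K
    temperature: float           # K
    method: str = "plain"
    n_replicates: int = 1
    region: str = "total"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class StateVariance:
    """Per-replicate enthalpy variances for one state, with the aggregate."""

    per_replicate: np.ndarray    # (kJ/mol)^2
    mean: float
    sd: float                    # across-replicate sd ("cumulative sd")
    temperature: float
    state: str
    method: str
    region: str = "total"

    @property
    def n_replicates(self) -> int:
        return int(self.per_replicate.size)


@dataclass
class WindowScan:
    """ΔCp‡ as a function of moving-window length, with plateau detection."""

    windows_ns: np.ndarray
    delta_cp: np.ndarray         # kJ/mol/K per window
    sd: np.ndarray
    plateau_value: Optional[float]
    plateau_range: Optional[tuple[float, float]]  # (ns, ns)
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_ns": self.windows_ns,
                "delta_cp": self.delta_cp,
                "sd": self.sd,
            }
        )


# ---------------------------------------------------------------------------
# variance primitives
# ---------------------------------------------------------------------------

def variance_cp(energies, T: float) -> CpEstimate:
    """Heat capacity from the enthalpy variance: Cp = Var(H)/(R·T²).

    Uses the unbiased (n−1) sample variance; the reported sd is the
    Gaussian-theory sampling error of the variance, Var·√(2/(n−1)), scaled
    by the same denominator.
    """
    x = np.asarray(energies, dtype=float)
    if T <= 0:
        raise ValueError("temperature must be positive")
    if x.size < 2:
        raise InsufficientDataError("need at least 2 samples for a variance")
    var = float(np.var(x, ddof=1))
    denom = R_KJ * T**2
    return CpEstimate(
        value=var / denom,
        sd=var * np.sqrt(2.0 / (x.size - 1)) / denom,
        temperature=T,
        method="plain",
    )


def cluster_weighted_variance(
    energies, labels, ddof: int = 1
) -> tuple[float, pd.DataFrame]:
    """Occupancy-weighted within-cluster variance, Σ_c f_c·Var_c.

    Removes the between-cluster (substate-switching) contribution that
    inflates the plain variance; by the law of total variance (ddof=0
    convention on every term),

        Var(H) = Σ_c f_c·Var_c(H) + Σ_c f_c·(μ_c − μ̄)².

    Returns the weighted variance and a per-cluster table with occupancy (%),
    mean and variance.
    """
    x = np.asarray(energies, dtype=float)
    lab = np.asarray(labels)
    if x.shape != lab.shape:
        raise ValueError("labels must align with energies")
    rows = []
    total = 0.0
    for c in np.unique(lab):
        sel = x[lab == c]
        if sel.size < int(2):
            raise DegenerateClusterError(
                f"cluster {c!r} has {sel.size} frame(s); need >= 2"
            )
        f = sel.size / x.size
        v = float(np.var(sel, ddof=ddof))
        total += f * v
        rows.append(
            {
                "cluster": c,
                "occupancy_pct": 100.0 * f,
                "mean": float(sel.mean()),
                "variance": v,
                "n_frames": sel.size,
            }
        )
    return total, pd.DataFrame(rows)


def moving_window_variance(energies, window: int, stride: int = 0) -> float:
    """Mean unbiased variance over windows slid along the trajectory.

    Windows start at multiples of ``stride`` (default window//10, at least
    one frame) and have fixed length ``window``; the final partial window is
    dropped. For ``window == len(energies)`` this is exactly the plain
    sample variance.
    """
    x = np.asarray(energies, dtype=float)
    n = x.size
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    if window > n:
        raise ValueError(f"window ({window}) exceeds trajectory length ({n})")
    if stride <= 0:
        stride = max(1, window // 10)
    # centre for numerical stability of the cumulative-sum formulation
    x = x - x.mean()
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(0, n - window + 1, stride)
    s1 = c1[starts + window] - c1[starts]
    s2 = c2[starts + window] - c2[starts]
    variances = (s2 - s1 * s1 / window) / (window - 1)
    return float(variances.mean())


# ---------------------------------------------------------------------------
# ensemble-level estimators
# ---------------------------------------------------------------------------

def _replicate_variance(
    x: np.ndarray,
    method: str,
    labels: Optional[np.ndarray],
    window: int,
    stride: int,
    ddof: int,
) -> float:
    if method == "plain":
        return float(np.var(x, ddof=1))
    if method == "cluster_weighted":
        if labels is None:
            raise ValueError("cluster_weighted requires cluster labels")
        v, _ = cluster_weighted_variance(x, labels, ddof=ddof)
        return v
    if method == "moving_window":
        return moving_window_variance(x, window=window, stride=stride)
    raise ValueError(f"unknown method {method!r}")


def state_variance(
    ensemble: StateEnsemble,
    method: str = "plain",
    region: str = "total",
    window: int = 0,
    stride: int = 0,
    ddof: int = 1,
) -> StateVariance:
    """Per-replicate enthalpy variances and their across-replicate aggregate.

    ``method`` is one of ``plain``, ``cluster_weighted`` (labels required on
    every replicate) or ``moving_window`` (``window`` in frames required).
    Burn-in is applied before anything else. The aggregate sd — the
    "cumulative standard deviation" of the state — is the standard deviation
    of the per-replicate variances (ddof=1 when more than one replicate).
    """
    series = ensemble.equilibrated(region)
    labels = (
        ensemble.equilibrated_labels() if method == "cluster_weighted" else
        [None] * len(series)
    )
    per_rep = np.array(
        [
            _replicate_variance(x, method, lab, window, stride, ddof)
            for x, lab in zip(series, labels)
        ]
    )
    sd = float(np.std(per_rep, ddof=1)) if per_rep.size > 1 else 0.0
    tag = method if method != "moving_window" else f"moving_window({window},{stride})"
    return StateVariance(
        per_replicate=per_rep,
        mean=float(per_rep.mean()),
        sd=sd,
        temperature=ensemble.temperature,
        state=ensemble.state,
        method=tag,
        region=region,
    )


def delta_cp(
    reactant: StateVariance,
    ts_analogue: StateVariance,
    T: Optional[float] = None,
) -> CpEstimate:
    """ΔCp‡ from two state variances: (V_TSA − V_RS)/(R·T²).

    State uncertainties combine in quadrature. Both states must share the
    analysis temperature.
    """
    if reactant.temperature != ts_analogue.temperature:
        raise ValueError(
            f"temperature mismatch: {reactant.temperature} K vs "
            f"{ts_analogue.temperature} K"
        )
    if T is None:
        T = reactant.temperature
    elif T != reactant.temperature:
        raise ValueError("requested T differs from the ensemble temperature")
    denom = R_KJ * T**2
    region = reactant.region
    return CpEstimate(
        value=(ts_analogue.mean - reactant.mean) / denom,
        sd=float(np.hypot(reactant.sd, ts_analogue.sd)) / denom,
        temperature=T,
        method=reactant.method,
        n_replicates=min(reactant.n_replicates, ts_analogue.n_replicates),
        region=region,
    )


def _detect_plateau(
    windows: np.ndarray, values: np.ndarray, rel_tol: float = 0.05
) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    """Plateau = maximal run of ≥3 consecutive points pairwise within rel_tol.

    Relative differences are measured against the largest magnitude in each
    triple; when several runs qualify, the one ending at the largest window
    wins (convergence is expected at long windows).
    """
    n = values.size
    ok = np.zeros(n, dtype=bool)  # ok[i]: triple (i, i+1, i+2) coheres
    for i in range(n - 2):
        trip = values[i : i + 3]
        scale = np.max(np.abs(trip))
        if scale == 0:
            ok[i] = True
        else:
            ok[i] = (trip.max() - trip.min()) / scale < rel_tol
    best = None
    i = 0
    while i < n - 2:
        if ok[i]:
            j = i
            while j + 1 < n - 2 and ok[j + 1]:
                j += 1
            best = (i, j + 2)  # indices of the run's windows
            i = j + 1
        i += 1
    if best is None:
        return None, None
    lo, hi = best
    return float(values[lo : hi + 1].mean()), (
        float(windows[lo]),
        float(windows[hi]),
    )


def window_scan(
    reactant: StateEnsemble,
    ts_analogue: StateEnsemble,
    windows_ns: Sequence[float],
    stride: int = 0,
    region: str = "total",
    plateau_rel_tol: float = 0.05,
) -> WindowScan:
    """ΔCp‡ versus moving-window length, with plateau detection.

    ``windows_ns`` (strictly increasing) are converted to frames using each
    ensemble's time step; the default stride is window/10. A plateau is
    declared when three consecutive scan points agree pairwise within
    ``plateau_rel_tol`` (relative); the plateau value is the mean ΔCp‡ over
    the detected run. Absence of a plateau is reported, not raised.
    """
    w = np.asarray(windows_ns, dtype=float)
    if w.size < 1 or np.any(np.diff(w) <= 0):
        raise ValueError("windows must be strictly increasing and non-empty")
    dt_ps = reactant.trajectories[0].time_step_ps
    values, sds = [], []
    for win_ns in w:
        frames = int(round(win_ns * 1000.0 / dt_ps))
        vr = state_variance(
            reactant, "moving_window", region=region, window=frames, stride=stride
        )
        vt = state_variance(
            ts_analogue, "moving_window", region=region, window=frames, stride=stride
        )
        est = delta_cp(vr, vt)
        values.append(est.value)
        sds.append(est.sd)
    values = np.asarray(values)
    sds = np.asarray(sds)
    plateau_value, plateau_range = _detect_plateau(w, values, plateau_rel_tol)
    return WindowScan(
        windows_ns=w,
        delta_cp=values,
        sd=sds,
        plateau_value=plateau_value,
        plateau_range=plateau_range,
        temperature=reactant.temperature,
    )


def partial_cp(
    reactant: StateEnsemble,
    ts_analogue: StateEnsemble,
    region: str,
    method: str = "plain",
    window: int = 0,
    stride: int = 0,
) -> CpEstimate:
    """Partial ΔCp‡ from a named region's energy column.

    Uses the same variance machinery as the total; because inter-region
    interaction energy is excluded, partial values need not sum to the total
    (the deficit equals twice the inter-region covariance term over R·T²).
    """
    for ens in (reactant, ts_analogue):
        for t in ens.trajectories:
            t.column(region)  # raises KeyError with a useful message
    vr = state_variance(reactant, method, region=region, window=window, stride=stride)
    vt = state_variance(ts_analogue, method, region=region, window=window, stride=stride)
    est = delta_cp(vr, vt)
    est.region = region
    return est


def energy_histogram(
    ensemble: StateEnsemble, bins: int | np.ndarray = 50, region: str = "total"
) -> dict:
    """Per-replicate and pooled (frame-weighted) energy histograms.

    Bin edges are shared across replicates (computed on the pooled range);
    densities are normalised so each histogram integrates to 1. The pooled
    histogram equals the frame-weighted mean of replicate histograms, which
    for equal-length replicates is the histogram of the concatenated data.
    """
    series = ensemble.equilibrated(region)
    pooled = np.concatenate(series)
    edges = np.histogram_bin_edges(pooled, bins=bins)
    per_rep = np.stack(
        [np.histogram(x, bins=edges, density=True)[0] for x in series]
    )
    weights = np.array([x.size for x in series], dtype=float)
    weights /= weights.sum()
    pooled_hist = (per_rep * weights[:, None]).sum(axis=0)
    return {
        "bin_edges": edges,
        "per_replicate": per_rep,
        "pooled": pooled_hist,
        "replicate_ids": [t.replicate_id for t in ensemble.trajectories],
    }
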
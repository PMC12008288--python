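"""Minimum control energy for BOLD state transitions.

The brain is modelled as a linear time-invariant network system

    dx/dt = A x(t) + B u(t)

with ``A`` the stabilized structural connectome and ``B = diag(v)`` a
diagonal control strategy assigning each region its input authority
(uniform ``v = 1`` except in the pharmacological simulation).  For a
transition from state ``x0`` to ``xf`` over a time horizon ``T`` the
unique input minimizing ``int_0^T u(t)' u(t) dt`` is

    u*(t) = B' exp(A'(T-t)) W_T^{-1} (xf - exp(A T) x0)

where ``W_T = int_0^T exp(A s) B B' exp(A' s) ds`` is the controllability
Gramian.  Regional energy is ``E_i = int_0^T u_i*(t)^2 dt`` and the
global minimum energy is both ``sum_i E_i`` and, in closed form,
``d' W_T^{-1} d`` with ``d = xf - exp(A T) x0``.

The Gramian is evaluated with Van Loan's block matrix-exponential
identity (one exponential of a 2N x 2N block matrix); the trajectory
integral uses composite Simpson quadrature on a uniform grid whose
matrix propagators ``exp(A'(T - t_k))`` are precomputed once per system
and shared across all transitions and subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .connectome import ALL_NETWORKS, StructuralConnectome, SystemMatrix
from .states import StateSeries

__all__ = [
    "ControlConfig",
    "ControlSchedule",
    "EnergyProfile",
    "controllability_gramian",
    "min_energy_transition",
    "min_energy_closed_form",
    "energy_timeseries",
    "windowed_mean",
]

logger = logging.getLogger(__name__)

_COND_WARN = 1e12


@dataclass(frozen=True)
class ControlConfig:
    """Numerical configuration of the energy computation.

    ``time_horizon`` is the duration T allotted to every transition
    (dimensionless, in units of the stabilized dynamics; T = 1 throughout
    the analyses).  ``integration_steps`` is the size of the uniform grid
    used for the trapezoidal trajectory integral.
    """

    time_horizon: float = 1.0
    integration_steps: int = 1001

    def __post_init__(self) -> None:
        if self.time_horizon <= 0:
            raise ValueError("time_horizon must be positive")
        if self.integration_steps < 3 or self.integration_steps % 2 == 0:
            raise ValueError("integration_steps must be odd and >= 3")


@dataclass(frozen=True)
class ControlSchedule:
    """Per-transition diagonal control weights: column k is diag(B) for transition k."""

    v: np.ndarray
    uniform: bool = False

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.v, dtype=float))
        if np.any(v <= 0):
            raise ValueError("control weights must be strictly positive")
        is_ones = bool(np.all(v == 1.0))
        if self.uniform and not is_ones:
            raise ValueError("uniform schedule must be all ones")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "uniform", is_ones)

    @classmethod
    def make_uniform(cls, n_regions: int, n_transitions: int) -> "ControlSchedule":
        return cls(np.ones((n_regions, n_transitions)), uniform=True)

    @property
    def n_transitions(self) -> int:
        return self.v.shape[1]


@dataclass(frozen=True)
class EnergyProfile:
    """Control energy time-series at regional, global, and network level."""

    regional: np.ndarray          # N x K, per-region energy per transition
    tr_seconds: float = 2.0
    injection_transition: int = 0
    subject_id: str = ""
    condition: str = "placebo"
    network_names: tuple[str, ...] = ()
    network: np.ndarray | None = None   # len(network_names) x K

    def __post_init__(self) -> None:
        r = np.asarray(self.regional, dtype=float)
        if np.any(r < -1e-12):
            raise ValueError("negative regional energy")
        object.__setattr__(self, "regional", np.maximum(r, 0.0))
        if self.network is not None:
            net = np.asarray(self.network, dtype=float)
            if net.shape != (len(self.network_names), r.shape[1]):
                raise ValueError("network matrix shape mismatch")
            tot = net.sum(axis=0)
            if not np.allclose(tot, self.global_, rtol=1e-9, atol=1e-12):
                raise ValueError("network energies do not sum to global energy")
            object.__setattr__(self, "network", net)

    @property
    def global_(self) -> np.ndarray:
        """Global energy per transition: the column sums of the regional matrix."""
        return self.regional.sum(axis=0)

    @property
    def n_transitions(self) -> int:
        return self.regional.shape[1]

    def to_files(self, prefix: str | Path) -> None:
        import json

        prefix = Path(prefix)
        pd.DataFrame(self.regional).to_csv(
            prefix.with_suffix(".tsv"), sep="\t", header=False, index=False
        )
        meta = {
            "tr_seconds": self.tr_seconds,
            "injection_transition": int(self.injection_transition),
            "subject_id": self.subject_id,
            "condition": self.condition,
            "network_names": list(self.network_names),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _as_matrix(A_s: SystemMatrix | np.ndarray) -> np.ndarray:
    return A_s.A_s if isinstance(A_s, SystemMatrix) else np.asarray(A_s, float)


def controllability_gramian(
    A_s: SystemMatrix | np.ndarray, b: np.ndarray | float, T: float = 1.0
) -> np.ndarray:
    """Finite-horizon controllability Gramian W_T for B = diag(b).

    Uses Van Loan's identity: with ``C = [[-A, B B'], [0, A']] * T``,
    ``expm(C) = [[F11, G], [0, F22]]`` and ``W_T = F22' @ G``.
    """
    a = _as_matrix(A_s)
    n = a.shape[0]
    b = np.broadcast_to(np.asarray(b, dtype=float), (n,))
    if np.any(b <= 0):
        raise ValueError("control weights must be strictly positive")
    q = np.diag(b * b)  # B B' for diagonal B
    block = np.zeros((2 * n, 2 * n))
    block[:n, :n] = -a
    block[:n, n:] = q
    block[n:, n:] = a.T
    f = scipy.linalg.expm(block * T)
    w = f[n:, n:].T @ f[:n, n:]
    w = 0.5 * (w + w.T)
    cond = np.linalg.cond(w)
    if cond > _COND_WARN:
        logger.warning(
            "Gramian condition number %.3g exceeds %.0e; proceeding with symmetric solve",
            cond, _COND_WARN,
        )
    return w


def min_energy_closed_form(
    A_s: SystemMatrix | np.ndarray,
    b: np.ndarray | float,
    x0: np.ndarray,
    xf: np.ndarray,
    T: float = 1.0,
) -> float:
    """Closed-form global minimum energy d' W_T^{-1} d."""
    a = _as_matrix(A_s)
    d = np.asarray(xf, float) - scipy.linalg.expm(a * T) @ np.asarray(x0, float)
    w = controllability_gramian(a, b, T)
    return float(d @ scipy.linalg.solve(w, d, assume_a="pos"))


class _Propagators:
    """Grid-time propagators exp(A'(T - t_k)) shared across transitions.

    Built by stable forward stepping from the identity: with
    ``E = expm(A' dt)``, ``Q_m = E^m`` and the propagator at ``t_k`` is
    ``Q_{M-1-k}``.  ``A`` is Hurwitz-stable, so repeated multiplication
    by ``E`` is contraction-dominated and well conditioned.
    """

    def __init__(self, a: np.ndarray, cfg: ControlConfig):
        m = cfg.integration_steps
        self.dt = cfg.time_horizon / (m - 1)
        step = scipy.linalg.expm(a.T * self.dt)
        n = a.shape[0]
        p = np.empty((m, n, n))
        q = np.eye(n)
        for i in range(m):
            p[m - 1 - i] = q
            if i < m - 1:
                q = q @ step
        self.p = p                       # p[k] = exp(A'(T - t_k))
        self.expm_AT = p[0].T            # exp(A T)
        # composite Simpson weights (integration_steps is odd)
        w = np.full(m, 2.0)
        w[1::2] = 4.0
        w[0] = w[-1] = 1.0
        self.quad_w = w * (self.dt / 3.0)


_PROP_CACHE: dict[tuple[int, bytes, float, int], _Propagators] = {}


def _propagators(a: np.ndarray, cfg: ControlConfig) -> _Propagators:
    key = (a.shape[0], a.tobytes(), cfg.time_horizon, cfg.integration_steps)
    prop = _PROP_CACHE.get(key)
    if prop is None:
        if len(_PROP_CACHE) > 4:   # keep the cache tiny; entries are O(M N^2)
            _PROP_CACHE.clear()
        prop = _Propagators(a, cfg)
        _PROP_CACHE[key] = prop
    return prop


def _batch_energy(
    a: np.ndarray,
    b_cols: np.ndarray,        # N x K strictly positive control weights
    x0: np.ndarray,            # N x K
    xf: np.ndarray,            # N x K
    cfg: ControlConfig,
) -> np.ndarray:
    """Regional energies (N x K) for a batch of transitions.

    Gramians are computed once per unique control-weight column and the
    grid propagators once per system; the trapezoidal accumulation runs
    over the grid with one matmul per grid point.
    """
    n, k = x0.shape
    prop = _propagators(a, cfg)
    d = xf - prop.expm_AT @ x0

    # solve W_b^{-1} d per unique schedule column
    wsol = np.empty((n, k))
    cols_by_key: dict[bytes, list[int]] = {}
    for j in range(k):
        cols_by_key.setdefault(b_cols[:, j].tobytes(), []).append(j)
    for key, cols in cols_by_key.items():
        bj = b_cols[:, cols[0]]
        w = controllability_gramian(a, bj, cfg.time_horizon)
        cho = scipy.linalg.cho_factor(w)
        idx = np.array(cols)
        wsol[:, idx] = scipy.linalg.cho_solve(cho, d[:, idx])

    # E_i = sum_m w_m * (b_i * (P_m wsol)_i)^2, chunked over grid points
    regional = np.zeros((n, k))
    b2 = b_cols * b_cols
    m = cfg.integration_steps
    chunk = max(1, int(2e7 // (n * max(k, 1))))
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        u = prop.p[start:stop] @ wsol            # (c, N, K)
        u *= u
        regional += np.tensordot(prop.quad_w[start:stop], u, axes=1) * b2
    return regional


def min_energy_transition(
    A_s: SystemMatrix | np.ndarray,
    b: np.ndarray | float,
    x0: np.ndarray,
    xf: np.ndarray,
    cfg: ControlConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Minimum control energy for a single state transition.

    Returns ``(regional, global)`` where ``regional[i]`` is the
    quadrature integral of ``u_i*(t)^2`` over the horizon and ``global``
    is the sum over regions.  The global value agrees with the closed
    form ``d' W^{-1} d`` to the resolution of the integration grid.
    """
    cfg = cfg or ControlConfig()
    a = _as_matrix(A_s)
    x0 = np.asarray(x0, float).reshape(-1)
    xf = np.asarray(xf, float).reshape(-1)
    if not (np.all(np.isfinite(x0)) and np.all(np.isfinite(xf))):
        raise ValueError("non-finite states")
    n = a.shape[0]
    b_col = np.broadcast_to(np.asarray(b, float), (n,)).reshape(n, 1)
    regional = _batch_energy(a, b_col, x0.reshape(n, 1), xf.reshape(n, 1), cfg)[:, 0]
    return regional, float(regional.sum())


def energy_timeseries(
    series: StateSeries,
    A_s: SystemMatrix | np.ndarray,
    schedule: ControlSchedule | None = None,
    cfg: ControlConfig | None = None,
    connectome: StructuralConnectome | None = None,
) -> EnergyProfile:
    """Control energy for every adjacent-volume transition of a scan.

    When ``connectome`` (with its network assignment) is given, the
    profile also carries per-network energy sums over the seven Yeo
    networks and the subcortex.
    """
    cfg = cfg or ControlConfig()
    a = _as_matrix(A_s)
    k = series.n_transitions
    if a.shape[0] != series.n_regions:
        raise ValueError("system matrix / state series region mismatch")
    if schedule is None:
        schedule = ControlSchedule.make_uniform(series.n_regions, k)
    if schedule.v.shape != (series.n_regions, k):
        raise ValueError(
            f"schedule shape {schedule.v.shape} does not match "
            f"{series.n_regions} regions x {k} transitions"
        )
    x0, xf = series.transition_pairs()
    regional = _batch_energy(a, schedule.v, x0, xf, cfg)

    network = None
    names: tuple[str, ...] = ()
    if connectome is not None and connectome.network_assignment:
        idx = connectome.network_indices()
        names = ALL_NETWORKS
        network = np.vstack([regional[idx[nm]].sum(axis=0) for nm in names])
    return EnergyProfile(
        regional=regional,
        tr_seconds=series.tr_seconds,
        injection_transition=series.injection_transition,
        subject_id=series.subject_id,
        condition=series.condition,
        network_names=names,
        network=network,
    )


def windowed_mean(
    values: np.ndarray | EnergyProfile,
    window_seconds: float = 60.0,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Non-overlapping window means on the transition grid.

    Windows hold ``window_seconds / tr_seconds`` transitions (must be an
    integer); a trailing partial window is dropped rather than averaged
    over fewer samples.  Accepts a 1-D series, a 2-D (rows x time) array,
    or an :class:`EnergyProfile` (windowed regionally).
    """
    if isinstance(values, EnergyProfile):
        tr_seconds = values.tr_seconds
        values = values.regional
    x = np.asarray(values, float)
    if window_seconds < tr_seconds:
        raise ValueError("window shorter than one TR")
    per = window_seconds / tr_seconds
    if abs(per - round(per)) > 1e-9:
        raise ValueError("window must be an integer multiple of the TR")
    per = int(round(per))
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    n_win = x.shape[1] // per
    out = x[:, : n_win * per].reshape(x.shape[0], n_win, per).mean(axis=2)
    return out[0] if one_d else out
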
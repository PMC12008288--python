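"""Synthetic study data with the statistical structure the analysis assumes.

The generator emulates the study conditions end to end so that every
pipeline stage runs and can be validated without any download: a modular
weighted connectome over generated 3-D coordinates; multi-subject
regional BOLD with temporal autocorrelation and network coupling; a drug
condition in which post-injection state amplitudes are damped in a
receptor-weighted, concentration-gated way; spatially autocorrelated
receptor maps on the cortical sphere; a signal-diversity series
inversely coupled to global energy; and a rise-and-decay intensity
rating curve.

Because un-normalized control energy scales quadratically with state
magnitude, multiplicative amplitude damping gives an analytically
predictable effect direction (drug energy below placebo post-injection,
more so in high-receptor regions), which the recovery tests exploit.
All generators are fully deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .connectome import ALL_NETWORKS, SUBCORTEX, YEO_NETWORKS, StructuralConnectome
from .regional import ReceptorMap
from .states import StateSeries

__all__ = [
    "SynthConfig",
    "gen_connectome",
    "gen_receptor_map",
    "gen_bold",
    "gen_reference_series",
    "sphere_coords",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic dataset.

    Geometry mirrors the scanning design: 116 regions (100 cortical),
    14 subjects, 840 volumes at TR = 2 s (28 min) with the injection at
    the end of the 8th minute (first post-injection volume 240).

    ``drug_effect_size`` is the peak fractional BOLD amplitude damping at
    the concentration-gate maximum; ``receptor_coupling`` is the share of
    that damping skewed by the (unit-mean) receptor map versus applied
    uniformly; ``noise_sd`` is the innovation standard deviation of the
    BOLD autoregression (a.u.).
    """

    n_regions: int = 116
    n_cortical: int = 100
    n_subjects: int = 14
    n_volumes: int = 840
    tr_seconds: float = 2.0
    injection_volume: int = 240
    drug_effect_size: float = 0.35
    receptor_coupling: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regions, self.n_subjects, self.n_volumes) <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.n_cortical <= self.n_regions:
            raise ValueError("n_cortical must lie in (0, n_regions]")
        if not 0 <= self.injection_volume < self.n_volumes:
            raise ValueError("injection_volume must lie in [0, n_volumes)")
        if self.drug_effect_size < 0:
            raise ValueError("drug_effect_size must be nonnegative")
        if not 0 <= self.receptor_coupling <= 1:
            raise ValueError("receptor_coupling must lie in [0, 1]")


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, salt])


def sphere_coords(cfg: SynthConfig) -> np.ndarray:
    """Deterministic unit-sphere centroids: cortical parcels first.

    Cortical centroids are drawn uniformly on the sphere; subcortical
    parcels get interior (non-unit) coordinates and are never spun.
    Derived purely from the seed, so the connectome and receptor-map
    generators agree on the geometry without sharing state.
    """
    rng = _rng(cfg, 101)
    pts = rng.standard_normal((cfg.n_regions, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    n_sub = cfg.n_regions - cfg.n_cortical
    if n_sub:
        pts[cfg.n_cortical:] *= 0.3     # subcortex sits centrally
    return pts


def _region_labels(cfg: SynthConfig) -> list[str]:
    labels = [f"ctx_{i:03d}" for i in range(cfg.n_cortical)]
    labels += [f"sub_{i:02d}" for i in range(cfg.n_regions - cfg.n_cortical)]
    return labels


def _network_assignment(cfg: SynthConfig) -> dict[str, str]:
    labels = _region_labels(cfg)
    assignment = {}
    for i, lab in enumerate(labels[: cfg.n_cortical]):
        assignment[lab] = YEO_NETWORKS[i % len(YEO_NETWORKS)]
    for lab in labels[cfg.n_cortical:]:
        assignment[lab] = SUBCORTEX
    return assignment


def gen_connectome(cfg: SynthConfig) -> StructuralConnectome:
    """Modular weighted connectome with distance-dependent weight decay.

    Eight modules follow the network assignment (seven Yeo networks plus
    subcortex).  Weights combine a within/between module factor, an
    exponential decay in Euclidean distance between centroids, and
    multiplicative lognormal noise; the matrix is symmetric, nonnegative
    with a zero diagonal.
    """
    if cfg.n_regions < len(ALL_NETWORKS):
        raise ValueError("fewer regions than modules")
    rng = _rng(cfg, 202)
    coords = sphere_coords(cfg)
    assignment = _network_assignment(cfg)
    labels = _region_labels(cfg)
    nets = np.array([assignment[lab] for lab in labels])

    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    same = nets[:, None] == nets[None, :]
    base = np.where(same, 3.0, 1.0) * np.exp(-dist / 1.0)
    noise = np.exp(0.4 * rng.standard_normal((cfg.n_regions, cfg.n_regions)))
    w = base * noise
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return StructuralConnectome(w, tuple(labels), assignment)


def gen_receptor_map(
    cfg: SynthConfig,
    smoothness: float = 0.6,
    receptor_name: str = "5-HT2a",
    salt: int = 303,
) -> tuple[ReceptorMap, np.ndarray]:
    """Spatially autocorrelated receptor density map plus sphere coordinates.

    The cortical field is a Gaussian process on the sphere with a
    squared-exponential kernel in chordal distance (length scale
    ``smoothness``), mapped through ``exp`` to positive densities;
    subcortical densities are drawn independently.  ``smoothness -> 0``
    approaches an iid map.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be nonnegative")
    rng = _rng(cfg, salt)
    coords = sphere_coords(cfg)
    ctx = coords[: cfg.n_cortical]
    d = np.linalg.norm(ctx[:, None, :] - ctx[None, :, :], axis=2)
    if smoothness > 0:
        cov = np.exp(-(d * d) / (2.0 * smoothness * smoothness))
    else:
        cov = np.eye(cfg.n_cortical)
    cov += 1e-8 * np.eye(cfg.n_cortical)
    z = scipy.linalg.cholesky(cov, lower=True) @ rng.standard_normal(cfg.n_cortical)
    density = np.empty(cfg.n_regions)
    density[: cfg.n_cortical] = np.exp(0.5 * z)
    n_sub = cfg.n_regions - cfg.n_cortical
    density[cfg.n_cortical:] = np.exp(0.5 * rng.standard_normal(n_sub))
    mask = np.zeros(cfg.n_regions, dtype=bool)
    mask[: cfg.n_cortical] = True
    return ReceptorMap(density, receptor_name, mask), coords


def concentration_gate(cfg: SynthConfig) -> np.ndarray:
    """Rise-and-decay gate g(t) on the volume grid, peak-normalized to 1.

    A difference of exponentials matching the effect-compartment shape
    (rise ~50 s, decay ~330 s), zero before the injection.
    """
    t = (np.arange(cfg.n_volumes) - cfg.injection_volume) * cfg.tr_seconds
    g = np.where(t >= 0, np.exp(-t / 330.0) - np.exp(-t / 50.0), 0.0)
    peak = g.max()
    return g / peak if peak > 0 else g


def gen_bold(
    cfg: SynthConfig,
    connectome: StructuralConnectome | None = None,
    rmap: ReceptorMap | None = None,
) -> tuple[list[StateSeries], list[StateSeries]]:
    """Per-subject BOLD state series for both conditions.

    Placebo follows a network-coupled first-order autoregression
    ``x_{t+1} = r (0.7 I + 0.3 What) x_t + eps`` with ``What`` the
    spectrally normalized connectome, ``r = 0.6`` and Gaussian
    innovations of ``noise_sd``.  The drug condition shares the placebo
    noise realization and applies the post-injection amplitude scale

        s_i(t) = 1 - beta_s * g(t) * (gamma * rho~_i + (1 - gamma))

    with the unit-maximum receptor map ``rho~``, the concentration-like gate
    ``g`` and a per-subject lognormal random effect on ``beta``.
    Returns ``(drug_series, placebo_series)``.
    """
    connectome = connectome or gen_connectome(cfg)
    if rmap is None:
        rmap, _ = gen_receptor_map(cfg)
    rng = _rng(cfg, 404)
    n, v = cfg.n_regions, cfg.n_volumes

    w_hat = connectome.weights / np.max(np.linalg.eigvalsh(connectome.weights))
    m = 0.6 * (0.7 * np.eye(n) + 0.3 * w_hat)

    rho_n = rmap.density / rmap.density.max()   # in (0, 1]: peak damping is beta
    gate = concentration_gate(cfg)
    gamma = cfg.receptor_coupling
    weight = gamma * rho_n + (1.0 - gamma)

    beta_subj = cfg.drug_effect_size * np.exp(
        0.15 * rng.standard_normal(cfg.n_subjects) - 0.5 * 0.15**2
    )
    worst = float(beta_subj.max() * gate.max() * weight.max())
    if worst >= 1:
        raise ValueError(
            f"drug effect too strong: peak damping {worst:.2f} >= 1 would flip signs"
        )

    drug, placebo = [], []
    for s in range(cfg.n_subjects):
        x = np.empty((n, v))
        x[:, 0] = rng.standard_normal(n) * cfg.noise_sd
        eps = rng.standard_normal((n, v - 1)) * cfg.noise_sd
        for t in range(v - 1):
            x[:, t + 1] = m @ x[:, t] + eps[:, t]
        scale = 1.0 - beta_subj[s] * gate[None, :] * weight[:, None]
        meta = dict(
            tr_seconds=cfg.tr_seconds,
            injection_volume=cfg.injection_volume,
            subject_id=f"sub-{s + 1:02d}",
        )
        placebo.append(StateSeries(x, condition="placebo", **meta))
        drug.append(StateSeries(x * scale, condition="drug", **meta))
    return drug, placebo


def gen_reference_series(
    cfg: SynthConfig,
    global_energy: np.ndarray,
    diversity_offset: float = 40.0,
    diversity_slope: float = 5.0,
    diversity_noise: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Diversity and intensity references coupled to a global energy series.

    Diversity is ``offset - slope * standardized(energy) + noise`` (the
    inverse coupling the analysis is designed to detect); intensity is a
    0-10 discretized rise-and-decay curve on the per-minute grid, zero
    before the injection.  Returns ``(diversity, intensity)``.
    """
    if diversity_slope <= 0:
        raise ValueError("diversity_slope must be positive to encode inverse coupling")
    rng = _rng(cfg, 505)
    e = np.asarray(global_energy, float).ravel()
    z = (e - e.mean()) / e.std()
    diversity = diversity_offset - diversity_slope * z
    diversity = diversity + diversity_noise * rng.standard_normal(e.size)

    minutes = int(cfg.n_volumes * cfg.tr_seconds // 60)
    t_min = (np.arange(1, minutes + 1) * 60.0
             - cfg.injection_volume * cfg.tr_seconds)
    curve = np.where(t_min >= 0, np.exp(-t_min / 330.0) - np.exp(-t_min / 50.0), 0.0)
    peak = curve.max()
    intensity = np.rint(10.0 * curve / peak).astype(int) if peak > 0 else np.zeros(minutes, int)
    return diversity, np.clip(intensity, 0, 10)
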
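"""Model / Results interface tying the pipeline stages together.

Two modelling objects mirror the two inferential halves of the analysis:

:class:`ControlEnergyModel`
    built from per-subject drug and placebo BOLD state series plus a
    structural connectome; ``fit()`` computes minimum-control-energy
    time-series at regional / network / global level, contrasts the
    conditions with a cluster-based permutation test, and returns a
    :class:`ControlEnergyResults` carrying the estimates and diagnostics
    with correlation, regional-metric and dominance helpers.

:class:`PharmacoControlModel`
    built from the placebo series, the empirical drug-condition global
    energy, a simulated drug concentration curve and a receptor map;
    ``fit()`` calibrates the control-strategy scaling alpha by grid
    search and returns a :class:`PharmacoControlResults` with the fitted
    alpha, the distance profile and the predicted energy series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import regional as _regional
from . import stats as _stats
from .connectome import StructuralConnectome, SystemMatrix, stabilize
from .control import ControlConfig, EnergyProfile, energy_timeseries, windowed_mean
from .pksim import (
    ConcentrationSeries,
    DEFAULT_ALPHA_GRID,
    ScheduleSpec,
    compare_models,
    fit_alpha_grid,
)
from .regional import ReceptorMap
from .states import StateSeries, normalize_states
from .stats import SpinNullSet

__all__ = [
    "ControlEnergyModel",
    "ControlEnergyResults",
    "PharmacoControlModel",
    "PharmacoControlResults",
]


class ControlEnergyModel:
    """Minimum-control-energy contrast of drug versus placebo scans.

    Parameters
    ----------
    drug, placebo
        Per-subject :class:`StateSeries`, matched in order (paired
        design).
    connectome
        Structural connectome; stabilized internally into the dynamics
        operator (``stabilization_c`` is the margin constant).
    state_norm
        One of ``none``/``radial``/``l2``/``distance``/``double``.
    """

    def __init__(
        self,
        drug: list[StateSeries],
        placebo: list[StateSeries],
        connectome: StructuralConnectome,
        state_norm: str = "none",
        config: ControlConfig | None = None,
        stabilization_c: float = 1.0,
    ):
        if len(drug) != len(placebo) or not drug:
            raise ValueError("need matched, non-empty drug and placebo series lists")
        self.drug = [normalize_states(s, state_norm) for s in drug]
        self.placebo = [normalize_states(s, state_norm) for s in placebo]
        self.connectome = connectome
        self.state_norm = state_norm
        self.config = config or ControlConfig()
        self.system = stabilize(connectome, stabilization_c)

    @classmethod
    def from_arrays(
        cls,
        drug: np.ndarray,
        placebo: np.ndarray,
        connectome: StructuralConnectome,
        tr_seconds: float = 2.0,
        injection_volume: int = 240,
        **kwargs,
    ) -> "ControlEnergyModel":
        """Build from subjects x regions x volumes arrays."""
        mk = lambda x, cond, i: StateSeries(
            x, tr_seconds, injection_volume, f"sub-{i + 1:02d}", cond
        )
        return cls(
            [mk(x, "drug", i) for i, x in enumerate(np.asarray(drug, float))],
            [mk(x, "placebo", i) for i, x in enumerate(np.asarray(placebo, float))],
            connectome,
            **kwargs,
        )

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> "ControlEnergyResults":
        """Compute energy profiles and the condition contrast."""
        profiles = {
            "drug": tuple(
                energy_timeseries(s, self.system, cfg=self.config, connectome=self.connectome)
                for s in self.drug
            ),
            "placebo": tuple(
                energy_timeseries(s, self.system, cfg=self.config, connectome=self.connectome)
                for s in self.placebo
            ),
        }
        glob = {
            c: np.vstack([p.global_ for p in profs]) for c, profs in profiles.items()
        }
        cluster = _stats.paired_cluster_test(
            glob["drug"], glob["placebo"], alpha=alpha, n_perm=n_perm, seed=seed
        )
        return ControlEnergyResults(
            model=self,
            profiles=profiles,
            subject_global=glob,
            cluster=cluster,
        )


@dataclass
class ControlEnergyResults:
    """Fitted energy time-series, condition contrast, and analysis helpers."""

    model: ControlEnergyModel
    profiles: dict[str, tuple[EnergyProfile, ...]]
    subject_global: dict[str, np.ndarray]      # condition -> subjects x K
    cluster: _stats.ClusterResult

    @property
    def group_global(self) -> dict[str, np.ndarray]:
        return {c: g.mean(axis=0) for c, g in self.subject_global.items()}

    @property
    def injection_transition(self) -> int:
        return self.profiles["drug"][0].injection_transition

    @property
    def tr_seconds(self) -> float:
        return self.profiles["drug"][0].tr_seconds

    @property
    def frac_significant_post(self) -> float:
        """Fraction of post-injection transitions in significant clusters."""
        mask = self.cluster.significant_mask[self.injection_transition:]
        return float(mask.mean())

    def delta_global(self) -> np.ndarray:
        g = self.group_global
        return _regional.delta_series(g["drug"], g["placebo"])

    def group_regional(self, condition: str) -> np.ndarray:
        """Across-subject mean regional energy series (N x K)."""
        return np.mean([p.regional for p in self.profiles[condition]], axis=0)

    def correlate_diversity(
        self,
        delta_diversity: np.ndarray,
        n_perm: int = 10000,
        seed: int | None = None,
        covariate: np.ndarray | None = None,
    ) -> tuple[float, float]:
        """Permutation Spearman of delta energy against delta diversity."""
        return _stats.perm_spearman(
            self.delta_global(), delta_diversity, n_perm=n_perm, seed=seed,
            covariate=covariate,
        )

    def correlate_intensity(
        self,
        intensity: np.ndarray,
        n_perm: int = 10000,
        seed: int | None = None,
        covariate: np.ndarray | None = None,
    ) -> tuple[float, float]:
        """Per-minute windowed delta energy against intensity ratings."""
        windowed = windowed_mean(self.delta_global(), 60.0, self.tr_seconds)
        intensity = np.asarray(intensity, float).ravel()[: windowed.size]
        return _stats.perm_spearman(
            windowed, intensity, n_perm=n_perm, seed=seed, covariate=covariate
        )

    def regional_metrics(
        self,
        diversity: np.ndarray | None = None,
        intensity: np.ndarray | None = None,
        condition: str = "drug",
        window_minutes: float = 8.0,
    ) -> dict[str, np.ndarray]:
        """The three regional maps: post/pre change and the two couplings.

        ``window_minutes`` is clamped to the largest window available on
        both sides of the injection, keeping pre/post sample counts equal
        on short scans.
        """
        group = self.group_regional(condition)
        inj = self.injection_transition
        avail = min(inj, group.shape[1] - inj) * self.tr_seconds / 60.0
        out = {
            "post_pre_change": _regional.post_pre_change(
                group,
                injection_transition=inj,
                window_minutes=min(window_minutes, avail),
                tr_seconds=self.tr_seconds,
            )
        }
        if diversity is not None:
            out["diversity_coupling"] = _regional.regional_coupling(group, diversity)
        if intensity is not None:
            wm = windowed_mean(group, 60.0, self.tr_seconds)
            intensity = np.asarray(intensity, float).ravel()[: wm.shape[1]]
            out["intensity_coupling"] = _regional.regional_coupling(
                wm[:, : intensity.size], intensity
            )
        return out

    def receptor_association(
        self, metric: np.ndarray, rmap: ReceptorMap, nulls: SpinNullSet, **kw
    ):
        return _regional.receptor_association(metric, rmap, nulls, **kw)

    def dominance(
        self, metric: np.ndarray, receptor_maps: dict[str, ReceptorMap],
        cortical_only: bool = False,
    ) -> dict[str, float]:
        """Percent relative importance of receptor maps for one metric map."""
        maps = list(receptor_maps.values())
        metric = np.asarray(metric, float).ravel()
        if cortical_only:
            mask = maps[0].cortical_mask
            X = np.column_stack([m.density[mask] for m in maps])
            y = metric[mask]
        else:
            X = np.column_stack([m.density for m in maps])
            y = metric
        return _stats.dominance_analysis(X, y, list(receptor_maps))

    def summary(self) -> str:
        k = self.subject_global["drug"].shape
        post = self.injection_transition
        delta = self.delta_global()
        lines = [
            "Control energy condition contrast",
            "=" * 48,
            f"subjects: {k[0]}    transitions: {k[1]}    state norm: {self.model.state_norm}",
            f"time horizon T = {self.model.config.time_horizon}",
            f"mean global energy  drug: {self.group_global['drug'].mean():.4g}"
            f"    placebo: {self.group_global['placebo'].mean():.4g}",
            f"mean post-injection delta (drug - placebo): {delta[post:].mean():.4g}",
            f"significant clusters (p <= {self.cluster.alpha:g}): "
            f"{sum(1 for c in self.cluster.clusters if c[3] <= self.cluster.alpha)}",
            f"fraction of post-injection time-points significant: "
            f"{100 * self.frac_significant_post:.1f}%",
        ]
        return "\n".join(lines)

    def plot_global(self, ax=None):
        """Group-mean global energy per condition with the significant mask."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(self.subject_global["drug"].shape[1]) * self.tr_seconds / 60.0
        for cond, color in (("drug", "C3"), ("placebo", "C0")):
            ax.plot(t, self.group_global[cond], color=color, label=cond)
        sig = self.cluster.significant_mask
        if sig.any():
            ax.fill_between(t, *ax.get_ylim(), where=sig, color="0.85", zorder=0)
        ax.axvline(self.injection_transition * self.tr_seconds / 60.0, ls="--", c="k", lw=0.8)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("global control energy (a.u.)")
        ax.legend()
        return ax


class PharmacoControlModel:
    """Predict drug-condition energy from placebo data and pharmacology."""

    def __init__(
        self,
        placebo: list[StateSeries],
        empirical_drug_global: np.ndarray,
        connectome: StructuralConnectome | SystemMatrix,
        concentration: ConcentrationSeries,
        receptor_map: ReceptorMap,
        spec: ScheduleSpec | None = None,
        config: ControlConfig | None = None,
        stabilization_c: float = 1.0,
    ):
        self.placebo = placebo
        self.empirical = np.asarray(empirical_drug_global, float).ravel()
        self.system = (
            connectome if isinstance(connectome, SystemMatrix)
            else stabilize(connectome, stabilization_c)
        )
        self.concentration = concentration
        self.receptor_map = receptor_map
        self.spec = spec or ScheduleSpec(injection_volume=placebo[0].injection_volume)
        self.config = config or ControlConfig()

    def fit(self, grid: tuple[float, ...] = DEFAULT_ALPHA_GRID) -> "PharmacoControlResults":
        best, distances, sims = fit_alpha_grid(
            self.placebo, self.empirical, self.system, self.concentration,
            self.receptor_map, spec=self.spec, grid=grid, cfg=self.config,
        )
        return PharmacoControlResults(self, best, distances, sims)

    def compare_variants(self, grid: tuple[float, ...] = DEFAULT_ALPHA_GRID):
        """Best-alpha distances for the alternative schedule models."""
        return compare_models(
            self.placebo, self.empirical, self.concentration, self.receptor_map,
            self.system, spec=self.spec, grid=grid, cfg=self.config,
        )


@dataclass
class PharmacoControlResults:
    """Calibrated control-strategy scaling and the predicted energy series."""

    model: PharmacoControlModel
    alpha: float
    distances: dict[float, float] = field(repr=False)
    simulated: dict[float, np.ndarray] = field(repr=False)

    @property
    def predicted_global(self) -> np.ndarray:
        return self.simulated[self.alpha]

    def summary(self) -> str:
        lines = [
            "Pharmacologically informed control simulation",
            "=" * 48,
            f"schedule mode: {self.model.spec.mode}    "
            f"fitted alpha: {self.alpha:g}",
            "alpha grid distances (Euclidean, group-level):",
        ]
        for a in sorted(self.distances):
            star = "  <-- minimum" if a == self.alpha else ""
            lines.append(f"  alpha = {a:5g}: {self.distances[a]:.6g}{star}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(self.model.empirical.size)
        ax.plot(t, self.model.empirical, label="empirical drug", color="C3")
        ax.plot(t, self.predicted_global, label=f"simulated (alpha={self.alpha:g})",
                color="C2")
        ax.set_xlabel("transition")
        ax.set_ylabel("global control energy (a.u.)")
        ax.legend()
        return ax
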
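"""Regional and global summaries of drug effects on control energy.

Three regional metrics summarize where in the brain a drug changes the
energetics of state transitions:

1. relative post- versus pre-injection change in mean regional energy
   (equal-width windows either side of the injection);
2. the Spearman coupling of each region's energy time-series with a
   global signal-diversity series;
3. the coupling of each region's per-minute windowed energy with
   subjective intensity ratings.

Each metric is a cortical map that can be tested against PET-derived
receptor density maps with spatial-autocorrelation-preserving spin
nulls.  Global delta-series (drug minus placebo group means) feed the
corresponding whole-brain correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .control import EnergyProfile, windowed_mean
from .stats import SpinNullSet, spin_test

__all__ = [
    "ReceptorMap",
    "post_pre_change",
    "regional_coupling",
    "delta_series",
    "receptor_association",
    "halfperiod_tstats",
]

RECEPTOR_NAMES = ("5-HT2a", "5-HT1a", "5-HT1b", "5-HT4", "5-HTT")


@dataclass(frozen=True)
class ReceptorMap:
    """Regional receptor/transporter density vector (PET Bmax, a.u.)."""

    density: np.ndarray
    receptor_name: str = "5-HT2a"
    cortical_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.density, float).ravel()
        if np.any(d < 0):
            raise ValueError("receptor densities must be nonnegative")
        if self.receptor_name not in RECEPTOR_NAMES:
            raise ValueError(
                f"receptor_name must be one of {RECEPTOR_NAMES}, got {self.receptor_name!r}"
            )
        mask = self.cortical_mask
        if mask is None:
            mask = np.ones(d.size, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool).ravel()
            if mask.size != d.size:
                raise ValueError("cortical mask length mismatch")
        object.__setattr__(self, "density", d)
        object.__setattr__(self, "cortical_mask", mask)

    @property
    def n_regions(self) -> int:
        return self.density.size

    @property
    def cortical(self) -> np.ndarray:
        return self.density[self.cortical_mask]


def post_pre_change(
    profile: EnergyProfile | np.ndarray,
    injection_transition: int | None = None,
    window_minutes: float = 8.0,
    tr_seconds: float | None = None,
    relative: bool = True,
) -> np.ndarray:
    """Per-region change in mean energy after versus before injection.

    Uses equal-length windows of ``window_minutes`` immediately before
    and after the injection transition, so the same amount of data
    enters both summaries.  By default the difference is adjusted by
    (divided by) the pre-injection mean; ``relative=False`` returns the
    raw difference.
    """
    if isinstance(profile, EnergyProfile):
        regional = profile.regional
        tr_seconds = tr_seconds or profile.tr_seconds
        if injection_transition is None:
            injection_transition = profile.injection_transition
    else:
        regional = np.atleast_2d(np.asarray(profile, float))
        if tr_seconds is None or injection_transition is None:
            raise ValueError("tr_seconds and injection_transition required for raw arrays")
    w = int(round(window_minutes * 60.0 / tr_seconds))
    if injection_transition < w or injection_transition + w > regional.shape[1]:
        raise ValueError(
            f"need {w} transitions on both sides of injection "
            f"(index {injection_transition} of {regional.shape[1]})"
        )
    pre = regional[:, injection_transition - w : injection_transition].mean(axis=1)
    post = regional[:, injection_transition : injection_transition + w].mean(axis=1)
    if not relative:
        return post - pre
    if np.any(pre == 0):
        raise ValueError("zero pre-injection mean energy; relative change undefined")
    return (post - pre) / pre


def regional_coupling(
    profile: EnergyProfile | np.ndarray,
    reference: np.ndarray,
    windowed: bool = False,
    window_seconds: float = 60.0,
    tr_seconds: float | None = None,
) -> np.ndarray:
    """Spearman rho of each region's energy series with a reference series.

    With ``windowed=True`` regional energies are first averaged over
    non-overlapping windows (per-minute by default) to match the grid of
    the reference (e.g. intensity ratings); otherwise the reference must
    live on the transition grid (e.g. an HRF-aligned diversity series).
    """
    if isinstance(profile, EnergyProfile):
        regional = profile.regional
        tr_seconds = tr_seconds or profile.tr_seconds
    else:
        regional = np.atleast_2d(np.asarray(profile, float))
        if windowed and tr_seconds is None:
            raise ValueError("tr_seconds required to window raw arrays")
    if windowed:
        regional = windowed_mean(regional, window_seconds, tr_seconds)
    ref = np.asarray(reference, float).ravel()
    if ref.size != regional.shape[1]:
        raise ValueError(
            f"reference length {ref.size} does not match series length {regional.shape[1]}"
        )
    res = scipy.stats.spearmanr(regional.T, ref)
    corr = np.atleast_2d(res.statistic)
    return np.asarray(corr[:-1, -1]).ravel()


def delta_series(group_mean_drug: np.ndarray, group_mean_placebo: np.ndarray) -> np.ndarray:
    """Elementwise drug-minus-placebo difference of group-mean series."""
    a = np.asarray(group_mean_drug, float)
    b = np.asarray(group_mean_placebo, float)
    if a.shape != b.shape:
        raise ValueError("series shapes differ")
    return a - b


def receptor_association(
    metric: np.ndarray,
    rmap: ReceptorMap,
    nulls: SpinNullSet,
    include_subcortex: bool = False,
) -> tuple[float, float] | tuple[float, float, float]:
    """Correlate a regional metric map with a receptor density map.

    Cortical values are Spearman-correlated and tested against the spin
    nulls (subcortical parcels cannot be spin-permuted).  With
    ``include_subcortex=True`` the whole-brain rho is returned as a
    third element, without a p-value.
    """
    metric = np.asarray(metric, float).ravel()
    if metric.size != rmap.n_regions:
        raise ValueError("metric length does not match receptor map")
    cortical_metric = metric[rmap.cortical_mask]
    rho, p = spin_test(cortical_metric, rmap.cortical, nulls)
    if not include_subcortex:
        return rho, p
    rho_full = float(scipy.stats.spearmanr(metric, rmap.density).statistic)
    return rho, p, rho_full


def halfperiod_tstats(
    a: np.ndarray,
    b: np.ndarray,
    injection_transition: int,
    split: int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Paired t per transition plus mean t over the two post-injection halves.

    ``a`` and ``b`` are subjects x time (e.g. one network's energy under
    drug and placebo); ``split`` is the first transition of the second
    half (defaults to the midpoint of the post-injection period).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be equal-shape subjects x time arrays")
    n_time = a.shape[1]
    if not (0 <= injection_transition < n_time):
        raise ValueError("injection index out of range")
    if split is None:
        split = injection_transition + (n_time - injection_transition) // 2
    if not (injection_transition < split < n_time):
        raise ValueError("empty post-injection half")
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd == 0, 0.0, mean / (sd / np.sqrt(n)))
    return t, float(t[injection_transition:split].mean()), float(t[split:].mean())
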
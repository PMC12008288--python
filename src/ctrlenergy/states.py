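"""BOLD state sequences and the four state-normalization variants.

A brain "state" here is simply the vector of regional BOLD amplitudes at
one fMRI volume; a scan is the N x V matrix of such vectors.  Control
energy is computed for every transition between adjacent volumes, and is
sensitive to both the magnitude of the states and the distance between
them.  The normalization variants disentangle the two:

``none``
    raw amplitudes (the primary analysis).
``radial``
    the target state of every transition is rescaled along the line from
    the initial state so that the pair is unit distance apart; the
    initial state is left untouched.
``l2``
    every state is divided by its own L2 norm (magnitude removed).
``distance``
    both states of a pair are divided by their inter-state distance.
``double``
    L2 normalization of all states first, then distance normalization of
    every pair (magnitude and distance both removed).

Pairs are processed independently per transition, so under the pairwise
variants a volume is generally scaled differently in its role as the
target of transition k versus the source of transition k+1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StateSeries", "normalize_states", "load_state_series", "NORM_METHODS"]

NORM_METHODS = ("none", "radial", "l2", "distance", "double")


@dataclass(frozen=True)
class StateSeries:
    """Regional BOLD state sequence for one subject and condition.

    ``states`` is N regions x V volumes; ``injection_volume`` indexes the
    first post-injection volume.
    """

    states: np.ndarray
    tr_seconds: float = 2.0
    injection_volume: int = 0
    subject_id: str = ""
    condition: str = "placebo"
    paired: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.states, dtype=float)
        if x.ndim != 2:
            raise ValueError("states must be a 2-D regions x volumes array")
        if x.shape[1] < 2:
            raise ValueError("need at least 2 volumes")
        if self.paired and x.shape[1] % 2:
            raise ValueError("paired layout needs an even number of columns")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite entries in states")
        if not (0 <= self.injection_volume < x.shape[1]):
            raise ValueError(
                f"injection_volume {self.injection_volume} outside [0, {x.shape[1]})"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.condition not in ("drug", "placebo"):
            raise ValueError(f"condition must be 'drug' or 'placebo', got {self.condition!r}")
        object.__setattr__(self, "states", x)

    @property
    def n_regions(self) -> int:
        return self.states.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.states.shape[1]

    @property
    def n_transitions(self) -> int:
        if self.paired:
            return self.states.shape[1] // 2
        return self.states.shape[1] - 1

    def transition_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(x0, xf) arrays of shape N x K, one column per transition."""
        x = self.states
        if self.paired:
            return x[:, 0::2], x[:, 1::2]
        return x[:, :-1], x[:, 1:]

    @property
    def injection_transition(self) -> int:
        """Index of the first transition whose target volume is post-injection."""
        return max(self.injection_volume - 1, 0)

    def to_files(self, prefix: str | Path) -> None:
        """Write states as TSV plus a JSON sidecar with the metadata."""
        prefix = Path(prefix)
        pd.DataFrame(self.states).to_csv(
            prefix.with_suffix(".tsv"), sep="\t", header=False, index=False
        )
        sidecar = {
            "tr_seconds": self.tr_seconds,
            "injection_volume": int(self.injection_volume),
            "subject_id": self.subject_id,
            "condition": self.condition,
            "paired": self.paired,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_state_series(prefix: str | Path) -> StateSeries:
    """Load a state series written by :meth:`StateSeries.to_files`."""
    prefix = Path(prefix)
    x = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", header=None).to_numpy(float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return StateSeries(x, **meta)


def _pairs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return x[:, :-1], x[:, 1:]


def normalize_states(series: StateSeries, method: str = "none") -> StateSeries:
    """Apply one of the BOLD state-normalization variants.

    For the pairwise variants (radial / distance / double) the output
    series is marked ``paired`` and its ``states`` matrix has
    ``2 * (V - 1)`` columns laid out as ``[x0_0, xf_0, x0_1, xf_1, ...]``:
    the per-transition scaling breaks the chain property (a volume is no
    longer shared between adjacent transitions), so every transition
    carries its own pair of states.  ``none`` and ``l2`` preserve the
    chained N x V layout.
    """
    if method not in NORM_METHODS:
        raise ValueError(f"unknown normalization {method!r}; choose from {NORM_METHODS}")
    x = series.states
    if method == "none":
        return series

    if method == "l2":
        norms = np.linalg.norm(x, axis=0)
        if np.any(norms == 0):
            raise ValueError("zero-norm state under l2 normalization")
        return replace(series, states=x / norms)

    if method == "double":
        norms = np.linalg.norm(x, axis=0)
        if np.any(norms == 0):
            raise ValueError("zero-norm state under double normalization")
        x = x / norms

    x0, xf = _pairs(x)
    dist = np.linalg.norm(xf - x0, axis=0)
    if np.any(dist == 0):
        raise ValueError("zero inter-state distance; cannot normalize pair")

    if method == "radial":
        # rescale xf along (xf - x0) so the pair is unit distance apart
        xf = x0 + (xf - x0) / dist
    else:  # distance, double
        x0 = x0 / dist
        xf = xf / dist

    stacked = np.empty((x.shape[0], 2 * x0.shape[1]))
    stacked[:, 0::2] = x0
    stacked[:, 1::2] = xf
    return replace(series, states=stacked, paired=True)
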
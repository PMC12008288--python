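"""Structural connectome handling and stabilization into a dynamics operator.

The weighted structural connectome (streamline counts between parcels,
normalized by parcel size) is the substrate over which brain-state
transitions are modelled.  Before use in the linear time-invariant model
``dx/dt = A x + B u`` the raw nonnegative adjacency matrix must be turned
into a Hurwitz-stable operator; we use the continuous-time convention

    A_s = W / (lambda_max(W) + c) - I,      c > 0 (default 1),

which places all eigenvalues of ``A_s`` in the open left half plane:
the largest becomes ``-c / (lambda_max + c)`` and the smallest stays
above ``-2``.  The constant ``c`` controls how close the slowest mode
sits to marginal stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructuralConnectome",
    "SystemMatrix",
    "load_connectome",
    "stabilize",
]

#: Canonical network names: the seven Yeo cortical networks plus subcortex.
YEO_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)
SUBCORTEX = "subcortex"
ALL_NETWORKS = YEO_NETWORKS + (SUBCORTEX,)

_SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class StructuralConnectome:
    """Validated weighted structural brain network.

    Parameters
    ----------
    weights
        N x N symmetric nonnegative matrix with zero diagonal
        (streamline count per voxel-pair, arbitrary units).
    region_labels
        Ordered region names, length N.
    network_assignment
        Maps each region label to one of the seven Yeo networks or
        ``"subcortex"``.
    """

    weights: np.ndarray
    region_labels: tuple[str, ...]
    network_assignment: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValueError("connectome needs at least 2 regions")
        if len(self.region_labels) != n:
            raise ValueError(
                f"label/matrix size mismatch: {len(self.region_labels)} labels "
                f"for {n} regions"
            )
        if np.any(w < 0):
            raise ValueError("negative weight in connectome")
        if not np.allclose(w, w.T, atol=1e-12, rtol=0.0):
            raise ValueError("weights not symmetric within 1e-12")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectome diagonal must be zero")
        if self.network_assignment:
            missing = [r for r in self.region_labels if r not in self.network_assignment]
            if missing:
                raise ValueError(f"regions without network assignment: {missing[:5]}")
            bad = {
                v for v in self.network_assignment.values() if v not in ALL_NETWORKS
            }
            if bad:
                raise ValueError(f"unknown networks: {sorted(bad)}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def network_indices(self) -> dict[str, np.ndarray]:
        """Region indices per network, in canonical network order."""
        if not self.network_assignment:
            raise ValueError("connectome has no network assignment")
        out: dict[str, np.ndarray] = {}
        for net in ALL_NETWORKS:
            out[net] = np.array(
                [i for i, r in enumerate(self.region_labels)
                 if self.network_assignment[r] == net],
                dtype=int,
            )
        return out


@dataclass(frozen=True)
class SystemMatrix:
    """Stabilized dynamics operator A_s with all eigenvalues in Re < 0."""

    A_s: np.ndarray
    stabilization_constant: float

    def __post_init__(self) -> None:
        a = np.asarray(self.A_s, dtype=float)
        max_re = float(np.max(np.linalg.eigvals(a).real))
        if max_re >= 0:
            raise ValueError(f"system matrix not Hurwitz-stable (max Re = {max_re:g})")
        object.__setattr__(self, "A_s", a)

    @property
    def n_regions(self) -> int:
        return self.A_s.shape[0]


def _read_matrix(path: str | Path) -> np.ndarray:
    """Read a tab- or comma-delimited square matrix, optional header row."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    first = path.read_text().splitlines()[0]
    # header if the first row contains any non-numeric token
    tokens = first.replace(sep, " ").split()
    header: int | None = 0
    try:
        [float(t) for t in tokens]
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep=sep, header=header)
    if header == 0 and not np.issubdtype(df.dtypes.iloc[0], np.number):
        df = df.set_index(df.columns[0])
    return df.to_numpy(dtype=float)


def load_connectome(
    path: str | Path,
    labels_path: str | Path | None = None,
    labels: Sequence[str] | None = None,
    network_assignment: Mapping[str, str] | None = None,
) -> StructuralConnectome:
    """Load and validate a structural connectome from a delimited matrix file.

    ``labels_path`` points at a TSV/CSV with columns ``region`` and
    (optionally) ``network``; alternatively pass ``labels`` directly.
    Asymmetries up to 1e-8 (relative to the largest weight) are repaired
    by averaging with the transpose; anything larger is an error, since
    it indicates an upstream problem rather than floating-point noise.
    """
    w = _read_matrix(path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"connectome file is not square: shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("negative weight in connectome file")
    scale = max(float(np.max(np.abs(w))), 1.0)
    asym = float(np.max(np.abs(w - w.T)))
    if asym > _SYMMETRY_TOL * scale:
        raise ValueError(
            f"connectome asymmetric beyond tolerance (max |W - W^T| = {asym:g})"
        )
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)

    assignment: Mapping[str, str] = dict(network_assignment or {})
    if labels_path is not None:
        sep = "\t" if str(labels_path).endswith((".tsv", ".txt")) else ","
        tab = pd.read_csv(labels_path, sep=sep)
        if "region" not in tab.columns:
            raise ValueError("labels file needs a 'region' column")
        labels = list(tab["region"].astype(str))
        if "network" in tab.columns and not assignment:
            assignment = dict(zip(labels, tab["network"].astype(str)))
    if labels is None:
        labels = [f"region_{i:03d}" for i in range(w.shape[0])]
    return StructuralConnectome(w, tuple(labels), assignment)


def stabilize(sc: StructuralConnectome | np.ndarray, c: float = 1.0) -> SystemMatrix:
    """Turn a nonnegative symmetric connectome into a stable dynamics operator.

    ``A_s = W / (lambda_max(W) + c) - I`` with ``c > 0``.  For a symmetric
    nonnegative ``W`` the spectral radius equals the largest eigenvalue, so
    every eigenvalue of ``A_s`` lies in ``[-2, -c/(lambda_max + c)]``.
    """
    if c <= 0:
        raise ValueError(f"stabilization constant must be positive, got {c}")
    w = sc.weights if isinstance(sc, StructuralConnectome) else np.asarray(sc, float)
    lam_max = float(np.max(np.linalg.eigvalsh(w))) if np.any(w) else 0.0
    a_s = w / (lam_max + c) - np.eye(w.shape[0])
    return SystemMatrix(a_s, float(c))
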
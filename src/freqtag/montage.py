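"""Idealized 10-20 / 10-10 scalp montages and electrode adjacency.

The analysis montage mirrors a 64-channel cap: 60 scalp electrodes enter the
spectral analysis, while the mastoids (M1, M2) serve as the offline reference
and the cerebellar leads (CB1, CB2) are excluded.  Electrode positions are
placed on a unit sphere by the standard construction: midline electrodes at
18-degree polar steps from the vertex, an outer ring at 72 degrees from the
vertex with 18-degree azimuthal spacing, and interior electrodes interpolated
along the arcs joining the outer ring to the midline.  Spatial adjacency --
needed by the cluster-based permutation test -- is defined by a Euclidean
(chord) distance threshold on these coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: 60 scalp electrodes retained for spectral analysis, in cap order.
SCALP_60: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
)

#: Full 64-channel cap: scalp + mastoids + cerebellar leads.
FULL_64: tuple[str, ...] = SCALP_60 + ("M1", "M2", "CB1", "CB2")

#: Reference / cerebellar leads excluded from spectral and spatial analysis.
NON_ANALYSIS_LABELS = frozenset({"M1", "M2", "CB1", "CB2"})

# Signed polar angle (degrees from vertex; positive = anterior) per row.
_ROW_POLAR = {
    "FP": 72.0, "AF": 54.0, "F": 36.0, "FC": 18.0, "C": 0.0,
    "CP": -18.0, "P": -36.0, "PO": -54.0, "O": -72.0,
}

# Outer-ring azimuths (degrees; 0 = right ear, 90 = nasion, 270 = inion).
_RING_AZ = {
    "FPZ": 90.0, "FP1": 108.0, "AF7": 126.0, "F7": 144.0, "FT7": 162.0,
    "T7": 180.0, "TP7": 198.0, "P7": 216.0, "PO7": 234.0, "O1": 252.0,
    "OZ": 270.0, "O2": 288.0, "PO8": 306.0, "P8": 324.0, "TP8": 342.0,
    "T8": 0.0, "FT8": 18.0, "F8": 36.0, "AF8": 54.0, "FP2": 72.0,
}

# Lateral anchor (outer-ring electrode) per interior row, left / right.
_ROW_ANCHOR = {
    "F": ("F7", "F8"), "FC": ("FT7", "FT8"), "C": ("T7", "T8"),
    "CP": ("TP7", "TP8"), "P": ("P7", "P8"),
}

# Fraction of the anchor->midline arc per lateral index (7=anchor, z=midline).
_LATERAL_FRACTION = {1: 0.75, 2: 0.75, 3: 0.5, 4: 0.5, 5: 0.25, 6: 0.25}


def _unit(polar_deg: float, az_deg: float) -> np.ndarray:
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.cos(az), np.sin(th) * np.sin(az), np.cos(th)])


def _slerp(p: np.ndarray, q: np.ndarray, t: float) -> np.ndarray:
    omega = np.arccos(np.clip(p @ q, -1.0, 1.0))
    if omega < 1e-12:
        return p.copy()
    return (np.sin((1 - t) * omega) * p + np.sin(t * omega) * q) / np.sin(omega)


def _midline(row: str) -> np.ndarray:
    polar = _ROW_POLAR[row]
    if polar == 0.0:
        return np.array([0.0, 0.0, 1.0])
    return _unit(abs(polar), 90.0 if polar > 0 else 270.0)


def _position(label: str) -> np.ndarray:
    if label in _RING_AZ:
        return _unit(72.0, _RING_AZ[label])
    if label == "CZ":
        return np.array([0.0, 0.0, 1.0])
    if label.endswith("Z"):
        return _midline(label[:-1])
    if label == "M1":
        return _unit(100.0, 180.0)
    if label == "M2":
        return _unit(100.0, 0.0)
    if label == "CB1":
        return _unit(95.0, 240.0)
    if label == "CB2":
        return _unit(95.0, 300.0)
    row, num = label[:-1], int(label[-1])
    left = num % 2 == 1
    if row == "AF":  # AF3/AF4: halfway along the AF7/AF8 -> AFz arc
        anchor = _unit(72.0, _RING_AZ["AF7" if left else "AF8"])
        return _slerp(anchor, _midline("AF"), 0.5)
    if row == "PO":  # PO3/PO5 and mirrors along the PO7/PO8 -> POz arc
        anchor = _unit(72.0, _RING_AZ["PO7" if left else "PO8"])
        return _slerp(anchor, _midline("PO"), _LATERAL_FRACTION[num])
    anchors = _ROW_ANCHOR[row]
    anchor = _unit(72.0, _RING_AZ[anchors[0] if left else anchors[1]])
    return _slerp(anchor, _midline(row), _LATERAL_FRACTION[num])


@dataclass
class Montage:
    """Electrode labels, unit-sphere positions, and boolean spatial adjacency."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3)
    adjacency: np.ndarray  # (n_channels, n_channels) bool
    neighbor_radius: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ConfigurationError("montage labels must be unique")
        if self.positions.shape != (n, 3):
            raise ConfigurationError("positions must be (n_channels, 3)")
        if self.adjacency.shape != (n, n):
            raise ConfigurationError("adjacency must be (n_channels, n_channels)")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ConfigurationError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ConfigurationError("adjacency diagonal must be empty")
        if n > 1:
            # the neighbor requirement binds analysis channels only; the
            # reference and cerebellar leads never enter spatial statistics
            has_nb = self.adjacency.any(axis=1)
            orphans = [l for l, ok in zip(self.labels, has_nb)
                       if not ok and l not in NON_ANALYSIS_LABELS]
            if orphans:
                raise ConfigurationError(f"channels without neighbors: {orphans}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def neighbor_counts(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def subset(self, labels: list[str]) -> "Montage":
        """Montage restricted to ``labels`` (adjacency sliced, not recomputed)."""
        idx = np.array([self.index(l) for l in labels])
        return Montage(
            labels=list(labels),
            positions=self.positions[idx],
            adjacency=self.adjacency[np.ix_(idx, idx)],
            neighbor_radius=self.neighbor_radius,
        )


def adjacency_from_positions(positions: np.ndarray, radius: float) -> np.ndarray:
    """Boolean adjacency: channel pairs with chord distance < ``radius``."""
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adj = d < radius
    np.fill_diagonal(adj, False)
    return adj


def make_montage(n_scalp: int = 60, neighbor_radius: float = 0.5) -> Montage:
    """Build the idealized 10-20 montage with ``n_scalp`` in {60, 64}.

    ``neighbor_radius`` is the chord-distance threshold (unit-sphere head
    model) defining adjacency; the default yields roughly 6 neighbors per
    electrode, comparable to sensor neighborhoods used by cluster statistics.
    """
    if n_scalp == 60:
        labels = list(SCALP_60)
    elif n_scalp == 64:
        labels = list(FULL_64)
    else:
        raise ConfigurationError(f"unsupported channel count {n_scalp}; expected 60 or 64")
    if neighbor_radius <= 0:
        raise ConfigurationError("neighbor_radius must be > 0")
    positions = np.array([_position(l) for l in labels])
    adjacency = adjacency_from_positions(positions, neighbor_radius)
    return Montage(labels, positions, adjacency, neighbor_radius=neighbor_radius)


def write_montage(montage: Montage, path) -> None:
    """Write an SFP-style whitespace-delimited ``label x y z`` file."""
    with open(path, "w") as fh:
        for label, pos in zip(montage.labels, montage.positions):
            fh.write(f"{label} {float(pos[0])!r} {float(pos[1])!r} {float(pos[2])!r}\n")


def read_montage(path, neighbor_radius: float = 0.5) -> Montage:
    """Read an SFP-style file; adjacency is derived from the positions."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    positions = np.array(rows)
    adjacency = adjacency_from_positions(positions, neighbor_radius)
    return Montage(labels, positions, adjacency, neighbor_radius=neighbor_radius)
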
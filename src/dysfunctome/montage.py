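"""Electrode layouts and dual-site 3x1 HD stimulation montages.

A :class:`Montage` is an ordered set of labelled 3D electrode positions.
Dual-site high-definition tACS places one stimulating electrode at each
endpoint of a target edge and surrounds each with a small ring of return
electrodes carrying the balancing current, so each site forms a focal
3x1 (one center, ``ring_size`` returns) unit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "StimMontage",
    "MontageFormatError",
    "AdmissibilityError",
    "load_montage",
    "standard_61_montage",
    "return_ring",
    "edge_admissible",
    "build_stim_montage",
]


class MontageFormatError(ValueError):
    """Raised when a montage table violates the expected format."""


class AdmissibilityError(ValueError):
    """Raised when a stimulation edge violates the site-separation rule."""


#: 61-channel extended 10-20 layout (10-10 names) matching a 64-channel
#: actiCAP-style cap with ground/reference positions omitted.
STANDARD_61_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "Oz",
)


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels with 3D coordinates.

    Coordinates may be in any consistent unit; only relative Euclidean
    distances are used (nearest-neighbour rings, admissibility).
    """

    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 3)
    ring_size: int = 3

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.labels) < 2:
            raise MontageFormatError("montage needs at least 2 channels")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise MontageFormatError(f"duplicate channel labels: {dupes}")
        if coords.shape != (len(self.labels), 3):
            raise MontageFormatError(
                f"coords shape {coords.shape} does not match {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(coords)):
            raise MontageFormatError("non-finite electrode coordinate")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def position(self, label: str) -> np.ndarray:
        return self.coords[self.index(label)]

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.position(a) - self.position(b)))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.coords, columns=["x", "y", "z"])
        df.insert(0, "label", list(self.labels))
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class StimMontage:
    """A charge-balanced dual-site 3x1 stimulation configuration.

    ``currents`` maps every participating channel to its signed current in
    mA; per site the center and its ring sum to zero exactly up to floating
    point. ``ring_current_report`` is the per-return-electrode magnitude
    rounded to two decimals, as printed in protocol descriptions.
    """

    site_a: str
    site_b: str
    ring_a: frozenset[str]
    ring_b: frozenset[str]
    currents: dict[str, float]
    phase_mode: str
    ring_current_report: float = field(default=0.0)

    def site_sum(self, site: str) -> float:
        ring = self.ring_a if site == self.site_a else self.ring_b
        return self.currents[site] + sum(self.currents[c] for c in ring)

    def to_json(self) -> str:
        return json.dumps(
            {
                "site_a": self.site_a,
                "site_b": self.site_b,
                "ring_a": sorted(self.ring_a),
                "ring_b": sorted(self.ring_b),
                "phase_mode": self.phase_mode,
                "ring_current_report": self.ring_current_report,
                "currents": {k: self.currents[k] for k in sorted(self.currents)},
            },
            indent=2,
        )


def load_montage(path, ring_size: int = 3) -> Montage:
    """Read a tab-separated montage table (columns label, x, y, z)."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise MontageFormatError(
            f"montage table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    labels = tuple(str(l) for l in df["label"])
    try:
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MontageFormatError(f"non-numeric coordinate: {exc}") from exc
    return Montage(labels=labels, coords=coords, ring_size=ring_size)


def standard_61_montage(ring_size: int = 3) -> Montage:
    """61-channel extended 10-20 montage with idealized head coordinates.

    Positions are drawn from MNE's standard 10-05 template (meters). The
    channel set is the conventional 61-electrode subset used by 64-channel
    caps once ground and reference positions are removed.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    coords = np.array([pos[l] for l in STANDARD_61_LABELS], dtype=float)
    return Montage(labels=STANDARD_61_LABELS, coords=coords, ring_size=ring_size)


def return_ring(montage: Montage, center: str, k: int | None = None) -> tuple[str, ...]:
    """The k channels nearest to ``center`` (excluded), ties by label order.

    These are the return-electrode positions of a 3x1 HD unit when
    ``k == 3``.
    """
    if k is None:
        k = montage.ring_size
    ci = montage.index(center)
    if k >= len(montage):
        raise ValueError(f"ring size {k} must be smaller than montage size {len(montage)}")
    if k < 1:
        raise ValueError("ring size must be >= 1")
    d = np.linalg.norm(montage.coords - montage.coords[ci], axis=1)
    order = sorted(
        (i for i in range(len(montage)) if i != ci),
        key=lambda i: (d[i], montage.labels[i]),
    )
    return tuple(montage.labels[i] for i in order[:k])


def edge_admissible(
    montage: Montage,
    edge: tuple[str, str],
    ring_size: int | None = None,
    rule: str = "ring_overlap",
    min_distance: float | None = None,
) -> tuple[bool, str]:
    """Whether two sites are far enough apart to host independent 3x1 units.

    Default rule: inadmissible iff either endpoint lies inside the other's
    return ring, or the two rings share an electrode — the geometric failure
    modes of a dual-site 3x1 montage. A plain Euclidean minimum-distance
    rule is available via ``rule='min_distance'``.
    Returns ``(admissible, reason)``; reason is '' when admissible.
    """
    u, v = edge
    if u == v:
        return False, "endpoints identical"
    montage.index(u), montage.index(v)  # raise on unknown labels
    if rule == "min_distance":
        if min_distance is None:
            raise ValueError("min_distance rule requires a distance threshold")
        if montage.distance(u, v) < min_distance:
            return False, "below minimum distance"
        return True, ""
    if rule != "ring_overlap":
        raise ValueError(f"unknown admissibility rule: {rule!r}")
    ring_u = set(return_ring(montage, u, ring_size))
    ring_v = set(return_ring(montage, v, ring_size))
    if u in ring_v or v in ring_u:
        return False, "endpoint inside partner ring"
    if ring_u & ring_v:
        return False, "ring overlap"
    return True, ""


def build_stim_montage(
    montage: Montage,
    edge: tuple[str, str],
    intensity_ma: float = 0.5,
    ring_size: int | None = None,
    phase_mode: str = "in_phase",
    admissibility_rule: str = "ring_overlap",
    min_distance: float | None = None,
) -> StimMontage:
    """Build a charge-balanced dual-site 3x1 montage for a target edge.

    Each stimulating electrode carries ``intensity_ma`` (default 0.5 mA);
    its ring electrodes split the balancing current equally with opposite
    polarity. In-phase mode drives both centers with the same sign,
    anti-phase with opposite signs.
    """
    if phase_mode not in ("in_phase", "anti_phase"):
        raise ValueError(f"phase_mode must be in_phase or anti_phase, got {phase_mode!r}")
    if intensity_ma <= 0:
        raise ValueError("intensity must be positive")
    k = montage.ring_size if ring_size is None else ring_size
    ok, reason = edge_admissible(
        montage, edge, ring_size=k, rule=admissibility_rule, min_distance=min_distance
    )
    if not ok:
        raise AdmissibilityError(f"edge {edge} inadmissible: {reason}")
    u, v = edge
    ring_u = return_ring(montage, u, k)
    ring_v = return_ring(montage, v, k)
    sign_b = 1.0 if phase_mode == "in_phase" else -1.0
    per_ring = intensity_ma / k
    currents: dict[str, float] = {u: intensity_ma, v: sign_b * intensity_ma}
    for c in ring_u:
        currents[c] = -per_ring
    for c in ring_v:
        currents[c] = -sign_b * per_ring
    return StimMontage(
        site_a=u,
        site_b=v,
        ring_a=frozenset(ring_u),
        ring_b=frozenset(ring_v),
        currents=currents,
        phase_mode=phase_mode,
        ring_current_report=round(per_ring, 2),
    )
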
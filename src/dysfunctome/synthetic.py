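"""Seeded synthetic cohorts with a planted severity-coupled subnetwork.

Two generators cover the two entry points of the analysis:

``simulate_signals``
    Raw band-limited multichannel oscillations plus pink noise, in which
    each planted edge (i, j) makes channel j mix a phase-delayed copy of
    channel i's narrowband component with a mixing weight that increases
    with the subject's severity score. This exercises the full
    filter -> epoch -> phase -> PLI path.

``simulate_matrices``
    Ready-made symmetric connectivity matrices whose planted-edge weights
    are linear in severity plus Gaussian noise — a fast path for
    network-statistic calibration and recovery studies.

``simulate_prepost``
    Paired pre/post matrices with a known node-strength increment on the
    two target nodes, for evaluating the pre/post outcome machinery.

All generators are pure functions of (spec, seed). Severity emulates an
aphasia-quotient-like score: evenly spread over [20, 95] by default
(higher = milder impairment), stored untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .connectivity import ConnectivityMatrix, EpochSet, bandpass
from .montage import STANDARD_61_LABELS

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "CohortSpecError",
    "default_planted_edges",
    "simulate_signals",
    "simulate_matrices",
    "simulate_prepost",
]


class CohortSpecError(ValueError):
    """Invalid cohort specification."""


def _default_labels(n_channels: int) -> tuple[str, ...]:
    if n_channels == len(STANDARD_61_LABELS):
        return STANDARD_61_LABELS
    return tuple(f"ch{i:02d}" for i in range(n_channels))


def default_planted_edges(
    labels: tuple[str, ...], n_edges: int = 20, n_nodes: int = 8, seed: int = 0
) -> tuple[tuple[str, str], ...]:
    """A connected planted subnetwork: ``n_edges`` edges on ``n_nodes`` nodes.

    A random spanning tree guarantees connectedness; the remaining edges are
    drawn uniformly from the untaken pairs among the chosen nodes.
    """
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise CohortSpecError(f"{n_edges} edges do not fit on {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    nodes = sorted(rng.choice(len(labels), size=n_nodes, replace=False))
    edges: set[tuple[int, int]] = set()
    shuffled = list(nodes)
    rng.shuffle(shuffled)
    for a, b in zip(shuffled[:-1], shuffled[1:]):  # spanning tree (path)
        edges.add((min(a, b), max(a, b)))
    remaining = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if (nodes[i], nodes[j]) not in edges
    ]
    rng.shuffle(remaining)
    for e in remaining[: n_edges - len(edges)]:
        edges.add(e)
    return tuple(sorted((labels[a], labels[b]) for a, b in edges))


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the reference cohort: 15 subjects, 61 channels,
    severity spanning 20-95, 4-s epochs at 250 Hz, theta band with a 7 Hz
    carrier, and a 20-edge planted subnetwork whose coupling increases with
    severity. ``coupling_slope`` (per severity s.d.) and ``noise_sd`` are
    chosen so each planted edge carries a population edge-severity
    correlation of 0.8 in the matrix generator:
    r = slope / sqrt(slope^2 + noise_sd^2) = 0.08 / 0.1 = 0.8.
    """

    n_subjects: int = 15
    n_channels: int = 61
    severity: np.ndarray | None = None
    severity_range: tuple[float, float] = (20.0, 95.0)
    planted_edges: tuple[tuple[str, str], ...] | None = None
    coupling_slope: float = 0.08
    baseline_coupling: float = 0.3
    phase_lag: float = np.pi / 4
    noise_sd: float = 0.06
    signal_noise_sd: float = 2.0
    signal_amplitude: float = 10.0
    bands: tuple[tuple[float, float], ...] = ((4.0, 8.0),)
    carrier_hz: float = 7.0
    epoch_s: float = 4.0
    fs: float = 250.0
    n_epochs: int = 20
    seed: int = 0
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise CohortSpecError("need at least 3 subjects")
        if not self.labels:
            self.labels = _default_labels(self.n_channels)
        if len(self.labels) != self.n_channels:
            raise CohortSpecError("labels do not match n_channels")
        if self.severity is None:
            rng = np.random.default_rng(self.seed)
            lo, hi = self.severity_range
            sev = np.linspace(lo, hi, self.n_subjects)
            rng.shuffle(sev)
            self.severity = sev
        self.severity = np.asarray(self.severity, dtype=float)
        if self.severity.shape != (self.n_subjects,):
            raise CohortSpecError("severity must have one score per subject")
        if self.planted_edges is None:
            self.planted_edges = default_planted_edges(self.labels, seed=self.seed)
        label_set = set(self.labels)
        for a, b in self.planted_edges:
            if a not in label_set or b not in label_set or a == b:
                raise CohortSpecError(f"planted edge ({a}, {b}) references invalid channels")
        for band in self.bands:
            if band[1] >= self.fs / 2:
                raise CohortSpecError(f"band {band} exceeds Nyquist at fs={self.fs}")
        z = self._severity_z()
        kappa = self.baseline_coupling + self.coupling_slope * z
        if kappa.min() < 0 or kappa.max() > 1:
            raise CohortSpecError(
                f"coupling outside [0, 1] after slope applied: "
                f"range [{kappa.min():.3f}, {kappa.max():.3f}]"
            )

    def _severity_z(self) -> np.ndarray:
        s = self.severity
        sd = s.std()
        if sd == 0:
            raise CohortSpecError("severity scores are constant")
        return (s - s.mean()) / sd

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:03d}" for i in range(self.n_subjects))

    def coupling(self) -> np.ndarray:
        """Per-subject planted-edge coupling strength kappa."""
        return self.baseline_coupling + self.coupling_slope * self._severity_z()


@dataclass
class SyntheticCohort:
    """Generated cohort with ground truth for recovery checks."""

    subject_ids: tuple[str, ...]
    severity: np.ndarray
    matrices: list[ConnectivityMatrix] | None = None
    epoch_sets: dict[str, EpochSet] | None = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.matrices:
            return self.matrices[0].labels
        first = next(iter(self.epoch_sets.values()))
        return first.labels


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """1/f-amplitude noise, unit RMS per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = pink.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return pink / rms


def _phase_shift(x: np.ndarray, phase_lag: float) -> np.ndarray:
    """Delay a narrowband signal by a constant analytic phase."""
    return np.real(hilbert(x) * np.exp(-1j * phase_lag))


def simulate_signals(spec: CohortSpec) -> SyntheticCohort:
    """Raw oscillatory signals with severity-coupled planted edges.

    Per subject and channel, the signal is a unit-RMS narrowband oscillation
    (band-pass filtered white noise in the first configured band, scaled to
    ``signal_amplitude``) plus pink noise of ``signal_noise_sd``. For each
    planted edge (i, j), channel j's oscillatory component is a mix of
    kappa x (phase-delayed copy of channel i) and (1 - kappa) x its own
    oscillation, so PLI on that edge grows with the subject's coupling.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.n_epochs * spec.epoch_s * spec.fs))
    band = spec.bands[0]
    kappa = spec.coupling()
    idx = {l: i for i, l in enumerate(spec.labels)}
    # orient each planted edge (source -> mixed target) in label-index order
    incoming: dict[int, list[int]] = {}
    for a, b in spec.planted_edges:
        i, j = idx[a], idx[b]
        if i > j:
            i, j = j, i
        incoming.setdefault(j, []).append(i)

    epoch_sets: dict[str, EpochSet] = {}
    for s, sid in enumerate(spec.subject_ids):
        raw = rng.standard_normal((spec.n_channels, n_samples))
        osc = bandpass(raw, band, spec.fs)
        osc /= osc.std(axis=-1, keepdims=True)
        mixed = osc.copy()
        k = float(kappa[s])
        for j, sources in incoming.items():
            shifted = np.mean([_phase_shift(osc[i], spec.phase_lag) for i in sources], axis=0)
            mixed[j] = (1.0 - k) * osc[j] + k * shifted
        signal = spec.signal_amplitude * mixed
        if spec.signal_noise_sd > 0:
            signal = signal + spec.signal_noise_sd * _pink_noise(
                rng, spec.n_channels, n_samples
            )
        samples_per_epoch = int(round(spec.epoch_s * spec.fs))
        data = signal[:, : spec.n_epochs * samples_per_epoch].reshape(
            spec.n_channels, spec.n_epochs, samples_per_epoch
        ).transpose(1, 0, 2)
        epoch_sets[sid] = EpochSet(
            data=data,
            fs=spec.fs,
            labels=spec.labels,
            band=band,
            subject_id=sid,
            task_id="synthetic",
        )
    return SyntheticCohort(
        subject_ids=spec.subject_ids,
        severity=spec.severity.copy(),
        epoch_sets=epoch_sets,
        ground_truth={
            "planted_edges": list(spec.planted_edges),
            "coupling": kappa.tolist(),
            "seed": spec.seed,
        },
    )


def simulate_matrices(spec: CohortSpec) -> SyntheticCohort:
    """Connectivity matrices with planted edge weights linear in severity.

    Edge weight for subject s on edge e is
    ``mu_e + slope_e * z(severity_s) + eps`` with ``eps ~ N(0, noise_sd)``,
    ``slope_e = coupling_slope`` on planted edges and 0 elsewhere; baselines
    ``mu_e`` are drawn once per cohort around ``baseline_coupling``. Weights
    are clipped to [0, 1].
    """
    if spec.noise_sd <= 0:
        raise CohortSpecError("matrix generator requires noise_sd > 0")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_channels
    iu, ju = np.triu_indices(n, 1)
    n_edges = len(iu)
    idx = {l: i for i, l in enumerate(spec.labels)}
    edge_index = {(iu[e], ju[e]): e for e in range(n_edges)}
    planted_idx = np.array(
        sorted(
            edge_index[tuple(sorted((idx[a], idx[b])))]
            for a, b in spec.planted_edges
        ),
        dtype=int,
    )
    mu = rng.uniform(
        spec.baseline_coupling - 0.1, spec.baseline_coupling + 0.1, size=n_edges
    )
    slope = np.zeros(n_edges)
    slope[planted_idx] = spec.coupling_slope
    z = spec._severity_z()
    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_subjects, n_edges))
    weights = mu[None, :] + z[:, None] * slope[None, :] + eps
    np.clip(weights, 0.0, 1.0, out=weights)

    matrices = []
    for s, sid in enumerate(spec.subject_ids):
        W = np.zeros((n, n))
        W[iu, ju] = weights[s]
        W = W + W.T
        matrices.append(
            ConnectivityMatrix(labels=spec.labels, W=W, meta={"subject_id": sid})
        )
    return SyntheticCohort(
        subject_ids=spec.subject_ids,
        severity=spec.severity.copy(),
        matrices=matrices,
        ground_truth={
            "planted_edges": list(spec.planted_edges),
            "coupling_slope": spec.coupling_slope,
            "noise_sd": spec.noise_sd,
            "population_r": spec.coupling_slope
            / float(np.hypot(spec.coupling_slope, spec.noise_sd)),
            "seed": spec.seed,
        },
    )


def simulate_prepost(
    n_subjects: int,
    target_nodes: tuple[str, str],
    strength_delta: float,
    noise_sd: float,
    seed: int,
    n_channels: int = 61,
    labels: tuple[str, ...] | None = None,
) -> tuple[list[tuple[ConnectivityMatrix, ConnectivityMatrix]], dict]:
    """Paired pre/post matrices with a planted node-strength increment.

    Every edge incident to either target node gains ``strength_delta /
    (n_channels - 1)`` so that, at zero noise, each target node's strength
    increases by exactly ``strength_delta``. Symmetric Gaussian noise of sd
    ``noise_sd`` is added to the post matrix.
    """
    if strength_delta < 0:
        raise CohortSpecError("strength_delta must be non-negative")
    if labels is None:
        labels = _default_labels(n_channels)
    idx = {l: i for i, l in enumerate(labels)}
    u, v = (idx[t] for t in target_nodes)
    rng = np.random.default_rng(seed)
    n = n_channels
    iu, ju = np.triu_indices(n, 1)
    inc = strength_delta / (n - 1)
    mask = np.zeros((n, n))
    mask[u, :] = 1.0
    mask[:, u] = 1.0
    mask[v, :] = 1.0
    mask[:, v] = 1.0
    np.fill_diagonal(mask, 0.0)

    pairs = []
    for s in range(n_subjects):
        W = np.zeros((n, n))
        W[iu, ju] = rng.uniform(0.3, 0.7, size=len(iu))
        pre = W + W.T
        noise = np.zeros((n, n))
        if noise_sd > 0:
            noise[iu, ju] = rng.normal(0.0, noise_sd, size=len(iu))
            noise = noise + noise.T
        post = pre + inc * mask + noise
        sid = f"S{s + 1:03d}"
        pairs.append(
            (
                ConnectivityMatrix(labels=labels, W=pre, meta={"subject_id": sid, "session": "pre"}),
                ConnectivityMatrix(labels=labels, W=post, meta={"subject_id": sid, "session": "post"}),
            )
        )
    ground_truth = {
        "target_nodes": list(target_nodes),
        "strength_delta": strength_delta,
        "per_edge_increment": inc,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return pairs, ground_truth
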
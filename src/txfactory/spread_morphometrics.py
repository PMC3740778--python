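"""Morphometrics of spread chromatin fibres.

Quantities measurable on chromatin spreads: the micron-to-kilobase spreading
calibration (estimated from measurements of a probe of known length, 47.26 Kb
by default), lognormal fits to track-length and gap distributions, detection
of clusters of hyperacetylated tracks (two or more tracks separated by less
than 100 Kb), cluster span/composition summaries, and nascent-transcript /
polymerase marks per track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic_data import SpreadFibre

__all__ = [
    "Calibration",
    "LognormalFit",
    "TrackCluster",
    "ClusterStats",
    "MarkSummary",
    "microns_to_kb",
    "kb_to_microns",
    "estimate_calibration",
    "simulate_probe_measurements",
    "fit_lognormal",
    "detect_clusters",
    "cluster_statistics",
    "marks_per_track",
]

DEFAULT_PROBE_KB = 47.26


@dataclass(frozen=True)
class Calibration:
    """Chromatin spreading calibration in Kb per micron."""

    kb_per_um: float
    se: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        if self.kb_per_um <= 0:
            raise ValueError("kb_per_um must be positive")
        if self.se < 0:
            raise ValueError("se must be non-negative")


def microns_to_kb(length_um: float | np.ndarray, cal: Calibration) -> float | np.ndarray:
    """Convert measured micron lengths to Kb via the spreading calibration."""
    length_um = np.asarray(length_um, dtype=float)
    if np.any(length_um < 0):
        raise ValueError("lengths must be non-negative")
    out = length_um * cal.kb_per_um
    return float(out) if out.ndim == 0 else out


def kb_to_microns(length_kb: float | np.ndarray, cal: Calibration) -> float | np.ndarray:
    length_kb = np.asarray(length_kb, dtype=float)
    if np.any(length_kb < 0):
        raise ValueError("lengths must be non-negative")
    out = length_kb / cal.kb_per_um
    return float(out) if out.ndim == 0 else out


def estimate_calibration(measured_um, probe_kb: float = DEFAULT_PROBE_KB) -> Calibration:
    """Estimate Kb/um from measured micron lengths of a probe of known size.

    kb_per_um = probe_kb / mean(measured); the standard error follows by
    first-order propagation from the standard error of the mean:
    se = probe_kb * se(mean) / mean**2.
    """
    x = np.asarray(measured_um, dtype=float)
    if x.size == 0:
        raise ValueError("at least one measurement is required")
    if np.any(x <= 0):
        raise ValueError("measured lengths must be positive")
    if probe_kb <= 0:
        raise ValueError("probe_kb must be positive")
    m = float(x.mean())
    if x.size > 1:
        sem = float(x.std(ddof=1)) / math.sqrt(x.size)
    else:
        sem = 0.0
    return Calibration(kb_per_um=probe_kb / m, se=probe_kb * sem / m**2, n=int(x.size))


def simulate_probe_measurements(
    n: int, cal_kb_per_um: float = 3.9, probe_kb: float = DEFAULT_PROBE_KB,
    noise_cv: float = 0.05, seed: int | None = None,
) -> np.ndarray:
    """Simulate micron measurements of a probe under multiplicative noise.

    Each measurement is (probe_kb / cal_kb_per_um) * LogNormal with unit
    arithmetic mean and coefficient of variation ``noise_cv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    true_um = probe_kb / cal_kb_per_um
    if noise_cv == 0:
        return np.full(n, true_um)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    factors = rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    return true_um * factors


@dataclass(frozen=True)
class LognormalFit:
    """Maximum-likelihood lognormal fit."""

    mu_log: float
    sigma_log: float
    arith_mean: float
    n: int
    log_likelihood: float


def fit_lognormal(values_kb) -> LognormalFit:
    """MLE of a lognormal: mu = mean(log x), sigma = population SD(log x).

    ``arith_mean`` is the fitted arithmetic mean exp(mu + sigma**2/2).
    """
    x = np.asarray(values_kb, dtype=float)
    if x.size < 2:
        raise ValueError("at least two values are required")
    if np.any(x <= 0):
        raise ValueError("all values must be positive")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    ll = float(
        -x.size * math.log(sigma if sigma > 0 else 1.0)
        - 0.5 * x.size * math.log(2 * math.pi)
        - logs.sum()
        - (0.5 * np.sum((logs - mu) ** 2) / sigma**2 if sigma > 0 else 0.0)
    )
    return LognormalFit(
        mu_log=mu, sigma_log=sigma,
        arith_mean=math.exp(mu + 0.5 * sigma**2),
        n=int(x.size), log_likelihood=ll,
    )


@dataclass(frozen=True)
class TrackCluster:
    """A maximal run of >= min_tracks tracks with consecutive gaps below the
    clustering bound, on one fibre."""

    fibre_id: str
    member_track_indices: tuple[int, ...]
    span_kb: float
    n_tus: int

    def __post_init__(self) -> None:
        if self.n_tus != len(self.member_track_indices):
            raise ValueError("n_tus must equal the member count")
        if self.span_kb <= 0:
            raise ValueError("span must be positive")


def detect_clusters(
    fibre: SpreadFibre, max_gap_kb: float = 100.0, min_tracks: int = 2
) -> list[TrackCluster]:
    """Find clusters: maximal runs of tracks whose consecutive gaps
    (next start - previous end) are strictly below ``max_gap_kb``.

    Runs with fewer than ``min_tracks`` members are discarded, so isolated
    tracks never form a cluster.  Clusters never span fibres.
    """
    tracks = fibre.tracks
    if len(tracks) == 0:
        return []
    if np.any(tracks[1:, 0] < tracks[:-1, 1]):
        raise ValueError("tracks must be sorted and non-overlapping")
    gaps = tracks[1:, 0] - tracks[:-1, 1]
    clusters: list[TrackCluster] = []
    run_start = 0
    for i in range(len(tracks)):
        last_in_run = i == len(tracks) - 1 or gaps[i] >= max_gap_kb
        if last_in_run:
            if i - run_start + 1 >= min_tracks:
                clusters.append(
                    TrackCluster(
                        fibre_id=fibre.fibre_id,
                        member_track_indices=tuple(range(run_start, i + 1)),
                        span_kb=float(tracks[i, 1] - tracks[run_start, 0]),
                        n_tus=i - run_start + 1,
                    )
                )
            run_start = i + 1
    return clusters


def _summary(x: np.ndarray) -> dict:
    if x.size == 0:
        return dict(mean=math.nan, sd=math.nan, min=math.nan, max=math.nan)
    return dict(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        min=float(x.min()),
        max=float(x.max()),
    )


@dataclass(frozen=True)
class ClusterStats:
    """Summary of detected clusters (sample SD; NaN summaries when empty)."""

    n_clusters: int
    tus_per_cluster_mean: float
    tus_per_cluster_sd: float
    span_mean_kb: float
    span_sd_kb: float
    span_min_kb: float
    span_max_kb: float


def cluster_statistics(clusters) -> ClusterStats:
    """Summarise cluster spans and TU counts; an empty input yields an
    explicit n_clusters=0 record with NaN summaries rather than an error."""
    clusters = list(clusters)
    if not clusters:
        nan = math.nan
        return ClusterStats(0, nan, nan, nan, nan, nan, nan)
    spans = np.array([c.span_kb for c in clusters])
    tus = np.array([c.n_tus for c in clusters], dtype=float)
    s, t = _summary(spans), _summary(tus)
    return ClusterStats(
        n_clusters=len(clusters),
        tus_per_cluster_mean=t["mean"], tus_per_cluster_sd=t["sd"],
        span_mean_kb=s["mean"], span_sd_kb=s["sd"],
        span_min_kb=s["min"], span_max_kb=s["max"],
    )


@dataclass(frozen=True)
class MarkSummary:
    """Per-track mark-count summary for one mark type."""

    mean: float
    sd: float
    histogram: dict  # count -> number of tracks
    n_tracks: int
    n_orphans: int  # marks falling outside every track


def _count_marks(tracks: np.ndarray, marks: np.ndarray) -> tuple[np.ndarray, int]:
    counts = np.zeros(len(tracks), dtype=int)
    orphans = 0
    for m in marks:
        hit = np.where((tracks[:, 0] <= m) & (m < tracks[:, 1]))[0]
        if hit.size:
            counts[hit[0]] += 1
        else:
            orphans += 1
    return counts, orphans


def marks_per_track(fibres) -> dict[str, MarkSummary]:
    """Count transcript and polymerase marks per track by half-open
    containment.  Marks outside every track are reported as orphans."""
    fibres = list(fibres)
    out = {}
    for kind, attr in (("transcripts", "transcript_marks"), ("polii", "polii_marks")):
        all_counts = []
        orphans = 0
        for f in fibres:
            c, o = _count_marks(f.tracks, getattr(f, attr))
            all_counts.append(c)
            orphans += o
        counts = np.concatenate(all_counts) if all_counts else np.empty(0, dtype=int)
        if counts.size == 0:
            out[kind] = MarkSummary(0.0, 0.0, {}, 0, orphans)
            continue
        vals, freq = np.unique(counts, return_counts=True)
        out[kind] = MarkSummary(
            mean=float(counts.mean()),
            sd=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
            histogram={int(v): int(f) for v, f in zip(vals, freq)},
            n_tracks=int(counts.size),
            n_orphans=orphans,
        )
    return out
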
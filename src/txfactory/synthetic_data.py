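"""Synthetic inputs with known ground truth.

Every measurement stage in this package (spread morphometrics, sliding-window
co-expression, nuclear-foci statistics) was originally performed on microscopy
or microarray data that cannot be redistributed.  This module generates
statistically calibrated stand-ins for those inputs:

* chromatin-spread fibres: hyperacetylated (H4K16ac) tracks with lognormal
  lengths (arithmetic mean 15 Kb), lognormal intra-cluster gaps (mean 30 Kb,
  truncated below the 100 Kb clustering bound), 8 +/- 2 tracks per cluster,
  Poisson-distributed nascent-transcript and elongating-polymerase marks
  (rates 0.7 and 0.8 per track), and long inter-cluster spacers sized so the
  genome-wide active fraction is ~12%;
* gene tables with binary expressed calls and optional planted co-expression
  clusters;
* nucleus images with near-circular elliptical foci whose true mean shape
  factor is 0.93.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ellipe
from skimage import draw

__all__ = [
    "SpreadGenParams",
    "SpreadFibre",
    "SpreadSample",
    "ExprGenParams",
    "ImageGenParams",
    "NucleusImage",
    "FOCUS_ASPECT_LOG_SD_093",
    "generate_spread_fibres",
    "generate_expression_table",
    "generate_nucleus_images",
    "generate_dispersal_series",
]

#: Log-SD of the focus aspect-ratio distribution for which the analytic mean
#: shape factor (4*pi*A/P**2 of the generating ellipses) equals 0.93.
#: Calibrated numerically against the exact elliptic-integral perimeter.
FOCUS_ASPECT_LOG_SD_093 = 0.4665


def lognormal_mu(arith_mean: float, sigma_log: float) -> float:
    """Log-mean such that the lognormal arithmetic mean equals ``arith_mean``.

    Uses arithmetic mean = exp(mu + sigma**2 / 2).
    """
    if arith_mean <= 0:
        raise ValueError("arithmetic mean must be positive")
    return math.log(arith_mean) - 0.5 * sigma_log**2


def _sample_lognormal_truncated(
    rng: np.random.Generator,
    arith_mean: float,
    sigma_log: float,
    n: int,
    upper: float | None = None,
    lower: float | None = None,
) -> np.ndarray:
    """Rejection-sample a lognormal with given arithmetic mean, truncated
    to (lower, upper)."""
    mu = lognormal_mu(arith_mean, sigma_log)
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        batch = rng.lognormal(mu, sigma_log, size=2 * (n - filled) + 16)
        if upper is not None:
            batch = batch[batch < upper]
        if lower is not None:
            batch = batch[batch > lower]
        take = min(batch.size, n - filled)
        out[filled : filled + take] = batch[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# chromatin spreads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpreadGenParams:
    """Parameters of the chromatin-spread generator.

    Lengths are in Kb.  Lognormal distributions are parameterised by their
    arithmetic mean and log-scale SD; the log-mean is derived internally as
    ``log(mean) - sigma**2/2``.
    """

    n_clusters: int = 100
    track_mean_kb: float = 15.0
    track_sigma_log: float = 0.6
    gap_mean_kb: float = 30.0
    gap_sigma_log: float = 0.6
    tus_per_cluster_mean: float = 8.0
    tus_per_cluster_sd: float = 2.0
    min_tus_per_cluster: int = 2
    spacer_mean_kb: float = 670.0
    spacer_sigma_log: float = 0.6
    transcripts_per_track_rate: float = 0.7
    polii_per_track_rate: float = 0.8
    mark_dispersion: float | None = None
    calibration_kb_per_um: float = 3.9
    calibration_noise_cv: float = 0.05
    cluster_gap_bound_kb: float = 100.0
    clusters_per_fibre: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("track_mean_kb", "gap_mean_kb", "spacer_mean_kb", "calibration_kb_per_um", "tus_per_cluster_mean", "cluster_gap_bound_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("track_sigma_log", "gap_sigma_log", "spacer_sigma_log", "tus_per_cluster_sd", "transcripts_per_track_rate", "polii_per_track_rate", "calibration_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_tus_per_cluster < 2:
            raise ValueError("min_tus_per_cluster must be >= 2")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.mark_dispersion is not None and self.mark_dispersion <= 0:
            raise ValueError("mark_dispersion must be positive when given")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible generation")


@dataclass
class SpreadFibre:
    """One spread chromatin fibre: ordered H4K16ac track intervals plus
    point marks, on a 1D Kb axis (0-based, half-open intervals)."""

    fibre_id: str
    tracks: np.ndarray  # shape (n, 2), columns start_kb, end_kb
    transcript_marks: np.ndarray  # positions in Kb
    polii_marks: np.ndarray
    truth_cluster_ids: np.ndarray  # per-track ground-truth cluster id
    total_kb: float  # genomic extent of the fibre including trailing spacer

    def __post_init__(self) -> None:
        self.tracks = np.asarray(self.tracks, dtype=float).reshape(-1, 2)
        self.transcript_marks = np.asarray(self.transcript_marks, dtype=float)
        self.polii_marks = np.asarray(self.polii_marks, dtype=float)
        self.truth_cluster_ids = np.asarray(self.truth_cluster_ids)
        if np.any(self.tracks[:, 1] <= self.tracks[:, 0]):
            raise ValueError("every track must have end_kb > start_kb")
        if np.any(self.tracks[1:, 0] < self.tracks[:-1, 1]):
            raise ValueError("tracks must be sorted and non-overlapping")

    @property
    def track_lengths_kb(self) -> np.ndarray:
        return self.tracks[:, 1] - self.tracks[:, 0]

    @property
    def gaps_kb(self) -> np.ndarray:
        """Gaps between consecutive tracks (next start minus previous end)."""
        if len(self.tracks) < 2:
            return np.empty(0)
        return self.tracks[1:, 0] - self.tracks[:-1, 1]


@dataclass
class SpreadSample:
    """Generated fibres plus their per-cluster ground truth."""

    fibres: list[SpreadFibre]
    truth: pd.DataFrame  # cluster_id, fibre_id, n_tus, start_kb, end_kb, span_kb
    params: SpreadGenParams

    def track_lengths_kb(self) -> np.ndarray:
        if not self.fibres:
            return np.empty(0)
        return np.concatenate([f.track_lengths_kb for f in self.fibres])

    def intra_cluster_gaps_kb(self) -> np.ndarray:
        """Ground-truth gaps between consecutive tracks of the same cluster."""
        out = []
        for f in self.fibres:
            same = f.truth_cluster_ids[1:] == f.truth_cluster_ids[:-1]
            out.append(f.gaps_kb[same])
        return np.concatenate(out) if out else np.empty(0)

    def active_fraction(self) -> float:
        """Fraction of the generated genomic extent covered by tracks."""
        active = sum(float(f.track_lengths_kb.sum()) for f in self.fibres)
        total = sum(f.total_kb for f in self.fibres)
        if total == 0:
            raise ValueError("no generated sequence")
        return active / total


def _mark_counts(rng: np.random.Generator, rate: float, n: int, dispersion: float | None) -> np.ndarray:
    if rate == 0:
        return np.zeros(n, dtype=int)
    if dispersion is None:
        return rng.poisson(rate, size=n)
    # negative binomial with mean=rate, shape=dispersion (variance rate + rate^2/k)
    p = dispersion / (dispersion + rate)
    return rng.negative_binomial(dispersion, p, size=n)


def generate_spread_fibres(params: SpreadGenParams) -> SpreadSample:
    """Generate spread fibres at the calibrated study conditions.

    Each cluster holds ``round(N(tus_mean, tus_sd))`` tracks (resampled until
    >= ``min_tus_per_cluster``), with lognormal track lengths and lognormal
    intra-cluster gaps rejection-truncated below ``cluster_gap_bound_kb`` so
    ground-truth clusters are exactly recoverable by the < 100 Kb rule.
    Clusters are separated by lognormal spacers truncated above the bound.
    A trailing spacer follows every cluster so the genomic extent (and hence
    the active fraction) of a fibre is well defined.
    """
    rng = np.random.default_rng(params.seed)
    empty_truth = pd.DataFrame(
        columns=["cluster_id", "fibre_id", "n_tus", "start_kb", "end_kb", "span_kb"]
    )
    if params.n_clusters == 0:
        return SpreadSample(fibres=[], truth=empty_truth, params=params)

    # tracks per cluster: rounded normal, resampled below the minimum
    n_tus = np.rint(
        rng.normal(params.tus_per_cluster_mean, params.tus_per_cluster_sd, size=params.n_clusters)
    ).astype(int)
    while np.any(n_tus < params.min_tus_per_cluster):
        bad = n_tus < params.min_tus_per_cluster
        n_tus[bad] = np.rint(
            rng.normal(params.tus_per_cluster_mean, params.tus_per_cluster_sd, size=int(bad.sum()))
        ).astype(int)

    per_fibre = params.clusters_per_fibre or params.n_clusters
    fibres: list[SpreadFibre] = []
    truth_rows = []
    cluster_id = 0
    for fi in range(math.ceil(params.n_clusters / per_fibre)):
        fibre_clusters = n_tus[fi * per_fibre : (fi + 1) * per_fibre]
        cursor = 0.0
        tracks = []
        cluster_ids = []
        fibre_id = f"fibre{fi:04d}"
        spacers = _sample_lognormal_truncated(
            rng, params.spacer_mean_kb, params.spacer_sigma_log, len(fibre_clusters),
            lower=params.cluster_gap_bound_kb,
        )
        for ci, k in enumerate(fibre_clusters):
            lengths = _sample_lognormal_truncated(rng, params.track_mean_kb, params.track_sigma_log, k)
            gaps = _sample_lognormal_truncated(
                rng, params.gap_mean_kb, params.gap_sigma_log, k - 1,
                upper=params.cluster_gap_bound_kb,
            )
            start = cursor
            for j in range(k):
                tracks.append((cursor, cursor + lengths[j]))
                cluster_ids.append(cluster_id)
                cursor += lengths[j]
                if j < k - 1:
                    cursor += gaps[j]
            truth_rows.append(
                dict(cluster_id=cluster_id, fibre_id=fibre_id, n_tus=int(k),
                     start_kb=start, end_kb=cursor, span_kb=cursor - start)
            )
            cluster_id += 1
            cursor += spacers[ci]
        track_arr = np.array(tracks)
        n_tracks = len(track_arr)
        t_counts = _mark_counts(rng, params.transcripts_per_track_rate, n_tracks, params.mark_dispersion)
        p_counts = _mark_counts(rng, params.polii_per_track_rate, n_tracks, params.mark_dispersion)
        t_marks, p_marks = [], []
        for (s, e), tc, pc in zip(track_arr, t_counts, p_counts):
            t_marks.extend(rng.uniform(s, e, size=tc))
            p_marks.extend(rng.uniform(s, e, size=pc))
        fibres.append(
            SpreadFibre(
                fibre_id=fibre_id,
                tracks=track_arr,
                transcript_marks=np.array(t_marks),
                polii_marks=np.array(p_marks),
                truth_cluster_ids=np.array(cluster_ids),
                total_kb=cursor,
            )
        )
    truth = pd.DataFrame(truth_rows) if truth_rows else empty_truth
    return SpreadSample(fibres=fibres, truth=truth, params=params)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExprGenParams:
    """Parameters of the gene-table generator for the sliding-window test."""

    n_genes: int = 2000
    chrom_length_kb: float = 20_000.0
    n_chromosomes: int = 1
    planted_clusters: tuple = ()  # (chrom_index, start_kb, span_kb, n_genes_expressed)
    background_expressed_rate: float = 0.02
    gene_length_kb: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_chromosomes < 1:
            raise ValueError("n_genes >= 0 and n_chromosomes >= 1 required")
        if self.chrom_length_kb <= 0 or self.gene_length_kb <= 0:
            raise ValueError("lengths must be positive")
        if not 0 <= self.background_expressed_rate <= 1:
            raise ValueError("background_expressed_rate must be in [0, 1]")
        for chrom, start, span, n in self.planted_clusters:
            if not 0 <= chrom < self.n_chromosomes:
                raise ValueError(f"planted cluster on unknown chromosome {chrom}")
            if start < 0 or start + span > self.chrom_length_kb:
                raise ValueError("planted cluster extends outside its chromosome")
            if n < 1:
                raise ValueError("planted cluster needs >= 1 expressed gene")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible generation")


def generate_expression_table(params: ExprGenParams) -> pd.DataFrame:
    """Gene table with columns chrom, start_kb, end_kb, gene_id, expressed.

    Background genes are placed uniformly per chromosome and expressed as a
    Bernoulli(``background_expressed_rate``) call; each planted cluster adds
    its stated count of expressed genes uniformly inside its interval.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    gid = 0
    glen = params.gene_length_kb
    per_chrom = np.full(params.n_chromosomes, params.n_genes // params.n_chromosomes)
    per_chrom[: params.n_genes % params.n_chromosomes] += 1
    for c in range(params.n_chromosomes):
        starts = rng.uniform(0, params.chrom_length_kb - glen, size=per_chrom[c])
        expr = rng.random(per_chrom[c]) < params.background_expressed_rate
        for s, e in zip(starts, expr):
            rows.append((f"chr{c + 1}", s, s + glen, f"gene{gid:06d}", int(e)))
            gid += 1
    for chrom, start, span, n in params.planted_clusters:
        hi = max(start, start + span - glen)
        starts = rng.uniform(start, hi, size=n)
        for s in starts:
            rows.append((f"chr{chrom + 1}", s, min(s + glen, start + span), f"gene{gid:06d}", 1))
            gid += 1
    df = pd.DataFrame(rows, columns=["chrom", "start_kb", "end_kb", "gene_id", "expressed"])
    return df.sort_values(["chrom", "start_kb"], ignore_index=True)


# ---------------------------------------------------------------------------
# nucleus images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGenParams:
    """Parameters of the synthetic confocal-nucleus generator.

    Foci are filled ellipses of fixed area ``pi * focus_radius_px**2`` whose
    aspect ratio is lognormal around 1; the default log-SD is calibrated so
    the analytic mean shape factor of the generated ellipses is 0.93.
    """

    image_size_px: tuple[int, int] = (256, 256)
    n_foci: int = 25
    focus_radius_px: float = 6.0
    focus_aspect_log_sd: float = FOCUS_ASPECT_LOG_SD_093
    background_level: float = 1000.0
    focus_level: float = 8000.0
    noise_sd: float = 150.0
    mask_radius_frac: float = 0.42
    n_images: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.focus_level <= self.background_level:
            raise ValueError("focus_level must exceed background_level")
        if self.focus_radius_px <= 0:
            raise ValueError("focus_radius_px must be positive")
        if self.noise_sd < 0 or self.focus_aspect_log_sd < 0:
            raise ValueError("noise_sd and focus_aspect_log_sd must be >= 0")
        if self.n_foci < 0 or self.n_images < 1:
            raise ValueError("n_foci >= 0 and n_images >= 1 required")
        if not 0 < self.mask_radius_frac <= 0.5:
            raise ValueError("mask_radius_frac must be in (0, 0.5]")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible generation")


@dataclass
class NucleusImage:
    """A synthetic nucleus: 16-bit intensity raster, boolean nuclear mask and
    the analytic ground truth of every rendered focus."""

    image_id: str
    image: np.ndarray  # uint16
    mask: np.ndarray  # bool, same shape
    truth: pd.DataFrame  # focus_id, cy, cx, a_px, b_px, theta, area_px, perimeter_px, shape_factor


def _ellipse_truth(a: float, b: float) -> tuple[float, float, float]:
    """Analytic area, perimeter and shape factor of an ellipse with
    semi-axes a >= b, via the complete elliptic integral."""
    area = math.pi * a * b
    perim = 4.0 * a * float(ellipe(1.0 - (b / a) ** 2))
    return area, perim, 4.0 * math.pi * area / perim**2


def _render_nucleus(
    rng: np.random.Generator, params: ImageGenParams, image_id: str,
    radius_scale: float = 1.0, amplitude_scale: float = 1.0,
    allow_overlap: bool = False,
) -> NucleusImage:
    h, w = params.image_size_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask_r = params.mask_radius_frac * min(h, w)
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw.disk((cy, cx), mask_r, shape=(h, w))
    mask[rr, cc] = True

    canvas = np.zeros((h, w), dtype=float)
    truth_rows = []
    placed: list[tuple[float, float, float]] = []  # (fy, fx, bounding radius)
    for k in range(params.n_foci):
        aspect = float(np.exp(abs(params.focus_aspect_log_sd * rng.standard_normal())))
        r = params.focus_radius_px * radius_scale
        a, b = r * math.sqrt(aspect), r / math.sqrt(aspect)
        theta = rng.uniform(0.0, math.pi)
        margin = a + 2.0
        if mask_r <= margin:
            raise ValueError(
                f"focus with semi-major axis {a:.1f} px cannot fit inside the "
                f"nuclear mask of radius {mask_r:.1f} px"
            )
        # uniform position in the shrunken disc so the focus stays inside the
        # mask; rejection keeps foci disjoint so each one's analytic ground
        # truth stays meaningful
        fy = fx = 0.0
        for attempt in range(200):
            rho = (mask_r - margin) * math.sqrt(rng.random())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            fy, fx = cy + rho * math.sin(phi), cx + rho * math.cos(phi)
            if allow_overlap or all(
                math.hypot(fy - py, fx - px) > margin + pr for py, px, pr in placed
            ):
                break
        else:
            raise ValueError(
                f"could not place focus {k} without overlap after 200 tries; "
                "reduce n_foci or focus_radius_px"
            )
        placed.append((fy, fx, margin))
        rr, cc = draw.ellipse(fy, fx, a, b, shape=(h, w), rotation=theta)
        canvas[rr, cc] += (params.focus_level - params.background_level) * amplitude_scale
        area, perim, sf = _ellipse_truth(a, b)
        truth_rows.append(
            dict(focus_id=k, cy=fy, cx=fx, a_px=a, b_px=b, theta=theta,
                 area_px=area, perimeter_px=perim, shape_factor=sf)
        )
    img = np.full((h, w), params.background_level, dtype=float)
    img[mask] += canvas[mask]
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        truth_rows,
        columns=["focus_id", "cy", "cx", "a_px", "b_px", "theta", "area_px", "perimeter_px", "shape_factor"],
    )
    return NucleusImage(image_id=image_id, image=img, mask=mask, truth=truth)


def generate_nucleus_images(params: ImageGenParams) -> list[NucleusImage]:
    """Render ``n_images`` synthetic nuclei with analytic focus ground truth."""
    rng = np.random.default_rng(params.seed)
    return [_render_nucleus(rng, params, f"nucleus{i:04d}") for i in range(params.n_images)]


def generate_dispersal_series(
    params: ImageGenParams, spread_factors: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0)
) -> list[tuple[float, NucleusImage]]:
    """Emulate progressive focus disassembly (the formamide series).

    For each spread factor f the focus radii are multiplied by f and the
    per-focus amplitude divided by f**2, so the integrated signal above
    background is held constant while the staining becomes more diffuse.
    The intensity coefficient of variation over the nuclear mask therefore
    decreases along the series.
    """
    out = []
    for i, f in enumerate(spread_factors):
        if f <= 0:
            raise ValueError("spread factors must be positive")
        rng = np.random.default_rng(params.seed)  # same layout for every factor
        out.append(
            (f, _render_nucleus(rng, params, f"dispersal{i:02d}", radius_scale=f,
                                amplitude_scale=1.0 / f**2, allow_overlap=True))
        )
    return out
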
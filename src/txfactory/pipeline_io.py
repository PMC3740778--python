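"""Readers, writers, configuration and the end-to-end pipeline.

Interval data travel as BED (0-based, half-open).  The default genomic unit
is Kb with fractional coordinates; a ``bp`` dialect divides coordinates by
1000 on read, and micron (``um``) input is converted through a spreading
calibration.  Tables are tab-separated text.  All file writes are atomic
(write to a temporary file, then rename), and every stage seed is derived
deterministically from the single global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import cowindow as cw
from . import foci_image_stats as fis
from . import spread_morphometrics as sm
from . import synthetic_data as sd
from . import copolymer_sim as cp

__all__ = [
    "PipelineConfig",
    "read_tracks_bed",
    "write_tracks_bed",
    "read_marks_bed",
    "write_marks_bed",
    "atomic_write_text",
    "write_table",
    "run_pipeline",
]

log = logging.getLogger("txfactory")


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------


def atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_table(df: pd.DataFrame, path: Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")  # tab or comma, autodetected


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"kb": 1.0, "bp": 1e-3}


def write_tracks_bed(fibres, path: Path) -> None:
    """Tracks as BED: fibre id in the chrom column, cluster id in the name.

    A ``#fibre`` header line per fibre records its total genomic extent so a
    read-back reconstructs the fibre exactly.
    """
    lines = []
    for f in fibres:
        lines.append(f"#fibre\t{f.fibre_id}\ttotal_kb={float(f.total_kb)!r}")
        for i, ((s, e), cid) in enumerate(zip(f.tracks, f.truth_cluster_ids)):
            lines.append(f"{f.fibre_id}\t{float(s)!r}\t{float(e)!r}\ttrack{i:05d};cluster={cid}")
    atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_tracks_bed(
    path: Path, unit: str = "kb", calibration: sm.Calibration | None = None
) -> list[sd.SpreadFibre]:
    """Read track BED into fibres, grouped by the chrom (fibre id) column.

    ``unit`` is ``kb`` (default), ``bp`` or ``um``; micron input requires a
    calibration.  Malformed lines and overlapping tracks are rejected with
    the offending line or fibre named.
    """
    if unit not in ("kb", "bp", "um"):
        raise ValueError("unit must be one of kb, bp, um")
    if unit == "um" and calibration is None:
        raise ValueError("micron input requires a spreading calibration")
    scale = calibration.kb_per_um if unit == "um" else _UNIT_SCALE[unit]
    per_fibre: dict[str, list] = {}
    totals: dict[str, float] = {}
    order: list[str] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("#fibre"):
            parts = raw.split("\t")
            if len(parts) == 3 and parts[2].startswith("total_kb="):
                totals[parts[1]] = float(parts[2].removeprefix("total_kb="))
            continue
        if raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: expected at least 3 BED fields")
        try:
            start, end = float(parts[1]) * scale, float(parts[2]) * scale
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: non-numeric coordinates") from err
        if end <= start:
            raise ValueError(f"{path}:{ln}: end must exceed start")
        cid = -1
        if len(parts) >= 4 and "cluster=" in parts[3]:
            cid = int(parts[3].split("cluster=")[1].split(";")[0])
        fid = parts[0]
        if fid not in per_fibre:
            per_fibre[fid] = []
            order.append(fid)
        per_fibre[fid].append((start, end, cid))
    fibres = []
    for fid in order:
        rows = per_fibre[fid]
        tracks = np.array([(s, e) for s, e, _ in rows])
        cids = np.array([c for _, _, c in rows])
        try:
            fibres.append(
                sd.SpreadFibre(
                    fibre_id=fid, tracks=tracks,
                    transcript_marks=np.empty(0), polii_marks=np.empty(0),
                    truth_cluster_ids=cids,
                    total_kb=totals.get(fid, float(tracks[:, 1].max())),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: fibre {fid}: {err}") from err
    return fibres


def write_marks_bed(fibres, path: Path, kind: str) -> None:
    """Point marks ('transcripts' or 'polii') as zero-length BED intervals."""
    attr = {"transcripts": "transcript_marks", "polii": "polii_marks"}[kind]
    lines = []
    for f in fibres:
        for i, pos in enumerate(getattr(f, attr)):
            lines.append(f"{f.fibre_id}\t{float(pos)!r}\t{float(pos)!r}\t{kind}{i:05d}")
    atomic_write_text(Path(path), "\n".join(lines) + ("\n" if lines else ""))


def read_marks_bed(path: Path, unit: str = "kb", calibration: sm.Calibration | None = None) -> dict[str, np.ndarray]:
    """Mark positions per fibre id."""
    if unit == "um" and calibration is None:
        raise ValueError("micron input requires a spreading calibration")
    scale = calibration.kb_per_um if unit == "um" else _UNIT_SCALE[unit]
    out: dict[str, list[float]] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected at least 2 fields")
        out.setdefault(parts[0], []).append(float(parts[1]) * scale)
    return {k: np.array(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    Per-stage seeds are spawned deterministically from ``seed``; parameter
    groups mirror the generator/analysis dataclasses.  The configuration
    round-trips losslessly through YAML.
    """

    seed: int = 0
    outdir: str = "txfactory_out"
    log_level: str = "INFO"
    stages: tuple[str, ...] = ("spreads", "cowindow", "images", "copolymer")
    spread: sd.SpreadGenParams = None  # type: ignore[assignment]
    expression: sd.ExprGenParams = None  # type: ignore[assignment]
    cowindow: cw.CowindowParams = None  # type: ignore[assignment]
    images: sd.ImageGenParams = None  # type: ignore[assignment]
    sim: cp.SimParams = None  # type: ignore[assignment]
    sim_clusters: int = 1
    sim_spacer_beads: int = 120  # desk-scale spacer for the pipeline demo run
    n_images: int = 5

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(hash_stage(stage),))
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def resolved(self) -> "PipelineConfig":
        """Fill unset parameter groups with defaults wired to derived seeds."""
        spread = self.spread or sd.SpreadGenParams(n_clusters=50, seed=self.stage_seed("spreads"))
        expression = self.expression or sd.ExprGenParams(
            planted_clusters=((0, 10_000.0, 500.0, 8),), seed=self.stage_seed("expression")
        )
        cowin = self.cowindow or cw.CowindowParams(n_permutations=200, seed=self.stage_seed("cowindow"))
        images = self.images or sd.ImageGenParams(n_images=self.n_images, seed=self.stage_seed("images"))
        sim = self.sim or cp.SimParams(n_steps=200_000, record_interval=5_000, seed=self.stage_seed("copolymer"))
        return dataclasses.replace(
            self, spread=spread, expression=expression, cowindow=cowin, images=images, sim=sim
        )

    def to_yaml(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return yaml.safe_dump(enc(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def tup(x):
            return tuple(tup(v) if isinstance(v, list) else v for v in x) if isinstance(x, list) else x

        groups = dict(
            spread=sd.SpreadGenParams, expression=sd.ExprGenParams,
            cowindow=cw.CowindowParams, images=sd.ImageGenParams, sim=cp.SimParams,
        )
        kwargs = {}
        for k, v in raw.items():
            if k in groups and v is not None:
                kwargs[k] = groups[k](**{kk: tup(vv) for kk, vv in v.items()})
            else:
                kwargs[k] = tup(v)
        return cls(**kwargs)


def hash_stage(stage: str) -> int:
    """Stable (non-salted) small integer key for a stage name."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _stage_spreads(cfg: PipelineConfig, outdir: Path) -> dict:
    sample = sd.generate_spread_fibres(cfg.spread)
    write_tracks_bed(sample.fibres, outdir / "tracks.bed")
    write_marks_bed(sample.fibres, outdir / "transcripts.bed", "transcripts")
    write_marks_bed(sample.fibres, outdir / "polii.bed", "polii")
    write_table(sample.truth, outdir / "truth_clusters.tsv")
    clusters = [c for f in sample.fibres for c in sm.detect_clusters(f)]
    stats = sm.cluster_statistics(clusters)
    lengths = sample.track_lengths_kb()
    fit = sm.fit_lognormal(lengths) if lengths.size >= 2 else None
    marks = sm.marks_per_track(sample.fibres)
    summary = pd.DataFrame(
        [
            dict(
                n_fibres=len(sample.fibres),
                n_tracks=int(lengths.size),
                track_mean_kb=float(lengths.mean()) if lengths.size else np.nan,
                track_lognormal_mu=fit.mu_log if fit else np.nan,
                track_lognormal_sigma=fit.sigma_log if fit else np.nan,
                n_clusters=stats.n_clusters,
                tus_per_cluster_mean=stats.tus_per_cluster_mean,
                span_mean_kb=stats.span_mean_kb,
                transcripts_per_track=marks["transcripts"].mean,
                polii_per_track=marks["polii"].mean,
                active_fraction=sample.active_fraction() if sample.fibres else np.nan,
            )
        ]
    )
    write_table(summary, outdir / "spread_summary.tsv")
    return dict(
        outputs=["tracks.bed", "transcripts.bed", "polii.bed", "truth_clusters.tsv", "spread_summary.tsv"],
        params=dataclasses.asdict(cfg.spread),
    )


def _stage_cowindow(cfg: PipelineConfig, outdir: Path) -> dict:
    genes = sd.generate_expression_table(cfg.expression)
    write_table(genes, outdir / "genes.tsv")
    results = cw.permutation_test(genes, cfg.cowindow, chrom_length_kb=cfg.expression.chrom_length_kb)
    write_table(results, outdir / "windows.tsv")
    regions = cw.merge_significant(results)
    write_table(regions, outdir / "coexpressed_regions.tsv")
    bed = "".join(f"{r.chrom}\t{r.start_kb!r}\t{r.end_kb!r}\tcoexpressed\n" for r in regions.itertuples())
    atomic_write_text(outdir / "coexpressed_regions.bed", bed)
    return dict(
        outputs=["genes.tsv", "windows.tsv", "coexpressed_regions.tsv", "coexpressed_regions.bed"],
        params={**dataclasses.asdict(cfg.expression), **dataclasses.asdict(cfg.cowindow)},
    )


def _stage_images(cfg: PipelineConfig, outdir: Path) -> dict:
    images = sd.generate_nucleus_images(cfg.images)
    focus_tables = []
    cv_rows = []
    outputs = []
    for im in images:
        tif = outdir / f"{im.image_id}.tiff"
        tmp = tif.with_name(tif.name + ".tmp")
        tifffile.imwrite(tmp, im.image)
        os.replace(tmp, tif)
        outputs.append(tif.name)
        labels = fis.segment_foci(im.image, im.mask)
        tab = fis.measure_foci(im.image, labels)
        tab.insert(0, "image_id", im.image_id)
        focus_tables.append(tab)
        st = fis.intensity_cv(im.image, im.mask, image_id=im.image_id)
        cv_rows.append(dataclasses.asdict(st))
    write_table(pd.concat(focus_tables, ignore_index=True), outdir / "foci.tsv")
    write_table(pd.DataFrame(cv_rows), outdir / "nuclei_cv.tsv")
    return dict(outputs=outputs + ["foci.tsv", "nuclei_cv.tsv"], params=dataclasses.asdict(cfg.images))


def _stage_copolymer(cfg: PipelineConfig, outdir: Path) -> dict:
    spec = cp.default_block_spec(n_clusters=cfg.sim_clusters, spacer_coil_beads=cfg.sim_spacer_beads)
    conf = cp.build_chain(spec)
    res = cp.run_mc(conf, cfg.sim)
    metrics = cp.domain_metrics(res.conformation)
    beads = pd.DataFrame(
        dict(
            bead=np.arange(spec.n_beads),
            x=res.conformation.coords[:, 0],
            y=res.conformation.coords[:, 1],
            z=res.conformation.coords[:, 2],
            label=np.where(res.conformation.labels, "rod", "coil"),
        )
    )
    write_table(beads, outdir / "final_conformation.tsv")
    trace = pd.DataFrame(
        dict(step=np.arange(len(res.energies)) * cfg.sim.record_interval, energy_kt=res.energies)
    )
    write_table(trace, outdir / "energy_trace.tsv")
    write_table(pd.DataFrame([dataclasses.asdict(metrics)]), outdir / "domain_metrics.tsv")
    return dict(
        outputs=["final_conformation.tsv", "energy_trace.tsv", "domain_metrics.tsv"],
        params=dataclasses.asdict(cfg.sim),
    )


_STAGES = {
    "spreads": _stage_spreads,
    "cowindow": _stage_cowindow,
    "images": _stage_images,
    "copolymer": _stage_copolymer,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and write a manifest.

    Rerunning with the same configuration reproduces byte-identical tables.
    A stage failure aborts with the stage named, after writing a manifest of
    the outputs produced so far.
    """
    cfg = config.resolved()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(name)s %(levelname)s %(message)s")
    atomic_write_text(outdir / "config.yaml", cfg.to_yaml())
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    for stage in cfg.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid stages: {sorted(_STAGES)}")
        log.info("stage %s: starting", stage)
        try:
            manifest["stages"][stage] = _STAGES[stage](cfg, outdir)
        except Exception as err:
            atomic_write_text(outdir / "manifest.json", json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        log.info("stage %s: done", stage)
    atomic_write_text(outdir / "manifest.json", json.dumps(manifest, indent=2, default=str))
    return manifest
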
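"""Measure chromatin-spread morphometrics on synthetic fibres.

Generates hyperacetylated-track fibres at the calibrated defaults (lognormal
track lengths averaging 15 Kb, intra-cluster gaps averaging 30 Kb, 8 +/- 2
tracks per cluster) and measures everything back: the spreading calibration
from a 47.26 Kb probe, the track-length lognormal fit, the <100 Kb cluster
rule, and marks per track.
"""

import numpy as np

from txfactory.spread_morphometrics import (
    cluster_statistics,
    detect_clusters,
    estimate_calibration,
    fit_lognormal,
    marks_per_track,
    simulate_probe_measurements,
)
from txfactory.synthetic_data import SpreadGenParams, generate_spread_fibres

sample = generate_spread_fibres(SpreadGenParams(n_clusters=500, seed=42))
lengths = sample.track_lengths_kb()
fit = fit_lognormal(lengths)
print(f"{lengths.size} tracks: lognormal fit mu={fit.mu_log:.3f}, sigma={fit.sigma_log:.3f}, "
      f"arithmetic mean {fit.arith_mean:.2f} Kb")
print("  -> the track-length distribution is right-skewed with a ~15 Kb mean,")
print("     one hyperacetylated track corresponding to one transcription unit")

clusters = [c for f in sample.fibres for c in detect_clusters(f)]
stats = cluster_statistics(clusters)
print(f"{stats.n_clusters} clusters (>=2 tracks separated by <100 Kb): "
      f"{stats.tus_per_cluster_mean:.2f} +/- {stats.tus_per_cluster_sd:.2f} TUs/cluster, "
      f"span {stats.span_mean_kb:.0f} +/- {stats.span_sd_kb:.0f} Kb "
      f"(range {stats.span_min_kb:.0f}-{stats.span_max_kb:.0f})")

gaps = np.concatenate([f.gaps_kb[f.gaps_kb < 100] for f in sample.fibres])
print(f"mean intra-cluster gap {gaps.mean():.1f} Kb over {gaps.size} gaps")

marks = marks_per_track(sample.fibres)
print(f"marks per track: {marks['transcripts'].mean:.2f} +/- {marks['transcripts'].sd:.2f} transcripts, "
      f"{marks['polii'].mean:.2f} +/- {marks['polii'].sd:.2f} P-RNA pol II")
print("  -> most tracks carry at most one engaged polymerase")

cal = estimate_calibration(simulate_probe_measurements(100, seed=7))
print(f"spreading calibration from 100 probe measurements: "
      f"{cal.kb_per_um:.2f} +/- {cal.se:.2f} Kb/um")
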
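#!/usr/bin/env python
"""Map statistics and marker-density tracks.

Summarises the map built in the previous step (total and per-group
lengths, markers per group, mean marker interval) and computes the
3 cM / 0.3 cM sliding-window density track per linkage group, plus an
optional heat-map rendering.
"""

import json
import pathlib

import pandas as pd

from grasspanel.linkage import GeneticMap
from grasspanel.reporting import density_heatmap, density_track, map_stats

BASE = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = BASE / "scratch"
RESULTS = BASE / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "map.tsv", sep="\t")
    groups = [
        (gid, list(sub["marker_id"]), list(sub["position_cM"]))
        for gid, sub in df.groupby("group", sort=True)
    ]
    gmap = GeneticMap(groups=groups)
    stats = map_stats(gmap)
    (RESULTS / "map_stats.json").write_text(json.dumps({
        "total_length_cM": stats.total_length_cM,
        "n_markers": stats.n_markers,
        "mean_group_length_cM": stats.mean_group_length,
        "mean_markers_per_group": stats.mean_markers_per_group,
        "mean_interval_cM": stats.mean_interval_cM,
        "group_lengths": stats.group_lengths,
        "group_counts": stats.group_counts,
    }, indent=1))
    tracks = []
    for gid, _, pos in gmap.groups:
        tr = density_track(pos, gid)
        tr.to_frame().to_csv(RESULTS / f"density_{gid}.tsv", sep="\t", index=False)
        tracks.append(tr)
    print(f"total map length : {stats.total_length_cM:.1f} cM over {len(groups)} groups")
    print(f"markers mapped   : {stats.n_markers}")
    print(f"mean group length: {stats.mean_group_length:.1f} cM")
    print(f"mean markers/LG  : {stats.mean_markers_per_group:.1f}")
    print(f"mean interval    : {stats.mean_interval_cM:.2f} cM")
    for tr in tracks:
        print(f"  {tr.group_id}: density {tr.min_count}-{tr.max_count} markers/3 cM")
    if density_heatmap(tracks, SCRATCH / "density_heatmap.png"):
        print("wrote density_heatmap.png")


if __name__ == "__main__":
    main()
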
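"""Merge hydration maps from several receptor conformations into sphere weights.

Three maps of the same (superposed) binding site disagree slightly on where
a hydration site sits and how unfavorable it is.  Merging averages the
scores of neighboring sites across maps; grouping then sums nearby merged
sites onto a single hydration sphere, and a carboxylate-adjacent weight is
distributed equally over the water-occupied members of the carboxylate
sphere set.  The total energetic weight is conserved at every step.
"""

from hydrabind import (
    ClusterConfig,
    HydrationMap,
    HydrationSite,
    distribute_carboxylate,
    group_nearby_sites,
    merge_maps,
)


def make_map(label, sites):
    cfg = ClusterConfig(n_frames=100)
    return HydrationMap(label, [
        HydrationSite(site_id=i, center=c, occupancy_p=0.7, n_waters=50, score=s)
        for i, (c, s) in enumerate(sites)
    ], cfg)


maps = [
    make_map("conf-A", [((0.0, 0.0, 0.0), 3.0), ((6.0, 0.0, 0.0), 1.0)]),
    make_map("conf-B", [((0.6, 0.2, 0.0), 2.0), ((6.3, 0.0, 0.0), 0.5)]),
    make_map("conf-C", [((0.2, -0.3, 0.0), 2.5)]),
]

merged = merge_maps(maps, merge_radius=2.0)
print("merged sites (score = mean over contributing maps):")
for m in merged:
    print(f"  site {m.merged_id}: center=({m.center[0]:.2f},{m.center[1]:.2f},"
          f"{m.center[2]:.2f})  score={m.averaged_score:.2f} "
          f"from {m.contributing_maps} maps {m.per_map_scores}")

assignments = group_nearby_sites(merged, group_radius=8.0)
print("grouping all merged sites onto one sphere sums their weights:")
for a in assignments:
    print(f"  sphere {a.agbnp_site_id}: h_s = {a.h_s:.2f} kcal/mol "
          f"(from merged sites {a.source_hsa_ids})")

total_in = sum(m.averaged_score for m in merged)
total_out = sum(a.h_s for a in assignments)
print(f"conservation: sum of merged scores {total_in:.2f} == sum of h_s {total_out:.2f}")

# a strongly unfavorable site next to an Asp carboxylate: its weight is
# split equally over the three water-occupied carboxylate spheres
shares = distribute_carboxylate(2.83, [3, 4, 5])
print("carboxylate distribution of 2.83 kcal/mol over occupied spheres 3,4,5:")
for sid, h in shares:
    print(f"  sphere {sid}: h_s = {h:.4f}")
print(f"  total = {sum(h for _, h in shares):.2f}")
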
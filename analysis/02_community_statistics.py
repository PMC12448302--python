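#!/usr/bin/env python
"""Diversity, group-difference and distance-decay statistics.

Consumes the simulated well-mixed and selection-gradient communities from
01_simulate_communities.py and reports Shannon/Simpson diversity, ANOSIM
between trenches, and OLS distance-decay of Bray-Curtis dissimilarity
against geographic distance and depth difference.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hadalvirome import ecology, io

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "community_stats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("well_mixed", "selection_gradient"):
        table = io.read_abundance(BASE / "simulated" / f"{name}.abundance.tsv")
        meta = io.read_metadata(BASE / "simulated" / f"{name}.metadata.tsv")

        div = ecology.alpha_diversity(table)
        div.to_csv(OUT / f"{name}.alpha.tsv", sep="\t")

        bc = ecology.bray_curtis(table)
        r, p = ecology.anosim(bc, meta["trench"].tolist(), n_perm=999, seed=1)

        geo = ecology.pairwise_geographic_km(meta)
        slope_g, _, r2_g, p_g = ecology.distance_decay(bc, geo)
        depth = meta["water_depth"].values
        ddiff = pd.DataFrame(np.abs(depth[:, None] - depth[None, :]),
                             index=meta.index, columns=meta.index)
        slope_d, _, r2_d, p_d = ecology.distance_decay(bc, ddiff)

        stats = pd.DataFrame([
            {"statistic": "anosim_R", "value": r, "p": p},
            {"statistic": "decay_slope_per_km", "value": slope_g, "p": p_g},
            {"statistic": "decay_r2_geo", "value": r2_g, "p": p_g},
            {"statistic": "decay_slope_per_m_depth", "value": slope_d, "p": p_d},
            {"statistic": "decay_r2_depth", "value": r2_d, "p": p_d},
        ])
        stats.to_csv(OUT / f"{name}.stats.tsv", sep="\t", index=False)
        print(f"{name}: Shannon median {div['shannon'].median():.3f}, "
              f"ANOSIM R={r:.3f} (p={p:.3g}), "
              f"geo decay slope {slope_g:.3g} (p={p_g:.3g})")


if __name__ == "__main__":
    main()
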
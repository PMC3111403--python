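"""Shared fixtures: reference ED50 values, noiseless fits, random feature
tables, and a deliberately naive brute-force oracle for the transcript
filter (nested loops, no grouping shortcuts) used for equivalence testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synray import (
    DoseResponseData,
    FourParamLogistic,
    MonoGenParams,
    simulate_monotherapy,
)

# Published monotherapy ED50s (μM) and display ratios for the five breast
# cell lines: (DHA ED50, CCM ED50, printed DHA:CCM ratio)
CELL_LINE_ED50S = {
    "MCF7": (56.5, 28.0, (55, 30)),
    "MCF10AT": (93.2, 45.8, (95, 45)),
    "MDA-MB-231": (36.7, 34.7, (35, 35)),
    "SK-BR-3": (63.8, 39.2, (60, 40)),
    "MDA-MB-361": (52.5, 23.0, (50, 25)),
}


@pytest.fixture(scope="session")
def cell_line_ed50s():
    return CELL_LINE_ED50S


def noiseless_fit(ed50, hillslope=-2.0, bottom=0.0, top=100.0, label="ref"):
    data = simulate_monotherapy(
        MonoGenParams(
            ed50=ed50, hillslope=hillslope, bottom=bottom, top=top, noise_sd=0.0, label=label
        )
    )
    return FourParamLogistic(data).fit()


@pytest.fixture(scope="session")
def skbr3_fits():
    """Noiseless 4PL fits at the SK-BR-3 monotherapy ED50s (DHA, CCM)."""
    return noiseless_fit(63.8, label="DHA"), noiseless_fit(39.2, label="CCM")


# ---------------------------------------------------------------------------
# brute-force transcript-filter oracle


def random_feature_tables(seed, n_features_max=100, max_features_per_gene=3):
    """Three replicate tables with ratios/P values clustered around the
    decision thresholds so boundary behaviour is exercised."""
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(5, max(6, n_features_max // 2)))
    rows = []
    for g in range(n_genes):
        for k in range(int(rng.integers(1, max_features_per_gene + 1))):
            rows.append((f"f{g:03d}_{k}", f"g{g:03d}"))
    rows = rows[:n_features_max]
    reps = []
    for _ in range(3):
        ratio = np.exp(rng.normal(0.0, 1.1, size=len(rows)))
        # sprinkle exact-boundary values
        bmask = rng.random(len(rows)) < 0.1
        ratio[bmask] = rng.choice([2.0, 0.5, 1.999, 0.501], size=bmask.sum())
        pv = rng.choice([0.001, 0.005, 0.01, 0.0101, 0.02, 0.2], size=len(rows))
        reps.append(
            pd.DataFrame(
                {
                    "feature_id": [f for f, _ in rows],
                    "gene_id": [g for _, g in rows],
                    "ratio": ratio,
                    "p_value": pv,
                }
            )
        )
    return reps


def brute_force_filter(reps, fc=2.0, p=0.01):
    """Reference implementation: plain nested loops over features/replicates.

    Returns (surviving, genes) where surviving maps feature_id ->
    (gene_id, direction, mean_ratio, mean_fc_signed, mean_p) and genes maps
    gene_id -> dict(status=..., feature_id=..., ...) after resolution.
    """
    by_rep = [{r.feature_id: r for r in rep.itertuples()} for rep in reps]
    surviving = {}
    for fid in by_rep[0]:
        directions = []
        for rep in by_rep:
            rec = rep[fid]
            if rec.ratio >= fc and rec.p_value <= p:
                directions.append("up")
            elif rec.ratio <= 1.0 / fc and rec.p_value <= p:
                directions.append("down")
            else:
                directions.append(None)
        if directions[0] is not None and directions.count(directions[0]) == 3:
            ratios = [rep[fid].ratio for rep in by_rep]
            pvals = [rep[fid].p_value for rep in by_rep]
            sfc = [r if r >= 1 else -1.0 / r for r in ratios]
            surviving[fid] = (
                by_rep[0][fid].gene_id,
                directions[0],
                sum(ratios) / 3.0,
                sum(sfc) / 3.0,
                sum(pvals) / 3.0,
            )
    genes = {}
    gene_ids = sorted({g for g, *_ in surviving.values()})
    for gid in gene_ids:
        feats = [(fid, v) for fid, v in surviving.items() if v[0] == gid]
        dirs = {v[1] for _, v in feats}
        if len(dirs) > 1:
            genes[gid] = {"status": "excluded_contradictory"}
        else:
            best = min(feats, key=lambda fv: (fv[1][4], fv[0]))
            fid, (g, direction, mean_ratio, mean_fc, mean_p) = best
            genes[gid] = {
                "status": "significant",
                "feature_id": fid,
                "direction": direction,
                "mean_ratio": mean_ratio,
                "signed_fold_change": mean_fc,
                "mean_p": mean_p,
            }
    return surviving, genes
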
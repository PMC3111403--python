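"""Three-replicate microarray responder filtering and matrix assembly.

Input is one treated/control ratio table per replicate (three replicates
per treatment) with one row per array feature: ``feature_id``, ``gene_id``,
``ratio`` (> 0) and an error-model ``p_value``.  The pipeline:

1. **feature call** — a feature responds in a replicate when its fold
   change is at least 2 in either direction (ratio >= 2 or <= 0.5) with
   P <= 0.01; both thresholds are inclusive;
2. **three-replicate filter** — a feature survives only if it responds in
   the *same* direction in all three replicates; its fold change and P are
   then averaged across the replicates;
3. **gene resolution** — a gene whose surviving features disagree in
   direction is excluded as contradictory; otherwise the gene takes the
   values of its surviving feature with the smallest mean P (ties broken
   lexicographically by feature id).  Sub-threshold features never veto a
   gene;
4. **matrix assembly** — rows are genes significant in at least one
   treatment; cells where a gene is not significant for a treatment are
   filled in from the replicate-averaged whole-array table (lowest-mean-P
   feature for the gene) and flagged non-significant.  Cell values are
   log2 of the mean ratio.

Down-regulation is displayed as a signed fold change of -1/ratio (so a
ratio of 0.135 reads as -7.4-fold), keeping magnitude >= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateSet",
    "ResponseMatrix",
    "call_feature",
    "signed_fold_change",
    "three_replicate_filter",
    "resolve_genes",
    "assemble_matrix",
    "count_responders",
]

FEATURE_COLUMNS = ["feature_id", "gene_id", "ratio", "p_value"]


def _validate_table(df: pd.DataFrame, name: str = "feature table") -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} lacks columns {missing}")
    if df["feature_id"].duplicated().any():
        dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"{name} has duplicate feature ids: {dupes[:5]}")
    r = df["ratio"].to_numpy(float)
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise ValueError(f"{name}: ratios must be finite and > 0")
    p = df["p_value"].to_numpy(float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{name}: p values must lie in [0, 1]")
    return df


@dataclass(frozen=True)
class ReplicateSet:
    """Exactly three replicate feature tables over one feature universe."""

    treatment: str
    replicates: tuple

    def __post_init__(self):
        if len(self.replicates) != 3:
            raise ValueError(
                f"treatment {self.treatment!r} needs exactly 3 replicates, "
                f"got {len(self.replicates)}"
            )
        universe = None
        for i, rep in enumerate(self.replicates):
            _validate_table(rep, f"{self.treatment} replicate {i + 1}")
            ids = frozenset(rep["feature_id"])
            if universe is None:
                universe = ids
            elif ids != universe:
                raise ValueError(
                    f"treatment {self.treatment!r}: replicate {i + 1} covers a "
                    "different feature universe"
                )


def signed_fold_change(ratio):
    """Signed fold change: ratio for up (>= 1), -1/ratio for down (< 1)."""
    r = np.asarray(ratio, float)
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if np.ndim(ratio) == 0 else out


def call_feature(ratio: float, p_value: float, fc: float = 2.0, p: float = 0.01):
    """Responder call for one feature in one replicate.

    Returns ``(responder, direction)`` where direction is "up"/"down" for a
    responder and None otherwise.  Thresholds are inclusive: ratio exactly
    ``fc`` (or ``1/fc``) with P exactly ``p`` is a responder.
    """
    if not (ratio > 0 and np.isfinite(ratio)):
        raise ValueError(f"ratio must be finite and > 0, got {ratio}")
    if ratio >= fc and p_value <= p:
        return True, "up"
    if ratio <= 1.0 / fc and p_value <= p:
        return True, "down"
    return False, None


def three_replicate_filter(
    reps: ReplicateSet, fc: float = 2.0, p: float = 0.01
) -> pd.DataFrame:
    """Features responding in the same direction in all three replicates.

    Returns a frame with one row per surviving feature: ``feature_id``,
    ``gene_id``, ``direction``, ``mean_ratio``, ``mean_fold_change``
    (signed, averaged over the replicate signed fold changes) and
    ``mean_p``, sorted by feature id.
    """
    frames = [
        rep.sort_values("feature_id").reset_index(drop=True) for rep in reps.replicates
    ]
    base = frames[0]
    ratios = np.column_stack([f["ratio"].to_numpy(float) for f in frames])
    pvals = np.column_stack([f["p_value"].to_numpy(float) for f in frames])
    up = (ratios >= fc) & (pvals <= p)
    down = (ratios <= 1.0 / fc) & (pvals <= p)
    keep_up = up.all(axis=1)
    keep_down = down.all(axis=1)
    keep = keep_up | keep_down
    out = pd.DataFrame(
        {
            "feature_id": base["feature_id"].to_numpy()[keep],
            "gene_id": base["gene_id"].to_numpy()[keep],
            "direction": np.where(keep_up[keep], "up", "down"),
            "mean_ratio": ratios[keep].mean(axis=1),
            "mean_fold_change": signed_fold_change(ratios[keep]).mean(axis=1),
            "mean_p": pvals[keep].mean(axis=1),
        }
    )
    return out.sort_values("feature_id").reset_index(drop=True)


def resolve_genes(surviving: pd.DataFrame) -> pd.DataFrame:
    """Collapse surviving features to one response per gene.

    Genes with surviving features in both directions get status
    ``excluded_contradictory`` (and NaN values); all other genes take the
    values of their smallest-mean-P surviving feature and status
    ``significant``.
    """
    rows = []
    for gene, grp in surviving.groupby("gene_id", sort=True):
        if grp["direction"].nunique() > 1:
            rows.append(
                {
                    "gene_id": gene,
                    "feature_id": None,
                    "signed_fold_change": np.nan,
                    "mean_ratio": np.nan,
                    "mean_p": np.nan,
                    "direction": None,
                    "status": "excluded_contradictory",
                }
            )
            continue
        best = grp.sort_values(["mean_p", "feature_id"]).iloc[0]
        rows.append(
            {
                "gene_id": gene,
                "feature_id": best["feature_id"],
                "signed_fold_change": float(best["mean_fold_change"]),
                "mean_ratio": float(best["mean_ratio"]),
                "mean_p": float(best["mean_p"]),
                "direction": best["direction"],
                "status": "significant",
            }
        )
    cols = [
        "gene_id",
        "feature_id",
        "signed_fold_change",
        "mean_ratio",
        "mean_p",
        "direction",
        "status",
    ]
    return pd.DataFrame(rows, columns=cols)


def gene_responses(
    reps: ReplicateSet, fc: float = 2.0, p: float = 0.01
) -> pd.DataFrame:
    """Full per-treatment pipeline: filter features, then resolve genes."""
    return resolve_genes(three_replicate_filter(reps, fc, p))


@dataclass(frozen=True)
class ResponseMatrix:
    """Gene x treatment matrix of log2 mean ratios with a significance mask.

    ``values``: log2(mean ratio); significant cells use the resolved gene's
    representative feature, non-significant cells are filled in from the
    replicate-averaged whole-array table and flagged False in
    ``significant``.
    """

    values: pd.DataFrame
    significant: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.significant.index) or not (
            self.values.columns.equals(self.significant.columns)
        ):
            raise ValueError("values and significance mask must share index/columns")


def _averaged_whole_array(tables) -> pd.DataFrame:
    """Replicate-mean ratio and P per feature of a whole-array table triple."""
    frames = [
        _validate_table(t, "whole-array table").sort_values("feature_id").reset_index(drop=True)
        for t in tables
    ]
    ids = [frozenset(f["feature_id"]) for f in frames]
    if len(frames) != 3 or ids[0] != ids[1] or ids[0] != ids[2]:
        raise ValueError("whole-array tables must be 3 replicates over one universe")
    base = frames[0]
    return pd.DataFrame(
        {
            "feature_id": base["feature_id"],
            "gene_id": base["gene_id"],
            "mean_ratio": np.column_stack(
                [f["ratio"].to_numpy(float) for f in frames]
            ).mean(axis=1),
            "mean_p": np.column_stack(
                [f["p_value"].to_numpy(float) for f in frames]
            ).mean(axis=1),
        }
    )


def assemble_matrix(responders: dict, whole_array: dict) -> ResponseMatrix:
    """Assemble the cross-treatment log2 response matrix.

    Parameters
    ----------
    responders : dict mapping treatment -> resolved gene frame
        Output of :func:`resolve_genes` (or :func:`gene_responses`).
    whole_array : dict mapping treatment -> list of 3 whole-array tables
        Full feature tables (all features) for the same treatments.

    Raises
    ------
    KeyError
        If a row gene is absent from a treatment's whole-array table
        (universe mismatch).
    """
    treatments = list(responders)
    sig_genes = {
        t: set(df.loc[df["status"] == "significant", "gene_id"]) for t, df in responders.items()
    }
    universe = sorted(set().union(*sig_genes.values())) if sig_genes else []
    if not universe:
        warnings.warn("no significant genes in any treatment; matrix is empty")
        empty = pd.DataFrame(index=pd.Index([], name="gene_id"), columns=treatments)
        return ResponseMatrix(empty.astype(float), empty.astype(bool))

    values = pd.DataFrame(index=pd.Index(universe, name="gene_id"), columns=treatments, dtype=float)
    mask = pd.DataFrame(False, index=values.index, columns=treatments)
    for t in treatments:
        resolved = responders[t].set_index("gene_id")
        avg = _averaged_whole_array(whole_array[t])
        best = (
            avg.sort_values(["mean_p", "feature_id"])
            .groupby("gene_id", sort=False)
            .first()
        )
        for gene in universe:
            if gene in sig_genes[t]:
                values.loc[gene, t] = np.log2(resolved.loc[gene, "mean_ratio"])
                mask.loc[gene, t] = True
            else:
                if gene not in best.index:
                    raise KeyError(
                        f"gene {gene!r} missing from whole-array table for {t!r}"
                    )
                values.loc[gene, t] = np.log2(best.loc[gene, "mean_ratio"])
    return ResponseMatrix(values, mask)


def count_responders(replicate_sets: dict, fc: float = 2.0, p: float = 0.01) -> pd.DataFrame:
    """Per-treatment responder counts, feature-level and gene-level.

    ``n_features`` counts features surviving the three-replicate filter;
    ``n_genes`` counts genes with status ``significant`` after resolution.
    """
    rows = []
    for t, reps in replicate_sets.items():
        surv = three_replicate_filter(reps, fc, p)
        resolved = resolve_genes(surv)
        rows.append(
            {
                "treatment": t,
                "n_features": len(surv),
                "n_genes": int((resolved["status"] == "significant").sum()),
            }
        )
    return pd.DataFrame(rows, columns=["treatment", "n_features", "n_genes"])
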
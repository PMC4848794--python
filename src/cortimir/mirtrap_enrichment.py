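"""RISC pull-down qPCR fold-enrichment analysis.

A MirTrap experiment immunoprecipitates a processing-deficient RISC loaded
with the miRNA of interest; bound transcripts are quantified by qPCR in a
"trap" arm and a scrambled-transfection control arm. Per replicate, each
gene's Ct is normalized to a reference gene (dCt); the arm difference of
mean dCt (ddCt) converts to fold enrichment 2^-ddCt — averaging replicates
on the Ct scale, i.e. a geometric mean of folds. Genes above a strict
2-fold gate versus control are called enriched, and the enriched list is
scored for overlap against the in-silico predicted target list.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "delta_ct",
    "fold_enrichment",
    "analyze_plate",
    "call_enriched",
    "validation_overlap",
]

PLATE_COLUMNS = ("gene", "arm", "replicate", "ct")


def _validate_plate(plate: pd.DataFrame) -> None:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"Ct plate is missing column(s): {sorted(missing)}")


def delta_ct(plate: pd.DataFrame, arm: str, reference_gene: str) -> pd.DataFrame:
    """Per-gene, per-replicate dCt = Ct_gene - Ct_reference within one arm.

    Undetermined Ct values (NaN) propagate to NaN dCt so the replicate is
    excluded downstream. A replicate lacking the reference gene is an error
    naming the arm and replicate.
    """
    _validate_plate(plate)
    sub = plate[plate["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no wells for arm {arm!r}")
    ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
    replicates = sorted(sub["replicate"].unique())
    missing_ref = [int(r) for r in replicates if r not in ref.index or pd.isna(ref.get(r))]
    if missing_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} missing or undetermined in arm "
            f"{arm!r}, replicate(s) {missing_ref}"
        )
    genes = sub[sub["gene"] != reference_gene]
    table = genes.pivot_table(index="gene", columns="replicate", values="ct", aggfunc="mean")
    return table.sub(ref, axis=1)


def fold_enrichment(delta_trap: pd.DataFrame, delta_control: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ddCt and fold enrichment from the two arms' dCt tables.

    ddCt = mean dCt(trap) - mean dCt(control), NaN replicates excluded;
    fold = 2^-ddCt. A gene with no usable replicate in an arm gets NaN fold
    (reported, not dropped). Columns: delta_ct_trap, delta_ct_control,
    delta_delta_ct, fold, n_replicates_used.
    """
    genes = sorted(set(delta_trap.index) | set(delta_control.index))
    mean_trap = delta_trap.mean(axis=1).reindex(genes)
    mean_ctrl = delta_control.mean(axis=1).reindex(genes)
    n_trap = delta_trap.notna().sum(axis=1).reindex(genes, fill_value=0)
    n_ctrl = delta_control.notna().sum(axis=1).reindex(genes, fill_value=0)
    ddct = mean_trap - mean_ctrl
    out = pd.DataFrame(
        {
            "delta_ct_trap": mean_trap,
            "delta_ct_control": mean_ctrl,
            "delta_delta_ct": ddct,
            "fold": np.power(2.0, -ddct),
            "n_replicates_used": np.minimum(n_trap, n_ctrl).astype(int),
        }
    )
    out.index.name = "gene"
    return out


def analyze_plate(plate: pd.DataFrame, reference_gene: str = "GAPDH") -> pd.DataFrame:
    """Convenience: dCt in both arms then fold enrichment, one call."""
    trap = delta_ct(plate, "trap", reference_gene)
    ctrl = delta_ct(plate, "scrambled", reference_gene)
    return fold_enrichment(trap, ctrl)


def call_enriched(results: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Genes with fold strictly above ``threshold``, sorted by fold desc."""
    enriched = results[results["fold"] > threshold]
    return enriched.sort_values("fold", ascending=False)


def validation_overlap(
    enriched_genes: Iterable, predicted_genes: Iterable
) -> tuple[int, float]:
    """Overlap of the experimentally enriched and in-silico predicted lists.

    Symbols are compared case-insensitively. Returns (count, fraction of the
    predicted list); an empty predicted list leaves the fraction undefined
    (NaN, with a warning).
    """
    enriched = {str(g).casefold() for g in enriched_genes}
    predicted = {str(g).casefold() for g in predicted_genes}
    count = len(enriched & predicted)
    if not predicted:
        warnings.warn("empty predicted list: overlap fraction undefined")
        return count, float("nan")
    return count, count / len(predicted)
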
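"""Integrative prioritization of miRNA targets.

Combines seed-site scanning on 3'UTRs (8mer, 7mer-m8, 7mer-A1 site classes
with cross-species conservation), retention of predictions with at least
one conserved site, homolog mapping of human predictions onto mouse gene
identifiers, merging of three parallel prediction runs, and literature
(trust-level) annotation into a five-class evidence ranking:

1. literature interaction with trust "Present";
2. predicted in all three runs + trust "Probably present";
3. predicted in all three runs + trust "Not likely present";
4. predicted in all three runs, no literature interaction;
5. predicted in one/two runs only, no literature interaction.

Rules are evaluated in this priority order; combinations the scheme does
not cover (partial prediction span with a non-"Present" literature trust)
are excluded with a log line rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSite",
    "RUN_IDS",
    "TRUST_LEVELS",
    "scan_seed_sites",
    "filter_conserved",
    "map_homologs",
    "merge_runs",
    "assign_class",
    "integrate",
]

RUN_IDS = ("mouse_on_mouse", "human_on_human", "human_on_mouse")
TRUST_LEVELS = ("Present", "Probably present", "Not likely present", "Absent")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SeedSite:
    """A canonical seed-match site on a UTR (0-based start of the match)."""

    utr_id: str
    position: int
    site_type: str  # "8mer" | "7mer-m8" | "7mer-A1"
    conserved: bool


def _revcomp_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _site_strings(mirna: str) -> dict[str, str]:
    """Target-strand (5'->3') match strings for the three site classes.

    The seed is miRNA positions 2-7; an 8mer pairs positions 2-8 and adds an
    adenine opposite position 1, a 7mer-m8 pairs 2-8, a 7mer-A1 pairs 2-7
    plus the A anchor.
    """
    m = _normalize_rna(mirna)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core_m8 = _revcomp_rna(m[1:8])  # complements positions 2-8
    core_seed = _revcomp_rna(m[1:7])  # complements positions 2-7
    return {"8mer": core_m8 + "A", "7mer-m8": core_m8, "7mer-A1": core_seed + "A"}


def scan_seed_sites(
    mirna_sequence: str,
    utr_sequence: str,
    alignment: Mapping[str, str] | None = None,
    min_species: int = 2,
    utr_id: str = "utr",
    reference_species: str | None = None,
) -> list[SeedSite]:
    """Find canonical seed-match sites on a UTR, with conservation calls.

    Sites are detected on the (ungapped) reference UTR; 8mers take priority,
    so neither a 7mer-m8 at the same start nor the 7mer-A1 nested one base
    downstream of an 8mer is double-reported. When a multi-species
    ``alignment`` (species -> gapped row, equal lengths) is supplied, a site
    is conserved iff the identical site string occurs, gap-free, at the
    aligned columns in at least ``min_species`` non-reference species.
    Without an alignment every site is reported unconserved.
    """
    utr = _normalize_rna(utr_sequence)
    sites_by_type = _site_strings(mirna_sequence)
    col_of: list[int] | None = None
    others: list[str] = []
    if alignment is not None:
        lengths = {len(row) for row in alignment.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        ref_name = reference_species or next(iter(alignment))
        ref_row = _normalize_rna(alignment[ref_name])
        if ref_row.replace("-", "") != utr:
            raise ValueError("reference alignment row does not match the UTR")
        col_of = [i for i, b in enumerate(ref_row) if b != "-"]
        others = [
            _normalize_rna(alignment[name]) for name in alignment if name != ref_name
        ]

    def conserved_at(start: int, site: str) -> bool:
        if col_of is None:
            return False
        cols = col_of[start : start + len(site)]
        n = sum(1 for row in others if "".join(row[c] for c in cols) == site)
        return n >= min_species

    found: list[SeedSite] = []
    taken_8mer: set[int] = set()
    site8 = sites_by_type["8mer"]
    for pos in _find_all(utr, site8):
        found.append(SeedSite(utr_id, pos, "8mer", conserved_at(pos, site8)))
        taken_8mer.add(pos)
    site7m8 = sites_by_type["7mer-m8"]
    for pos in _find_all(utr, site7m8):
        if pos in taken_8mer:
            continue  # subsumed by the 8mer starting here
        found.append(SeedSite(utr_id, pos, "7mer-m8", conserved_at(pos, site7m8)))
    site7a1 = sites_by_type["7mer-A1"]
    for pos in _find_all(utr, site7a1):
        if pos - 1 in taken_8mer:
            continue  # the A anchor belongs to an 8mer one base upstream
        found.append(SeedSite(utr_id, pos, "7mer-A1", conserved_at(pos, site7a1)))
    found.sort(key=lambda s: s.position)
    return found


def _find_all(haystack: str, needle: str) -> list[int]:
    positions = []
    pos = haystack.find(needle)
    while pos != -1:
        positions.append(pos)
        pos = haystack.find(needle, pos + 1)
    return positions


def filter_conserved(predictions: pd.DataFrame) -> pd.DataFrame:
    """Retain prediction rows annotated with at least one conserved site."""
    kept = predictions[predictions["n_conserved_sites"] >= 1].copy()
    dropped = len(predictions) - len(kept)
    if dropped:
        logger.info("conservation filter dropped %d prediction row(s)", dropped)
    return kept


def map_homologs(human_rows: pd.DataFrame, homolog_map: pd.DataFrame) -> pd.DataFrame:
    """Rekey human-gene prediction rows to mouse genes via homolog pairs.

    One human gene paired with several mouse genes yields one row per mouse
    gene; human genes without a pair are dropped (count logged).
    """
    if human_rows.empty or homolog_map.empty:
        if not human_rows.empty:
            logger.info("dropped %d human row(s) with no homolog", len(human_rows))
        return human_rows.iloc[0:0].copy()
    merged = human_rows.merge(
        homolog_map.drop_duplicates(),
        left_on="gene_id",
        right_on="human_gene_id",
        how="inner",
    )
    dropped = human_rows["gene_id"].nunique() - merged["gene_id"].nunique()
    if dropped > 0:
        logger.info("dropped %d human gene(s) with no homolog", dropped)
    out = merged.drop(columns=["gene_id", "human_gene_id"]).rename(
        columns={"mouse_gene_id": "gene_id"}
    )
    return out[human_rows.columns]


def merge_runs(
    run_mouse: Iterable, run_human_on_human_mapped: Iterable, run_human_on_mouse: Iterable
) -> pd.Series:
    """Per-gene prediction span across the three parallel runs.

    ``all_three`` if the (mouse-keyed) gene occurs in every run, otherwise
    ``mouse_or_human``; genes in no run are absent from the output.
    """
    sets = [set(_gene_ids(r)) for r in (run_mouse, run_human_on_human_mapped, run_human_on_mouse)]
    union = set.union(*sets)
    inter = set.intersection(*sets)
    span = {g: ("all_three" if g in inter else "mouse_or_human") for g in union}
    return pd.Series(span, name="targetscan_span", dtype=object)


def _gene_ids(run) -> list:
    if isinstance(run, pd.DataFrame):
        return list(run["gene_id"])
    return list(run)


def assign_class(span: str, trust: str) -> int | None:
    """Evidence class 1-5 for a (prediction span, literature trust) pair.

    Literature trust "Present" dominates regardless of span. ``None`` marks
    the combinations the scheme leaves undefined (partial span with
    "Probably present"/"Not likely present" literature support).
    """
    if trust not in TRUST_LEVELS:
        raise ValueError(f"unknown trust level {trust!r}")
    if span not in ("all_three", "mouse_or_human", "absent"):
        raise ValueError(f"unknown span {span!r}")
    if trust == "Present":
        return 1
    if span == "all_three":
        return {"Probably present": 2, "Not likely present": 3, "Absent": 4}[trust]
    if span == "mouse_or_human" and trust == "Absent":
        return 5
    return None


def integrate(
    runs: Mapping[str, pd.DataFrame],
    homolog_map: pd.DataFrame,
    interactions: pd.DataFrame,
    prior_lists: Mapping[str, Iterable] | None = None,
) -> pd.DataFrame:
    """Produce the integrated target list from raw evidence tables.

    Pipeline: conservation filter on each run -> homolog mapping of the
    human-on-human run -> span merge -> class assignment against literature
    trust (absence of an interaction row means trust "Absent") -> exclusion
    of unclassifiable genes -> prior-dataset flags (one boolean column
    ``in_prior_<name>`` per supplied list, plus ``novel`` when all are
    false). Output is sorted by class, then gene id.
    """
    filtered = {run_id: filter_conserved(df) for run_id, df in runs.items()}
    mapped_hh = map_homologs(filtered.get("human_on_human", _empty_run()), homolog_map)
    span = merge_runs(
        filtered.get("mouse_on_mouse", _empty_run()),
        mapped_hh,
        filtered.get("human_on_mouse", _empty_run()),
    )
    inter = (
        interactions.copy()
        if interactions is not None and len(interactions)
        else pd.DataFrame(columns=["gene_id", "trust"])
    )
    if inter.duplicated("gene_id").any():
        logger.warning("duplicate interaction rows collapsed (best trust kept)")
        rank = {t: i for i, t in enumerate(TRUST_LEVELS)}
        inter = (
            inter.assign(_rank=inter["trust"].map(rank))
            .sort_values("_rank")
            .drop_duplicates("gene_id")
            .drop(columns="_rank")
        )
    trust_of = dict(zip(inter["gene_id"], inter["trust"]))
    genes = sorted(set(span.index) | set(trust_of), key=str)
    records = []
    for gene in genes:
        gene_span = span.get(gene, "absent")
        gene_trust = trust_of.get(gene, "Absent")
        cls = assign_class(gene_span, gene_trust)
        if cls is None:
            logger.info(
                "gene %s excluded: span=%s with trust=%s has no class", gene, gene_span, gene_trust
            )
            continue
        records.append(
            {
                "gene_id": gene,
                "targetscan_span": gene_span,
                "trust": gene_trust,
                "class": cls,
            }
        )
    out = pd.DataFrame.from_records(
        records, columns=["gene_id", "targetscan_span", "trust", "class"]
    )
    prior_lists = prior_lists or {}
    prior_cols = []
    for name, members in prior_lists.items():
        col = f"in_prior_{name}"
        member_set = set(members)
        out[col] = out["gene_id"].isin(member_set)
        prior_cols.append(col)
    out["novel"] = ~out[prior_cols].any(axis=1) if prior_cols else True
    return out.sort_values(["class", "gene_id"], key=_sort_key).reset_index(drop=True)


def _sort_key(col: pd.Series) -> pd.Series:
    return col.astype(str) if col.name == "gene_id" else col


def _empty_run() -> pd.DataFrame:
    return pd.DataFrame(columns=["run_id", "gene_id", "n_conserved_sites"])
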
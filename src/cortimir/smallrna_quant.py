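"""Small-RNA read processing: 3' adapter trimming, exact-match mapping to
hairpin references, mature-region counting with a 4-nt overhang allowance,
reads-per-million normalization, and replicate QC (Spearman correlation,
PCA of normalized expression).

The counting rule attributes an aligned read to a mature miRNA when its
alignment interval lies within the mature region extended by at most
``overhang`` nucleotides on either side — containment with slack, so
templated isomiR ends are kept while star-arm and loop spill-over is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import HairpinReference, MatureRegion

__all__ = [
    "TrimmedRead",
    "HairpinAlignment",
    "MatureCounts",
    "trim_adapter",
    "map_exact",
    "count_mature",
    "rpm_normalize",
    "replicate_correlation",
    "pca_qc",
    "read_hairpins",
    "quantify_fastq",
]


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sequence: str
    kept: bool


@dataclass(frozen=True)
class HairpinAlignment:
    """An exact placement of a read on a hairpin (0-based, half-open)."""

    read_id: str
    hairpin_id: str
    start: int
    end: int
    n_placements: int = 1


@dataclass
class MatureCounts:
    """Mature-miRNA x sample count matrix plus per-sample aligned-read totals."""

    counts: pd.DataFrame
    aligned_reads: pd.Series


def trim_adapter(
    read: str,
    adapter: str,
    min_length: int = 16,
    min_overlap: int = 6,
    read_id: str = "",
) -> TrimmedRead:
    """Clip the 3' adapter from a read, fastx-clipper style.

    The read is cut at the first position where the remainder of the read
    matches a prefix of the adapter: the full adapter if the match is
    internal, or at least ``min_overlap`` adapter bases when the adapter runs
    off the 3' end. Reads shorter than ``min_length`` after trimming are
    flagged ``kept=False``.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    if not read:
        return TrimmedRead(read_id, "", False)
    cut = len(read)
    for i in range(len(read)):
        tail = read[i:]
        if len(tail) >= len(adapter):
            if tail.startswith(adapter):
                cut = i
                break
        elif len(tail) >= min_overlap and adapter.startswith(tail):
            cut = i
            break
    trimmed = read[:cut]
    return TrimmedRead(read_id, trimmed, len(trimmed) >= min_length)


def map_exact(
    read: str,
    hairpins: Sequence[HairpinReference],
    read_id: str = "",
    min_length: int = 16,
) -> list[HairpinAlignment]:
    """All exact substring placements of ``read`` on the hairpin set.

    Overlapping occurrences count separately; ``n_placements`` on every
    returned alignment is the total number of placements found. An empty
    list means the read does not occur anywhere.
    """
    if len(read) < min_length:
        raise ValueError(f"read shorter than min_length={min_length}")
    hits: list[tuple[str, int]] = []
    for hp in hairpins:
        pos = hp.sequence.find(read)
        while pos != -1:
            hits.append((hp.hairpin_id, pos))
            pos = hp.sequence.find(read, pos + 1)
    n = len(hits)
    return [
        HairpinAlignment(read_id, hp_id, start, start + len(read), n)
        for hp_id, start in hits
    ]


def _assign_weight(n_placements: int, policy: str) -> float:
    if policy == "fractional":
        return 1.0 / n_placements
    if policy == "all":
        return 1.0
    if policy == "discard":
        return 1.0 if n_placements == 1 else 0.0
    raise ValueError(f"unknown multimap policy {policy!r}")


def count_mature(
    alignments: Mapping[str, Sequence[HairpinAlignment]] | Sequence[HairpinAlignment],
    mature_regions: Sequence[MatureRegion],
    overhang: int = 4,
    multimap_policy: str = "fractional",
) -> MatureCounts:
    """Count aligned reads per mature region with an overhang allowance.

    A placement ``[a, b)`` on a hairpin is attributed to a mature region
    ``[s, e)`` on the same hairpin iff ``a >= s - overhang`` and
    ``b <= e + overhang``. Multi-placed reads contribute per
    ``multimap_policy``: ``"fractional"`` (weight 1/n_placements, default),
    ``"all"`` (full weight at each placement), or ``"discard"``.

    ``alignments`` is either a mapping sample -> alignments or a flat
    sequence (treated as a single sample named ``"sample"``).
    """
    if overhang < 0:
        raise ValueError("overhang must be non-negative")
    if not isinstance(alignments, Mapping):
        alignments = {"sample": list(alignments)}
    by_hairpin: dict[str, list[MatureRegion]] = {}
    for region in mature_regions:
        by_hairpin.setdefault(region.hairpin_id, []).append(region)
    mature_ids = [r.mature_id for r in mature_regions]
    samples = list(alignments)
    matrix = pd.DataFrame(0.0, index=pd.Index(mature_ids, name="mature_mirna"), columns=samples)
    aligned = pd.Series(0, index=samples, dtype=int)
    for sample, alns in alignments.items():
        aligned[sample] = len({a.read_id for a in alns})
        for aln in alns:
            weight = _assign_weight(aln.n_placements, multimap_policy)
            if weight == 0.0:
                continue
            for region in by_hairpin.get(aln.hairpin_id, ()):
                if aln.start >= region.start - overhang and aln.end <= region.end + overhang:
                    matrix.loc[region.mature_id, sample] += weight
    return MatureCounts(matrix, aligned)


def rpm_normalize(counts: MatureCounts, denominator_mode: str = "aligned") -> pd.DataFrame:
    """Reads-per-million: count * 1e6 / per-sample denominator.

    ``denominator_mode="aligned"`` divides by the reads aligned to hairpins
    (the library-size definition used for depth-bias removal);
    ``"mirna_assigned"`` divides by the mature-assigned column sum instead.
    """
    if denominator_mode == "aligned":
        denom = counts.aligned_reads.astype(float)
    elif denominator_mode == "mirna_assigned":
        denom = counts.counts.sum(axis=0)
    else:
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero denominator for sample(s): {list(zero.index)}")
    return counts.counts * 1e6 / denom


def replicate_correlation(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between sample columns.

    Constant columns have no defined rank correlation; their entries are NaN
    and a warning names them.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    constant = [c for c in counts.columns if counts[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s), correlation undefined: {constant}")
    n = counts.shape[1]
    rho = np.ones((n, n))
    cols = list(counts.columns)
    for i in range(n):
        for j in range(i + 1, n):
            if cols[i] in constant or cols[j] in constant:
                r = np.nan
            else:
                r = stats.spearmanr(counts[cols[i]], counts[cols[j]]).statistic
            rho[i, j] = rho[j, i] = r
    for c in constant:
        rho[cols.index(c), cols.index(c)] = 1.0
    return pd.DataFrame(rho, index=cols, columns=cols)


def pca_qc(rpm: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the leading principal components.

    Each miRNA row is centered across samples; components are ordered by
    explained variance (non-increasing). Returns (coordinates indexed by
    sample, explained variances).
    """
    if rpm.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    centered = rpm.sub(rpm.mean(axis=1), axis=0).to_numpy().T  # samples x genes
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        u[:, :k] * s[:k],
        index=rpm.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    explained = s**2 / (rpm.shape[1] - 1)
    return coords, explained


def read_hairpins(fasta_path, bed_path) -> list[HairpinReference]:
    """Assemble hairpin references from a FASTA plus a mature-region BED."""
    from Bio import SeqIO

    regions: dict[str, list[MatureRegion]] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            regions.setdefault(chrom, []).append(
                MatureRegion(name, chrom, int(start), int(end))
            )
    hairpins = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        hairpins.append(
            HairpinReference(
                record.id, str(record.seq).upper(), tuple(regions.get(record.id, ()))
            )
        )
    return hairpins


def quantify_fastq(
    fastq_by_sample: Mapping[str, object],
    hairpins: Sequence[HairpinReference],
    adapter: str,
    min_length: int = 16,
    overhang: int = 4,
    multimap_policy: str = "fractional",
) -> tuple[MatureCounts, pd.DataFrame]:
    """Trim, map and count one FASTQ per sample; returns counts and a QC
    table of per-sample read fates (total / kept after trimming / aligned)."""
    from Bio import SeqIO

    regions = [r for hp in hairpins for r in hp.mature_regions]
    alignments: dict[str, list[HairpinAlignment]] = {}
    stats_rows = []
    for sample, path in fastq_by_sample.items():
        alns: list[HairpinAlignment] = []
        total = kept = 0
        for record in SeqIO.parse(str(path), "fastq"):
            total += 1
            trimmed = trim_adapter(str(record.seq), adapter, min_length, read_id=record.id)
            if not trimmed.kept:
                continue
            kept += 1
            alns.extend(map_exact(trimmed.sequence, hairpins, read_id=record.id, min_length=min_length))
        alignments[sample] = alns
        stats_rows.append(
            {"sample": sample, "total_reads": total, "kept_after_trim": kept,
             "aligned_reads": len({a.read_id for a in alns})}
        )
    counts = count_mature(alignments, regions, overhang=overhang, multimap_policy=multimap_policy)
    return counts, pd.DataFrame(stats_rows).set_index("sample")
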
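"""Synthetic inputs with known ground truth for every pipeline stage.

This module generates hairpin references, adapter-bearing small-RNA reads,
two-condition negative-binomial count matrices, target-evidence tables built
to satisfy a requested prioritization class, and duplicate qPCR Ct plates.
All generators are pure functions of their arguments and a seed, so any
downstream result can be checked against the ground truth that produced it.

It also ships transcriptions of the study's three published summary tables
(differentially expressed precursor-stage miRNAs, the integrated miR-210
target list, and the MirTrap-enriched gene list) as packaged TSV fixtures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatureRegion",
    "HairpinReference",
    "SimulationConfig",
    "CountMatrix",
    "TRUSEQ_SMALL_RNA_ADAPTER",
    "gen_hairpins",
    "gen_reads",
    "gen_count_experiment",
    "gen_evidence_tables",
    "evidence_from_annotations",
    "gen_ct_plate",
    "load_fixture",
    "write_hairpins_fasta",
    "write_mature_bed",
    "write_fastq",
]

#: Full Illumina TruSeq small-RNA 3' adapter (RA3), 5'->3'.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

_BASES = np.array(list("ACGT"))

# Gene-to-gene spread of baseline expression on the natural-log scale.
# Fixed rather than configurable: it shapes the abundance distribution the
# generator emulates (deep small-RNA-seq spans ~2 orders of magnitude).
_LOG_EXPRESSION_SD = 1.5


@dataclass(frozen=True)
class MatureRegion:
    """A mature-miRNA interval on hairpin coordinates (0-based, half-open)."""

    mature_id: str
    hairpin_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid mature region [{self.start}, {self.end})")


@dataclass(frozen=True)
class HairpinReference:
    """A pre-miRNA sequence carrying one or two mature regions."""

    hairpin_id: str
    sequence: str
    mature_regions: tuple[MatureRegion, ...]

    def __post_init__(self) -> None:
        for region in self.mature_regions:
            if region.end > len(self.sequence):
                raise ValueError(
                    f"mature region {region.mature_id} exceeds hairpin "
                    f"{self.hairpin_id} (length {len(self.sequence)})"
                )

    def mature_sequence(self, region: MatureRegion) -> str:
        return self.sequence[region.start : region.end]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-condition count simulation.

    Defaults mirror the study design: five precursor-stage (33C) replicates
    against three differentiating (39C) replicates, ~10% of miRNAs truly
    changing with a 4-fold mean effect, and a moderate NB dispersion
    (variance = mu + dispersion * mu**2).
    """

    n_mirna: int = 1000
    n_replicates_a: int = 5
    n_replicates_b: int = 3
    de_fraction: float = 0.1
    log2_effect: float = 2.0
    dispersion: float = 0.05
    mean_log_expression: float = 6.0
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 1 or self.n_replicates_a < 1 or self.n_replicates_b < 1:
            raise ValueError("n_mirna and replicate counts must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_mirna))


@dataclass
class CountMatrix:
    """Raw miRNA x sample counts with condition labels and library sizes."""

    counts: pd.DataFrame
    conditions: pd.Series
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        if list(self.conditions.index) != list(self.counts.columns):
            raise ValueError("condition labels must be indexed by sample")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def rpm(self) -> pd.DataFrame:
        """Reads-per-million using the stored library sizes."""
        return self.counts * 1e6 / self.library_sizes


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gen_hairpins(n: int, seed: int) -> list[HairpinReference]:
    """Generate ``n`` hairpin references with 1-2 mature regions each.

    Hairpins are 60-120 nt; mature regions are 18-25 nt, non-overlapping,
    and their sequences are unique across the whole set (re-drawn on the
    rare collision) so exact-match mapping is unambiguous.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    hairpins: list[HairpinReference] = []
    seen: set[str] = set()
    for i in range(n):
        for _attempt in range(100):
            length = int(rng.integers(60, 121))
            sequence = _random_sequence(rng, length)
            n_mature = int(rng.integers(1, 3))
            len5 = int(rng.integers(18, 26))
            regions = [(int(rng.integers(0, 8)), len5)]
            if n_mature == 2:
                len3 = int(rng.integers(18, 26))
                start3 = length - len3 - int(rng.integers(0, 8))
                # keep the two arms disjoint; short hairpins may only fit one
                if start3 >= regions[0][0] + len5:
                    regions.append((start3, len3))
            matures = [sequence[s : s + l] for s, l in regions]
            if len(set(matures)) == len(matures) and not any(m in seen for m in matures):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw unique mature sequences")
        hairpin_id = f"sim-mir-{i + 1:04d}"
        arms = ("5p", "3p")
        mature_regions = tuple(
            MatureRegion(f"{hairpin_id}-{arms[j]}", hairpin_id, s, s + l)
            for j, (s, l) in enumerate(regions)
        )
        hairpins.append(HairpinReference(hairpin_id, sequence, mature_regions))
        seen.update(matures)
    return hairpins


def gen_reads(
    hairpins: Sequence[HairpinReference],
    abundances: Mapping[str, float],
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
    read_length: int = 50,
    seed: int = 0,
    max_jitter: int = 6,
    background_fraction: float = 0.05,
) -> list[tuple[str, str, str]]:
    """Simulate adapter-bearing small-RNA reads over hairpin references.

    Per-miRNA read numbers are Poisson around the expected abundance. Each
    read is a mature sequence, optionally shifted by up to ``max_jitter`` nt
    in either direction (templated isomiR ends), followed by the 3' adapter,
    truncated to ``read_length`` (poly-A filler if the template runs out).
    A ``background_fraction`` of extra reads is drawn from non-mature hairpin
    windows. Returns ``(read_id, sequence, quality)`` FASTQ records.
    """
    regions: dict[str, tuple[HairpinReference, MatureRegion]] = {}
    for hp in hairpins:
        for region in hp.mature_regions:
            regions[region.mature_id] = (hp, region)
    unknown = set(abundances) - set(regions)
    if unknown:
        raise KeyError(f"unknown mature ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    total = 0

    def finish(core: str) -> str:
        read = (core + adapter)[:read_length]
        if len(read) < read_length:
            read += "A" * (read_length - len(read))
        return read

    for mature_id in sorted(abundances):
        hp, region = regions[mature_id]
        n_reads = int(rng.poisson(abundances[mature_id]))
        for r in range(n_reads):
            shift = int(rng.integers(-max_jitter, max_jitter + 1)) if max_jitter else 0
            start = max(0, region.start + shift)
            end = min(len(hp.sequence), region.end + shift)
            core = hp.sequence[start:end]
            total += 1
            reads.append((f"read_{total}|{mature_id}", finish(core), "I" * read_length))
    n_background = int(rng.poisson(background_fraction * max(total, 1))) if background_fraction else 0
    mature_spans = {
        hp.hairpin_id: [(r.start, r.end) for r in hp.mature_regions] for hp in hairpins
    }
    for _ in range(n_background):
        hp = hairpins[int(rng.integers(len(hairpins)))]
        length = int(rng.integers(18, 26))
        if len(hp.sequence) <= length:
            continue
        for _attempt in range(20):
            start = int(rng.integers(0, len(hp.sequence) - length))
            window = (start, start + length)
            # background must not coincide with a mature region (within the
            # counting rule's 4-nt overhang) or it would inflate truth counts
            if all(
                window[0] < s - 4 or window[1] > e + 4
                for s, e in mature_spans[hp.hairpin_id]
            ):
                total += 1
                core = hp.sequence[window[0] : window[1]]
                reads.append((f"read_{total}|background", finish(core), "I" * read_length))
                break
    return reads


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, variance = mean + dispersion*mean^2) sample; Poisson limit."""
    if dispersion < 1e-10:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    prob = size / (size + mean)
    return rng.negative_binomial(size, prob)


def gen_count_experiment(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a two-condition miRNA count matrix with a known DE subset.

    Baseline means are log-normal around ``mean_log_expression``; the first
    ``round(de_fraction * n_mirna)`` miRNAs (after shuffling) receive a
    ``+/- log2_effect`` shift in condition B ("39C"), signs alternating so up-
    and down-regulation are balanced. Counts are NB with the configured
    dispersion. Returns the count matrix and a truth table with columns
    ``mirna_id, is_de, true_log2fc``.
    """
    rng = np.random.default_rng(config.seed)
    ids = [f"sim-miR-{i + 1:04d}" for i in range(config.n_mirna)]
    base_mean = rng.lognormal(config.mean_log_expression, _LOG_EXPRESSION_SD, config.n_mirna)
    true_lfc = np.zeros(config.n_mirna)
    n_de = config.n_de
    de_idx = rng.permutation(config.n_mirna)[:n_de]
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    true_lfc[de_idx] = signs * config.log2_effect

    mean_a = base_mean
    mean_b = base_mean * np.power(2.0, true_lfc)
    samples, conditions, columns = [], [], []
    for r in range(config.n_replicates_a):
        samples.append(f"33C_{r + 1}")
        conditions.append("33C")
        columns.append(_nb_draw(rng, mean_a, config.dispersion))
    for r in range(config.n_replicates_b):
        samples.append(f"39C_{r + 1}")
        conditions.append("39C")
        columns.append(_nb_draw(rng, mean_b, config.dispersion))
    counts = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(ids, name="mirna_id"), columns=samples
    )
    truth = pd.DataFrame(
        {"mirna_id": ids, "is_de": true_lfc != 0.0, "true_log2fc": true_lfc}
    )
    matrix = CountMatrix(counts, pd.Series(conditions, index=samples, name="condition"))
    return matrix, truth


_RUN_IDS = ("mouse_on_mouse", "human_on_human", "human_on_mouse")
_TRUST_BY_CLASS = {1: "Present", 2: "Probably present", 3: "Not likely present"}


def evidence_from_annotations(
    annotations: Mapping[str, tuple[str, str]],
    seed: int = 0,
    n_decoys: int = 0,
) -> dict[str, pd.DataFrame]:
    """Build evidence tables from per-gene ``(targetscan_span, trust)`` pairs.

    ``targetscan_span`` is ``"Mouse and Human"`` (gene present in all three
    prediction runs) or ``"Mouse or Human"`` (a proper, non-empty subset) or
    ``"Absent"``; ``trust`` is a MetaBase level or ``"Absent"``. Human-run
    rows use a ``HS_`` prefixed identifier resolved by the homolog table.
    Decoy genes with zero conserved sites exercise the conservation filter.
    """
    rng = np.random.default_rng(seed)
    runs: dict[str, list[dict]] = {run: [] for run in _RUN_IDS}
    homologs: list[dict] = []
    interactions: list[dict] = []
    for gene in annotations:
        span, trust = annotations[gene]
        if span == "Mouse and Human":
            members: Sequence[str] = _RUN_IDS
        elif span == "Mouse or Human":
            k = int(rng.integers(1, 3))
            members = tuple(rng.choice(_RUN_IDS, size=k, replace=False))
        elif span == "Absent":
            members = ()
        else:
            raise ValueError(f"unknown targetscan span {span!r}")
        human_id = f"HS_{gene}"
        homologs.append({"mouse_gene_id": gene, "human_gene_id": human_id})
        for run in members:
            gene_id = human_id if run == "human_on_human" else gene
            runs[run].append(
                {
                    "run_id": run,
                    "gene_id": gene_id,
                    "n_conserved_sites": int(rng.integers(1, 4)),
                }
            )
        if trust != "Absent":
            interactions.append(
                {
                    "gene_id": gene,
                    "trust": trust,
                    "pubmed_ids": str(int(rng.integers(10_000_000, 30_000_000))),
                }
            )
    for d in range(n_decoys):
        decoy = f"DECOY_{d + 1}"
        run = _RUN_IDS[d % 3]
        gene_id = f"HS_{decoy}" if run == "human_on_human" else decoy
        homologs.append({"mouse_gene_id": decoy, "human_gene_id": f"HS_{decoy}"})
        runs[run].append({"run_id": run, "gene_id": gene_id, "n_conserved_sites": 0})
    run_frames = {
        run: pd.DataFrame(rows, columns=["run_id", "gene_id", "n_conserved_sites"])
        for run, rows in runs.items()
    }
    return {
        **run_frames,
        "homologs": pd.DataFrame(homologs, columns=["mouse_gene_id", "human_gene_id"]),
        "interactions": pd.DataFrame(
            interactions, columns=["gene_id", "trust", "pubmed_ids"]
        ),
    }


def gen_evidence_tables(
    genes: Sequence[str],
    class_assignment: Mapping[str, int],
    seed: int = 0,
    n_decoys: int = 0,
) -> dict[str, pd.DataFrame]:
    """Emit evidence tables whose integration recovers ``class_assignment``.

    Inverts the five-class prioritization: each gene's emitted evidence
    satisfies exactly its assigned class's criteria and no higher-priority
    class's (class 1: literature trust "Present"; 2/3: all three prediction
    runs plus "Probably present"/"Not likely present"; 4: all three runs, no
    literature; 5: a single/partial run, no literature).
    """
    annotations: dict[str, tuple[str, str]] = {}
    for gene in genes:
        cls = class_assignment[gene]
        if cls not in (1, 2, 3, 4, 5):
            raise ValueError(f"class for {gene!r} must be in 1..5, got {cls}")
        span = "Mouse and Human" if cls in (1, 2, 3, 4) else "Mouse or Human"
        trust = _TRUST_BY_CLASS.get(cls, "Absent")
        annotations[gene] = (span, trust)
    return evidence_from_annotations(annotations, seed=seed, n_decoys=n_decoys)


def gen_ct_plate(
    targets: Sequence[str],
    reference_gene: str,
    true_fold: Mapping[str, float],
    ct_noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a paired qPCR plate (trap and scrambled arms).

    Ct values are constructed so that the reference-normalized 2^-ddCt
    recovers ``true_fold`` in expectation: the scrambled-arm dCt of each gene
    is a fixed offset and the trap arm subtracts log2(fold). Gaussian noise
    of sd ``ct_noise_sd`` cycles is added independently to every target-gene
    well; the reference well carries no separate error term (its deviation
    is absorbed into the per-gene sd), so gene-level dCt errors are
    independent and averaging across genes converges on the true folds.
    Returns a tidy plate with columns ``gene, arm, replicate, ct`` holding
    both arms (biological duplicates by default, as in the assay).
    """
    if reference_gene in targets:
        raise ValueError("reference gene must not be among the targets")
    folds = {g: float(true_fold.get(g, 1.0)) for g in targets}
    bad = [g for g, f in folds.items() if f <= 0]
    if bad:
        raise ValueError(f"true fold must be positive, offending genes: {bad}")
    rng = np.random.default_rng(seed)
    base_ct_ref = 20.0
    base_delta = 5.0
    rows = []
    for arm in ("trap", "scrambled"):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {"gene": reference_gene, "arm": arm, "replicate": rep,
                 "ct": base_ct_ref}
            )
            for gene in targets:
                delta = base_delta
                if arm == "trap":
                    delta -= np.log2(folds[gene])
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
                rows.append(
                    {"gene": gene, "arm": arm, "replicate": rep,
                     "ct": base_ct_ref + delta + noise}
                )
    return pd.DataFrame(rows, columns=["gene", "arm", "replicate", "ct"])


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged transcription of one of the study's summary tables.

    ``"table1"``: the eight most significant precursor-stage-high miRNAs with
    per-condition mean counts/RPM, log2 ratio and FDR. ``"table2"``: the 35
    integrated putative miR-210 targets with class, trust, span and
    prior-dataset flags. ``"table3"``: the MirTrap-enriched genes; the
    ``in_silico`` column carries the published overlap (bold) annotation.
    """
    if name not in ("table1", "table2", "table3"):
        raise KeyError(f"unknown fixture {name!r}")
    text = resources.files("cortimir.data").joinpath(f"{name}.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t")


def write_hairpins_fasta(hairpins: Iterable[HairpinReference], path) -> None:
    with open(path, "w") as fh:
        for hp in hairpins:
            fh.write(f">{hp.hairpin_id}\n{hp.sequence}\n")


def write_mature_bed(hairpins: Iterable[HairpinReference], path) -> None:
    """BED intervals of mature regions (0-based, half-open, hairpin coords)."""
    with open(path, "w") as fh:
        for hp in hairpins:
            for region in hp.mature_regions:
                fh.write(f"{hp.hairpin_id}\t{region.start}\t{region.end}\t{region.mature_id}\n")


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, sequence, quality in reads:
            fh.write(f"@{read_id}\n{sequence}\n+\n{quality}\n")
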
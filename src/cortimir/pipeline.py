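"""End-to-end orchestration: simulate -> quant -> de -> integrate -> mirtrap.

Each stage reads/writes plain-text files in the run directory, records the
SHA-256 of every output in a reproducibility manifest, and derives its own
RNG seed from the single global seed, so stages can be re-run in isolation
and a full re-run with the same config+seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffexpr, mirtrap_enrichment, smallrna_quant, synthetic_data, target_integration
from .synthetic_data import CountMatrix, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report"]

STAGES = ("simulate", "quant", "de", "integrate", "mirtrap")


@dataclass
class PipelineConfig:
    """All stage toggles and parameters; defaults are the study's settings
    (4-nt counting overhang, 2-fold and FDR<0.01 DE gates, 2-fold
    enrichment gate, 5 vs 3 replicate design)."""

    stages: tuple[str, ...] = STAGES
    seed: int = 0
    # simulate
    n_mirna: int = 300
    n_replicates_a: int = 5
    n_replicates_b: int = 3
    de_fraction: float = 0.1
    log2_effect: float = 2.0
    dispersion: float = 0.05
    mean_log_expression: float = 6.0
    adapter: str = synthetic_data.TRUSEQ_SMALL_RNA_ADAPTER
    read_length: int = 50
    n_hairpins: int = 20
    mean_reads_per_mirna: float = 50.0
    n_evidence_genes: int = 30
    n_plate_targets: int = 84
    ct_noise_sd: float = 0.2
    # quant
    overhang: int = 4
    multimap_policy: str = "fractional"
    denominator_mode: str = "aligned"
    min_read_length: int = 16
    # de
    lfc_cut: float = 1.0
    fdr_cut: float = 0.01
    # integrate
    min_species: int = 2
    # mirtrap
    enrichment_threshold: float = 2.0
    reference_gene: str = "GAPDH"
    # optional external inputs (simulate stage fills these when enabled)
    reads_dir: str | None = None
    hairpins_fasta: str | None = None
    mature_bed: str | None = None
    counts_tsv: str | None = None
    conditions_tsv: str | None = None
    evidence_dir: str | None = None
    plate_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        problems = [f"unknown config key: {k}" for k in raw if k not in known]
        if "stages" in raw:
            bad = [s for s in raw["stages"] if s not in STAGES]
            problems += [f"unknown stage: {s}" for s in bad]
            raw = {**raw, "stages": tuple(raw["stages"])}
        if problems:
            raise ValueError("; ".join(problems))
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str = ""
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    config_text = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_text.encode()).hexdigest(),
        seed=seed,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    state: dict[str, Any] = {}
    runners = {
        "simulate": _stage_simulate,
        "quant": _stage_quant,
        "de": _stage_de,
        "integrate": _stage_integrate,
        "mirtrap": _stage_mirtrap,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        written = runners[stage](config, out, _stage_seed(seed, stage), state)
        manifest.outputs[stage] = {str(p.relative_to(out)): _sha256(p) for p in written}
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    rng = np.random.default_rng(seed)
    written: list[Path] = []
    # hairpin references + small per-condition read sets for the quant demo
    hairpins = synthetic_data.gen_hairpins(config.n_hairpins, seed)
    fasta = out / "hairpins.fa"
    bed = out / "mature.bed"
    synthetic_data.write_hairpins_fasta(hairpins, fasta)
    synthetic_data.write_mature_bed(hairpins, bed)
    written += [fasta, bed]
    mature_ids = [r.mature_id for hp in hairpins for r in hp.mature_regions]
    abundances = {
        m: float(a)
        for m, a in zip(
            mature_ids,
            rng.lognormal(np.log(config.mean_reads_per_mirna), 1.0, len(mature_ids)),
        )
    }
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    for i, sample in enumerate(["33C_1", "39C_1"]):
        reads = synthetic_data.gen_reads(
            hairpins,
            abundances,
            adapter=config.adapter,
            read_length=config.read_length,
            seed=seed + 1 + i,
            max_jitter=2,
        )
        path = reads_dir / f"{sample}.fastq"
        synthetic_data.write_fastq(reads, path)
        written.append(path)
    # two-condition count experiment for the DE stage
    sim = SimulationConfig(
        n_mirna=config.n_mirna,
        n_replicates_a=config.n_replicates_a,
        n_replicates_b=config.n_replicates_b,
        de_fraction=config.de_fraction,
        log2_effect=config.log2_effect,
        dispersion=config.dispersion,
        mean_log_expression=config.mean_log_expression,
        adapter=config.adapter,
        read_length=config.read_length,
        seed=seed,
    )
    matrix, truth = synthetic_data.gen_count_experiment(sim)
    counts_path, cond_path, truth_path = out / "counts.tsv", out / "conditions.tsv", out / "truth.tsv"
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.conditions.rename("condition").to_csv(cond_path, sep="\t")
    truth.to_csv(truth_path, sep="\t", index=False)
    written += [counts_path, cond_path, truth_path]
    # evidence tables with a known class assignment
    genes = [f"Gene{i + 1:03d}" for i in range(config.n_evidence_genes)]
    assignment = {g: int(rng.integers(1, 6)) for g in genes}
    tables = synthetic_data.gen_evidence_tables(genes, assignment, seed=seed, n_decoys=5)
    evidence_dir = out / "evidence"
    evidence_dir.mkdir(exist_ok=True)
    for name, df in tables.items():
        path = evidence_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    assign_path = evidence_dir / "true_classes.tsv"
    pd.DataFrame(
        {"gene_id": genes, "true_class": [assignment[g] for g in genes]}
    ).to_csv(assign_path, sep="\t", index=False)
    written.append(assign_path)
    # duplicate Ct plates: in-silico genes plus fillers, a subset truly bound
    plate_targets = genes + [f"Filler{i + 1:02d}" for i in range(max(0, config.n_plate_targets - len(genes)))]
    bound = rng.choice(plate_targets, size=max(1, len(plate_targets) // 4), replace=False)
    true_fold = {g: (4.0 if g in set(bound) else 1.0) for g in plate_targets}
    plate = synthetic_data.gen_ct_plate(
        plate_targets,
        config.reference_gene,
        true_fold,
        ct_noise_sd=config.ct_noise_sd,
        n_replicates=2,
        seed=seed,
    )
    plate_path = out / "ct_plate.csv"
    plate.to_csv(plate_path, index=False)
    written.append(plate_path)
    state.update(
        hairpins=hairpins,
        matrix=matrix,
        truth=truth,
        evidence=tables,
        plate=plate,
        reads={"33C_1": reads_dir / "33C_1.fastq", "39C_1": reads_dir / "39C_1.fastq"},
    )
    config.hairpins_fasta = str(fasta)
    config.mature_bed = str(bed)
    config.reads_dir = str(reads_dir)
    config.counts_tsv = str(counts_path)
    config.conditions_tsv = str(cond_path)
    config.evidence_dir = str(evidence_dir)
    config.plate_csv = str(plate_path)
    return written


def _require(path_str: str | None, stage: str, what: str) -> Path:
    if path_str is None or not Path(path_str).exists():
        raise FileNotFoundError(f"stage {stage!r}: missing {what}: {path_str}")
    return Path(path_str)


def _stage_quant(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    reads_dir = _require(config.reads_dir, "quant", "reads directory")
    fasta = _require(config.hairpins_fasta, "quant", "hairpin FASTA")
    bed = _require(config.mature_bed, "quant", "mature-region BED")
    hairpins = smallrna_quant.read_hairpins(fasta, bed)
    fastqs = {p.stem: p for p in sorted(reads_dir.glob("*.fastq"))}
    if not fastqs:
        raise FileNotFoundError(f"stage 'quant': no FASTQ files in {reads_dir}")
    counts, qc = smallrna_quant.quantify_fastq(
        fastqs,
        hairpins,
        adapter=config.adapter,
        min_length=config.min_read_length,
        overhang=config.overhang,
        multimap_policy=config.multimap_policy,
    )
    rpm = smallrna_quant.rpm_normalize(counts, config.denominator_mode)
    written = []
    for name, df in [
        ("quant_counts.tsv", counts.counts),
        ("quant_rpm.tsv", rpm),
        ("quant_qc.tsv", qc),
    ]:
        (out / name).write_text(df.to_csv(sep="\t"))
        written.append(out / name)
    if counts.counts.shape[1] >= 2:
        corr = smallrna_quant.replicate_correlation(counts.counts)
        (out / "quant_spearman.tsv").write_text(corr.to_csv(sep="\t"))
        written.append(out / "quant_spearman.tsv")
    state["quant_counts"] = counts
    return written


def _stage_de(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    counts_path = _require(config.counts_tsv, "de", "counts TSV")
    cond_path = _require(config.conditions_tsv, "de", "conditions TSV")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    conditions = pd.read_csv(cond_path, sep="\t", index_col=0)["condition"]
    matrix = CountMatrix(counts, conditions)
    table, summary = diffexpr.run_de(matrix, lfc_cut=config.lfc_cut, fdr_cut=config.fdr_cut)
    de_path = out / "de.tsv"
    table.to_csv(de_path, sep="\t")
    summary_path = out / "de_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    state["de_table"], state["de_summary"] = table, summary
    return [de_path, summary_path]


def _stage_integrate(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    evidence_dir = _require(config.evidence_dir, "integrate", "evidence directory")
    runs = {
        run_id: pd.read_csv(_require(str(evidence_dir / f"{run_id}.tsv"), "integrate", f"{run_id} table"), sep="\t")
        for run_id in target_integration.RUN_IDS
    }
    homologs = pd.read_csv(evidence_dir / "homologs.tsv", sep="\t")
    interactions = pd.read_csv(evidence_dir / "interactions.tsv", sep="\t")
    targets = target_integration.integrate(runs, homologs, interactions)
    path = out / "targets.tsv"
    targets.to_csv(path, sep="\t", index=False)
    state["targets"] = targets
    return [path]


def _stage_mirtrap(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    plate_path = _require(config.plate_csv, "mirtrap", "Ct plate CSV")
    plate = pd.read_csv(plate_path)
    results = mirtrap_enrichment.analyze_plate(plate, reference_gene=config.reference_gene)
    enriched = mirtrap_enrichment.call_enriched(results, threshold=config.enrichment_threshold)
    written = []
    results_path = out / "enrichment.tsv"
    results.to_csv(results_path, sep="\t")
    written.append(results_path)
    overlap_path = out / "overlap.json"
    targets = state.get("targets")
    if targets is None and (out / "targets.tsv").exists():
        targets = pd.read_csv(out / "targets.tsv", sep="\t")
    if targets is not None and len(targets):
        count, fraction = mirtrap_enrichment.validation_overlap(
            enriched.index, targets["gene_id"]
        )
        overlap = {
            "n_enriched": int(len(enriched)),
            "n_predicted": int(len(targets)),
            "overlap": count,
            "fraction": fraction,
        }
    else:
        overlap = {"n_enriched": int(len(enriched)), "n_predicted": 0,
                   "overlap": 0, "fraction": None}
    overlap_path.write_text(json.dumps(overlap, indent=2) + "\n")
    written.append(overlap_path)
    state["enriched"], state["overlap"] = enriched, overlap
    return written


def report(out_dir) -> str:
    """Human-readable markdown summary of a finished (or partial) run."""
    out = Path(out_dir)
    lines = ["# cortimir run summary", ""]
    de_summary = out / "de_summary.json"
    if de_summary.exists():
        s = json.loads(de_summary.read_text())
        lines += [
            f"Differential expression: {s['n_total']} miRNAs pass the gates "
            f"({s['n_up']} up, {s['n_down']} down).",
        ]
    else:
        lines.append("Differential expression: (missing)")
    targets_path = out / "targets.tsv"
    if targets_path.exists():
        targets = pd.read_csv(targets_path, sep="\t")
        breakdown = targets["class"].value_counts().sort_index() if len(targets) else pd.Series(dtype=int)
        per_class = ", ".join(f"class {c}: {n}" for c, n in breakdown.items()) or "all classes empty"
        lines.append(f"Integrated targets: {len(targets)} ({per_class}).")
    else:
        lines.append("Integrated targets: (missing)")
    overlap_path = out / "overlap.json"
    if overlap_path.exists():
        o = json.loads(overlap_path.read_text())
        frac = "n/a" if o.get("fraction") is None else f"{100 * o['fraction']:.0f}%"
        lines.append(
            f"MirTrap: {o['n_enriched']} genes enriched; overlap with "
            f"predicted targets {o['overlap']}/{o['n_predicted']} ({frac})."
        )
    else:
        lines.append("MirTrap enrichment: (missing)")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
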
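"""Pipeline orchestration: scan -> annotate -> conserve -> consensus.

Each stage writes its table so stages are independently runnable and
re-testable; a run manifest (config echo, config hash, tool version,
seed) makes a run reproducible bit-identically.  Analysis stages are
seed-free and deterministic; only the synthetic-data generator consumes
randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import ElementAnnotation, GeneModel, annotate_hits
from .conservation import ConservationCriteria, ConservedGroup, find_conserved
from .consensus import ConsensusModel, consensus_by_class, information_content
from .io import (
    annotations_to_frame,
    config_hash,
    groups_to_frame,
    hits_to_frame,
    read_fasta,
    read_gene_table,
    read_validated_flags,
    write_bed,
    write_hits_tsv,
    write_tsv,
)
from .motif import DRPattern, builtin_pattern
from .scanner import (
    DRElementHit,
    GenomicSequence,
    ScanConfig,
    cluster_window,
    scan_collection,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_scan", "run_full", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Settings for a full run.

    Defaults reproduce the standard survey: canonical pattern with 0-9 nt
    spacer, both strands, 20 kb windows up/downstream of the cluster, and
    all-species exact-element conservation.
    """

    fasta: Mapping[str, str] = field(default_factory=dict)  # species -> path
    genes: str = ""  # gene-table TSV path
    pattern_names: tuple[str, ...] = ("canonical-RARE",)
    strand_mode: str = "both"
    masked_policy: str = "match"
    window_up: int = 20_000
    window_down: int = 20_000
    criteria: ConservationCriteria = field(default_factory=ConservationCriteria)
    theta: float = 0.0
    pseudocount: float = 0.0
    validated_flags: Optional[str] = None
    outdir: str = "rarescan_out"
    seed: int = 0

    def patterns(self) -> tuple[DRPattern, ...]:
        return tuple(builtin_pattern(n) for n in self.pattern_names)

    def to_manifest(self) -> dict:
        d = {
            "tool": "rarescan",
            "version": __version__,
            "fasta": {k: str(v) for k, v in sorted(self.fasta.items())},
            "genes": str(self.genes),
            "pattern_names": list(self.pattern_names),
            "strand_mode": self.strand_mode,
            "masked_policy": self.masked_policy,
            "window_up": self.window_up,
            "window_down": self.window_down,
            "criteria": asdict(self.criteria),
            "theta": self.theta,
            "pseudocount": self.pseudocount,
            "validated_flags": str(self.validated_flags) if self.validated_flags else None,
            "seed": self.seed,
        }
        d["config_hash"] = config_hash(d)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    sequences: dict[str, list[GenomicSequence]]
    genes: dict[str, list[GeneModel]]
    windows: dict[str, tuple[int, int]]
    hits: dict[str, list[DRElementHit]]
    annotations: dict[str, list[ElementAnnotation]]
    groups: list[ConservedGroup]
    consensus: dict[str, ConsensusModel]

    def class_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for g in self.groups:
            tally[g.dr_class] = tally.get(g.dr_class, 0) + 1
        return dict(sorted(tally.items()))


def _load_inputs(
    config: PipelineConfig,
) -> tuple[dict[str, list[GenomicSequence]], dict[str, list[GeneModel]]]:
    sequences = {
        sp: read_fasta(path, sp) for sp, path in sorted(config.fasta.items())
    }
    genes = read_gene_table(config.genes)
    missing = sorted(set(sequences) - set(genes))
    if missing:
        raise ValueError(f"no gene models for species: {missing}")
    return sequences, genes


def _scan_stage(
    config: PipelineConfig,
    sequences: Mapping[str, Sequence[GenomicSequence]],
    genes: Mapping[str, Sequence[GeneModel]],
    outdir: Optional[Path],
) -> tuple[dict[str, tuple[int, int]], dict[str, list[DRElementHit]]]:
    extra = {"config_hash": config.to_manifest()["config_hash"]}
    windows: dict[str, tuple[int, int]] = {}
    hits: dict[str, list[DRElementHit]] = {}
    for sp in sorted(sequences):
        seqs = sequences[sp]
        gene_seq_ids = {g.seq_id for g in genes[sp]}
        per_species: list[DRElementHit] = []
        for seq in seqs:
            window = None
            if seq.id in gene_seq_ids:
                seq_genes = [g for g in genes[sp] if g.seq_id == seq.id]
                window = cluster_window(
                    seq_genes, config.window_up, config.window_down, len(seq)
                )
                windows[sp] = window
            scan_cfg = ScanConfig(
                patterns=config.patterns(),
                strand_mode=config.strand_mode,
                masked_policy=config.masked_policy,
                window=window,
            )
            per_species.extend(scan_collection([seq], scan_cfg))
        hits[sp] = per_species
        tally: dict[str, int] = {}
        for h in per_species:
            tally[h.dr_class] = tally.get(h.dr_class, 0) + 1
        logger.info(
            "scan %s: %d hits (%s)",
            sp,
            len(per_species),
            ", ".join(f"{k}:{v}" for k, v in sorted(tally.items())) or "none",
        )
        if outdir is not None:
            write_hits_tsv(per_species, outdir / f"hits_{sp}.tsv", extra=extra)
            write_bed(per_species, outdir / f"hits_{sp}.bed", extra=extra)
            summary = {
                "species": sp,
                "n_hits": len(per_species),
                "class_tally": dict(sorted(tally.items())),
                "window": list(windows.get(sp, (0, 0))),
            }
            (outdir / f"hits_{sp}.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n"
            )
    return windows, hits


def run_scan(config: PipelineConfig) -> dict[str, list[DRElementHit]]:
    """Windowed, both-strand scan per species; writes BED + TSV + summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, genes = _load_inputs(config)
    _, hits = _scan_stage(config, sequences, genes, outdir)
    return hits


def run_full(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute scan -> annotate -> conserve -> consensus, writing every
    intermediate and a run manifest."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = config.to_manifest()
    extra = {"config_hash": manifest["config_hash"]}
    stage = "load-inputs"
    try:
        sequences, genes = _load_inputs(config)
        if len(sequences) < 2:
            raise ValueError(
                "conservation filtering requires at least 2 species; "
                f"got {sorted(sequences)}"
            )

        stage = "scan"
        windows, hits = _scan_stage(
            config, sequences, genes, outdir if write else None
        )

        stage = "annotate"
        annotations: dict[str, list[ElementAnnotation]] = {}
        for sp in sorted(hits):
            seq_lengths = {s.id: len(s) for s in sequences[sp]}
            anns: list[ElementAnnotation] = []
            for seq_id, length in sorted(seq_lengths.items()):
                seq_genes = [g for g in genes[sp] if g.seq_id == seq_id]
                seq_hits = [h for h in hits[sp] if h.sequence_id == seq_id]
                if not seq_genes:
                    continue
                anns.extend(annotate_hits(seq_hits, seq_genes, length))
            annotations[sp] = anns
            if write:
                write_tsv(
                    annotations_to_frame(anns), outdir / f"annotated_{sp}.tsv", extra=extra
                )

        stage = "conserve"
        groups = find_conserved(annotations, config.criteria)
        if write:
            write_tsv(groups_to_frame(groups), outdir / "conserved_groups.tsv", extra=extra)

        stage = "consensus"
        flags = (
            read_validated_flags(config.validated_flags)
            if config.validated_flags
            else None
        )
        sites_by_class: dict[str, list[str]] = {}
        for g in groups:
            if flags is not None and not flags.get(g.group_id, False):
                continue
            anchor_sp = sorted(g.members)[0]
            sites_by_class.setdefault(g.dr_class, []).append(
                g.members[anchor_sp].hit.element
            )
        models = consensus_by_class(sites_by_class, theta=config.theta)
        if write:
            for cls, model in sorted(models.items()):
                counts = model.counts
                counts_df = pd.DataFrame(
                    counts, index=list("ACGT"),
                    columns=[f"pos{j + 1}" for j in range(model.site_length)],
                )
                counts_df.insert(0, "base", counts_df.index)
                write_tsv(
                    counts_df.reset_index(drop=True),
                    outdir / f"consensus_{cls}_counts.tsv",
                    coords="alignment columns",
                    extra=extra,
                )
                ic = information_content(model, config.pseudocount)
                ic_df = pd.DataFrame(
                    {
                        "position": np.arange(1, model.site_length + 1),
                        "information_bits": ic,
                    }
                )
                write_tsv(
                    ic_df, outdir / f"consensus_{cls}_ic.tsv",
                    coords="alignment columns", extra=extra,
                )
                (outdir / f"consensus_{cls}.txt").write_text(model.iupac + "\n")

        if write:
            with open(outdir / "manifest.yaml", "w") as fh:
                yaml.safe_dump(manifest, fh, sort_keys=True)
        return PipelineResult(
            config=config,
            sequences=sequences,
            genes=genes,
            windows=windows,
            hits=hits,
            annotations=annotations,
            groups=groups,
            consensus=models,
        )
    except Exception as exc:
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, exc) from exc
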
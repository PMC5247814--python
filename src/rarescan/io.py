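"""File formats.

FASTA in/out goes through Biopython.  Tabular interchange is TSV with a
commented header carrying the tool version and a config hash; coordinates
in TSV and BED are 0-based half-open (BED convention), GFF3 input is
1-based inclusive and converted on read.  Conversions are centralized
here so every stage shares them.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .annotation import Compartment, ElementAnnotation, GeneModel
from .conservation import ConservedGroup
from .scanner import DRElementHit, GenomicSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_gff3_genes",
    "hits_to_frame",
    "frame_to_hits",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_bed",
    "annotations_to_frame",
    "frame_to_annotations",
    "groups_to_frame",
    "read_validated_flags",
    "config_hash",
    "write_tsv",
    "read_tsv",
]

GENE_COLUMNS = [
    "species",
    "seq_id",
    "gene_id",
    "start_codon_pos",
    "stop_codon_end",
    "strand",
    "cluster_rank",
]

HIT_COLUMNS = [
    "species",
    "sequence_id",
    "start",
    "end",
    "strand",
    "dr_class",
    "spacer_length",
    "half_site_1",
    "spacer",
    "half_site_2",
    "pattern_name",
    "validated",
]


def config_hash(obj) -> str:
    """Stable short hash of a config-like mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def _open_maybe_gzip(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, species: str) -> list[GenomicSequence]:
    """Read a (possibly gzipped) multi-record FASTA for one species."""
    with _open_maybe_gzip(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [
        GenomicSequence(id=r.id, species=species, residues=str(r.seq)) for r in records
    ]


def write_fasta(sequences: Sequence[GenomicSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"species={s.species}")
        for s in sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _tsv_header(coords: str, extra: Optional[Mapping] = None) -> str:
    meta = {"tool": f"rarescan {__version__}", "coordinates": coords}
    if extra:
        meta.update(extra)
    return "# " + "; ".join(f"{k}={v}" for k, v in meta.items()) + "\n"


def write_tsv(frame: pd.DataFrame, path, coords="0-based half-open", extra=None) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(coords, extra))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_gene_table(genes: Mapping[str, Sequence[GeneModel]], path) -> None:
    rows = [
        {
            "species": g.species,
            "seq_id": g.seq_id,
            "gene_id": g.gene_id,
            "start_codon_pos": g.start_codon_pos,
            "stop_codon_end": g.stop_codon_end,
            "strand": g.strand,
            "cluster_rank": g.cluster_rank,
        }
        for sp in sorted(genes)
        for g in sorted(genes[sp], key=lambda x: x.cluster_rank)
    ]
    write_tsv(pd.DataFrame(rows, columns=GENE_COLUMNS), path)


def read_gene_table(path) -> dict[str, list[GeneModel]]:
    df = read_tsv(path)
    missing = set(GENE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    if "cluster_rank" not in df.columns:
        df = df.sort_values(["species", "start_codon_pos"])
        df["cluster_rank"] = df.groupby("species").cumcount() + 1
    out: dict[str, list[GeneModel]] = {}
    for r in df.itertuples():
        out.setdefault(r.species, []).append(
            GeneModel(
                gene_id=str(r.gene_id),
                species=str(r.species),
                seq_id=str(r.seq_id),
                strand=str(r.strand),
                start_codon_pos=int(r.start_codon_pos),
                stop_codon_end=int(r.stop_codon_end),
                cluster_rank=int(r.cluster_rank),
            )
        )
    for sp in out:
        out[sp].sort(key=lambda g: g.cluster_rank)
    return out


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path, species: str, seq_id: Optional[str] = None) -> dict[str, list[GeneModel]]:
    """Extract gene models from GFF3 start_codon / stop_codon features.

    Features are grouped by the ``gene_id`` attribute (falling back to
    ``Parent`` then ``ID``).  ``cluster_rank`` is taken from a
    ``cluster_rank`` attribute when present, else assigned by coordinate
    order.  GFF3 coordinates (1-based inclusive) are converted to the
    internal 0-based convention.
    """
    cols = [
        "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols, header=None)
    feats: dict[str, dict] = {}
    for r in df.itertuples():
        if r.type not in ("start_codon", "stop_codon"):
            continue
        attrs = _gff3_attributes(str(r.attributes))
        gid = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID")
        if gid is None:
            raise ValueError(f"GFF3 {path}: {r.type} feature without gene identity")
        rec = feats.setdefault(
            gid, {"seqid": r.seqid, "strand": r.strand, "rank": attrs.get("cluster_rank")}
        )
        rec[r.type] = (int(r.start), int(r.end))
    genes: list[GeneModel] = []
    for gid, rec in feats.items():
        if "start_codon" not in rec or "stop_codon" not in rec:
            raise ValueError(f"GFF3 {path}: gene {gid!r} lacks start or stop codon")
        sc, st = rec["start_codon"], rec["stop_codon"]
        if rec["strand"] == "+":
            start_codon_pos, stop_codon_end = sc[0] - 1, st[1]
        else:
            start_codon_pos, stop_codon_end = sc[1] - 1, st[0] - 2
        genes.append(
            GeneModel(
                gene_id=gid,
                species=species,
                seq_id=str(seq_id or rec["seqid"]),
                strand=str(rec["strand"]),
                start_codon_pos=start_codon_pos,
                stop_codon_end=stop_codon_end,
                cluster_rank=int(rec["rank"]) if rec["rank"] is not None else -1,
            )
        )
    if any(g.cluster_rank == -1 for g in genes):
        genes.sort(key=lambda g: g.body_start)
        genes = [
            GeneModel(
                gene_id=g.gene_id,
                species=g.species,
                seq_id=g.seq_id,
                strand=g.strand,
                start_codon_pos=g.start_codon_pos,
                stop_codon_end=g.stop_codon_end,
                cluster_rank=i + 1,
            )
            for i, g in enumerate(genes)
        ]
    genes.sort(key=lambda g: g.cluster_rank)
    return {species: genes}


def hits_to_frame(hits: Sequence[DRElementHit]) -> pd.DataFrame:
    rows = [
        {
            "species": h.species,
            "sequence_id": h.sequence_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "dr_class": h.dr_class,
            "spacer_length": h.spacer_length,
            "half_site_1": h.half_site_1,
            "spacer": h.spacer,
            "half_site_2": h.half_site_2,
            "pattern_name": h.pattern_name,
            "validated": h.validated,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(df: pd.DataFrame) -> list[DRElementHit]:
    hits = []
    for r in df.itertuples():
        validated = None if pd.isna(r.validated) else bool(r.validated)
        hits.append(
            DRElementHit(
                sequence_id=str(r.sequence_id),
                species=str(r.species),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                half_site_1=str(r.half_site_1),
                spacer="" if pd.isna(r.spacer) else str(r.spacer),
                half_site_2=str(r.half_site_2),
                pattern_name=str(r.pattern_name),
                validated=validated,
            )
        )
    return hits


def write_hits_tsv(hits: Sequence[DRElementHit], path, extra=None) -> None:
    write_tsv(hits_to_frame(hits), path, extra=extra)


def read_hits_tsv(path) -> list[DRElementHit]:
    return frame_to_hits(read_tsv(path))


def write_bed(hits: Sequence[DRElementHit], path, extra=None) -> None:
    """BED6: name packs pattern, class and element parts; score is 0."""
    with open(path, "w") as fh:
        fh.write(_tsv_header("0-based half-open (BED6)", extra))
        for h in hits:
            name = "|".join(
                [h.pattern_name, h.dr_class, h.half_site_1, h.spacer, h.half_site_2]
            )
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{name}\t0\t{h.strand}\n"
            )


def annotations_to_frame(annotations: Sequence[ElementAnnotation]) -> pd.DataFrame:
    base = hits_to_frame([a.hit for a in annotations])
    base["compartment"] = [a.compartment.label() for a in annotations]
    base["compartment_key"] = ["/".join(map(str, a.compartment.key)) for a in annotations]
    base["compartment_start"] = [a.compartment.start for a in annotations]
    base["compartment_end"] = [a.compartment.end for a in annotations]
    base["nearest_downstream_gene"] = [a.nearest_downstream_gene for a in annotations]
    base["distance_to_start_codon"] = [a.distance_to_start_codon for a in annotations]
    base["cluster_orientation"] = [a.cluster_orientation for a in annotations]
    base["normalized_position"] = [a.normalized_position for a in annotations]
    return base


def _compartment_from_row(r) -> Compartment:
    parts = str(r.compartment_key).split("/")
    kind = parts[0]
    ranks = tuple(int(x) for x in parts[1:])
    gene_ids: tuple[str, ...] = ()
    if kind == "intragenic":
        gene_ids = (str(r.nearest_downstream_gene),)
    return Compartment(
        kind=kind,
        ranks=ranks,
        gene_ids=gene_ids,
        start=int(r.compartment_start),
        end=int(r.compartment_end),
    )


def frame_to_annotations(df: pd.DataFrame) -> list[ElementAnnotation]:
    hits = frame_to_hits(df)
    out = []
    for h, r in zip(hits, df.itertuples()):
        dist = r.distance_to_start_codon
        out.append(
            ElementAnnotation(
                hit=h,
                compartment=_compartment_from_row(r),
                nearest_downstream_gene=(
                    None if pd.isna(r.nearest_downstream_gene) else str(r.nearest_downstream_gene)
                ),
                distance_to_start_codon=None if pd.isna(dist) else int(dist),
                cluster_orientation=str(r.cluster_orientation),
                normalized_position=float(r.normalized_position),
            )
        )
    return out


def groups_to_frame(groups: Sequence[ConservedGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        for sp, ann in sorted(g.members.items()):
            h = ann.hit
            rows.append(
                {
                    "group_id": g.group_id,
                    "dr_class": g.dr_class,
                    "identity_level": g.identity_level,
                    "species": sp,
                    "sequence_id": h.sequence_id,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "element": h.element,
                    "compartment_key": "/".join(map(str, ann.compartment.key)),
                    "cluster_orientation": ann.cluster_orientation,
                    "normalized_position": ann.normalized_position,
                }
            )
    cols = [
        "group_id", "dr_class", "identity_level", "species", "sequence_id",
        "start", "end", "strand", "element", "compartment_key",
        "cluster_orientation", "normalized_position",
    ]
    return pd.DataFrame(rows, columns=cols)


def read_validated_flags(path) -> dict[str, bool]:
    """TSV keyed by element/group name with a boolean ``validated`` column."""
    df = read_tsv(path)
    if "element" not in df.columns or "validated" not in df.columns:
        raise ValueError(f"validated-flags table {path} needs columns element, validated")
    truthy = {"1", "true", "yes", "y"}

    def as_bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in truthy
        return bool(v)

    return {str(r.element): as_bool(r.validated) for r in df.itertuples()}
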
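"""Readers and writers for every external format the pipeline touches.

Inputs: FASTA contigs, features as GFF3 or the versioned TSV dialect
below, read-pair links as TSV, YAML configs.  Outputs: TSV reports.
All coordinates at these surfaces are 1-based inclusive.

TSV feature dialect (version 1) — header required::

    #mge-scout-features v1
    contig  start  end  strand  ftype  product  domain_tags

``domain_tags`` is semicolon-joined; unknown tags are rejected with a
warning (never silently dropped).  The same columns come back out of
the ``simulate`` subcommand, so fixtures need not be GFF3.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO

from .records import (
    AnnotatedReplicon,
    ElementProfile,
    FeatureRecord,
    PROFILE_FLAGS,
    ReadPairLink,
)
from .seqstats import round_percent
from .vocab import normalize_tag

logger = logging.getLogger(__name__)

FEATURE_TSV_MAGIC = "#mge-scout-features v1"
_FEATURE_COLUMNS = (
    "contig", "start", "end", "strand", "ftype", "product", "domain_tags"
)


class LoadError(RuntimeError):
    """Fatal input problem (missing file, bad coordinates, unknown contig)."""


def _norm_ftype(raw: str) -> str:
    if raw == "CDS":
        return "CDS"
    if raw.lower() == "trna":
        return "tRNA"
    return "other"


def _clean_tags(raw_tags: Iterable[str], context: str) -> frozenset[str]:
    tags = set()
    for raw in raw_tags:
        if not raw.strip():
            continue
        tag = normalize_tag(raw)
        if tag is None:
            logger.warning("unknown domain tag %r (%s); rejected", raw, context)
        else:
            tags.add(tag)
    return frozenset(tags)


def _features_from_gff3(path: Path) -> dict[str, list[FeatureRecord]]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    out: dict[str, list[FeatureRecord]] = {}
    for feat in db.all_features():
        product = ";".join(
            feat.attributes.get("product", feat.attributes.get("Name", []))
        )
        raw_tags = []
        for val in feat.attributes.get("domain_tags", []):
            raw_tags.extend(val.split(","))
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        out.setdefault(feat.seqid, []).append(
            FeatureRecord(
                start=feat.start,
                end=feat.end,
                strand=strand,
                ftype=_norm_ftype(feat.featuretype),
                product=product,
                domain_tags=_clean_tags(
                    raw_tags, f"{path.name}:{feat.seqid}:{feat.start}"
                ),
            )
        )
    return out


def _features_from_tsv(path: Path) -> dict[str, list[FeatureRecord]]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=0, dtype=str, keep_default_na=False
    )
    missing = set(_FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing feature columns {sorted(missing)}")
    out: dict[str, list[FeatureRecord]] = {}
    for row in df.itertuples(index=False):
        try:
            rec = FeatureRecord(
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                ftype=_norm_ftype(row.ftype),
                product=row.product,
                domain_tags=_clean_tags(
                    row.domain_tags.split(";"),
                    f"{path.name}:{row.contig}:{row.start}",
                ),
            )
        except ValueError as exc:
            raise LoadError(f"{path}: bad feature row {tuple(row)}: {exc}")
        out.setdefault(row.contig, []).append(rec)
    return out


def _is_gff3(path: Path) -> bool:
    if path.suffix.lower() in (".gff", ".gff3"):
        return True
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##gff-version")


def load_annotated_replicons(
    fasta_path: str | Path, features_path: str | Path | None = None
) -> list[AnnotatedReplicon]:
    """Load contigs plus annotations into AnnotatedReplicon objects.

    ``features_path`` may be GFF3 or the TSV dialect (sniffed); None
    loads bare sequences.  A feature naming an unknown contig, or with
    coordinates outside its contig, is fatal and names the offender.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise LoadError(f"FASTA not found: {fasta_path}")
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not contigs:
        raise LoadError(f"no FASTA records in {fasta_path}")

    feats: dict[str, list[FeatureRecord]] = {}
    if features_path is not None:
        features_path = Path(features_path)
        if not features_path.exists():
            raise LoadError(f"features file not found: {features_path}")
        feats = (
            _features_from_gff3(features_path)
            if _is_gff3(features_path)
            else _features_from_tsv(features_path)
        )
        for contig_id in feats:
            if contig_id not in contigs:
                raise LoadError(
                    f"{features_path}: feature references unknown contig "
                    f"{contig_id!r}"
                )

    replicons = []
    for contig_id, seq in contigs.items():
        try:
            rep = AnnotatedReplicon(
                id=contig_id,
                sequence=seq,
                features=feats.get(contig_id, []),
                source_path=str(fasta_path),
            )
        except ValueError as exc:
            raise LoadError(f"{contig_id}: {exc}")
        replicons.append(rep)
    logger.info(
        "loaded %d replicon(s), %d feature(s) from %s",
        len(replicons), sum(len(r.features) for r in replicons), fasta_path,
    )
    return replicons


# alias matching the operation name used in the docs
load_annotated_replicon = load_annotated_replicons


def write_fasta(replicons: Sequence[AnnotatedReplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, len(rep.sequence), 80):
                fh.write(rep.sequence[i : i + 80] + "\n")


def write_features_tsv(
    replicons: Sequence[AnnotatedReplicon], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(FEATURE_TSV_MAGIC + "\n")
        fh.write("\t".join(_FEATURE_COLUMNS) + "\n")
        for rep in replicons:
            for f in rep.features:
                fh.write(
                    "\t".join(
                        [
                            rep.id, str(f.start), str(f.end), f.strand,
                            f.ftype, f.product,
                            ";".join(sorted(f.domain_tags)),
                        ]
                    )
                    + "\n"
                )


def load_read_links(path: str | Path) -> list[ReadPairLink]:
    """Read-pair links TSV: pair_id, contig, pos1, orient1, pos2, orient2."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"read-links file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    needed = {"pair_id", "contig", "pos1", "orient1", "pos2", "orient2"}
    if not needed <= set(df.columns):
        raise LoadError(
            f"{path}: missing link columns {sorted(needed - set(df.columns))}"
        )
    return [
        ReadPairLink(
            pair_id=r.pair_id, contig=r.contig,
            pos1=int(r.pos1), orient1=r.orient1,
            pos2=int(r.pos2), orient2=r.orient2,
        )
        for r in df.itertuples(index=False)
    ]


def write_read_links(links: Sequence[ReadPairLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tcontig\tpos1\torient1\tpos2\torient2\n")
        for l in links:
            fh.write(
                f"{l.pair_id}\t{l.contig}\t{l.pos1}\t{l.orient1}\t"
                f"{l.pos2}\t{l.orient2}\n"
            )


REPORT_COLUMNS = (
    ("replicon_id", "size_bp", "gc_percent", "n_cds", "topology")
    + PROFILE_FLAGS
    + ("classification", "notes")
)


def write_element_report(
    profiles: Sequence[ElementProfile], out_path: str | Path
) -> None:
    """Element report TSV: one row per element, fixed column order,
    flags as 1/0, GC rounded to integer percent for display."""
    rows = []
    for p in profiles:
        row = {
            "replicon_id": p.replicon_id,
            "size_bp": p.size_bp,
            "gc_percent": round_percent(p.gc_percent),
            "n_cds": p.n_cds,
            "topology": p.topology,
            "classification": p.classification,
            "notes": "; ".join(p.notes),
        }
        for flag in PROFILE_FLAGS:
            row[flag] = int(p.flags.get(flag, False))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    df.to_csv(out_path, sep="\t", index=False)


def load_config(path: str | Path | None) -> dict:
    """YAML config; empty dict when no path given."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise LoadError(f"{path}: config must be a mapping")
    return cfg


def write_truth_yaml(truths, path: str | Path) -> None:
    payload = [t.to_dict() for t in truths]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
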
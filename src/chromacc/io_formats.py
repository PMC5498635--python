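"""Readers and writers for on-disk formats, plus model serialization.

Coordinate convention
---------------------
Everything in memory is **0-based, half-open** ``[start, end)``, the BED
convention.  Conversion from the 1-based, fully-closed GTF/GFF3 convention
happens only at the I/O boundary; converting an annotation to the internal
representation and writing it back is the identity on spans.
"""

from __future__ import annotations

import logging
import pickle
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """A file could not be parsed in the declared format."""


class ValidationError(ValueError):
    """Parsed content violates a semantic invariant (e.g. negative FPKM)."""


class ModelFormatError(RuntimeError):
    """A model archive is corrupt or written by an incompatible version."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene body span (union over isoforms, UTRs included) plus metadata."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_type: str = ""
    gc_content: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.gene_id}: end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.gc_content is not None and not 0.0 <= self.gc_content <= 1.0:
            raise ValueError(f"{self.gene_id}: gc_content must be in [0, 1]")

    @property
    def tss(self) -> int:
        """Transcription start site: 5'-most coordinate of the gene."""
        return self.start if self.strand == "+" else self.end

    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id)


@dataclass(frozen=True)
class ChromHmmSegment:
    """One ChromHMM segment with the histone marks its state is annotated to."""

    interval: GenomicInterval
    state: str
    marks: frozenset[str]

    def __post_init__(self) -> None:
        if not self.state:
            raise ValueError("state must be non-empty")


@dataclass
class ModelArchive:
    """Versioned container for a serialized hierarchical model."""

    format_version: int
    payload: object


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _bed_fields(line: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        fields = line.split()
    return fields


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (coordinates kept as-is).

    Track/browser/comment/blank lines are skipped.  Malformed coordinates
    raise :class:`ParseError` naming the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            fields = _bed_fields(stripped)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            intervals.append(GenomicInterval(chrom, start, end, name=name, score=score))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; name/score columns emitted when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation (GTF / GFF3)
# ---------------------------------------------------------------------------

_GENE_LIKE = {"gene", "transcript", "mRNA"}
_BIOTYPE_KEYS = ("gene_type", "gene_biotype", "biotype")


def read_gene_annotation(path: str | Path, dialect: str = "gtf") -> list[GeneRecord]:
    """Read a GTF/GFF3 annotation into one record per gene.

    Transcript isoforms are condensed to the union span of all gene-level
    and transcript-level features sharing a ``gene_id``; 1-based inclusive
    source coordinates become 0-based half-open.  Features on strand ``.``
    are rejected (promoter placement needs a strand) and counted in a
    warning.
    """
    import gffutils

    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    spans: dict[str, list] = defaultdict(list)
    meta: dict[str, dict] = {}
    n_skipped = 0
    for feat in db.all_features():
        if feat.featuretype not in _GENE_LIKE:
            continue
        attrs = feat.attributes
        if "gene_id" not in attrs and "ID" not in attrs:
            raise ParseError(f"{path}: feature at {feat.seqid}:{feat.start} lacks gene_id")
        gene_id = attrs["gene_id"][0] if "gene_id" in attrs else attrs["ID"][0]
        if feat.strand not in ("+", "-"):
            n_skipped += 1
            continue
        spans[gene_id].append((feat.seqid, feat.start - 1, feat.end, feat.strand))
        if gene_id not in meta:
            biotype = ""
            for key in _BIOTYPE_KEYS:
                if key in attrs:
                    biotype = attrs[key][0]
                    break
            gc = None
            if "gc_content" in attrs:
                gc = float(attrs["gc_content"][0])
            meta[gene_id] = {"gene_type": biotype, "gc_content": gc}
    if n_skipped:
        logger.warning("skipped %d feature(s) with strand '.'", n_skipped)
    records = []
    for gene_id, parts in spans.items():
        chroms = {p[0] for p in parts}
        if len(chroms) > 1:
            raise ParseError(f"{path}: gene {gene_id} spans multiple chromosomes")
        strand = parts[0][3]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=parts[0][0],
                start=min(p[1] for p in parts),
                end=max(p[2] for p in parts),
                strand=strand,
                gene_type=meta[gene_id]["gene_type"],
                gc_content=meta[gene_id]["gc_content"],
            )
        )
    return records


def write_gene_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as a minimal GTF (one ``gene`` feature per gene)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            if g.gene_type:
                attrs += f' gene_biotype "{g.gene_type}";'
            if g.gc_content is not None:
                attrs += f' gc_content "{g.gc_content!r}";'
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "chromacc",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression table
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path) -> pd.Series:
    """Read a gene-level FPKM table (TSV with columns gene_id, fpkm).

    Returns a float Series indexed by gene_id.  Duplicate gene ids and
    negative FPKM values raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "fpkm"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ValidationError(f"{path}: duplicate gene_id(s): {list(dups)[:5]}")
    fpkm = pd.to_numeric(df["fpkm"], errors="raise").astype(float)
    if (fpkm < 0).any():
        raise ValidationError(f"{path}: negative FPKM values present")
    profile = pd.Series(fpkm.values, index=df["gene_id"].astype(str).values, name="fpkm")
    profile.index.name = "gene_id"
    return profile


def write_expression_table(profile: pd.Series, path: str | Path) -> None:
    df = profile.rename("fpkm").rename_axis("gene_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ChromHMM segmentation
# ---------------------------------------------------------------------------


def read_chromhmm(
    path: str | Path, state_to_marks: Mapping[str, Iterable[str]]
) -> list[ChromHmmSegment]:
    """Read a ChromHMM BED4 segmentation, attaching histone-mark sets.

    ``state_to_marks`` must cover every state observed in the file (state
    names differ between the 15/18/25-state Roadmap models, so no names are
    hardcoded here); unmapped states raise :class:`ValidationError` listing
    them all.
    """
    segments: list[ChromHmmSegment] = []
    unmapped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            fields = _bed_fields(stripped)
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: ChromHMM BED needs >= 4 columns")
            chrom, state = fields[0], fields[3]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if state not in state_to_marks:
                unmapped.add(state)
                continue
            segments.append(
                ChromHmmSegment(
                    interval=GenomicInterval(chrom, start, end),
                    state=state,
                    marks=frozenset(state_to_marks[state]),
                )
            )
    if unmapped:
        raise ValidationError(
            f"{path}: states missing from state_to_marks: {sorted(unmapped)}"
        )
    return segments


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------


def write_model(model: object, path: str | Path) -> None:
    """Serialize a trained model inside a versioned archive."""
    archive = {"format_version": MODEL_FORMAT_VERSION, "payload": model}
    with open(path, "wb") as fh:
        pickle.dump(archive, fh, protocol=4)


def read_model(path: str | Path) -> object:
    """Load a model archive, checking the format version."""
    try:
        with open(path, "rb") as fh:
            archive = pickle.load(fh)
    except Exception as exc:  # noqa: BLE001 - any unpickling failure is corruption
        raise ModelFormatError(f"{path}: corrupt or unreadable model archive") from exc
    if not isinstance(archive, dict) or "format_version" not in archive:
        raise ModelFormatError(f"{path}: not a chromacc model archive")
    version = archive["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: archive format_version {version} is incompatible with "
            f"this build (expects {MODEL_FORMAT_VERSION})"
        )
    return archive["payload"]
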
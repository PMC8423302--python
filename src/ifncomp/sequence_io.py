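"""Input parsing and validation for transcript sequences, DE tables and alignments.

The analysis consumes three kinds of input:

* per-gene transcript sequences — a cDNA FASTA and a matching CDS FASTA
  (Ensembl-style, several transcripts per gene; we keep one per gene),
* a differential-expression (DE) table produced upstream by an RNA-seq
  pipeline (gene id, mean log2 fold change, BH-adjusted FDR, and a flag for
  expression evidence in every sample),
* multi-species per-gene alignments in aligned FASTA.

Sequences are uppercased on read; IUPAC ambiguity codes other than A/C/G/T
are mapped to N with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
GAP = "-"


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed or violates expectations."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: its (longest) cDNA, the matching protein-coding ORF, species."""

    gene_id: str
    cdna: str
    cds: str | None = None
    species: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.cdna) < 2:
            raise ValueError(f"{self.gene_id}: cDNA must be at least 2 nt")
        bad = set(self.cdna) - VALID_BASES
        if bad:
            raise ValueError(f"{self.gene_id}: invalid cDNA characters {sorted(bad)}")
        if self.cds is not None:
            if len(self.cds) < 3 or len(self.cds) % 3 != 0:
                raise ValueError(
                    f"{self.gene_id}: CDS length {len(self.cds)} is not a "
                    "positive multiple of 3"
                )
            bad = set(self.cds) - VALID_BASES
            if bad:
                raise ValueError(f"{self.gene_id}: invalid CDS characters {sorted(bad)}")


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression summary (IFN-treated vs untreated)."""

    gene_id: str
    log2fc: float
    fdr: float
    expressed_all_samples: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.gene_id}: fdr {self.fdr} outside [0, 1]")


@dataclass(frozen=True)
class AlignmentBlock:
    """One gene's multi-species alignment: equal-length rows over {A,C,G,T,N,-}."""

    gene_id: str
    rows: tuple[str, ...]
    species_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"{self.gene_id}: alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: unequal aligned row lengths {sorted(lengths)}")
        for r in self.rows:
            bad = set(r) - VALID_BASES - {GAP}
            if bad:
                raise ValueError(f"{self.gene_id}: invalid alignment characters {sorted(bad)}")

    @property
    def n_species(self) -> int:
        return len(self.rows)

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0])

    def ungapped_lengths(self) -> list[int]:
        return [len(r) - r.count(GAP) for r in self.rows]


def _clean_sequence(seq: str, name: str) -> str:
    """Uppercase and map non-ACGTN characters (IUPAC ambiguity codes) to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        logger.warning("%s: mapping ambiguity codes %s to N", name, sorted(bad))
        seq = "".join(b if b in VALID_BASES else "N" for b in seq)
    return seq


def _parse_header(description: str) -> tuple[str, str]:
    """Extract (gene_id, transcript_id) from an Ensembl-style FASTA header.

    The record id is the transcript id; the gene id comes from a
    ``gene:<id>`` token when present, otherwise the transcript id itself.
    """
    parts = description.split()
    transcript_id = parts[0]
    gene_id = transcript_id
    for token in parts[1:]:
        if token.startswith("gene:"):
            gene_id = token[len("gene:"):]
            break
    return gene_id, transcript_id


def _read_fasta_by_transcript(path: str | Path) -> dict[str, tuple[str, str]]:
    """Return {transcript_id: (gene_id, sequence)}; duplicate ids are an error."""
    out: dict[str, tuple[str, str]] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython names the offending content
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in records:
        gene_id, transcript_id = _parse_header(rec.description)
        if transcript_id in out:
            raise FastaParseError(f"{path}: duplicate transcript id {transcript_id!r}")
        out[transcript_id] = (gene_id, _clean_sequence(str(rec.seq), transcript_id))
    return out


def read_gene_records(
    cdna_path: str | Path,
    cds_path: str | Path | None = None,
    species: str = "unknown",
) -> list[GeneRecord]:
    """Read cDNA (and optionally CDS) FASTA, keeping one transcript per gene.

    For each gene the transcript with the longest cDNA is retained; ties are
    broken by the lexicographically smallest transcript id. A gene whose
    chosen transcript has no CDS entry yields a record with ``cds=None``.
    Records are returned sorted by gene id.
    """
    cdna = _read_fasta_by_transcript(cdna_path)
    cds = _read_fasta_by_transcript(cds_path) if cds_path is not None else {}

    best: dict[str, tuple[int, str]] = {}  # gene_id -> (-length, transcript_id)
    for tid, (gid, seq) in cdna.items():
        key = (-len(seq), tid)
        if gid not in best or key < best[gid]:
            best[gid] = key

    records = []
    for gid in sorted(best):
        tid = best[gid][1]
        seq = cdna[tid][1]
        cds_seq = cds.get(tid, (None, None))[1]
        if cds_seq is not None and (len(cds_seq) < 3 or len(cds_seq) % 3 != 0):
            logger.warning("%s/%s: CDS length %d not a multiple of 3; dropped",
                           gid, tid, len(cds_seq))
            cds_seq = None
        records.append(GeneRecord(gene_id=gid, cdna=seq, cds=cds_seq, species=species))
    return records


def filter_by_length(records: Iterable[GeneRecord], min_len: int) -> list[GeneRecord]:
    """Keep records whose cDNA is strictly longer than ``min_len`` nucleotides."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in records if len(r.cdna) > min_len]


DE_COLUMNS = ["gene_id", "log2fc", "fdr", "expressed_all_samples"]


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a tab-separated DE table with header gene_id/log2fc/fdr/expressed_all_samples."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE-table columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        expressed = row.expressed_all_samples
        if isinstance(expressed, str):
            expressed = expressed.strip().lower() in {"true", "1", "yes"}
        records.append(
            DERecord(
                gene_id=str(row.gene_id),
                log2fc=float(row.log2fc),
                fdr=float(row.fdr),
                expressed_all_samples=bool(expressed),
            )
        )
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.log2fc, r.fdr, r.expressed_all_samples) for r in records],
        columns=DE_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_gene_records(
    records: Iterable[GeneRecord],
    cdna_path: str | Path,
    cds_path: str | Path,
) -> None:
    """Write records back to cDNA and CDS FASTA (gene id doubles as transcript id)."""
    records = list(records)
    with open(cdna_path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id}.t1 gene:{r.gene_id}\n{r.cdna}\n")
    with open(cds_path, "w") as fh:
        for r in records:
            if r.cds is not None:
                fh.write(f">{r.gene_id}.t1 gene:{r.gene_id}\n{r.cds}\n")


def read_alignment(path: str | Path, gene_id: str | None = None) -> AlignmentBlock:
    """Read one aligned FASTA file into an AlignmentBlock."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    if len(records) < 2:
        raise FastaParseError(f"{path}: alignment needs at least 2 sequences")
    rows = []
    labels = []
    for rec in records:
        seq = rec.seq.upper()
        cleaned = "".join(
            b if (b in VALID_BASES or b == GAP) else "N" for b in str(seq)
        )
        rows.append(cleaned)
        labels.append(rec.id)
    return AlignmentBlock(
        gene_id=gene_id or path.stem,
        rows=tuple(rows),
        species_labels=tuple(labels),
    )


def read_alignment_dir(path: str | Path, pattern: str = "*.fa*") -> list[AlignmentBlock]:
    """Read every aligned FASTA under ``path`` (sorted by filename)."""
    files = sorted(Path(path).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no alignment files matching {pattern!r} in {path}")
    return [read_alignment(f) for f in files]


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    labels: Sequence[str] = block.species_labels or tuple(
        f"species{i+1}" for i in range(block.n_species)
    )
    with open(path, "w") as fh:
        for label, row in zip(labels, block.rows):
            fh.write(f">{label}\n{row}\n")
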
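"""Input/output: FASTA and SNP-table reading, report writing, domain types.

Internally every coordinate is 0-based half-open; file formats (VCF POS,
report ``position`` column) are 1-based inclusive, converted exactly at the
boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: report columns with fixed 4-decimal formatting
_FLOAT_COLS = ("gc", "mfe", "rnaseh1_score")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _check_alphabet(seq: str, record_id: str) -> str:
    """Upper-case ``seq`` and reject characters outside {A,C,G,T,N}.

    Error positions are reported 1-based, matching file conventions.
    """
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise DataError(
                f"illegal character {ch!r} in record {record_id} at position {i + 1}"
            )
    return seq


@dataclass
class TargetGene:
    """A target pre-mRNA: the sense strand a gapmer ASO is designed against."""

    gene_id: str
    sequence: str
    species: str = "human"
    exons: list[tuple[int, int]] | None = None

    def __post_init__(self):
        self.sequence = _check_alphabet(self.sequence, self.gene_id)
        if self.exons is not None:
            self._check_exons()

    def _check_exons(self):
        prev_end = 0
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.sequence)):
                raise DataError(
                    f"exon [{start}, {end}) outside gene {self.gene_id} "
                    f"of length {len(self.sequence)}"
                )
            if start < prev_end:
                raise DataError(
                    f"exons of {self.gene_id} overlap or are unsorted at [{start}, {end})"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnpRecord:
    """An annotated variant position (0-based) on the target pre-mRNA."""

    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    maf: float | None = None


@dataclass
class OrthologSet:
    """Per-species ortholog sequences for cross-species conservation."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.sequences = {
            sp: _check_alphabet(seq, sp) for sp, seq in self.sequences.items()
        }

    def __contains__(self, species: str) -> bool:
        return species in self.sequences

    def get(self, species: str) -> str | None:
        return self.sequences.get(species)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(id, SEQUENCE), ...]``.

    Identifiers are the first whitespace-delimited header token; sequences
    are upper-cased and alphabet-checked. Order is preserved.
    """
    records = [
        (rec.id, _check_alphabet(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise DataError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def load_gene(path: str | Path, species: str = "human") -> TargetGene:
    """Load the first FASTA record of ``path`` as the target gene."""
    records = read_fasta(path)
    if len(records) > 1:
        logger.warning("gene FASTA %s has %d records; using the first", path, len(records))
    gene_id, seq = records[0]
    return TargetGene(gene_id=gene_id, sequence=seq, species=species)


def load_orthologs(path: str | Path) -> OrthologSet:
    """Load ortholog sequences; FASTA headers are species names."""
    records = read_fasta(path)
    seen: dict[str, str] = {}
    for sp, seq in records:
        if sp in seen:
            raise DataError(f"duplicate species {sp!r} in ortholog FASTA {path}")
        seen[sp] = seq
    return OrthologSet(sequences=seen)


def read_snps(path: str | Path, gene: TargetGene) -> list[SnpRecord]:
    """Read SNPs from a minimal VCF (CHROM POS ID REF ALT) or 3-column TSV
    (pos, ref, alt), both with 1-based positions.

    Positions are converted to 0-based. Records on other chromosomes or
    outside ``gene`` are dropped (count logged). A ref allele that does not
    match the gene sequence is a warning only: masking needs the position,
    and dbSNP extracts may come from a different build than the FASTA.
    """
    snps: list[SnpRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) >= 5:  # minimal VCF
                    chrom, pos_s, rsid, ref, alt = parts[:5]
                    if chrom != gene.gene_id:
                        dropped += 1
                        continue
                    pos = int(pos_s) - 1
                    rsid = None if rsid in (".", "") else rsid
                elif len(parts) == 3:  # pos ref alt
                    pos = int(parts[0]) - 1
                    ref, alt, rsid = parts[1].upper(), parts[2].upper(), None
                else:
                    raise ValueError("expected 5-column VCF or 3-column TSV line")
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: unparseable SNP line: {exc}") from exc
            if not 0 <= pos < len(gene):
                dropped += 1
                continue
            ref, alt = ref.upper(), alt.upper()
            if gene.sequence[pos] != ref:
                logger.warning(
                    "%s:%d: SNP ref %s does not match gene base %s at position %d",
                    path, lineno, ref, gene.sequence[pos], pos + 1,
                )
            snps.append(SnpRecord(pos=pos, ref=ref, alt=alt, rsid=rsid))
    if dropped:
        logger.info("dropped %d SNP record(s) outside gene %s", dropped, gene.gene_id)
    return snps


def write_snps_vcf(snps: list[SnpRecord], gene_id: str, path: str | Path) -> None:
    """Write SNPs as a minimal VCF (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for s in snps:
            fh.write(f"{gene_id}\t{s.pos + 1}\t{s.rsid or '.'}\t{s.ref}\t{s.alt}\n")


def report_columns(species: tuple[str, ...]) -> list[str]:
    cols = ["position", "target_site", "aso_sequence", "gc", "mfe", "rnaseh1_score"]
    cols += [f"offtargets_mm{k}" for k in range(5)]
    cols += [f"homology_{sp}" for sp in species]
    cols += ["tier", "rank"]
    return cols


def rows_to_frame(rows, species: tuple[str, ...]) -> pd.DataFrame:
    """Flatten ReportRow-like objects into the canonical report table."""
    data = []
    for r in rows:
        rec = {
            "position": r.start + 1,  # 1-based display
            "target_site": r.target_site,
            "aso_sequence": r.aso_sequence,
            "gc": round(r.gc, 4),
            "mfe": round(r.mfe, 4),
            "rnaseh1_score": round(r.rnaseh1_score, 4),
        }
        for k in range(5):
            rec[f"offtargets_mm{k}"] = r.offtarget_counts.get(k, 0)
        homology = r.homology or {}
        for sp in species:
            val = homology.get(sp)
            rec[f"homology_{sp}"] = "NA" if val is None else round(val, 4)
        rec["tier"] = r.tier
        rec["rank"] = r.rank
        data.append(rec)
    return pd.DataFrame(data, columns=report_columns(species))


def write_report(rows, path: str | Path, fmt: str = "tsv",
                 species: tuple[str, ...] | None = None) -> None:
    """Write the ranked candidate table as TSV or JSON.

    TSV floats are printed with 4 decimals; absent homology values are NA.
    """
    if species is None:
        from .config import CANONICAL_SPECIES
        species = CANONICAL_SPECIES
    gene_ids = {r.gene_id for r in rows}
    if len(gene_ids) > 1:
        raise DataError(f"report rows span multiple genes: {sorted(gene_ids)}")
    frame = rows_to_frame(rows, species)
    if fmt == "tsv":
        out = frame.copy()
        for col in _FLOAT_COLS + tuple(f"homology_{sp}" for sp in species):
            out[col] = out[col].map(
                lambda v: v if isinstance(v, str) else f"{v:.4f}")
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        frame.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
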
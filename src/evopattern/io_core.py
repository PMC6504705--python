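"""Input/output layer: genomes, annotations, multi-sample haploid VCFs,
GATK-style hard filters, and genic/intergenic assignment.

Internal coordinates are 0-based half-open everywhere; the VCF boundary
stays 1-based and GFF3 (1-based inclusive) is converted on read. A variant
is "genic" when its POS falls inside the full span of at least one gene
(UTRs and introns included); InDel assignment uses POS only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: INFO annotations consulted by the hard filters, in canonical order.
FILTER_ANNOTATIONS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")

PASS = "PASS"
FAIL = "FAIL"
UNEVALUATED = "UNEVALUATED"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A haploid reference genome held fully in memory."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} contains non-nucleotide characters {sorted(bad)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def contig_length(self, name: str) -> int:
        return len(self.sequences[name])


@dataclass(frozen=True)
class GeneModel:
    """A gene span with optional GO annotations (0-based half-open)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SampleSeries:
    """The ordered sample layout of the experiment.

    Samples are grouped cold-block first, then hot-block, each ordered by
    time index. ``generations`` optionally records the per-condition number
    of generations elapsed over the series (used for mutation rates).
    """

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    time_indices: tuple[int, ...]
    generations: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (n == len(self.conditions) == len(self.time_indices)):
            raise ValueError("sample_ids, conditions and time_indices must have equal length")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        bad = set(self.conditions) - {"cold", "hot"}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        # cold block strictly precedes hot block
        seen_hot = False
        for c in self.conditions:
            if c == "hot":
                seen_hot = True
            elif seen_hot:
                raise ValueError("samples must be grouped cold-block first, then hot-block")
        for cond in ("cold", "hot"):
            times = [t for c, t in zip(self.conditions, self.time_indices) if c == cond]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"time indices must be strictly increasing within {cond} block")
            if any(t < 1 for t in times):
                raise ValueError("time indices must be >= 1")

    @property
    def n_cold(self) -> int:
        return sum(c == "cold" for c in self.conditions)

    @property
    def n_hot(self) -> int:
        return sum(c == "hot" for c in self.conditions)

    @classmethod
    def default(cls, n_cold: int = 6, n_hot: int = 4,
                generations: Optional[Mapping[str, float]] = None) -> "SampleSeries":
        """The study layout: six cold samples followed by four hot samples."""
        ids = tuple(f"cold_{i}" for i in range(1, n_cold + 1)) + \
              tuple(f"hot_{i}" for i in range(1, n_hot + 1))
        conds = ("cold",) * n_cold + ("hot",) * n_hot
        times = tuple(range(1, n_cold + 1)) + tuple(range(1, n_hot + 1))
        if generations is None:
            generations = {"cold": 102.0, "hot": 181.0}
        return cls(ids, conds, times, dict(generations))

    @classmethod
    def from_table(cls, path: str | Path,
                   generations: Optional[Mapping[str, float]] = None) -> "SampleSeries":
        """Read a series definition TSV with columns sample_id, condition, time_index."""
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        required = {"sample_id", "condition", "time_index"}
        if not required <= set(df.columns):
            raise ValueError(f"series table must have columns {sorted(required)}")
        return cls(tuple(df["sample_id"]), tuple(df["condition"]),
                   tuple(int(t) for t in df["time_index"]), generations)

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame({
            "sample_id": self.sample_ids,
            "condition": self.conditions,
            "time_index": self.time_indices,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class VariantRecord:
    """One called site with per-sample binary haploid calls.

    ``calls`` are ordered like the SampleSeries: 0 = reference haplotype,
    1 = any variant haplotype, None = missing. ``pos`` keeps the VCF
    1-based convention.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    calls: tuple[Optional[int], ...]
    annotations: dict[str, float] = field(default_factory=dict)
    filter_status: str = UNEVALUATED
    region: Optional[str] = None          # 'genic' | 'intergenic'
    gene_ids: tuple[str, ...] = ()

    @property
    def variant_type(self) -> str:
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "SNP"
        return "InDel"


Clause = tuple[str, str, float]  # (annotation, comparator '<' or '>', threshold)


@dataclass(frozen=True)
class FilterSpec:
    """Per-variant-type OR-combined hard-filter clauses.

    A record fails when at least one clause evaluates true; clauses whose
    annotation is absent are skipped; when every clause is skipped the
    record is UNEVALUATED.
    """

    snp: tuple[Clause, ...]
    indel: tuple[Clause, ...]

    def __post_init__(self) -> None:
        for clause in self.snp + self.indel:
            name, op, thr = clause
            if op not in {"<", ">"}:
                raise ValueError(f"comparator must be '<' or '>', got {op!r}")
            if not math.isfinite(thr):
                raise ValueError(f"threshold for {name} must be finite")

    @classmethod
    def gatk_default(cls) -> "FilterSpec":
        """The GATK-recommended hard filters used for the study's call set."""
        snp = (("QD", "<", 1.0), ("FS", ">", 30.0), ("MQ", "<", 45.0),
               ("SOR", ">", 9.0), ("MQRankSum", "<", -4.0), ("ReadPosRankSum", "<", -10.0))
        indel = (("QD", "<", 1.0), ("FS", ">", 200.0), ("MQ", "<", 45.0),
                 ("MQRankSum", "<", -6.5), ("ReadPosRankSum", "<", -10.0))
        return cls(snp, indel)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Raises ``ValueError`` on an empty file or duplicate contig ids.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return Genome(sequences)


def read_go_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (gene_id, go_id; one pair per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "go_id"} <= set(df.columns):
        raise ValueError("GO map must have columns gene_id, go_id")
    out: dict[str, set[str]] = {}
    for gene, go in zip(df["gene_id"], df["go_id"]):
        out.setdefault(gene, set()).add(go)
    return {g: frozenset(s) for g, s in out.items()}


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path: str | Path,
                    go_map: Optional[Mapping[str, Iterable[str]] | str | Path] = None,
                    genome: Optional[Genome] = None,
                    feature_types: Sequence[str] = ("gene",)) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive) or BED (0-based half-open).

    Both are normalized to internal 0-based half-open coordinates. When a
    ``genome`` is supplied, genes on unknown contigs are skipped with a
    warning and out-of-bounds spans raise. GO terms are attached from
    ``go_map`` (a mapping or a TSV path).
    """
    path = Path(path)
    if isinstance(go_map, (str, Path)):
        go_map = read_go_map(go_map)
    go_map = {g: frozenset(v) for g, v in (go_map or {}).items()}

    genes: list[GeneModel] = []
    seen: set[str] = set()
    is_bed = path.suffix.lower() == ".bed"
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if is_bed:
                if len(cols) < 4:
                    raise ValueError(f"{path}:{ln}: BED needs >= 4 columns")
                contig, start, end, gene_id = cols[0], int(cols[1]), int(cols[2]), cols[3]
                strand = cols[5] if len(cols) >= 6 else "."
            else:
                if len(cols) < 9:
                    raise ValueError(f"{path}:{ln}: GFF3 needs 9 columns")
                if cols[2] not in feature_types:
                    continue
                contig, strand = cols[0], cols[6]
                start, end = int(cols[3]) - 1, int(cols[4])  # 1-based incl -> 0-based half-open
                attrs = _parse_gff3_attributes(cols[8])
                gene_id = attrs.get("ID") or attrs.get("Name") or attrs.get("gene_id")
                if gene_id is None:
                    raise ValueError(f"{path}:{ln}: feature without ID/Name attribute")
            if start >= end:
                raise ValueError(f"{path}:{ln}: empty or inverted span after normalization")
            if gene_id in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene id {gene_id!r}")
            if genome is not None:
                if contig not in genome.sequences:
                    log.warning("%s:%d: unknown contig %r, skipping gene %s", path, ln, contig, gene_id)
                    continue
                if end > genome.contig_length(contig):
                    raise ValueError(f"{path}:{ln}: gene {gene_id} exceeds contig {contig}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, contig, start, end, strand,
                                   go_map.get(gene_id, frozenset())))
    return genes


def read_variants(path: str | Path, series: SampleSeries) -> list[VariantRecord]:
    """Read a multi-sample VCF of haploid calls into VariantRecords.

    Genotypes are collapsed to presence/absence: allele index 0 -> 0, any
    non-reference index -> 1, "." -> missing. Diploid genotypes raise.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = set(vf.header.samples)
        absent = [s for s in series.sample_ids if s not in vcf_samples]
        if absent:
            raise ValueError(f"samples missing from VCF: {absent}")
        for rec in vf:
            calls: list[Optional[int]] = []
            for sid in series.sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or len(gt) == 0 or (len(gt) == 1 and gt[0] is None):
                    calls.append(None)
                    continue
                if len(gt) > 1:
                    raise ValueError(
                        f"{rec.contig}:{rec.pos}: expected haploid calls, got ploidy {len(gt)}")
                calls.append(0 if gt[0] == 0 else 1)
            ann = {}
            for key in FILTER_ANNOTATIONS:
                if key in rec.info:
                    val = rec.info[key]
                    if isinstance(val, tuple):
                        val = val[0]
                    ann[key] = float(val)
            records.append(VariantRecord(
                contig=rec.contig, pos=rec.pos, ref=rec.ref,
                alts=tuple(rec.alts or ()), calls=tuple(calls), annotations=ann))
    return records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_genome(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_annotation(genes: Sequence[GeneModel], path: str | Path,
                     source: str = "evopattern") -> None:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write("\t".join([g.contig, source, "gene", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", attrs]) + "\n")


def write_go_map(go_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(g, t) for g, terms in go_map.items() for t in sorted(terms)]
    pd.DataFrame(rows, columns=["gene_id", "go_id"]).to_csv(path, sep="\t", index=False)


_VCF_INFO_HEADER = {
    "QD": "Variant confidence normalized by depth",
    "FS": "Phred-scaled strand-bias Fisher p-value",
    "MQ": "RMS mapping quality",
    "SOR": "Symmetric odds ratio of strand bias",
    "MQRankSum": "Mapping-quality rank-sum Z",
    "ReadPosRankSum": "Read-position rank-sum Z",
}


def write_variants(records: Sequence[VariantRecord], series: SampleSeries,
                   path: str | Path, genome: Optional[Genome] = None) -> None:
    """Write records as an uncompressed multi-sample VCF v4.2 (haploid GTs)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=evopattern\n")
        if genome is not None:
            for name, seq in genome.sequences.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        else:
            for name in dict.fromkeys(r.contig for r in records):
                fh.write(f"##contig=<ID={name}>\n")
        for key, desc in _VCF_INFO_HEADER.items():
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(series.sample_ids) + "\n")
        for r in records:
            info = ";".join(f"{k}={r.annotations[k]:.6g}" for k in FILTER_ANNOTATIONS
                            if k in r.annotations) or "."
            gts = "\t".join("." if c is None else str(min(c, 1)) for c in r.calls)
            fh.write("\t".join([r.contig, str(r.pos), ".", r.ref,
                                ",".join(r.alts) if r.alts else ".",
                                ".", ".", info, "GT", gts]) + "\n")


# ---------------------------------------------------------------------------
# Hard filters
# ---------------------------------------------------------------------------

def _clause_true(record: VariantRecord, clause: Clause) -> Optional[bool]:
    name, op, thr = clause
    if name not in record.annotations:
        return None  # skipped
    val = record.annotations[name]
    return val < thr if op == "<" else val > thr


def apply_hard_filters(records: Iterable[VariantRecord],
                       spec: Optional[FilterSpec] = None) -> list[VariantRecord]:
    """Set ``filter_status`` on every record: FAIL iff >=1 clause is true.

    Clauses with absent annotations are skipped; if all clauses are skipped
    the record stays UNEVALUATED.
    """
    spec = spec or FilterSpec.gatk_default()
    records = list(records)
    for r in records:
        clauses = spec.snp if r.variant_type == "SNP" else spec.indel
        results = [_clause_true(r, c) for c in clauses]
        if any(res is True for res in results):
            r.filter_status = FAIL
        elif all(res is None for res in results):
            r.filter_status = UNEVALUATED
        else:
            r.filter_status = PASS
    return records


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

def build_gene_index(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    index: dict[str, IntervalTree] = {}
    for g in genes:
        index.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g.gene_id)
    return index


def classify_region(record: VariantRecord,
                    index: dict[str, IntervalTree]) -> VariantRecord:
    """Assign genic/intergenic by POS (0-based containment in gene spans)."""
    pos0 = record.pos - 1
    hits = index.get(record.contig, IntervalTree())[pos0]
    ids = tuple(sorted(iv.data for iv in hits))
    record.gene_ids = ids
    record.region = "genic" if ids else "intergenic"
    return record


def assign_regions(records: Iterable[VariantRecord],
                   genes: Sequence[GeneModel]) -> list[VariantRecord]:
    index = build_gene_index(genes)
    return [classify_region(r, index) for r in records]


def intergenic_intervals(genome: Genome,
                         genes: Sequence[GeneModel]) -> list[tuple[str, int, int]]:
    """Complement of the merged gene spans, per contig (0-based half-open)."""
    index = build_gene_index(genes)
    out: list[tuple[str, int, int]] = []
    for contig, seq in genome.sequences.items():
        tree = index.get(contig, IntervalTree()).copy()
        tree.merge_overlaps()
        cursor = 0
        for iv in sorted(tree):
            if iv.begin > cursor:
                out.append((contig, cursor, iv.begin))
            cursor = max(cursor, iv.end)
        if cursor < len(seq):
            out.append((contig, cursor, len(seq)))
    return out


# ---------------------------------------------------------------------------
# Tabular export of records (the CLI interchange format)
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[VariantRecord],
                     series: SampleSeries) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "contig": r.contig, "pos": r.pos, "ref": r.ref,
            "alt": ",".join(r.alts), "variant_type": r.variant_type,
            "filter_status": r.filter_status,
            "region": r.region or "", "gene_ids": ",".join(r.gene_ids),
        }
        for sid, call in zip(series.sample_ids, r.calls):
            row[f"call_{sid}"] = "." if call is None else call
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, series: SampleSeries) -> list[VariantRecord]:
    call_cols = [f"call_{s}" for s in series.sample_ids]
    missing = [c for c in call_cols if c not in df.columns]
    if missing:
        raise ValueError(f"records table lacks call columns {missing}")
    out = []
    for _, row in df.iterrows():
        calls = tuple(None if str(row[c]) == "." else int(row[c]) for c in call_cols)
        alts = tuple(str(row["alt"]).split(",")) if str(row["alt"]) else ()
        gene_ids = tuple(str(row["gene_ids"]).split(",")) if str(row.get("gene_ids", "")) not in ("", "nan") else ()
        out.append(VariantRecord(
            contig=str(row["contig"]), pos=int(row["pos"]), ref=str(row["ref"]),
            alts=alts, calls=calls,
            filter_status=str(row.get("filter_status", UNEVALUATED)),
            region=str(row["region"]) if str(row.get("region", "")) not in ("", "nan") else None,
            gene_ids=gene_ids))
    return out
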
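"""Ground-truth simulator for the whole pipeline.

Generates a compact haploid genome with a genic/intergenic partition and
CpG-dense intergenic islands, a multi-sample haploid VCF with variants
planted as Background / ColdFixed / HotFixed / Random trajectories, GO
assignments, a growth series with condition-specific doubling times, and a
ledger recording every planted truth so each downstream stage can be
checked for exact recovery.

One global seed drives independent child generators for the genome,
variant and growth stages, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_core, pattern_engine
from .io_core import GeneModel, Genome, SampleSeries, VariantRecord

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the simulator, with defaults set to the study design:
    six cold + four hot samples, 102 / 181 generations, Fig-2-scale class
    counts, doubling times 2.70 d (cold, drifting -30%) and 1.32 d (hot),
    six vs ten re-plating events from ~1,000-cell inocula."""

    seed: int = 0
    # genome
    n_contigs: int = 1
    contig_length: int = 200_000
    n_genes: int = 100
    gene_length: int = 1_000
    gc_content: float = 0.45
    island_fraction: float = 0.15        # of intergenic bp covered by CpG islands
    island_cg_rate: float = 0.30         # per-step CG-dinucleotide emission prob
    max_island_length: int = 2_000
    n_go_terms: int = 60
    go_per_gene: tuple[int, int] = (1, 5)
    # sample layout
    n_cold: int = 6
    n_hot: int = 4
    generations: Mapping[str, float] = field(
        default_factory=lambda: {"cold": 102.0, "hot": 181.0})
    # planted variant classes
    n_background: int = 100
    n_cold_fixed: int = 23
    n_hot_fixed: int = 18
    n_random: int = 1_000
    # alternatively, rate-driven condition-attributed counts
    rate_cold: Optional[float] = None    # per base per generation
    rate_hot: Optional[float] = None
    fixed_fraction: float = 0.033        # of rate-driven variants that fix
    # variant properties
    snp_fraction: float = 0.48
    max_indel_length: int = 6
    cg_variant_weight: float = 1.0       # >1 biases placement onto intergenic CG
    variant_region: str = "any"          # 'any' | 'genic' | 'intergenic'
    hotspot_gene_variants: int = 0       # extra Random variants forced into one gene
    one_variant_per_gene: bool = False   # spread genic placements over distinct genes
    # growth
    td: Mapping[str, float] = field(default_factory=lambda: {"cold": 2.70, "hot": 1.32})
    td_drift: Mapping[str, float] = field(default_factory=lambda: {"cold": -0.30, "hot": 0.0})
    n_replate: Mapping[str, int] = field(default_factory=lambda: {"cold": 6, "hot": 10})
    doublings_per_interval: float = 17.0
    growth_noise_sd: float = 0.05        # lognormal sigma on harvested OD
    inoculum: int = 1_000
    od_per_cell: float = 1e-8

    @property
    def series(self) -> SampleSeries:
        return SampleSeries.default(self.n_cold, self.n_hot, dict(self.generations))

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _island_sequence(rng: np.random.Generator, length: int, cg_rate: float,
                     gc: float) -> np.ndarray:
    out: list[str] = []
    while len(out) < length:
        if rng.random() < cg_rate:
            out.extend("CG")
        else:
            out.append(str(_random_sequence(rng, 1, gc)[0]))
    return np.array(out[:length])


def simulate_genome(cfg: SimulationConfig,
                    ) -> tuple[Genome, list[GeneModel],
                               list[tuple[str, int, int]],
                               dict[str, frozenset[str]]]:
    """Build the genome, non-overlapping gene spans, intergenic CpG islands
    and per-gene GO assignments. Returns (genome, genes, islands, go_map)."""
    rng = cfg._rng(0)
    genes_per_contig = [cfg.n_genes // cfg.n_contigs] * cfg.n_contigs
    for i in range(cfg.n_genes % cfg.n_contigs):
        genes_per_contig[i] += 1

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    islands: list[tuple[str, int, int]] = []
    go_pool = [f"GO:{i:07d}" for i in range(1, cfg.n_go_terms + 1)]
    go_map: dict[str, frozenset[str]] = {}
    gene_counter = itertools.count(1)

    for ci in range(cfg.n_contigs):
        contig = f"contig_{ci + 1}"
        length = cfg.contig_length
        n_genes = genes_per_contig[ci]
        total_genic = n_genes * cfg.gene_length
        if total_genic > 0.9 * length:
            raise ValueError(
                f"{n_genes} genes of {cfg.gene_length} bp cannot fit on a "
                f"{length} bp contig; reduce n_genes/gene_length or grow the contig")
        seq = _random_sequence(rng, length, cfg.gc_content)

        # evenly spaced non-overlapping gene spans with uniform gaps
        gap = (length - total_genic) / (n_genes + 1) if n_genes else 0
        contig_genes = []
        for gi in range(n_genes):
            start = round((gi + 1) * gap + gi * cfg.gene_length)
            gene_id = f"gene_{next(gene_counter):05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(gene_id, contig, start, start + cfg.gene_length, strand)
            contig_genes.append(g)
            n_terms = int(rng.integers(cfg.go_per_gene[0], cfg.go_per_gene[1] + 1))
            go_map[gene_id] = frozenset(rng.choice(go_pool, size=n_terms, replace=False))

        # CpG islands in the intergenic gaps
        gaps = []
        cursor = 0
        for g in contig_genes:
            if g.start > cursor:
                gaps.append((cursor, g.start))
            cursor = g.end
        if cursor < length:
            gaps.append((cursor, length))
        intergenic_bp = sum(e - s for s, e in gaps)
        target = int(cfg.island_fraction * intergenic_bp)
        placed = 0
        for s, e in sorted(gaps, key=lambda g: g[1] - g[0], reverse=True):
            if placed >= target:
                break
            usable = (e - s) - 2
            if usable < 20:
                continue
            isl_len = min(usable, cfg.max_island_length, target - placed)
            isl_start = s + 1 + (usable - isl_len) // 2
            seq[isl_start:isl_start + isl_len] = _island_sequence(
                rng, isl_len, cfg.island_cg_rate, cfg.gc_content)
            islands.append((contig, isl_start, isl_start + isl_len))
            placed += isl_len

        # GO terms were assigned above; attach them to the gene models
        genes.extend(dataclasses.replace(g, go_terms=go_map[g.gene_id])
                     for g in contig_genes)
        sequences[contig] = "".join(seq)

    return Genome(sequences), genes, islands, go_map


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _enumerate_random_patterns(n_cold: int, n_hot: int
                               ) -> tuple[list[str], list[str], list[str]]:
    """All Random-class patterns for a layout, split by attribution:
    (any, cold-attributed, hot-attributed)."""
    all_random, cold_attr, hot_attr = [], [], []
    for bits in itertools.product("01", repeat=n_cold + n_hot):
        s = "".join(bits[:n_cold]) + "|" + "".join(bits[n_cold:])
        p = pattern_engine.BinaryPattern.from_string(s)
        if pattern_engine.classify_pattern(p).label != "Random":
            continue
        all_random.append(s)
        if any(v == 1 for v in p.cold):
            cold_attr.append(s)
        else:
            hot_attr.append(s)
    return all_random, cold_attr, hot_attr


def _pattern_for(label: str, gain: Optional[int], n_cold: int, n_hot: int) -> str:
    if label == "Background":
        return "1" * n_cold + "|" + "1" * n_hot
    if label == "ColdFixed":
        return "0" * (gain - 1) + "1" * (n_cold - gain + 1) + "|" + "0" * n_hot
    if label == "HotFixed":
        return "0" * n_cold + "|" + "0" * (gain - 1) + "1" * (n_hot - gain + 1)
    raise ValueError(label)


def _position_weights(cfg: SimulationConfig, genome: Genome,
                      genes: Sequence[GeneModel]) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-base sampling weights over a flattened genome coordinate space."""
    contigs = list(genome.sequences)
    offsets = np.cumsum([0] + [len(genome.sequences[c]) for c in contigs])
    total = int(offsets[-1])
    w = np.ones(total, dtype=float)
    margin = cfg.max_indel_length + 2

    genic = np.zeros(total, dtype=bool)
    for g in genes:
        off = offsets[contigs.index(g.contig)]
        genic[off + g.start: off + g.end] = True
    if cfg.variant_region == "genic":
        w[~genic] = 0.0
    elif cfg.variant_region == "intergenic":
        w[genic] = 0.0

    if cfg.cg_variant_weight != 1.0:
        for i, c in enumerate(contigs):
            seq = np.frombuffer(genome.sequences[c].encode(), dtype=np.uint8)
            is_c = seq[:-1] == ord("C")
            is_g = seq[1:] == ord("G")
            cg_start = np.nonzero(is_c & is_g)[0]
            for p in (cg_start, cg_start + 1):   # both bases of each CG
                idx = offsets[i] + p
                keep = ~genic[idx]               # bias applies to intergenic CpG only
                w[idx[keep]] = cfg.cg_variant_weight
    # keep InDel reference spans inside the contig
    for i, c in enumerate(contigs):
        L = len(genome.sequences[c])
        w[offsets[i]: offsets[i] + 1] = 0.0
        w[offsets[i] + L - margin: offsets[i] + L] = 0.0
    return w, contigs, offsets


def simulate_series_variants(cfg: SimulationConfig, genome: Genome,
                             genes: Sequence[GeneModel],
                             ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Plant variants with known trajectory classes.

    Returns the sorted record list (regions already assigned) and the
    ground-truth ledger, one row per emitted record.
    """
    rng = cfg._rng(1)
    series = cfg.series
    n_cold, n_hot = cfg.n_cold, cfg.n_hot
    _, cold_random, hot_random = _enumerate_random_patterns(n_cold, n_hot)
    all_random = cold_random + hot_random

    # -- how many variants of each class, possibly rate-driven
    L = genome.total_length
    plan: list[tuple[str, Optional[str]]] = []   # (label, attribution constraint)
    if cfg.rate_cold is not None or cfg.rate_hot is not None:
        for cond, rate in (("cold", cfg.rate_cold), ("hot", cfg.rate_hot)):
            if rate is None:
                continue
            trials = int(L * cfg.generations[cond])
            n_attr = int(rng.binomial(trials, rate))
            n_fixed = int(rng.binomial(n_attr, cfg.fixed_fraction))
            label = "ColdFixed" if cond == "cold" else "HotFixed"
            plan += [(label, cond)] * n_fixed
            plan += [("Random", cond)] * (n_attr - n_fixed)
        plan += [("Background", None)] * cfg.n_background
    else:
        plan += [("Background", None)] * cfg.n_background
        plan += [("ColdFixed", "cold")] * cfg.n_cold_fixed
        plan += [("HotFixed", "hot")] * cfg.n_hot_fixed
        plan += [("Random", None)] * cfg.n_random
    plan += [("Random", None)] * cfg.hotspot_gene_variants
    n_total = len(plan)

    # -- positions
    w, contigs, offsets = _position_weights(cfg, genome, genes)
    hotspot_gene: Optional[GeneModel] = None
    flat_positions = np.empty(n_total, dtype=np.int64)
    n_main = n_total - cfg.hotspot_gene_variants
    if cfg.hotspot_gene_variants:
        hotspot_gene = genes[len(genes) // 2]
        off = offsets[contigs.index(hotspot_gene.contig)]
        span = np.arange(off + hotspot_gene.start, off + hotspot_gene.end)
        if cfg.hotspot_gene_variants > span.size:
            raise ValueError("hotspot gene too short for the requested variant count")
        flat_positions[n_main:] = rng.choice(span, cfg.hotspot_gene_variants, replace=False)
        w[span] = 0.0   # keep the remaining placements outside the hotspot gene
    if cfg.one_variant_per_gene:
        if cfg.variant_region != "genic":
            raise ValueError("one_variant_per_gene requires variant_region='genic'")
        pool = [g for g in genes if g is not hotspot_gene]
        if n_main > len(pool):
            raise ValueError("more variants than genes for one_variant_per_gene")
        chosen = rng.choice(len(pool), size=n_main, replace=False)
        for slot, gi in enumerate(chosen):
            g = pool[int(gi)]
            off = offsets[contigs.index(g.contig)]
            flat_positions[slot] = off + int(rng.integers(g.start, g.end))
    else:
        if (w > 0).sum() < n_main:
            raise ValueError("requested variant count exceeds available positions")
        flat_positions[:n_main] = rng.choice(
            w.size, size=n_main, replace=False, p=w / w.sum())

    # -- assemble records
    order = np.argsort(flat_positions)
    records: list[VariantRecord] = []
    ledger_rows = []
    for idx in order:
        label, attr = plan[idx]
        flat = int(flat_positions[idx])
        ci = int(np.searchsorted(offsets, flat, side="right") - 1)
        contig = contigs[ci]
        pos0 = flat - int(offsets[ci])
        seq = genome.sequences[contig]

        gain: Optional[int] = None
        if label == "Background":
            pattern = _pattern_for(label, None, n_cold, n_hot)
        elif label == "ColdFixed":
            gain = int(rng.integers(1, n_cold + 1))
            pattern = _pattern_for(label, gain, n_cold, n_hot)
        elif label == "HotFixed":
            gain = int(rng.integers(1, n_hot + 1))
            pattern = _pattern_for(label, gain, n_cold, n_hot)
        else:
            pool = {None: all_random, "cold": cold_random, "hot": hot_random}[attr]
            pattern = pool[int(rng.integers(len(pool)))]

        is_snp = rng.random() < cfg.snp_fraction
        if is_snp:
            ref = seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        else:
            ilen = int(rng.integers(1, cfg.max_indel_length + 1))
            if rng.random() < 0.5:  # insertion
                ref = seq[pos0]
                alt = ref + "".join(rng.choice(BASES, size=ilen))
            else:                   # deletion
                ref = seq[pos0: pos0 + ilen + 1]
                alt = seq[pos0]
        ann = {
            "QD": float(rng.uniform(15, 35)),
            "FS": float(rng.uniform(0, 3)),
            "MQ": 60.0,
            "SOR": float(rng.uniform(0.5, 2.0)),
            "MQRankSum": float(rng.normal(0, 0.5)),
            "ReadPosRankSum": float(rng.normal(0, 0.5)),
        }
        bp = pattern_engine.BinaryPattern.from_string(pattern)
        calls = bp.cold + bp.hot
        records.append(VariantRecord(contig=contig, pos=pos0 + 1, ref=ref,
                                     alts=(alt,), calls=calls, annotations=ann))
        ledger_rows.append({
            "contig": contig, "pos": pos0 + 1, "ref": ref, "alt": alt,
            "variant_type": records[-1].variant_type,
            "true_class": label, "gain_index": gain if gain is not None else "",
            "pattern": pattern,
            "attributed_condition": attr or
                (pattern_engine.attribute_condition(bp) or ""),
        })

    io_core.assign_regions(records, genes)
    ledger = pd.DataFrame(ledger_rows)
    ledger["region"] = [r.region for r in records]
    ledger["gene_ids"] = [",".join(r.gene_ids) for r in records]
    ledger["seed"] = cfg.seed
    return records, ledger


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def simulate_growth(cfg: SimulationConfig) -> pd.DataFrame:
    """Exponential growth between re-platings with lognormal OD noise and an
    optional linear doubling-time drift emulating adaptation."""
    rng = cfg._rng(2)
    rows = []
    for cond in ("cold", "hot"):
        td0 = cfg.td[cond]
        if td0 <= 0:
            raise ValueError("doubling time must be positive")
        drift = cfg.td_drift.get(cond, 0.0)
        n = cfg.n_replate[cond]
        day = 0.0
        for i in range(n):
            frac = i / (n - 1) if n > 1 else 0.0
            td_i = td0 * (1.0 + drift * frac)
            dt = cfg.doublings_per_interval * td_i
            day += dt
            n_end = cfg.inoculum * 2.0 ** (dt / td_i)
            noise = math.exp(rng.normal(0.0, cfg.growth_noise_sd)) \
                if cfg.growth_noise_sd > 0 else 1.0
            rows.append({"condition": cond, "day": round(day, 4),
                         "od750": n_end * cfg.od_per_cell * noise,
                         "inoculum": cfg.inoculum})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-call convenience
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all three stages and write FASTA/GFF3/VCF/TSV outputs + config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, islands, go_map = simulate_genome(cfg)
    records, ledger = simulate_series_variants(cfg, genome, genes)
    growth = simulate_growth(cfg)
    series = cfg.series

    paths = {
        "fasta": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "go_map": outdir / "go_map.tsv",
        "vcf": outdir / "variants.vcf",
        "series": outdir / "series.tsv",
        "ledger": outdir / "ledger.tsv",
        "growth": outdir / "growth.tsv",
        "islands": outdir / "islands.tsv",
        "config": outdir / "config.txt",
    }
    io_core.write_genome(genome, paths["fasta"])
    io_core.write_annotation(genes, paths["gff"])
    io_core.write_go_map(go_map, paths["go_map"])
    io_core.write_variants(records, series, paths["vcf"], genome=genome)
    series.to_table(paths["series"])
    ledger.to_csv(paths["ledger"], sep="\t", index=False)
    growth.to_csv(paths["growth"], sep="\t", index=False)
    pd.DataFrame(islands, columns=["contig", "start", "end"]).to_csv(
        paths["islands"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        for f in dataclasses.fields(cfg):
            fh.write(f"{f.name}={getattr(cfg, f.name)}\n")
    return paths
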
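"""Fisher/Benjamini–Hochberg machinery with three consumers:

* GO-term enrichment over variant-bearing genes,
* k-mer enrichment of the intergenic space (with IUPAC motif annotation),
* variant x differential-expression overlap.

The contingency scheme follows the study's convention: the focal unit's
affected/unaffected counts versus the pooled counts of every other unit of
the same family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special
from statsmodels.stats.multitest import multipletests

from .io_core import GeneModel, Genome, VariantRecord, intergenic_intervals

log = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# Core machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = focal & affected, b = focal & unaffected,
    c = other & affected, d = other & unaffected."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


_TWO_SIDED_REL_TOL = 1e-7


def fisher_exact(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    Conditioning on the margins, the focal cell ``a`` follows a
    hypergeometric law; one-sided p-values are tail sums and the two-sided
    p-value sums every outcome whose point mass does not exceed the
    observed one (within relative tolerance 1e-7, the usual convention).
    Implemented by direct summation over the support via log-gamma point
    masses, which stays fast for the large-margin tables the k-mer scan
    produces.
    """
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logpmf = (_lchoose(col1, support) + _lchoose(n - col1, row1 - support)
              - _lchoose(n, row1))
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    obs = pmf[a - lo]
    if alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        p = pmf[pmf <= obs * (1.0 + _TWO_SIDED_REL_TOL)].sum()
    return float(min(1.0, p))


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GO-term enrichment
# ---------------------------------------------------------------------------

def go_enrichment(gene_go: Mapping[str, Iterable[str]],
                  variant_genes: Iterable[str],
                  min_count: int = 2,
                  alpha: float = ALPHA_DEFAULT,
                  count_unit: str = "genes") -> pd.DataFrame:
    """Per-GO Fisher tests of variant-bearing versus variant-free genes.

    For each GO: a = variant genes annotated with it, b = variant-free
    genes annotated with it, c/d = the remaining gene-GO associations of
    each gene set. GOs seen fewer than ``min_count`` times among variant
    genes are dropped before testing; BH correction runs over the tested
    family. ``count_unit='occurrences'`` weighs a gene by how many of its
    variants exist is not implemented at this layer — genes count once per
    GO (the default and the only supported unit here).
    """
    if not gene_go:
        raise ValueError("empty gene->GO mapping")
    if count_unit != "genes":
        raise ValueError("only count_unit='genes' is supported")
    gene_go = {g: frozenset(t) for g, t in gene_go.items()}
    variant_set = set(variant_genes)
    unknown = variant_set - set(gene_go)
    if unknown:
        log.warning("dropping %d variant genes absent from the GO map", len(unknown))
        variant_set -= unknown
    other_set = set(gene_go) - variant_set

    def go_counts(genes: set[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in genes:
            for t in gene_go[g]:
                out[t] = out.get(t, 0) + 1
        return out

    var_counts = go_counts(variant_set)
    other_counts = go_counts(other_set)
    total_var = sum(var_counts.values())
    total_other = sum(other_counts.values())

    rows = []
    for go, a in sorted(var_counts.items()):
        if a < min_count:
            continue
        b = other_counts.get(go, 0)
        c = total_var - a
        d = total_other - b
        table = ContingencyTable(a, b, c, d)
        rows.append({"unit_id": go, "a": a, "b": b, "c": c, "d": d,
                     "p_raw": fisher_exact(table)})
    df = pd.DataFrame(rows, columns=["unit_id", "a", "b", "c", "d", "p_raw"])
    if len(df):
        df["q_bh"] = bh_adjust(df["p_raw"].to_numpy())
        df["significant"] = df["q_bh"] <= alpha
    else:
        df["q_bh"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df.sort_values(["q_bh", "p_raw", "unit_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# k-mer scan and enrichment
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_scan(sequences: Sequence[str],
              variant_positions: Sequence[Iterable[int]],
              k_min: int = 1, k_max: int = 10) -> pd.DataFrame:
    """Count, per k in [k_min, k_max], every forward-strand window occurrence.

    An occurrence is "variant" when its window covers at least one of the
    sequence's variant positions (0-based offsets). Windows containing a
    non-ACGT character are skipped. Returns columns k, kmer, variant,
    nonvariant aggregated over all sequences.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    if len(sequences) != len(variant_positions):
        raise ValueError("sequences and variant_positions must align")

    frames = []
    for k in range(k_min, k_max + 1):
        n_bins = 4 ** k
        var_counts = np.zeros(n_bins, dtype=np.int64)
        all_counts = np.zeros(n_bins, dtype=np.int64)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for seq, positions in zip(sequences, variant_positions):
            n = len(seq)
            if n < k:
                log.debug("sequence of length %d contributes no %d-mers", n, k)
                continue
            codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            windows = sliding_window_view(codes, k)
            valid = (windows >= 0).all(axis=1)
            ids = windows @ powers
            ind = np.zeros(n + 1, dtype=np.int64)
            pos_arr = np.fromiter((p for p in positions), dtype=np.int64)
            if pos_arr.size:
                if pos_arr.min() < 0 or pos_arr.max() >= n:
                    raise ValueError("variant position outside sequence bounds")
                ind[pos_arr] = 1
            cum = np.concatenate([[0], np.cumsum(ind[:-1])])
            has_var = (cum[k:] - cum[:-k]) > 0  # window [i, i+k) holds a variant
            all_counts += np.bincount(ids[valid], minlength=n_bins)
            var_counts += np.bincount(ids[valid & has_var], minlength=n_bins)
        present = np.nonzero(all_counts)[0]
        frames.append(pd.DataFrame({
            "k": k,
            "kmer": [_decode_kmer(int(c), k) for c in present],
            "variant": var_counts[present],
            "nonvariant": (all_counts - var_counts)[present],
        }))
    return pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["k", "kmer", "variant", "nonvariant"])


def kmer_enrichment(counts: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                    scope: str = "per_k") -> pd.DataFrame:
    """Fisher + BH over k-mer counts; each k-length forms its own BH family
    by default (``scope='global'`` corrects across all k at once)."""
    if scope not in {"per_k", "global"}:
        raise ValueError(f"unknown scope {scope!r}")
    results = []
    for k, group in counts.groupby("k"):
        group = group[(group["variant"] + group["nonvariant"]) > 0]
        if len(group) < 2:
            log.warning("k=%d has fewer than two occurring k-mers; untestable, skipped", k)
            continue
        tot_var = int(group["variant"].sum())
        tot_non = int(group["nonvariant"].sum())
        rows = []
        for _, row in group.iterrows():
            a, b = int(row["variant"]), int(row["nonvariant"])
            table = ContingencyTable(a, b, tot_var - a, tot_non - b)
            rows.append({"k": int(k), "unit_id": row["kmer"], "a": a, "b": b,
                         "c": tot_var - a, "d": tot_non - b,
                         "p_raw": fisher_exact(table)})
        results.append(pd.DataFrame(rows))
    if not results:
        return pd.DataFrame(columns=["k", "unit_id", "a", "b", "c", "d",
                                     "p_raw", "q_bh", "significant"])
    df = pd.concat(results, ignore_index=True)
    if scope == "per_k":
        df["q_bh"] = df.groupby("k")["p_raw"].transform(lambda p: bh_adjust(p.to_numpy()))
    else:
        df["q_bh"] = bh_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["q_bh"] <= alpha
    return df.sort_values(["k", "q_bh", "unit_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# Motif annotation
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifEntry:
    """A cis-regulatory motif: name, one or more IUPAC sequences, free text."""

    name: str
    sequences: tuple[str, ...]
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequences or any(not s for s in self.sequences):
            raise ValueError(f"motif {self.name}: sequences must be non-empty")
        for s in self.sequences:
            bad = set(s) - set(IUPAC)
            if bad:
                raise ValueError(f"motif {self.name}: non-IUPAC characters {sorted(bad)}")


def read_motif_table(path: str | Path) -> list[MotifEntry]:
    """TSV with columns name, sequence, description (one sequence per row;
    repeated names aggregate)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"name", "sequence"} <= set(df.columns):
        raise ValueError("motif table must have columns name, sequence")
    grouped: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry = grouped.setdefault(row["name"], {"seqs": [], "desc": row.get("description", "")})
        entry["seqs"].append(row["sequence"].upper())
    return [MotifEntry(name, tuple(v["seqs"]), v["desc"]) for name, v in grouped.items()]


def iupac_contains(motif_seq: str, kmer: str) -> bool:
    """True when ``kmer`` occurs as a substring of ``motif_seq``, letting the
    motif's IUPAC ambiguity codes match their nucleotide sets."""
    m, k = len(motif_seq), len(kmer)
    for off in range(m - k + 1):
        if all(base in IUPAC[motif_seq[off + i]] for i, base in enumerate(kmer)):
            return True
    return False


def annotate_motifs(enriched: pd.DataFrame, motifs: Sequence[MotifEntry],
                    confident_min_len: int = 6,
                    significant_only: bool = True) -> pd.DataFrame:
    """Match enriched k-mers into motif sequences as IUPAC substrings.

    Hits from k-mers shorter than ``confident_min_len`` are flagged
    low-confidence (partial hits below that length are "potential" only).
    """
    rows = []
    subset = enriched[enriched["significant"]] if significant_only and "significant" in enriched \
        else enriched
    for _, row in subset.iterrows():
        kmer = str(row["unit_id"]).upper()
        for motif in motifs:
            matched = [s for s in motif.sequences if iupac_contains(s, kmer)]
            if matched:
                rows.append({
                    "kmer": kmer, "k": len(kmer), "motif": motif.name,
                    "motif_sequence": matched[0],
                    "description": motif.description,
                    "confident": len(kmer) >= confident_min_len,
                })
    return pd.DataFrame(rows, columns=["kmer", "k", "motif", "motif_sequence",
                                       "description", "confident"])


# ---------------------------------------------------------------------------
# DE overlap
# ---------------------------------------------------------------------------

def de_overlap_test(variant_genes: Iterable[str],
                    de_flags: Mapping[str, bool]) -> tuple[ContingencyTable, float]:
    """Two-sided Fisher test of variant-bearing x differentially-expressed.

    The gene universe is the DE-flag table; variant genes outside it are
    dropped with a warning. An empty variant set (after reconciliation) or
    an empty universe is an error.
    """
    universe = set(de_flags)
    if not universe:
        raise ValueError("empty DE-flag table")
    variant_set = set(variant_genes)
    dropped = variant_set - universe
    if dropped:
        log.warning("dropping %d variant genes absent from the DE table", len(dropped))
    variant_set &= universe
    if not variant_set:
        raise ValueError("no variant genes overlap the DE-flag universe")
    a = sum(1 for g in variant_set if de_flags[g])
    b = len(variant_set) - a
    other = universe - variant_set
    c = sum(1 for g in other if de_flags[g])
    d = len(other) - c
    table = ContingencyTable(a, b, c, d)
    return table, fisher_exact(table, "two-sided")


def read_de_flags(path: str | Path) -> dict[str, bool]:
    """TSV with columns gene_id, de (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "de"} <= set(df.columns):
        raise ValueError("DE table must have columns gene_id, de")
    return {g: bool(int(v)) for g, v in zip(df["gene_id"], df["de"])}


# ---------------------------------------------------------------------------
# Glue: extract intergenic sequences + variant offsets from a record set
# ---------------------------------------------------------------------------

def collect_intergenic_inputs(genome: Genome, genes: Sequence[GeneModel],
                              records: Sequence[VariantRecord],
                              ) -> tuple[list[str], list[list[int]]]:
    """Slice the intergenic space and map intergenic variant POS values into
    per-interval 0-based offsets, ready for :func:`kmer_scan`."""
    intervals = intergenic_intervals(genome, genes)
    seqs: list[str] = []
    positions: list[list[int]] = []
    by_contig: dict[str, list[int]] = {}
    for r in records:
        by_contig.setdefault(r.contig, []).append(r.pos - 1)
    for contig, start, end in intervals:
        seqs.append(genome.sequences[contig][start:end])
        pos0 = sorted(p - start for p in by_contig.get(contig, [])
                      if start <= p < end)
        positions.append(pos0)
    return seqs, positions
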
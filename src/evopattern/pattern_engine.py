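"""Binary fixation-pattern encoding and trajectory classification.

Each variant's per-sample presence calls are laid out as a condition-
partitioned binary string, cold block then hot block ("cccccc|hhhh").
A variant counts as *fixed* in a condition when its block shows a single
0->1 switch maintained to the end of that block while the other block is
all-reference; such trajectories are the experiment's candidate adaptive
("non-random") variants. All-ones patterns are background disagreements
with the reference assembly, not new mutations, and are tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_core import SampleSeries, VariantRecord

LABELS = ("Background", "ColdFixed", "HotFixed", "Random", "NoVariant", "Unresolved")


@dataclass(frozen=True)
class BinaryPattern:
    """A condition-partitioned vector of {0, 1, missing} calls."""

    cold: tuple[Optional[int], ...]
    hot: tuple[Optional[int], ...]

    def display(self, missing_char: str = ".") -> str:
        def block(vals):
            return "".join(missing_char if v is None else str(v) for v in vals)
        return f"{block(self.cold)}|{block(self.hot)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display()

    @classmethod
    def from_string(cls, text: str) -> "BinaryPattern":
        """Parse a display-form string like ``"110011|0000"`` ('.' = missing)."""
        text = text.replace(" ", "")
        if text.count("|") != 1:
            raise ValueError(f"pattern must contain exactly one '|': {text!r}")
        cold_s, hot_s = text.split("|")

        def parse(block: str) -> tuple[Optional[int], ...]:
            out = []
            for ch in block:
                if ch == ".":
                    out.append(None)
                elif ch in "01":
                    out.append(int(ch))
                else:
                    raise ValueError(f"invalid pattern character {ch!r}")
            return tuple(out)

        return cls(parse(cold_s), parse(hot_s))

    def swapped(self) -> "BinaryPattern":
        """Exchange the cold and hot blocks (used for symmetry checks)."""
        return BinaryPattern(self.hot, self.cold)


@dataclass(frozen=True)
class PatternClass:
    label: str
    gain_time_ambiguous: bool = False


def encode_pattern(record: VariantRecord, series: SampleSeries) -> BinaryPattern:
    """Split a record's calls (already in series order) into cold|hot blocks."""
    if len(record.calls) != len(series.sample_ids):
        raise ValueError("record carries a different number of calls than the series")
    cold = tuple(c for c, cond in zip(record.calls, series.conditions) if cond == "cold")
    hot = tuple(c for c, cond in zip(record.calls, series.conditions) if cond == "hot")
    return BinaryPattern(cold, hot)


def _is_fixed_block(block: Sequence[Optional[int]]) -> bool:
    # matches 0^a 1^b with b >= 1: a single 0->1 switch held to the end
    try:
        first_one = block.index(1)
    except ValueError:
        return False
    return all(v == 0 for v in block[:first_one]) and all(v == 1 for v in block[first_one:])


def classify_pattern(p: BinaryPattern) -> PatternClass:
    """Label a pattern Background / ColdFixed / HotFixed / Random / NoVariant.

    Any missing call makes the pattern Unresolved. Fixation in a condition
    with an all-ones block means the gain predates the first sampling, so
    the gain condition is unknowable (``gain_time_ambiguous``).
    """
    values = p.cold + p.hot
    if any(v is None for v in values):
        return PatternClass("Unresolved")
    if all(v == 1 for v in values):
        return PatternClass("Background")
    if all(v == 0 for v in values):
        return PatternClass("NoVariant")
    if _is_fixed_block(p.cold) and all(v == 0 for v in p.hot):
        return PatternClass("ColdFixed", gain_time_ambiguous=all(v == 1 for v in p.cold))
    if _is_fixed_block(p.hot) and all(v == 0 for v in p.cold):
        return PatternClass("HotFixed", gain_time_ambiguous=all(v == 1 for v in p.hot))
    return PatternClass("Random")


def attribute_condition(p: BinaryPattern) -> Optional[str]:
    """Condition of the first sample carrying the variant, for rate attribution.

    Background/NoVariant/Unresolved patterns attribute to neither condition.
    """
    label = classify_pattern(p).label
    if label in {"Background", "NoVariant", "Unresolved"}:
        return None
    return "cold" if any(v == 1 for v in p.cold) else "hot"


def classification_frame(records: Iterable[VariantRecord],
                         series: SampleSeries) -> pd.DataFrame:
    """One row per record: pattern string, class label, ambiguity, attribution."""
    rows = []
    for r in records:
        p = encode_pattern(r, series)
        c = classify_pattern(p)
        rows.append({
            "contig": r.contig, "pos": r.pos,
            "variant_type": r.variant_type,
            "region": r.region or "",
            "gene_ids": ",".join(r.gene_ids),
            "pattern": p.display(),
            "label": c.label,
            "gain_time_ambiguous": c.gain_time_ambiguous,
            "attributed_condition": attribute_condition(p) or "",
        })
    return pd.DataFrame(rows, columns=["contig", "pos", "variant_type", "region",
                                       "gene_ids", "pattern", "label",
                                       "gain_time_ambiguous", "attributed_condition"])


@dataclass
class PatternSummary:
    """Class counts with the study's two percentage denominators.

    ``pct_background`` is taken over all classified records (the filtered
    set); the per-class percentages are taken over the non-background
    trajectory set (ColdFixed + HotFixed + Random). Undefined percentages
    (zero denominator) are ``None`` rather than 0.
    """

    counts: dict[str, int]
    n_total: int
    pct_background: Optional[float]
    pct_of_trajectories: dict[str, Optional[float]]
    by_type: pd.DataFrame
    by_region: pd.DataFrame


def summarize_patterns(classified: pd.DataFrame) -> PatternSummary:
    """Summarize a :func:`classification_frame` output."""
    counts = {label: 0 for label in LABELS}
    if len(classified):
        for label, n in classified["label"].value_counts().items():
            counts[str(label)] = int(n)
    n_total = int(sum(counts.values()))
    pct_background = 100.0 * counts["Background"] / n_total if n_total else None
    n_traj = counts["ColdFixed"] + counts["HotFixed"] + counts["Random"]
    pct_traj = {
        label: (100.0 * counts[label] / n_traj if n_traj else None)
        for label in ("ColdFixed", "HotFixed", "Random")
    }
    if len(classified):
        by_type = classified.pivot_table(index="label", columns="variant_type",
                                         values="pos", aggfunc="count", fill_value=0)
        by_region = classified.pivot_table(index="label", columns="region",
                                           values="pos", aggfunc="count", fill_value=0)
    else:
        by_type = pd.DataFrame()
        by_region = pd.DataFrame()
    return PatternSummary(counts, n_total, pct_background, pct_traj, by_type, by_region)


def estimate_mutation_rate(variant_count: int, genome_length: float,
                           generations: float) -> float:
    """Per-base per-generation mutation rate: count / (L * G)."""
    if variant_count < 0:
        raise ValueError("variant_count must be >= 0")
    if genome_length <= 0 or generations <= 0:
        raise ValueError("genome length and generations must be positive")
    return variant_count / (genome_length * generations)


def condition_attributed_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Number of non-background trajectory variants first seen in each condition."""
    out = {"cold": 0, "hot": 0}
    if len(classified):
        vc = classified.loc[classified["attributed_condition"] != "",
                            "attributed_condition"].value_counts()
        for cond, n in vc.items():
            out[str(cond)] = int(n)
    return out
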
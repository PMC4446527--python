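"""Sequence composition of a target region versus control regions.

GC content and coverage by repeat classes (SINEs, LINEs, LTRs, DNA
transposons, small RNAs, low-complexity repeats) are computed for the
centromeric target region and a panel of control regions, then compared
class by class with a two-sided one-sample Student's t test of the
control values against the target value (df = n_controls - 1).  With one
target region and many controls this is the defensible reading of
"Student's t test" for this design; raw p values are reported without
multiple-testing correction.

Repeat annotations are accepted either as native RepeatMasker ``.out``
files (standard 15-column layout, 1-based inclusive coordinates) or as a
simple TSV (chrom, start, end, class).  Same-class overlapping elements
are counted once (coverage of the union, never a sum of lengths);
different classes may overlap each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, merge_intervals, overlap_length

__all__ = [
    "REPEAT_CLASSES",
    "RepeatElement",
    "CompositionRecord",
    "CompositionComparison",
    "gc_content",
    "normalize_repeat_class",
    "read_repeatmasker_out",
    "read_repeat_tsv",
    "composition_table",
    "compare_composition",
    "plot_comparison",
]

REPEAT_CLASSES = (
    "SINE",
    "LINE",
    "LTR",
    "DNA_transposon",
    "small_RNA",
    "low_complexity",
)

_CLASS_ALIASES = {
    "SINE": "SINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "DNA": "DNA_transposon",
    "DNA_TRANSPOSON": "DNA_transposon",
    "RC": "DNA_transposon",  # rolling-circle transposons (Helitrons)
    "SMALL_RNA": "small_RNA",
    "SNRNA": "small_RNA",
    "TRNA": "small_RNA",
    "RRNA": "small_RNA",
    "SCRNA": "small_RNA",
    "SRPRNA": "small_RNA",
    "LOW_COMPLEXITY": "low_complexity",
}


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int  # 0-based half-open
    end: int
    repeat_class: str


@dataclass
class CompositionRecord:
    region_id: str
    chrom: str
    start: int
    end: int
    gc_percent: float
    class_percent: dict[str, float] = field(default_factory=dict)


@dataclass
class CompositionComparison:
    label: str
    target_value: float
    control_mean: float
    control_sd: float
    t_statistic: float
    p_value: float


def normalize_repeat_class(raw: str) -> str | None:
    """Map a RepeatMasker class/family string (e.g. ``SINE/tRNA``,
    ``Low_complexity``) to one of the six analysed classes, or None for
    classes outside the analysis (satellites, simple repeats, unknowns)."""
    head = raw.split("/")[0].strip().upper().replace("-", "_")
    return _CLASS_ALIASES.get(head)


def gc_content(sequence: str, allow_ambiguity: bool = False) -> float:
    """GC percentage, 100*(G+C)/(A+C+G+T); N bases are excluded from the
    denominator.  Ambiguity codes other than N raise unless
    ``allow_ambiguity`` (then they are excluded like N)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    other = len(seq) - sum(counts.values())
    if other and not allow_ambiguity:
        raise ValueError(f"{other} non-ACGTN characters in sequence")
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def read_repeatmasker_out(path: str | Path) -> list[RepeatElement]:
    """Parse a RepeatMasker ``.out`` annotation file.

    Standard layout: a 3-line header, then whitespace-separated columns
    with query sequence in column 5, begin/end in columns 6-7 (1-based
    inclusive) and repeat class/family in column 11.
    """
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0] in ("SW", "score") or not fields[0][0].isdigit():
                continue
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line")
            chrom = fields[4]
            start1, end1 = int(fields[5]), int(fields[6])
            klass = normalize_repeat_class(fields[10])
            if klass is None:
                continue
            elements.append(RepeatElement(chrom, start1 - 1, end1, klass))
    return elements


def read_repeat_tsv(path: str | Path) -> list[RepeatElement]:
    """Parse a simple TSV of (chrom, start, end, class), 0-based half-open,
    with optional ``#`` header lines."""
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            klass = normalize_repeat_class(fields[3])
            if klass is None:
                continue
            elements.append(
                RepeatElement(fields[0], int(fields[1]), int(fields[2]), klass)
            )
    return elements


def composition_table(
    regions: list[GenomicInterval],
    genome: Mapping[str, str],
    repeats: list[RepeatElement],
    region_ids: list[str] | None = None,
) -> list[CompositionRecord]:
    """One composition record per region.

    ``genome`` is any mapping from chromosome name to sequence (a plain
    dict, or a ``pyfaidx.Fasta`` object).  Class percentages are coverage
    of the union of same-class elements over the region's non-N length.
    """
    if region_ids is None:
        region_ids = [str(r) for r in regions]
    by_chrom_class: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for el in repeats:
        by_chrom_class.setdefault((el.chrom, el.repeat_class), []).append(
            (el.start, el.end)
        )

    records = []
    for rid, region in zip(region_ids, regions):
        if region.chrom not in genome:
            raise ValueError(f"region {rid}: chromosome {region.chrom} not in genome")
        chrom_seq = genome[region.chrom]
        chrom_len = len(chrom_seq)
        if region.end > chrom_len:
            raise ValueError(
                f"region {rid} ({region}) extends past end of {region.chrom} "
                f"({chrom_len} bp)"
            )
        seq = str(chrom_seq[region.start : region.end]).upper()
        non_n = sum(seq.count(b) for b in "ACGT")
        if non_n == 0:
            raise ValueError(f"region {rid} contains no unambiguous bases")
        gc = gc_content(seq, allow_ambiguity=True)
        class_percent = {}
        for klass in REPEAT_CLASSES:
            ivs = by_chrom_class.get((region.chrom, klass), [])
            clipped = [
                (max(s, region.start), min(e, region.end))
                for s, e in ivs
                if overlap_length((s, e), (region.start, region.end)) > 0
            ]
            covered = sum(e - s for s, e in merge_intervals(clipped))
            class_percent[klass] = 100.0 * covered / non_n
        records.append(
            CompositionRecord(rid, region.chrom, region.start, region.end, gc, class_percent)
        )
    return records


def compare_composition(
    target: CompositionRecord,
    controls: list[CompositionRecord],
) -> list[CompositionComparison]:
    """Compare the target region's composition against the controls.

    For GC and each repeat class: a two-sided one-sample Student's t test
    of the control values against the target's value as the hypothesised
    mean, df = n_controls - 1.  Zero variance among controls yields p = 1
    if the target equals the control mean and p = 0 otherwise.
    """
    if len(controls) < 3:
        raise ValueError("need at least 3 control regions")

    comparisons = []
    labels = ["GC"] + list(REPEAT_CLASSES)
    for label in labels:
        if label == "GC":
            values = np.array([c.gc_percent for c in controls])
            tval = target.gc_percent
        else:
            values = np.array([c.class_percent.get(label, 0.0) for c in controls])
            tval = target.class_percent.get(label, 0.0)
        sd = float(np.std(values, ddof=1))
        mean = float(values.mean())
        if sd == 0.0:
            t_stat = 0.0 if mean == tval else float("inf") * np.sign(mean - tval)
            p = 1.0 if mean == tval else 0.0
        else:
            res = stats.ttest_1samp(values, popmean=tval)
            t_stat, p = float(res.statistic), float(res.pvalue)
        comparisons.append(CompositionComparison(label, tval, mean, sd, t_stat, p))
    return comparisons


def plot_comparison(comparisons: list[CompositionComparison], path) -> None:
    """Write a paired bar chart of target vs control-mean composition, with
    the per-class p values annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as _np

    labels = [c.label for c in comparisons]
    x = _np.arange(len(labels))
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.bar(x - 0.2, [c.target_value for c in comparisons], 0.4, label="target region")
    ax.bar(x + 0.2, [c.control_mean for c in comparisons], 0.4,
           yerr=[c.control_sd for c in comparisons], capsize=3, label="controls (mean)")
    for xi, c in zip(x, comparisons):
        ax.text(xi, max(c.target_value, c.control_mean) * 1.02, f"p={c.p_value:.2g}",
                ha="center", fontsize=7)
    ax.set_xticks(x, labels, rotation=30, ha="right")
    ax.set_ylabel("% of bases")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
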
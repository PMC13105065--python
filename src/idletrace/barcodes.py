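"""ClonMapper-style lineage barcode design, extraction, counting and statistics.

Barcodes are gRNA-embedded 20-mers: a shared 4-nt prefix followed by 16
strong/weak (SW) paired positions — S positions admit {G, C}, W positions
admit {A, T} — giving a maximum library complexity of 2^16 sequences. The SW
alternation limits GC-content variation and hence PCR amplification bias.

In amplicon reads the barcode sits between two fixed flanking adapters; the
extraction here locates both flanks (allowing a configurable number of
mismatches per flank, no indels), takes the intervening fixed-length
candidate, validates it against the design, and accumulates per-sample
counts. Counts are depth-normalised to reads per million (RPM; the
literature also calls the same quantity CPM) and low-abundance barcodes
below a counts-per-million threshold (default 100, strict "less than") are
filtered before lineage-level statistics: per-barcode log2 fold-changes
between conditions, unique-barcode complexity and cross-replicate sharing.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeDesign",
    "BarcodeCountTable",
    "FoldChangeTable",
    "ExtractionResult",
    "SharingSummary",
    "design_space_size",
    "enumerate_barcodes",
    "sample_library",
    "extract_barcodes",
    "normalize_rpm",
    "filter_low_abundance",
    "fold_changes",
    "complexity_and_sharing",
]

_SW_ALPHABET = {"S": "GC", "W": "AT"}
_NUC = set("ACGT")


@dataclass(frozen=True)
class BarcodeDesign:
    """Barcode layout: shared prefix + SW pattern, bounded by fixed flanks.

    The flank sequences are experiment-specific adapter context and must be
    supplied by the user for real data; the defaults are the documented
    synthetic fixture pair used by the generators in this package.
    """

    shared_prefix: str = "GTCA"
    sw_pattern: str = "SW" * 8
    flank5: str = "ATCACGCTGA"
    flank3: str = "GACTGTGCAT"

    def __post_init__(self) -> None:
        if not self.sw_pattern or set(self.sw_pattern) - set("SW"):
            raise ValueError("sw_pattern must be a non-empty string over {S, W}")
        for label, seq in (("shared_prefix", self.shared_prefix),
                           ("flank5", self.flank5), ("flank3", self.flank3)):
            if label != "shared_prefix" and not seq:
                raise ValueError(f"{label} must be non-empty")
            if set(seq) - _NUC:
                raise ValueError(f"{label} must contain only A/C/G/T")

    @property
    def barcode_length(self) -> int:
        return len(self.shared_prefix) + len(self.sw_pattern)

    def conforms(self, candidate: str) -> bool:
        """True iff candidate is prefix + a pattern-conformant SW core."""
        if len(candidate) != self.barcode_length:
            return False
        if not candidate.startswith(self.shared_prefix):
            return False
        core = candidate[len(self.shared_prefix):]
        return all(base in _SW_ALPHABET[sw]
                   for base, sw in zip(core, self.sw_pattern))

    def decode_index(self, index: int) -> str:
        """Bijection {0, ..., 2^k - 1} -> barcode sequences (bit per position)."""
        core = []
        for pos, sw in enumerate(self.sw_pattern):
            bit = (index >> pos) & 1
            core.append(_SW_ALPHABET[sw][bit])
        return self.shared_prefix + "".join(core)


def design_space_size(design: BarcodeDesign) -> int:
    """Number of expressible barcodes: 2^len(sw_pattern)."""
    return 2 ** len(design.sw_pattern)


def enumerate_barcodes(design: BarcodeDesign):
    """Yield every barcode in the design space (guarded to patterns <= 20)."""
    if len(design.sw_pattern) > 20:
        raise ValueError("exhaustive enumeration limited to patterns <= 20")
    choices = [_SW_ALPHABET[sw] for sw in design.sw_pattern]
    for combo in itertools.product(*choices):
        yield design.shared_prefix + "".join(combo)


def sample_library(design: BarcodeDesign, n: int, seed: int) -> set[str]:
    """Sample n distinct barcodes from the design space, seed-reproducibly."""
    space = design_space_size(design)
    if n < 0 or n > space:
        raise ValueError(f"n must be in [0, {space}]")
    rng = np.random.default_rng(seed)
    if space <= 2 ** 24:
        idx = rng.choice(space, size=n, replace=False)
    else:  # rejection sampling for astronomically large patterns
        chosen: set[int] = set()
        while len(chosen) < n:
            chosen.update(int(i) for i in
                          rng.integers(0, space, size=n - len(chosen)))
        idx = np.fromiter(chosen, dtype=np.int64)[:n]
    return {design.decode_index(int(i)) for i in idx}


@dataclass
class BarcodeCountTable:
    """Per-sample barcode read counts, with optional RPM and filter columns.

    Backed by a long-format DataFrame with columns
    ``sample, barcode, count[, rpm, pass_filter]``.
    """

    data: pd.DataFrame

    REQUIRED = ("sample", "barcode", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_counts(cls, counts_by_sample: dict[str, dict[str, int]]
                    ) -> "BarcodeCountTable":
        rows = [(s, bc, int(c))
                for s, counts in counts_by_sample.items()
                for bc, c in sorted(counts.items())]
        return cls(pd.DataFrame(rows, columns=["sample", "barcode", "count"]))

    @property
    def samples(self) -> list[str]:
        return list(self.data["sample"].unique())

    def sample_totals(self) -> pd.Series:
        return self.data.groupby("sample")["count"].sum()

    def sample_counts(self, sample: str) -> pd.Series:
        sub = self.data[self.data["sample"] == sample]
        return sub.set_index("barcode")["count"]

    def sample_rpm(self, sample: str) -> pd.Series:
        if "rpm" not in self.data.columns:
            raise ValueError("RPM not computed; call normalize_rpm first")
        sub = self.data[self.data["sample"] == sample]
        return sub.set_index("barcode")["rpm"]

    def barcode_sets(self) -> dict[str, set[str]]:
        return {s: set(g["barcode"]) for s, g in self.data.groupby("sample")}


@dataclass
class ExtractionResult:
    """One sample's extraction outcome."""

    counts: Counter
    n_reads: int
    n_unassigned: int
    n_nonconformant: int
    n_skipped: int = 0
    nonconformant_counts: Counter = field(default_factory=Counter)

    def to_table(self, sample: str) -> BarcodeCountTable:
        return BarcodeCountTable.from_counts({sample: dict(self.counts)})


def _hamming_find(seq: str, pattern: str, max_mm: int, start: int = 0) -> int:
    """Leftmost index >= start where pattern matches seq with <= max_mm
    substitutions; -1 if none. Exact find is tried first as a fast path."""
    i = seq.find(pattern, start)
    if i != -1 or max_mm == 0:
        return i
    m = len(pattern)
    for i in range(start, len(seq) - m + 1):
        mm = 0
        for a, b in zip(seq[i:i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def _hamming_at(seq: str, pattern: str, pos: int, max_mm: int) -> bool:
    if pos + len(pattern) > len(seq):
        return False
    mm = 0
    for a, b in zip(seq[pos:pos + len(pattern)], pattern):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def _iter_sequences(reads):
    """Accept a FASTQ path, an open handle, or an iterable of sequences /
    (id, seq) pairs / Biopython SeqRecords."""
    if isinstance(reads, (str, Path)):
        from .io import read_fastq

        for _rid, seq, _qual in read_fastq(reads):
            yield seq
        return
    for item in reads:
        if isinstance(item, str):
            yield item
        elif hasattr(item, "seq"):
            yield str(item.seq)
        else:
            yield str(item[1])


def extract_barcodes(
    reads,
    design: BarcodeDesign,
    max_flank_mismatches: int = 1,
    strict: bool = True,
) -> ExtractionResult:
    """Extract barcode counts for one sample from amplicon reads.

    For each read the 5' flank is located (allowing up to
    ``max_flank_mismatches`` substitutions), the following
    ``design.barcode_length`` bases form the candidate, and the 3' flank must
    match immediately after. Candidates that violate the prefix/SW pattern
    are tallied separately and, in strict mode (default), excluded from the
    count table. Reads where the flank pair cannot be located are counted as
    unassigned.
    """
    counts: Counter = Counter()
    bad: Counter = Counter()
    n_reads = n_unassigned = n_skipped = 0
    bl = design.barcode_length
    for seq in _iter_sequences(reads):
        n_reads += 1
        if not seq or set(seq) - set("ACGTN"):
            n_skipped += 1
            continue
        pos = _hamming_find(seq, design.flank5, max_flank_mismatches)
        found = False
        while pos != -1:
            start = pos + len(design.flank5)
            if _hamming_at(seq, design.flank3, start + bl,
                           max_flank_mismatches):
                candidate = seq[start:start + bl]
                if len(candidate) == bl:
                    found = True
                    if design.conforms(candidate):
                        counts[candidate] += 1
                    else:
                        bad[candidate] += 1
                        if not strict:
                            counts[candidate] += 1
                    break
            pos = _hamming_find(seq, design.flank5, max_flank_mismatches,
                                pos + 1)
        if not found:
            n_unassigned += 1
    return ExtractionResult(
        counts=counts,
        n_reads=n_reads,
        n_unassigned=n_unassigned,
        n_nonconformant=int(sum(bad.values())),
        n_skipped=n_skipped,
        nonconformant_counts=bad,
    )


def normalize_rpm(table: BarcodeCountTable) -> BarcodeCountTable:
    """Depth-normalise counts: rpm = count * 1e6 / sample total."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total reads: {list(zero.index)}")
    df = table.data.copy()
    df["rpm"] = df["count"] * 1e6 / df["sample"].map(totals)
    return BarcodeCountTable(df)


def filter_low_abundance(
    table: BarcodeCountTable, threshold_cpm: float = 100.0
) -> tuple[BarcodeCountTable, pd.Series]:
    """Drop barcodes whose RPM is strictly below threshold_cpm.

    Barcodes at exactly the threshold are retained (the removal rule is
    "less than"). Returns the filtered table and the per-sample
    unique-barcode counts after filtering.
    """
    if threshold_cpm < 0:
        raise ValueError("threshold must be >= 0")
    if "rpm" not in table.data.columns:
        raise ValueError("RPM not computed; call normalize_rpm first")
    df = table.data.copy()
    df["pass_filter"] = df["rpm"] >= threshold_cpm
    kept = df[df["pass_filter"]].reset_index(drop=True)
    unique = kept.groupby("sample")["barcode"].nunique()
    unique = unique.reindex(table.samples, fill_value=0)
    return BarcodeCountTable(kept), unique


@dataclass
class FoldChangeTable:
    """Per-barcode log2 fold-change between two RPM-normalised samples."""

    data: pd.DataFrame  # columns: barcode, ref_rpm, treated_rpm, log2fc
    reference: str
    treated: str
    pseudocount: float

    @property
    def mean(self) -> float:
        return float(self.data["log2fc"].mean())

    @property
    def sd(self) -> float:
        return float(self.data["log2fc"].std(ddof=1))

    @property
    def n(self) -> int:
        return len(self.data)

    def top_n(self, n: int) -> "FoldChangeTable":
        sub = self.data.nlargest(n, "ref_rpm").reset_index(drop=True)
        return FoldChangeTable(sub, self.reference, self.treated,
                               self.pseudocount)


def fold_changes(
    table: BarcodeCountTable,
    reference: str,
    treated: str,
    pseudocount: float = 0.5,
    top_n: int | None = None,
    restrict_to_reference: bool = True,
) -> FoldChangeTable:
    """log2((RPM_treated + c) / (RPM_ref + c)) per barcode.

    By default only barcodes observed in the reference sample contribute
    (so, on a filtered table, only barcodes passing the filter in the
    reference condition); the treated side of a missing barcode gets RPM 0
    plus the pseudocount. ``restrict_to_reference=False`` widens to the
    union of both samples. Barcodes absent in both are dropped by
    construction. ``top_n`` optionally restricts to the most abundant
    reference barcodes (the figure-style top-24 view).
    """
    ref = table.sample_rpm(reference)
    trt = table.sample_rpm(treated)
    if ref.empty and trt.empty:
        raise ValueError("no barcodes in either sample")
    barcodes = ref.index if restrict_to_reference else ref.index.union(trt.index)
    if restrict_to_reference and barcodes.empty:
        raise ValueError("no barcodes in reference sample")
    if barcodes.empty:
        raise ValueError("no shared barcodes")
    r = ref.reindex(barcodes, fill_value=0.0)
    t = trt.reindex(barcodes, fill_value=0.0)
    fc = np.log2((t + pseudocount) / (r + pseudocount))
    df = pd.DataFrame({
        "barcode": barcodes,
        "ref_rpm": r.values,
        "treated_rpm": t.values,
        "log2fc": fc.values,
    }).sort_values("ref_rpm", ascending=False).reset_index(drop=True)
    out = FoldChangeTable(df, reference, treated, float(pseudocount))
    if top_n is not None:
        out = out.top_n(top_n)
    return out


@dataclass
class SharingSummary:
    """Unique-barcode complexity per condition and sharing statistics."""

    unique_per_condition: dict[str, int]
    unique_per_replicate: dict[str, list[int]]
    shared_between_conditions: int
    pairwise_replicate_sharing: dict[str, list[float]]
    relative_complexity_change: float | None


def complexity_and_sharing(
    tables_by_condition: dict[str, list[BarcodeCountTable]],
    reference: str | None = None,
    treated: str | None = None,
) -> SharingSummary:
    """Set cardinalities and intersections of (already filtered) barcode sets.

    Per condition, replicate barcode sets are unioned for the condition-level
    unique count; pairwise replicate sharing is the Jaccard index. When
    ``reference``/``treated`` name two of the conditions, the relative
    complexity change (unique_treated - unique_ref) / unique_ref is reported
    — the quantity behind the "complexity reduced by less than 10%" readout.
    """
    if not tables_by_condition:
        raise ValueError("no conditions given")
    sets_by_cond: dict[str, list[set[str]]] = {}
    for cond, tables in tables_by_condition.items():
        if not tables:
            raise ValueError(f"condition {cond!r} has no replicates")
        sets = []
        for tab in tables:
            for s in tab.barcode_sets().values():
                sets.append(s)
        sets_by_cond[cond] = sets

    union_by_cond = {c: set().union(*s) for c, s in sets_by_cond.items()}
    unique = {c: len(u) for c, u in union_by_cond.items()}
    per_rep = {c: [len(s) for s in sets] for c, sets in sets_by_cond.items()}

    pairwise = {}
    for cond, sets in sets_by_cond.items():
        vals = []
        for a, b in itertools.combinations(sets, 2):
            union = a | b
            vals.append(len(a & b) / len(union) if union else 1.0)
        pairwise[cond] = vals

    conds = list(sets_by_cond)
    if reference is None and treated is None and len(conds) == 2:
        reference, treated = conds
    if reference is not None and treated is not None:
        shared = len(union_by_cond[reference] & union_by_cond[treated])
        denom = unique[reference]
        rel = (unique[treated] - denom) / denom if denom else None
    else:
        shared = len(set.intersection(*union_by_cond.values()))
        rel = None
    return SharingSummary(
        unique_per_condition=unique,
        unique_per_replicate=per_rep,
        shared_between_conditions=shared,
        pairwise_replicate_sharing=pairwise,
        relative_complexity_change=rel,
    )
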
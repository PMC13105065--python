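"""Lineage-to-cell assignment and lineage-phenotype association statistics.

In a CROP-seq-style experiment the lineage barcode is carried on a captured
transcript, so the link between a cell and its clonal lineage is made by
joining two cleaned record streams on the shared mRNA transcript ID: one
stream pairs transcript IDs with single-cell barcodes and UMIs, the other
pairs transcript IDs with lineage barcodes. Per cell, each candidate
lineage's support is the number of *distinct* UMIs backing it (distinct
molecules, robust to PCR duplication); the lineage with strictly maximal
support wins, ties and sub-threshold support yield UNASSIGNED.

Downstream, lineage composition across phenotype clusters and cell-cycle
classes (slow = G1, fast = S-G2-M) is tabulated, and the association between
a lineage's fast-dividing fraction and its barcode-abundance fold-change is
quantified with a Pearson correlation over the most abundant lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .barcodes import FoldChangeTable

__all__ = [
    "UNASSIGNED",
    "CellLineageAssignment",
    "CompositionResult",
    "CorrelationResult",
    "assign_lineages",
    "lineage_composition",
    "fast_fraction",
    "fast_fraction_correlation",
]

UNASSIGNED = "UNASSIGNED"

_CELL_COLS = ["transcript_id", "cell_barcode", "umi"]
_LIN_COLS = ["transcript_id", "lineage_barcode"]


@dataclass
class CellLineageAssignment:
    """Per-cell lineage call plus the UMI support behind it.

    ``assignments`` has columns ``cell_barcode, lineage, n_umi``;
    ``support`` retains the full per-(cell, lineage) distinct-UMI counts.
    """

    assignments: pd.DataFrame
    support: pd.DataFrame
    n_duplicates_dropped: int = 0

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.assignments["cell_barcode"],
                        self.assignments["lineage"]))

    @property
    def n_assigned(self) -> int:
        return int((self.assignments["lineage"] != UNASSIGNED).sum())


def _as_frame(records, cols) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records[cols].copy()
    else:
        df = pd.DataFrame(list(records), columns=cols)
    for c in cols:
        df[c] = df[c].astype(str)
        if (df[c] == "").any():
            raise ValueError(f"empty values in column {c!r}")
    return df


def assign_lineages(cell_records, lineage_records,
                    min_umi: int = 1) -> CellLineageAssignment:
    """Join record streams on transcript_id and call one lineage per cell.

    Duplicate (transcript, cell, UMI) records are de-duplicated (counted,
    not an error). A cell is assigned the lineage with the most distinct
    supporting UMIs when that maximum is unique and >= min_umi; otherwise
    UNASSIGNED. The result is deterministic and independent of record order.
    """
    cells = _as_frame(cell_records, _CELL_COLS)
    lins = _as_frame(lineage_records, _LIN_COLS)
    n0 = len(cells)
    cells = cells.drop_duplicates()
    lins = lins.drop_duplicates()
    n_dup = n0 - len(cells)

    merged = cells.merge(lins, on="transcript_id", how="inner")
    if merged.empty:
        return CellLineageAssignment(
            assignments=pd.DataFrame(columns=["cell_barcode", "lineage",
                                              "n_umi"]),
            support=pd.DataFrame(columns=["cell_barcode", "lineage_barcode",
                                          "n_umi"]),
            n_duplicates_dropped=n_dup,
        )
    support = (
        merged.groupby(["cell_barcode", "lineage_barcode"])["umi"]
        .nunique()
        .reset_index(name="n_umi")
        .sort_values(["cell_barcode", "lineage_barcode"])
        .reset_index(drop=True)
    )

    rows = []
    for cell, grp in support.groupby("cell_barcode", sort=True):
        best = grp["n_umi"].max()
        winners = grp[grp["n_umi"] == best]
        if best >= min_umi and len(winners) == 1:
            rows.append((cell, winners["lineage_barcode"].iloc[0], int(best)))
        else:
            rows.append((cell, UNASSIGNED, int(best)))
    assignments = pd.DataFrame(rows,
                               columns=["cell_barcode", "lineage", "n_umi"])
    return CellLineageAssignment(assignments=assignments, support=support,
                                 n_duplicates_dropped=n_dup)


@dataclass
class CompositionResult:
    """Per-lineage occupancy proportions across clusters / cycle classes."""

    by_cluster: pd.DataFrame   # lineages x clusters, rows sum to 1
    by_cycle: pd.DataFrame     # lineages x {slow, fast}, rows sum to 1
    cells_per_lineage: pd.Series
    excluded: list[str]

    def fast_fraction(self) -> pd.Series:
        if "fast" in self.by_cycle.columns:
            return self.by_cycle["fast"]
        return pd.Series(0.0, index=self.by_cycle.index)


def lineage_composition(annotations: pd.DataFrame,
                        min_cells: int = 1) -> CompositionResult:
    """Tabulate per-lineage proportions by cluster and by cycle class.

    ``annotations`` needs columns cell_barcode, lineage, cluster,
    cycle_class. Lineages with fewer than min_cells cells are excluded and
    listed. UNASSIGNED cells are ignored.
    """
    required = {"cell_barcode", "lineage", "cluster", "cycle_class"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotations missing columns: {sorted(missing)}")
    ann = annotations[annotations["lineage"] != UNASSIGNED]
    sizes = ann.groupby("lineage").size()
    keep = sizes[sizes >= min_cells].index
    excluded = sorted(set(sizes.index) - set(keep))
    ann = ann[ann["lineage"].isin(keep)]
    if ann.empty:
        import warnings

        warnings.warn("no lineages pass min_cells; empty composition")
        empty = pd.DataFrame()
        return CompositionResult(empty, empty, sizes[keep], excluded)

    def _prop(col: str) -> pd.DataFrame:
        tab = pd.crosstab(ann["lineage"], ann[col])
        return tab.div(tab.sum(axis=1), axis=0)

    return CompositionResult(
        by_cluster=_prop("cluster"),
        by_cycle=_prop("cycle_class"),
        cells_per_lineage=sizes[keep],
        excluded=excluded,
    )


def fast_fraction(annotations: pd.DataFrame, min_cells: int = 1) -> pd.Series:
    """Fraction of each lineage's cells in the fast (S-G2-M) cycle class."""
    return lineage_composition(annotations, min_cells).fast_fraction()


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    pairs: pd.DataFrame  # lineage, fast_fraction, log2fc, ref_rpm

    @property
    def n(self) -> int:
        return len(self.pairs)


def fast_fraction_correlation(
    composition: pd.Series,
    foldchanges: FoldChangeTable,
    top_n: int | None = 24,
) -> CorrelationResult:
    """Pearson correlation between per-lineage fast fraction and log2
    fold-change, over the top_n most abundant reference lineages.

    This is the package's version of the lineage-fitness readout: lineages
    whose cells disproportionately occupy the fast-dividing persister state
    should show elevated barcode-abundance fold-changes after treatment.
    """
    fc = foldchanges.data.set_index("barcode")
    shared = fc.index.intersection(composition.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 lineages shared between composition and fold-changes, "
            f"got {len(shared)}"
        )
    fc = fc.loc[shared]
    if top_n is not None:
        fc = fc.nlargest(top_n, "ref_rpm")
    pairs = pd.DataFrame({
        "lineage": fc.index,
        "fast_fraction": composition.loc[fc.index].values,
        "log2fc": fc["log2fc"].values,
        "ref_rpm": fc["ref_rpm"].values,
    }).reset_index(drop=True)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 lineages after top-n restriction")
    x = pairs["fast_fraction"].to_numpy()
    y = pairs["log2fc"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one variable; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), pairs=pairs)
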
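"""Readers and writers for the package's interchange formats.

Canonical formats are headered TSV/CSV (gzip transparently supported),
FASTQ for reads, YAML/JSON for landscape and run configuration, and JSON
for fitted parameters. Column layouts:

* barcode count table TSV: sample, barcode, count[, rpm, pass_filter]
* fold-change TSV: barcode, ref_rpm, treated_rpm, log2fc
* growth curve CSV: well, condition, conc_molar, time_h, cell_count
* flux trace CSV: well, condition, time_s, intensity
* GO table TSV: term, category, pvalue
* record streams TSV: (transcript_id, cell_barcode, umi) and
  (transcript_id, lineage_barcode)
* trajectory CSV: time, lineage, state, count
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .barcodes import BarcodeCountTable, FoldChangeTable
from .calcium import FluxTrace
from .doseresponse import DoseResponseCurve, GrowthCurve
from .population import PhenotypeLandscape, PhenotypeState
from .synthetic import FastqRead

__all__ = [
    "read_fastq", "write_fastq",
    "read_count_table", "write_count_table",
    "read_fold_changes", "write_fold_changes",
    "read_growth_curves", "write_growth_curves",
    "read_flux_traces", "write_flux_traces",
    "read_go_table", "write_go_table",
    "read_records", "write_records",
    "write_trajectory",
    "read_landscape", "write_landscape",
    "write_fit_json",
    "load_config",
]


def _opener(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# -- FASTQ ------------------------------------------------------------------

def read_fastq(path):
    """Yield (id, sequence, quality) triples from plain or gzipped FASTQ."""
    from Bio import SeqIO

    with _opener(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33)
                           for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq), qual


def write_fastq(path, reads) -> None:
    """Write FastqRead-like (id, seq, qual) records as FASTQ (gz-aware)."""
    with _opener(path, "w") as fh:
        for r in reads:
            rid, seq, qual = ((r.id, r.seq, r.qual)
                              if isinstance(r, FastqRead) else r)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# -- tabular artifacts ------------------------------------------------------

def write_count_table(path, table: BarcodeCountTable) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_count_table(path) -> BarcodeCountTable:
    df = pd.read_csv(path, sep="\t")
    return BarcodeCountTable(df)


def write_fold_changes(path, fc: FoldChangeTable) -> None:
    fc.data.to_csv(path, sep="\t", index=False)


def read_fold_changes(path, reference: str = "reference",
                      treated: str = "treated",
                      pseudocount: float = 0.5) -> FoldChangeTable:
    df = pd.read_csv(path, sep="\t")
    return FoldChangeTable(df, reference, treated, pseudocount)


def write_growth_curves(path, curves: list[GrowthCurve]) -> None:
    rows = []
    for c in curves:
        for t, n in zip(c.times, c.counts):
            rows.append((c.well, c.condition, c.conc_molar, t, n))
    pd.DataFrame(rows, columns=["well", "condition", "conc_molar",
                                "time_h", "cell_count"]).to_csv(path,
                                                                index=False)


def read_growth_curves(path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    curves = []
    for (well, cond, conc), grp in df.groupby(["well", "condition",
                                               "conc_molar"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(GrowthCurve(
            well=str(well), condition=str(cond), conc_molar=float(conc),
            times=grp["time_h"].to_numpy(),
            counts=grp["cell_count"].to_numpy(),
        ))
    return curves


def write_flux_traces(path, traces: list[FluxTrace]) -> None:
    rows = []
    for tr in traces:
        for t, y in zip(tr.times, tr.intensities):
            rows.append((tr.well, tr.condition, t, y))
    pd.DataFrame(rows, columns=["well", "condition", "time_s",
                                "intensity"]).to_csv(path, index=False)


def read_flux_traces(path) -> list[FluxTrace]:
    df = pd.read_csv(path)
    traces = []
    for (well, cond), grp in df.groupby(["well", "condition"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(FluxTrace(
            well=str(well), condition=str(cond),
            times=grp["time_s"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
        ))
    return traces


def write_go_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_go_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_records(path, records: pd.DataFrame) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_trajectory(path, trajectory) -> None:
    trajectory.to_frame().to_csv(path, index=False)


# -- landscape config -------------------------------------------------------

def load_config(path) -> dict:
    """YAML or JSON configuration file -> dict."""
    path = Path(path)
    with _opener(path, "r") as fh:
        if path.suffix in (".json",):
            return json.load(fh)
        return yaml.safe_load(fh)


def read_landscape(spec) -> PhenotypeLandscape:
    """Build a landscape from a config path or an already-parsed mapping.

    Schema::

        label: drugged
        states:
          - {name: slow, division_rate: 0.015, death_rate: 0.035}
          - {name: fast, division_rate: 0.055, death_rate: 0.035}
        transition_rates: [[0, 0.002], [0.002, 0]]
    """
    cfg = spec if isinstance(spec, dict) else load_config(spec)
    states = tuple(
        PhenotypeState(s["name"], float(s["division_rate"]),
                       float(s["death_rate"]))
        for s in cfg["states"]
    )
    return PhenotypeLandscape(
        states=states,
        transition_rates=np.asarray(cfg["transition_rates"], dtype=float),
        label=str(cfg.get("label", "")),
    )


def write_landscape(path, landscape: PhenotypeLandscape) -> None:
    cfg = {
        "label": landscape.label,
        "states": [
            {"name": s.name, "division_rate": s.division_rate,
             "death_rate": s.death_rate}
            for s in landscape.states
        ],
        "transition_rates": np.asarray(landscape.transition_rates).tolist(),
    }
    with _opener(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_fit_json(path, fit: DoseResponseCurve) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with _opener(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2, default=default)
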
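"""Synthesize barcoded amplicon reads, extract and filter barcode counts.

The lineage barcodes are 20-mers: a shared 4-nt prefix plus 16 strong/weak
(S = G/C, W = A/T) positions, giving 2^16 expressible sequences. Reads
carry the barcode between two fixed flanks; extraction locates the flanks,
validates the SW pattern, counts per barcode, normalises to reads per
million (RPM) and removes barcodes under 100 counts per million.
"""

import numpy as np

from idletrace import (
    BarcodeCountTable,
    BarcodeDesign,
    design_space_size,
    extract_barcodes,
    filter_low_abundance,
    normalize_rpm,
    sample_library,
)
from idletrace.synthetic import gen_barcoded_reads

design = BarcodeDesign()
print(f"design space: 2^{len(design.sw_pattern)} ="
      f" {design_space_size(design):,} barcodes")

lineages = sorted(sample_library(design, 30, seed=1))
rng = np.random.default_rng(2)
abundances = dict(zip(lineages, rng.dirichlet(np.full(30, 0.5))))
reads, truth = gen_barcoded_reads(design, abundances, n_reads=50_000,
                                  error_rate=0.001, seed=3)

result = extract_barcodes(reads, design, max_flank_mismatches=1)
print(f"extracted {sum(result.counts.values()):,} of {result.n_reads:,} "
      f"reads ({result.n_unassigned} unassigned, "
      f"{result.n_nonconformant} pattern-violating)")

table = normalize_rpm(result.to_table("sample1"))
filtered, unique = filter_low_abundance(table, threshold_cpm=100)
print(f"unique barcodes after the 100-CPM filter: {unique['sample1']} "
      f"(of {len(truth['counts'])} truly present)")
true_set = set(truth["counts"])
kept = set(filtered.sample_counts("sample1").index)
print(f"true lineages recovered: {len(kept & true_set)}; "
      f"error-derived neighbours passing the filter: {len(kept - true_set)}")
print("abundant lineages are recovered essentially exactly; substitution")
print("errors on very abundant barcodes can promote a few one-off neighbour")
print("sequences past the filter, exactly as in real amplicon data.")
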
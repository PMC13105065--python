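"""Seeded generators for every input the analysis consumes.

Each generator emulates one experimental data stream with the statistical
structure the downstream operations assume, and emits a ground-truth record
sufficient to score recovery exactly:

* amplicon FASTQ reads carrying flanked SW barcodes (multinomial lineage
  sampling, i.i.d. substitution errors);
* transcript-level record streams linking cells to lineages (low-MOI-style
  single lineage per cell, configurable doublet rate) plus per-cell
  annotations tied to the simulated phenotypic state;
* log-linear growth curves whose DIP rates follow a 4PL dose-response truth
  (lognormal multiplicative count noise);
* three-phase calcium-flux traces (CPA-induced ER-release transient, SOCE
  rise, ionomycin plateau; Gaussian noise, per-well gain/offset jitter);
* paired GO-term p-value tables with a prescribed rank correlation on the
  shared terms (Gaussian copula).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .barcodes import BarcodeDesign, sample_library
from .calcium import FluxProtocol, FluxTrace
from .doseresponse import GrowthCurve, four_pl
from .population import (
    LineagePopulation,
    PhenotypeLandscape,
    PhenotypeState,
    SimTrajectory,
    simulate,
)

__all__ = [
    "FastqRead",
    "gen_barcoded_reads",
    "sample_read_counts",
    "gen_cell_records",
    "gen_growth_curves",
    "gen_calcium_traces",
    "gen_go_tables",
    "CalciumTruth",
    "FourPLTruth",
    "idling_landscape",
    "untreated_landscape",
    "gen_lineage_scenario",
    "LineageScenario",
]

_NUC = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    qual: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_NUC, size=length).tobytes().decode()


def gen_barcoded_reads(
    design: BarcodeDesign,
    abundances: dict[str, float],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 80,
) -> tuple[list[FastqRead], dict]:
    """Synthesize amplicon reads: random context + flank5 + barcode + flank3
    + random context, barcode drawn multinomially from ``abundances``.

    Substitution errors hit every base i.i.d. at ``error_rate``. The read
    position of the barcode cassette is randomised so extraction cannot rely
    on a fixed offset. Returns the reads and a ground truth holding the
    error-free multinomial counts.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    barcodes = sorted(abundances)
    weights = np.array([abundances[b] for b in barcodes], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("abundance weights must be >= 0 and not all zero")
    for bc in barcodes:
        if not design.conforms(bc):
            raise ValueError(f"abundance key {bc!r} violates the design")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    cassette_extra = read_length - (len(design.flank5) + design.barcode_length
                                    + len(design.flank3))
    if cassette_extra < 0:
        raise ValueError("read_length shorter than the barcode cassette")

    reads: list[FastqRead] = []
    i = 0
    for bc, c in zip(barcodes, counts):
        for _ in range(int(c)):
            left = int(rng.integers(0, cassette_extra + 1))
            seq = (_random_seq(rng, left) + design.flank5 + bc
                   + design.flank3 + _random_seq(rng, cassette_extra - left))
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                hit = np.flatnonzero(rng.random(arr.size) < error_rate)
                if hit.size:
                    # substitute with one of the three other bases
                    subs = rng.integers(1, 4, size=hit.size)
                    idx = (np.searchsorted(_NUC, arr[hit]) + subs) % 4
                    arr[hit] = _NUC[idx]
                    seq = arr.tobytes().decode()
            reads.append(FastqRead(id=f"read{i:07d}", seq=seq,
                                   qual="I" * len(seq)))
            i += 1
    order = rng.permutation(len(reads))
    reads = [reads[j] for j in order]
    truth = {"counts": {b: int(c) for b, c in zip(barcodes, counts) if c},
             "n_reads": n_reads, "error_rate": error_rate}
    return reads, truth


def sample_read_counts(abundances: dict[str, float], depth: int,
                       seed: int = 0) -> dict[str, int]:
    """Multinomial read sampling of lineage abundances at a given depth —
    the counting layer of an amplicon experiment without the per-base
    error process."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    barcodes = sorted(abundances)
    w = np.array([abundances[b] for b in barcodes], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("abundance weights must be >= 0 and not all zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, w / w.sum())
    return {b: int(c) for b, c in zip(barcodes, counts) if c}


def gen_cell_records(
    trajectory: SimTrajectory,
    landscape: PhenotypeLandscape,
    sample_time: float,
    n_cells: int,
    mean_lineage_umis: float = 3.0,
    mean_background: float = 8.0,
    doublet_rate: float = 0.05,
    fast_division_threshold: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Emulate the cleaned CROP-seq record streams from a simulated snapshot.

    Cells are drawn without replacement from the (lineage, state) occupancy
    at ``sample_time``. Each cell emits 1 + Poisson(mean_lineage_umis - 1)
    lineage-transcript records (shared transcript IDs appear in both
    streams) and Poisson(mean_background) background transcript records.
    A ``doublet_rate`` fraction of cell barcodes receive a second cell's
    records, mimicking droplet doublets at low MOI. Cluster labels are the
    simulated state names; cycle_class is "fast" iff the cell's state has
    division_rate above ``fast_division_threshold``.

    Returns (cell_records, lineage_records, annotations, truth).
    """
    if not 0 <= doublet_rate < 1:
        raise ValueError("doublet_rate must be in [0, 1)")
    snap = trajectory.snapshot_at(sample_time)
    lins, mat = snap.as_matrix()
    flat = mat.ravel()
    population = int(flat.sum())
    if n_cells > population:
        raise ValueError(
            f"n_cells={n_cells} exceeds population {population} at "
            f"t={sample_time}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(population, size=n_cells, replace=False)
    class_of = np.searchsorted(np.cumsum(flat), chosen, side="right")
    lin_idx, state_idx = np.divmod(class_of, mat.shape[1])

    n_doublets = int(round(doublet_rate * n_cells))
    # the last n_doublets sampled cells are folded into the first ones
    host = rng.choice(n_cells - n_doublets, size=n_doublets, replace=False) \
        if n_doublets else np.array([], dtype=int)

    cell_rows: list[tuple[str, str, str]] = []
    lin_rows: list[tuple[str, str]] = []
    ann_rows: list[tuple[str, str, str, str]] = []
    truth_map: dict[str, dict] = {}
    tid_counter = 0

    def emit(cell_bc: str, lineage: str) -> None:
        nonlocal tid_counter
        n_lin = 1 + int(rng.poisson(max(mean_lineage_umis - 1, 0)))
        n_bg = int(rng.poisson(mean_background))
        for j in range(n_lin + n_bg):
            tid = f"T{tid_counter:08d}"
            tid_counter += 1
            umi = f"{cell_bc}:U{j:04d}"
            cell_rows.append((tid, cell_bc, umi))
            if j < n_lin:
                lin_rows.append((tid, lineage))

    n_singlets = n_cells - n_doublets
    for i in range(n_singlets):
        cb = f"C{i:06d}"
        lineage = lins[lin_idx[i]]
        state = landscape.states[state_idx[i]]
        emit(cb, lineage)
        cycle = ("fast" if state.division_rate > fast_division_threshold
                 else "slow")
        ann_rows.append((cb, lineage, state.name, cycle))
        truth_map[cb] = {"lineage": lineage, "state": state.name,
                         "doublet": False}
    for k in range(n_doublets):
        i = n_singlets + k
        cb = f"C{int(host[k]):06d}"
        emit(cb, lins[lin_idx[i]])
        truth_map[cb]["doublet"] = True
        truth_map[cb]["second_lineage"] = lins[lin_idx[i]]

    cell_records = pd.DataFrame(cell_rows,
                                columns=["transcript_id", "cell_barcode",
                                         "umi"])
    lineage_records = pd.DataFrame(lin_rows,
                                   columns=["transcript_id",
                                            "lineage_barcode"])
    annotations = pd.DataFrame(ann_rows,
                               columns=["cell_barcode", "lineage",
                                        "cluster", "cycle_class"])
    truth = {"cells": truth_map, "n_doublets": n_doublets,
             "sample_time": sample_time}
    return cell_records, lineage_records, annotations, truth


@dataclass(frozen=True)
class FourPLTruth:
    """True dose-response parameters: DIP(d) = 4PL(d; e0, emax, ec50, h)."""

    e0: float = 0.03      # log2/h at zero dose
    emax: float = -0.03   # log2/h at saturating dose
    ec50: float = 1e-6    # molar
    h: float = 2.0

    def dip(self, dose: float) -> float:
        return float(four_pl(dose, self.e0, self.emax, self.ec50, self.h))


def gen_growth_curves(
    truth: FourPLTruth,
    doses,
    n_replicates: int = 6,
    times=None,
    noise_sigma: float = 0.0,
    n0: float = 1000.0,
    condition: str = "treated",
    seed: int = 0,
) -> tuple[list[GrowthCurve], dict]:
    """Log-linear growth curves with the DIP rate set by a 4PL truth.

    counts = n0 * 2^(DIP(d) * t) * exp(N(0, sigma)) per timepoint; the
    default grid is twice-daily sampling over 150 hours. Six replicate wells
    per dose by default.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if times is None:
        times = np.arange(0.0, 150.0 + 1e-9, 12.0)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    curves: list[GrowthCurve] = []
    dips = {}
    for dose in doses:
        rate = truth.dip(float(dose))
        dips[float(dose)] = rate
        for rep in range(n_replicates):
            noise = (rng.normal(0.0, noise_sigma, size=times.size)
                     if noise_sigma > 0 else np.zeros(times.size))
            counts = n0 * np.exp2(rate * times) * np.exp(noise)
            curves.append(GrowthCurve(
                well=f"{condition}-d{dose:g}-r{rep}",
                condition=condition,
                conc_molar=float(dose),
                times=times.copy(),
                counts=counts,
            ))
    return curves, {"dip_by_dose": dips, "params": truth.__dict__ if not
                    hasattr(truth, "_asdict") else truth._asdict()}


@dataclass(frozen=True)
class CalciumTruth:
    """Template amplitudes for the three-phase trace, in units of the
    ionomycin plateau (the post-normalisation scale)."""

    er_amp: float = 0.4
    soce_amp: float = 0.6
    iono_plateau: float = 1.0
    er_rise_s: float = 10.0
    er_decay_s: float = 60.0
    soce_rise_s: float = 30.0
    iono_ramp_s: float = 20.0

    def __post_init__(self) -> None:
        if min(self.er_amp, self.soce_amp) < 0 or self.iono_plateau <= 0:
            raise ValueError("amplitudes must be >= 0, plateau > 0")


def _calcium_template(times: np.ndarray, protocol: FluxProtocol,
                      truth: CalciumTruth) -> np.ndarray:
    """Noise-free normalised-scale template. Within each response window the
    shape is renormalised on the sampled grid so the discrete peak equals
    the truth amplitude exactly."""
    y = np.zeros_like(times)
    er = (times > protocol.cpa_add) & (times <= protocol.ca_add)
    s = times[er] - protocol.cpa_add
    shape = (1 - np.exp(-s / truth.er_rise_s)) * np.exp(-s / truth.er_decay_s)
    if shape.size:
        y[er] = truth.er_amp * shape / shape.max()
    v_ca = y[times <= protocol.ca_add][-1] if er.any() else 0.0

    so = (times > protocol.ca_add) & (times <= protocol.iono_window_start)
    s = times[so] - protocol.ca_add
    shape = 1 - np.exp(-s / truth.soce_rise_s)
    if shape.size:
        y[so] = v_ca + truth.soce_amp * shape / shape.max()
    v_pre = y[times <= protocol.iono_window_start][-1]

    io = times > protocol.iono_window_start
    s = times[io] - protocol.iono_window_start
    ramp = np.clip(s / truth.iono_ramp_s, 0.0, 1.0)
    y[io] = v_pre + (truth.iono_plateau - v_pre) * ramp
    return y


def gen_calcium_traces(
    truth: CalciumTruth,
    protocol: FluxProtocol | None = None,
    n_wells: int = 8,
    noise_sigma: float = 0.01,
    gain_jitter: float = 0.1,
    offset_jitter: float = 0.05,
    condition: str = "untreated",
    duration_s: float = 600.0,
    seed: int = 0,
) -> tuple[list[FluxTrace], dict]:
    """Raw (arbitrary-unit) traces: offset + gain * (template + noise).

    The per-well gain and offset jitter exercise the normalisation; the
    template's ER peak, SOCE peak and ionomycin plateau are exact on the
    1 Hz grid, so at zero noise the normalised metrics equal the truth
    (divided by the plateau, which defaults to 1).
    """
    protocol = protocol or FluxProtocol()
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    times = np.arange(0.0, duration_s + 1e-9, 1.0)
    template = _calcium_template(times, protocol, truth)
    rng = np.random.default_rng(seed)
    traces = []
    for w in range(n_wells):
        gain = 100.0 * float(np.exp(rng.normal(0.0, gain_jitter)))
        offset = 50.0 * float(np.exp(rng.normal(0.0, offset_jitter)))
        noise = (rng.normal(0.0, noise_sigma, size=times.size)
                 if noise_sigma > 0 else 0.0)
        traces.append(FluxTrace(
            well=f"{condition}-w{w}",
            condition=condition,
            times=times.copy(),
            intensities=offset + gain * (template + noise),
        ))
    norm_truth = {
        "er_release_peak": truth.er_amp / truth.iono_plateau,
        "soce_peak": truth.soce_amp / truth.iono_plateau,
    }
    return traces, {"normalized_peaks": norm_truth,
                    "template": truth.__dict__}


def gen_go_tables(
    n_terms: int = 300,
    n_shared: int = 200,
    rho: float = 0.5,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two GO-term p-value tables whose shared significant terms have rank
    correlation ``rho`` (Gaussian copula; the Pearson parameter is chosen as
    2*sin(pi*rho/6) so the Spearman correlation targets rho).

    Shared terms get p-values inside (0, alpha) so they survive the
    significance filter; each table also carries independent unshared terms
    with uniform p-values.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    if n_shared > n_terms:
        raise ValueError("n_shared cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    r = 2 * np.sin(np.pi * rho / 6)
    cov = [[1.0, r], [r, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)
    u = stats.norm.cdf(z)
    # map to significant p-values, preserving ranks
    p_shared = np.clip(u * alpha, 1e-300, None)

    cats = np.array(["BP", "MF", "CC"])

    def table(col: int, tag: str) -> pd.DataFrame:
        terms = [f"GO:{i:07d}" for i in range(n_shared)]
        pvals = list(p_shared[:, col])
        for i in range(n_terms - n_shared):
            terms.append(f"GO:{tag}{i:06d}")
            pvals.append(float(rng.uniform(1e-12, 1.0)))
        return pd.DataFrame({
            "term": terms,
            "category": rng.choice(cats, size=len(terms)),
            "pvalue": pvals,
        })

    a = table(0, "A")
    b = table(1, "B")
    truth = {"rho": rho, "pearson_param": float(r), "n_shared": n_shared}
    return a, b, truth


# ---------------------------------------------------------------------------
# Landscape presets and the lineage-tracing scenario
# ---------------------------------------------------------------------------

def untreated_landscape(net_rate: float = 0.0,
                        turnover: float = 0.04,
                        switch_rate: float = 0.01) -> PhenotypeLandscape:
    """Two untreated sub-states with equal net growth ``net_rate`` and
    division/death turnover around it."""
    states = (
        PhenotypeState("U1", turnover + max(net_rate, 0),
                       turnover + max(-net_rate, 0)),
        PhenotypeState("U2", turnover + max(net_rate, 0),
                       turnover + max(-net_rate, 0)),
    )
    k = np.array([[0.0, switch_rate], [switch_rate, 0.0]])
    return PhenotypeLandscape(states, k, label="untreated")


def idling_landscape(coupled: bool = True,
                     rate_gap: float = 0.02,
                     switch_rate: float = 0.002) -> PhenotypeLandscape:
    """Drug-modified landscape with a slow-dividing and a fast-dividing
    persister state.

    ``coupled=True``: the fast state has net growth +rate_gap and the slow
    state -rate_gap, so lineage fitness is tied to fast-state occupancy
    while a balanced mixture idles. ``coupled=False``: both states have net
    growth zero (division equals death) — the equal-fitness (neutral)
    landscape — while keeping the same division-rate contrast so the
    fast/slow classification is unchanged.
    """
    div_slow, div_fast = 0.015, 0.055
    if coupled:
        states = (
            PhenotypeState("idling_slow", div_slow, div_slow + rate_gap),
            PhenotypeState("idling_fast", div_fast, div_fast - rate_gap),
        )
    else:
        states = (
            PhenotypeState("idling_slow", div_slow, div_slow),
            PhenotypeState("idling_fast", div_fast, div_fast),
        )
    k = np.array([[0.0, switch_rate], [switch_rate, 0.0]])
    return PhenotypeLandscape(states, k, label="idling")


@dataclass
class LineageScenario:
    """A generated lineage-tracing experiment plus its ground truth."""

    landscape: PhenotypeLandscape
    trajectory: SimTrajectory
    lineages: list[str]
    initial_fast_fraction: dict[str, float]
    initial_sizes: dict[str, int]
    t_post: float
    design: BarcodeDesign = field(default_factory=BarcodeDesign)

    def abundances(self, t: float) -> dict[str, float]:
        totals = self.trajectory.snapshot_at(t).lineage_totals()
        return {lin: float(c) for lin, c in totals.items()}


def gen_lineage_scenario(
    coupled: bool = True,
    n_lineages: int = 24,
    cells_per_lineage: int = 4000,
    size_sd_log: float = 0.15,
    fast_alpha: float = 2.0,
    fast_beta: float = 8.0,
    equal_composition: bool = False,
    t_post: float = 48.0,
    method: str = "direct",
    seed: int = 0,
) -> LineageScenario:
    """Simulate barcoded lineages entering the drug-modified landscape.

    Each lineage enters treatment with its own fast-state occupancy q drawn
    from Beta(fast_alpha, fast_beta) (mean 0.2 by default, mirroring the
    minority fast-dividing persister cluster), or a fixed q = mean when
    ``equal_composition`` — the configuration under which fold-changes must
    centre on zero for the neutral landscape. Lineage identities are the
    actual barcode sequences from the default SW design, so the simulated
    abundances feed the counting and fold-change operations directly.
    """
    rng = np.random.default_rng(seed)
    design = BarcodeDesign()
    lineages = sorted(sample_library(design, n_lineages,
                                     seed=int(rng.integers(2**31))))
    landscape = idling_landscape(coupled=coupled)
    q_mean = fast_alpha / (fast_alpha + fast_beta)
    counts: dict[str, np.ndarray] = {}
    q_map: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for lin in lineages:
        size = max(2, int(round(cells_per_lineage
                                * np.exp(rng.normal(0.0, size_sd_log)))))
        q = q_mean if equal_composition else float(rng.beta(fast_alpha,
                                                            fast_beta))
        n_fast = int(rng.binomial(size, q))
        counts[lin] = np.array([size - n_fast, n_fast], dtype=np.int64)
        q_map[lin] = n_fast / size
        sizes[lin] = size
    init = LineagePopulation(counts)
    traj = simulate(landscape, init, t_max=t_post,
                    record_times=[0.0, t_post],
                    seed=int(rng.integers(2**31)), method=method)
    return LineageScenario(
        landscape=landscape,
        trajectory=traj,
        lineages=lineages,
        initial_fast_fraction=q_map,
        initial_sizes=sizes,
        t_post=t_post,
        design=design,
    )
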
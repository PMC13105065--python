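"""Reusable in-silico experiments composing the simulator with the analysis.

Each function runs one complete study at its stated conditions and returns
plain dictionaries of the measured quantities, so the same recipes back the
example scripts, the test suite and the acceptance report. Problem sizes are
chosen to be desk-scale: large enough for the statistics to be meaningful,
small enough to run in seconds to a couple of minutes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .barcodes import (
    BarcodeCountTable,
    BarcodeDesign,
    design_space_size,
    filter_low_abundance,
    fold_changes,
    normalize_rpm,
)
from .calcium import FluxProtocol, compare_soce, group_summary, normalize_trace
from .doseresponse import dip_rate, fit_4pl
from .lineage import assign_lineages, fast_fraction, fast_fraction_correlation
from .population import (
    LineagePopulation,
    PhenotypeLandscape,
    PhenotypeState,
    mean_field_solution,
    simulate,
)
from .synthetic import (
    CalciumTruth,
    FourPLTruth,
    gen_calcium_traces,
    gen_cell_records,
    gen_growth_curves,
    gen_lineage_scenario,
    idling_landscape,
    sample_read_counts,
)

__all__ = [
    "neutral_foldchange_study",
    "idling_dip_study",
    "oracle_equivalence_study",
    "fourpl_recovery_study",
    "lineage_correlation_study",
    "soce_comparison_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def neutral_foldchange_study(
    seed: int = 0,
    n_seeds: int = 20,
    n_lineages: int = 50,
    cells_per_lineage: int = 8000,
    t_post: float = 72.0,
    depth: int = 500_000,
    threshold_cpm: float = 100.0,
) -> dict:
    """Per-lineage log2 fold-change under the equal-fitness landscape.

    Every lineage starts with the same size and state composition on the
    neutral idling landscape (all states divide and die at equal rates), the
    population is simulated with tau-leaping (populations of ~4x10^5 cells),
    both timepoints are read-sampled multinomially and the 100-CPM filter is
    applied before fold-changes. The fold-changes from all seeds are pooled
    into one distribution and the 95% t-interval for that distribution's
    mean is reported; with no fitness differences it should cover zero —
    barcode abundances drift but do not move systematically.
    """
    values: list[float] = []
    means = []
    for s in _child_seeds(seed, n_seeds):
        scen = gen_lineage_scenario(
            coupled=False, equal_composition=True, size_sd_log=0.0,
            n_lineages=n_lineages, cells_per_lineage=cells_per_lineage,
            t_post=t_post, method="tau", seed=s,
        )
        rs, ts = _child_seeds(s + 1, 2)
        table = BarcodeCountTable.from_counts({
            "untreated": sample_read_counts(scen.abundances(0.0), depth, rs),
            "idling": sample_read_counts(scen.abundances(t_post), depth, ts),
        })
        filtered, _ = filter_low_abundance(normalize_rpm(table),
                                           threshold_cpm)
        fc = fold_changes(filtered, "untreated", "idling")
        values.extend(fc.data["log2fc"].tolist())
        means.append(fc.mean)
    pooled = np.asarray(values)
    sem = pooled.std(ddof=1) / np.sqrt(pooled.size)
    tcrit = stats.t.ppf(0.975, pooled.size - 1)
    return {
        "mean_log2fc": float(pooled.mean()),
        "sd_log2fc": float(pooled.std(ddof=1)),
        "ci95": (float(pooled.mean() - tcrit * sem),
                 float(pooled.mean() + tcrit * sem)),
        "per_seed_means": means,
        "n_lineage_foldchanges": int(pooled.size),
        "n_seeds": n_seeds,
    }


def idling_dip_study(
    seed: int = 0,
    n_wells: int = 6,
    n0: int = 2000,
    turnover: float = 0.03,
) -> dict:
    """DIP rate of a simulated idling (division = death) population.

    Six replicate wells are simulated exactly and sampled twice daily for
    150 hours; each well's DIP rate is the OLS slope of its log2 counts,
    and the 95% CI of the mean rate is taken across wells (replicate wells
    are the unit of error for growth-curve experiments). Idling means the
    CI should cover zero.
    """
    landscape = PhenotypeLandscape(
        (PhenotypeState("idling", turnover, turnover),),
        np.zeros((1, 1)), label="idling",
    )
    times = np.arange(0.0, 150.0 + 1e-9, 12.0)
    rates = []
    single = None
    for s in _child_seeds(seed, n_wells):
        init = LineagePopulation({"pop": np.array([n0])})
        traj = simulate(landscape, init, t_max=150.0,
                        record_times=times, seed=s)
        counts = np.maximum(traj.totals(), 1.0)
        from .doseresponse import GrowthCurve

        curve = GrowthCurve(well=f"w{s}", condition="idling",
                            conc_molar=0.0, times=times, counts=counts)
        est = dip_rate(curve)
        rates.append(est.rate)
        single = single or est
    rates = np.asarray(rates)
    sem = rates.std(ddof=1) / np.sqrt(len(rates))
    tcrit = stats.t.ppf(0.975, len(rates) - 1)
    return {
        "dip_rate": float(rates.mean()),
        "ci95": (float(rates.mean() - tcrit * sem),
                 float(rates.mean() + tcrit * sem)),
        "per_well": rates.tolist(),
        "single_well_estimate": single,
    }


def _random_landscape(rng: np.random.Generator,
                      max_states: int = 4) -> PhenotypeLandscape:
    n = int(rng.integers(1, max_states + 1))
    states = tuple(
        PhenotypeState(f"s{i}", float(rng.uniform(0, 0.05)),
                       float(rng.uniform(0, 0.05)))
        for i in range(n)
    )
    k = rng.uniform(0, 0.05, size=(n, n))
    np.fill_diagonal(k, 0.0)
    return PhenotypeLandscape(states, k, label="random")


def oracle_equivalence_study(
    seed: int = 0,
    n_landscapes: int = 4,
    n_replicates: int = 500,
    n0_per_state: int = 40,
    t_max: float = 24.0,
) -> dict:
    """Gillespie ensemble means vs the matrix-exponential mean field.

    For each randomized landscape (up to 4 states), 500 exact replicates
    are run and the per-state ensemble mean at each recorded time is
    compared to the analytic expectation; the report is the largest
    |z| = |mean - expected| / SEM over all landscapes, states and times.
    Agreement within 3 SEM is the oracle-equivalence bar.
    """
    rng = np.random.default_rng(seed)
    record_times = [t_max / 2, t_max]
    max_z = 0.0
    details = []
    for _ in range(n_landscapes):
        landscape = _random_landscape(rng)
        n = landscape.n_states
        n0 = np.full(n, n0_per_state)
        expected = mean_field_solution(landscape, n0, record_times)
        ens = np.zeros((n_replicates, n, len(record_times)))
        for r in range(n_replicates):
            init = LineagePopulation({"L": n0.copy()})
            traj = simulate(landscape, init, t_max=t_max,
                            record_times=record_times,
                            seed=int(rng.integers(2**31)))
            for j, snap in enumerate(traj.snapshots):
                ens[r, :, j] = snap.counts["L"]
        mean = ens.mean(axis=0)
        sem = ens.std(axis=0, ddof=1) / np.sqrt(n_replicates)
        z = np.abs(mean - expected) / np.where(sem > 0, sem, np.inf)
        max_z = max(max_z, float(z.max()))
        details.append({"n_states": n, "max_z": float(z.max())})
    return {"max_z": max_z, "landscapes": details,
            "n_replicates": n_replicates}


def fourpl_recovery_study(
    seed: int = 0,
    n_noisy_seeds: int = 100,
    noise_frac: float = 0.10,
) -> dict:
    """Self-consistency of the 4PL fit on generated dose-response data.

    Noiseless: 8 doses spanning 4 orders of magnitude around the true EC50;
    the fitted parameters must match the generating ones. Noisy: Gaussian
    noise with sd = 10% of |E0 - Emax| on each of 6 replicate DIP rates per
    dose, repeated over 100 seeds; the report is the median relative EC50
    error.
    """
    truth = FourPLTruth(e0=0.03, emax=-0.03, ec50=1e-6, h=2.0)
    doses = np.logspace(-8, -4, 8)
    effects_clean = np.array([truth.dip(d) for d in doses])
    fit = fit_4pl(doses, effects_clean)
    rel = {
        "e0": abs(fit.e0 - truth.e0) / abs(truth.e0),
        "emax": abs(fit.emax - truth.emax) / abs(truth.emax),
        "ec50": abs(fit.ec50 - truth.ec50) / truth.ec50,
        "h": abs(fit.hill - truth.h) / truth.h,
    }

    sd = noise_frac * abs(truth.e0 - truth.emax)
    n_rep = 6
    d_rep = np.repeat(doses, n_rep)
    e_rep = np.repeat(effects_clean, n_rep)
    errors = []
    for s in _child_seeds(seed, n_noisy_seeds):
        rng = np.random.default_rng(s)
        e_noisy = e_rep + rng.normal(0.0, sd, size=e_rep.size)
        try:
            f = fit_4pl(d_rep, e_noisy)
        except Exception:
            errors.append(np.inf)
            continue
        errors.append(abs(f.ec50 - truth.ec50) / truth.ec50)
    return {
        "noiseless_max_rel_error": float(max(rel.values())),
        "noiseless_rel_errors": {k: float(v) for k, v in rel.items()},
        "median_ec50_rel_error_noisy": float(np.median(errors)),
        "n_noisy_seeds": n_noisy_seeds,
    }


def lineage_correlation_study(
    coupled: bool,
    seed: int = 0,
    n_lineages: int = 24,
    cells_per_lineage: int = 4000,
    t_post: float = 48.0,
    depth: int = 500_000,
    n_cells_sampled: int = 4000,
    n_permutations: int = 1000,
) -> dict:
    """End-to-end lineage pipeline: simulate -> count -> assign -> correlate.

    A scenario with lineage-varying fast-state occupancy is simulated on the
    coupled (fitness-coupled) or neutral idling landscape; barcode reads are
    multinomially sampled at both timepoints, single-cell records are
    generated from the final snapshot, lineages are assigned by the
    UMI-majority rule, and the fast-fraction vs fold-change Pearson r is
    computed over the top-24 lineages, with a label-permutation p-value.
    """
    s_scen, s_counts, s_cells, s_perm = _child_seeds(seed, 4)
    scen = gen_lineage_scenario(
        coupled=coupled, n_lineages=n_lineages,
        cells_per_lineage=cells_per_lineage, t_post=t_post, seed=s_scen,
    )
    rs, ts = _child_seeds(s_counts, 2)
    table = BarcodeCountTable.from_counts({
        "untreated": sample_read_counts(scen.abundances(0.0), depth, rs),
        "idling": sample_read_counts(scen.abundances(t_post), depth, ts),
    })
    filtered, _ = filter_low_abundance(normalize_rpm(table))
    fc = fold_changes(filtered, "untreated", "idling")

    population = scen.trajectory.snapshot_at(t_post).total()
    n_cells = min(n_cells_sampled, population)
    cell_rec, lin_rec, annotations, _truth = gen_cell_records(
        scen.trajectory, scen.landscape, sample_time=t_post,
        n_cells=n_cells, doublet_rate=0.05, seed=s_cells,
    )
    assignment = assign_lineages(cell_rec, lin_rec)
    ann = annotations.drop(columns=["lineage"]).merge(
        assignment.assignments[["cell_barcode", "lineage"]],
        on="cell_barcode",
    )
    frac = fast_fraction(ann, min_cells=5)
    result = fast_fraction_correlation(frac, fc, top_n=24)

    rng = np.random.default_rng(s_perm)
    x = result.pairs["fast_fraction"].to_numpy()
    y = result.pairs["log2fc"].to_numpy()
    null = np.array([
        stats.pearsonr(x, rng.permutation(y))[0]
        for _ in range(n_permutations)
    ])
    p_perm = float((np.abs(null) >= abs(result.r)).mean())
    return {
        "pearson_r": result.r,
        "p_value": result.p_value,
        "p_permutation": p_perm,
        "n_lineages": result.n,
        "pairs": result.pairs,
    }


def soce_comparison_study(
    seed: int = 0,
    n_wells: int = 8,
    noise_sigma: float = 0.01,
    suppression: float = 0.5,
) -> dict:
    """Untreated vs idling SOCE comparison on generated traces.

    The idling group's SOCE amplitude is halved (the drug-tolerant
    phenotype's reduced store-operated entry); eight wells per group with
    per-well gain/offset jitter are normalised, quantified and compared by
    Welch's t-test on the SOCE peak.
    """
    protocol = FluxProtocol()
    s_u, s_i = _child_seeds(seed, 2)
    untreated, _ = gen_calcium_traces(
        CalciumTruth(), protocol, n_wells=n_wells, noise_sigma=noise_sigma,
        condition="untreated", seed=s_u,
    )
    base = CalciumTruth()
    idling_truth = CalciumTruth(er_amp=base.er_amp,
                                soce_amp=base.soce_amp * suppression)
    idling, _ = gen_calcium_traces(
        idling_truth, protocol, n_wells=n_wells, noise_sigma=noise_sigma,
        condition="idling", seed=s_i,
    )
    normalized = [normalize_trace(tr, protocol)
                  for tr in untreated + idling]
    summary = group_summary(normalized, protocol)
    t, p = compare_soce(summary, "idling", "untreated")
    means = summary.metrics.groupby("condition")["soce_peak"].mean()
    return {
        "t_statistic": t,
        "p_value": p,
        "soce_peak_untreated": float(means["untreated"]),
        "soce_peak_idling": float(means["idling"]),
        "ratio": float(means["idling"] / means["untreated"]),
        "summary": summary,
    }
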
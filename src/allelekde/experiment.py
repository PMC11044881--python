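"""Simulation experiment harness: bias/accuracy/concordance of KDE diversity.

Runs the factorial design at desk scale: simulate a finite population per
(mutation rate, replicate), resample it at each sample size, estimate
allele frequencies with the kernel truncated at each mutation number
(0 = plain counting, no bandwidth selection) under each cross-validation
method, and score the approximate nucleotide diversity and the allele
frequency concordance rate against the known population. One population is
simulated per (rate, replicate) and shared across sample sizes, mutation
numbers and CV methods; everything is deterministic given one seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import resample, simulate_population
from .diversity import counting_diversity, evaluation_stats, nucleotide_diversity_approx
from .estimator import AlleleFrequencyKDE
from .io import tally_alleles
from .spaces import build_distance_space

CELL_COLUMNS = ["mutation_rate", "sample_size", "mutation_number", "cv_method"]


@dataclass(frozen=True)
class ExperimentGrid:
    """Factorial design of the simulation experiment.

    Defaults are the desk-scale profile: population size 100, 200 bp,
    mutation rate 0.01 per base per generation, sample sizes 20 and 100,
    mutation numbers 0 and 1, both CV methods, 20 replicates. The full
    profile (1000 bp, rates {0.01, 0.1}, sample sizes 20..100, mutation
    numbers up to 2) is expressible but slow.
    """

    population_size: int = 100
    length: int = 200
    mutation_rates: tuple[float, ...] = (0.01,)
    sample_sizes: tuple[int, ...] = (20, 100)
    mutation_numbers: tuple[int, ...] = (0, 1)
    cv_methods: tuple[str, ...] = ("lscv", "lcv")
    replicates: int = 20
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(m < 0 for m in self.mutation_numbers):
            raise ValueError("mutation numbers must be >= 0")


@dataclass
class ExperimentReport:
    """Long-format per-replicate results plus aggregation helpers."""

    grid: ExperimentGrid
    seed: int
    data: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """Per-cell bias/accuracy/concordance statistics across replicates."""
        rows = []
        for keys, sub in self.data.groupby(CELL_COLUMNS, sort=True):
            stats = evaluation_stats(sub["pi_estimate"], sub["pi_population"])
            row = dict(zip(CELL_COLUMNS, keys))
            row.update(
                pi_relative_bias=stats.relative_bias,
                pi_accuracy=stats.accuracy,
                pi_squared_accuracy=stats.squared_accuracy,
                sd_pi_relative_bias=stats.sd_relative_bias,
                sd_pi_accuracy=stats.sd_accuracy,
                concordance_mean=float(sub["concordance"].mean()),
                concordance_sd=float(sub["concordance"].std(ddof=1)),
                bandwidth_mean=float(sub["bandwidth"].mean()),
                fallback_rate=float(sub["fallback"].mean()),
                n_replicates=int(len(sub)),
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(outdir / "report.tsv", sep="\t", index=False)
        payload = {
            "grid": asdict(self.grid),
            "seed": self.seed,
            "summary": self.summary().to_dict(orient="records"),
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=float))


def run_grid(grid: ExperimentGrid, seed: int) -> ExperimentReport:
    """Execute the full design deterministically from one seed."""
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(grid.mutation_rates) * grid.replicates)
    rows = []
    idx = 0
    for mu in grid.mutation_rates:
        for rep in range(grid.replicates):
            pop_ss, samp_ss = cell_seeds[idx].spawn(2)
            idx += 1
            pop = simulate_population(
                grid.population_size,
                grid.length,
                mu,
                rng=np.random.default_rng(pop_ss),
            )
            pop_table = tally_alleles(pop.alignment)
            pop_freqs = pop_table.frequencies
            pi_pop = counting_diversity(pop_table).pi
            samp_rngs = [
                np.random.default_rng(s) for s in samp_ss.spawn(len(grid.sample_sizes))
            ]
            for k, samp_rng in zip(grid.sample_sizes, samp_rngs):
                if k > grid.population_size:
                    warnings.warn(
                        f"skipping infeasible cell: sample size {k} exceeds "
                        f"population size {grid.population_size}"
                    )
                    continue
                sample = resample(pop.alignment, k, rng=samp_rng)
                table = tally_alleles(sample)
                for m in grid.mutation_numbers:
                    space = build_distance_space(table.alleles, m)
                    model = AlleleFrequencyKDE(
                        table,
                        mutation_number=m,
                        renormalize=grid.renormalize,
                        space=space,
                    )
                    if m == 0:
                        fits = [("none", model.fit(bandwidth=0.0))]
                    else:
                        fits = [
                            (method, model.fit(method=method))
                            for method in grid.cv_methods
                        ]
                    for method, res in fits:
                        pi_est = nucleotide_diversity_approx(res.estimate).pi
                        conc = res.concordance(pop_freqs)
                        rows.append(
                            {
                                "mutation_rate": mu,
                                "replicate": rep,
                                "sample_size": k,
                                "mutation_number": m,
                                "cv_method": method,
                                "bandwidth": res.bandwidth,
                                "fallback": bool(res.cv.fallback) if res.cv else False,
                                "pi_estimate": pi_est,
                                "pi_population": pi_pop,
                                "pi_rel_err": (pi_est - pi_pop) / pi_pop,
                                "pi_abs_rel_err": abs(pi_est - pi_pop) / pi_pop,
                                "concordance": conc,
                            }
                        )
    return ExperimentReport(grid=grid, seed=seed, data=pd.DataFrame(rows))


def compare_cells(
    report: ExperimentReport,
    cell_a: dict,
    cell_b: dict,
    statistic: str = "pi_abs_rel_err",
):
    """Paired per-replicate differences (cell_a - cell_b) of one statistic.

    The two cells must share mutation rate and sample size so the pairing
    over replicates is meaningful.
    """
    for key in ("mutation_rate", "sample_size"):
        if cell_a.get(key) != cell_b.get(key):
            raise ValueError(f"cells must share {key} for a paired comparison")

    def rows_of(cell: dict) -> pd.DataFrame:
        sub = report.data
        for col, val in cell.items():
            sub = sub[sub[col] == val]
        return sub.set_index("replicate").sort_index()

    a, b = rows_of(cell_a), rows_of(cell_b)
    if len(a) != len(b) or not a.index.equals(b.index):
        raise ValueError("cells do not pair replicate-for-replicate")
    diffs = (a[statistic] - b[statistic]).to_numpy()
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan")
    return {
        "statistic": statistic,
        "differences": diffs,
        "mean": float(diffs.mean()),
        "sd": sd,
    }
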
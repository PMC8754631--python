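"""Mutation–selection-balance scaling of centromeric A+T enrichment.

If selection favours A+T-rich centromeric DNA while mutation pushes the
sequence back toward the genomic base composition, the equilibrium
enrichment should increase with the efficacy of selection, i.e. with
effective population size N_e.  N_e is unknown for most species, but
genome size is inversely related to it, so the testable prediction is a
negative linear relationship between

    relative centromeric A+T  =  centromere A+T − genome A+T   (percentage points)

and log10(genome size in bp) across species.  This module fits that
relationship by ordinary least squares with full inference (slope standard
error, two-sided t test, R², adjusted R², F on (1, n−2) df) and supports
restricting the fit to a clade subset with an explicit
insufficient-species outcome for tiny subsets.  No phylogenetic correction
is applied — the model is deliberately a plain cross-species OLS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SpeciesRecord",
    "ScalingFit",
    "CladeFit",
    "relative_at",
    "fit_scaling",
    "clade_subset_fit",
    "load_species_table",
    "write_species_table",
    "plot_scaling",
]


@dataclass(frozen=True)
class SpeciesRecord:
    """One organism: genome size plus genome and centromere A+T content.

    A+T values are percentages in [0, 100].
    """

    species: str
    clade: str
    genome_size: float  # bp
    genome_at: float  # percent
    centromere_at: float  # percent

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError(f"{self.species}: genome_size must be positive")
        for v, name in ((self.genome_at, "genome_at"),
                        (self.centromere_at, "centromere_at")):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.species}: {name} must be in [0, 100]")


def relative_at(record: SpeciesRecord) -> float:
    """Centromeric A+T enrichment over the genome average, in points."""
    return record.centromere_at - record.genome_at


@dataclass(frozen=True)
class ScalingFit:
    """Full OLS summary of relative A+T on log genome size."""

    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    df: tuple[int, int]
    n: int
    log_base: float

    def to_json(self, path: str | Path) -> None:
        payload = dict(self.__dict__)
        payload["df"] = list(self.df)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_scaling(records: Sequence[SpeciesRecord], log_base: float = 10.0) -> ScalingFit:
    """OLS of relative centromeric A+T on log(genome size).

    Genome size is in bp and the default log base is 10, so a slope of −8
    means eight percentage points of enrichment lost per tenfold increase
    in genome size.
    """
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 species, got {n}")
    x = np.array([math.log(r.genome_size, log_base) for r in records])
    y = np.array([relative_at(r) for r in records])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log genome size; fit undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return ScalingFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        t_statistic=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        adjusted_r_squared=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        df=(1, n - 2),
        n=n,
        log_base=log_base,
    )


@dataclass(frozen=True)
class CladeFit:
    """Scaling fit restricted to one clade, with a significance verdict.

    ``fit`` is None (and ``reason`` set) when the clade has fewer than
    three species — an explicit outcome rather than an exception, since
    small clades are an expected input.
    """

    clade: str
    n: int
    alpha: float
    fit: ScalingFit | None
    significant: bool | None
    reason: str | None = None


def clade_subset_fit(records: Sequence[SpeciesRecord], clade: str,
                     alpha: float = 0.05, log_base: float = 10.0) -> CladeFit:
    """Fit the scaling relationship within one clade and test slope != 0."""
    subset = [r for r in records if r.clade == clade]
    if len(subset) < 3:
        return CladeFit(clade=clade, n=len(subset), alpha=alpha, fit=None,
                        significant=None,
                        reason=f"insufficient species ({len(subset)} < 3)")
    fit = fit_scaling(subset, log_base=log_base)
    return CladeFit(clade=clade, n=len(subset), alpha=alpha, fit=fit,
                    significant=bool(fit.p_value < alpha))


_COLUMNS = ["species", "clade", "genome_size_bp", "genome_at_pct",
            "centromere_at_pct"]


def load_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read the species TSV (species, clade, genome_size_bp, genome_at_pct,
    centromere_at_pct); duplicate species names are rejected."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"species TSV missing columns {sorted(missing)}")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate species in table: {sorted(set(dupes))}")
    return [
        SpeciesRecord(species=row.species, clade=row.clade,
                      genome_size=float(row.genome_size_bp),
                      genome_at=float(row.genome_at_pct),
                      centromere_at=float(row.centromere_at_pct))
        for row in df.itertuples()
    ]


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.species, r.clade, r.genome_size, r.genome_at, r.centromere_at)
         for r in records],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def plot_scaling(records: Sequence[SpeciesRecord], fit: ScalingFit,
                 path: str | Path) -> None:
    """Scatter of relative A+T vs genome size (log x) with the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([r.genome_size for r in records])
    y = np.array([relative_at(r) for r in records])
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(x, y, s=20, color="tab:blue", alpha=0.8)
    xs = np.logspace(math.log10(x.min()), math.log10(x.max()), 100)
    ax.plot(xs, fit.slope * np.log(xs) / math.log(fit.log_base) + fit.intercept,
            color="tab:red")
    ax.set_xscale("log")
    ax.set_xlabel("genome size (bp)")
    ax.set_ylabel("centromere A+T − genome A+T (points)")
    ax.set_title(f"slope {fit.slope:.3f}, adj. R² {fit.adjusted_r_squared:.3f}, "
                 f"p {fit.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
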
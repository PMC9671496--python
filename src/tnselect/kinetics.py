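"""Phage adsorption and center-of-infection statistics.

Adsorption is read out as depletion of free phage from the supernatant
relative to a mock-infected input; ECOI (efficiency of centers of
infection) is the fraction of cell-associated phage producing plaques on a
permissive lawn, normalized to the wild-type host.  Group comparisons use
the two-tailed t test with the significance tiers *p<0.05, **p<0.005,
***p<0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdsorptionSeries",
    "InfectionCenterAssay",
    "fraction_unadsorbed",
    "fraction_adsorbed",
    "AdsorptionFit",
    "adsorption_rate",
    "ecoi",
    "GroupComparison",
    "compare_groups",
    "star_label",
    "read_adsorption_tsv",
    "read_infection_centers_tsv",
]


@dataclass
class AdsorptionSeries:
    """Free-phage titers over time for one host x phage x replicate.

    ``input_titer`` is the mock-infection control titer (pfu/mL); technical
    titer duplicates should be averaged in pfu space before construction.
    """

    host_id: str
    phage_id: str
    replicate: int
    points: list[tuple[float, float]]  # (time min, free titer pfu/mL)
    input_titer: float

    def __post_init__(self):
        if self.input_titer <= 0:
            raise ValueError("input_titer must be > 0")
        times = [t for t, _ in self.points]
        if any(t < 0 for t in times):
            raise ValueError("times must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])) is True:
            raise ValueError("times must be strictly increasing")
        if any(f < 0 for _, f in self.points):
            raise ValueError("titers must be >= 0")

    def free_titer(self, t: float) -> float:
        for time, titer in self.points:
            if time == t:
                return titer
        raise KeyError(f"no titer recorded at t={t} min")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.points]


@dataclass
class InfectionCenterAssay:
    """Plaque counts from a washed, phage-exposed cell pellet."""

    host_id: str
    phage_id: str
    replicate: int
    centers: float  # pfu-equivalent plaques from the pellet
    input_pfu: float
    reference_host_id: str = ""

    def __post_init__(self):
        if self.centers < 0 or self.input_pfu <= 0:
            raise ValueError("centers must be >= 0 and input_pfu > 0")


def fraction_unadsorbed(series: AdsorptionSeries, t: float) -> float:
    """Free titer at time t over the mock-infection input titer.

    Values above 1 are possible with plating noise; they are surfaced with
    a warning rather than clipped.
    """
    frac = series.free_titer(t) / series.input_titer
    if frac > 1:
        warnings.warn(
            f"fraction unadsorbed {frac:.3g} > 1 at t={t} (titer counting noise)",
            stacklevel=2,
        )
    return frac


def fraction_adsorbed(series: AdsorptionSeries, t: float) -> float:
    """1 - fraction unadsorbed (bookkeeping identity)."""
    return 1.0 - fraction_unadsorbed(series, t)


class AdsorptionFit(NamedTuple):
    k: float  # adsorption rate constant, mL/min
    r_squared: float
    n_points: int


def adsorption_rate(series: AdsorptionSeries, cell_density: float) -> AdsorptionFit:
    """First-order adsorption rate constant from the free-phage decay.

    Fits ln(free/input) = -k * B * t by least squares, where B is the cell
    density (cells/mL); k = -slope / B.  Timepoints with nonpositive free
    titer cannot enter the log fit and are excluded with a warning.
    """
    if cell_density <= 0:
        raise ValueError("cell_density must be > 0")
    usable = [(t, f) for t, f in series.points if f > 0]
    dropped = len(series.points) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} timepoint(s) with nonpositive free titer",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError("need >= 2 timepoints with positive free titer")
    t = np.array([p[0] for p in usable])
    y = np.log(np.array([p[1] for p in usable]) / series.input_titer)
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AdsorptionFit(k=-slope / cell_density, r_squared=r2, n_points=len(usable))


def ecoi(assay: InfectionCenterAssay, reference: InfectionCenterAssay) -> float:
    """Efficiency of centers of infection relative to the reference host.

    (centers / input) of the test host divided by (centers / input) of the
    reference (wild-type) host; the reference against itself is exactly 1.
    """
    if assay.phage_id != reference.phage_id:
        raise ValueError(
            f"phage mismatch: {assay.phage_id!r} vs {reference.phage_id!r}"
        )
    if reference.centers == 0:
        raise ZeroDivisionError("reference assay has zero centers; ECOI undefined")
    return (assay.centers / assay.input_pfu) / (reference.centers / reference.input_pfu)


def star_label(p: float) -> str:
    """Significance tier: '***' p<0.001, '**' p<0.005, '*' p<0.05, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


class GroupComparison(NamedTuple):
    t: float
    p: float
    label: str
    degenerate: bool


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sample two-tailed t test with the figure-legend star tiers.

    Welch's unequal-variance test by default (``equal_var=True`` selects
    Student's pooled test).  Two zero-variance groups with equal means are
    degenerate: no evidence, reported 'ns'.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return GroupComparison(t=0.0, p=1.0, label="ns", degenerate=True)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(t=t_stat, p=p, label=star_label(p), degenerate=False)


# ---------------------------------------------------------------------------
# Tidy TSV input

ADSORPTION_COLUMNS = ["host_id", "phage_id", "replicate", "time_min", "free_titer", "input_titer"]
COI_COLUMNS = ["host_id", "phage_id", "replicate", "centers", "input_pfu"]


def read_adsorption_tsv(path) -> list[AdsorptionSeries]:
    """Read tidy adsorption data: one row per host/phage/replicate/timepoint."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ADSORPTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"adsorption TSV lacks columns {sorted(missing)}")
    out = []
    for (host, phage, rep), grp in df.groupby(["host_id", "phage_id", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            AdsorptionSeries(
                host_id=str(host),
                phage_id=str(phage),
                replicate=int(rep),
                points=list(zip(grp["time_min"], grp["free_titer"])),
                input_titer=float(grp["input_titer"].iloc[0]),
            )
        )
    return out


def read_infection_centers_tsv(path) -> list[InfectionCenterAssay]:
    df = pd.read_csv(path, sep="\t")
    missing = set(COI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"infection-centers TSV lacks columns {sorted(missing)}")
    return [
        InfectionCenterAssay(
            host_id=str(r.host_id),
            phage_id=str(r.phage_id),
            replicate=int(r.replicate),
            centers=float(r.centers),
            input_pfu=float(r.input_pfu),
        )
        for r in df.itertuples()
    ]
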
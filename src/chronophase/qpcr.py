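"""qPCR relative quantification.

Efficiency-corrected two-gene normalization: with amplification
efficiencies E (fold amplification per cycle, E = 2 for perfect
doubling) estimated from standard-curve slopes (E = 10^(-1/slope)),
the expression of a target gene relative to a reference gene is

    ratio = E_target^(-Cq_target) / E_ref^(-Cq_ref)

With E_target = E_ref = 2 this reduces to the familiar 2^(-dCq).
Time courses are reported as percent of peak: all values are scaled so
the largest per-time-point group mean equals 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GeneTimecourse

__all__ = [
    "CqMeasurement",
    "PrimerEfficiency",
    "collapse_replicates",
    "fit_efficiency",
    "relative_expression",
    "percent_of_peak",
]


@dataclass(frozen=True)
class CqMeasurement:
    """Replicate cycle-threshold values for one sample x gene well group."""

    sample_id: str
    gene: str
    replicate_cq: tuple[float, ...]
    dilution: float | None = None  # relative template input (standard curves)

    def __post_init__(self) -> None:
        if len(self.replicate_cq) < 1:
            raise ValueError("at least one replicate Cq required")
        if not all(np.isfinite(self.replicate_cq)):
            raise ValueError("Cq values must be finite")


@dataclass(frozen=True)
class PrimerEfficiency:
    """Amplification efficiency of a primer pair.

    ``slope`` is the standard-curve slope (Cq per log10 input, < 0);
    ``efficiency`` is the fold amplification per cycle, 10^(-1/slope).
    Values outside (1.8, 2.1] are permitted but atypical.
    """

    gene: str
    slope: float
    efficiency: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError("efficiency must lie in (1, 2.2]")


@dataclass(frozen=True)
class CollapsedCq:
    mean_cq: float
    n_used: int
    dropped: tuple[float, ...]


def collapse_replicates(m: CqMeasurement, outlier_limit: float = 0.5) -> CollapsedCq:
    """Mean Cq over replicates with a one-outlier drop rule.

    A replicate deviating from the replicate median by more than
    ``outlier_limit`` cycles is dropped (at most one, the worst).  If
    the remaining replicates are still mutually discordant (all pairwise
    gaps exceed the limit) the well group is unusable and an error is
    raised.
    """
    cq = np.asarray(m.replicate_cq, dtype=float)
    if len(cq) == 1:
        return CollapsedCq(float(cq[0]), 1, ())
    med = np.median(cq)
    dev = np.abs(cq - med)
    dropped: tuple[float, ...] = ()
    keep = cq
    if dev.max() > outlier_limit:
        worst = int(np.argmax(dev))
        dropped = (float(cq[worst]),)
        keep = np.delete(cq, worst)
    if len(keep) > 1:
        pairwise = np.abs(keep[:, None] - keep[None, :])
        iu = np.triu_indices(len(keep), k=1)
        if np.all(pairwise[iu] > outlier_limit):
            raise ValueError(
                f"{m.sample_id}/{m.gene}: replicates mutually discordant "
                f"(all pairwise gaps > {outlier_limit} cycles)"
            )
    return CollapsedCq(float(keep.mean()), int(len(keep)), dropped)


def fit_efficiency(standards: list[CqMeasurement]) -> PrimerEfficiency:
    """Primer efficiency from a serial-dilution standard curve.

    Least-squares line of mean Cq against log10(dilution);
    E = 10^(-1/slope).  Requires at least three distinct dilutions.
    """
    if any(s.dilution is None or s.dilution <= 0 for s in standards):
        raise ValueError("all standards need a positive dilution")
    dils = np.array([s.dilution for s in standards], dtype=float)
    if len(np.unique(dils)) < 3:
        raise ValueError("need >= 3 distinct dilutions")
    genes = {s.gene for s in standards}
    if len(genes) != 1:
        raise ValueError(f"standards mix genes: {sorted(genes)}")
    cqs = np.array([collapse_replicates(s).mean_cq for s in standards])
    res = stats.linregress(np.log10(dils), cqs)
    if res.slope >= 0:
        raise ValueError("non-negative standard-curve slope: invalid dilution series")
    eff = 10.0 ** (-1.0 / res.slope)
    return PrimerEfficiency(
        gene=genes.pop(),
        slope=float(res.slope),
        efficiency=float(eff),
        r_squared=float(res.rvalue**2),
    )


def relative_expression(
    cq_target: float,
    cq_ref: float,
    e_target: PrimerEfficiency,
    e_ref: PrimerEfficiency,
) -> float:
    """Efficiency-corrected expression of target relative to reference."""
    if not (np.isfinite(cq_target) and np.isfinite(cq_ref)):
        raise ValueError("Cq values must be finite")
    return float(
        e_target.efficiency ** (-cq_target) / e_ref.efficiency ** (-cq_ref)
    )


def percent_of_peak(tc: GeneTimecourse) -> GeneTimecourse:
    """Scale a time course so its peak per-time-point group mean is 100.

    Matches the convention of plotting expression relative to the peak
    (set at 100%) within each genotype.  Idempotent and invariant under
    positive rescaling of the input.
    """
    means = tc.group_means()
    peak = means.max()
    if not (peak > 0):
        raise ValueError("all-zero time course cannot be scaled to peak")
    data = tc.data.copy()
    data["value"] = data["value"] * (100.0 / peak)
    return GeneTimecourse(gene=tc.gene, tissue=tc.tissue, genotype=tc.genotype, data=data)
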
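"""Synthetic circadian data generators.

Three generators produce data with the statistical structure the
analysis chain assumes:

* :func:`simulate_activity` — binned locomotor/wheel counts for one
  animal.  The expected rate is a rectangular nocturnal bout (onset
  anchored to dark onset under LD, drifting with the free-running
  period tau under DD); counts are Poisson per bin; light multiplies
  the activity component by a masking factor.
* :func:`simulate_expression` — gene-expression time courses sampled at
  ZT points, multiplicative lognormal between-animal noise.
* :func:`simulate_corticosterone` — urinary hormone profiles passed
  through an immunoassay error model (recovery, duplicate wells with
  intra-assay CV, a shared batch factor per collection time with
  inter-assay CV, and a lower detection limit).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ActivitySeries, GeneTimecourse, HormoneTimecourse
from .presets import AssayModel, GenotypePreset, RhythmProfile
from .schedules import LightSchedule, Regime

__all__ = [
    "simulate_activity",
    "simulate_activity_cohort",
    "expected_activity",
    "simulate_expression",
    "simulate_corticosterone",
    "profile_value",
]


def _cum_active(t, anchor: float, period: float, duration: float):
    """Cumulative active time of a periodic rectangular bout up to ``t``.

    The bout occupies ``[anchor + k*period, anchor + k*period + duration)``
    for all integers ``k``; the overlap of any interval ``[a, b)`` with
    the bout train is ``_cum_active(b) - _cum_active(a)``.
    """
    u = np.asarray(t, dtype=float) - anchor
    return np.floor(u / period) * duration + np.clip(u % period, 0.0, duration)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal multipliers with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def expected_activity(
    preset: GenotypePreset,
    schedule: LightSchedule,
    n_days: int,
    bin_width_min: int,
    modality: str = "wheel",
) -> np.ndarray:
    """Expected counts per bin (the noiseless limit of the simulator)."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if 60 % bin_width_min != 0:
        raise ValueError("bin width must divide 60 minutes")
    cycle = schedule.cycle_length_h
    r_active = preset.activity_rate[modality]
    r_base = preset.baseline_rate[modality]
    shift_h = preset.onset_shift_min[modality] / 60.0
    alpha = preset.activity_duration_h
    # Entrained bout start: dark onset minus the onset offset.
    s0 = schedule.dark_onset_zt - shift_h

    n_bins = int(round(n_days * cycle * 60 / bin_width_min))
    edges = np.arange(n_bins + 1) * (bin_width_min / 60.0)
    a, b = edges[:-1], edges[1:]
    mid = 0.5 * (a + b)

    dd_start = schedule.dd_start_h()
    overlap = np.empty(n_bins)
    if dd_start is None:  # pure LD
        overlap[:] = _cum_active(b, s0, cycle, alpha) - _cum_active(a, s0, cycle, alpha)
        in_dd = np.zeros(n_bins, dtype=bool)
    else:
        in_dd = mid >= dd_start
        # Free run: the bout of the last LD day recurs every tau hours.
        # Its start carries the entrained phase into DD, then drifts by
        # (tau - 24) h per cycle.
        tau = preset.tau_h
        anchor_dd = dd_start + s0 + (tau - cycle)
        ld = ~in_dd
        overlap[ld] = _cum_active(b[ld], s0, cycle, alpha) - _cum_active(
            a[ld], s0, cycle, alpha
        )
        overlap[in_dd] = _cum_active(b[in_dd], anchor_dd, tau, alpha) - _cum_active(
            a[in_dd], anchor_dd, tau, alpha
        )

    is_light = np.array([schedule.is_light_at(t) for t in mid]) & ~in_dd
    mask = np.where(is_light, preset.masking_factor, 1.0)
    width_h = bin_width_min / 60.0
    # Activity component is masked during lights-on; baseline is not.
    mu = 60.0 * (r_base * width_h + mask * (r_active - r_base) * overlap)
    return np.maximum(mu, 0.0)


def simulate_activity(
    preset: GenotypePreset,
    schedule: LightSchedule,
    n_days: int,
    bin_width_min: int,
    seed: int,
    modality: str = "wheel",
    subject_id: str = "sim0",
) -> ActivitySeries:
    """Simulate one animal's binned activity record.

    Counts are Poisson with the analytic per-bin expectation from
    :func:`expected_activity`; identical arguments and seed give a
    bitwise-identical series.
    """
    mu = expected_activity(preset, schedule, n_days, bin_width_min, modality)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu)
    return ActivitySeries(
        subject_id=subject_id,
        genotype=preset.label,
        modality=modality,
        bin_width_min=bin_width_min,
        counts=counts,
        schedule=schedule,
    )


def simulate_activity_cohort(
    preset: GenotypePreset,
    schedule: LightSchedule,
    n_days: int,
    bin_width_min: int,
    n_animals: int,
    seed: int,
    modality: str = "wheel",
) -> list[ActivitySeries]:
    """Simulate a cohort; animal ``i`` uses stream ``seed + i``."""
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    return [
        simulate_activity(
            preset,
            schedule,
            n_days,
            bin_width_min,
            seed=seed + i,
            modality=modality,
            subject_id=f"{preset.label}:{modality}:{i}",
        )
        for i in range(n_animals)
    ]


def profile_value(profile: RhythmProfile, t) -> np.ndarray:
    """Expected value of a rhythm profile at ZT ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, profile.mesor)
    for k, amp in enumerate(profile.amplitudes, start=1):
        out = out + amp * np.cos(
            2 * np.pi * k * (t - profile.acrophase_zt) / profile.base_period_h
        )
    return out


def simulate_expression(
    profile: RhythmProfile,
    times,
    n_per_time: int,
    seed: int,
    gene: str = "gene",
    tissue: str = "tissue",
    genotype: str = "sim",
) -> GeneTimecourse:
    """Simulate an expression time course (one animal per observation).

    Animals are sacrificed at sampling, so every observation is an
    independent animal: value = profile expectation times a lognormal
    multiplier with mean 1 and CV ``profile.noise_cv``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any((times < 0) | (times >= 24)):
        raise ValueError("times must lie in [0, 24)")
    if n_per_time < 1:
        raise ValueError("n_per_time must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for t in times:
        mu = float(profile_value(profile, t))
        eps = _lognormal_unit_mean(rng, profile.noise_cv, n_per_time)
        for j in range(n_per_time):
            rows.append(
                {
                    "subject_id": f"{genotype}:t{t:g}:a{j}",
                    "zt_h": t,
                    "value": mu * eps[j],
                    "replicate": 0,
                    "below_detection": False,
                }
            )
    return GeneTimecourse(
        gene=gene, tissue=tissue, genotype=genotype, data=pd.DataFrame(rows)
    )


def simulate_corticosterone(
    profile: RhythmProfile,
    assay: AssayModel,
    times,
    n_animals: int,
    seed: int,
    genotype: str = "sim",
) -> HormoneTimecourse:
    """Simulate urinary corticosterone profiles through the assay model.

    The same ``n_animals`` animals are sampled at every collection time.
    Animal-level lognormal noise (CV ``profile.noise_cv``) scales a whole
    animal's profile and a Gaussian phase offset (SD ``profile.phase_sd_h``)
    shifts its peak time; each collection time forms one assay batch with
    a shared lognormal factor (CV ``cv_inter``); duplicate wells carry
    independent Gaussian errors (CV ``cv_intra``); values are scaled by
    the mean recovery and flagged when below the detection limit.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any((times < 0) | (times >= 24)):
        raise ValueError("times must lie in [0, 24)")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")

    master = np.random.default_rng(seed)
    batch = _lognormal_unit_mean(master, assay.cv_inter, len(times))
    animal_eps = _lognormal_unit_mean(master, profile.noise_cv, n_animals)
    animal_shift = (
        master.normal(0.0, profile.phase_sd_h, n_animals)
        if profile.phase_sd_h
        else np.zeros(n_animals)
    )

    rows = []
    for a in range(n_animals):
        rng = np.random.default_rng(seed + 1 + a)  # per-animal stream
        for ti, t in enumerate(times):
            true = float(profile_value(profile, t - animal_shift[a])) * animal_eps[a]
            for r in range(assay.n_replicates):
                noise = 1.0 + (rng.normal(0.0, assay.cv_intra) if assay.cv_intra else 0.0)
                measured = true * assay.recovery * batch[ti] * noise
                measured = max(measured, 1e-9)  # assay readouts are positive
                rows.append(
                    {
                        "subject_id": f"{genotype}:a{a}",
                        "zt_h": t,
                        "value": measured,
                        "replicate": r,
                        "below_detection": measured < assay.sensitivity_ng_ml,
                    }
                )
    return HormoneTimecourse(
        hormone="corticosterone", genotype=genotype, data=pd.DataFrame(rows)
    )
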
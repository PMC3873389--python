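"""Genotype presets: ground-truth simulation parameters.

The presets describe wild-type, short-period *Cry1*-deficient and
long-period *Cry2*-deficient mice on a C57BL/6 background.  Free-running
periods, entrained activity-onset offsets and the phase markers
(centers of gravity) of SCN/peripheral gene expression and urinary
corticosterone are the published cohort estimates for these genotypes;
quantities never reported for this design (bout duration, count
magnitudes, unreported acrophases) are fixed defaults chosen to be
realistic for C57BL/6 mice and are marked ``assumed`` below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenotypePreset",
    "RhythmProfile",
    "AssayModel",
    "preset_table",
    "preset",
    "expression_profile",
    "corticosterone_profile",
    "CORTICOSTERONE_ASSAY",
    "EXPRESSION_PANELS",
]


@dataclass(frozen=True)
class GenotypePreset:
    """Ground-truth parameters for one genotype.

    ``onset_shift_min`` is the entrained activity-onset offset relative
    to dark onset in minutes, positive when activity onset precedes dark
    onset; it is recorded per modality because wheel-running and general
    locomotor recordings resolve the onset differently.  ``acrophases``
    maps ``(tissue, gene-or-hormone)`` to the peak time in ZT hours.
    """

    label: str
    tau_h: float
    onset_shift_min: dict[str, float]
    activity_duration_h: float
    activity_rate: dict[str, float]  # expected counts per minute, active
    baseline_rate: dict[str, float]  # expected counts per minute, inactive
    masking_factor: float
    acrophases: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if not (20.0 < self.tau_h < 28.0):
            raise ValueError("tau must lie in (20, 28) h")
        if not (0.0 < self.activity_duration_h < 24.0):
            raise ValueError("activity_duration must lie in (0, 24) h")
        if any(r < 0 for r in self.activity_rate.values()) or any(
            r < 0 for r in self.baseline_rate.values()
        ):
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.masking_factor <= 1.0):
            raise ValueError("masking_factor must lie in [0, 1]")
        for key, zt in self.acrophases.items():
            if not (0.0 <= zt < 24.0):
                raise ValueError(f"acrophase out of [0, 24): {key} -> {zt}")


@dataclass(frozen=True)
class RhythmProfile:
    """Generative model of a 24 h rhythmic quantity.

    Expected value at ZT ``t``:
    ``mesor + sum_k amplitudes[k] * cos(2*pi*(k+1)*(t - acrophase)/base_period)``.
    Between-subject variation is multiplicative lognormal with
    coefficient of variation ``noise_cv``.
    """

    mesor: float
    amplitudes: tuple[float, ...]
    acrophase_zt: float
    base_period_h: float = 24.0
    noise_cv: float = 0.0
    phase_sd_h: float = 0.0  # between-subject acrophase jitter (hours)

    def __post_init__(self) -> None:
        if self.mesor <= 0:
            raise ValueError("mesor must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if self.amplitudes and self.amplitudes[0] > self.mesor:
            raise ValueError("fundamental amplitude must not exceed the mesor")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.phase_sd_h < 0:
            raise ValueError("phase_sd_h must be non-negative")


@dataclass(frozen=True)
class AssayModel:
    """Immunoassay error model for hormone measurements."""

    sensitivity_ng_ml: float = 0.29  # lower detection limit
    recovery: float = 0.973  # mean recovery fraction
    cv_intra: float = 0.031  # within-assay (replicate) CV
    cv_inter: float = 0.111  # between-assay (batch) CV
    dilution_factor: float = 4.0
    n_replicates: int = 2  # samples analyzed in duplicate

    def __post_init__(self) -> None:
        if self.sensitivity_ng_ml < 0:
            raise ValueError("sensitivity must be non-negative")
        if not (0 < self.recovery <= 1.5):
            raise ValueError("recovery must lie in (0, 1.5]")
        if self.cv_intra < 0 or self.cv_inter < 0:
            raise ValueError("CVs must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


#: Published corticosterone ELISA quality-control parameters.
CORTICOSTERONE_ASSAY = AssayModel()

# Shared defaults for quantities the source cohorts did not report
# (assumed, realistic for C57BL/6): consolidated nocturnal bout of 10 h,
# wheel revolutions ~40/min when running, locomotor counts ~40/min.
_ACTIVITY_DURATION_H = 10.0
_ACTIVITY_RATE = {"wheel": 40.0, "locomotor": 40.0}
_BASELINE_RATE = {"wheel": 0.2, "locomotor": 1.0}
_MASKING = 0.8


def _acrophases(
    scn_bmal1: float,
    liver_per2: float,
    corticosterone: float,
    peripheral_shift_h: float,
) -> dict[tuple[str, str], float]:
    """Assemble the per-tissue acrophase table for one genotype.

    ``scn_bmal1``, ``liver_per2`` and ``corticosterone`` are published
    centers of gravity.  All other entries are assumed: canonical mouse
    phase relations (peripheral Bmal1 ~ZT22, Per2 ~ZT15, Dbp ~ZT11 in
    the wild type; SCN Per2/Dbp/Pk2 near-synchronous across genotypes)
    shifted by ``peripheral_shift_h`` in peripheral tissues (advance
    negative) to mirror the genotype's peripheral phase shift.
    """
    s = peripheral_shift_h
    table: dict[tuple[str, str], float] = {
        # SCN: central clock, near-synchronous across genotypes except Bmal1.
        ("SCN", "Bmal1"): scn_bmal1,
        ("SCN", "Per2"): 12.0,  # assumed
        ("SCN", "Dbp"): 8.0,  # assumed
        ("SCN", "Pk2"): 4.0,  # assumed
        ("liver", "Per2"): liver_per2,
        ("urine", "corticosterone"): corticosterone,
    }
    peripheral = {
        ("liver", "Bmal1"): 22.0,
        ("liver", "Dbp"): 11.0,
        ("kidney", "Bmal1"): 22.0,
        ("kidney", "Per2"): 15.0,
        ("kidney", "Dbp"): 11.0,
        ("intestine", "Bmal1"): 22.0,
        ("intestine", "Per2"): 15.0,
        ("intestine", "Dbp"): 11.0,
        ("skin", "Bmal1"): 22.0,
        ("skin", "Per2"): 15.0,
        ("skin", "Dbp"): 11.0,
    }
    for key, zt in peripheral.items():  # assumed wild-type values + shift
        table[key] = (zt + s) % 24.0
    return table


_PRESETS: dict[str, GenotypePreset] = {
    "wt": GenotypePreset(
        label="wt",
        tau_h=23.77,  # published free-running period 23.77 +/- 0.01 h
        onset_shift_min={"wheel": 0.0, "locomotor": 0.0},  # reference genotype
        activity_duration_h=_ACTIVITY_DURATION_H,
        activity_rate=_ACTIVITY_RATE,
        baseline_rate=_BASELINE_RATE,
        masking_factor=_MASKING,
        acrophases=_acrophases(
            scn_bmal1=20.9,  # published SCN Bmal1 COG
            liver_per2=14.9,  # published liver Per2 COG
            corticosterone=14.53,  # published urinary corticosterone COG
            peripheral_shift_h=0.0,
        ),
    ),
    "Cry1-/-": GenotypePreset(
        label="Cry1-/-",
        tau_h=22.59,  # published 22.59 +/- 0.11 h
        onset_shift_min={
            "wheel": 19.4,  # published onset advance vs wt, wheel running
            "locomotor": 28.0,  # published onset advance vs wt, video tracking
        },
        activity_duration_h=_ACTIVITY_DURATION_H,
        activity_rate=_ACTIVITY_RATE,
        baseline_rate=_BASELINE_RATE,
        masking_factor=_MASKING,
        acrophases=_acrophases(
            scn_bmal1=18.1,  # published
            liver_per2=14.4,  # published
            corticosterone=12.04,  # published
            peripheral_shift_h=-2.5,  # assumed peripheral advance
        ),
    ),
    "Cry2-/-": GenotypePreset(
        label="Cry2-/-",
        tau_h=24.19,  # published 24.19 +/- 0.10 h
        onset_shift_min={
            "wheel": 0.0,  # indistinguishable from wt
            "locomotor": -5.1,  # published (not significant) onset delay
        },
        activity_duration_h=_ACTIVITY_DURATION_H,
        activity_rate=_ACTIVITY_RATE,
        baseline_rate=_BASELINE_RATE,
        masking_factor=_MASKING,
        acrophases=_acrophases(
            scn_bmal1=18.4,  # published
            liver_per2=15.4,  # assumed: liver Per2 mildly delayed
            corticosterone=14.12,  # published
            peripheral_shift_h=3.0,  # assumed peripheral delay
        ),
    ),
}

_ALIASES = {
    "wt": "wt",
    "wildtype": "wt",
    "wild-type": "wt",
    "cry1": "Cry1-/-",
    "cry1-/-": "Cry1-/-",
    "cry2": "Cry2-/-",
    "cry2-/-": "Cry2-/-",
}


def preset_table() -> list[GenotypePreset]:
    """The three genotype presets (wild type, Cry1-/-, Cry2-/-)."""
    return [_PRESETS["wt"], _PRESETS["Cry1-/-"], _PRESETS["Cry2-/-"]]


def preset(label: str) -> GenotypePreset:
    """Look up a genotype preset by (case-insensitive) label."""
    key = _ALIASES.get(label.lower())
    if key is None:
        raise KeyError(
            f"unknown genotype {label!r}; known: {sorted(set(_ALIASES))}"
        )
    return _PRESETS[key]


#: Expression panels simulated by the study replay: SCN core clock and
#: clock-controlled genes, and three clock genes in four peripheral tissues.
EXPRESSION_PANELS: tuple[tuple[str, str], ...] = (
    ("SCN", "Bmal1"),
    ("SCN", "Per2"),
    ("SCN", "Dbp"),
    ("SCN", "Pk2"),
    ("liver", "Bmal1"),
    ("liver", "Per2"),
    ("liver", "Dbp"),
    ("kidney", "Bmal1"),
    ("kidney", "Per2"),
    ("kidney", "Dbp"),
    ("intestine", "Bmal1"),
    ("intestine", "Per2"),
    ("intestine", "Dbp"),
    ("skin", "Bmal1"),
    ("skin", "Per2"),
    ("skin", "Dbp"),
)


def expression_profile(
    genotype: str,
    tissue: str,
    gene: str,
    noise_cv: float = 0.2,
    relative_amplitude: float = 0.9,
) -> RhythmProfile:
    """Rhythm profile for a gene x tissue panel of a genotype.

    Mesor and amplitude are in arbitrary relative-expression units; only
    the relative amplitude matters because time courses are normalized
    to percent-of-peak downstream.  ``relative_amplitude`` = fundamental
    amplitude / mesor (clock genes are high-amplitude; default 0.9).
    """
    p = preset(genotype)
    key = (tissue, gene)
    if key not in p.acrophases:
        raise KeyError(f"no acrophase preset for {key} in genotype {p.label}")
    mesor = 50.0
    return RhythmProfile(
        mesor=mesor,
        amplitudes=(relative_amplitude * mesor,),
        acrophase_zt=p.acrophases[key],
        noise_cv=noise_cv,
    )


def corticosterone_profile(
    genotype: str, noise_cv: float = 0.25, phase_sd_h: float = 1.0
) -> RhythmProfile:
    """Urinary corticosterone rhythm profile for a genotype (ng/ml).

    ``phase_sd_h`` is the between-animal dispersion of peak time.  Its
    default (1.0 h) is the dispersion implied by the published group
    ANOVA: F(2,23) = 13.47 with group peaks 14.53/12.04/14.12 ZT h and
    n = 8 per genotype gives a within-group phase SD near one hour.
    """
    p = preset(genotype)
    return RhythmProfile(
        mesor=40.0,  # assumed scale, ng/ml after 1:4 dilution correction
        amplitudes=(30.0,),
        acrophase_zt=p.acrophases[("urine", "corticosterone")],
        noise_cv=noise_cv,
        phase_sd_h=phase_sd_h,
    )
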
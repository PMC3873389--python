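"""End-to-end study replay: simulate -> analyze -> compare.

``run_replay`` generates the full synthetic study for the configured
genotypes (LD + DD activity in both modalities, gene-expression panels,
urinary corticosterone), runs the analysis chain (onset and phase angle,
chi-square periodogram, percent-of-peak normalization, wave fits and
centers of gravity, group statistics) and returns a :class:`StudyReport`
that is fully reproducible from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .activity import detect_onsets, estimate_period, phase_angle
from .containers import HormoneTimecourse
from .group_stats import mann_whitney, one_way_anova, two_way_anova
from .presets import (
    CORTICOSTERONE_ASSAY,
    EXPRESSION_PANELS,
    corticosterone_profile,
    expression_profile,
    preset,
)
from .qpcr import percent_of_peak
from .rhythm import cog_of_fit, cog_of_samples, fit_harmonic
from .schedules import LD12_12, ld_then_dd
from .simulate import simulate_activity_cohort, simulate_corticosterone, simulate_expression

__all__ = ["PipelineConfig", "StudyReport", "run_replay", "per_animal_cogs"]

_SCHEMA: dict[str, dict[str, object]] = {
    "activity": {
        "n_animals_wheel": 6,
        "n_animals_locomotor": 10,
        "ld_days": 5,
        "dd_days": 13,
        "wheel_bin_min": 2,
        "locomotor_bin_min": 15,
        "skip_days": 1,
        "use_days": 12,
    },
    "expression": {
        "times": [0.0, 4.0, 8.0, 12.0, 16.0, 20.0],
        "n_per_time_wt": 4,
        "n_per_time_ko": 3,
        "noise_cv": 0.2,
    },
    "corticosterone": {"n_animals": 8, "noise_cv": 0.25},
    "analysis": {
        "alpha": 0.05,
        "p_min_h": 20.0,
        "p_max_h": 28.0,
        "h_max": 2,
        "threshold_frac": 0.30,
    },
}


@dataclass
class PipelineConfig:
    """Study-replay configuration (see module docstring of ``pipeline``)."""

    seed: int = 1
    outdir: str | None = None
    genotypes: list[str] = field(default_factory=lambda: ["wt", "Cry1-/-", "Cry2-/-"])
    activity: dict = field(default_factory=lambda: dict(_SCHEMA["activity"]))
    expression: dict = field(default_factory=lambda: dict(_SCHEMA["expression"]))
    corticosterone: dict = field(default_factory=lambda: dict(_SCHEMA["corticosterone"]))
    analysis: dict = field(default_factory=lambda: dict(_SCHEMA["analysis"]))

    def __post_init__(self) -> None:
        self.seed = int(self.seed)
        for section in ("activity", "expression", "corticosterone", "analysis"):
            given = getattr(self, section)
            allowed = _SCHEMA[section]
            unknown = set(given) - set(allowed)
            if unknown:
                raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}")
            merged = dict(allowed)
            merged.update(given)
            setattr(self, section, merged)
        alpha = self.analysis["alpha"]
        if not (0 < alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for g in self.genotypes:
            preset(g)  # raises on unknown genotype

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "outdir"
        }
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All recovered estimates of one replay, traceable to config + seed."""

    seed: int
    config_hash: str
    version: str
    tau_h: dict[str, dict[str, float]]  # genotype -> {mean, sd, n}
    phase_angle_min: dict[str, dict[str, dict[str, float]]]  # genotype -> modality -> stats
    expression_cog: dict[str, dict[str, dict[str, float]]]  # genotype -> "tissue/gene" -> stats
    corticosterone_cog: dict[str, dict[str, float]]  # genotype -> {mean, sd, n}
    onset_tests: dict[str, dict[str, float]]  # "geno|modality" -> {U, p}
    corticosterone_anova: dict
    expression_anova: dict[str, dict[str, float]]  # "tissue/gene" -> term p-values

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)


def per_animal_cogs(tc: HormoneTimecourse) -> np.ndarray:
    """Sample-level center of gravity per animal (duplicates averaged)."""
    collapsed = tc.collapse_replicates()
    cogs = []
    for _, sub in collapsed.groupby("subject_id"):
        cogs.append(cog_of_samples(sub["zt_h"], sub["value"]).cog_zt)
    return np.asarray(cogs)


def _n_per_time(cfg: PipelineConfig, genotype: str) -> int:
    key = "n_per_time_wt" if genotype == "wt" else "n_per_time_ko"
    return int(cfg.expression[key])


def run_replay(config: PipelineConfig) -> StudyReport:
    """Run the full synthetic study and return its report.

    Intermediate CSVs and the JSON report are written to
    ``config.outdir`` when set.
    """
    cfg = config
    act, ana = cfg.activity, cfg.analysis
    times = list(cfg.expression["times"])
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    tau: dict[str, dict[str, float]] = {}
    angles: dict[str, dict[str, dict[str, float]]] = {}
    angle_samples: dict[tuple[str, str], np.ndarray] = {}
    expr_cog: dict[str, dict[str, dict[str, float]]] = {}
    cort_cog: dict[str, dict[str, float]] = {}
    cort_groups: dict[str, np.ndarray] = {}
    expr_frames: dict[tuple[str, str], list] = {}

    for gi, gname in enumerate(cfg.genotypes):
        p = preset(gname)
        gseed = cfg.seed + 10_000 * gi

        # --- free-running period from DD wheel running -------------------
        dd_sched = ld_then_dd(0)
        cohort = simulate_activity_cohort(
            p,
            dd_sched,
            n_days=int(act["skip_days"]) + int(act["use_days"]),
            bin_width_min=int(act["wheel_bin_min"]),
            n_animals=int(act["n_animals_wheel"]),
            seed=gseed,
            modality="wheel",
        )
        taus = [
            estimate_period(
                s,
                skip_days=int(act["skip_days"]),
                use_days=int(act["use_days"]),
                p_min_h=float(ana["p_min_h"]),
                p_max_h=float(ana["p_max_h"]),
                alpha=float(ana["alpha"]),
            ).tau_hat_h
            for s in cohort
        ]
        taus = np.asarray([t for t in taus if t is not None])
        tau[gname] = {
            "mean": float(taus.mean()),
            "sd": float(taus.std(ddof=1)) if len(taus) > 1 else 0.0,
            "n": int(len(taus)),
        }

        # --- entrained onsets and phase angles ---------------------------
        angles[gname] = {}
        for modality, bin_min, n_animals in (
            ("wheel", int(act["wheel_bin_min"]), int(act["n_animals_wheel"])),
            ("locomotor", int(act["locomotor_bin_min"]), int(act["n_animals_locomotor"])),
        ):
            ld_cohort = simulate_activity_cohort(
                p,
                LD12_12,
                n_days=int(act["ld_days"]) + 1,  # extra day so 5 scan windows fit
                bin_width_min=bin_min,
                n_animals=n_animals,
                seed=gseed + 1000,
                modality=modality,
            )
            per_animal = []
            for s in ld_cohort:
                onsets = detect_onsets(s, threshold_frac=float(ana["threshold_frac"]))
                per_animal.append(phase_angle(onsets, LD12_12).mean_min)
            arr = np.asarray(per_animal)
            angle_samples[(gname, modality)] = arr
            angles[gname][modality] = {
                "mean": float(arr.mean()),
                "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
                "n": int(len(arr)),
            }

        # --- expression panels -------------------------------------------
        expr_cog[gname] = {}
        for pi, (tissue, gene) in enumerate(EXPRESSION_PANELS):
            profile = expression_profile(
                gname, tissue, gene, noise_cv=float(cfg.expression["noise_cv"])
            )
            tc = simulate_expression(
                profile,
                times,
                n_per_time=_n_per_time(cfg, gname),
                seed=gseed + 2000 + pi,
                gene=gene,
                tissue=tissue,
                genotype=gname,
            )
            scaled = percent_of_peak(tc)
            fit = fit_harmonic(
                scaled.data["zt_h"],
                scaled.data["value"],
                h_max=int(ana["h_max"]),
                alpha=float(ana["alpha"]),
            )
            phase = cog_of_fit(fit)
            expr_cog[gname][f"{tissue}/{gene}"] = {
                "cog_zt": phase.cog_zt,
                "circular_sd_h": phase.circular_sd_h,
                "rhythm_p": fit.p_value_,
                "rhythmic": bool(fit.rhythmic_),
            }
            df = scaled.data.copy()
            df["genotype"] = gname
            expr_frames.setdefault((tissue, gene), []).append(df)
            if outdir is not None:
                from .io import write_timecourse_csv

                write_timecourse_csv(
                    scaled, outdir / f"expr_{gname.replace('/', '')}_{tissue}_{gene}.csv"
                )

        # --- corticosterone ----------------------------------------------
        tc_h = simulate_corticosterone(
            corticosterone_profile(gname, noise_cv=float(cfg.corticosterone["noise_cv"])),
            CORTICOSTERONE_ASSAY,
            times,
            n_animals=int(cfg.corticosterone["n_animals"]),
            seed=gseed + 5000,
            genotype=gname,
        )
        cogs = per_animal_cogs(tc_h)
        cort_groups[gname] = cogs
        cort_cog[gname] = {
            "mean": float(cogs.mean()),
            "sd": float(cogs.std(ddof=1)) if len(cogs) > 1 else 0.0,
            "n": int(len(cogs)),
        }
        if outdir is not None:
            from .io import write_timecourse_csv

            write_timecourse_csv(tc_h, outdir / f"cort_{gname.replace('/', '')}.csv")

    # --- group statistics ---------------------------------------------------
    onset_tests: dict[str, dict[str, float]] = {}
    if "wt" in cfg.genotypes:
        for gname in cfg.genotypes:
            if gname == "wt":
                continue
            for modality in ("wheel", "locomotor"):
                r = mann_whitney(
                    angle_samples[(gname, modality)], angle_samples[("wt", modality)]
                )
                onset_tests[f"{gname}|{modality}"] = {"U": r.u, "p": r.p}

    cort_anova: dict = {}
    if len(cort_groups) >= 2:
        res = one_way_anova(cort_groups, circular=True)
        cort_anova = {
            "F": float(res.table.loc["group", "F"]),
            "p": float(res.table.loc["group", "p"]),
            "df_between": int(res.table.loc["group", "df"]),
            "df_within": int(res.table.loc["Residual", "df"]),
            "pairwise": {
                f"{row.group_a} vs {row.group_b}": float(row.p_adjusted)
                for row in res.pairwise.itertuples()
            },
        }

    expr_anova: dict[str, dict[str, float]] = {}
    if len(cfg.genotypes) >= 2:
        import pandas as pd

        for (tissue, gene), frames in expr_frames.items():
            df = pd.concat(frames, ignore_index=True)
            res = two_way_anova(df, value="value", factor_a="genotype", factor_b="zt_h")
            expr_anova[f"{tissue}/{gene}"] = {
                "p_genotype": res.p("genotype"),
                "p_time": res.p("zt_h"),
                "p_interaction": res.p("genotype:zt_h"),
            }

    report = StudyReport(
        seed=cfg.seed,
        config_hash=cfg.hash(),
        version=__version__,
        tau_h=tau,
        phase_angle_min=angles,
        expression_cog=expr_cog,
        corticosterone_cog=cort_cog,
        onset_tests=onset_tests,
        corticosterone_anova=cort_anova,
        expression_anova=expr_anova,
    )
    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json())
    return report
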
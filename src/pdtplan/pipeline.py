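"""Retrospective cohort experiment on synthetic subjects.

Generates N synthetic subjects (cavity phantom + optical-property draw),
runs the three simulation conditions for each configured fiber type plus
the post-MB-everywhere (three-region) and 0%-Intralipid variants, and
emits figure-ready tables: per-row endpoints, per-subject plans, and the
study's statistical comparisons.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import build_four_region, build_three_region, wall_surface_area
from .io import write_manifest
from .phantoms import OpticsRanges, PhantomSpec, make_cavity_mask, sample_subject_optics
from .planning import PlanTargets, plan_subject, run_condition
from .stats import fisher_exact_two_sided, spearman_correlation, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

__all__ = ["CohortConfig", "CohortResult", "run_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults mirror the clinical study: 13 subjects, cavities spanning
    1–8 cm, flat-cleaved and spherical-diffuser fibers, targets of 4 and
    20 mW cm⁻², plus the three-region post-MB-everywhere and 0%-Intralipid
    variants.
    """

    n_subjects: int = 13
    master_seed: int = 0
    semi_axis_mm: tuple[float, float] = (5.0, 40.0)
    lobe_amplitude_max: float = 0.3
    pitch_mm: float = 1.0
    padding_mm: float = 3.0
    optics_ranges: OpticsRanges = field(default_factory=OpticsRanges)
    targets_mw_cm2: tuple[float, ...] = (4.0, 20.0)
    fiber_kinds: tuple[str, ...] = ("flat_cleaved", "spherical_diffuser")
    include_three_region: bool = True
    include_zero_intralipid: bool = True
    n_packets: int = 100_000
    concentration_grid: tuple[float, ...] | None = None
    refine: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least one subject")
        lo, hi = self.semi_axis_mm
        if not 0 < lo <= hi:
            raise ValueError("semi-axis range must be a positive interval")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "optics_ranges" in raw:
            raw["optics_ranges"] = OpticsRanges(
                **{k: tuple(v) for k, v in raw["optics_ranges"].items()}
            )
        for key in ("semi_axis_mm", "targets_mw_cm2", "fiber_kinds", "concentration_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CohortResult:
    endpoints: pd.DataFrame
    plans: list[dict]
    stats: pd.DataFrame
    summary: dict
    config: CohortConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.endpoints.to_csv(outdir / "endpoints.csv", index=False)
        self.stats.to_csv(outdir / "stats.csv", index=False)
        write_manifest({"plans": self.plans}, outdir / "plans.json")
        write_manifest(self.summary, outdir / "summary.json")


def _subject_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64) % (2**31)


def _draw_phantom(seed: int, config: CohortConfig) -> PhantomSpec:
    rng = np.random.default_rng(seed)
    shape = rng.choice(["sphere", "ellipsoid", "lobulated"])
    lo, hi = config.semi_axis_mm
    axes = np.sort(rng.uniform(lo, hi, size=3))[::-1]
    if shape == "sphere":
        axes[:] = axes[0]
    amp = float(rng.uniform(0.05, config.lobe_amplitude_max)) if shape == "lobulated" else 0.0
    if shape == "lobulated":
        axes[:] = axes[0]
    return PhantomSpec(
        shape=str(shape),
        semi_axes_mm=tuple(float(a) for a in axes),
        lobe_amplitude=amp,
        n_lobes=int(rng.integers(2, 6)) if shape == "lobulated" else 0,
        pitch_mm=config.pitch_mm,
        padding_mm=config.padding_mm,
        seed=int(seed),
    )


def run_cohort(config: CohortConfig, outdir: str | Path | None = None) -> CohortResult:
    """Run the full synthetic retrospective experiment.

    Fully reproducible from ``config.master_seed``: per-subject seeds are
    spawned from it, and each simulation's seed is derived from the
    subject's. When ``outdir`` is given, a manifest (config + seeds +
    version) is written before any results, then the result tables.
    """
    seeds = _subject_seeds(config.master_seed, config.n_subjects)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        write_manifest(
            {
                "version": __version__,
                "config": dataclasses.asdict(config),
                "subject_seeds": seeds.tolist(),
            },
            Path(outdir) / "manifest.json",
        )

    conc_grid = (
        None if config.concentration_grid is None else np.asarray(config.concentration_grid)
    )
    rows: list[dict] = []
    plans: list[dict] = []

    for i, seed in enumerate(map(int, seeds)):
        t0 = time.perf_counter()
        try:
            spec = _draw_phantom(seed, config)
            mask, pitch = make_cavity_mask(spec)
            lv4 = build_four_region(mask, pitch)
            lv3 = build_three_region(mask, pitch) if config.include_three_region else None
            shortest_axis_cm = 2.0 * min(spec.semi_axes_mm) / 10.0
            subject = sample_subject_optics(
                seed, config.optics_ranges, shortest_axis_cm=shortest_axis_cm
            )
            area_cm2 = wall_surface_area(lv4)

            base = {
                "subject": i,
                "seed": seed,
                "shape": spec.shape,
                "shortest_axis_cm": shortest_axis_cm,
                "surface_area_cm2": area_cm2,
                "pre_mua": subject.pre_mua,
                "post_mua": subject.post_mua,
                "clinical_power_mw": subject.power_mw,
            }

            for fiber in config.fiber_kinds:
                for target in config.targets_mw_cm2:
                    targets = PlanTargets(target_mw_cm2=target)
                    for cond in (1, 2, 3):
                        rec = run_condition(
                            lv4, subject, cond, source_kind=fiber, targets=targets,
                            seed=seed + cond, n_packets=config.n_packets,
                            concentration_grid=conc_grid, refine=config.refine,
                        )
                        rows.append({**base, "variant": "four_region",
                                     "target_mw_cm2": target, **dataclasses.asdict(rec)})
                    if config.include_three_region and lv3 is not None:
                        rec = run_condition(
                            lv3, subject, 2, source_kind=fiber, targets=targets,
                            seed=seed + 2, n_packets=config.n_packets,
                        )
                        rows.append({**base, "variant": "post_mb_everywhere",
                                     "target_mw_cm2": target, **dataclasses.asdict(rec)})
                    if config.include_zero_intralipid:
                        plan0 = plan_subject(
                            lv4, subject, source_kind=fiber, targets=targets,
                            concentration_grid=np.array([0.0]), seed=seed + 3,
                            n_packets=config.n_packets, refine=False,
                        )
                        rows.append({
                            **base, "variant": "zero_intralipid",
                            "target_mw_cm2": target, "condition": "3",
                            "source_kind": fiber,
                            "power_mw": plan0.power_mw,
                            "intralipid_pct": 0.0,
                            "coverage_4": plan0.coverage_4,
                            "coverage_20": plan0.coverage_20,
                            "coverage_400": plan0.coverage_400,
                            "threshold_power_mw": plan0.power_mw,
                            "feasible": plan0.feasible,
                        })
                # retain the full plan (curve) once per fiber, primary target
                plan = plan_subject(
                    lv4, subject, source_kind=fiber,
                    targets=PlanTargets(target_mw_cm2=config.targets_mw_cm2[0]),
                    concentration_grid=conc_grid, seed=seed + 3,
                    n_packets=config.n_packets, refine=config.refine,
                )
                plans.append({
                    "subject": i,
                    "source_kind": fiber,
                    "target_mw_cm2": config.targets_mw_cm2[0],
                    "feasible": plan.feasible,
                    "concentration_pct": plan.concentration_pct,
                    "power_mw": plan.power_mw,
                    "curve": [dataclasses.asdict(p) for p in plan.curve],
                })
            logger.info(
                "subject %d/%d done in %.1f s (%d packets/run)",
                i + 1, config.n_subjects, time.perf_counter() - t0, config.n_packets,
            )
        except Exception as exc:  # annotate with subject context, then propagate
            raise RuntimeError(f"cohort subject {i} (seed {seed}) failed: {exc}") from exc

    endpoints = pd.DataFrame(rows)
    stats_df, summary = _cohort_stats(endpoints, config)
    result = CohortResult(endpoints=endpoints, plans=plans, stats=stats_df,
                          summary=summary, config=config)
    if outdir is not None:
        result.write(outdir)
    return result


def _cohort_stats(endpoints: pd.DataFrame, config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """The study's comparisons on the cohort endpoint table."""
    rows = []
    summary: dict = {"n_subjects": config.n_subjects, "proportions": {}, "plan": {}}
    cov_col = {4.0: "coverage_4", 20.0: "coverage_20"}

    four = endpoints[endpoints["variant"] == "four_region"]
    for fiber in config.fiber_kinds:
        sub = four[four["source_kind"] == fiber]
        for target in config.targets_mw_cm2:
            col = cov_col.get(target)
            if col is None:
                continue
            st = sub[sub["target_mw_cm2"] == target]
            by_cond = {
                c: st[st["condition"] == str(c)].sort_values("subject") for c in (1, 2, 3)
            }
            ach = {c: (df[col] >= 0.95).to_numpy() for c, df in by_cond.items()}
            for c in (1, 2, 3):
                summary["proportions"][f"{fiber}_t{target:g}_cond{c}"] = float(ach[c].mean())
            # Fisher: assumed vs measured achievement proportions
            tbl = [
                [int(ach[1].sum()), int((~ach[1]).sum())],
                [int(ach[2].sum()), int((~ach[2]).sum())],
            ]
            rows.append({
                "comparison": "fisher_achieved_cond1_vs_cond2",
                "fiber": fiber, "target_mw_cm2": target,
                "statistic": math.nan, "p_value": fisher_exact_two_sided(tbl),
            })
            # Wilcoxon: paired coverage between conditions 1 and 2
            x = by_cond[1][col].to_numpy()
            y = by_cond[2][col].to_numpy()
            if np.count_nonzero(x - y) >= 3:
                stat, p = wilcoxon_signed_rank(x, y)
                rows.append({
                    "comparison": "wilcoxon_coverage_cond1_vs_cond2",
                    "fiber": fiber, "target_mw_cm2": target,
                    "statistic": stat, "p_value": p,
                })
            # Spearman: condition-3 required power vs wall mua and surface area
            c3 = by_cond[3]
            feas = c3[np.isfinite(c3["threshold_power_mw"])]
            if len(feas) >= 4:
                for xcol, name in (("post_mua", "wall_mua"), ("surface_area_cm2", "surface_area")):
                    if feas[xcol].nunique() > 1 and feas["threshold_power_mw"].nunique() > 1:
                        rho, p = spearman_correlation(
                            feas[xcol].to_numpy(), feas["threshold_power_mw"].to_numpy()
                        )
                        rows.append({
                            "comparison": f"spearman_power_vs_{name}",
                            "fiber": fiber, "target_mw_cm2": target,
                            "statistic": rho, "p_value": p,
                        })
            # plan summary: mean +/- SD of optimal concentration and power
            c3f = c3[c3["feasible"] == True]  # noqa: E712
            if len(c3f):
                summary["plan"][f"{fiber}_t{target:g}"] = {
                    "concentration_pct_mean": float(c3f["intralipid_pct"].mean()),
                    "concentration_pct_sd": float(c3f["intralipid_pct"].std(ddof=1))
                    if len(c3f) > 1 else 0.0,
                    "power_mw_mean": float(c3f["power_mw"].mean()),
                    "power_mw_sd": float(c3f["power_mw"].std(ddof=1)) if len(c3f) > 1 else 0.0,
                }
    return pd.DataFrame(rows), summary
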
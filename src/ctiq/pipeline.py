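"""End-to-end study orchestration: two simulated scanners compared.

Mirrors the full measurement design: two arms (e.g. a photon-counting
system and a dual-energy system), virtual monoenergetic energy labels of
70 and 40 keV, dose levels of 15, 7.5 and 3 mGy, two iodine contrast
rods.  Per condition the pipeline simulates acquisitions, averages repeat
scans, estimates TTF (per rod), NPS and SSP, applies the slice-thickness
NPS correction against the reference arm, measures the task contrast and
computes d' and SPF^2 per task, then assembles comparison tables:
per-condition d', FWHM ratios (two decimals) and percentage increases of
d' (one decimal, round half up).

Everything is deterministic under the configured seed: every random
stream is derived from (seed, arm, energy, dose, stage, repeat).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .curves import FrequencyCurve, TaskSpec
from .detectability import correction_factor, detectability_index, measure_delta_hu
from .nps import NPSEstimator
from .phantom import (GaussianMTF, GaussianSSP, ImageStack, PhantomSpec,
                      RampLowpassNPS, SyntheticTruth, average_repeats,
                      generate_axial_stack, generate_tilted_rod_stack)
from .ssp import SSPEstimator
from .ttf import LowCNRWarning, TTFEstimator


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage_increase(value_test: float, value_reference: float) -> float:
    """100 * (test - reference) / reference, to one decimal (round half up)."""
    if value_reference == 0:
        raise ValueError("reference value must be nonzero")
    return round_half_up(100.0 * (value_test - value_reference) / value_reference, 1)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

Key = Tuple[int, float]          # (energy keV, dose mGy)


@dataclass
class ArmConfig:
    """Ground-truth models and acquisition plan of one simulated scanner."""

    name: str
    f50_mm: Dict[Key, float]                 # truth MTF 50% point per condition
    ssp_fwhm_mm: Dict[Key, float]            # truth SSP FWHM per condition
    nps_peak_hu2mm2: Dict[int, float]        # NPS peak level at the reference dose
    nps_f_peak_mm: Dict[int, float]          # NPS peak frequency per energy
    repeats: Dict[float, int]                # repeat scans per dose


@dataclass
class StudyConfig:
    test_arm: ArmConfig
    baseline_arm: ArmConfig
    energies: Tuple[int, ...] = (70, 40)
    doses: Tuple[float, ...] = (15.0, 7.5, 3.0)
    ref_dose: float = 15.0
    contrasts: Dict[str, Dict[int, float]] = field(default_factory=dict)
    task_diameter_mm: float = 5.0
    grid: int = 512
    fov_mm: float = 300.0
    rod_diameter_mm: float = 30.0
    rod_offset_mm: float = 50.0
    ssp_rod_diameter_mm: float = 70.0
    tilt_deg: float = 5.0
    n_nps_slices: int = 50
    n_dhu_slices: int = 10
    n_ttf_slices: int = 1
    n_ssp_repeats: int = 2
    ssp_mode: str = "measure"                # or "truth"
    ssp_slice_spacing_mm: float = 0.2
    detrend: str = "poly2"
    seed: int = 0
    share_noise_across_arms: bool = False
    supersample: int = 4

    @property
    def reference_arm(self) -> str:
        """The arm whose slice thickness anchors the NPS correction."""
        return self.test_arm.name

    @property
    def arms(self) -> Tuple[ArmConfig, ArmConfig]:
        return (self.test_arm, self.baseline_arm)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The full study design with measured set-points where available.

    Truth f50 values at 40 keV (12 mgI/mL) and all SSP FWHMs follow the
    published measurements; 70 keV f50s, contrast levels and noise levels
    are plausible stand-ins (the source tables do not print them) and are
    documented in the methods note.
    """
    pcd = ArmConfig(
        name="PCD",
        f50_mm={(40, 15.0): 0.41, (40, 7.5): 0.39, (40, 3.0): 0.31,
                (70, 15.0): 0.42, (70, 7.5): 0.41, (70, 3.0): 0.38},
        ssp_fwhm_mm={(70, 15.0): 1.31, (70, 7.5): 1.34, (70, 3.0): 1.51,
                     (40, 15.0): 1.26, (40, 7.5): 1.27, (40, 3.0): 1.43},
        nps_peak_hu2mm2={40: 600.0, 70: 140.0},
        nps_f_peak_mm={40: 0.22, 70: 0.22},
        repeats={15.0: 5, 7.5: 8, 3.0: 12},
    )
    dect = ArmConfig(
        name="DECT",
        f50_mm={(40, 15.0): 0.34, (40, 7.5): 0.29, (40, 3.0): 0.25,
                (70, 15.0): 0.40, (70, 7.5): 0.38, (70, 3.0): 0.35},
        ssp_fwhm_mm={(70, 15.0): 1.38, (70, 7.5): 1.52, (70, 3.0): 1.67,
                     (40, 15.0): 1.43, (40, 7.5): 1.68, (40, 3.0): 1.80},
        nps_peak_hu2mm2={40: 1000.0, 70: 150.0},
        nps_f_peak_mm={40: 0.18, 70: 0.20},
        repeats={15.0: 6, 7.5: 11, 3.0: 14},
    )
    # iodine contrast ~ 50 HU per mgI/mL at 40 keV, ~ 18 HU/mgI/mL at 70 keV
    return StudyConfig(
        test_arm=pcd, baseline_arm=dect,
        contrasts={"12 mgI/mL": {40: 600.0, 70: 216.0},
                   "2 mgI/mL": {40: 100.0, 70: 36.0}},
        seed=seed,
    )


# --- YAML round trip (tuple keys flattened to "energy/dose" strings) -------

def _flatten(d: dict) -> dict:
    return {("/".join(str(p) for p in k) if isinstance(k, tuple) else str(k)): v
            for k, v in d.items()}


def study_config_to_yaml(config: StudyConfig, path) -> None:
    def arm(a: ArmConfig) -> dict:
        return {"name": a.name, "f50_mm": _flatten(a.f50_mm),
                "ssp_fwhm_mm": _flatten(a.ssp_fwhm_mm),
                "nps_peak_hu2mm2": _flatten(a.nps_peak_hu2mm2),
                "nps_f_peak_mm": _flatten(a.nps_f_peak_mm),
                "repeats": _flatten(a.repeats)}
    d = asdict(config)
    d["test_arm"], d["baseline_arm"] = arm(config.test_arm), arm(config.baseline_arm)
    d["energies"] = list(config.energies)
    d["doses"] = list(config.doses)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def study_config_from_yaml(path) -> StudyConfig:
    d = yaml.safe_load(Path(path).read_text())

    def keys2(m):
        return {(int(k.split("/")[0]), float(k.split("/")[1])): v for k, v in m.items()}

    def arm(m):
        return ArmConfig(name=m["name"], f50_mm=keys2(m["f50_mm"]),
                         ssp_fwhm_mm=keys2(m["ssp_fwhm_mm"]),
                         nps_peak_hu2mm2={int(k): v for k, v in m["nps_peak_hu2mm2"].items()},
                         nps_f_peak_mm={int(k): v for k, v in m["nps_f_peak_mm"].items()},
                         repeats={float(k): v for k, v in m["repeats"].items()})

    d["test_arm"], d["baseline_arm"] = arm(d["test_arm"]), arm(d["baseline_arm"])
    d["energies"] = tuple(int(e) for e in d["energies"])
    d["doses"] = tuple(float(x) for x in d["doses"])
    d["contrasts"] = {lbl: {int(e): float(v) for e, v in m.items()}
                      for lbl, m in d["contrasts"].items()}
    return StudyConfig(**d)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    f50_table: pd.DataFrame          # arm, energy, dose, contrast, f50
    fwhm_table: pd.DataFrame         # arm, energy, dose, fwhm
    ratio_table: pd.DataFrame        # energy, dose, fwhm_ratio (2 decimals)
    delta_hu_table: pd.DataFrame     # arm, energy, dose, contrast, delta_hu
    dprime_table: pd.DataFrame       # energy, dose, contrast, d' per arm
    increase_table: pd.DataFrame     # energy, dose, contrast, pct increase
    spf2_curves: Dict[str, FrequencyCurve]
    log: List[str]
    seed: int

    def to_json_dict(self) -> dict:
        d = {name: getattr(self, f"{name}_table").to_dict(orient="records")
             for name in ("f50", "fwhm", "ratio", "delta_hu", "dprime", "increase")}
        d["spf2_curves"] = {k: {"f": c.f.tolist(), "spf2": c.values.tolist()}
                            for k, c in self.spf2_curves.items()}
        d["log"] = self.log
        d["seed"] = self.seed
        return d


def write_report(report: ComparisonReport, directory) -> None:
    """Write the comparison tables as CSVs plus a JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.f50_table.to_csv(directory / "ttf_f50.csv", index=False)
    report.fwhm_table.to_csv(directory / "ssp_fwhm.csv", index=False)
    report.ratio_table.to_csv(directory / "fwhm_ratio.csv", index=False)
    report.delta_hu_table.to_csv(directory / "delta_hu.csv", index=False)
    report.dprime_table.to_csv(directory / "dprime_table.csv", index=False)
    report.increase_table.to_csv(directory / "increase_table.csv", index=False)
    (directory / "report.json").write_text(
        json.dumps(report.to_json_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

_STAGE_TTF, _STAGE_DHU, _STAGE_NPS, _STAGE_SSP = 0, 1, 2, 3


def _seed_for(config: StudyConfig, arm_idx: int, e_idx: int, d_idx: int,
              stage: int, rep: int = 0) -> int:
    a = 0 if config.share_noise_across_arms else arm_idx + 1
    ss = np.random.SeedSequence([config.seed, a, e_idx, d_idx, stage, rep])
    return int(ss.generate_state(1)[0])


def _condition_label(arm: str, energy: int, dose: float, contrast: str) -> str:
    return f"{arm}|{energy}keV|{dose:g}mGy|{contrast}"


def run_comparison(config: StudyConfig) -> ComparisonReport:
    """Run the full simulated comparison and assemble the report tables."""
    labels = list(config.contrasts)
    log: List[str] = []
    meas: Dict[Tuple[str, int, float], dict] = {}

    for arm_idx, arm in enumerate(config.arms):
        for e_idx, energy in enumerate(config.energies):
            for d_idx, dose in enumerate(config.doses):
                key = (energy, dose)
                level = arm.nps_peak_hu2mm2[energy] * config.ref_dose / dose
                nps_model = RampLowpassNPS(level, arm.nps_f_peak_mm[energy])
                mtf = GaussianMTF(arm.f50_mm[key])
                dhu_truth = tuple(config.contrasts[lbl][energy] for lbl in labels)
                rod_spec = PhantomSpec(
                    background_diameter_mm=config.fov_mm,
                    rod_diameter_mm=config.rod_diameter_mm,
                    rod_offsets_mm=((config.rod_offset_mm, 0.0),
                                    (-config.rod_offset_mm, 0.0)),
                    rod_contrasts_hu=dhu_truth)
                grid = (config.grid, config.grid)

                def truth(stage, rep=0, ssp=None):
                    return SyntheticTruth(
                        mtf_model=mtf, nps_model=nps_model, ssp_model=ssp,
                        seed=_seed_for(config, arm_idx, e_idx, d_idx, stage, rep))

                # --- TTF: average repeat scans, then circular-edge fit per rod
                repeats = arm.repeats.get(dose, 1)
                stacks = [generate_axial_stack(
                    rod_spec, truth(_STAGE_TTF, rep), n_slices=config.n_ttf_slices,
                    mode="rod_section", grid=grid, fov_mm=config.fov_mm,
                    supersample=config.supersample) for rep in range(repeats)]
                averaged = average_repeats(stacks)
                cx, cy = averaged.center_mm
                ttf_res = {}
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", LowCNRWarning)
                    for lbl, (ox, oy) in zip(labels, rod_spec.rod_offsets_mm):
                        est = TTFEstimator(
                            approx_center_mm=(cx + ox, cy + oy),
                            rod_diameter_mm=config.rod_diameter_mm).fit(averaged)
                        ttf_res[lbl] = est.result_
                for w in caught:
                    log.append(f"{arm.name}|{energy}keV|{dose:g}mGy: {w.message}")

                # --- task contrast from the two-rod section
                dhu_stack = generate_axial_stack(
                    rod_spec, truth(_STAGE_DHU), n_slices=config.n_dhu_slices,
                    mode="rod_section", grid=grid, fov_mm=config.fov_mm,
                    supersample=config.supersample)
                dhu = {}
                for lbl, (ox, oy) in zip(labels, rod_spec.rod_offsets_mm):
                    dhu[lbl] = measure_delta_hu(
                        dhu_stack, (cx + ox, cy + oy), (cx, cy),
                        roi_px=25, n_slices=config.n_dhu_slices,
                        rod_diameter_mm=config.rod_diameter_mm)

                # --- NPS from the uniform water section
                water = generate_axial_stack(
                    rod_spec, truth(_STAGE_NPS), n_slices=config.n_nps_slices,
                    mode="water_section", grid=grid, fov_mm=config.fov_mm,
                    supersample=config.supersample)
                nps_est = NPSEstimator(detrend=config.detrend).fit(water)

                # --- SSP: slant-edge measurement or configured truth
                fwhm_truth = arm.ssp_fwhm_mm[key]
                if config.ssp_mode == "truth":
                    fwhm = fwhm_truth
                elif config.ssp_mode == "measure":
                    ssp_spec = PhantomSpec(
                        background_diameter_mm=config.fov_mm,
                        rod_diameter_mm=config.ssp_rod_diameter_mm,
                        rod_offsets_mm=((0.0, 0.0),),
                        rod_contrasts_hu=(config.contrasts[labels[0]][energy],),
                        tilt_deg=config.tilt_deg)
                    tilted = average_repeats([
                        generate_tilted_rod_stack(
                            ssp_spec,
                            truth(_STAGE_SSP, rep, ssp=GaussianSSP(fwhm_truth)),
                            slice_spacing_mm=config.ssp_slice_spacing_mm,
                            grid=grid, fov_mm=config.fov_mm,
                            supersample=config.supersample)
                        for rep in range(config.n_ssp_repeats)])
                    fwhm = SSPEstimator().fit(tilted).fwhm_
                else:
                    raise ValueError(f"unknown ssp_mode {config.ssp_mode!r}")

                meas[(arm.name, energy, dose)] = {
                    "ttf": ttf_res, "dhu": dhu, "nps": nps_est.radial_,
                    "fwhm": fwhm}

    # --- correction factors and detectability --------------------------------
    ref = config.reference_arm
    rows_f50, rows_fwhm, rows_ratio, rows_dhu, rows_dp, rows_inc = ([] for _ in range(6))
    spf2_curves: Dict[str, FrequencyCurve] = {}
    dprimes: Dict[Tuple[str, int, float, str], float] = {}

    for energy in config.energies:
        for dose in config.doses:
            fwhm_ref = meas[(ref, energy, dose)]["fwhm"]
            for arm in config.arms:
                m = meas[(arm.name, energy, dose)]
                factor = correction_factor(fwhm_ref, m["fwhm"])
                rows_fwhm.append({"arm": arm.name, "energy_keV": energy,
                                  "dose_mGy": dose, "fwhm_mm": m["fwhm"]})
                if arm.name != ref:
                    rows_ratio.append({"energy_keV": energy, "dose_mGy": dose,
                                       "fwhm_ratio": round_half_up(factor, 2)})
                for lbl in labels:
                    res = detectability_index(
                        m["ttf"][lbl], m["nps"],
                        TaskSpec(config.task_diameter_mm, m["dhu"][lbl]),
                        correction=factor)
                    dprimes[(arm.name, energy, dose, lbl)] = res.d_prime
                    spf2_curves[_condition_label(arm.name, energy, dose, lbl)] = res.spf2
                    rows_f50.append({"arm": arm.name, "energy_keV": energy,
                                     "dose_mGy": dose, "contrast": lbl,
                                     "f50_mm": m["ttf"][lbl].f50})
                    rows_dhu.append({"arm": arm.name, "energy_keV": energy,
                                     "dose_mGy": dose, "contrast": lbl,
                                     "delta_hu": m["dhu"][lbl]})

    test, base = config.test_arm.name, config.baseline_arm.name
    for energy in config.energies:
        for dose in config.doses:
            for lbl in labels:
                dt = dprimes[(test, energy, dose, lbl)]
                db = dprimes[(base, energy, dose, lbl)]
                rows_dp.append({"energy_keV": energy, "dose_mGy": dose,
                                "contrast": lbl, test: dt, base: db})
                rows_inc.append({"energy_keV": energy, "dose_mGy": dose,
                                 "contrast": lbl,
                                 "pct_increase": percentage_increase(dt, db)})

    return ComparisonReport(
        f50_table=pd.DataFrame(rows_f50), fwhm_table=pd.DataFrame(rows_fwhm),
        ratio_table=pd.DataFrame(rows_ratio),
        delta_hu_table=pd.DataFrame(rows_dhu),
        dprime_table=pd.DataFrame(rows_dp),
        increase_table=pd.DataFrame(rows_inc),
        spf2_curves=spf2_curves, log=log, seed=config.seed)
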
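"""End-to-end study pipeline: simulate a cohort to disk, then analyze it.

``simulate_study`` writes a complete synthetic data set (cohort CSV,
per-animal cine loops with ROI masks, strain acquisitions) emulating a
three-arm antiangiogenic-interruption experiment:

* group 1 — placebo throughout;
* group 2 — drug on days 0-4, interrupted, resumed on days 9-12;
* group 3 — drug on days 0-4, then stopped definitively (rebound).

``run_study`` consumes those files with the quantification modules and
produces a report table (per-group median/range for every endpoint and
timepoint) plus a JSON summary with the between-group tests.  Deltas
are computed per animal and then summarized (median-of-deltas).  Both
steps are pure functions of (config, seed), so a rerun writes
byte-identical outputs.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .cohort import (
    group_summary,
    kruskal_wallis,
    mann_whitney,
    percent_delta,
    spearman,
    tumor_volume,
    wilcoxon_signed_rank,
)
from .compression import CompressionLaw
from .dte import compute_dte, detect_flash, roi_tic
from .elastography import analyze_pair
from .errors import ParameterError, StudyDataError
from .perfusion import score_exam
from .synthetic_data import (
    GrowthParams,
    KineticParams,
    TreatmentSchedule,
    make_phantom,
    render_cine,
    simulate_growth_cohort,
    simulate_strain_pair,
)
from .containers import StrainPair

log = logging.getLogger("mbceus.study")

__all__ = ["default_config", "simulate_study", "run_study"]

GROUPS = ("1", "2", "3")

#: Observed per-animal non-enhanced percentages by group and exam used as
#: generator defaults (first and second targeted-CEUS exam).
OBSERVED_NON_ENHANCED = {
    "5": {"1": [20, 0, 30, 10], "2": [0, 30, 0, 30, 20, 0], "3": [30, 10, 30, 0]},
    "13": {"1": [20, 20, 50, 40], "2": [0, 30, 10, 20, 40, 0], "3": [10, 0, 10, 0]},
}

#: Group-median elasticity ratios at the two elastography sessions.
OBSERVED_ELASTICITY = {
    "9": {"1": 1.34, "2": 1.10, "3": 1.14},
    "11": {"1": 1.15, "2": 1.33, "3": 1.08},
}


def default_config() -> dict:
    """Stated-world defaults for the synthetic three-arm study."""
    return {
        "n_per_group": {"1": 4, "2": 6, "3": 4},
        "volume_days": [0, 5, 9, 11, 13],
        "ceus_days": [5, 13],
        "elasto_days": [9, 11],
        "volume_delta_pairs": [[13, 0], [13, 5]],
        "image": {
            "shape": [48, 48],
            "tumor_radius": 15.0,
            "pad_rows": 6,
            "frame_rate_hz": 10.0,
            "pixel_size_mm": 0.1,
        },
        "law": {"dr_db": 40.0, "e_ref": 2000.0, "levels": 256},
        "kinetics": {},  # overrides for KineticParams defaults
        "growth": {},  # overrides for GrowthParams defaults
        "speckle_noise_sd": 0.10,
        # receptor density: group medians per exam day, lognormal per-animal
        # and per-day variation (bound signal ~ 217 a.u. per unit density)
        "receptor_density": {
            "medians": {
                "5": {"1": 1.35, "2": 0.88, "3": 0.61},
                "13": {"1": 1.27, "2": 0.83, "3": 2.35},
            },
            "animal_sd": 0.30,
            "day_sd": 0.10,
        },
        "necrotic_fraction": {
            "percent": copy.deepcopy(OBSERVED_NON_ENHANCED),
        },
        "strain": {
            "ratio_medians": copy.deepcopy(OBSERVED_ELASTICITY),
            "animal_sd": 0.10,
            "day_sd": 0.02,
            "noise_sd": 0.05,
        },
        "reader_thresholds": [1.5, 2.5],
    }


def _merged_config(config: dict | None) -> dict:
    cfg = default_config()
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _schedules() -> dict:
    return {
        "1": TreatmentSchedule.placebo(),
        "2": TreatmentSchedule.interrupted(),
        "3": TreatmentSchedule.stopped(),
    }


def _animal_ids(cfg: dict) -> dict:
    return {
        gid: [f"g{gid}m{i + 1:02d}" for i in range(int(cfg["n_per_group"][gid]))]
        for gid in GROUPS
    }


def simulate_study(config: dict | None, seed: int, out_dir) -> Path:
    """Write a full synthetic study data set under ``out_dir``.

    Layout: ``cohort.csv``, ``manifest.json``, ``exams/`` (cine TIFF +
    JSON sidecar + ROI mask per animal and CEUS day), ``strain/``
    (float32 replicate stack + tumor/pad masks per animal and session).
    """
    cfg = _merged_config(config)
    out = Path(out_dir)
    (out / "exams").mkdir(parents=True, exist_ok=True)
    (out / "strain").mkdir(exist_ok=True)

    root = np.random.SeedSequence(seed)
    ss_cohort, ss_exams, ss_strain = root.spawn(3)

    schedules = _schedules()
    gp = GrowthParams(**cfg["growth"])
    cohort = simulate_growth_cohort(
        gp,
        [schedules[g] for g in GROUPS],
        [int(cfg["n_per_group"][g]) for g in GROUPS],
        days=cfg["volume_days"],
        seed=ss_cohort.generate_state(1)[0] % 2**31,
    )
    mio.write_cohort_csv(out / "cohort.csv", cohort)

    law = CompressionLaw.from_dict(cfg["law"])
    img = cfg["image"]
    ids = _animal_ids(cfg)

    # targeted-CEUS exams
    rho_cfg = cfg["receptor_density"]
    rng_rho = np.random.default_rng(ss_exams.generate_state(1)[0] % 2**31)
    exam_seeds = iter(ss_exams.spawn(sum(len(v) for v in ids.values()) * len(cfg["ceus_days"])))
    for gid in GROUPS:
        for i, animal in enumerate(ids[gid]):
            animal_factor = np.exp(rng_rho.normal(0.0, rho_cfg["animal_sd"]))
            for day in cfg["ceus_days"]:
                dkey = str(day)
                rho = (
                    rho_cfg["medians"][dkey][gid]
                    * animal_factor
                    * np.exp(rng_rho.normal(0.0, rho_cfg["day_sd"]))
                )
                frac_list = cfg["necrotic_fraction"]["percent"][dkey][gid]
                frac = frac_list[i % len(frac_list)] / 100.0
                phantom = make_phantom(
                    shape=tuple(img["shape"]),
                    tumor_radius=img["tumor_radius"],
                    necrotic_fraction=frac,
                    rho=rho,
                    pad_rows=img["pad_rows"],
                )
                kin = KineticParams(**cfg["kinetics"])
                cine = render_cine(
                    phantom,
                    kin,
                    law,
                    noise_sd=cfg["speckle_noise_sd"],
                    seed=next(exam_seeds).generate_state(1)[0] % 2**31,
                    frame_rate_hz=img["frame_rate_hz"],
                    pixel_size_mm=img["pixel_size_mm"],
                )
                stem = out / "exams" / f"{animal}_d{day}"
                mio.write_cine(stem.with_suffix(".tif"), cine)
                mio.write_mask(out / "exams" / f"{animal}_d{day}_roi.tif", phantom.tumor_mask)

    # strain sessions
    strain_cfg = cfg["strain"]
    rng_strain = np.random.default_rng(ss_strain.generate_state(1)[0] % 2**31)
    strain_seeds = iter(ss_strain.spawn(sum(len(v) for v in ids.values()) * len(cfg["elasto_days"])))
    mask_phantom = make_phantom(
        shape=tuple(img["shape"]),
        tumor_radius=img["tumor_radius"],
        necrotic_fraction=0.0,
        rho=0.0,
        pad_rows=img["pad_rows"],
    )
    mio.write_mask(out / "strain" / "tumor_mask.tif", mask_phantom.tumor_mask)
    mio.write_mask(out / "strain" / "pad_mask.tif", mask_phantom.pad_mask)
    for gid in GROUPS:
        for animal in ids[gid]:
            animal_factor = np.exp(rng_strain.normal(0.0, strain_cfg["animal_sd"]))
            for day in cfg["elasto_days"]:
                dkey = str(day)
                ratio = (
                    strain_cfg["ratio_medians"][dkey][gid]
                    * animal_factor
                    * np.exp(rng_strain.normal(0.0, strain_cfg["day_sd"]))
                )
                pair = simulate_strain_pair(
                    ratio,
                    strain_cfg["noise_sd"],
                    mask_phantom,
                    seed=next(strain_seeds).generate_state(1)[0] % 2**31,
                )
                mio.write_strain(out / "strain" / f"{animal}_d{day}.tif", pair.strains)

    manifest = {"seed": int(seed), "config": cfg, "animals": ids}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def _per_animal_volumes(cohort: pd.DataFrame, cfg: dict, ids: dict) -> dict:
    """{animal: {day: volume}}, erroring on any missing record."""
    volumes: dict = {}
    index = {(r.animal_id, int(r.day)): r for r in cohort.itertuples()}
    gaps = []
    for gid in GROUPS:
        for animal in ids[gid]:
            volumes[animal] = {}
            for day in cfg["volume_days"]:
                rec = index.get((animal, int(day)))
                if rec is None:
                    gaps.append(f"{animal} day {day}")
                    continue
                volumes[animal][int(day)] = tumor_volume(
                    rec.height_mm, rec.width_mm, rec.thickness_mm
                )
    if gaps:
        raise StudyDataError("missing cohort records: " + ", ".join(gaps))
    return volumes


def _summaries(per_group: dict) -> dict:
    return {
        gid: vars(group_summary(vals)) for gid, vals in per_group.items() if len(vals) > 0
    }


def _test_result_dict(res) -> dict:
    return {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "method": res.method,
    }


def run_study(data_dir, out_dir) -> dict:
    """Analyze a simulated (or equivalently structured) study directory.

    Returns the summary dict; writes ``report.csv`` and
    ``summary.json`` under ``out_dir``.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(data / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = manifest["config"]
    ids = manifest["animals"]
    law = CompressionLaw.from_dict(cfg["law"])

    cohort = mio.read_cohort_csv(data / "cohort.csv")
    volumes = _per_animal_volumes(cohort, cfg, ids)

    endpoints: dict = {}  # endpoint -> timepoint -> group -> {animal: value}

    def put(endpoint, timepoint, gid, animal, value):
        endpoints.setdefault(endpoint, {}).setdefault(timepoint, {}).setdefault(gid, {})[
            animal
        ] = value

    for gid in GROUPS:
        for animal in ids[gid]:
            for day in cfg["volume_days"]:
                put("volume", f"d{day}", gid, animal, volumes[animal][int(day)])
            for final, start in cfg["volume_delta_pairs"]:
                put(
                    "volume_delta",
                    f"d{final}_vs_d{start}",
                    gid,
                    animal,
                    percent_delta(volumes[animal][int(start)], volumes[animal][int(final)]),
                )

    # targeted CEUS: dTE and non-enhanced fraction per exam
    missing = []
    for gid in GROUPS:
        for animal in ids[gid]:
            dte_by_day = {}
            for day in cfg["ceus_days"]:
                cine_path = data / "exams" / f"{animal}_d{day}.tif"
                roi_path = data / "exams" / f"{animal}_d{day}_roi.tif"
                if not cine_path.exists() or not roi_path.exists():
                    missing.append(f"{animal} day {day} exam")
                    continue
                cine = mio.read_cine(cine_path)
                roi = mio.read_mask(roi_path)
                flash = detect_flash(cine)
                tic = roi_tic(cine, roi, law)
                tic.flash = flash
                res = compute_dte(tic)
                dte_by_day[int(day)] = res.dte
                put("dte", f"d{day}", gid, animal, res.dte)
                _, cons, _ = score_exam(
                    cine, roi, law, threshold_factors=tuple(cfg["reader_thresholds"])
                )
                put("non_enhanced_pct", f"d{day}", gid, animal, float(cons))
            if len(cfg["ceus_days"]) == 2:
                d0, d1 = (int(d) for d in cfg["ceus_days"])
                if d0 in dte_by_day and d1 in dte_by_day and dte_by_day[d0] > 0:
                    put(
                        "dte_delta",
                        f"d{d1}_vs_d{d0}",
                        gid,
                        animal,
                        percent_delta(dte_by_day[d0], dte_by_day[d1]),
                    )
    if missing:
        raise StudyDataError("missing exam files: " + ", ".join(missing))

    # elastography
    tumor_mask = mio.read_mask(data / "strain" / "tumor_mask.tif")
    pad_mask = mio.read_mask(data / "strain" / "pad_mask.tif")
    for gid in GROUPS:
        for animal in ids[gid]:
            ratio_by_day = {}
            for day in cfg["elasto_days"]:
                spath = data / "strain" / f"{animal}_d{day}.tif"
                if not spath.exists():
                    raise StudyDataError(f"missing strain acquisition: {animal} day {day}")
                pair = StrainPair(mio.read_strain(spath), tumor_mask, pad_mask)
                res = analyze_pair(pair)
                ratio_by_day[int(day)] = res.mean_ratio
                put("elasticity", f"d{day}", gid, animal, res.mean_ratio)
            if len(cfg["elasto_days"]) == 2:
                d0, d1 = (int(d) for d in cfg["elasto_days"])
                put(
                    "elasticity_delta",
                    f"d{d1}_vs_d{d0}",
                    gid,
                    animal,
                    percent_delta(ratio_by_day[d0], ratio_by_day[d1]),
                )

    # summaries
    rows = []
    summary: dict = {"endpoints": {}, "tests": {}}
    for endpoint in sorted(endpoints):
        summary["endpoints"][endpoint] = {}
        for timepoint in sorted(endpoints[endpoint]):
            per_group = {
                gid: list(vals.values())
                for gid, vals in sorted(endpoints[endpoint][timepoint].items())
            }
            summ = _summaries(per_group)
            summary["endpoints"][endpoint][timepoint] = summ
            for gid, s in summ.items():
                rows.append({"endpoint": endpoint, "timepoint": timepoint, "group": gid, **s})
    report = pd.DataFrame(rows)[
        ["endpoint", "timepoint", "group", "n", "median", "range_low", "range_high"]
    ]
    report = report.sort_values(["endpoint", "timepoint", "group"], kind="stable")

    # between-group and within-group tests
    n_animals = sum(len(v) for v in ids.values())
    if n_animals < 3:
        log.warning("fewer than 3 animals: group tests skipped")
    else:
        tests: dict = {}
        for endpoint in sorted(endpoints):
            for timepoint in sorted(endpoints[endpoint]):
                groups = [
                    list(vals.values())
                    for _, vals in sorted(endpoints[endpoint][timepoint].items())
                    if len(vals) > 0
                ]
                if len(groups) >= 2 and sum(len(g) for g in groups) >= 3:
                    res = kruskal_wallis(groups)
                    tests[f"kruskal:{endpoint}:{timepoint}"] = _test_result_dict(res)
        # pairwise comparisons of dTE at the final targeted-CEUS exam
        if "dte" in endpoints and cfg["ceus_days"]:
            last = f"d{cfg['ceus_days'][-1]}"
            by_group = endpoints["dte"].get(last, {})
            for ga, gb in (("1", "3"), ("2", "3"), ("1", "2")):
                if len(by_group.get(ga, {})) and len(by_group.get(gb, {})):
                    res = mann_whitney(
                        list(by_group[ga].values()), list(by_group[gb].values())
                    )
                    tests[f"mannwhitney:dte:{last}:g{ga}_vs_g{gb}"] = _test_result_dict(res)
        # within-group change in dTE across the two exams
        if "dte" in endpoints and len(cfg["ceus_days"]) == 2:
            t0, t1 = (f"d{d}" for d in cfg["ceus_days"])
            for gid in GROUPS:
                a = endpoints["dte"].get(t0, {}).get(gid, {})
                b = endpoints["dte"].get(t1, {}).get(gid, {})
                shared = sorted(set(a) & set(b))
                if len(shared) >= 3:
                    try:
                        res = wilcoxon_signed_rank(
                            [a[k] for k in shared], [b[k] for k in shared]
                        )
                        tests[f"wilcoxon:dte:{gid}:{t0}_vs_{t1}"] = _test_result_dict(res)
                    except ParameterError:
                        pass
        # correlation of dTE change with volume change
        if "dte_delta" in endpoints and "volume_delta" in endpoints:
            dd = next(iter(endpoints["dte_delta"].values()))
            vd = endpoints["volume_delta"].get("d13_vs_d5")
            if vd is not None:
                flat_d = {a: v for g in dd.values() for a, v in g.items()}
                flat_v = {a: v for g in vd.values() for a, v in g.items()}
                shared = sorted(set(flat_d) & set(flat_v))
                if len(shared) >= 4:
                    res = spearman(
                        [flat_d[a] for a in shared], [flat_v[a] for a in shared]
                    )
                    tests["spearman:dte_delta_vs_volume_delta"] = _test_result_dict(res)
        summary["tests"] = tests

    report.to_csv(out / "report.csv", index=False, float_format="%.6g")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
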
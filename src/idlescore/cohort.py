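"""Synthetic stage IA NSCLC screening cohorts.

Generates patients with the statistical structure the downstream analysis
assumes: a latent progression risk that mixes a CT-platform signal (lesion
solidity, intensity skewness, high-intensity clustering), a tissue-platform
signal (tumor grade, invasive size), and a cross-platform interaction term;
progression-free survival times from a Weibull proportional-hazards model on
that latent risk with independent exponential censoring and a 12-year
administrative cap; pathologist-style ROI reading tables; and CT phantom
volumes with the planted lesions.

The defaults emulate the scale of a resected stage IA screening cohort:
182 patients, ~30% progression over 12 years, ~6 annotated ROIs on 2-3
slides per patient, invasive sizes <= 30 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct.volume import Volume3D
from .phantom import (CLEARANCE_MM, LesionParams, add_lesion,
                      generate_ct_volume, gross_box)

DIAGNOSES = ("AIS", "invasive adenocarcinoma", "carcinoid", "large-cell", "squamous")
LOBE_NAMES = ("rul", "rml", "rll", "lul", "lll")
MAX_INTERVAL_DAYS = 730      # surgery within 2 years of the last screening CT
MAX_INVASIVE_SIZE_MM = 30.0  # largest pathological invasive size no greater than 30 mm


class CohortSpecError(ValueError):
    """Invalid cohort specification."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_sizes`` are the log-hazard coefficients of the standardized
    CT-platform signal, tissue-platform signal, and their product in the
    latent risk.  ``censoring_rate`` is an exponential dropout hazard
    (1/years) on top of the administrative follow-up cap.
    """

    n_patients: int = 182
    progression_fraction: float = 0.30
    effect_sizes: dict = field(default_factory=lambda: {
        "ct_signal": 0.5, "tissue_signal": 0.5, "interaction_signal": 1.0})
    censoring_rate: float = 0.05
    followup_cap: float = 12.0
    voxel_spacing: tuple = (0.5, 0.5, 0.5)
    volume_shape: tuple = (96, 96, 96)
    seed: int = 0
    weibull_shape: float = 1.1
    risk_noise_sd: float = 0.25
    cause_fractions: dict = field(default_factory=lambda: {
        "local_recurrence": 0.4, "distant_metastasis": 0.4, "lung_cancer_death": 0.2})

    def validate(self) -> None:
        if self.n_patients < 2:
            raise CohortSpecError("n_patients must be >= 2")
        if not 0.0 <= self.progression_fraction <= 1.0:
            raise CohortSpecError("progression_fraction must be in [0, 1]")
        if any(s <= 0 for s in self.voxel_spacing):
            raise CohortSpecError("voxel spacing must be positive")
        if self.censoring_rate < 0 or self.followup_cap <= 0:
            raise CohortSpecError("censoring_rate must be >= 0 and followup_cap > 0")
        missing = {"ct_signal", "tissue_signal", "interaction_signal"} - set(self.effect_sizes)
        if missing:
            raise CohortSpecError(f"effect_sizes missing {sorted(missing)}")
        if abs(sum(self.cause_fractions.values()) - 1.0) > 1e-9:
            raise CohortSpecError("cause_fractions must sum to 1")


@dataclass
class VolumeBundle:
    """One patient's phantom: CT volume, primary-lesion mask, gross box, and
    the per-lesion lung summary table."""
    volume: Volume3D
    lesion_mask: np.ndarray
    gross_box: tuple
    lesion_table: pd.DataFrame


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    patients: pd.DataFrame
    outcomes: pd.DataFrame
    roi_readings: pd.DataFrame
    ground_truth: pd.DataFrame
    volumes: dict  # patient_id -> VolumeBundle (empty when volumes were skipped)

    def write_tables(self, outdir, include_volumes: bool = False) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.roi_readings.to_csv(out / "roi_readings.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        if include_volumes:
            for pid, bundle in self.volumes.items():
                bundle.volume.to_nifti(out / f"{pid}_ct.nii.gz")
                Volume3D(bundle.lesion_mask.astype(float), bundle.volume.spacing,
                         bundle.volume.origin).to_nifti(out / f"{pid}_mask.nii.gz")


def _lobe_of(center_vox, shape) -> str:
    x, _, z = center_vox
    if x <= shape[0] / 2.0:  # synthetic convention: low first axis = right lung
        band = z / shape[2]
        return "rll" if band < 1 / 3 else ("rml" if band < 2 / 3 else "rul")
    return "lll" if z < shape[2] / 2.0 else "lul"


def _calibrate_weibull_scale(etas, shape_k, cens_rate, cap, target) -> float:
    """Scale of the Weibull baseline such that the expected observed-event
    fraction matches ``target`` under exponential censoring and the cap."""
    if target <= 0:
        return 1e9
    t = np.linspace(1e-6, cap, 512)

    def event_fraction(lam):
        # f_T(t) = (k/lam)(t/lam)^(k-1) e^eta exp(-(t/lam)^k e^eta)
        out = 0.0
        for eta in etas:
            h = (shape_k / lam) * (t / lam) ** (shape_k - 1) * np.exp(eta)
            s = np.exp(-((t / lam) ** shape_k) * np.exp(eta))
            out += np.trapezoid(h * s * np.exp(-cens_rate * t), t)
        return out / len(etas)

    lo, hi = 1e-2, 1e4
    if event_fraction(lo) < target:
        return lo
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if event_fraction(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _diameter_cap_mm(spec: CohortSpec) -> float:
    # leave room for the boundary clearance plus the +/-1 mm center jitter
    extent = min(n * s for n, s in zip(spec.volume_shape, spec.voxel_spacing))
    cap = min(0.42 * extent, extent - 2 * CLEARANCE_MM - 3.0)
    if cap < 5.0:
        raise CohortSpecError("volume_shape too small to host eligible lesions")
    return cap


def generate_cohort(spec: CohortSpec, include_volumes: bool = True) -> SyntheticCohort:
    """Generate a complete synthetic cohort.

    Deterministic for a fixed ``spec.seed``; the tabular outputs are
    identical whether or not volumes are generated (separate random
    streams).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_tab, ss_vol = root.spawn(2)
    rng = np.random.default_rng(ss_tab)
    n = spec.n_patients
    b = spec.effect_sizes

    pids = [f"P{i:04d}" for i in range(1, n + 1)]
    z_ct = rng.normal(size=n)
    z_ti = rng.normal(size=n)
    latent = (b["ct_signal"] * z_ct + b["tissue_signal"] * z_ti
              + b["interaction_signal"] * z_ct * z_ti
              + rng.normal(0.0, spec.risk_noise_sd, size=n))

    # lesion morphology driven by the CT-platform signal
    d_cap = _diameter_cap_mm(spec)
    solidity = np.clip(0.65 + 0.15 * z_ct + 0.08 * rng.normal(size=n), 0.30, 1.0)
    skewness = np.clip(0.45 + 0.25 * z_ct + 0.15 * rng.normal(size=n), 0.0, 0.90)
    clusters = np.minimum(rng.poisson(np.exp(0.1 + 0.45 * z_ct)), 4)
    diameter = np.clip(rng.lognormal(np.log(9.0), 0.35, size=n), 5.0, d_cap)

    roi_rows = []
    largest_invasive = np.zeros(n)
    for i, pid in enumerate(pids):
        n_slides = int(rng.integers(2, 4))
        n_rois = int(np.clip(rng.poisson(5.0) + 1, 1, 10))
        slide_ids = [f"{pid}_S{k+1}" for k in range(n_slides)]
        for r in range(n_rois):
            region = rng.choice(["invasive tumor", "pre-malignant", "nontumor"],
                                p=[0.75, 0.10, 0.15])
            diag, grade, dim = "", "", 0.0
            if region == "invasive tumor":
                w = np.array([0.20 * np.exp(-0.7 * z_ti[i]), 0.45, 0.03,
                              0.22 * np.exp(0.15 * z_ti[i]), 0.10])
                diag = rng.choice(DIAGNOSES, p=w / w.sum())
                if rng.random() < 0.02:
                    grade = "GX"
                else:
                    g_star = z_ti[i] + 0.8 * rng.normal()
                    grade = str(1 + int(np.searchsorted([-1.0, 0.8, 2.0], g_star)))
                if diag != "AIS":
                    dim = float(np.clip(rng.lognormal(np.log(7.0) + 0.30 * z_ti[i], 0.45),
                                        1.0, MAX_INVASIVE_SIZE_MM - 0.5))
            elif region == "pre-malignant":
                diag, grade = "AIS", ""
            roi_rows.append({
                "patient_id": pid,
                "slide_id": slide_ids[int(rng.integers(0, n_slides))],
                "roi_id": f"{pid}_R{r+1}",
                "region_class": region,
                "diagnosis": diag,
                "grade": grade,
                "invasive_dimension_mm": dim,
            })
        dims = [row["invasive_dimension_mm"] for row in roi_rows
                if row["patient_id"] == pid]
        largest_invasive[i] = max(max(dims), 1.0)
    roi_readings = pd.DataFrame(roi_rows)

    # delayed diagnosis is mildly more common in high-risk patients
    latent_std = (latent - latent.mean()) / max(latent.std(), 1e-12)
    days = np.clip(rng.lognormal(np.log(140.0) + 0.15 * latent_std, 0.75), 5, 1400)
    stage = np.where(largest_invasive <= 10, "T1a",
                     np.where(largest_invasive <= 20, "T1b", "T1c"))
    patients = pd.DataFrame({
        "patient_id": pids,
        "age_at_surgery": np.round(rng.normal(65.0, 5.0, size=n), 1),
        "sex": rng.choice(["M", "F"], size=n, p=[0.55, 0.45]),
        "smoke_pack_years": np.round(np.clip(rng.normal(66.0, 30.0, size=n), 10, 200), 1),
        "received_surgery": True,
        "surgery_type": rng.choice(["lobectomy", "sublobar"], size=n, p=[0.84, 0.16]),
        "residual_disease": rng.choice(["R0", "R1"], size=n, p=[0.97, 0.03]),
        "lymphadenectomy": rng.random(n) < 0.90,
        "days_ldct_to_surgery": np.round(days).astype(int),
        "pathological_stage": stage,
        "largest_invasive_size": np.round(largest_invasive, 1),
        "chemotherapy": rng.random(n) < 0.03,
        "radiotherapy": rng.random(n) < 0.02,
    })

    # Weibull PH event times calibrated to the target observed-event fraction
    lam = _calibrate_weibull_scale(latent, spec.weibull_shape, spec.censoring_rate,
                                   spec.followup_cap, spec.progression_fraction)
    u = rng.uniform(size=n)
    t_event = lam * (-np.log(u) / np.exp(latent)) ** (1.0 / spec.weibull_shape)
    t_cens = (rng.exponential(1.0 / spec.censoring_rate, size=n)
              if spec.censoring_rate > 0 else np.full(n, np.inf))
    t_cens = np.minimum(t_cens, spec.followup_cap)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-4)
    event = (t_event <= t_cens).astype(int)
    causes = np.array(list(spec.cause_fractions))
    cause_p = np.array(list(spec.cause_fractions.values()))
    cause = np.where(event == 1,
                     rng.choice(causes, size=n, p=cause_p),
                     "")
    outcomes = pd.DataFrame({"patient_id": pids, "time": np.round(time, 4),
                             "event": event, "cause": cause})

    ground_truth = pd.DataFrame({
        "patient_id": pids, "latent_risk": latent, "z_ct": z_ct, "z_ti": z_ti,
        "solidity": solidity, "skewness": skewness,
        "cluster_count": clusters, "diameter_mm": diameter,
    })

    volumes = {}
    if include_volumes:
        for i, (pid, child) in enumerate(zip(pids, ss_vol.spawn(n))):
            volumes[pid] = _patient_volume(spec, child,
                                           LesionParams(float(diameter[i]),
                                                        float(solidity[i]),
                                                        float(skewness[i]),
                                                        int(clusters[i])))
    return SyntheticCohort(spec, patients, outcomes, roi_readings, ground_truth, volumes)


def _patient_volume(spec: CohortSpec, seed_seq, params: LesionParams) -> VolumeBundle:
    rng = np.random.default_rng(seed_seq)
    shape = tuple(spec.volume_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    extent = np.array(shape) * spacing
    jitter = rng.uniform(-1.0, 1.0, size=3)
    vol, mask = generate_ct_volume(params, tuple(spacing), shape, rng,
                                   center_mm=extent / 2.0 + jitter)
    rows = [{
        "lesion_id": "primary", "lobe": _lobe_of(np.array(shape) / 2.0, shape),
        "volume_mm3": float(mask.sum() * spacing.prod()),
        "mean_hu": float(vol.data[mask].mean()),
        "diameter_mm": params.diameter_mm,
    }]
    # secondary small nodules elsewhere in the lung
    lung_semi = np.array(shape) * 0.38 * spacing
    for k in range(int(min(rng.poisson(0.7), 3))):
        d = float(rng.uniform(4.0, 7.0))
        sol = float(rng.uniform(0.2, 0.9))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        c = extent / 2.0 + direction * rng.uniform(0.45, 0.65) * lung_semi
        if np.linalg.norm(c - extent / 2.0) < (params.diameter_mm + d) / 2.0 + 5.0:
            continue
        p2 = LesionParams(d, sol, 0.2, 0)
        m2 = add_lesion(vol, p2, c, rng)
        rows.append({
            "lesion_id": f"secondary_{k+1}",
            "lobe": _lobe_of(c / spacing, shape),
            "volume_mm3": float(m2.sum() * spacing.prod()),
            "mean_hu": float(vol.data[m2].mean()),
            "diameter_mm": d,
        })
    box = gross_box(mask, spacing, margin_mm=10.0)
    return VolumeBundle(vol, mask, box, pd.DataFrame(rows))


def generate_pathology_readings(z_tissue, seed=0) -> pd.DataFrame:
    """ROI reading table for given tissue-platform signals (one per patient).

    Convenience wrapper used by tests that need the reading generator in
    isolation; patients are labelled P0001..  Distributions match
    :func:`generate_cohort`.
    """
    z_tissue = np.asarray(z_tissue, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(z_tissue)):
        pid = f"P{i+1:04d}"
        zt = z_tissue[i]
        n_slides = int(rng.integers(2, 4))
        n_rois = int(np.clip(rng.poisson(5.0) + 1, 1, 10))
        for r in range(n_rois):
            region = rng.choice(["invasive tumor", "pre-malignant", "nontumor"],
                                p=[0.75, 0.10, 0.15])
            diag, grade, dim = "", "", 0.0
            if region == "invasive tumor":
                w = np.array([0.20 * np.exp(-0.7 * zt), 0.45, 0.03,
                              0.22 * np.exp(0.15 * zt), 0.10])
                diag = rng.choice(DIAGNOSES, p=w / w.sum())
                if rng.random() < 0.02:
                    grade = "GX"
                else:
                    grade = str(1 + int(np.searchsorted([-1.0, 0.8, 2.0],
                                                        zt + 0.8 * rng.normal())))
                if diag != "AIS":
                    dim = float(np.clip(rng.lognormal(np.log(7.0) + 0.30 * zt, 0.45),
                                        1.0, MAX_INVASIVE_SIZE_MM - 0.5))
            elif region == "pre-malignant":
                diag, grade = "AIS", ""
            rows.append({"patient_id": pid,
                         "slide_id": f"{pid}_S{int(rng.integers(1, n_slides + 1))}",
                         "roi_id": f"{pid}_R{r+1}", "region_class": region,
                         "diagnosis": diag, "grade": grade,
                         "invasive_dimension_mm": dim})
    return pd.DataFrame(rows)


SELECTION_FILTERS = (
    "received primary lung tumor surgery",
    "pathologist readings available",
    "pathological stage IA",
    "largest invasive size <= 30 mm",
    "surgery within 2 years of last LDCT",
)


def apply_selection_criteria(patients: pd.DataFrame, roi_readings: pd.DataFrame):
    """Apply the five cohort eligibility filters sequentially.

    Returns ``(eligible_patients, report)`` where ``report`` is a
    CONSORT-style table with one row per filter (patients excluded by an
    earlier filter are not recounted).  Size exactly 30 mm and an interval of
    exactly 730 days are retained.
    """
    required = {"patient_id", "pathological_stage", "largest_invasive_size",
                "days_ldct_to_surgery"}
    missing = required - set(patients.columns)
    if missing:
        raise KeyError(f"patients table is missing required columns: {sorted(missing)}")
    if "patient_id" not in roi_readings.columns:
        raise KeyError("roi_readings table is missing 'patient_id'")

    current = patients.copy()
    report = []
    surgery = (current["received_surgery"].astype(bool)
               if "received_surgery" in current.columns
               else pd.Series(True, index=current.index))
    with_rois = current["patient_id"].isin(roi_readings["patient_id"])
    checks = [
        surgery,
        with_rois,
        current["pathological_stage"].isin(["T1a", "T1b", "T1c"]),
        current["largest_invasive_size"] <= MAX_INVASIVE_SIZE_MM,
        current["days_ldct_to_surgery"] <= MAX_INTERVAL_DAYS,
    ]
    keep = pd.Series(True, index=current.index)
    for name, ok in zip(SELECTION_FILTERS, checks):
        newly_excluded = int((keep & ~ok).sum())
        keep &= ok
        report.append({"filter": name, "n_excluded": newly_excluded,
                       "n_remaining": int(keep.sum())})
    return current[keep].reset_index(drop=True), pd.DataFrame(report)
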
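"""Synthetic data with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_plates` — qPCR plate tables.  Each plate carries
  triplicate High/Middle/Low/Blank calibrators, triplicate QC1/QC2 pools,
  triplicate negative controls and patient-sample wells whose true
  concentrations are lognormal.  The observed Ct of a well/assay is
  built from the assay's 4PL concentration-response evaluated at the
  (ten-fold prediluted) true concentration, anchored to the well's
  extension-control Ct, then perturbed by a per-plate run offset and
  Gaussian Ct-level noise.  Noise lives at the Ct level on purpose: the
  extension-control and calibrator normalization downstream then has real
  work to do, mirroring the qPCR measurement process.
* :func:`simulate_reference_assay` — paired measurements from a reference
  method with a log2-scale bias and noise, for value-reassignment and
  method-comparison tests.
* :func:`simulate_case_cohort` — exponential proportional-hazards survival
  data with administrative censoring, sampled under a case-cohort design
  (all cases plus roughly twice as many non-cases) with Barlow weights.

Every generator is deterministic for a given seed; the hidden truth
(concentrations, hazard coefficients) is returned so recovery tests can
close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_model import (
    ROLE_CAL_BLANK,
    ROLE_CAL_HIGH,
    ROLE_CAL_LOW,
    ROLE_CAL_MIDDLE,
    ROLE_NEG_CTRL,
    ROLE_QC1,
    ROLE_QC2,
    ROLE_SAMPLE,
    PanelConfig,
    PlateTable,
    ValidationError,
    WellRecord,
)
from .quantify import fourpl
from .risk_models import SurvivalCohort

#: Baseline extension-control Ct; an arbitrary realistic qPCR cycle count.
EXT_CTRL_CT = 17.0

#: Ct anchor: dCt = CT_ANCHOR - NPX_true, so more protein -> lower Ct.
CT_ANCHOR = 10.0

#: Calibrator true concentrations relative to the assay's inflection c:
#: High = 16 c, Middle = c, Low = c/16, Blank = 0 (spans the dynamic region).
CALIBRATOR_MULTIPLES = {
    ROLE_CAL_HIGH: 16.0,
    ROLE_CAL_MIDDLE: 1.0,
    ROLE_CAL_LOW: 1.0 / 16.0,
    ROLE_CAL_BLANK: 0.0,
}


@dataclass(frozen=True)
class SimAssayTruth:
    """Generative truth for one assay.

    ``fourpl`` is (a, d, c, b) of the NPX response; ``b < 0`` makes NPX rise
    with concentration as in PEA.  ``c`` is on the on-plate (prediluted)
    concentration scale.  Sample concentrations (neat scale) are
    lognormal(sample_logmean, sample_logsd) in natural-log parameters.
    """

    assay_id: str
    fourpl: tuple[float, float, float, float] = (10.0, 0.0, 50.0, -1.0)
    ct_noise_sd: float = 0.05
    sample_logmean: float = 6.0
    sample_logsd: float = 1.0
    qc1_conc: float = 300.0
    qc2_conc: float = 1500.0

    def __post_init__(self) -> None:
        a, d, c, _b = self.fourpl
        if not (a > d):
            raise ValidationError(f"{self.assay_id}: 4PL needs a > d, got a={a} d={d}")
        if not (c > 0):
            raise ValidationError(f"{self.assay_id}: 4PL needs c > 0")
        if self.ct_noise_sd < 0 or self.sample_logsd < 0:
            raise ValidationError(f"{self.assay_id}: noise SDs must be >= 0")

    def npx_true(self, plate_conc) -> np.ndarray:
        a, d, c, b = self.fourpl
        return fourpl(plate_conc, a, d, c, b)


def default_panel_truth(panel: PanelConfig, **overrides) -> list[SimAssayTruth]:
    """One SimAssayTruth per panel assay with staggered inflections."""
    truths = []
    for i, a in enumerate(panel.assays):
        c = 50.0 * (2.0 ** (i % 5))
        truths.append(
            SimAssayTruth(
                assay_id=a.assay_id,
                fourpl=(10.0, 0.0, c, -1.0),
                sample_logmean=math.log(c * a.predilution_factor),
                qc1_conc=c * a.predilution_factor * 0.6,
                qc2_conc=c * a.predilution_factor * 3.0,
                **overrides,
            )
        )
    return truths


def simulate_plates(
    panel: PanelConfig,
    truth: list[SimAssayTruth],
    n_plates: int,
    n_samples_per_plate: int,
    run_offsets="random",
    seed: int = 0,
    sample_concs: dict[str, np.ndarray] | None = None,
    run_offset_sd: float = 0.5,
) -> tuple[PlateTable, pd.DataFrame]:
    """Generate plate tables plus the hidden true concentrations.

    ``run_offsets``: per-plate Ct shifts applied to *every* Ct of the plate
    including the extension control and calibrators ("random" draws them
    N(0, run_offset_sd)).  ``sample_concs`` optionally fixes the neat-scale
    true sample concentrations per assay (length ``n_samples_per_plate``,
    reused on every plate) instead of lognormal draws.

    Returns the :class:`PlateTable` and a truth table with columns
    ``plate_id, well_id, sample_id, assay_id, true_conc`` (neat scale).
    """
    if n_plates < 1:
        raise ValidationError("n_plates must be >= 1")
    truth_by_id = {t.assay_id: t for t in truth}
    missing = [a for a in panel.assay_ids if a not in truth_by_id]
    if missing:
        raise ValidationError(f"no simulation truth for assays: {missing}")
    rng = np.random.default_rng(seed)

    if isinstance(run_offsets, str) and run_offsets == "random":
        offsets = rng.normal(0.0, run_offset_sd, size=n_plates)
    else:
        offsets = np.broadcast_to(np.asarray(run_offsets, dtype=float), (n_plates,))

    wells: list[WellRecord] = []
    truth_rows: list[dict] = []
    control_layout = (
        [(ROLE_CAL_HIGH, 3), (ROLE_CAL_MIDDLE, 3), (ROLE_CAL_LOW, 3),
         (ROLE_CAL_BLANK, 3), (ROLE_QC1, 3), (ROLE_QC2, 3), (ROLE_NEG_CTRL, 3)]
    )
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        off = float(offsets[p])
        well_no = 0

        def add_well(role: str, sample_id: str, conc_neat: dict[str, float]) -> None:
            nonlocal well_no
            well_no += 1
            well_id = f"W{well_no:03d}"
            ext = EXT_CTRL_CT + off
            ct: dict[str, float] = {}
            for aid in panel.assay_ids:
                t = truth_by_id[aid]
                pf = panel.assay(aid).predilution_factor
                x_neat = conc_neat[aid]
                # calibrators / controls live on the plate scale already
                x_plate = x_neat / pf if role in (ROLE_SAMPLE, ROLE_QC1, ROLE_QC2) else x_neat
                npx_t = float(t.npx_true(x_plate))
                dct = CT_ANCHOR - npx_t
                noise = rng.normal(0.0, t.ct_noise_sd) if t.ct_noise_sd > 0 else 0.0
                ct[aid] = ext + dct + noise
                truth_rows.append({
                    "plate_id": plate_id, "well_id": well_id, "sample_id": sample_id,
                    "role": role, "assay_id": aid, "true_conc": x_neat,
                    "true_conc_plate": x_plate,
                })
            wells.append(WellRecord(plate_id=plate_id, well_id=well_id, role=role,
                                    sample_id=sample_id, ext_ctrl_ct=ext, ct=ct))

        for role, n_rep in control_layout:
            for _ in range(n_rep):
                conc = {}
                for aid in panel.assay_ids:
                    t = truth_by_id[aid]
                    c = t.fourpl[2]
                    if role in CALIBRATOR_MULTIPLES:
                        conc[aid] = c * CALIBRATOR_MULTIPLES[role]
                    elif role == ROLE_QC1:
                        conc[aid] = t.qc1_conc
                    elif role == ROLE_QC2:
                        conc[aid] = t.qc2_conc
                    else:  # negative control: background, no antigen
                        conc[aid] = 0.0
                add_well(role, "", conc)

        for s in range(n_samples_per_plate):
            sample_id = f"S{p + 1:02d}_{s + 1:03d}"
            conc = {}
            for aid in panel.assay_ids:
                t = truth_by_id[aid]
                if sample_concs is not None and aid in sample_concs:
                    conc[aid] = float(np.asarray(sample_concs[aid], dtype=float)[s])
                else:
                    conc[aid] = float(rng.lognormal(t.sample_logmean, t.sample_logsd))
            add_well(ROLE_SAMPLE, sample_id, conc)

    table = PlateTable(panel=panel, wells=wells)
    truth_df = pd.DataFrame(truth_rows)
    truth_df.attrs["seed"] = seed
    return table, truth_df


def extract_standards(
    npx_values: pd.DataFrame, truth_df: pd.DataFrame, assay_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a standard-curve dataset from simulated plates.

    Sample wells paired with their true on-plate concentrations (from the
    simulator's truth table) plus blank-calibrator wells at concentration 0,
    ready for :func:`peaquant.quantify.fit_4pl`.
    """
    sub = npx_values[npx_values["assay_id"] == assay_id]
    samp = sub[sub["role"] == ROLE_SAMPLE]
    tt = truth_df[truth_df["assay_id"] == assay_id]
    merged = samp.merge(
        tt[["plate_id", "well_id", "true_conc_plate"]], on=["plate_id", "well_id"]
    )
    blanks = sub[sub["role"] == ROLE_CAL_BLANK]
    conc = np.concatenate([merged["true_conc_plate"].to_numpy(float), np.zeros(len(blanks))])
    npx = np.concatenate([merged["npx"].to_numpy(float), blanks["npx"].to_numpy(float)])
    return conc, npx


def simulate_reference_assay(
    truth_conc, bias_log2: float = 0.0, noise_log2_sd: float = 0.0, seed: int = 0
):
    """Reference-method measurements: ``truth * 2**(bias + N(0, sd))``.

    ``truth_conc`` may be an array of positive concentrations or a DataFrame
    with a ``true_conc`` column (returned with an added ``reference_conc``).
    """
    if noise_log2_sd < 0:
        raise ValidationError("noise_log2_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(truth_conc, pd.DataFrame):
        vals = truth_conc["true_conc"].to_numpy(dtype=float)
    else:
        vals = np.asarray(truth_conc, dtype=float)
    if np.any(vals <= 0):
        raise ValidationError("true concentrations must be positive")
    noise = rng.normal(0.0, noise_log2_sd, size=vals.shape) if noise_log2_sd > 0 else 0.0
    ref = vals * 2.0 ** (bias_log2 + noise)
    if isinstance(truth_conc, pd.DataFrame):
        out = truth_conc.copy()
        out["reference_conc"] = ref
        return out
    return ref


# ---------------------------------------------------------------------------
# Case-cohort survival data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimCohortTruth:
    """Generative truth for the survival cohort.

    Exponential event times with hazard ``baseline_hazard * exp(x' log_hr)``,
    administratively censored at ``censor_time``; the case-cohort sample
    keeps all cases plus ``noncase_multiple`` times as many non-cases.
    """

    n_cohort: int = 5000
    baseline_hazard: float = 0.05
    log_hr: dict[str, float] = field(default_factory=dict)
    censor_time: float = 3.0
    noncase_multiple: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cohort <= 0:
            raise ValidationError("n_cohort must be > 0")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        if self.noncase_multiple <= 0:
            raise ValidationError("noncase_multiple must be > 0")


def default_covariate_spec() -> dict[str, tuple]:
    """Clinical-plus-biomarker covariates typical of a cardiovascular cohort."""
    return {
        "age": ("normal", 65.0, 9.0),
        "male": ("binary", 0.8),
        "bmi": ("normal", 28.0, 4.5),
        "smoker": ("binary", 0.2),
        "diabetes": ("binary", 0.35),
        "biomarker1": ("lognormal", 5.0, 1.0),
        "biomarker2": ("lognormal", 2.0, 0.8),
    }


def simulate_full_cohort(
    truth: SimCohortTruth, covariate_spec: dict[str, tuple], seed: int = 0
) -> pd.DataFrame:
    """The complete source cohort: covariates, event times, censoring."""
    rng = np.random.default_rng(seed)
    n = truth.n_cohort
    data: dict[str, np.ndarray] = {"subject_id": np.array([f"ID{i + 1:06d}" for i in range(n)])}
    for name, spec in covariate_spec.items():
        kind = spec[0]
        if kind == "normal":
            data[name] = rng.normal(spec[1], spec[2], size=n)
        elif kind == "binary":
            data[name] = rng.binomial(1, spec[1], size=n).astype(float)
        elif kind == "lognormal":
            data[name] = rng.lognormal(spec[1], spec[2], size=n)
        else:
            raise ValidationError(f"unknown covariate kind {kind!r} for {name}")
    unknown = set(truth.log_hr) - set(covariate_spec)
    if unknown:
        raise ValidationError(f"log_hr references unknown covariates: {sorted(unknown)}")
    eta = np.zeros(n)
    for name, beta in truth.log_hr.items():
        x = data[name]
        # biomarkers act on the log scale, as modelled downstream
        if covariate_spec[name][0] == "lognormal":
            x = np.log(x)
        eta = eta + beta * (x - np.mean(x))
    rate = truth.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    event = (t_event <= truth.censor_time).astype(int)
    time = np.minimum(t_event, truth.censor_time)
    df = pd.DataFrame(data)
    df["time"] = time
    df["event"] = event
    return df


def case_cohort_sample(
    full: pd.DataFrame, noncase_multiple: float = 2.0, seed: int = 0
) -> SurvivalCohort:
    """Case-cohort sampling with Barlow weights.

    Keeps every case, samples ``round(noncase_multiple * n_cases)`` of the
    non-cases at random, and weights sampled non-cases by the inverse
    sampling fraction (cases keep weight 1).
    """
    rng = np.random.default_rng(seed)
    cases = full[full["event"] == 1]
    noncases = full[full["event"] == 0]
    n_cases = len(cases)
    if n_cases == 0:
        raise ValidationError(
            "no cases simulated; increase n_cohort, baseline_hazard or censor_time"
        )
    m = min(int(round(noncase_multiple * n_cases)), len(noncases))
    pick = rng.choice(len(noncases), size=m, replace=False)
    sampled = noncases.iloc[np.sort(pick)]
    frac = m / len(noncases)
    out = pd.concat([cases, sampled], ignore_index=True)
    out["in_subcohort"] = np.concatenate([np.zeros(n_cases, bool), np.ones(m, bool)])
    out["weight"] = np.where(out["event"] == 1, 1.0, 1.0 / frac)
    return SurvivalCohort(out)


def simulate_case_cohort(
    truth: SimCohortTruth, covariate_spec: dict[str, tuple] | None = None, seed: int = 0
) -> tuple[SurvivalCohort, pd.DataFrame]:
    """Full pipeline: simulate the source cohort, then case-cohort sample it.

    Returns (case-cohort sample with weights, full source cohort) — the full
    cohort is the oracle for parameter-recovery tests.
    """
    spec = covariate_spec if covariate_spec is not None else default_covariate_spec()
    full = simulate_full_cohort(truth, spec, seed=seed)
    cohort = case_cohort_sample(full, truth.noncase_multiple, seed=seed + 1)
    return cohort, full
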
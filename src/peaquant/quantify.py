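"""Standard curves and absolute quantification.

The concentration-response of each assay is modelled by a four-parameter
logistic (4PL):

    NPX(x) = d + (a - d) / (1 + (x / c)^b)

with lower/upper plateaus ``d < a``, inflection concentration ``c`` and slope
``b``.  The sign of ``b`` sets the orientation: ``b < 0`` gives the
physically usual case for PEA, NPX rising from the blank background ``d``
toward the saturation plateau ``a`` as concentration grows (the ``(a, d, b)
-> (d, a, -b)`` substitution is an exact symmetry of the curve, so fits are
canonicalised to ``a > d``).

From a fitted curve the module derives:

* LOD — limit of detection, ``mean(blank NPX) + 3 * SD(blank NPX)`` mapped
  through the inverse curve to a concentration;
* LLOQ / ULOQ — the smallest and largest standard concentrations of a
  contiguous run where back-calculated accuracy and precision are both
  <= 30%;
* sample concentrations — inverse prediction of NPX, multiplied by the
  predilution factor to return to the neat-sample scale, with censoring
  flags for values outside the quantifiable range;
* value reassignment — a single multiplicative rescaling of the standard
  concentrations that aligns PEA quantification with a clinically validated
  reference assay, followed by a refit;
* censored lognormal imputation for below-LLOQ / above-ULOQ values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .plate_model import PanelConfig, ValidationError

log = logging.getLogger("peaquant")

FLAG_IN_RANGE = "in_range"
FLAG_BELOW_LLOQ = "below_lloq"
FLAG_ABOVE_ULOQ = "above_uloq"
FLAG_BELOW_LOD = "below_lod"

#: accuracy / precision acceptance bound for LLOQ/ULOQ (inclusive)
LOQ_THRESHOLD = 0.30


class FitError(RuntimeError):
    """4PL optimisation failed to converge after all restarts."""


# ---------------------------------------------------------------------------
# 4PL forward / inverse
# ---------------------------------------------------------------------------


def fourpl(x, a: float, d: float, c: float, b: float):
    """Evaluate the 4PL at concentration ``x >= 0`` (vectorised).

    At ``x = 0`` the limit is ``a`` for ``b > 0`` and ``d`` for ``b < 0``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x1 = np.atleast_1d(x)
    out = np.empty_like(x1)
    zero = x1 == 0
    out[zero] = a if b > 0 else d
    with np.errstate(over="ignore"):
        u = np.power(x1[~zero] / c, b)
    out[~zero] = d + (a - d) / (1.0 + u)
    return float(out[0]) if scalar else out


def fourpl_inverse(npx, a: float, d: float, c: float, b: float):
    """Inverse prediction ``x = c * ((a - d)/(npx - d) - 1)^(1/b)``.

    Valid on the open interval ``d < npx < a``; outside it returns NaN (the
    censoring signal, resolved by :func:`quantify_samples`).
    """
    npx = np.asarray(npx, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (a - d) / (npx - d) - 1.0
        x = np.where((npx > d) & (npx < a), c * np.power(ratio, 1.0 / b), np.nan)
    return x if x.ndim else float(x)


# ---------------------------------------------------------------------------
# Curve container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Fitted 4PL parameters plus detection/quantification limits.

    ``c`` is on the on-plate (prediluted) concentration scale; ``lod_conc``,
    ``lloq_conc`` and ``uloq_conc`` are on the reported neat-sample scale
    (multiplied by the predilution factor).  ``scale`` records any value
    reassignment applied; ``quantitative`` is False when no standard
    concentration passed the 30% accuracy/precision rule.
    """

    assay_id: str
    a: float
    d: float
    c: float
    b: float
    rss: float = math.nan
    n_points: int = 0
    lod_npx: float = math.nan
    lod_conc: float = math.nan
    lloq_conc: float = math.nan
    uloq_conc: float = math.nan
    scale: float = 1.0
    quantitative: bool = True

    def __post_init__(self) -> None:
        if not (self.a > self.d):
            raise ValidationError(f"{self.assay_id}: require a > d, got a={self.a} d={self.d}")
        if not (self.c > 0):
            raise ValidationError(f"{self.assay_id}: require c > 0, got {self.c}")
        if (
            math.isfinite(self.lod_conc)
            and math.isfinite(self.lloq_conc)
            and self.lod_conc > self.lloq_conc
        ):
            log.warning("%s: LOD %.4g above LLOQ %.4g", self.assay_id, self.lod_conc, self.lloq_conc)

    def predict(self, x):
        return fourpl(x, self.a, self.d, self.c, self.b)

    def invert(self, npx):
        return fourpl_inverse(npx, self.a, self.d, self.c, self.b)

    def to_row(self) -> dict:
        return {
            "assay_id": self.assay_id,
            "a": self.a,
            "d": self.d,
            "c": self.c,
            "b": self.b,
            "rss": self.rss,
            "n_points": self.n_points,
            "lod_npx": self.lod_npx,
            "lod": self.lod_conc,
            "lloq": self.lloq_conc,
            "uloq": self.uloq_conc,
            "scale": self.scale,
            "quantitative": self.quantitative,
        }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_4pl(conc, npx, assay_id: str = "") -> StandardCurve:
    """Least-squares 4PL fit of NPX against standard concentrations.

    ``conc`` may contain zeros (blank wells); those points inform the
    baseline plateau.  Requires at least five distinct concentrations
    including the blank.  Initialisation: baseline = mean blank NPX, the
    other plateau = the extreme NPX on the far side, ``c`` = geometric
    mid-concentration, slope from a small multi-start grid; the best
    converged restart by residual sum of squares wins.
    """
    conc = np.asarray(conc, dtype=float)
    npx = np.asarray(npx, dtype=float)
    keep = np.isfinite(conc) & np.isfinite(npx)
    conc, npx = conc[keep], npx[keep]
    if np.unique(conc).size < 5 or 0.0 not in conc:
        raise ValidationError(
            f"{assay_id or '4PL'}: need >=5 distinct concentrations including a blank"
        )
    if conc.size < 4:
        raise ValidationError("fewer points than parameters")

    pos = conc > 0
    logc = np.log(conc[pos])
    c0 = math.exp((logc.min() + logc.max()) / 2.0)
    blank_mean = float(np.mean(npx[~pos]))
    # orientation: does NPX rise or fall with concentration?
    rising = np.corrcoef(logc, npx[pos])[0, 1] >= 0
    if rising:
        d0, a0 = blank_mean, float(np.max(npx))
        b_grid = (-1.0, -0.5, -2.0)
    else:
        a0, d0 = blank_mean, float(np.min(npx))
        b_grid = (1.0, 0.5, 2.0)
    if a0 <= d0:
        a0 = d0 + 1.0

    def residuals(p):
        a, d, log_c, b = p
        return fourpl(conc, a, d, math.exp(log_c), b) - npx

    best = None
    for b0 in b_grid + tuple(-b for b in b_grid):
        try:
            sol = optimize.least_squares(
                residuals,
                x0=[a0, d0, math.log(c0), b0],
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=20000,
            )
        except Exception:  # singular Jacobian etc. -> try next start
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or rss < best[1]):
            best = (sol.x, rss)
        if best is not None and best[1] < 1e-20:
            break
    if best is None:
        raise FitError(f"{assay_id or '4PL'}: no restart converged")
    (a, d, log_c, b), rss = best
    if a < d:  # canonicalise via the exact (a,d,b)->(d,a,-b) symmetry
        a, d, b = d, a, -b
    return StandardCurve(
        assay_id=assay_id, a=float(a), d=float(d), c=float(math.exp(log_c)),
        b=float(b), rss=rss, n_points=int(conc.size),
    )


def invert_4pl(curve: StandardCurve, npx):
    """Inverse prediction on the on-plate concentration scale (NaN = censored)."""
    return curve.invert(npx)


# ---------------------------------------------------------------------------
# Detection and quantification limits
# ---------------------------------------------------------------------------


def determine_lod(curve: StandardCurve, blank_npx, predilution: float = 1.0) -> StandardCurve:
    """LOD = mean of blank replicates + 3 sample standard deviations (NPX),
    mapped through the inverse curve and scaled to the neat-sample scale.
    """
    blank_npx = np.asarray(blank_npx, dtype=float)
    blank_npx = blank_npx[np.isfinite(blank_npx)]
    if blank_npx.size < 2:
        raise ValidationError("need >=2 blank replicates for LOD")
    sd = float(np.std(blank_npx, ddof=1))
    lod_npx = float(np.mean(blank_npx)) + 3.0 * sd
    x = curve.invert(lod_npx)
    lod_conc = float(x) * predilution if math.isfinite(x) else math.nan
    return replace(curve, lod_npx=lod_npx, lod_conc=lod_conc)


def backcalc_accuracy_precision(curve: StandardCurve, conc, npx) -> pd.DataFrame:
    """Back-calculate replicate standards and summarise per nominal level.

    Returns one row per non-zero nominal concentration with ``accuracy``
    (absolute relative bias of the mean back-calculated concentration) and
    ``precision`` (CV of the back-calculated replicates); NaN when fewer
    than two replicates are invertible.
    """
    conc = np.asarray(conc, dtype=float)
    npx = np.asarray(npx, dtype=float)
    rows = []
    for nominal in np.unique(conc[conc > 0]):
        back = curve.invert(npx[conc == nominal])
        back = np.asarray(back)[np.isfinite(np.asarray(back))]
        if back.size < 2:
            rows.append({"nominal": nominal, "accuracy": np.nan, "precision": np.nan,
                         "n_replicates": int(back.size)})
            continue
        m = float(np.mean(back))
        rows.append({
            "nominal": float(nominal),
            "accuracy": abs(m - nominal) / nominal,
            "precision": float(np.std(back, ddof=1)) / m,
            "n_replicates": int(back.size),
        })
    return pd.DataFrame(rows).sort_values("nominal", ignore_index=True)


def determine_loq(curve: StandardCurve, conc, npx, predilution: float = 1.0) -> StandardCurve:
    """LLOQ/ULOQ from the <=30% accuracy-and-precision rule.

    Operates on the standard-curve concentration grid (no interpolation):
    the quantifiable range is the longest contiguous run of nominal
    concentrations whose back-calculated accuracy and precision are both
    <= 0.30; LLOQ and ULOQ are its endpoints on the neat-sample scale.
    When no level passes the curve is flagged non-quantitative.
    """
    summary = backcalc_accuracy_precision(curve, conc, npx)
    ok = (
        (summary["accuracy"] <= LOQ_THRESHOLD) & (summary["precision"] <= LOQ_THRESHOLD)
    ).fillna(False).to_numpy()
    # longest contiguous passing run
    best_start = best_len = 0
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j < len(ok) and ok[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if best_len == 0:
        log.warning("%s: no standard passes the 30%% rule; flagged non-quantitative",
                    curve.assay_id)
        return replace(curve, lloq_conc=math.nan, uloq_conc=math.nan, quantitative=False)
    lo = float(summary["nominal"].iloc[best_start]) * predilution
    hi = float(summary["nominal"].iloc[best_start + best_len - 1]) * predilution
    return replace(curve, lloq_conc=lo, uloq_conc=hi, quantitative=True)


# ---------------------------------------------------------------------------
# Value reassignment
# ---------------------------------------------------------------------------


def reassign_values(
    curve: StandardCurve,
    standards_conc,
    standards_npx,
    pea_conc,
    reference_conc,
    predilution: float = 1.0,
) -> tuple[StandardCurve, float]:
    """Rescale the standard-concentration axis to agree with a reference assay.

    ``pea_conc`` / ``reference_conc`` are paired neat-scale concentrations of
    samples measured by both methods; pairs outside the curve's
    [LLOQ, ULOQ] are excluded (logged).  The single multiplicative scale
    minimising the squared log2 difference is the geometric mean of
    ``reference / pea``; the 4PL is then refit on the rescaled standards and
    LOD/LLOQ/ULOQ rederived.
    """
    pea = np.asarray(pea_conc, dtype=float)
    ref = np.asarray(reference_conc, dtype=float)
    if pea.shape != ref.shape:
        raise ValidationError("pea and reference arrays must be paired")
    keep = np.isfinite(pea) & np.isfinite(ref) & (pea > 0) & (ref > 0)
    if math.isfinite(curve.lloq_conc) and math.isfinite(curve.uloq_conc):
        in_loq = (pea >= curve.lloq_conc) & (pea <= curve.uloq_conc)
        n_excl = int(np.sum(keep & ~in_loq))
        if n_excl:
            log.info("%s: excluded %d pairs outside [LLOQ, ULOQ]", curve.assay_id, n_excl)
        keep &= in_loq
    if int(keep.sum()) < 10:
        raise ValidationError(
            f"{curve.assay_id}: need >=10 in-range pairs for reassignment, "
            f"have {int(keep.sum())}"
        )
    scale = float(2.0 ** np.mean(np.log2(ref[keep] / pea[keep])))

    conc = np.asarray(standards_conc, dtype=float) * scale
    npx = np.asarray(standards_npx, dtype=float)
    new = fit_4pl(conc, npx, assay_id=curve.assay_id)
    new = replace(new, scale=curve.scale * scale, lod_npx=curve.lod_npx)
    if math.isfinite(curve.lod_npx):
        x = new.invert(curve.lod_npx)
        new = replace(new, lod_conc=float(x) * predilution if math.isfinite(x) else math.nan)
    new = determine_loq(new, conc, npx, predilution=predilution)
    return new, scale


# ---------------------------------------------------------------------------
# Sample quantification
# ---------------------------------------------------------------------------


def quantify_samples(
    npx_long: pd.DataFrame,
    curves: dict[str, StandardCurve],
    panel: PanelConfig,
) -> pd.DataFrame:
    """Invert NPX to neat-scale concentrations with censoring flags.

    ``npx_long`` needs columns ``sample_id, assay_id, npx`` (the NPXMatrix
    ``values`` frame qualifies).  Flags: NPX at or above the upper plateau
    -> ``above_uloq``; at or below the baseline -> ``below_lod``; otherwise
    the concentration is compared against LOD, LLOQ and ULOQ.
    """
    out_rows = []
    for aid, grp in npx_long.groupby("assay_id", sort=False):
        if aid not in curves:
            raise ValidationError(f"no standard curve for assay {aid}")
        cv = curves[aid]
        pf = panel.assay(str(aid)).predilution_factor
        npx = grp["npx"].to_numpy(dtype=float)
        conc = np.asarray(cv.invert(npx)) * pf
        flag = np.full(npx.shape, FLAG_IN_RANGE, dtype=object)
        flag[npx >= cv.a] = FLAG_ABOVE_ULOQ
        flag[npx <= cv.d] = FLAG_BELOW_LOD
        ok = np.isfinite(conc)
        if math.isfinite(cv.uloq_conc):
            flag[ok & (conc > cv.uloq_conc)] = FLAG_ABOVE_ULOQ
        if math.isfinite(cv.lloq_conc):
            flag[ok & (conc < cv.lloq_conc)] = FLAG_BELOW_LLOQ
        if math.isfinite(cv.lod_conc):
            flag[ok & (conc < cv.lod_conc)] = FLAG_BELOW_LOD
        sub = grp[[c for c in ("plate_id", "well_id", "sample_id") if c in grp.columns]].copy()
        sub["assay_id"] = aid
        sub["npx"] = npx
        sub["conc"] = conc
        sub["flag"] = flag
        out_rows.append(sub)
    return pd.concat(out_rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Censored lognormal imputation
# ---------------------------------------------------------------------------


def _censored_lognormal_mle(obs: np.ndarray, n_left: int, n_right: int,
                            lloq: float, uloq: float) -> tuple[float, float]:
    """ML estimate of (mu, sigma) of log-concentration with interval censoring."""
    y = np.log(obs)
    mu0, s0 = float(np.mean(y)), max(float(np.std(y, ddof=0)), 1e-3)

    def nll(p):
        mu, log_s = p
        s = math.exp(log_s)
        val = -np.sum(stats.norm.logpdf(y, mu, s))
        if n_left:
            val -= n_left * stats.norm.logcdf(math.log(lloq), mu, s)
        if n_right:
            val -= n_right * stats.norm.logsf(math.log(uloq), mu, s)
        return val

    res = optimize.minimize(nll, x0=[mu0, math.log(s0)], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
    mu, log_s = res.x
    return float(mu), float(math.exp(log_s))


def fit_censored_lognormal(values, flags, lloq: float, uloq: float) -> tuple[float, float]:
    """ML estimate of the lognormal (mu, sigma) of concentrations with
    left/right censoring at LLOQ/ULOQ (natural-log parameters).
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=object)
    left = np.isin(flags, (FLAG_BELOW_LLOQ, FLAG_BELOW_LOD))
    right = flags == FLAG_ABOVE_ULOQ
    obs = values[~(left | right)]
    obs = obs[np.isfinite(obs)]
    if obs.size == 0:
        raise ValidationError("all values censored; cannot fit the lognormal")
    if np.any(obs <= 0):
        raise ValidationError("uncensored concentrations must be positive")
    return _censored_lognormal_mle(obs, int(left.sum()), int(right.sum()), lloq, uloq)


def impute_censored(
    values,
    flags,
    lloq: float,
    uloq: float,
    seed: int,
) -> np.ndarray:
    """Replace censored concentrations by draws from a censored-ML lognormal.

    Below-LLOQ values (including below-LOD) are drawn from the fitted
    lognormal truncated above at the minimum observed uncensored value;
    above-ULOQ values are drawn truncated below at the ULOQ.  Uncensored
    values pass through untouched.  Deterministic for a given seed.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=object)
    left = np.isin(flags, (FLAG_BELOW_LLOQ, FLAG_BELOW_LOD))
    right = flags == FLAG_ABOVE_ULOQ
    obs_mask = ~(left | right)
    obs = values[obs_mask]
    obs = obs[np.isfinite(obs)]
    if obs.size == 0:
        raise ValidationError("all values censored; cannot fit the lognormal")
    if obs.size < 10:
        raise ValidationError(f"need >=10 uncensored values, have {obs.size}")
    if np.any(obs <= 0):
        raise ValidationError("uncensored concentrations must be positive")
    if not (left.any() or right.any()):
        return values.copy()

    mu, sigma = _censored_lognormal_mle(obs, int(left.sum()), int(right.sum()), lloq, uloq)
    rng = np.random.default_rng(seed)
    out = values.copy()
    if left.any():
        upper = float(np.min(obs))  # truncation bound: minimum observed value
        p_hi = stats.norm.cdf(math.log(upper), mu, sigma)
        u = rng.uniform(0.0, p_hi, size=int(left.sum()))
        out[left] = np.exp(stats.norm.ppf(u, mu, sigma))
    if right.any():
        p_lo = stats.norm.cdf(math.log(uloq), mu, sigma)
        u = rng.uniform(p_lo, 1.0, size=int(right.sum()))
        out[right] = np.exp(stats.norm.ppf(u, mu, sigma))
    return out
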
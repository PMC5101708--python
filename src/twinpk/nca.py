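"""Non-compartmental pharmacokinetic analysis (NCA).

Turns one concentration–time profile into the standard exposure
battery: terminal elimination rate constant λz (log-linear regression
over an adjusted-R²-selected trailing window), AUC by the
linear-up/log-down trapezoidal rule, AUC extrapolated to infinity from
the *predicted* concentration at the last quantifiable time, apparent
oral clearance Cl/F = dose/AUC∞, terminal half-life ln(2)/λz, and
Vz = dose/(λz·AUC∞).

Unit conventions (fixed): dose in mg, concentrations in µg/l, times in
hours; AUC reported in mg·min/l (1 µg·h/l = 0.06 mg·min/l), clearance
in l/min, Vz in litres (Vz = 60·Cl/F / λz for λz in 1/h).

BLQ (below limit of quantification) handling: pre-dose and pre-Cmax
BLQ samples are set to 0; an embedded or trailing BLQ after Cmax
truncates the profile at the last quantifiable point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationProfile",
    "TerminalFit",
    "PKParameters",
    "InsufficientTerminalData",
    "NonPositiveSlope",
    "ExtrapolationRequired",
    "estimate_lambda_z",
    "auc_partial",
    "auc_to_infinity",
    "compute_pk_parameters",
    "aggregate_occasions",
    "nca_table",
]

UGH_PER_L_TO_MGMIN_PER_L = 0.06  # 1 µg·h/l = 0.001 mg · 60 min / l


class InsufficientTerminalData(ValueError):
    """Fewer than 3 usable post-peak points for the terminal regression."""


class NonPositiveSlope(ValueError):
    """Best terminal window yields λz ≤ 0."""


class ExtrapolationRequired(ValueError):
    """Partial AUC requested beyond the last quantifiable sample."""


@dataclass(frozen=True)
class ConcentrationProfile:
    subject_id: str
    occasion: int
    dose_mg: float
    times_h: np.ndarray
    concentrations: np.ndarray  # µg/l; NaN where BLQ
    blq: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        q = np.asarray(self.blq, dtype=bool)
        order = np.argsort(t, kind="stable")
        t, c, q = t[order], c[order], q[order]
        if len(t) != len(c) or len(t) != len(q):
            raise ValueError("times, concentrations and blq must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"times must be strictly increasing ({self.subject_id})")
        if t[0] != 0.0:
            raise ValueError("first sampling time must be 0")
        if np.any(c[~q] < 0):
            raise ValueError("non-BLQ concentrations must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "blq", q)

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Working profile after BLQ handling: pre-Cmax BLQ → 0,
        post-Cmax BLQ truncates at the last quantifiable point."""
        t, c, q = self.times_h, self.concentrations, self.blq
        obs = np.where(q, 0.0, c)
        if not np.any(~q):
            raise InsufficientTerminalData(
                f"all samples BLQ for {self.subject_id} occasion {self.occasion}"
            )
        imax = int(np.argmax(obs))
        keep = np.ones(len(t), dtype=bool)
        after = np.arange(len(t)) > imax
        bad = after & q
        if np.any(bad):
            keep[np.argmax(bad):] = False  # truncate at first post-peak BLQ
        return t[keep], obs[keep]


@dataclass(frozen=True)
class TerminalFit:
    lambda_z: float  # 1/h
    intercept_log_conc: float
    n_points_used: int
    adjusted_r2: float
    time_window: tuple[float, float]

    def predict(self, t: float) -> float:
        return float(np.exp(self.intercept_log_conc - self.lambda_z * t))


@dataclass(frozen=True)
class PKParameters:
    subject_id: str
    occasion: int | float
    dose_mg: float
    cl_f: float  # l/min
    auc_inf: float  # mg·min/l
    auc_7h: float  # mg·min/l
    lambda_z: float  # 1/h
    t_half: float  # h
    vz: float  # l
    cmax: float  # µg/l
    tmax: float  # h
    extrapolated_fraction: float
    cl_f_per_kg: float | None = None  # ml/min/kg
    n_occasions: int = 1


def estimate_lambda_z(profile: ConcentrationProfile) -> TerminalFit:
    """Select the trailing log-linear window maximising adjusted R².

    Candidate windows are the last k points for k = 3 … all points
    strictly after Cmax (Cmax itself excluded); ties go to the window
    with more points; λz is the negated slope.
    """
    t, c = profile.quantifiable()
    imax = int(np.argmax(c))
    tt, cc = t[imax + 1 :], c[imax + 1 :]
    pos = cc > 0
    tt, cc = tt[pos], cc[pos]
    if len(tt) < 3:
        raise InsufficientTerminalData(
            f"need >=3 post-peak points, have {len(tt)} "
            f"({profile.subject_id} occasion {profile.occasion})"
        )
    logc = np.log(cc)
    best: TerminalFit | None = None
    for k in range(3, len(tt) + 1):
        x, y = tt[-k:], logc[-k:]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        fit = TerminalFit(-slope, intercept, k, adj, (float(x[0]), float(x[-1])))
        if best is None or adj > best.adjusted_r2 + 1e-12 or (
            abs(adj - best.adjusted_r2) <= 1e-12 and k > best.n_points_used
        ):
            best = fit
    assert best is not None
    if best.lambda_z <= 0:
        raise NonPositiveSlope(
            f"terminal slope non-negative for {profile.subject_id} "
            f"occasion {profile.occasion}"
        )
    return best


def _interval_auc(t1, t2, c1, c2) -> float:
    """Linear-up/log-down trapezoid for one interval, in µg·h/l."""
    dt = t2 - t1
    if c1 > c2 > 0:
        return dt * (c1 - c2) / np.log(c1 / c2)
    return dt * 0.5 * (c1 + c2)


def _interp_conc(t1, t2, c1, c2, t, mode: str = "log") -> float:
    """Concentration at t within [t1,t2]: linear on a rising limb,
    log-linear (mode='log') or linear (mode='linear') on a falling one."""
    f = (t - t1) / (t2 - t1)
    if c1 > c2 > 0 and mode == "log":
        return float(c1 * (c2 / c1) ** f)
    return float(c1 + f * (c2 - c1))


def auc_partial(
    profile: ConcentrationProfile, t_end: float, interpolation: str = "log"
) -> float:
    """AUC from 0 to ``t_end`` (mg·min/l) by linear-up/log-down trapezoids.

    If ``t_end`` falls between samples the bounding concentration is
    interpolated.  Raises :class:`ExtrapolationRequired` if ``t_end``
    lies beyond the last quantifiable sample.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    t, c = profile.quantifiable()
    if t_end > t[-1] + 1e-12:
        raise ExtrapolationRequired(
            f"t_end={t_end} beyond last quantifiable sample at {t[-1]} h; "
            "use auc_to_infinity for extrapolation"
        )
    total = 0.0
    for i in range(len(t) - 1):
        if t[i + 1] <= t_end + 1e-12:
            total += _interval_auc(t[i], t[i + 1], c[i], c[i + 1])
        else:
            if t[i] < t_end:
                ce = _interp_conc(t[i], t[i + 1], c[i], c[i + 1], t_end, interpolation)
                total += _interval_auc(t[i], t_end, c[i], ce)
            break
    return total * UGH_PER_L_TO_MGMIN_PER_L


def auc_to_infinity(
    profile: ConcentrationProfile, terminal_fit: TerminalFit | None = None
) -> tuple[float, float]:
    """AUC extrapolated to infinity (mg·min/l) and the extrapolated fraction.

    The tail is Ĉ(tlast)/λz with Ĉ the terminal-regression *predicted*
    concentration at the last quantifiable time.
    """
    if terminal_fit is None:
        terminal_fit = estimate_lambda_z(profile)
    t, _ = profile.quantifiable()
    tlast = t[-1]
    auc_last = auc_partial(profile, tlast)
    tail = terminal_fit.predict(tlast) / terminal_fit.lambda_z * UGH_PER_L_TO_MGMIN_PER_L
    auc_inf = auc_last + tail
    return auc_inf, tail / auc_inf


def compute_pk_parameters(
    profile: ConcentrationProfile,
    body_weight_kg: float | None = None,
    auc7_interpolation: str = "log",
) -> PKParameters:
    """Full NCA for one profile: Cl/F, AUC∞, AUC_7h, λz, t½, Vz, Cmax, tmax."""
    t, c = profile.quantifiable()
    fit = estimate_lambda_z(profile)
    auc_inf, extrap = auc_to_infinity(profile, fit)
    t7 = min(7.0, t[-1])
    auc7 = auc_partial(profile, t7, interpolation=auc7_interpolation)
    imax = int(np.argmax(c))  # argmax returns the earliest maximiser
    cl_f = profile.dose_mg / auc_inf  # l/min
    return PKParameters(
        subject_id=profile.subject_id,
        occasion=profile.occasion,
        dose_mg=profile.dose_mg,
        cl_f=cl_f,
        auc_inf=auc_inf,
        auc_7h=auc7,
        lambda_z=fit.lambda_z,
        t_half=np.log(2.0) / fit.lambda_z,
        vz=60.0 * cl_f / fit.lambda_z,
        cmax=float(c[imax]),
        tmax=float(t[imax]),
        extrapolated_fraction=extrap,
        cl_f_per_kg=None
        if body_weight_kg is None
        else 1000.0 * cl_f / body_weight_kg,
    )


_MEAN_FIELDS = (
    "cl_f",
    "auc_inf",
    "auc_7h",
    "lambda_z",
    "t_half",
    "vz",
    "cmax",
    "tmax",
    "extrapolated_fraction",
)


def aggregate_occasions(per_occasion: list[PKParameters]) -> PKParameters:
    """Per-subject parameters: arithmetic mean over available occasions."""
    if not per_occasion:
        raise ValueError("need at least one occasion")
    first = per_occasion[0]
    means = {
        f: float(np.mean([getattr(p, f) for p in per_occasion])) for f in _MEAN_FIELDS
    }
    kgs = [p.cl_f_per_kg for p in per_occasion if p.cl_f_per_kg is not None]
    return PKParameters(
        subject_id=first.subject_id,
        occasion=np.nan,
        dose_mg=first.dose_mg,
        cl_f_per_kg=float(np.mean(kgs)) if kgs else None,
        n_occasions=len(per_occasion),
        **means,
    )


def nca_table(
    conc: pd.DataFrame,
    dose_mg: float | None = None,
    auc7_interpolation: str = "log",
    on_error: str = "skip",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run NCA on a long concentration table.

    Expects columns subject_id, occasion, time_h, conc, blq (and
    optionally dose_mg).  Returns ``(per_occasion, per_subject)``
    parameter frames; profiles failing NCA are skipped (on_error='skip')
    or raise (on_error='raise').
    """
    rows: list[PKParameters] = []
    for (sid, occ), g in conc.groupby(["subject_id", "occasion"], sort=True):
        dose = dose_mg if dose_mg is not None else float(g["dose_mg"].iloc[0])
        profile = ConcentrationProfile(
            subject_id=str(sid),
            occasion=int(occ),
            dose_mg=dose,
            times_h=g["time_h"].to_numpy(),
            concentrations=g["conc"].to_numpy(),
            blq=g["blq"].to_numpy().astype(bool),
        )
        try:
            rows.append(
                compute_pk_parameters(profile, auc7_interpolation=auc7_interpolation)
            )
        except (InsufficientTerminalData, NonPositiveSlope):
            if on_error == "raise":
                raise
    per_occ = pd.DataFrame([vars(p) for p in rows])
    subj_rows = [
        vars(aggregate_occasions(list(grp)))
        for _, grp in pd.Series(rows, index=[p.subject_id for p in rows]).groupby(level=0)
    ]
    per_subj = pd.DataFrame(subj_rows)
    return per_occ, per_subj
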
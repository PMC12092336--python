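"""Precision, agreement, monitoring-summary, and derived-hemodynamic statistics.

The measurement-error toolkit for a repeated-measures method-comparison
study of MAPSE:

* least significant change (LSC) from a residual SD,
* a linked-replicates variance-component model (Carstensen's adjustment of
  Bland-Altman analysis to replicated, linked measurements),
* conventional Bland-Altman limits of agreement for paired readings,
* time-weighted averaging of monitoring series,
* Spearman rank correlation with exact small-sample p-values, and
* non-invasive hemodynamic indices (Ea, single-beat Ees, Ea/Ees, cardiac
  output, cardiac power output).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "lsc",
    "AgreementResult",
    "fit_linked_replicates",
    "bland_altman",
    "MonitoringSeries",
    "time_weighted_average",
    "spearman",
    "HemoInputs",
    "DerivedHemodynamics",
    "derived_hemodynamics",
    "compare_correlations",
]

#: Normal-theory multiplier for 95 % limits of agreement (not t-adjusted).
LOA_Z = 1.96


def lsc(sd: float, n: int) -> float:
    """Least significant change for the mean of ``n`` measurements.

    ``LSC = 2 * 1.96 * sd / sqrt(n)``: the smallest difference between two
    such means that exceeds measurement error at the 95 % level.
    """
    if n is None or n < 1:
        raise ValueError("n must be a positive count")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return 2.0 * LOA_Z * sd / math.sqrt(n)


@dataclass(frozen=True)
class AgreementResult:
    """Bias and limits of agreement between two methods.

    ``bias`` is method A minus method B.  For the linked-replicates model the
    variance components are populated: subject, shared (linked) replicate,
    method-by-subject interaction, and per-method residual SDs, from which
    per-method LSC values derive.  For a conventional Bland-Altman analysis
    the components are ``None``.
    """

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_subjects: int
    methods: tuple[str, str] = ("A", "B")
    n_replicates: int | None = None
    bias_se: float | None = None
    var_subject: float | None = None
    var_replicate: float | None = None
    var_interaction: float | None = None
    resid_sd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        mid = 0.5 * (self.loa_low + self.loa_high)
        if not math.isclose(mid, self.bias, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError("limits of agreement must be symmetric about the bias")

    def lsc_for(self, method: str, n: int = 1) -> float:
        """Per-method LSC for the mean of ``n`` measurements."""
        if self.resid_sd is None:
            raise ValueError("no per-method residual SDs: not a replicated fit")
        return lsc(self.resid_sd[method], n)

    def to_dict(self) -> dict:
        d = {
            "bias_mm": self.bias,
            "loa_low_mm": self.loa_low,
            "loa_high_mm": self.loa_high,
            "sd_diff_mm": self.sd_diff,
            "n_subjects": self.n_subjects,
            "methods": list(self.methods),
        }
        if self.n_replicates is not None:
            d["n_replicates"] = self.n_replicates
        if self.bias_se is not None:
            d["bias_se_mm"] = self.bias_se
        if self.resid_sd is not None:
            d.update(
                {
                    "var_subject": self.var_subject,
                    "var_replicate": self.var_replicate,
                    "var_interaction": self.var_interaction,
                    "resid_sd_mm": dict(self.resid_sd),
                    "lsc1_mm": {m: lsc(s, 1) for m, s in self.resid_sd.items()},
                }
            )
        return d


def _check_replicate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "method", "replicate", "value_mm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    return table


def fit_linked_replicates(
    table: pd.DataFrame, method_a: str | None = None, method_b: str | None = None
) -> AgreementResult:
    """Method-comparison fit for linked replicated measurements.

    Model: ``y_mir = alpha_m + mu_i + a_ir + c_mi + e_mir`` for method m,
    subject i, replicate r, with a replicate effect ``a_ir`` shared between
    the methods (the replicates are *linked*: replicate r of both methods is
    taken under the same conditions), a method-by-subject interaction
    ``c_mi``, and method-specific residuals ``e_mir``.

    Estimation is by method of moments on the balanced linked layout
    (negative variance estimates truncated at zero): the between/within
    subject mean squares of the per-replicate differences give the bias, the
    interaction variance and the limits of agreement, while the within-
    subject mean squares of each method separate the shared replicate
    variance from the per-method residual variances.  The residual SDs feed
    :func:`lsc` — the precision of each method.

    Only (subject, replicate) pairs observed for both methods enter the fit;
    single-replicate or unlinked input raises an error naming the violated
    design assumption.
    """
    table = _check_replicate_table(table)
    methods = sorted(table["method"].unique())
    if method_a is None or method_b is None:
        if len(methods) != 2:
            raise ValueError(f"expected exactly 2 methods, found {methods}")
        method_a, method_b = methods
    wide = table.pivot_table(
        index=["subject", "replicate"], columns="method", values="value_mm", aggfunc="first"
    )
    if method_a not in wide.columns or method_b not in wide.columns:
        raise ValueError("both methods must appear in the table")
    wide = wide.dropna(subset=[method_a, method_b])
    if len(wide) == 0:
        raise ValueError(
            "unlinked design: no (subject, replicate) pair was measured by both methods"
        )
    counts = wide.groupby(level="subject").size()
    keep = counts[counts >= 2].index
    if len(keep) < 2:
        raise ValueError(
            "linked replicated design requires >= 2 replicates for >= 2 subjects"
        )
    wide = wide.loc[wide.index.get_level_values("subject").isin(keep)]

    ya = wide[method_a].to_numpy(dtype=float)
    yb = wide[method_b].to_numpy(dtype=float)
    subj = wide.index.get_level_values("subject").to_numpy()
    d = ya - yb
    m = 0.5 * (ya + yb)

    df_sub = pd.DataFrame({"subject": subj, "d": d, "m": m, "a": ya, "b": yb})
    g = df_sub.groupby("subject")
    n_i = g.size().to_numpy(dtype=float)
    I = len(n_i)
    N = float(len(df_sub))
    # balanced-layout replicate count (harmonic-style n0 for mild unbalance)
    n0 = (N - (n_i**2).sum() / N) / (I - 1)

    def _anova(col: str) -> tuple[float, float]:
        """Between- and within-subject mean squares of one column."""
        x = df_sub[col].to_numpy(dtype=float)
        means = g[col].transform("mean").to_numpy(dtype=float)
        grand = x.mean()
        ssw = float(((x - means) ** 2).sum())
        sub_means = g[col].mean().to_numpy(dtype=float)
        ssb = float((n_i * (sub_means - grand) ** 2).sum())
        msw = ssw / (N - I) if N > I else 0.0
        msb = ssb / (I - 1)
        return msb, msw

    msb_d, msw_d = _anova("d")
    bias = float(d.mean())
    two_tau2 = max(0.0, (msb_d - msw_d) / n0)
    var_diff = two_tau2 + msw_d
    sd_diff = math.sqrt(var_diff)
    bias_se = math.sqrt(msb_d / N) if msb_d > 0 else 0.0

    _, w_a = _anova("a")
    _, w_b = _anova("b")
    sigma2_a = max(0.0, 0.5 * (msw_d + w_a - w_b))
    sigma2_b = max(0.0, 0.5 * (msw_d - w_a + w_b))
    var_replicate = max(0.0, 0.5 * ((w_a - sigma2_a) + (w_b - sigma2_b)))
    var_interaction = 0.5 * two_tau2

    msb_m, msw_m = _anova("m")
    var_subject = max(0.0, (msb_m - msw_m) / n0 - var_interaction / 2.0)

    return AgreementResult(
        bias=bias,
        loa_low=bias - LOA_Z * sd_diff,
        loa_high=bias + LOA_Z * sd_diff,
        sd_diff=sd_diff,
        n_subjects=I,
        methods=(method_a, method_b),
        n_replicates=int(round(n0)),
        bias_se=bias_se,
        var_subject=var_subject,
        var_replicate=var_replicate,
        var_interaction=var_interaction,
        resid_sd={method_a: math.sqrt(sigma2_a), method_b: math.sqrt(sigma2_b)},
    )


def bland_altman(a, b, methods: tuple[str, str] = ("A", "B")) -> AgreementResult:
    """Conventional Bland-Altman analysis of paired single measurements.

    ``bias = mean(a - b)`` and ``LOA = bias +/- 1.96 * SD(a - b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d arrays of equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("Bland-Altman analysis requires at least 2 complete pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias,
        loa_low=bias - LOA_Z * sd,
        loa_high=bias + LOA_Z * sd,
        sd_diff=sd,
        n_subjects=len(a),
        methods=methods,
    )


@dataclass(frozen=True)
class MonitoringSeries:
    """A monitored scalar over time: strictly increasing minutes, mm values."""

    t_min: np.ndarray
    value_mm: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.t_min, dtype=float))
        v = np.atleast_1d(np.asarray(self.value_mm, dtype=float))
        if t.shape != v.shape:
            raise ValueError("t_min and value_mm must have equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "value_mm", v)

    @property
    def duration_min(self) -> float:
        return float(self.t_min[-1] - self.t_min[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t_min, "value_mm": self.value_mm})


def time_weighted_average(series: MonitoringSeries) -> float:
    """Trapezoidal time integral of the series divided by the minutes monitored."""
    t, v = series.t_min, series.value_mm
    if len(t) < 2:
        raise ValueError("time-weighted average requires at least 2 points")
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicated timestamps")
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all permutations of one rank vector (conditional on the
    observed, possibly tied, ranks), in chunks to bound memory.
    """
    n = len(ry)
    rx_c = rx - rx.mean()
    denom = math.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
    count = 0
    total = 0
    chunk = []
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            P = np.asarray(chunk)
            r = (P - P.mean(axis=1, keepdims=True)) @ rx_c / denom
            count += int((np.abs(r) >= target).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        P = np.asarray(chunk)
        r = (P - P.mean(axis=1, keepdims=True)) @ rx_c / denom
        count += int((np.abs(r) >= target).sum())
        total += len(chunk)
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Incomplete pairs are removed (pairwise-complete deletion); ranks are
    tie-corrected (midranks).  The p-value uses the t approximation for
    n > 10 and exact permutation enumeration for n <= 10.  All-tied input
    leaves the coefficient undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation requires at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined: an input is constant (all ties)")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > 10:
        res = scipy.stats.spearmanr(x, y)
        return rho, float(res.pvalue)
    return rho, float(_exact_spearman_p(rx, ry, rho))


#: Normalized-elastance polynomial of the single-beat Ees method (Chen et al.):
#: E_Nd(avg) as a 7th-degree polynomial in t_Nd, the ratio of the
#: pre-ejection period to total systolic period.  Coefficients in ascending
#: order of power.
CHEN_END_POLY: tuple[float, ...] = (
    0.35695,
    -7.2266,
    74.249,
    -307.39,
    684.54,
    -856.92,
    571.95,
    -159.1,
)

#: Group-averaged regression that refines E_Nd from EF and the pressure
#: ratio: E_Nd(est) = b0 + b1*EF + b2*(Pd/Pes) + b3*E_Nd(avg).
CHEN_END_REGRESSION: tuple[float, float, float, float] = (0.0275, -0.165, 0.3656, 0.515)


def chen_normalized_elastance(t_nd: float, lvef: float, dbp: float, sbp: float) -> float:
    """Estimated normalized elastance at arterial end-diastole, E_Nd(est)."""
    e_avg = float(np.polynomial.polynomial.polyval(t_nd, CHEN_END_POLY))
    b0, b1, b2, b3 = CHEN_END_REGRESSION
    pes = 0.9 * sbp
    return b0 + b1 * lvef + b2 * (dbp / pes) + b3 * e_avg


@dataclass(frozen=True)
class HemoInputs:
    """Scalar inputs for the derived hemodynamic indices.

    Pressures in mmHg, heart rate in beats/min, stroke volume in mL, LVEF as
    a fraction, ejection times in seconds (pre-ejection: R-wave to flow
    onset; ejection: flow onset to flow end).
    """

    sbp: float
    dbp: float
    mean_ap: float
    hr: float
    sv: float
    lvef: float
    pre_ejection_s: float
    ejection_s: float

    def __post_init__(self) -> None:
        if min(self.sbp, self.dbp, self.mean_ap, self.hr) <= 0:
            raise ValueError("pressures and heart rate must be positive")
        if self.sv <= 0:
            raise ValueError("stroke volume must be positive")
        if not (0.0 < self.lvef < 1.0):
            raise ValueError("lvef must be a fraction in (0, 1)")
        if self.pre_ejection_s < 0 or self.ejection_s <= 0:
            raise ValueError("ejection times must be positive")
        if self.pre_ejection_s >= self.pre_ejection_s + self.ejection_s:
            raise ValueError("pre-ejection time must be shorter than total systole")


@dataclass(frozen=True)
class DerivedHemodynamics:
    """Derived indices: elastances in mmHg/mL, CO in L/min, CPO in W."""

    ea: float
    ees: float
    ea_ees: float
    co_l_min: float
    cpo_w: float
    valid: bool = True

    def to_dict(self) -> dict:
        return {
            "Ea_mmHg_per_mL": self.ea,
            "Ees_mmHg_per_mL": self.ees,
            "Ea_over_Ees": self.ea_ees,
            "CO_L_min": self.co_l_min,
            "CPO_W": self.cpo_w,
            "valid": self.valid,
        }


def derived_hemodynamics(h: HemoInputs) -> DerivedHemodynamics:
    """Arterial and ventricular elastance, coupling, CO and CPO.

    * Ea = 0.9 * SBP / SV  (mmHg/mL)
    * Ees by the non-invasive single-beat method (normalized elastance from
      the ejection-time ratio, refined by EF and the diastolic/end-systolic
      pressure ratio): Ees = (DBP - E_Nd(est) * 0.9 * SBP) / (E_Nd(est) * SV)
    * CO = HR * SV (reported in L/min)
    * CPO = CO[L/min] * MAP / 451  (W)

    A non-positive Ees intermediate marks the result invalid (the coupling
    ratio is then meaningless) but the arithmetic is still returned.
    """
    ea = 0.9 * h.sbp / h.sv
    t_nd = h.pre_ejection_s / (h.pre_ejection_s + h.ejection_s)
    e_nd = chen_normalized_elastance(t_nd, h.lvef, h.dbp, h.sbp)
    valid = e_nd > 0
    ees = (h.dbp - e_nd * 0.9 * h.sbp) / (e_nd * h.sv) if valid else float("nan")
    if not (valid and ees > 0):
        valid = False
    co = h.hr * h.sv / 1000.0
    cpo = co * h.mean_ap / 451.0
    return DerivedHemodynamics(
        ea=ea,
        ees=ees,
        ea_ees=ea / ees if valid else float("nan"),
        co_l_min=co,
        cpo_w=cpo,
        valid=valid,
    )


def compare_correlations(rho_by_label: dict[str, float]) -> pd.DataFrame:
    """Descriptive ordering of labelled correlation coefficients.

    Ranks by absolute magnitude, strongest first; equal magnitudes share a
    rank and are flagged as tied.  No inferential test is performed.
    """
    if len(rho_by_label) < 2:
        raise ValueError("need at least 2 labelled coefficients to compare")
    df = pd.DataFrame(
        {"label": list(rho_by_label), "rho": [float(v) for v in rho_by_label.values()]}
    )
    df["abs_rho"] = df["rho"].abs()
    df = df.sort_values(["abs_rho", "label"], ascending=[False, True], kind="stable")
    df["rank"] = df["abs_rho"].rank(method="min", ascending=False).astype(int)
    df["tied"] = df.duplicated("abs_rho", keep=False)
    return df[["rank", "label", "rho", "abs_rho", "tied"]].reset_index(drop=True)
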
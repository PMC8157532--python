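"""Two-state relaxation-dispersion forward models and global fitting.

CPMG profiles are evaluated either with the Carver-Richards closed form or by
propagating the 2x2 complex Bloch-McConnell matrix over the echo train; R1rho
profiles with the Miloushev-Palmer (Laguerre) approximation or the full 6x6
two-state Bloch-McConnell propagator.  Global fits share the exchange rate
``kex`` and the minor-state population ``pB`` across residues, fields and
experiments, with per-residue |dw| (ppm) and per-(residue, field) intrinsic
R2,0, minimising the error-weighted sum of squares via multi-start
Levenberg-Marquardt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import lmfit
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import f as f_dist

from .constants import ppm_to_rad_s, rad_s_to_ppm
from .errors import ConvergenceError, ValidationError

#: total CPMG relaxation delay (s); the canonical nu_cpmg grids are integer
#: multiples of 25 Hz so the echo train always contains a whole number of
#: cycles.
T_RELAX_CPMG = 0.04


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DispersionDataset:
    """Tidy table of R2eff / R1rho measurements plus acquisition metadata."""

    points: pd.DataFrame
    metadata: dict = dc_field(default_factory=dict)

    COLUMNS = ("residue", "field_mhz", "experiment", "nu_cpmg_hz",
               "omega1_hz", "offset_hz", "rate_s", "error_s")

    def validate(self) -> None:
        missing = set(self.COLUMNS) - set(self.points.columns)
        if missing:
            raise ValidationError(f"dispersion table missing columns {missing}")
        if (self.points["error_s"] <= 0).any():
            raise ValidationError("per-point errors must be > 0")
        for (r, fmhz, exp), grp in self.points.groupby(
                ["residue", "field_mhz", "experiment"]):
            if len(grp) < 4:
                raise ValidationError(
                    f"curve ({r}, {fmhz} MHz, {exp}) has {len(grp)} < 4 points")

    @property
    def residues(self) -> list:
        return sorted(self.points["residue"].unique())

    @property
    def fields(self) -> list:
        return sorted(self.points["field_mhz"].unique())


@dataclass
class TwoStateFit:
    """Result of a global two-state dispersion fit."""

    kex: float
    pB: float
    dw_ppm: dict
    r20: dict  # (residue, field_mhz) -> s^-1
    chi2: float
    redchi: float
    n_params: int
    n_points: int
    ci: dict = dc_field(default_factory=dict)
    r1: float = 0.0

    def dw_rad_s(self, residue, field_mhz: float) -> float:
        return float(ppm_to_rad_s(self.dw_ppm[residue], field_mhz))

    def validate(self) -> None:
        if not 0.0 < self.pB < 0.5:
            raise ValidationError("fitted pB outside the minor-state convention")
        if self.kex <= 0 or self.chi2 < 0:
            raise ValidationError("non-physical fit result")
        if self.n_points <= self.n_params:
            raise ValidationError("fewer points than parameters")


# ---------------------------------------------------------------------------
# CPMG forward models
# ---------------------------------------------------------------------------


def _r2eff_carver_richards(pB, kex, dw, r20, nu_cpmg):
    """Carver-Richards closed form (equal intrinsic R2 in both states)."""
    pA = 1.0 - pB
    nu = np.asarray(nu_cpmg, dtype=float)
    psi = kex**2 - dw**2
    zeta = -2.0 * dw * kex * (pA - pB)
    root = np.sqrt(psi**2 + zeta**2)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
    eta_plus = np.sqrt(np.maximum(psi + root, 0.0)) / (2.0 * np.sqrt(2.0) * nu)
    eta_minus = np.sqrt(np.maximum(-psi + root, 0.0)) / (2.0 * np.sqrt(2.0) * nu)
    with np.errstate(over="raise", invalid="raise"):
        arg = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
        return r20 + 0.5 * kex - nu * np.arccosh(np.maximum(arg, 1.0))


def _r2eff_numerical_one(pB, kex, dw, r20, nu, t_relax=T_RELAX_CPMG):
    """Decay rate of the slowest eigenmode of the Bloch-McConnell echo train.

    One CPMG cycle is delta-180-2*delta-180-delta with delta = 1/(4 nu); the
    180 pulses conjugate the transverse magnetisation.  R2eff is extracted
    from the decay per cycle of the dominant eigenmode, i.e. the
    long-relaxation-delay limit of -(1/T) ln(I/I0), which is independent of
    the arbitrary relaxation delay and of amplitude factors from the minor
    mode.
    """
    pA = 1.0 - pB
    kab, kba = pB * kex, pA * kex
    A = np.array([[-r20 - kab, kba],
                  [kab, -r20 - kba + 1j * dw]], dtype=complex)
    delta = 1.0 / (4.0 * nu)
    e1 = expm(A * delta)
    e2c = expm(A.conj() * 2.0 * delta)
    cycle = e1 @ e2c @ e1
    lam = np.linalg.eigvals(cycle)
    return -nu * np.log(np.max(np.abs(lam)))


def r2eff_two_state_cpmg(pB, kex, dw, r20, nu_cpmg,
                         method: str = "carver_richards"):
    """Effective transverse relaxation rate under a CPMG train.

    Parameters are the minor-state population, exchange rate (s^-1), shift
    difference (rad s^-1), intrinsic R2 (s^-1) and refocusing frequency (Hz);
    scalar or array ``nu_cpmg``.  The closed form falls back to the numerical
    propagator on overflow.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValidationError("nu_cpmg must be positive")
    if method == "numerical":
        out = np.array([_r2eff_numerical_one(pB, kex, dw, r20, v)
                        for v in np.atleast_1d(nu)])
    elif method == "carver_richards":
        if dw == 0.0:
            return np.full_like(nu, float(r20)) if nu.ndim else float(r20)
        try:
            out = _r2eff_carver_richards(pB, kex, dw, r20, np.atleast_1d(nu))
        except FloatingPointError:
            warnings.warn("Carver-Richards overflow; falling back to the "
                          "numerical Bloch-McConnell propagator")
            out = np.array([_r2eff_numerical_one(pB, kex, dw, r20, v)
                            for v in np.atleast_1d(nu)])
    else:
        raise ValidationError(f"unknown CPMG method {method!r}")
    return float(out[0]) if nu.ndim == 0 else out


# ---------------------------------------------------------------------------
# R1rho forward models
# ---------------------------------------------------------------------------


def _r1rho_analytic(pB, kex, dw, r20, r1, w1, omega_a):
    """Miloushev-Palmer (Laguerre second-order) two-state R1rho."""
    pA = 1.0 - pB
    omega_b = omega_a + dw
    omega_bar = pA * omega_a + pB * omega_b
    wa2 = omega_a**2 + w1**2
    wb2 = omega_b**2 + w1**2
    weff2 = omega_bar**2 + w1**2
    sin2t = w1**2 / weff2
    cos2t = 1.0 - sin2t
    if dw == 0.0:
        return r1 * cos2t + r20 * sin2t
    num = pA * pB * dw**2 * kex
    den = (wa2 * wb2 / weff2 + kex**2
           - sin2t * pA * pB * dw**2
           * (1.0 + 2.0 * kex**2 * (pA * wa2 + pB * wb2)
              / (wa2 * wb2 + weff2 * kex**2)))
    return r1 * cos2t + sin2t * (r20 + num / den)


def _r1rho_numerical(pB, kex, dw, r20, r1, w1, omega_a,
                     t1: float = 0.05, t2: float = 0.10):
    """Two-delay decay of spin-locked magnetisation from the 6x6 propagator."""
    pA = 1.0 - pB
    kab, kba = pB * kex, pA * kex
    omega_b = omega_a + dw

    def single(om):
        return np.array([[-r20, -om, 0.0],
                         [om, -r20, -w1],
                         [0.0, w1, -r1]])

    eye = np.eye(3)
    L = np.block([[single(omega_a) - kab * eye, kba * eye],
                  [kab * eye, single(omega_b) - kba * eye]])
    omega_bar = pA * omega_a + pB * omega_b
    weff = np.hypot(omega_bar, w1)
    e = np.array([w1 / weff, 0.0, omega_bar / weff])
    m0 = np.concatenate([pA * e, pB * e])
    axis = np.concatenate([e, e])
    i1 = axis @ (expm(L * t1) @ m0)
    i2 = axis @ (expm(L * t2) @ m0)
    return np.log(i1 / i2) / (t2 - t1)


def r1rho_two_state(pB, kex, dw, r20, r1, omega1_hz, offset_hz,
                    method: str = "analytic"):
    """Rotating-frame relaxation rate under a spin lock.

    ``omega1_hz`` is the spin-lock field strength, ``offset_hz`` the offset of
    the major-state resonance from the carrier; ``dw`` in rad s^-1.
    """
    if omega1_hz <= 0:
        raise ValidationError("spin-lock omega1 must be positive")
    w1 = 2.0 * np.pi * omega1_hz
    omega_a = 2.0 * np.pi * offset_hz
    if method == "analytic":
        return float(_r1rho_analytic(pB, kex, dw, r20, r1, w1, omega_a))
    if method == "numerical":
        return float(_r1rho_numerical(pB, kex, dw, r20, r1, w1, omega_a))
    raise ValidationError(f"unknown R1rho method {method!r}")


# ---------------------------------------------------------------------------
# Rex estimation
# ---------------------------------------------------------------------------


def rex_estimate(data: DispersionDataset) -> pd.Series:
    """Per-residue exchange contribution to R2.

    For each CPMG curve, R2eff at the lowest refocusing frequency minus R2eff
    at the highest, averaged over fields; single-point curves are skipped.
    """
    cpmg = data.points[data.points["experiment"] == "cpmg"]
    out = {}
    for residue, res_grp in cpmg.groupby("residue"):
        diffs = []
        for _, grp in res_grp.groupby("field_mhz"):
            if len(grp) < 2:
                warnings.warn(f"residue {residue}: single-point CPMG curve "
                              f"skipped")
                continue
            g = grp.sort_values("nu_cpmg_hz")
            diffs.append(g["rate_s"].iloc[0] - g["rate_s"].iloc[-1])
        if diffs:
            out[residue] = float(np.mean(diffs))
        else:
            warnings.warn(f"residue {residue}: no usable CPMG curve")
    return pd.Series(out, name="rex_s")


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------


def _r20_key(residue, field_mhz) -> str:
    return f"r20_{residue}_{int(round(field_mhz))}"


def _dw_key(residue) -> str:
    return f"dw_{residue}"


def _fit_residual(params, data_arrays, r1):
    kex = params["kex"].value
    pB = params["pB"].value
    out = []
    for arr in data_arrays:
        dw_rad = float(ppm_to_rad_s(params[arr["dw_name"]].value,
                                    arr["field_mhz"]))
        r20 = params[arr["r20_name"]].value
        if arr["experiment"] == "cpmg":
            calc = r2eff_two_state_cpmg(pB, kex, dw_rad, r20, arr["nu"],
                                        method="carver_richards")
        else:
            calc = np.array([
                r1rho_two_state(pB, kex, dw_rad, r20, r1, w1, off,
                                method="analytic")
                for w1, off in zip(arr["omega1"], arr["offset"])])
        out.append((calc - arr["rate"]) / arr["error"])
    return np.concatenate(out)


def _prepare_arrays(data: DispersionDataset):
    arrays = []
    for (residue, fmhz, exp), grp in data.points.groupby(
            ["residue", "field_mhz", "experiment"], sort=True):
        arr = {"residue": residue, "field_mhz": float(fmhz),
               "experiment": exp, "rate": grp["rate_s"].to_numpy(),
               "error": grp["error_s"].to_numpy(),
               "dw_name": _dw_key(residue),
               "r20_name": _r20_key(residue, fmhz)}
        if exp == "cpmg":
            arr["nu"] = grp["nu_cpmg_hz"].to_numpy(dtype=float)
        else:
            arr["omega1"] = grp["omega1_hz"].to_numpy(dtype=float)
            arr["offset"] = grp["offset_hz"].to_numpy(dtype=float)
        arrays.append(arr)
    return arrays


def _initial_params(data: DispersionDataset, kex0, pB0, rex) -> lmfit.Parameters:
    params = lmfit.Parameters()
    params.add("kex", value=kex0, min=1.0, max=1e6)
    params.add("pB", value=pB0, min=1e-4, max=0.499)
    pA0 = 1.0 - pB0
    for residue in data.residues:
        rex_r = max(float(rex.get(residue, 0.5)), 0.05)
        f0 = data.fields[0]
        # invert the fast-exchange Rex to seed |dw|
        dw_rad0 = np.sqrt(rex_r * kex0 / (pA0 * pB0))
        dw_ppm0 = float(np.clip(rad_s_to_ppm(dw_rad0, f0), 0.05, 15.0))
        params.add(_dw_key(residue), value=dw_ppm0, min=0.0, max=30.0)
    for (residue, fmhz), grp in data.points.groupby(["residue", "field_mhz"]):
        r20_0 = float(grp["rate_s"].min())
        params.add(_r20_key(residue, fmhz), value=max(r20_0, 0.5),
                   min=0.05, max=200.0)
    return params


DEFAULT_KEX_GRID = tuple(np.logspace(2, np.log10(30000), 7))
DEFAULT_PB_GRID = (0.005, 0.01, 0.02, 0.05, 0.10)


def global_fit_two_state(data: DispersionDataset, init=None, seed: int = 0,
                         r1: float = 1.2, n_boot: int = 0,
                         level: float = 0.95, n_refine: int = 3) -> TwoStateFit:
    """Globally fit a two-state exchange model to a dispersion dataset.

    ``kex`` and ``pB`` are shared across all residues, fields and experiments;
    |dw| (ppm) is per residue and R2,0 per (residue, field).  A deterministic
    multi-start over ``init`` (default: kex log-spaced 100-30000 s^-1 crossed
    with pB in {0.5, 1, 2, 5, 10}%) is pruned by the chi^2 of each start and
    the best ``n_refine`` starts are refined by Levenberg-Marquardt; ties are
    broken towards the lowest kex.  Optional residual-resampling bootstrap
    gives percentile confidence intervals.
    """
    data.validate()
    if len(data.residues) < 2:
        warnings.warn("fewer than 2 residues: global parameters are weakly "
                      "constrained")
    arrays = _prepare_arrays(data)
    rex = rex_estimate(data)
    if init is None:
        init = [(k, p) for k in DEFAULT_KEX_GRID for p in DEFAULT_PB_GRID]

    starts = []
    for kex0, pB0 in init:
        params = _initial_params(data, kex0, pB0, rex)
        chi2_0 = float(np.sum(_fit_residual(params, arrays, r1) ** 2))
        starts.append((chi2_0, kex0, params))
    starts.sort(key=lambda s: (s[0], s[1]))

    best = None
    diagnostics = []
    for chi2_0, kex0, params in starts[:max(1, n_refine)]:
        try:
            res = lmfit.minimize(_fit_residual, params, args=(arrays, r1),
                                 method="leastsq")
        except Exception as exc:  # pragma: no cover - diagnostic path
            diagnostics.append((kex0, str(exc)))
            continue
        if not np.isfinite(res.chisqr):
            diagnostics.append((kex0, "non-finite chi2"))
            continue
        key = (res.chisqr, res.params["kex"].value)
        if best is None or key < (best.chisqr, best.params["kex"].value):
            best = res
    if best is None:
        raise ConvergenceError(
            f"no multi-start converged; start diagnostics: {diagnostics}")

    p = best.params
    n_points = sum(len(a["rate"]) for a in arrays)
    fit = TwoStateFit(
        kex=float(p["kex"].value),
        pB=float(p["pB"].value),
        dw_ppm={r: float(p[_dw_key(r)].value) for r in data.residues},
        r20={(r, f): float(p[_r20_key(r, f)].value)
             for r in data.residues for f in data.fields
             if _r20_key(r, f) in p},
        chi2=float(best.chisqr),
        redchi=float(best.chisqr / max(1, n_points - best.nvarys)),
        n_params=int(best.nvarys),
        n_points=int(n_points),
        r1=r1,
    )
    fit.validate()

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid_w = _fit_residual(p, arrays, r1)
        errors = np.concatenate([a["error"] for a in arrays])
        calc = np.concatenate([a["rate"] for a in arrays]) + resid_w * errors
        samples = {"kex": [], "pB": []}
        dw_samples = {r: [] for r in data.residues}
        for _ in range(n_boot):
            fake = calc - errors * rng.choice(resid_w, size=len(resid_w),
                                              replace=True)
            boot_arrays = []
            pos = 0
            for a in arrays:
                b = dict(a)
                b["rate"] = fake[pos:pos + len(a["rate"])]
                pos += len(a["rate"])
                boot_arrays.append(b)
            try:
                bres = lmfit.minimize(_fit_residual, p.copy(),
                                      args=(boot_arrays, r1), method="leastsq")
            except Exception:
                continue
            samples["kex"].append(bres.params["kex"].value)
            samples["pB"].append(bres.params["pB"].value)
            for r in data.residues:
                dw_samples[r].append(bres.params[_dw_key(r)].value)
        lo, hi = 50 * (1 - level), 50 * (1 + level)
        ci = {}
        for name, vals in samples.items():
            if vals:
                ci[name] = (level, float(np.percentile(vals, lo)),
                            float(np.percentile(vals, hi)))
        for r, vals in dw_samples.items():
            if vals:
                ci[_dw_key(r)] = (level, float(np.percentile(vals, lo)),
                                  float(np.percentile(vals, hi)))
        fit.ci = ci
    return fit


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class FlatFit:
    """No-exchange reference model: one constant rate per curve."""

    chi2: float
    n_params: int
    n_points: int
    values: dict


def fit_flat(data: DispersionDataset) -> FlatFit:
    """Fit the exchange-free model (flat R2eff per residue/field curve)."""
    chi2 = 0.0
    values = {}
    n_points = 0
    for (residue, fmhz, exp), grp in data.points.groupby(
            ["residue", "field_mhz", "experiment"]):
        w = 1.0 / grp["error_s"].to_numpy() ** 2
        y = grp["rate_s"].to_numpy()
        mean = float(np.sum(w * y) / np.sum(w))
        chi2 += float(np.sum(w * (y - mean) ** 2))
        values[(residue, fmhz, exp)] = mean
        n_points += len(grp)
    return FlatFit(chi2=chi2, n_params=len(values), n_points=n_points,
                   values=values)


def model_compare(data: DispersionDataset, fit_1state: FlatFit,
                  fit_2state: TwoStateFit, alpha: float = 0.01) -> dict:
    """F-test between the flat and two-state models fitted to the same data.

    Returns the preferred model at significance ``alpha`` together with the
    F statistic, p-value and both AIC values.
    """
    if fit_1state.n_points != fit_2state.n_points:
        raise ValidationError("model comparison requires fits on the same data")
    chi1, chi2 = fit_1state.chi2, fit_2state.chi2
    p1, p2 = fit_1state.n_params, fit_2state.n_params
    n = fit_2state.n_points
    if p2 <= p1:
        raise ValidationError("two-state model must have more parameters")
    chi2_eff = min(chi1, chi2)  # nested in the model class sense
    fstat = ((chi1 - chi2_eff) / (p2 - p1)) / (chi2_eff / max(1, n - p2))
    pval = float(f_dist.sf(fstat, p2 - p1, max(1, n - p2)))
    aic1 = chi1 + 2 * p1
    aic2 = chi2_eff + 2 * p2
    preferred = "2-state" if (pval < alpha and chi2_eff < chi1) else "1-state"
    return {"preferred": preferred, "F": float(fstat), "p_value": pval,
            "aic_1state": aic1, "aic_2state": aic2, "alpha": alpha}
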
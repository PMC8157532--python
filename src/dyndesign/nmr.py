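"""Forward prediction of NMR observables from kinetic ensembles.

Covers population-averaged chemical shifts and chemical shift perturbations
(CSPs), the mapping of a multi-state kinetic model onto a two-state NMR
exchange model (closed vs open 70s-loop groups) with a forward-predicted
exchange contribution Rex, and the steady-state 15N-{1H} heteronuclear NOE
from Lipari-Szabo model-free spectral densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .constants import (GAMMA_RATIO_HN, csa_constant, dipolar_constant,
                        n15_larmor_mhz, ppm_to_rad_s)
from .errors import ValidationError
from .msm import MSMEstimate, mfpt

#: default 15N weighting in the combined 1H/15N CSP
CSP_ALPHA = 0.14


# ---------------------------------------------------------------------------
# shift tables and CSPs
# ---------------------------------------------------------------------------


@dataclass
class ShiftTable:
    """Per-residue amide 1H/15N chemical shifts (ppm)."""

    df: pd.DataFrame  # columns: residue, dH_ppm, dN_ppm
    provenance: str = "per_state"
    label: str | None = None

    @classmethod
    def from_dict(cls, shifts: dict[int, tuple[float, float]],
                  provenance: str = "per_state",
                  label: str | None = None) -> "ShiftTable":
        df = pd.DataFrame(
            [(r, h, n) for r, (h, n) in sorted(shifts.items())],
            columns=["residue", "dH_ppm", "dN_ppm"])
        return cls(df=df, provenance=provenance, label=label)

    @property
    def residues(self) -> list[int]:
        return self.df["residue"].tolist()

    def to_dict(self) -> dict[int, tuple[float, float]]:
        return {int(r): (float(h), float(n))
                for r, h, n in self.df.itertuples(index=False)}

    def validate(self) -> None:
        if self.df["residue"].duplicated().any():
            raise ValidationError("duplicate residue ids in shift table")
        if not np.all(np.isfinite(self.df[["dH_ppm", "dN_ppm"]])):
            raise ValidationError("non-finite chemical shifts")


@dataclass
class CSPProfile:
    """Combined 1H/15N chemical shift perturbations (ppm)."""

    df: pd.DataFrame  # columns: residue, csp_ppm
    alpha: float = CSP_ALPHA

    def validate(self) -> None:
        if (self.df["csp_ppm"] < 0).any():
            raise ValidationError("CSPs must be non-negative")

    def get(self, residue: int) -> float:
        row = self.df[self.df["residue"] == residue]
        return float(row["csp_ppm"].iloc[0])


def ensemble_average_shifts(populations, tables: list[ShiftTable]) -> ShiftTable:
    """Population-weighted (fast-exchange) average of per-state shift tables.

    Residues missing from any state are omitted with a warning.
    """
    populations = np.asarray(populations, dtype=float)
    if len(populations) != len(tables):
        raise ValidationError("populations do not align with the state list")
    if abs(populations.sum() - 1.0) > 1e-6:
        raise ValidationError("populations must sum to 1")
    dicts = [t.to_dict() for t in tables]
    shared = set(dicts[0])
    union = set(dicts[0])
    for d in dicts[1:]:
        shared &= set(d)
        union |= set(d)
    if union - shared:
        warnings.warn(f"residues {sorted(union - shared)} missing from some "
                      f"states: omitted from the ensemble average")
    avg = {}
    for r in sorted(shared):
        h = float(sum(p * d[r][0] for p, d in zip(populations, dicts)))
        n = float(sum(p * d[r][1] for p, d in zip(populations, dicts)))
        avg[r] = (h, n)
    out = ShiftTable.from_dict(avg, provenance="ensemble_average")
    out.validate()
    return out


def csp(a: ShiftTable, b: ShiftTable, alpha: float = CSP_ALPHA) -> CSPProfile:
    """Combined CSP per residue: sqrt(dH^2 + (alpha*dN)^2), symmetric in a, b."""
    da, db = a.to_dict(), b.to_dict()
    shared = sorted(set(da) & set(db))
    if not shared:
        raise ValidationError("no shared residues between shift tables")
    rows = []
    for r in shared:
        dh = da[r][0] - db[r][0]
        dn = da[r][1] - db[r][1]
        rows.append((r, float(np.hypot(dh, alpha * dn))))
    prof = CSPProfile(df=pd.DataFrame(rows, columns=["residue", "csp_ppm"]),
                      alpha=alpha)
    prof.validate()
    return prof


# ---------------------------------------------------------------------------
# two-state exchange mapping
# ---------------------------------------------------------------------------


@dataclass
class ExchangeMapping:
    """Two-state NMR view of a multi-state kinetic model.

    Group A collects the 70s-closed macrostates, group B the open ones
    (including the intermediate); ``kex`` is the sum of the two group-to-group
    rate constants; ``dw_ppm`` is the signed 15N shift difference (B minus A)
    of the within-group population-weighted averages.
    """

    pA: float
    pB: float
    kex: float  # s^-1
    group_assignment: dict[str, str]
    dw_ppm: dict[int, float]
    field_mhz: float

    def dw_rad_s(self, residue: int) -> float:
        return float(ppm_to_rad_s(self.dw_ppm[residue], self.field_mhz))

    def validate(self) -> None:
        if abs(self.pA + self.pB - 1.0) > 1e-9:
            raise ValidationError("pA + pB must be 1")
        if self.kex <= 0:
            raise ValidationError("kex must be positive")


def map_to_exchange_model(msm: MSMEstimate, state_labels,
                          shift_tables: dict[str, ShiftTable],
                          timestep_ns: float,
                          closed_labels=("o100_c70", "c100_c70"),
                          field_mhz: float = 600.0) -> ExchangeMapping:
    """Collapse a kinetic model onto a two-state exchange model.

    ``state_labels`` assigns each MSM state a macrostate label; states whose
    label is in ``closed_labels`` form NMR state A, all others state B.
    pA/pB are aggregated stationary populations; kex = 1/MFPT(A->B) +
    1/MFPT(B->A); per-residue dw is the difference of the within-group
    population-weighted 15N shifts, reported in ppm (signed) and convertible
    to rad/s at ``field_mhz``.
    """
    state_labels = list(state_labels)
    if len(state_labels) != msm.n_states:
        raise ValidationError("state_labels do not align with the MSM")
    a_idx = [i for i, l in enumerate(state_labels) if l in closed_labels]
    b_idx = [i for i, l in enumerate(state_labels) if l not in closed_labels]
    if not a_idx or not b_idx:
        raise ValidationError("both exchange groups must be populated")
    pA = float(msm.pi[a_idx].sum())
    pB = float(msm.pi[b_idx].sum())
    m_ab_ms = mfpt(msm, a_idx, b_idx, timestep_ns)
    m_ba_ms = mfpt(msm, b_idx, a_idx, timestep_ns)
    kex = 1e3 / m_ab_ms + 1e3 / m_ba_ms

    def group_shifts(idx):
        w = msm.pi[idx] / msm.pi[idx].sum()
        dicts = [shift_tables[state_labels[i]].to_dict() for i in idx]
        shared = set(dicts[0])
        for d in dicts[1:]:
            shared &= set(d)
        return {r: float(sum(wi * d[r][1] for wi, d in zip(w, dicts)))
                for r in shared}

    na = group_shifts(a_idx)
    nb = group_shifts(b_idx)
    dw = {r: nb[r] - na[r] for r in sorted(set(na) & set(nb))}
    mapping = ExchangeMapping(
        pA=pA, pB=pB, kex=float(kex),
        group_assignment={l: ("A" if l in closed_labels else "B")
                          for l in dict.fromkeys(state_labels)},
        dw_ppm=dw, field_mhz=field_mhz)
    mapping.validate()
    return mapping


def rex_forward(mapping: ExchangeMapping, nu_min: float = 25.0,
                nu_max: float = 1000.0, r20: float = 10.0,
                method: str = "numerical") -> pd.DataFrame:
    """Forward-predicted exchange contribution to R2 per residue.

    Rex = R2eff(nu_min) - R2eff(nu_max) from the two-state dispersion forward
    model, with the fast-exchange closed form pA*pB*dw^2/kex alongside.
    """
    from .dispersion import r2eff_two_state_cpmg

    mapping.validate()
    rows = []
    for r, dw_ppm in sorted(mapping.dw_ppm.items()):
        dw = abs(float(ppm_to_rad_s(dw_ppm, mapping.field_mhz)))
        lo = r2eff_two_state_cpmg(mapping.pB, mapping.kex, dw, r20, nu_min,
                                  method=method)
        hi = r2eff_two_state_cpmg(mapping.pB, mapping.kex, dw, r20, nu_max,
                                  method=method)
        fast = mapping.pA * mapping.pB * dw**2 / mapping.kex
        rows.append((r, float(lo - hi), float(fast)))
    return pd.DataFrame(rows, columns=["residue", "rex_s", "rex_fast_s"])


# ---------------------------------------------------------------------------
# model-free heteronuclear NOE
# ---------------------------------------------------------------------------


@dataclass
class ModelFreeParams:
    """Lipari-Szabo parameters for one amide N-H vector."""

    s2: float
    tau_c_ns: float
    tau_e_ps: float
    field_mhz: float

    def validate(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValidationError("S2 must be in [0, 1]")
        if self.tau_c_ns <= 0 or self.tau_e_ps < 0:
            raise ValidationError("correlation times must be positive")
        if self.tau_e_ps * 1e-3 >= self.tau_c_ns:
            raise ValidationError("tau_e must be shorter than tau_c")


def spectral_density(omega, s2: float, tau_c_s: float, tau_e_s: float):
    """Model-free J(w) = (2/5)[S^2 tc/(1+(w tc)^2) + (1-S^2) t/(1+(w t)^2)]."""
    omega = np.asarray(omega, dtype=float)
    j = s2 * tau_c_s / (1.0 + (omega * tau_c_s) ** 2)
    if tau_e_s > 0 and s2 < 1.0:
        tau = 1.0 / (1.0 / tau_c_s + 1.0 / tau_e_s)
        j = j + (1.0 - s2) * tau / (1.0 + (omega * tau) ** 2)
    return 0.4 * j


def noe_from_modelfree(params: ModelFreeParams) -> float:
    """Steady-state 15N-{1H} heteronuclear NOE.

    NOE = 1 + (gammaH/gammaN) * sigma_NH / R1 with the cross-relaxation rate
    sigma and longitudinal rate R1 from dipolar + CSA spectral densities; the
    signed (negative) 15N gyromagnetic ratio is used throughout.
    """
    params.validate()
    tau_c = params.tau_c_ns * 1e-9
    tau_e = params.tau_e_ps * 1e-12
    omega_h = 2.0 * np.pi * params.field_mhz * 1e6
    omega_n = -2.0 * np.pi * n15_larmor_mhz(params.field_mhz) * 1e6

    def j(w):
        return float(spectral_density(abs(w), params.s2, tau_c, tau_e))

    d2_4 = dipolar_constant() ** 2 / 4.0
    c2 = csa_constant(params.field_mhz) ** 2
    r1 = d2_4 * (j(omega_h - omega_n) + 3 * j(omega_n)
                 + 6 * j(omega_h + omega_n)) + c2 * j(omega_n)
    sigma = d2_4 * (6 * j(omega_h + omega_n) - j(omega_h - omega_n))
    return 1.0 + GAMMA_RATIO_HN * sigma / r1
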
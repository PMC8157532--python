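"""Synthetic kinetic landscapes and observables for the CypA loop-dynamics pipeline.

The canonical models encode a five-macrostate free-energy landscape in which
two surface loops (the "70s" loop, residues 65-77, and the "100s" loop,
residues 100-110) each exchange between open and closed conformations, with
the 70s-loop interconversion an order of magnitude slower than the 100s loop
and passing through an intermediate state.  Three variants are provided:

``WT``
    ground state 100s-open/70s-closed at 41%; 70s closed:open aggregate 70:30.
``D66A``
    designed mutant: former ground state reduced to 15%, intermediate raised
    to 40%, 70s closed:open aggregate 25:75, and all loop kinetics 12x faster.
``H70A``
    negative control, identical landscape to WT.

Every stochastic generator takes an explicit integer seed and is bit
reproducible.  Populations, rate-matrix structure and emission parameters are
model constants, not fits; see docs/methods.md for their provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from .constants import ppm_to_rad_s
from .errors import MissingEmissionError, TimescaleSeparationError, ValidationError

# ---------------------------------------------------------------------------
# canonical landscape constants
# ---------------------------------------------------------------------------

MACRO_LABELS = ("o100_c70", "c100_c70", "intermediate", "o100_o70", "c100_o70")
LOOP70_STATE = {
    "o100_c70": "closed",
    "c100_c70": "closed",
    "intermediate": "intermediate",
    "o100_o70": "open",
    "c100_o70": "open",
}
LOOP100_STATE = {
    "o100_c70": "open",
    "c100_c70": "closed",
    "intermediate": "intermediate",
    "o100_o70": "open",
    "c100_o70": "closed",
}

#: 70s-loop group membership used for aggregate populations and exchange
#: mapping: the intermediate counts with the open group.
CLOSED_GROUP = ("o100_c70", "c100_c70")
OPEN_GROUP = ("intermediate", "o100_o70", "c100_o70")

CANONICAL_POPULATIONS = {
    "WT": (0.41, 0.29, 0.05, 0.13, 0.12),
    "D66A": (0.15, 0.10, 0.40, 0.18, 0.17),
    "H70A": (0.41, 0.29, 0.05, 0.13, 0.12),
}

#: allowed direct transitions: 100s-loop flips within each 70s group, and
#: 70s opening/closing only through the intermediate state.
EDGES = ((0, 1), (3, 4), (0, 2), (1, 2), (2, 3), (2, 4))

#: mean time for 70s-loop group interconversion (average of the two
#: directions), milliseconds.
TARGET_MFPT_70S_MS = {"WT": 5.0, "D66A": 5.0 / 12.0, "H70A": 5.0}

#: calibrated 70s/100s MFPT ratio for WT-like structures: "one order of
#: magnitude", placed at 11 so the whole [8, 12] band has support.
TARGET_RATIO_70S_100S = 11.0

#: 2-D feature space: (70s-loop openness, 100s-loop openness)
FEATURE_MEANS = {
    "o100_c70": (0.0, 1.0),
    "c100_c70": (0.0, 0.0),
    "intermediate": (0.5, 0.5),
    "o100_o70": (1.0, 1.0),
    "c100_o70": (1.0, 0.0),
}
FEATURE_SPREAD = 0.12

#: (donor, acceptor) -> (P(bond | 70s closed), P(bond | 70s open)).
#: D66 anchors the closed loop through several bonds; H70 is indifferent.
CANONICAL_HBONDS = {
    ("D66", "N71"): (0.75, 0.10),
    ("D66", "G72"): (0.90, 0.10),
    ("D66", "T73"): (0.80, 0.15),
    ("H70", "G74"): (0.45, 0.45),
    ("H70", "N71"): (0.30, 0.30),
    ("R69", "G74"): (0.35, 0.25),
    ("S77", "G80"): (0.50, 0.50),
}

#: 15N shift change (ppm, open minus closed) planted on 70s-loop residues.
DW_N_PPM = {
    65: 0.8, 66: 3.5, 67: 1.2, 68: 0.5, 69: 1.0, 70: 0.6, 71: 2.8,
    72: 3.0, 73: 2.2, 74: 3.2, 75: 1.5, 76: 0.9, 77: 1.1,
}
SHIFT_RESIDUES = tuple(range(55, 90)) + tuple(range(98, 113))


def _base_shifts(residue: int) -> tuple[float, float]:
    """Deterministic pseudo-random but fixed backbone amide shifts (ppm)."""
    d_h = 7.6 + 0.9 * (((residue * 13) % 17) / 17.0)
    d_n = 105.0 + 20.0 * (((residue * 7) % 29) / 29.0)
    return round(d_h, 3), round(d_n, 3)


def _state_shift_table(label: str) -> dict[int, tuple[float, float]]:
    frac = {"closed": 0.0, "intermediate": 0.5, "open": 1.0}[LOOP70_STATE[label]]
    table = {}
    for r in SHIFT_RESIDUES:
        d_h, d_n = _base_shifts(r)
        dw = DW_N_PPM.get(r, 0.0)
        table[r] = (d_h + frac * dw / 12.0, d_n + frac * dw)
    return table


def _state_hbond_probs(label: str, variant: str) -> dict[tuple[str, str], float]:
    frac = {"closed": 0.0, "intermediate": 0.5, "open": 1.0}[LOOP70_STATE[label]]
    probs = {}
    for pair, (p_closed, p_open) in CANONICAL_HBONDS.items():
        p = (1 - frac) * p_closed + frac * p_open
        if variant == "D66A" and pair[0] == "D66":
            p = 0.05  # alanine cannot donate the carboxylate bonds
        if variant == "H70A" and pair[0] == "H70":
            p = 0.05
        probs[pair] = p
    return probs


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MacrostateSpec:
    """One macrostate of a kinetic landscape and its emission parameters."""

    label: str
    loop70: str
    loop100: str
    population: float
    n_micro: int
    feature_mean: np.ndarray
    feature_spread: np.ndarray
    hbond_prob: dict[tuple[str, str], float]
    shifts: dict[int, tuple[float, float]]

    def validate(self) -> None:
        if not 0.0 <= self.population <= 1.0:
            raise ValidationError(f"population {self.population} outside [0, 1]")
        if self.n_micro < 1:
            raise ValidationError("n_micro must be >= 1")
        for pair, p in self.hbond_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"hbond_prob[{pair}] = {p} outside [0, 1]")
        if self.loop70 not in ("closed", "open", "intermediate"):
            raise ValidationError(f"loop70 flag {self.loop70!r} unknown")


@dataclass
class KineticModel:
    """Ground-truth landscape: macrostates, rates, and microstate expansion.

    ``macro_rates`` is a continuous-time generator in ms^-1; ``micro_T`` is the
    row-stochastic microstate transition matrix at one sampling interval
    ``timestep_ns``.
    """

    variant: str
    macrostates: list[MacrostateSpec]
    macro_rates: np.ndarray  # (n_macro, n_macro) generator, per ms
    timestep_ns: float
    micro_T: np.ndarray
    micro_to_macro: np.ndarray
    micro_pi: np.ndarray
    micro_feature_mean: np.ndarray  # (n_micro_total, 2)
    micro_feature_spread: np.ndarray
    seed_policy: str = "one numpy default_rng per stochastic call, seeded explicitly"

    @property
    def n_macro(self) -> int:
        return len(self.macrostates)

    @property
    def n_micro(self) -> int:
        return self.micro_T.shape[0]

    @property
    def macro_pi(self) -> np.ndarray:
        return np.array([m.population for m in self.macrostates])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.label for m in self.macrostates)

    def macro_T(self, lag_steps: int = 1) -> np.ndarray:
        """Macro-level transition matrix at ``lag_steps`` sampling intervals."""
        tau_ms = self.timestep_ns * 1e-6 * lag_steps
        return expm(self.macro_rates * tau_ms)

    def aggregate_population(self, loop70_flags: tuple[str, ...]) -> float:
        return float(
            sum(m.population for m in self.macrostates if m.loop70 in loop70_flags)
        )

    def validate(self) -> None:
        pi = self.macro_pi
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValidationError("macrostate populations do not sum to 1")
        Q = self.macro_rates
        off = Q - np.diag(np.diag(Q))
        if np.any(off < -1e-12):
            raise ValidationError("negative off-diagonal macro rate")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-9:
            raise ValidationError("generator rows do not sum to 0")
        if np.max(np.abs(self.micro_T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValidationError("micro_T rows do not sum to 1")
        agg = np.zeros(self.n_macro)
        np.add.at(agg, self.micro_to_macro, self.micro_pi)
        if np.max(np.abs(agg - pi)) > 1e-6:
            raise ValidationError("aggregated microstate stationary distribution "
                                  "does not reproduce macro populations")
        flux = self.micro_pi[:, None] * self.micro_T
        if np.max(np.abs(flux - flux.T)) > 1e-10:
            raise ValidationError("micro_T violates detailed balance")
        for m in self.macrostates:
            m.validate()


@dataclass
class SyntheticTrajectorySet:
    """Discrete microstate trajectories (and optional features) from one model."""

    dtrajs: list[np.ndarray]
    features: list[np.ndarray] | None
    timestep_ns: float
    seed: int
    model_ref: str

    @property
    def n_frames(self) -> int:
        return int(sum(len(d) for d in self.dtrajs))

    def validate(self, n_states: int | None = None) -> None:
        for d in self.dtrajs:
            if d.ndim != 1:
                raise ValidationError("dtrajs must be 1-D integer sequences")
            if n_states is not None and (d.min() < 0 or d.max() >= n_states):
                raise ValidationError("state index outside model range")
        if self.features is not None:
            if len(self.features) != len(self.dtrajs):
                raise ValidationError("features/dtrajs trajectory count mismatch")
            for f, d in zip(self.features, self.dtrajs):
                if len(f) != len(d):
                    raise ValidationError("features length != dtraj length")


@dataclass
class DispersionSimSpec:
    """Ground truth and measurement grid for a two-state dispersion dataset."""

    pB: float
    kex: float  # s^-1
    dw_ppm: dict[int, float]
    r20: dict[tuple[int, float], float]  # (residue, field MHz) -> s^-1
    fields_mhz: list[float]
    nu_cpmg_grid: list[float]
    spinlock_grid: list[tuple[float, float]]  # (omega1 Hz, offset Hz)
    noise_sd: float
    r1: float = 1.2

    def validate(self) -> None:
        if not 0.0 < self.pB < 0.5:
            raise ValidationError(f"pB = {self.pB} outside (0, 0.5)")
        if self.kex <= 0:
            raise ValidationError("kex must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not self.fields_mhz or not self.nu_cpmg_grid:
            raise ValidationError("field and nu_cpmg grids must be non-empty")
        if any(nu <= 0 for nu in self.nu_cpmg_grid):
            raise ValidationError("nu_cpmg grid must be strictly positive")
        if any(w1 <= 0 for w1, _ in self.spinlock_grid):
            raise ValidationError("spin-lock omega1 grid must be strictly positive")


# ---------------------------------------------------------------------------
# rate-matrix construction and calibration
# ---------------------------------------------------------------------------


def _build_generator(pi: np.ndarray, c100: float, cint: float) -> np.ndarray:
    """Detailed-balanced generator k_ij = c_ij * pi_j on the canonical edges."""
    n = len(pi)
    Q = np.zeros((n, n))
    for i, j in EDGES:
        c = c100 if (i, j) in ((0, 1), (3, 4)) else cint
        Q[i, j] = c * pi[j]
        Q[j, i] = c * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mfpt_from_generator(Q: np.ndarray, source: list[int], target: list[int],
                        pi: np.ndarray) -> float:
    """Continuous-time MFPT (units of 1/Q) from source set to target set.

    Solves the hitting-time linear system -Q_AA h = 1 on the complement of the
    target and averages over the source weighted by the restricted stationary
    distribution.
    """
    n = Q.shape[0]
    keep = np.array([i for i in range(n) if i not in set(target)])
    h = np.zeros(n)
    h[keep] = np.linalg.solve(-Q[np.ix_(keep, keep)], np.ones(len(keep)))
    w = pi[source] / pi[source].sum()
    return float(np.dot(w, h[source]))


def _loop_mfpts(Q: np.ndarray, pi: np.ndarray) -> tuple[float, float]:
    """(mean 70s group interconversion MFPT, mean 100s single-flip MFPT)."""
    closed = [0, 1]
    open_ = [2, 3, 4]
    m70 = 0.5 * (mfpt_from_generator(Q, closed, [3, 4], pi)
                 + mfpt_from_generator(Q, [3, 4], closed, pi))
    m100 = 0.5 * (mfpt_from_generator(Q, [0], [1], pi)
                  + mfpt_from_generator(Q, [1], [0], pi))
    return m70, m100


def _calibrated_generator(pi: np.ndarray, mfpt70_ms: float,
                          ratio: float = TARGET_RATIO_70S_100S) -> np.ndarray:
    """Generator with the 70s/100s MFPT ratio and absolute 70s MFPT fixed."""

    def ratio_gap(log_c100: float) -> float:
        Q = _build_generator(pi, 10.0 ** log_c100, 1.0)
        m70, m100 = _loop_mfpts(Q, pi)
        return m70 / m100 - ratio

    log_c = brentq(ratio_gap, -2.0, 5.0, xtol=1e-12)
    Q = _build_generator(pi, 10.0 ** log_c, 1.0)
    m70, _ = _loop_mfpts(Q, pi)
    return Q * (m70 / mfpt70_ms)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_canonical_model(variant: str, timestep_ns: float = 2000.0) -> KineticModel:
    """Construct the canonical five-macrostate kinetic model for a variant.

    The macrostate populations, adjacency and MFPT calibration targets are
    fixed model constants (see module docstring); the returned model carries a
    trivial one-microstate-per-macrostate expansion.
    """
    if variant not in CANONICAL_POPULATIONS:
        raise ValidationError(
            f"unknown variant {variant!r}; expected one of WT, D66A, H70A")
    pi = np.array(CANONICAL_POPULATIONS[variant], dtype=float)
    Q = _calibrated_generator(pi, TARGET_MFPT_70S_MS[variant])
    tau_ms = timestep_ns * 1e-6
    micro_T = expm(Q * tau_ms)
    macrostates = []
    for k, label in enumerate(MACRO_LABELS):
        macrostates.append(MacrostateSpec(
            label=label,
            loop70=LOOP70_STATE[label],
            loop100=LOOP100_STATE[label],
            population=float(pi[k]),
            n_micro=1,
            feature_mean=np.array(FEATURE_MEANS[label], dtype=float),
            feature_spread=np.full(2, FEATURE_SPREAD),
            hbond_prob=_state_hbond_probs(label, variant),
            shifts=_state_shift_table(label),
        ))
    model = KineticModel(
        variant=variant,
        macrostates=macrostates,
        macro_rates=Q,
        timestep_ns=timestep_ns,
        micro_T=micro_T,
        micro_to_macro=np.arange(len(MACRO_LABELS)),
        micro_pi=pi.copy(),
        micro_feature_mean=np.array([FEATURE_MEANS[l] for l in MACRO_LABELS]),
        micro_feature_spread=np.full((len(MACRO_LABELS), 2), FEATURE_SPREAD),
    )
    model.validate()
    return model


def _implied_timescales(T: np.ndarray, pi: np.ndarray, tau_ms: float,
                        n: int) -> np.ndarray:
    """Slowest ``n`` nontrivial implied timescales (ms) of a reversible T."""
    s = np.sqrt(pi)
    sym = (s[:, None] * T) / s[None, :]
    vals = np.linalg.eigvalsh(0.5 * (sym + sym.T))
    vals = np.sort(vals)[::-1]
    lam = np.clip(vals[1:n + 1], 1e-300, 1 - 1e-16)
    return -tau_ms / np.log(lam)


def expand_to_microstates(model: KineticModel, n_micro_per_macro: int,
                          intra_rate_scale: float = 100.0) -> KineticModel:
    """Expand each macrostate into ``n_micro_per_macro`` fast-mixing microstates.

    Microstates carry uniform sub-populations; intra-macrostate exchange is a
    complete graph relaxing at ``intra_rate_scale`` times the fastest
    inter-macrostate rate, so the slow spectrum of the expanded chain
    reproduces the macro-level kinetics.
    """
    if n_micro_per_macro < 1:
        raise ValidationError("n_micro_per_macro must be >= 1")
    n = n_micro_per_macro
    if n == 1:
        return model
    Q = model.macro_rates
    pi = model.macro_pi
    max_inter = float(np.max(Q - np.diag(np.diag(Q))))
    if intra_rate_scale < 50.0:
        raise TimescaleSeparationError(
            f"intra_rate_scale = {intra_rate_scale} < 50: intra-macrostate "
            f"relaxation ({intra_rate_scale * max_inter:.3g}/ms) would not be "
            f"separated from the fastest inter-macrostate rate "
            f"({max_inter:.3g}/ms)")
    n_macro = model.n_macro
    N = n_macro * n
    Qm = np.zeros((N, N))
    member = np.repeat(np.arange(n_macro), n)
    intra = intra_rate_scale * max_inter / n
    for a in range(N):
        for b in range(N):
            if a == b:
                continue
            ma, mb = member[a], member[b]
            if ma == mb:
                Qm[a, b] = intra
            elif Q[ma, mb] > 0:
                Qm[a, b] = Q[ma, mb] / n
    np.fill_diagonal(Qm, -Qm.sum(axis=1))
    micro_pi = np.repeat(pi / n, n)
    tau_ms = model.timestep_ns * 1e-6
    micro_T = expm(Qm * tau_ms)
    # deterministic jitter so microstates are distinguishable in feature space
    jitter = np.random.default_rng(20240501).normal(0.0, 0.03, size=(N, 2))
    mean = np.array([model.macrostates[m].feature_mean for m in member]) + jitter
    spread = np.array([model.macrostates[m].feature_spread for m in member])

    its_macro = _implied_timescales(model.macro_T(), pi, tau_ms, n_macro - 1)
    its_micro = _implied_timescales(micro_T, micro_pi, tau_ms, n_macro - 1)
    rel = np.abs(its_micro - its_macro) / its_macro
    if np.max(rel) > 0.05:
        raise TimescaleSeparationError(
            f"slow implied timescales of the expanded chain deviate by up to "
            f"{100 * np.max(rel):.1f}% from the macro-level timescales; "
            f"intra rate {intra * n:.3g}/ms vs fastest inter rate "
            f"{max_inter:.3g}/ms is insufficient separation")

    macrostates = [replace(m, n_micro=n) for m in model.macrostates]
    out = KineticModel(
        variant=model.variant,
        macrostates=macrostates,
        macro_rates=Q,
        timestep_ns=model.timestep_ns,
        micro_T=micro_T,
        micro_to_macro=member,
        micro_pi=micro_pi,
        micro_feature_mean=mean,
        micro_feature_spread=spread,
    )
    out.validate()
    return out


def simulate_dtrajs(model: KineticModel, n_traj: int, n_steps: int,
                    seed: int) -> SyntheticTrajectorySet:
    """Sample discrete microstate trajectories from the model's Markov chain.

    All trajectories start from the stationary distribution and are advanced
    synchronously with one seeded generator, so identical seeds give
    bit-identical output.
    """
    if n_traj < 1 or n_steps < 2:
        raise ValidationError("need n_traj >= 1 and n_steps >= 2")
    T = model.micro_T
    if np.any(T < -1e-12) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-9:
        raise ValidationError("micro_T is not row-stochastic")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    start_cum = np.cumsum(model.micro_pi)
    states = np.searchsorted(start_cum, rng.random(n_traj), side="right")
    states = np.minimum(states, model.n_micro - 1).astype(np.int64)
    out = np.empty((n_traj, n_steps), dtype=np.int32)
    out[:, 0] = states
    for t in range(1, n_steps):
        u = rng.random(n_traj)
        states = (cum[states] < u[:, None]).sum(axis=1)
        out[:, t] = states
    traj = SyntheticTrajectorySet(
        dtrajs=[out[i].copy() for i in range(n_traj)],
        features=None,
        timestep_ns=model.timestep_ns,
        seed=seed,
        model_ref=model.variant,
    )
    traj.validate(n_states=model.n_micro)
    return traj


def emit_observables(traj: SyntheticTrajectorySet, model: KineticModel, seed: int):
    """Draw per-frame features and H-bond indicators conditioned on the state.

    Returns ``(features, hbond_table, shift_tables)`` where ``features`` is a
    list of (n_frames, 2) arrays, ``hbond_table`` a
    :class:`~dyndesign.designability.HBondTable` with macrostate labels, and
    ``shift_tables`` the per-macrostate :class:`~dyndesign.nmr.ShiftTable`
    objects copied from the model.
    """
    from .designability import HBondTable
    from .nmr import ShiftTable

    rng = np.random.default_rng(seed)
    all_states = np.concatenate(traj.dtrajs)
    if all_states.max() >= model.n_micro:
        raise MissingEmissionError(
            f"trajectory visits state {int(all_states.max())} with no "
            f"emission parameters (model has {model.n_micro} microstates)")

    features = []
    for d in traj.dtrajs:
        z = rng.standard_normal((len(d), 2))
        features.append(model.micro_feature_mean[d]
                        + model.micro_feature_spread[d] * z)

    macro = model.micro_to_macro[all_states]
    pairs = list(model.macrostates[0].hbond_prob)
    prob_by_state = np.array(
        [[m.hbond_prob[p] for p in pairs] for m in model.macrostates])
    data = {"frame": np.arange(len(all_states))}
    traj_idx = np.concatenate(
        [np.full(len(d), i) for i, d in enumerate(traj.dtrajs)])
    data["traj"] = traj_idx
    draws = rng.random((len(all_states), len(pairs)))
    present = (draws < prob_by_state[macro]).astype(np.int64)
    for j, (donor, acceptor) in enumerate(pairs):
        data[f"{donor}:{acceptor}"] = present[:, j]
    df = pd.DataFrame(data)
    labels = pd.Series([model.macrostates[m].label for m in macro],
                       name="state")
    hbond = HBondTable(df=df, state_labels=labels)

    shift_tables = [
        ShiftTable.from_dict(m.shifts, provenance="per_state", label=m.label)
        for m in model.macrostates
    ]
    return features, hbond, shift_tables


def canonical_dispersion_spec(variant: str, noise_sd: float = 0.3) -> DispersionSimSpec:
    """Two-state dispersion ground truth matching the published global fits.

    WT: kex = 2200 s^-1, pB = 2.0%; D66A: kex = 2000 s^-1, pB = 0.5%.  The
    per-residue 15N shift differences follow the planted 70s-loop pattern.
    """
    if variant == "WT":
        pB, kex = 0.020, 2200.0
    elif variant == "D66A":
        pB, kex = 0.005, 2000.0
    else:
        raise ValidationError(f"no canonical dispersion spec for {variant!r}")
    residues = [65, 66, 68, 69, 71, 72, 73, 74, 75, 77]
    dw = {r: DW_N_PPM[r] for r in residues}
    fields = [600.0, 800.0]
    r20 = {(r, f): round(11.0 + 0.004 * f + 0.15 * (r % 5), 3)
           for r in residues for f in fields}
    spec = DispersionSimSpec(
        pB=pB,
        kex=kex,
        dw_ppm=dw,
        r20=r20,
        fields_mhz=fields,
        nu_cpmg_grid=[25, 50, 75, 100, 150, 200, 250, 300,
                      400, 500, 600, 700, 800, 900, 1000],
        spinlock_grid=[(1000.0, 0.0), (1500.0, 0.0),
                       (2000.0, 0.0), (3000.0, 0.0)],
        noise_sd=noise_sd,
    )
    spec.validate()
    return spec


def simulate_dispersion(spec: DispersionSimSpec, seed: int):
    """Simulate a noisy dispersion dataset from the numerical forward model.

    Noiseless R2eff / R1rho values come from the Bloch-McConnell propagators in
    :mod:`dyndesign.dispersion`; independent Gaussian noise of sd
    ``spec.noise_sd`` is added and recorded as the per-point error (unit
    weights are recorded when ``noise_sd`` is 0).
    """
    from .dispersion import (DispersionDataset, r1rho_two_state,
                             r2eff_two_state_cpmg)

    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for r in sorted(spec.dw_ppm):
        for f in spec.fields_mhz:
            dw_rad = float(ppm_to_rad_s(spec.dw_ppm[r], f))
            r20 = spec.r20[(r, f)]
            for nu in spec.nu_cpmg_grid:
                rate = r2eff_two_state_cpmg(spec.pB, spec.kex, dw_rad, r20,
                                            nu, method="numerical")
                rows.append((r, f, "cpmg", nu, np.nan, np.nan, float(rate)))
            for w1, off in spec.spinlock_grid:
                rate = r1rho_two_state(spec.pB, spec.kex, dw_rad, r20, spec.r1,
                                       w1, off, method="numerical")
                rows.append((r, f, "r1rho", np.nan, w1, off, float(rate)))
    df = pd.DataFrame(rows, columns=["residue", "field_mhz", "experiment",
                                     "nu_cpmg_hz", "omega1_hz", "offset_hz",
                                     "rate_s"])
    if spec.noise_sd > 0:
        df["rate_s"] = df["rate_s"] + rng.normal(0.0, spec.noise_sd, len(df))
        df["error_s"] = spec.noise_sd
    else:
        df["error_s"] = 1.0
        warnings.warn("noise_sd = 0: recording unit errors for uniform weights")
    meta = {"pB": spec.pB, "kex": spec.kex, "r1": spec.r1, "seed": seed,
            "noise_sd": spec.noise_sd, "provenance": "synthetic"}
    return DispersionDataset(points=df, metadata=meta)
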
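"""Markov state model estimation, kinetic lumping and first-passage analysis.

Implements the standard reversible MSM workflow: transition counting at a lag
time, restriction to the largest strongly connected state set, maximum
likelihood estimation of a detailed-balanced transition matrix by the
self-consistent fixed-point iteration, spectral (PCCA+-style) lumping into
macrostates, mean first passage times by linear solve, and trajectory-level
bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (ConnectivityError, ConvergenceError,
                     DegenerateSpectrumError, ValidationError)


def _as_dtrajs(dtrajs) -> list[np.ndarray]:
    if hasattr(dtrajs, "dtrajs"):
        dtrajs = dtrajs.dtrajs
    return [np.asarray(d, dtype=np.int64) for d in dtrajs]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Transition counts at one lag time."""

    counts: np.ndarray
    lag: int
    mode: str
    n_frames_used: int

    def validate(self) -> None:
        if np.any(self.counts < 0):
            raise ValidationError("negative transition counts")
        if self.mode not in ("sliding", "strided"):
            raise ValidationError(f"unknown counting mode {self.mode!r}")


@dataclass
class MSMEstimate:
    """Reversible MSM on the largest connected set."""

    T: np.ndarray
    pi: np.ndarray
    lag: int
    active_set: np.ndarray
    loglik: float

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def validate(self) -> None:
        if np.max(np.abs(self.T.sum(axis=1) - 1.0)) > 1e-10:
            raise ValidationError("T rows do not sum to 1")
        if np.any(self.pi < -1e-15) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValidationError("pi is not a distribution")
        flux = self.pi[:, None] * self.T
        if np.max(np.abs(flux - flux.T)) > 1e-8:
            raise ValidationError("detailed balance violated beyond 1e-8")


@dataclass
class MacrostateModel:
    """Lumped macrostate model with populations and MFPTs.

    ``membership`` maps each active microstate to a macrostate index (crisp,
    argmax of the fuzzy memberships, ties to the lowest index);
    ``mfpt_matrix`` is in milliseconds.
    """

    membership: np.ndarray
    fuzzy_membership: np.ndarray
    macro_pi: np.ndarray
    mfpt_matrix: np.ndarray
    lag: int
    timestep_ns: float
    active_set: np.ndarray
    ci: dict = dc_field(default_factory=dict)
    n_boot_dropped: int = 0

    @property
    def n_macro(self) -> int:
        return len(self.macro_pi)

    def validate(self) -> None:
        if abs(self.macro_pi.sum() - 1.0) > 1e-9:
            raise ValidationError("macro populations do not sum to 1")
        if np.any(np.abs(np.diag(self.mfpt_matrix)) > 0):
            raise ValidationError("MFPT diagonal must be 0")
        lag_ms = self.lag * self.timestep_ns * 1e-6
        off = self.mfpt_matrix[~np.eye(self.n_macro, dtype=bool)]
        if np.any(off < lag_ms - 1e-12):
            raise ValidationError("MFPT below one lag time")


# ---------------------------------------------------------------------------
# counting and connectivity
# ---------------------------------------------------------------------------


def count_transitions(dtrajs, lag: int, mode: str = "sliding") -> CountMatrix:
    """Count (t, t+lag) state pairs; trajectories are never concatenated."""
    dtrajs = _as_dtrajs(dtrajs)
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    usable = [d for d in dtrajs if len(d) > lag]
    if not usable:
        raise ValidationError(f"no trajectory longer than lag {lag}")
    n_states = int(max(d.max() for d in usable)) + 1
    counts = np.zeros((n_states, n_states))
    n_used = 0
    step = 1 if mode == "sliding" else lag
    if mode not in ("sliding", "strided"):
        raise ValidationError(f"unknown counting mode {mode!r}")
    for d in usable:
        src = d[:-lag:step]
        dst = d[lag::step]
        np.add.at(counts, (src, dst), 1.0)
        n_used += len(src)
    cm = CountMatrix(counts=counts, lag=lag, mode=mode, n_frames_used=n_used)
    cm.validate()
    return cm


def largest_connected_set(counts: CountMatrix) -> np.ndarray:
    """Largest set of states mutually reachable through nonzero counts."""
    C = counts.counts
    if C.size == 0 or C.sum() == 0:
        raise ValidationError("empty count matrix")
    n_comp, labels = connected_components(csr_matrix(C > 0), directed=True,
                                          connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.where(labels == comp)[0]
        mass = C[np.ix_(members, members)].sum()
        key = (len(members), mass, -members[0])
        if best_key is None or key > best_key:
            best, best_key = members, key
    return np.sort(best)


# ---------------------------------------------------------------------------
# reversible maximum-likelihood estimation
# ---------------------------------------------------------------------------


def estimate_reversible_T(counts: CountMatrix, tol: float = 1e-10,
                          max_iter: int = 100_000,
                          x_init: np.ndarray | None = None) -> MSMEstimate:
    """Reversible MLE transition matrix by self-consistent fixed-point iteration.

    Maximises the likelihood over detailed-balanced transition matrices via
    the standard update on the unnormalised symmetric flux x_ij:
    x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j).  Convergence is declared when
    the stationary distribution changes by less than ``tol`` (max norm).
    """
    active = largest_connected_set(counts)
    C = counts.counts[np.ix_(active, active)]
    c_i = C.sum(axis=1)
    sym = C + C.T
    x = sym.copy() if x_init is None else x_init.copy()
    x /= x.sum()
    pi_old = x.sum(axis=1)
    mask = sym > 0
    resid = np.inf
    for _ in range(max_iter):
        x_i = x.sum(axis=1)
        denom = c_i[:, None] / x_i[:, None] + c_i[None, :] / x_i[None, :]
        x = np.where(mask, sym / np.where(denom > 0, denom, 1.0), 0.0)
        x /= x.sum()
        pi = x.sum(axis=1)
        resid = float(np.max(np.abs(pi - pi_old)))
        if resid < tol:
            break
        pi_old = pi
    else:
        raise ConvergenceError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(last max |dpi| = {resid:.3e})", residual=resid)
    x_i = x.sum(axis=1)
    T = x / x_i[:, None]
    # clean roundoff so the documented invariants hold exactly enough
    T = T / T.sum(axis=1, keepdims=True)
    pi = x_i / x_i.sum()
    with np.errstate(divide="ignore"):
        logT = np.where(T > 0, np.log(np.where(T > 0, T, 1.0)), 0.0)
    loglik = float(np.sum(C * logT))
    est = MSMEstimate(T=T, pi=pi, lag=counts.lag, active_set=active,
                      loglik=loglik)
    est.validate()
    return est


# ---------------------------------------------------------------------------
# spectral analysis
# ---------------------------------------------------------------------------


def _reversible_eig(T: np.ndarray, pi: np.ndarray):
    """Full real spectrum of a reversible T via symmetrisation."""
    s = np.sqrt(np.maximum(pi, 1e-300))
    sym = (s[:, None] * T) / s[None, :]
    vals, vecs = np.linalg.eigh(0.5 * (sym + sym.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    psi = vecs[:, order] / s[:, None]  # right eigenvectors of T
    return vals, psi


def implied_timescales(T: np.ndarray, pi: np.ndarray, lag: int,
                       n: int) -> np.ndarray:
    """Slowest ``n`` nontrivial implied timescales in units of steps."""
    vals, _ = _reversible_eig(T, pi)
    lam = np.clip(vals[1:n + 1], 1e-300, 1.0 - 1e-16)
    return -lag / np.log(lam)


def _pcca_memberships(T: np.ndarray, pi: np.ndarray, n_macro: int,
                      degeneracy_tol: float = 1e-10) -> np.ndarray:
    """Fuzzy memberships from the dominant eigenvectors (PCCA+ inner simplex).

    Vertices of the simplex spanned by the first ``n_macro`` right
    eigenvectors are located by successive orthogonal farthest-point search;
    memberships are the barycentric coordinates, clipped to [0, 1] and
    renormalised.
    """
    n = T.shape[0]
    if not 2 <= n_macro <= n:
        raise ValidationError(f"n_macro must be in [2, {n}]")
    vals, psi = _reversible_eig(T, pi)
    if vals[n_macro - 1] - vals[n_macro] < degeneracy_tol:
        raise DegenerateSpectrumError(
            f"eigenvalues {n_macro - 1} and {n_macro} are degenerate "
            f"({vals[n_macro - 1]:.12f} vs {vals[n_macro]:.12f}); "
            f"try a different n_macro")
    X = psi[:, :n_macro].copy()
    X[:, 0] = 1.0
    # inner-simplex vertex search
    idx = np.zeros(n_macro, dtype=int)
    ortho = X.copy()
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho -= ortho[idx[0]]
    for j in range(1, n_macro):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        v = ortho[idx[j]] / max(norms[idx[j]], 1e-300)
        ortho -= np.outer(ortho @ v, v)
    A = np.linalg.inv(X[idx])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


# ---------------------------------------------------------------------------
# MFPT
# ---------------------------------------------------------------------------


def mfpt(msm: MSMEstimate, source, target, timestep_ns: float = 1.0) -> float:
    """Mean first passage time (ms) from a source set to a target set.

    Solves the hitting-time system (I - T_restricted) h = lag on the
    complement of the target and averages h over the source states weighted
    by the restricted stationary distribution.  State indices refer to the
    active set of the estimate.
    """
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    n = msm.n_states
    if len(source) == 0 or len(target) == 0:
        raise ValidationError("source and target must be non-empty")
    if np.intersect1d(source, target).size:
        raise ValidationError("source and target sets must be disjoint")
    if source.max() >= n or target.max() >= n:
        raise ValidationError("state index outside the active set")
    keep = np.setdiff1d(np.arange(n), target)
    A = np.eye(len(keep)) - msm.T[np.ix_(keep, keep)]
    try:
        h_keep = np.linalg.solve(A, np.full(len(keep), float(msm.lag)))
    except np.linalg.LinAlgError as exc:
        raise ConnectivityError(f"target set unreachable: {exc}") from exc
    if np.any(~np.isfinite(h_keep)) or np.any(h_keep < 0):
        raise ConnectivityError("target set unreachable from part of the chain")
    h = np.zeros(n)
    h[keep] = h_keep
    w = msm.pi[source] / msm.pi[source].sum()
    return float(np.dot(w, h[source])) * timestep_ns * 1e-6


# ---------------------------------------------------------------------------
# lumping
# ---------------------------------------------------------------------------


def pcca_lump(msm: MSMEstimate, n_macro: int,
              timestep_ns: float = 1.0) -> MacrostateModel:
    """Lump an MSM into macrostates by PCCA+-style spectral clustering."""
    if n_macro == msm.n_states:
        chi = np.eye(n_macro)
    else:
        chi = _pcca_memberships(msm.T, msm.pi, n_macro)
    crisp = np.argmax(chi, axis=1)
    if len(np.unique(crisp)) < n_macro:
        raise DegenerateSpectrumError(
            f"crisp lumping left {n_macro - len(np.unique(crisp))} empty "
            f"macrostates; try a different n_macro")
    macro_pi = np.zeros(n_macro)
    np.add.at(macro_pi, crisp, msm.pi)
    M = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        for b in range(n_macro):
            if a == b:
                continue
            M[a, b] = mfpt(msm, np.where(crisp == a)[0],
                           np.where(crisp == b)[0], timestep_ns)
    model = MacrostateModel(
        membership=crisp, fuzzy_membership=chi, macro_pi=macro_pi,
        mfpt_matrix=M, lag=msm.lag, timestep_ns=timestep_ns,
        active_set=msm.active_set)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# validation (implied timescales + Chapman-Kolmogorov)
# ---------------------------------------------------------------------------


def _coarse_grain(T: np.ndarray, pi: np.ndarray,
                  membership: np.ndarray, n_macro: int) -> np.ndarray:
    P = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        ia = membership == a
        wa = pi[ia] / pi[ia].sum()
        for b in range(n_macro):
            P[a, b] = float(wa @ T[np.ix_(ia, membership == b)].sum(axis=1))
    return P


def validate_msm(dtrajs, lags, n_macro: int, mode: str = "sliding",
                 max_ck: int = 5):
    """Implied timescales across lags and Chapman-Kolmogorov deviations.

    Returns ``(its, ck)``: a DataFrame of the n_macro-1 slowest implied
    timescales (steps) per lag, and a dict k -> max |[T(tau)]^k - T(k tau)|
    coarse-grained onto the macrostate sets of the base-lag model.
    """
    lags = sorted(set(int(l) for l in lags))
    if len(lags) < 2:
        raise ValidationError("need at least two lags")
    rows = []
    estimates = {}
    for lag in lags:
        est = estimate_reversible_T(count_transitions(dtrajs, lag, mode))
        estimates[lag] = est
        its = implied_timescales(est.T, est.pi, lag, n_macro - 1)
        rows.append([lag, *its])
    its_df = pd.DataFrame(
        rows, columns=["lag"] + [f"ts_{k}" for k in range(1, n_macro)])

    base = lags[0]
    base_est = estimates[base]
    lump = pcca_lump(base_est, n_macro)
    ck = {}
    for k in range(2, max_ck + 1):
        lag_k = base * k
        try:
            est_k = estimate_reversible_T(
                count_transitions(dtrajs, lag_k, mode))
        except (ValidationError, ConnectivityError):
            break
        shared = np.intersect1d(base_est.active_set, est_k.active_set)
        sel_b = np.searchsorted(base_est.active_set, shared)
        sel_k = np.searchsorted(est_k.active_set, shared)
        Tb = np.linalg.matrix_power(base_est.T, k)[np.ix_(sel_b, sel_b)]
        Tk = est_k.T[np.ix_(sel_k, sel_k)]
        mem = lump.membership[sel_b]
        Pb = _coarse_grain(Tb, base_est.pi[sel_b], mem, n_macro)
        Pk = _coarse_grain(Tk, est_k.pi[sel_k], mem, n_macro)
        ck[k] = float(np.max(np.abs(Pb - Pk)))
    return its_df, ck


# ---------------------------------------------------------------------------
# feature clustering
# ---------------------------------------------------------------------------


def cluster_features(features, k: int, seed: int) -> list[np.ndarray]:
    """k-means microstate assignment preserving trajectory boundaries."""
    from sklearn.cluster import KMeans

    features = [np.asarray(f, dtype=float) for f in features]
    X = np.concatenate(features, axis=0)
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(X):
        raise ValidationError(f"k = {k} exceeds the {len(X)} available frames")
    if k == 1:
        labels = np.zeros(len(X), dtype=np.int64)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(X).astype(np.int64)
    out, pos = [], 0
    for f in features:
        out.append(labels[pos:pos + len(f)])
        pos += len(f)
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _per_traj_counts(dtrajs, lag: int, n_states: int, mode: str):
    mats = []
    step = 1 if mode == "sliding" else lag
    for d in dtrajs:
        C = np.zeros((n_states, n_states))
        if len(d) > lag:
            np.add.at(C, (d[:-lag:step], d[lag::step]), 1.0)
        mats.append(C)
    return mats


def _match_macrostates(ref: MacrostateModel, ref_est: MSMEstimate,
                       rep: MacrostateModel, rep_est: MSMEstimate) -> np.ndarray:
    """Permutation aligning replicate macrostates to the reference ones."""
    n_macro = ref.n_macro
    overlap = np.zeros((n_macro, n_macro))
    rep_pos = {s: i for i, s in enumerate(rep_est.active_set)}
    for i_ref, state in enumerate(ref_est.active_set):
        if state not in rep_pos:
            continue
        i_rep = rep_pos[state]
        overlap[ref.membership[i_ref], rep.membership[i_rep]] += \
            rep_est.pi[i_rep]
    _, perm = linear_sum_assignment(-overlap)
    return perm


def bootstrap_msm(dtrajs, lag: int, n_macro: int, n_boot: int = 200,
                  level: float = 0.95, seed: int = 0,
                  timestep_ns: float = 1.0,
                  mode: str = "sliding") -> MacrostateModel:
    """Trajectory-level bootstrap of macrostate populations and MFPTs.

    Whole trajectories are resampled with replacement ``n_boot`` times; each
    replicate is re-estimated, re-lumped and aligned to the full-data
    macrostates by maximal stationary-weight overlap.  Percentile intervals at
    ``level`` are attached to the returned full-data model.  Replicates that
    lose connectivity (or any macrostate) are dropped and counted; more than
    50% drops is an error.
    """
    dtrajs = _as_dtrajs(dtrajs)
    counts = count_transitions(dtrajs, lag, mode)
    ref_est = estimate_reversible_T(counts)
    ref = pcca_lump(ref_est, n_macro, timestep_ns)

    n_states = counts.counts.shape[0]
    traj_counts = _per_traj_counts(dtrajs, lag, n_states, mode)
    rng = np.random.default_rng(seed)
    n_traj = len(dtrajs)
    pis, mfpts = [], []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_traj, size=n_traj)
        C = np.zeros((n_states, n_states))
        for i in pick:
            C += traj_counts[i]
        cm = CountMatrix(counts=C, lag=lag, mode=mode,
                         n_frames_used=counts.n_frames_used)
        warm = ref_est.pi[:, None] * ref_est.T  # warm start from full data
        try:
            rep_active = largest_connected_set(cm)
            x_init = warm if np.array_equal(rep_active, ref_est.active_set) \
                else None
            est = estimate_reversible_T(cm, x_init=x_init)
            rep = pcca_lump(est, n_macro, timestep_ns)
        except (ValidationError, ConnectivityError, DegenerateSpectrumError,
                ConvergenceError):
            dropped += 1
            continue
        perm = _match_macrostates(ref, ref_est, rep, est)
        pis.append(rep.macro_pi[perm])
        mfpts.append(rep.mfpt_matrix[np.ix_(perm, perm)])
    if dropped > n_boot / 2:
        raise ConnectivityError(
            f"{dropped}/{n_boot} bootstrap replicates lost connectivity")
    if dropped:
        warnings.warn(f"{dropped}/{n_boot} bootstrap replicates dropped")
    lo, hi = 50 * (1 - level), 50 * (1 + level)
    pis = np.array(pis)
    mfpts = np.array(mfpts)
    ref.ci = {
        "macro_pi": (level, np.percentile(pis, lo, axis=0),
                     np.percentile(pis, hi, axis=0)),
        "mfpt": (level, np.percentile(mfpts, lo, axis=0),
                 np.percentile(mfpts, hi, axis=0)),
    }
    ref.n_boot_dropped = dropped
    return ref
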
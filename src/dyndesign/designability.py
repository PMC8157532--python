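"""Hydrogen-bond statistics, designability ranking and structural metrics.

The design strategy scores each residue by the difference in the average
number of hydrogen bonds it makes to a partner loop between the 70s-closed
and 70s-open macrostate groups: a residue that bonds strongly in one group
and weakly in the other is "designable" — mutating it should shift the
populations towards the weakly bonded group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ValidationError

#: macrostate groups used for closed-vs-open comparisons (the intermediate
#: counts with the open group).
CLOSED_STATES = ("o100_c70", "c100_c70")
OPEN_STATES = ("intermediate", "o100_o70", "c100_o70")

#: default geometric hydrogen-bond criterion: donor-acceptor distance (A)
#: and donor-hydrogen-acceptor angle (degrees), both inclusive.
DEFAULT_CRITERION = (3.5, 120.0)

#: 70s-loop partner residues for the canonical per-residue profiles.
LOOP70_PARTNERS = tuple(range(65, 78))

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def residue_tag(res_name: str, res_id: int) -> str:
    """One-letter-code residue tag, e.g. ('ASP', 66) -> 'D66'."""
    return f"{_THREE_TO_ONE.get(res_name.upper(), 'X')}{res_id}"


def parse_residue_tag(tag: str) -> int:
    """Residue number from a tag like 'D66'."""
    return int("".join(ch for ch in tag if ch.isdigit()))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HBondTable:
    """Per-frame hydrogen-bond indicators in wide form.

    ``df`` has a contiguous ``frame`` column and one 0/1 column per observed
    donor:acceptor residue pair (e.g. ``"D66:G72"``); ``state_labels`` is an
    optional per-frame macrostate label series.
    """

    df: pd.DataFrame
    state_labels: pd.Series | None = None
    inferred_hydrogens: bool = False

    @property
    def frames(self) -> int:
        return len(self.df)

    @property
    def pair_columns(self) -> list[str]:
        return [c for c in self.df.columns if ":" in c]

    def validate(self) -> None:
        if "frame" not in self.df.columns:
            raise ValidationError("H-bond table needs a 'frame' column")
        fr = self.df["frame"].to_numpy()
        if len(fr) and not np.array_equal(fr, np.arange(len(fr))):
            raise ValidationError("frame indices must be contiguous from 0")
        for c in self.pair_columns:
            vals = self.df[c].unique()
            if not set(vals) <= {0, 1}:
                raise ValidationError(f"column {c} is not boolean 0/1")
        if self.state_labels is not None and len(self.state_labels) != len(self.df):
            raise ValidationError("state_labels length mismatch")

    def long(self) -> pd.DataFrame:
        """Long-form records (frame, donor, acceptor, present)."""
        recs = []
        for c in self.pair_columns:
            donor, acceptor = c.split(":")
            sub = self.df[["frame", c]].rename(columns={c: "present"})
            sub["donor"] = donor
            sub["acceptor"] = acceptor
            recs.append(sub)
        return pd.concat(recs, ignore_index=True)[
            ["frame", "donor", "acceptor", "present"]]


@dataclass
class DesignabilityScore:
    """Closed-vs-open mean H-bond difference for one residue."""

    residue: str
    mean_closed: float
    mean_open: float
    delta: float
    rank: int

    def validate(self) -> None:
        if abs(self.delta - (self.mean_closed - self.mean_open)) > 1e-12:
            raise ValidationError("delta != mean_closed - mean_open")


# ---------------------------------------------------------------------------
# geometric H-bond detection
# ---------------------------------------------------------------------------


def _infer_hydrogen(coord, donor_idx, neighbor_coords):
    """Place a hydrogen 1.01 A from the donor, away from its heavy neighbours."""
    d = coord[donor_idx]
    if len(neighbor_coords) == 0:
        return None
    v = d - np.mean(neighbor_coords, axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        return None
    return d + 1.01 * v / norm


def detect_hbonds(structure, criterion=DEFAULT_CRITERION) -> HBondTable:
    """Detect hydrogen bonds in a multi-model structure.

    ``structure`` is a biotite ``AtomArrayStack`` or a path to a multi-model
    PDB file.  A bond between a donor (N/O with at least one hydrogen, which
    is inferred geometrically and flagged when absent) and an acceptor (N/O in
    a different residue) is present iff the donor-acceptor distance is at most
    ``criterion[0]`` A and the best D-H...A angle is at least ``criterion[1]``
    degrees (inclusive bounds).
    """
    import biotite.structure as struc

    if isinstance(structure, (str, bytes)) or hasattr(structure, "__fspath__"):
        from biotite.structure.io.pdb import PDBFile
        structure = PDBFile.read(str(structure)).get_structure()
    if isinstance(structure, struc.AtomArray):
        structure = struc.stack([structure])
    max_dist, min_angle = criterion
    if max_dist <= 0 or min_angle <= 0:
        raise ValidationError("criterion must be positive")

    elem = np.char.upper(structure.element.astype(str))
    res_ids = structure.res_id
    res_names = structure.res_name.astype(str)
    is_h = np.char.startswith(elem, "H")
    is_no = (elem == "N") | (elem == "O")

    rows = []
    inferred_any = False
    n_skipped = 0
    for m in range(structure.stack_depth()):
        coord = structure.coord[m]
        if not np.all(np.isfinite(coord)):
            warnings.warn(f"model {m}: non-finite coordinates, frame skipped")
            n_skipped += 1
            continue
        bonds = {}
        heavy_idx = np.where(is_no)[0]
        h_idx = np.where(is_h)[0]
        for d_i in heavy_idx:
            # hydrogens covalently attached to this heavy atom
            if len(h_idx):
                dists_h = np.linalg.norm(coord[h_idx] - coord[d_i], axis=1)
                mine = h_idx[dists_h < 1.3]
            else:
                mine = np.array([], dtype=int)
            if len(mine):
                h_coords = coord[mine]
            else:
                near = np.where(
                    (np.linalg.norm(coord - coord[d_i], axis=1) < 1.7)
                    & ~is_h & (np.arange(len(coord)) != d_i))[0]
                h = _infer_hydrogen(coord, d_i, coord[near])
                if h is None:
                    continue  # not a plausible donor
                h_coords = h[None, :]
                inferred_any = True
            for a_i in heavy_idx:
                if res_ids[a_i] == res_ids[d_i]:
                    continue
                da = np.linalg.norm(coord[a_i] - coord[d_i])
                if da > max_dist:
                    continue
                v1 = coord[d_i] - h_coords
                v2 = coord[a_i] - h_coords
                cosang = np.sum(v1 * v2, axis=1) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if np.max(ang) >= min_angle:
                    pair = (residue_tag(res_names[d_i], int(res_ids[d_i])),
                            residue_tag(res_names[a_i], int(res_ids[a_i])))
                    bonds[pair] = 1
        rows.append(bonds)
    if not rows:
        raise ValidationError("all frames were skipped")
    if n_skipped:
        warnings.warn(f"{n_skipped} malformed models skipped")
    pairs = sorted({p for r in rows for p in r})
    data = {"frame": np.arange(len(rows))}
    for donor, acceptor in pairs:
        data[f"{donor}:{acceptor}"] = [r.get((donor, acceptor), 0)
                                       for r in rows]
    table = HBondTable(df=pd.DataFrame(data),
                       inferred_hydrogens=inferred_any)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# per-state profiles and ranking
# ---------------------------------------------------------------------------


def _residue_pair_columns(table: HBondTable, residue: str,
                          partners) -> list[str]:
    partners = {str(p) for p in partners} | {
        str(parse_residue_tag(p)) if isinstance(p, str) else str(p)
        for p in partners}
    cols = []
    for c in table.pair_columns:
        donor, acceptor = c.split(":")
        for mine, other in ((donor, acceptor), (acceptor, donor)):
            if mine == residue and (
                    other in partners
                    or str(parse_residue_tag(other)) in partners):
                cols.append(c)
                break
    return cols


def state_hbond_profiles(table: HBondTable, residue: str,
                         partners) -> dict[str, np.ndarray]:
    """Per-macrostate distribution of the residue's H-bond count to a partner set.

    Returns, for each state label, the empirical probability distribution of
    the per-frame number of present bonds between ``residue`` and any residue
    in ``partners`` (distributions sum to 1; zero-frame states are omitted
    with a warning).
    """
    if table.state_labels is None:
        raise ValidationError("state_hbond_profiles requires state_labels")
    cols = _residue_pair_columns(table, residue, partners)
    counts = (table.df[cols].to_numpy().sum(axis=1) if cols
              else np.zeros(table.frames, dtype=int))
    n_max = int(counts.max()) if len(counts) else 0
    out = {}
    labels = np.asarray(table.state_labels)
    for state in pd.unique(labels):
        sel = counts[labels == state]
        if len(sel) == 0:
            warnings.warn(f"state {state}: zero frames, omitted")
            continue
        dist = np.bincount(sel, minlength=n_max + 1).astype(float)
        out[str(state)] = dist / dist.sum()
    return out


def profiles_by_residue(table: HBondTable, partners,
                        residues=None) -> dict[str, dict[str, np.ndarray]]:
    """Convenience: :func:`state_hbond_profiles` for every donor residue."""
    if residues is None:
        residues = sorted({c.split(":")[0] for c in table.pair_columns})
    return {r: state_hbond_profiles(table, r, partners) for r in residues}


def designability_rank(profiles: dict[str, dict[str, np.ndarray]],
                       closed_states=CLOSED_STATES, open_states=OPEN_STATES,
                       weights: dict[str, float] | None = None,
                       ) -> list[DesignabilityScore]:
    """Rank residues by |mean H-bond count (closed) - mean (open)|.

    Group means are population-weighted expectations over the member states
    (weights renormalised within each group); if no weights are supplied the
    states are averaged uniformly, with a warning.
    """
    closed = [s for s in closed_states]
    open_ = [s for s in open_states]
    if not closed or not open_:
        raise ValidationError("both state groups must be non-empty")
    if weights is None:
        warnings.warn("no populations supplied: using unweighted state means")

    def group_mean(state_dists, states):
        present = [s for s in states if s in state_dists]
        if not present:
            return np.nan
        if weights is not None:
            w = np.array([weights.get(s, 0.0) for s in present])
            w = w / w.sum() if w.sum() > 0 else np.full(len(present),
                                                        1 / len(present))
        else:
            w = np.full(len(present), 1.0 / len(present))
        means = [float(np.dot(np.arange(len(state_dists[s])), state_dists[s]))
                 for s in present]
        return float(np.dot(w, means))

    scored = []
    for residue, dists in profiles.items():
        mc = group_mean(dists, closed)
        mo = group_mean(dists, open_)
        scored.append((residue, mc, mo, mc - mo))
    scored.sort(key=lambda s: (-abs(s[3]), s[0]))
    out = [DesignabilityScore(residue=r, mean_closed=mc, mean_open=mo,
                              delta=d, rank=i + 1)
           for i, (r, mc, mo, d) in enumerate(scored)]
    for s in out:
        s.validate()
    return out


# ---------------------------------------------------------------------------
# structural metrics
# ---------------------------------------------------------------------------


def superpose(frame: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of one frame onto a reference."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    ref_c = reference - reference.mean(axis=0)
    frm_c = frame - frame.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, frm_c)
    return rot.apply(frm_c) + reference.mean(axis=0)


def structure_metrics(ensemble: np.ndarray, reference: np.ndarray):
    """Per-atom RMSF and per-frame RMSD after optimal superposition.

    ``ensemble`` is (n_frames, n_atoms, 3) — typically C-alpha coordinates —
    and ``reference`` (n_atoms, 3).  Frames are superposed onto the reference
    before both metrics; RMSF is computed about the mean of the superposed
    frames.
    """
    ensemble = np.asarray(ensemble, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if ensemble.ndim != 3 or ensemble.shape[1:] != reference.shape:
        raise ValidationError("ensemble/reference shape mismatch")
    if reference.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    aligned = np.array([superpose(f, reference) for f in ensemble])
    rmsd = np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=2), axis=1))
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    return rmsf, rmsd
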
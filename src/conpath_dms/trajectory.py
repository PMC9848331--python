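"""MD-ensemble post-processing: RMSD/RMSF, H-bond occupancies and alerts.

Operates on coordinate ensembles (multi-model PDB or generated in memory)
standing in for MD production trajectories of hRPE65 dimer models (chain A =
the mutated or WT monomer under study, chain B = the partner monomer).

Two alert rules are derived by wild-type vs mutant comparison:

* structural alert — the dimer-mediating-sequence (DMS) Cα RMSD mean over the
  second half of the trajectory exceeds a threshold (default 1.5 Å), or the
  mutant Cα RMSF shows a localized peak (>= 2 Å over >= 3 consecutive
  residues) where the WT profile stays below 1 Å;
* interaction alert — a native WT hydrogen bond involving the mutated
  residue's network is not maintained in the mutant ensemble (occupancy below
  max(floor, WT occupancy - drop)).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT"}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

DIRECT = "direct"
WATER_MEDIATED = "water_mediated"


class SelectionError(ValueError):
    """An atom selection is empty or inconsistent between frames/ensembles."""


# ---------------------------------------------------------------------------
# Ensemble container and selections
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryEnsemble:
    """An ordered stack of frames over a fixed topology.

    coords has shape (n_frames, n_atoms, 3) in Å.  All annotation arrays have
    length n_atoms.  ``frame_spacing`` is metadata only (arbitrary time units).
    """

    coords: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray | None = None
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n = self.coords.shape[1]
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        for arr, label in (
            (self.atom_names, "atom_names"),
            (self.res_ids, "res_ids"),
            (self.res_names, "res_names"),
            (self.chain_ids, "chain_ids"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != atom count {n}")
        if self.elements is None:
            # infer from the first alphabetic character of the atom name
            self.elements = np.array(
                [_element_from_name(a) for a in self.atom_names], dtype=object
            )
        else:
            self.elements = np.asarray(self.elements, dtype=object)
            blank = [i for i, e in enumerate(self.elements) if not str(e).strip()]
            for i in blank:
                self.elements[i] = _element_from_name(self.atom_names[i])
            self.elements = np.array([str(e).strip().upper() for e in self.elements],
                                     dtype=object)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_mask(self, chain: str, resid: int) -> np.ndarray:
        return (self.chain_ids == chain) & (self.res_ids == resid)

    def concat(self, other: "TrajectoryEnsemble") -> "TrajectoryEnsemble":
        if other.n_atoms != self.n_atoms or not np.array_equal(
            other.atom_names, self.atom_names
        ):
            raise SelectionError("cannot concatenate ensembles with different topologies")
        return replace(self, coords=np.concatenate([self.coords, other.coords], axis=0))


def _element_from_name(name: str) -> str:
    m = re.search(r"[A-Za-z]", str(name))
    return m.group(0).upper() if m else "X"


@dataclass(frozen=True)
class AtomSelection:
    """Predicate over (chain, residue range, atom names).

    Text form ``CHAIN:RESRANGE:NAMES`` with ``*`` wildcards, residue ranges
    inclusive, names joined by ``+``: e.g. ``A:70-125:CA`` or ``A:*:N+O``.
    """

    chain: str | None = None
    res_start: int | None = None
    res_stop: int | None = None
    atom_names: tuple[str, ...] | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        parts = text.strip().split(":")
        if len(parts) != 3:
            raise SelectionError(f"selection {text!r} must have form CHAIN:RESRANGE:NAMES")
        chain_s, res_s, name_s = (p.strip() for p in parts)
        chain = None if chain_s in ("*", "") else chain_s
        if res_s in ("*", ""):
            start = stop = None
        elif "-" in res_s:
            a, b = res_s.split("-", 1)
            start, stop = int(a), int(b)
        else:
            start = stop = int(res_s)
        names = None if name_s in ("*", "") else tuple(n.strip().upper() for n in name_s.split("+"))
        return cls(chain=chain, res_start=start, res_stop=stop, atom_names=names)

    def resolve(self, ens: TrajectoryEnsemble) -> np.ndarray:
        """Indices of matching atoms; raises if the selection is empty."""
        mask = np.ones(ens.n_atoms, dtype=bool)
        if self.chain is not None:
            mask &= ens.chain_ids == self.chain
        if self.res_start is not None:
            mask &= (ens.res_ids >= self.res_start) & (ens.res_ids <= self.res_stop)
        if self.atom_names is not None:
            names = {n.upper() for n in self.atom_names}
            mask &= np.array([str(a).upper() in names for a in ens.atom_names])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"selection {self} matches no atoms")
        return idx


@dataclass(frozen=True)
class ResidueMap:
    """Translate model residue numbering to hRPE65 numbering.

    The DMS-focussed model numbers residues 1..141; adding the offset
    (default 277) gives hRPE65 positions, e.g. model 98-102 -> hRPE65 375-379.
    """

    offset: int = 277

    def to_hrpe65(self, model_resid: int) -> int:
        return model_resid + self.offset

    def to_model(self, hrpe65_resid: int) -> int:
        return hrpe65_resid - self.offset


# ---------------------------------------------------------------------------
# Superposition / RMSD / RMSF
# ---------------------------------------------------------------------------


@dataclass
class SuperposeResult:
    rotation: np.ndarray        # 3x3 proper rotation
    translation: np.ndarray     # applied after rotation about mobile centroid
    transformed: np.ndarray     # all mobile atoms, transformed
    fit_rmsd: float


def _check_fit_geometry(xyz: np.ndarray, label: str) -> None:
    if xyz.shape[0] < 3:
        raise SelectionError(f"{label}: need >= 3 fit atoms, got {xyz.shape[0]}")
    centered = xyz - xyz.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise SelectionError(f"{label}: fit atoms are collinear/degenerate")


def superpose(
    mobile_frame: np.ndarray,
    reference_frame: np.ndarray,
    fit_idx_mobile: np.ndarray | None = None,
    fit_idx_reference: np.ndarray | None = None,
) -> SuperposeResult:
    """Least-squares rigid superposition (optimal proper rotation + translation).

    The transform minimising RMSD over the fit atoms is computed (Kabsch, via
    scipy's align_vectors) and applied to the whole mobile frame.
    """
    mobile_frame = np.asarray(mobile_frame, dtype=float)
    reference_frame = np.asarray(reference_frame, dtype=float)
    fit_m = mobile_frame if fit_idx_mobile is None else mobile_frame[fit_idx_mobile]
    fit_r = reference_frame if fit_idx_reference is None else reference_frame[fit_idx_reference]
    if fit_m.shape != fit_r.shape:
        raise SelectionError(
            f"fit selections differ in size: mobile {fit_m.shape[0]} vs reference {fit_r.shape[0]}"
        )
    _check_fit_geometry(fit_r, "reference")
    _check_fit_geometry(fit_m, "mobile")
    cm, cr = fit_m.mean(axis=0), fit_r.mean(axis=0)
    rot, _ = Rotation.align_vectors(fit_r - cr, fit_m - cm)
    matrix = rot.as_matrix()
    transformed = (mobile_frame - cm) @ matrix.T + cr
    fit_t = transformed if fit_idx_mobile is None else transformed[fit_idx_mobile]
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fit_t - fit_r) ** 2, axis=1))))
    return SuperposeResult(rotation=matrix, translation=cr - cm @ matrix.T,
                           transformed=transformed, fit_rmsd=fit_rmsd)


def rmsd_series(
    traj: TrajectoryEnsemble,
    fit_selection: AtomSelection,
    measure_selection: AtomSelection,
    reference: np.ndarray | int = 0,
) -> np.ndarray:
    """Per-frame RMSD of the measure selection after fitting on the fit selection.

    Each frame is superposed on the reference over ``fit_selection`` (the
    restrained external residues, standing in for the simulation's positional
    restraints), then the RMSD is measured over ``measure_selection`` (e.g.
    the DMS α-carbons) without refitting.
    """
    fit_idx = fit_selection.resolve(traj)
    meas_idx = measure_selection.resolve(traj)
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, float)
    if ref.shape != traj.coords[0].shape:
        raise SelectionError("reference frame does not match the ensemble topology")
    out = np.empty(traj.n_frames)
    ref_meas = ref[meas_idx]
    for i in range(traj.n_frames):
        sup = superpose(traj.coords[i], ref, fit_idx, fit_idx)
        diff = sup.transformed[meas_idx] - ref_meas
        out[i] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return out


def second_half_mean(series: np.ndarray) -> float:
    """Mean over frames [N/2, N) — the 'second half of the MD' summary."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n == 0:
        raise ValueError("empty RMSD series")
    return float(series[n // 2:].mean())


def rmsf_profile(
    traj: TrajectoryEnsemble,
    selection: AtomSelection,
    window: slice | None = None,
    fit_selection: AtomSelection | None = None,
) -> pd.Series:
    """Per-residue RMSF (Å) of the selected atoms about their window-mean positions.

    Frames in the window are superposed on the fit selection (default: the
    measured selection itself), the time-mean position of each selected atom
    is taken, and the root-mean-square deviation from it is reported per
    residue (intended for Cα selections: one atom per residue).
    """
    window = window if window is not None else slice(0, traj.n_frames)
    frames = range(*window.indices(traj.n_frames))
    if len(frames) < 2:
        raise ValueError("RMSF needs a window of >= 2 frames")
    sel_idx = selection.resolve(traj)
    fit_idx = (fit_selection or selection).resolve(traj)
    ref = traj.coords[frames[0]]
    stacked = np.empty((len(frames), sel_idx.size, 3))
    for k, i in enumerate(frames):
        sup = superpose(traj.coords[i], ref, fit_idx, fit_idx)
        stacked[k] = sup.transformed[sel_idx]
    mean = stacked.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stacked - mean) ** 2, axis=2), axis=0))
    frame = pd.DataFrame({"resid": traj.res_ids[sel_idx], "rmsf": per_atom})
    per_res = frame.groupby("resid")["rmsf"].apply(lambda v: float(np.sqrt(np.mean(v**2))))
    per_res.name = "rmsf"
    return per_res


@dataclass
class StructuralMetrics:
    """RMSD/RMSF summary for one ensemble, used by the structural alert."""

    rmsd_series: np.ndarray
    second_half_mean_rmsd: float
    rmsf: pd.Series  # indexed by residue number

    def __post_init__(self) -> None:
        self.rmsd_series = np.asarray(self.rmsd_series, dtype=float)
        if (self.rmsd_series < 0).any() or (np.asarray(self.rmsf) < 0).any():
            raise ValueError("RMSD/RMSF values must be non-negative")


def compute_structural_metrics(
    traj: TrajectoryEnsemble,
    fit_selection: AtomSelection,
    rmsd_selection: AtomSelection,
    rmsf_selection: AtomSelection,
    reference: np.ndarray | int = 0,
    residue_map: ResidueMap | None = None,
) -> StructuralMetrics:
    """One-stop RMSD series + second-half mean + per-residue RMSF."""
    series = rmsd_series(traj, fit_selection, rmsd_selection, reference)
    rmsf = rmsf_profile(traj, rmsf_selection, fit_selection=fit_selection)
    if residue_map is not None:
        rmsf.index = [residue_map.to_hrpe65(int(r)) for r in rmsf.index]
    return StructuralMetrics(
        rmsd_series=series,
        second_half_mean_rmsd=second_half_mean(series),
        rmsf=rmsf,
    )


def average_structure(
    traj: TrajectoryEnsemble,
    window: slice | None = None,
    fit_selection: AtomSelection | None = None,
) -> tuple[np.ndarray, bool]:
    """Plain per-atom coordinate mean of superposed window frames.

    Returns ``(coords, minimised)`` with ``minimised`` always False: no
    force-field relaxation is applied to the averaged coordinates.
    """
    window = window if window is not None else slice(0, traj.n_frames)
    frames = range(*window.indices(traj.n_frames))
    if len(frames) == 0:
        raise ValueError("empty averaging window")
    fit_idx = None if fit_selection is None else fit_selection.resolve(traj)
    ref = traj.coords[frames[0]]
    acc = np.zeros_like(ref)
    for i in frames:
        sup = superpose(traj.coords[i], ref, fit_idx, fit_idx)
        acc += sup.transformed
    return acc / len(frames), False


def last_third_window(n_frames: int) -> slice:
    """Window standing in for 'the last µs' of a 3 µs trajectory."""
    return slice(n_frames - n_frames // 3, n_frames)


# ---------------------------------------------------------------------------
# Hydrogen bonds and occupancies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueRef:
    chain: str
    resid: int
    name: str = ""

    def key(self) -> tuple[str, int]:
        return (self.chain, self.resid)

    def __str__(self) -> str:  # noqa: D105
        tag = f"{self.name}{self.resid}" if self.name else str(self.resid)
        return f"{tag}{'' if self.chain == 'A' else self.chain}"


PairKey = frozenset


def pair_key(a: tuple[str, int], b: tuple[str, int]) -> frozenset:
    return frozenset((tuple(a), tuple(b)))


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond definition.

    Donor–acceptor heavy-atom distance <= dist_max and donor–H–acceptor angle
    >= angle_min.  When the topology carries no hydrogens, a heavy-atom-only
    fallback (distance <= heavy_dist_max, no angle term) is used if enabled.
    Water bridges use the distance criterion from the water oxygen to one
    polar atom of each residue in the same frame.
    """

    dist_max: float = 3.5
    angle_min: float = 135.0
    heavy_dist_max: float = 3.3
    allow_heavy_fallback: bool = True

    def __post_init__(self) -> None:
        if self.dist_max <= 0 or self.heavy_dist_max <= 0:
            raise ValueError("distance criteria must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must be in (0, 180]")


@dataclass(frozen=True)
class HBondContact:
    donor_idx: int
    hydrogen_idx: int | None
    acceptor_idx: int


@dataclass
class HBondOccupancyRecord:
    """A residue-pair contact with its fraction-of-frames occupancy.

    A frame counts once even when several atom pairs bond simultaneously
    (bidentate contacts are not double counted).  ``salt_bridge`` tags
    contacts between charged side-chain groups; the alert rule treats them
    like any other native bond.
    """

    donor: ResidueRef
    acceptor: ResidueRef
    contact_class: str
    occupancy: float
    n_frames: int
    atom_pairs: tuple[tuple[str, str], ...] = ()
    salt_bridge: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.contact_class not in (DIRECT, WATER_MEDIATED):
            raise ValueError(f"unknown contact class {self.contact_class!r}")

    @property
    def pair(self) -> frozenset:
        return pair_key(self.donor.key(), self.acceptor.key())


# charged side-chain atoms used only for the salt-bridge tag
_CHARGED_ATOMS = {
    ("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}


def _polar_mask(ens: TrajectoryEnsemble, include_water: bool = False) -> np.ndarray:
    polar = np.isin(ens.elements, ("N", "O"))
    if not include_water:
        polar &= ~np.isin(ens.res_names, tuple(WATER_RESNAMES))
    return polar


def _hydrogen_map(
    ens: TrajectoryEnsemble, frame: np.ndarray, heavy_idx: np.ndarray | None = None
) -> dict[int, list[int]]:
    """Map heavy-atom index -> covalently attached hydrogen indices (<=1.25 Å, same residue)."""
    h_idx = np.flatnonzero(ens.elements == "H")
    if heavy_idx is None:
        heavy_idx = np.flatnonzero(_polar_mask(ens, include_water=True))
    attach: dict[int, list[int]] = {}
    if h_idx.size == 0 or heavy_idx.size == 0:
        return attach
    d = cdist(frame[heavy_idx], frame[h_idx])
    for i, hi in enumerate(heavy_idx):
        for j in np.flatnonzero(d[i] <= 1.25):
            hj = h_idx[j]
            if ens.res_ids[hi] == ens.res_ids[hj] and ens.chain_ids[hi] == ens.chain_ids[hj]:
                attach.setdefault(int(hi), []).append(int(hj))
    return attach


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of a-b-c."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    ens: TrajectoryEnsemble,
    frame_index: int,
    criteria: HBondCriteria = HBondCriteria(),
    candidate_idx: np.ndarray | None = None,
) -> list[HBondContact]:
    """All atom-level H-bond contacts in one frame (intra-residue excluded).

    Donors are N/O atoms with an attached hydrogen; acceptors are N/O atoms.
    Without hydrogens in the topology, the heavy-atom fallback applies (if
    allowed) and contacts carry ``hydrogen_idx=None``.
    """
    frame = ens.coords[frame_index]
    polar = np.flatnonzero(_polar_mask(ens))
    if candidate_idx is not None:
        polar = polar[np.isin(polar, candidate_idx)]
    if polar.size == 0:
        return []
    has_h = (ens.elements == "H").any()
    if not has_h and not criteria.allow_heavy_fallback:
        raise ValueError("topology has no hydrogens and heavy-atom fallback is disabled")
    contacts: list[HBondContact] = []
    if not has_h:
        d = cdist(frame[polar], frame[polar])
        for i in range(polar.size):
            for j in range(polar.size):
                if i == j:
                    continue
                di, dj = int(polar[i]), int(polar[j])
                if ens.res_ids[di] == ens.res_ids[dj] and ens.chain_ids[di] == ens.chain_ids[dj]:
                    continue
                if d[i, j] <= criteria.heavy_dist_max:
                    contacts.append(HBondContact(di, None, dj))
        return contacts
    attach = _hydrogen_map(ens, frame, heavy_idx=polar)
    donors = [i for i in polar if int(i) in attach]
    if not donors:
        return []
    d = cdist(frame[donors], frame[polar])
    for i, di in enumerate(donors):
        for j in np.flatnonzero(d[i] <= criteria.dist_max):
            aj = int(polar[j])
            di_ = int(di)
            if di_ == aj:
                continue
            if ens.res_ids[di_] == ens.res_ids[aj] and ens.chain_ids[di_] == ens.chain_ids[aj]:
                continue
            for h in attach[di_]:
                if _angle_deg(frame[di_], frame[h], frame[aj]) >= criteria.angle_min:
                    contacts.append(HBondContact(di_, h, aj))
                    break
    return contacts


def _residue_ref(ens: TrajectoryEnsemble, chain: str, resid: int) -> ResidueRef:
    mask = ens.residue_mask(chain, resid)
    if not mask.any():
        raise SelectionError(f"residue {chain}:{resid} not found in topology")
    name = str(ens.res_names[np.flatnonzero(mask)[0]])
    return ResidueRef(chain=chain, resid=resid, name=name)


def _is_salt_bridge(ens: TrajectoryEnsemble, i: int, j: int) -> bool:
    a = (str(ens.res_names[i]).upper(), str(ens.atom_names[i]).upper())
    b = (str(ens.res_names[j]).upper(), str(ens.atom_names[j]).upper())
    return a in _CHARGED_ATOMS and b in _CHARGED_ATOMS


def hbond_occupancy(
    traj: TrajectoryEnsemble,
    residue_pair: tuple[tuple[str, int], tuple[str, int]],
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondOccupancyRecord:
    """Fraction of frames in which the two residues share >= 1 direct H-bond.

    Either residue may act as donor; the frame counts once regardless of how
    many atom pairs qualify.  The atom-level breakdown is retained.
    """
    (ca, ra), (cb, rb) = residue_pair
    ref_a = _residue_ref(traj, ca, ra)
    ref_b = _residue_ref(traj, cb, rb)
    idx = np.flatnonzero(traj.residue_mask(ca, ra) | traj.residue_mask(cb, rb))
    bonded = 0
    atom_pairs: set[tuple[str, str]] = set()
    salt = False
    mask_a = traj.residue_mask(ca, ra)
    for f in range(traj.n_frames):
        frame_hit = False
        for contact in detect_hbonds(traj, f, criteria, candidate_idx=idx):
            i, j = contact.donor_idx, contact.acceptor_idx
            across = mask_a[i] != mask_a[j]
            if not across:
                continue
            frame_hit = True
            atom_pairs.add((str(traj.atom_names[i]), str(traj.atom_names[j])))
            salt = salt or _is_salt_bridge(traj, i, j)
        if frame_hit:
            bonded += 1
    return HBondOccupancyRecord(
        donor=ref_a,
        acceptor=ref_b,
        contact_class=DIRECT,
        occupancy=bonded / traj.n_frames,
        n_frames=traj.n_frames,
        atom_pairs=tuple(sorted(atom_pairs)),
        salt_bridge=salt,
    )


def water_bridge_occupancy(
    traj: TrajectoryEnsemble,
    residue_pair: tuple[tuple[str, int], tuple[str, int]],
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondOccupancyRecord:
    """Fraction of frames in which a single water bridges the two residues.

    A frame is bridged when one water oxygen simultaneously lies within the
    distance criterion of >= 1 polar atom of each residue.  Two different
    waters each reaching one partner do not count.
    """
    (ca, ra), (cb, rb) = residue_pair
    ref_a = _residue_ref(traj, ca, ra)
    ref_b = _residue_ref(traj, cb, rb)
    polar = _polar_mask(traj)
    idx_a = np.flatnonzero(traj.residue_mask(ca, ra) & polar)
    idx_b = np.flatnonzero(traj.residue_mask(cb, rb) & polar)
    waters = np.flatnonzero(
        np.isin(traj.res_names, tuple(WATER_RESNAMES)) & (traj.elements == "O")
    )
    if waters.size == 0:
        logger.warning("water_bridge_occupancy: no water residues in topology")
        return HBondOccupancyRecord(ref_a, ref_b, WATER_MEDIATED, 0.0, traj.n_frames)
    bonded = 0
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        da = cdist(frame[waters], frame[idx_a]).min(axis=1)
        db = cdist(frame[waters], frame[idx_b]).min(axis=1)
        if ((da <= criteria.dist_max) & (db <= criteria.dist_max)).any():
            bonded += 1
    return HBondOccupancyRecord(
        donor=ref_a,
        acceptor=ref_b,
        contact_class=WATER_MEDIATED,
        occupancy=bonded / traj.n_frames,
        n_frames=traj.n_frames,
    )


def contact_occupancy(
    traj: TrajectoryEnsemble,
    residue_pair: tuple[tuple[str, int], tuple[str, int]],
    dist_max: float = 4.5,
) -> float:
    """Fraction of frames with any side-chain heavy-atom pair within dist_max.

    A hydrophobic-contact report only — this quantity never feeds the
    interaction alert.
    """
    (ca, ra), (cb, rb) = residue_pair
    heavy = traj.elements != "H"
    sidechain = ~np.isin([str(a).upper() for a in traj.atom_names], tuple(BACKBONE_NAMES))
    idx_a = np.flatnonzero(traj.residue_mask(ca, ra) & heavy & sidechain)
    idx_b = np.flatnonzero(traj.residue_mask(cb, rb) & heavy & sidechain)
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError(f"residue pair {residue_pair} has no side-chain heavy atoms")
    hits = 0
    for f in range(traj.n_frames):
        if cdist(traj.coords[f][idx_a], traj.coords[f][idx_b]).min() <= dist_max:
            hits += 1
    return hits / traj.n_frames


# ---------------------------------------------------------------------------
# Alerts
# ---------------------------------------------------------------------------


def native_interactions(
    wt_records: Iterable[HBondOccupancyRecord],
    native_min: float = 0.5,
) -> dict[frozenset, HBondOccupancyRecord]:
    """Native WT contact set: direct records with occupancy >= native_min, by pair."""
    natives: dict[frozenset, HBondOccupancyRecord] = {}
    for rec in wt_records:
        if rec.contact_class != DIRECT or rec.occupancy < native_min:
            continue
        prev = natives.get(rec.pair)
        if prev is None or rec.occupancy > prev.occupancy:
            natives[rec.pair] = rec
    return natives


@dataclass
class InteractionAlert:
    alert: bool
    disrupted: list[dict]
    maintained: list[dict]


def interaction_alert(
    wt_natives: Mapping[frozenset, HBondOccupancyRecord] | Iterable[HBondOccupancyRecord],
    mut_records: Iterable[HBondOccupancyRecord],
    mutated_residue: tuple[str, int] | int,
    drop_points: float = 0.20,
    floor: float = 0.50,
) -> InteractionAlert:
    """Flag loss of native interactions in the mutated residue's local network.

    A native WT pair is *maintained* iff some mutant direct contact between
    the same residue pair reaches occupancy >= max(floor, WT occupancy -
    drop_points); otherwise it is disrupted.  The alert fires when >= 1
    native pair involving the mutated residue is disrupted.
    """
    if not isinstance(wt_natives, Mapping):
        wt_natives = native_interactions(wt_natives)
    if isinstance(mutated_residue, int):
        mutated_residue = ("A", mutated_residue)
    mutated_residue = (str(mutated_residue[0]), int(mutated_residue[1]))

    mut_occ: dict[frozenset, float] = {}
    for rec in mut_records:
        if rec.contact_class != DIRECT:
            continue
        mut_occ[rec.pair] = max(mut_occ.get(rec.pair, 0.0), rec.occupancy)

    disrupted, maintained = [], []
    for pair, wt_rec in sorted(wt_natives.items(), key=lambda kv: str(kv[1].donor)):
        if mutated_residue not in pair:
            continue
        required = max(floor, wt_rec.occupancy - drop_points)
        got = mut_occ.get(pair, 0.0)
        entry = {
            "pair": f"{wt_rec.donor}-{wt_rec.acceptor}",
            "wt_occupancy": wt_rec.occupancy,
            "mut_occupancy": got,
            "required": required,
        }
        (maintained if got >= required else disrupted).append(entry)
    return InteractionAlert(alert=len(disrupted) > 0, disrupted=disrupted, maintained=maintained)


@dataclass
class StructuralAlert:
    alert: bool
    rmsd_criterion: bool
    rmsf_criterion: bool
    evidence: dict


def structural_alert(
    metrics_mut: StructuralMetrics,
    metrics_wt: StructuralMetrics,
    rmsd_min: float = 1.5,
    rmsf_min: float = 2.0,
    rmsf_window: int = 3,
    wt_rmsf_max: float = 1.0,
) -> StructuralAlert:
    """Conformational-deviation alert by WT-vs-mutant comparison.

    Fires when the mutant second-half mean DMS RMSD reaches ``rmsd_min``
    (the WT reference sits near 1.0 Å), OR when >= ``rmsf_window`` consecutive
    residues have mutant RMSF >= ``rmsf_min`` while the WT profile stays
    below ``wt_rmsf_max`` there (a localized misfolding peak).
    """
    mut_rmsf, wt_rmsf = metrics_mut.rmsf, metrics_wt.rmsf
    if list(mut_rmsf.index) != list(wt_rmsf.index):
        raise SelectionError("WT and mutant RMSF profiles cover different residues")
    if len(metrics_mut.rmsd_series) != len(metrics_wt.rmsd_series):
        raise SelectionError("WT and mutant RMSD series have different window lengths")

    rmsd_hit = metrics_mut.second_half_mean_rmsd >= rmsd_min

    flags = (mut_rmsf.values >= rmsf_min) & (wt_rmsf.values < wt_rmsf_max)
    resids = np.asarray(mut_rmsf.index, dtype=int)
    peak_run: list[int] = []
    run: list[int] = []
    for i, flagged in enumerate(flags):
        if flagged and (not run or resids[i] == resids[i - 1] + 1):
            run.append(int(resids[i]))
        else:
            run = [int(resids[i])] if flagged else []
        if len(run) > len(peak_run):
            peak_run = list(run)
    rmsf_hit = len(peak_run) >= rmsf_window

    evidence = {
        "second_half_mean_rmsd_mut": metrics_mut.second_half_mean_rmsd,
        "second_half_mean_rmsd_wt": metrics_wt.second_half_mean_rmsd,
        "rmsd_min": rmsd_min,
        "rmsf_peak_residues": peak_run if rmsf_hit else [],
        "rmsf_peak_max": float(mut_rmsf.max()),
    }
    return StructuralAlert(
        alert=bool(rmsd_hit or rmsf_hit),
        rmsd_criterion=bool(rmsd_hit),
        rmsf_criterion=bool(rmsf_hit),
        evidence=evidence,
    )
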
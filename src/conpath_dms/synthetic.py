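"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators, both fully seeded:

* :func:`make_benchmark` — labelled variant sets with a configurable
  pathogenic:benign imbalance (default 27:3, the reference cohort) and
  per-tool sensitivity/specificity, for exercising the benchmarking and
  consensus machinery;
* :func:`make_ensemble` — multi-frame coordinate ensembles over a toy
  two-chain dimer, with per-residue fluctuation targets and residue pairs
  placed in or out of hydrogen-bond geometry with a prescribed per-frame
  probability (the target occupancy), including single-water bridges.

The ensembles are statistical stand-ins, not physics: frames are independent
(no autocorrelation) and each residue moves as a rigid body under isotropic
Gaussian displacements whose magnitude is the target RMSF.  Occupancy and
RMSF estimators are frame-order independent, so nothing downstream depends on
the missing dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .consensus import (
    BENIGN,
    NEUTRAL,
    PATHOGENIC,
    BenchmarkLabelSet,
    PredictionMatrix,
)
from .trajectory import TrajectoryEnsemble, WATER_RESNAMES

# re-exported here because the reference-table transcriptions belong to the
# synthetic/fixture layer of the package
from .fixtures import make_reference_fixtures  # noqa: F401

_BONDED_DIST = (2.7, 3.3)     # safely inside the 3.5 Å criterion
_BONDED_ANGLE = (150.0, 180.0)  # safely above the 135 deg criterion
_NONBONDED_DIST = (4.5, 6.0)  # safely outside the criterion
_WATER_DIST = 2.9


# ---------------------------------------------------------------------------
# Benchmark generator
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSpec:
    """A labelled cohort plus per-tool error rates.

    ``tools`` maps tool name -> (sensitivity, specificity): the probability of
    a Pathogenic call on a pathogenic variant, and of a Neutral call on a
    benign one.
    """

    n_pathogenic: int = 27
    n_benign: int = 3
    tools: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"toolA": (0.9, 0.67), "toolB": (0.8, 1.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathogenic < 0 or self.n_benign < 0:
            raise ValueError("cohort counts must be non-negative")
        for tool, (sens, spec) in self.tools.items():
            if not (0 <= sens <= 1 and 0 <= spec <= 1):
                raise ValueError(f"tool {tool}: sensitivity/specificity must lie in [0,1]")


def make_benchmark(spec: BenchmarkSpec) -> tuple[BenchmarkLabelSet, PredictionMatrix]:
    """Draw a labelled benchmark and a binary prediction matrix.

    Each tool's call on each variant is an independent Bernoulli draw:
    Pathogenic with probability = sensitivity on pathogenic variants and
    1 - specificity on benign ones.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pathogenic + spec.n_benign
    variants = [f"A{i + 1}V" for i in range(n)]
    labels = {
        v: (PATHOGENIC if i < spec.n_pathogenic else BENIGN) for i, v in enumerate(variants)
    }
    is_path = np.array([labels[v] == PATHOGENIC for v in variants])
    calls = {}
    for tool, (sens, specificity) in spec.tools.items():
        p_call = np.where(is_path, sens, 1.0 - specificity)
        hit = rng.random(n) < p_call
        calls[tool] = np.where(hit, PATHOGENIC, NEUTRAL)
    frame = pd.DataFrame(calls, index=variants)
    return BenchmarkLabelSet(labels), PredictionMatrix.from_binary_frame(frame)


# ---------------------------------------------------------------------------
# Toy dimer topology
# ---------------------------------------------------------------------------

#: polar side-chain layouts: name -> list of (atom_name, dx, dy, dz) added to
#: the residue origin; dy is multiplied by the chain's side direction
_SIDECHAINS = {
    "SER": [("OG", 1.2, 3.0, 0.6), ("HG", 1.2, 3.8, 0.6)],
    "ASN": [("OD1", 1.0, 3.0, 0.6), ("ND2", 1.8, 3.0, 0.9), ("HD21", 1.8, 3.9, 0.9)],
    "LYS": [("NZ", 1.2, 3.6, 0.6), ("HZ1", 1.2, 4.5, 0.6)],
    "GLU": [("OE1", 1.0, 3.2, 0.6), ("OE2", 2.0, 3.2, 0.9)],
    "TRP": [("NE1", 1.2, 3.2, 0.6), ("HE1", 1.2, 4.1, 0.6)],
}

_DONOR_PRIORITY = ("NZ", "OG", "ND2", "NE1", "N")
_ACCEPTOR_PRIORITY = ("OE1", "OD1", "OG", "O")
_POLAR_TIP_PRIORITY = ("NZ", "OG", "OD1", "OE1", "NE1", "ND2", "N", "O")

#: default polar-residue placement along each toy chain
_DEFAULT_SEQUENCE = {3: "SER", 5: "ASN", 7: "LYS", 9: "GLU", 11: "TRP",
                     13: "SER", 15: "GLU", 18: "LYS", 21: "SER", 24: "GLU"}


def toy_dimer(n_res: int = 30, chain_gap: float = 12.0, n_waters: int = 6) -> TrajectoryEnsemble:
    """A ~60-residue two-chain poly-alanine construct with polar side chains.

    Chains A and B run parallel, ``chain_gap`` Å apart, side chains pointing
    into the interface (mimicking the W402-E404-S307B bridge topology of the
    hRPE65 dimer interface); waters sit in a reservoir away from both chains
    until a bridge prescription moves one.  Single-frame ensemble; generators
    add frames on top of it.
    """
    names, resids, resnames, chains, coords = [], [], [], [], []

    def add(chain: str, resid: int, resname: str, atom: str, xyz: tuple) -> None:
        chains.append(chain)
        resids.append(resid)
        resnames.append(resname)
        names.append(atom)
        coords.append(xyz)

    for chain, base_y, side in (("A", 0.0, +1.0), ("B", chain_gap, -1.0)):
        for i in range(1, n_res + 1):
            resname = _DEFAULT_SEQUENCE.get(i, "ALA")
            # gentle backbone wobble so Cα traces are never collinear
            x0, y0, z0 = 3.5 * i, base_y + 0.5 * np.cos(0.8 * i), 1.0 * np.sin(0.8 * i)
            add(chain, i, resname, "N", (x0, y0, z0))
            add(chain, i, resname, "H", (x0, y0 - 1.0 * side, z0))
            add(chain, i, resname, "CA", (x0 + 1.2, y0 + 0.8 * side, z0 + 0.3))
            add(chain, i, resname, "CB", (x0 + 1.2, y0 + 1.9 * side, z0 + 0.6))
            add(chain, i, resname, "C", (x0 + 2.4, y0 + 0.2 * side, z0))
            add(chain, i, resname, "O", (x0 + 2.4, y0 + 0.2 * side, z0 - 1.3))
            for atom, dx, dy, dz in _SIDECHAINS.get(resname, ()):
                add(chain, i, resname, atom, (x0 + dx, y0 + dy * side, z0 + dz))
    for w in range(1, n_waters + 1):
        add("W", w, "HOH", "O", (12.0 * w, 30.0, 0.0))

    return TrajectoryEnsemble(
        coords=np.asarray(coords, dtype=float)[None, :, :],
        atom_names=np.array(names, dtype=object),
        res_ids=np.array(resids),
        res_names=np.array(resnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
    )


# ---------------------------------------------------------------------------
# Ensemble generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BondSpec:
    """A prescribed residue-pair contact with a target fraction of bonded frames."""

    donor: tuple[str, int]
    acceptor: tuple[str, int]
    occupancy: float
    kind: str = "direct"

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("target occupancy must lie in [0,1]")
        if self.kind not in ("direct", "water_mediated"):
            raise ValueError(f"unknown bond kind {self.kind!r}")
        if tuple(self.donor) == tuple(self.acceptor):
            raise ValueError("donor and acceptor residue must differ")


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic coordinate ensemble.

    ``sigma`` maps (chain, resid) -> target per-residue RMSF in Å (isotropic;
    each residue moves rigidly so attached hydrogens keep their geometry);
    residues not listed use ``sigma_default``.  ``bonds`` lists prescribed
    contacts.  Identical seeds give identical frames.
    """

    n_frames: int = 200
    seed: int = 0
    sigma_default: float = 0.3
    sigma: dict[tuple[str, int], float] = field(default_factory=dict)
    bonds: list[BondSpec] = field(default_factory=list)
    reference: TrajectoryEnsemble | None = None
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.sigma_default < 0 or any(s < 0 for s in self.sigma.values()):
            raise ValueError("fluctuation sigma must be >= 0")
        self.sigma = {(str(c), int(r)): float(s) for (c, r), s in self.sigma.items()}


def _find_atom(ens: TrajectoryEnsemble, chain: str, resid: int,
               priority: Sequence[str]) -> int:
    mask = ens.residue_mask(chain, resid)
    if not mask.any():
        raise ValueError(f"residue {chain}:{resid} not in reference topology")
    idx = np.flatnonzero(mask)
    names = [str(ens.atom_names[i]).upper() for i in idx]
    for want in priority:
        if want in names:
            return int(idx[names.index(want)])
    raise ValueError(f"residue {chain}:{resid} has none of {priority}")


def _attached_h(ens: TrajectoryEnsemble, heavy: int) -> int:
    mask = ens.residue_mask(str(ens.chain_ids[heavy]), int(ens.res_ids[heavy]))
    idx = np.flatnonzero(mask & (ens.elements == "H"))
    ref = ens.coords[0]
    for i in idx:
        if np.linalg.norm(ref[i] - ref[heavy]) <= 1.25:
            return int(i)
    raise ValueError(
        f"no hydrogen attached to donor atom {ens.atom_names[heavy]} of "
        f"{ens.chain_ids[heavy]}:{ens.res_ids[heavy]}"
    )


def _perpendicular(u: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, probe)
    return v / np.linalg.norm(v)


def _check_baseline_clearance(
    ens: TrajectoryEnsemble, bond: BondSpec, moved: int, min_clear: float = 4.0
) -> None:
    """The two residues' unmanaged polar atoms must start out of bonding range."""
    polar = np.isin(ens.elements, ("N", "O"))
    a = np.flatnonzero(ens.residue_mask(*bond.donor) & polar)
    b = np.flatnonzero(ens.residue_mask(*bond.acceptor) & polar)
    a, b = a[a != moved], b[b != moved]
    if a.size and b.size and cdist(ens.coords[0][a], ens.coords[0][b]).min() < min_clear:
        raise ValueError(
            f"bond {bond.donor}-{bond.acceptor}: residues too close at baseline for an "
            "unambiguous occupancy target"
        )


def make_ensemble(spec: EnsembleSpec) -> tuple[TrajectoryEnsemble, dict]:
    """Generate frames with controlled fluctuations and bond occupancies.

    Frames are the reference plus independent per-residue rigid Gaussian
    displacements of scale sigma (per-coordinate sigma/sqrt(3), so the
    per-atom RMSF converges to sigma).  For each prescribed bond, every frame
    is independently placed in bonded geometry with probability = target
    occupancy (donor-acceptor distance in [2.7, 3.3] Å, donor-H-acceptor angle
    in [150, 180] deg; water bridges put one water oxygen within 2.9-3.5 Å of
    a polar atom of each residue) and otherwise out of it (distance in
    [4.5, 6.0] Å).  Returns the ensemble and a ground-truth manifest.
    """
    ref = spec.reference if spec.reference is not None else toy_dimer()
    rng = np.random.default_rng(spec.seed)
    base = ref.coords[0]
    n_atoms = base.shape[0]

    residues = list(dict.fromkeys(zip(ref.chain_ids, ref.res_ids)))
    res_index = {key: i for i, key in enumerate(residues)}
    atom_res = np.array([res_index[(c, r)] for c, r in zip(ref.chain_ids, ref.res_ids)])
    sigma_res = np.array(
        [spec.sigma.get((str(c), int(r)), spec.sigma_default) for c, r in residues]
    )

    coords = np.empty((spec.n_frames, n_atoms, 3))
    per_coord = sigma_res / np.sqrt(3.0)
    for f in range(spec.n_frames):
        disp = rng.normal(0.0, 1.0, size=(len(residues), 3)) * per_coord[:, None]
        coords[f] = base + disp[atom_res]

    moved_atoms: set[int] = set()
    water_pool = [
        int(i)
        for i in np.flatnonzero(
            np.isin(ref.res_names, tuple(WATER_RESNAMES)) & (ref.elements == "O")
        )
    ]
    manifest_bonds = []

    for bond in spec.bonds:
        bonded = rng.random(spec.n_frames) < bond.occupancy
        if bond.kind == "direct":
            d_idx = _find_atom(ref, *bond.donor, priority=_DONOR_PRIORITY)
            h_idx = _attached_h(ref, d_idx)
            a_idx = _find_atom(ref, *bond.acceptor, priority=_ACCEPTOR_PRIORITY)
            if a_idx in moved_atoms:
                raise ValueError(f"atom {a_idx} prescribed by more than one bond")
            moved_atoms.add(a_idx)
            _check_baseline_clearance(ref, bond, a_idx)
            away = base[d_idx] - base[_find_atom(ref, *bond.donor, priority=("CA", "N"))]
            away = away / np.linalg.norm(away)
            for f in range(spec.n_frames):
                d_pos, h_pos = coords[f, d_idx], coords[f, h_idx]
                if bonded[f]:
                    dist = rng.uniform(*_BONDED_DIST)
                    theta = np.radians(rng.uniform(*_BONDED_ANGLE))
                    u = h_pos - d_pos
                    h_len = np.linalg.norm(u)
                    u = u / h_len
                    disc = dist**2 - (h_len * np.sin(theta)) ** 2
                    if disc <= 0:  # geometrically impossible: fall back to linear
                        coords[f, a_idx] = h_pos + (dist - h_len) * u
                        continue
                    r = h_len * np.cos(theta) + np.sqrt(disc)
                    v = _perpendicular(u)
                    phi = rng.uniform(0.0, 2.0 * np.pi)
                    w = np.cos(phi) * v + np.sin(phi) * np.cross(u, v)
                    m = -np.cos(theta) * u + np.sin(theta) * w
                    coords[f, a_idx] = h_pos + r * m
                else:
                    dist = rng.uniform(*_NONBONDED_DIST)
                    jitter = rng.normal(0.0, 0.15, size=3)
                    direction = away + jitter
                    direction /= np.linalg.norm(direction)
                    coords[f, a_idx] = d_pos + dist * direction
        else:  # water bridge
            if not water_pool:
                raise ValueError("no free water available for a water-mediated prescription")
            w_idx = water_pool.pop(0)
            if w_idx in moved_atoms:
                raise ValueError(f"water atom {w_idx} prescribed by more than one bond")
            moved_atoms.add(w_idx)
            p1 = _find_atom(ref, *bond.donor, priority=_POLAR_TIP_PRIORITY)
            p2 = _find_atom(ref, *bond.acceptor, priority=_POLAR_TIP_PRIORITY)
            far = base[w_idx]
            for f in range(spec.n_frames):
                if not bonded[f]:
                    coords[f, w_idx] = far
                    continue
                x1, x2 = coords[f, p1], coords[f, p2]
                mid = 0.5 * (x1 + x2)
                half = 0.5 * np.linalg.norm(x2 - x1)
                if half > 3.5:
                    raise ValueError(
                        f"water bridge {bond.donor}-{bond.acceptor}: partners too far "
                        f"apart ({2 * half:.1f} Å) to bridge"
                    )
                if half < _WATER_DIST:
                    axis = (x2 - x1) / (2 * half)
                    coords[f, w_idx] = mid + _perpendicular(axis) * np.sqrt(
                        _WATER_DIST**2 - half**2
                    )
                else:
                    coords[f, w_idx] = mid
        manifest_bonds.append(
            {
                "donor": list(bond.donor),
                "acceptor": list(bond.acceptor),
                "kind": bond.kind,
                "target_occupancy": bond.occupancy,
                "realized_occupancy": float(bonded.mean()),
            }
        )

    ens = replace(ref, coords=coords, frame_spacing=spec.frame_spacing)
    manifest = {
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "sigma_default": spec.sigma_default,
        "sigma": {f"{c}:{r}": s for (c, r), s in spec.sigma.items()},
        "bonds": manifest_bonds,
    }
    return ens, manifest
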
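"""File IO, run configuration and the end-to-end evaluation driver.

Glues the stages together: prediction-matrix ingestion and binarisation,
benchmarking and panel selection, ConPath consensus, per-variant ensemble
analytics (when coordinate ensembles are supplied), alert aggregation and the
four-class report.  All tables are written as CSV, evidence as JSON; two runs
with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import fixtures
from .alerts import AlertProfile, CohortReport, cohort_report
from .consensus import (
    BenchmarkLabelSet,
    CutoffTable,
    DEFAULT_CUTOFFS,
    PredictionMatrix,
    ToolPerformance,
    benchmark_tools,
    binarize,
    canonical_tool_name,
    conpath,
    conpath_frame,
    performance_frame,
    select_tools,
    VariantId,
)
from .trajectory import (
    AtomSelection,
    HBondCriteria,
    HBondOccupancyRecord,
    ResidueMap,
    StructuralMetrics,
    TrajectoryEnsemble,
    compute_structural_metrics,
    hbond_occupancy,
    interaction_alert,
    native_interactions,
    structural_alert,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PDB ensemble IO
# ---------------------------------------------------------------------------


def _model_atom_counts(lines: Iterable[str]) -> list[int]:
    counts, current, in_model, seen_model = [], 0, False, False
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model, in_model, current = True, True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not seen_model:
        return [current]
    if in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_pdb_ensemble(path: str | Path) -> TrajectoryEnsemble:
    """Read a multi-model PDB (MODEL/ENDMDL blocks) into an ensemble.

    Atom count and order must be identical across models; insertion codes are
    rejected.  A single-MODEL (or model-less) file yields a 1-frame ensemble,
    valid for static analyses only.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    counts = _model_atom_counts(pdb.lines)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"{path.name}: model {bad} has {counts[bad - 1]} atoms, expected {counts[0]}"
        )
    stack = pdb.get_structure(model=None)
    ins = stack.ins_code if hasattr(stack, "ins_code") else None
    if ins is not None and any(str(c).strip() for c in ins):
        raise ValueError(f"{path.name}: insertion codes are not supported")
    return TrajectoryEnsemble(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=stack.atom_name,
        res_ids=stack.res_id,
        res_names=stack.res_name,
        chain_ids=stack.chain_id,
        elements=stack.element,
    )


def write_pdb_ensemble(ens: TrajectoryEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (coordinates to 3 decimals)."""
    n_frames, n_atoms = ens.n_frames, ens.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = np.asarray(ens.coords, dtype=np.float32)
    stack.atom_name = np.array([str(a) for a in ens.atom_names], dtype="U6")
    stack.res_id = np.asarray(ens.res_ids)
    stack.res_name = np.array([str(r) for r in ens.res_names], dtype="U5")
    stack.chain_id = np.array([str(c) for c in ens.chain_ids], dtype="U4")
    stack.element = np.array([str(e) for e in ens.elements], dtype="U2")
    stack.hetero = np.isin(stack.res_name, ("HOH", "WAT"))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------


def read_prediction_matrix(
    matrix_path: str | Path, tool_meta_path: str | Path | None = None
) -> tuple[PredictionMatrix, CutoffTable]:
    """Read `variant,<tool>,...` predictions plus the tool-metadata companion.

    The metadata CSV declares ``tool,type,cutoff,alias`` (type binary|scored;
    cutoff blank for binary tools; alias optional).  Without metadata, every
    column is treated as binary and the published default cutoffs apply.
    """
    frame = pd.read_csv(matrix_path, dtype=str).set_index("variant")
    cutoffs = CutoffTable()
    types: dict[str, str] = {}
    if tool_meta_path is not None:
        meta = pd.read_csv(tool_meta_path)
        rename = {}
        for _, row in meta.iterrows():
            tool = canonical_tool_name(str(row["tool"]))
            types[tool] = str(row["type"]).strip().lower()
            if "alias" in meta.columns and isinstance(row.get("alias"), str) and row["alias"].strip():
                rename[row["alias"].strip()] = tool
            if "cutoff" in meta.columns and pd.notna(row.get("cutoff")):
                cutoffs.cutoffs[tool] = float(row["cutoff"])
        frame = frame.rename(columns=rename)
    cells = {}
    for col in frame.columns:
        tool = canonical_tool_name(col)
        kind = types.get(tool, "binary")
        if kind == "scored":
            cells[col] = pd.to_numeric(frame[col], errors="raise")
        else:
            cells[col] = frame[col]
        types[tool] = kind
    matrix = PredictionMatrix(pd.DataFrame(cells, index=frame.index), types)
    return matrix, cutoffs


def read_benchmark(path: str | Path) -> BenchmarkLabelSet:
    frame = pd.read_csv(path)
    return BenchmarkLabelSet(dict(zip(frame["variant"].astype(str), frame["label"].astype(str))))


def write_benchmark(labels: BenchmarkLabelSet, path: str | Path) -> None:
    pd.DataFrame(
        {"variant": list(labels.labels), "label": list(labels.labels.values())}
    ).to_csv(path, index=False)


def write_matrix(matrix: PredictionMatrix, path: str | Path) -> None:
    out = matrix.calls.copy()
    out.index.name = "variant"
    out.to_csv(path)


def occupancy_frame(records: Iterable[HBondOccupancyRecord]) -> pd.DataFrame:
    rows = [
        {
            "donor_res": str(r.donor),
            "acceptor_res": str(r.acceptor),
            "class": r.contact_class,
            "occupancy": r.occupancy,
            "n_frames": r.n_frames,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["donor_res", "acceptor_res", "class", "occupancy", "n_frames"])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Validated configuration for the end-to-end evaluation.

    Unknown keys are rejected.  Paths are interpreted relative to the caller's
    working directory.  ``use_reference_fixtures`` swaps file inputs for the
    packaged reference transcriptions.
    """

    model_config = ConfigDict(extra="forbid")

    matrix: Optional[str] = None
    tool_meta: Optional[str] = None
    benchmark: Optional[str] = None
    wt_ensemble: Optional[str] = None
    ensembles: dict[str, str] = Field(default_factory=dict)  # variant -> PDB path
    use_reference_fixtures: bool = False

    fit_selection: str = "*:*:CA"
    rmsd_selection: str = "A:*:CA"
    rmsf_selection: str = "A:*:CA"

    recall_min: float = 0.78
    specificity_min: float = 0.67
    pathogenic_min: Optional[int] = None
    native_min: float = 0.50
    drop_points: float = 0.20
    floor: float = 0.50
    rmsd_min: float = 1.5
    rmsf_min: float = 2.0
    rmsf_window: int = 3
    hbond_dist_max: float = 3.5
    hbond_angle_min: float = 135.0
    residue_offset: int = 277
    missing_as_neutral: bool = False

    seed: int = 0
    outdir: str = "results"

    @field_validator(
        "recall_min", "specificity_min", "native_min", "drop_points", "floor"
    )
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("must lie in [0, 1]")
        return v

    @field_validator("rmsd_min", "rmsf_min", "hbond_dist_max")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("rmsf_window")
    @classmethod
    def _window(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# Ensemble-route analytics
# ---------------------------------------------------------------------------


def _scan_partner_residues(
    wt: TrajectoryEnsemble, mutated: tuple[str, int], reach: float
) -> list[tuple[str, int]]:
    """Residues with a polar atom within ``reach`` of the mutated residue's polar
    atoms in any of three probe frames (first, middle, last)."""
    from scipy.spatial.distance import cdist

    polar = np.isin(wt.elements, ("N", "O")) & ~np.isin(wt.res_names, ("HOH", "WAT"))
    idx_m = np.flatnonzero(wt.residue_mask(*mutated) & polar)
    if idx_m.size == 0:
        return []
    partners: set[tuple[str, int]] = set()
    probes = sorted({0, wt.n_frames // 2, wt.n_frames - 1})
    others = np.flatnonzero(polar & ~wt.residue_mask(*mutated))
    for f in probes:
        d = cdist(wt.coords[f][idx_m], wt.coords[f][others]).min(axis=0)
        for j in np.flatnonzero(d <= reach):
            k = others[j]
            partners.add((str(wt.chain_ids[k]), int(wt.res_ids[k])))
    return sorted(partners)


def analyse_variant_ensembles(
    wt: TrajectoryEnsemble,
    mut: TrajectoryEnsemble,
    mutated_residue: tuple[str, int],
    config: RunConfig,
) -> tuple[bool, bool, dict]:
    """Structural + interaction alerts for one mutant ensemble vs WT."""
    criteria = HBondCriteria(dist_max=config.hbond_dist_max, angle_min=config.hbond_angle_min)
    fit = AtomSelection.parse(config.fit_selection)
    rmsd_sel = AtomSelection.parse(config.rmsd_selection)
    rmsf_sel = AtomSelection.parse(config.rmsf_selection)
    rmap = ResidueMap(config.residue_offset)

    metrics_wt = compute_structural_metrics(wt, fit, rmsd_sel, rmsf_sel, residue_map=rmap)
    metrics_mut = compute_structural_metrics(mut, fit, rmsd_sel, rmsf_sel, residue_map=rmap)
    s_alert = structural_alert(
        metrics_mut, metrics_wt,
        rmsd_min=config.rmsd_min, rmsf_min=config.rmsf_min, rmsf_window=config.rmsf_window,
    )

    partners = _scan_partner_residues(wt, mutated_residue, reach=config.hbond_dist_max + 2.5)
    wt_records = [hbond_occupancy(wt, (mutated_residue, p), criteria) for p in partners]
    mut_records = [hbond_occupancy(mut, (mutated_residue, p), criteria) for p in partners]
    natives = native_interactions(wt_records, native_min=config.native_min)
    i_alert = interaction_alert(
        natives, mut_records, mutated_residue,
        drop_points=config.drop_points, floor=config.floor,
    )
    evidence = {
        "structural": s_alert.evidence,
        "interaction": {"disrupted": i_alert.disrupted, "maintained": i_alert.maintained},
    }
    return s_alert.alert, i_alert.alert, evidence


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    performance: pd.DataFrame | None
    panel: list[str]
    conpath_table: pd.DataFrame
    cohort: CohortReport
    profiles: list[AlertProfile]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_full_evaluation(config: RunConfig) -> EvaluationReport:
    """Execute consensus scoring, ensemble analytics and classification.

    The ConPath track is mandatory; trajectory analytics run per variant where
    ensembles are provided (variants without one get an unknown structural /
    interaction flag and are reported but not classified).  All intermediate
    tables are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run_full_evaluation: seed=%d thresholds=%s", config.seed,
                {k: getattr(config, k) for k in
                 ("recall_min", "specificity_min", "pathogenic_min", "native_min",
                  "drop_points", "floor", "rmsd_min", "rmsf_min")})

    perf_table: pd.DataFrame | None = None
    evidence_bundle: dict[str, dict] = {}

    if config.use_reference_fixtures:
        with _stage("consensus"):
            matrix = fixtures.combined_matrix()
            perfs = [
                ToolPerformance(tool=t, counts=c, **_metric_kwargs(c))
                for t, c in fixtures.benchmark_confusion_counts().items()
            ]
            panel = select_tools(perfs, config.recall_min, config.specificity_min)
            perf_table = performance_frame(perfs)
            results = conpath(matrix, panel, config.pathogenic_min,
                              missing_as_neutral=config.missing_as_neutral)
        with _stage("trajectory"):
            wt_natives = native_interactions(
                fixtures.hbond_records("WT"), native_min=config.native_min
            )
            metrics_wt = fixtures.structural_metrics("WT")
            flags: dict[str, tuple[bool, bool]] = {}
            for variant in fixtures.ALL_VARIANTS:
                resid = VariantId.parse(variant).position
                s = structural_alert(
                    fixtures.structural_metrics(variant), metrics_wt,
                    rmsd_min=config.rmsd_min, rmsf_min=config.rmsf_min,
                    rmsf_window=config.rmsf_window,
                )
                i = interaction_alert(
                    wt_natives, fixtures.hbond_records(variant), ("A", resid),
                    drop_points=config.drop_points, floor=config.floor,
                )
                flags[variant] = (s.alert, i.alert)
                evidence_bundle[variant] = {
                    "structural": s.evidence,
                    "interaction": {"disrupted": i.disrupted, "maintained": i.maintained},
                }
    else:
        if config.matrix is None:
            raise StageError("stage 'consensus' failed: no prediction matrix configured")
        with _stage("consensus"):
            matrix, cutoffs = read_prediction_matrix(config.matrix, config.tool_meta)
            matrix = binarize(matrix, cutoffs)
            if config.benchmark is not None:
                labels = read_benchmark(config.benchmark)
                perfs = benchmark_tools(matrix, labels)
                panel = select_tools(perfs, config.recall_min, config.specificity_min)
                perf_table = performance_frame(perfs)
            else:
                panel = matrix.tools
            results = conpath(matrix, panel, config.pathogenic_min,
                              missing_as_neutral=config.missing_as_neutral)
        flags = {}
        if config.wt_ensemble and config.ensembles:
            with _stage("trajectory"):
                wt = read_pdb_ensemble(config.wt_ensemble)
                for variant, path in config.ensembles.items():
                    mut = read_pdb_ensemble(path)
                    resid = VariantId.parse(variant).position
                    s, i, ev = analyse_variant_ensembles(wt, mut, ("A", resid), config)
                    flags[variant] = (s, i)
                    evidence_bundle[variant] = ev

    with _stage("classification"):
        by_variant = {r.variant: r for r in results}
        threshold = (
            config.pathogenic_min
            if config.pathogenic_min is not None
            else len(panel) // 2 + 1
        )
        profiles = []
        for variant, result in by_variant.items():
            s_flag, i_flag = flags.get(variant, (None, None))
            profiles.append(
                AlertProfile(
                    variant=variant,
                    structural=s_flag,
                    interaction=i_flag,
                    conpath=result.votes >= threshold,
                    conpath_votes=result.votes,
                    evidence=evidence_bundle.get(variant, {}),
                )
            )
        complete = [p for p in profiles if p.is_complete]
        partial = [p for p in profiles if not p.is_complete]
        if partial:
            logger.warning(
                "%d variants lack ensemble data and are reported unclassified: %s",
                len(partial), [p.variant for p in partial],
            )
        cohort = cohort_report(complete)

    if perf_table is not None:
        perf_table.to_csv(outdir / "performance.csv", index=False)
    conpath_table = conpath_frame(results)
    conpath_table.to_csv(outdir / "conpath.csv", index=False)
    cohort.table.to_csv(outdir / "classification.csv", index=False)
    with open(outdir / "evidence.json", "w") as fh:
        json.dump(evidence_bundle, fh, indent=2, sort_keys=True)
    with open(outdir / "run_config.json", "w") as fh:
        fh.write(config.model_dump_json(indent=2))

    return EvaluationReport(
        performance=perf_table,
        panel=panel,
        conpath_table=conpath_table,
        cohort=cohort,
        profiles=profiles,
    )


def _metric_kwargs(counts) -> dict:
    from .consensus import metrics as _metrics

    perf = _metrics(counts)
    return {
        "precision": perf.precision,
        "specificity": perf.specificity,
        "recall": perf.recall,
        "accuracy": perf.accuracy,
        "undefined": perf.undefined,
    }
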
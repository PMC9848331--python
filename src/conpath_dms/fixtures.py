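"""Packaged reference fixtures: the published hRPE65 evaluation matrices.

Machine-readable transcriptions of the published benchmark statistics for the
19 selected predictors, the two P/N consensus prediction matrices (9 + 4
VUS), the per-variant alert table, and the reported WT/mutant hydrogen-bond
occupancies and RMSD/RMSF summary magnitudes.  Where the source quantified an
occupancy only as a phrase ("more than 50%", "almost 100%"), a single
representative value on the stated side of the threshold was fixed here once;
the RMSD/RMSF entries are likewise transcriptions of reported summary
magnitudes, not recomputed trajectories.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .alerts import AlertProfile
from .consensus import ConfusionCounts, PredictionMatrix
from .trajectory import (
    HBondOccupancyRecord,
    ResidueRef,
    StructuralMetrics,
)

#: nominal frame count attached to transcribed occupancy records
_NOMINAL_FRAMES = 1000

#: hRPE65 residue range covered by the DMS-focussed model (141 residues)
MODEL_RESIDUE_RANGE = range(278, 419)

#: residues of the reported mutant RMSF peak (hRPE65 numbering)
RMSF_PEAK_RESIDUES = range(375, 380)

FIRST_GROUP = ["K303N", "N373S", "D375N", "D375H", "E399K", "T390I", "V407A", "T400S", "W402S"]
SECOND_GROUP = ["N301S", "S307F", "V384F", "T306I"]
ALL_VARIANTS = FIRST_GROUP + SECOND_GROUP


def _read(name: str) -> pd.DataFrame:
    with resources.files("conpath_dms.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def benchmark_performance_table() -> pd.DataFrame:
    """Published per-tool benchmark statistics with implied confusion counts."""
    return _read("table1_performance.csv")


def benchmark_confusion_counts() -> dict[str, ConfusionCounts]:
    """Confusion counts implied by the printed metrics on the 27+3 benchmark."""
    table = benchmark_performance_table()
    return {
        row["tool"]: ConfusionCounts(tp=row["TP"], tn=row["TN"], fp=row["FP"], fn=row["FN"])
        for _, row in table.iterrows()
    }


def _calls_matrix(name: str) -> PredictionMatrix:
    frame = _read(name).set_index("tool").T  # variants x tools
    frame.index.name = "variant"
    return PredictionMatrix.from_binary_frame(frame)


def first_group_matrix() -> PredictionMatrix:
    """19-tool P/N calls for the first nine VUS."""
    return _calls_matrix("table2_calls.csv")


def second_group_matrix() -> PredictionMatrix:
    """19-tool P/N calls for the remaining four VUS."""
    return _calls_matrix("table3_calls.csv")


def combined_matrix() -> PredictionMatrix:
    """All 13 VUS x 19 tools."""
    a, b = first_group_matrix(), second_group_matrix()
    frame = pd.concat([a.calls, b.calls.loc[:, a.calls.columns]], axis=0)
    return PredictionMatrix(frame, {t: "binary" for t in frame.columns})


def alert_profiles() -> list[AlertProfile]:
    """The 13 published alert triples (with published ConPath votes attached)."""
    table = _read("table4_alerts.csv")
    profiles = []
    for _, row in table.iterrows():
        profiles.append(
            AlertProfile(
                variant=row["variant"],
                structural=row["structural"] == "+",
                interaction=row["interaction"] == "+",
                conpath=row["conpath"] == "+",
                conpath_votes=int(row["conpath_votes"]),
            )
        )
    return profiles


def published_classes() -> dict[str, str]:
    table = _read("table4_alerts.csv")
    return dict(zip(table["variant"], table["class"]))


def hbond_records(system: str) -> list[HBondOccupancyRecord]:
    """Transcribed residue-pair occupancies for ``'WT'`` or a variant name."""
    table = _read("hbond_occupancies.csv")
    sub = table[table["system"] == system]
    if sub.empty and system != "WT":
        known = set(table["system"])
        if system not in known and system not in ALL_VARIANTS:
            raise KeyError(f"unknown system {system!r}")
    records = []
    for _, row in sub.iterrows():
        records.append(
            HBondOccupancyRecord(
                donor=ResidueRef(row["donor_chain"], int(row["donor_resid"]), row["donor_name"]),
                acceptor=ResidueRef(
                    row["acceptor_chain"], int(row["acceptor_resid"]), row["acceptor_name"]
                ),
                contact_class=row["class"],
                occupancy=float(row["occupancy"]),
                n_frames=_NOMINAL_FRAMES,
            )
        )
    return records


def structural_metrics(system: str) -> StructuralMetrics:
    """Transcribed RMSD/RMSF summaries as a StructuralMetrics object.

    The RMSD series is a constant stand-in whose second-half mean equals the
    reported value; the RMSF profile is flat at the reported baseline with the
    reported peak (if any) over hRPE65 residues 375-379.
    """
    table = _read("structural_summaries.csv").set_index("system")
    if system not in table.index:
        raise KeyError(f"no structural summary for system {system!r}")
    row = table.loc[system]
    rmsd_value = float(row["second_half_mean_rmsd"])
    rmsf = pd.Series(float(row["rmsf_baseline"]), index=list(MODEL_RESIDUE_RANGE), name="rmsf")
    if not pd.isna(row["rmsf_peak_max"]):
        rmsf.loc[list(RMSF_PEAK_RESIDUES)] = float(row["rmsf_peak_max"])
    return StructuralMetrics(
        rmsd_series=np.full(100, rmsd_value),
        second_half_mean_rmsd=rmsd_value,
        rmsf=rmsf,
    )


def make_reference_fixtures() -> dict:
    """Bundle of every transcription, keyed by content."""
    return {
        "performance": benchmark_performance_table(),
        "confusion_counts": benchmark_confusion_counts(),
        "first_group_matrix": first_group_matrix(),
        "second_group_matrix": second_group_matrix(),
        "alert_profiles": alert_profiles(),
        "classes": published_classes(),
        "wt_hbonds": hbond_records("WT"),
        "mutant_hbonds": {v: hbond_records(v) for v in ALL_VARIANTS},
        "structural_metrics": {s: structural_metrics(s) for s in ["WT"] + ALL_VARIANTS},
    }
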
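"""Four-level pathogenic-potential classification from three binary alerts.

Each variant carries three evidence flags: a structural alert (conformational
deviation from wild type in the MD ensemble), a pairwise-interaction alert
(disruption of native H-bonds around the mutated residue) and a ConPath alert
(consensus score at or above the pathogenic threshold).  The count of raised
alerts maps to a class:

    3 -> HPPV   (high pathogenic potential)
    2 -> MHPPV  (moderate/high)
    1 -> MLPPV  (moderate/low)
    0 -> LPPV   (low)

Variants with 0 or 3 alerts form the high-confidence subset: all lines of
evidence agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import pandas as pd

from .consensus import VariantId

CLASS_BY_ALERT_COUNT = {3: "HPPV", 2: "MHPPV", 1: "MLPPV", 0: "LPPV"}
CLASSES = ("HPPV", "MHPPV", "MLPPV", "LPPV")


@dataclass
class AlertProfile:
    """Per-variant alert flags plus the evidence that fired them.

    A flag may be ``None`` (unknown, e.g. no MD ensemble available); such
    partial profiles can be reported but never classified.
    """

    variant: str
    structural: bool | None
    interaction: bool | None
    conpath: bool | None
    conpath_votes: int | None = None
    evidence: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        VariantId.parse(self.variant)

    @property
    def alert_count(self) -> int:
        if None in (self.structural, self.interaction, self.conpath):
            raise ValueError(f"profile for {self.variant} has unknown flags; cannot count alerts")
        return int(self.structural) + int(self.interaction) + int(self.conpath)

    @property
    def is_complete(self) -> bool:
        return None not in (self.structural, self.interaction, self.conpath)


def classify(profile: AlertProfile) -> str:
    """Map a complete alert profile to its pathogenic-potential class."""
    if not profile.is_complete:
        raise ValueError(
            f"variant {profile.variant} has unknown alert flags; partial profiles are "
            "reported, never classified"
        )
    return CLASS_BY_ALERT_COUNT[profile.alert_count]


@dataclass
class CohortReport:
    table: pd.DataFrame
    class_counts: dict[str, int]
    high_confidence: list[str]


def cohort_report(profiles: Sequence[AlertProfile]) -> CohortReport:
    """Classify a cohort and summarise class counts and the high-confidence subset.

    High confidence = 0 or 3 alerts (LPPV or HPPV): the structural,
    interaction and consensus evidence all point the same way.
    """
    seen = set()
    for p in profiles:
        if p.variant in seen:
            raise ValueError(f"duplicate variant in cohort: {p.variant}")
        seen.add(p.variant)

    rows = []
    counts = {c: 0 for c in CLASSES}
    high_conf = []
    for p in profiles:
        cls = classify(p)
        counts[cls] += 1
        if p.alert_count in (0, 3):
            high_conf.append(p.variant)
        rows.append(
            {
                "variant": p.variant,
                "structural": p.structural,
                "interaction": p.interaction,
                "conpath": p.conpath,
                "conpath_votes": p.conpath_votes,
                "class": cls,
            }
        )
    columns = ["variant", "structural", "interaction", "conpath", "conpath_votes", "class"]
    table = pd.DataFrame(rows, columns=columns)
    return CohortReport(table=table, class_counts=counts, high_confidence=high_conf)
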
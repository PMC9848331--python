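"""Consensus pathogenicity scoring (ConPath) for hRPE65 missense variants.

This module turns heterogeneous per-tool predictions (binary calls or raw
scores) into a single consensus statistic: the ConPath score, the number of
tools in a benchmarked panel that call a variant pathogenic.  The pipeline is

    binarize -> confusion -> metrics -> select_tools -> conpath

Tools are benchmarked against a labelled variant set (27 pathogenic + 3
benign hRPE65 ClinVar variants in the reference cohort), and only tools whose
recall and specificity clear configurable thresholds enter the voting panel.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PATHOGENIC = "Pathogenic"
NEUTRAL = "Neutral"
BENIGN = "Benign"

#: Amino-acid one-letter codes accepted in variant names.
_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class ConfigurationError(ValueError):
    """A matrix, cutoff table or panel is inconsistent with the request."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VariantId:
    """A protein-level missense change, e.g. ``K303N`` (hRPE65 numbering)."""

    wt: str
    position: int
    mutant: str

    def __post_init__(self) -> None:
        if self.wt not in _AA_CODES or self.mutant not in _AA_CODES:
            raise ValueError(f"unknown amino-acid code in variant {self}")
        if self.position < 1:
            raise ValueError(f"residue number must be positive: {self}")
        if self.wt == self.mutant:
            raise ValueError(f"wild-type and mutant residue identical: {self}")

    @classmethod
    def parse(cls, text: str) -> "VariantId":
        m = _VARIANT_RE.match(text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse variant name {text!r} (expect e.g. 'K303N')")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:  # noqa: D105
        return f"{self.wt}{self.position}{self.mutant}"


# Canonical predictor names.  The literature uses variant spellings; every
# alias maps to one canonical name so benchmark rows and prediction columns
# always join correctly.
TOOL_ALIASES: dict[str, str] = {
    "mut. assessor": "Mut. Assessor",
    "mut. assesor": "Mut. Assessor",
    "mutationassessor": "Mut. Assessor",
    "mutation assessor": "Mut. Assessor",
    "suspect": "SuSPect",
    "nei mut. search": "NEI Mut. Search",
    "nei commons mutation search": "NEI Mut. Search",
    "integrated fitcons": "Integrated FitCons",
    "integrated_fitcons": "Integrated FitCons",
}


def canonical_tool_name(name: str) -> str:
    """Map a tool-name spelling to its canonical form (identity if unknown)."""
    return TOOL_ALIASES.get(name.strip().lower(), name.strip())


#: Published score cutoffs for tools that emit raw scores rather than calls.
#: Convention: score >= cutoff => Pathogenic.
DEFAULT_CUTOFFS: dict[str, float] = {
    "Eigen": 0.0,
    "Eigen-PC": 0.0,
    "SNPs3D": 0.0,
    "INPS-sequence": 0.0,
    "PROST": 0.0,
    "Integrated FitCons": 0.4,
    "REVEL": 0.5,
    "VEST4": 0.5,
    "DANN": 0.5,
    "MutPred2": 0.5,
    "PON-P2": 0.5,
    "MVP": 0.75,
    "CADD": 20.0,
    "CADD_hg19": 20.0,
    "SuSPect": 50.0,
}


@dataclass
class CutoffTable:
    """Per-tool score cutoffs with a score >= cutoff => Pathogenic convention.

    ``strict`` lists tools for which the inequality is strict instead
    (score > cutoff), an override for the undocumented boundary case.
    """

    cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    strict: set[str] = field(default_factory=set)

    def call(self, tool: str, score: float) -> str:
        tool = canonical_tool_name(tool)
        if tool not in self.cutoffs:
            raise ConfigurationError(f"scored tool {tool!r} has no cutoff entry")
        cut = self.cutoffs[tool]
        hit = score > cut if tool in self.strict else score >= cut
        return PATHOGENIC if hit else NEUTRAL


def _normalise_call(value: object) -> str | None:
    """Map a cell to 'Pathogenic'/'Neutral'/None (missing)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    low = text.lower()
    if low in ("p", "pathogenic"):
        return PATHOGENIC
    if low in ("n", "neutral", "benign", "b"):
        return NEUTRAL
    raise ValueError(f"unrecognised binary call {value!r}")


@dataclass
class PredictionMatrix:
    """Variants x tools table of predictions.

    ``calls`` is a DataFrame indexed by variant name with canonical tool
    columns; cells hold ``'Pathogenic'``/``'Neutral'`` for binary tools, raw
    floats for scored tools, and ``None``/NaN for missing predictions.
    ``tool_types`` declares each column as ``'binary'`` or ``'scored'``.
    """

    calls: pd.DataFrame
    tool_types: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = self.calls.copy()
        self.calls.columns = [canonical_tool_name(c) for c in self.calls.columns]
        self.tool_types = {canonical_tool_name(k): v for k, v in self.tool_types.items()}
        if self.calls.columns.duplicated().any():
            dup = self.calls.columns[self.calls.columns.duplicated()].tolist()
            raise ValueError(f"duplicate tool columns after canonicalisation: {dup}")
        if self.calls.index.duplicated().any():
            dup = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValueError(f"duplicate variants: {dup}")
        for tool in self.calls.columns:
            kind = self.tool_types.get(tool)
            if kind not in ("binary", "scored"):
                raise ValueError(f"tool {tool!r} must be declared 'binary' or 'scored'")
        for v in self.calls.index:
            VariantId.parse(v)  # validates naming

    @property
    def variants(self) -> list[str]:
        return list(self.calls.index)

    @property
    def tools(self) -> list[str]:
        return list(self.calls.columns)

    def is_binary(self) -> bool:
        return all(t == "binary" for t in self.tool_types.values())

    @classmethod
    def from_binary_frame(cls, frame: pd.DataFrame) -> "PredictionMatrix":
        """Build from a P/N DataFrame (variants x tools)."""
        norm = frame.map(_normalise_call)
        return cls(norm, {c: "binary" for c in frame.columns})


@dataclass
class BenchmarkLabelSet:
    """Known variant labels used to benchmark predictors."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for variant, label in self.labels.items():
            VariantId.parse(variant)
            label = label.strip().capitalize()
            if label not in (PATHOGENIC, BENIGN):
                raise ValueError(f"label for {variant} must be Pathogenic/Benign, got {label!r}")
            clean[variant] = label
        self.labels = clean

    @property
    def n_pathogenic(self) -> int:
        return sum(1 for v in self.labels.values() if v == PATHOGENIC)

    @property
    def n_benign(self) -> int:
        return sum(1 for v in self.labels.values() if v == BENIGN)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def round2(value: float | None) -> float | None:
    """Round half-up to 2 decimals, for report columns only."""
    if value is None:
        return None
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ToolPerformance:
    """Benchmark statistics for one predictor.

    Metrics are raw fractions; a metric whose denominator is zero is ``None``
    and listed in ``undefined`` rather than silently reported as 0.
    """

    tool: str
    counts: ConfusionCounts
    precision: float | None
    specificity: float | None
    recall: float | None
    accuracy: float | None
    undefined: tuple[str, ...] = ()

    def rounded(self) -> dict[str, float | None]:
        return {
            "recall": round2(self.recall),
            "precision": round2(self.precision),
            "specificity": round2(self.specificity),
            "accuracy": round2(self.accuracy),
        }


@dataclass
class ConPathResult:
    """Consensus vote for one variant over a selected tool panel."""

    variant: str
    votes: int
    panel_size: int
    call: str
    per_tool_calls: dict[str, str]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def binarize(matrix: PredictionMatrix, cutoffs: CutoffTable | None = None) -> PredictionMatrix:
    """Convert scored columns to Pathogenic/Neutral calls via the cutoff table.

    Binary columns pass through unchanged; missing cells stay missing.
    Raising a score can never flip a Pathogenic call back to Neutral.
    """
    cutoffs = cutoffs or CutoffTable()
    out = {}
    for tool in matrix.tools:
        col = matrix.calls[tool]
        if matrix.tool_types[tool] == "binary":
            out[tool] = col.map(_normalise_call)
            continue
        if canonical_tool_name(tool) not in cutoffs.cutoffs:
            raise ConfigurationError(f"scored tool {tool!r} has no cutoff entry")
        out[tool] = col.map(
            lambda s, t=tool: None
            if s is None or (isinstance(s, float) and math.isnan(s))
            else cutoffs.call(t, float(s))
        )
    frame = pd.DataFrame(out, index=matrix.calls.index)
    return PredictionMatrix(frame, {t: "binary" for t in matrix.tools})


def confusion(calls: Mapping[str, str | None], labels: BenchmarkLabelSet) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for one tool's per-variant binary calls.

    Positives are pathogenic variants; a benign variant called Pathogenic is a
    false positive.  Missing predictions are excluded from the counts (and
    logged); an unlabeled variant is an error.
    """
    unlabeled = [v for v in calls if v not in labels.labels]
    if unlabeled:
        raise ValueError(f"variants missing benchmark labels: {sorted(unlabeled)}")
    tp = tn = fp = fn = 0
    skipped = []
    for variant, call in calls.items():
        if call is None:
            skipped.append(variant)
            continue
        truth_pathogenic = labels.labels[variant] == PATHOGENIC
        pred_pathogenic = call == PATHOGENIC
        if truth_pathogenic and pred_pathogenic:
            tp += 1
        elif truth_pathogenic:
            fn += 1
        elif pred_pathogenic:
            fp += 1
        else:
            tn += 1
    if skipped:
        logger.warning("confusion: %d missing predictions excluded: %s", len(skipped), skipped)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts, tool: str = "") -> ToolPerformance:
    """Precision, specificity, recall and accuracy from confusion counts.

    Precision = TP/(TP+FP);  Specificity = TN/(TN+FP);
    Recall    = TP/(TP+FN);  Accuracy    = (TP+TN)/(TP+TN+FP+FN).
    Zero-denominator metrics are flagged undefined.
    """
    undefined = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    return ToolPerformance(
        tool=tool,
        counts=counts,
        precision=ratio(counts.tp, counts.tp + counts.fp, "precision"),
        specificity=ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        recall=ratio(counts.tp, counts.tp + counts.fn, "recall"),
        accuracy=ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        undefined=tuple(undefined),
    )


def benchmark_tools(matrix: PredictionMatrix, labels: BenchmarkLabelSet) -> list[ToolPerformance]:
    """Confusion + metrics for every tool of a binary matrix."""
    perfs = []
    for tool in matrix.tools:
        counts = confusion(dict(matrix.calls[tool]), labels)
        perfs.append(metrics(counts, tool=tool))
    return perfs


def select_tools(
    perfs: Sequence[ToolPerformance],
    recall_min: float = 0.78,
    specificity_min: float = 0.67,
) -> list[str]:
    """Retain tools with recall >= recall_min and specificity >= specificity_min.

    Comparison happens at the 2-decimal reporting precision: thresholds like
    0.67 are quoted at that precision and must admit a specificity of 2/3
    (0.6667), which a raw-fraction comparison would reject.  Input order is
    preserved.  Tools with an undefined recall or specificity cannot
    demonstrate reliability and are excluded.
    """
    for p in perfs:
        if p.recall is None or p.specificity is None:
            logger.warning("select_tools: %s has undefined metrics, excluded", p.tool)
    eps = 1e-9
    selected = [
        p.tool
        for p in perfs
        if p.recall is not None
        and p.specificity is not None
        and round2(p.recall) >= recall_min - eps
        and round2(p.specificity) >= specificity_min - eps
    ]
    if not selected:
        logger.warning("select_tools: no tool met recall>=%.2f and specificity>=%.2f",
                       recall_min, specificity_min)
    return selected


def default_pathogenic_min(panel_size: int) -> int:
    """Majority threshold: 10 for the reference 19-tool panel, floor(n/2)+1 otherwise."""
    return panel_size // 2 + 1


def conpath(
    matrix: PredictionMatrix,
    panel: Sequence[str] | None = None,
    pathogenic_min: int | None = None,
    missing_as_neutral: bool = False,
) -> list[ConPathResult]:
    """ConPath consensus: votes = number of panel tools calling each variant pathogenic.

    With the reference 19-tool panel the call is Pathogenic iff votes >= 10
    (score <= 9 is potentially neutral).  By default a missing panel
    prediction is an error; ``missing_as_neutral`` opts into the conservative
    policy of counting it as a Neutral vote (logged).
    """
    if not matrix.is_binary():
        raise ConfigurationError("conpath requires a binary matrix; run binarize first")
    panel = [canonical_tool_name(t) for t in (panel or matrix.tools)]
    unknown = [t for t in panel if t not in matrix.tools]
    if unknown:
        raise ConfigurationError(f"panel tools absent from matrix: {unknown}")
    threshold = pathogenic_min if pathogenic_min is not None else default_pathogenic_min(len(panel))
    results = []
    for variant in matrix.variants:
        per_tool = {}
        for tool in panel:
            call = matrix.calls.at[variant, tool]
            call = _normalise_call(call)
            if call is None:
                if not missing_as_neutral:
                    raise ConfigurationError(
                        f"missing prediction for variant {variant}, tool {tool}"
                    )
                logger.warning("conpath: missing %s/%s counted as Neutral", variant, tool)
                call = NEUTRAL
            per_tool[tool] = call
        votes = sum(1 for c in per_tool.values() if c == PATHOGENIC)
        results.append(
            ConPathResult(
                variant=variant,
                votes=votes,
                panel_size=len(panel),
                call=PATHOGENIC if votes >= threshold else NEUTRAL,
                per_tool_calls=per_tool,
            )
        )
    return results


def performance_frame(perfs: Iterable[ToolPerformance]) -> pd.DataFrame:
    """Report table: one row per tool with counts and 2-decimal metrics."""
    rows = []
    for p in perfs:
        rows.append(
            {
                "tool": p.tool,
                "TP": p.counts.tp,
                "TN": p.counts.tn,
                "FP": p.counts.fp,
                "FN": p.counts.fn,
                **p.rounded(),
            }
        )
    return pd.DataFrame(rows)


def conpath_frame(results: Iterable[ConPathResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"variant": r.variant, "votes": r.votes, "panel_size": r.panel_size, "call": r.call}
            for r in results
        ]
    )
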
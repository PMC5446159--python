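"""Deep-mutational-scanning variant counts -> fitness -> reference-anchored
ddG estimates.

Fitness of a variant is the ratio of its count change across one round of
selection to that of wild type. A mutation B's stability change is then
estimated against a marginally stable reference background A from the
fitness drop of the double mutant AB:

    ddG_fit(B) = -ln[(W_B - W_AB) / W_AB] + ln[(1 - W_A) / W_A]

with three quality filters: the estimate is rejected when W_B <= W_AB
(the underlying two-state assumption is violated), when the AB double
mutant's input count is below 90 (sequencing noise), or when W_B < 0.24
(insufficient dynamic range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

MIN_AB_INPUT = 90
MIN_WB = 0.24

FILTER_FITNESS_ORDER = "filter1_wb_le_wab"
FILTER_LOW_COUNT = "filter2_low_ab_input"
FILTER_LOW_WB = "filter3_wb_below_0.24"


class UndefinedFitnessError(ValueError):
    """A zero count makes the fitness ratio undefined."""


@dataclass(frozen=True)
class Rejection:
    reason: str

    def __bool__(self) -> bool:  # rejections are falsy results
        return False


@dataclass
class CountTable:
    """Variant label -> (input count, selected count), plus the wt counts.

    Labels are single mutations like ``I8A`` or double mutations joined by
    '/', e.g. ``Y3A/I8A`` (order-insensitive).
    """

    rows: dict[str, tuple[int, int]]
    wt: tuple[int, int]

    def __post_init__(self) -> None:
        if self.wt[0] <= 0 or self.wt[1] <= 0:
            raise ValueError("wild-type counts must be strictly positive")
        self.rows = {self._norm(k): v for k, v in self.rows.items()}

    @staticmethod
    def _norm(label: str) -> str:
        parts = sorted(label.strip().split("/"))
        return "/".join(parts)

    def counts(self, label: str) -> tuple[int, int]:
        key = self._norm(label)
        if key not in self.rows:
            raise KeyError(f"variant {label!r} not in table")
        return self.rows[key]

    def __contains__(self, label: str) -> bool:
        return self._norm(label) in self.rows

    def single_mutations(self) -> list[str]:
        return sorted(k for k in self.rows if "/" not in k)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant": str})
        rows = {}
        wt = None
        for _, r in df.iterrows():
            if r["variant"].lower() == "wt":
                wt = (int(r["n_input"]), int(r["n_selected"]))
            else:
                rows[r["variant"]] = (int(r["n_input"]), int(r["n_selected"]))
        if wt is None:
            raise ValueError("count table must contain a 'wt' row")
        return cls(rows, wt)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["variant\tn_input\tn_selected", f"wt\t{self.wt[0]}\t{self.wt[1]}"]
        for k in sorted(self.rows):
            n_in, n_sel = self.rows[k]
            lines.append(f"{k}\t{n_in}\t{n_sel}")
        Path(path).write_text("\n".join(lines) + "\n")


def fitness(table: CountTable, variant: str, orientation: str = "as_printed") -> float:
    """Fitness W of a variant relative to wild type.

    ``orientation='as_printed'`` uses the variant's input/selected ratio
    (times the wild type's selected/input); ``'enrichment'`` uses the
    reciprocal, the conventional enrichment ratio. Both are supported
    because published transcriptions of the formula disagree with the
    enrichment convention; pick the one matching your pipeline.
    """
    n_in, n_sel = table.counts(variant)
    wt_in, wt_sel = table.wt
    if 0 in (n_in, n_sel, wt_in, wt_sel):
        raise UndefinedFitnessError(f"zero count for variant {variant!r}")
    if orientation == "as_printed":
        return (n_in / n_sel) * (wt_sel / wt_in)
    if orientation == "enrichment":
        return (n_sel / n_in) * (wt_in / wt_sel)
    raise ValueError(f"unknown orientation {orientation!r}")


def _double_label(a: str, b: str) -> str:
    return "/".join(sorted([a, b]))


def ddg_fit(
    table: CountTable,
    B: str,
    A: str,
    orientation: str = "as_printed",
    min_ab_input: int = MIN_AB_INPUT,
    min_wb: float = MIN_WB,
) -> float | Rejection:
    """ddG of single mutation B estimated in reference background A.

    Returns a Rejection (with machine-readable reason) when any of the
    three quality filters fires, checked in their stated order.
    """
    ab = _double_label(A, B)
    w_b = fitness(table, B, orientation)
    w_a = fitness(table, A, orientation)
    w_ab = fitness(table, ab, orientation)
    if w_b <= w_ab:
        return Rejection(FILTER_FITNESS_ORDER)
    n_ab_input, _ = table.counts(ab)
    if n_ab_input < min_ab_input:
        return Rejection(FILTER_LOW_COUNT)
    if w_b < min_wb:
        return Rejection(FILTER_LOW_WB)
    return -math.log((w_b - w_ab) / w_ab) + math.log((1.0 - w_a) / w_a)


@dataclass
class DdgFitEstimate:
    mutation: str
    per_reference: dict[str, float]
    mean: float
    n_references_used: int


def ddg_fit_dataset(
    table: CountTable,
    references: list[str],
    orientation: str = "as_printed",
    min_ab_input: int = MIN_AB_INPUT,
    min_wb: float = MIN_WB,
) -> tuple[list[DdgFitEstimate], dict[str, int]]:
    """Estimate ddG for every single mutation against every reference.

    A mutation survives iff at least one reference yields an accepted
    estimate; its value is the mean over surviving references. Also
    returns rejection counts keyed by filter reason.
    """
    if not references:
        raise ValueError("need at least one reference mutation")
    out: list[DdgFitEstimate] = []
    rejections: dict[str, int] = {}
    for b in table.single_mutations():
        if b in references:
            continue
        per_ref: dict[str, float] = {}
        for a in references:
            if a not in table or _double_label(a, b) not in table:
                continue
            try:
                val = ddg_fit(table, b, a, orientation, min_ab_input, min_wb)
            except UndefinedFitnessError:
                continue
            if isinstance(val, Rejection):
                rejections[val.reason] = rejections.get(val.reason, 0) + 1
            else:
                per_ref[a] = val
        if per_ref:
            vals = list(per_ref.values())
            out.append(DdgFitEstimate(b, per_ref, sum(vals) / len(vals), len(vals)))
    return out, rejections
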
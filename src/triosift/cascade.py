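"""Five-stage family-based variant screening cascade.

Order of application (the study's order; the final set is order-independent
because every stage is a pure per-record predicate):

1. ``frequency``          — population allele frequency below a cut-off (default
   1%, gnomAD-style cohort AF; absent AF passes by default: novel = rare).
2. ``affected_sharing``   — every affected sample carries at least one alt
   allele (het or hom-alt both qualify as "shared").
3. ``unaffected_carrier`` — no unaffected control carries an alt allele.
4. ``class_consequence``  — drop benign/likely-benign classifications and
   consequences that do not affect the protein.
5. ``depth``              — read depth at the site at least ``min_depth``
   (default 20x) in every family sample that reports one.

A final report restriction (default: missense only) selects what goes into the
candidate table; it is a separate knob because the protein-affecting filter is
broader than the reported consequence class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .pedigree import FamilyDesign
from .variant_model import (
    Classification,
    Consequence,
    TriosiftError,
    VariantKey,
    VariantRecord,
    VariantSet,
)

logger = logging.getLogger("triosift")

STAGE_FREQUENCY = "frequency"
STAGE_SHARING = "affected_sharing"
STAGE_UNAFFECTED = "unaffected_carrier"
STAGE_CLASS = "class_consequence"
STAGE_DEPTH = "depth"
STAGE_REPORT = "report"
STAGE_NONE = "none"

DEFAULT_STAGE_ORDER = (
    STAGE_FREQUENCY,
    STAGE_SHARING,
    STAGE_UNAFFECTED,
    STAGE_CLASS,
    STAGE_DEPTH,
)

STRICT_DROP = "strict_drop"
LENIENT_KEEP = "lenient_keep"


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and policies of the five filters.

    ``af_threshold`` is strict-less (<): an AF of exactly 1% is removed.
    Missing-genotype policies are conservative by default (``strict_drop``):
    an unverifiable genotype removes the variant rather than promoting it.
    """

    af_threshold: float = 0.01
    missing_af_passes: bool = True
    excluded_classes: frozenset[Classification] = frozenset(
        {Classification.benign, Classification.likely_benign}
    )
    allowed_consequences: frozenset[Consequence] = frozenset(
        {
            Consequence.missense,
            Consequence.nonsense,
            Consequence.frameshift,
            Consequence.splice_region,
            Consequence.inframe_indel,
        }
    )
    report_consequences: frozenset[Consequence] = frozenset({Consequence.missense})
    min_depth: int = 20
    unaffected_missing_gt_policy: str = STRICT_DROP
    affected_missing_gt_policy: str = STRICT_DROP
    snv_only: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.af_threshold <= 1.0):
            raise TriosiftError(f"af_threshold must lie in (0, 1], got {self.af_threshold}")
        if self.min_depth < 0:
            raise TriosiftError(f"min_depth must be >= 0, got {self.min_depth}")
        if not self.report_consequences <= self.allowed_consequences:
            raise TriosiftError(
                "report_consequences must be a subset of allowed_consequences"
            )
        for pol in (self.unaffected_missing_gt_policy, self.affected_missing_gt_policy):
            if pol not in (STRICT_DROP, LENIENT_KEEP):
                raise TriosiftError(f"unknown missing-GT policy {pol!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CascadeConfig":
        """Build a config from string-valued key=value pairs (config files, CLI)."""
        kwargs: dict = {}
        known = {f.name for f in fields(cls)}
        for key, raw in mapping.items():
            if key not in known:
                raise TriosiftError(f"unknown cascade config key {key!r}")
            if key == "af_threshold":
                kwargs[key] = float(raw)
            elif key == "min_depth":
                kwargs[key] = int(raw)
            elif key in ("missing_af_passes", "snv_only"):
                kwargs[key] = str(raw).strip().lower() in ("1", "true", "yes", "on")
            elif key == "excluded_classes":
                kwargs[key] = frozenset(
                    Classification(v.strip()) for v in str(raw).split(",") if v.strip()
                )
            elif key in ("allowed_consequences", "report_consequences"):
                kwargs[key] = frozenset(
                    Consequence(v.strip()) for v in str(raw).split(",") if v.strip()
                )
            else:
                kwargs[key] = str(raw).strip()
        return cls(**kwargs)


def read_config(path: str | Path) -> CascadeConfig:
    """Read a ``key = value`` cascade config file (# comments allowed)."""
    mapping: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise TriosiftError(f"bad config line (expected key=value): {ln!r}")
        key, val = ln.split("=", 1)
        mapping[key.strip()] = val.strip()
    return CascadeConfig.from_mapping(mapping)


# ---------------------------------------------------------------------------
# Per-record predicates (pure; the stages and any brute-force check share them)
# ---------------------------------------------------------------------------

def passes_frequency(rec: VariantRecord, cfg: CascadeConfig) -> bool:
    af = rec.annotation.pop_af
    if af is None:
        return cfg.missing_af_passes
    return af < cfg.af_threshold


def passes_affected_sharing(
    rec: VariantRecord, design: FamilyDesign, cfg: CascadeConfig
) -> bool:
    for sid in design.affected_ids:
        call = rec.calls[sid]
        if call.is_missing:
            if cfg.affected_missing_gt_policy == STRICT_DROP:
                return False
            continue  # lenient: an uncallable genotype does not veto sharing
        if not call.has_alt:
            return False
    return True


def passes_unaffected_exclusion(
    rec: VariantRecord, design: FamilyDesign, cfg: CascadeConfig
) -> bool:
    for sid in design.unaffected_ids:
        call = rec.calls[sid]
        if call.is_missing:
            if cfg.unaffected_missing_gt_policy == STRICT_DROP:
                return False  # absence in the control could not be confirmed
            continue
        if call.has_alt:
            return False
    return True


def passes_class_consequence(rec: VariantRecord, cfg: CascadeConfig) -> bool:
    ann = rec.annotation
    if ann.classification is not None and ann.classification in cfg.excluded_classes:
        return False
    # missing classification is treated as uncertain significance (kept)
    if ann.consequence not in cfg.allowed_consequences:
        return False
    if cfg.snv_only and not rec.is_snv:
        return False
    return True


def passes_depth(rec: VariantRecord, design: FamilyDesign, cfg: CascadeConfig) -> bool:
    any_depth = False
    for sid in design.sample_ids:
        dp = rec.calls[sid].depth
        if dp is None:
            continue
        any_depth = True
        if dp < cfg.min_depth:
            return False
    if not any_depth:
        # no depth assertion anywhere: absence of data is not evidence of low
        # coverage (the study verified coverage by inspection, outside the VCF)
        logger.warning("no depth data at %s:%s; kept", rec.chrom, rec.pos)
    return True


def passes_report(rec: VariantRecord, cfg: CascadeConfig) -> bool:
    return rec.annotation.consequence in cfg.report_consequences


STAGE_PREDICATES: dict[str, Callable[[VariantRecord, FamilyDesign, CascadeConfig], bool]] = {
    STAGE_FREQUENCY: lambda r, d, c: passes_frequency(r, c),
    STAGE_SHARING: passes_affected_sharing,
    STAGE_UNAFFECTED: passes_unaffected_exclusion,
    STAGE_CLASS: lambda r, d, c: passes_class_consequence(r, c),
    STAGE_DEPTH: passes_depth,
}


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def _keep(vset: VariantSet, pred: Callable[[VariantRecord], bool]) -> VariantSet:
    return VariantSet.from_records(
        (r for r in vset if pred(r)), vset.sample_ids
    )


def filter_by_population_frequency(vset: VariantSet, cfg: CascadeConfig) -> VariantSet:
    return _keep(vset, lambda r: passes_frequency(r, cfg))


def keep_shared_by_affected(
    vset: VariantSet, design: FamilyDesign, cfg: CascadeConfig
) -> VariantSet:
    return _keep(vset, lambda r: passes_affected_sharing(r, design, cfg))


def drop_unaffected_carriers(
    vset: VariantSet, design: FamilyDesign, cfg: CascadeConfig
) -> VariantSet:
    return _keep(vset, lambda r: passes_unaffected_exclusion(r, design, cfg))


def drop_benign_and_silent(vset: VariantSet, cfg: CascadeConfig) -> VariantSet:
    return _keep(vset, lambda r: passes_class_consequence(r, cfg))


def enforce_min_depth(
    vset: VariantSet, design: FamilyDesign, cfg: CascadeConfig
) -> VariantSet:
    return _keep(vset, lambda r: passes_depth(r, design, cfg))


# ---------------------------------------------------------------------------
# Trace and full run
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_out: int


@dataclass
class FilterTrace:
    """Per-variant removal provenance plus telescoping per-stage counts."""

    stage_counts: list[StageCount] = field(default_factory=list)
    removal_stage: dict[VariantKey, str] = field(default_factory=dict)

    def survivors(self) -> set[VariantKey]:
        return {k for k, s in self.removal_stage.items() if s == STAGE_NONE}

    def removed_at(self, stage: str) -> set[VariantKey]:
        return {k for k, s in self.removal_stage.items() if s == stage}

    def check_telescoping(self) -> None:
        for prev, nxt in zip(self.stage_counts, self.stage_counts[1:]):
            if prev.n_out != nxt.n_in:
                raise TriosiftError(
                    f"trace does not telescope: {prev.stage} out={prev.n_out} "
                    f"but {nxt.stage} in={nxt.n_in}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "stage": s}
            for k, s in sorted(self.removal_stage.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "stage"])


def write_trace_tsv(trace: FilterTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, sep="\t", index=False)


def run_cascade(
    vset: VariantSet,
    design: FamilyDesign,
    cfg: CascadeConfig | None = None,
    stage_order: Sequence[str] | None = None,
) -> tuple[VariantSet, FilterTrace]:
    """Run the five filters then the report restriction; return candidates + trace.

    ``stage_order`` permutes the five filter stages (the candidate set is
    invariant to the order; the trace is not).  The report restriction always
    runs last.
    """
    cfg = cfg or CascadeConfig()
    order = tuple(stage_order) if stage_order is not None else DEFAULT_STAGE_ORDER
    if sorted(order) != sorted(DEFAULT_STAGE_ORDER):
        raise TriosiftError(
            f"stage_order must be a permutation of {DEFAULT_STAGE_ORDER}, got {order}"
        )
    trace = FilterTrace()
    current = vset
    for stage in order:
        pred = STAGE_PREDICATES[stage]
        kept, removed = [], []
        for rec in current:
            (kept if pred(rec, design, cfg) else removed).append(rec)
        for rec in removed:
            trace.removal_stage[rec.key] = stage
        trace.stage_counts.append(StageCount(stage, len(current), len(kept)))
        current = VariantSet.from_records(kept, current.sample_ids)
    # report restriction: what goes into the candidate table
    kept, removed = [], []
    for rec in current:
        (kept if passes_report(rec, cfg) else removed).append(rec)
    for rec in removed:
        trace.removal_stage[rec.key] = STAGE_REPORT
    trace.stage_counts.append(StageCount(STAGE_REPORT, len(current), len(kept)))
    candidates = VariantSet.from_records(kept, current.sample_ids)
    for rec in candidates:
        trace.removal_stage[rec.key] = STAGE_NONE
    trace.check_telescoping()
    return candidates, trace
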
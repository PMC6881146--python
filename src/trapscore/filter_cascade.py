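"""The ordered filter cascade that refines raw enrichment lists.

Raw per-replicate enrichment lists are noisy: averaging can hide a
technical run that saw nothing, low-count proteins produce unstable F
values, and ribosomal subunits dominate any pulldown from whole-animal
lysate.  The cascade removes, in a fixed order:

  1. proteins not enriched in every biological replicate (F >= 0 cull),
  2. proteins with a technical-replicate inconsistency (>= 2 PSMs in
     one technical run, 0 in its paired run, within a replicate),
  3. proteins whose F-score standard deviation exceeds that of the
     spiked positive control (the bait's known ligand, the ubiquitin
     role),
  4. ribosomal subunits (by annotation flag or name pattern),
  5. proteins whose bait count beats the matched mock in fewer than a
     minimum number of technical runs,
  6. optionally, proteins failing manual tandem-spectra inspection
     (carried as an annotation flag; inspection itself is not
     automatable).

Every stage records what it removed and why; the trace partitions the
input exactly (retained plus removals, pairwise disjoint).  A separate
compile step (`filter_enriched_in_k`) implements the looser
"enriched in at least k of n replicates" list used before the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enrichment import FScoreRecord, FSentinel, _is_enriched
from .psm_io import ProteinAnnotation, ValidationError

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "Partition",
    "filter_enriched_in_k",
    "filter_all_replicates",
    "filter_technical_consistency",
    "filter_sd_vs_control",
    "filter_ribosomal",
    "filter_min_technical_enrichment",
    "filter_inspection",
    "apply_cascade",
]

DEFAULT_RIBOSOMAL_PATTERNS = ("RpL", "RpS", "ribosomal")


@dataclass(frozen=True)
class FilterConfig:
    """Tunable knobs of the cascade; defaults mirror the stringent defaults
    of the substrate-trap analysis (3-replicate cull, control-anchored SD
    filter, >= 2 technically enriched runs)."""

    control_protein_id: str
    min_enriched_bio_reps_compile: int = 2
    require_all_bio_reps: bool = True
    ribosomal_patterns: tuple[str, ...] = DEFAULT_RIBOSOMAL_PATTERNS
    min_technical_enrichment: int = 2
    use_inspection_flag: bool = True
    compile_threshold_mode: str = "strict"  # F > 0 for the k-of-n compile
    cull_threshold_mode: str = "inclusive"  # F >= 0 for the all-replicates cull

    def __post_init__(self) -> None:
        if not self.control_protein_id:
            raise ValidationError("control_protein_id must be non-empty")
        if self.min_enriched_bio_reps_compile < 1:
            raise ValidationError("min_enriched_bio_reps_compile must be >= 1")
        if self.min_technical_enrichment < 0:
            raise ValidationError("min_technical_enrichment must be >= 0")


@dataclass(frozen=True)
class Partition:
    """Outcome of one filter stage over a set of records."""

    retained: dict  # protein_id -> FScoreRecord
    removed: dict  # protein_id -> human-readable reason


@dataclass
class FilterTrace:
    """Ordered audit of the cascade: per stage, what was removed and why."""

    stages: list = field(default_factory=list)  # (stage_name, {pid: reason})
    retained: set = field(default_factory=set)

    def add(self, stage_name: str, removed: Mapping[str, str]) -> None:
        self.stages.append((stage_name, dict(removed)))

    @property
    def removed_ids(self) -> set:
        out: set = set()
        for _, removed in self.stages:
            out |= set(removed)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("stage\tprotein_id\treason\n")
            for stage_name, removed in self.stages:
                for pid in sorted(removed):
                    fh.write(f"{stage_name}\t{pid}\t{removed[pid]}\n")


def _partition(records: Mapping[str, FScoreRecord], removed: dict) -> Partition:
    return Partition(
        retained={p: r for p, r in records.items() if p not in removed},
        removed=removed,
    )


def filter_enriched_in_k(
    records: Mapping[str, FScoreRecord], k: int, mode: str = "strict"
) -> Partition:
    """Keep proteins enriched in at least k biological replicates."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    n_bio = max(
        (len(r.per_rep_F) for r in records.values()), default=k
    )
    if k > n_bio:
        raise ValidationError(f"k={k} exceeds the {n_bio} biological replicates")
    removed = {}
    for pid, rec in records.items():
        n = sum(_is_enriched(f, mode) for _, f in rec.per_rep_F)
        if n < k:
            removed[pid] = f"enriched in {n} < {k} biological replicates"
    return _partition(records, removed)


def filter_all_replicates(
    records: Mapping[str, FScoreRecord], mode: str = "inclusive"
) -> Partition:
    """Keep proteins enriched in every biological replicate (sentinels fail)."""
    removed = {}
    for pid, rec in records.items():
        bad = [
            (b, f) for b, f in rec.per_rep_F if not _is_enriched(f, mode)
        ]
        if bad:
            b, f = bad[0]
            shown = f.value if isinstance(f, FSentinel) else f"F={f:.3g}"
            removed[pid] = f"not enriched in bio_rep {b} ({shown})"
    return _partition(records, removed)


def filter_technical_consistency(
    records: Mapping[str, FScoreRecord], multiple: int = 2
) -> Partition:
    """Drop proteins where a replicate average hides a technical dropout.

    A protein fails if, within any biological replicate, one bait
    technical run has >= ``multiple`` PSMs while another technical run
    of the same replicate has 0.
    """
    removed = {}
    for pid, rec in records.items():
        for rep in rec.reps:
            if len(rep.tech_C) < 2:
                continue
            if max(rep.tech_C) >= multiple and min(rep.tech_C) == 0:
                shown = tuple(f"{c:g}" for c in rep.tech_C)
                removed[pid] = (
                    f"technical inconsistency in bio_rep {rep.bio_rep}: "
                    f"bait tech counts ({', '.join(shown)})"
                )
                break
    return _partition(records, removed)


def filter_sd_vs_control(
    records: Mapping[str, FScoreRecord], control_protein_id: str
) -> Partition:
    """Drop proteins whose F-score SD exceeds the positive control's.

    The spiked control binds the bait in every pulldown, so its
    replicate-to-replicate F variability calibrates how much scatter a
    genuine interactor can show.  Strictly-greater SDs are removed; the
    control itself always survives this stage.
    """
    control = records.get(control_protein_id)
    if control is None:
        raise ValidationError(
            f"control protein {control_protein_id!r} not found among records"
        )
    if not control.sd_defined:
        raise ValidationError(
            f"control protein {control_protein_id!r} has undefined F-score SD"
        )
    removed = {}
    for pid, rec in records.items():
        if pid == control_protein_id:
            continue
        if rec.sd_defined and rec.sd_F > control.sd_F:
            removed[pid] = (
                f"F-score SD {rec.sd_F:.4g} > control SD {control.sd_F:.4g}"
            )
        elif not rec.sd_defined:
            removed[pid] = "F-score SD undefined (fewer than 2 defined F values)"
    return _partition(records, removed)


def filter_ribosomal(
    records: Mapping[str, FScoreRecord],
    annotations: Mapping[str, ProteinAnnotation],
    patterns: Sequence[str] = DEFAULT_RIBOSOMAL_PATTERNS,
) -> Partition:
    """Drop ribosomal subunits by annotation flag or name pattern."""
    pats = [p.lower() for p in patterns]
    removed = {}
    for pid, rec in records.items():
        annot = annotations.get(pid)
        name = annot.name if annot else pid
        if annot is not None and annot.is_ribosomal:
            removed[pid] = "annotated ribosomal subunit"
        elif any(p in name.lower() for p in pats):
            removed[pid] = f"name {name!r} matches ribosomal pattern"
    return _partition(records, removed)


def filter_min_technical_enrichment(
    records: Mapping[str, FScoreRecord], threshold: int = 2
) -> Partition:
    """Require bait > matched mock in at least ``threshold`` technical runs.

    Counts, across all biological replicates, the technical runs in
    which the bait count strictly exceeds the paired mock count.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    removed = {}
    for pid, rec in records.items():
        n = sum(
            c > m
            for rep in rec.reps
            for c, m in zip(rep.tech_C, rep.tech_M)
        )
        if n < threshold:
            removed[pid] = (
                f"bait > mock in only {n} technical runs (< {threshold})"
            )
    return _partition(records, removed)


def filter_inspection(
    records: Mapping[str, FScoreRecord],
    annotations: Mapping[str, ProteinAnnotation],
) -> Partition:
    """Drop proteins flagged as failing manual spectra inspection."""
    removed = {}
    for pid in records:
        annot = annotations.get(pid)
        if annot is not None and not annot.spectra_inspection_pass:
            removed[pid] = "failed manual tandem-spectra inspection"
    return _partition(records, removed)


#: Fixed cascade order; stages can be disabled via config but not reordered.
CASCADE_STAGES = (
    "all_replicates",
    "technical_consistency",
    "sd_vs_control",
    "ribosomal",
    "min_technical_enrichment",
    "inspection",
)


def apply_cascade(
    records: Mapping[str, FScoreRecord],
    annotations: Mapping[str, ProteinAnnotation],
    config: FilterConfig,
) -> tuple[dict, FilterTrace]:
    """Run every enabled stage in the fixed order, keeping a full trace.

    The positive control must survive the stages upstream of the SD
    filter — if the spiked control itself fails the cull or the
    technical-consistency rule, the SD anchor is meaningless and the
    run aborts with an error rather than silently filtering without it.
    """
    trace = FilterTrace()
    current: dict = dict(records)
    ctrl = config.control_protein_id

    def step(name: str, part: Partition) -> None:
        nonlocal current
        trace.add(name, part.removed)
        current = part.retained

    if config.require_all_bio_reps:
        part = filter_all_replicates(current, mode=config.cull_threshold_mode)
        if ctrl in part.removed:
            raise ValidationError(
                f"positive control {ctrl!r} removed at all_replicates stage "
                f"({part.removed[ctrl]}); SD anchoring impossible"
            )
        step("all_replicates", part)
    part = filter_technical_consistency(current)
    if ctrl in part.removed:
        raise ValidationError(
            f"positive control {ctrl!r} removed at technical_consistency stage "
            f"({part.removed[ctrl]}); SD anchoring impossible"
        )
    step("technical_consistency", part)
    step("sd_vs_control", filter_sd_vs_control(current, ctrl))
    step(
        "ribosomal",
        filter_ribosomal(current, annotations, config.ribosomal_patterns),
    )
    step(
        "min_technical_enrichment",
        filter_min_technical_enrichment(current, config.min_technical_enrichment),
    )
    if config.use_inspection_flag:
        step("inspection", filter_inspection(current, annotations))
    trace.retained = set(current)
    return current, trace
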
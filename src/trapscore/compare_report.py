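"""Ranked interactome tables, multi-bait comparison and the pipeline driver.

A final interactome is reported as a table ranked by mean F-score
(descending), with per-protein bait/mock PSM means and a Welch t-test
p-value comparing the per-replicate bait sums to the matched mock sums.
Ties in F break by bait PSM mean (descending) then protein id
(ascending), so the ranking is a total order and outputs are
byte-reproducible.  Multiple bait interactomes are compared as exact
Venn regions, and hits can be summarized by annotated functional
category.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import enrichment, filter_cascade, psm_io
from .enrichment import FScoreRecord, TestResult, welch_ttest
from .filter_cascade import FilterConfig, FilterTrace
from .psm_io import ProteinAnnotation, ValidationError

__all__ = [
    "InteractomeRow",
    "InteractomeTable",
    "VennCounts",
    "CategorySummary",
    "rank_table",
    "venn_counts",
    "categorize",
    "run_pipeline",
    "PipelineResult",
]

log = logging.getLogger("trapscore")


@dataclass(frozen=True)
class InteractomeRow:
    protein_id: str
    display_name: str
    kda: float
    uniprot: str
    f_score: float
    bait_psm: float
    mock_psm: float
    p_value: float


@dataclass(frozen=True)
class InteractomeTable:
    bait_label: str
    rows: tuple[InteractomeRow, ...]


def rank_table(
    records: Mapping[str, FScoreRecord],
    tests: Mapping[str, TestResult],
    annotations: Mapping[str, ProteinAnnotation],
    bait_label: str,
) -> InteractomeTable:
    """Build the ranked table for one bait from retained records."""
    missing = sorted(set(records) - set(tests))
    if missing:
        raise ValidationError(
            f"missing test results for retained proteins: {missing}"
        )
    rows = []
    for pid, rec in records.items():
        annot = annotations.get(pid, ProteinAnnotation(protein_id=pid))
        rows.append(
            InteractomeRow(
                protein_id=pid,
                display_name=annot.name,
                kda=annot.kda,
                uniprot=annot.uniprot,
                f_score=rec.mean_F,
                bait_psm=rec.C_mean,
                mock_psm=rec.M_mean,
                p_value=tests[pid].p_value,
            )
        )
    rows.sort(key=lambda r: (-r.f_score, -r.bait_psm, r.protein_id))
    return InteractomeTable(bait_label=bait_label, rows=tuple(rows))


@dataclass(frozen=True)
class VennCounts:
    """Exact region partition of 2 or 3 labelled protein-id sets."""

    labels: tuple[str, ...]
    regions: dict  # frozenset(labels present) -> sorted tuple of members

    def count(self, *labels: str) -> int:
        return len(self.regions.get(frozenset(labels), ()))

    def members(self, *labels: str) -> tuple[str, ...]:
        return self.regions.get(frozenset(labels), ())

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("region\tcount\tmembers\n")
            for r in sorted(self.regions, key=lambda s: (len(s), sorted(s))):
                fh.write(
                    "&".join(sorted(r))
                    + f"\t{len(self.regions[r])}\t"
                    + ",".join(self.regions[r])
                    + "\n"
                )


def venn_counts(sets: Mapping[str, set]) -> VennCounts:
    """Partition 2 or 3 labelled sets into exclusive Venn regions.

    Each element of the union is assigned to exactly one region: the
    frozenset of labels whose sets contain it.  Region counts therefore
    sum to the union size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValidationError("venn_counts takes 2 or 3 labelled sets")
    labels = tuple(sets)
    regions: dict = {}
    for n in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, n):
            regions[frozenset(combo)] = []
    universe = set().union(*sets.values())
    for el in sorted(universe):
        membership = frozenset(l for l in labels if el in sets[l])
        regions[membership].append(el)
    return VennCounts(
        labels=labels, regions={k: tuple(v) for k, v in regions.items()}
    )


@dataclass(frozen=True)
class CategorySummary:
    """Functional-category breakdown of a hit list."""

    counts: dict  # category -> count
    total: int

    def fraction(self, category: str) -> float:
        return self.counts[category] / self.total if self.total else 0.0

    def as_rows(self) -> list[tuple[str, int, float]]:
        """(category, count, fraction), largest category first."""
        return sorted(
            ((c, n, n / self.total) for c, n in self.counts.items()),
            key=lambda t: (-t[1], t[0]),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("category\tcount\tpercent\n")
            for cat, n, frac in self.as_rows():
                fh.write(f"{cat}\t{n}\t{round(100 * frac)}%\n")


def categorize(
    protein_ids: Sequence[str],
    annotations: Mapping[str, ProteinAnnotation],
) -> CategorySummary:
    counts: dict = {}
    for pid in protein_ids:
        annot = annotations.get(pid)
        cat = annot.category if annot else "unknown"
        counts[cat] = counts.get(cat, 0) + 1
    return CategorySummary(counts=counts, total=len(protein_ids))


# ---------------------------------------------------------------------------
# pipeline driver

_CONFIG_KEYS = {
    "counts",
    "design",
    "annotations",
    "baits",
    "out_dir",
    "control_protein_id",
    "normalization",
    "compile_threshold_mode",
    "cull_threshold_mode",
    "min_enriched_bio_reps_compile",
    "require_all_bio_reps",
    "ribosomal_patterns",
    "min_technical_enrichment",
    "use_inspection_flag",
    "seed",
}


@dataclass
class PipelineResult:
    tables: dict  # bait_label -> InteractomeTable
    traces: dict  # bait_label -> FilterTrace
    venn: VennCounts | None
    categories: dict  # bait_label -> CategorySummary
    out_dir: Path


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping")
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("counts", "design", "control_protein_id", "out_dir"):
        if key not in config:
            raise ValidationError(f"config missing required key {key!r}")
    return config


def run_pipeline(config) -> PipelineResult:
    """Run the full analysis from a config mapping or YAML file.

    Per bait: collapse technical runs, optionally normalize, score F per
    replicate, compile the k-of-n enriched list, apply the cascade,
    Welch-test the per-replicate bait vs mock sums of retained proteins,
    and write the ranked interactome.  Across baits: Venn comparison and
    per-bait category summaries.  Deterministic for fixed inputs.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, err: Exception):
        raise ValidationError(f"pipeline stage {stage!r} failed: {err}") from err

    try:
        layout = psm_io.read_design(cfg["design"])
    except Exception as e:
        fail("read_design", e)
    try:
        matrix = psm_io.read_counts(cfg["counts"], layout)
    except Exception as e:
        fail("read_counts", e)
    annotations: dict[str, ProteinAnnotation] = {}
    if cfg.get("annotations"):
        try:
            annotations = psm_io.read_annotations(cfg["annotations"])
        except Exception as e:
            fail("read_annotations", e)

    fconfig = FilterConfig(
        control_protein_id=cfg["control_protein_id"],
        min_enriched_bio_reps_compile=int(
            cfg.get("min_enriched_bio_reps_compile", 2)
        ),
        require_all_bio_reps=bool(cfg.get("require_all_bio_reps", True)),
        ribosomal_patterns=tuple(
            cfg.get("ribosomal_patterns", filter_cascade.DEFAULT_RIBOSOMAL_PATTERNS)
        ),
        min_technical_enrichment=int(cfg.get("min_technical_enrichment", 2)),
        use_inspection_flag=bool(cfg.get("use_inspection_flag", True)),
        compile_threshold_mode=cfg.get("compile_threshold_mode", "strict"),
        cull_threshold_mode=cfg.get("cull_threshold_mode", "inclusive"),
    )
    baits = list(cfg.get("baits") or layout.bait_labels)
    normalization = cfg.get("normalization", "none")

    log_lines = []
    tables: dict = {}
    traces: dict = {}
    categories: dict = {}
    hit_sets: dict = {}
    for bait in baits:
        try:
            records = enrichment.fscore_table(
                matrix,
                layout,
                bait,
                threshold_mode=fconfig.compile_threshold_mode,
                normalization=normalization,
            )
        except Exception as e:
            fail(f"fscore[{bait}]", e)
        log_lines.append(f"{bait}: scored {len(records)} proteins")
        compiled = filter_cascade.filter_enriched_in_k(
            records,
            fconfig.min_enriched_bio_reps_compile,
            mode=fconfig.compile_threshold_mode,
        ).retained
        log_lines.append(
            f"{bait}: compile (>= {fconfig.min_enriched_bio_reps_compile} "
            f"replicates enriched) kept {len(compiled)}"
        )
        try:
            retained, trace = filter_cascade.apply_cascade(
                compiled, annotations, fconfig
            )
        except Exception as e:
            fail(f"cascade[{bait}]", e)
        for stage_name, removed in trace.stages:
            log_lines.append(f"{bait}: {stage_name} removed {len(removed)}")
        tests = {
            pid: welch_ttest(
                [r.C for r in rec.reps], [r.M for r in rec.reps], protein_id=pid
            )
            for pid, rec in retained.items()
        }
        table = rank_table(retained, tests, annotations, bait)
        tables[bait] = table
        traces[bait] = trace
        hit_sets[bait] = set(retained)
        categories[bait] = categorize(sorted(retained), annotations)
        safe = bait.replace("/", "_")
        psm_io.write_interactome_table(table, out_dir / f"interactome_{safe}.tsv")
        trace.to_tsv(out_dir / f"filter_trace_{safe}.tsv")
        categories[bait].to_tsv(out_dir / f"categories_{safe}.tsv")
        log_lines.append(f"{bait}: final table {len(table.rows)} proteins")

    venn = None
    if 2 <= len(hit_sets) <= 3:
        venn = venn_counts(hit_sets)
        venn.to_tsv(out_dir / "venn.tsv")
        log_lines.append(
            "venn: union "
            f"{venn.union_size} across {', '.join(venn.labels)}"
        )
    with open(out_dir / "pipeline.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    for line in log_lines:
        log.info(line)
    return PipelineResult(
        tables=tables,
        traces=traces,
        venn=venn,
        categories=categories,
        out_dir=out_dir,
    )
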
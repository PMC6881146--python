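"""Tabular I/O and the core experiment data model.

An AP-MS spectral-counting experiment is a protein x run matrix of
non-negative integer PSM (peptide spectral match) counts, plus a run
design binding each run to a condition (bait or mock), a bait label, a
biological replicate and a technical replicate.  All tables are
tab-separated UTF-8 with "." as the decimal point; a protein absent from
a run must be encoded as an explicit 0 — missing cells are errors, never
implicit zeros.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ValidationError",
    "RunKey",
    "ExperimentLayout",
    "PSMMatrix",
    "ProteinAnnotation",
    "read_design",
    "read_counts",
    "write_counts",
    "read_annotations",
    "write_interactome_table",
]

CONDITIONS = ("bait", "mock")


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


@dataclass(frozen=True, order=True)
class RunKey:
    """Identity of one LC-MS/MS run within the replicated design."""

    run_id: str
    condition: str  # "bait" or "mock"
    bait_label: str  # the bait this run belongs to (mocks are matched)
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"run {self.run_id!r}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValidationError(
                f"run {self.run_id!r}: bio_rep and tech_rep must be >= 1"
            )

    @property
    def cell(self) -> tuple[str, str, int, int]:
        return (self.condition, self.bait_label, self.bio_rep, self.tech_rep)


@dataclass(frozen=True)
class ExperimentLayout:
    """A complete factorial bait/mock design.

    For every bait label, every (bio_rep, tech_rep) cell must contain
    exactly one bait run and one matched mock run; the default design is
    3 biological x 2 technical replicates (12 runs per bait).
    """

    runs: tuple[RunKey, ...]
    n_bio: int = 3
    n_tech: int = 2

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int, int]] = set()
        ids: set[str] = set()
        for run in self.runs:
            if run.run_id in ids:
                raise ValidationError(f"duplicate run id {run.run_id!r}")
            ids.add(run.run_id)
            if run.cell in seen:
                raise ValidationError(
                    f"duplicate run for cell {run.cell} (run {run.run_id!r})"
                )
            seen.add(run.cell)
        missing = [
            (cond, bait, b, t)
            for bait in self.bait_labels
            for cond in CONDITIONS
            for b in range(1, self.n_bio + 1)
            for t in range(1, self.n_tech + 1)
            if (cond, bait, b, t) not in seen
        ]
        if missing:
            cells = ", ".join(
                f"{cond}/{bait}/bio{b}/tech{t}" for cond, bait, b, t in missing
            )
            raise ValidationError(f"incomplete design; missing cells: {cells}")
        extra = len(self.runs) - 2 * len(self.bait_labels) * self.n_bio * self.n_tech
        if extra:
            raise ValidationError("incomplete design: extra runs beyond the factorial")

    @property
    def bait_labels(self) -> tuple[str, ...]:
        return tuple(sorted({r.bait_label for r in self.runs}))

    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(r.run_id for r in sorted(self.runs))

    def run(self, condition: str, bait_label: str, bio_rep: int, tech_rep: int) -> RunKey:
        for r in self.runs:
            if r.cell == (condition, bait_label, bio_rep, tech_rep):
                return r
        raise KeyError((condition, bait_label, bio_rep, tech_rep))

    def runs_for(
        self, bait_label: str, condition: str | None = None, bio_rep: int | None = None
    ) -> list[RunKey]:
        out = [r for r in self.runs if r.bait_label == bait_label]
        if condition is not None:
            out = [r for r in out if r.condition == condition]
        if bio_rep is not None:
            out = [r for r in out if r.bio_rep == bio_rep]
        return sorted(out, key=lambda r: (r.bio_rep, r.tech_rep, r.condition))


@dataclass(frozen=True)
class PSMMatrix:
    """Protein x run table of non-negative integer spectral counts.

    ``counts`` is a DataFrame indexed by protein id with one column per
    run id, column order normalized to the layout's sorted run order.
    """

    counts: pd.DataFrame
    layout: ExperimentLayout

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate protein id {dup!r}")
        want = set(self.layout.run_ids)
        have = set(df.columns)
        if want - have:
            raise ValidationError(
                "run not found in counts table: " + ", ".join(sorted(want - have))
            )
        if have - want:
            raise ValidationError(
                "counts column not in design: " + ", ".join(sorted(have - want))
            )
        values = df.to_numpy(dtype=float)
        if (values < 0).any():
            r, c = [int(i[0]) for i in (values < 0).nonzero()]
            raise ValidationError(
                f"negative count at protein {df.index[r]!r}, run "
                f"{df.columns[c]!r}: {values[r, c]:g}"
            )
        if (values != values.round()).any():
            r, c = [int(i[0]) for i in (values != values.round()).nonzero()]
            raise ValidationError(
                f"non-integer count at protein {df.index[r]!r}, run "
                f"{df.columns[c]!r}: {values[r, c]:g}"
            )
        ordered = df[list(self.layout.run_ids)].astype(int)
        object.__setattr__(self, "counts", ordered)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    def run_totals(self) -> pd.Series:
        """Total PSMs per run (the per-run library size)."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ProteinAnnotation:
    """Static per-protein metadata used for reporting and filtering."""

    protein_id: str
    display_name: str = ""
    uniprot: str = ""
    kda: float = float("nan")
    category: str = "unknown"
    is_ribosomal: bool = False
    spectra_inspection_pass: bool = True

    @property
    def name(self) -> str:
        return self.display_name or self.protein_id


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_design(path) -> ExperimentLayout:
    """Read a run-design TSV (run_id, condition, bait_label, bio_rep, tech_rep)."""
    df = _read_tsv(path)
    required = ["run_id", "condition", "bait_label", "bio_rep", "tech_rep"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"design table missing columns: {missing}")
    runs = []
    for _, row in df.iterrows():
        try:
            bio = int(row["bio_rep"])
            tech = int(row["tech_rep"])
        except ValueError as e:
            raise ValidationError(
                f"run {row['run_id']!r}: non-integer replicate index"
            ) from e
        runs.append(
            RunKey(
                run_id=row["run_id"],
                condition=row["condition"],
                bait_label=row["bait_label"],
                bio_rep=bio,
                tech_rep=tech,
            )
        )
    if not runs:
        raise ValidationError("empty design table")
    n_bio = max(r.bio_rep for r in runs)
    n_tech = max(r.tech_rep for r in runs)
    return ExperimentLayout(runs=tuple(runs), n_bio=n_bio, n_tech=n_tech)


def read_counts(path, layout: ExperimentLayout) -> PSMMatrix:
    """Read a counts TSV (first column protein id, one column per run)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError("counts table needs a protein id column and run columns")
    pid_col = df.columns[0]
    df = df.set_index(pid_col)
    for col in df.columns:
        for pid, v in df[col].items():
            try:
                fv = float(v)
            except ValueError as e:
                raise ValidationError(
                    f"non-numeric count at protein {pid!r}, run {col!r}: {v!r}"
                ) from e
            df.loc[pid, col] = fv
    return PSMMatrix(counts=df.astype(float), layout=layout)


def write_counts(matrix: PSMMatrix, path) -> None:
    out = matrix.counts.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def write_design(layout: ExperimentLayout, path) -> None:
    rows = [
        {
            "run_id": r.run_id,
            "condition": r.condition,
            "bait_label": r.bait_label,
            "bio_rep": r.bio_rep,
            "tech_rep": r.tech_rep,
        }
        for r in sorted(layout.runs)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_ANNOT_COLS = (
    "protein_id",
    "display_name",
    "uniprot",
    "kda",
    "category",
    "is_ribosomal",
    "spectra_inspection_pass",
)

_TRUTHY = {"1", "true", "yes"}


def read_annotations(path) -> dict[str, ProteinAnnotation]:
    """Read an annotation TSV into a protein_id -> ProteinAnnotation map."""
    df = _read_tsv(path)
    if "protein_id" not in df.columns:
        raise ValidationError("annotation table missing protein_id column")
    out: dict[str, ProteinAnnotation] = {}
    for _, row in df.iterrows():
        pid = row["protein_id"]
        if pid in out:
            raise ValidationError(f"duplicate protein id {pid!r} in annotations")
        kda = row.get("kda", "")
        out[pid] = ProteinAnnotation(
            protein_id=pid,
            display_name=row.get("display_name", "") or pid,
            uniprot=row.get("uniprot", ""),
            kda=float(kda) if kda not in ("", None) else float("nan"),
            category=row.get("category", "") or "unknown",
            is_ribosomal=str(row.get("is_ribosomal", "")).lower() in _TRUTHY,
            spectra_inspection_pass=(
                str(row.get("spectra_inspection_pass", "true")).lower() in _TRUTHY
            ),
        )
    return out


def write_annotations(annotations: Mapping[str, ProteinAnnotation], path) -> None:
    rows = [
        {
            "protein_id": a.protein_id,
            "display_name": a.display_name,
            "uniprot": a.uniprot,
            "kda": "" if a.kda != a.kda else f"{a.kda:g}",
            "category": a.category,
            "is_ribosomal": str(a.is_ribosomal).lower(),
            "spectra_inspection_pass": str(a.spectra_inspection_pass).lower(),
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows, columns=list(_ANNOT_COLS)).to_csv(path, sep="\t", index=False)


def _fmt(value: float, nd: int) -> str:
    return f"{float(value):.{nd}f}"


def write_interactome_table(table, path) -> None:
    """Write a ranked interactome table as TSV.

    Display rounding: F-score to 2 decimals, PSM means to 1, p-values to
    3; full precision lives in the in-memory rows.  Output is bit-stable
    for identical input.
    """
    header = "Protein\tkDa\tUniProt\tF-Score\tbait PSM mean\tmock PSM mean\tp-value"
    lines = [header]
    for row in table.rows:
        kda = "" if row.kda != row.kda else f"{row.kda:g}"
        lines.append(
            "\t".join(
                [
                    row.display_name,
                    kda,
                    row.uniprot,
                    _fmt(row.f_score, 2),
                    _fmt(row.bait_psm, 1),
                    _fmt(row.mock_psm, 1),
                    _fmt(row.p_value, 3),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
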
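"""Per-replicate enrichment (F) scores and the unequal-variance t-test.

The enrichment statistic for a protein in one biological replicate is

    F = (C - M) / C

where C is the protein's bait-column PSM count and M the matched mock
count, each summed over that replicate's technical runs.  F = 1 means
bait-exclusive detection (M = 0 with C > 0), F = 0 means no enrichment,
and F < 0 means the protein was more abundant in the mock.  Two corner
cases have no finite F and are carried as sentinels: ABSENT (C = M = 0,
the protein was never seen) and DEPLETED (C = 0 < M, mock-only).
Sentinels never count as enriched and sort below every finite F.

F is computed per biological replicate on technical-replicate sums and
then averaged; it is *not* the F of the averaged counts, and the two
differ whenever replicates differ (see the mean-vs-pooled property in
the test suite).
"""

from __future__ import annotations

import enum
import math
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .psm_io import ExperimentLayout, PSMMatrix, ValidationError

__all__ = [
    "FSentinel",
    "ReplicateCounts",
    "FScoreRecord",
    "TestResult",
    "collapse_technical",
    "normalize_counts",
    "fscore_replicate",
    "fscore_protein",
    "fscore_table",
    "welch_ttest",
    "f_sort_key",
]


class FSentinel(enum.Enum):
    """Non-finite F outcomes: protein unseen, or mock-only."""

    ABSENT = "absent"
    DEPLETED = "depleted"


FValue = "float | FSentinel"


def f_sort_key(f) -> float:
    """Total-order key: ABSENT < DEPLETED < any finite F."""
    if f is FSentinel.ABSENT:
        return -math.inf
    if f is FSentinel.DEPLETED:
        return -1e300  # below any realistic finite F, above ABSENT
    return float(f)


@dataclass(frozen=True)
class ReplicateCounts:
    """One protein's counts in one biological replicate.

    ``C``/``M`` are bait/mock PSMs summed over the technical runs (after
    any normalization); the per-technical-run vectors and per-run totals
    are kept so the technical-consistency filter and total-spectra
    normalization can operate downstream.
    """

    protein_id: str
    bio_rep: int
    C: float
    M: float
    tech_C: tuple[float, ...]
    tech_M: tuple[float, ...]
    tech_C_totals: tuple[float, ...] = ()
    tech_M_totals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if min(self.C, self.M, *self.tech_C, *self.tech_M) < 0:
            raise ValidationError(f"negative count for protein {self.protein_id!r}")


@dataclass(frozen=True)
class FScoreRecord:
    """Per-protein F summary across biological replicates."""

    protein_id: str
    per_rep_F: tuple  # (bio_rep, float | FSentinel) pairs
    mean_F: float  # nan when no replicate has a defined F
    sd_F: float  # nan when fewer than 2 defined F values
    C_mean: float
    M_mean: float
    enriched_reps: int
    reps: tuple[ReplicateCounts, ...] = ()

    @property
    def sd_defined(self) -> bool:
        return self.sd_F == self.sd_F

    def f_in_rep(self, bio_rep: int):
        for b, f in self.per_rep_F:
            if b == bio_rep:
                return f
        raise KeyError(bio_rep)


@dataclass(frozen=True)
class TestResult:
    protein_id: str
    t_stat: float
    df: float
    p_value: float


def collapse_technical(
    matrix: PSMMatrix, layout: ExperimentLayout, bait: str
) -> list[ReplicateCounts]:
    """Sum technical runs into per-biological-replicate bait/mock counts.

    Returns one record per protein per biological replicate, ordered by
    protein (matrix order) then bio_rep.  Technical vectors are ordered
    by tech_rep, and paired bait/mock entries share (bio_rep, tech_rep).
    """
    if bait not in layout.bait_labels:
        raise ValidationError(f"bait label {bait!r} not in layout")
    totals = matrix.run_totals()
    records: list[ReplicateCounts] = []
    # resolve run ids once per (bio, tech) cell
    cells = []
    for b in range(1, layout.n_bio + 1):
        bait_ids = [
            layout.run("bait", bait, b, t).run_id for t in range(1, layout.n_tech + 1)
        ]
        mock_ids = [
            layout.run("mock", bait, b, t).run_id for t in range(1, layout.n_tech + 1)
        ]
        cells.append((b, bait_ids, mock_ids))
    col_idx = {c: i for i, c in enumerate(matrix.counts.columns)}
    values = matrix.counts.to_numpy(dtype=float)
    cell_idx = [
        (
            b,
            [col_idx[r] for r in bait_ids],
            [col_idx[r] for r in mock_ids],
            tuple(float(totals.iloc[col_idx[r]]) for r in bait_ids),
            tuple(float(totals.iloc[col_idx[r]]) for r in mock_ids),
        )
        for b, bait_ids, mock_ids in cells
    ]
    for i, pid in enumerate(matrix.protein_ids):
        row = values[i]
        for b, bait_cols, mock_cols, c_tot, m_tot in cell_idx:
            tech_C = tuple(row[j] for j in bait_cols)
            tech_M = tuple(row[j] for j in mock_cols)
            records.append(
                ReplicateCounts(
                    protein_id=pid,
                    bio_rep=b,
                    C=float(sum(tech_C)),
                    M=float(sum(tech_M)),
                    tech_C=tech_C,
                    tech_M=tech_M,
                    tech_C_totals=c_tot,
                    tech_M_totals=m_tot,
                )
            )
    return records


def normalize_counts(
    records: Sequence[ReplicateCounts], mode: str = "none"
) -> list[ReplicateCounts]:
    """Optionally rescale counts to per-10,000-PSM units per run.

    ``none`` is the identity.  ``total_spectra`` divides each technical
    run's counts by that run's total PSMs and multiplies by 10,000
    before re-summation, correcting for unequal sampling depth.
    """
    if mode == "none":
        return list(records)
    if mode != "total_spectra":
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = []
    for rec in records:
        if not rec.tech_C_totals or not rec.tech_M_totals:
            raise ValidationError(
                f"protein {rec.protein_id!r}: run totals required for "
                "total_spectra normalization"
            )
        if min(*rec.tech_C_totals, *rec.tech_M_totals) <= 0:
            raise ValidationError(
                f"protein {rec.protein_id!r} bio_rep {rec.bio_rep}: "
                "run with zero total PSMs cannot be normalized"
            )
        tech_C = tuple(
            1e4 * c / tot for c, tot in zip(rec.tech_C, rec.tech_C_totals)
        )
        tech_M = tuple(
            1e4 * m / tot for m, tot in zip(rec.tech_M, rec.tech_M_totals)
        )
        out.append(
            ReplicateCounts(
                protein_id=rec.protein_id,
                bio_rep=rec.bio_rep,
                C=sum(tech_C),
                M=sum(tech_M),
                tech_C=tech_C,
                tech_M=tech_M,
                tech_C_totals=rec.tech_C_totals,
                tech_M_totals=rec.tech_M_totals,
            )
        )
    return out


def fscore_replicate(C: float, M: float):
    """F = (C - M) / C, or a sentinel when C = 0."""
    if C < 0 or M < 0:
        raise ValidationError("counts must be non-negative")
    if C == 0:
        return FSentinel.ABSENT if M == 0 else FSentinel.DEPLETED
    return (C - M) / C


def _is_enriched(f, mode: str) -> bool:
    if isinstance(f, FSentinel):
        return False
    if mode == "strict":
        return f > 0
    if mode == "inclusive":
        return f >= 0
    raise ValueError(f"unknown threshold mode {mode!r}")


def fscore_protein(
    records: Sequence[ReplicateCounts], threshold_mode: str = "strict"
) -> FScoreRecord:
    """Summarize one protein's replicates into an FScoreRecord.

    mean_F and sd_F are taken over defined (finite) per-replicate F
    values only; sd_F is NaN (undefined) with fewer than two of them.
    C_mean/M_mean are plain means of the per-replicate sums.
    ``enriched_reps`` counts replicates with F > 0 (strict mode) or
    F >= 0 (inclusive); sentinels never count.
    """
    if not records:
        raise ValidationError("empty record list")
    pids = {r.protein_id for r in records}
    if len(pids) > 1:
        raise ValidationError(f"records mix proteins: {sorted(pids)}")
    recs = tuple(sorted(records, key=lambda r: r.bio_rep))
    per_rep = tuple((r.bio_rep, fscore_replicate(r.C, r.M)) for r in recs)
    defined = [f for _, f in per_rep if not isinstance(f, FSentinel)]
    mean_F = float(statistics.fmean(defined)) if defined else math.nan
    sd_F = float(statistics.stdev(defined)) if len(defined) >= 2 else math.nan
    return FScoreRecord(
        protein_id=recs[0].protein_id,
        per_rep_F=per_rep,
        mean_F=mean_F,
        sd_F=sd_F,
        C_mean=float(statistics.fmean(r.C for r in recs)),
        M_mean=float(statistics.fmean(r.M for r in recs)),
        enriched_reps=sum(_is_enriched(f, threshold_mode) for _, f in per_rep),
        reps=recs,
    )


def fscore_table(
    matrix: PSMMatrix,
    layout: ExperimentLayout,
    bait: str,
    threshold_mode: str = "strict",
    normalization: str = "none",
) -> dict[str, FScoreRecord]:
    """Convenience: collapse, normalize and score every protein for one bait."""
    records = normalize_counts(
        collapse_technical(matrix, layout, bait), mode=normalization
    )
    by_protein: dict[str, list[ReplicateCounts]] = {}
    for rec in records:
        by_protein.setdefault(rec.protein_id, []).append(rec)
    return {
        pid: fscore_protein(recs, threshold_mode=threshold_mode)
        for pid, recs in by_protein.items()
    }


def welch_ttest(
    xs: Sequence[float], ys: Sequence[float], protein_id: str = ""
) -> TestResult:
    """Two-sample two-sided t-test assuming unequal variances.

    Welch statistic with Welch-Satterthwaite degrees of freedom.  When
    both sample variances are exactly zero the statistic is undefined;
    the degenerate policy reports p = 0 for different means (the
    difference is seen without noise) and p = 1 for equal means.
    """
    if len(xs) < 2 or len(ys) < 2:
        raise ValidationError("welch_ttest needs at least 2 values per sample")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        equal = x.mean() == y.mean()
        return TestResult(
            protein_id=protein_id,
            t_stat=0.0 if equal else math.copysign(math.inf, x.mean() - y.mean()),
            df=float(len(x) + len(y) - 2),
            p_value=1.0 if equal else 0.0,
        )
    with warnings.catch_warnings():
        # one sample may legitimately have zero variance (e.g. an all-zero
        # mock); scipy warns about the cancellation but the Welch statistic
        # is still well defined there
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        protein_id=protein_id,
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )
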
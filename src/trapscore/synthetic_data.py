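"""Seeded synthetic PSM experiments with known ground truth.

The generator emulates the replicated substrate-trap pulldown design:
one bait column and one matched mock column, 3 biological x 2 technical
replicates by default.  Three protein populations are planted:

* background binders — present at the same mean abundance in bait and
  mock runs (they stick to the resin, not the bait).  Their detection
  in bait-column runs is thinned by a per-run Bernoulli (low-abundance
  proteins are sampled stochastically by the instrument), which is what
  creates the sporadic bait-only observations the filter cascade must
  reject.
* true interactors — bait-column mean equal to ``enrichment_fold``
  times the background mean, absent from the mock (pure binding).
* one spiked positive control (the ubiquitin role) — present in both
  columns (bait mean ``control_mean``, mock mean half that) with a
  controlled, low coefficient of variation, so it anchors the SD filter
  and exercises the 0 < F < 1 regime.

Counts are gamma-mixed Poisson (negative binomial) with a single
dispersion parameter; dispersion 0 degenerates to plain Poisson so
analytic mean/variance checks stay exact.  Everything is reproducible
bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .psm_io import (
    ExperimentLayout,
    ProteinAnnotation,
    PSMMatrix,
    RunKey,
    ValidationError,
    write_annotations,
    write_counts,
    write_design,
)

__all__ = [
    "SimParams",
    "TruthEntry",
    "SyntheticTruth",
    "SimulatedExperiment",
    "make_layout",
    "simulate_experiment",
    "planted_violation_fixture",
    "write_experiment",
]

CONTROL_ID = "Ubiquitin"
DEFAULT_BAIT = "trap"


@dataclass(frozen=True)
class SimParams:
    """Generator knobs; defaults are the stringent-screen study conditions
    (2000-protein background at mean 3 PSM/run, 20 interactors at 15-fold,
    mild overdispersion, 30% bait-column detection of background)."""

    n_proteins: int = 2000
    n_true: int = 20
    n_bio: int = 3
    n_tech: int = 2
    background_mean: float = 3.0
    enrichment_fold: float = 15.0
    dispersion: float = 0.2
    detect_prob: float = 0.3
    control_mean: float = 60.0
    control_cv: float = 0.1
    ribosomal_frac: float = 0.05
    bait_label: str = DEFAULT_BAIT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0 or self.n_true < 0:
            raise ValidationError("protein counts must be non-negative")
        if self.n_proteins and self.n_true > self.n_proteins - 1:
            raise ValidationError(
                "n_true must leave room for the control within n_proteins"
            )
        if min(self.background_mean, self.enrichment_fold, self.control_mean) < 0:
            raise ValidationError("means and fold must be non-negative")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.detect_prob <= 1:
            raise ValidationError("detect_prob must be in [0, 1]")
        if not 0 <= self.ribosomal_frac <= 1:
            raise ValidationError("ribosomal_frac must be in [0, 1]")


@dataclass(frozen=True)
class TruthEntry:
    is_true_interactor: bool
    fold: float
    is_control: bool
    is_ribosomal: bool


@dataclass(frozen=True)
class SyntheticTruth:
    entries: dict  # protein_id -> TruthEntry

    @property
    def true_ids(self) -> tuple[str, ...]:
        return tuple(p for p, e in self.entries.items() if e.is_true_interactor)

    @property
    def background_ids(self) -> tuple[str, ...]:
        return tuple(
            p
            for p, e in self.entries.items()
            if not e.is_true_interactor and not e.is_control
        )

    @property
    def control_id(self) -> str | None:
        for p, e in self.entries.items():
            if e.is_control:
                return p
        return None


@dataclass(frozen=True)
class SimulatedExperiment:
    matrix: PSMMatrix
    layout: ExperimentLayout
    annotations: dict  # protein_id -> ProteinAnnotation
    truth: SyntheticTruth
    params: SimParams | None = None


def make_layout(
    n_bio: int = 3, n_tech: int = 2, bait_label: str = DEFAULT_BAIT
) -> ExperimentLayout:
    """Complete factorial bait/mock layout with systematic run ids."""
    runs = [
        RunKey(
            run_id=f"{cond}_b{b}_t{t}",
            condition=cond,
            bait_label=bait_label,
            bio_rep=b,
            tech_rep=t,
        )
        for cond in ("bait", "mock")
        for b in range(1, n_bio + 1)
        for t in range(1, n_tech + 1)
    ]
    return ExperimentLayout(runs=tuple(runs), n_bio=n_bio, n_tech=n_tech)


def _nb_counts(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Gamma-mixed Poisson draw; dispersion 0 is plain Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    rates = np.where(
        mean > 0, rng.gamma(shape, np.maximum(mean, 1e-300) * dispersion), 0.0
    )
    return rng.poisson(rates)


def simulate_experiment(params: SimParams) -> SimulatedExperiment:
    """Draw one full experiment (counts, layout, annotations, truth)."""
    rng = np.random.default_rng(params.seed)
    layout = make_layout(params.n_bio, params.n_tech, params.bait_label)
    run_ids = list(layout.run_ids)
    bait_cols = {
        layout.run("bait", params.bait_label, b, t).run_id
        for b in range(1, params.n_bio + 1)
        for t in range(1, params.n_tech + 1)
    }
    is_bait_col = np.array([r in bait_cols for r in run_ids])

    if params.n_proteins == 0:
        empty = pd.DataFrame(
            np.zeros((0, len(run_ids)), dtype=int), index=[], columns=run_ids
        )
        return SimulatedExperiment(
            matrix=PSMMatrix(counts=empty, layout=layout),
            layout=layout,
            annotations={},
            truth=SyntheticTruth(entries={}),
            params=params,
        )

    n_bg = params.n_proteins - params.n_true - 1
    n_ribo = int(round(params.ribosomal_frac * n_bg))
    pids: list[str] = [CONTROL_ID]
    entries: dict[str, TruthEntry] = {
        CONTROL_ID: TruthEntry(False, 1.0, True, False)
    }
    for i in range(params.n_true):
        pid = f"prey{i + 1:03d}"
        pids.append(pid)
        entries[pid] = TruthEntry(True, params.enrichment_fold, False, False)
    for i in range(n_bg):
        ribo = i < n_ribo
        pid = (f"RpL{i + 1}" if ribo else f"bg{i + 1:04d}")
        pids.append(pid)
        entries[pid] = TruthEntry(False, 1.0, False, ribo)

    n_runs = len(run_ids)
    mean = np.zeros((params.n_proteins, n_runs))
    # control row
    mean[0, :] = np.where(is_bait_col, params.control_mean, params.control_mean / 2)
    # true interactors: bait-only
    t0, t1 = 1, 1 + params.n_true
    mean[t0:t1, is_bait_col] = params.enrichment_fold * params.background_mean
    # background: both columns
    mean[t1:, :] = params.background_mean

    counts = np.zeros_like(mean, dtype=int)
    # control: its own CV, independent of the global dispersion
    cv = params.control_cv
    ctrl_disp = cv * cv
    counts[0, :] = _nb_counts(rng, mean[0, :], ctrl_disp)
    counts[1:, :] = _nb_counts(rng, mean[1:, :], params.dispersion)
    # bait-column detection thinning for background proteins
    if params.detect_prob < 1 and t1 < params.n_proteins:
        detected = rng.random((params.n_proteins - t1, int(is_bait_col.sum())))
        detected = detected < params.detect_prob
        sub = counts[t1:, :][:, is_bait_col]
        counts[np.ix_(np.arange(t1, params.n_proteins), np.flatnonzero(is_bait_col))] = (
            sub * detected
        )

    df = pd.DataFrame(counts, index=pids, columns=run_ids)
    matrix = PSMMatrix(counts=df, layout=layout)
    annotations = {
        pid: ProteinAnnotation(
            protein_id=pid,
            display_name=pid,
            uniprot=f"SYN_{pid.upper()}",
            kda=float("nan"),
            category=(
                "positive control"
                if entries[pid].is_control
                else "planted interactor"
                if entries[pid].is_true_interactor
                else "ribosome structure/biogenesis/translation"
                if entries[pid].is_ribosomal
                else "background"
            ),
            is_ribosomal=entries[pid].is_ribosomal,
        )
        for pid in pids
    }
    return SimulatedExperiment(
        matrix=matrix,
        layout=layout,
        annotations=annotations,
        truth=SyntheticTruth(entries=entries),
        params=params,
    )


# ---------------------------------------------------------------------------
# planted single-violation fixtures

_STAGES = (
    "all_replicates",
    "technical_consistency",
    "sd_vs_control",
    "ribosomal",
    "min_technical_enrichment",
    "inspection",
)


def _tech(*pairs):
    """Flatten ((bait_t1, bait_t2), (mock_t1, mock_t2)) per rep into rows."""
    return pairs


def planted_violation_fixture(stage: str) -> tuple[SimulatedExperiment, str]:
    """A <=10-protein experiment where exactly one protein violates the
    named cascade stage's rule (and no other stage's).

    Returns the experiment and the violator's protein id.  The fixture
    always contains the positive control (passing everything, with a
    small nonzero F-score SD) and one clean bait-exclusive hit.
    """
    if stage not in _STAGES:
        raise ValidationError(f"unknown cascade stage {stage!r}")
    layout = make_layout(3, 2)

    # per protein: {bio_rep: (tech_C pair, tech_M pair)}
    # control F per rep: 0.6, 0.5, 0.55 — SD 0.05, every stage passed
    proteins: dict[str, dict[int, tuple]] = {
        CONTROL_ID: {
            1: ((5, 5), (2, 2)),
            2: ((5, 5), (2, 3)),
            3: ((10, 10), (4, 5)),
        },
        "good_hit": {
            1: ((5, 5), (0, 0)),
            2: ((5, 5), (0, 0)),
            3: ((5, 5), (0, 0)),
        },
    }
    inspection_fail = False
    if stage == "all_replicates":
        violator = "neg_rep"
        # F = -0.05 in every replicate (SD 0, bait > mock in 3 technical
        # runs): fails the F >= 0 cull and nothing else
        proteins[violator] = {
            1: ((10, 10), (9, 12)),
            2: ((10, 10), (9, 12)),
            3: ((10, 10), (9, 12)),
        }
    elif stage == "technical_consistency":
        violator = "tech_dropout"
        # (3, 0) in rep 1: multiple PSMs in one technical run, zero in pair
        proteins[violator] = {
            1: ((3, 0), (0, 0)),
            2: ((2, 2), (0, 0)),
            3: ((2, 1), (0, 0)),
        }
    elif stage == "sd_vs_control":
        violator = "noisy_f"
        # F = (1, 0.2, 0.9): SD 0.44 >> control's 0.05, but enriched in
        # all replicates and technically consistent
        proteins[violator] = {
            1: ((5, 5), (0, 0)),
            2: ((5, 5), (4, 4)),
            3: ((5, 5), (1, 0)),
        }
    elif stage == "ribosomal":
        violator = "RpL7"
        proteins[violator] = {
            1: ((4, 4), (0, 0)),
            2: ((4, 4), (0, 0)),
            3: ((4, 4), (0, 0)),
        }
    elif stage == "min_technical_enrichment":
        violator = "never_above_mock"
        # F = 0 in every replicate, bait > mock in zero technical runs
        proteins[violator] = {
            1: ((1, 1), (1, 1)),
            2: ((1, 1), (1, 1)),
            3: ((1, 1), (1, 1)),
        }
    else:  # inspection
        violator = "bad_spectra"
        proteins[violator] = {
            1: ((4, 4), (0, 0)),
            2: ((4, 4), (0, 0)),
            3: ((4, 4), (0, 0)),
        }
        inspection_fail = True

    rows = {}
    for pid, reps in proteins.items():
        row = {}
        for b, (tc, tm) in reps.items():
            for t in (1, 2):
                row[f"bait_b{b}_t{t}"] = tc[t - 1]
                row[f"mock_b{b}_t{t}"] = tm[t - 1]
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(layout.run_ids)]
    matrix = PSMMatrix(counts=df, layout=layout)
    annotations = {
        pid: ProteinAnnotation(
            protein_id=pid,
            display_name=pid,
            is_ribosomal=(stage == "ribosomal" and pid == violator),
            spectra_inspection_pass=not (inspection_fail and pid == violator),
        )
        for pid in proteins
    }
    truth = SyntheticTruth(
        entries={
            pid: TruthEntry(
                is_true_interactor=(pid == "good_hit"),
                fold=1.0,
                is_control=(pid == CONTROL_ID),
                is_ribosomal=(stage == "ribosomal" and pid == violator),
            )
            for pid in proteins
        }
    )
    return (
        SimulatedExperiment(
            matrix=matrix, layout=layout, annotations=annotations, truth=truth
        ),
        violator,
    )


def write_experiment(experiment: SimulatedExperiment, out_dir) -> dict:
    """Write counts/design/annotations/truth TSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
    }
    write_counts(experiment.matrix, paths["counts"])
    write_design(experiment.layout, paths["design"])
    write_annotations(experiment.annotations, paths["annotations"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("protein_id\tis_true_interactor\tfold\tis_control\tis_ribosomal\n")
        for pid, e in experiment.truth.entries.items():
            fh.write(
                f"{pid}\t{str(e.is_true_interactor).lower()}\t{e.fold:g}\t"
                f"{str(e.is_control).lower()}\t{str(e.is_ribosomal).lower()}\n"
            )
    return paths
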
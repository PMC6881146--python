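import pandas as pd
import pytest

from trapscore.enrichment import ReplicateCounts, fscore_protein
from trapscore.psm_io import PSMMatrix
from trapscore.synthetic_data import make_layout


@pytest.fixture
def layout():
    """3 biological x 2 technical bait/mock design for one bait ('trap')."""
    return make_layout(3, 2)


def matrix_from_tech(layout, proteins):
    """Build a PSMMatrix from {pid: {bio_rep: ((bait_t1, bait_t2), (mock_t1, mock_t2))}}."""
    rows = {}
    for pid, reps in proteins.items():
        row = {}
        for b, (tc, tm) in reps.items():
            for t in (1, 2):
                row[f"bait_b{b}_t{t}"] = tc[t - 1]
                row[f"mock_b{b}_t{t}"] = tm[t - 1]
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(layout.run_ids)]
    return PSMMatrix(counts=df, layout=layout)


def record_from_tech(pid, reps, threshold_mode="strict"):
    """FScoreRecord from {bio_rep: (tech_C tuple, tech_M tuple)}."""
    recs = [
        ReplicateCounts(
            protein_id=pid,
            bio_rep=b,
            C=float(sum(tc)),
            M=float(sum(tm)),
            tech_C=tuple(float(c) for c in tc),
            tech_M=tuple(float(m) for m in tm),
        )
        for b, (tc, tm) in reps.items()
    ]
    return fscore_protein(recs, threshold_mode=threshold_mode)


def record_from_cm(pid, cms, threshold_mode="strict"):
    """FScoreRecord from a list of per-replicate (C, M) sums (one tech run)."""
    return record_from_tech(
        pid,
        {b: ((c,), (m,)) for b, (c, m) in enumerate(cms, start=1)},
        threshold_mode=threshold_mode,
    )
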
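"""Reference detection counts from the original 18-capture field campaign.

The raw imagery of that campaign is available only on request, but its
published per-capture detection counts (ground-truth contours P, predicted
positives PP, true positives TP, false negatives FN, false positives FP, and
the capture-to-fold assignment of the 5-fold protocol) are packaged as a
plain CSV so metric aggregation can be recomputed from counts at any time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from olivegrove.evaluation import DetectionOutcome, aggregate


def load_crossval_counts() -> pd.DataFrame:
    """Per-capture detection counts of the reference 5-fold cross-validation."""
    with resources.files("olivegrove.data").joinpath("crossval_counts.csv").open() as fh:
        return pd.read_csv(fh)


def counts_to_outcomes(df: pd.DataFrame) -> list[DetectionOutcome]:
    return [
        DetectionOutcome(P=int(r.P), PP=int(r.PP), TP=int(r.TP), FN=int(r.FN), FP=int(r.FP))
        for r in df.itertuples()
    ]


def reference_aggregate() -> DetectionOutcome:
    """Micro-aggregate outcome over the 18 reference captures."""
    return aggregate(counts_to_outcomes(load_crossval_counts()))
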
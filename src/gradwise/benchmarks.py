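"""Published cross-validated accuracy grids for the two glioma cohorts.

These are the reported mean-accuracy sweep tables (5-fold CV, minimum
weight k from 15 down to 1, five classifiers) for the rank-weighted hybrid
selector on the TCGA and CGGA glioma-grading cohorts.  They serve as
printed worked examples for the best-configuration selection rule: the
rule's winner on these grids can be checked without access to the
underlying patient tables.  Feature names per row are not part of the
published grids, so ``features`` is None in every row.
"""

from __future__ import annotations

from .evaluation import MODEL_ORDER, SweepRow, SweepTable

# (k, number of features, SVM, LR, KNN, RF, AdaBoost) — accuracy in percent
_TCGA_ROWS = (
    (15, 4, 85.340, 86.054, 84.626, 80.100, 84.264),
    (14, 4, 85.340, 86.054, 84.626, 80.100, 84.264),
    (13, 4, 85.340, 86.054, 84.626, 80.100, 84.264),
    (12, 5, 85.102, 85.816, 84.983, 80.814, 84.502),
    (11, 6, 85.698, 85.816, 84.627, 81.172, 84.859),
    (10, 13, 87.007, 86.890, 84.983, 82.481, 84.862),
    (9, 13, 87.007, 86.890, 84.983, 82.481, 84.862),
    (8, 18, 87.007, 86.533, 82.599, 82.481, 85.577),
    (7, 18, 87.007, 86.533, 82.599, 82.481, 85.577),
    (6, 20, 86.768, 86.533, 82.479, 82.484, 85.458),
    (5, 20, 86.768, 86.533, 82.479, 82.484, 85.458),
    (4, 22, 86.768, 86.414, 82.718, 82.603, 85.339),
    (3, 22, 86.768, 86.414, 82.718, 82.603, 85.339),
    (2, 23, 86.769, 86.414, 82.837, 82.244, 85.339),
    (1, 23, 86.769, 86.414, 82.837, 82.244, 85.339),
)

_CGGA_ROWS = (
    (15, 4, 79.371, 78.669, 74.477, 74.476, 77.278),
    (14, 4, 79.371, 78.669, 74.477, 74.476, 77.278),
    (13, 4, 79.371, 78.669, 74.477, 74.476, 77.278),
    (12, 5, 80.412, 79.014, 75.178, 75.886, 76.225),
    (11, 5, 80.412, 79.014, 75.178, 75.886, 76.225),
    (10, 8, 80.073, 79.716, 76.219, 73.799, 76.231),
    (9, 8, 80.073, 79.716, 76.219, 73.799, 76.231),
    (8, 10, 79.722, 76.921, 75.517, 75.535, 74.840),
    (7, 10, 79.722, 76.921, 75.517, 75.535, 74.840),
    (6, 11, 76.219, 77.623, 75.535, 72.396, 74.834),
    (5, 11, 76.219, 77.623, 75.535, 72.396, 74.834),
    (4, 13, 76.915, 76.921, 75.173, 73.799, 73.781),
    (3, 14, 76.915, 77.272, 74.822, 75.892, 73.073),
    (2, 16, 76.915, 77.272, 75.523, 72.752, 72.371),
    (1, 16, 76.915, 77.272, 75.523, 72.752, 72.371),
)


def _build(rows) -> SweepTable:
    return SweepTable(
        rows=tuple(
            SweepRow(
                k=k,
                n_features=n,
                acc_by_model=dict(zip(MODEL_ORDER, accs)),
            )
            for k, n, *accs in rows
        ),
        models=MODEL_ORDER,
    )


def tcga_sweep() -> SweepTable:
    """The published 15-row TCGA sweep grid (23 features total)."""
    return _build(_TCGA_ROWS)


def cgga_sweep() -> SweepTable:
    """The published 15-row CGGA sweep grid (22 features total)."""
    return _build(_CGGA_ROWS)
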
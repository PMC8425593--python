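"""Tissue-enriched target selection from a gene × tissue expression matrix.

A transcript is a useful liquid-biopsy marker for an organ only if it is
essentially private to that organ. Candidates are screened from a bulk
expression matrix (TPM-like units, e.g. a Human Protein Atlas consensus
table): a gene is *tissue-enriched* for the target tissue when its
expression there exceeds the highest expression in any other tissue by more
than a fold threshold (default 4×, strict), and it must also clear an
absolute expression floor so that rare-but-exclusive transcripts with no
hope of detection in plasma are not carried forward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def select_enriched(matrix: pd.DataFrame, tissue: str,
                    fold_threshold: float = 4.0,
                    expression_floor: float = 10.0) -> pd.DataFrame:
    """Select tissue-enriched genes.

    Parameters
    ----------
    matrix
        Genes (index) × tissues (columns), nonnegative expression values.
    tissue
        Target tissue; must be a column of ``matrix``.
    fold_threshold
        A gene passes when ``expression[tissue] > fold_threshold · max(other
        tissues)`` (strict). Genes expressed in the target tissue only get an
        infinite fold change.
    expression_floor
        Minimum absolute expression in the target tissue (inclusive).

    Returns
    -------
    DataFrame indexed by gene with columns ``target_expression,
    max_other_expression, fold_change, passes_floor``, containing only the
    selected genes, ordered by descending fold change.
    """
    if tissue not in matrix.columns:
        raise KeyError(f"tissue {tissue!r} not in matrix")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if matrix.shape[1] < 2:
        raise ValueError("matrix needs at least 2 tissues")
    if (matrix.values < 0).any():
        raise ValueError("expression values must be nonnegative")

    target = matrix[tissue].astype(float)
    max_other = matrix.drop(columns=[tissue]).astype(float).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(max_other > 0, target / max_other,
                        np.where(target > 0, np.inf, np.nan))
    enriched = target > fold_threshold * max_other
    floor_ok = target >= expression_floor
    out = pd.DataFrame(
        {
            "target_expression": target,
            "max_other_expression": max_other,
            "fold_change": fold,
            "passes_floor": floor_ok,
        },
        index=matrix.index,
    )
    out = out[enriched & floor_ok]
    return out.sort_values("fold_change", ascending=False, kind="stable")
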
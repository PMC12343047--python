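"""Internal-control evaluation of spillover-driven false positives.

Cell-type-specific markers (CD4, CD20, aSMA, ...) are expected only in
their owning cell type. When such a marker surfaces as a proximity
association inside a *different* cell type, the association is almost
certainly an artefact of lateral spillover, so these relationships serve
as labelled false positives, while cell-state marker relationships count
as (potential) true positives. Walking the relationship list in order of
increasing p-value and accumulating both labels yields a partial ROC
curve; the number of cell-state relationships accrued when the false
positives first reach a cutoff (default 100) summarises how well a model
variant keeps artefacts out of its top ranks.

A cell-type marker tested within its own owner type is legitimately
expressed there and is excluded from false-positive counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_data import MarkerClassification

DEFAULT_FP_CUTOFF = 100

LABEL_TP = "tp"
LABEL_FP = "fp"
LABEL_OWN_TYPE = "own_type"


@dataclass
class PartialROC:
    """Significance-ranked cumulative TP/FP curve with its cutoff summary."""

    curve: pd.DataFrame  # ranked relationships with cum_tp / cum_fp
    fp_cutoff: int
    tp_at_fp_cutoff: float  # NaN when the cutoff is never reached

    @property
    def total_tp(self) -> int:
        return int(self.curve["cum_tp"].iloc[-1]) if len(self.curve) else 0

    @property
    def total_fp(self) -> int:
        return int(self.curve["cum_fp"].iloc[-1]) if len(self.curve) else 0


def label_relationships(
    results: pd.DataFrame, classification: MarkerClassification
) -> pd.DataFrame:
    """Attach TP/FP labels to a relationship result table.

    Cell-state markers label ``tp``; cell-type-specific markers label
    ``fp`` except within their own owner type, which labels ``own_type``
    and is excluded from FP counting. Every marker in the results must be
    classified.
    """
    unclassified = sorted(set(results["marker"]) - set(classification.roles))
    if unclassified:
        raise ValueError(f"markers missing from classification: {unclassified}")
    labels = []
    for _, row in results.iterrows():
        role = classification.roles[row["marker"]]
        if role == "cell_state":
            labels.append(LABEL_TP)
        elif row["cell_type_A"] in classification.owner_types.get(row["marker"], ()):
            labels.append(LABEL_OWN_TYPE)
        else:
            labels.append(LABEL_FP)
    out = results.copy()
    out["label"] = labels
    return out


def partial_roc(
    labelled: pd.DataFrame, fp_cutoff: int = DEFAULT_FP_CUTOFF
) -> PartialROC:
    """Cumulative TP/FP curve over the significance-ranked relationship list.

    Relationships sort by ascending p-value; ties break by |t| descending
    and then lexicographically by (A, B, marker), so the curve is
    deterministic. Own-type rows and untested rows (p = NA) are dropped.
    """
    df = labelled.loc[
        labelled["label"].isin([LABEL_TP, LABEL_FP]) & labelled["p_value"].notna()
    ].copy()
    df["_abs_t"] = -df["t_stat"].abs()
    df = df.sort_values(
        ["p_value", "_abs_t", "cell_type_A", "cell_type_B", "marker"],
        kind="mergesort",
    ).drop(columns="_abs_t")
    df["cum_tp"] = (df["label"] == LABEL_TP).cumsum()
    df["cum_fp"] = (df["label"] == LABEL_FP).cumsum()
    hit = df.index[df["cum_fp"] == fp_cutoff]
    if len(hit):
        tp_at = float(df.loc[hit[0], "cum_tp"])
    else:
        warnings.warn(
            f"only {int(df['cum_fp'].iloc[-1]) if len(df) else 0} false positives "
            f"available; cutoff {fp_cutoff} never reached",
            stacklevel=2,
        )
        tp_at = np.nan
    return PartialROC(curve=df.reset_index(drop=True), fp_cutoff=fp_cutoff,
                      tp_at_fp_cutoff=tp_at)
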
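"""Multiplicative-model scoring of double-perturbation viability.

Implements the genetic-interaction determination used for cell-line
validation: relative proliferation of each condition against a control,
a multiplicative null for the double perturbation (predicted = product of
the two singles), the proliferative defect

    defect = 1 - observed / predicted,

and an SL call when the defect reaches 15% or more (boundary inclusive).
The defect is oriented so that aggravating interactions (observed below the
multiplicative prediction) are positive; the reversed orientation is
available via ``orientation="predicted_over_observed"`` for comparison.
Nuclei counts and colony-formation counts share the same code path.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedValueError

__all__ = [
    "relative_proliferation",
    "predicted_double",
    "proliferative_defect",
    "call_sl",
    "score_experiment",
    "DEFAULT_SL_THRESHOLD",
]

DEFAULT_SL_THRESHOLD = 0.15
CONTROL = "control"


def _aggregate(values: np.ndarray, agg: str) -> float:
    if agg == "mean":
        return float(np.mean(values))
    if agg == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregation {agg!r}")


def relative_proliferation(records: pd.DataFrame, condition: str,
                           control: str = CONTROL, agg: str = "mean") -> float:
    """Mean (or median) count of a condition relative to the control."""
    cond = records.loc[records["condition"] == condition, "count"]
    ctrl = records.loc[records["condition"] == control, "count"]
    if cond.empty:
        raise UndefinedValueError(f"no replicates for condition {condition!r}")
    if ctrl.empty:
        raise UndefinedValueError(f"no replicates for control {control!r}")
    ctrl_value = _aggregate(ctrl.to_numpy(dtype=float), agg)
    if ctrl_value == 0:
        raise UndefinedValueError("control aggregate is zero")
    return _aggregate(cond.to_numpy(dtype=float), agg) / ctrl_value


def predicted_double(prolif_a: float, prolif_b: float) -> float:
    """Multiplicative-null prediction for a double perturbation."""
    if prolif_a < 0 or prolif_b < 0:
        raise DomainError("proliferation values must be non-negative")
    return prolif_a * prolif_b


def proliferative_defect(observed: float, predicted: float,
                         orientation: str = "observed_over_predicted") -> float:
    """Deviation of observed double-perturbation growth from the null.

    Default orientation 1 - observed/predicted: 0 under an exact
    multiplicative null, positive when observed growth falls short of the
    prediction (aggravating / SL direction), negative when it exceeds it
    (alleviating).
    """
    if orientation == "observed_over_predicted":
        if predicted <= 0:
            raise UndefinedValueError("defect undefined for predicted <= 0")
        return 1.0 - observed / predicted
    if orientation == "predicted_over_observed":
        if observed <= 0:
            raise UndefinedValueError("defect undefined for observed <= 0")
        return 1.0 - predicted / observed
    raise ValueError(f"unknown orientation {orientation!r}")


def call_sl(defect: float, threshold: float = DEFAULT_SL_THRESHOLD) -> bool:
    """SL when the proliferative defect is ``threshold`` (15%) or greater."""
    return defect >= threshold


def _condition_means(records: pd.DataFrame, agg: str) -> dict[str, float]:
    grouped = records.groupby("condition")["count"]
    if agg == "mean":
        series = grouped.mean()
    elif agg == "median":
        series = grouped.median()
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    return series.to_dict()


def score_experiment(records: pd.DataFrame,
                     pairs: Iterable[Sequence[str]],
                     threshold: float = DEFAULT_SL_THRESHOLD,
                     agg: str = "mean",
                     orientation: str = "observed_over_predicted",
                     ) -> pd.DataFrame:
    """Score a set of gene pairs from a proliferation-count table.

    ``records`` must contain a ``control`` condition, ``single:<gene>``
    conditions for each gene and ``double:<geneA>+<geneB>`` conditions for
    each pair (either gene order accepted). A pair with a missing condition
    produces an error row (NaN scores, message in the ``error`` column)
    without aborting the remaining pairs. Rows are ordered by the canonical
    (geneA, geneB) pair.
    """
    means = _condition_means(records, agg)
    if CONTROL not in means:
        raise UndefinedValueError("no control condition in records")
    ctrl = means[CONTROL]
    if ctrl == 0:
        raise UndefinedValueError("control aggregate is zero")

    rows = []
    canon_pairs = sorted({tuple(sorted((a, b))) for a, b in pairs})
    for gene_a, gene_b in canon_pairs:
        row: dict[str, object] = {"geneA": gene_a, "geneB": gene_b,
                                  "prolif_A": np.nan, "prolif_B": np.nan,
                                  "observed_AB": np.nan, "predicted_AB": np.nan,
                                  "defect": np.nan, "is_SL": False, "error": ""}
        try:
            missing = [c for c in (f"single:{gene_a}", f"single:{gene_b}")
                       if c not in means]
            double = f"double:{gene_a}+{gene_b}"
            if double not in means:
                alt = f"double:{gene_b}+{gene_a}"
                if alt in means:
                    double = alt
                else:
                    missing.append(double)
            if missing:
                raise UndefinedValueError(f"missing conditions: {missing}")
            pa = means[f"single:{gene_a}"] / ctrl
            pb = means[f"single:{gene_b}"] / ctrl
            observed = means[double] / ctrl
            predicted = predicted_double(pa, pb)
            defect = proliferative_defect(observed, predicted, orientation)
            row.update(prolif_A=pa, prolif_B=pb, observed_AB=observed,
                       predicted_AB=predicted, defect=defect,
                       is_SL=call_sl(defect, threshold))
        except (UndefinedValueError, DomainError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=["geneA", "geneB", "prolif_A", "prolif_B",
                                       "observed_AB", "predicted_AB", "defect",
                                       "is_SL", "error"])
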
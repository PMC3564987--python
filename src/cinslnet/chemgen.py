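"""Chemical-genetic sensitivity scoring and CIN-enrichment statistics.

Turns replicated colony-size measurements (strain x chemical, with matched
no-chemical controls) into per-gene relative growth and boolean sensitivity
calls, then summarises sensitivity lists against the CIN gene set: the
enrichment quotient (fraction of CIN genes in a sensitivity list divided by
the fraction of CIN genes in the genome), multi-chemical coverage ("how many
CIN genes are sensitive to at least one chemical"), and the full overlap
table across chemicals.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedValueError

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_growth",
    "call_sensitive",
    "enrichment_quotient",
    "coverage_at_least_one",
    "Coverage",
    "overlap_table",
]

# consistency factor making the MAD estimate the normal sd
_MAD_SCALE = 1.4826


def normalize_growth(measurements: pd.DataFrame) -> pd.DataFrame:
    """Median-based relative growth per strain x chemical.

    Each colony size is first divided by its plate-wide median (a plate being
    one chemical x control-status arm across the whole array) to remove
    plate-level growth effects; relative growth is then the median normalized
    chemical size over the median normalized control size for the strain.
    Medians are used throughout because pinned-colony data contain outliers
    from pinning failures.

    Strains lacking a control (or with zero control median) are excluded and
    logged. Returns columns gene, chemical, relative_growth.
    """
    df = measurements.copy()
    plate_median = df.groupby(["chemical", "is_control"])["colony_size"].transform("median")
    df["norm_size"] = df["colony_size"] / plate_median

    med = (df.groupby(["strain", "chemical", "is_control"])["norm_size"]
             .median().unstack("is_control"))
    rows = []
    for (strain, chemical), vals in med.iterrows():
        chem_med = vals.get(False, np.nan)
        ctrl_med = vals.get(True, np.nan)
        if np.isnan(chem_med):
            continue  # no chemical measurement for this strain
        if np.isnan(ctrl_med) or ctrl_med == 0:
            logger.warning("excluding %s/%s: missing or zero control", strain, chemical)
            continue
        rows.append((strain, chemical, chem_med / ctrl_med))
    return pd.DataFrame(rows, columns=["gene", "chemical", "relative_growth"])


def call_sensitive(relative_growth: pd.DataFrame,
                   growth_threshold: float = 0.5,
                   z_threshold: float = 2.0) -> pd.DataFrame:
    """Call chemical sensitivity from relative growth.

    A gene is sensitive to a chemical when its relative growth is at most
    ``growth_threshold`` AND its robust z-score (median/MAD across the whole
    array for that chemical) is at most ``-z_threshold``. The two conditions
    mirror a stringent cut-off: an absolute growth defect that is also an
    outlier relative to the array. When the array MAD is zero (noise-free
    data), any value below the median is treated as an infinitely negative
    z-score.

    Returns columns gene, chemical, relative_growth, score (robust z),
    sensitive.
    """
    if relative_growth.empty:
        return pd.DataFrame(columns=["gene", "chemical", "relative_growth",
                                     "score", "sensitive"])
    out = []
    for chemical, grp in relative_growth.groupby("chemical", sort=True):
        rg = grp["relative_growth"].to_numpy(dtype=float)
        med = np.median(rg)
        mad = np.median(np.abs(rg - med))
        if mad > 0:
            z = (rg - med) / (_MAD_SCALE * mad)
        else:
            z = np.where(rg == med, 0.0, np.where(rg < med, -np.inf, np.inf))
        sub = grp[["gene", "chemical", "relative_growth"]].copy()
        sub["score"] = z
        sub["sensitive"] = (rg <= growth_threshold) & (z <= -z_threshold)
        out.append(sub)
    return (pd.concat(out, ignore_index=True)
              .sort_values(["chemical", "gene"], kind="mergesort")
              .reset_index(drop=True))


def enrichment_quotient(sensitive_genes: Iterable[str],
                        cin_genes: Iterable[str],
                        genome: Iterable[str]) -> float:
    """Fold-enrichment of CIN genes in a sensitivity list.

    Quotient of the percentage of CIN genes in the list and the percentage of
    CIN genes in the entire genome:
    (|sensitive ∩ CIN| / |sensitive|) / (|CIN| / |genome|).
    """
    sensitive = set(sensitive_genes)
    cin = set(cin_genes)
    universe = set(genome)
    if not sensitive:
        raise UndefinedValueError("enrichment undefined for an empty sensitivity list")
    if not cin:
        raise UndefinedValueError("enrichment undefined for an empty CIN set")
    if not sensitive <= universe or not cin <= universe:
        raise ValueError("sensitive and CIN sets must be subsets of the genome")
    frac_list = len(sensitive & cin) / len(sensitive)
    frac_genome = len(cin) / len(universe)
    return frac_list / frac_genome


@dataclass(frozen=True)
class Coverage:
    """Count and percentage of target genes hit by at least one chemical."""

    count: int
    total: int
    percentage: float  # full precision

    @property
    def percentage_display(self) -> int:
        """Percentage rounded to the nearest integer, for reporting."""
        return int(np.floor(self.percentage + 0.5))


def coverage_at_least_one(sensitivity_lists: Mapping[str, Iterable[str]],
                          target_genes: Iterable[str],
                          chemicals: Sequence[str] | None = None) -> Coverage:
    """How many target genes are sensitive to at least one chosen chemical.

    ``chemicals`` selects a subset of the lists (default: all). The count is
    |target ∩ union(chosen lists)|; the percentage is 100*count/total at full
    precision (see :attr:`Coverage.percentage_display` for the rounded form).
    """
    target = set(target_genes)
    if not target:
        raise UndefinedValueError("coverage undefined for an empty target set")
    chosen = list(sensitivity_lists) if chemicals is None else list(chemicals)
    union: set[str] = set()
    for chem in chosen:
        union |= set(sensitivity_lists.get(chem, ()))
    count = len(target & union)
    return Coverage(count=count, total=len(target),
                    percentage=100.0 * count / len(target))


def overlap_table(sensitivity_lists: Mapping[str, Iterable[str]],
                  target_genes: Iterable[str],
                  ) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Per-gene membership matrix and per-combination overlap counts.

    Returns (membership, counts): ``membership`` is a boolean matrix indexed
    by target gene with one column per chemical; ``counts`` maps every
    combination of chemicals (as a sorted tuple, including the empty tuple
    for genes in no list) to the number of target genes with exactly that
    membership pattern. The counts over non-empty combinations sum to
    |target ∩ union of lists|.
    """
    target = sorted(set(target_genes))
    chems = list(sensitivity_lists)
    sets = {c: set(sensitivity_lists[c]) for c in chems}
    membership = pd.DataFrame(
        {c: [g in sets[c] for g in target] for c in chems},
        index=pd.Index(target, name="gene"), dtype=bool)

    counts: dict[tuple[str, ...], int] = {}
    for k in range(len(chems) + 1):
        for combo in itertools.combinations(sorted(chems), k):
            counts[combo] = 0
    for _, row in membership.iterrows():
        combo = tuple(sorted(c for c in chems if row[c]))
        counts[combo] += 1
    return membership, counts
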
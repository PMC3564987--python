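"""Surrogate synthetic-lethality prediction through physical-complex partners.

A highly connected but hard-to-drug hub gene (the motivating case is the
replication-fork scaffold Ctf4) shares genetic interactions with the members
of the protein complexes it anchors. This module propagates a hub's SL
profile — the cancer-gene orthologs it negatively interacts with — one hop
onto its physical-interaction partners, yielding (partner, cancer gene)
surrogate SL predictions. Propagation is deliberately limited to direct
partners; multi-hop closure would inflate predictions uncontrollably.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .errors import UndefinedValueError
from .network import CINNetwork

logger = logging.getLogger(__name__)

__all__ = ["hub_sl_profile", "predict_partner_sl", "evaluate_predictions"]


def hub_sl_profile(network: CINNetwork, hub: str,
                   cancer_set: Iterable[str]) -> frozenset[str]:
    """Cancer-ortholog CIN queries adjacent to a hub in the network.

    A hub absent from the network yields an empty profile (logged), since a
    gene with no retained interactions simply predicts nothing.
    """
    cancer = frozenset(cancer_set)
    neighbors = network.queries_of(hub)
    if not neighbors:
        logger.warning("hub %s has no interactions in the network", hub)
    return neighbors & cancer


def predict_partner_sl(profiles: Mapping[str, Iterable[str]],
                       complexes: pd.DataFrame) -> pd.DataFrame:
    """Propagate hub SL profiles onto their complex partners.

    For every (hub, partner) membership and every cancer gene in the hub's
    profile, emit a (partner, cancer_gene) prediction. Duplicates arising
    from several hubs supporting the same prediction are merged, accumulating
    the supporting hub set (hubs, not complexes, are deduplicated — one hub
    may anchor several complexes). Output columns: partner, cancer_gene,
    supporting_hubs (sorted tuple), support; sorted by descending support,
    then partner, then cancer gene.
    """
    missing = set(complexes["hub"]) - set(profiles)
    if missing:
        raise ValueError(f"no SL profile provided for hubs: {sorted(missing)}")
    support: dict[tuple[str, str], set[str]] = {}
    memberships = complexes[["hub", "partner"]].drop_duplicates()
    for row in memberships.itertuples(index=False):
        for cancer_gene in profiles[row.hub]:
            support.setdefault((row.partner, cancer_gene), set()).add(row.hub)
    rows = [
        {"partner": partner, "cancer_gene": cancer_gene,
         "supporting_hubs": tuple(sorted(hubs)), "support": len(hubs)}
        for (partner, cancer_gene), hubs in support.items()
    ]
    out = pd.DataFrame(rows, columns=["partner", "cancer_gene",
                                      "supporting_hubs", "support"])
    return (out.sort_values(["support", "partner", "cancer_gene"],
                            ascending=[False, True, True], kind="mergesort")
               .reset_index(drop=True))


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def evaluate_predictions(predictions: pd.DataFrame,
                         truth_sl_pairs: Iterable[tuple[str, str]],
                         partner_universe: Iterable[str] | None = None,
                         cancer_universe: Iterable[str] | None = None,
                         ) -> tuple[float, float]:
    """Precision and recall of predictions against planted SL pairs.

    Pairs are order-insensitive. When partner/cancer universes are given,
    recall is computed against the truth pairs restricted to that
    (partner, cancer) universe — pairs outside the space the predictor could
    possibly emit are not held against it.
    """
    pred = {_canon(r.partner, r.cancer_gene)
            for r in predictions.itertuples(index=False)}
    truth = {_canon(a, b) for a, b in truth_sl_pairs}
    if partner_universe is not None or cancer_universe is not None:
        partners = set(partner_universe or ())
        cancers = set(cancer_universe or ())
        truth = {p for p in truth
                 if (p[0] in partners and p[1] in cancers)
                 or (p[1] in partners and p[0] in cancers)}
    if not pred:
        raise UndefinedValueError("precision undefined: no predictions")
    if not truth:
        raise UndefinedValueError("recall undefined: no truth pairs in universe")
    tp = len(pred & truth)
    return tp / len(pred), tp / len(truth)
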
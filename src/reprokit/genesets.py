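"""Pluripotency-/fibroblast-associated gene sets from presence calls.

A probe is pluripotency-associated when it is present (group-level:
detected in all replicates) in every pluripotent line but absent in both
donor fibroblast replicates; fibroblast-associated is the mirror image.
The module also tracks the activation of those sets over the time course
and offers annotation-term subsetting plus a classic one-sided
hypergeometric term-enrichment test with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .expression import DetectionCalls, adjust_bh

logger = logging.getLogger(__name__)

SURFACE_TERMS = ("integral to membrane", "cell surface")


@dataclass
class GeneSetPartition:
    """Disjoint pluripotency- and fibroblast-associated probe sets."""

    pluripotency_associated: pd.Index
    fibroblast_associated: pd.Index

    def __post_init__(self) -> None:
        if len(self.pluripotency_associated.intersection(self.fibroblast_associated)):
            raise ValueError("associated sets must be disjoint")


def derive_associated_sets(calls: DetectionCalls, donor: str = "donor",
                           pluripotent_groups=("iPS", "ES"),
                           require_all: bool = True) -> GeneSetPartition:
    """Derive the two state-associated probe sets from detection calls.

    ``require_all=True`` (default) demands presence in *all* pluripotent
    samples; ``False`` relaxes to group-level presence in at least one
    pluripotent group.  Both sets are restricted to the analysis set.
    """
    groups = list(pluripotent_groups)
    for g in (donor, *groups):
        if not (calls.groups == g).any():
            raise KeyError(f"missing required group {g!r}")
    pluri_present = pd.concat([calls.group_present(g) for g in groups], axis=1)
    pluri_all = pluri_present.all(axis=1) if require_all else pluri_present.any(axis=1)
    donor_cols = list(calls.groups.index[calls.groups == donor])
    donor_any = calls.present[donor_cols].any(axis=1)
    donor_all = calls.present[donor_cols].all(axis=1)
    pluri_any = pd.concat(
        [calls.present[list(calls.groups.index[calls.groups == g])].any(axis=1)
         for g in groups], axis=1).any(axis=1)

    analysis = calls.analysis_set
    pluri_set = calls.present.index[pluri_all & ~donor_any].intersection(analysis)
    fibro_set = calls.present.index[donor_all & ~pluri_any].intersection(analysis)
    return GeneSetPartition(pluri_set, fibro_set)


def activation_timecourse(calls: DetectionCalls,
                          partition: GeneSetPartition) -> pd.DataFrame:
    """Fraction of each associated set group-level present, per group.

    Returns a groups x {pluripotency, fibroblast} DataFrame; empty sets
    yield NaN columns with a warning.
    """
    if not len(partition.pluripotency_associated) and not len(partition.fibroblast_associated):
        logger.warning("both associated sets are empty; nothing to track")
        return pd.DataFrame(columns=["pluripotency", "fibroblast"])
    groups = list(dict.fromkeys(calls.groups))
    rows = {}
    for g in groups:
        present = calls.group_present(g)
        row = {}
        for name, ids in (("pluripotency", partition.pluripotency_associated),
                          ("fibroblast", partition.fibroblast_associated)):
            row[name] = present.loc[ids].mean() if len(ids) else float("nan")
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def annotate_surface(partition: GeneSetPartition, annotation: dict[str, list[str]],
                     terms=SURFACE_TERMS) -> pd.Index:
    """Pluripotency-associated probes annotated with any of ``terms``.

    Unknown term names are skipped with a warning; the result is always
    a subset of the pluripotency-associated set.
    """
    members: set[str] = set()
    for term in terms:
        if term not in annotation:
            logger.warning("annotation term %r not found", term)
            continue
        members.update(annotation[term])
    return partition.pluripotency_associated.intersection(sorted(members))


def enrich_hypergeometric(query, universe, annotation: dict[str, list[str]]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each annotation term.

    For each term with members K in the universe (size N) and a query of
    size n overlapping k of them, p = P(X >= k) with
    X ~ Hypergeom(N, K, n); BH adjustment across the tested terms.
    """
    query = pd.Index(query).unique()
    universe = pd.Index(universe).unique()
    if not query.isin(universe).all():
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, members in annotation.items():
        term_set = universe.intersection(pd.Index(members).unique())
        K = len(term_set)
        k = len(query.intersection(term_set))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                      "query_size", "universe_size", "p"])
    out["p_adj"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    return out.set_index("term")
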
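"""Pathway overrepresentation analysis (ORA).

Tests whether a signature's top-weighted metabolites overlap a pathway's
member set more than expected by chance, with the exact upper-tail
hypergeometric probability (one-sided Fisher test) and Benjamini-Hochberg
adjustment across pathways.  The universe is restricted to metabolites
that were actually measured: the signature's metabolite identifiers
intersected with the library universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyHitsError, ValidationError
from .matrix import SignatureSet
from .signatures import top_metabolites
from .simulate import PathwayLibrary

__all__ = ["ora_test", "enrich_signature"]


def ora_test(hits: set, pathway: set, universe: set) -> float:
    """Exact upper-tail hypergeometric overrepresentation probability.

    ``P(overlap >= observed)`` when ``|hits|`` metabolites are drawn
    without replacement from a universe of which ``|pathway|`` are pathway
    members.
    """
    hits, pathway, universe = set(hits), set(pathway), set(universe)
    stray = sorted(hits - universe)
    if stray:
        raise ValidationError(f"hit(s) outside the universe: {stray}")
    stray = sorted(pathway - universe)
    if stray:
        raise ValidationError(f"pathway member(s) outside the universe: {stray}")
    overlap = len(hits & pathway)
    # survival function is P(X > k), so shift by one for P(X >= overlap)
    return float(hypergeom.sf(overlap - 1, len(universe), len(pathway), len(hits)))


def enrich_signature(
    signatures: SignatureSet,
    signature: str,
    library: PathwayLibrary,
    q: float | None = None,
    floor: float | None = None,
    exclude_signature: str | None = None,
) -> pd.DataFrame:
    """Overrepresentation table for one signature against a library.

    Hits are the signature's top metabolites (see
    :func:`~metasig.signatures.top_metabolites`; cumulative mass q=0.5 by
    default) intersected with the universe.  With ``exclude_signature``,
    metabolites that are also top metabolites of that other signature are
    removed first (signature-exclusive mode).  Rows are sorted by ascending
    raw p, ties by pathway name; ``adjusted_p`` is Benjamini-Hochberg
    across all tested pathways.
    """
    hits = set(top_metabolites(signatures, signature, q=q, floor=floor).index)
    if exclude_signature is not None:
        other = set(
            top_metabolites(signatures, exclude_signature, q=q, floor=floor).index
        )
        hits -= other
    measured = set(
        signatures.weights.index
        if isinstance(signatures, SignatureSet)
        else signatures.index
    )
    universe = measured & library.universe
    hits &= universe
    if not hits:
        raise EmptyHitsError(
            f"no top metabolite of signature {signature!r} resolves against "
            "the pathway universe"
        )
    rows = []
    for name in sorted(library.pathways):
        members = library.pathways[name] & universe
        if not members:
            continue
        overlap = len(hits & members)
        rows.append(
            {
                "pathway": name,
                "overlap": overlap,
                "pathway_size": len(members),
                "hits_size": len(hits),
                "universe_size": len(universe),
                "p_value": ora_test(hits, members, universe),
            }
        )
    if not rows:
        raise EmptyHitsError("no pathway has members in the measured universe")
    table = pd.DataFrame(rows)
    table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values(
        ["p_value", "pathway"], kind="stable", ignore_index=True
    )
    return table
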
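"""Master regulator analysis: hypergeometric over-representation of a
signature gene set within each regulon.

The universe is the candidate target-gene space used for network inference;
a regulon's p-value is the upper tail P(X >= observed) of a hypergeometric
draw of ``regulon_size`` genes from the universe containing ``total_hits``
signature genes.  Regulons at or below the size threshold are dropped before
testing, and BH correction runs over exactly the retained regulons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .netinf import TRN
from .stats import bh_adjust

__all__ = ["hypergeom_upper", "run_mra"]


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def upper_tail_probs(universe: int, hits: int, draws: int) -> np.ndarray:
    """P(X >= k) for every k in 0..draws, X ~ Hypergeometric(universe, hits,
    draws), accumulated in log space from the top of the support."""
    kmax = min(draws, hits)
    kmin = max(0, draws - (universe - hits))
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        _log_comb(hits, k)
        + _log_comb(universe - hits, draws - k)
        - _log_comb(universe, draws)
    )
    rev_tail = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    out = np.zeros(draws + 1)
    out[: kmin + 1] = 1.0
    out[kmin: kmax + 1] = np.minimum(1.0, np.exp(rev_tail))
    out[0] = 1.0
    return out

_COLUMNS = [
    "regulator", "universe_size", "regulon_size", "total_hits",
    "expected_hits", "observed_hits", "p", "adj_p",
]


def hypergeom_upper(universe: int, hits: int, draws: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeometric(universe, hits, draws).

    Summed in log space over the upper tail for numerical stability.
    """
    universe, hits, draws, observed = int(universe), int(hits), int(draws), int(observed)
    if not (0 <= hits <= universe):
        raise ValueError("need 0 <= hits <= universe")
    if not (0 <= draws <= universe):
        raise ValueError("need 0 <= draws <= universe")
    if not (0 <= observed <= draws):
        raise ValueError("need 0 <= observed <= draws")
    if observed == 0:
        return 1.0
    return float(upper_tail_probs(universe, hits, draws)[observed])


def run_mra(
    trn: TRN,
    signature: set[str],
    universe: set[str],
    min_regulon: int = 15,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``signature`` in each sufficiently large
    regulon.

    Only regulons with strictly more than ``min_regulon`` genes (counted
    within the universe) are tested; BH runs across the retained rows; the
    result is sorted by p ascending.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    signature = set(map(str, signature))
    universe = set(map(str, universe))
    n_universe = len(universe)
    total_hits = len(signature & universe)

    rows = []
    for reg, regulon in sorted(trn.regulons.items()):
        regulon_u = regulon & universe
        size = len(regulon_u)
        if size <= min_regulon:
            continue
        observed = len(regulon_u & signature)
        expected = size * total_hits / n_universe
        p = hypergeom_upper(n_universe, total_hits, size, observed)
        rows.append((reg, n_universe, size, total_hits, expected, observed, p))

    out = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    if out.empty:
        out["adj_p"] = pd.Series(dtype=float)
        return out.reindex(columns=_COLUMNS)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out.reindex(columns=_COLUMNS)
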
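"""Cross-graph integration of driver-term results into a consensus ranking.

Within each graph, all retained pairs are ranked (ascending, average ranks
for ties, so the best value gets the largest rank) on -log10 weighted FDR
and on ΔFDR; ranks of candidate (non-top) drivers are scaled by 0.33 and
every rank is multiplied by the pair's term coverage in that graph.  The
scaled ranks are summed per (hub, term) across graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

OUTPUT_COLUMNS = [
    "hub",
    "term",
    "term_domain",
    "n_graphs",
    "sum_rank_fdr",
    "sum_rank_delta",
    "sum_delta_fdr",
    "ever_top",
]


@dataclass(frozen=True)
class IntegrationParams:
    nontop_scale: float = 0.33
    fdr_max: float = 0.05
    coverage_min: float = 0.25
    rank_normalize: bool = False

    def __post_init__(self):
        if not (0.0 < self.nontop_scale <= 1.0):
            raise ValueError("nontop_scale must lie in (0, 1]")


def integrate_drivers(
    per_graph_records: Mapping[str, pd.DataFrame],
    params: IntegrationParams = IntegrationParams(),
    term_domains: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Combine filtered driver records from several graphs.

    ``per_graph_records`` maps graph/domain label -> frame with columns
    hub, term, fdr_weighted, delta_fdr, coverage, is_top_for_term (the
    output of the driver filter).  Output is sorted by sum_rank_fdr
    descending with sum_rank_delta as tie-break.
    """
    pieces = []
    for graph_label in sorted(per_graph_records):
        df = per_graph_records[graph_label]
        if df is None or not len(df):
            continue
        df = df.copy()
        neglog_fdr = -np.log10(df["fdr_weighted"].to_numpy())
        r_fdr = rankdata(neglog_fdr, method="average")
        r_delta = rankdata(df["delta_fdr"].to_numpy(), method="average")
        if params.rank_normalize:
            r_fdr = r_fdr / len(df)
            r_delta = r_delta / len(df)
        nontop = ~df["is_top_for_term"].to_numpy(dtype=bool)
        r_fdr = np.where(nontop, r_fdr * params.nontop_scale, r_fdr)
        r_delta = np.where(nontop, r_delta * params.nontop_scale, r_delta)
        cov = df["coverage"].to_numpy(dtype=float)
        pieces.append(
            pd.DataFrame(
                {
                    "hub": df["hub"].to_numpy(),
                    "term": df["term"].to_numpy(),
                    "rank_fdr": r_fdr * cov,
                    "rank_delta": r_delta * cov,
                    "delta_fdr": df["delta_fdr"].to_numpy(),
                    "is_top": df["is_top_for_term"].to_numpy(dtype=bool),
                }
            )
        )
    if not pieces:
        return pd.DataFrame(columns=OUTPUT_COLUMNS)
    stacked = pd.concat(pieces, ignore_index=True)
    agg = (
        stacked.groupby(["hub", "term"], as_index=False)
        .agg(
            n_graphs=("rank_fdr", "size"),
            sum_rank_fdr=("rank_fdr", "sum"),
            sum_rank_delta=("rank_delta", "sum"),
            sum_delta_fdr=("delta_fdr", "sum"),
            ever_top=("is_top", "any"),
        )
    )
    if term_domains:
        agg["term_domain"] = agg["term"].map(lambda t: ";".join(sorted(term_domains.get(t, frozenset()))))
    else:
        agg["term_domain"] = ""
    agg = agg.sort_values(
        ["sum_rank_fdr", "sum_rank_delta", "hub", "term"],
        ascending=[False, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return agg[OUTPUT_COLUMNS]
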
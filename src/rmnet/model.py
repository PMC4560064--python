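"""Model/Results interface for rule-based microbial network inference.

`RMNModel` is built from data (an SRP matrix, a raw count table, or a
DataFrame) and `fit()` scans, filters and ranks all OTU-triplets, returning
an `RMNResults` object carrying the scored triplets, the assembled signed
network, and a `summary()` table — the statsmodels idiom applied to network
inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocess, triplet_scan
from .preprocess import AbundanceTable, SRPMatrix
from .triplet_scan import RegulatoryNetwork, ThresholdConfig

__all__ = ["RMNModel", "RMNResults"]


class RMNModel:
    """Nonlinear regulatory OTU-triplet model over an SRP matrix.

    Parameters
    ----------
    srp : SRPMatrix or ndarray
        Standardized relative proportions (rows OTUs, columns time points).
    otu_ids : sequence of str, optional
        Row labels; defaults to the SRPMatrix's ids or ``OTU0..``.
    """

    def __init__(self, srp, otu_ids=None):
        if isinstance(srp, SRPMatrix):
            self.srp = srp
        else:
            values = np.asarray(srp, dtype=float)
            ids = list(otu_ids) if otu_ids is not None else [
                f"OTU{i}" for i in range(values.shape[0])
            ]
            self.srp = SRPMatrix(
                values=values, otu_ids=ids, time_labels=list(range(values.shape[1]))
            )
        self.otu_ids = list(self.srp.otu_ids)

    @classmethod
    def from_counts(cls, table: AbundanceTable, **preprocess_params) -> "RMNModel":
        """Build from a raw count table via the full preprocessing chain."""
        return cls(preprocess.counts_to_srp(table, **preprocess_params))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, preprocessed: bool = False, **params) -> "RMNModel":
        """Build from a DataFrame (index = OTU ids, columns = time points).

        With ``preprocessed=True`` the values are taken as an SRP matrix;
        otherwise they are treated as counts and preprocessed.
        """
        if preprocessed:
            return cls(df.to_numpy(dtype=float), otu_ids=list(df.index))
        table = AbundanceTable(
            counts=np.nan_to_num(df.to_numpy(dtype=float)),
            otu_ids=list(df.index),
            time_labels=list(df.columns),
            missing_mask=df.isna().to_numpy(),
        )
        return cls.from_counts(table, **params)

    def fit(
        self,
        ld_max: float = 3.8,
        d_max: float = 0.8,
        top_k: int | None = None,
        conflict: str = "error",
    ) -> "RMNResults":
        """Scan all triplets, filter by (ld_max, d_max), rank, build the network."""
        cfg = ThresholdConfig(ld_max=ld_max, d_max=d_max, top_k=top_k)
        triplets = triplet_scan.scan_triplets(self.srp.values)
        ranked_all = triplet_scan.rank_triplets(triplets)
        retained = triplet_scan.rank_triplets(triplet_scan.filter_triplets(triplets, cfg))
        network = triplet_scan.build_network(
            retained, top_k=cfg.top_k, otu_ids=self.otu_ids, conflict=conflict
        )
        return RMNResults(self, cfg, ranked_all, retained, network)


class RMNResults:
    """Fit results: scored triplets, retained subset, and the signed network."""

    def __init__(self, model, config, all_triplets, retained, network: RegulatoryNetwork):
        self.model = model
        self.config = config
        self.all_triplets = all_triplets
        self.retained = retained
        self.network = network

    def triplet_frame(self, retained_only: bool = True) -> pd.DataFrame:
        """Triplets as a DataFrame with columns m, c, t, L, Ld, D, I, rank."""
        trips = self.retained if retained_only else self.all_triplets
        ids = self.model.otu_ids
        rows = [
            {
                "m": ids[tr.m],
                "c": ids[tr.c],
                "t": ids[tr.t],
                "L": tr.scores.L,
                "Ld": tr.scores.L_d,
                "D": tr.scores.D,
                "I": tr.scores.I,
                "rank": rank,
            }
            for rank, tr in enumerate(trips, start=1)
        ]
        return pd.DataFrame(rows, columns=["m", "c", "t", "L", "Ld", "D", "I", "rank"])

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": src,
                "target": tgt,
                "sign": sign,
                "n_supporting_triplets": len(support),
                "best_I": self.network.best_integrated_score((src, tgt, sign)),
            }
            for (src, tgt, sign), support in sorted(self.network.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "sign", "n_supporting_triplets", "best_I"]
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        n_otus, k = self.model.srp.values.shape
        lines = [
            "Rule-based microbial network inference",
            "=" * 54,
            f"OTUs: {n_otus}    time points: {k}",
            f"triplets scanned: {len(self.all_triplets)}",
            f"thresholds: 0 <= Ld <= {self.config.ld_max}, D < {self.config.d_max}"
            + (f", top_k={self.config.top_k}" if self.config.top_k else ""),
            f"triplets retained: {len(self.retained)}",
            f"network: {len(self.network.nodes)} nodes, {len(self.network)} signed edges",
            "-" * 54,
        ]
        head = self.triplet_frame().head(10)
        if len(head):
            lines.append("top retained triplets (cooperator m, competitor c, target t):")
            lines.append(
                head.to_string(
                    index=False,
                    formatters={c: "{:.4f}".format for c in ("L", "Ld", "D", "I")},
                )
            )
        else:
            lines.append("no triplets passed the thresholds")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<RMNResults: {len(self.retained)}/{len(self.all_triplets)} triplets, "
            f"{len(self.network)} edges>"
        )
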
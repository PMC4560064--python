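"""Table and network readers/writers plus the end-to-end inference runner.

Input OTU tables are TSV: first column OTU id, optional second column
``taxonomy``, remaining columns time-ordered counts; an empty cell or "NA"
marks a missing measurement.  Networks are written as TSV edge lists and as
SIF (``source  coop|comp  target``); outputs are deterministically ordered
and reruns with an identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import RMNModel
from .preprocess import AbundanceTable, SRPMatrix
from .triplet_scan import COMPETITIVE, COOPERATIVE, RegulatoryNetwork

__all__ = [
    "RunConfig",
    "read_otu_table",
    "write_srp",
    "write_network",
    "read_network",
    "run_infer",
]

logger = logging.getLogger(__name__)

_SIF_SIGN = {COOPERATIVE: "coop", COMPETITIVE: "comp"}
_SIGN_FROM_SIF = {v: k for k, v in _SIF_SIGN.items()}


@dataclasses.dataclass
class RunConfig:
    """Everything one inference run needs; hashed into the output manifest."""

    input_path: str
    output_dir: str
    min_fraction: float = 0.5
    max_prop: float = 0.1
    cv_max: float = 3.4
    otu_fraction: float = 0.6
    n_components: int = 5
    ld_max: float = 3.8
    d_max: float = 0.8
    top_k: int | None = None
    conflict: str = "error"
    seed: int | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_otu_table(path) -> AbundanceTable:
    """Parse a TSV OTU count table (see module docstring for the layout)."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=["", "NA"]
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an OTU id column plus count columns")
    otu_ids = df.iloc[:, 0].tolist()
    dupes = sorted({x for x in otu_ids if otu_ids.count(x) > 1})
    if dupes:
        lines = [i + 2 for i, x in enumerate(otu_ids) if x in dupes]
        raise ValueError(f"{path}: duplicate OTU id(s) {dupes} (lines {lines})")
    taxonomy = None
    data = df.iloc[:, 1:]
    if data.columns[0].lower() == "taxonomy":
        taxonomy = data.iloc[:, 0].tolist()
        data = data.iloc[:, 1:]
    missing = data.isna().to_numpy()
    try:
        counts = data.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric count value ({exc})") from exc
    counts = np.where(missing, 0.0, counts)
    if np.any(counts < 0):
        bad = int(np.argwhere(counts < 0)[0, 0]) + 2
        raise ValueError(f"{path}: negative count near line {bad}")
    return AbundanceTable(
        counts=counts,
        otu_ids=otu_ids,
        time_labels=list(data.columns),
        taxonomy=taxonomy,
        missing_mask=missing,
    )


def write_srp(srp: SRPMatrix, path) -> None:
    """SRP matrix as TSV with the same row/column labelling as the input."""
    pd.DataFrame(srp.values, index=srp.otu_ids, columns=srp.time_labels).to_csv(
        path, sep="\t", index_label="otu_id", float_format="%.10g"
    )


def write_network(net: RegulatoryNetwork, path, format: str = "tsv") -> None:
    """Write a network as a TSV edge list or as SIF, deterministically ordered."""
    path = Path(path)
    keys = sorted(net.edges)
    if format == "tsv":
        lines = ["source\ttarget\tsign\tn_supporting_triplets\tbest_I"]
        for key in keys:
            src, tgt, sign = key
            best = net.best_integrated_score(key)
            best_s = "" if np.isnan(best) else f"{best:.10g}"
            lines.append(f"{src}\t{tgt}\t{sign}\t{len(net.edges[key])}\t{best_s}")
    elif format == "sif":
        lines = [f"{src}\t{_SIF_SIGN[sign]}\t{tgt}" for src, tgt, sign in keys]
    else:
        raise ValueError("format must be 'tsv' or 'sif'")
    path.write_text("\n".join(lines) + "\n")


def read_network(path, format: str = "tsv") -> RegulatoryNetwork:
    """Read a network written by :func:`write_network` (round-trip partner)."""
    net = RegulatoryNetwork()
    lines = Path(path).read_text().splitlines()
    if format == "tsv":
        for line in lines[1:]:
            src, tgt, sign = line.split("\t")[:3]
            net.add_edge(src, tgt, sign)
    elif format == "sif":
        for line in lines:
            src, rel, tgt = line.split("\t")
            net.add_edge(src, tgt, _SIGN_FROM_SIF[rel])
    else:
        raise ValueError("format must be 'tsv' or 'sif'")
    return net


def run_infer(cfg: RunConfig):
    """Full pipeline: read -> preprocess -> fit -> write triplets/network/manifest.

    Returns the fitted :class:`~rmnet.model.RMNResults`.  Every output file
    name is fixed and the manifest records all parameters plus the config
    hash, so identical configurations rerun byte-identically.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        table = read_otu_table(cfg.input_path)
        stage = "preprocess"
        model = RMNModel.from_counts(
            table,
            min_fraction=cfg.min_fraction,
            max_prop=cfg.max_prop,
            cv_max=cfg.cv_max,
            otu_fraction=cfg.otu_fraction,
            n_components=cfg.n_components,
        )
        stage = "scan"
        res = model.fit(
            ld_max=cfg.ld_max, d_max=cfg.d_max, top_k=cfg.top_k, conflict=cfg.conflict
        )
    except Exception as exc:
        raise RuntimeError(f"inference failed at stage '{stage}': {exc}") from exc

    write_srp(model.srp, outdir / "srp.tsv")
    res.triplet_frame(retained_only=False).to_csv(
        outdir / "triplets_all.tsv", sep="\t", index=False, float_format="%.10g"
    )
    res.triplet_frame(retained_only=True).to_csv(
        outdir / "triplets_retained.tsv", sep="\t", index=False, float_format="%.10g"
    )
    write_network(res.network, outdir / "network.tsv", "tsv")
    write_network(res.network, outdir / "network.sif", "sif")
    manifest = dict(dataclasses.asdict(cfg), config_hash=cfg.config_hash())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("inference complete: %d retained triplets, %d edges",
                len(res.retained), len(res.network))
    return res
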
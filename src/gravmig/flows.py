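"""Flow conversion, cross-scale aggregation/disaggregation and validation metrics.

Fitted proportions become person flows via the origin population and the
census sampling fraction; flows aggregate exactly across nested partitions;
coarse proportions disaggregate uniformly to sub-unit pairs (the
broad-scale baseline); and estimated and observed flow matrices are
compared by Pearson correlation, by default on the log10(x+1) scale used
for plotting flows that span orders of magnitude.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def _as_partition(partition) -> pd.Series:
    part = pd.Series(dict(partition) if isinstance(partition, dict) else partition)
    if part.isna().any():
        raise ValueError("partition contains missing group ids")
    return part


def flows_from_proportions(v: pd.DataFrame, units: pd.DataFrame,
                           sampling_fraction: float = 1.0) -> pd.DataFrame:
    """Convert proportions to expected person flows:
    flow_ij = sampling_fraction * N_i * v_ij."""
    if not 0 < sampling_fraction <= 1:
        raise ValueError("sampling fraction must lie in (0, 1]")
    units = units.set_index("id")
    N = units.loc[v.index, "population"].to_numpy(dtype=float)
    out = v.to_numpy(dtype=float) * (sampling_fraction * N)[:, None]
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=v.index, columns=v.columns)


def aggregate_flows(f: pd.DataFrame, partition) -> pd.DataFrame:
    """Sum member-pair flows onto group pairs.

    Within-group flows land on the group diagonal, reported but meant to be
    excluded from between-group comparisons.
    """
    part = _as_partition(partition)
    unmapped = [u for u in f.index if u not in part.index]
    if unmapped:
        raise ValueError(f"units missing from partition: {unmapped[:5]}")
    groups = part.loc[f.index].to_numpy()
    labels = list(pd.unique(groups))
    gpos = {g: k for k, g in enumerate(labels)}
    B = np.zeros((len(f.index), len(labels)))
    B[np.arange(len(f.index)), [gpos[g] for g in groups]] = 1.0
    out = B.T @ f.to_numpy(dtype=float) @ B
    return pd.DataFrame(out, index=labels, columns=labels)


def disaggregate_uniform(P_coarse: pd.DataFrame, partition) -> pd.DataFrame:
    """Broadcast each coarse-pair proportion unchanged to every sub-unit pair.

    Every ordered sub-unit pair (u in I, w in J) with I != J receives P_IJ;
    pairs inside a common coarse unit get 0 (undefined at the coarse level).
    """
    part = _as_partition(partition)
    subunits = list(part.index)
    missing = set(part.unique()) - set(P_coarse.index)
    if missing:
        raise ValueError(f"coarse proportions missing for groups: {sorted(missing)[:5]}")
    gi = P_coarse.index.get_indexer(part.loc[subunits])
    out = P_coarse.to_numpy(dtype=float)[np.ix_(gi, gi)]
    same_group = gi[:, None] == gi[None, :]
    out[same_group] = 0.0
    return pd.DataFrame(out, index=subunits, columns=subunits)


def offdiag_pairs(mat: pd.DataFrame) -> np.ndarray:
    """Off-diagonal entries in a fixed ordered-pair order."""
    a = mat.to_numpy(dtype=float)
    return a[~np.eye(len(a), dtype=bool)]


def compare_flows(estimated: pd.DataFrame, observed: pd.DataFrame,
                  scale: str = "log10p1") -> tuple[float, np.ndarray]:
    """Pearson correlation and residuals between flow matrices.

    Ordered pairs only (self-pairs excluded); ``scale`` is ``"raw"`` or
    ``"log10p1"`` (log10(x + 1), tolerant of zero flows).  Residuals are
    estimated minus observed on the chosen scale.
    """
    if list(estimated.index) != list(observed.index) or \
            list(estimated.columns) != list(observed.columns):
        observed = observed.reindex(index=estimated.index, columns=estimated.columns)
        if observed.isna().any().any():
            raise ValueError("flow matrices cover different pair sets")
    e = offdiag_pairs(estimated)
    o = offdiag_pairs(observed)
    if e.size < 3:
        raise ValueError("need at least three pairs")
    if scale == "log10p1":
        e, o = np.log10(e + 1.0), np.log10(o + 1.0)
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'log10p1'")
    if e.std() == 0 or o.std() == 0:
        raise ValueError("zero variance in a flow vector")
    r = float(stats.pearsonr(e, o).statistic)
    return r, e - o


def read_flow_matrix(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, comment="#", dtype={"origin_id": str, "dest_id": str})
    mat = long.pivot(index="origin_id", columns="dest_id", values="flow")
    return mat.fillna(0.0).rename_axis(index=None, columns=None)


def write_flow_matrix(mat: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    long = mat.rename_axis(index="origin_id", columns="dest_id").stack().rename("flow")
    long = long.reset_index()
    long = long[long["origin_id"] != long["dest_id"]]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        long.to_csv(fh, index=False)


def read_partition(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, comment="#", dtype=str)
    return df.set_index("unit_id")["group_id"]


def write_partition(partition, path: str | Path, header: str | None = None) -> None:
    part = _as_partition(partition)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        part.rename_axis("unit_id").rename("group_id").to_csv(fh)
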